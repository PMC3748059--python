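import numpy as np
import pytest

from trapdyn.data_io import AlignedDataset, EntomoSeries, MeteoSeries, week_range
from trapdyn.glm import LagTerm, ModelSpec
from trapdyn.synthetic import simulate_dataset

#: best-fit study coefficients used as generator defaults
TABLE2 = {
    "ar": 0.8344,
    "temperature": -0.0714,
    "humidity": -0.0257,
    "interaction": 0.0016,
    "theta": 19.11,
}


@pytest.fixture(scope="session")
def dataset90() -> AlignedDataset:
    """One default 90-week synthetic dataset."""
    return simulate_dataset(90, seed=20240901)


@pytest.fixture(scope="session")
def dataset109() -> AlignedDataset:
    """90 fitted weeks plus a 19-week hold-out."""
    return simulate_dataset(109, seed=20240902)


@pytest.fixture
def best_model_spec() -> ModelSpec:
    tt, ht = LagTerm("tmin", 4), LagTerm("hmin", 2)
    return ModelSpec(terms=(tt, ht), interactions=((tt, ht),), include_ar=True)


def make_entomo(counts, positive=None, observed=None, start="2009-W11"):
    counts = np.asarray(counts, dtype=int)
    n = len(counts)
    if positive is None:
        positive = np.maximum(counts // 2, 1)
    if observed is None:
        observed = np.full(n, max(int(np.max(positive)) + 5, 10))
    return EntomoSeries(
        weeks=tuple(week_range(start, n)),
        total_captures=counts,
        positive_traps=np.asarray(positive, dtype=int),
        observed_traps=np.asarray(observed, dtype=int),
    )


def make_meteo(n, start="2009-W11", seed=0):
    rng = np.random.default_rng(seed)
    tavg = 25 + 2 * rng.standard_normal(n)
    havg = 75 + 3 * rng.standard_normal(n)
    return MeteoSeries(
        weeks=tuple(week_range(start, n)),
        precip=np.abs(rng.standard_normal(n)) * 30,
        tmin=tavg - 5, tavg=tavg, tmax=tavg + 5,
        hmin=havg - 15, havg=havg, hmax=np.clip(havg + 10, None, 100),
        wind=np.abs(rng.standard_normal(n)) + 2,
    )
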