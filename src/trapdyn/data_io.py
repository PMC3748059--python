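"""Weekly entomological and meteorological series: reading, validation,
alignment, lagging and summaries.

The entomological table records, per epidemiological week, the total number
of adult female *Aedes aegypti* captured in sticky traps, the number of
traps that captured at least one mosquito ("positive" traps) and the number
of traps actually inspected.  Two denominators coexist deliberately: the
positive-trap count is the denominator of the per-trap abundance (the
autoregressive signal), while the observed-trap count enters the model
offset that corrects for uneven sampling effort.

Week labels use the ISO-style form ``"YYYY-Www"`` (e.g. ``"2009-W11"``) and
a valid series is strictly consecutive, with year rollover handled; gaps are
an error rather than silently imputed.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "EntomoSeries",
    "MeteoSeries",
    "AlignedDataset",
    "parse_week",
    "week_range",
    "next_week",
    "read_entomo",
    "write_entomo",
    "read_meteo",
    "write_meteo",
    "capture_rate",
    "lagged",
    "align",
    "summarize",
]

ENTOMO_COLUMNS = ("week", "total_captures", "positive_traps", "observed_traps")
METEO_COLUMNS = (
    "week",
    "precip_mm",
    "tmin_c",
    "tavg_c",
    "tmax_c",
    "hmin_pct",
    "havg_pct",
    "hmax_pct",
    "wind_ms",
)

#: meteorological variable short names used throughout the package
METEO_VARIABLES = ("precip", "tmin", "tavg", "tmax", "hmin", "havg", "hmax", "wind")

_COLUMN_TO_VAR = {
    "precip_mm": "precip",
    "tmin_c": "tmin",
    "tavg_c": "tavg",
    "tmax_c": "tmax",
    "hmin_pct": "hmin",
    "havg_pct": "havg",
    "hmax_pct": "hmax",
    "wind_ms": "wind",
}
_VAR_TO_COLUMN = {v: k for k, v in _COLUMN_TO_VAR.items()}

_WEEK_RE = re.compile(r"^(\d{4})-W(\d{2})$")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant.

    The message names the offending row (week label) and field.
    """


# ---------------------------------------------------------------------------
# Epidemiological week axis
# ---------------------------------------------------------------------------

def parse_week(label: str) -> tuple[int, int]:
    """Parse ``"YYYY-Www"`` into ``(year, week)``, validating the week number."""
    m = _WEEK_RE.match(str(label))
    if not m:
        raise ValidationError(f"malformed week label {label!r}; expected 'YYYY-Www'")
    year, week = int(m.group(1)), int(m.group(2))
    try:
        _dt.date.fromisocalendar(year, week, 1)
    except ValueError as exc:
        raise ValidationError(f"invalid week label {label!r}: {exc}") from None
    return year, week


def _format_week(year: int, week: int) -> str:
    return f"{year:04d}-W{week:02d}"


def next_week(label: str) -> str:
    """The label of the following epidemiological week (year rollover handled)."""
    year, week = parse_week(label)
    d = _dt.date.fromisocalendar(year, week, 1) + _dt.timedelta(weeks=1)
    iso = d.isocalendar()
    return _format_week(iso[0], iso[1])


def week_range(start: str, n: int) -> list[str]:
    """``n`` consecutive week labels starting at ``start``."""
    out = [start]
    for _ in range(n - 1):
        out.append(next_week(out[-1]))
    return out


def _check_consecutive(weeks: Sequence[str], what: str) -> None:
    seen = set()
    for w in weeks:
        parse_week(w)
        if w in seen:
            raise ValidationError(f"{what}: duplicated week {w}")
        seen.add(w)
    for prev, cur in zip(weeks, weeks[1:]):
        if next_week(prev) != cur:
            raise ValidationError(
                f"{what}: weeks not consecutive at {prev} -> {cur}"
            )


# ---------------------------------------------------------------------------
# Series containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EntomoSeries:
    """Weekly trap-capture series.

    Attributes
    ----------
    weeks : tuple of str
        Consecutive epidemiological week labels ``"YYYY-Www"``.
    total_captures : ndarray of int
        Total female captures per week (the count response y_t).
    positive_traps : ndarray of int
        Traps with at least one capture; denominator of the per-trap
        abundance a_t = y_t / positive_traps_t.
    observed_traps : ndarray of int
        Traps inspected that week (N_t); ln N_t is the model offset.
    """

    weeks: tuple[str, ...]
    total_captures: np.ndarray
    positive_traps: np.ndarray
    observed_traps: np.ndarray

    MIN_LENGTH = 6  # max covariate lag (4) + AR lag (1) + one usable row

    def __post_init__(self) -> None:
        weeks = tuple(str(w) for w in self.weeks)
        object.__setattr__(self, "weeks", weeks)
        for name in ("total_captures", "positive_traps", "observed_traps"):
            arr = np.asarray(getattr(self, name))
            if arr.ndim != 1 or len(arr) != len(weeks):
                raise ValidationError(f"{name}: length mismatch with weeks")
            if not np.issubdtype(arr.dtype, np.integer):
                fl = np.asarray(arr, dtype=float)
                if np.any(fl != np.floor(fl)) or np.any(~np.isfinite(fl)):
                    raise ValidationError(f"{name}: non-integer values present")
                arr = fl.astype(int)
            object.__setattr__(self, name, arr)
        if len(weeks) < self.MIN_LENGTH:
            raise ValidationError(
                f"series too short: {len(weeks)} weeks < minimum {self.MIN_LENGTH}"
            )
        _check_consecutive(weeks, "entomological series")
        for i, w in enumerate(weeks):
            if self.total_captures[i] < 0:
                raise ValidationError(f"week {w}: total_captures < 0")
            if self.positive_traps[i] < 1:
                raise ValidationError(f"week {w}: positive_traps < 1")
            if self.positive_traps[i] > self.observed_traps[i]:
                raise ValidationError(
                    f"week {w}: positive_traps ({self.positive_traps[i]}) "
                    f"> observed_traps ({self.observed_traps[i]})"
                )

    def __len__(self) -> int:
        return len(self.weeks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "week": list(self.weeks),
                "total_captures": self.total_captures,
                "positive_traps": self.positive_traps,
                "observed_traps": self.observed_traps,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EntomoSeries":
        missing = [c for c in ENTOMO_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"entomological table: missing columns {missing}")
        return cls(
            weeks=tuple(df["week"].astype(str)),
            total_captures=df["total_captures"].to_numpy(),
            positive_traps=df["positive_traps"].to_numpy(),
            observed_traps=df["observed_traps"].to_numpy(),
        )


@dataclass(frozen=True)
class MeteoSeries:
    """Weekly meteorological series (eight covariates).

    Units: precipitation mm/week, temperatures °C, relative humidities %
    (in [0, 100]), wind m/s.  Per-week orderings tmin ≤ tavg ≤ tmax and
    hmin ≤ havg ≤ hmax are invariants.
    """

    weeks: tuple[str, ...]
    precip: np.ndarray
    tmin: np.ndarray
    tavg: np.ndarray
    tmax: np.ndarray
    hmin: np.ndarray
    havg: np.ndarray
    hmax: np.ndarray
    wind: np.ndarray

    def __post_init__(self) -> None:
        weeks = tuple(str(w) for w in self.weeks)
        object.__setattr__(self, "weeks", weeks)
        for name in METEO_VARIABLES:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1 or len(arr) != len(weeks):
                raise ValidationError(f"{name}: length mismatch with weeks")
            if np.any(~np.isfinite(arr)):
                raise ValidationError(f"{name}: non-finite values present")
            object.__setattr__(self, name, arr)
        _check_consecutive(weeks, "meteorological series")
        def _bad(mask: np.ndarray, msg: str) -> None:
            if np.any(mask):
                w = weeks[int(np.argmax(mask))]
                raise ValidationError(f"week {w}: {msg}")
        _bad(self.precip < 0, "precip < 0")
        _bad(self.wind < 0, "wind < 0")
        _bad(self.tmin > self.tavg, "tmin > tavg")
        _bad(self.tavg > self.tmax, "tavg > tmax")
        _bad(self.hmin > self.havg, "hmin > havg")
        _bad(self.havg > self.hmax, "havg > hmax")
        _bad((self.hmin < 0) | (self.hmax > 100), "humidity outside [0, 100]")

    def __len__(self) -> int:
        return len(self.weeks)

    def variable(self, name: str) -> np.ndarray:
        """A covariate by its short name (``tmin``, ``havg``, ...)."""
        if name not in METEO_VARIABLES:
            raise KeyError(f"unknown meteorological variable {name!r}")
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, object] = {"week": list(self.weeks)}
        for col, var in _COLUMN_TO_VAR.items():
            data[col] = getattr(self, var)
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MeteoSeries":
        missing = [c for c in METEO_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"meteorological table: missing columns {missing}")
        kwargs = {var: df[col].to_numpy(dtype=float) for col, var in _COLUMN_TO_VAR.items()}
        return cls(weeks=tuple(df["week"].astype(str)), **kwargs)

    def tail(self, n: int) -> "MeteoSeries":
        """The last ``n`` weeks as a new series."""
        kwargs = {var: getattr(self, var)[-n:] for var in METEO_VARIABLES}
        return MeteoSeries(weeks=self.weeks[-n:], **kwargs)


@dataclass(frozen=True)
class AlignedDataset:
    """An entomological and a meteorological series joined on the week axis."""

    entomo: EntomoSeries
    meteo: MeteoSeries
    abundance: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.entomo.weeks != self.meteo.weeks:
            raise ValidationError(
                "alignment failed: entomological and meteorological week axes differ"
            )
        object.__setattr__(self, "abundance", capture_rate(self.entomo))

    def __len__(self) -> int:
        return len(self.entomo)

    @property
    def weeks(self) -> tuple[str, ...]:
        return self.entomo.weeks

    def subset(self, start: int, stop: int) -> "AlignedDataset":
        """Rows ``start:stop`` as a new aligned dataset."""
        e = self.entomo
        ent = EntomoSeries(
            weeks=e.weeks[start:stop],
            total_captures=e.total_captures[start:stop],
            positive_traps=e.positive_traps[start:stop],
            observed_traps=e.observed_traps[start:stop],
        )
        m = self.meteo
        met = MeteoSeries(
            weeks=m.weeks[start:stop],
            **{v: getattr(m, v)[start:stop] for v in METEO_VARIABLES},
        )
        return AlignedDataset(ent, met)


def align(entomo: EntomoSeries, meteo: MeteoSeries) -> AlignedDataset:
    """Join the two series on their common consecutive week range.

    Raises :class:`ValidationError` if the intersection is empty or would
    leave a gap (both inputs are consecutive, so the intersection — if any —
    is a single contiguous block).
    """
    common = [w for w in entomo.weeks if w in set(meteo.weeks)]
    if not common:
        raise ValidationError("alignment failed: no common weeks")
    ei = entomo.weeks.index(common[0])
    mi = meteo.weeks.index(common[0])
    n = len(common)
    ent = EntomoSeries(
        weeks=entomo.weeks[ei : ei + n],
        total_captures=entomo.total_captures[ei : ei + n],
        positive_traps=entomo.positive_traps[ei : ei + n],
        observed_traps=entomo.observed_traps[ei : ei + n],
    )
    met = MeteoSeries(
        weeks=meteo.weeks[mi : mi + n],
        **{v: getattr(meteo, v)[mi : mi + n] for v in METEO_VARIABLES},
    )
    return AlignedDataset(ent, met)


# ---------------------------------------------------------------------------
# File I/O (comma-delimited text)
# ---------------------------------------------------------------------------

def read_entomo(path) -> EntomoSeries:
    """Read and validate a weekly capture table (CSV with a header row)."""
    return EntomoSeries.from_frame(pd.read_csv(path))


def write_entomo(series: EntomoSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_meteo(path) -> MeteoSeries:
    """Read and validate a weekly meteorological table (CSV with a header row)."""
    return MeteoSeries.from_frame(pd.read_csv(path))


def write_meteo(series: MeteoSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def capture_rate(entomo: EntomoSeries) -> np.ndarray:
    """Per-trap abundance a_t: weekly captures divided by positive traps."""
    return entomo.total_captures / entomo.positive_traps


def lagged(series: Iterable[float], lag: int) -> np.ndarray:
    """Shift a weekly series by ``lag`` weeks (0–4).

    Element ``t`` of the output is element ``t - lag`` of the input; the
    first ``lag`` entries, for which no earlier value exists, are NaN so
    downstream design-matrix construction can drop them explicitly.
    """
    if not (0 <= int(lag) <= 4):
        raise ValueError(f"lag must be in 0..4, got {lag}")
    lag = int(lag)
    arr = np.asarray(list(series) if not isinstance(series, np.ndarray) else series,
                     dtype=float)
    if arr.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if len(arr) <= lag:
        raise ValueError(f"series of length {len(arr)} too short for lag {lag}")
    out = np.full_like(arr, np.nan)
    if lag == 0:
        out[:] = arr
    else:
        out[lag:] = arr[:-lag]
    return out


def summarize(dataset: AlignedDataset) -> dict:
    """Descriptive summary of counts, per-trap abundance and covariates.

    Means, min, max and sample variance per quantity, plus the number of
    zero-rain weeks.  Serializable as flat JSON.
    """
    def _stats(x: np.ndarray) -> dict:
        x = np.asarray(x, dtype=float)
        return {
            "mean": float(np.mean(x)),
            "min": float(np.min(x)),
            "max": float(np.max(x)),
            "variance": float(np.var(x, ddof=1)) if len(x) > 1 else 0.0,
        }

    out: dict[str, object] = {
        "n_weeks": len(dataset),
        "first_week": dataset.weeks[0],
        "last_week": dataset.weeks[-1],
        "total_captures_sum": int(dataset.entomo.total_captures.sum()),
        "captures": _stats(dataset.entomo.total_captures),
        "abundance_per_trap": _stats(dataset.abundance),
        "zero_rain_weeks": int(np.sum(dataset.meteo.precip == 0)),
    }
    for var in METEO_VARIABLES:
        out[var] = _stats(dataset.meteo.variable(var))
    return out


def write_summary(summary: Mapping, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
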