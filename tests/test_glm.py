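"""Negative-binomial fitting, screening, selection, diagnostics, forecasting."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from trapdyn.data_io import align
from trapdyn.glm import (
    DesignData,
    FitError,
    LagTerm,
    ModelSpec,
    acf_pacf,
    build_design,
    fit_model,
    fit_nb,
    forecast,
    nb_loglik,
    select_model,
    univariate_screen,
)
from trapdyn.synthetic import (
    SeasonalVarParams,
    ClimateGenParams,
    MosquitoGenParams,
    generate_climate,
    generate_counts,
    simulate_dataset,
)

from conftest import TABLE2, make_entomo, make_meteo


class TestModelSpec:
    def test_two_temperatures_rejected(self):
        with pytest.raises(ValueError, match="one temperature"):
            ModelSpec(terms=(LagTerm("tmin", 1), LagTerm("tmax", 0)))

    def test_interaction_requires_included_terms(self):
        t1, t2 = LagTerm("tmin", 1), LagTerm("hmin", 2)
        with pytest.raises(ValueError, match="interaction"):
            ModelSpec(terms=(t1,), interactions=((t1, t2),))

    def test_ar_lag_fixed(self):
        with pytest.raises(ValueError):
            LagTerm("ar", 2)


class TestBuildDesign:
    def test_row_counts_for_max_lag(self, dataset90, best_model_spec):
        d = build_design(dataset90, best_model_spec)
        assert len(d.y) == 86  # first 4 weeks dropped for the lag-4 term

    def test_ar_only_drops_single_row(self, dataset90):
        d = build_design(dataset90, ModelSpec(include_ar=True))
        assert len(d.y) == 89

    def test_interaction_column_is_product_of_lagged_columns(self, dataset90,
                                                             best_model_spec):
        d = build_design(dataset90, best_model_spec)
        t4 = dataset90.meteo.tmin[:-4]
        h2 = dataset90.meteo.hmin[2:-2]
        np.testing.assert_allclose(d.X["tmin_lag4:hmin_lag2"].to_numpy(),
                                   t4 * h2)

    def test_offset_is_log_observed_traps(self, dataset90, best_model_spec):
        d = build_design(dataset90, best_model_spec)
        np.testing.assert_allclose(
            d.offset, np.log(dataset90.entomo.observed_traps[4:]))

    def test_no_intercept_column(self, dataset90, best_model_spec):
        d = build_design(dataset90, best_model_spec)
        assert not any((d.X[c] == 1).all() for c in d.X.columns)


def _constant_covariate_design(n=300, N=50.0, mu_scale=1.4, theta=8.0, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.negative_binomial(theta, theta / (theta + N * mu_scale), n)
    X = pd.DataFrame({"one": np.ones(n)})
    spec = ModelSpec(terms=(), include_ar=False)
    return DesignData(X=X, y=y, offset=np.full(n, np.log(N)),
                      weeks=tuple(f"w{i}" for i in range(n)), spec=spec), y, N


class TestFitNB:
    def test_single_covariate_closed_form(self):
        # with one all-ones column and constant offset ln N, the MLE of the
        # coefficient is ln(mean(y)/N), independent of theta
        design, y, N = _constant_covariate_design()
        fit = fit_nb(design)
        assert fit.params["one"] == pytest.approx(np.log(y.mean() / N), abs=1e-5)

    def test_agrees_with_independent_optimizer(self, dataset90, best_model_spec):
        design = build_design(dataset90, best_model_spec)
        fit = fit_model(dataset90, best_model_spec)
        X = design.X.to_numpy()
        y = np.asarray(design.y, float)

        def neg(params):
            beta, log_theta = params[:-1], params[-1]
            return -nb_loglik(beta, np.exp(log_theta), X, y, design.offset)

        x0 = np.r_[fit.params.to_numpy() * 0.5, 0.0]
        res = optimize.minimize(neg, x0, method="Nelder-Mead",
                                options={"maxiter": 20000, "xatol": 1e-10,
                                         "fatol": 1e-10})
        assert res.fun == pytest.approx(-fit.loglik, rel=1e-6)
        np.testing.assert_allclose(res.x[:-1], fit.params.to_numpy(),
                                   rtol=1e-3, atol=1e-5)

    def test_aic_counts_theta(self, dataset90, best_model_spec):
        fit = fit_model(dataset90, best_model_spec)
        k = len(fit.params)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * (k + 1))

    def test_poisson_generated_data_gives_large_theta(self):
        rng = np.random.default_rng(3)
        n, N = 400, 60.0
        y = rng.poisson(N * 1.2, n)
        design = DesignData(X=pd.DataFrame({"one": np.ones(n)}), y=y,
                            offset=np.full(n, np.log(N)),
                            weeks=tuple(f"w{i}" for i in range(n)),
                            spec=ModelSpec(terms=(), include_ar=False))
        fit = fit_nb(design)
        assert fit.theta > 50  # effectively Poisson

    def test_rank_deficient_design_rejected(self, dataset90):
        tt, ht = LagTerm("tmin", 4), LagTerm("hmin", 2)
        spec = ModelSpec(terms=(tt, ht), include_ar=False)
        d = build_design(dataset90, spec)
        X = d.X.copy()
        X["dup"] = X["tmin_lag4"]
        with pytest.raises(FitError, match="rank"):
            fit_nb(DesignData(X=X, y=d.y, offset=d.offset, weeks=d.weeks,
                              spec=spec))

    def test_wald_interval_coverage_of_interaction(self, best_model_spec):
        # generate from the study coefficients and check ~95 % coverage
        rng = np.random.default_rng(99)
        hits = tries = 0
        for _ in range(60):
            d = simulate_dataset(90, seed=rng)
            try:
                f = fit_model(d, best_model_spec)
            except FitError:
                continue
            tries += 1
            est = f.params["tmin_lag4:hmin_lag2"]
            se = f.bse["tmin_lag4:hmin_lag2"]
            hits += abs(est - TABLE2["interaction"]) < 1.96 * se
        assert tries >= 55
        # binomial band around 0.95 for ~60 tries
        assert 0.85 <= hits / tries <= 1.0

    def test_nested_deviance_monotone(self, dataset90):
        tt, ht = LagTerm("tmin", 4), LagTerm("hmin", 2)
        drop = 4
        specs = [
            ModelSpec(terms=(), include_ar=True),
            ModelSpec(terms=(tt,), include_ar=True),
            ModelSpec(terms=(tt, ht), include_ar=True),
            ModelSpec(terms=(tt, ht), interactions=((tt, ht),), include_ar=True),
        ]
        devs = [fit_model(dataset90, s, drop_first=drop).deviance for s in specs]
        assert all(a >= b - 1e-6 for a, b in zip(devs, devs[1:]))


class TestScreening:
    def test_empty_when_nothing_significant(self):
        # null counts with per-trap mean one and inert climate
        rng = np.random.default_rng(11)
        n, N, theta = 90, 425, 19.11
        counts = rng.negative_binomial(theta, theta / (theta + N), n)
        e = make_entomo(counts, positive=np.maximum(counts // 2, 1),
                        observed=np.full(n, N))
        d = align(e, make_meteo(n, seed=12))
        table = univariate_screen(d, variables=("wind",), lags=(0,), alpha=1e-6)
        assert len(table) == 0

    # weekly climate with weak seasonality and white noise: adjacent lags
    # decorrelate enough for the screen to attribute the correct lag
    IDENTIFIABLE_CLIMATE = ClimateGenParams(
        tavg=SeasonalVarParams(24.8, 1.5, phi=0.0, sigma=2.0),
        temp_gap_sigma=1.5,
        havg=SeasonalVarParams(76.22, 3.0, phi=0.0, sigma=4.0),
        hum_gap_low_sigma=7.0,
    )

    def test_active_lag_outranks_inert_lags(self):
        # tmin at lag 4 drives the counts; lag 4 should win among tmin lags
        from trapdyn.glm import best_lag_per_variable
        rng = np.random.default_rng(21)
        wins = 0
        reps = 12
        p = MosquitoGenParams(beta_ar=0.0, beta_t=0.08, beta_h=0.0, beta_int=0.0)
        for _ in range(reps):
            m = generate_climate(self.IDENTIFIABLE_CLIMATE, 102, seed=rng)
            e = generate_counts(m, p, seed=rng)
            d = align(e, m.tail(90))
            tab = univariate_screen(d, variables=("tmin",), alpha=1.0)
            wins += best_lag_per_variable(tab).get("tmin") == 4
        assert wins >= reps * 0.9

    def test_ranked_ascending_by_p(self, dataset90):
        tab = univariate_screen(dataset90)
        p = tab["p_value"].to_numpy()
        assert np.all(np.diff(p) >= 0)


class TestSelection:
    def test_nine_candidates_and_consistent_ranking(self, dataset90):
        screened = univariate_screen(dataset90)
        sel = select_model(dataset90, screened)
        assert len(sel.ranking) == 9
        aics = sel.ranking["aic"].dropna().to_numpy()
        assert np.all(np.diff(aics) >= 0)
        assert sel.best.aic == pytest.approx(aics[0])

    def test_extra_useless_column_pays_aic_penalty(self):
        # adding a causally inert covariate raises AIC in expectation
        rng = np.random.default_rng(55)
        tt, ht = LagTerm("tmin", 4), LagTerm("hmin", 2)
        small_spec = ModelSpec(terms=(tt, ht), interactions=((tt, ht),),
                               include_ar=True)
        wide_spec = ModelSpec(terms=(tt, ht, LagTerm("wind", 0)),
                              interactions=((tt, ht),), include_ar=True)
        diffs = []
        for _ in range(10):
            d = simulate_dataset(90, seed=rng)
            try:
                small = fit_model(d, small_spec, drop_first=4)
                wide = fit_model(d, wide_spec, drop_first=4)
            except FitError:
                continue
            diffs.append(wide.aic - small.aic)
        assert len(diffs) >= 8
        assert np.mean(diffs) > 0

    def test_generating_pair_selected_in_majority(self):
        # clear main effects of tmin(4) and hmin(2) under low-autocorrelation
        # climate: screening + AIC selection should recover the generating
        # pair in most replicates
        rng = np.random.default_rng(31)
        mp = MosquitoGenParams(beta_ar=0.3, beta_t=0.06, beta_h=-0.03,
                               beta_int=0.0)
        picks = []
        for _ in range(12):
            d = simulate_dataset(
                90, climate_params=TestScreening.IDENTIFIABLE_CLIMATE,
                mosquito_params=mp, seed=rng)
            try:
                sel = select_model(d, univariate_screen(d))
            except FitError:
                continue
            name = sel.ranking.iloc[0]["model"]
            picks.append("tmin" in name and "hmin" in name)
        assert np.mean(picks) > 0.5


class TestAcfPacf:
    def test_white_noise_inside_bands(self):
        rng = np.random.default_rng(41)
        x = rng.standard_normal(400)
        out = acf_pacf(x, 20)
        frac_inside = np.mean(np.abs(out["acf"][1:]) < out["band"])
        assert frac_inside > 0.85

    def test_ar1_closed_form(self):
        rng = np.random.default_rng(42)
        phi, n = 0.8, 6000
        x = np.zeros(n)
        eps = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        out = acf_pacf(x, 6)
        np.testing.assert_allclose(out["acf"][1:4], [phi, phi**2, phi**3],
                                   atol=0.05)
        assert out["pacf"][1] == pytest.approx(phi, abs=0.05)
        assert np.all(np.abs(out["pacf"][2:]) < 0.06)

    def test_acf_zero_is_one_and_constant_rejected(self):
        out = acf_pacf(np.sin(np.arange(50.0)), 5)
        assert out["acf"][0] == 1.0
        with pytest.raises(ValueError, match="constant"):
            acf_pacf(np.ones(50), 5)


@pytest.fixture(scope="module")
def fitted_and_data(dataset109):
    tt, ht = LagTerm("tmin", 4), LagTerm("hmin", 2)
    spec = ModelSpec(terms=(tt, ht), interactions=((tt, ht),), include_ar=True)
    fit_window = dataset109.subset(0, 90)
    return fit_model(fit_window, spec), dataset109


class TestForecast:

    def test_spearman_sign_conventions(self):
        assert stats.spearmanr([1, 2, 3], [10, 20, 30]).statistic == 1.0
        assert stats.spearmanr([1, 2, 3], [30, 20, 10]).statistic == -1.0

    @pytest.mark.parametrize("mode", ["one-step", "iterated"])
    def test_modes_produce_positive_means_and_ordered_intervals(
            self, fitted_and_data, mode):
        fit, data = fitted_and_data
        fc = forecast(fit, data, horizon=19, mode=mode)
        assert len(fc.mean) == 19
        assert np.all(fc.mean > 0)
        assert np.all(fc.lower <= fc.upper)
        assert -1.0 <= fc.spearman <= 1.0

    def test_self_generated_holdout_scores_positive(self, fitted_and_data):
        # mirrors the out-of-fit rank-correlation check of the study design
        fit, data = fitted_and_data
        fc = forecast(fit, data, horizon=19, mode="one-step")
        assert fc.spearman > 0.2

    def test_horizon_beyond_data_rejected(self, fitted_and_data):
        fit, data = fitted_and_data
        with pytest.raises(ValueError, match="horizon"):
            forecast(fit, data, horizon=50)
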