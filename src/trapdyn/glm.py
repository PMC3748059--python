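"""Negative-binomial lagged-covariate modelling of weekly trap counts.

Model: counts y_t ~ NB(μ_t, θ) with variance μ_t + μ_t²/θ and

    ln μ_t = ln N_t + Σ_i β_i x_{i, t−ℓ_i} + β_ar a_{t−1} + Σ γ (x·x') terms

where N_t is the number of observed traps (offset with coefficient 1),
x are meteorological covariates lagged 0–4 weeks, a_t is the per-trap
abundance, and the intercept is deliberately excluded from the linear
predictor.  The workflow is: univariate lag screening at a fixed
significance level, then AIC selection over all temperature × humidity
pairs (each at its best screened lag) with the pairwise interaction and
the AR(1) term, residual ACF/PACF diagnostics, and out-of-fit forecasting
scored with Spearman rank correlation.

Fitting is by joint maximum likelihood over (β, θ) through
``statsmodels.discrete.NegativeBinomial`` (NB2); standard errors are Wald,
from the observed information at the maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.discrete.discrete_model import NegativeBinomial
from statsmodels.tsa.stattools import acf as _sm_acf, pacf as _sm_pacf

from .data_io import METEO_VARIABLES, AlignedDataset, lagged

__all__ = [
    "TEMPERATURE_VARIABLES",
    "HUMIDITY_VARIABLES",
    "LagTerm",
    "ModelSpec",
    "NBFit",
    "FitError",
    "DesignData",
    "build_design",
    "fit_nb",
    "fit_model",
    "nb_loglik",
    "univariate_screen",
    "select_model",
    "SelectionResult",
    "acf_pacf",
    "forecast",
    "ForecastResult",
]

TEMPERATURE_VARIABLES = ("tmin", "tavg", "tmax")
HUMIDITY_VARIABLES = ("hmin", "havg", "hmax")


class FitError(RuntimeError):
    """Raised when maximum-likelihood estimation fails (non-convergence,
    rank deficiency, separation/overflow)."""


@dataclass(frozen=True)
class LagTerm:
    """One lagged covariate: a meteorological variable at lag 0–4, or the
    autoregressive per-trap abundance term ``"ar"`` (lag fixed at 1)."""

    variable: str
    lag: int = 0

    def __post_init__(self) -> None:
        if self.variable == "ar":
            if self.lag != 1:
                raise ValueError("the AR term uses lag 1")
        elif self.variable not in METEO_VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")
        elif not (0 <= self.lag <= 4):
            raise ValueError(f"lag must be in 0..4, got {self.lag}")

    @property
    def name(self) -> str:
        return "ar1" if self.variable == "ar" else f"{self.variable}_lag{self.lag}"


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: lagged main effects, interaction pairs, AR flag.

    At most one temperature and one humidity main effect are allowed (to
    avoid multicollinearity between sister variables); interactions must be
    between included main effects.  The intercept is always excluded.
    """

    terms: tuple[LagTerm, ...] = ()
    interactions: tuple[tuple[LagTerm, LagTerm], ...] = ()
    include_ar: bool = True

    def __post_init__(self) -> None:
        terms = tuple(self.terms)
        inter = tuple(tuple(p) for p in self.interactions)
        object.__setattr__(self, "terms", terms)
        object.__setattr__(self, "interactions", inter)
        n_temp = sum(t.variable in TEMPERATURE_VARIABLES for t in terms)
        n_hum = sum(t.variable in HUMIDITY_VARIABLES for t in terms)
        if n_temp > 1 or n_hum > 1:
            raise ValueError(
                "at most one temperature and one humidity main effect allowed"
            )
        if len({t.name for t in terms}) != len(terms):
            raise ValueError("duplicated main-effect terms")
        for a, b in inter:
            if a not in terms or b not in terms:
                raise ValueError("interaction references a term not in the model")

    @property
    def max_lag(self) -> int:
        lags = [t.lag for t in self.terms if t.variable != "ar"]
        if self.include_ar:
            lags.append(1)
        return max(lags, default=0)

    def column_names(self) -> list[str]:
        names = ["ar1"] if self.include_ar else []
        names += [t.name for t in self.terms]
        names += [f"{a.name}:{b.name}" for a, b in self.interactions]
        return names


@dataclass(frozen=True)
class DesignData:
    """Design matrix, response and offset after dropping lag-incomplete rows."""

    X: pd.DataFrame
    y: np.ndarray
    offset: np.ndarray
    weeks: tuple[str, ...]
    spec: ModelSpec


def build_design(dataset: AlignedDataset, spec: ModelSpec,
                 drop_first: int | None = None) -> DesignData:
    """Assemble the no-intercept design matrix for ``spec``.

    Columns are the (already lagged) main effects, interaction columns as
    elementwise products of their main-effect columns, and the AR(1)
    per-trap abundance.  Rows whose lagged values are unavailable are
    dropped; ``drop_first`` forces a common number of leading rows to drop
    (used to align candidate models on identical data for AIC comparison).
    """
    n = len(dataset)
    cols: dict[str, np.ndarray] = {}
    if spec.include_ar:
        cols["ar1"] = lagged(dataset.abundance, 1)
    for term in spec.terms:
        if term.variable == "ar":
            continue
        cols[term.name] = lagged(dataset.meteo.variable(term.variable), term.lag)
    for a, b in spec.interactions:
        cols[f"{a.name}:{b.name}"] = cols[a.name] * cols[b.name]
    if not cols:
        raise ValueError("model spec has no columns")
    X = pd.DataFrame(cols, index=range(n))[spec.column_names()]
    first = spec.max_lag if drop_first is None else int(drop_first)
    if first < spec.max_lag:
        raise ValueError("drop_first smaller than the spec's maximum lag")
    keep = np.arange(first, n)
    X = X.iloc[keep]
    if X.isna().any().any():
        raise ValueError("NaN left in design after dropping lag rows")
    return DesignData(
        X=X,
        y=dataset.entomo.total_captures[keep].astype(int),
        offset=np.log(dataset.entomo.observed_traps[keep].astype(float)),
        weeks=tuple(dataset.weeks[i] for i in keep),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Likelihood and fitting
# ---------------------------------------------------------------------------

def nb_loglik(beta: np.ndarray, theta: float, X: np.ndarray, y: np.ndarray,
              offset: np.ndarray) -> float:
    """NB2 log-likelihood at (β, θ) for a log link with offset.

    Kept as an explicit function so tests can maximize it with a
    general-purpose optimizer independently of the fitting routine.
    """
    eta = X @ beta + offset
    mu = np.exp(eta)
    from scipy.special import gammaln
    return float(np.sum(
        gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    ))


def _nb_deviance(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y + theta) * np.log((y + theta) / (mu + theta))))


@dataclass(frozen=True)
class NBFit:
    """A fitted negative-binomial model.

    ``params``/``bse``/``pvalues`` index the β coefficients by column name;
    θ is reported separately with its own standard error.  ``aic`` counts
    θ as one extra parameter: AIC = −2·loglik + 2·(n_coefficients + 1).
    """

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame
    theta: float
    theta_se: float
    loglik: float
    aic: float
    deviance: float
    fitted: np.ndarray
    resid_deviance: np.ndarray
    resid_pearson: np.ndarray
    weeks_used: tuple[str, ...]

    @property
    def n_obs(self) -> int:
        return len(self.weeks_used)

    def coefficient(self, name: str) -> float:
        return float(self.params[name])

    def coef_by_role(self) -> dict[str, float]:
        """Coefficients keyed by role: ar, temperature, humidity, interaction.

        Available when the model has the selected structure (one temperature
        main effect, one humidity main effect, their interaction, AR term).
        """
        out: dict[str, float] = {}
        for t in self.spec.terms:
            if t.variable in TEMPERATURE_VARIABLES:
                out["temperature"] = self.coefficient(t.name)
            elif t.variable in HUMIDITY_VARIABLES:
                out["humidity"] = self.coefficient(t.name)
        if self.spec.include_ar:
            out["ar"] = self.coefficient("ar1")
        if self.spec.interactions:
            a, b = self.spec.interactions[0]
            out["interaction"] = self.coefficient(f"{a.name}:{b.name}")
        return out

    def summary_table(self) -> pd.DataFrame:
        tab = pd.DataFrame(
            {"estimate": self.params, "std_error": self.bse, "p_value": self.pvalues}
        )
        tab.loc["theta"] = [self.theta, self.theta_se, np.nan]
        return tab

    def to_dict(self) -> dict:
        return {
            "model": self.spec.column_names(),
            "coefficients": {
                k: {"estimate": float(self.params[k]), "std_error": float(self.bse[k]),
                    "p_value": float(self.pvalues[k])}
                for k in self.params.index
            },
            "theta": self.theta,
            "theta_se": self.theta_se,
            "loglik": self.loglik,
            "aic": self.aic,
            "deviance": self.deviance,
            "n_obs": self.n_obs,
        }


_FIT_METHODS = ("newton", "bfgs", "nm")


def fit_nb(design: DesignData, maxiter: int = 300) -> NBFit:
    """Jointly maximize the NB2 likelihood over (β, θ).

    Starts from a Poisson GLM fit for β and a small dispersion, trying a
    Newton step first and falling back to quasi-Newton and simplex.  Raises
    :class:`FitError` on rank deficiency or non-convergence.
    """
    X = design.X.to_numpy(dtype=float)
    y = np.asarray(design.y)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise FitError("response must be non-negative integers")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("design matrix is rank deficient")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            start_beta = sm.GLM(
                y, X, family=sm.families.Poisson(), offset=design.offset
            ).fit(maxiter=100).params
        except Exception:
            start_beta = np.zeros(X.shape[1])
        model = NegativeBinomial(y, X, offset=design.offset, loglike_method="nb2")
        res = None
        trace: list[str] = []
        boundary = False
        for method in _FIT_METHODS:
            try:
                cand = model.fit(
                    start_params=np.r_[start_beta, 0.05],
                    method=method, maxiter=maxiter, disp=0,
                )
            except Exception as exc:  # pragma: no cover - optimizer internals
                trace.append(f"{method}: {exc}")
                continue
            ok = cand.mle_retvals.get("converged", False)
            finite = np.all(np.isfinite(cand.params)) and np.all(np.isfinite(cand.bse))
            if ok and finite and cand.params[-1] > 0:
                res = cand
                break
            if np.isfinite(cand.params[-1]) and cand.params[-1] < 1e-4:
                boundary = True
            trace.append(f"{method}: converged={ok}, finite={finite}")
        if res is None and boundary:
            # dispersion driven to the boundary alpha -> 0: data are
            # effectively Poisson; refit at a tiny fixed alpha so theta is
            # reported as a very large, finite value
            alpha_floor = 1e-6
            try:
                glm_res = sm.GLM(y, X, family=sm.families.Poisson(),
                                 offset=design.offset).fit(maxiter=200)
            except Exception as exc:
                raise FitError(f"Poisson-limit refit failed: {exc}") from exc
            names = list(design.X.columns)
            beta = pd.Series(glm_res.params, index=names)
            theta = 1.0 / alpha_floor
            mu = np.exp(X @ beta.to_numpy() + design.offset)
            k = len(names)
            llf = nb_loglik(beta.to_numpy(), theta, X, np.asarray(y, float),
                            design.offset)
            resid_pearson = (y - mu) / np.sqrt(mu + mu**2 / theta)
            dev_terms = np.where(y > 0, y * np.log(y / mu), 0.0) \
                - (y + theta) * np.log((y + theta) / (mu + theta))
            resid_dev = np.sign(y - mu) * np.sqrt(np.clip(2.0 * dev_terms, 0.0, None))
            return NBFit(
                spec=design.spec, params=beta,
                bse=pd.Series(glm_res.bse, index=names),
                pvalues=pd.Series(glm_res.pvalues, index=names),
                cov_params=pd.DataFrame(np.asarray(glm_res.cov_params()),
                                        index=names, columns=names),
                theta=theta, theta_se=float("nan"),
                loglik=float(llf), aic=-2.0 * float(llf) + 2.0 * (k + 1),
                deviance=_nb_deviance(y, mu, theta),
                fitted=mu, resid_deviance=resid_dev,
                resid_pearson=resid_pearson, weeks_used=design.weeks,
            )
        if res is None:
            raise FitError("NB fit did not converge; trace: " + "; ".join(trace))

    names = list(design.X.columns)
    alpha = float(res.params[-1])
    theta = 1.0 / alpha
    # delta method: theta = 1/alpha => se(theta) = se(alpha)/alpha^2
    theta_se = float(res.bse[-1]) / alpha**2
    beta = pd.Series(res.params[:-1], index=names)
    mu = np.exp(X @ beta.to_numpy() + design.offset)
    k = len(names)
    aic = -2.0 * float(res.llf) + 2.0 * (k + 1)
    resid_pearson = (y - mu) / np.sqrt(mu + mu**2 / theta)
    dev_terms = np.where(y > 0, y * np.log(y / mu), 0.0) \
        - (y + theta) * np.log((y + theta) / (mu + theta))
    resid_dev = np.sign(y - mu) * np.sqrt(np.clip(2.0 * dev_terms, 0.0, None))
    cov = pd.DataFrame(np.asarray(res.cov_params())[:k, :k], index=names, columns=names)
    return NBFit(
        spec=design.spec,
        params=beta,
        bse=pd.Series(res.bse[:-1], index=names),
        pvalues=pd.Series(res.pvalues[:-1], index=names),
        cov_params=cov,
        theta=theta,
        theta_se=theta_se,
        loglik=float(res.llf),
        aic=aic,
        deviance=_nb_deviance(y, mu, theta),
        fitted=mu,
        resid_deviance=resid_dev,
        resid_pearson=resid_pearson,
        weeks_used=design.weeks,
    )


def fit_model(dataset: AlignedDataset, spec: ModelSpec,
              drop_first: int | None = None) -> NBFit:
    """Convenience: :func:`build_design` then :func:`fit_nb`."""
    return fit_nb(build_design(dataset, spec, drop_first=drop_first))


# ---------------------------------------------------------------------------
# Screening and selection
# ---------------------------------------------------------------------------

def univariate_screen(dataset: AlignedDataset,
                      variables: tuple[str, ...] = METEO_VARIABLES,
                      lags: range | tuple[int, ...] = range(5),
                      alpha: float = 0.05) -> pd.DataFrame:
    """Screen each (variable, lag) pair as the sole model covariate.

    Each candidate is fitted alone with the trap-effort offset, an
    intercept, and no AR term, and its Wald p-value recorded.  The
    intercept is essential here: without it a lone covariate with a large
    mean (temperature ~19 °C, humidity ~56 %) is pinned by the
    mean-matching constraint and the screen has virtually no power against
    fluctuation effects.  (The final multivariable candidates are fitted
    without an intercept.)  The returned table keeps only terms with
    p < ``alpha``, sorted by ascending p-value; ties — which occur when
    strong signals underflow p to exactly zero — are broken by the larger
    Wald statistic |z|, then smaller lag, then variable name.  Fit
    failures are recorded per cell (``error`` column) rather than aborting
    the screen.
    """
    rows = []
    for var in variables:
        for lag in lags:
            term = LagTerm(var, lag)
            spec = ModelSpec(terms=(term,), include_ar=False)
            try:
                base = build_design(dataset, spec)
                X = base.X.copy()
                X.insert(0, "const", 1.0)
                fit = fit_nb(DesignData(X=X, y=base.y, offset=base.offset,
                                        weeks=base.weeks, spec=spec))
                rows.append({
                    "variable": var, "lag": lag,
                    "estimate": fit.coefficient(term.name),
                    "std_error": float(fit.bse[term.name]),
                    "p_value": float(fit.pvalues[term.name]),
                    "error": "",
                })
            except FitError as exc:
                rows.append({"variable": var, "lag": lag, "estimate": np.nan,
                             "std_error": np.nan, "p_value": np.nan,
                             "error": str(exc)})
    table = pd.DataFrame(rows, columns=["variable", "lag", "estimate",
                                        "std_error", "p_value", "error"])
    table["wald_z"] = table["estimate"] / table["std_error"]
    sig = table[table["p_value"] < alpha].copy()
    sig = _rank_screen(sig)
    sig.attrs["full_table"] = table
    sig.attrs["alpha"] = alpha
    return sig


def _rank_screen(table: pd.DataFrame) -> pd.DataFrame:
    tab = table.copy()
    tab["_negabsz"] = -tab["wald_z"].abs()
    tab = tab.sort_values(["p_value", "_negabsz", "lag", "variable"])
    return tab.drop(columns="_negabsz").reset_index(drop=True)


def best_lag_per_variable(screened: pd.DataFrame) -> dict[str, int]:
    """The single best (smallest p, ties by |z|) lag per variable."""
    best: dict[str, int] = {}
    tab = screened.copy()
    if "wald_z" not in tab.columns:
        tab["wald_z"] = tab["estimate"] / tab["std_error"]
    for _, row in _rank_screen(tab).iterrows():
        if row["variable"] not in best and np.isfinite(row["p_value"]):
            best[row["variable"]] = int(row["lag"])
    return best


@dataclass(frozen=True)
class SelectionResult:
    best: NBFit
    ranking: pd.DataFrame
    fits: dict[str, NBFit]


def select_model(dataset: AlignedDataset, screened: pd.DataFrame,
                 include_ar: bool = True) -> SelectionResult:
    """AIC selection over all temperature × humidity pairs.

    Each of the nine candidate models pairs one temperature variable with
    one humidity variable (each at its best screened lag — falling back to
    the best lag from the full screening table when a variable did not pass
    the significance cut), plus their interaction and the AR(1) term.  All
    candidates are fitted on an identical row window (rows dropped up to
    the maximum lag over candidates) so AIC values are comparable.
    """
    full = screened.attrs.get("full_table", screened)
    best = best_lag_per_variable(screened)
    fallback = best_lag_per_variable(
        full[np.isfinite(full["p_value"])] if len(full) else full
    )
    lags = {**fallback, **best}
    have_t = [v for v in TEMPERATURE_VARIABLES if v in lags]
    have_h = [v for v in HUMIDITY_VARIABLES if v in lags]
    if not have_t or not have_h:
        raise FitError("selection needs at least one temperature and one humidity term")

    specs = []
    for tv in have_t:
        for hv in have_h:
            tt, ht = LagTerm(tv, lags[tv]), LagTerm(hv, lags[hv])
            specs.append(ModelSpec(terms=(tt, ht), interactions=((tt, ht),),
                                   include_ar=include_ar))
    common_drop = max(s.max_lag for s in specs)

    rows, fits = [], {}
    for spec in specs:
        label = "+".join(spec.column_names())
        try:
            fit = fit_model(dataset, spec, drop_first=common_drop)
        except FitError as exc:
            rows.append({"model": label, "aic": np.nan, "deviance": np.nan,
                         "loglik": np.nan, "theta": np.nan, "error": str(exc)})
            continue
        fits[label] = fit
        rows.append({"model": label, "aic": fit.aic, "deviance": fit.deviance,
                     "loglik": fit.loglik, "theta": fit.theta, "error": ""})
    if not fits:
        raise FitError("all candidate models failed to fit")
    ranking = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    best_fit = fits[ranking.iloc[0]["model"]]
    return SelectionResult(best=best_fit, ranking=ranking, fits=fits)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def acf_pacf(series: np.ndarray, max_lag: int) -> dict:
    """Sample ACF and PACF with ±1.96/√n white-noise bands.

    PACF uses the Durbin–Levinson recursion on the sample autocovariances.
    A constant series has undefined autocorrelation and raises ValueError.
    """
    x = np.asarray(series, dtype=float)
    if len(x) <= max_lag:
        raise ValueError("series must be longer than max_lag")
    if np.ptp(x) == 0:
        raise ValueError("autocorrelation undefined for a constant series")
    acf_vals = _sm_acf(x, nlags=max_lag, fft=False)
    pacf_vals = _sm_pacf(x, nlags=max_lag, method="ld")
    band = 1.96 / np.sqrt(len(x))
    return {"acf": acf_vals, "pacf": pacf_vals, "band": band, "n": len(x)}


# ---------------------------------------------------------------------------
# Forecasting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForecastResult:
    weeks: tuple[str, ...]
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    observed: np.ndarray
    spearman: float
    mode: str


def forecast(fit: NBFit, dataset: AlignedDataset, horizon: int,
             mode: str = "one-step", level: float = 0.95) -> ForecastResult:
    """Project the fitted model ``horizon`` weeks past its fitted window.

    ``dataset`` must contain the fitted window followed by at least
    ``horizon`` further weeks with meteorology (and, for scoring, observed
    counts).  ``one-step`` mode uses the observed per-trap abundance of the
    previous week for the AR term each week; ``iterated`` propagates the
    model's own predicted abundance (predicted mean divided by the expected
    number of positive traps, taken as the fitted-window mean positive
    fraction times the observed traps).

    Intervals combine Wald uncertainty on the linear predictor (delta
    method) with negative-binomial count quantiles at the interval
    endpoints of μ.  The Spearman score uses average ranks for ties.
    """
    if mode not in ("one-step", "iterated"):
        raise ValueError(f"unknown forecast mode {mode!r}")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    n = len(dataset)
    fitted_end = None
    # locate the end of the fitted window within the dataset
    last_fit_week = fit.weeks_used[-1]
    for i, w in enumerate(dataset.weeks):
        if w == last_fit_week:
            fitted_end = i + 1
            break
    if fitted_end is None:
        raise ValueError("fitted window not found inside the dataset")
    if n - fitted_end < horizon:
        raise ValueError(
            f"dataset extends only {n - fitted_end} weeks past the fitted "
            f"window; horizon {horizon} requested"
        )

    design = build_design(dataset, fit.spec)
    offset_full = np.log(dataset.entomo.observed_traps.astype(float))
    names = list(fit.params.index)
    beta = fit.params.to_numpy()
    cov = fit.cov_params.to_numpy()
    z = stats.norm.ppf(0.5 + level / 2)

    pos_frac = float(np.mean(
        dataset.entomo.positive_traps[:fitted_end]
        / dataset.entomo.observed_traps[:fitted_end]
    ))

    idx_by_week = {w: i for i, w in enumerate(design.weeks)}
    a_hat = None
    mean, lo, hi = [], [], []
    target_rows = range(fitted_end, fitted_end + horizon)
    for t in target_rows:
        w = dataset.weeks[t]
        if w not in idx_by_week:
            raise ValueError(f"missing covariates for forecast week {w}")
        x = design.X.iloc[idx_by_week[w]][names].to_numpy(dtype=float).copy()
        if mode == "iterated" and fit.spec.include_ar and a_hat is not None:
            iar = names.index("ar1")
            # interaction columns never involve the AR term, so only this
            # column changes under propagation
            x[iar] = a_hat
        eta = float(x @ beta + offset_full[t])
        se_eta = float(np.sqrt(x @ cov @ x))
        mu = np.exp(eta)
        mu_lo, mu_hi = np.exp(eta - z * se_eta), np.exp(eta + z * se_eta)
        p_lo = fit.theta / (fit.theta + mu_lo)
        p_hi = fit.theta / (fit.theta + mu_hi)
        lo.append(float(stats.nbinom.ppf((1 - level) / 2, fit.theta, p_lo)))
        hi.append(float(stats.nbinom.ppf(0.5 + level / 2, fit.theta, p_hi)))
        mean.append(mu)
        if mode == "iterated":
            a_hat = mu / max(pos_frac * dataset.entomo.observed_traps[t], 1.0)
    observed = dataset.entomo.total_captures[fitted_end : fitted_end + horizon]
    rho = float(stats.spearmanr(mean, observed).statistic)
    return ForecastResult(
        weeks=tuple(dataset.weeks[fitted_end : fitted_end + horizon]),
        mean=np.asarray(mean), lower=np.asarray(lo), upper=np.asarray(hi),
        observed=np.asarray(observed), spearman=rho, mode=mode,
    )
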