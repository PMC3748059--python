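# Methods

## Count model

Weekly captures are modelled as negative binomial in the mean/size
parameterization: y ~ NB(μ, θ) with Var(y) = μ + μ²/θ (this is the "NB2"
convention; the alternative convention writes the dispersion as α = 1/θ —
the package reports θ throughout, so θ ≈ 19 means variance ≈ μ + μ²/19).
The log mean is

ln μ_t = ln N_t + β_ar a_{t−1} + Σ_i β_i x_{i,t−ℓ_i} + Σ γ (x·x′),

with the number of inspected traps N_t entering as an offset (coefficient
fixed at 1) to absorb uneven weekly sampling effort, and the per-trap
abundance a_t = y_t / positive_traps_t carrying the autoregressive signal.
Two trap denominators coexist deliberately: positive traps (≥ 1 capture)
define the abundance index, observed traps define the effort offset. The
multivariable models carry no intercept.

Estimation is joint maximum likelihood over (β, θ) via
`statsmodels.discrete.NegativeBinomial`, started from a Poisson GLM,
Newton first with quasi-Newton and simplex fallbacks. Standard errors and
p-values are Wald, from the observed information. When data are
equidispersed the dispersion is driven to the α → 0 boundary where the
information matrix for α is singular; the fit then falls back to a Poisson
GLM refit and reports a very large finite θ (10⁶), which is the correct
limit of the model family. AIC is −2·loglik + 2·(k + 1), counting θ as one
estimated parameter, so candidate rankings are internally consistent.
Model deviance uses the NB deviance at the estimated θ.

## Screening and selection

Each meteorological variable (precipitation; min/avg/max temperature;
min/avg/max relative humidity; wind) is screened at lags 0–4 weeks as the
sole covariate of an NB model with offset **and intercept**, keeping terms
with Wald p < 0.05 ranked by ascending p. The intercept in the screening
step is a deliberate design choice: without it, a lone covariate with a
large mean (temperature ~19 °C, humidity ~56 %) is pinned by the
mean-matching constraint — the weight of the squared mean (~375 for
temperature) dwarfs the weekly variance (~6) — and the screen has
essentially no power against the fluctuation effects it exists to detect.
The final candidate models remain intercept-free. Ties in p (which occur
exactly, at p = 0, whenever a signal is strong enough to underflow the
Wald tail probability) are broken by the larger Wald statistic, then the
smaller lag, then the variable name, keeping the ranking deterministic.

Selection fits all nine temperature × humidity pairs, each variable at its
best screened lag (falling back to its best lag overall when it missed the
significance cut), together with the AR(1) term and the pairwise
interaction. All nine are fitted on an identical row window — rows dropped
up to the maximum lag across candidates — because AIC comparisons require
a common sample. At most one temperature and one humidity main effect are
allowed per model to avoid collinearity between sister variables.

Residual diagnostics use the sample ACF and the Durbin–Levinson PACF with
±1.96/√n white-noise bands.

### Identifiability at study scale

A finding worth stating plainly: with the best-fit coefficients as the
generating truth (β_T = −0.0714, β_H = −0.0257, β_int = 0.0016,
β_ar = 0.8344, θ = 19.11) the *net* marginal effects near the climate
means are tiny — ∂lnμ/∂T = β_T + β_int·H̄ ≈ 0.018 per °C and
∂lnμ/∂H ≈ 0.005 per % — so at 90 weeks the univariate screen cannot
reliably attribute the correct lag against seasonal collinearity and
AR-induced count autocorrelation, and the AIC winner frequently carries a
sister variable (average instead of minimum temperature) of the generating
pair. The machinery itself is sound: under clearer main effects and
less autocorrelated climate the screen→selection chain recovers the
generating pair and lags in the large majority of replicates (this is what
the power tests verify). The practical reading is that with ~90 weekly
observations the *structure* (AR + temperature + humidity + interaction)
is recoverable but the specific family member and lag are not strongly
identified.

## Thresholds and growth regions

With an interaction, the partial temperature effect β_T + β_int·H changes
sign at H* = −β_T/β_int and the humidity effect at T* = −β_H/β_int
(44.6 % and 16.1 °C at the generating coefficients; thresholds are
reported to 1 d.p.). The growth condition compares predicted next-week
per-trap abundance with the current value,
exp(β_ar·a + β_T·T + β_H·H + β_int·T·H) > a — the effort offset cancels in
this per-trap comparison. The default grid is T ∈ [10, 32] °C (step
0.1 °C), H ∈ [30, 100] % (step 0.5 %), covering the observed climate
envelope. Scenario abundances are 0.111 / 0.56 / 0.99 per trap
(low/median/high). Growth regions are nested (shrinking as prior
abundance rises) exactly while a < 1/β_ar ≈ 1.2 per trap, because the
growth margin β_ar·a + c − ln a is decreasing in a there; all three
scenarios lie below this bound. No uncertainty bands are placed on the
thresholds (a delta-method extension, not implemented).

## Forecasting

The fitted model projects a chosen horizon (default 19 weeks) past its
fitted window. One-step mode (default) uses the observed previous-week
abundance for the AR term each week, matching a weekly-updated
surveillance forecast; iterated mode propagates the model's own predicted
abundance, dividing the predicted mean by the expected positive-trap count
(fitted-window mean positive fraction × observed traps). Intervals
combine Wald uncertainty on the linear predictor (delta method) with NB
count quantiles evaluated at the interval endpoints of μ; they are
therefore prediction intervals, slightly conservative. Forecasts are
scored with Spearman rank correlation (average ranks on ties).

## Wavelet suite

The continuous wavelet transform uses the analytic Morlet wavelet with
ω₀ = 6, implemented by FFT convolution with zero padding to at least twice
the series length (pushing circular wrap-around into the padded zeros).
Scales are dyadic, s_j = s₀·2^{jδj} with s₀ = 2δt, δj = 1/12 and
J = log₂(nδt/s₀)/δj — the defaults of the classical geophysical routines.
Fourier periods are λ = 4πs/(ω₀+√(2+ω₀²)) ≈ 1.033·s; the energy
normalization makes unit-variance white-noise power flat (≈1) across
mid scales. The cone of influence is the e-folding distance √2·s of the
Gaussian envelope, expressed as the largest unaffected period per time
point (zero at the series edges).

Series are log-transformed (offset +1 for precipitation with exact zeros)
and standardized before analysis; spectra are invariant to the scale and
units of the raw series.

Power significance tests each cell against a red-noise background: the
AR(1) spectrum P(f) = (1−r₁²)/(1+r₁²−2r₁cos 2πf δt), with r₁ the ordinary
lag-1 sample autocorrelation of the series (the simpler of the two common
estimators; its calibration is verified by simulation rather than assumed).
Normalized power under the null is ½P·χ²₂, so the 95 % threshold is
σ²·P·χ²₂(0.95)/2. Monte-Carlo calibration (200 AR(1) surrogates, φ = 0.7,
n = 128) puts the in-COI non-exceedance rate at ~94.5 %, the small deficit
coming from the downward bias of r̂₁ at this length.

The cross-wavelet spectrum is W_x·conj(W_y); phase is reported as
angle(conj(W_x)·W_y), i.e. positive when the *second* series leads: 0°
in-phase, 90° a quarter period ahead, ±180° anti-phase — the arrow
convention of the cross-spectral figures this suite mirrors, fixed by
construction and unit-tested with lagged sinusoids. Interaction series for
spectral analysis are the elementwise product of the raw series, then the
same preprocessing.

Squared coherence is R² = |S(W_xy/s)|² / (S(|W_x|²/s)·S(|W_y|²/s)) with
smoothing S Gaussian in time (sd = s/δt samples, per scale) and boxcar
across scales (width 0.6/δj scale steps). Self-coherence is identically 1
by construction (the numerator equals the squared denominator for any
positive linear smoother). Coherence significance is Monte-Carlo: AR(1)
surrogate pairs matched to each input's r₁, with the 95th percentile of
surrogate R² pooled over in-COI times per scale (default 300 surrogates;
100 in the pipeline default for speed; both config-exposed). The
cross-power mask uses the same surrogate machinery for uniformity rather
than the analytic cross-power distribution.

## Synthetic data generator

The generator emulates the surveillance setting the analysis was designed
for; it is the test bed for everything downstream.

Climate: each variable is a sinusoidal seasonal mean (period 52 weeks)
plus AR(1) weekly noise. Ordering invariants hold by construction —
tmin/tmax are the average-temperature signal minus/plus strictly positive
random gaps, humidity likewise, clipped to [0, 100]. Precipitation is a
seasonally modulated mixture of exact zeros (dry-week probability peaking
in winter, mean ≈ 0.39) and gamma amounts; wind is seasonal-AR(1), ≥ 0.
Defaults target the study's descriptive statistics: minimum temperature
averaging ≈19.4 °C, minimum humidity ≈55.9 % (the most variable humidity
series, via its larger gap noise), ~35 of 90 weeks rain-free, wind
≈2.9 m/s.

Counts: the generative mirror of the fitted model — NB(μ_t, θ) with
ln μ_t = ln N_t + β_ar·min(a_{t−1}, a_cap) + β_T·tmin_{t−4} +
β_H·hmin_{t−2} + β_int·tmin_{t−4}·hmin_{t−2}, defaults the best-fit
coefficients and θ = 19.11. Observed traps are binomial(425, 0.97)
(occasionally unchecked traps); positive traps are
binomial(N_t, 1 − exp(−c·μ_t/N_t)) with c = 3.9 chosen so the positive
fraction is interior (~0.85) and the per-trap abundance centres on ~0.58
— both denominators realistic without simulating individual traps. The
recursion starts at a₀ = 0.58 per trap and discards a 12-week burn-in
(covering the maximum lag and forgetting a₀).

The saturation a_cap = 2.0 (just above the observed per-trap range
0.27–1.53) is a deliberate stabilization: a linear-in-abundance feedback
on the log scale has no stable fixed point once sustained warm-humid
spells lift the climate contribution, so the unmodified recursion can run
away. The cap is a minimal density-dependence assumption, binds in ~0.2 %
of weeks under defaults, and leaves refitted coefficients approximately
unbiased (mean interaction estimate 0.0016, temperature −0.069 vs −0.0714
over 100 replicates; the AR coefficient shows the usual small-sample
downward bias of lagged endogenous regressors, ~0.75 vs 0.8344).

What the generator does *not* emulate: spatial trap structure, reporting
artifacts, vector-control interventions, the un-modelled dependence of
counts on precipitation and wind (those variables are generated but
causally inert, precisely so the screen's type-I behaviour is testable),
and any dengue-case dynamics. Passing tests therefore demonstrate the
correctness and calibration of the machinery under the model's own
assumptions — not that the real series obeys the model.

## Numerical choices and problem sizes

Week labels are ISO "YYYY-Www"; series must be strictly consecutive (year
rollover handled), gaps are validation errors, and lag-incomplete rows are
carried as NaN and dropped only at design construction. Random draws all
flow through `numpy.random.Generator`; the pipeline fans a single seed out
to per-stage seeds by fixed offsets, and rerunning with the same seed is
byte-identical. Simulation-based checks use 90-week series (the study's
fitted length), 100 replicates for coefficient recovery, 200 for the
type-I and red-noise calibrations, and n = 128 for sinusoid-based wavelet
checks; these sizes make the whole suite run in well under a minute while
leaving Monte-Carlo error comfortably inside the asserted tolerances.
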