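# Methods

`gppattrib` attributes centennial-scale changes in gross primary
productivity (GPP) — the gross photosynthetic CO₂ uptake of the land
surface, the largest land carbon flux — to individual forcing factors, and
quantifies the uncertainty of every attributed change.  This note records
the models, procedures, numerical choices and known limitations.

## Attribution by simulation differencing

The method rests on semi-factorial ensembles of Earth-system model runs in
which time-varying forcing factors are enabled one at a time.  For the
offline (land-only) ensemble the run sequence is

| run  | enabled factors |
|------|-----------------|
| RG1  | steady state: repeated randomized 30-yr block of trend-free weather, constant CO₂, N deposition and land cover |
| SG1  | + time-varying climate |
| SG2  | + land use / land cover change (LULCC) |
| SG3  | + time-varying CO₂ |
| BG1  | + time-varying nitrogen deposition (only carbon–nitrogen-coupled models) |

and for the coupled analog: `piControl`, `historicalNat` (natural forcing
only), `historicalGHG`, `historical`.  Because consecutive runs differ by
exactly one factor, the per-cell, per-month difference of two runs is
attributed entirely to that factor (e.g. SG3 − SG2 → CO₂ fertilization;
historicalNat − piControl → natural forcing).  The differences telescope:
the four offline factor effects sum identically to BG1 − RG1, which the
package verifies to 1e-6 g C m⁻² month⁻¹.

Ensemble statistics follow *one-model-one-vote*: the unweighted mean over
distinct models is the best estimate.  Uncertainty is ensemble spread,
estimated by resampling models with replacement (1000 replicates by
default) and reported as 90% intervals.

Two related but distinct interval constructions are used deliberately:

* `attribution.bootstrap_ci` — the plain percentile interval, used for
  effect-size uncertainty envelopes.  At ensemble sizes near 10 it covers
  the population truth at roughly 85% for a nominal 90%; the package's
  calibration check accepts [80%, 97%].
* `change_metrics.significance_mask` — a studentized (bootstrap-t)
  interval per grid cell.  The percentile form was measured to flag
  16–17% of truly unchanged cells at a nominal 10%; the bootstrap-t form
  holds ~11% and is therefore the significance procedure.

Two estimands appear in the recovery checks and should not be conflated.
The consensus estimator targets the mean effect of *its own members*, so
estimator-quality checks compare against the ensemble mean of the member
truth fields; agreement is better than 1% at the default configuration.
Interval-coverage checks instead target the central (population) truth,
because the model-sampling spread is exactly what the bootstrap is
supposed to capture.

## Climate-driver decomposition by emulation

The net climate effect (SG1 − RG1) is decomposed into temperature,
precipitation and shortwave-radiation contributions with per-grid-cell
random-forest regressions: monthly SG1 GPP is the target, the same-month
drivers (tas, pr, rsds) are the predictors; no lags, no memory.  Skill is
out-of-bag variance explained, R²_oob = 1 − MSE_oob/Var(y); the median
over vegetated cells exceeds 0.97 on the default synthetic world.
Because the reference climate is a randomized subset of the historical
climate space, predictions never extrapolate far beyond the training
support (the emulator warns when >1% of months at a cell fall outside the
per-predictor training range).

Per-driver effects come from sequential substitution in the fixed order
radiation → precipitation → temperature:

    E0 = f(R_ref, P_ref, T_ref)        effect_rsds = E1 − E0
    E1 = f(R_hist, P_ref, T_ref)       effect_pr   = E2 − E1
    E2 = f(R_hist, P_hist, T_ref)      effect_tas  = E3 − E2
    E3 = f(R_hist, P_hist, T_hist)     total       = E3 − E0

The three effects telescope to the total by construction.  The
decomposition is strictly first order: interaction terms are excluded and
never claimed.

Forest hyperparameters: 100 trees, all predictors considered at every
split (`max_features=1.0`, the standard regression default), minimum leaf
size 5, bootstrap sampling on, per-cell seeds derived from the run seed.
Restricting candidate predictors per split (`max_features=1`) was tested
against the analytic oracle below and attenuates *all* per-driver
responses by 15–22%, so it was rejected.

**Known limitation — weak-driver attenuation.**  A regression forest's
effective smoothing kernel adapts to each predictor's share of the target
variance, so the response to the *weakest* driver is biased toward zero.
On an additive synthetic world with closed-form per-driver effects the
forest recovers the temperature and precipitation effects within 10–14%
but underestimates the radiation effect by ~20–35%, across every
forest configuration tested (feature subsampling 1–3, leaf sizes 1–5,
100–300 trees, bootstrap on/off, randomized-split trees).  A
residual-fitting gradient-boosting emulator reaches ~14%, confirming the
limit belongs to the forest estimator rather than to the substitution
scheme.  The corresponding acceptance check is intentionally left failing
for the radiation term; radiation-effect magnitudes from this module
should be read as lower bounds.

## The synthetic world

The generator replaces hundreds of GB of archived model output with a
desk-scale world whose per-factor effects are known exactly.  GPP follows
a light-use-efficiency chain,

    GPP = ε · R_MJ · f_T(tas) · f_W(pr) · g(CO₂) · h(N) · (1 − L) + AR(1) noise

with monthly shortwave radiation converted to MJ m⁻², a Gaussian
temperature response f_T = exp(−((T − T_opt)/T_w)²) (T_opt = 298 K,
T_w = 14 K, so warming helps cold regions and slightly depresses the
tropics), Michaelis–Menten moisture limitation f_W = P/(P + 40 mm),
logarithmic CO₂ fertilization g = 1 + β ln(C/C_pi) (β = 0.63,
C_pi = 285 ppm), a saturating nitrogen response
h = 1 + 0.28·D/(D + 6 kg N ha⁻¹ a⁻¹), and a prescribed land-conversion
loss fraction L (5% maximum in converted cells, ramped in from 1850 so
the footprint is nearly static after 1930).  Runs with a factor disabled
hold it at its preindustrial level, so attributed changes at 1901 are not
a priori zero — anthropogenic forcing predates the analysis period.

Default scale: a global 24×48 (7.5°) grid — global rather than a regional
window so that tropics/extratropics screening, dominance areal fractions
and Pg C integrals are meaningful — 11 pseudo-models of which 4 carry the
nitrogen run, monthly fields for 1901–2010.  Calibration (chosen once):
global GPP ≈ 100 Pg C a⁻¹ at 1901; final-decade effects ≈ +20 (CO₂),
+9 to +11 (N deposition), +1.7 (climate), −1.0 to −1.3 (LULCC) Pg C a⁻¹,
i.e. the magnitude ordering and rough sizes of the real ensembles.

Drivers: latitude-dependent monthly climatologies with deliberately
*unlocked* seasonal phases — insolation peaks at the solstice month,
temperature lags it by one month, extratropical precipitation is
winter-peaked while tropical precipitation is sun-phased.  Phase-locked
(perfectly collinear) cycles would make per-driver responses
unidentifiable to any emulator; real climatology is not collinear in that
way.  Stationary AR(1) anomalies fill a 30-yr weather block that is tiled
to form the reference climate; historical mode adds linear trends
(+1 K, +6% precipitation, −1 W m⁻² per century), and the coupled analog
adds an 11-yr solar cycle and episodic volcanic dimming (−8 W m⁻²,
−0.3 K, 1-yr e-folding, events in 1902/1912/1963/1982/1991).

Inter-model spread is produced by multiplicative parameter perturbations
(SD 12%) on ε, β, the nitrogen gain and the LULCC loss — parameters that
enter their factor effects linearly, which keeps the ensemble-mean truth
unbiased for the central truth.  AR(1) noise (φ = 0.3, innovation SD 5%
of the local climatological GPP) is drawn independently per experiment,
stressing the differencing estimator with non-shared noise.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real archives: structural (non-scalar) model error;
trends in interannual variance (the synthetic volatility ratio stays near
1, unlike the observed-era widening); spatially heterogeneous factor
dominance (CO₂ dominates essentially everywhere here); disturbance,
phenology, soil pools, crop management; observational driver error.

## Other numerical choices

* Canonical unit g C m⁻² month⁻¹; fixed 365-day calendar with standard
  month lengths; conversion from kg C m⁻² s⁻¹ uses per-month day counts.
* Regridding is first-order conservative on rectilinear grids, with
  latitude overlaps computed in sin(lat) so overlap areas are exact; the
  global integral is preserved to 0.1%.
* Cell areas use the spherical shell formula A = R²Δλ(sin φ₂ − sin φ₁),
  R = 6 371 000 m.
* Decades run 1901–1910, …, 2001–2010; partial decades are excluded.
* The anthropogenic/natural dominance ratio floors its denominator at
  1e-6 g C m⁻² a⁻¹; dominance winners are defined only on vegetated
  (and, where provided, significant) cells, with exact ties broken by the
  fixed order CO₂, Ndep, climate, LULCC.
* The interannual-variability (IAV) ratio deseasonalizes each period with
  its *own* monthly climatology, so it measures anomaly variance, not
  climatology shift; zero early-period variance yields a missing value.
* Seasonal amplitude is computed per year (max − min of the 12 monthly
  values) and then period-averaged, which is robust to phase drift.
* The CO₂ vegetation-feedback correction divides the CO₂ effect by 1.3
  (a ~30% overestimate read as an inflation factor; the alternative ×0.7
  reading cannot reproduce the corrected totals) and adjusts the
  anthropogenic sum accordingly; raw and adjusted values are both
  reported.
* Critical-load screening uses configurable thresholds (10 and
  3 kg N ha⁻¹ a⁻¹), tropics defined as |lat| ≤ 23.5°, and — in the
  synthetic world — a forest proxy of vegetated cells with mean annual
  GPP above 400 g C m⁻² a⁻¹ (the productive tropical and mid-latitude
  belts).
* All randomness flows from named, CRC-hashed substreams of a single
  master seed; same seed ⇒ bit-identical archives, forests and CSVs.

## Problem sizes used by the shipped checks

The test suite and the acceptance script run the default 24×48 world for
end-to-end checks; emulator training covers the ~430 vegetated cells of
one model; interval-coverage calibration uses 200 replicate 6×10 worlds
of 30 years with 200 bootstrap draws; significance calibration uses four
16×24 worlds (40 years, CO₂ response disabled) giving ~550 zero-effect
cells; these sizes keep a full run within a few minutes on one CPU while
leaving every statistical check adequately powered.
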