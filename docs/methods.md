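# Methods

## The model

`edseries` implements an interrupted time-series (ITS) analysis of weekly
emergency-department (ED) visit counts for a focal patient group against a
contemporaneous comparison group. Weeks run Friday through Thursday so that a
policy shock landing on a Friday opens a fresh bin; week indices are 1-based.

The dependent weekly count y_t follows a transfer-function regression with
subset-autoregressive errors:

    y_t = α + β x_t + ω I_t + Σ_j λ_j z_jt + N_t
    (1 − φ1 B − φ5 B^5)(1 − B)^d N_t = ε_t,    ε_t ~ N(0, σ²)

where

* x_t — the control series (weekly ED visits of the comparison group),
  entered contemporaneously (order-0). It absorbs shared patterns: seasonal
  variation, population change, and the economy-wide collapse in ED
  help-seeking at the start of the COVID-19 pandemic.
* I_t — the coded intervention: a pulse (1 during a fixed window of weeks,
  default the nine weeks beginning 2020-03-13) or a step (1 from the event
  week onward, the "binary switch" sensitivity).
* z_jt — outlier regressors accepted by the detection loop (below).
* N_t — the noise term. The AR polynomial is a *subset* model: only the
  configured lags (default 1 and 5) carry free coefficients; intermediate
  lags are pinned at zero. d ∈ {0, 1}, default 0: the pre-pandemic level is
  treated as stable and trend is absorbed by the control series.

An intercept is included throughout; with counts in the hundreds the
regression is far from the origin and omitting it would distort β.

Counts are modeled as Gaussian. At weekly totals of ~300–700 the normal
approximation to count variation is adequate, and it matches the estimator
whose behavior the synthetic experiments are designed to probe.

### Estimation

The exact Gaussian likelihood is evaluated by the state-space innovations
recursion (statsmodels SARIMAX) with stationary initialization. Optimizer
starts are the OLS regression coefficients, zero ARMA terms, and the OLS
residual variance; with no ARMA terms the start is already the maximizer, so
the no-ARMA fit reproduces closed-form least squares (coefficients and
standard errors to ~1e-9). Standard errors come from the observed information
at the optimum; intervals are estimate ± 1.96·SE with two-tailed z tests.

Two numerical safeguards matter in practice. First, with lag-subset orders
the stationarity-enforcing reparameterization does not bound the *subset*
polynomial, and the optimizer can escape into a region where the Kalman
filter degenerates (the log-likelihood collapses to exactly zero); every fit
is therefore validated (finite nonzero likelihood, positive σ², AR roots
outside the unit circle) with a Nelder–Mead fallback, and an invalid final
fit raises `ConvergenceError` carrying the best point found. Second,
near-boundary optima can make the observed information singular; standard
errors then fall back to the numerically differentiated Hessian.

### Pipeline

`run_pipeline` executes the five analysis steps: (1) regression of the
dependent on the control series alone; (2) identification of residual
autocorrelation from the PACF (lags exceeding the ±1.96/√T Bartlett band),
adopted only when it matches the configured spec — Box–Jenkins
identification is analyst-guided, so the configuration wins on disagreement,
with a logged notice; (3) the intervention-augmented fit; (4) a Ljung–Box
whiteness check on the post-burn-in residuals (12 lags, degrees of freedom
reduced by the fitted ARMA terms), surfaced as a warning on failure;
(5) iterative outlier detection and adjustment. The first 6 residuals
(`burn_in_weeks`) are dropped from reporting as start-up transients of the
lagged model; the value 6 is a reporting convention, configurable, and does
not affect estimation.

## Outlier detection

Three outlier types are scanned at every week w: additive outlier (AO, unit
pulse), temporary change (TC, pulse decaying as δ^(t−w), δ = 0.7 — the
conventional default; the decay rate is configurable), and level shift (LS,
unit step). The innovational-outlier type is deliberately absent.

Each iteration proceeds in two stages, after Chen and Liu's
detection-and-correction approach:

1. **Fast scan.** The dependent series, the current regressors, and all
   candidate regressors are filtered by π(B) = φ(B)(1−B)^d/θ(B) at the
   current ARMA estimates (conditioning out the first max-lag rows, whose
   filtered values are start-up transients, not innovations). Each
   candidate's statistic is the *added-variable* t: its coefficient when the
   regression block is re-estimated jointly with it by GLS under the current
   filter. Re-estimating the regression matters — a large unmodelled shift
   can otherwise hide inside distorted intercept/intervention estimates.
   Under a pure white-noise model the AO statistic reduces to the
   (studentized) standardized residual. The scale estimate standardizing the
   statistics is a Huber proposal-2 robust scale of the filtered residuals
   (median-absolute-deviation and plain ML options are exposed): the ML σ is
   inflated by the very outliers being hunted, which masks them, while the
   MAD is too noisy at T ≈ 140 and randomly inflates the whole scan. A
   degrees-of-freedom correction √(T/(T−k)) is applied, since all scale
   estimates shrink with the number of fitted mean parameters.

2. **Confirmation and acceptance.** The decisive criterion is the
   operational one: a variable is an outlier if its coefficient has
   |t| > 3.5 *when added to the equation*, i.e. in the fully
   re-estimated augmented model.
   A clear scan winner (lead ≥ 0.3 over the runner-up) is re-fitted and
   accepted if its joint |t| clears the threshold. Otherwise the top
   screened candidates (up to 2 per type above 0.7 × threshold, plus each
   type's best candidate regardless) are each re-fitted jointly, and the
   accepted one is chosen by maximized log-likelihood. Screening below the
   final threshold is essential: an unmodelled level shift biases the AR
   estimates toward a unit root, and the resulting near-differencing filter
   deflates every scan statistic; the joint re-fit removes that bias before
   the threshold is applied.

   Likelihoods within 2 support units are treated as ties. Ties are resolved
   to the candidate least collinear with the coded intervention indicator,
   then higher likelihood, earlier week, and LS > TC > AO. The collinearity
   rule settles a real degeneracy: with the pulse in the model, an LS
   starting at the window's first week spans exactly the same column space
   as an LS starting the week after the window plus a shift in ω, so their
   fits tie to numerical precision; preferring the onset outside the window
   preserves the coded intervention's interpretation.

Accepted outliers are never removed; the loop stops when nothing clears the
threshold or the cap (default 10) is reached, the latter flagging a warning.
Every acceptance strictly increases the maximized log-likelihood (the
augmented model nests the previous optimum at coefficient zero, which is
kept as a warm-start fallback). Detected outliers inside the intervention
window are reported with a flag, since they compete with ω for the same
variation.

With 3 types × ~140 weeks of candidates, the |t| > 3.5 threshold implies
roughly 0.2–0.3 expected false detections per clean series once the
finite-sample t calibration is accounted for, i.e. a ~75–80% chance of a
clean scan ending with zero detections. That is the operating characteristic
the threshold buys; it is not a defect of the scan.

## Effect translation

A fitted ω is translated as avoided visits = |ω| × duration and percent
shortfall = 100·|ω| / weekly mean. The report emits both the 8-week and the
9-week duration conventions with labels, because the study's methods code a
nine-week indicator while its results multiply by an 8-week duration; with
ω = −54.33 and weekly mean 544.25 the 8-week translation gives 434.64 ≈ 435
avoided visits and a 9.98% shortfall. The magnitude change between the
initial and outlier-adjusted coefficients, 100·(|ω_adj| − |ω_init|)/|ω_init|,
is reported alongside (−38.67 → −54.33 is +40.5%).

## Synthetic data generator

No public data exist — the source records are confidential hospital files —
so the generator is the package's experimental bench, emulating the study
conditions:

* **Control series**: iid Gaussian level noise, mean 571.08, SD 91.14
  (the printed control moments, treated as pre-drop targets), with a
  sustained fractional level drop (default 0.35) from the intervention start
  week onward representing the pandemic-wide decline. The 0.35 default is
  a free parameter loosely motivated by the reported ~42% national decline;
  it is not a paper estimate. An optional seasonal sinusoid (amplitude
  default 0) and an optional window-localized dip (`control_pulse_effect`,
  default 0, used for alternate-pair fixtures) are available.
* **Dependent series**: α + 0.97·x_t − 54.33·I_t + injected outlier effects
  + subset-AR{1,5} noise with φ1 = 0.09, φ5 = 0.06 (the outlier-adjusted
  estimates) and innovation SD 60 — chosen once so that the dependent
  series' SD is *emergent* near the printed 107 (β²·91² + noise variance);
  the SD is checked, never enforced. α is set so the pre-intervention
  expected mean equals 544.25. Values are rounded and clipped at zero;
  the clip binds only in extreme scenarios (e.g. a −5σ level shift on top
  of the pandemic drop pushes expectations near zero), which is a real
  feature of count floors.
* **Encounter records**: one row per counted visit with uniform within-week
  dates (the data's within-week distribution is unstated; uniform is the
  neutral choice), demographics drawn from the cohort table's margins, plus
  configurable decoys (minors, unknown ethnicity, other payers, inpatient
  dispositions) that the ingest filters must remove, and an optional
  non-Latino Medi-Cal series (mean 520, SD 85, drop 0.25 — free choices)
  for the alternate-pair sensitivity. Binning the non-decoy records
  reproduces the weekly counts exactly, by construction and by test.

All randomness flows from one integer seed through named substreams;
identical seed and configuration give byte-identical output, and every
generated object carries a truth record sufficient to score any estimator.

What the generator does *not* emulate: overdispersed or Poisson-type count
noise (a Gaussian generator matches the estimator's assumptions — recovery
tests validate the machinery, not the Gaussian assumption itself), diagnosis
mix, repeat-visit dependence within patients, holiday calendar effects, and
slow secular trends beyond the shared drop. Passing tests therefore show
that the inference machinery is calibrated under its stated model, not that
the model is correct for any particular hospital's data.

## Problem sizes and experiment design

The calibration experiments run at the study scale, T = 142 weeks:
parameter recovery and interval coverage use 200 replicates (coverage is
required to land in [90%, 98%]); each outlier operating characteristic
(exact-week location of a −5σ level shift, joint recovery of a 4σ TC at
week 81 with a −5σ LS at week 124, and the clean-series zero-detection
rate) uses 50 replicates; residual-whiteness calibration uses 100 fits and
the ACF sanity check one series of length 10,000. Unit tests use a 60-week
variant of the same generator to keep individual fits cheap.

## Known limitations

* The subset-AR stationarity region is enforced by post-fit validation
  rather than by reparameterization (see above); pathological data can
  still cost a Nelder–Mead restart.
* Adjacent-week confusion for temporary changes of moderate size (≈4σ) is
  irreducible: a TC one week off explains almost the same variation, and at
  that signal size the likelihoods occasionally favor the neighbor.
* The exact likelihood treats the pre-sample noise as stationary; with d=1
  the differenced model relies on SARIMAX's diffuse handling and has seen
  less testing here than d=0, the study's configuration.
* `describe_cohort` prints the age bands with the labels "45-55" and
  "55-64" following the study's table, but assigns age 55 to the second
  band (half-open intervals); the printed labels overlap, the binning does
  not.
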