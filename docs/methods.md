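# Methods

This note documents the statistical models implemented in `earlygrowth`,
the design of the synthetic cohort generator that drives the test suite,
and the numerical choices a user should know about.

## Measurement derivations

**Estimated fetal weight.** The Hadlock three-biometric formula,
`log10 EFW[g] = 1.326 − 0.00326·AC·FL + 0.0107·HC + 0.0438·AC + 0.158·FL`
with head circumference (HC), abdominal circumference (AC) and femur
length (FL) in centimetres. Inputs are strict centimetres; a
millimetre-scaled table must be converted by the caller (the reader
errors on implausible magnitudes rather than silently converting). The
coefficients are exposed read-only and overridable, since several Hadlock
variants circulate; this is the variant conventionally used when exactly
these three biometrics are available.

**Other closed forms.** BMI = kg/m²; MRI fat volumes convert to mass at
the specific gravity of adipose tissue, 0.9 g/mL; the liver fat fraction
is the arithmetic mean of the sampled hepatic regions (four samples is
the acquisition standard; any non-empty subset is accepted).

## Reference charts and SDS

A chart is an ordered grid of (age, mean, SD) of the possibly
log-transformed measure, per sex or pooled. `fit_reference` builds grids
from a reference sample by quantile age bins (or explicit bin edges —
the pipeline places edges inside visit clusters and at the midpoints of
the empty gaps between them, so no bin straddles two visits); each bin
contributes its mean age, mean and SD (ddof = 1). SDS are
`(transform(x) − mean(age)) / SD(age)` with linear interpolation between
grid ages; outside the outer bin centres the edge slope is extended
linearly (a flat extension would bias the outer half-bins), and queries
beyond the observed support plus a configurable margin (default 1
week/month) are errors. Skewness is handled by the log transform option,
not LMS/Box–Cox modelling, which is out of scope.

Charts come from three sources: fitted internally on the analysis cohort
(default for real data), read from a delimited chart file (the external
national-reference scenario), or — for simulated cohorts — the
generator's own population curves (`chart_source: generating`). The last
mirrors a study that standardizes against external references: such
charts carry no sampling noise. This matters quantitatively: internally
fitted charts at n = 3000 add ~0.1–0.17 SDS of measurement error at the
fetal/birth points, which misclassifies ~13% of growth patterns and
attenuates pattern contrasts by roughly a third. Parameter-recovery tests
therefore run against the generating charts; chart quality itself is
validated by a self-calibration criterion (per-bin SDS mean within
±0.05, SD within [0.95, 1.05] on the chart's own reference sample).

**Birth size.** SGA/LGA cutoffs are the 5th/95th percentiles converted to
z-cutoffs under normality (±1.6449), read as strict inequalities; SDS are
constructed to be standard normal, so the normal quantile is the natural
default. Fetal EFW SDS are gestational-age-adjusted but not sex-adjusted;
birth and infant SDS are both.

## Growth patterns

Interval change is `SDS_to − SDS_from`; more than +0.67 is acceleration,
less than −0.67 deceleration, the boundary itself normal ("more than"
read strictly). 0.67 SD corresponds to the width of one centile band on
a growth chart and is a named, overridable constant. The infant interval
uses the last available infant weight in the order 24 months → ~12 months
(tagged `11mo`, matching the typical visit age of ~11.1 months) → 6
months, with the source recorded per child. The 3×3 fetal-by-infant
cross-classification yields 9 patterns with normal/normal as reference.

## Conditional growth

For ordered time points t₁ < … < t_K, the conditional variable at t_k is
the standardized (ddof = 1) residual of OLS of SDS_k on an intercept and
SDS₁…SDS_{k−1}, computed over children complete at t_k **and all prior
points** — so each time point has its own eligible subsample and its own
n. Orthogonality to prior weights is an exact OLS property (asserted to
1e−10); on a common complete-case sample, joint and one-at-a-time
inclusion give identical coefficients. Models per time point are fitted
separately with shared covariates (the joint mode is equivalent on
complete data and available).

## Trajectory models

**Reed1.** `W(t) = A + B·t + C·ln t + D/t`, t in years, fitted per sex.
Default estimation is a linear mixed model (ML, lbfgs) with random
intercept and linear term per child — a full random Reed1 basis is not
identifiable at 3–7 observations per child, and keeping C, D at the sex
level guarantees a well-defined velocity peak per child. A per-child OLS
mode (≥ 4 observations) exists for dense data; if a mixed fit fails the
code falls back to pooled OLS with zero offsets and logs a warning.
Observations below 2 weeks of age are dropped (ln t, 1/t blow up);
t ≤ 0 is an error. Velocity `v(t) = B + C/t − D/t²` has an interior
maximum at `t* = 2D/C` with `PWV = B + C²/(4D)` when C > 0 and D > 0 and
t* falls in (0, 1.5] years; otherwise the velocity is maximized on the
boundary of the admissible window (lower end 2 weeks) and the result
flagged rather than silently truncated.

**Adiposity peak.** A cubic in age (months) on log BMI over [0.5, 18]
months, sex as an intercept shift, random intercept and linear term per
child; fitted on a unit-scaled age internally for conditioning. AGEAP is
the real root of `3β₃t² + 2β₂t + β₁ = 0` inside the window with negative
second derivative (the quadratic vertex in the β₃ → 0 limit); BMIAP is
`exp` of the child's fitted curve there. Children whose curve has no
admissible interior maximum are flagged missing, not clamped.

## Allometric indices

The slope of OLS of ln(measure) on ln(height) is the power that renders
`measure/height^power` uncorrelated with height. Indices use the
conventional integer powers (4, 2, 3, 3) with height in metres — this
puts FMI on its familiar kg/m⁴ scale — while the unrounded slope is kept
for diagnostics. FMI, visceral and pericardial indices and the liver fat
fraction are natural-log transformed (right-skewed) before
standardization; BMI and FFMI are standardized raw. SDS are computed on
each outcome's own analysis sample (outcome non-missing), so per-outcome
n's differ.

## Association models and pooling

All models are OLS on outcome SDS, CIs and p-values from the t
distribution with residual degrees of freedom. The basic covariate set is
child age and sex; the main set adds maternal age, education (binary
lower/higher), prepregnancy BMI, smoking, folic acid use, parity
(nulli/multiparous), child ethnicity (European / non-European) and
breastfeeding (ever/never); birth-size-stratified models add birth
weight. The fetal × infant interaction is tested as the continuous
ΔSDS × ΔSDS product in a basic-adjusted model — one Wald p per outcome
(a categorical 3×3 test would need a multi-df statistic; the continuous
form is the more powerful single-df choice). Strata with fewer than 30
complete rows are flagged and skipped. No multiple-testing adjustment is
performed anywhere.

Missing covariates (never exposures or outcomes) are completed by
chained equations written for this package: Bayesian linear draws for
continuous covariates, logistic models with asymptotic-normal coefficient
draws and Bernoulli sampling for binary ones, ten burn-in sweeps, one
independent chain per imputed dataset, all seeded through a single
`SeedSequence`. Estimates pool by Rubin's rules — mean estimate, total
variance W + (1 + 1/m)·B — with Barnard–Rubin small-sample degrees of
freedom; with zero between-imputation variance the pooled SE equals the
within SE exactly.

## The synthetic cohort generator

The generator defines the study conditions the tests assume; its defaults
are fixed, not tuning knobs.

- **Latent tracking.** Weight SDS across the six time points (20 w, 30 w,
  birth, 6, 12, 24 mo) follow a stationary AR(1) with coefficient 0.7.
  This reproduces both tracking and regression to the mean, so infant
  acceleration is more common after fetal deceleration — the phenomenon
  that makes the decel→accel pattern epidemiologically interesting.
- **Raw measurements.** Fetal EFW is lognormal around a smooth gestational
  age curve (anchored at ~378 g at 20.6 w, ~1622 g at 30.4 w, ~3444 g at
  term); HC/AC/FL are backed out by scaling base biometry curves so the
  Hadlock formula returns the latent EFW exactly. Birth weight is normal
  around a gestational-age- and sex-specific curve (SD ≈ 440 g at term).
  Infant weights sit on per-sex Reed1 curves whose coefficients give PWV
  12.7 (boys) / 11.6 (girls) kg/y — population mean ≈ 12.1 — and the
  population infant length curve is defined implicitly so that log BMI is
  an exact cubic in age peaking at 8.4 months (BMIAP 17.6/17.7): the
  generating process lies inside the trajectory models' function classes,
  so peak-recovery tests measure estimation, not approximation, error.
  Per-child deviations follow a z-score line in age matched to the latent
  SDS at the 6- and 24-month visits, scaled by age-specific SDs.
- **Outcomes.** School-age adiposity measures are lognormal with the
  published-scale medians and spreads, built on height to the same powers
  the indices assume (so the log-log regression genuinely recovers them),
  with a shared latent factor (loading 0.6) inducing realistic
  cross-outcome correlation. Pattern effects (defaults: the decel→accel
  liver-fat effect 0.34 SDS, visceral 0.18, and the full 9-level maps),
  covariate effects, and optional conditional / trajectory / interaction
  effects are injected additively on the log-z scale. Pattern effects
  attach to the pattern at the time point the fallback rule will select,
  so recovery tests quantify measurement error, not source
  misclassification. Trajectory and interaction effects default to zero:
  injecting them alongside pattern effects would confound the pattern
  contrasts, since PWV and the ΔSDS product are correlated with pattern
  membership.
- **Missingness.** Infant availability follows the fallback-chain rates
  (24 mo 66.3%; 12 mo given no 24 mo 40.1%; 6 mo given neither 15.2%;
  complete fetal 71.4%); the 24-month rate and several covariate
  missingness rates are tilted by maternal education with the marginal
  preserved, making the mechanism MAR with signal for the imputation
  model to exploit. Covariate missingness rates mirror the observed
  denominators of the cohort's descriptive table (folic acid ~31%,
  smoking ~20%, education ~8%, …); MRI outcome availability is ~85–95%.

What the generator does **not** emulate: ultrasound/MRI measurement-error
structure beyond Gaussian jitter, secular trends, within-visit
correlated device error, non-European growth references, or dropout that
depends on the outcomes themselves. Passing tests therefore demonstrate
that the statistical machinery is correct under a faithful longitudinal
dependence structure — not that any particular real-world cohort would
yield the same estimates.

## Numerical choices and problem sizes

Residual standardization and all SDs use ddof = 1. Rank deficiency is
detected by pivoted QR and reported with the aliased column names.
Mixed models use ML with lbfgs (tolerance at statsmodels defaults,
maxiter 200). The closed-form peaks are cross-checked against brute-force
grid maximization (steps 1e−4 years / 1e−3 months). Simulation-based
tests use cohorts of 350–3000 children and 5–50 replicate seeds — sizes
chosen so Monte-Carlo error is well below the tolerances asserted — and
the null-calibration check uses 200 replicates of n = 500 with the
pattern contrasts and interaction test pooled. All randomness flows from
explicit seeds; fixed seeds make the suite and the acceptance script
deterministic.

## Known limitations

- Internally fitted charts are binned grids; with few children per bin
  the SDS carry sampling noise that attenuates downstream contrasts (see
  above). Real analyses should prefer external reference charts when
  available.
- The chained-equation imputer assumes linear/logistic conditionals;
  ordinal covariates with more than two levels must be encoded binary.
- The Reed1 mixed model shares C and D within sex; true inter-child
  variation in peak *timing* is therefore absorbed into the intercept and
  linear offsets.
- `run_pipeline` fits the interaction test on the first imputed dataset
  only (its covariates, age and sex, are complete in practice, so
  imputation does not affect it).
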