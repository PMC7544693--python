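# Methods

## Model and construction

The outcome is the Clinical Dementia Rating Sum of Boxes (CDR-SB), a
discrete 0–18 staging score in 0.5-point steps.  All modelling happens on
y = ln(CDR-SB + 0.5); the 0.5 offset admits the zero score and the log
tames the right skew.  Within a cohort, visit j of patient i at t months
since that patient's baseline is modelled as

    y_ij = beta0 + beta1 t + beta2 t^2 + u_i + e_ij,
    u_i ~ N(0, sigma_b^2),   e_ij ~ N(0, sigma_e^2).

The random-effects structure is a patient intercept only — no random
slopes — which treats between-patient heterogeneity as a vertical shift
of one common curve.  Estimation is full maximum likelihood (statsmodels
`MixedLM`, `reml=False`): REML likelihoods are not comparable across
fixed-effect specifications, and the procedure compares linear vs
quadratic time and before/after outlier removal by information criteria.

The continuum is built in three stages:

1. **Per-cohort fits.**  Each severity cohort (SCI, AMCI, ADD) is fitted
   on its own follow-up clock.  The quadratic term is kept iff a Wald
   z-test of beta2 = 0 rejects at alpha = 0.05.  One outlier pass
   follows: conditional studentized residuals are computed as
   (y − fixed part − BLUP intercept)/sigma_e, with the BLUP obtained from
   the closed-form shrinkage sigma_b^2/(sigma_b^2 + sigma_e^2/n_i) of the
   patient's mean marginal residual; observations with |r| > 3 are
   dropped (whole patients only when < 2 visits remain) and the model is
   refitted once.  AIC, BIC and AICC are reported for both stages with
   k = (#fixed effects) + 2 variance components.
2. **Stitching.**  For each consecutive pair, pointwise 95% CIs of the
   earlier cohort's fixed-effect curve are computed at its patients'
   observed times (on the log scale as x'beta ± z·sqrt(x' Cov x), then
   back-transformed — the transform is monotone, so coverage and ordering
   are preserved).  A later-cohort point estimate contained in the union
   of these intervals (the *CI envelope*) is an overlapped score; the
   smallest one is substituted into the earlier cohort's quadratic and
   its unique positive root is the pairwise shift.  The later cohort's
   records are translated to *start* at that time, so shifts accumulate
   additively along the severity order, and any constant added to a
   cohort's clock beforehand is absorbed.  Shifts beyond the earlier
   cohort's observed time range are allowed but flagged as extrapolated.
3. **Continuum.**  The pooled shifted records get the same fit
   machinery (quadratic test + outlier pass).  Milestone times are roots
   of the continuum quadratic at the target scores; transition analyses
   carry the overlap scores and shifts of stage 2.

The continuum clock's origin is the first cohort's t = 0, where the
fitted score is exp(beta0) − 0.5 (≈ 0.44 for the published combined
curve), not exactly 0; "time from 0 to 18" therefore means "from t = 0
to the time the mean curve reaches 18", the only reading under which the
published equations reproduce their published times.  Milestones at or
below the origin score are clamped to t = 0 and flagged, never silently
dropped, so segment durations always telescope.

## Confidence intervals for derived times

Published tables report CIs for milestone and transition times without a
stated method.  The default here is a parametric bootstrap: draw the
fixed-effect vector B times (default 10,000) from N(beta_hat, Cov_hat),
invert each draw, and take percentile bounds; segment-duration CIs use
the same draws' successive differences, so they respect the correlation
between neighbouring milestones.  Draws whose curve never reaches the
target are recorded as missing and excluded from the percentiles (their
count is reported).  A delta-method alternative
(dt/dbeta = −(1, t, t²)/(beta1 + 2·beta2·t)) is available via
`method="delta"` and agrees with the bootstrap to a few percent at
realistic covariance scales.  Transition-score CIs re-evaluate the whole
overlap rule per draw, redrawing both cohorts' mean curves while holding
the per-time CI half-widths at their fitted values; the envelope-union
search is exact (merged intervals), not an endpoints approximation.

## Synthetic-data generator

No public accession exists for the motivating clinic data, so the
package ships a generator with the statistical structure the analysis
assumes.  Its defaults mirror the study design: 85/240/240 patients in
SCI/AMCI/ADD with a 49+36/144+96/185+55 lower/higher education split;
3–6 visits per patient; truncated-normal visit gaps (floor 1 month) with
cohort means 26/16/14 months, placing median follow-up near 80/47/43
months; entry severities drawn uniformly from windows at the cohorts'
typical baseline scores, stratum-specific because the higher-education
group presents milder (SCI 0–0.5 vs 0.5–1.0, AMCI 1.0–1.5 vs 1.0–2.0,
ADD 2.5–4.5 vs 3.0–5.0); and stratum truths equal to the published
lower/higher-education equations.  Entry severities are converted to
latent entry times by inverting the stratum's noiseless curve (scores at
or below the curve origin map to time 0).  Noise is added on the log
scale — matching the model's error structure — before back-transforming,
clamping to [0, 18] and rounding to the half-point grid.  The default
noise scales sigma_b = 0.30, sigma_e = 0.20 (ln units) are not published
values; they were chosen once as plausible for a staging instrument
(between-patient spread of roughly ±35% in CDR-SB + 0.5, visit-level
noise of roughly ±20%) and give per-cohort fits with R²-like behaviour
typical of CDR-SB series.  An optional non-decliner fraction simulates
patients whose score never moves; the decliner filter excludes a patient
iff last − first score ≤ 0 over follow-up (the net-change reading of "no
decline", chosen because the sensitivity analysis treats these patients
as one class; a pointwise-constant reading would misclassify noisy
fluctuating series).

Each synthetic visit carries `latent_time` (true position on the disease
clock) purely as a test oracle; no inference stage reads it.

What the generator does *not* emulate: attrition and death, visit-time
informative of severity, rater effects, practice effects, floor/ceiling
response styles, or correlation between education and follow-up length.
Passing tests therefore demonstrate correctness of the machinery under
the stated generative model, not robustness to every feature of real
clinic data.

## Numerical choices and degenerate inputs

* Exactly noiseless input (data on one polynomial) makes the mixed-model
  likelihood unbounded; `fit_lmm` detects a numerically zero residual sum
  of squares and returns the exact least-squares interpolant with
  sigma_b = 0 and sigma_e clamped to a tiny positive value, so the
  zero-noise limiting cases remain representable.
* Quadratic inversion uses the explicit positive root; targets below the
  curve origin raise ("target precedes model origin"), as do negative
  discriminants.  `invert_trajectory` round-trips with the mean
  prediction to ≤ 1e-9.
* Fits are invariant to row order and patient relabeling (rows are
  canonically sorted before fitting); the fit is cross-checked against
  R lme4 to ~6 significant digits on a fixture.
* All randomness flows from one seed through `numpy.random.SeedSequence`
  spawning, so every pipeline artifact is byte-reproducible from
  (config, seed); the config hash excludes the output directory.

## Problem sizes used by the test-suite simulations

Simulation-based checks are scaled to what the properties need, chosen
up front: stitching recovery uses 200 patients/cohort with entries at
0/110/170 months on the latent clock; CI-coverage uses 100 replicates of
200 patients; the quadratic-test size check uses 1000 replicates of 60
patients; pipeline-level checks run the default design at 20–50% patient
counts.  Calibration simulations disable score rounding: with the small
residual scales probed there, half-point rounding would dominate the
error budget and test the instrument's discretization rather than the
estimator.

## Known limitations

* The overlap rule inherits the envelope reading of "falls within the
  CIs": containment is checked against the union of per-time intervals,
  the weakest faithful interpretation; pairing times differently would
  give slightly different shifts.
* The stitched clock is anchored at the first cohort's baseline mix, so
  absolute milestone times depend on where that cohort enters the
  disease; between-stratum comparisons are meaningful because each
  stratum is anchored the same way.
* Transition-time uncertainty ignores uncertainty in the CI half-widths
  (variance parameters) and in cohort composition; a full hierarchical
  bootstrap would be wider.
* The selection induced by the decliner filter steepens fitted curves
  relative to the generating truth; this mirrors the analysed estimand
  (progressors only), not a bug, but it means generator coefficients are
  not recovered verbatim by the end-to-end pipeline.
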