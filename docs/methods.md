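# Methods

This note documents the statistical procedures, the synthetic-data model,
and the numerical and design choices behind `deprisk`.

## Outcome and predictor coding

Depression at each wave is classified from nine binary DSM-IV
major-depression symptom items: positive iff at least five items are
endorsed *and* at least one of the two core symptoms (item 0 depressed mood,
item 1 anhedonia) is among them. The implementation is checked against a
brute-force enumeration of all 512 symptom vectors.

The seven predictors are coded as in the source surveys: school failure
(ever repeated a class), social isolation (zero close friends), fights
(started a fight *and* hurt someone on purpose), ran away from home, drug
use (any use of alcohol, cigarettes or marijuana), biological sex, and an
ordered maltreatment factor — *severe* if "a lot" of domestic violence or
physical abuse, else *probable* if "a little" of both or not living with any
biological parent, else *none*. The rule set defines only the severe and
probable categories positively; mixed answers ("a little" on exactly one
exposure item while living with a parent) are therefore coded *none*. This
is a deliberate conservative reading; the alternative (coding such cases
probable) would raise the probable marginal above its documented value.

Missing values in any coding input exclude the record (complete-case) with a
per-column audit; no imputation is attempted. Sample selection applies an
inclusive integer age window (default 14–16) and then removes respondents
depressed at baseline, recording counts at every stage.

## Penalized logistic model

The risk model maximizes the Bernoulli log-likelihood minus
`penalty/2 · Σ βj²` over the slope coefficients; the intercept is never
penalized, so the fitted average risk is unbiased at any penalty and the
infinite-penalty limit is the intercept-only model at the observed log-odds.
Maltreatment enters as two dummies (reference *none*) rather than a linear
score: the ordered factor's two contrasts are cheap and make no linearity
assumption across its levels.

Fitting is Newton/IRLS with step-halving on the penalized objective,
convergence at a maximum coefficient change below 1e-8, and at most 100
iterations. Non-convergence raises an error carrying the step-size trace.
At penalty 0 a diverging coefficient norm (>30 on the log-odds scale for
binary predictors) is diagnosed as outcome separation and reported with the
advice to refit with a positive penalty. The penalty-0 path is verified
against an independent zooming-grid likelihood maximizer and against
scikit-learn's ridge logistic regression (C = 1/λ) in the test suite.

The default penalty is chosen by 10-fold stratified cross-validated deviance
over the grid {0, 0.25, 0.5, 1, 2, 4, 8, 16} with a fixed fold seed; a grid
point at which any training fold separates is assigned infinite deviance.
The grid is coarse by design — held-out deviance is flat near its minimum
and the model has only eight terms. An explicit `--penalty` override exists
because the original tuning rule for this kind of model is generally not
reported.

## Validation regimes

* **Standard:** coefficients frozen; the linear predictor is evaluated on
  the new cohort as-is.
* **Adjusted:** the intercept is shifted by the maximum-likelihood
  offset-intercept `a` fitted on the validation data; slopes untouched.
  CITL of the adjusted model on the same data is zero by construction
  (score equation), and its AUC is bit-identical to the standard regime.
  Adjustment is idempotent to optimizer tolerance.
* **Refitted:** all coefficients re-estimated on the validation cohort.
  The default refit is unpenalized, which makes the in-sample CITL = 0 and
  slope = 1 identities exact; a penalized refit is also supported (its
  in-sample slope then exceeds 1 in proportion to the shrinkage), because
  published refits are not always plain ML and both behaviours are worth
  having on hand.

All regimes on one dataset share a single stream of stratified bootstrap
resample indices, so AUC confidence intervals are paired across regimes.
Age-window sensitivity analyses rerun selection and all three regimes per
inclusive window; windows selecting nobody are skipped with a warning, and
windows under 50 records still report metrics but omit the smoothed curve.

## Performance panel

**CITL** is defined on the logit scale via the offset-intercept fit, not as
a probability-scale difference; this makes the adjusted regime's zero an
exact identity and matches standard recalibration practice. The
probability-scale difference `mean(y) − mean(p)` is exposed alongside as a
secondary field.

**AUC** uses the midrank formula (ties count one half) and is tested against
an O(n²) pairwise oracle. The **bootstrap CI** is a stratified percentile
interval, B = 2000 by default, resampling cases and non-cases separately
(which also guarantees both classes in every resample); "bootstrap
corrected" interval variants differ between publications, and the percentile
form was chosen as the most transparent.

The **unreliability test** is a likelihood-ratio test (not Wald or score):
twice the log-likelihood gap between the free recalibration fit `(a, b)` and
the fixed ideal `(0, 1)`, referred to chi-square with 2 df. Its type-I
error is verified at n = 2000 over 1000 null simulations.

The **flexible calibration curve** is a hand-rolled local-linear smoother:
at each of 100 grid points spanning the observed probability range, the
nearest `span` fraction of observations (default 0.75) is tricube-weighted
and a weighted line fitted; the pointwise variance combines the smoother's
equivalent-kernel weights with the binomial variance `f(1−f)` of the
smoothed value, giving 95% bands clipped to [0, 1]. Decile
(mean-predicted, observed-rate) points are attached for plotting. No
installed library exposes a loess with standard errors suited to this use,
hence the in-package implementation.

**Wilson intervals** for prevalences come from `scipy.stats.binomtest`.

## Synthetic cohorts

The generator's defaults are the study conditions, not tuning knobs:

* validation predictor marginals — female 49.4% (male 50.6%), school
  failure 25.8%, fights 3.9%, drug use 6.0%, social isolation 4.4%, ran
  away 2.3%, maltreatment probable 18.4% / severe 6.7%;
* validation follow-up prevalence 11.8%; development prevalence 3.1%;
* default validation shrinkage k = 0.64 on the effective coefficients,
  emulating the over-fitted transport setting (standard-regime slope well
  below 1).

The generating log-odds coefficients are not published for this kind of
model, so the package fixes a plausible default once — sex 0.55,
maltreatment probable 0.45 / severe 0.90, school failure 0.40, isolation
0.65, fights 0.55, ran away 0.75, drug use 0.50 — chosen as moderate
adversity effects that yield discrimination in the low-to-mid 0.6 AUC range
at these marginals, the regime typical of sociodemographic-only depression
models. They are package constants, documented here, and all
parameter-recovery tests condition on them rather than assuming particular
values.

Outcomes are Bernoulli draws from `logit⁻¹(c + k·x'β)`. The intercept `c`
is solved so the population mean probability equals the target prevalence:
the expectation is Monte-Carlo (a fixed 200,000-vector predictor draw, so
the objective is smooth and monotone) and the root is found by Brent's
method to 1e-6. When a target prevalence is given, any intercept drift
would be absorbed by this solve, so drift only applies together with an
explicit base intercept; the miscalibration-recovery tests use that path via
`inject_miscalibration` (coefficients × k, intercept + drift).

Predictors are generated independently — only marginals are documented for
the real cohorts, and no joint distribution is assumed. A Gaussian-copula
correlation hook (7×7 latent correlation, thresholded; one latent with two
cut-points for the ordered maltreatment factor) exists for stress tests.

The raw-survey fixture assigns the selection-flow counts deterministically —
3171 followed up, the first 2321 inside the age window, 393 of those
baseline-depressed, the remaining 1928 split 976 male / 952 female — then
shuffles row order and draws every item-level field reproducibly from the
seed. Symptom vectors are drawn conditional on the intended depression
status (depressed: 5–9 items including a core symptom; not depressed:
usually ≤ 4 items, occasionally ≥ 5 without a core symptom), and the raw
adversity/substance/friendship items are drawn from the preimage of each
coded value, so re-coding the raw records reproduces the coded cohort
exactly. The flow counts live in a named `RawSurveyFlowSpec`, not in the
generator logic.

### What the generator does and does not emulate

It reproduces marginal predictor frequencies, a prevalence shift between
cohorts, coefficient shrinkage on transport, and the exact selection flow.
It does **not** model school-level clustering or the sampling design,
predictor correlations (unless supplied), item-level nonresponse mechanisms,
or the four development-only predictors' real distributions (extra
predictors for rebuild tests are generic Bernoulli(0.2) variables with
coefficient 0.3). Passing tests therefore demonstrate the correctness and
statistical behaviour of the pipeline under these idealized conditions, not
the real cohorts' values of the transported metrics.

## Problem sizes and determinism

Simulation-based checks use n = 50,000–100,000 for parameter-recovery
assertions (slope recovers 1/k within ±0.1; CITL recovers −drift within
±0.05), n = 2000 × 1000 replicates for the unreliability test's type-I
error, and a 5-replicate average of n = 50,000 draws for the
slope-of-the-true-model anchor, which keeps the Monte-Carlo standard error
(≈ 0.014) well inside the ±0.05 tolerance. Every stochastic component —
cohort draws, bootstrap resampling, CV folds — is driven by named integer
seeds, and identical configurations produce byte-identical CSV/JSON output.

## Known limitations

* The ridge penalty is the only penalized-ML variant offered; L1 and
  elastic-net fits are out of scope.
* The calibration smoother's bands are pointwise, not simultaneous, and use
  a plug-in binomial variance rather than a full sandwich estimate.
* The bootstrap CI is percentile; BCa and optimism-corrected variants are
  not implemented.
* Development-cohort size (default 10,000 at 3.1% prevalence, ≈ 300 events)
  was chosen to give a stable 8-term penalized fit; much smaller development
  samples will make the cross-validated penalty noisy.
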