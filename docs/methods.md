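# Methods

`omicox` implements a sex-specific multi-omics extension of a clinical
10-year cardiovascular risk model for adults with type-2 diabetes, under a
case-cohort design, together with a synthetic cohort generator that emulates
the statistical structure such a study assumes.  This note records the
models, the defaults and why, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## Case-cohort design and Barlow weighting

The analysis sample is a random sub-cohort of the full T2D cohort plus every
case outside it.  All Cox models use Barlow's original inverse-probability
weights: a non-case sub-cohort member carries weight 1/α throughout
follow-up (α = realized sub-cohort sampling fraction), a sub-cohort case
carries 1/α before its event and 1 at it, and a case outside the sub-cohort
has pre-event weight 0 — it enters the risk set only at its own failure
time.  With α = 1 every weight is 1 and the machinery reduces exactly to the
ordinary Cox model (tested).

Estimation maximizes the weighted Breslow partial likelihood by
Newton–Raphson with step-halving (the weighted likelihood never decreases
across iterations).  Convergence requires max |score| ≤ 1e−8 or a relative
log-likelihood change ≤ 1e−10; non-convergence is flagged on the result.
Ties are handled by Breslow's approximation — the standard choice in
weighted/case-cohort pseudo-likelihood software.  Model-based standard
errors (inverse information) are reported alongside robust sandwich errors
built from per-subject weighted score residuals; the robust errors are the
default for inference because the weighted pseudo-likelihood is not a true
likelihood.  In 200 simulated case-cohort draws (sub-cohort fraction 0.2 of
n = 8000) the weighted estimates show < 1% relative bias against the
full-cohort fit and 93–95% robust-CI coverage.

Absolute 10-year risks are 1 − exp(−H₀(10)·exp(lp)) with H₀ the weighted
Breslow baseline cumulative hazard and the linear predictor centered at the
fitting sample's weighted covariate means, so a subject at the mean has risk
1 − exp(−H₀(10)).

Per-biomarker associations are reported as hazard ratios per one SD
increment, with the SD computed using the subject-level Barlow weights
(cases outside the sub-cohort count with weight 1); this weighted
standardization is the default and switchable, since either convention is
defensible.

## Penalized selection

The LASSO-penalized weighted Cox model minimizes
−loglik(β)/n + λ·Σⱼ pfⱼ|βⱼ| where the eight clinical base covariates are
force-included (penalty factor 0) and only omics features are penalized.
The solver is glmnet-style: iteratively reweighted least squares around the
current linear predictor using the diagonal Hessian of the weighted Breslow
likelihood, cyclic coordinate descent with soft-thresholding on the working
problem, warm starts along a decreasing λ grid, and active-set iteration.
Every returned path point is certified against the exact KKT conditions of
the penalized objective to 1e−7 (the tests assert 1e−6).  The solution was
additionally cross-checked against R glmnet: with no penalty factors the
coefficient paths agree to ~1e−5; with penalty factors glmnet internally
rescales them to sum to the number of predictors, which is a pure
reparametrization of λ.

Numerical defaults: 100 λ values log-spaced from λ_max (the smallest λ at
which every penalized coefficient is zero, computed from the gradient at the
forced-covariates-only fit) down to 0.001·λ_max; coordinate-descent
tolerance 1e−10 on the weighted squared coefficient change; the path stops
early once the active penalized set exceeds `dfmax` (glmnet's device; 45
during stability selection, where the cross-validation optimum sits far
inside that boundary — verified ~17 active at λ_min under the recovery
conditions below).  Penalized predictors are standardized by the weighted
mean/SD of the fitting (re)sample; coefficients are reported on the native
scale.

λ is chosen by 10-fold cross-validation minimizing the cross-validated
partial-likelihood deviance in the Verweij–van Houwelingen form
(−2·[ll_full(β₋ₖ) − ll_without-fold-k(β₋ₖ)]); the basic fold-wise form is
available.  Folds are stratified on event status because per-sex event
counts are small.  Fold fits use a relaxed certification tolerance (3e−4);
this leaves the deviance curve — a statistical quantity with sampling noise
orders of magnitude larger — unchanged (identical λ_min in direct
comparison) while saving reweighting rounds.

## Bootstrap stability selection

For each of B resamples (study protocol B = 1000; the bundled analyses and
tests run desk-scale B = 50–100), subjects are drawn with replacement
stratified jointly on case status and sub-cohort membership, so the design
composition — and hence α — is preserved and the Barlow weights remain
well-defined per resample.  Standardization and λ (by 10-fold CV) are
recomputed inside every resample; the active penalized set at λ_min is
recorded.  Features selected in ≥ 95% of resamples are retained and refit
unpenalized together with the clinical base covariates, per sex.

A caveat the simulations make explicit: because all resamples share the
same underlying dataset, a null feature that is strongly chance-correlated
with the outcome *in that dataset* is selected by λ_min in nearly every
resample, and no amount of resampling can reject it.  Under the recovery
conditions (4 planted proteins with |β| ≥ 0.4/SD among 150 nulls, n = 1500,
~15% events, B = 100) the planted signature is recovered in full in every
run, but roughly half the runs additionally retain exactly one such
chance-correlated null whose selection frequency sits at or above 0.95 —
occasionally at 1.0, where even B = 1000 cannot help.  The retained-set
false-positive rate is therefore a property of λ_min's permissiveness at
these dimensions, not of the resample count; a sparser rule (e.g. the
1-SE rule) would trade it against sensitivity but is not what the protocol
specifies.  Under pure noise the retained set is empty in most runs, with
the same rare exception.

## Missing data

QC first removes omics features with > 20% missing values or > 25% of
values at/below the detection limit (strict inequalities; a feature at
exactly 20% is retained).  Remaining missing values — clinical covariates
and omics alike, in one pass — are singly imputed by iterative
random-forest chained equations: initialize with mean/mode, visit incomplete
variables in order of ascending missingness, re-predict each from all
others with a random forest (scikit-learn, 100 trees by default), and stop
at the first iteration where the normalized change statistic (normalized
squared difference for continuous, disagreement proportion for categorical)
increases, returning the previous iterate.  Observed cells are never
altered.  Out-of-bag error estimates (√(1−R²_OOB) for continuous, OOB
misclassification for categorical) are reported per variable.  The outcome
columns are not used as imputation predictors, so imputed covariates cannot
leak follow-up information into the risk models.

## Evaluation

Harrell's C is computed by exact pair counting: a pair is comparable when
the earlier time carries an event (time ties: event vs censored only);
score ties count 1/2.  It is computed unweighted on the analysis sample by
default — matching standard practice — with the case-cohort-weighted
variant available behind a flag.  The difference between two correlated
C-indices on the same subjects is tested with a U-statistic variance
estimator: both C's share the comparability kernel, per-subject Hájek
projections give the influence values, and the variance of the difference
follows by the delta method (the approach of Kang and colleagues for paired
concordance estimators).  Its empirical type-I error at nominal 0.05 is
~0.05–0.06 over 500 null replicates at n = 400.

NRI (categorical, with absolute-risk categories 0–15%, >15–30%, >30%, and
category-free) and IDI handle censoring at the 10-year horizon through
Kaplan–Meier conditional event-status weights: an observed event by the
horizon contributes weight 1, a subject followed beyond it weight 0, and a
subject censored at c < 10 contributes (S(c) − S(10))/S(c) from the overall
KM curve.  With no censoring before the horizon these reduce exactly to the
classical proportions, which is what the hand-enumerated test fixtures
exercise; zero-at-identity and antisymmetry under model swap hold exactly.
Confidence intervals are percentile bootstrap (1000 resamples by default,
seeded).  Calibration tables use equal-count bins of predicted risk with
KM-observed event rates; rank-based tie-breaking keeps identical risks in a
single effective bin.  One consequence of computing observed rates
unweighted on the analysis sample: a case-cohort sample over-represents
cases, so its raw KM event rates sit above the Barlow-weighted model's
population-calibrated predictions in the middle deciles — visible in the
bundled runs, and expected; calibration is self-consistent (max per-decile
gap < 0.03 at n = 10000) when predictions and observations come from the
same unenriched cohort.

## Two-stage pipeline

Stage 1 derives sex-specific protein signatures on the larger proteomics
case-cohort sample (~1751 subjects).  Stage 2 works on the nested
complete-multi-omics subset (~56.5% of subjects, ~990): each single-layer
extension (proteins, metabolites, polygenic score) is compared to the
clinical base model with the correlated-C test on pooled sex-specific
risks; the largest statistically significant ΔC becomes the reference, and
remaining layers are added greedily while the test stays significant
(two-sided p < 0.05).  The significance gate is discrimination only — NRI
and IDI are reported at every step but do not drive the stopping rule.
"Overall" metrics pool the per-sex predicted risks rather than fitting a
single pooled model; the layering can also be run entirely within one sex.

## Synthetic cohort generator

The generator emulates the study's data structure, not its biology:

- **Design arithmetic.** Full cohort n = 2365 with sub-cohort fraction
  0.707 gives a ~1672-subject sub-cohort plus ~79 outside cases → a
  case-cohort sample of ~1751 with ~15.4% observed events.  The full-cohort
  size is derived from the design itself: the sub-cohort event fraction
  (191/1672 ≈ 11.4%) estimates full-cohort incidence, and ~79 outside cases
  then imply n ≈ 1672 + 79/0.114.  Sex ratio 59.7% male.
- **Covariates.** A Gaussian copula on the latent scale hits the configured
  Spearman targets (converted by r = 2·sin(πρ/6); positive-definiteness is
  checked and violations rejected naming the offending pairs).  Clinical
  marginals use the cohort's means/SDs (age 60.3 ± 6.6, SBP 144.5 ± 17.7,
  …); smoking is thresholded at 10.7% prevalence.  Omics features stay on
  the standardized latent scale.  Defaults plant one strong within-layer
  protein pair (ρ = 0.64) and weak (≤ 0.47) cross-layer links.
- **Effects.** Sparse sex-specific protein effects (four male-only, three
  female-only, one shared, 0.35–0.5 per SD), male-only metabolite effects
  (0.45, 0.35) and a male-only polygenic-score effect (0.3) — the
  qualitative sex asymmetry the pipeline is designed to detect, at effect
  sizes chosen so the stage-2 tests have reasonable power at n ≈ 990.
- **Event times.** Sex-specific Weibull proportional hazards (shape 1.3),
  with the scale calibrated by deterministic bisection so the mean observed
  event probability by 10 years (including exponential dropout at 0.008/yr
  and administrative censoring at 10) hits the sex-specific targets (male
  13.7%, female 8.1%, weighted mean ≈ 11.4%).
- **Missingness.** MAR masking whose probability depends only on age and
  sex (both always observed), with intercepts solved so marginal rates meet
  the per-variable targets (HDL-C 12.0%, HbA1c 6.9%, age at diagnosis 6.6%,
  eGFR 6.0%, total cholesterol 5.8%, smoking 0.8%, SBP 0.3%, plus two
  proteins at 22%/15%).  Two proteins carry left-censoring at a detection
  limit (30%/10% below LOD) so the QC filter has work to do.
- **Scale.** 150 protein columns rather than the thousands of a real
  proteomics panel: the selection problem's difficulty is governed by the
  number of chance-correlated nulls relative to events, and 150 already
  exhibits the relevant failure modes while keeping the bootstrap-LASSO
  loop tractable on one CPU.

What passing tests show: the estimation machinery is unbiased and
calibrated under the design it assumes, selection recovers planted signals,
and the layering logic reproduces the intended sex asymmetry.  What they do
not show: robustness to model misspecification (non-proportional hazards,
non-Gaussian copulas, informative censoring, MNAR missingness), assay
artifacts, or anything about real biology.

## Problem sizes used in the bundled runs

Stability selection runs at B = 100 in the validation suite and B = 50 in
the end-to-end analyses (study protocol: B = 1000); reclassification CIs
use 200–1000 bootstrap resamples; the imputation forest uses 30–50 trees in
the end-to-end runs and 100 by default.  These sizes are stated here once;
the analysis scripts take `--B`/`--rf-trees` to run at protocol scale.
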