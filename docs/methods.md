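# Methods

## Problem setting

A psychosis-risk screening interview rates 60 symptom items, grouped into
four positive-symptom scales, on 0–6 severity and 0–6 frequency scales.
Per-item cutoffs dichotomize each (severity, frequency) pair into a
risk indicator; a participant meets clinical-high-risk (CHR-P) criteria
if **any** item is positive, and crosses the psychosis threshold if any
item reaches psychosis-level severity (such participants are excluded
from the binary CHR-P vs not-at-risk analysis set).  The package derives
a *short form* — a subset of items whose any-item rule approximates the
full instrument — and quantifies its diagnostic and downstream prognostic
accuracy.

The published cutoff tables are not reproduced here; the shipped default
(severity positive in [3, 5], frequency ≥ 3, psychosis severity ≥ 6) is a
documented stand-in, and every pipeline stage reads cutoffs from the
instrument configuration rather than assuming them.

## Item selection

Selection runs inside five-fold nested cross-validation.  Within each
outer training portion (four folds), an L1-penalized logistic regression
of the CHR-P label on the dichotomized items is tuned over a descending
log-spaced grid of 100 penalties from λ_max (the smallest penalty that
zeroes every coefficient, computable from the data) down to λ_max·10⁻⁴.
The tuning criterion is inner five-fold cross-validated binomial
log-likelihood; exact ties resolve to the smaller λ.  The model is refit
on the whole training portion at the chosen λ and items with nonzero
coefficients (|β| > 10⁻¹⁰, guarding against solver epsilon) are recorded.
Items retained in ≥ 4 of the 5 outer folds form the **mini** set; items
retained in all 5 form the **ultra** set.

Numerical choices:

- Objective convention (1/n)·NLL + λ‖β‖₁ with unpenalized intercept,
  mapped onto scikit-learn's liblinear solver via C = 1/(n·λ) and a large
  intercept scaling.  λ = 0 degrades to an effectively unpenalized fit.
- Binary 0/1 predictors are **not** standardized before penalization;
  standardizing indicator columns would reweight rare items and change
  the selection.
- Outer and inner folds are stratified by outcome and fully seeded
  (≈111 events over 5 folds need balancing).
- Columns constant within a training portion or inner fold carry no
  signal there and are masked for that fit.

## Detection performance

A candidate subset is evaluated against the full-scale label by repeated
nested cross-validation: 5 repeats × 5 outer folds = 25 fold-level metric
sets, each repeat splitting with seed + r.  Two predictions coexist per
fold:

- the **threshold-0 rule** (positive iff any subset item endorsed)
  supplies κ, sensitivity, specificity, balanced accuracy, PPV, NPV and
  F1.  Because a subset endorsement is also a full-scale endorsement,
  this rule *structurally* forbids false positives: specificity and PPV
  are identically 1 whenever defined.
- an L1-logistic model refit on the training portion restricted to the
  subset items supplies predicted probabilities for Harrell's C
  (equal to AUC for a binary outcome; ties count 0.5).

Fold metrics are pooled as arithmetic means with normal-approximation
95% CIs (mean ± 1.96·sd/√k over non-missing folds).  Fold metrics are
not independent; the CI is reported without correction, matching common
practice for repeated-CV summaries.  Undefined ratios (zero denominator)
are reported as missing with a warning and excluded from pooling, never
silently zeroed.

## Prognostic composition

The short form is validated against the full instrument, while the full
instrument's 2-year accuracy for predicting transition to psychosis is
known meta-analytically.  Composing the two tests:

    Se_prog = Se_meta·Se_sub + (1 − Sp_meta)·(1 − Sp_sub)
    Sp_prog = Sp_meta·Sp_sub + (1 − Se_meta)·(1 − Se_sub)

Uncertainty propagates by Monte Carlo (default 10,000 draws): each
accuracy is drawn from a beta prior fitted by method of moments to its
reported mean and 95% CI, reading the CI width as 2×1.96 standard errors
(v = ((hi − lo)/3.92)²; α = m·(m(1−m)/v − 1), β = (1−m)·(m(1−m)/v − 1)).
The fit preserves the reported mean exactly, so the Monte Carlo mean
converges to the product-form composition of the reported means.
Accuracies reported as exactly 1 (the threshold-0 rule's specificity)
enter as fixed values with no sampling variability.  Draws are sampled
independently across the four priors.  Summaries are means and
percentile-bootstrap 95% CIs of the mean (1,000 resamples).

Two meta-analytic prior presets are shipped, reflecting two published
estimate sets: `metapooled` (Se 0.93, CI 0.87–0.96; Sp 0.58, CI
0.50–0.66) and `meta2y` (Se 0.86, CI 0.76–0.92; Sp 0.55, CI 0.48–0.63).
Neither is privileged; both are named configurations.  Short-form
diagnostic-sensitivity presets are `mini` (0.956, CI 0.938–0.974) and
`ultra` (0.944, CI 0.923–0.965), and in the full pipeline the prior is
instead taken from the pooled cross-validated estimate of the run.

## Synthetic cohorts

No interview cohort ships with the package; the generator produces
seeded cohorts with the statistical skeleton the pipeline assumes:

- n = 490 participants; ~23% CHR-P prevalence; ~2.5% psychosis-threshold
  cases; 80% female; 73% White; ages 12–35 (mean ≈ 23.8, SD 5).
- a single latent risk trait t ~ N(0, 1); item j endorsed with
  probability sigmoid(a_j·t − b_j) (two-parameter logistic link).
- 23 **informative** items (a = 2.0) with marginal endorsement rates
  spread over ~5–20%; their difficulties receive a common calibration
  shift, solved by Brent root-finding on a Gauss–Hermite quadrature of
  the any-item probability, so the full-scale positive share hits the
  prevalence target (quadrature/rootfinding tolerance ~10⁻¹⁰).
- 6 **silent** items that are never endorsed — four from the
  disorganized-speech scale and one each from non-bizarre ideas and
  perceptual abnormalities — reproducing the zero-variance pattern of
  real interview data.
- 31 **noise** items that are rare (target rates 0.7–1.2%) and sharply
  trait-thresholded (a = 8.0): their endorsers are the most severely
  affected participants, who almost always also endorse informative
  items.  This emulates the empirical behaviour of the items a short
  form drops — rarely endorsed, and usually redundant with retained
  items — and is what makes fold-consistency selection testable: a
  near-independent noise model cannot simultaneously keep all 60 columns
  non-degenerate at n = 490, keep an informative-item subset ~95%
  sensitive, and leave noise items unselected, because under the
  any-item labelling every endorsed column is structurally predictive.
- severity/frequency ratings are sampled consistently with the intended
  binary endorsement (positive items draw severity inside the positive
  range with a trait-graded distribution and frequency above the cutoff;
  negative items stay below the severity range), so dichotomization
  reproduces the endorsement matrix exactly, and total severity
  separates predicted classes realistically.
- demographics are sampled independently of the trait; a bias-scenario
  variant adds a configurable shift to one stratum's trait mean for
  auditing.

What the generator does **not** emulate: multi-factor symptom structure
(correlations beyond the single trait), two-stage pre-screened
recruitment, item-level missingness, distress/onset ratings, and the
genetic-risk (GRD) pathway to risk status.  Passing tests therefore show
that the pipeline recovers the structure this model encodes — not that
the particular items selected on any real cohort are correct.

## Post-hoc analyses

- **Misclassification**: full-scale positives negative under the subset
  rule, with the endorsement count and share of each omitted item among
  them.
- **Severity contrast**: Welch two-sample t-test (Welch–Satterthwaite
  degrees of freedom) of total raw severity between predicted classes,
  with the 95% CI of the mean difference.  "Total severity" is the sum
  of per-item severity ratings — an interpretation, since aggregate
  severity scores can be defined in several ways.
- **Fairness audit**: detection metrics recomputed within demographic
  strata (sex; White vs non-White) of each test fold, models fit on all
  training data without stratum-specific refits — refitting per stratum
  would change the estimand from bias auditing to subgroup modelling.
  Strata with a single outcome class are reported as not evaluable.

## Reproducibility and problem sizes

All randomness descends from explicit integer seeds; the experiment
runner splits a single root seed into named substreams (generation,
splitting, evaluation, simulation, audit), so identical configurations
reproduce byte-identical reports.  The test suite exercises selection at
n = 2,000 with 12 informative items (parameter recovery over 10 seeds),
evaluation and audits at n = 250–3,000 with reduced λ grids, and the
prognostic Monte Carlo at its full 10,000 draws; these sizes were chosen
to make the suite's statistical assertions stable while keeping each
module's checks proportionate to what they demonstrate.

## Known limitations

- The cutoff stand-ins are not the published clinical thresholds;
  analyses on real data must supply the licensed cutoff table via the
  instrument YAML.
- The CV-pooled CI treats fold metrics as independent; it understates
  variance.
- "Partial likelihood" tuning is read as cross-validated binomial
  log-likelihood (the deviance-minimizing λ convention); for a binomial
  outcome this is the natural reading of a term that originates in
  proportional-hazards models.
- The prognostic composition assumes the short form's errors are
  independent of the full instrument's prognostic errors, and composes
  marginal accuracies only.
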