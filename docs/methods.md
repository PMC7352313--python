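# Methods

`seropanel` implements a wrapper-style discovery procedure for multi-marker
serum diagnostic panels in a case-control setting, modeled on the workflow
used for pancreatic ductal adenocarcinoma (PDAC) screening panels: an
exhaustive search over all non-empty subsets of a candidate marker list, a
five-algorithm classification suite scored by cross-validated ROC AUC, and a
cascade of stability filters that prefers panels performing consistently
across data splits and across learning algorithms. Because the package is
meant to be testable without access to patient sera, it also ships a
synthetic cohort generator with a *planted* informative marker set, giving
every downstream stage a known recovery target.

## The pipeline

Given a subject-level table (marker concentrations, age, sex, case/control
label, and AJCC stage 1-4 for cases):

1. **Screen (descriptive).** Each marker is compared between cases and
   controls with a two-sided Wilcoxon rank-sum / Mann-Whitney U test; markers
   with p < 0.01 are flagged. The screen is reported but does not prune the
   search: the exhaustive enumeration runs over the full candidate list, so
   a non-significant marker can still appear in candidate panels (and its
   failure to survive selection is itself informative). A small-sample exact
   null (full enumeration, used when both groups have ≤ 8 tie-free
   observations) backs the p-values; otherwise the normal approximation with
   tie and continuity corrections is used.
2. **Preprocess.** Marker values are replaced by their natural logarithms
   (the screen is rank-based and unaffected; classifiers see
   location-shifted, roughly Gaussian features). Age is categorized into
   left-closed decade bins (<40, 40-49, 50-59, 60-69, 70+) and one-hot
   encoded against the youngest bin; sex enters as a male indicator.
3. **Split.** Subjects are assigned at random to training/validation within
   each label stratum, with the training count fixed at
   round(train_fraction × stratum size) (round half up; the default 2:1
   split of 180 cases / 573 controls gives exactly 120/382 training and
   60/191 validation subjects). Only membership is random; counts are
   deterministic.
4. **Enumerate.** All 2^n − 1 non-empty marker subsets, in size-then-
   lexicographic order (11 candidates → 2047 panels). Panels serialize as
   '+'-joined sorted names.
5. **Evaluate.** Every panel × algorithm is scored three ways: pooled
   out-of-fold scores from a stratified k-fold CV on the training set
   (`train_cv`, default k = 10), resubstitution scores of the full training
   fit (`train_resub`), and validation scores of that same fit
   (`validation`). Sensitivity/specificity/accuracy are reported at a fixed
   operating point: the threshold is the smallest training control order
   statistic achieving the target specificity (default 0.95) and is
   transported unchanged to validation — validation metrics are never
   re-thresholded. Per-stage sensitivities are computed within each stage's
   cases at the same threshold.
6. **Select.** The cascade: (i) rank panels by mean `train_cv` AUC across
   the five algorithms and keep the top fraction (default 10%, ceiling);
   (ii) keep panels containing the mandatory clinical markers (default CEA
   and CA19-9); (iii) keep panels whose |train_cv − validation| AUC gap is
   ≤ max_gap (default 0.02) for *every* algorithm; (iv) pick the panel with
   the largest minimum validation AUC across algorithms, ties broken by the
   smaller standard deviation of those AUCs, then fewer markers, then the
   canonical string. Every stage's survivors and all parameters are recorded
   in a JSON-serializable ledger.

## The classifier suite

Five algorithms behind one fit/score contract (`PanelClassifier`, a
scikit-learn estimator; scores are probability-scale, higher = more
case-like):

- **GLM** — unpenalized logistic regression (Newton solver, iteration-capped
  so separable folds terminate; scores are fitted probabilities).
- **RIDGE** — L2-penalized logistic regression on standardized features; the
  penalty is chosen by internal stratified 3-fold CV over a small grid
  (AUC criterion) unless a fixed `ridge_C` is supplied.
- **SVM** — RBF support vector machine on standardized features
  (C = 1, gamma = 'scale'); margins are mapped to [0, 1] by a logistic
  sigmoid. The map is strictly monotone, so AUC and every rank-based
  quantity are unaffected by the calibration choice; only the numerical
  threshold value is.
- **RF** — random forest (default 500 trees, √p features per split); the
  score is the fraction of trees voting case, hence takes at most
  n_trees + 1 distinct values — relevant for ties at the operating threshold
  (strict '>' casing) and for AUC granularity.
- **GLM_RF** — the unweighted mean of the GLM and RF probability scores, a
  linear/non-linear combination. Inside the search loop the two member fits
  are computed once and averaged; fold assignment is shared across
  algorithms within a panel so the combination is well defined out-of-fold.

Randomized fits derive their seeds from (global seed, algorithm, fold) via
a stable cryptographic hash, and the CV fold assignment is likewise derived
once per run: every candidate panel is scored on identical folds with
identical estimator randomness, the paired design scikit-learn's own model
selection applies to candidate configurations. The pairing matters
materially here: the cascade's final stage compares near-tied panels by
their minimum validation AUC, where true differences between a good panel
and a null-contaminated neighbor are a few thousandths of AUC; with
independent per-panel forest seeds those comparisons would be dominated by
forest-sampling noise unless the forest were impractically large, whereas
with shared seeds the noise is common to both sides and cancels from the
difference. Results remain deterministic given the global seed, are
independent of evaluation order, and evaluating one panel never perturbs
another's results.

## AUC and the operating point

AUC is the tie-aware concordance probability, computed from midranks:
(#{case > control} + ½·#{ties}) / (n_case · n_control). For tie-free scores
it coincides with the trapezoidal area under the empirical ROC; the test
suite checks both identities against independent oracles (O(n²) pairwise
counting; sklearn's trapezoidal implementation). The fixed-specificity
threshold is the ⌈target·n⌉-th smallest control score: with the rule
"case iff score > t" this is the *smallest* control order statistic whose
specificity reaches the target, and the achieved training specificity is
always ≥ the target. Cross-validated AUC defaults to pooled out-of-fold
scoring (one AUC over the pooled vector) rather than per-fold averaging, for
lower variance; per-fold averaging is available as an option.

## The synthetic cohort

Marker concentrations are log-normal. Controls draw log-values from
N(control_log_mean, log_sd) per marker (defaults 0 and 1 — absolute assay
units are irrelevant after the log transform); cases add an
`effect_shift` to the log-mean, scaled by a per-stage multiplier
(default 0.8/0.9/1.1/1.2 for stages 1-4, monotone so later-stage disease is
more separable, reproducing the stage-graded sensitivity pattern seen in
real panels). Under the defaults every marker analog shifts by 1.0 log-SD
except the B2M analog (shift 0), making B2M the built-in null. Stages are
categorical with probabilities 0.294/0.411/0.167/0.128; ages are normal
(cases 64.4 ± 9.8, controls 56.9 ± 8.8 years) truncated at 18; sex is
Bernoulli (65.0% male cases, 58.3% male controls). A single seed governs all
draws in a fixed order (case stages, case ages, case sexes, control ages,
control sexes, then per-marker case and control values), so an identical
configuration reproduces the table bit for bit.

What the generator deliberately does *not* model: assay noise or batch
effects, missing data, inter-marker correlation (markers are conditionally
independent given label and stage), non-lognormal tails, or any
survival/outcome structure. Tests passing on this generator therefore
demonstrate that the *procedure* behaves as specified (correct counts,
correct operating characteristics, recovery of a planted signal, no signal
under the null) — not that any particular marker panel works in real sera.

## Problem sizes used by the test suite

The full study grid (2047 panels × 5 algorithms × 10-fold CV) is a
multi-hour computation on one CPU, so the Monte-Carlo acceptance studies run
at reduced scale, chosen once for a single-CPU machine:

- **Planted-panel recovery**: candidates are the six planted markers
  (ApoA1, ApoA2, CA125, CA19-9, CEA, TTR; flat 1.5 log-SD shifts, stage
  multipliers set to 1) plus the null B2M analog — 127 panels; cohorts of
  180/573 as in the full design; 20 seeds; 5-fold CV with a 30-tree forest
  and a fixed ridge penalty (C = 1). Within a fixed compute budget, forest
  size matters more than fold count here: the planted panel's validation
  edge over null-contaminated competitors is a few thousandths of AUC, and
  the vote-fraction noise of a very small forest — not fold noise — is what
  blurs the final max-min-AUC pick. Library defaults (10 folds, 500 trees)
  are unchanged.
- **Null sanity**: four candidate markers, all shifts zero, and case
  demographics matched to controls (same age law, same male fraction) so
  that cases and controls are exchangeable — with the default demographic
  gap (cases ~7.5 years older, more often male) the age/sex covariates carry
  genuine signal and every panel honestly scores AUC ≈ 0.68, which is
  covariate signal, not selection bias. 20 seeds, with the top-fraction and
  stability filters vacuous: under the null the CV ranking is uninformative
  and would otherwise frequently abort the cascade at the mandatory filter,
  while the bias of interest (signal invented by maximizing the minimum
  validation AUC) lives in the selection stage, which is exercised over all
  panels.
- **Determinism and CLI checks**: 4-marker cohorts (15 panels).

## Numerical and edge-case conventions

- Round half up for per-stratum training counts (reproduces 120/382 from
  2/3 exactly).
- Ties at the operating threshold: a subject is called a case only if its
  score is strictly above t; specificity counts controls ≤ t.
- A constant marker yields U = n₁n₂/2, p = 1, never flagged.
- Age bins are left-closed (40 → "40-49"); bin edges are configurable.
- Rankings and the final pick break ties deterministically (fewer markers,
  then canonical string), so ledgers are byte-reproducible; ledger JSON is
  sorted-key with no timestamps.
- The enumeration refuses more than 16 candidate markers unless the cap is
  raised explicitly (2^n growth).
- An empty stability stage aborts selection with advice to relax `max_gap`
  or `top_fraction` rather than silently returning nothing.

## Known limitations

- The generator's conditional-independence assumption makes panels more
  complementary than correlated real serum markers would be; recovery rates
  here are optimistic relative to real data.
- With strong planted effects the candidate panels saturate (validation AUC
  ≈ 0.99), and the cascade's final comparison — minimum validation AUC
  across algorithms — must then separate panels whose true difference is a
  few thousandths of AUC. On a validation set of a few hundred subjects the
  sampling noise of that difference is of the same order, so the single
  best panel is not reliably identified even though the selected panel is
  essentially always a near-optimal neighbor (the planted set plus or minus
  one marker). Exact-recovery rates are therefore an optimistic-looking but
  stringent summary; top-set membership is far more stable.
- The "small train/validation gap" and "consistent across algorithms"
  criteria are operationalized with explicit numeric rules (max_gap; max-min
  validation AUC with an SD tie-break); other reasonable operationalizations
  exist, and the thresholds that real studies used for the analogous filters
  are not recoverable — both are exposed as parameters.
- Validation-set operating metrics use the threshold fixed on training
  resubstitution scores of the deployed model; reported validation
  specificity is the achieved, not the targeted, value.
- No confidence intervals on AUC and no formal tests comparing panels.
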