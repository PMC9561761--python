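# Methods

This note documents the statistical model, the estimators, the synthetic
data generator, and the design decisions behind `pairsig`, in the order the
pipeline runs them.

## The pair transform

For genes a < b (lexicographic, the canonical orientation) and one
expression profile x, the feature is `1{x[a] > x[b]}`, with ties scoring 0.
The tie rule and direction are conventions: flipping the direction flips
the sign of every downstream coefficient, which the penalized Cox fit
absorbs, so nothing substantive depends on them — but they must be fixed
for signatures to be portable, and they are recorded in every signature
file (`tie_rule: "gt_zero_ties"`).

The transform is *exactly* invariant under strictly increasing maps applied
per sample. This is the package's core guarantee and is asserted
bit-for-bit in the tests, not approximately. It is the entire batch
strategy: no quantile normalization or location/scale correction is applied
anywhere. Per-gene additive batch shifts (different array chemistry per
cohort, say) are **not** monotone within-sample transforms; they can flip
indicators of closely expressed gene pairs. The generator provides exactly
this violation (`gene_shift`) so the degradation can be measured rather
than assumed away.

Prevalence filtering keeps pairs whose indicator mean across samples lies
in [0.2, 0.8] (configurable). A pair that is 1 in nearly every sample
carries almost no cohort information but can still soak up a spurious Cox
coefficient; the band is the established convention for rank-pair
signatures. By default the filter is computed on the full cohort before the
train/validation split — reproducing the common published order of
operations — with `filter_on_training` exposed for the leakage-free
variant. The filter uses only indicator prevalence, never survival, so the
leakage is mild either way.

## Screening: vectorized univariate Cox

Each candidate pair is screened with a single-covariate Cox model on its
binary indicator, keeping Wald *P* < 0.001 (raw, no multiplicity
correction — the screen is a pre-filter for the penalized fit, not an
inference). For a binary covariate the Breslow partial likelihood depends
on the data only through, at each event time, the number at risk, the
number at risk with indicator 1, and the number of events with indicator 1.
These reduce to cumulative sums over the time-sorted indicator matrix, so
all pairs are fitted simultaneously by a few damped Newton iterations on
arrays — necessary at the 10⁴–10⁵-pair scale where one general-purpose fit
per pair is prohibitive. Fits agree with `lifelines` to ~10⁻⁵ on tie-free
data (the test tolerance reflects lifelines' own stopping rule, not ours).
Constant indicators and separated fits (|β| ≥ 15) are skipped and counted.
Ties are handled with the Breslow approximation throughout; cohorts with
continuous survival times are effectively tie-free.

## The penalized fit

The LASSO Cox fit uses the glmnet-style coordinate-descent path from
`scikit-survival` (`CoxnetSurvivalAnalysis`, l1_ratio = 1, standardized
features, coefficients returned on the original scale). Model selection is
in-package: folds are assigned stratified by event status with a seeded
shuffle (preventing event-free folds), each held-out fold is scored by its
own Breslow partial log-likelihood at every λ on the path, and λ is taken
at the minimum mean cross-validated deviance. The one-standard-error rule
is available as a flag but is not the default, matching the convention of
selecting at the minimum. A single-candidate input degenerates to an
unpenalized fit; a selection in which every coefficient is zero raises an
error that suggests a weaker penalty rather than returning an empty
signature silently.

The held-out deviance is the "basic" fold-wise partial likelihood (each
test fold scored on its own risk sets), not the Verweij–van Houwelingen
full-minus-train decomposition; with the fold sizes used here the two rank
λ nearly identically and the basic form is simpler to reason about.

## Cutoff: time-dependent ROC at a fixed horizon

The risk cutoff is chosen on the training arm from the cumulative/dynamic
ROC at a 12-month horizon, with the Kaplan–Meier plug-in estimator: for
threshold c,

    Sens(c) = (1 − S(t|X>c)) P(X>c) / (1 − S(t))
    Spec(c) = S(t|X≤c) P(X≤c) / S(t)

where S(·) are KM estimates (overall and within the thresholded
subgroups). Candidate thresholds are the midpoints between adjacent sorted
unique scores; the cutoff maximizes Youden's J = Sens + Spec − 1, with ties
broken toward the lower threshold (the more inclusive high-risk group).
Youden is the standard reading of an "optimal" ROC cutoff when no
cost ratio is specified. The KM plug-in can be locally non-monotone in c
for small subgroups; estimates are clipped to [0, 1] and the AUC is the
trapezoid over the FPR-sorted curve with (0,0) and (1,1) appended. This
estimator family (not the IPCW/Uno family) is implemented in-package and
verified against an independent brute-force midpoint search in the tests.

## Evaluation

Risk score = Σ βᵢ·valueᵢ; a sample is high risk iff score **strictly**
exceeds the cutoff (boundary behavior must be fixed somewhere; strict
inequality keeps a sample exactly at the cutoff out of the high-risk
group). KM curves, the k-group log-rank test, and uni-/multivariate Cox
models are delegated to `lifelines`. Covariate coding follows the clinical
convention: gender 0 = female / 1 = male, MGMT promoter 0 = methylated /
1 = unmethylated, age in years, all treated as continuous in the Cox
models. Missing covariates are handled complete-case per model: KM and
log-rank use all samples, multivariate Cox drops incomplete rows. No
imputation is attempted — the pairing transform needs complete expression
anyway, and covariate imputation would add a modelling assumption the
evaluation does not need.

Discrimination is Harrell's C (ties in score credit 0.5; pairs made
incomparable by censoring are excluded), via `lifelines`, cross-checked in
tests against exhaustive pair enumeration and `scikit-survival`. Signature
comparison reports both C-indices and a seeded bootstrap percentile CI of
the difference — the minimal honest uncertainty statement when no
analytical paired test is assumed. Quartile analysis contrasts the top and
bottom score quartiles (boundaries at ranks ⌊0.25n⌋ and ⌈0.75n⌉ of the
stable ascending order) by log-rank.

`score_external_profile` scores one expression profile with no cohort
context — the defining capability of the single-sample construction — and
is invariant to any monotone rescaling of the measurement (linear fold
change vs ΔΔCt, for instance), which the tests assert exactly.

## Robustness by outcome permutation

The robustness test asks whether the *amount* of signal selected by the
screen+LASSO pipeline exceeds what randomized outcomes produce. Each
randomization jointly permutes the (time, event) rows across samples —
preserving both the survival marginal and the full pair-matrix correlation
structure — and re-runs selection at reduced path resolution. The headline
statistic is the selected-pair count; `empirical_p` is the add-one
estimator (1 + #{null ≥ observed}) / (1 + B). Per-pair re-selection counts
of the observed signature pairs are reported as diagnostics.

The count statistic, rather than the re-selection frequency of the observed
signature's own pairs, is deliberate: any statistic conditioned on the
observed selection is anti-conservative under the null (on pure-noise data
the spuriously selected pairs are, by construction, never re-found under
permutation, driving p to its minimum even when there is nothing to find).
The count statistic is exchangeable under the null, and the tests verify
both calibration on noise cohorts and power on planted-signal cohorts.

## The synthetic cohort generator

`simulate_cohort` draws per-gene log-normal expression (gene means
~N(3, 1), within-gene sd 1 on the log scale), plants `n_true_pairs` pair
effects on disjoint genes, and generates event times from an exponential
proportional-hazards model: rate = h₀·exp(Σ βₖ·indicatorₖ) with
h₀ = 0.05/month by default (median survival ≈ 14 months at baseline,
typical of the aggressive brain-tumor setting the method targets). Defaults
are the validated study conditions: 400 samples, 50 genes, 3 planted pairs
with log-HRs (1.0, 0.8, −0.8), 30% censoring, 2 batches.

Details that matter:

* **Planted pairs are rejection-sampled to indicator prevalence in
  [0.3, 0.7].** An unconstrained random pair has a substantial chance of a
  near-constant indicator (whenever the two gene means differ by more than
  about one log unit), which cannot carry the promised hazard signal and
  would be removed by the pipeline's own prevalence filter. The constraint
  makes the generator's effect sizes mean what they say.
* **Censoring is calibrated, not nominal.** Censoring times are
  exponential with the rate chosen by bisection so the *realized* censored
  fraction matches the target for the drawn event times; the realized rate
  is part of the returned ground truth and is tested to ±5 points.
* **Noise before distortion.** Log-scale gaussian measurement noise
  (sd 0.1 by default) is applied to the latent expression first, then the
  batch distortion. Planted indicators are defined on the *latent* values,
  so measurement noise genuinely corrupts the observable signal.
* **Two distortion flavors.** `monotone_per_sample` (x → a·xᵖ with random
  a, p per sample) is provably invisible to the transform and is asserted
  bit-for-bit; `gene_shift` (per-batch per-gene multiplicative shifts)
  partially violates rank invariance and is only ever evaluated
  empirically. This separates what is provable from what is merely
  plausible.
* Everything derives from one seeded generator: identical configs give
  bit-identical cohorts.

What the generator does **not** emulate: realistic gene–gene covariance,
tumor purity and cell-type mixtures, non-proportional hazards, informative
censoring, platform-specific detection floors. Passing recovery tests
therefore demonstrate correctness of the estimators under the model's own
assumptions, not performance on real tumors.

## Known limits and numerical notes

* With 3 planted pairs at log-HRs (1.0, 0.8, −0.8), the Harrell C of the
  *true* linear predictor is ≈ 0.706 in expectation (and ≈ 0.68 ± 0.02
  realized at n = 400); fitted signatures land a few points below that.
  Discrimination targets above ~0.70 are not reachable under these study
  conditions by any estimator, a ceiling worth keeping in mind when
  comparing to published C-indices obtained on real cohorts with stronger
  effective signal.
* The end-to-end recovery and calibration tests use training arms of
  400 samples, 50-gene universes, and 10–20 seeds per property; these sizes
  were chosen so the full suite exercises every stage at meaningful power
  while staying fast enough to run habitually.
* The 6-decimal agreements quoted for the screen hold on tie-free data;
  with heavily tied times Breslow and Efron approximations diverge and
  only approximate agreement with Efron-based references is expected.
* Duplicate gene rows on load keep the highest-mean row (a deterministic
  microarray convention); genes with any missing value are dropped, since
  the transform needs complete within-sample information and imputation
  would inject rank noise.
* Survival times are months internally; day-scaled inputs are converted by
  30.4375 days/month via `time_unit="days"` so the 1-year ROC horizon is
  unambiguous.
* The train/validation split is simple random (default fraction 204/377
  ≈ 0.541, the convention of the motivating study design), with optional
  stratification by dataset label. The validation arm only ever receives
  the frozen signature; the tests enforce this by poisoning training
  outcomes and asserting unchanged validation metrics.
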