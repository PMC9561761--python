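# pairsig

Single-sample gene-pair prognostic signatures for censored survival data.

## The problem

Prognostic gene-expression signatures usually depend on absolute expression
values, which makes them fragile: a score trained on RNA-seq FPKM cannot be
applied to a microarray profile, a qPCR panel, or even a differently
normalized cohort without batch correction. Rank-based gene-*pair*
signatures sidestep this. For a pair of genes (a, b) the feature is the
binary indicator

```
value(a, b) = 1  if expr[a] > expr[b] within the sample, else 0
```

which depends only on the ordering of two genes inside one profile. Any
strictly increasing per-sample transformation of the measurements — log,
quantile rescaling, platform-specific intensity response — leaves every
indicator unchanged, so the resulting risk score is computable for a single
patient on any platform with no reference cohort. The approach was motivated
by prognosis modelling in IDH-wild-type glioblastoma from metabolic gene
pairs, but the machinery is generic.

## The method

Given a gene universe of n genes shared across cohorts, the pipeline:

1. builds all n(n−1)/2 canonical pairs and the binary pair matrix
   (monotone-invariant by construction);
2. removes near-constant pairs (indicator prevalence outside [0.2, 0.8] by
   default);
3. screens each pair with a univariate Cox proportional-hazards model on
   overall survival, keeping Wald *P* < 0.001;
4. fits an L1-penalized (LASSO) Cox model over the survivors, with λ chosen
   by stratified 10-fold cross-validated partial-likelihood deviance,
   yielding a sparse signature {(pairᵢ, βᵢ)};
5. scores each sample as `risk = Σᵢ βᵢ · valueᵢ` and fixes the high/low-risk
   cutoff at the Youden-optimal threshold of the 1-year time-dependent ROC
   (Kaplan–Meier cumulative/dynamic estimator);
6. evaluates stratification on a held-out arm: Kaplan–Meier curves and
   log-rank test, uni-/multivariate Cox with standard clinical covariates,
   Harrell's C-index, quartile contrasts; and
7. optionally quantifies selection robustness by re-running the
   screen+LASSO selection under joint permutation of the (time, event)
   rows, reporting an add-one permutation p-value.

A seeded synthetic-cohort generator (multi-batch log-normal expression,
planted pair effects driving an exponential proportional-hazards model,
calibrated independent censoring, monotone or gene-shift batch distortions)
makes every stage testable without any external data.

## Worked example

```python
from pairsig import (SimulationConfig, simulate_cohort,
                     PipelineConfig, run_pipeline_frames)

cfg = SimulationConfig(n_samples=800, seed=1,
                       batch_distortion="monotone_per_sample")
expr, clin, truth = simulate_cohort(cfg)

res = run_pipeline_frames(expr, clin, PipelineConfig(seed=1, train_fraction=0.5))
sig = res["signature"]
print(f"signature: {len(sig)} pairs, cutoff {sig.cutoff:.3f}")
print(f"recovered planted pairs: {sorted(set(truth.planted_pair_ids) & set(sig.pair_ids))}")
print(f"training 1-year AUC: {res['train_auc']:.3f}")
ev = res["evaluation_valid"]
print(f"held-out C-index: {ev['c_index']:.3f}, log-rank p: {ev['logrank_p']:.2e}")
```

prints

```
signature: 13 pairs, cutoff 0.697
recovered planted pairs: ['G0011|G0037', 'G0012|G0046', 'G0022|G0033']
training 1-year AUC: 0.778
held-out C-index: 0.663, log-rank p: 6.48e-12
```

The cohort hides three planted pair effects (log hazard ratios 1.0, 0.8,
−0.8) behind per-sample monotone batch distortions; the pipeline recovers
all three in a 13-pair signature, and the frozen signature separates the
400-sample held-out arm into risk groups with strongly different survival.
The held-out C-index of ~0.66 is close to the theoretical ceiling for these
effect sizes (the true linear predictor itself scores ≈ 0.68–0.71).

The same workflow is available from the shell:

```bash
pairsig simulate --seed 1 --out-prefix cohort
pairsig pipeline --expression cohort_expression.tsv \
                 --clinical cohort_clinical.tsv --out-dir results/ --seed 1
```

A bundled synthetic stand-in of a published 21-pair metabolic glioblastoma
signature (21 pairs, 38 unique genes, cutoff −0.211; constructed pair list —
see its file docstring) is available via
`pairsig.load_synthetic_reference_signature()` for exercising single-sample
scoring, e.g. `score_external_profile`, on a realistic signature shape.

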