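# evdeconv

Tissue and cell-of-origin deconvolution for bulk extracellular-vesicle (EV)
long-RNA expression profiles.

Circulating EVs carry RNA from essentially every cell type that releases them
into a body fluid, so a plasma (or serum, or CSF) EV RNA-seq profile is a
mixture of contributions from blood cells and solid tissues. `evdeconv`
estimates those contributions. It assumes the standard linear mixing model

```
a = B x,    x >= 0
```

where `a` is the mixture expression vector over signature genes (TPM), `B` is
a signature matrix (genes × subsets, mean TPM of subset-specific marker genes
in each tissue or blood-cell type), and `x` is the vector of subset
coefficients, reported both as relative fractions (normalized to sum to 1)
and absolute scores (unnormalized, comparable across samples).

The package provides:

- **Signature construction** from a grouped reference atlas: an integer
  tissue-specific score (TSS, 0–5, counting satisfied fold-change tiers
  2/4/8/16/32 of a gene's subset mean over the maximum of the other subsets),
  subset exclusion lists for confounded organs, a detection-frequency filter
  against a background cohort of real mixtures, and selection of the top-*n*
  markers per subset with *n* chosen to minimize the signature's 2-norm
  condition number κ(B).
- **Six solvers** behind one interface: linear-kernel ν-support-vector
  regression (the core method; ν selected per sample by minimum reconstruction
  RMSE over a grid), NNLS, nonnegative QP, OLS, Huber robust regression, and
  ridge regression (GCV-selected penalty).
- **Monte-Carlo empirical p-values** testing the null that a profile contains
  none of the signature's subsets (random gene sets re-solved 500 times,
  Pearson-R statistic, add-one correction).
- **Benchmarking utilities**: multi-solver comparison (reconstruction
  PCC/RMSE, detection frequency, estimate variance), spike-in detection-limit
  experiments, rank-statistic ROC AUC, and a normality-gated two-group test
  (Shapiro–Wilk, then t-test or Wilcoxon rank-sum).
- **A synthetic-data generator** producing reference atlases, mixture cohorts
  with known ground truth (Dirichlet proportions, log-normal noise, optional
  unmodeled content), and null cohorts, so the whole pipeline is testable
  without any external download.

## Worked example

Build a signature from a synthetic 7-subset blood-cell atlas, simulate three
mixtures with 20 % unmodeled content and log-normal noise (σ = 0.1), and
deconvolve them with ν-SVR plus a 500-iteration permutation p-value:

```python
import numpy as np
import evdeconv as ev

rng = np.random.default_rng(42)
spec = ev.blood_spec(unmodeled_fraction=0.2, noise_sigma=0.1, seed=42)
atlas, groups = ev.generate_reference(spec, rng)
sig = ev.optimize_signature(
    atlas, groups,
    ev.select_specific_genes(ev.compute_tss(atlas, groups), 2),
    range(2, 51),
)
cohort, truth = ev.generate_cohort(sig, 3, spec, rng)
results, _ = ev.deconvolve(
    cohort, sig, ev.SolverOptions(method="svr"),
    permutations=ev.PermutationConfig(n_iter=500, seed=42, reuse_hyperparameters=True),
)
```

Output (top three estimated fractions per sample, with the simulated truth):

```
signature: 350 genes x 7 subsets, n=50, condition number 1.949
sample_001: cd4_t_cell 0.37, b_cell 0.20, neutrophil 0.17 | PCC 0.995, RMSE 0.105, nu 0.15, p 0.002
   truth: cd4_t_cell 0.37, b_cell 0.20, neutrophil 0.16
sample_002: monocyte 0.38, b_cell 0.24, cd8_t_cell 0.17 | PCC 0.993, RMSE 0.118, nu 0.3, p 0.002
   truth: monocyte 0.37, b_cell 0.25, cd8_t_cell 0.17
sample_003: platelet 0.26, cd8_t_cell 0.26, neutrophil 0.26 | PCC 0.994, RMSE 0.106, nu 0.25, p 0.002
   truth: platelet 0.28, cd8_t_cell 0.26, neutrophil 0.25
```

PCC/RMSE measure how well `B x` reconstructs the standardized mixture; the
p-value of 0.002 (= 1/501, the smallest attainable with 500 iterations) says a
random gene set essentially never fits this well, i.e. the profile genuinely
contains signature signal.

The same pipeline is available from the shell:

```sh
evdeconv simulate --preset blood --n 20 --seed 42 --out-prefix demo
evdeconv deconvolve --mixture demo.cohort.tsv --signature demo.signature.tsv \
    --method svr --out demo.results.tsv
evdeconv benchmark --mixture demo.cohort.tsv --signature demo.signature.tsv \
    --models svr,nnls,qp,ols,rlr,ridge --out-prefix demo.bench
```

See `docs/methods.md` for the model, parameter and design details.

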