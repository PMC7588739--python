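# Methods

## The mixing model

A bulk EV long-RNA profile is modeled as a nonnegative linear combination of
subset-specific expression signatures: `a = B x` with `a` the mixture vector
over signature genes (TPM), `B` the genes × subsets signature matrix of mean
TPM values, and `x` the subset coefficients. The model assumes (i) TPM-space
additivity of EV contributions, (ii) that the signature genes are expressed in
circulation predominantly by their home subset, and (iii) that content not
represented by any subset column acts as approximately unstructured noise over
the signature genes. Relative fractions are the positive part of `x`
normalized to sum to one; absolute scores are the unnormalized positive part,
comparable across samples run against the same signature with the same
normalization (no total-signal rescaling is applied — the literature uses
"absolute" in several inequivalent senses, and the truncated raw coefficient
is the least processed of them).

## Signature construction

**Tissue-specific score (TSS).** For gene g and subset t, with m_t the mean
TPM in t and m_o the maximum mean TPM over the other subsets, the score is the
number of satisfied fold-change tiers:

    TSS(g, t) = |{k ∈ {2, 4, 8, 16, 32} : m_t + 1 ≥ k · (m_o + 1)}|

The pseudocount of 1 TPM protects against zero denominators and spurious
specificity of near-silent genes. The score is an integer 0–5, monotone in
enrichment, and scale-free once expression is well above the pseudocount. A
gene can score above zero only in a subset where it is strictly maximally
expressed. (The tiered definition is this package's; only the 0–5 range and
its use as a specificity screen are fixed by the approach it implements.)

**Filtration cascade.** Building a basis from a whole-body atlas proceeds as:
subset exclusion → TSS threshold → background-frequency filter → top-n
selection. Exclusion lists drop subsets that confound a solid-tissue basis
(immune-dominated organs such as spleen and thyroid; sex-biased organs;
hemopoietic compartments, which belong in the blood-cell basis instead); the
built-in defaults reduce a 31-tissue whole-body atlas to 16 solid tissues.
Both threshold comparisons are strict: a gene is kept when TSS > threshold
(so TSS = 3 passes a threshold of 2) and when its detection frequency in the
background cohort is > min_freq (so frequency exactly 0.10 fails at 0.1).
Detection means TPM above a configurable threshold, 0 by default. Each kept
gene is assigned to the subset of its maximal score, ties broken
lexicographically by subset label.

**Top-n selection and condition-number optimization.** Candidates are ranked
per subset by TSS (descending), then mean TPM in the home subset (descending),
then gene identifier — a deterministic key favoring specificity, then
abundance. For each n in a grid (default 2–150), the top-n genes per subset
form a candidate matrix whose 2-norm condition number κ (ratio of extreme
singular values, ∞ when rank-deficient) is computed; the n minimizing κ wins,
ties toward smaller n. A flatter singular spectrum means coefficient estimates
are less amplified by input noise. The full (n, κ) trace is stored in the
signature's provenance.

**Merging bases.** Two signatures with disjoint subset labels (e.g. blood
cells and solid tissues) can be stacked to estimate the total blood vs tissue
split; a gene absent from one source gets that source's atlas mean when
provided, else zero.

## Deconvolution

**Pre-processing.** The mixture and signature are restricted to their shared
genes (at least max(10, #subsets) required; unmatched signature genes are
dropped with a warning and the matched fraction is reported — no imputation
is attempted). The mixture vector is z-scored; by default each signature
column is z-scored too, keeping both sides on a common scale, which the
ε-tube geometry of SVR requires (`standardize="mixture-only"` disables the
column scaling). Solvers run in this standardized space and the fit metrics
(PCC, RMSE between `B x` and the mixture) are measured there; the reported
coefficients are mapped back to the raw signature scale
(`x_raw_j = x_std_j · sd(mixture) / sd(column j)`), so relative fractions are
proportions of signature-column units rather than of z-score units. Without
the back-mapping, per-column standardization would silently reweight each
subset by its column spread.

**Solvers.**

- `svr` (core): linear-kernel ν-SVR (scikit-learn NuSVR, C = 1) fitted for
  each ν in a grid (default 0.05–0.95, step 0.05 — the open interval (0, 1)
  excluding the degenerate endpoints); the ν with the lowest reconstruction
  RMSE wins, ties toward smaller ν (fewer support vectors). The coefficient
  vector is the primal weight vector of the linear model.
- `nnls`: nonnegative least squares (scipy).
- `qp`: the same objective as a quadratic program (scipy `lsq_linear` for the
  nonneg mode; SLSQP when the optional sum-to-one constraint is on). The
  nonneg mode must agree with NNLS to solver tolerance — same optimum,
  different algorithm.
- `ols`: unconstrained least squares; minimum-norm solution with a warning if
  the basis is rank-deficient.
- `rlr`: Huber M-estimation (tuning constant 1.345, IRLS to 1e-6, max 100
  iterations; statsmodels RLM).
- `ridge`: closed form (BᵀB + λI)⁻¹Bᵀa; λ by generalized cross-validation
  over a 33-point log grid (1e-4 to 1e4) when unset.

Negative coefficients are truncated to zero for both output modes. If no
coefficient is positive the sample is flagged degenerate with all-zero
fractions rather than normalized.

## Empirical p-value

The null hypothesis is that the mixture contains none of the signature's
subsets — gene identity carries no information, so the observed signature
gene set should fit no better than a random gene set of the same size drawn
from the same profile. Each of n_iter (default 500) iterations draws such a
set without replacement, assigns its values to the signature rows, re-solves,
and records the reconstruction Pearson R. The one-sided p-value is
(1 + #{R_null ≥ R_obs}) / (1 + n_iter); the add-one correction keeps p off
zero. By default the SVR ν is re-selected inside every null fit (an honest
null); `reuse_hyperparameters=True` freezes the observed ν, which is ~20×
cheaper and changes p little in practice. An undefined reconstruction R (an
all-zero constrained fit) is ranked below every defined R on both the
observed and null sides, with exact ties counting as exceedances — this
keeps the observed and null draws exchangeable, which is what makes the
p-value uniform under the null.

## Benchmarking

`compare_models` runs several solvers on one cohort and aggregates per-sample
PCC/RMSE, per-subset detection frequency (share of samples with relative
fraction strictly > 0), and per-subset estimate variance. `spike_in_experiment`
mixes a spike profile into a background at a grid of proportions
((1−f)·background + f·spike in TPM space), perturbs each gene by
multiplicative log-normal noise exp(N(0, σ²)) (σ default 0.1 — multiplicative
so TPMs stay nonnegative), deconvolves, and reports the per-point absolute
error and the largest proportion recovered within tolerance (default 0.05
absolute). ROC AUC uses the rank statistic (probability a positive outranks a
negative, ties ½); higher score is taken as disease-positive and is never
auto-flipped. The two-group test runs Shapiro–Wilk on each group at α = 0.05
and picks a two-sided t-test when both pass, else a two-sided Wilcoxon
rank-sum with tie correction; a constant group goes straight to the rank
branch.

A note on reconstruction-PCC comparisons between solvers: in-sample PCC of
unconstrained least squares is an upper bound for every linear solver on the
same genes, so "solver A fits at least as well as OLS" can only hold as a tie
(NNLS, QP and ridge-at-λ→0 coincide with OLS exactly when the unconstrained
optimum is nonnegative). The benchmark tests therefore treat PCC differences
below 1e-3 as ties when asserting solver orderings.

## Synthetic data

The generator emulates what the deconvolution model assumes, with defaults
sized like a hemopoietic reference (7 subsets × 100 markers; a 16-subset × 6
marker solid-tissue preset is also provided): gene baselines are log-normal
(log-mean 2.0, log-sd 1.0 for background genes; log-mean 3.0 for markers,
since usable markers are well expressed in their home tissue), markers are
multiplied by a fold enrichment (default 50×) in their home subset, replicate
and mixture noise is multiplicative log-normal (σ default 0.1), mixing
proportions are symmetric Dirichlet (concentration 1.0), and unmodeled
content is a block of unrelated log-normal genes scaled to a configured share
of total signal (default 0). Null cohorts draw every (gene, sample) value
i.i.d. log-normal, making gene subsets exchangeable — exactly the p-value
null. The generator does not attempt to mimic real EV RNA-seq count
distributions, fragment-length or GC bias, platelet-activation kinetics
during sample handling, or cross-subset correlation of marker leakage; tests
passing on these fixtures demonstrate correctness of the algorithms under
the model's assumptions, not performance on real plasma profiles.

## Problem sizes and numerical choices

The test and acceptance workloads use the generator at moderate sizes chosen
to exercise the full pipeline: the 7 × 100-marker reference (signature ~350
genes after optimization) for recovery, ranking and spike-in experiments, and
a compact 7 × 8-marker signature for the permutation-heavy calibration runs
(200 null samples × 500 iterations with the NNLS solver). Degenerate inputs
are handled explicitly: constant mixtures are rejected (cannot be z-scored),
rank-deficient signatures get a κ = ∞ sentinel and are skipped during
optimization, and per-sample solver failures are recorded without aborting a
cohort run. Seeds fix every stochastic step; identical inputs and seeds give
byte-identical output files.

## Known limitations

- The TSS definition is a reconstruction from its stated 0–5 range and
  intended behavior; other monotone specificity scores would select
  overlapping but not identical marker sets.
- Absolute scores are not calibrated to physical EV counts; they are only
  comparable within a signature/normalization regime.
- The merged blood+tissue basis inherits any cross-talk between blood- and
  tissue-enriched genes; the package does not model co-expression leakage.
- The permutation null preserves each profile's value distribution but not
  inter-gene correlation structure.
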