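"""Synthetic reference atlases and mixture cohorts with known ground truth.

The generator emulates the statistical structure bulk deconvolution assumes: a
grouped reference atlas whose subsets carry strongly fold-enriched marker
genes over a shared log-normal background, mixture cohorts whose profiles are
linear combinations of subset signatures under Dirichlet-distributed
proportions with multiplicative log-normal noise, an optional unrelated
(unmodeled) content fraction, and signature-free null cohorts for p-value
calibration.  Expression is log-normal throughout: TPMs are nonnegative and
heavy-tailed, which Gaussian noise would violate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SignatureMatrix, SubsetAssignment

BLOOD_SUBSETS = (
    "b_cell",
    "cd4_t_cell",
    "cd8_t_cell",
    "monocyte",
    "neutrophil",
    "nk_cell",
    "platelet",
)
TISSUE_SUBSETS = (
    "adipose",
    "bladder",
    "brain",
    "colon",
    "esophagus",
    "heart",
    "kidney",
    "liver",
    "lung",
    "muscle",
    "nerve",
    "pancreas",
    "pituitary",
    "skin",
    "small_intestine",
    "stomach",
)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic expression generator.

    Defaults mirror a hemopoietic-cell reference: 7 subsets with ~100 markers
    each.  ``fold_enrichment`` multiplies a marker's baseline in its home
    subset; baselines are log-normal (natural-log mean/sd), markers drawn with
    a higher log-mean since usable markers are well expressed in their home
    tissue.  ``noise_sigma`` is the log-sd of the multiplicative noise applied
    to replicates and mixtures; ``unmodeled_fraction`` is the share of a
    mixture's total signal contributed by genes unrelated to any subset.
    """

    n_subsets: int = 7
    markers_per_subset: int = 100
    samples_per_subset: int = 5
    n_background_genes: int = 1000
    fold_enrichment: float = 50.0
    background_log_mean: float = 2.0
    background_log_sd: float = 1.0
    marker_log_mean: float = 3.0
    dirichlet_concentration: float = 1.0
    unmodeled_fraction: float = 0.0
    noise_sigma: float = 0.1
    seed: int = 42
    subset_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if min(self.n_subsets, self.markers_per_subset, self.samples_per_subset) < 1:
            raise ValueError("subset, marker and sample counts must be >= 1")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        if self.fold_enrichment <= 1:
            raise ValueError("fold_enrichment must exceed 1")
        if not 0 <= self.unmodeled_fraction < 1:
            raise ValueError("unmodeled_fraction must lie in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be > 0")
        if self.subset_labels is not None and len(self.subset_labels) != self.n_subsets:
            raise ValueError("subset_labels length must equal n_subsets")

    @property
    def labels(self) -> list[str]:
        if self.subset_labels is not None:
            return list(self.subset_labels)
        return [f"subset_{i + 1:02d}" for i in range(self.n_subsets)]


def blood_spec(**overrides) -> GeneratorSpec:
    """Hemopoietic-cell preset: 7 subsets, ~100 markers each."""
    params = dict(n_subsets=7, markers_per_subset=100, subset_labels=BLOOD_SUBSETS)
    params.update(overrides)
    return GeneratorSpec(**params)


def tissue_spec(**overrides) -> GeneratorSpec:
    """Solid-tissue preset: 16 subsets, ~6 markers each."""
    params = dict(n_subsets=16, markers_per_subset=6, subset_labels=TISSUE_SUBSETS)
    params.update(overrides)
    return GeneratorSpec(**params)


def _rng(spec: GeneratorSpec, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(spec.seed)


def generate_reference(
    spec: GeneratorSpec = GeneratorSpec(), rng: np.random.Generator | None = None
) -> tuple[ExpressionMatrix, SubsetAssignment]:
    """A grouped reference atlas: replicate samples per subset, marker genes
    fold-enriched in their home subset over a shared log-normal background."""
    rng = _rng(spec, rng)
    labels = spec.labels
    marker_genes = [
        f"MK_{label}_{i + 1:03d}" for label in labels for i in range(spec.markers_per_subset)
    ]
    background_genes = [f"BG_{i + 1:05d}" for i in range(spec.n_background_genes)]
    genes = marker_genes + background_genes
    n_genes = len(genes)

    base = np.empty(n_genes)
    n_markers = len(marker_genes)
    base[:n_markers] = rng.lognormal(spec.marker_log_mean, spec.background_log_sd, n_markers)
    base[n_markers:] = rng.lognormal(
        spec.background_log_mean, spec.background_log_sd, spec.n_background_genes
    )

    # genes x subsets mean matrix: markers multiplied by the fold in their home subset
    means = np.tile(base[:, None], (1, spec.n_subsets))
    for j in range(spec.n_subsets):
        start = j * spec.markers_per_subset
        means[start : start + spec.markers_per_subset, j] *= spec.fold_enrichment

    columns: dict[str, np.ndarray] = {}
    assignment: dict[str, str] = {}
    for j, label in enumerate(labels):
        for r in range(spec.samples_per_subset):
            sample = f"{label}_rep{r + 1}"
            noise = (
                rng.lognormal(0.0, spec.noise_sigma, n_genes) if spec.noise_sigma > 0 else 1.0
            )
            columns[sample] = means[:, j] * noise
            assignment[sample] = label
    atlas = ExpressionMatrix(pd.DataFrame(columns, index=pd.Index(genes, name="gene_id")))
    groups = SubsetAssignment(pd.Series(assignment))
    return atlas, groups


def generate_cohort(
    sig: SignatureMatrix,
    n_samples: int,
    spec: GeneratorSpec = GeneratorSpec(),
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Mixture cohort with known ground truth.

    Per sample: proportions drawn from a symmetric Dirichlet; signal =
    signature @ proportions with per-gene multiplicative log-normal noise;
    plus ``n_background_genes`` unrelated log-normal genes scaled so they
    contribute ``unmodeled_fraction`` of the sample's total signal.  Returns
    the cohort and a samples x subsets table of true proportions (rows sum
    to 1; the unmodeled share is not a subset and is excluded by design).
    """
    rng = _rng(spec, rng)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    n_subsets = sig.n_subsets
    alpha = np.full(n_subsets, spec.dirichlet_concentration)
    props = rng.dirichlet(alpha, size=n_samples)  # (n_samples, n_subsets)
    signal = sig.values @ props.T  # (genes, n_samples)
    if spec.noise_sigma > 0:
        signal = signal * rng.lognormal(0.0, spec.noise_sigma, signal.shape)

    unrel_genes = [f"UNREL_{i + 1:05d}" for i in range(spec.n_background_genes)]
    unrel = rng.lognormal(
        spec.background_log_mean, spec.background_log_sd, (len(unrel_genes), n_samples)
    )
    if spec.unmodeled_fraction > 0 and unrel.size:
        target = spec.unmodeled_fraction / (1 - spec.unmodeled_fraction)
        scale = target * signal.sum(axis=0) / unrel.sum(axis=0)
        unrel = unrel * scale
    elif unrel.size:
        unrel = np.zeros_like(unrel)

    sample_ids = [f"sample_{i + 1:03d}" for i in range(n_samples)]
    genes = list(sig.gene_ids) + unrel_genes
    data = pd.DataFrame(
        np.vstack([signal, unrel]) if unrel.size else signal,
        index=pd.Index(genes, name="gene_id"),
        columns=sample_ids,
    )
    truth = pd.DataFrame(props, index=sample_ids, columns=sig.subset_labels)
    return ExpressionMatrix(data), truth


def generate_null_cohort(
    gene_ids: Sequence[str],
    n_samples: int,
    spec: GeneratorSpec = GeneratorSpec(),
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Mixtures with no signature structure at all.

    Every (gene, sample) value is an independent log-normal draw, so gene
    identity carries no information: any gene subset is exchangeable with any
    other, which is exactly the null the empirical p-value tests.
    """
    rng = _rng(spec, rng)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if spec.background_log_sd <= 0:
        raise ValueError("background_log_sd must be > 0 for a null cohort")
    gene_ids = list(gene_ids)
    values = rng.lognormal(
        spec.background_log_mean, spec.background_log_sd, (len(gene_ids), n_samples)
    )
    sample_ids = [f"null_{i + 1:03d}" for i in range(n_samples)]
    return ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    )
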