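"""Tissue-specific gene scoring and signature-matrix construction.

The pipeline mirrors how CIBERSORT-style deconvolution bases are built from a
grouped reference atlas, specialised for circulating-EV work:

1. score every gene for subset specificity (integer tissue-specific score,
   TSS, 0-5);
2. drop confounded subsets (immune-dominated, sex-biased, hemopoietic) before
   building a solid-tissue basis;
3. keep genes whose TSS exceeds a threshold, assigning each to its best
   subset;
4. keep genes detected in more than a minimum fraction of a background cohort
   of real mixtures (genes never seen in circulation cannot be deconvolved);
5. take the top-n candidates per subset and pick the n whose signature matrix
   has the smallest 2-norm condition number — flatter spectra tolerate more
   input noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    SignatureMatrix,
    SubsetAssignment,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Fold-change tiers defining the integer specificity score: a gene scores one
#: point for every tier k with (mean_target + 1) >= k * (max_other + 1).
TSS_FOLD_TIERS = (2, 4, 8, 16, 32)
TSS_PSEUDOCOUNT = 1.0

#: Default subset-exclusion lists for a whole-body solid-tissue atlas.
#: Immune-dominated organs, sex-biased organs, and hemopoietic compartments
#: confound a solid-tissue basis meant to be complementary to a blood-cell one.
IMMUNE_DOMINATED_SUBSETS = ("adrenal gland", "salivary gland", "spleen", "thyroid")
SEX_BIASED_SUBSETS = (
    "breast",
    "cervix uteri",
    "fallopian tube",
    "testis",
    "ovary",
    "vagina",
    "prostate",
    "uterus",
)
HEMOPOIETIC_SUBSETS = ("blood", "bone marrow", "blood vessel")
DEFAULT_TISSUE_EXCLUSIONS = IMMUNE_DOMINATED_SUBSETS + SEX_BIASED_SUBSETS + HEMOPOIETIC_SUBSETS

#: Condition-number sentinel for rank-deficient matrices.
RANK_DEFICIENT = float("inf")


@dataclass
class TSSTable:
    """Integer specificity scores (genes x subsets) plus the subset means used to derive them."""

    scores: pd.DataFrame        # int in [0, 5]
    subset_means: pd.DataFrame  # mean TPM, same shape

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy()
        if vals.min() < 0 or vals.max() > len(TSS_FOLD_TIERS):
            raise ValidationError("TSS scores must lie in [0, 5]")

    @property
    def gene_ids(self) -> list[str]:
        return self.scores.index.tolist()

    @property
    def subset_labels(self) -> list[str]:
        return self.scores.columns.tolist()


@dataclass
class CandidateGeneSet:
    """Per-subset candidate marker genes with their ranking keys.

    ``table`` columns: gene_id, subset, tss, mean_tpm (mean in the assigned
    subset), frequency (background-cohort detection frequency; NaN until the
    frequency filter has run).  Within each subset rows are ordered by the
    deterministic ranking used for top-n selection: TSS descending, then
    mean_tpm descending, then gene_id ascending.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "subset", "tss", "mean_tpm", "frequency"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"candidate table missing columns {sorted(missing)}")
        self.table = _rank_candidates(self.table)

    @property
    def subsets(self) -> list[str]:
        return sorted(self.table["subset"].unique().tolist())

    def genes_of(self, subset: str, n: int | None = None) -> list[str]:
        rows = self.table[self.table["subset"] == subset]
        genes = rows["gene_id"].tolist()
        return genes if n is None else genes[:n]

    def __len__(self) -> int:
        return len(self.table)


def _rank_candidates(table: pd.DataFrame) -> pd.DataFrame:
    return table.sort_values(
        ["subset", "tss", "mean_tpm", "gene_id"],
        ascending=[True, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)


def subset_mean_expression(atlas: ExpressionMatrix, groups: SubsetAssignment) -> pd.DataFrame:
    """Mean TPM of every gene in every subset (genes x subsets)."""
    groups.validate_against(atlas)
    means = {
        subset: atlas.data[groups.samples_of(subset)].mean(axis=1)
        for subset in groups.subset_labels
    }
    return pd.DataFrame(means)


def compute_tss(atlas: ExpressionMatrix, groups: SubsetAssignment) -> TSSTable:
    """Score every gene 0-5 for specificity to each subset.

    With m_t the gene's mean TPM in subset t and m_o the maximum mean over all
    other subsets, the score for t counts the satisfied fold tiers:
    ``|{k in {2,4,8,16,32} : m_t + 1 >= k * (m_o + 1)}|``.  The pseudocount of
    1 TPM guards against zero denominators and spurious specificity of
    near-silent genes.  A gene can only score above 0 in a subset where it is
    strictly maximally expressed.
    """
    if len(groups.subset_labels) < 2:
        raise ValidationError("specificity is undefined with fewer than two subsets")
    means = subset_mean_expression(atlas, groups)
    m = means.to_numpy(dtype=float) + TSS_PSEUDOCOUNT
    n_genes, n_subsets = m.shape
    scores = np.zeros((n_genes, n_subsets), dtype=int)
    for j in range(n_subsets):
        others = np.delete(m, j, axis=1).max(axis=1)
        ratio = m[:, j] / others
        for k in TSS_FOLD_TIERS:
            scores[:, j] += ratio >= k
    frame = pd.DataFrame(scores, index=means.index, columns=means.columns)
    return TSSTable(scores=frame, subset_means=means)


def select_specific_genes(tss: TSSTable, threshold: int) -> CandidateGeneSet:
    """Keep genes whose best TSS is strictly greater than ``threshold``.

    Each kept gene is assigned to the subset of its maximal score; exact ties
    break lexicographically by subset label.
    """
    if not 0 <= threshold < len(TSS_FOLD_TIERS):
        raise ValueError(f"TSS threshold must be in [0, 5), got {threshold}")
    cols = sorted(tss.subset_labels)
    scores = tss.scores[cols]
    best = scores.max(axis=1)
    keep = best > threshold
    assigned = scores.loc[keep].idxmax(axis=1)  # idxmax -> first (lexicographic) on ties
    rows = pd.DataFrame(
        {
            "gene_id": assigned.index,
            "subset": assigned.values,
            "tss": best[keep].values,
            "mean_tpm": [
                tss.subset_means.at[g, s] for g, s in zip(assigned.index, assigned.values)
            ],
            "frequency": np.nan,
        }
    )
    return CandidateGeneSet(rows)


def exclude_subsets(groups: SubsetAssignment, exclusions: Iterable[str]) -> SubsetAssignment:
    """Drop the given subset labels from an assignment.

    Unknown labels warn rather than fail (exclusion lists are atlas-specific);
    removing every subset is an error.
    """
    exclusions = list(exclusions)
    present = set(groups.subset_labels)
    unknown = [e for e in exclusions if e not in present]
    if unknown:
        logger.warning("exclusion list names absent subsets: %s", unknown)
    retained = [s for s in groups.subset_labels if s not in set(exclusions)]
    if not retained:
        raise ValidationError("all subsets excluded")
    return groups.restrict(retained)


def expression_frequency(
    cohort: ExpressionMatrix,
    genes: Sequence[str],
    detection_threshold: float = 0.0,
) -> pd.Series:
    """Fraction of cohort samples in which each gene exceeds the detection threshold.

    Genes absent from the cohort get frequency 0 with a warning — a marker
    never quantified in circulating samples cannot contribute to deconvolution.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in cohort.data.index]
    if missing:
        logger.warning("%d gene(s) absent from background cohort, frequency set to 0", len(missing))
    present = [g for g in genes if g in cohort.data.index]
    freq = pd.Series(0.0, index=pd.Index(genes, name="gene_id"))
    if present:
        detected = (cohort.data.loc[present] > detection_threshold).sum(axis=1)
        freq.loc[present] = detected / cohort.n_samples
    return freq


def filter_by_frequency(
    candidates: CandidateGeneSet,
    frequencies: Mapping[str, float] | pd.Series,
    min_freq: float = 0.1,
) -> CandidateGeneSet:
    """Retain candidates with background detection frequency strictly above ``min_freq``."""
    if not 0 <= min_freq <= 1:
        raise ValueError(f"min_freq must be in [0, 1], got {min_freq}")
    freq = pd.Series(frequencies)
    table = candidates.table.copy()
    table["frequency"] = table["gene_id"].map(freq).fillna(0.0)
    kept = table[table["frequency"] > min_freq]
    lost = set(candidates.subsets) - set(kept["subset"].unique())
    for subset in sorted(lost):
        logger.warning("frequency filter removed every candidate of subset %r", subset)
    return CandidateGeneSet(kept.reset_index(drop=True))


def condition_number(matrix: SignatureMatrix | pd.DataFrame | np.ndarray) -> float:
    """2-norm condition number (ratio of extreme singular values).

    Returns ``inf`` for rank-deficient matrices.
    """
    if isinstance(matrix, SignatureMatrix):
        values = matrix.values
    elif isinstance(matrix, pd.DataFrame):
        values = matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(matrix, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot take the condition number of an empty matrix")
    svals = np.linalg.svd(values, compute_uv=False)
    tol = max(values.shape) * np.finfo(float).eps * svals[0] if svals[0] > 0 else 0.0
    if svals[-1] <= tol:
        return RANK_DEFICIENT
    return float(svals[0] / svals[-1])


def build_signature(
    atlas: ExpressionMatrix,
    groups: SubsetAssignment,
    candidates: CandidateGeneSet,
    n: int,
    provenance: dict | None = None,
) -> SignatureMatrix:
    """Assemble the signature matrix from the top-n candidates of each subset.

    Subsets with fewer than n candidates contribute all of them.  Values are
    the mean TPM of each selected gene in each retained subset.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    subsets = [s for s in groups.subset_labels if s in set(candidates.subsets)]
    if not subsets:
        raise ValidationError("no subset has any candidate genes")
    selected: list[str] = []
    for subset in subsets:
        genes = candidates.genes_of(subset, n)
        if 0 < len(genes) < n:
            logger.info("subset %r has only %d candidates (n=%d)", subset, len(genes), n)
        selected.extend(g for g in genes if g not in selected)
    means = subset_mean_expression(atlas.subset_genes(selected), groups)[subsets]
    if means.shape[0] < means.shape[1]:
        raise ValidationError(
            f"signature with n={n} has {means.shape[0]} genes for {means.shape[1]} subsets"
        )
    kappa = condition_number(means)
    prov = {"n_per_subset": n, **(provenance or {})}
    return SignatureMatrix(means, condition_number=kappa, provenance=prov)


def optimize_signature(
    atlas: ExpressionMatrix,
    groups: SubsetAssignment,
    candidates: CandidateGeneSet,
    n_range: Iterable[int] = range(2, 151),
    provenance: dict | None = None,
) -> SignatureMatrix:
    """Pick the per-subset marker count n minimising the condition number.

    Evaluates :func:`build_signature` for every n in ``n_range`` and returns
    the matrix with minimal kappa; ties break toward smaller n (smaller bases
    generalise no worse and cost less).  The full (n, kappa) trace is stored in
    the result's provenance.
    """
    n_values = sorted(set(int(n) for n in n_range))
    if not n_values or n_values[0] < 1:
        raise ValueError("n_range must be a nonempty collection of integers >= 1")
    trace: list[tuple[int, float]] = []
    best: SignatureMatrix | None = None
    for n in n_values:
        try:
            sig = build_signature(atlas, groups, candidates, n, provenance=provenance)
        except ValidationError:
            trace.append((n, float("nan")))
            continue
        trace.append((n, sig.condition_number))
        if np.isfinite(sig.condition_number) and (
            best is None or sig.condition_number < best.condition_number
        ):
            best = sig
    if best is None:
        raise ValidationError("every n in the grid yielded a rank-deficient or invalid signature")
    best.provenance["n_trace"] = trace
    best.provenance["chosen_n"] = best.provenance.get("n_per_subset")
    return best


def merge_signatures(
    first: SignatureMatrix,
    second: SignatureMatrix,
    first_atlas_means: pd.DataFrame | None = None,
    second_atlas_means: pd.DataFrame | None = None,
) -> SignatureMatrix:
    """Stack two signature matrices (e.g. blood cells + solid tissues) side by side.

    Subset labels must be disjoint; the merged gene set is the union.  A gene
    present in only one source matrix gets, for the other source's subsets, the
    mean TPM from that source's atlas when ``*_atlas_means`` (a genes x subsets
    frame, e.g. from :func:`subset_mean_expression`) is provided, else 0.
    """
    overlap = set(first.subset_labels) & set(second.subset_labels)
    if overlap:
        raise ValidationError(f"subset labels appear in both signatures: {sorted(overlap)}")
    genes = list(dict.fromkeys(first.gene_ids + second.gene_ids))
    merged = pd.DataFrame(0.0, index=pd.Index(genes, name="gene_id"),
                          columns=first.subset_labels + second.subset_labels)
    n_filled = 0
    for sig, means in ((first, first_atlas_means), (second, second_atlas_means)):
        block = sig.data.reindex(genes)
        absent = block.index[block.isna().any(axis=1)]
        if means is not None:
            fill = means.reindex(index=genes, columns=sig.subset_labels)
            block = block.fillna(fill)
            absent = block.index[block.isna().any(axis=1)]
        block = block.fillna(0.0)
        n_filled += len(absent)
        merged[sig.subset_labels] = block
    if n_filled:
        logger.info("merge: %d gene/source pairs had no atlas mean and were zero-filled", n_filled)
    kappa = condition_number(merged)
    prov = {
        "merged_from": [first.subset_labels, second.subset_labels],
        "sources": [first.provenance, second.provenance],
    }
    return SignatureMatrix(merged, condition_number=kappa, provenance=prov)
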