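"""Data model and TSV readers/writers shared by all modules.

Expression tables follow the GTEx-style convention: genes in rows, samples in
columns, tab-separated, first column ``gene_id``.  All expression values are
TPM (transcripts per million), hence nonnegative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENE_ID_COLUMN = "gene_id"

HARMONIZE_POLICIES = ("as-is", "strip-version-suffix", "uppercase")
DUPLICATE_POLICIES = ("sum", "mean", "first", "error")


class ParseError(ValueError):
    """Malformed input table (missing header, non-numeric cell, empty file)."""


class ValidationError(ValueError):
    """Structurally valid input violating a domain invariant (e.g. negative TPM)."""


def harmonize_gene_ids(
    ids: Sequence[str], policy: str = "as-is", strict: bool = False
) -> list[str]:
    """Map gene identifiers to a canonical form.

    Policies: ``as-is`` (identity), ``strip-version-suffix`` (drop a trailing
    ``.N`` Ensembl version, e.g. ``ENSG00000139618.14`` -> ``ENSG00000139618``),
    ``uppercase``.  The mapping is deterministic and idempotent.  Collisions
    (two inputs mapping to the same output) raise under ``strict``; otherwise
    they are reported via a warning and left for the caller's duplicate policy.
    """
    if policy not in HARMONIZE_POLICIES:
        raise ValueError(f"unknown harmonization policy {policy!r}; choose from {HARMONIZE_POLICIES}")
    if policy == "as-is":
        out = [str(i) for i in ids]
    elif policy == "strip-version-suffix":
        out = [str(i).rsplit(".", 1)[0] if _has_version_suffix(str(i)) else str(i) for i in ids]
    else:
        out = [str(i).upper() for i in ids]
    seen: dict[str, str] = {}
    collisions: list[tuple[str, str, str]] = []
    for orig, new in zip(ids, out):
        if new in seen and seen[new] != orig:
            collisions.append((seen[new], str(orig), new))
        else:
            seen.setdefault(new, str(orig))
    if collisions:
        msg = "; ".join(f"{a!r} and {b!r} both map to {t!r}" for a, b, t in collisions[:10])
        if strict:
            raise ValidationError(f"gene-id collisions under policy {policy!r}: {msg}")
        logger.warning("gene-id collisions under policy %r: %s", policy, msg)
    return out


def _has_version_suffix(gene_id: str) -> bool:
    head, sep, tail = gene_id.rpartition(".")
    return bool(sep) and tail.isdigit()


@dataclass
class ExpressionMatrix:
    """Genes x samples nonnegative TPM table.

    ``data`` is indexed by gene identifier with one column per sample.
    Invariants (checked on construction): unique gene and sample identifiers,
    all values finite and >= 0, at least one gene and one sample.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValidationError("expression matrix needs at least 1 gene and 1 sample")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups[:10]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups[:10]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ParseError("expression values must be numeric")
        if not np.isfinite(values).all():
            raise ValidationError("expression matrix contains NaN or infinite values")
        if (values < 0).any():
            rows, cols = np.nonzero(values < 0)
            gene, sample = self.data.index[rows[0]], self.data.columns[cols[0]]
            raise ValidationError(f"negative TPM at gene {gene!r}, sample {sample!r}")

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample(self, sample_id: str) -> pd.Series:
        """One sample's profile as a gene-indexed Series."""
        return self.data[sample_id]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[genes])


@dataclass
class SubsetAssignment:
    """Sample -> subset (tissue or blood-cell type) mapping for a reference atlas."""

    mapping: pd.Series  # index: sample_id, values: subset label

    def __post_init__(self) -> None:
        if not isinstance(self.mapping, pd.Series):
            self.mapping = pd.Series(dict(self.mapping), dtype=object)
        if self.mapping.empty:
            raise ValidationError("subset assignment is empty")
        if self.mapping.index.has_duplicates:
            raise ValidationError("a sample is assigned to more than one subset")

    @property
    def sample_ids(self) -> list[str]:
        return self.mapping.index.tolist()

    @property
    def subset_labels(self) -> list[str]:
        return sorted(self.mapping.unique().tolist())

    def samples_of(self, subset: str) -> list[str]:
        return self.mapping.index[self.mapping == subset].tolist()

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = set(self.sample_ids) - set(matrix.sample_ids)
        if missing:
            raise ValidationError(
                f"assigned samples absent from expression matrix: {sorted(missing)[:10]}"
            )

    def restrict(self, subsets: Iterable[str]) -> "SubsetAssignment":
        keep = self.mapping[self.mapping.isin(list(subsets))]
        return SubsetAssignment(keep)


@dataclass
class SignatureMatrix:
    """Signature genes x subsets basis of mean TPM per subset.

    ``condition_number`` is the 2-norm condition number of ``data`` (ratio of
    extreme singular values); ``provenance`` records how the matrix was built.
    """

    data: pd.DataFrame  # index: gene_id, columns: subset labels
    condition_number: float = float("nan")
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValidationError("signature matrix has duplicate gene or subset identifiers")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all() or (values < 0).any():
            raise ValidationError("signature values must be finite and nonnegative")
        if self.data.shape[0] < self.data.shape[1]:
            raise ValidationError(
                f"signature has fewer genes ({self.data.shape[0]}) than subsets ({self.data.shape[1]})"
            )

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def subset_labels(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_subsets(self) -> int:
        return self.data.shape[1]


@dataclass
class DeconvolutionResult:
    """Per-sample deconvolution output for one solver.

    ``raw_coefficients`` are the solver's regression weights; ``relative_fractions``
    are their nonnegative part normalized to sum to one (all-zero with
    ``degenerate=True`` when no coefficient is positive); ``absolute_scores`` are
    the unnormalized nonnegative parts, comparable across samples run against
    the same signature.
    """

    sample_id: str
    method: str
    subset_labels: list[str]
    raw_coefficients: np.ndarray
    relative_fractions: np.ndarray
    absolute_scores: np.ndarray
    pcc: float
    rmse: float
    degenerate: bool = False
    empirical_p: float | None = None
    hyperparameters: dict = field(default_factory=dict)
    matched_fraction: float = float("nan")

    def __post_init__(self) -> None:
        self.raw_coefficients = np.asarray(self.raw_coefficients, dtype=float)
        self.relative_fractions = np.asarray(self.relative_fractions, dtype=float)
        self.absolute_scores = np.asarray(self.absolute_scores, dtype=float)
        if (self.absolute_scores < 0).any():
            raise ValidationError("absolute scores must be nonnegative")
        if self.rmse < 0:
            raise ValidationError("RMSE must be nonnegative")
        total = self.relative_fractions.sum()
        if not self.degenerate and abs(total - 1.0) > 1e-8:
            raise ValidationError(f"relative fractions sum to {total}, expected 1")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path: str | Path,
    sep: str = "\t",
    duplicate_policy: str = "sum",
    harmonize: str = "as-is",
) -> ExpressionMatrix:
    """Read a genes x samples TSV/CSV into an :class:`ExpressionMatrix`.

    The first column holds gene identifiers, the header row sample identifiers.
    Duplicate gene rows (including duplicates created by identifier
    harmonization) are resolved per ``duplicate_policy``: ``sum`` (default —
    TPM of duplicated annotations is additive), ``mean``, ``first`` or
    ``error``.
    """
    path = Path(path)
    if duplicate_policy not in DUPLICATE_POLICIES:
        raise ValueError(f"unknown duplicate policy {duplicate_policy!r}")
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    if frame.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found (missing header?)")
    bad = frame.columns[frame.dtypes == object]
    if len(bad) > 0:
        col = bad[0]
        row = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()].index
        raise ParseError(
            f"{path}: non-numeric value in column {col!r}"
            + (f", row {row[0]!r}" if len(row) else "")
        )
    frame.index = pd.Index(
        harmonize_gene_ids(frame.index.astype(str).tolist(), harmonize), name=GENE_ID_COLUMN
    )
    if frame.index.has_duplicates:
        n_dup = int(frame.index.duplicated().sum())
        if duplicate_policy == "error":
            raise ValidationError(f"{path}: {n_dup} duplicate gene rows")
        logger.warning("%s: resolving %d duplicate gene rows with policy %r", path, n_dup, duplicate_policy)
        grouped = frame.groupby(level=0, sort=False)
        frame = {"sum": grouped.sum, "mean": grouped.mean, "first": grouped.first}[duplicate_policy]()
    return ExpressionMatrix(frame.astype(float))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    frame = matrix.data.copy()
    frame.index.name = GENE_ID_COLUMN
    frame.to_csv(Path(path), sep=sep)


def read_subset_assignment(path: str | Path, sep: str = "\t") -> SubsetAssignment:
    """Read a two-column sample -> subset table (header ``sample_id<TAB>subset``)."""
    frame = pd.read_csv(Path(path), sep=sep, comment="#")
    if frame.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (sample_id, subset)")
    mapping = pd.Series(frame.iloc[:, 1].astype(str).values, index=frame.iloc[:, 0].astype(str))
    return SubsetAssignment(mapping)


def write_subset_assignment(groups: SubsetAssignment, path: str | Path, sep: str = "\t") -> None:
    frame = pd.DataFrame({"sample_id": groups.mapping.index, "subset": groups.mapping.values})
    frame.to_csv(Path(path), sep=sep, index=False)


def read_signature_matrix(path: str | Path, sep: str = "\t") -> SignatureMatrix:
    """Read a signature TSV with its ``#``-prefixed provenance header."""
    path = Path(path)
    provenance: dict = {}
    with open(path) as handle:
        for line in handle:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, value = line.lstrip("# ").rstrip("\n").partition("=")
                provenance[key.strip()] = _parse_scalar(value.strip())
    frame = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    cond = float(provenance.pop("condition_number", float("nan")))
    return SignatureMatrix(frame.astype(float), condition_number=cond, provenance=provenance)


def write_signature_matrix(sig: SignatureMatrix, path: str | Path, sep: str = "\t") -> None:
    path = Path(path)
    with open(path, "w") as handle:
        handle.write(f"# condition_number = {sig.condition_number!r}\n")
        for key, value in sig.provenance.items():
            handle.write(f"# {key} = {value!r}\n")
        frame = sig.data.copy()
        frame.index.name = GENE_ID_COLUMN
        frame.to_csv(handle, sep=sep)


def _parse_scalar(text: str):
    text = text.strip("'\"")
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


def results_to_frame(results: Sequence[DeconvolutionResult]) -> pd.DataFrame:
    """Flatten results to one row per sample x method.

    Columns: ``sample``, ``method``, ``rel_<subset>`` for relative fractions,
    ``abs_<subset>`` for absolute scores, then ``pcc``, ``rmse``, ``p_value``,
    ``degenerate`` and the chosen hyperparameters.
    """
    if not results:
        raise ValidationError("no results to write")
    labels = results[0].subset_labels
    rows = []
    for res in results:
        if res.subset_labels != labels:
            raise ValidationError("results mix different subset label sets")
        row: dict = {"sample": res.sample_id, "method": res.method}
        row.update({f"rel_{s}": v for s, v in zip(labels, res.relative_fractions)})
        row.update({f"abs_{s}": v for s, v in zip(labels, res.absolute_scores)})
        row["pcc"] = res.pcc
        row["rmse"] = res.rmse
        row["p_value"] = res.empirical_p if res.empirical_p is not None else float("nan")
        row["degenerate"] = res.degenerate
        row["hyperparameters"] = ";".join(f"{k}={v}" for k, v in sorted(res.hyperparameters.items()))
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(results: Sequence[DeconvolutionResult], path: str | Path, sep: str = "\t") -> None:
    """Write a results table; ``rel_*`` columns are relative fractions, ``abs_*`` absolute scores."""
    frame = results_to_frame(results)
    with open(Path(path), "w") as handle:
        handle.write("# rel_<subset>: relative fraction; abs_<subset>: absolute score\n")
        frame.to_csv(handle, sep=sep, index=False)


def read_results(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(Path(path), sep=sep, comment="#")
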