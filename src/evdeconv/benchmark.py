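"""Model comparison, spike-in detection-limit experiments, and downstream
statistics on estimated fractions."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .deconvolution import SolverOptions, deconvolve, deconvolve_sample
from .io import ExpressionMatrix, SignatureMatrix, ValidationError

logger = logging.getLogger(__name__)

SHAPIRO_ALPHA = 0.05


@dataclass
class ModelComparison:
    """Aggregates from running several solvers on the same mixture cohort.

    ``pcc``/``rmse``: samples x models reconstruction fit;
    ``detection_frequency``: subsets x models, fraction of samples in which the
    subset's relative fraction is strictly positive;
    ``estimate_variance``: subsets x models variance of the relative fraction
    across samples; ``fractions``: per-model samples x subsets tables.
    """

    pcc: pd.DataFrame
    rmse: pd.DataFrame
    detection_frequency: pd.DataFrame
    estimate_variance: pd.DataFrame
    fractions: dict[str, pd.DataFrame]


def compare_models(
    mixtures: ExpressionMatrix,
    sig: SignatureMatrix,
    models: Sequence[str | SolverOptions],
    base_options: SolverOptions = SolverOptions(),
) -> ModelComparison:
    """Run each solver on every sample and aggregate fit and stability metrics.

    A model failing on every sample is excluded with a warning.
    """
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    if mixtures.n_samples < 2:
        raise ValueError("need at least two samples")
    pcc, rmse, det, var, fractions = {}, {}, {}, {}, {}
    for model in models:
        options = model if isinstance(model, SolverOptions) else replace(base_options, method=model)
        name = options.method
        results, failures = deconvolve(mixtures, sig, options)
        if not results:
            logger.warning("model %r failed on all samples, excluded: %s", name, failures[:3])
            continue
        frame = pd.DataFrame(
            {r.sample_id: r.relative_fractions for r in results},
            index=sig.subset_labels,
        ).T
        fractions[name] = frame
        pcc[name] = pd.Series({r.sample_id: r.pcc for r in results})
        rmse[name] = pd.Series({r.sample_id: r.rmse for r in results})
        det[name] = (frame > 0).mean(axis=0)
        var[name] = frame.var(axis=0)
    if not fractions:
        raise ValidationError("every model failed on every sample")
    return ModelComparison(
        pcc=pd.DataFrame(pcc),
        rmse=pd.DataFrame(rmse),
        detection_frequency=pd.DataFrame(det),
        estimate_variance=pd.DataFrame(var),
        fractions=fractions,
    )


@dataclass
class SpikeInCurve:
    """Recovery of a known spiked-in component across a proportion grid.

    ``table`` columns: true_fraction, estimated_fraction, abs_error, within_tol.
    ``max_in_tolerance`` is the largest true proportion recovered within the
    tolerance (NaN if none).
    """

    table: pd.DataFrame
    tolerance: float
    spike_subsets: list[str]

    @property
    def max_in_tolerance(self) -> float:
        ok = self.table.loc[self.table["within_tol"], "true_fraction"]
        return float(ok.max()) if len(ok) else float("nan")


def spike_in_experiment(
    background: pd.Series,
    spike: pd.Series,
    sig: SignatureMatrix,
    spike_subsets: Sequence[str],
    grid: Sequence[float] = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2)),
    noise_sigma: float = 0.1,
    tolerance: float = 0.05,
    seed: int = 0,
    options: SolverOptions = SolverOptions(),
) -> SpikeInCurve:
    """Mix a spike profile into a background at each grid proportion and
    measure how well the deconvolution recovers the spiked subset's fraction.

    For each grid point f the mixture is ``(1-f)*background + f*spike`` with
    per-gene multiplicative log-normal noise ``exp(N(0, sigma^2))`` (noise is
    multiplicative so TPMs stay nonnegative).  The estimated spiked fraction is
    the summed relative fraction of ``spike_subsets``.
    """
    unknown = [s for s in spike_subsets if s not in sig.subset_labels]
    if unknown:
        raise ValidationError(f"spike subsets absent from signature: {unknown}")
    grid = [float(f) for f in grid]
    if any(f < 0 or f > 1 for f in grid) or sorted(grid) != grid or len(set(grid)) != len(grid):
        raise ValueError("grid must be strictly increasing within [0, 1]")
    genes = background.index.intersection(spike.index)
    if len(genes) == 0:
        raise ValidationError("background and spike profiles share no genes")
    bg = background.loc[genes].to_numpy(dtype=float)
    sp = spike.loc[genes].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    spike_idx = [sig.subset_labels.index(s) for s in spike_subsets]
    rows = []
    for f in grid:
        mix = (1 - f) * bg + f * sp
        if noise_sigma > 0:
            mix = mix * rng.lognormal(mean=0.0, sigma=noise_sigma, size=mix.shape)
        profile = pd.Series(mix, index=genes)
        res = deconvolve_sample(profile, sig, options, sample_id=f"spike_{f:.2f}")
        est = float(res.relative_fractions[spike_idx].sum())
        err = abs(est - f)
        rows.append((f, est, err, err <= tolerance))
    table = pd.DataFrame(rows, columns=["true_fraction", "estimated_fraction", "abs_error", "within_tol"])
    return SpikeInCurve(table=table, tolerance=tolerance, spike_subsets=list(spike_subsets))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    Equals the probability that a random positive outranks a random negative,
    with ties counted one half.  Higher score is treated as the positive
    direction; orientation is never flipped automatically.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs both classes present")
    ranks = scipy.stats.rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc)


def group_difference_test(
    values: Sequence[float], groups: Sequence
) -> tuple[str, float, float]:
    """Two-group comparison with a normality-gated choice of test.

    Shapiro-Wilk is run on each group at alpha 0.05; if both look normal a
    two-sided two-sample t-test is used, otherwise a two-sided Wilcoxon
    rank-sum (Mann-Whitney with tie correction).  Returns
    ``(test name, statistic, p)``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {len(labels)}")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")
    normal = True
    for sample in (a, b):
        if np.ptp(sample) == 0:
            normal = False  # constant group: Shapiro undefined, fall back to ranks
            continue
        _, p_sw = scipy.stats.shapiro(sample)
        if p_sw < SHAPIRO_ALPHA:
            normal = False
    if normal:
        stat, p = scipy.stats.ttest_ind(a, b)
        return "t-test", float(stat), float(p)
    stat, p = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
    return "wilcoxon-rank-sum", float(stat), float(p)
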