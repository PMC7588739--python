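"""Monte-Carlo empirical p-value for the deconvolution of one mixture.

Null hypothesis: the mixture contains none of the signature's subsets — its
expression over the signature genes is no more explainable by the basis than a
random gene set of the same size drawn from the same profile.  Each iteration
draws such a random gene set (without replacement), assigns its values to the
signature gene positions, re-solves the deconvolution, and records the
reconstruction Pearson R.  The one-sided p-value compares the observed R to
this null distribution with an add-one correction, so p is never exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .deconvolution import (
    NormalizedPair,
    SolverOptions,
    match_and_normalize,
    reconstruction_fit,
    solve,
)
from .io import DeconvolutionResult, SignatureMatrix, ValidationError


@dataclass(frozen=True)
class PermutationConfig:
    """Monte-Carlo settings: iteration count (default 500), seed, and whether
    stochastic hyperparameters (the SVR nu) are re-selected inside each null
    fit (default) or frozen at the observed sample's choice (cheaper)."""

    n_iter: int = 500
    seed: int = 0
    reuse_hyperparameters: bool = False

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


def empirical_pvalue(
    mixture: pd.Series,
    sig: SignatureMatrix,
    options: SolverOptions = SolverOptions(),
    config: PermutationConfig = PermutationConfig(),
    observed: DeconvolutionResult | None = None,
) -> tuple[float, float]:
    """Observed reconstruction R and its Monte-Carlo empirical p-value.

    ``p = (1 + #{R_null >= R_obs}) / (1 + n_iter)``.  The mixture must contain
    more genes than the matched signature gene set, or there is nothing to
    draw null gene sets from.  Pass ``observed`` (a result already computed
    for this sample/signature/options) to skip re-solving the observed fit.
    """
    pair = match_and_normalize(mixture, sig, options)
    if observed is not None:
        r_obs = observed.pcc
    else:
        raw, _ = solve(pair, options)
        r_obs, _ = reconstruction_fit(pair, raw)
    # an undefined correlation (e.g. an all-zero constrained fit) is the worst
    # possible evidence of signal; ranking it below every defined R — and tying
    # with other undefined ones — keeps observed and null draws exchangeable
    if not np.isfinite(r_obs):
        r_obs = -np.inf

    n_total = mixture.shape[0]
    m = pair.matched_count
    if n_total <= m:
        raise ValidationError(
            f"mixture has {n_total} genes, not more than the {m} matched signature genes; "
            "cannot draw null gene sets"
        )
    null_options = options
    if config.reuse_hyperparameters and options.method == "svr" and observed is not None:
        nu = observed.hyperparameters.get("nu")
        if nu is not None:
            null_options = replace(options, nu_grid=(float(nu),))

    rng = np.random.default_rng(config.seed)
    values = mixture.to_numpy(dtype=float)
    exceed = 0
    for _ in range(config.n_iter):
        idx = rng.choice(n_total, size=m, replace=False)
        y = values[idx]
        sd = y.std()
        r_null = -np.inf
        if sd > 0:
            y = (y - y.mean()) / sd
            null_pair = NormalizedPair(
                genes=pair.genes,
                mixture=y,
                basis=pair.basis,
                subset_labels=pair.subset_labels,
                matched_count=m,
                matched_fraction=pair.matched_fraction,
                mixture_scale=sd,
                basis_scale=pair.basis_scale,
            )
            try:
                raw, _ = solve(null_pair, null_options)
                r, _ = reconstruction_fit(null_pair, raw)
                if np.isfinite(r):
                    r_null = r
            except (ValidationError, ValueError):
                pass
        if r_null >= r_obs:
            exceed += 1
    p = (1 + exceed) / (1 + config.n_iter)
    return float(r_obs), float(p)
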