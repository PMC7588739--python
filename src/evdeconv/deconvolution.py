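"""Mixture deconvolution: solve mixture = signature x proportions per sample.

The core solver is linear-kernel nu-support-vector regression (nu-SVR) with
the regularisation fraction nu selected per sample by minimum reconstruction
RMSE over a grid — the approach popularised for immune-cell deconvolution and
adopted here for circulating-EV profiles.  Five comparator solvers (NNLS, QP,
OLS, robust linear regression, ridge) share the same pre-processing so their
coefficients are directly comparable.

Pre-processing z-scores the mixture vector and, by default, each signature
column over the matched gene set; the SVR epsilon-tube geometry is only
meaningful when mixture and basis live on a common scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import statsmodels.api as sm
from sklearn.svm import NuSVR

from .io import (
    DeconvolutionResult,
    ExpressionMatrix,
    SignatureMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)

SOLVER_NAMES = ("svr", "nnls", "qp", "ols", "rlr", "ridge")

DEFAULT_NU_GRID = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))
DEFAULT_RIDGE_GRID = tuple(np.logspace(-4, 4, 33))

HUBER_TUNING = 1.345
RLR_TOL = 1e-6
RLR_MAX_ITER = 100


@dataclass(frozen=True)
class SolverOptions:
    """Configuration shared by all solvers.

    ``standardize`` is ``"both"`` (z-score mixture and signature columns) or
    ``"mixture-only"``; ``qp_mode`` is ``"nonneg"`` or ``"nonneg-sum-to-one"``.
    ``ridge_lambda=None`` selects the penalty by generalized cross-validation.
    """

    method: str = "svr"
    nu_grid: tuple[float, ...] = DEFAULT_NU_GRID
    ridge_lambda: float | None = None
    qp_mode: str = "nonneg"
    standardize: str = "both"

    def __post_init__(self) -> None:
        if self.method not in SOLVER_NAMES:
            raise ValueError(f"unknown method {self.method!r}; choose from {SOLVER_NAMES}")
        if not self.nu_grid or not all(0 < v < 1 for v in self.nu_grid):
            raise ValueError("nu grid values must lie strictly inside (0, 1)")
        if self.ridge_lambda is not None and self.ridge_lambda < 0:
            raise ValueError("ridge penalty must be nonnegative")
        if self.qp_mode not in ("nonneg", "nonneg-sum-to-one"):
            raise ValueError(f"unknown qp mode {self.qp_mode!r}")
        if self.standardize not in ("both", "mixture-only"):
            raise ValueError(f"unknown standardization scheme {self.standardize!r}")


@dataclass
class NormalizedPair:
    """A mixture vector and signature basis restricted to their shared genes and standardized.

    ``mixture_scale`` and ``basis_scale`` record the standard deviations
    divided out during standardization, so coefficients fitted in standardized
    space can be mapped back to the raw signature scale with :meth:`descale`.
    """

    genes: list[str]
    mixture: np.ndarray          # (n_genes,), mean 0
    basis: np.ndarray            # (n_genes, n_subsets)
    subset_labels: list[str]
    matched_count: int
    matched_fraction: float
    mixture_scale: float = 1.0
    basis_scale: np.ndarray | None = None  # (n_subsets,); None means unscaled columns

    def descale(self, coef: np.ndarray) -> np.ndarray:
        """Map standardized-space coefficients to the raw signature scale."""
        coef = np.asarray(coef, dtype=float) * self.mixture_scale
        if self.basis_scale is not None:
            coef = coef / self.basis_scale
        return coef


def match_and_normalize(
    mixture: pd.Series,
    sig: SignatureMatrix,
    options: SolverOptions = SolverOptions(),
) -> NormalizedPair:
    """Intersect mixture and signature genes and standardize both sides.

    The mixture is z-scored to mean 0, variance 1 over the matched genes;
    signature columns are z-scored too unless ``standardize="mixture-only"``.
    Requires at least ``max(10, n_subsets)`` matched genes; a constant mixture
    (zero variance) cannot be standardized and is rejected.
    """
    matched = [g for g in sig.gene_ids if g in mixture.index]
    required = max(10, sig.n_subsets)
    if len(matched) < required:
        raise ValidationError(
            f"only {len(matched)} of {len(sig.gene_ids)} signature genes matched; need >= {required}"
        )
    dropped = len(sig.gene_ids) - len(matched)
    if dropped:
        logger.warning("%d signature gene(s) missing from mixture, dropped", dropped)
    y = mixture.loc[matched].to_numpy(dtype=float)
    sd = float(y.std())
    if sd == 0:
        raise ValidationError("mixture is constant over matched genes; cannot standardize")
    y = (y - y.mean()) / sd
    basis = sig.data.loc[matched].to_numpy(dtype=float)
    basis_scale = None
    if options.standardize == "both":
        col_sd = basis.std(axis=0)
        col_sd[col_sd == 0] = 1.0
        basis = (basis - basis.mean(axis=0)) / col_sd
        basis_scale = col_sd
    return NormalizedPair(
        genes=matched,
        mixture=y,
        basis=basis,
        subset_labels=sig.subset_labels,
        matched_count=len(matched),
        matched_fraction=len(matched) / len(sig.gene_ids),
        mixture_scale=sd,
        basis_scale=basis_scale,
    )


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------

def solve_nu_svr(
    pair: NormalizedPair, nu_grid: Sequence[float] = DEFAULT_NU_GRID
) -> tuple[np.ndarray, float, pd.DataFrame]:
    """Fit a linear-kernel nu-SVR for each nu; keep the fit with minimal RMSE.

    Returns ``(coefficients, chosen_nu, trace)`` where ``trace`` holds the
    per-nu RMSE of the reconstruction (basis @ coefficients vs mixture).
    Ties in RMSE resolve to the smaller nu (fewer support vectors).
    """
    records: list[tuple[float, float]] = []
    fits: dict[float, np.ndarray] = {}
    errors: list[str] = []
    for nu in nu_grid:
        try:
            model = NuSVR(kernel="linear", nu=float(nu), C=1.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(pair.basis, pair.mixture)
            coef = model.coef_.ravel().astype(float)
        except Exception as exc:  # noqa: BLE001 - per-nu failure is recoverable
            errors.append(f"nu={nu}: {exc}")
            records.append((float(nu), float("nan")))
            continue
        rmse = _rmse(pair.basis @ coef, pair.mixture)
        fits[float(nu)] = coef
        records.append((float(nu), rmse))
    trace = pd.DataFrame(records, columns=["nu", "rmse"])
    if not fits:
        raise ValidationError("nu-SVR failed for every nu: " + "; ".join(errors))
    valid = trace.dropna()
    best_rmse = valid["rmse"].min()
    chosen = float(valid.loc[np.isclose(valid["rmse"], best_rmse), "nu"].min())
    return fits[chosen], chosen, trace


def solve_nnls(pair: NormalizedPair) -> np.ndarray:
    """Least squares with all coefficients constrained nonnegative."""
    coef, _ = scipy.optimize.nnls(pair.basis, pair.mixture)
    return coef


def solve_qp(pair: NormalizedPair, mode: str = "nonneg") -> np.ndarray:
    """Quadratic program: minimise the squared reconstruction error.

    ``nonneg`` constrains x >= 0 (same optimum as NNLS, different solver);
    ``nonneg-sum-to-one`` additionally imposes sum(x) = 1.
    """
    if mode == "nonneg":
        result = scipy.optimize.lsq_linear(pair.basis, pair.mixture, bounds=(0, np.inf))
        if not result.success:
            raise ValidationError(f"QP solver failed: {result.message}")
        return np.asarray(result.x, dtype=float)
    if mode != "nonneg-sum-to-one":
        raise ValueError(f"unknown qp mode {mode!r}")
    A, b = pair.basis, pair.mixture
    p = A.shape[1]

    def objective(x: np.ndarray) -> float:
        r = A @ x - b
        return 0.5 * float(r @ r)

    def gradient(x: np.ndarray) -> np.ndarray:
        return A.T @ (A @ x - b)

    x0 = np.full(p, 1.0 / p)
    result = scipy.optimize.minimize(
        objective,
        x0,
        jac=gradient,
        bounds=[(0.0, None)] * p,
        constraints=[{"type": "eq", "fun": lambda x: x.sum() - 1.0, "jac": lambda x: np.ones(p)}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    if not result.success:
        raise ValidationError(f"QP (sum-to-one) solver failed: {result.message}")
    return np.asarray(result.x, dtype=float)


def solve_ols(pair: NormalizedPair) -> np.ndarray:
    """Unconstrained least squares; minimum-norm solution (with a warning) when rank-deficient."""
    coef, _, rank, _ = np.linalg.lstsq(pair.basis, pair.mixture, rcond=None)
    if rank < pair.basis.shape[1]:
        logger.warning("signature is rank-deficient (rank %d < %d); minimum-norm OLS solution",
                       rank, pair.basis.shape[1])
    return np.asarray(coef, dtype=float)


def solve_rlr(pair: NormalizedPair) -> np.ndarray:
    """Robust linear regression: Huber M-estimation, iteratively reweighted."""
    model = sm.RLM(pair.mixture, pair.basis, M=sm.robust.norms.HuberT(t=HUBER_TUNING))
    try:
        fit = model.fit(maxiter=RLR_MAX_ITER, tol=RLR_TOL)
    except Exception as exc:  # pragma: no cover - statsmodels failure path
        raise ValidationError(f"robust regression failed: {exc}") from exc
    if not getattr(fit, "converged", True):
        logger.warning("robust regression did not converge in %d iterations; using last iterate",
                       RLR_MAX_ITER)
    return np.asarray(fit.params, dtype=float)


def solve_ridge(
    pair: NormalizedPair,
    ridge_lambda: float | None = None,
    lambda_grid: Sequence[float] = DEFAULT_RIDGE_GRID,
) -> tuple[np.ndarray, float]:
    """Ridge regression (BtB + lambda I)^-1 Bt a; GCV over a log grid when lambda is unset."""
    if ridge_lambda is not None and ridge_lambda < 0:
        raise ValueError("ridge penalty must be nonnegative")
    A, b = pair.basis, pair.mixture
    if ridge_lambda is None:
        ridge_lambda = _gcv_lambda(A, b, lambda_grid)
    p = A.shape[1]
    coef = np.linalg.solve(A.T @ A + ridge_lambda * np.eye(p), A.T @ b)
    return np.asarray(coef, dtype=float), float(ridge_lambda)


def _gcv_lambda(A: np.ndarray, b: np.ndarray, grid: Sequence[float]) -> float:
    """Generalized cross-validation score minimised over the penalty grid."""
    n = A.shape[0]
    U, s, _ = np.linalg.svd(A, full_matrices=False)
    Utb = U.T @ b
    best_lambda, best_score = None, np.inf
    for lam in grid:
        shrink = s**2 / (s**2 + lam)
        fitted = U @ (shrink * Utb)
        rss = float(np.sum((b - fitted) ** 2))
        dof = n - float(shrink.sum())
        score = n * rss / dof**2
        if score < best_score:
            best_lambda, best_score = float(lam), score
    return best_lambda


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------

def to_relative(raw: np.ndarray) -> tuple[np.ndarray, bool]:
    """Truncate negatives to zero and normalise to sum 1.

    Returns ``(fractions, degenerate)``; when no coefficient is positive the
    fractions are all zero and the degenerate flag is set.
    """
    clipped = np.clip(np.asarray(raw, dtype=float), 0, None)
    total = clipped.sum()
    if total <= 0:
        return np.zeros_like(clipped), True
    return clipped / total, False


def to_absolute(raw: np.ndarray) -> np.ndarray:
    """Truncated raw coefficients, unnormalised — comparable across samples
    processed with the same signature and normalization."""
    return np.clip(np.asarray(raw, dtype=float), 0, None)


def reconstruction_fit(pair: NormalizedPair, raw: np.ndarray) -> tuple[float, float]:
    """Pearson correlation and RMSE between basis @ coefficients and the mixture.

    PCC is NaN when the reconstruction has zero variance.
    """
    recon = pair.basis @ np.asarray(raw, dtype=float)
    rmse = _rmse(recon, pair.mixture)
    if recon.std() == 0 or pair.mixture.std() == 0:
        return float("nan"), rmse
    pcc = float(np.corrcoef(recon, pair.mixture)[0, 1])
    return pcc, rmse


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


def solve(pair: NormalizedPair, options: SolverOptions) -> tuple[np.ndarray, dict]:
    """Dispatch to the configured solver; returns (raw coefficients, chosen hyperparameters)."""
    if options.method == "svr":
        coef, nu, _ = solve_nu_svr(pair, options.nu_grid)
        return coef, {"nu": nu}
    if options.method == "nnls":
        return solve_nnls(pair), {}
    if options.method == "qp":
        return solve_qp(pair, options.qp_mode), {"mode": options.qp_mode}
    if options.method == "ols":
        return solve_ols(pair), {}
    if options.method == "rlr":
        return solve_rlr(pair), {}
    if options.method == "ridge":
        coef, lam = solve_ridge(pair, options.ridge_lambda)
        return coef, {"lambda": lam}
    raise ValueError(f"unknown method {options.method!r}")


def deconvolve_sample(
    mixture: pd.Series,
    sig: SignatureMatrix,
    options: SolverOptions = SolverOptions(),
    sample_id: str = "sample",
) -> DeconvolutionResult:
    """Run the full per-sample pipeline: match/normalize, solve, post-process.

    Solvers operate in standardized space (where the fit metrics are
    measured); reported coefficients are mapped back to the raw signature
    scale so relative fractions are proportions of signature-column units.
    """
    pair = match_and_normalize(mixture, sig, options)
    fitted, hyper = solve(pair, options)
    pcc, rmse = reconstruction_fit(pair, fitted)
    raw = pair.descale(fitted)
    relative, degenerate = to_relative(raw)
    absolute = to_absolute(raw)
    return DeconvolutionResult(
        sample_id=sample_id,
        method=options.method,
        subset_labels=pair.subset_labels,
        raw_coefficients=raw,
        relative_fractions=relative,
        absolute_scores=absolute,
        pcc=pcc,
        rmse=rmse,
        degenerate=degenerate,
        hyperparameters=hyper,
        matched_fraction=pair.matched_fraction,
    )


def deconvolve(
    mixtures: ExpressionMatrix,
    sig: SignatureMatrix,
    options: SolverOptions = SolverOptions(),
    permutations: "PermutationConfig | None" = None,
) -> tuple[list[DeconvolutionResult], list[tuple[str, str]]]:
    """Deconvolve every sample of a mixture matrix.

    Per-sample failures are recorded and the run continues; the second return
    value lists ``(sample_id, error message)`` pairs.  With ``permutations``
    set, a Monte-Carlo empirical p-value is attached to each result.
    """
    from .significance import empirical_pvalue  # local import to avoid a cycle

    results: list[DeconvolutionResult] = []
    failures: list[tuple[str, str]] = []
    for sample_id in mixtures.sample_ids:
        profile = mixtures.sample(sample_id)
        try:
            res = deconvolve_sample(profile, sig, options, sample_id=sample_id)
            if permutations is not None:
                _, p = empirical_pvalue(profile, sig, options, permutations, observed=res)
                res.empirical_p = p
        except (ValidationError, ValueError) as exc:
            failures.append((sample_id, str(exc)))
            logger.warning("sample %r failed: %s", sample_id, exc)
            continue
        results.append(res)
    return results, failures
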