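"""Sparsity selection by element-deletion cross-validation with EM imputation.

Row-wise holdout cannot validate an unsupervised factorization (every row is
needed to place every sample on the circle), so folds delete a speckled 1/K
of the *elements* of X instead.  Deleted entries are imputed by alternating
the sparse-cyclic-PCA fit with reconstruction from its rank-2 approximation
-- an expectation-maximization scheme -- and the mean squared error between
the true and final imputed values is the CV error.  A clear interior minimum
of the error over the sparsity grid selects s*; a curve whose minimum sits
at the sparsest grid point, or that never rises meaningfully above its
minimum, flags data with no exploitable rhythmic structure (pure noise, or
samples confined to an arc of the cycle).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .scpca import ScpcaFit, fit_multistart, fit_once

__all__ = [
    "DeletionPattern",
    "CvResult",
    "ImputationDivergence",
    "make_deletion_patterns",
    "impute_fit",
    "cross_validate",
    "default_s_grid",
]

DEFAULT_K = 5
DEFAULT_REPEATS = 3
DEFAULT_CV_RESTARTS = 3
DEFAULT_EM_TOL = 1e-6
DEFAULT_MAX_EM_ITER = 60
DEFAULT_EM_INNER_ITER = 3
# inner-fit settings for the cold multistart that seeds the EM: looser than
# the final fit (imputation errors are compared at the 1e-2 scale)
CV_FIT_TOL = 1e-5
CV_ANGLE_TOL = 1e-5
CV_MAX_ITER = 100
# CV-level EM tolerance: imputed entries are O(1) for standardized data and
# the error curve is read at the 1e-2 scale
CV_EM_TOL = 1e-3


class ImputationDivergence(RuntimeError):
    """EM imputation error grew far beyond its starting value."""


@dataclasses.dataclass
class DeletionPattern:
    """Assignment of every matrix element to one of K folds.

    Folds are circularly shifted pseudo-diagonals: element (i, j) belongs to
    fold ((j - c*i + o) mod K) + 1 for a random offset o and a stride c
    coprime with K.  Every row and every column then touches every fold
    (for N, p >= K), spreading the deletions evenly over samples and
    features.  Fold sizes are exactly balanced when K divides N or p.
    """

    fold_assignment: np.ndarray  # N x p ints in 1..K
    K: int
    offset: int
    stride: int

    def mask(self, fold: int) -> np.ndarray:
        """Boolean N x p mask of the elements deleted in ``fold``."""
        if not 1 <= fold <= self.K:
            raise ValueError(f"fold must be in 1..{self.K}")
        return self.fold_assignment == fold


def make_deletion_patterns(
    N: int, p: int, K: int, seed: int, repeats: int = 1
) -> List[DeletionPattern]:
    """One pseudo-diagonal deletion pattern per repeat."""
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > min(N, p):
        raise ValueError(f"K={K} exceeds min(N, p)={min(N, p)}")
    rng = np.random.default_rng(seed)
    strides = [c for c in range(1, max(K, 2)) if math.gcd(c, K) == 1]
    i = np.arange(N)[:, None]
    j = np.arange(p)[None, :]
    patterns = []
    for _ in range(repeats):
        o = int(rng.integers(K))
        c = int(strides[rng.integers(len(strides))])
        fold = ((j - c * i + o) % K) + 1
        patterns.append(DeletionPattern(fold_assignment=fold, K=K,
                                        offset=o, stride=c))
    return patterns


def impute_fit(
    X: np.ndarray,
    held_out: np.ndarray,
    s: float,
    seed: int = 0,
    max_em_iter: int = DEFAULT_MAX_EM_ITER,
    tol: float = DEFAULT_EM_TOL,
    restarts: int = DEFAULT_CV_RESTARTS,
    max_iter: int = CV_MAX_ITER,
    fit_tol: float = CV_FIT_TOL,
    init_values: Optional[np.ndarray] = None,
    init_fit: Optional[ScpcaFit] = None,
    angle_tol: float = CV_ANGLE_TOL,
    em_inner_iter: Optional[int] = None,
) -> tuple:
    """Fit scPCA on X with held-out entries imputed by EM.

    Held-out entries start at the column means of the retained entries
    (about zero for standardized data).  The first sweep fits the model on
    the filled matrix from ``restarts`` cold initializations; every later
    sweep refits from the previous solution -- to full convergence by
    default, or by ``em_inner_iter`` alternating updates when set -- and
    overwrites the held-out entries with the rank-2 reconstruction
    d(u1 v1' + u2 v2').  Interleaving a few fit iterations with each
    imputation update (classical EM-PCA style; ``cross_validate`` uses 3)
    keeps sweeps cheap while letting the joint iteration run to
    convergence, which matters statistically: at overly dense sparsity the
    EM progressively overfits the retained noise and the held-out error
    *rises* before the iteration settles, and that rise is the signal
    that lets cross-validation reject dense solutions.  Truncating the
    loop early suppresses it and biases selection toward denser s.

    The loop stops when the held-out entries change by less than ``tol``
    (relative Frobenius) or after ``max_em_iter`` sweeps.  Returns the
    final fit and the mean squared imputation error on the held-out
    entries.

    ``init_values`` (starting values for the held-out entries) and
    ``init_fit`` (a solution to warm-start from, bypassing the cold
    multistart) support continuation along a sparsity path, where the
    solution at one grid point seeds the next.
    """
    X = np.asarray(X)
    if X.dtype != np.float32:
        X = np.asarray(X, dtype=np.float64)
    held_out = np.asarray(held_out, dtype=bool)
    if held_out.shape != X.shape:
        raise ValueError("mask shape does not match the matrix")
    n_held = int(held_out.sum())
    if n_held == 0:
        raise ValueError("empty holdout mask: nothing to impute")
    if n_held > X.size // 2:
        raise ValueError("mask deletes more than half of the matrix")
    if held_out.all(axis=0).any():
        raise ValueError("a column is fully deleted; imputation undefined")
    truth = X[held_out]
    Xw = X.copy()
    keep = ~held_out
    col_sums = np.where(keep, X, 0.0).sum(axis=0)
    col_counts = keep.sum(axis=0)
    col_means = col_sums / col_counts
    mean_fill = np.broadcast_to(col_means, X.shape)[held_out]
    Xw[held_out] = mean_fill if init_values is None else init_values
    # divergence is judged against the column-mean baseline regardless of
    # how the entries were initialized
    err0 = float(np.mean((truth - mean_fill) ** 2))
    rng = np.random.default_rng(seed)
    fit: Optional[ScpcaFit] = init_fit
    for sweep in range(max_em_iter):
        if fit is None:
            fit = fit_multistart(Xw, s, restarts=restarts,
                                 seed=int(rng.integers(2**31 - 1)),
                                 max_iter=max_iter, tol=fit_tol,
                                 angle_tol=angle_tol)
        elif em_inner_iter is None:
            fit = fit_once(Xw, s, seed=fit.seed, max_iter=max_iter,
                           tol=fit_tol, angle_tol=angle_tol,
                           init=(fit.u1, fit.u2, fit.v1, fit.v2))
        else:
            fit = fit_once(Xw, s, seed=fit.seed, max_iter=em_inner_iter,
                           tol=0.0, angle_tol=0.0,
                           init=(fit.u1, fit.u2, fit.v1, fit.v2))
        recon = fit.d * (np.outer(fit.u1, fit.v1) + np.outer(fit.u2, fit.v2))
        new_vals = recon[held_out]
        old_vals = Xw[held_out]
        denom = max(float(np.linalg.norm(old_vals)), 1e-12)
        rel_change = float(np.linalg.norm(new_vals - old_vals)) / denom
        Xw[held_out] = new_vals
        err = float(np.mean((truth - new_vals) ** 2))
        if err0 > 0 and err > 10.0 * err0:
            raise ImputationDivergence(
                f"imputation error {err:.3g} exceeds 10x its initial "
                f"value {err0:.3g} at EM sweep {sweep + 1}"
            )
        if rel_change < tol:
            break
    assert fit is not None
    return fit, err


@dataclasses.dataclass
class CvResult:
    """Imputation-error curves over the sparsity grid and the selected s*."""

    s_grid: np.ndarray
    errors: np.ndarray          # (repeats, K, len(s_grid)); NaN = failed fold
    mean_curve: np.ndarray
    se_curve: np.ndarray
    s_star: Optional[float]
    flag: str                   # "valid" | "no_minimum"
    notes: str = ""

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: repeat, fold, s, error."""
        reps, K, S = self.errors.shape
        rep, fold, si = np.meshgrid(
            np.arange(1, reps + 1), np.arange(1, K + 1), np.arange(S),
            indexing="ij",
        )
        return pd.DataFrame({
            "repeat": rep.ravel(),
            "fold": fold.ravel(),
            "s": self.s_grid[si.ravel()],
            "error": self.errors.ravel(),
        })

    def summary(self) -> dict:
        return {
            "s_star": self.s_star,
            "flag": self.flag,
            "s_grid": self.s_grid.tolist(),
            "mean_curve": self.mean_curve.tolist(),
            "se_curve": self.se_curve.tolist(),
            "notes": self.notes,
        }


def default_s_grid(p: int, n_points: int = 12, s_min: float = 1.5
                   ) -> np.ndarray:
    """Logarithmically spaced sparsity grid from ``s_min`` to sqrt(p)."""
    return np.geomspace(s_min, np.sqrt(p), n_points)


def _select_s(s_grid, mean_curve, se_curve):
    """Non-trivial-minimum rule.

    The argmin of the mean curve is accepted only when it is not the
    sparsest grid point and the curve at the largest s exceeds the minimum
    by more than one pooled standard error; otherwise the data carry no
    evidence of a rhythmic low-rank structure and no s is selected.
    """
    idx = int(np.nanargmin(mean_curve))
    pooled_se = float(np.sqrt(se_curve[idx] ** 2 + se_curve[-1] ** 2))
    rises = mean_curve[-1] > mean_curve[idx] + pooled_se
    if idx > 0 and rises:
        return float(s_grid[idx]), "valid", ""
    if idx == 0:
        note = "CV error minimized at the sparsest grid point"
    else:
        note = "CV curve does not rise above its minimum by > 1 pooled SE"
    return None, "no_minimum", note


def cross_validate(
    X: np.ndarray,
    s_grid: Optional[Sequence[float]] = None,
    K: int = DEFAULT_K,
    repeats: int = DEFAULT_REPEATS,
    seed: int = 0,
    restarts: int = DEFAULT_CV_RESTARTS,
    max_em_iter: int = DEFAULT_MAX_EM_ITER,
    em_tol: float = CV_EM_TOL,
    max_iter: int = CV_MAX_ITER,
    fit_tol: float = CV_FIT_TOL,
    angle_tol: float = CV_ANGLE_TOL,
    warm_path: bool = False,
) -> CvResult:
    """Repeated K-fold element-deletion CV over a sparsity grid.

    X must already be standardized (the workflow standardizes once on the
    full matrix, then cross-validates).  Diverged folds are recorded as NaN
    and excluded from the mean with a warning; if every fold fails at some
    s, that grid point is dropped from the selection.

    Every grid point is fitted cold (column-mean imputation, fresh
    multistart) by default.  ``warm_path=True`` instead continues each
    (repeat, fold) along the grid from sparsest to densest, warm-starting
    from the previous point's solution and imputed values.  That is several
    times faster but biases the dense side of the curve downward -- the
    carried-over structure suppresses the EM overfitting whose error rise
    localizes the minimum -- and can shift s* toward denser solutions, so
    it is an exploratory mode, not the default.

    CV arithmetic runs in single precision: imputation errors are compared
    at the 1e-2 scale, far above float32 resolution, and the halved memory
    traffic roughly doubles throughput.  The final model fit (outside this
    function) stays in double precision.
    """
    X = np.asarray(X, dtype=np.float32)
    N, p = X.shape
    if s_grid is None:
        s_grid = default_s_grid(p)
    s_grid = np.asarray(sorted(s_grid), dtype=float)
    if s_grid[0] < 1.0 - 1e-9 or s_grid[-1] > np.sqrt(p) * (1 + 1e-9):
        raise ValueError("s_grid must lie within [1, sqrt(p)]")
    rng = np.random.default_rng(seed)
    patterns = make_deletion_patterns(
        N, p, K, seed=int(rng.integers(2**31 - 1)), repeats=repeats
    )
    fit_seeds = rng.integers(0, 2**31 - 1, size=(repeats, K, len(s_grid)))
    errors = np.full((repeats, K, len(s_grid)), np.nan)
    for rep, pattern in enumerate(patterns):
        for fold in range(1, K + 1):
            mask = pattern.mask(fold)
            prev_fit = None
            prev_values = None
            for si in range(len(s_grid)):
                s = s_grid[si]
                try:
                    fit, err = impute_fit(
                        X, mask, s, seed=int(fit_seeds[rep, fold - 1, si]),
                        max_em_iter=max_em_iter, tol=em_tol,
                        restarts=restarts, max_iter=max_iter,
                        fit_tol=fit_tol, angle_tol=angle_tol,
                        em_inner_iter=DEFAULT_EM_INNER_ITER,
                        init_values=prev_values, init_fit=prev_fit,
                    )
                    errors[rep, fold - 1, si] = err
                    if warm_path:
                        recon = fit.d * (np.outer(fit.u1, fit.v1)
                                         + np.outer(fit.u2, fit.v2))
                        prev_fit = fit
                        prev_values = recon[mask]
                except ImputationDivergence as exc:
                    warnings.warn(
                        f"repeat {rep + 1} fold {fold} s={s:.3g}: {exc}",
                        RuntimeWarning,
                    )
                    prev_fit = None
                    prev_values = None
    n_ok = np.sum(np.isfinite(errors), axis=(0, 1))
    if np.any(n_ok == 0):
        dead = s_grid[n_ok == 0]
        warnings.warn(
            f"all folds failed at s={np.round(dead, 3).tolist()}; "
            "dropped from the curve",
            RuntimeWarning,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_curve = np.nanmean(errors.reshape(-1, len(s_grid)), axis=0)
        sd = np.nanstd(errors.reshape(-1, len(s_grid)), axis=0, ddof=1)
    se_curve = sd / np.sqrt(np.maximum(n_ok, 1))
    s_star, flag, notes = _select_s(s_grid, mean_curve, se_curve)
    return CvResult(
        s_grid=s_grid, errors=errors, mean_curve=mean_curve,
        se_curve=se_curve, s_star=s_star, flag=flag, notes=notes,
    )
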