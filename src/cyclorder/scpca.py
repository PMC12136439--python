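"""Sparse cyclic PCA solved by alternating convex search.

The model approximates a column-standardized data matrix X (N samples x p
features) by a rank-2 cyclic factorization::

    X  ~  d * (u1 v1' + u2 v2')

where each sample's pair (u1_i, u2_i) is constrained to the unit circle --
so the samples live on a closed loop in component space -- and the loading
vectors v1, v2 are unit l2-norm with an l1 budget ``s`` that makes them
sparse.  Nonzero loadings mark the rhythmic features; the angle of
(u1_i, u2_i) is sample i's position within the cycle.

Dropping the bi-linear cross term 2 d^2 (u1'u2)(v1'v2) makes the problem
bi-convex, so block updates in closed form (radial projection for the u's,
soft-thresholding for the v's, a scalar least-squares step for d) ascend the
objective monotonically.  Restarts with random initializations guard against
local maxima; the winner is the restart with the smallest *matrix
approximation error* ||X - d u1 v1' - d u2 v2'||_F^2, not the best simplified
objective, which keeps the neglected cross term honest.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import List, Optional, Tuple

import numpy as np

__all__ = [
    "ScpcaFit",
    "update_u",
    "soft_threshold",
    "project_v",
    "update_d",
    "objective_value",
    "approximation_error",
    "fit_once",
    "fit_multistart",
]

# Convergence defaults; the objective criterion is relative, the angle
# criterion is in cycles.
DEFAULT_MAX_ITER = 500
DEFAULT_TOL = 1e-7
ANGLE_TOL = 1e-6
DEFAULT_RESTARTS = 20


@dataclasses.dataclass
class ScpcaFit:
    """One converged sparse-cyclic-PCA solution."""

    u1: np.ndarray
    u2: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    d: float
    s: float
    objective_trace: List[float]
    approx_error: float
    cross_term: float
    n_iter: int
    converged: bool
    seed: int
    restart_summary: Optional[list] = None

    def check_feasible(self, s_tol: float = 1e-8) -> None:
        """Raise if any constraint of the optimization is violated."""
        radius = self.u1**2 + self.u2**2
        if np.max(np.abs(radius - 1.0)) > 1e-10:
            raise AssertionError("u rows not on the unit circle")
        for v in (self.v1, self.v2):
            if abs(np.linalg.norm(v) - 1.0) > 1e-10:
                raise AssertionError("loading vector not unit l2-norm")
            if np.abs(v).sum() > self.s + s_tol:
                raise AssertionError("loading vector violates the l1 budget")
        if self.d < 0:
            raise AssertionError("negative scale d")

    def to_dict(self) -> dict:
        return {
            "u1": self.u1.tolist(),
            "u2": self.u2.tolist(),
            "v1": self.v1.tolist(),
            "v2": self.v2.tolist(),
            "d": self.d,
            "s": self.s,
            "objective_trace": list(self.objective_trace),
            "approx_error": self.approx_error,
            "cross_term": self.cross_term,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "seed": self.seed,
        }


def update_u(X: np.ndarray, v1: np.ndarray, v2: np.ndarray
             ) -> Tuple[np.ndarray, np.ndarray]:
    """Closed-form update of the cyclic components: radial projection.

    With y1 = X v1 and y2 = X v2, each pair (y1_i, y2_i) is projected onto
    the unit circle.  A zero-radius row (y1_i = y2_i = 0) has no defined
    angle; it is deterministically assigned angle 0 with a warning.
    """
    y1 = X @ v1
    y2 = X @ v2
    return _project_circle(y1, y2)


def _project_circle(y1: np.ndarray, y2: np.ndarray
                    ) -> Tuple[np.ndarray, np.ndarray]:
    r = np.hypot(y1, y2)
    zero = r == 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} sample(s) projected from the origin; "
            "assigned angle 0",
            RuntimeWarning,
            stacklevel=3,
        )
        r = np.where(zero, 1.0, r)
        y1 = np.where(zero, 1.0, y1)
        y2 = np.where(zero, 0.0, y2)
    return y1 / r, y2 / r


def soft_threshold(x: np.ndarray, delta: float) -> np.ndarray:
    """S(x, delta) = (x - delta)_+ - (-x - delta)_+ (shrink toward zero)."""
    return np.sign(x) * np.maximum(np.abs(x) - delta, 0.0)


def _threshold_for_budget(aw: np.ndarray, s: float) -> float:
    """Smallest delta with ||S(aw, delta)||_1 / ||S(aw, delta)||_2 = s.

    The ratio is continuous and non-increasing in delta and piecewise
    algebraic between consecutive order statistics of ``aw``, so the
    crossing segment can be located from cumulative sums of the sorted
    magnitudes and the threshold solved exactly from a quadratic.  With k
    entries surviving, l1 = S1 - k*delta and l2^2 = S2 - 2*delta*S1 +
    k*delta^2 (S1, S2 the top-k partial sums), and l1^2 = s^2 l2^2 gives

        k (k - s^2) delta^2 + 2 S1 (s^2 - k) delta + S1^2 - s^2 S2 = 0.
    """
    a = np.sort(aw)[::-1]
    k = np.arange(1, len(a) + 1, dtype=float)
    S1 = np.cumsum(a)
    S2 = np.cumsum(a * a)
    # Ratio at the low end of each segment (delta = next order statistic).
    nxt = np.append(a[1:], 0.0)
    l1 = S1 - k * nxt
    l2sq = S2 - 2.0 * nxt * S1 + k * nxt * nxt
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = l1 / np.sqrt(l2sq)
    ratio = np.where(l2sq <= 0, 0.0, ratio)
    idx = np.flatnonzero(ratio >= s)
    if idx.size == 0:
        return 0.0  # budget never binds (caller already handled this)
    ki = int(idx[0])
    kk, s1, s2 = float(ki + 1), float(S1[ki]), float(S2[ki])
    A = kk * (kk - s * s)
    B = 2.0 * s1 * (s * s - kk)
    C = s1 * s1 - s * s * s2
    if A == 0.0:
        delta = -C / B if B != 0.0 else float(nxt[ki])
    else:
        disc = max(B * B - 4.0 * A * C, 0.0)
        r1 = (-B + np.sqrt(disc)) / (2.0 * A)
        r2 = (-B - np.sqrt(disc)) / (2.0 * A)
        lo, hi = float(nxt[ki]), float(a[ki])
        cands = [r for r in (r1, r2) if lo - 1e-12 <= r <= hi + 1e-12]
        delta = max(cands) if cands else lo  # ties toward sparser solution
    return float(min(max(delta, 0.0), a[0]))


def project_v(w: np.ndarray, s: float) -> np.ndarray:
    """Maximize w'v subject to ||v||_2 = 1 and ||v||_1 <= s.

    The maximizer is the soft-thresholded w, rescaled to unit l2-norm, with
    the threshold delta chosen so the l1-norm constraint is active (or
    delta = 0 if the plain normalization already satisfies it); delta is
    solved exactly from the sorted magnitudes of w.
    """
    w = np.asarray(w, dtype=float)
    if s < 1.0 - 1e-12:
        raise ValueError(f"s must be >= 1 (got {s}); ||v||_1 >= ||v||_2 = 1")
    aw = np.abs(w)
    top = aw.max()
    if top == 0.0:
        raise ValueError("cannot project the zero vector")
    l2 = np.linalg.norm(w)
    if aw.sum() / l2 <= s:
        return w / l2
    # The soft-threshold family bottoms out at ratio sqrt(#tied maxima);
    # below that, keep the largest floor(s^2) tied coordinates.
    ties = np.flatnonzero(aw >= top * (1.0 - 1e-12))
    if s <= np.sqrt(len(ties)) - 1e-12:
        m = max(1, min(len(ties), int(s * s + 1e-12)))
        v = np.zeros_like(w)
        v[ties[:m]] = np.sign(w[ties[:m]]) / np.sqrt(m)
        return v
    delta = _threshold_for_budget(aw, s)
    a = soft_threshold(w, delta)
    nrm = np.linalg.norm(a)
    if nrm == 0.0:  # numerical corner: fall back to the top coordinate
        v = np.zeros_like(w)
        v[int(np.argmax(aw))] = np.sign(w[int(np.argmax(aw))])
        return v
    v = a / nrm
    # guard the budget against roundoff from the closed-form root
    l1v = np.abs(v).sum()
    if l1v > s + 1e-9:
        lo, hi = delta, top
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            av = soft_threshold(w, mid)
            n = np.linalg.norm(av)
            if n == 0 or np.abs(av).sum() / n > s:
                lo = mid
            else:
                hi = mid
        av = soft_threshold(w, hi)
        v = av / np.linalg.norm(av)
    return v


def update_d(X: np.ndarray, u1, u2, v1, v2) -> float:
    """Closed-form scale: d = (u1' X v1 + u2' X v2) / N, clipped at zero.

    After a u-update the numerator is a sum of radii and hence nonnegative,
    so the clip only fires on adversarial inputs.
    """
    n = X.shape[0]
    d = float(u1 @ (X @ v1) + u2 @ (X @ v2)) / n
    if d < 0:
        warnings.warn("negative scale clipped to 0", RuntimeWarning,
                      stacklevel=2)
        d = 0.0
    return d


def objective_value(X, u1, u2, v1, v2, d) -> float:
    """Simplified (cross-term-free) objective 2d(u1'Xv1 + u2'Xv2) - d^2 N."""
    n = X.shape[0]
    m = float(u1 @ (X @ v1) + u2 @ (X @ v2))
    return 2.0 * d * m - d * d * n


def approximation_error(X, u1, u2, v1, v2, d) -> float:
    """Squared Frobenius error ||X - d u1 v1' - d u2 v2'||_F^2."""
    n = X.shape[0]
    m = float(u1 @ (X @ v1) + u2 @ (X @ v2))
    cross = 2.0 * d * d * float(u1 @ u2) * float(v1 @ v2)
    return float(np.sum(X * X)) - 2.0 * d * m + d * d * n + cross


def _init_vectors(n: int, p: int, s: float, rng: np.random.Generator
                  ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    # Angles uniform on the circle; loadings from a sparsity-inducing
    # Laplacian (scale 1/sqrt(p)) projected onto the constraint set.
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    u1, u2 = np.cos(theta), np.sin(theta)
    v1 = project_v(_nonzero_laplace(rng, p), s)
    v2 = project_v(_nonzero_laplace(rng, p), s)
    return u1, u2, v1, v2


def _nonzero_laplace(rng: np.random.Generator, p: int) -> np.ndarray:
    for _ in range(8):
        v = rng.laplace(scale=1.0 / np.sqrt(p), size=p)
        if np.any(v != 0.0):
            return v
    raise RuntimeError("could not draw a nonzero initialization")


def fit_once(
    X: np.ndarray,
    s: float,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    init: Optional[Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = None,
    angle_tol: float = ANGLE_TOL,
) -> ScpcaFit:
    """Run alternating convex search from one initialization.

    Each sweep applies the u-update, both v-updates (from the same fresh
    u's), and the d-update, all in closed form, so the objective trace is
    non-decreasing.  Convergence requires both a relative objective
    improvement below ``tol`` and a maximum angle change below
    ``angle_tol`` cycles (default 1e-6).

    ``init`` warm-starts from given (u1, u2, v1, v2); used by the EM
    imputation loop in cross-validation.

    A float32 ``X`` is processed in float32 (the loading projection is
    still solved in float64); cross-validation exploits this, as its
    errors are read at a far coarser scale than single precision.
    """
    X = np.asarray(X)
    if X.dtype != np.float32:
        X = np.asarray(X, dtype=np.float64)
    dt = X.dtype
    n, p = X.shape
    smax = np.sqrt(p)
    if not (1.0 - 1e-9 <= s <= smax * (1.0 + 1e-9)):
        raise ValueError(f"s={s} outside the feasible range [1, sqrt(p)={smax:.3f}]")
    rng = np.random.default_rng(seed)
    if init is None:
        u1, u2, v1, v2 = _init_vectors(n, p, s, rng)
    else:
        u1, u2, v1, v2 = (np.array(a, dtype=np.float64) for a in init)
    u1, u2 = u1.astype(dt), u2.astype(dt)
    v1, v2 = v1.astype(dt), v2.astype(dt)
    prev_angle = np.arctan2(u2, u1)
    trace: List[float] = []
    prev_obj = -np.inf
    converged = False
    n_iter = 0
    for it in range(1, max_iter + 1):
        n_iter = it
        y1, y2 = X @ v1, X @ v2
        u1, u2 = _project_circle(y1, y2)
        w1, w2 = X.T @ u1, X.T @ u2
        v1 = project_v(w1, s).astype(dt)
        v2 = project_v(w2, s).astype(dt)
        m = float(w1 @ v1 + w2 @ v2)
        d = max(m / n, 0.0)
        obj = 2.0 * d * m - d * d * n
        if not np.isfinite(obj):
            raise FloatingPointError(f"non-finite objective at iteration {it}")
        trace.append(obj)
        angle = np.arctan2(u2, u1)
        dang = np.abs(angle - prev_angle)
        max_shift = float(np.min([dang, 2.0 * np.pi - dang], axis=0).max()) / (2.0 * np.pi)
        prev_angle = angle
        rel = (obj - prev_obj) / max(abs(prev_obj), 1e-30)
        if it > 1 and rel < tol and max_shift < angle_tol:
            converged = True
            break
        prev_obj = obj
    # close the sweep with a final u-update so the returned components are
    # the exact radial projection of X onto the returned loadings (another
    # ascent step, so monotonicity is preserved); new-sample prediction
    # through v then reproduces the training labels exactly
    u1, u2 = _project_circle(X @ v1, X @ v2)
    d = max(float((X.T @ u1) @ v1 + (X.T @ u2) @ v2) / n, 0.0)
    cross = 2.0 * d * d * float(u1 @ u2) * float(v1 @ v2)
    err = approximation_error(X, u1, u2, v1, v2, d)
    return ScpcaFit(
        u1=u1, u2=u2, v1=v1, v2=v2, d=d, s=float(s),
        objective_trace=trace, approx_error=err, cross_term=cross,
        n_iter=n_iter, converged=converged, seed=int(seed),
    )


def fit_multistart(
    X: np.ndarray,
    s: float,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    angle_tol: float = ANGLE_TOL,
) -> ScpcaFit:
    """Fit from ``restarts`` random initializations; keep the fit with the
    smallest matrix approximation error (not the best simplified objective,
    which ignores the cross term)."""
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    child_seeds = np.random.default_rng(seed).integers(
        0, 2**31 - 1, size=restarts
    )
    best: Optional[ScpcaFit] = None
    summary = []
    for child in child_seeds:
        fit = fit_once(X, s, seed=int(child), max_iter=max_iter, tol=tol,
                       angle_tol=angle_tol)
        summary.append({
            "seed": fit.seed,
            "approx_error": fit.approx_error,
            "objective": fit.objective_trace[-1],
            "n_iter": fit.n_iter,
            "converged": fit.converged,
        })
        if best is None or fit.approx_error < best.approx_error:
            best = fit
    assert best is not None
    best.restart_summary = summary
    return best
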