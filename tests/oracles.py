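"""Independent reference computations used by the test suite."""

import numpy as np
from scipy.optimize import minimize


def brute_force_max_projection(w, s, n_starts=8, seed=0):
    """Maximize w'v over {||v||_2 = 1, ||v||_1 <= s} with a generic solver.

    The maximizer shares the signs of w, so the search runs over the
    nonnegative orthant against |w| with SLSQP from several random starting
    points; the best objective found is returned.  Independent of the
    soft-threshold construction used by the implementation.
    """
    aw = np.abs(w)
    p = len(w)
    rng = np.random.default_rng(seed)
    best = -np.inf

    def neg_obj(v):
        return -aw @ v

    cons = [
        {"type": "eq", "fun": lambda v: v @ v - 1.0},
        {"type": "ineq", "fun": lambda v: s - np.sum(v)},
    ]
    for k in range(n_starts):
        v0 = rng.uniform(size=p) if k else aw / np.linalg.norm(aw)
        v0 /= np.linalg.norm(v0)
        if v0.sum() > s:
            v0 = v0 * 0.0
            v0[np.argmax(aw)] = 1.0
        res = minimize(neg_obj, v0, method="SLSQP", constraints=cons,
                       bounds=[(0.0, 1.0)] * p,
                       options={"maxiter": 500, "ftol": 1e-12})
        if res.success:
            v = res.x / np.linalg.norm(res.x)
            if np.sum(v) <= s + 1e-8:
                best = max(best, aw @ v)
    return best
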