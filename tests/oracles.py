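"""Independent brute-force oracles used to check the closed-form updates.

These deliberately avoid the code paths they validate: the membership
oracle enumerates every possible active set of the simplex QP and solves
the equality-constrained problem on each support exactly, and the expert
oracle solves the weighted L1 problem as a smooth bound-constrained QP in
the split variables (w+, w-, b) with L-BFGS-B.
"""

from itertools import combinations

import numpy as np
from scipy.optimize import minimize


def simplex_qp_oracle(a: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Minimize a.m + (c/2).m^2 over the probability simplex, row by row.

    Brute force: for every nonempty support S the stationary point under
    the sum constraint is m_S = (lam - a_S) / c_S with lam fixed by the
    constraint; the global optimum is the feasible candidate with the
    smallest objective (KKT). Exact to machine precision for c > 0.
    """
    a = np.atleast_2d(np.asarray(a, float))
    c = np.atleast_2d(np.asarray(c, float))
    out = np.empty_like(a)
    K = a.shape[1]
    supports = [
        list(s) for r in range(1, K + 1) for s in combinations(range(K), r)
    ]
    for i in range(a.shape[0]):
        ai, ci = a[i], c[i]
        best_f, best_m = np.inf, None
        for S in supports:
            inv = 1.0 / ci[S]
            lam = (1.0 + np.sum(ai[S] * inv)) / np.sum(inv)
            m_S = (lam - ai[S]) * inv
            if np.any(m_S < -1e-12):
                continue
            m = np.zeros(K)
            m[S] = np.clip(m_S, 0.0, None)
            m /= m.sum()
            f = float(ai @ m + 0.5 * ci @ m**2)
            if f < best_f:
                best_f, best_m = f, m
        out[i] = best_m
    return out


def weighted_l1_oracle(X, y, sw, C, fit_intercept=True):
    """Minimize 0.5||w||_1 + C sum_i sw_i (y_i - w.x_i - b)^2 directly."""
    n, p = X.shape
    nb = 1 if fit_intercept else 0

    def fun(z):
        wp, wm = z[:p], z[p: 2 * p]
        b = z[-1] if nb else 0.0
        w = wp - wm
        r = y - X @ w - b
        val = 0.5 * (wp.sum() + wm.sum()) + C * float(sw @ r**2)
        g = -2.0 * C * (sw * r)
        gw = X.T @ g
        grad = np.concatenate([gw + 0.5, -gw + 0.5, [g.sum()] if nb else []])
        return val, grad

    z0 = np.zeros(2 * p + nb)
    bounds = [(0, None)] * (2 * p) + ([(None, None)] if nb else [])
    res = minimize(fun, z0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12})
    w = res.x[:p] - res.x[p: 2 * p]
    b = float(res.x[-1]) if nb else 0.0
    return w, b, float(res.fun)


def expert_objective(X, y, sw, C, w, b):
    """Value of one expert's subproblem at (w, b)."""
    r = y - X @ w - b
    return 0.5 * float(np.abs(w).sum()) + C * float(sw @ r**2)
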