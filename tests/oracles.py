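"""Independent numerical oracles used by the test suite.

These minimize the solvers' objectives by generic smoothed first-order
optimization (an epsilon-continuation ladder of L-BFGS runs, with a
derivative-free Powell polish on the exact nonsmooth objective), never
by the closed forms under test.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

EPS_LADDER = (1e-4, 1e-8, 1e-12, 1e-16, 1e-20)
_LBFGS_OPTS = dict(maxiter=5000, ftol=1e-18, gtol=1e-14, maxls=100)


def _smoothed_prox_objective(M, tau, axis, nuclear, eps):
    shape = M.shape
    if nuclear:
        def f(z):
            Z = z.reshape(shape)
            s = np.linalg.svd(Z, compute_uv=False)
            return 0.5 * ((Z - M) ** 2).sum() + tau * np.sqrt(s * s + eps).sum()

        def grad(z):
            Z = z.reshape(shape)
            U, s, Vt = np.linalg.svd(Z, full_matrices=False)
            return ((Z - M) + tau * (U * (s / np.sqrt(s * s + eps))) @ Vt).ravel()
    else:
        red = 1 if axis == "rows" else 0

        def f(z):
            Z = z.reshape(shape)
            g = np.sqrt((Z * Z).sum(axis=red) + eps)
            return 0.5 * ((Z - M) ** 2).sum() + tau * g.sum()

        def grad(z):
            Z = z.reshape(shape)
            g = np.sqrt((Z * Z).sum(axis=red) + eps)
            scale = g[:, None] if red == 1 else g[None, :]
            return ((Z - M) + tau * Z / scale).ravel()

    return f, grad


def minimize_prox_objective(M, tau, axis=None, nuclear=False):
    """Numerically minimize 0.5||Z - M||_F^2 + tau * penalty(Z).

    penalty is the L2,1 norm grouped by ``axis`` or, with
    ``nuclear=True``, the nuclear norm.  Continuation over smoothing
    levels from two neutral starts (M and 0), then a Powell polish on
    the exact objective.
    """
    M = np.asarray(M, dtype=float)
    f_exact, _ = _smoothed_prox_objective(M, tau, axis, nuclear, 0.0)
    best = None
    for z0 in (M.ravel().copy(), np.zeros(M.size)):
        z = z0
        for eps in EPS_LADDER:
            f, grad = _smoothed_prox_objective(M, tau, axis, nuclear, eps)
            z = minimize(f, z, jac=grad, method="L-BFGS-B", options=_LBFGS_OPTS).x
        z = minimize(
            f_exact, z, method="Powell",
            options=dict(maxiter=100000, xtol=1e-12, ftol=1e-16),
        ).x
        if best is None or f_exact(z) < f_exact(best):
            best = z
    return best.reshape(M.shape)


def best_projected_objective(Xc, V, lam, n_restarts=200, seed=0):
    """Best value of ||Xc V - W||_{2,1(rows)} + lam ||W||_* found by
    random-restart smoothed L-BFGS over W (generic minimizer)."""
    M = Xc @ V
    m, k = M.shape

    def make(eps):
        def f(w):
            W = w.reshape(m, k)
            R = M - W
            g = np.sqrt((R * R).sum(axis=1) + eps).sum()
            s = np.linalg.svd(W, compute_uv=False)
            return g + lam * np.sqrt(s * s + eps).sum()

        def grad(w):
            W = w.reshape(m, k)
            R = M - W
            gr = np.sqrt((R * R).sum(axis=1) + eps)
            U, s, Vt = np.linalg.svd(W, full_matrices=False)
            G = -R / gr[:, None] + lam * (U * (s / np.sqrt(s * s + eps))) @ Vt
            return G.ravel()

        return f, grad

    rng = np.random.default_rng(seed)
    f_exact, _ = make(0.0)
    best = np.inf
    for r in range(n_restarts):
        w = M.ravel() + rng.standard_normal(m * k) * (0.5 if r else 0.0)
        for eps in (1e-6, 1e-10, 1e-14):
            f, grad = make(eps)
            w = minimize(
                f, w, jac=grad, method="L-BFGS-B",
                options=dict(maxiter=2000, ftol=1e-18, gtol=1e-12, maxls=100),
            ).x
        best = min(best, f_exact(w))
    return best
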