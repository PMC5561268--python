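"""Norms, proximal operators and centering constructions shared by all solvers.

This is the pure math layer underneath the robust feature-extraction
solvers: the :math:`\\ell_{2,1}` norm and its proximal operator (group
soft-thresholding), singular value thresholding (the proximal operator of
the nuclear norm), and the unweighted / weighted centering matrices used
to absorb the data mean into a trace maximization.

Grouping convention
-------------------
The :math:`\\ell_{2,1}` norm sums Euclidean norms over *groups*.  Which
axis forms a group is ambiguous in general usage: for an ``m x n`` data
residual the groups are sample columns, while for the ``m x k`` factor
residual used by the ALM solver the groups are feature rows (row sparsity
is what isolates feature genes).  Every operation here therefore takes an
explicit ``axis`` argument, one of ``"rows"`` or ``"columns"``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "GROUP_AXES",
    "l21_norm",
    "l21_prox",
    "svt",
    "nuclear_norm",
    "centering_matrix",
    "weighted_centering_matrix",
]

GROUP_AXES = ("rows", "columns")

#: group norms below this are treated as exactly zero in l21_prox (0/0 guard)
_GROUP_NORM_FLOOR = 1e-12


def _check_matrix(M: np.ndarray, name: str = "M") -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError(f"{name} must be a 2-d matrix, got ndim={M.ndim}")
    if M.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(M)):
        raise ValueError(f"{name} contains non-finite entries")
    return M


def _check_axis(axis: str) -> int:
    if axis not in GROUP_AXES:
        raise ValueError(f"axis must be one of {GROUP_AXES}, got {axis!r}")
    # groups are rows -> reduce over columns (axis=1) and vice versa
    return 1 if axis == "rows" else 0


def l21_norm(M: np.ndarray, axis: str = "rows") -> float:
    """Sum of Euclidean norms of the rows (or columns) of ``M``.

    ``l21_norm(M, "columns")`` is the classical :math:`\\|M\\|_{2,1} =
    \\sum_i \\|m_i\\|_2` over sample columns; ``axis="rows"`` groups by
    feature rows instead.  Zero iff ``M`` is all-zero.
    """
    M = _check_matrix(M)
    red = _check_axis(axis)
    return float(np.sqrt((M * M).sum(axis=red)).sum())


def l21_prox(M: np.ndarray, tau: float, axis: str = "rows") -> np.ndarray:
    """Proximal operator of ``tau * l21_norm(., axis)``.

    Solves ``argmin_Z 0.5*||Z - M||_F^2 + tau*||Z||_{2,1}`` in closed form:
    each group is scaled by ``max(0, 1 - tau/||group||)``, so groups with
    norm at most ``tau`` vanish exactly (group soft-thresholding).
    """
    M = _check_matrix(M)
    red = _check_axis(axis)
    if tau < 0:
        raise ValueError(f"tau must be nonnegative, got {tau}")
    if tau == 0:
        return M.copy()
    norms = np.sqrt((M * M).sum(axis=red))
    scale = np.zeros_like(norms)
    live = norms > max(tau, _GROUP_NORM_FLOOR)
    scale[live] = 1.0 - tau / norms[live]
    if red == 1:
        return M * scale[:, None]
    return M * scale[None, :]


def nuclear_norm(M: np.ndarray) -> float:
    """Sum of singular values of ``M``."""
    M = _check_matrix(M)
    return float(np.linalg.svd(M, compute_uv=False).sum())


def svt(M: np.ndarray, tau: float) -> np.ndarray:
    """Singular value thresholding: prox of ``tau * ||.||_*``.

    Solves ``argmin_Z 0.5*||Z - M||_F^2 + tau*||Z||_*`` by soft-
    thresholding the singular values of ``M``.  Singular values equal to
    ``tau`` shrink to exactly zero (the closed form is continuous there);
    the output rank never exceeds ``rank(M)``.
    """
    M = _check_matrix(M)
    if tau < 0:
        raise ValueError(f"tau must be nonnegative, got {tau}")
    if tau == 0:
        return M.copy()
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    return (U * s) @ Vt


def centering_matrix(n: int) -> np.ndarray:
    """The ``n x n`` centering matrix ``C = I - (1/n) a a^T`` (``a`` all ones).

    ``C`` is symmetric idempotent and annihilates constant vectors, so
    ``Tr(W^T X C X^T W)`` is unchanged by any per-feature shift
    ``X -> X + u a^T``.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    return np.eye(n) - np.full((n, n), 1.0 / n)


def weighted_centering_matrix(d: np.ndarray) -> np.ndarray:
    """Weighted centering matrix ``C_d = D - D a a^T D / (a^T D a)``.

    ``D = diag(d)`` holds nonnegative per-sample weights ``d_ii``.  ``C_d``
    is symmetric positive semidefinite, annihilates the constant vector,
    and reduces to :func:`centering_matrix` when all weights are one.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("d must be a nonempty 1-d weight vector")
    if not np.all(np.isfinite(d)) or np.any(d < 0):
        raise ValueError("weights must be finite and nonnegative")
    total = d.sum()
    if total <= 0:
        raise ValueError("at least one weight must be positive (a^T D a = 0)")
    # D a = d, a^T D a = sum(d)
    return np.diag(d) - np.outer(d, d) / total
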