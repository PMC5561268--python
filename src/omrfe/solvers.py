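"""Robust feature-extraction solvers.

The primary method (OMRFE) factorizes a features-by-samples matrix
``X`` as ``X - b a^T = W V^T`` with the column mean ``b`` treated as an
optimization variable ("optimal mean"), an L2,1 loss for robustness, and
a nuclear-norm penalty on the factor ``W``:

    min_{W, b}  || (X - b a^T) V - W ||_{2,1}  +  lambda * ||W||_*

solved by inexact Augmented Lagrangian (ALM) iterations that alternate
singular value thresholding (W), a closed-form least-squares mean (b),
and group soft-thresholding of a sparse residual (E).  The regularizer
follows the rule ``lambda = sqrt(l * max(m, n))`` with a small constant
``l`` (default 1e-4).

OMBRFE applies the same solver independently to contiguous row blocks of
an integrated multi-omics matrix (copy number / mutation / methylation /
expression), each with its own ``l``, and concatenates the block factors.

Ablation baselines are included: ``solve_fe`` (plain L2 / PCA feature
extraction), ``solve_rfe`` (L2,1 loss with the Euclidean mean frozen) and
``solve_om_pca`` (iteratively reweighted optimal-mean PCA).

A note on the orthogonality constraint: writing ``X - b a^T = W V^T``
with *both* factors orthonormal would make ``||W||_*`` a constant ``k``
and the nuclear penalty vacuous.  Here ``V`` carries the orthonormality
(``V^T V = I``) and ``W`` is left free, so singular value thresholding
acts on a meaningful quantity.  How ``V`` itself is obtained is a solver
option (``v_mode``): ``"fixed"`` computes it once as the ``k`` leading
right singular vectors of the column-mean-centered data (the L2-optimal
substitution ``V = (X - b a^T)^T W``), while ``"procrustes"`` re-solves
the orthogonal Procrustes problem for ``V`` at every outer iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .core_math import GROUP_AXES, l21_norm, l21_prox, nuclear_norm, svt

__all__ = [
    "SolverConfig",
    "FactorResult",
    "Block",
    "BlockSpec",
    "compute_lambda",
    "omrfe_objective",
    "solve_fe",
    "solve_om_pca",
    "solve_rfe",
    "solve_omrfe",
    "solve_ombrfe",
]

logger = logging.getLogger(__name__)

V_MODES = ("fixed", "procrustes")

#: below this, V^T a is considered zero and the mean subproblem degenerate
_Q_NORM_FLOOR = 1e-10


@dataclass(frozen=True)
class SolverConfig:
    """Configuration shared by the ALM solvers.

    Parameters
    ----------
    k : number of factors (K); must satisfy ``k <= min(m, n)``.
    l : constant in the regularizer rule ``lambda = sqrt(l * max(m, n))``.
    mu0 : initial ALM penalty; ``None`` means ``1 / sigma_max(X)``.
    rho : multiplicative growth factor of the penalty (> 1).
    tol : relative primal-residual tolerance for convergence.
    max_iter : outer-iteration cap.
    v_mode : ``"fixed"`` or ``"procrustes"`` (how V is obtained).
    group_axis : grouping of the L2,1 residual, ``"rows"`` (features) by
        default so that row sparsity of E isolates feature genes.
    seed : recorded for provenance; the solvers themselves are
        deterministic.
    """

    k: int = 4
    l: float = 1e-4
    mu0: float | None = None
    rho: float = 1.1
    tol: float = 1e-7
    max_iter: int = 500
    v_mode: str = "fixed"
    group_axis: str = "rows"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be a positive integer, got {self.k}")
        if self.l <= 0:
            raise ValueError(f"l must be positive, got {self.l}")
        if self.mu0 is not None and self.mu0 <= 0:
            raise ValueError(f"mu0 must be positive, got {self.mu0}")
        if self.rho <= 1:
            raise ValueError(f"rho must exceed 1, got {self.rho}")
        if self.tol <= 0:
            raise ValueError(f"tol must be positive, got {self.tol}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be positive, got {self.max_iter}")
        if self.v_mode not in V_MODES:
            raise ValueError(f"v_mode must be one of {V_MODES}, got {self.v_mode!r}")
        if self.group_axis not in GROUP_AXES:
            raise ValueError(
                f"group_axis must be one of {GROUP_AXES}, got {self.group_axis!r}"
            )


@dataclass
class FactorResult:
    """Output of a factorization solver.

    ``W`` (m x k) carries the per-feature loadings used for gene scoring,
    ``V`` (n x k) the sample-side factor (orthonormal columns for the ALM
    solvers; ``None`` for a multi-block fit, where each block has its
    own V in ``block_results``), ``b`` (length m) the fitted mean, and
    ``E`` (m x k) the sparse residual of the ALM split.  The traces hold
    one entry per completed outer iteration.
    """

    W: np.ndarray
    V: np.ndarray | None
    b: np.ndarray
    E: np.ndarray
    objective_trace: np.ndarray
    primal_residual_trace: np.ndarray
    converged: bool
    n_iter: int
    method: str = ""
    block_results: list["FactorResult"] | None = None


@dataclass(frozen=True)
class Block:
    """One contiguous row block ``[row_start, row_end)`` with its own ``l``."""

    name: str
    row_start: int
    row_end: int
    l: float

    def __post_init__(self) -> None:
        if self.row_start < 0 or self.row_end <= self.row_start:
            raise ValueError(
                f"block {self.name!r}: invalid row range "
                f"[{self.row_start}, {self.row_end})"
            )
        if self.l <= 0:
            raise ValueError(f"block {self.name!r}: l must be positive, got {self.l}")

    @property
    def height(self) -> int:
        return self.row_end - self.row_start


@dataclass(frozen=True)
class BlockSpec:
    """Ordered partition of the rows of an integrated matrix into blocks.

    Blocks use 0-based half-open ranges, must be contiguous (each block
    starts where the previous one ends) and, at fit time, must exactly
    tile ``range(m)`` of the matrix they are applied to.
    """

    blocks: tuple[Block, ...]

    def __init__(self, blocks) -> None:
        blocks = tuple(blocks)
        if not blocks:
            raise ValueError("BlockSpec needs at least one block")
        for prev, cur in zip(blocks, blocks[1:]):
            if cur.row_start != prev.row_end:
                raise ValueError(
                    f"blocks {prev.name!r} and {cur.name!r} do not meet: "
                    f"{prev.row_end} != {cur.row_start}"
                )
        object.__setattr__(self, "blocks", blocks)

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)

    def validate_against(self, m: int) -> None:
        """Check the blocks exactly tile ``range(m)``."""
        first, last = self.blocks[0], self.blocks[-1]
        if first.row_start != 0:
            raise ValueError(
                f"first block {first.name!r} starts at row {first.row_start}, not 0"
            )
        if last.row_end != m:
            raise ValueError(
                f"last block {last.name!r} ends at row {last.row_end}, "
                f"but the matrix has {m} rows"
            )


def compute_lambda(l: float, m: int, n: int) -> float:
    """Regularization strength ``lambda = sqrt(l * max(m, n))``."""
    if l <= 0:
        raise ValueError(f"l must be positive, got {l}")
    if m < 1 or n < 1:
        raise ValueError(f"m and n must be positive, got m={m}, n={n}")
    return float(np.sqrt(l * max(m, n)))


def _as_values(X) -> np.ndarray:
    """Accept a FeatureMatrix or a plain array; return validated ndarray."""
    values = getattr(X, "values", X)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.size == 0:
        raise ValueError("X must be a nonempty 2-d matrix")
    if not np.all(np.isfinite(values)):
        raise ValueError("X contains NaN or Inf entries")
    return values


def _check_k(k: int, m: int, n: int) -> None:
    if not 1 <= k <= min(m, n):
        raise ValueError(f"k={k} must satisfy 1 <= k <= min(m, n) = {min(m, n)}")


def _top_right_singular_vectors(Xc: np.ndarray, k: int) -> np.ndarray:
    """Leading k right singular vectors of Xc as an n x k matrix."""
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    return Vt[:k].T.copy()


def omrfe_objective(
    X, W: np.ndarray, b: np.ndarray, V: np.ndarray, lam: float, group_axis: str = "rows"
) -> float:
    """The projected robust objective ``||(X - b a^T) V - W||_{2,1} + lam ||W||_*``."""
    Xv = _as_values(X)
    R = (Xv - np.asarray(b, dtype=float)[:, None]) @ V - W
    return l21_norm(R, group_axis) + lam * nuclear_norm(W)


def solve_fe(X, k: int) -> FactorResult:
    """Plain L2 feature extraction (PCA of the column-mean-centered data).

    ``W`` holds the top-k eigenvectors of ``X C X^T`` (equivalently the
    leading left singular vectors of the centered data), ``b`` the
    Euclidean column mean, and ``V = (X - b a^T)^T W`` the coordinates.
    """
    Xv = _as_values(X)
    m, n = Xv.shape
    _check_k(k, m, n)
    b = Xv.mean(axis=1)
    Xc = Xv - b[:, None]
    U, _, _ = np.linalg.svd(Xc, full_matrices=False)
    W = U[:, :k].copy()
    V = Xc.T @ W
    return FactorResult(
        W=W,
        V=V,
        b=b,
        E=np.zeros((m, k)),
        objective_trace=np.array([float(np.linalg.norm(Xc - W @ V.T))]),
        primal_residual_trace=np.array([0.0]),
        converged=True,
        n_iter=1,
        method="fe",
    )


def solve_om_pca(
    X,
    k: int,
    tol: float = 1e-8,
    max_iter: int = 100,
    eps: float = 1e-12,
) -> FactorResult:
    """Iteratively reweighted optimal-mean PCA.

    Minimizes the L2,1 reconstruction error
    ``sum_i ||(I - W W^T)(x_i - b)||_2`` over an orthonormal ``W`` and a
    free mean ``b`` by alternating (i) ``W`` = top-k eigenvectors of
    ``X C_d X^T`` for the current sample weights, (ii) the weighted mean
    ``b = X D a / (a^T D a)``, and (iii) the reweighting
    ``d_ii = 1 / (2 ||(I - W W^T)(x_i - b)|| + eps)``.  The objective is
    non-increasing across iterations (IRLS majorization).  Weights start
    at one, so a single iteration reproduces :func:`solve_fe`.
    """
    Xv = _as_values(X)
    m, n = Xv.shape
    _check_k(k, m, n)
    if tol <= 0 or max_iter < 1:
        raise ValueError("tol must be positive and max_iter >= 1")
    d = np.ones(n)
    obj_trace: list[float] = []
    converged = False
    W = np.empty((m, k))
    b = np.empty(m)
    for _ in range(max_iter):
        b = (Xv @ d) / d.sum()
        Xc = Xv - b[:, None]
        # eigvecs of X C_d X^T == left singular vectors of (X - b a^T) sqrt(D)
        U, _, _ = np.linalg.svd(Xc * np.sqrt(d)[None, :], full_matrices=False)
        W = U[:, :k].copy()
        resid = Xc - W @ (W.T @ Xc)
        r = np.sqrt((resid * resid).sum(axis=0))
        obj = float(r.sum())
        obj_trace.append(obj)
        if len(obj_trace) > 1 and abs(obj_trace[-2] - obj) <= tol * max(1.0, obj_trace[-2]):
            converged = True
            break
        d = 1.0 / (2.0 * r + eps)
    Xc = Xv - b[:, None]
    V = Xc.T @ W
    n_iter = len(obj_trace)
    return FactorResult(
        W=W,
        V=V,
        b=b,
        E=np.zeros((m, k)),
        objective_trace=np.asarray(obj_trace),
        primal_residual_trace=np.zeros(n_iter),
        converged=converged,
        n_iter=n_iter,
        method="ompca",
    )


def _alm_solve(X, cfg: SolverConfig, optimize_mean: bool, method: str) -> FactorResult:
    """Shared inexact-ALM loop behind :func:`solve_omrfe` and :func:`solve_rfe`.

    Per outer iteration: update V (if ``v_mode == "procrustes"``), then
    ``W <- svt((X - b a^T) V - E + Lam/mu, lam/mu)``, then the mean b
    (closed-form least squares when ``optimize_mean`` and ``V^T a`` is
    nonzero; frozen at the Euclidean mean otherwise), then
    ``E <- l21_prox((X - b a^T) V - W + Lam/mu, 1/mu)``, then the
    multiplier ascent ``Lam += mu * P`` and penalty growth ``mu *= rho``.
    Stops when ``||P||_F / max(1, ||X||_F) < tol`` with
    ``P = (X - b a^T) V - W - E``.
    """
    Xv = _as_values(X)
    m, n = Xv.shape
    cfg_k = cfg.k
    _check_k(cfg_k, m, n)
    lam = compute_lambda(cfg.l, m, n)

    b_euclid = Xv.mean(axis=1)
    b = b_euclid.copy()
    Xc = Xv - b_euclid[:, None]
    sigma_max = float(np.linalg.norm(Xv, 2))
    mu = cfg.mu0 if cfg.mu0 is not None else (1.0 / sigma_max if sigma_max > 0 else 1.0)

    V = _top_right_singular_vectors(Xc, cfg_k)
    XV = Xv @ V
    q = V.sum(axis=0)  # V^T a
    W = XV - np.outer(b, q)
    E = np.zeros((m, cfg_k))
    Lam = np.zeros((m, cfg_k))
    norm_scale = max(1.0, float(np.linalg.norm(Xv)))

    obj_trace: list[float] = []
    primal_trace: list[float] = []
    converged = False
    for it in range(cfg.max_iter):
        if cfg.v_mode == "procrustes" and it > 0:
            T = (Xv - b[:, None]).T @ (W + E - Lam / mu)
            P_, _, Q_ = np.linalg.svd(T, full_matrices=False)
            V = P_ @ Q_
            XV = Xv @ V
            q = V.sum(axis=0)
        bq = np.outer(b, q)
        W = svt(XV - bq - E + Lam / mu, lam / mu)
        if optimize_mean:
            qn = float(q @ q)
            if qn < _Q_NORM_FLOOR**2:
                # V orthogonal to the constant vector: b drops out of the
                # subproblem; report the unit-weight optimal mean instead.
                b = b_euclid
            else:
                R = XV - W - E + Lam / mu
                b = (R @ q) / qn
        bq = np.outer(b, q)
        E = l21_prox(XV - bq - W + Lam / mu, 1.0 / mu, cfg.group_axis)
        P = XV - bq - W - E
        Lam = Lam + mu * P
        primal = float(np.linalg.norm(P)) / norm_scale
        obj_trace.append(l21_norm(XV - bq - W, cfg.group_axis) + lam * nuclear_norm(W))
        primal_trace.append(primal)
        if primal < cfg.tol:
            converged = True
            break
        mu *= cfg.rho

    n_iter = len(obj_trace)
    if not converged:
        logger.info(
            "%s did not reach tol=%.1e in %d iterations (residual %.3e)",
            method,
            cfg.tol,
            n_iter,
            primal_trace[-1],
        )
    return FactorResult(
        W=W,
        V=V,
        b=b,
        E=E,
        objective_trace=np.asarray(obj_trace),
        primal_residual_trace=np.asarray(primal_trace),
        converged=converged,
        n_iter=n_iter,
        method=method,
    )


def solve_omrfe(X, cfg: SolverConfig | None = None) -> FactorResult:
    """Optimal-mean robust feature extraction via inexact ALM.

    Minimizes ``||(X - b a^T) V - W||_{2,1} + lambda ||W||_*`` jointly
    over the loadings ``W`` and the mean ``b``; see the module docstring
    for the splitting scheme.  Non-convergence within ``cfg.max_iter`` is
    reported through ``converged=False``, never as an exception.
    """
    cfg = cfg or SolverConfig()
    return _alm_solve(X, cfg, optimize_mean=True, method="omrfe")


def solve_rfe(X, cfg: SolverConfig | None = None) -> FactorResult:
    """L2,1 robust feature extraction with the mean frozen at the Euclidean
    column mean (the ablation without the optimal-mean update)."""
    cfg = cfg or SolverConfig()
    return _alm_solve(X, cfg, optimize_mean=False, method="rfe")


def solve_ombrfe(X, spec: BlockSpec, cfg: SolverConfig | None = None) -> FactorResult:
    """Block robust feature extraction for integrated multi-omics matrices.

    Runs :func:`solve_omrfe` independently on each contiguous row block
    ``X_i`` with its own regularizer ``lambda_i = sqrt(l_i * max(m_i, n))``
    and concatenates the block loadings ``W = [W_1; ...; W_c]`` (rows keep
    their original order), means and sparse residuals.  ``converged`` is
    true only if every block converged.  With a single block the result is
    identical to :func:`solve_omrfe`.
    """
    cfg = cfg or SolverConfig()
    Xv = _as_values(X)
    m, _ = Xv.shape
    spec.validate_against(m)
    block_results: list[FactorResult] = []
    for block in spec:
        sub = Xv[block.row_start : block.row_end]
        res = solve_omrfe(sub, replace(cfg, l=block.l))
        block_results.append(res)
    W = np.vstack([r.W for r in block_results])
    b = np.concatenate([r.b for r in block_results])
    E = np.vstack([r.E for r in block_results])
    single = len(block_results) == 1
    first = block_results[0]
    return FactorResult(
        W=W,
        V=first.V if single else None,
        b=b,
        E=E,
        objective_trace=first.objective_trace
        if single
        else np.asarray([r.objective_trace[-1] for r in block_results]),
        primal_residual_trace=first.primal_residual_trace
        if single
        else np.asarray([r.primal_residual_trace[-1] for r in block_results]),
        converged=all(r.converged for r in block_results),
        n_iter=first.n_iter if single else max(r.n_iter for r in block_results),
        method="ombrfe",
        block_results=block_results,
    )
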