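"""Planted-eigenvector synthetic benchmark and robustness experiments.

Data are drawn from a zero-mean Gaussian whose covariance is white noise
plus a handful of planted spike directions,

    Sigma = c_bg * I + sum_k (c_k - c_bg) * v_k v_k^T,

where each unit vector ``v_k`` is the normalized indicator of a
contiguous block of features (the blocks are disjoint, so the spikes are
orthonormal).  The default configuration plants four 125-feature blocks
covering the first 500 of 5000 features with spike eigenvalues
200/150/100/50 over a unit background, across 200 samples; the first
500 features are the ground-truth "feature genes" a solver should
recover.  Sampling uses the square-root construction
``X = sqrt(c_bg) Z + sum_k sqrt(c_k - c_bg) v_k z_k^T`` with standard
normal ``Z`` and ``z_k``, so no 5000 x 5000 covariance is ever formed.

Robustness experiments add white noise at a prescribed noise-to-signal
ratio (NSR, a Frobenius-energy ratio ``||noise||_F^2 / ||X||_F^2``) and
optionally contaminate the mean of a fraction of samples with a constant
offset.  ``run_l_sweep`` and ``run_nsr_comparison`` repeat the
generate-fit-select-score cycle over seeds and summarize identification
accuracy.

The generator emulates the covariance structure of the benchmark, not
real transcriptomic marginals; :func:`make_integrated_blocks` adds a
coarse four-type integrated matrix (integer copy-number-like, binary
mutation-like, (0,1)-bounded methylation-like and continuous
expression-like blocks) sharing a planted set of informative genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import FeatureMatrix
from .scoring import FeatureGeneMap, aggregate_gene_scores, score_features
from .solvers import (
    Block,
    BlockSpec,
    SolverConfig,
    solve_fe,
    solve_omrfe,
    solve_rfe,
)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "scaled_spec",
    "sample_synthetic",
    "add_contamination",
    "add_mean_contamination",
    "identification_accuracy",
    "select_top_features",
    "make_integrated_blocks",
    "run_l_sweep",
    "run_nsr_comparison",
]

NSR_METHODS = ("FE", "RFE", "OMRFE")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-covariance generator (defaults: the
    5000 x 200 benchmark with four 125-feature planted blocks)."""

    m: int = 5000
    n: int = 200
    planted_blocks: tuple[tuple[int, int], ...] = (
        (0, 125),
        (125, 250),
        (250, 375),
        (375, 500),
    )
    eigenvalues: tuple[float, ...] = (200.0, 150.0, 100.0, 50.0)
    background_eigenvalue: float = 1.0
    nsr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ValueError("m and n must be positive")
        if len(self.eigenvalues) != len(self.planted_blocks):
            raise ValueError("one eigenvalue per planted block is required")
        prev_end = -1
        for start, end in self.planted_blocks:
            if not 0 <= start < end <= self.m:
                raise ValueError(f"planted block ({start}, {end}) out of range")
            if start <= prev_end - 1 and start < prev_end:
                raise ValueError("planted blocks must be disjoint")
            if start < prev_end:
                raise ValueError("planted blocks must be disjoint and sorted")
            prev_end = end
        if self.background_eigenvalue <= 0:
            raise ValueError("background eigenvalue must be positive")
        for c in self.eigenvalues:
            if c < self.background_eigenvalue:
                raise ValueError(
                    "planted eigenvalues must not fall below the background"
                )
        if self.nsr < 0:
            raise ValueError("nsr must be nonnegative")


@dataclass(frozen=True)
class GroundTruth:
    """Sorted 0-based indices of the planted (true) features."""

    true_feature_indices: tuple[int, ...]

    def __init__(self, indices) -> None:
        object.__setattr__(
            self, "true_feature_indices", tuple(sorted(int(i) for i in indices))
        )

    def __len__(self) -> int:
        return len(self.true_feature_indices)

    def as_set(self) -> set[int]:
        return set(self.true_feature_indices)


def scaled_spec(seed: int = 0, nsr: float = 0.0) -> SyntheticSpec:
    """A 1000 x 100 reduction of the benchmark: four 25-feature planted
    blocks (features 0..99) with the same spike eigenvalues."""
    return SyntheticSpec(
        m=1000,
        n=100,
        planted_blocks=((0, 25), (25, 50), (50, 75), (75, 100)),
        eigenvalues=(200.0, 150.0, 100.0, 50.0),
        background_eigenvalue=1.0,
        nsr=nsr,
        seed=seed,
    )


def _feature_ids(m: int) -> list[str]:
    width = len(str(m))
    return [f"g{i + 1:0{width}d}" for i in range(m)]


def _sample_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"s{j + 1:0{width}d}" for j in range(n)]


def sample_synthetic(spec: SyntheticSpec) -> tuple[FeatureMatrix, GroundTruth]:
    """Draw a seeded features-by-samples matrix from the planted-spike
    Gaussian and return it with the ground-truth feature indices."""
    rng = np.random.default_rng(spec.seed)
    X = np.sqrt(spec.background_eigenvalue) * rng.standard_normal((spec.m, spec.n))
    for (start, end), c in zip(spec.planted_blocks, spec.eigenvalues):
        v = np.zeros(spec.m)
        v[start:end] = 1.0 / np.sqrt(end - start)
        z = rng.standard_normal(spec.n)
        X += np.sqrt(c - spec.background_eigenvalue) * np.outer(v, z)
    if spec.nsr > 0:
        X = add_contamination(X, spec.nsr, seed=int(rng.integers(2**31)))
    truth = GroundTruth(
        i for start, end in spec.planted_blocks for i in range(start, end)
    )
    fm = FeatureMatrix(X, _feature_ids(spec.m), _sample_ids(spec.n))
    return fm, truth


def _values(X) -> np.ndarray:
    return np.asarray(getattr(X, "values", X), dtype=float)


def add_contamination(X, nsr: float, seed: int = 0) -> np.ndarray:
    """Add white Gaussian noise scaled so ``||noise||_F^2 / ||X||_F^2 = nsr``.

    ``nsr=0`` returns the input unchanged (as an array copy).
    """
    Xv = _values(X)
    if nsr < 0:
        raise ValueError(f"nsr must be nonnegative, got {nsr}")
    if nsr == 0:
        return Xv.copy()
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(Xv.shape)
    scale = np.sqrt(nsr) * np.linalg.norm(Xv) / np.linalg.norm(noise)
    return Xv + scale * noise


def add_mean_contamination(
    X, offset: float, fraction: float, seed: int = 0
) -> np.ndarray:
    """Shift a random fraction of sample columns by a constant offset,
    corrupting the Euclidean column mean."""
    Xv = _values(X).copy()
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    n = Xv.shape[1]
    n_bad = int(round(fraction * n))
    if n_bad and offset != 0:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=n_bad, replace=False)
        Xv[:, idx] += offset
    return Xv


def identification_accuracy(selected, truth: GroundTruth) -> float:
    """Fraction of the truth recovered by ``selected``.

    With ``|selected| == |truth|`` this is ``|intersection| / |truth|``;
    otherwise ``|intersection| / |selected|`` is returned with a warning.
    Also accepts gene-symbol sets for gene-level evaluation.
    """
    selected = set(selected)
    if not selected:
        raise ValueError("selected set is empty")
    truth_set = truth.as_set() if isinstance(truth, GroundTruth) else set(truth)
    hits = len(selected & truth_set)
    if len(selected) == len(truth_set):
        return hits / len(truth_set)
    warnings.warn(
        f"|selected|={len(selected)} != |truth|={len(truth_set)}; "
        "reporting precision |hits|/|selected|",
        stacklevel=2,
    )
    return hits / len(selected)


def select_top_features(W: np.ndarray, n_select: int) -> np.ndarray:
    """Indices of the ``n_select`` features with the largest evaluating-
    vector scores.

    Ties are broken in a fixed pseudorandom order (deterministic across
    runs) rather than by feature index, so that a degenerate fit — e.g. a
    W shrunk to all zeros — cannot look accurate merely because the
    planted features occupy the first rows of the benchmark layout.
    """
    scores = score_features(W)
    if not 1 <= n_select <= scores.size:
        raise ValueError(f"n_select={n_select} out of range [1, {scores.size}]")
    tiebreak = np.random.default_rng(1729).permutation(scores.size)
    order = np.lexsort((tiebreak, -scores))
    return np.sort(order[:n_select])


# ---------------------------------------------------------------------------
# integrated multi-omics emulation

_BLOCK_TYPES = ("copy_number", "mutation", "methylation", "expression")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def make_integrated_blocks(
    m_per_block: tuple[int, int, int, int] = (111, 91, 208, 108),
    n: int = 40,
    shared_gene_fraction: float = 0.2,
    seed: int = 0,
    signal_strength: float = 2.0,
) -> tuple[FeatureMatrix, BlockSpec, FeatureGeneMap, GroundTruth]:
    """Build a four-block integrated matrix with a shared planted-gene set.

    The blocks emulate (coarsely) the marginals of an integrated genomic
    matrix: integer copy-number calls in {-2..2}, binary somatic
    mutations, (0,1)-bounded methylation fractions, and continuous
    expression values.  A set of informative genes — a
    ``shared_gene_fraction`` of the smallest block height — appears once
    in *every* block and carries a shared rank-one latent signal scaled
    by ``signal_strength``; the remaining features map to background
    genes supported by a single block.  Returned ground truth holds the
    informative feature row indices (their genes are recoverable through
    the map).
    """
    m_per_block = tuple(int(m) for m in m_per_block)
    if len(m_per_block) != len(_BLOCK_TYPES):
        raise ValueError(f"expected {len(_BLOCK_TYPES)} block heights")
    if min(m_per_block) < 2 or n < 2:
        raise ValueError("block heights and n must be at least 2")
    if not 0 < shared_gene_fraction <= 1:
        raise ValueError("shared_gene_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n_info = max(1, int(round(shared_gene_fraction * min(m_per_block))))
    info_genes = [f"GENE{i + 1:04d}" for i in range(n_info)]
    z = rng.standard_normal(n)  # shared latent sample factor

    rows: list[np.ndarray] = []
    entries: list[tuple[str, str, str]] = []
    blocks: list[Block] = []
    truth_idx: list[int] = []
    row_offset = 0
    gene_counter = n_info
    for btype, m_b in zip(_BLOCK_TYPES, m_per_block):
        amp = signal_strength * rng.uniform(0.8, 1.2, size=n_info)
        signal = np.zeros((m_b, n))
        signal[:n_info] = amp[:, None] * z[None, :]
        noise = rng.standard_normal((m_b, n))
        if btype == "copy_number":
            block = np.clip(np.round(0.8 * signal + 0.7 * noise), -2, 2)
        elif btype == "mutation":
            p = _sigmoid(-2.0 + 1.5 * signal)
            block = (rng.uniform(size=(m_b, n)) < p).astype(float)
        elif btype == "methylation":
            block = _sigmoid(0.8 * signal + 0.5 * noise)
        else:  # expression
            block = signal + noise
        rows.append(block)
        for i in range(m_b):
            fid = f"{btype}_{i + 1:04d}"
            if i < n_info:
                gene = info_genes[i]
                truth_idx.append(row_offset + i)
            else:
                gene_counter += 1
                gene = f"GENE{gene_counter:04d}"
            entries.append((fid, gene, btype))
        blocks.append(Block(btype, row_offset, row_offset + m_b, 1e-4))
        row_offset += m_b

    X = np.vstack(rows)
    feature_ids = [fid for fid, _, _ in entries]
    fm = FeatureMatrix(X, feature_ids, _sample_ids(n))
    return fm, BlockSpec(blocks), FeatureGeneMap(entries), GroundTruth(truth_idx)


# ---------------------------------------------------------------------------
# repeated-run experiments


def _child_seeds(master_seed: int, count: int) -> list[int]:
    rng = np.random.default_rng(master_seed)
    return [int(s) for s in rng.integers(2**31, size=count)]


def run_l_sweep(
    l_values,
    reps: int,
    spec: SyntheticSpec,
    cfg: SolverConfig | None = None,
) -> pd.DataFrame:
    """Mean identification accuracy of OMRFE per regularizer constant ``l``.

    For each repetition a fresh dataset is drawn (child seeds derived
    from ``spec.seed``), OMRFE is fitted at every ``l``, the top-|truth|
    features are selected by evaluating-vector score, and accuracies are
    averaged per ``l``.  Deterministic given ``spec.seed``.
    """
    l_values = [float(l) for l in l_values]
    if not l_values:
        raise ValueError("l_values must be nonempty")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    cfg = cfg or SolverConfig()
    acc: dict[float, list[float]] = {l: [] for l in l_values}
    for seed in _child_seeds(spec.seed, reps):
        fm, truth = sample_synthetic(replace(spec, seed=seed))
        for l in l_values:
            res = solve_omrfe(fm.values, replace(cfg, l=l))
            sel = select_top_features(res.W, len(truth))
            acc[l].append(identification_accuracy(sel, truth))
    return pd.DataFrame(
        {"l": l_values, "mean_accuracy": [float(np.mean(acc[l])) for l in l_values]}
    )


def _fit_and_score(method: str, X: np.ndarray, cfg: SolverConfig, truth: GroundTruth):
    if method == "FE":
        res = solve_fe(X, cfg.k)
    elif method == "RFE":
        res = solve_rfe(X, cfg)
    elif method == "OMRFE":
        res = solve_omrfe(X, cfg)
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {NSR_METHODS}")
    sel = select_top_features(res.W, len(truth))
    return identification_accuracy(sel, truth)


def run_nsr_comparison(
    nsr_values,
    reps: int,
    spec: SyntheticSpec,
    cfg: SolverConfig | None = None,
    methods=NSR_METHODS,
    mean_offset: float = 0.0,
    mean_fraction: float = 0.0,
) -> pd.DataFrame:
    """Median identification accuracy and IQR per method and NSR level.

    Each repetition draws a fresh planted dataset, adds white noise at
    every requested NSR and (optionally) a constant-offset mean
    contamination of a random sample fraction, then fits each method
    (FE / RFE / OMRFE) and records the top-|truth| identification
    accuracy.  Summaries are the median and interquartile range over
    repetitions.  Deterministic given ``spec.seed``.
    """
    nsr_values = [float(v) for v in nsr_values]
    if not nsr_values:
        raise ValueError("nsr_values must be nonempty")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    methods = tuple(methods)
    for method in methods:
        if method not in NSR_METHODS:
            raise ValueError(
                f"unknown method {method!r}; expected one of {NSR_METHODS}"
            )
    cfg = cfg or SolverConfig()
    records: dict[tuple[str, float], list[float]] = {
        (method, nsr): [] for method in methods for nsr in nsr_values
    }
    for seed in _child_seeds(spec.seed, reps):
        fm, truth = sample_synthetic(replace(spec, seed=seed))
        for i, nsr in enumerate(nsr_values):
            Xn = add_contamination(fm.values, nsr, seed=seed + i + 1)
            if mean_offset and mean_fraction:
                Xn = add_mean_contamination(
                    Xn, mean_offset, mean_fraction, seed=seed + i + 1
                )
            for method in methods:
                records[(method, nsr)].append(_fit_and_score(method, Xn, cfg, truth))
    rows = []
    for method in methods:
        for nsr in nsr_values:
            vals = np.asarray(records[(method, nsr)])
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append((method, nsr, float(med), float(q3 - q1)))
    return pd.DataFrame(rows, columns=["method", "nsr", "median_accuracy", "iqr"])
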