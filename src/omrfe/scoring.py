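"""Feature and gene scoring from an optimized loading matrix W.

The per-feature "evaluating vector" is the row sum of absolute loadings,
``score_i = sum_k |w_ik|``: the more differentially expressed a feature,
the larger its entry.  For integrated multi-omics fits one gene may own
several genomic features (a copy-number row, a mutation row, ...); the
gene score is the plain sum of its features' scores, and genes are
ranked by descending score with a deterministic tie-break (gene symbol
ascending).

Up-/down-regulation is encoded in the signs of W but ranking uses
absolute values only; a ``direction`` column (majority sign of the
supporting loadings) is emitted for information and never used to rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FeatureGeneMap",
    "score_features",
    "feature_signs",
    "aggregate_gene_scores",
    "top_h",
]


@dataclass(frozen=True)
class FeatureGeneMap:
    """Mapping from genomic features to gene symbols.

    ``entries`` is a sequence of ``(feature_id, gene_symbol, block_name)``
    triples.  Feature ids are unique; a gene may be supported by many
    features (one per genomic data type that covers it).
    """

    entries: tuple[tuple[str, str, str], ...]

    def __init__(self, entries) -> None:
        entries = tuple((str(f), str(g), str(b)) for f, g, b in entries)
        seen: set[str] = set()
        for fid, _, _ in entries:
            if fid in seen:
                raise ValueError(f"duplicate feature_id in map: {fid!r}")
            seen.add(fid)
        object.__setattr__(self, "entries", entries)

    def __len__(self) -> int:
        return len(self.entries)

    def gene_of(self) -> dict[str, str]:
        return {fid: gene for fid, gene, _ in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.entries), columns=["feature_id", "gene_symbol", "block_name"]
        )

    @classmethod
    def identity(cls, feature_ids, block_name: str = "all") -> "FeatureGeneMap":
        """One-to-one map using the feature ids themselves as gene symbols."""
        return cls((fid, fid, block_name) for fid in feature_ids)


def score_features(W: np.ndarray) -> np.ndarray:
    """Evaluating vector: ``score_i = sum_k |w_ik|`` (nonnegative, length m)."""
    W = np.asarray(W, dtype=float)
    if W.size == 0:
        raise ValueError("W is empty")
    if W.ndim == 1:
        W = W[:, None]
    if not np.all(np.isfinite(W)):
        raise ValueError("W contains non-finite entries")
    return np.abs(W).sum(axis=1)


def feature_signs(W: np.ndarray) -> np.ndarray:
    """Majority sign of each feature's loadings (informational only)."""
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    return np.sign(np.sign(W).sum(axis=1))


def aggregate_gene_scores(
    feature_scores: np.ndarray,
    feature_ids,
    gene_map: FeatureGeneMap,
    feature_directions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Aggregate per-feature scores into a ranked per-gene table.

    Each gene's score is the sum of the scores of the features mapping to
    it; ``n_supporting_features`` counts them.  The table is sorted by
    score descending with ties broken by gene symbol ascending, and
    ``rank`` runs 1..G.  Map entry order is irrelevant: scores align with
    ``feature_ids``.

    Raises ``ValueError`` listing any feature id absent from the map.
    """
    scores = np.asarray(feature_scores, dtype=float)
    feature_ids = [str(f) for f in feature_ids]
    if scores.ndim != 1 or len(feature_ids) != scores.size:
        raise ValueError(
            f"feature_scores (n={scores.size}) and feature_ids "
            f"(n={len(feature_ids)}) must align"
        )
    gene_of = gene_map.gene_of()
    missing = sorted(set(feature_ids) - gene_of.keys())
    if missing:
        raise ValueError(f"feature ids missing from the gene map: {missing}")
    frame = pd.DataFrame(
        {
            "gene_symbol": [gene_of[f] for f in feature_ids],
            "score": scores,
            "direction": np.zeros(scores.size)
            if feature_directions is None
            else np.asarray(feature_directions, dtype=float),
        }
    )
    table = (
        frame.groupby("gene_symbol", sort=False)
        .agg(score=("score", "sum"), n_supporting_features=("score", "size"),
             direction=("direction", "sum"))
        .reset_index()
    )
    table["direction"] = np.sign(table["direction"])
    table = table.sort_values(
        ["score", "gene_symbol"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    cols = ["gene_symbol", "score", "n_supporting_features", "rank"]
    if feature_directions is not None:
        cols.append("direction")
    return table[cols]


def top_h(table: pd.DataFrame, h: int) -> pd.DataFrame:
    """First ``h`` rows of a ranked gene table (``1 <= h <= #genes``)."""
    if not 1 <= h <= len(table):
        raise ValueError(f"h={h} out of range [1, {len(table)}]")
    return table.iloc[:h].reset_index(drop=True)
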