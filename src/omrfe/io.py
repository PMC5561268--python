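"""Delimited-text readers and writers for matrices, block specs and tables.

All artifact files are plain TSV/CSV (the delimiter is sniffed on read):
a feature matrix has sample ids in the first row and feature ids in the
first column; a block spec lists one block per line with 1-based
*inclusive* row ranges, matching the prose convention used for
integrated genomic matrices ("rows 1~1117 are copy number"), and is
converted to 0-based half-open ranges internally; a gene map lists
``feature_id, gene_symbol, block_name``.

Missing values are rejected with their coordinates rather than imputed:
the factorization model assumes a complete matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .scoring import FeatureGeneMap
from .solvers import Block, BlockSpec

__all__ = [
    "FeatureMatrix",
    "read_matrix",
    "write_matrix",
    "read_blockspec",
    "write_blockspec",
    "read_gene_map",
    "write_gene_map",
]

#: number of significant digits written for floats (round-trips to ~1e-12)
FLOAT_FORMAT = "%.12g"


@dataclass
class FeatureMatrix:
    """A features-by-samples numeric matrix with row and column identifiers."""

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        m, n = self.values.shape
        if len(self.feature_ids) != m or len(self.sample_ids) != n:
            raise ValueError(
                f"id lengths ({len(self.feature_ids)}, {len(self.sample_ids)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise ValueError(f"duplicate {name} ids: {dupes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_matrix(path, transpose: bool = False) -> FeatureMatrix:
    """Read a delimited feature matrix (first row sample ids, first column
    feature ids; tab or comma delimiter sniffed from the header).

    ``transpose=True`` reads a samples-by-features file.  Duplicate ids,
    missing cells and non-numeric cells raise ``ValueError`` with the
    offending location.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_sep(path)
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed delimited file: {exc}") from exc
    if transpose:
        frame = frame.T
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell at feature {frame.index[r]!r}, "
            f"sample {frame.columns[c]!r}: {frame.iat[r, c]!r}"
        )
    missing = numeric.isna()
    if missing.to_numpy().any():
        r, c = np.argwhere(missing.to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at feature {frame.index[r]!r}, "
            f"sample {frame.columns[c]!r}"
        )
    return FeatureMatrix.from_frame(numeric)


def write_matrix(fm: FeatureMatrix, path, sep: str = "\t") -> None:
    """Write a feature matrix as delimited text (12 significant digits)."""
    fm.to_frame().to_csv(path, sep=sep, float_format=FLOAT_FORMAT, index_label="feature_id")


def read_blockspec(path) -> BlockSpec:
    """Read a block spec table with columns ``name, start, end, l``.

    ``start``/``end`` are 1-based inclusive row numbers (the prose
    convention); they become 0-based half-open internally.  Contiguity is
    validated here; exact tiling against a matrix height at fit time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=_sniff_sep(path))
    required = {"name", "start", "end", "l"}
    if not required.issubset(frame.columns):
        raise ValueError(
            f"{path}: block spec needs columns {sorted(required)}, "
            f"got {list(frame.columns)}"
        )
    blocks = [
        Block(str(row["name"]), int(row["start"]) - 1, int(row["end"]), float(row["l"]))
        for _, row in frame.iterrows()
    ]
    return BlockSpec(blocks)


def write_blockspec(spec: BlockSpec, path, sep: str = "\t") -> None:
    """Write a block spec using 1-based inclusive row ranges."""
    frame = pd.DataFrame(
        [(b.name, b.row_start + 1, b.row_end, b.l) for b in spec],
        columns=["name", "start", "end", "l"],
    )
    frame.to_csv(path, sep=sep, index=False, float_format=FLOAT_FORMAT)


def read_gene_map(path) -> FeatureGeneMap:
    """Read a ``feature_id, gene_symbol, block_name`` table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    required = {"feature_id", "gene_symbol", "block_name"}
    if not required.issubset(frame.columns):
        raise ValueError(
            f"{path}: gene map needs columns {sorted(required)}, "
            f"got {list(frame.columns)}"
        )
    return FeatureGeneMap(
        frame[["feature_id", "gene_symbol", "block_name"]].itertuples(index=False)
    )


def write_gene_map(gene_map: FeatureGeneMap, path, sep: str = "\t") -> None:
    gene_map.to_frame().to_csv(path, sep=sep, index=False)
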