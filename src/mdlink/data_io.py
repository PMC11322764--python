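"""Association-table I/O, adjacency construction and synthetic fixtures.

The single source of truth for everything downstream is the binary
disease x microbe adjacency matrix ``A`` (rows: diseases, columns:
microbes).  Curated databases such as HMDAD and Disbiome export edge
lists of (disease name, microbe name) records; this module reads those,
de-duplicates them, and indexes them into a dense 0/1 matrix.

For testing without any download, :func:`generate_synthetic_associations`
plants low-rank block structure: latent non-negative factors U, V give a
score matrix ``S = U @ V.T`` whose densest cells become the known
associations, so similarity-propagation methods can recover held-out
edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AssociationData",
    "AssociationMatrix",
    "SyntheticSpec",
    "SyntheticResult",
    "FormatError",
    "read_association_table",
    "build_adjacency",
    "generate_synthetic_associations",
    "write_matrix",
    "read_matrix",
]


class FormatError(ValueError):
    """Malformed input table or matrix file."""


@dataclass
class AssociationData:
    """De-duplicated edge list with stable name indices (0-based)."""

    disease_names: list[str]
    microbe_names: list[str]
    pairs: set[tuple[int, int]]
    n_rows_read: int = 0
    n_pairs_kept: int = 0

    def __post_init__(self):
        nd, nm = len(self.disease_names), len(self.microbe_names)
        for i, j in self.pairs:
            if not (0 <= i < nd and 0 <= j < nm):
                raise ValueError(f"pair index ({i},{j}) out of range {nd}x{nm}")

    @property
    def nd(self) -> int:
        return len(self.disease_names)

    @property
    def nm(self) -> int:
        return len(self.microbe_names)


@dataclass
class AssociationMatrix:
    """Dense binary adjacency; rows are diseases, columns are microbes."""

    values: np.ndarray
    disease_names: list[str]
    microbe_names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.disease_names), len(self.microbe_names)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match label counts "
                f"({len(self.disease_names)}, {len(self.microbe_names)})"
            )

    @property
    def nd(self) -> int:
        return len(self.disease_names)

    @property
    def nm(self) -> int:
        return len(self.microbe_names)

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())


@dataclass
class SyntheticSpec:
    """Parameters of the planted low-rank fixture generator."""

    nd: int
    nm: int
    rank: int
    density: float
    seed: int

    def __post_init__(self):
        if self.rank > min(self.nd, self.nm):
            raise ValueError(
                f"rank {self.rank} exceeds min(nd, nm) = {min(self.nd, self.nm)}"
            )
        if not 0 < self.density < 1:
            raise ValueError(f"density must lie in (0, 1), got {self.density}")
        n_ones = math.ceil(self.density * self.nd * self.nm)
        if n_ones >= self.nd * self.nm:
            raise ValueError(
                "density leaves no unknown pairs for cross-validation negatives"
            )


@dataclass
class SyntheticResult:
    matrix: AssociationMatrix
    factors_u: np.ndarray = field(repr=False)
    factors_v: np.ndarray = field(repr=False)


def _normalize_name(name: str) -> str:
    return " ".join(name.split()).casefold()


def read_association_table(
    path,
    disease_col: str | int = "disease",
    microbe_col: str | int = "microbe",
    sep: str | None = None,
    header: bool = True,
) -> AssociationData:
    """Read a disease/microbe edge list from a TSV or CSV file.

    Extra columns are ignored.  Names are trimmed; de-duplication of names
    and of (disease, microbe) pairs is case-insensitive after whitespace
    normalization, preserving first-occurrence order and spelling.

    Parameters
    ----------
    disease_col, microbe_col
        Column names (``header=True``) or 0-based positions (``header=False``).
    sep
        Field separator; inferred from the file extension when omitted
        (``.csv`` -> comma, otherwise tab).
    """
    if sep is None:
        sep = "," if str(path).lower().endswith(".csv") else "\t"
    try:
        df = pd.read_csv(
            path,
            sep=sep,
            header=0 if header else None,
            dtype=str,
            keep_default_na=False,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty input file") from None
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no data rows")
    for col in (disease_col, microbe_col):
        ok = col in df.columns if isinstance(col, str) else col < df.shape[1]
        if not ok:
            raise FormatError(f"{path}: missing required column {col!r}")

    d_series = df[disease_col] if isinstance(disease_col, str) else df.iloc[:, disease_col]
    m_series = df[microbe_col] if isinstance(microbe_col, str) else df.iloc[:, microbe_col]

    disease_names: list[str] = []
    microbe_names: list[str] = []
    d_index: dict[str, int] = {}
    m_index: dict[str, int] = {}
    pairs: set[tuple[int, int]] = set()
    offset = 2 if header else 1  # 1-based line number of the first data row
    for row_no, (d_raw, m_raw) in enumerate(zip(d_series, m_series)):
        d = " ".join(str(d_raw).split())
        m = " ".join(str(m_raw).split())
        if not d or not m:
            raise FormatError(
                f"{path}: line {row_no + offset}: empty disease or microbe field"
            )
        dk, mk = d.casefold(), m.casefold()
        if dk not in d_index:
            d_index[dk] = len(disease_names)
            disease_names.append(d)
        if mk not in m_index:
            m_index[mk] = len(microbe_names)
            microbe_names.append(m)
        pairs.add((d_index[dk], m_index[mk]))

    return AssociationData(
        disease_names=disease_names,
        microbe_names=microbe_names,
        pairs=pairs,
        n_rows_read=len(df),
        n_pairs_kept=len(pairs),
    )


def build_adjacency(data: AssociationData) -> AssociationMatrix:
    """Index an edge list into the dense binary adjacency matrix A."""
    values = np.zeros((data.nd, data.nm))
    for i, j in data.pairs:
        values[i, j] = 1.0
    return AssociationMatrix(values, list(data.disease_names), list(data.microbe_names))


def generate_synthetic_associations(spec: SyntheticSpec) -> SyntheticResult:
    """Plant low-rank structure and threshold it into a binary adjacency.

    Latent factors are |N(0,1)| draws, so ``S = U @ V.T`` is non-negative
    with block-like hot spots; exactly ``ceil(density*nd*nm)`` cells with
    the highest scores become associations.  Ties at the threshold break
    by (row, column) order.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    u = np.abs(rng.standard_normal((spec.nd, spec.rank)))
    v = np.abs(rng.standard_normal((spec.nm, spec.rank)))
    scores = u @ v.T
    n_ones = math.ceil(spec.density * spec.nd * spec.nm)
    flat = scores.ravel()  # row-major, so flat index orders by (row, column)
    order = np.lexsort((np.arange(flat.size), -flat))
    values = np.zeros(flat.size)
    values[order[:n_ones]] = 1.0
    matrix = AssociationMatrix(
        values.reshape(spec.nd, spec.nm),
        [f"disease_{i}" for i in range(spec.nd)],
        [f"microbe_{j}" for j in range(spec.nm)],
    )
    return SyntheticResult(matrix=matrix, factors_u=u, factors_v=v)


def write_matrix(path, values: np.ndarray, row_labels, col_labels) -> None:
    """Write a labeled dense matrix as TSV (header row, first column = row labels)."""
    values = np.asarray(values, dtype=float)
    if values.shape != (len(row_labels), len(col_labels)):
        raise FormatError(
            f"shape {values.shape} does not match labels "
            f"({len(row_labels)}, {len(col_labels)})"
        )
    if not np.isfinite(values).all():
        raise FormatError("refusing to write a matrix with NaN or infinite entries")
    df = pd.DataFrame(values, index=list(row_labels), columns=list(col_labels))
    df.to_csv(path, sep="\t", index_label="")


def read_matrix(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a labeled TSV matrix written by :func:`write_matrix`."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty matrix file") from None
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric matrix entry ({exc})") from None
    return values, [str(x) for x in df.index], [str(x) for x in df.columns]
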