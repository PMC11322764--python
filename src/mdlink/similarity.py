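"""Similarity kernels, network diffusion and the heterogeneous network.

All similarities derive from the binary adjacency A alone:

* GIP kernel: ``exp(-gamma * ||x - y||^2)`` between interaction profiles,
  with the bandwidth ``gamma = n / sum_i ||x_i||^2`` set from the mean
  squared profile norm across the axis.
* Hamming similarity: one minus the fraction of differing profile
  positions.
* Cosine similarity between profiles, with all-zero profiles given
  similarity 0 off-diagonal and 1 on the diagonal.
* Random walk with restart (RWR): ``q <- phi * M @ q + (1 - phi) * e_i``
  over the column-normalized similarity graph, giving one proximity row
  per node.

The integrated similarity (GIP + Hamming)/2 for both axes, together with
A, forms the two-node-type heterogeneous network
``HN = [[SD, A], [A^T, SM]]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import AssociationMatrix, read_matrix

__all__ = [
    "SimilarityMatrix",
    "HeterogeneousNetwork",
    "RwrParams",
    "gip_similarity",
    "hamming_similarity",
    "integrate_similarity",
    "cosine_similarity",
    "rwr_diffusion",
    "load_functional_similarity",
    "build_heterogeneous_network",
    "split_heterogeneous_network",
]

_SYMMETRIC_KINDS = {"gip", "hamming", "integrated", "cosine", "functional"}


@dataclass
class SimilarityMatrix:
    values: np.ndarray
    axis_role: str  # "disease" | "microbe"
    kind: str  # gip | hamming | integrated | cosine | functional | diffusion
    labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity matrix must be {n}x{n}, got {self.values.shape}")
        if self.kind in _SYMMETRIC_KINDS:
            if not np.allclose(self.values, self.values.T, atol=1e-10):
                raise ValueError(f"{self.kind} similarity must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class HeterogeneousNetwork:
    """Block matrix [[SD, A], [A^T, SM]] over diseases then microbes."""

    values: np.ndarray
    nd: int
    nm: int
    node_labels: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.nd + self.nm
        if self.values.shape != (n, n):
            raise ValueError(f"heterogeneous network must be {n}x{n}")


@dataclass
class RwrParams:
    """Random-walk-with-restart settings; `phi` weights the walk term."""

    phi: float = 0.1
    tol: float = 1e-6
    max_iter: int = 100

    def __post_init__(self):
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


def _profiles(A: AssociationMatrix, axis_role: str) -> tuple[np.ndarray, list[str]]:
    """Per-entity interaction profiles as rows: disease profiles are rows
    of A (length Nm), microbe profiles are columns of A (length Nd)."""
    if axis_role == "disease":
        return A.values, A.disease_names
    if axis_role == "microbe":
        return A.values.T, A.microbe_names
    raise ValueError(f"axis_role must be 'disease' or 'microbe', got {axis_role!r}")


def _check_binary(A: AssociationMatrix) -> None:
    if not np.isin(A.values, (0.0, 1.0)).all():
        raise ValueError("adjacency matrix must be binary (0/1)")


def gip_similarity(A: AssociationMatrix, axis_role: str) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over one axis of A.

    The bandwidth is ``gamma = n / sum_i ||p_i||^2`` where the ``p_i`` are
    the n interaction profiles of the chosen axis.
    """
    P, labels = _profiles(A, axis_role)
    sq_norms = (P**2).sum(axis=1)
    total = sq_norms.sum()
    if total == 0:
        raise ZeroDivisionError(
            "GIP bandwidth gamma is undefined for an all-zero adjacency "
            "(zero total squared profile norm)"
        )
    gamma = len(labels) / total
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2 * P @ P.T
    np.maximum(d2, 0, out=d2)
    values = np.exp(-gamma * d2)
    values = (values + values.T) / 2
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, axis_role, "gip", list(labels))


def hamming_similarity(A: AssociationMatrix, axis_role: str) -> SimilarityMatrix:
    """1 - (fraction of differing positions) between binary profiles.

    Normalized by the actual profile length (Nd for microbe profiles,
    Nm for disease profiles) so values stay in [0, 1] with unit diagonal.
    """
    _check_binary(A)
    P, labels = _profiles(A, axis_role)
    length = P.shape[1]
    # for binary vectors, |x - y| summed == x.(1-y) + (1-x).y
    ones = P.sum(axis=1)
    diff = ones[:, None] + ones[None, :] - 2 * P @ P.T
    values = 1.0 - diff / length
    return SimilarityMatrix(values, axis_role, "hamming", list(labels))


def integrate_similarity(gip: SimilarityMatrix, ham: SimilarityMatrix) -> SimilarityMatrix:
    """Average the GIP and Hamming kernels into the integrated similarity."""
    if gip.axis_role != ham.axis_role:
        raise ValueError(f"axis_role mismatch: {gip.axis_role} vs {ham.axis_role}")
    if gip.values.shape != ham.values.shape:
        raise ValueError("shape mismatch between similarity matrices")
    return SimilarityMatrix(
        (gip.values + ham.values) / 2, gip.axis_role, "integrated", list(gip.labels)
    )


def cosine_similarity(A: AssociationMatrix, axis_role: str) -> SimilarityMatrix:
    _check_binary(A)
    P, labels = _profiles(A, axis_role)
    norms = np.sqrt((P**2).sum(axis=1))
    safe = np.where(norms == 0, 1.0, norms)
    values = (P @ P.T) / (safe[:, None] * safe[None, :])
    values[norms == 0, :] = 0.0
    values[:, norms == 0] = 0.0
    np.clip(values, 0.0, 1.0, out=values)
    values = (values + values.T) / 2
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, axis_role, "cosine", list(labels))


def transfer_matrix(S: np.ndarray) -> np.ndarray:
    """Column-normalize S into a column-stochastic transfer matrix;
    all-zero columns become uniform."""
    S = np.asarray(S, dtype=float)
    if (S < 0).any():
        raise ValueError("similarity entries must be non-negative for diffusion")
    col_sums = S.sum(axis=0)
    M = np.where(col_sums == 0, 1.0 / S.shape[0], S / np.where(col_sums == 0, 1.0, col_sums))
    return M


def rwr_diffusion(S: SimilarityMatrix, params: RwrParams | None = None) -> SimilarityMatrix:
    """Random walk with restart over the similarity graph.

    Iterates ``q_i <- phi * M @ q_i + (1 - phi) * e_i`` for every node i
    until the L1 change drops below ``tol``.  Row i of the output is the
    converged proximity vector of node i; rows sum to 1 because M is
    column-stochastic.
    """
    params = params or RwrParams()
    n = S.n
    M = transfer_matrix(S.values)
    Q = np.eye(n)  # columns are the q_i, started at the restart vectors
    E = np.eye(n)
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iter + 1):
        Q_next = params.phi * (M @ Q) + (1 - params.phi) * E
        if np.abs(Q_next - Q).sum(axis=0).max() < params.tol:
            Q = Q_next
            converged = True
            break
        Q = Q_next
    if not converged:
        warnings.warn(
            f"RWR did not converge within {params.max_iter} iterations; "
            "returning the last iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    return SimilarityMatrix(
        Q.T,
        S.axis_role,
        "diffusion",
        list(S.labels),
        meta={"converged": converged, "iterations": iterations, "phi": params.phi},
    )


def load_functional_similarity(path, labels, axis_role: str = "disease") -> SimilarityMatrix:
    """Load an externally computed functional-similarity matrix.

    The file must cover every dataset label; values are re-ordered to the
    dataset label order, clipped to [0, 1] and symmetrized by averaging
    with the transpose.  With ``path=None`` the neutral identity fallback
    is returned (no external functional information).
    """
    labels = list(labels)
    n = len(labels)
    if path is None:
        return SimilarityMatrix(np.eye(n), axis_role, "functional", labels,
                                meta={"fallback": True})
    values, row_labels, col_labels = read_matrix(path)
    if row_labels != col_labels:
        raise ValueError(f"{path}: functional similarity must have matching row/column labels")
    index = {name.casefold(): k for k, name in enumerate(row_labels)}
    missing = [name for name in labels if name.casefold() not in index]
    if missing:
        raise ValueError(f"{path}: labels missing from functional similarity: {missing}")
    order = [index[name.casefold()] for name in labels]
    sub = values[np.ix_(order, order)]
    sub = np.clip((sub + sub.T) / 2, 0.0, 1.0)
    return SimilarityMatrix(sub, axis_role, "functional", labels)


def build_heterogeneous_network(
    SD: SimilarityMatrix, SM: SimilarityMatrix, A: AssociationMatrix
) -> HeterogeneousNetwork:
    """Assemble HN = [[SD, A], [A^T, SM]]."""
    if SD.n != A.nd:
        raise ValueError(f"SD is {SD.n}x{SD.n} but A has {A.nd} disease rows")
    if SM.n != A.nm:
        raise ValueError(f"SM is {SM.n}x{SM.n} but A has {A.nm} microbe columns")
    top = np.hstack([SD.values, A.values])
    bottom = np.hstack([A.values.T, SM.values])
    return HeterogeneousNetwork(
        np.vstack([top, bottom]),
        nd=A.nd,
        nm=A.nm,
        node_labels=list(A.disease_names) + list(A.microbe_names),
    )


def split_heterogeneous_network(
    hn: HeterogeneousNetwork,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`build_heterogeneous_network`: (SD, SM, A) blocks."""
    nd = hn.nd
    return (
        hn.values[:nd, :nd].copy(),
        hn.values[nd:, nd:].copy(),
        hn.values[:nd, nd:].copy(),
    )
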