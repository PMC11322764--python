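"""Topological embeddings from an attention-normalized graph convolution.

The propagation operator is built in three pieces over the heterogeneous
network HN (diseases then microbes, N = Nd + Nm nodes):

* attention scores ``A_att(i, j) = exp(LeakyReLU([H_i || H_j] . a))``
  masked to each node's HN neighborhood plus itself,
* their row normalization ``D_att_r^{-1} A_att`` (rows sum to 1 on the
  support),
* a symmetric self-loop degree rescaling ``(I + D)^{-1/2} . (I + D)^{-1/2}``
  where D holds the *bipartite* degrees: row sums of A for disease nodes,
  column sums for microbe nodes.

One propagation layer ``H' = ReLU(T @ H @ W)`` (width k1) produces the
embedding Z = [Zd; Zm].  Training reconstructs HN through the decoder
``sigmoid(Z @ Z.T)`` under a row-mean squared-error loss, optimized with
Adam over the attention vector ``a`` and the layer weights ``W``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import Adam, Tensor
from .data_io import AssociationMatrix
from .similarity import HeterogeneousNetwork

__all__ = [
    "GcanConfig",
    "TopologicalEmbedding",
    "attention_scores",
    "transition_matrix",
    "gcan_forward",
    "gcan_decode",
    "gcan_loss",
    "train_gcan",
    "neighborhood_mask",
    "bipartite_degrees",
]


@dataclass
class GcanConfig:
    k1: int = 128
    n_layers: int = 1
    lr1: float = 0.01
    epochs: int = 200
    leaky_slope: float = 0.2
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.k1 < 1 or self.n_layers < 1:
            raise ValueError("k1 and n_layers must be >= 1")
        if self.lr1 <= 0:
            raise ValueError("lr1 must be positive")


@dataclass
class TopologicalEmbedding:
    Zd: np.ndarray
    Zm: np.ndarray
    loss_trace: list[float] = field(default_factory=list, repr=False)


def neighborhood_mask(hn_values: np.ndarray) -> np.ndarray:
    """Boolean attention support: j in N_i (HN(i,j) > 0) or j == i."""
    mask = np.asarray(hn_values) > 0
    mask = mask.copy()
    np.fill_diagonal(mask, True)
    return mask


def bipartite_degrees(A: np.ndarray, nd: int, nm: int) -> np.ndarray:
    """Degree vector of the self-loop-free bipartite graph: row sums of A
    for the Nd disease nodes, column sums for the Nm microbe nodes."""
    A = np.asarray(A, dtype=float)
    if A.shape != (nd, nm):
        raise ValueError(f"A must be {nd}x{nm}, got {A.shape}")
    return np.concatenate([A.sum(axis=1), A.sum(axis=0)])


def attention_scores(
    H: np.ndarray, a: np.ndarray, mask: np.ndarray, leaky_slope: float = 0.2
) -> np.ndarray:
    """Masked attention matrix exp(LeakyReLU([H_i || H_j] . a)).

    The concatenated inner product splits as ``H_i.a1 + H_j.a2`` with
    ``a = [a1; a2]``, so scores come from an outer sum of two projections.
    """
    H = np.asarray(H, dtype=float)
    a = np.asarray(a, dtype=float)
    n, w = H.shape
    if a.shape != (2 * w,):
        raise ValueError(f"attention vector must have length {2 * w}, got {a.shape}")
    if mask.shape != (n, n):
        raise ValueError("mask shape mismatch")
    u = H @ a[:w]
    v = H @ a[w:]
    e = u[:, None] + v[None, :]
    e = np.where(e > 0, e, leaky_slope * e)
    return np.where(mask, np.exp(e), 0.0)


def transition_matrix(A_att: np.ndarray, A: np.ndarray, nd: int, nm: int) -> np.ndarray:
    """(I + D)^{-1/2} (D_att_r^{-1} A_att) (I + D)^{-1/2}.

    ``D_att_r`` is the diagonal of row sums of the masked attention, so the
    inner factor is row-stochastic on its support; D holds the bipartite
    degrees of the N = nd + nm nodes.
    """
    A_att = np.asarray(A_att, dtype=float)
    n = nd + nm
    if A_att.shape != (n, n):
        raise ValueError(f"attention matrix must be {n}x{n}")
    row_sums = A_att.sum(axis=1, keepdims=True)
    P = A_att / row_sums
    scale = 1.0 / np.sqrt(1.0 + bipartite_degrees(A, nd, nm))
    return scale[:, None] * P * scale[None, :]


def gcan_forward(
    hn_values: np.ndarray,
    weights: list[np.ndarray],
    attn_vectors: list[np.ndarray],
    A: np.ndarray,
    nd: int,
    nm: int,
    leaky_slope: float = 0.2,
) -> np.ndarray:
    """Layer-by-layer propagation H <- ReLU(T @ H @ W), with the attention
    (and hence T) recomputed from the current H at every layer."""
    H = np.asarray(hn_values, dtype=float)
    mask = neighborhood_mask(hn_values)
    for W, a in zip(weights, attn_vectors):
        A_att = attention_scores(H, a, mask, leaky_slope)
        T = transition_matrix(A_att, A, nd, nm)
        H = np.maximum(T @ H @ W, 0.0)
        if not np.isfinite(H).all():
            raise FloatingPointError("non-finite activations in graph propagation")
    return H


def gcan_decode(Z: np.ndarray) -> np.ndarray:
    """Inner-product decoder sigmoid(Z @ Z.T); symmetric, entries in (0, 1)."""
    Z = np.asarray(Z, dtype=float)
    return 1.0 / (1.0 + np.exp(-np.clip(Z @ Z.T, -500, 500)))


def gcan_loss(ZZ: np.ndarray, hn_values: np.ndarray) -> float:
    """Mean over rows of the squared row-difference norm between the
    reconstruction and HN."""
    ZZ = np.asarray(ZZ, dtype=float)
    hn_values = np.asarray(hn_values, dtype=float)
    if ZZ.shape != hn_values.shape:
        raise ValueError("reconstruction and network shapes differ")
    return float(((ZZ - hn_values) ** 2).sum() / ZZ.shape[0])


def _xavier(rng: np.random.Generator, shape: tuple, dtype) -> np.ndarray:
    bound = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


def _forward_graph(
    hn: Tensor,
    params_w: list[Tensor],
    params_a: list[Tensor],
    mask: np.ndarray,
    scale_outer: np.ndarray,
    slope: float,
) -> Tensor:
    """Autodiff twin of :func:`gcan_forward` (numerically stabilized:
    a per-row constant is subtracted before exp, which leaves the
    row-normalized attention unchanged)."""
    H = hn
    n = mask.shape[0]
    neg = np.where(mask, 0.0, -np.inf)
    for W, a in zip(params_w, params_a):
        w = H.shape[1]
        u = H @ a[:w]
        v = H @ a[w:]
        e = (u.reshape(n, 1) + v.reshape(1, n)).leaky_relu(slope)
        row_max = np.max(e.data + neg, axis=1, keepdims=True)
        att = (e - Tensor(row_max)).exp() * Tensor(mask.astype(H.dtype))
        P = att / att.sum(axis=1, keepdims=True)
        T = P * Tensor(scale_outer)
        H = (T @ H @ W).relu()
    return H


def train_gcan(hn: HeterogeneousNetwork, config: GcanConfig) -> TopologicalEmbedding:
    """Fit the attention vector and layer weights with Adam and return the
    final (Zd, Zm) embedding plus the training-loss trace."""
    dtype = np.dtype(config.dtype)
    n = hn.nd + hn.nm
    hn_values = hn.values.astype(dtype)
    A = hn_values[: hn.nd, hn.nd :]
    mask = neighborhood_mask(hn_values)
    scale = (1.0 / np.sqrt(1.0 + bipartite_degrees(A, hn.nd, hn.nm))).astype(dtype)
    scale_outer = np.outer(scale, scale)

    rng = np.random.default_rng(config.seed)
    params_w: list[Tensor] = []
    params_a: list[Tensor] = []
    width = n
    for _ in range(config.n_layers):
        params_w.append(Tensor(_xavier(rng, (width, config.k1), dtype), requires_grad=True))
        params_a.append(Tensor(np.zeros(2 * width, dtype=dtype), requires_grad=True))
        width = config.k1

    hn_t = Tensor(hn_values)
    opt = Adam(params_w + params_a, lr=config.lr1)
    trace: list[float] = []
    for epoch in range(config.epochs):
        Z = _forward_graph(hn_t, params_w, params_a, mask, scale_outer, config.leaky_slope)
        ZZ = (Z @ Z.T).sigmoid()
        loss = ((ZZ - hn_t) ** 2).sum() / n
        value = float(loss.data)
        if not np.isfinite(value):
            raise FloatingPointError(
                f"training loss diverged at epoch {epoch}; try a lower lr1"
            )
        trace.append(value)
        opt.zero_grad()
        loss.backward()
        opt.step()

    Z = _forward_graph(hn_t, params_w, params_a, mask, scale_outer, config.leaky_slope)
    ZZ = (Z @ Z.T).sigmoid()
    trace.append(float(((ZZ.data - hn_values) ** 2).sum() / n))
    Zd = Z.data[: hn.nd].astype(float)
    Zm = Z.data[hn.nd :].astype(float)
    return TopologicalEmbedding(Zd=Zd, Zm=Zm, loss_trace=trace)
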