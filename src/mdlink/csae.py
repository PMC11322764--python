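"""Attribute embeddings from a multi-channel convolutional sparse autoencoder.

Input attribute matrices concatenate, column-wise, the adjacency with
diffusion, cosine and functional similarities:

* disease role:  ``AD = [A | SDMM | SDCOS | SDFS]``  (Nd x (Nm + 3 Nd))
* microbe role:  ``AM = [A^T | SMDD | SMCOS | SMFS]`` (Nm x (Nd + 3 Nm))

The autoencoder is: 3x3 convolution (1 -> l channels, same padding, ReLU)
-> flatten channels along columns -> sigmoid linear bottleneck of width k2
-> sigmoid linear expansion -> partition back into l channels -> 3x3
transposed convolution (l -> 1, ReLU).  The loss is the row-mean squared
reconstruction error plus ``beta`` times a Bernoulli KL penalty pulling
each bottleneck unit's mean activation toward the sparsity target ``rho``.
The trained bottleneck activations are the attribute embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from ._autograd import Adam, Tensor

__all__ = [
    "CsaeConfig",
    "AttributeMatrix",
    "AttributeEmbedding",
    "assemble_attribute_matrix",
    "conv_encode",
    "linear_encode",
    "linear_decode",
    "conv_decode",
    "flatten_channels",
    "partition_channels",
    "sparsity_penalty",
    "csae_loss",
    "train_csae",
]

_CLAMP = 1e-8


@dataclass
class CsaeConfig:
    k2: int = 32
    channels: int = 6
    lr2: float = 0.1
    beta: float = 0.1
    rho: float = 0.05
    epochs: int = 200
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.k2 < 1 or self.channels < 1:
            raise ValueError("k2 and channels must be >= 1")
        if not 0 < self.rho < 1:
            raise ValueError("rho must lie in (0, 1)")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")


@dataclass
class AttributeMatrix:
    values: np.ndarray
    role: str  # "disease" | "microbe"
    block_layout: list[tuple[str, int]]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        total = sum(w for _, w in self.block_layout)
        if self.values.shape[1] != total:
            raise ValueError(
                f"block widths sum to {total} but matrix has {self.values.shape[1]} columns"
            )

    def block(self, name: str) -> np.ndarray:
        start = 0
        for block_name, width in self.block_layout:
            if block_name == name:
                return self.values[:, start : start + width].copy()
            start += width
        raise KeyError(name)


@dataclass
class AttributeEmbedding:
    values: np.ndarray
    role: str
    loss_trace: list[float] = field(default_factory=list, repr=False)


def assemble_attribute_matrix(A, diffusion, cosine, functional, role: str) -> AttributeMatrix:
    """Concatenate [adjacency-profile | diffusion | cosine | functional]."""
    A = np.asarray(A, dtype=float)
    profiles = A if role == "disease" else A.T
    if role not in ("disease", "microbe"):
        raise ValueError(f"role must be 'disease' or 'microbe', got {role!r}")
    n = profiles.shape[0]
    names = (
        ["A", "SDMM", "SDCOS", "SDFS"]
        if role == "disease"
        else ["AT", "SMDD", "SMCOS", "SMFS"]
    )
    blocks = [profiles]
    for name, mat in zip(names[1:], (diffusion, cosine, functional)):
        mat = np.asarray(mat, dtype=float)
        if mat.shape != (n, n):
            raise ValueError(f"block {name} must be {n}x{n}, got {mat.shape}")
        blocks.append(mat)
    layout = [(names[0], profiles.shape[1])] + [(name, n) for name in names[1:]]
    return AttributeMatrix(np.hstack(blocks), role, layout)


# -- reference (numpy) forward operations --------------------------------


def _shift(x: np.ndarray, du: int, dv: int) -> np.ndarray:
    """x translated by (du, dv) with zero fill: out[p, q] = x[p - du, q - dv]."""
    out = np.zeros_like(x)
    nr, nc = x.shape[:2]
    src_r = slice(max(0, -du), min(nr, nr - du))
    src_c = slice(max(0, -dv), min(nc, nc - dv))
    dst_r = slice(max(0, du), min(nr, nr + du))
    dst_c = slice(max(0, dv), min(nc, nc + dv))
    out[dst_r, dst_c] = x[src_r, src_c]
    return out


def conv_encode(AX: np.ndarray, kernels: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """3x3 cross-correlation of the single-channel input with l kernels,
    zero same-padding, ReLU: output (Nr, Nc, l)."""
    AX = np.asarray(AX, dtype=float)
    kernels = np.asarray(kernels, dtype=float)
    if kernels.shape[:2] != (3, 3):
        raise ValueError("kernels must be 3x3xl")
    if AX.ndim != 2 or AX.size == 0:
        raise ValueError("input must be a non-empty 2D matrix")
    nr, nc = AX.shape
    channels = kernels.shape[2]
    out = np.zeros((nr, nc, channels)) + np.asarray(bias, dtype=float)
    for u in range(3):
        for v in range(3):
            # correlation: out[p,q] += AX[p+u-1, q+v-1] * K[u,v]
            out += _shift(AX, 1 - u, 1 - v)[:, :, None] * kernels[u, v]
    return np.maximum(out, 0.0)


def flatten_channels(fX: np.ndarray) -> np.ndarray:
    """(Nr, Nc, l) -> (Nr, Nc*l), channels concatenated along columns."""
    nr, nc, channels = fX.shape
    return fX.transpose(0, 2, 1).reshape(nr, channels * nc)


def partition_channels(y: np.ndarray, channels: int) -> np.ndarray:
    """Inverse of :func:`flatten_channels`: (Nr, Nc*l) -> (Nr, Nc, l)."""
    nr, total = y.shape
    if total % channels:
        raise ValueError(f"{total} columns cannot split into {channels} equal channels")
    nc = total // channels
    return y.reshape(nr, channels, nc).transpose(0, 2, 1)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def linear_encode(fX: np.ndarray, W: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Flatten then sigmoid affine map to the k2-wide bottleneck."""
    return _sigmoid(flatten_channels(np.asarray(fX, dtype=float)) @ W + B)


def linear_decode(h: np.ndarray, W: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Sigmoid affine expansion back to Nc*l columns."""
    return _sigmoid(np.asarray(h, dtype=float) @ W + B)


def conv_decode(y: np.ndarray, channels: int, kernel: np.ndarray, bias: float) -> np.ndarray:
    """Partition y into l channels and collapse them to one plane with a
    3x3 transposed convolution (each input cell scatters a kernel patch
    around itself), zero same-cropping, ReLU."""
    kernel = np.asarray(kernel, dtype=float)
    if kernel.shape != (3, 3, channels):
        raise ValueError(f"kernel must be 3x3x{channels}")
    f = partition_channels(np.asarray(y, dtype=float), channels)
    nr, nc, _ = f.shape
    out = np.full((nr, nc), float(bias))
    for du in (-1, 0, 1):
        for dv in (-1, 0, 1):
            # scatter form: F[i+du, j+dv] += f[i,j,c] * K[1+du, 1+dv, c]
            out += (_shift(f, du, dv) * kernel[1 + du, 1 + dv]).sum(axis=2)
    return np.maximum(out, 0.0)


def sparsity_penalty(h: np.ndarray, rho: float) -> float:
    """Sum over bottleneck units of KL(rho || rho_hat_t) between Bernoulli
    means, where rho_hat_t is unit t's average activation over rows."""
    h = np.asarray(h, dtype=float)
    rho_hat = h.mean(axis=0)
    if ((rho_hat <= 0) | (rho_hat >= 1)).any():
        warnings.warn(
            "bottleneck mean activation hit 0 or 1; clamping for the KL penalty",
            RuntimeWarning,
            stacklevel=2,
        )
        rho_hat = np.clip(rho_hat, _CLAMP, 1 - _CLAMP)
    kl = rho * np.log(rho / rho_hat) + (1 - rho) * np.log((1 - rho) / (1 - rho_hat))
    return float(kl.sum())


def csae_loss(reconstruction: np.ndarray, AX: np.ndarray, h: np.ndarray,
              beta: float, rho: float) -> float:
    """Row-mean squared reconstruction error plus beta * KL sparsity penalty."""
    reconstruction = np.asarray(reconstruction, dtype=float)
    AX = np.asarray(AX, dtype=float)
    if reconstruction.shape != AX.shape:
        raise ValueError("reconstruction and input shapes differ")
    mse = ((reconstruction - AX) ** 2).sum() / AX.shape[0]
    return float(mse + beta * sparsity_penalty(h, rho))


# -- training ------------------------------------------------------------


def _im2col_const(AX: np.ndarray) -> np.ndarray:
    """Constant (Nr*Nc, 9) patch matrix of the zero-padded input, so the
    encoder convolution becomes a single matmul with the (9, l) kernels."""
    nr, nc = AX.shape
    cols = np.empty((nr * nc, 9), dtype=AX.dtype)
    k = 0
    for u in range(3):
        for v in range(3):
            cols[:, k] = _shift(AX, 1 - u, 1 - v).ravel()
            k += 1
    return cols


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape, dtype):
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


def _add_shifted(out: np.ndarray, x: np.ndarray, du: int, dv: int) -> None:
    """out[p, q] += x[p - du, q - dv] restricted to the overlap."""
    nr, nc = x.shape[:2]
    src_r = slice(max(0, -du), min(nr, nr - du))
    src_c = slice(max(0, -dv), min(nc, nc - dv))
    dst_r = slice(max(0, du), min(nr, nr + du))
    dst_c = slice(max(0, dv), min(nc, nc + dv))
    out[dst_r, dst_c] += x[src_r, src_c]


def _deconv(f: Tensor, kernel: Tensor, bias: Tensor, nr: int, nc: int) -> Tensor:
    """Fused autodiff op: 3x3 transposed convolution collapsing l channels
    to one plane (scatter form, zero same-cropping), pre-activation.

    ``f`` holds the channel tensor flattened to (Nr*Nc, l) in row-major
    (p, q) pixel order; the kernel is the matching (9, l) matrix with row
    m = (1 + du) * 3 + (1 + dv).
    """
    fd, Kd = f.data, kernel.data
    channels = fd.shape[1]
    G = fd @ Kd.T  # (Nr*Nc, 9): per-pixel channel contraction per offset
    out_data = np.full((nr, nc), bias.data, dtype=fd.dtype)
    m = 0
    for du in (-1, 0, 1):
        for dv in (-1, 0, 1):
            _add_shifted(out_data, G[:, m].reshape(nr, nc), du, dv)
            m += 1

    out = Tensor(out_data)
    if f.requires_grad or kernel.requires_grad or bias.requires_grad:
        out.requires_grad = True
        out._parents = (f, kernel, bias)

        def backward(g):
            # Sg[:, m] = g shifted by (-du, -dv): the scatter adjoint
            Sg = np.empty((nr * nc, 9), dtype=fd.dtype)
            m = 0
            for du in (-1, 0, 1):
                for dv in (-1, 0, 1):
                    Sg[:, m] = _shift(g, -du, -dv).ravel()
                    m += 1
            if f.requires_grad:
                f._accum(Sg @ Kd)
            if kernel.requires_grad:
                kernel._accum(Sg.T @ fd)
            if bias.requires_grad:
                bias._accum(np.asarray(g.sum(), dtype=Kd.dtype))

        out._backward = backward
    return out


def _forward_graph(patches: Tensor, params: dict, nr: int, nc: int, channels: int):
    """Autodiff forward pass; returns (bottleneck h, reconstruction F).

    Internally the channel axis stays minor (pixel-major layout) to keep
    every array contiguous; the dense bottleneck weights absorb the fixed
    column permutation relative to the reference channel-major flatten,
    so the trained model family is identical.
    """
    fX = (patches @ params["K_enc"] + params["b_enc"]).relu()  # (Nr*Nc, l)
    ft = fX.reshape(nr, nc * channels)
    h = (ft @ params["W_enc"] + params["B_enc"]).sigmoid()
    y = (h @ params["W_dec"] + params["B_dec"]).sigmoid()
    f = y.reshape(nr * nc, channels)
    F = _deconv(f, params["K_dec"], params["b_dec"], nr, nc).relu()
    return h, F


def train_csae(AX: AttributeMatrix, config: CsaeConfig) -> AttributeEmbedding:
    """Fit the autoencoder with Adam and return the bottleneck activations
    of the trained model as the attribute embedding (Nr x k2)."""
    dtype = np.dtype(config.dtype)
    values = AX.values.astype(dtype)
    nr, nc = values.shape
    channels, k2 = config.channels, config.k2

    rng = np.random.default_rng(config.seed)
    params = {
        "K_enc": Tensor(_xavier(rng, 9, 9 * channels, (9, channels), dtype), requires_grad=True),
        "b_enc": Tensor(np.zeros(channels, dtype=dtype), requires_grad=True),
        "W_enc": Tensor(_xavier(rng, channels * nc, k2, (channels * nc, k2), dtype),
                        requires_grad=True),
        "B_enc": Tensor(np.zeros(k2, dtype=dtype), requires_grad=True),
        "W_dec": Tensor(_xavier(rng, k2, channels * nc, (k2, channels * nc), dtype),
                        requires_grad=True),
        "B_dec": Tensor(np.zeros(channels * nc, dtype=dtype), requires_grad=True),
        "K_dec": Tensor(_xavier(rng, 9 * channels, 9, (9, channels), dtype),
                        requires_grad=True),
        "b_dec": Tensor(np.zeros((), dtype=dtype), requires_grad=True),
    }
    patches = Tensor(_im2col_const(values))
    target = Tensor(values)
    rho = config.rho

    opt = Adam(list(params.values()), lr=config.lr2)
    trace: list[float] = []
    for epoch in range(config.epochs):
        h, F = _forward_graph(patches, params, nr, nc, channels)
        mse = ((F - target) ** 2).sum() / nr
        rho_hat = h.mean(axis=0).clip(_CLAMP, 1 - _CLAMP)
        kl = (rho * (rho / rho_hat).log() + (1 - rho) * ((1 - rho) / (1 - rho_hat)).log()).sum()
        loss = mse + config.beta * kl
        value = float(loss.data)
        if not np.isfinite(value):
            raise FloatingPointError(
                f"training loss diverged at epoch {epoch}; try a lower lr2"
            )
        trace.append(value)
        opt.zero_grad()
        loss.backward()
        opt.step()

    h, F = _forward_graph(patches, params, nr, nc, channels)
    mse = float(((F.data - values) ** 2).sum() / nr)
    trace.append(mse + config.beta * sparsity_penalty(np.asarray(h.data, dtype=float), rho))
    return AttributeEmbedding(values=h.data.astype(float), role=AX.role, loss_trace=trace)
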