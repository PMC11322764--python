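"""Final feature assembly and sigmoid inner-product scoring.

Each disease row and microbe row is the column-wise concatenation of its
learned embeddings and its raw similarity/adjacency profiles, interleaved
so that the disease and microbe feature matrices pair block-for-block:

* disease: [Zd | A~D | SDFS | A | SDCOS | A | SDMM | A]
* microbe: [Zm | A~M | A^T | SMFS | A^T | SMCOS | A^T | SMDD]

Both have k1 + k2 + 3 (Nd + Nm) columns, so the score of pair (i, j) is
``sigmoid(FD[i] . FM[j])``.  Because the sigmoid saturates to exactly 1.0
in double precision above ~37, the raw inner products are retained for
ranking and AUC (sigmoid is strictly increasing, so orderings agree).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EigenMatrix",
    "ScoreMatrix",
    "assemble_eigenmatrices",
    "predict_scores",
    "rank_candidates",
]


@dataclass
class EigenMatrix:
    values: np.ndarray
    role: str
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
class ScoreMatrix:
    values: np.ndarray  # sigmoid scores, clipped into the open (0, 1)
    logits: np.ndarray = field(repr=False)  # raw inner products
    disease_names: list[str] = field(default_factory=list)
    microbe_names: list[str] = field(default_factory=list)


def _concat_blocks(named_blocks, n_rows: int, role: str) -> EigenMatrix:
    widths = []
    arrays = []
    for name, arr in named_blocks:
        arr = np.asarray(arr, dtype=float)
        if arr.shape[0] != n_rows:
            raise ValueError(
                f"{role} block {name!r} has {arr.shape[0]} rows, expected {n_rows}"
            )
        widths.append((name, arr.shape[1]))
        arrays.append(arr)
    return EigenMatrix(np.hstack(arrays), role, widths)


def assemble_eigenmatrices(
    Zd, Zm, Ad, Am, SDFS, SMFS, SDCOS, SMCOS, SDMM, SMDD, A,
    ablation: str = "full",
) -> tuple[EigenMatrix, EigenMatrix]:
    """Build the disease and microbe feature matrices, block-aligned.

    ``ablation`` drops matched blocks from both sides: ``gcan_only``
    removes the autoencoder embeddings, ``csae_only`` the topological
    embeddings, and ``cosine_only`` keeps only the cosine + adjacency
    pairing.
    """
    A = np.asarray(A, dtype=float)
    nd, nm = A.shape
    disease_blocks = [
        ("Zd", Zd), ("Ad", Ad),
        ("SDFS", SDFS), ("A1", A),
        ("SDCOS", SDCOS), ("A2", A),
        ("SDMM", SDMM), ("A3", A),
    ]
    microbe_blocks = [
        ("Zm", Zm), ("Am", Am),
        ("AT1", A.T), ("SMFS", SMFS),
        ("AT2", A.T), ("SMCOS", SMCOS),
        ("AT3", A.T), ("SMDD", SMDD),
    ]
    if ablation == "full":
        keep_d = keep_m = None
    elif ablation == "gcan_only":
        keep_d = {"Zd", "SDFS", "A1", "SDCOS", "A2", "SDMM", "A3"}
        keep_m = {"Zm", "AT1", "SMFS", "AT2", "SMCOS", "AT3", "SMDD"}
    elif ablation == "csae_only":
        keep_d = {"Ad", "SDFS", "A1", "SDCOS", "A2", "SDMM", "A3"}
        keep_m = {"Am", "AT1", "SMFS", "AT2", "SMCOS", "AT3", "SMDD"}
    elif ablation == "cosine_only":
        keep_d = {"SDCOS", "A2"}
        keep_m = {"AT2", "SMCOS"}
    else:
        raise ValueError(f"unknown ablation mode {ablation!r}")
    if keep_d is not None:
        disease_blocks = [(n, b) for n, b in disease_blocks if n in keep_d]
        microbe_blocks = [(n, b) for n, b in microbe_blocks if n in keep_m]

    FD = _concat_blocks(disease_blocks, nd, "disease")
    FM = _concat_blocks(microbe_blocks, nm, "microbe")
    if FD.values.shape[1] != FM.values.shape[1]:
        raise ValueError(
            f"feature widths differ: disease {FD.values.shape[1]} vs "
            f"microbe {FM.values.shape[1]}"
        )
    return FD, FM


def predict_scores(
    FD: EigenMatrix, FM: EigenMatrix,
    disease_names=None, microbe_names=None,
) -> ScoreMatrix:
    """Score every pair as sigmoid(FD[i] . FM[j])."""
    if FD.values.shape[1] != FM.values.shape[1]:
        raise ValueError("disease and microbe feature widths differ")
    logits = FD.values @ FM.values.T
    scores = 1.0 / (1.0 + np.exp(-np.clip(logits, -500, 500)))
    tiny = np.nextafter(0.0, 1.0)
    top = np.nextafter(1.0, 0.0)
    np.clip(scores, tiny, top, out=scores)
    nd, nm = logits.shape
    return ScoreMatrix(
        values=scores,
        logits=logits,
        disease_names=list(disease_names) if disease_names is not None
        else [f"disease_{i}" for i in range(nd)],
        microbe_names=list(microbe_names) if microbe_names is not None
        else [f"microbe_{j}" for j in range(nm)],
    )


def rank_candidates(
    S: ScoreMatrix,
    disease: str,
    exclude_known=None,
    top_n: int | None = None,
    rescale: bool = False,
) -> list[tuple[str, float]]:
    """Rank candidate microbes for one disease by descending score.

    Microbes already associated with the disease in ``exclude_known`` are
    dropped (the case-study convention: recover *potential* partners).
    Ordering uses the raw inner products so saturated sigmoids do not tie;
    residual ties break alphabetically by microbe name.  With ``rescale``
    the reported scores are min-max rescaled over the ranked candidates.
    """
    try:
        i = S.disease_names.index(disease)
    except ValueError:
        raise KeyError(f"unknown disease {disease!r}") from None
    known = set()
    if exclude_known is not None:
        values = getattr(exclude_known, "values", exclude_known)
        known = {j for j in range(len(S.microbe_names)) if values[i, j] > 0}
    candidates = [j for j in range(len(S.microbe_names)) if j not in known]
    candidates.sort(key=lambda j: (-S.logits[i, j], S.microbe_names[j]))
    if top_n is not None:
        candidates = candidates[:top_n]
    out_scores = S.values[i, candidates]
    if rescale and len(candidates) > 1:
        row = S.values[i, [j for j in range(len(S.microbe_names)) if j not in known]]
        lo, hi = row.min(), row.max()
        if hi > lo:
            out_scores = (out_scores - lo) / (hi - lo)
    return [(S.microbe_names[j], float(s)) for j, s in zip(candidates, out_scores)]
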