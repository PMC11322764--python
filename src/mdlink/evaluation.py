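"""k-fold cross-validation over association matrix cells, and ROC-AUC.

Known pairs are partitioned into k disjoint folds; the unknown (zero)
cells are partitioned the same way, so each fold tests on 1/k of the
knowns as positives and 1/k of the unknowns as negatives, with the
remaining 80% (for k = 5) of both used for training.  Crucially the test
positives are zeroed in the training adjacency *before* any similarity is
computed, since every similarity derives from A.

AUC is the Mann-Whitney statistic: the probability that a random positive
outscores a random negative, ties counted 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata

from .data_io import AssociationMatrix
from .pipeline import ABLATION_MODES, PipelineConfig, score_associations
from .scoring import ScoreMatrix

__all__ = [
    "CvConfig",
    "CvFold",
    "CvResult",
    "make_cv_splits",
    "compute_auc",
    "run_cross_validation",
]


@dataclass
class CvConfig:
    k: int = 5
    repeats: int = 10
    seed: int = 0
    test_fraction: float | None = None  # informational; folds hold 1/k each

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.repeats < 1:
            raise ValueError("repeats must be at least 1")
        if self.test_fraction is None:
            self.test_fraction = 1.0 / self.k
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")


@dataclass
class CvFold:
    train_values: np.ndarray  # adjacency with this fold's positives zeroed
    test_pos: list[tuple[int, int]]
    test_neg: list[tuple[int, int]]


@dataclass
class CvResult:
    auc_per_run: list[float]
    mean_auc: float
    std_auc: float
    per_fold: list[dict] = field(default_factory=list, repr=False)

    @classmethod
    def from_runs(cls, aucs: list[float], per_fold: list[dict]) -> "CvResult":
        arr = np.asarray(aucs, dtype=float)
        return cls(
            auc_per_run=[float(x) for x in arr],
            mean_auc=float(arr.mean()),
            std_auc=float(arr.std()),
            per_fold=per_fold,
        )


def make_cv_splits(A: AssociationMatrix, config: CvConfig) -> list[CvFold]:
    """Partition known and unknown cells into k folds (seeded).

    Fold f's test positives are its share of the known pairs; its test
    negatives are its share of the zero cells.  The folds partition both
    populations, so no cell is tested twice within one repeat.
    """
    rng = np.random.default_rng(config.seed)
    values = A.values
    pos = np.argwhere(values == 1)
    neg = np.argwhere(values == 0)
    if len(pos) < config.k or len(neg) < config.k:
        raise ValueError(
            f"need at least k={config.k} known and unknown pairs "
            f"(have {len(pos)} and {len(neg)})"
        )
    pos = pos[rng.permutation(len(pos))]
    neg = neg[rng.permutation(len(neg))]
    folds = []
    for pos_part, neg_part in zip(
        np.array_split(pos, config.k), np.array_split(neg, config.k)
    ):
        train = values.copy()
        train[pos_part[:, 0], pos_part[:, 1]] = 0.0
        folds.append(
            CvFold(
                train_values=train,
                test_pos=[tuple(map(int, p)) for p in pos_part],
                test_neg=[tuple(map(int, p)) for p in neg_part],
            )
        )
    return folds


def compute_auc(scores, positives, negatives) -> float:
    """Mann-Whitney ROC-AUC over two pair sets, ties counted 1/2.

    ``scores`` may be a ScoreMatrix (its raw inner products are used, an
    order-preserving transform of the sigmoid scores) or a plain array.
    """
    if isinstance(scores, ScoreMatrix):
        grid = scores.logits
    else:
        grid = np.asarray(scores, dtype=float)
    positives = list(positives)
    negatives = list(negatives)
    if not positives or not negatives:
        raise ValueError("both pair sets must be non-empty")
    if set(positives) & set(negatives):
        raise ValueError("positive and negative pair sets overlap")
    s_pos = np.array([grid[i, j] for i, j in positives])
    s_neg = np.array([grid[i, j] for i, j in negatives])
    ranks = rankdata(np.concatenate([s_pos, s_neg]))
    n_pos, n_neg = len(s_pos), len(s_neg)
    return float((ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def run_cross_validation(
    A: AssociationMatrix,
    pipeline_config: PipelineConfig,
    cv_config: CvConfig,
    ablation: str | None = None,
) -> CvResult:
    """k-fold CV, `repeats` times with fresh seeded partitions each repeat.

    Every fold re-derives all similarities and retrains both embedding
    components from the fold's training adjacency alone.
    """
    ablation = ablation or pipeline_config.ablation
    if ablation not in ABLATION_MODES:
        raise ValueError(f"unknown ablation mode {ablation!r}")
    aucs: list[float] = []
    per_fold: list[dict] = []
    base = np.random.SeedSequence(cv_config.seed)
    for repeat, child in enumerate(base.spawn(cv_config.repeats)):
        split_seed = int(child.generate_state(1)[0] % (2**31))
        folds = make_cv_splits(A, replace(cv_config, seed=split_seed))
        for fold_idx, fold in enumerate(folds):
            train = AssociationMatrix(
                fold.train_values, list(A.disease_names), list(A.microbe_names)
            )
            cfg = replace(
                pipeline_config,
                ablation=ablation,
                seed=int(
                    np.random.SeedSequence(
                        [pipeline_config.seed, repeat, fold_idx]
                    ).generate_state(1)[0]
                    % (2**31)
                ),
            )
            scores = score_associations(train, cfg)
            auc = compute_auc(scores, fold.test_pos, fold.test_neg)
            aucs.append(auc)
            per_fold.append(
                {
                    "repeat": repeat,
                    "fold": fold_idx,
                    "auc": auc,
                    "n_test_pos": len(fold.test_pos),
                    "n_test_neg": len(fold.test_neg),
                }
            )
    return CvResult.from_runs(aucs, per_fold)
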