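"""End-to-end orchestration: adjacency -> similarities -> embeddings -> scores.

Everything downstream is recomputed from whatever adjacency it is given,
so cross-validation can pass a training adjacency with held-out
associations zeroed and no information about them leaks into any
similarity, network, or training loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import csae, gcan, scoring, similarity
from .data_io import AssociationMatrix

__all__ = ["PipelineConfig", "score_associations"]

ABLATION_MODES = ("full", "gcan_only", "csae_only", "cosine_only")


@dataclass
class PipelineConfig:
    """Aggregated settings for one prediction run.

    Sub-component seeds are derived deterministically from ``seed`` so a
    single integer reproduces the whole run.
    """

    gcan: gcan.GcanConfig = field(default_factory=gcan.GcanConfig)
    csae: csae.CsaeConfig = field(default_factory=csae.CsaeConfig)
    rwr: similarity.RwrParams = field(default_factory=similarity.RwrParams)
    seed: int = 0
    ablation: str = "full"
    disease_functional: str | None = None  # optional TSV paths
    microbe_functional: str | None = None

    def __post_init__(self):
        if self.ablation not in ABLATION_MODES:
            raise ValueError(
                f"ablation must be one of {ABLATION_MODES}, got {self.ablation!r}"
            )

    def component_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(3)
        return {
            name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(("gcan", "csae_d", "csae_m"), children)
        }


def score_associations(A: AssociationMatrix, config: PipelineConfig) -> scoring.ScoreMatrix:
    """Run the five pipeline stages on the given adjacency and score all pairs.

    Stages: (1) GIP + Hamming -> integrated similarities and the
    heterogeneous network; (2) attention-GCN topological embeddings;
    (3) RWR / cosine / functional attribute matrices and autoencoder
    embeddings; (4) feature assembly (honouring the ablation mode);
    (5) sigmoid inner-product scores.
    """
    seeds = config.component_seeds()
    need_gcan = config.ablation in ("full", "gcan_only")
    need_csae = config.ablation in ("full", "csae_only")

    SD = similarity.integrate_similarity(
        similarity.gip_similarity(A, "disease"), similarity.hamming_similarity(A, "disease")
    )
    SM = similarity.integrate_similarity(
        similarity.gip_similarity(A, "microbe"), similarity.hamming_similarity(A, "microbe")
    )
    hn = similarity.build_heterogeneous_network(SD, SM, A)

    k1 = config.gcan.k1
    k2 = config.csae.k2
    if need_gcan:
        emb = gcan.train_gcan(hn, replace(config.gcan, seed=seeds["gcan"]))
        Zd, Zm = emb.Zd, emb.Zm
    else:
        Zd = np.zeros((A.nd, k1))
        Zm = np.zeros((A.nm, k1))

    SDCOS = similarity.cosine_similarity(A, "disease")
    SMCOS = similarity.cosine_similarity(A, "microbe")
    SDMM = similarity.rwr_diffusion(SD, config.rwr)
    SMDD = similarity.rwr_diffusion(SM, config.rwr)
    SDFS = similarity.load_functional_similarity(
        config.disease_functional, A.disease_names, "disease"
    )
    SMFS = similarity.load_functional_similarity(
        config.microbe_functional, A.microbe_names, "microbe"
    )

    if need_csae:
        AD = csae.assemble_attribute_matrix(
            A.values, SDMM.values, SDCOS.values, SDFS.values, "disease"
        )
        AM = csae.assemble_attribute_matrix(
            A.values, SMDD.values, SMCOS.values, SMFS.values, "microbe"
        )
        Ad = csae.train_csae(AD, replace(config.csae, seed=seeds["csae_d"])).values
        Am = csae.train_csae(AM, replace(config.csae, seed=seeds["csae_m"])).values
    else:
        Ad = np.zeros((A.nd, k2))
        Am = np.zeros((A.nm, k2))

    FD, FM = scoring.assemble_eigenmatrices(
        Zd, Zm, Ad, Am,
        SDFS.values, SMFS.values,
        SDCOS.values, SMCOS.values,
        SDMM.values, SMDD.values,
        A.values,
        ablation=config.ablation,
    )
    return scoring.predict_scores(FD, FM, A.disease_names, A.microbe_names)
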