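# Methods

## Problem and data model

`mdlink` predicts unobserved disease–microbe associations from a curated
binary bipartite matrix. The input is an edge list of (disease, microbe)
records, de-duplicated case-insensitively after whitespace trimming (curated
databases give no normalization rule for name variants, so the package fixes
and documents its own), and indexed into a dense adjacency `A` with `Nd`
disease rows and `Nm` microbe columns. Every downstream quantity derives from
`A` alone, except the optional externally supplied functional-similarity
matrices.

## Similarities and the heterogeneous network

Two profile kernels are computed per axis:

- **GIP kernel** `G(i,j) = exp(-γ ‖p_i - p_j‖²)` with bandwidth
  `γ = n / Σ_i ‖p_i‖²` over the n profiles of that axis.
- **Hamming similarity** `H(i,j) = 1 - (#differing positions) / L`.
  The normalizer `L` is the *actual* profile length (`Nd` for microbe
  profiles, `Nm` for disease profiles); the alternative convention that
  divides a length-`Nd` profile difference by `Nm` would leave the diagonal
  below 1 and break the [0, 1] range, so the profile-length normalizer is
  used.

The integrated similarities `SD = (GD + HD)/2`, `SM = (GM + HM)/2` and the
adjacency form the heterogeneous network `HN = [[SD, A], [Aᵀ, SM]]`, a single
symmetric graph over `N = Nd + Nm` nodes.

Attribute inputs add two more views per axis: cosine similarity between
profiles (all-zero profiles get off-diagonal similarity 0 and diagonal 1),
and a random-walk-with-restart (RWR) diffusion of the integrated similarity,
iterating `q_i ← φ M q_i + (1-φ) e_i` to convergence (L1 tolerance 1e-6,
max 100 iterations, default φ = 0.1). The walk weight φ multiplies the
transfer matrix `M` and `1-φ` the restart vector — the update is implemented
exactly in this form. `M` is the column-normalized similarity (all-zero
columns become uniform), so each converged proximity row sums to 1; the
closed form `(1-φ)(I - φM)^{-1} e_i` is used as the test oracle. Convergence
rather than a fixed iteration count defines the output.

Functional similarities (gene-family-based for microbes, PPI-derived for
diseases) require external biological databases; the package accepts them as
labeled TSV matrices (re-ordered to dataset label order, clipped to [0, 1],
symmetrized by averaging) and otherwise falls back to the identity matrix —
a neutral choice that preserves all shapes while adding no cross-entity
information.

## Topological embeddings (attention-normalized GCN)

The propagation operator over HN is

```
T = (I + D)^{-1/2} · D_att,r^{-1} A_att · (I + D)^{-1/2}
A_att(i,j) = exp(LeakyReLU([H_i ‖ H_j] · a))   for j ∈ N_i ∪ {i}, else 0
```

where `N_i` is the HN support of node i (any positive similarity or
association creates an edge; self always included), `D_att,r` holds the row
sums of the masked attention (so `D_att,r^{-1} A_att` is row-stochastic on
its support — the normalizer runs over the same `N_i ∪ {i}` support as the
scores), and `D` is diagonal with the *bipartite* degrees: row sums of `A`
for disease nodes, column sums for microbe nodes. Isolated nodes are safe
because of the `+I`. One propagation layer (`H' = ReLU(T H W)`, width
k1 = 128) produces `Z = [Zd; Zm]`; with several layers the attention is
recomputed from the current layer input. LeakyReLU slope is 0.2 (the usual
graph-attention convention). The training loss is the row-mean squared error
between the inner-product reconstruction `sigmoid(Z Zᵀ)` and HN, minimized
by Adam at lr 0.01 for 200 epochs, over the attention vector `a`
(initialized to zero, i.e. uniform attention) and Xavier-uniform `W`.

Numerical note: the training path subtracts a detached per-row maximum
before exponentiating the attention scores. The row-normalized attention is
mathematically invariant to this shift, so the trained operator is unchanged
while overflow is impossible.

## Attribute embeddings (convolutional sparse autoencoder)

Per axis, an attribute matrix concatenates the association profiles with the
diffusion, cosine and functional views:
`AD = [A | SDMM | SDCOS | SDFS]` (Nd × (Nm + 3Nd)) and
`AM = [Aᵀ | SMDD | SMCOS | SMFS]` (Nm × (Nd + 3Nm)).

The autoencoder is: 3×3 convolution, 1 → l = 6 channels, zero same-padding,
ReLU (spatial shape preserved, as required for the elementwise
reconstruction loss) → flatten channels along columns → sigmoid linear
bottleneck of width k2 = 32 → sigmoid linear expansion → partition back into
channels → 3×3 transposed convolution collapsing l channels to one plane,
ReLU. Stride 1 everywhere, no pooling, no weight tying. The sigmoid
bottleneck keeps activations in (0, 1), which the Bernoulli-KL sparsity
penalty requires:

```
L = (1/Nr) Σ_k ‖F(k) - AX(k)‖² + β Σ_t KL(ρ ‖ ρ̂_t)
```

with `ρ̂_t` the mean activation of bottleneck unit t over rows (clamped to
[1e-8, 1-1e-8] with a warning if it saturates), sparsity target ρ = 0.05
(the classical sparse-autoencoder default; exposed as config), β = 0.1, Adam
at lr 0.1, 200 epochs, Xavier-uniform weights, zero biases. The loss
normalizes by the row count of the input (`Nd` for the disease matrix, `Nm`
for the microbe matrix). The trained bottleneck activations are the
attribute embedding (Nr × k2).

Implementation notes:

- Both convolutions are expressed as shift-and-accumulate / im2col matrix
  products; a nested-loop scatter oracle pins their semantics in the tests.
- The training graph keeps the channel axis minor (pixel-major layout) so
  every intermediate array is contiguous. This is a fixed column permutation
  relative to the documented channel-major `flatten`; the dense bottleneck
  weights absorb it, so the trained model family is identical (verified by a
  permutation-equivalence test).
- Gradients come from a small reverse-mode autodiff engine written for this
  package; a central-difference check of the full sparse loss validates it
  to 1e-4 relative error.

## Feature assembly and scoring

The final per-entity feature rows interleave learned and raw views so the
disease and microbe matrices pair block-for-block:

```
FD = [Zd | ÃD | SDFS | A | SDCOS | A | SDMM | A]
FM = [Zm | ÃM | Aᵀ | SMFS | Aᵀ | SMCOS | Aᵀ | SMDD]
```

both of width `k1 + k2 + 3(Nd + Nm)`. Blocks are not re-normalized before
concatenation; scale differences are left to the learned representations.
The score of pair (i, j) is `sigmoid(FD(i) · FM(j))`.

Ablation modes drop matched blocks from both sides: `gcan_only` removes
`ÃD/ÃM`, `csae_only` removes `Zd/Zm`, `cosine_only` keeps only
`[SDCOS | A]` vs `[Aᵀ | SMCOS]`.

Numerical note: inner products above ~37 saturate the double-precision
sigmoid to exactly 1.0, which would create large artificial ties. The score
matrix therefore retains the raw inner products, and ranking/AUC order by
them; since the sigmoid is strictly increasing this is exactly the ordering
of the mathematical (unrounded) scores. Reported sigmoid scores are clipped
into the open interval (0, 1) by one ulp. Candidate ranking excludes the
training-known partners of a disease by default (the case-study convention
of surfacing *potential* associations) and breaks residual ties
alphabetically; an optional flag min–max rescales the reported scores, since
a raw sigmoid cannot reach 1.0 exactly.

## Cross-validation protocol

Known pairs are partitioned into k disjoint folds (k = 2 or 5); the zero
cells are partitioned the same way, so each fold tests its 1/k share of the
knowns as positives against its 1/k share of the unknowns as negatives —
for k = 5, the 20%/80% test/train split of both populations. The protocol is
repeated (default 10×) with fresh seeded partitions, including fresh
negative partitions, each repeat. Test positives are zeroed in the training
adjacency *before any similarity is computed* — every kernel, the network,
both attribute matrices and both training losses derive from the training
adjacency only, so no held-out label can leak. AUC is the Mann–Whitney
statistic (ties ½); a brute-force concordance count and scikit-learn's
implementation serve as test oracles.

## Synthetic data

The generator plants recoverable low-rank structure: non-negative latent
factors `U (nd × rank)`, `V (nm × rank)` with |N(0,1)| entries give scores
`S = U Vᵀ`; exactly `⌈density · nd · nm⌉` top-scoring cells become
associations (ties at the threshold break by row-major position, making the
output byte-deterministic per seed). The default study condition is
nd = 40, nm = 300, rank = 3, density = 0.05 — a desk-scale stand-in with
HMDAD-like shape (tall microbe axis, ~5% density, block-structured
co-occurrence). What it does *not* emulate: name noise and duplicates,
ontology structure, hub-dominated degree distributions beyond what low rank
induces, or any real biology in the functional-similarity channels (the
identity fallback is active). Passing the recovery criterion therefore shows
that the pipeline propagates planted co-association structure to held-out
cells — not that it reproduces database-level benchmark figures.

## Numerical and training choices

- Components train in float32 by default (single-CPU speed); the reference
  forward operators and all oracle comparisons run in float64, and the
  gradient check uses float64. Training is bit-deterministic per seed in
  either precision.
- Component seeds derive from the pipeline seed via `SeedSequence` spawning,
  so one integer reproduces a whole run.
- Adam uses the standard (0.9, 0.999, 1e-8) moments in both components.
- The problem sizes exercised by the tests (40 × 300 fixture, 5-fold CV,
  200 epochs, 3 seeds) keep the full suite at desk scale.

## Known limitations

- At the default lr 0.1 the autoencoder's first Adam step moves every
  weight by ±0.1, which can overshoot the 3×3 decoder into an all-negative
  pre-activation region on wide inputs; the output ReLU then goes dark and
  the reconstruction term stalls (the loss keeps falling only through the
  sparsity term). On the planted fixture this affects the wide microbe-side
  matrix but not the disease side; at lr 0.01 both reconstruct properly.
  Because the embedding blocks are concatenated with the raw similarity
  views, held-out-link recovery is robust to this collapse. The learning
  rate is kept at 0.1 as the selected default and exposed as config.
- The GIP bandwidth is undefined on an all-zero adjacency (error), and GIP/
  Hamming treat each axis's profiles over the *training* adjacency, so very
  sparse folds weaken all similarity channels simultaneously.
- Microbe/disease functional similarity computation from biological
  databases is out of scope; the identity fallback carries no cross-entity
  information, and the corresponding feature blocks are then inert.
- Benchmark-database AUCs (HMDAD/Disbiome) require downloads and curation
  and are not reproduced here; the evaluation is property-based on synthetic
  data.
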