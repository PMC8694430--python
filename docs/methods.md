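# Methods

This note records the model, its assumptions, the defaults, and the design
decisions taken where the architecture left genuine choices open. It is the
companion to the README's overview; nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Model and assumptions

The method is a link predictor for a bipartite miRNA–disease graph,
resting on the standard guilt-by-association premise: miRNAs with similar
sequences (and diseases with nearby ontology terms) tend to share
associations. It assumes the verified association matrix `A` is a partial
observation of a denser true matrix — zeros mean *unverified*, not
*negative* — which is why training uses a positive-weighted reconstruction
loss and evaluation treats all zeros as candidate negatives.

Four similarity matrices feed the model. The Gaussian interaction-profile
(GIP) kernel treats each entity's row (or column) of `A` as a binary
profile and applies a Gaussian kernel whose bandwidth is the raw bandwidth
(default 1) divided by the mean squared profile norm; it therefore encodes
association-pattern similarity and is recomputed from the *training* matrix
in every cross-validation fold by default (see "Leakage" below). Sequence
and semantic similarity are association-independent and computed once.

Each of the two sub-networks (miRNA-based, disease-based) is a binary graph
over all `nm+nd` nodes: one thresholded similarity block plus all
association edges, with the opposite-type block empty. Both share the
feature matrix `X = [[M, A],[Aᵀ, D]]` built from the symmetrically
normalized integrated similarities. A 3-layer GCN encoder with layer
attention and an inner-product decoder reconstructs each sub-network's
adjacency; the two miRNA–disease score blocks are averaged into the final
prediction.

## Parameters

| parameter | default | notes |
|---|---|---|
| raw GIP bandwidth ρ′ | 1 | dimensionless; divided by mean squared profile norm |
| alignment scoring (match/mismatch/gap) | 1 / 0 / 0 | score = longest-common-subsequence length; normalized by match × longer length, so self-similarity is exactly 1 |
| semantic decay | 0.5 | per-edge contribution factor in (0,1) |
| thresholds tm, td | 0.9 | binarization of SM/SD; inclusive (≥) comparison |
| layers / width | 3 / 64 | all hidden layers share the embedding width so layer outputs can be summed |
| learning rate / epochs | 1e-4 / 400 | full-batch Adam |
| dropout γ | 0.3 | inverted dropout after ReLU, training only |
| attention | learned (softmax) | `fixed` mode available, e.g. (0.50, 0.35, 0.15) weighting low-order neighborhoods more to counter over-smoothing |
| positive weight ω | #zeros/#ones of the target adjacency | overridable |

The alignment scoring and normalization, the semantic-similarity recursion,
and the attention mode are all config-exposed because different curated
similarity tables can be injected instead (`read_similarity_matrix`), which
bypasses those choices entirely.

## Numerical choices

* **Loss.** The reconstruction loss is standard positive-weighted binary
  cross-entropy between the target adjacency and the decoder *logits*,
  evaluated via `softplus` for stability; the sigmoid is applied exactly
  once, inside the loss. The loss covers the full `(nm+nd)²` reconstruction;
  only the cross block is used for prediction.
* **Integration zero test.** The "primary similarity nonzero" branch of the
  integration rule is tested with exact equality to zero: zeros in sequence
  or semantic similarity arise structurally (disjoint ancestor sets), not
  from rounding.
* **Thresholding.** Inclusive (`≥`), applied to the raw integrated
  similarities (which are calibrated to `[0,1]`), not to the normalized
  blocks of `X`; the unit diagonal never creates a self-edge — self-loops
  enter only through the encoder's `adj + I`.
* **Initialization and randomness.** Glorot-uniform weights; attention
  logits start at zero (uniform weights). Per-layer random streams for
  initialization and dropout are spawned positionally from the seed, so a
  1-layer model consumes exactly the layer-1 streams of a deeper model;
  with fixed attention `(1,0,0)` a 3-layer run is bitwise identical to the
  1-layer run (asserted in the tests). Zero-weight layers are skipped in the
  attention sum to keep that equivalence exact.
* **Backpropagation.** Gradients for this fixed architecture are derived in
  closed form and implemented directly in numpy (the model is small and
  full-batch, so a framework would add dependencies without capability);
  training is deterministic given the seed on a fixed BLAS.
* **Degenerate inputs.** An all-zero association matrix makes the GIP
  bandwidth undefined and is rejected with an explicit error; a target
  adjacency without positives similarly rejects the default ω. Isolated
  nodes cannot produce zero degrees because of the self-loop.
* **Ties.** AUC uses the midrank (Mann–Whitney) convention; ranked exports
  break score ties by registry order, so output is deterministic.

## Cross-validation and leakage

Folds partition the verified pairs (five-fold sizes differ by at most one;
leave-one-out holds one pair per fold, with a subsampling option for
desk-scale runs). Per fold, held-out positives are zeroed in the training
matrix and *everything* downstream — GIP kernels, integrated similarities,
`X`, both adjacencies — is recomputed from the masked matrix; a structural
audit counts held-out links found in any training adjacency (must be zero,
asserted). Whether published full-scale analyses recomputed GIP per fold is
not determinable; a `naive_gip` flag reproduces the variant that computes
GIP from the full matrix, and the two modes measurably differ (tested).
Pooling is global: each repeat's held-out positives are scored against all
pairs outside that fold's training positives and merged into one ROC;
per-fold AUCs are also reported. Repeated runs average pooled AUCs over
independently seeded partitions.

## The synthetic generator

`make_fixture` plants recoverable block structure: miRNAs and diseases are
assigned round-robin to clusters; each cluster has an ancestral 22-nt RNA
sequence whose members are substitution-mutated copies (rate 0.15); each
cluster's diseases sit under a shared ontology subtree (depth 3, branching
2); associations are Bernoulli with probability 0.5 within matching
clusters and 0.02 otherwise. Defaults (60×40, 4 clusters) give density
≈ 0.5/4 + 0.02·3/4 ≈ 0.14 and let full training plus five-fold
cross-validation finish in seconds on one CPU core; the same generator
scales to benchmark size for stress runs.

What it does *not* emulate: real HMDD degree distributions (heavy-tailed,
hub-dominated), name-matching noise across sources, indel variation between
sequences, or ontology terms with multiple parents across clusters. Passing
recovery tests on the fixture therefore demonstrates mechanical correctness
and end-to-end signal recovery, not benchmark-level performance.

**Information ceiling.** Because fixture links are independent Bernoulli
draws given the cluster pair, ranking by true cluster co-membership is
Bayes-optimal; `scripts/acceptance.py` computes this ceiling
(`cluster_oracle_ceiling_auc`, ≈ 0.87–0.88 at default settings) alongside
the model's cross-validated AUC. Held-out within-cluster positives are
statistically exchangeable with within-cluster negatives at within-cluster
probability 0.5, which caps *any* method's pooled AUC near that value; the
autoencoder ensemble lands within about 0.01 of the ceiling. The naive
baseline reported next to it averages *centered* similarities
(`(SM1−mean) A (SD1−mean)`): short RNA sequences share a large alignment
floor even between clusters, and centering removes that floor so the
average reflects co-membership.

## Known limitations

* Full leave-one-out at benchmark scale trains two models per verified
  pair and is expensive by construction; use the subsample mode or
  five-fold repeats for routine work.
* Sequence similarity is quadratic in the number of miRNAs with an
  alignment per pair; fine to a few thousand sequences.
* The inner-product decoder scores all node pairs, including intra-type
  pairs that are never evaluated; memory is `O((nm+nd)²)`.
* Curated full-scale similarity matrices are not distributed; published
  benchmark AUCs (≈ 0.94/0.95) are reference points, not asserted results.
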