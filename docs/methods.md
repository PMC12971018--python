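# Methods

## Model

`metapathdr` predicts drug–disease associations in a heterogeneous
biomedical network with four node types (drugs `Dr`, diseases `Di`, proteins
`P`, biological functions `F`) and five relation types (drug–protein,
disease–protein, protein–protein, protein–function, function–function).
Protein–protein and function–function edges are undirected; the other three
relations are stored with a fixed orientation and transposed on demand.
Node identifiers are opaque strings scoped per type; an identifier reused
across two types is rejected at load time so that matrix indices stay
unambiguous.  All row/column orderings are frozen lexicographically at load,
which makes every downstream matrix, embedding and fold reproducible.

### Meta-path filtered networks

A meta-path is a chain of node types joined by relation types.  The filtered
network for meta-path `P` is the product of the oriented typed adjacencies,
`A_P = Π A_{R_i}`.  Two semantics points are deliberate:

- **Walks, not simple paths.**  The matrix product counts node sequences
  that may revisit a node at different positions (e.g. the same protein at
  both `P` slots of `Dr-P-P-Di` is *not* counted, because self-edges are
  dropped, but `p1` at positions 2 and 4 of `Dr-P-F-P-Di` is).  The
  brute-force enumeration oracle (`count_paths`) implements exactly these
  walk semantics, and the test suite checks product/oracle agreement entry
  by entry on random networks.
- **Exact arithmetic.**  With unit edge weights the factors are cast to
  int64 after an a-priori overflow bound check (product of per-factor max
  entries times inner dimensions must stay below 2^62); weighted inputs fall
  back to float64.

Base edges default to weight 1 (path *counts*); a third TSV column is
honoured, turning counts into weighted path sums.  Duplicate edges are
deduplicated with a warning (summing is available as an option) so that
`A_P` remains a distinct-instance count.

The curated default meta-path set is `Dr-P-Di`, `Dr-P-P-Di`, `Dr-P-F-P-Di`
and `Dr-P-F-F-P-Di`.  The maximum parsed length is configurable and defaults
to 6 node positions, which is what the longest curated path requires;
shorter caps can be set by users who want to exclude long chains.

### Walks and embeddings

Each filtered network is a weighted bipartite drug–disease graph.  Forward
transition probabilities are the row normalization of `A_P`; the reverse
(disease → drug) direction uses the row-normalized transpose — the only
construction consistent with reading `A_P` as an undirected weighted
bipartite graph.  Zero-degree nodes are flagged unwalkable and emit no
walks.  From every walkable drug and disease node, `N` walks of length `L`
(node positions) are drawn; all walks are pooled into one corpus per
meta-path.

Embeddings come from a skip-gram with negative sampling trained on the walk
corpus, written in-package (single-threaded numba kernel, word2vec-style:
linear learning-rate decay from 0.025, per-token uniformly shrunk window,
±6 logit clipping, unigram^0.75 sampling tables).  The *heterogeneous*
variant draws negatives for a context node only from that node's type
(metapath2vec++-style); a single shared table gives the vanilla skip-gram
for ablation.  Randomness comes from an explicit xorshift64* generator, so a
fixed seed yields bit-identical vectors.  By default the input vectors are
exported; `combine="sum"` exports input+output sums instead.

Defaults: `N = 100`, `L = 40`, dimension 16, window 2, 5 negatives, 15
epochs, `min_count = 1`.  These are sized for desk-scale networks (a few
hundred embedded nodes), where wide embeddings (e.g. 128 dimensions) are
heavily over-parameterized and measurably degrade the downstream classifier;
for networks with thousands of drugs and diseases users should raise the
dimension and can lower the epoch count.  All of these are exposed in
`PipelineConfig`.

### Prediction and integration

A pair is represented by concatenating the drug embedding with the disease
embedding (drug half first, feature length `2d`).  A node missing from the
table yields a zero half-vector by default (logged); a strict mode raises
instead.  For each known positive `(d, i)`, two negatives are sampled: one
drug corruption `(d', i)` and one disease corruption `(d, i')`, rejection
resampled until the pair is neither a known positive nor already drawn —
giving an exact 2:1 negative:positive ratio with corruption sides balanced.

One gradient-boosted-tree classifier (XGBoost, logistic objective, `hist`
tree method, single thread) is trained per meta-path; defaults are 300
trees, depth 6, learning rate 0.1, all seeded and recorded in the model
state.  Per-path probabilities are integrated with the MAX rule (MEAN and
MIN are supported alternatives; learned integrators are intentionally out of
scope behind the same interface), and labels use the fixed threshold 0.5
with ties classified positive — a convention fixed for reproducibility.

### Evaluation protocol

Cross-validation splits drug–disease *pairs*.  Negatives are drawn once per
run (a global drawn-set prevents duplicate pairs anywhere) and shared across
all meta-path models so the MAX integration compares like with like — but
each negative is assigned to the fold of the positive it corrupts
("anchored" folds).  This anchoring matters: if a held-out positive's own
corruptions are left in the training folds, the model is explicitly taught
that exactly that drug and that disease are unassociated, and held-out AUROC
drops systematically *below* chance.  Anchored assignment keeps the 2:1
class ratio exact per fold (±1) and removes that reverse leakage.  A generic
stratified k-fold splitter is also provided.

Embeddings are trained once per run, not per fold: the filtered networks
are built exclusively from the five mechanism relations, never from
drug–disease label edges, so they cannot leak held-out labels.  AUROC uses
the rank (Mann–Whitney) formulation with ties averaged; AUPR uses step-wise
interpolation over distinct thresholds (no linear interpolation).  Both are
cross-checked in the test suite against independent brute-force oracles
(all-pairs comparison; exhaustive threshold sweep) to 1e-9.  Fold metrics
are aggregated as the unweighted mean over folds (pooling is the noted
alternative); confusion counts are summed.  A shuffled-label null control
permutes the labels over the fixed fold structure and should sit at AUROC
0.5.

### Seed discipline

One master seed drives everything.  Component seeds are derived as the
first four bytes of `SHA-256("{master}:{stage}")` mod 2^31, where the stage
name encodes the meta-path and fold where relevant (`walks:Dr-P-Di`,
`xgb:Dr-P-Di:3`, ...).  Two runs with the same master seed are byte-identical
end to end (walk corpora, prediction TSVs, metric reports); each stage is
independently re-runnable.

## Synthetic data generator

The generator emulates the *structure* of a multiscale drug–disease
interactome: four node types, five relations, and positive drug–disease
pairs that are reachable through shared proteins and shared biological
functions.  Background edges are Erdős–Rényi per relation (a
preferential-attachment option mimics hub bias and is off by default).  For
each planted positive `(d, i)`, `m` proteins are attached to both `d` and
`i` (guaranteeing at least `m` instances of `Dr-P-Di`), and, with the
function bridge on, a function is wired to one of `d`'s and one of `i`'s
planted proteins (guaranteeing a `Dr-P-F-P-Di` instance).  A configurable
fraction of extra random drug–protein/disease–protein noise edges is added.

The default desk-scale study is 150 drugs, 80 diseases, 800 proteins, 300
functions, 400 planted positives, `m = 2`, bridge on, 10% noise edges.
Background densities (0.006, 0.02, 0.01, 0.005, 0.01 for the five relations
respectively) were chosen once to reproduce realistic mean degrees at this
scale — roughly 5 targets per drug, 16 proteins per disease, protein–protein
degree 8, 1.5 functions per protein, function–function degree 3 — so the
whole pipeline runs in minutes on one CPU.

What the generator does **not** emulate: hub-skewed degree distributions
(unless `degree_skewed` is enabled), community/module structure among
disease proteins (each pair's mechanism proteins are drawn independently, so
distinct positives share proteins only by chance), identifier vocabularies,
and edge weights.  Consequently, passing tests demonstrate correctness of
the machinery and genuine planted-signal recovery above a clean null — they
do not certify performance levels on real interactome data, where entity
degree distributions and mechanism sharing differ substantially.

## Known limitations

- **Concatenated pair features under-use the embedding at small scale.**
  The planted signal lives largely in the *relation* between the two halves
  of the feature vector (planted pairs are close in embedding space), and
  axis-aligned tree splits cannot form inner products.  At the desk scale of
  the default study the cross-validated ensemble AUROC is therefore markedly
  above the shuffled-label null (which sits at chance) but well below what a
  direct similarity readout of the same embeddings would give — run
  `scripts/acceptance.py` and `examples/03_cross_validation.py` for the
  computed numbers.  With many more entities and positives (and hub
  structure), trees have far more data per entity; this limitation is
  specific to small networks.
- MAX integration is only as good as its weakest informative path: paths
  whose filtered networks are background-dominated contribute near-chance
  scores whose upper tail can mask the informative path's ranking.
- Walk semantics count repeated-node walks, which slightly inflates counts
  on dense protein neighbourhoods relative to simple-path counting.
- No probability calibration, no hyperparameter search harness, no cold-start
  (unseen drug/disease) splits — the splitter interface admits them but they
  are not implemented.
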