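"""Edge-weight-guided random walks and heterogeneous skip-gram embeddings.

Each meta-path's filtered network A_P is a weighted bipartite drug-disease
graph.  Transition probabilities are its row normalization,

    P(v_j | v_i) = A_P(i, j) / sum_k A_P(i, k),

and the reverse (disease -> drug) direction uses the row-normalized
transpose, the construction consistent with reading A_P as an undirected
weighted bipartite graph.  From every walkable drug and disease node we
start N walks of length L (L node positions), sampling each step from the
current node's transition row; the pooled walks form the corpus for a
skip-gram model with type-aware negative sampling, yielding one embedding
table per meta-path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from . import _sgns
from .hetnet import NODE_TYPES, NodeRef
from .metapath import FilteredNetwork

logger = logging.getLogger(__name__)


class EmbeddingError(Exception):
    pass


@dataclass
class TransitionModel:
    """Row-stochastic transition matrices for both walk directions."""

    drug_to_disease: sp.csr_matrix
    disease_to_drug: sp.csr_matrix
    drug_index: list[str]
    disease_index: list[str]
    unwalkable_drugs: list[str]
    unwalkable_diseases: list[str]
    metapath_label: str
    source_type: str = "Dr"
    target_type: str = "Di"


@dataclass
class WalkConfig:
    """N walks of length L (node positions) per walkable start node."""

    walks_per_start: int = 20
    walk_length: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.walks_per_start < 1:
            raise ValueError("walks_per_start must be >= 1")
        if self.walk_length < 2:
            raise ValueError("walk_length must be >= 2")


@dataclass
class WalkCorpus:
    walks: list[list[NodeRef]]
    metapath_label: str

    def save(self, path: str | Path) -> Path:
        """One walk per line; tokens are type-prefixed node ids."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with path.open("w") as fh:
            for walk in self.walks:
                fh.write(" ".join(ref.token() for ref in walk) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path, metapath_label: str = "") -> "WalkCorpus":
        walks = []
        with Path(path).open() as fh:
            for line in fh:
                toks = line.split()
                if toks:
                    walks.append([NodeRef.from_token(t) for t in toks])
        return cls(walks, metapath_label)


@dataclass
class EmbeddingTable:
    dimension: int
    vectors: dict[NodeRef, np.ndarray]
    metapath_label: str = ""

    def __contains__(self, ref: NodeRef) -> bool:
        return ref in self.vectors

    def __getitem__(self, ref: NodeRef) -> np.ndarray:
        return self.vectors[ref]

    def save(self, path: str | Path) -> Path:
        """word2vec text format: header ``count dim``, then token + floats."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with path.open("w") as fh:
            fh.write(f"{len(self.vectors)} {self.dimension}\n")
            for ref in sorted(self.vectors):
                vec = " ".join(f"{x:.8g}" for x in self.vectors[ref])
                fh.write(f"{ref.token()} {vec}\n")
        return path

    @classmethod
    def load(cls, path: str | Path, metapath_label: str = "") -> "EmbeddingTable":
        with Path(path).open() as fh:
            header = fh.readline().split()
            count, dim = int(header[0]), int(header[1])
            vectors: dict[NodeRef, np.ndarray] = {}
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                ref = NodeRef.from_token(parts[0])
                vectors[ref] = np.asarray(parts[1:], dtype=np.float32)
                if vectors[ref].shape[0] != dim:
                    raise EmbeddingError(f"bad vector length for {parts[0]}")
        if len(vectors) != count:
            raise EmbeddingError("embedding file header count mismatch")
        return cls(dim, vectors, metapath_label)


def _row_normalize(matrix: sp.csr_matrix) -> tuple[sp.csr_matrix, np.ndarray]:
    matrix = sp.csr_matrix(matrix, dtype=np.float64)
    sums = np.asarray(matrix.sum(axis=1)).ravel()
    walkable = sums > 0
    inv = np.zeros_like(sums)
    inv[walkable] = 1.0 / sums[walkable]
    normalized = sp.diags(inv) @ matrix
    return sp.csr_matrix(normalized), walkable


def transition_probs(filtered: FilteredNetwork) -> TransitionModel:
    """Row-normalize A_P and its transpose; zero-degree nodes are flagged."""
    fwd, drug_ok = _row_normalize(filtered.matrix)
    bwd, dis_ok = _row_normalize(filtered.matrix.T)
    return TransitionModel(
        drug_to_disease=fwd,
        disease_to_drug=bwd,
        drug_index=filtered.drug_index,
        disease_index=filtered.disease_index,
        unwalkable_drugs=[d for d, ok in zip(filtered.drug_index, drug_ok) if not ok],
        unwalkable_diseases=[d for d, ok in zip(filtered.disease_index, dis_ok) if not ok],
        metapath_label=filtered.metapath.label,
        source_type=filtered.metapath.node_types[0],
        target_type=filtered.metapath.node_types[-1],
    )


def _row_samplers(matrix: sp.csr_matrix) -> list[tuple[np.ndarray, np.ndarray] | None]:
    """Per-row (neighbor columns, cumulative probabilities) or None if empty."""
    samplers: list[tuple[np.ndarray, np.ndarray] | None] = []
    indptr, indices, data = matrix.indptr, matrix.indices, matrix.data
    for i in range(matrix.shape[0]):
        lo, hi = indptr[i], indptr[i + 1]
        if lo == hi:
            samplers.append(None)
            continue
        probs = data[lo:hi]
        samplers.append((indices[lo:hi].copy(), np.cumsum(probs)))
    return samplers


def generate_walks(model: TransitionModel, config: WalkConfig) -> WalkCorpus:
    """N seeded walks from every walkable drug and disease node.

    Node types alternate along each walk (the filtered network is bipartite);
    a walk that reaches a zero-degree node stops early.  A fixed seed yields
    a bit-identical corpus.
    """
    rng = np.random.default_rng(config.seed)
    fwd = _row_samplers(model.drug_to_disease)
    bwd = _row_samplers(model.disease_to_drug)
    src_refs = [NodeRef(model.source_type, n) for n in model.drug_index]
    dst_refs = [NodeRef(model.target_type, n) for n in model.disease_index]
    unwalkable = set(model.unwalkable_drugs)
    starts: list[tuple[int, int]] = [  # (side, row): side 0 = source type
        (0, i) for i, n in enumerate(model.drug_index) if n not in unwalkable
    ]
    unwalkable_d = set(model.unwalkable_diseases)
    starts += [
        (1, i) for i, n in enumerate(model.disease_index) if n not in unwalkable_d
    ]
    if not starts:
        raise EmbeddingError(
            f"no walkable start nodes for meta-path {model.metapath_label!r}"
        )
    n_skipped = len(unwalkable) + len(unwalkable_d)
    if n_skipped:
        logger.info(
            "meta-path %s: %d isolated start nodes emit no walks",
            model.metapath_label,
            n_skipped,
        )
    refs = (src_refs, dst_refs)
    samplers = (fwd, bwd)
    walks: list[list[NodeRef]] = []
    n_steps = config.walk_length - 1
    for side0, row0 in starts:
        # one uniform per potential step, drawn up front for speed
        randoms = rng.random((config.walks_per_start, n_steps))
        for w in range(config.walks_per_start):
            side, row = side0, row0
            walk = [refs[side][row]]
            for s in range(n_steps):
                sampler = samplers[side][row]
                if sampler is None:  # guarded; unreachable after first step
                    break
                cols, cum = sampler
                idx = int(np.searchsorted(cum, randoms[w, s] * cum[-1], side="right"))
                if idx >= cols.shape[0]:
                    idx = cols.shape[0] - 1
                row = int(cols[idx])
                side = 1 - side
                walk.append(refs[side][row])
            walks.append(walk)
    return WalkCorpus(walks, model.metapath_label)


_TYPE_ID = {t: i for i, t in enumerate(NODE_TYPES)}


def train_skipgram(
    corpus: WalkCorpus,
    dimension: int = 128,
    window: int = 5,
    epochs: int = 5,
    negative_samples: int = 5,
    min_count: int = 1,
    seed: int = 0,
    alpha: float = 0.025,
    heterogeneous: bool = True,
    combine: str = "input",
) -> EmbeddingTable:
    """Train skip-gram with negative sampling on a walk corpus.

    With ``heterogeneous=True`` (default), negatives for a context node are
    drawn only from nodes of the same type, the metapath2vec++-style
    heterogeneous skip-gram; ``heterogeneous=False`` uses one global unigram
    table (vanilla skip-gram, for ablation).  ``combine`` selects the
    exported vector: ``"input"`` (default) exports the input vectors, the
    word2vec convention; ``"sum"`` adds the input and output (context)
    vectors so first-order co-occurrence also contributes to dot products.
    Single-threaded and fully deterministic for a fixed seed.
    """
    if combine not in ("sum", "input"):
        raise EmbeddingError(f"unknown combine mode {combine!r}")
    if dimension < 1:
        raise EmbeddingError("dimension must be >= 1")
    if not corpus.walks:
        raise EmbeddingError("empty walk corpus")

    counts: dict[NodeRef, int] = {}
    for walk in corpus.walks:
        for ref in walk:
            counts[ref] = counts.get(ref, 0) + 1
    vocab = sorted(ref for ref, c in counts.items() if c >= min_count)
    if not vocab:
        raise EmbeddingError(f"no node occurs >= min_count={min_count} times")
    index = {ref: i for i, ref in enumerate(vocab)}
    vocab_counts = np.asarray([counts[r] for r in vocab], dtype=np.int64)
    if heterogeneous:
        types = np.asarray([_TYPE_ID[r.node_type] for r in vocab], dtype=np.int8)
        n_types = len(NODE_TYPES)
    else:
        types = np.zeros(len(vocab), dtype=np.int8)
        n_types = 1

    flat: list[int] = []
    offsets = [0]
    for walk in corpus.walks:
        kept = [index[r] for r in walk if r in index]
        if len(kept) >= 2:
            flat.extend(kept)
            offsets.append(len(flat))
    if len(offsets) == 1:
        raise EmbeddingError("corpus has no walk with >= 2 in-vocabulary nodes")

    tokens = np.asarray(flat, dtype=np.int32)
    offsets_arr = np.asarray(offsets, dtype=np.int64)
    neg_table, table_offsets = _sgns.build_negative_tables(
        vocab_counts, types, n_types
    )
    syn0, syn1 = _sgns.init_vectors(len(vocab), dimension, seed)
    _sgns.train_sgns(
        tokens,
        offsets_arr,
        types,
        neg_table,
        table_offsets,
        syn0,
        syn1,
        window,
        epochs,
        negative_samples,
        alpha,
        seed,
    )
    vectors = syn0 + syn1 if combine == "sum" else syn0
    if not np.isfinite(vectors).all():
        raise EmbeddingError("non-finite values in trained vectors")
    return EmbeddingTable(
        dimension,
        {ref: vectors[i].copy() for ref, i in index.items()},
        corpus.metapath_label,
    )
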