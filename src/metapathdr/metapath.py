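"""Meta-paths and meta-path-filtered drug-disease networks.

A meta-path P is an ordered chain of node types joined by relation types,
e.g. ``Dr-P-F-P-Di`` (drug targets a protein that participates in a
biological function that involves another protein associated with a
disease).  The filtered network for P is the drug x disease matrix

    A_P = A_{R_1} @ A_{R_2} @ ... @ A_{R_{k-1}}

where each factor is the typed adjacency of the corresponding relation,
oriented (transposed where necessary) so inner dimensions match.  With unit
edge weights, ``A_P(i, j)`` counts the distinct meta-path instances -- i.e.
WALKS, not simple paths: a node may recur at different positions, exactly as
the matrix product implies.

``count_paths`` is an independent brute-force oracle (typed depth-first
enumeration) used to cross-check the product on small networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .hetnet import (
    RELATIONS,
    HeteroNetwork,
    HetnetError,
    NodeRef,
    RelationType,
)

#: Curated default meta-path set (drug action mechanisms at increasing scale:
#: shared target, target interaction cascade, shared function, function
#: hierarchy bridge).
CURATED_METAPATHS = (
    "Dr-P-Di",
    "Dr-P-P-Di",
    "Dr-P-F-P-Di",
    "Dr-P-F-F-P-Di",
)

_TYPE_TOKENS = {"Dr", "Di", "P", "F"}

# (source_type, target_type) -> (relation, reversed)
_SIGNATURES: dict[tuple[str, str], tuple[RelationType, bool]] = {}
for _rel in RELATIONS.values():
    _SIGNATURES[(_rel.source_type, _rel.target_type)] = (_rel, False)
    if not _rel.symmetric:
        _SIGNATURES[(_rel.target_type, _rel.source_type)] = (_rel, True)


class MetaPathError(HetnetError):
    pass


@dataclass(frozen=True)
class MetaPath:
    """A validated type chain with its resolved, oriented relations."""

    node_types: tuple[str, ...]
    relations: tuple[tuple[RelationType, bool], ...]  # (relation, reversed?)
    label: str

    def __len__(self) -> int:  # number of node positions
        return len(self.node_types)


@dataclass
class FilteredNetwork:
    """Weighted source x target network induced by one meta-path."""

    metapath: MetaPath
    drug_index: list[str]  # nodes of the meta-path's first type
    disease_index: list[str]  # nodes of the meta-path's last type
    matrix: sp.csr_matrix


def parse_metapath(spec: str, max_length: int = 6) -> MetaPath:
    """Parse a dash-separated type chain such as ``"Dr-P-F-P-Di"``.

    Tokens are case-sensitive; each consecutive type pair must be connected
    by one of the five canonical relations.  ``max_length`` caps the number
    of node positions (default 6, admitting Dr-P-F-F-P-Di).
    """
    tokens = tuple(spec.strip().split("-"))
    if len(tokens) < 2:
        raise MetaPathError(f"meta-path {spec!r} needs at least two node types")
    for tok in tokens:
        if tok not in _TYPE_TOKENS:
            raise MetaPathError(f"unknown node type token {tok!r} in {spec!r}")
    if len(tokens) > max_length:
        raise MetaPathError(
            f"meta-path {spec!r} has {len(tokens)} nodes, exceeding the cap {max_length}"
        )
    relations: list[tuple[RelationType, bool]] = []
    for a, b in zip(tokens, tokens[1:]):
        sig = _SIGNATURES.get((a, b))
        if sig is None:
            raise MetaPathError(f"no relation connects {a}-{b} in {spec!r}")
        relations.append(sig)
    return MetaPath(tokens, tuple(relations), "-".join(tokens))


def _oriented_adjacency(network: HeteroNetwork, rel: RelationType, reverse: bool) -> sp.csr_matrix:
    adj = network.adjacency(rel)
    return adj.matrix.T.tocsr() if reverse else adj.matrix


def build_filtered_network(network: HeteroNetwork, metapath: MetaPath) -> FilteredNetwork:
    """Compute A_P as the left-to-right product of oriented typed adjacencies.

    Unit-weight (integral) inputs are multiplied in int64 with an a-priori
    overflow bound check; weighted inputs fall back to float64.
    """
    src_nodes = network.nodes(metapath.node_types[0])
    dst_nodes = network.nodes(metapath.node_types[-1])
    if not src_nodes or not dst_nodes:
        raise MetaPathError(
            f"empty {metapath.node_types[0]} or {metapath.node_types[-1]} node set"
        )
    factors = [
        _oriented_adjacency(network, rel, rev) for rel, rev in metapath.relations
    ]
    integral = all(
        f.nnz == 0 or np.allclose(f.data, np.round(f.data)) for f in factors
    )
    if integral:
        # bound on any product entry: prod(max_entry_i) * prod(inner dims)
        bound = 1
        for f in factors[:-1]:
            fmax = int(f.data.max()) if f.nnz else 0
            bound *= max(fmax, 1) * f.shape[1]
        last = factors[-1]
        bound *= int(last.data.max()) if last.nnz else 1
        if bound < 2**62:
            factors = [f.astype(np.int64) for f in factors]
    product = factors[0]
    for f in factors[1:]:
        product = product @ f
    product = sp.csr_matrix(product)
    product.sum_duplicates()
    product.eliminate_zeros()
    return FilteredNetwork(metapath, src_nodes, dst_nodes, product)


def count_paths(
    network: HeteroNetwork,
    metapath: MetaPath,
    drug: NodeRef,
    disease: NodeRef,
) -> float:
    """Brute-force oracle: enumerate typed walks from ``drug`` to ``disease``.

    Counts node sequences whose types match the meta-path and whose
    consecutive pairs are edges of the required relation; node revisits are
    permitted (walk semantics, matching the matrix product).  With unit
    weights the result is the exact instance count; with weights it is the
    sum of per-walk weight products.
    """
    for ref, expected in ((drug, metapath.node_types[0]), (disease, metapath.node_types[-1])):
        if ref.node_type != expected or not network.has_node(ref):
            raise MetaPathError(f"node {ref} unknown or of wrong type for {metapath.label}")

    # oriented neighbor maps per step: node_id -> list[(next_id, weight)]
    step_neighbors: list[dict[str, list[tuple[str, float]]]] = []
    for rel, rev in metapath.relations:
        nbrs: dict[str, list[tuple[str, float]]] = {}
        for (s, t), w in network.edges(rel).items():
            pairs = [(s, t)] if not rel.symmetric else [(s, t), (t, s)]
            if rev:
                pairs = [(b, a) for a, b in pairs]
            for a, b in pairs:
                nbrs.setdefault(a, []).append((b, w))
        step_neighbors.append(nbrs)

    target = disease.node_id
    k = len(metapath.relations)

    def walk(node_id: str, step: int, acc: float) -> float:
        if step == k:
            return acc if node_id == target else 0.0
        total = 0.0
        for nxt, w in step_neighbors[step].get(node_id, ()):
            total += walk(nxt, step + 1, acc * w)
        return total

    return walk(drug.node_id, 0, 1.0)


def write_filtered_network(filtered: FilteredNetwork, path) -> None:
    """Export A_P as a weighted drug-disease edge TSV."""
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    coo = filtered.matrix.tocoo()
    order = np.lexsort((coo.col, coo.row))
    with path.open("w") as fh:
        fh.write(f"# meta-path: {filtered.metapath.label}\n")
        fh.write("# drug_id\tdisease_id\tweight\n")
        for idx in order:
            fh.write(
                f"{filtered.drug_index[coo.row[idx]]}\t"
                f"{filtered.disease_index[coo.col[idx]]}\t{coo.data[idx]:g}\n"
            )
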