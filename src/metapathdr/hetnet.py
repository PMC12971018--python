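"""Typed heterogeneous-network data model and edge-list I/O.

The network G = (V, E, T_V, T_E) has four node types -- drugs (``Dr``),
diseases (``Di``), proteins (``P``) and biological functions (``F``) -- and
five relation types: drug-protein, disease-protein, protein-protein,
protein-function and function-function.  Protein-protein and
function-function edges are undirected (symmetric); the other three are
stored with a fixed source/target orientation but answered in both
directions by downstream meta-path machinery.

Node identifiers are opaque strings scoped per node type.  An identifier
reused across two types is rejected at load time because meta-path matrix
indices must be unambiguous.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

NODE_TYPES = ("Dr", "Di", "P", "F")


class HetnetError(Exception):
    """Base class for network construction errors."""


class ConfigurationError(HetnetError):
    pass


class SchemaError(HetnetError):
    pass


class ParseError(HetnetError):
    pass


@dataclass(frozen=True, order=True)
class NodeRef:
    """A typed node reference; (node_type, node_id) is globally unique."""

    node_type: str
    node_id: str

    def token(self) -> str:
        """Type-prefixed token used in walk corpora and embedding files."""
        return f"{self.node_type}::{self.node_id}"

    @classmethod
    def from_token(cls, token: str) -> "NodeRef":
        node_type, _, node_id = token.partition("::")
        if node_type not in NODE_TYPES or not node_id:
            raise ValueError(f"malformed node token: {token!r}")
        return cls(node_type, node_id)


@dataclass(frozen=True)
class RelationType:
    name: str
    source_type: str
    target_type: str
    symmetric: bool


#: The five canonical relation types and their signatures.
RELATIONS: dict[str, RelationType] = {
    "drug-protein": RelationType("drug-protein", "Dr", "P", False),
    "disease-protein": RelationType("disease-protein", "Di", "P", False),
    "protein-protein": RelationType("protein-protein", "P", "P", True),
    "protein-function": RelationType("protein-function", "P", "F", False),
    "function-function": RelationType("function-function", "F", "F", True),
}


def _canonical_relation(name: str) -> RelationType:
    key = name.replace("–", "-").replace("_", "-").lower()
    if key not in RELATIONS:
        raise ConfigurationError(
            f"unknown relation name {name!r}; expected one of {sorted(RELATIONS)}"
        )
    return RELATIONS[key]


@dataclass
class TypedAdjacency:
    """Sparse adjacency of one relation over frozen lexicographic orderings."""

    relation: RelationType
    row_index: list[str]
    col_index: list[str]
    matrix: sp.csr_matrix


@dataclass
class ValidationReport:
    node_counts: dict[str, int]
    edge_counts: dict[str, int]
    isolated_counts: dict[str, int]
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


class HeteroNetwork:
    """Typed graph with per-type node sets and per-relation weighted edges.

    Edges are stored as ``{relation name: {(source_id, target_id): weight}}``.
    Symmetric relations store one canonical orientation (lexicographically
    smaller id first) and are expanded to both orientations on demand.
    """

    def __init__(self) -> None:
        self._nodes: dict[str, set[str]] = {t: set() for t in NODE_TYPES}
        self._edges: dict[str, dict[tuple[str, str], float]] = {
            name: {} for name in RELATIONS
        }
        self._id_owner: dict[str, str] = {}  # node_id -> node_type
        self._order_cache: dict[str, list[str]] = {}

    # ------------------------------------------------------------------ nodes
    def add_node(self, node_type: str, node_id: str) -> None:
        if node_type not in NODE_TYPES:
            raise SchemaError(f"unknown node type {node_type!r}")
        owner = self._id_owner.get(node_id)
        if owner is not None and owner != node_type:
            raise SchemaError(
                f"node id {node_id!r} appears under two types ({owner!r} and {node_type!r})"
            )
        if node_id not in self._nodes[node_type]:
            self._nodes[node_type].add(node_id)
            self._id_owner[node_id] = node_type
            self._order_cache.pop(node_type, None)

    def nodes(self, node_type: str) -> list[str]:
        """Node ids of one type in frozen lexicographic order."""
        if node_type not in self._order_cache:
            self._order_cache[node_type] = sorted(self._nodes[node_type])
        return self._order_cache[node_type]

    def node_refs(self, node_type: str) -> list[NodeRef]:
        return [NodeRef(node_type, nid) for nid in self.nodes(node_type)]

    def has_node(self, ref: NodeRef) -> bool:
        return ref.node_id in self._nodes.get(ref.node_type, ())

    # ------------------------------------------------------------------ edges
    def add_edge(
        self,
        relation: str | RelationType,
        source_id: str,
        target_id: str,
        weight: float = 1.0,
        duplicate: str = "dedup",
    ) -> bool:
        """Add one edge; returns False if dropped (self-edge or duplicate).

        ``duplicate`` is either ``"dedup"`` (keep the first weight, warn) or
        ``"sum"`` (accumulate weights).
        """
        rel = relation if isinstance(relation, RelationType) else _canonical_relation(relation)
        if weight < 0:
            raise SchemaError(f"negative edge weight {weight} on {rel.name}")
        if source_id == target_id:
            warnings.warn(f"self-edge {source_id!r} on {rel.name} dropped", stacklevel=2)
            return False
        self.add_node(rel.source_type, source_id)
        self.add_node(rel.target_type, target_id)
        key = (source_id, target_id)
        if rel.symmetric and target_id < source_id:
            key = (target_id, source_id)
        store = self._edges[rel.name]
        if key in store:
            if duplicate == "sum":
                store[key] += weight
            else:
                warnings.warn(
                    f"duplicate edge {key} on {rel.name} deduplicated", stacklevel=2
                )
            return False
        store[key] = float(weight)
        return True

    def edges(self, relation: str | RelationType) -> dict[tuple[str, str], float]:
        rel = relation if isinstance(relation, RelationType) else _canonical_relation(relation)
        return dict(self._edges[rel.name])

    def n_edges(self, relation: str | None = None) -> int:
        if relation is None:
            return sum(len(e) for e in self._edges.values())
        rel = relation if isinstance(relation, RelationType) else _canonical_relation(relation)
        return len(self._edges[rel.name])

    # -------------------------------------------------------------- adjacency
    def adjacency(self, relation: str | RelationType) -> TypedAdjacency:
        """Typed adjacency with deterministic lexicographic row/col orderings.

        For symmetric relations one shared ordering is used and the matrix
        satisfies ``M == M.T`` exactly.
        """
        rel = relation if isinstance(relation, RelationType) else _canonical_relation(relation)
        if rel.name not in self._edges:
            raise ConfigurationError(f"relation {rel.name!r} not registered")
        rows = self.nodes(rel.source_type)
        cols = self.nodes(rel.target_type)
        row_pos = {nid: i for i, nid in enumerate(rows)}
        col_pos = {nid: j for j, nid in enumerate(cols)}
        store = self._edges[rel.name]
        r: list[int] = []
        c: list[int] = []
        w: list[float] = []
        for (s, t), weight in store.items():
            r.append(row_pos[s])
            c.append(col_pos[t])
            w.append(weight)
            if rel.symmetric:
                r.append(row_pos[t])
                c.append(col_pos[s])
                w.append(weight)
        mat = sp.csr_matrix(
            (np.asarray(w, dtype=np.float64), (r, c)), shape=(len(rows), len(cols))
        )
        return TypedAdjacency(rel, rows, cols, mat)

    # ------------------------------------------------------------- validation
    def validate(self) -> ValidationReport:
        """Invariant audit: per-type/per-relation counts plus violations.

        Never mutates the network; violations are reported, not raised.
        """
        violations: list[str] = []
        node_counts = {t: len(self._nodes[t]) for t in NODE_TYPES}
        edge_counts = {name: len(store) for name, store in self._edges.items()}
        touched: dict[str, set[str]] = {t: set() for t in NODE_TYPES}
        for name, store in self._edges.items():
            rel = RELATIONS[name]
            for (s, t) in store:
                if s == t:
                    violations.append(f"self-edge ({s},{t}) on {name}")
                s_type = self._id_owner.get(s)
                t_type = self._id_owner.get(t)
                forward = (s_type, t_type) == (rel.source_type, rel.target_type)
                backward = rel.symmetric and (t_type, s_type) == (
                    rel.source_type,
                    rel.target_type,
                )
                if not (forward or backward):
                    violations.append(
                        f"signature violation on {name}: ({s}:{s_type})-({t}:{t_type})"
                    )
                for nid, ntype in ((s, s_type), (t, t_type)):
                    if ntype is not None:
                        touched[ntype].add(nid)
        isolated = {
            t: len(self._nodes[t] - touched[t]) for t in NODE_TYPES
        }
        return ValidationReport(node_counts, edge_counts, isolated, violations)


# ---------------------------------------------------------------------- I/O
def load_hetnet(
    edge_files: Mapping[str, str | Path],
    duplicate: str = "dedup",
) -> HeteroNetwork:
    """Load a heterogeneous network from one TSV edge list per relation.

    Each file is tab-separated with columns ``source_id  target_id  [weight]``;
    lines starting with ``#`` and blank lines are ignored.  Duplicate edges
    are deduplicated (default) or weight-summed per ``duplicate``.
    """
    net = HeteroNetwork()
    for name, path in edge_files.items():
        rel = _canonical_relation(name)  # raises ConfigurationError early
        path = Path(path)
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2 or not parts[0] or not parts[1]:
                    raise ParseError(f"{path}:{lineno}: malformed line {line!r}")
                weight = 1.0
                if len(parts) >= 3 and parts[2]:
                    try:
                        weight = float(parts[2])
                    except ValueError as exc:
                        raise ParseError(
                            f"{path}:{lineno}: bad weight {parts[2]!r}"
                        ) from exc
                net.add_edge(rel, parts[0], parts[1], weight, duplicate=duplicate)
    return net


def write_hetnet(network: HeteroNetwork, out_dir: str | Path) -> dict[str, Path]:
    """Write one canonical TSV per relation; returns relation -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in RELATIONS:
        path = out_dir / f"{name}.tsv"
        with path.open("w") as fh:
            fh.write("# source_id\ttarget_id\tweight\n")
            for (s, t), w in sorted(network.edges(name).items()):
                fh.write(f"{s}\t{t}\t{w:g}\n")
        written[name] = path
    return written


def load_pairs(path: str | Path) -> list[tuple[NodeRef, NodeRef]]:
    """Load drug-disease pairs from a two-column TSV (drug_id, disease_id)."""
    pairs: list[tuple[NodeRef, NodeRef]] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: malformed pair line {line!r}")
            pairs.append((NodeRef("Dr", parts[0]), NodeRef("Di", parts[1])))
    return pairs


def write_pairs(pairs: Iterable[tuple[NodeRef, NodeRef]], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("# drug_id\tdisease_id\n")
        for d, i in pairs:
            fh.write(f"{d.node_id}\t{i.node_id}\n")
    return path
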