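"""Generator of desk-scale heterogeneous networks with planted mechanisms.

Emulates the structure of a multiscale drug-disease interactome: four node
types (drugs, diseases, proteins, biological functions), five relation
types, and a set of known drug-disease associations that are reachable
through shared target proteins and, optionally, through a shared biological
function.  Background edges follow an Erdos-Renyi model per relation (a
preferential-attachment option mimics hub bias); each planted positive pair
(d, i) gets m proteins attached to both d and i -- guaranteeing Dr-P-Di
instances -- and, with the function bridge on, a function wired to one of
d's and one of i's planted proteins -- guaranteeing Dr-P-F-P-Di instances.

Default sizes and densities are chosen so that mean degrees mirror the
reference interactome at desk scale (drugs ~5 protein targets, diseases ~16
associated proteins, protein-protein degree ~8, proteins ~1.5 functions,
function-function degree ~3) while the full pipeline runs in minutes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .hetnet import RELATIONS, HeteroNetwork, NodeRef

DEFAULT_DENSITIES: dict[str, float] = {
    "drug-protein": 0.006,
    "disease-protein": 0.02,
    "protein-protein": 0.01,
    "protein-function": 0.005,
    "function-function": 0.01,
}


class SyntheticError(Exception):
    pass


@dataclass
class SyntheticConfig:
    n_drugs: int = 150
    n_diseases: int = 80
    n_proteins: int = 800
    n_functions: int = 300
    densities: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DENSITIES))
    n_positive_pairs: int = 400
    planted_shared_proteins: int = 2  # m
    planted_function_bridge: bool = True
    noise_edge_fraction: float = 0.1
    degree_skewed: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("n_drugs", self.n_drugs),
            ("n_diseases", self.n_diseases),
            ("n_proteins", self.n_proteins),
            ("n_functions", self.n_functions),
            ("n_positive_pairs", self.n_positive_pairs),
            ("planted_shared_proteins", self.planted_shared_proteins),
        ):
            if value < 1:
                raise SyntheticError(f"{name} must be positive, got {value}")
        for rel, p in self.densities.items():
            if rel not in RELATIONS:
                raise SyntheticError(f"unknown relation {rel!r} in densities")
            if not 0 < p <= 1:
                raise SyntheticError(f"density for {rel} must be in (0, 1], got {p}")
        if self.n_positive_pairs > self.n_drugs * self.n_diseases:
            raise SyntheticError("more positive pairs than drug-disease combinations")
        if self.planted_shared_proteins > self.n_proteins:
            raise SyntheticError("m exceeds the number of proteins")
        if not 0 <= self.noise_edge_fraction < 1:
            raise SyntheticError("noise_edge_fraction must be in [0, 1)")


def _node_names(prefix: str, n: int) -> list[str]:
    width = max(len(str(n - 1)), 1)
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def _er_bipartite(rng, n_a: int, n_b: int, p: float) -> list[tuple[int, int]]:
    mask = rng.random((n_a, n_b)) < p
    rows, cols = np.nonzero(mask)
    return list(zip(rows.tolist(), cols.tolist()))


def _er_symmetric(rng, n: int, p: float) -> list[tuple[int, int]]:
    mask = rng.random((n, n)) < p
    rows, cols = np.nonzero(np.triu(mask, k=1))
    return list(zip(rows.tolist(), cols.tolist()))


def _pa_bipartite(rng, n_a: int, n_b: int, n_edges: int) -> list[tuple[int, int]]:
    """Preferential attachment on the target side (hub-biased background)."""
    deg = np.ones(n_b, dtype=np.float64)
    edges: set[tuple[int, int]] = set()
    while len(edges) < min(n_edges, n_a * n_b):
        a = int(rng.integers(n_a))
        b = int(rng.choice(n_b, p=deg / deg.sum()))
        if (a, b) not in edges:
            edges.add((a, b))
            deg[b] += 1
    return sorted(edges)


def _pa_symmetric(rng, n: int, n_edges: int) -> list[tuple[int, int]]:
    deg = np.ones(n, dtype=np.float64)
    edges: set[tuple[int, int]] = set()
    cap = n * (n - 1) // 2
    while len(edges) < min(n_edges, cap):
        a = int(rng.integers(n))
        b = int(rng.choice(n, p=deg / deg.sum()))
        if a == b:
            continue
        key = (min(a, b), max(a, b))
        if key not in edges:
            edges.add(key)
            deg[a] += 1
            deg[b] += 1
    return sorted(edges)


def generate_hetnet(
    config: SyntheticConfig,
) -> tuple[HeteroNetwork, list[tuple[NodeRef, NodeRef]]]:
    """Build a synthetic network and its planted positive pair list.

    Fully deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    drugs = _node_names("drug", config.n_drugs)
    diseases = _node_names("dis", config.n_diseases)
    proteins = _node_names("prot", config.n_proteins)
    functions = _node_names("func", config.n_functions)

    net = HeteroNetwork()
    for t, names in (("Dr", drugs), ("Di", diseases), ("P", proteins), ("F", functions)):
        for name in names:
            net.add_node(t, name)

    shapes = {
        "drug-protein": (drugs, proteins),
        "disease-protein": (diseases, proteins),
        "protein-protein": (proteins, proteins),
        "protein-function": (proteins, functions),
        "function-function": (functions, functions),
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicates between background/planted
        for rel in (
            "drug-protein",
            "disease-protein",
            "protein-protein",
            "protein-function",
            "function-function",
        ):
            src, dst = shapes[rel]
            p = config.densities[rel]
            symmetric = RELATIONS[rel].symmetric
            if config.degree_skewed:
                if symmetric:
                    n_edges = int(round(p * len(src) * (len(src) - 1) / 2))
                    idx = _pa_symmetric(rng, len(src), n_edges)
                else:
                    n_edges = int(round(p * len(src) * len(dst)))
                    idx = _pa_bipartite(rng, len(src), len(dst), n_edges)
            elif symmetric:
                idx = _er_symmetric(rng, len(src), p)
            else:
                idx = _er_bipartite(rng, len(src), len(dst), p)
            for a, b in idx:
                net.add_edge(rel, src[a], dst[b])

        # planted positives: m shared proteins per pair (+ function bridge)
        flat = rng.choice(
            config.n_drugs * config.n_diseases, config.n_positive_pairs, replace=False
        )
        m = config.planted_shared_proteins
        positives: list[tuple[NodeRef, NodeRef]] = []
        for code in flat:
            d_idx, i_idx = divmod(int(code), config.n_diseases)
            d, i = drugs[d_idx], diseases[i_idx]
            shared = rng.choice(config.n_proteins, m, replace=False)
            for p_idx in shared:
                net.add_edge("drug-protein", d, proteins[p_idx])
                net.add_edge("disease-protein", i, proteins[p_idx])
            if config.planted_function_bridge:
                f_idx = int(rng.integers(config.n_functions))
                if m >= 2:
                    p_d, p_i = rng.choice(shared, 2, replace=False)
                else:
                    p_d = p_i = shared[0]
                net.add_edge("protein-function", proteins[int(p_d)], functions[f_idx])
                net.add_edge("protein-function", proteins[int(p_i)], functions[f_idx])
            positives.append((NodeRef("Dr", d), NodeRef("Di", i)))

        # extra random drug/disease-protein noise edges
        if config.noise_edge_fraction > 0:
            for rel, (src, dst) in (
                ("drug-protein", (drugs, proteins)),
                ("disease-protein", (diseases, proteins)),
            ):
                extra = int(config.noise_edge_fraction * net.n_edges(rel))
                for _ in range(extra):
                    net.add_edge(
                        rel,
                        src[int(rng.integers(len(src)))],
                        dst[int(rng.integers(len(dst)))],
                    )
    return net, positives


def generate_scores_fixture(
    n: int, seed: int = 0, prior: float = 0.35
) -> tuple[np.ndarray, np.ndarray]:
    """Reproducible random label/score vectors for metric-oracle tests."""
    if n < 2:
        raise SyntheticError(f"n must be >= 2, got {n}")
    rng = np.random.default_rng(seed)
    labels = (rng.random(n) < prior).astype(np.int64)
    scores = rng.random(n)
    return labels, scores
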