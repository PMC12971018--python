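import numpy as np
import pytest

from metapathdr import HeteroNetwork, NodeRef, SyntheticConfig, generate_hetnet


@pytest.fixture
def toy_network() -> HeteroNetwork:
    """d1 reaches i1 through two shared proteins; d2 is isolated from i1."""
    net = HeteroNetwork()
    net.add_edge("drug-protein", "d1", "p1")
    net.add_edge("drug-protein", "d1", "p2")
    net.add_edge("disease-protein", "i1", "p1")
    net.add_edge("disease-protein", "i1", "p2")
    net.add_edge("drug-protein", "d2", "p3")
    net.add_edge("disease-protein", "i2", "p3")
    return net


@pytest.fixture
def small_synthetic():
    config = SyntheticConfig(
        n_drugs=30,
        n_diseases=20,
        n_proteins=120,
        n_functions=50,
        n_positive_pairs=50,
        seed=42,
    )
    network, positives = generate_hetnet(config)
    return config, network, positives


def random_hetnet(rng: np.random.Generator, max_nodes: int = 60) -> HeteroNetwork:
    """Small random typed network used by the oracle-equivalence tests."""
    n_dr = int(rng.integers(3, 9))
    n_di = int(rng.integers(3, 8))
    n_p = int(rng.integers(6, 25))
    n_f = int(rng.integers(4, 12))
    assert n_dr + n_di + n_p + n_f <= max_nodes
    net = HeteroNetwork()
    names = {
        "Dr": [f"d{i}" for i in range(n_dr)],
        "Di": [f"i{i}" for i in range(n_di)],
        "P": [f"p{i}" for i in range(n_p)],
        "F": [f"f{i}" for i in range(n_f)],
    }
    for t, ids in names.items():
        for nid in ids:
            net.add_node(t, nid)
    dens = {
        "drug-protein": 0.25,
        "disease-protein": 0.25,
        "protein-protein": 0.12,
        "protein-function": 0.15,
        "function-function": 0.12,
    }
    shapes = {
        "drug-protein": ("Dr", "P"),
        "disease-protein": ("Di", "P"),
        "protein-protein": ("P", "P"),
        "protein-function": ("P", "F"),
        "function-function": ("F", "F"),
    }
    for rel, (st, tt) in shapes.items():
        src, dst = names[st], names[tt]
        for a in range(len(src)):
            for b in range(len(dst)):
                if st == tt and b <= a:
                    continue
                if rng.random() < dens[rel]:
                    net.add_edge(rel, src[a], dst[b])
    return net


@pytest.fixture
def pair_universe():
    drugs = [NodeRef("Dr", f"d{i}") for i in range(12)]
    diseases = [NodeRef("Di", f"i{i}") for i in range(9)]
    positives = [(drugs[i], diseases[i % 9]) for i in range(10)]
    return drugs, diseases, positives
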