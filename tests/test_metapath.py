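import numpy as np
import pytest

from metapathdr import (
    CURATED_METAPATHS,
    HeteroNetwork,
    NodeRef,
    build_filtered_network,
    count_paths,
    parse_metapath,
)
from metapathdr.metapath import MetaPathError

from conftest import random_hetnet


class TestParsing:
    def test_shared_target_path_resolves_relations(self):
        mp = parse_metapath("Dr-P-Di")
        assert mp.node_types == ("Dr", "P", "Di")
        names = [(rel.name, rev) for rel, rev in mp.relations]
        assert names == [("drug-protein", False), ("disease-protein", True)]

    def test_longest_curated_path_parses(self):
        mp = parse_metapath("Dr-P-F-F-P-Di")
        assert len(mp.node_types) == 6 and len(mp.relations) == 5

    @pytest.mark.parametrize(
        "spec,match",
        [
            ("Dr-X-Di", "unknown node type"),
            ("Dr-F-Di", "no relation connects"),
            ("Dr-P-F-F-F-P-Di", "exceeding the cap"),
            ("Dr", "at least two"),
        ],
    )
    def test_invalid_specs_rejected(self, spec, match):
        with pytest.raises(MetaPathError, match=match):
            parse_metapath(spec)

    def test_length_cap_is_configurable(self):
        mp = parse_metapath("Dr-P-F-F-F-P-Di", max_length=7)
        assert len(mp.node_types) == 7


class TestFilteredNetwork:
    def test_two_shared_proteins_give_count_two(self, toy_network):
        mp = parse_metapath("Dr-P-Di")
        filtered = build_filtered_network(toy_network, mp)
        r = filtered.drug_index.index("d1")
        c = filtered.disease_index.index("i1")
        assert filtered.matrix[r, c] == 2
        assert count_paths(
            toy_network, mp, NodeRef("Dr", "d1"), NodeRef("Di", "i1")
        ) == 2

    def test_missing_link_relation_gives_all_zero(self, toy_network):
        filtered = build_filtered_network(toy_network, parse_metapath("Dr-P-F-P-Di"))
        assert filtered.matrix.nnz == 0

    def test_unit_weights_give_integer_matrix(self, toy_network):
        filtered = build_filtered_network(toy_network, parse_metapath("Dr-P-Di"))
        assert filtered.matrix.dtype == np.int64

    def test_disconnected_pair_counts_zero(self, toy_network):
        mp = parse_metapath("Dr-P-Di")
        assert count_paths(toy_network, mp, NodeRef("Dr", "d2"), NodeRef("Di", "i1")) == 0

    def test_unknown_node_rejected(self, toy_network):
        mp = parse_metapath("Dr-P-Di")
        with pytest.raises(MetaPathError):
            count_paths(toy_network, mp, NodeRef("Dr", "ghost"), NodeRef("Di", "i1"))

    def test_empty_drug_set_is_an_error(self):
        net = HeteroNetwork()
        net.add_edge("disease-protein", "i1", "p1")
        with pytest.raises(MetaPathError, match="empty"):
            build_filtered_network(net, parse_metapath("Dr-P-Di"))

    def test_protein_triangle_walk_semantics(self):
        # p-p edges form a triangle: matrix product counts walks that may
        # revisit proteins; the oracle must agree
        net = HeteroNetwork()
        net.add_edge("drug-protein", "d1", "p1")
        for a, b in (("p1", "p2"), ("p2", "p3"), ("p1", "p3")):
            net.add_edge("protein-protein", a, b)
        for p in ("p1", "p2", "p3"):
            net.add_edge("disease-protein", "i1", p)
        mp = parse_metapath("Dr-P-P-Di")
        filtered = build_filtered_network(net, mp)
        product = filtered.matrix[0, 0]
        assert product == count_paths(net, mp, NodeRef("Dr", "d1"), NodeRef("Di", "i1"))
        assert product == 2  # d1-p1-p2-i1 and d1-p1-p3-i1


class TestProductProperties:
    def test_oracle_equivalence_on_random_networks(self):
        rng = np.random.default_rng(2024)
        for _ in range(8):
            net = random_hetnet(rng)
            for spec in CURATED_METAPATHS:
                mp = parse_metapath(spec)
                filtered = build_filtered_network(net, mp)
                dense = filtered.matrix.toarray()
                for r, d in enumerate(filtered.drug_index):
                    for c, i in enumerate(filtered.disease_index):
                        expected = count_paths(
                            net, mp, NodeRef("Dr", d), NodeRef("Di", i)
                        )
                        assert dense[r, c] == expected

    def test_product_associativity(self):
        rng = np.random.default_rng(7)
        net = random_hetnet(rng)
        mp = parse_metapath("Dr-P-F-P-Di")
        factors = [
            net.adjacency(rel).matrix.T if rev else net.adjacency(rel).matrix
            for rel, rev in mp.relations
        ]
        left = factors[0]
        for f in factors[1:]:
            left = left @ f
        right = factors[-1]
        for f in reversed(factors[:-1]):
            right = f @ right
        assert (left != right).nnz == 0

    def test_adding_edge_never_decreases_entries(self):
        rng = np.random.default_rng(11)
        net = random_hetnet(rng)
        mp = parse_metapath("Dr-P-Di")
        before = build_filtered_network(net, mp).matrix.toarray()
        d = net.nodes("Dr")[0]
        p_new = next(
            p for p in net.nodes("P") if (d, p) not in net.edges("drug-protein")
        )
        net.add_edge("drug-protein", d, p_new)
        after = build_filtered_network(net, mp).matrix.toarray()
        assert (after >= before).all()

    def test_single_relation_path_returns_adjacency(self, toy_network):
        mp = parse_metapath("Dr-P")
        filtered = build_filtered_network(toy_network, mp)
        adj = toy_network.adjacency("drug-protein")
        assert (filtered.matrix != adj.matrix.astype(np.int64)).nnz == 0

    def test_weighted_edges_use_weight_products(self):
        net = HeteroNetwork()
        net.add_edge("drug-protein", "d1", "p1", weight=2.0)
        net.add_edge("disease-protein", "i1", "p1", weight=0.5)
        mp = parse_metapath("Dr-P-Di")
        filtered = build_filtered_network(net, mp)
        assert filtered.matrix[0, 0] == pytest.approx(1.0)
        assert count_paths(
            net, mp, NodeRef("Dr", "d1"), NodeRef("Di", "i1")
        ) == pytest.approx(1.0)
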