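import numpy as np
import pytest

from metapathdr import (
    HeteroNetwork,
    NodeRef,
    WalkConfig,
    WalkCorpus,
    build_filtered_network,
    generate_walks,
    parse_metapath,
    train_skipgram,
    transition_probs,
)
from metapathdr.embedding import EmbeddingError, EmbeddingTable

from conftest import random_hetnet


def _filtered(net):
    return build_filtered_network(net, parse_metapath("Dr-P-Di"))


def _star_network():
    """d1 -> i1 with A_P weight 3, d1 -> i2 with weight 1."""
    net = HeteroNetwork()
    for p in ("p1", "p2", "p3"):
        net.add_edge("drug-protein", "d1", p)
        net.add_edge("disease-protein", "i1", p)
    net.add_edge("drug-protein", "d1", "p4")
    net.add_edge("disease-protein", "i2", "p4")
    return net


class TestTransitionModel:
    def test_row_normalization_arithmetic(self):
        model = transition_probs(_filtered(_star_network()))
        row = model.drug_to_disease[0].toarray().ravel()
        assert row == pytest.approx([0.75, 0.25])

    def test_zero_degree_node_flagged(self, toy_network):
        toy_network.add_node("Dr", "d_alone")
        model = transition_probs(_filtered(toy_network))
        assert "d_alone" in model.unwalkable_drugs
        r = model.drug_index.index("d_alone")
        assert model.drug_to_disease[r].nnz == 0

    def test_nonzero_rows_sum_to_one_on_random_networks(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            model = transition_probs(_filtered(random_hetnet(rng)))
            for mat in (model.drug_to_disease, model.disease_to_drug):
                sums = np.asarray(mat.sum(axis=1)).ravel()
                nonzero = sums[sums > 0]
                assert np.abs(nonzero - 1.0).max() < 1e-12


class TestWalks:
    def test_single_edge_walks_alternate(self):
        net = HeteroNetwork()
        net.add_edge("drug-protein", "d1", "p1")
        net.add_edge("disease-protein", "i1", "p1")
        corpus = generate_walks(
            transition_probs(_filtered(net)), WalkConfig(2, 4, seed=0)
        )
        assert len(corpus.walks) == 4  # 2 starts x 2 walks
        for walk in corpus.walks:
            ids = [r.node_id for r in walk]
            assert ids in (["d1", "i1", "d1", "i1"], ["i1", "d1", "i1", "d1"])

    def test_every_transition_has_positive_probability(self, toy_network):
        model = transition_probs(_filtered(toy_network))
        corpus = generate_walks(model, WalkConfig(5, 8, seed=1))
        mats = {0: model.drug_to_disease, 1: model.disease_to_drug}
        d_pos = {n: k for k, n in enumerate(model.drug_index)}
        i_pos = {n: k for k, n in enumerate(model.disease_index)}
        for walk in corpus.walks:
            for a, b in zip(walk, walk[1:]):
                assert {a.node_type, b.node_type} == {"Dr", "Di"}
                if a.node_type == "Dr":
                    assert mats[0][d_pos[a.node_id], i_pos[b.node_id]] > 0
                else:
                    assert mats[1][i_pos[a.node_id], d_pos[b.node_id]] > 0

    def test_isolated_start_emits_no_walks(self, toy_network):
        toy_network.add_node("Dr", "d_alone")
        corpus = generate_walks(
            transition_probs(_filtered(toy_network)), WalkConfig(3, 5, seed=0)
        )
        assert all(w[0].node_id != "d_alone" for w in corpus.walks)

    def test_no_walkable_starts_is_an_error(self):
        net = HeteroNetwork()
        net.add_edge("drug-protein", "d1", "p1")
        net.add_edge("disease-protein", "i1", "p2")
        with pytest.raises(EmbeddingError, match="walkable"):
            generate_walks(transition_probs(_filtered(net)), WalkConfig(1, 3, seed=0))

    def test_first_step_frequencies_match_probabilities(self):
        model = transition_probs(_filtered(_star_network()))
        corpus = generate_walks(model, WalkConfig(10_000, 2, seed=3))
        first = [w[1].node_id for w in corpus.walks if w[0].node_id == "d1"]
        freq = first.count("i1") / len(first)
        assert freq == pytest.approx(0.75, abs=0.02)

    def test_seed_determinism_and_corpus_round_trip(self, toy_network, tmp_path):
        model = transition_probs(_filtered(toy_network))
        c1 = generate_walks(model, WalkConfig(4, 6, seed=9))
        c2 = generate_walks(model, WalkConfig(4, 6, seed=9))
        assert c1.walks == c2.walks
        path = c1.save(tmp_path / "walks.txt")
        assert WalkCorpus.load(path).walks == c1.walks

    def test_invalid_walk_config_rejected(self):
        with pytest.raises(ValueError):
            WalkConfig(0, 5)
        with pytest.raises(ValueError):
            WalkConfig(1, 1)


def _cooccurrence_corpus(seed: int) -> WalkCorpus:
    """dA and dB share context diseases {i0..i3}; dC sees {i4..i7} only."""
    rng = np.random.default_rng(seed)
    shared = [NodeRef("Di", f"i{k}") for k in range(4)]
    other = [NodeRef("Di", f"i{k}") for k in range(4, 8)]
    walks = []
    for drug, ctx in (("dA", shared), ("dB", shared), ("dC", other)):
        for _ in range(120):
            walk = []
            for _ in range(5):
                walk.append(NodeRef("Dr", drug))
                walk.append(ctx[int(rng.integers(len(ctx)))])
            walks.append(walk)
    return WalkCorpus(walks, "toy")


class TestSkipGram:
    def test_vector_dimension_honored(self, toy_network):
        corpus = generate_walks(
            transition_probs(_filtered(toy_network)), WalkConfig(10, 10, seed=0)
        )
        table = train_skipgram(corpus, dimension=64, epochs=2, seed=0)
        assert table.dimension == 64
        assert all(v.shape == (64,) for v in table.vectors.values())

    def test_min_count_excludes_rare_nodes(self):
        a, b, c = NodeRef("Dr", "a"), NodeRef("Di", "b"), NodeRef("Dr", "rare")
        corpus = WalkCorpus([[a, b, a, b], [a, b, a, b], [c, b]], "toy")
        table = train_skipgram(corpus, dimension=8, min_count=3, epochs=1, seed=0)
        assert c not in table and a in table

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_shared_contexts_give_similar_vectors(self, seed):
        table = train_skipgram(
            _cooccurrence_corpus(seed), dimension=16, window=2, epochs=5, seed=seed
        )
        def cos(x, y):
            return float(x @ y / (np.linalg.norm(x) * np.linalg.norm(y)))
        va = table[NodeRef("Dr", "dA")]
        vb = table[NodeRef("Dr", "dB")]
        vc = table[NodeRef("Dr", "dC")]
        assert cos(va, vb) > cos(va, vc)

    def test_training_is_deterministic(self):
        corpus = _cooccurrence_corpus(0)
        t1 = train_skipgram(corpus, dimension=12, epochs=2, seed=5)
        t2 = train_skipgram(corpus, dimension=12, epochs=2, seed=5)
        for ref, vec in t1.vectors.items():
            assert np.array_equal(vec, t2.vectors[ref])

    def test_empty_corpus_and_bad_dimension_rejected(self):
        with pytest.raises(EmbeddingError):
            train_skipgram(WalkCorpus([], "x"), dimension=8)
        with pytest.raises(EmbeddingError):
            train_skipgram(_cooccurrence_corpus(0), dimension=0)

    def test_table_save_load_round_trip(self, tmp_path):
        table = train_skipgram(_cooccurrence_corpus(1), dimension=8, epochs=1, seed=0)
        path = table.save(tmp_path / "x.emb")
        loaded = EmbeddingTable.load(path, "toy")
        assert loaded.dimension == 8 and set(loaded.vectors) == set(table.vectors)
        for ref in table.vectors:
            assert loaded[ref] == pytest.approx(table[ref], rel=1e-5)
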