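import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metapathdr import (
    EnsemblePrediction,
    NodeRef,
    classify,
    integrate,
    integrate_arrays,
    make_pair_features,
    sample_negatives,
    train_path_model,
)
from metapathdr.embedding import EmbeddingTable
from metapathdr.prediction import (
    PathModel,
    PredictionError,
    SamplingExhaustionError,
)


@pytest.fixture
def tiny_table():
    return EmbeddingTable(
        4,
        {
            NodeRef("Dr", "d1"): np.array([1.0, 0, 0, 0], dtype=np.float32),
            NodeRef("Di", "i1"): np.array([0, 1.0, 0, 0], dtype=np.float32),
        },
        "Dr-P-Di",
    )


class TestPairFeatures:
    def test_concatenation_order_drug_first(self, tiny_table):
        vec = make_pair_features(tiny_table, NodeRef("Dr", "d1"), NodeRef("Di", "i1"))
        assert vec.tolist() == [1, 0, 0, 0, 0, 1, 0, 0]

    def test_unembedded_node_gets_zero_half_by_default(self, tiny_table):
        vec = make_pair_features(tiny_table, NodeRef("Dr", "ghost"), NodeRef("Di", "i1"))
        assert vec[:4].tolist() == [0, 0, 0, 0] and vec.shape == (8,)

    def test_strict_mode_raises_for_missing_node(self, tiny_table):
        with pytest.raises(PredictionError):
            make_pair_features(
                tiny_table, NodeRef("Dr", "ghost"), NodeRef("Di", "i1"), missing="strict"
            )


class TestNegativeSampling:
    def test_two_negatives_per_positive(self, pair_universe):
        drugs, diseases, positives = pair_universe
        ps = sample_negatives(positives, drugs, diseases, seed=0)
        assert len(ps.positives) == 10 and len(ps.negatives) == 20

    def test_corruption_sides_balanced_and_disjoint(self, pair_universe):
        drugs, diseases, positives = pair_universe
        pos_set = set(positives)
        for seed in range(10):
            ps = sample_negatives(positives, drugs, diseases, seed=seed)
            negs = ps.negatives
            assert len(set(negs)) == len(negs)
            assert not (set(negs) & pos_set)
            # anchored structure: one drug-corrupted, one disease-corrupted
            for anchor, (d, i) in enumerate(positives):
                n1, n2 = negs[2 * anchor], negs[2 * anchor + 1]
                assert n1[1] == i and n1[0] != d  # drug corrupted
                assert n2[0] == d and n2[1] != i  # disease corrupted

    def test_fixed_seed_reproduces_pairs(self, pair_universe):
        drugs, diseases, positives = pair_universe
        a = sample_negatives(positives, drugs, diseases, seed=7)
        b = sample_negatives(positives, drugs, diseases, seed=7)
        assert a.pairs == b.pairs and a.anchors == b.anchors

    def test_exhaustion_raises(self):
        d, i = NodeRef("Dr", "d"), NodeRef("Di", "i")
        with pytest.raises(SamplingExhaustionError):
            sample_negatives([(d, i)], [d], [i], seed=0)


class TestPathModel:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-2, 0.3, (10, 2)), rng.normal(2, 0.3, (10, 2))])
        y = np.array([0] * 10 + [1] * 10)
        model = train_path_model(X, y, seed=0)
        assert ((model.predict_scores(X) >= 0.5) == y).all()

    def test_uninformative_features_score_near_prior(self):
        X = np.ones((90, 4))
        y = np.array([1] * 30 + [0] * 60)
        model = train_path_model(X, y, seed=0)
        scores = model.predict_scores(X)
        assert np.abs(scores - 1 / 3).max() < 0.15

    def test_scores_bounded_and_single_class_rejected(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, 40)
        model = train_path_model(X, y, seed=0)
        s = model.predict_scores(X)
        assert (s >= 0).all() and (s <= 1).all()
        with pytest.raises(PredictionError, match="single class"):
            train_path_model(X, np.zeros(40, dtype=int), seed=0)

    def test_model_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 4))
        y = rng.integers(0, 2, 30)
        model = train_path_model(X, y, seed=0, metapath_label="Dr-P-Di")
        model.save(tmp_path / "m.ubj")
        loaded = PathModel.load(tmp_path / "m.ubj")
        assert loaded.metapath_label == "Dr-P-Di"
        assert loaded.predict_scores(X) == pytest.approx(model.predict_scores(X))


class TestIntegration:
    def test_strategies_match_elementwise_reductions(self):
        scores = {"a": 0.2, "b": 0.9, "c": 0.1, "d": 0.3}
        assert integrate(scores, "MAX") == 0.9
        assert integrate(scores, "MEAN") == pytest.approx(0.375)
        assert integrate(scores, "MIN") == 0.1

    def test_single_path_identity(self):
        for strategy in ("MAX", "MEAN", "MIN"):
            assert integrate({"only": 0.42}, strategy) == pytest.approx(0.42)

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=6),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariance(self, values, rnd):
        keys = [f"p{i}" for i in range(len(values))]
        shuffled = list(zip(keys, values))
        rnd.shuffle(shuffled)
        for strategy in ("MAX", "MEAN", "MIN"):
            assert integrate(dict(zip(keys, values)), strategy) == pytest.approx(
                integrate(dict(shuffled), strategy)
            )

    def test_errors_on_empty_or_out_of_range(self):
        with pytest.raises(PredictionError):
            integrate({}, "MAX")
        with pytest.raises(PredictionError):
            integrate({"a": 1.4}, "MAX")
        with pytest.raises(PredictionError):
            integrate({"a": 0.5}, "MEDIAN")

    def test_array_form_matches_scalar_form(self):
        rng = np.random.default_rng(3)
        arrs = {k: rng.random(20) for k in ("a", "b", "c")}
        for strategy in ("MAX", "MEAN", "MIN"):
            out = integrate_arrays(arrs, strategy)
            for j in range(20):
                assert out[j] == pytest.approx(
                    integrate({k: float(v[j]) for k, v in arrs.items()}, strategy)
                )


class TestClassify:
    @pytest.mark.parametrize("score,label", [(0.5, 1), (0.499999, 0), (1.0, 1), (0.0, 0)])
    def test_threshold_tie_rule(self, score, label):
        assert classify(score) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(PredictionError):
            classify(1.2)

    def test_max_preserves_any_single_path_positive(self):
        pred = EnsemblePrediction.from_scores(
            (NodeRef("Dr", "d"), NodeRef("Di", "i")),
            {"p1": 0.1, "p2": 0.62, "p3": 0.2},
            strategy="MAX",
        )
        assert pred.predicted_label == 1
        assert pred.final_score == pytest.approx(0.62)
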