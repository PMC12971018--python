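"""Pair features, negative sampling, per-meta-path classifiers, integration.

A drug-disease pair is represented by concatenating the drug embedding with
the disease embedding (drug half first).  Known associations are positives;
for each positive two negatives are drawn -- one by corrupting the drug, one
by corrupting the disease -- giving the 2:1 negative:positive ratio.  One
gradient-boosted-tree classifier is trained per meta-path on that path's own
embeddings; per-path probabilities are fused by the MAX rule (MEAN and MIN
are supported alternatives) and thresholded at 0.5.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import xgboost as xgb
from xgboost import XGBClassifier

from .embedding import EmbeddingTable
from .hetnet import NodeRef

logger = logging.getLogger(__name__)

Pair = tuple[NodeRef, NodeRef]

INTEGRATION_STRATEGIES = ("MAX", "MEAN", "MIN")

#: Boosted-tree defaults (logistic objective); exposed via PipelineConfig.
DEFAULT_XGB_PARAMS: dict = {
    "n_estimators": 300,
    "max_depth": 6,
    "learning_rate": 0.1,
}


class PredictionError(Exception):
    pass


class SamplingExhaustionError(PredictionError):
    pass


# ------------------------------------------------------------------ features
def make_pair_features(
    table: EmbeddingTable,
    drug: NodeRef,
    disease: NodeRef,
    missing: str = "zero",
) -> np.ndarray:
    """Concatenated [drug | disease] feature vector of length 2*dimension.

    A node absent from the table yields a zero half-vector (default policy,
    logged); ``missing="strict"`` raises instead.
    """
    d = table.dimension
    halves = []
    for ref in (drug, disease):
        if ref in table:
            halves.append(np.asarray(table[ref], dtype=np.float32))
        elif missing == "strict":
            raise PredictionError(f"node {ref} has no embedding")
        else:
            logger.debug("node %s unembedded; zero feature half", ref)
            halves.append(np.zeros(d, dtype=np.float32))
    return np.concatenate(halves)


def feature_matrix(
    table: EmbeddingTable, pairs: Sequence[Pair], missing: str = "zero"
) -> np.ndarray:
    if not pairs:
        return np.zeros((0, 2 * table.dimension), dtype=np.float32)
    return np.vstack([make_pair_features(table, d, i, missing) for d, i in pairs])


# ---------------------------------------------------------- negative sampling
@dataclass
class LabeledPairSet:
    """Positives plus corruption-sampled negatives (2 per positive).

    ``anchors[j]`` is the index (into ``pairs``) of the positive that row j
    was derived from: positives anchor themselves, each negative points at
    the positive it corrupts.  Cross-validation assigns every negative to
    its anchor's fold so that a held-out positive's corruptions can never
    appear in training.
    """

    pairs: list[tuple[NodeRef, NodeRef, int]]
    seed: int
    scheme: str = "pair-corruption-2:1"
    anchors: list[int] = field(default_factory=list)

    @property
    def positives(self) -> list[Pair]:
        return [(d, i) for d, i, y in self.pairs if y == 1]

    @property
    def negatives(self) -> list[Pair]:
        return [(d, i) for d, i, y in self.pairs if y == 0]

    def labels(self) -> np.ndarray:
        return np.asarray([y for _, _, y in self.pairs], dtype=np.int64)


def _corrupt(
    fixed: NodeRef,
    universe: list[NodeRef],
    make_pair,
    forbidden: set[Pair],
    drawn: set[Pair],
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> Pair:
    for _ in range(max_attempts):
        cand = universe[int(rng.integers(len(universe)))]
        pair = make_pair(cand)
        if pair not in forbidden and pair not in drawn:
            return pair
    # exact feasibility check before declaring exhaustion
    remaining = [
        p for cand in universe
        if (p := make_pair(cand)) not in forbidden and p not in drawn
    ]
    if not remaining:
        raise SamplingExhaustionError(
            f"no valid corruption left for pair anchored at {fixed}"
        )
    return remaining[int(rng.integers(len(remaining)))]


def sample_negatives(
    positives: Sequence[Pair],
    drug_universe: Sequence[NodeRef],
    disease_universe: Sequence[NodeRef],
    seed: int = 0,
) -> LabeledPairSet:
    """For each positive (d, i): one drug-corrupted and one disease-corrupted
    negative, rejection-resampled until non-positive and not already drawn.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    pos_set = set(positives)
    if len(pos_set) != len(positives):
        raise PredictionError("duplicate pairs in the positive set")
    drugs = sorted(drug_universe)
    diseases = sorted(disease_universe)
    drawn: set[Pair] = set()
    pairs: list[tuple[NodeRef, NodeRef, int]] = [
        (d, i, 1) for d, i in positives
    ]
    anchors = list(range(len(positives)))
    for anchor, (d, i) in enumerate(positives):
        neg1 = _corrupt(i, drugs, lambda dr: (dr, i), pos_set, drawn, rng)
        drawn.add(neg1)
        neg2 = _corrupt(d, diseases, lambda di: (d, di), pos_set, drawn, rng)
        drawn.add(neg2)
        pairs.append((*neg1, 0))
        pairs.append((*neg2, 0))
        anchors.extend((anchor, anchor))
    return LabeledPairSet(pairs, seed, anchors=anchors)


# ------------------------------------------------------------------- training
@dataclass
class PathModel:
    """A fitted per-meta-path boosted-tree classifier.

    Holds the trained booster directly; scores are logistic probabilities.
    """

    metapath_label: str
    booster: xgb.Booster
    feature_dimension: int
    hyperparams: dict = field(default_factory=dict)

    def predict_scores(self, features: np.ndarray) -> np.ndarray:
        features = np.ascontiguousarray(features, dtype=np.float32)
        scores = self.booster.inplace_predict(features, validate_features=False)
        return np.clip(np.asarray(scores, dtype=np.float64), 0.0, 1.0)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.booster.save_model(str(path))
        meta = {
            "metapath": self.metapath_label,
            "feature_dimension": self.feature_dimension,
            "hyperparams": self.hyperparams,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "PathModel":
        path = Path(path)
        booster = xgb.Booster()
        booster.load_model(str(path))
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        return cls(meta["metapath"], booster, meta["feature_dimension"], meta["hyperparams"])


def train_path_model(
    features: np.ndarray,
    labels: np.ndarray,
    hyperparams: Mapping | None = None,
    seed: int = 0,
    metapath_label: str = "",
) -> PathModel:
    """Fit a binary boosted-tree classifier; scores are probabilities."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise PredictionError("training set contains a single class")
    params = dict(DEFAULT_XGB_PARAMS)
    if hyperparams:
        params.update(hyperparams)
    clf = XGBClassifier(
        **params,
        objective="binary:logistic",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
    )
    clf.fit(np.asarray(features, dtype=np.float32), labels)
    return PathModel(metapath_label, clf.get_booster(), features.shape[1], params)


# ---------------------------------------------------------------- integration
def integrate(path_scores: Mapping[str, float], strategy: str = "MAX") -> float:
    """Fuse per-meta-path scores by elementwise max / mean / min."""
    if not path_scores:
        raise PredictionError("empty score map")
    values = np.asarray(list(path_scores.values()), dtype=np.float64)
    if np.any(values < 0) or np.any(values > 1):
        raise PredictionError(f"scores outside [0, 1]: {path_scores}")
    if strategy == "MAX":
        return float(values.max())
    if strategy == "MEAN":
        return float(values.mean())
    if strategy == "MIN":
        return float(values.min())
    raise PredictionError(
        f"unknown strategy {strategy!r}; expected one of {INTEGRATION_STRATEGIES}"
    )


def integrate_arrays(
    path_scores: Mapping[str, np.ndarray], strategy: str = "MAX"
) -> np.ndarray:
    """Vectorized integrate over aligned per-path score arrays."""
    if not path_scores:
        raise PredictionError("empty score map")
    stacked = np.vstack(list(path_scores.values()))
    if stacked.min() < 0 or stacked.max() > 1:
        raise PredictionError("scores outside [0, 1]")
    if strategy == "MAX":
        return stacked.max(axis=0)
    if strategy == "MEAN":
        return stacked.mean(axis=0)
    if strategy == "MIN":
        return stacked.min(axis=0)
    raise PredictionError(f"unknown strategy {strategy!r}")


def classify(final_score: float, threshold: float = 0.5) -> int:
    """Label 1 iff score >= threshold (a tie at the threshold is positive)."""
    if not 0.0 <= final_score <= 1.0:
        raise PredictionError(f"score {final_score} outside [0, 1]")
    return int(final_score >= threshold)


@dataclass
class EnsemblePrediction:
    pair: Pair
    path_scores: dict[str, float]
    final_score: float
    predicted_label: int

    @classmethod
    def from_scores(
        cls,
        pair: Pair,
        path_scores: Mapping[str, float],
        strategy: str = "MAX",
        threshold: float = 0.5,
    ) -> "EnsemblePrediction":
        final = integrate(path_scores, strategy)
        return cls(pair, dict(path_scores), final, classify(final, threshold))
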