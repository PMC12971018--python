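"""Five-fold cross-validation protocol and threshold/ranking metrics.

Pairs (not drugs or diseases) are the CV unit: the labeled pair set is
stratified-split into k folds, per-meta-path classifiers are fitted on the
training pairs only, and MAX-integrated scores on the held-out pairs yield
per-fold metric reports aggregated as the unweighted mean over folds.

Embeddings are trained once per run, on walks over the meta-path filtered
networks.  Those networks are built exclusively from drug-protein,
disease-protein, protein-protein, protein-function and function-function
edges -- never from drug-disease label edges -- so sharing them across folds
leaks no held-out label information.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .config import PipelineConfig, derive_seed
from .embedding import (
    EmbeddingTable,
    WalkConfig,
    generate_walks,
    train_skipgram,
    transition_probs,
)
from .hetnet import HeteroNetwork, NodeRef
from .metapath import build_filtered_network, parse_metapath
from .prediction import (
    LabeledPairSet,
    Pair,
    feature_matrix,
    integrate_arrays,
    sample_negatives,
    train_path_model,
)

logger = logging.getLogger(__name__)


class EvaluationError(Exception):
    pass


@dataclass
class FoldAssignment:
    k: int
    assignment: dict[tuple[NodeRef, NodeRef, int], int]

    def fold_indices(self, pairs: Sequence[tuple[NodeRef, NodeRef, int]], fold: int):
        test = [i for i, p in enumerate(pairs) if self.assignment[p] == fold]
        train = [i for i, p in enumerate(pairs) if self.assignment[p] != fold]
        return np.asarray(train), np.asarray(test)


@dataclass
class MetricReport:
    auroc: float
    aupr: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "aupr": self.aupr,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "counts": {"TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn},
        }


def kfold_split(pair_set: LabeledPairSet, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Stratified-by-label random partition of the pairs; seed-deterministic."""
    if k < 2:
        raise EvaluationError("k must be >= 2 (no held-out data otherwise)")
    labels = pair_set.labels()
    for cls in (0, 1):
        if int((labels == cls).sum()) < k:
            raise EvaluationError(f"fewer than k={k} pairs of class {cls}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % 2**32)
    assignment: dict = {}
    dummy = np.zeros(len(labels))
    for fold, (_, test_idx) in enumerate(splitter.split(dummy, labels)):
        for i in test_idx:
            assignment[pair_set.pairs[i]] = fold
    return FoldAssignment(k, assignment)


def anchored_kfold(
    pair_set: LabeledPairSet, k: int = 5, seed: int = 0
) -> FoldAssignment:
    """Fold assignment where each negative follows its anchor positive.

    The positives are randomly partitioned into k near-equal folds; every
    corruption-sampled negative is assigned to the fold of the positive it
    was derived from.  This keeps the 2:1 class ratio exact per fold (+-1)
    and -- crucially -- guarantees that a held-out positive's own anchored
    negatives are never seen in training, which would otherwise teach the
    model that exactly that pair's drug and disease are unassociated.
    """
    if k < 2:
        raise EvaluationError("k must be >= 2 (no held-out data otherwise)")
    if not pair_set.anchors:
        raise EvaluationError("pair set carries no anchor indices")
    pos_idx = [j for j, (_, _, y) in enumerate(pair_set.pairs) if y == 1]
    if len(pos_idx) < k:
        raise EvaluationError(f"fewer than k={k} positive pairs")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pos_idx))
    pos_fold = {pos_idx[j]: int(rank % k) for rank, j in enumerate(order)}
    assignment = {
        pair: pos_fold[pair_set.anchors[j]]
        for j, pair in enumerate(pair_set.pairs)
    }
    return FoldAssignment(k, assignment)


def compute_metrics(
    labels: Sequence[int] | np.ndarray,
    scores: Sequence[float] | np.ndarray,
    threshold: float = 0.5,
) -> MetricReport:
    """Six-metric report: AUROC (rank-based, ties averaged), AUPR (step
    interpolation over distinct thresholds), and thresholded accuracy,
    precision, recall and F1 with the >= tie rule.
    """
    labels = np.asarray(labels, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise EvaluationError("labels and scores length mismatch")
    if not np.isin(labels, (0, 1)).all():
        raise EvaluationError("labels must be 0/1")
    if scores.min() < 0 or scores.max() > 1:
        raise EvaluationError("scores must lie in [0, 1]")
    if np.unique(labels).size < 2:
        raise EvaluationError("AUROC/AUPR undefined for single-class labels")
    auroc = float(roc_auc_score(labels, scores))
    aupr = float(average_precision_score(labels, scores))
    preds = (scores >= threshold).astype(np.int64)
    tp = int(((preds == 1) & (labels == 1)).sum())
    fp = int(((preds == 1) & (labels == 0)).sum())
    tn = int(((preds == 0) & (labels == 0)).sum())
    fn = int(((preds == 0) & (labels == 1)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = (tp + tn) / labels.size
    return MetricReport(auroc, aupr, accuracy, precision, recall, f1, tp, fp, tn, fn)


def build_path_embeddings(
    network: HeteroNetwork,
    config: PipelineConfig,
    master_seed: int,
) -> dict[str, EmbeddingTable]:
    """build -> walk -> embed for every configured meta-path.

    Per-stage seeds are derived from the master seed and the meta-path label,
    so each table is independently reproducible.
    """
    tables: dict[str, EmbeddingTable] = {}
    for spec in config.metapaths:
        t0 = time.perf_counter()
        mp = parse_metapath(spec)
        filtered = build_filtered_network(network, mp)
        model = transition_probs(filtered)
        corpus = generate_walks(
            model,
            WalkConfig(
                config.walks_per_start,
                config.walk_length,
                derive_seed(master_seed, f"walks:{mp.label}"),
            ),
        )
        tables[mp.label] = train_skipgram(
            corpus,
            dimension=config.dimension,
            window=config.window,
            epochs=config.epochs,
            negative_samples=config.negative_samples,
            min_count=config.min_count,
            seed=derive_seed(master_seed, f"sgns:{mp.label}"),
            heterogeneous=config.heterogeneous,
            combine=config.combine,
        )
        logger.info(
            "meta-path %s: %d walks, embedded %d nodes in %.1fs",
            mp.label,
            len(corpus.walks),
            len(tables[mp.label].vectors),
            time.perf_counter() - t0,
        )
    return tables


@dataclass
class CVResult:
    fold_reports: list[MetricReport]
    mean: MetricReport
    provenance: dict = field(default_factory=dict)
    #: one row per held-out pair: fold, drug_id, disease_id,
    #: {metapath: score}, final_score, label
    predictions: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "folds": [r.to_dict() for r in self.fold_reports],
            "mean": self.mean.to_dict(),
            "provenance": self.provenance,
        }


def _mean_report(reports: list[MetricReport]) -> MetricReport:
    return MetricReport(
        auroc=float(np.mean([r.auroc for r in reports])),
        aupr=float(np.mean([r.aupr for r in reports])),
        accuracy=float(np.mean([r.accuracy for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        tp=sum(r.tp for r in reports),
        fp=sum(r.fp for r in reports),
        tn=sum(r.tn for r in reports),
        fn=sum(r.fn for r in reports),
    )


def run_cv(
    network: HeteroNetwork,
    positives: Sequence[Pair],
    config: PipelineConfig | None = None,
    seed: int = 0,
    shuffle_labels: bool = False,
    embeddings: Mapping[str, EmbeddingTable] | None = None,
) -> CVResult:
    """Full k-fold cross-validated evaluation of the ensemble.

    Negatives are sampled once globally (2 per positive) and shared across
    all meta-path models; labels can be permuted (``shuffle_labels``) as a
    null-signal control.  Precomputed ``embeddings`` may be supplied, e.g. to
    reuse them across a matched null run.
    """
    config = config or PipelineConfig()
    if embeddings is None:
        embeddings = build_path_embeddings(network, config, seed)
    pair_set = sample_negatives(
        list(positives),
        network.node_refs("Dr"),
        network.node_refs("Di"),
        seed=derive_seed(seed, "negatives"),
    )
    # folds follow the anchored positives and are fixed before any label
    # shuffling, so the null control evaluates the same splits
    folds = anchored_kfold(pair_set, config.k_folds, derive_seed(seed, "folds"))
    pairs = pair_set.pairs
    labels = pair_set.labels()
    if shuffle_labels:
        rng = np.random.default_rng(derive_seed(seed, "shuffle"))
        labels = labels[rng.permutation(labels.size)]
        new_pairs = [(d, i, int(y)) for (d, i, _), y in zip(pairs, labels)]
        folds = FoldAssignment(
            folds.k,
            {np_: folds.assignment[op] for np_, op in zip(new_pairs, pairs)},
        )
        pairs = new_pairs

    features = {
        label: feature_matrix(table, [(d, i) for d, i, _ in pairs])
        for label, table in embeddings.items()
    }
    fold_reports: list[MetricReport] = []
    prediction_rows: list[dict] = []
    for fold in range(config.k_folds):
        train_idx, test_idx = folds.fold_indices(pairs, fold)
        path_scores: dict[str, np.ndarray] = {}
        for label, X in features.items():
            model = train_path_model(
                X[train_idx],
                labels[train_idx],
                config.xgb_params,
                seed=derive_seed(seed, f"xgb:{label}:{fold}"),
                metapath_label=label,
            )
            path_scores[label] = model.predict_scores(X[test_idx])
        final = integrate_arrays(path_scores, config.strategy)
        fold_reports.append(
            compute_metrics(labels[test_idx], final, config.threshold)
        )
        for pos, idx in enumerate(test_idx):
            d, i, _ = pairs[idx]
            prediction_rows.append(
                {
                    "fold": fold,
                    "drug_id": d.node_id,
                    "disease_id": i.node_id,
                    "path_scores": {
                        label: float(path_scores[label][pos]) for label in path_scores
                    },
                    "final_score": float(final[pos]),
                    "label": int(labels[idx]),
                }
            )
    return CVResult(
        fold_reports,
        _mean_report(fold_reports),
        predictions=prediction_rows,
        provenance={
            "seed": seed,
            "config_hash": config.config_hash(),
            "n_pairs": len(pairs),
            "k": config.k_folds,
            "shuffled": shuffle_labels,
            "strategy": config.strategy,
        },
    )
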