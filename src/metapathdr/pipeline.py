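"""Run configuration and end-to-end orchestration.

Ties the stages together: load or generate the network, build the meta-path
filtered networks, walk and embed, train per-path classifiers, integrate,
and evaluate.  One master seed drives everything: every stage's seed is
derived as SHA-256(master ":" stage-name) mod 2**31 (see
:func:`metapathdr.config.derive_seed`), so changing nothing reproduces every
artifact byte for byte and each stage is independently re-runnable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .config import PipelineConfig, derive_seed
from .embedding import EmbeddingTable
from .evaluation import CVResult, build_path_embeddings, run_cv
from .hetnet import HeteroNetwork, NodeRef, load_hetnet, load_pairs, write_hetnet, write_pairs
from .prediction import (
    PathModel,
    classify,
    feature_matrix,
    integrate_arrays,
    sample_negatives,
    train_path_model,
)
from .synthetic import SyntheticConfig, generate_hetnet

logger = logging.getLogger(__name__)


class PipelineError(Exception):
    pass


@dataclass
class RunConfig:
    """One run: input source, pipeline tunables, master seed, output dir."""

    edge_files: dict[str, str] | None = None
    positives_path: str | None = None
    synthetic: SyntheticConfig | None = None
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    master_seed: int = 0
    outdir: str = "out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synthetic = (
            SyntheticConfig(**raw["synthetic"]) if "synthetic" in raw else None
        )
        pipeline = PipelineConfig(**raw.get("pipeline", {}))
        return cls(
            edge_files=raw.get("edges"),
            positives_path=raw.get("positives"),
            synthetic=synthetic,
            pipeline=pipeline,
            master_seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "out")),
        )


def load_inputs(config: RunConfig) -> tuple[HeteroNetwork, list[tuple[NodeRef, NodeRef]]]:
    """Resolve the network and positive pairs from files or the generator."""
    if config.synthetic is not None:
        synth = dataclasses.replace(
            config.synthetic, seed=derive_seed(config.master_seed, "synthetic")
        )
        return generate_hetnet(synth)
    if not config.edge_files:
        raise PipelineError("config provides neither edge files nor a synthetic block")
    network = load_hetnet(config.edge_files)
    positives = load_pairs(config.positives_path) if config.positives_path else []
    return network, positives


def write_generated(config: RunConfig) -> Path:
    """Generate synthetic inputs and write them as the standard TSV files."""
    if config.synthetic is None:
        raise PipelineError("no synthetic block in config")
    network, positives = load_inputs(config)
    outdir = Path(config.outdir)
    write_hetnet(network, outdir / "edges")
    write_pairs(positives, outdir / "positives.tsv")
    logger.info("synthetic network written under %s", outdir)
    return outdir


def save_embeddings(
    tables: Mapping[str, EmbeddingTable], outdir: str | Path
) -> dict[str, Path]:
    outdir = Path(outdir)
    return {label: table.save(outdir / f"{label}.emb") for label, table in tables.items()}


def load_embeddings(outdir: str | Path) -> dict[str, EmbeddingTable]:
    tables = {}
    for path in sorted(Path(outdir).glob("*.emb")):
        label = path.stem
        tables[label] = EmbeddingTable.load(path, label)
    if not tables:
        raise PipelineError(f"no .emb files under {outdir}")
    return tables


def _score_pairs(
    models: Mapping[str, PathModel],
    embeddings: Mapping[str, EmbeddingTable],
    pairs: Sequence[tuple[NodeRef, NodeRef]],
    strategy: str,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    path_scores = {
        label: models[label].predict_scores(feature_matrix(embeddings[label], list(pairs)))
        for label in sorted(models)
    }
    return path_scores, integrate_arrays(path_scores, strategy)


def run_train_predict(
    config: RunConfig,
    pairs: Sequence[tuple[NodeRef, NodeRef]] | None = None,
) -> Path:
    """Train per-path models on the full labeled set and score pairs.

    Scores the requested ``pairs`` (default: all labeled pairs).  Writes
    ``predictions.tsv`` (one row per pair: per-path scores, final score,
    label at the configured threshold), the per-path models and the
    embedding tables under the output directory.  Seed-deterministic end to
    end: reruns with the same master seed are byte-identical.
    """
    network, positives = load_inputs(config)
    if not positives:
        raise PipelineError("no positive pairs available for training")
    pc = config.pipeline
    seed = config.master_seed
    embeddings = build_path_embeddings(network, pc, seed)
    pair_set = sample_negatives(
        positives,
        network.node_refs("Dr"),
        network.node_refs("Di"),
        seed=derive_seed(seed, "negatives"),
    )
    labels = pair_set.labels()
    models: dict[str, PathModel] = {}
    for label, table in embeddings.items():
        X = feature_matrix(table, [(d, i) for d, i, _ in pair_set.pairs])
        models[label] = train_path_model(
            X,
            labels,
            pc.xgb_params,
            seed=derive_seed(seed, f"xgb:{label}:full"),
            metapath_label=label,
        )

    outdir = Path(config.outdir)
    save_embeddings(embeddings, outdir / "embeddings")
    for label, model in models.items():
        model.save(outdir / "models" / f"{label}.ubj")

    if pairs is None:
        pairs = [(d, i) for d, i, _ in pair_set.pairs]
    path_scores, final = _score_pairs(models, embeddings, pairs, pc.strategy)
    labels_out = [classify(float(s), pc.threshold) for s in final]
    pred_path = outdir / "predictions.tsv"
    path_labels = sorted(models)
    with pred_path.open("w") as fh:
        fh.write(
            "drug_id\tdisease_id\t"
            + "\t".join(f"score:{p}" for p in path_labels)
            + "\tfinal_score\tlabel\n"
        )
        for idx, (d, i) in enumerate(pairs):
            cols = "\t".join(f"{path_scores[p][idx]:.6f}" for p in path_labels)
            fh.write(
                f"{d.node_id}\t{i.node_id}\t{cols}\t{final[idx]:.6f}\t{labels_out[idx]}\n"
            )
    logger.info("predictions written to %s", pred_path)
    return pred_path


def run_evaluate(config: RunConfig, shuffle_labels: bool = False) -> CVResult:
    """k-fold cross-validated evaluation; writes report.json and per-fold TSV."""
    network, positives = load_inputs(config)
    if not positives:
        raise PipelineError("no positive pairs available for evaluation")
    result = run_cv(
        network,
        positives,
        config.pipeline,
        seed=config.master_seed,
        shuffle_labels=shuffle_labels,
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(json.dumps(result.to_dict(), indent=2))
    path_labels = sorted(config.pipeline.metapaths)
    with (outdir / "fold_predictions.tsv").open("w") as fh:
        fh.write(
            "fold\tdrug_id\tdisease_id\t"
            + "\t".join(f"score:{p}" for p in path_labels)
            + "\tfinal_score\tlabel\n"
        )
        for row in result.predictions:
            cols = "\t".join(f"{row['path_scores'][p]:.6f}" for p in path_labels)
            fh.write(
                f"{row['fold']}\t{row['drug_id']}\t{row['disease_id']}\t{cols}\t"
                f"{row['final_score']:.6f}\t{row['label']}\n"
            )
    logger.info("evaluation report written under %s", outdir)
    return result


def rank_candidates(
    models: Mapping[str, PathModel],
    embeddings: Mapping[str, EmbeddingTable],
    disease: NodeRef,
    drug_universe: Sequence[NodeRef],
    top_n: int = 10,
    strategy: str = "MAX",
    known_positives: set[tuple[str, str]] | None = None,
) -> list[dict]:
    """Rank candidate drugs for one disease by final ensemble score.

    Descending by score; ties broken lexicographically by drug id.  Known
    positives (if supplied) are annotated, not removed.
    """
    if not any(disease in t for t in embeddings.values()):
        raise PipelineError(f"disease {disease.node_id!r} has no embedding in any table")
    drugs = sorted(set(drug_universe))
    pairs = [(d, disease) for d in drugs]
    path_scores, final = _score_pairs(models, embeddings, pairs, strategy)
    order = sorted(range(len(drugs)), key=lambda i: (-final[i], drugs[i].node_id))
    known = known_positives or set()
    rows = []
    for rank, i in enumerate(order[: max(top_n, 0) or len(order)], start=1):
        rows.append(
            {
                "rank": rank,
                "drug_id": drugs[i].node_id,
                "final_score": float(final[i]),
                "path_scores": {p: float(path_scores[p][i]) for p in path_scores},
                "known": (drugs[i].node_id, disease.node_id) in known,
            }
        )
    return rows
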