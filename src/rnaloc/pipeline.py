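"""End-to-end orchestration: simulate -> embed -> priors -> train -> predict -> evaluate.

One :class:`RunConfig` (YAML-serializable) drives the whole run; a single
global seed deterministically derives every stage seed, so re-running an
identical config reproduces the report bit-for-bit.  Every stage persists
its artifacts under the output directory and reads its inputs back from
disk, so any suffix of the pipeline can be re-run after a restart.

Following common practice for unsupervised encoders, the skip-gram
embedding is trained on all sequences (training and test); labels are never
consulted outside the training partition.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dataset as dio
from . import simulate as sim
from .encoding import EmbeddingTable, SkipgramConfig, TokenizerConfig, segment, train_skipgram
from .metrics import EvaluationBatch, MetricsReport, evaluate_all
from .predictor import ModelConfig, TrainedPredictor, decide_labels, train
from .prior import CooccurrenceModel, fit_cooccurrence

logger = logging.getLogger("rnaloc")


@dataclass
class SimulateParams:
    n: int = 1000
    copies: float = 3.0
    length_min: int = 200
    length_max: int = 400
    background_gc: float = 0.5


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    If ``fasta``/``labels`` are set, that dataset is used; otherwise a
    synthetic dataset is generated from ``simulate``.  Stage seeds are
    derived from ``seed``.
    """

    seed: int = 0
    fasta: str | None = None
    labels: str | None = None
    simulate: SimulateParams = field(default_factory=SimulateParams)
    test_fraction: float = 0.1
    k: int = 3
    skipgram: SkipgramConfig = field(default_factory=lambda: SkipgramConfig(dim=16, context=3, epochs=2))
    alpha: float = 0.0
    model: ModelConfig = field(
        default_factory=lambda: ModelConfig(
            hidden=32, epochs=20, lr=1e-2, batch=64, dropout=0.1
        )
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "simulate" in kwargs:
            kwargs["simulate"] = SimulateParams(**kwargs["simulate"])
        if "skipgram" in kwargs:
            kwargs["skipgram"] = SkipgramConfig(**kwargs["skipgram"])
        if "model" in kwargs:
            kwargs["model"] = ModelConfig(**kwargs["model"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    def stage_seeds(self) -> dict[str, int]:
        names = ["simulate", "split", "skipgram", "model"]
        state = np.random.SeedSequence(self.seed).generate_state(len(names))
        return {name: int(s % (2**31)) for name, s in zip(names, state)}


def write_predictions(
    ids: list[str],
    scores: np.ndarray,
    decisions: np.ndarray,
    labels: list[str],
    path: str | Path,
) -> None:
    table = pd.DataFrame({"id": ids})
    for j, label in enumerate(labels):
        table[f"score_{label}"] = scores[:, j]
    for j, label in enumerate(labels):
        table[f"pred_{label}"] = decisions[:, j].astype(int)
    table.to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path, labels: list[str]):
    table = pd.read_csv(path, sep="\t", dtype={"id": str})
    scores = table[[f"score_{l}" for l in labels]].to_numpy(dtype=np.float64)
    preds = table[[f"pred_{l}" for l in labels]].to_numpy(dtype=np.int64).astype(bool)
    return list(table["id"]), scores, preds


def evaluate_predictions(
    predictions_path: str | Path,
    truth_ds: dio.LocalizationDataset,
) -> MetricsReport:
    labels = list(truth_ds.universe.labels)
    ids, scores, preds = read_predictions(predictions_path, labels)
    by_id = {rid: i for i, rid in enumerate(truth_ds.ids)}
    order = [by_id[rid] for rid in ids]
    batch = EvaluationBatch(
        true=truth_ds.label_matrix[order].astype(bool), predicted=preds, scores=scores
    )
    return evaluate_all(batch, labels)


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> MetricsReport:
    """Execute all stages, persisting every intermediate artifact.

    Raises with the failing stage named; returns the evaluation report,
    which is also written to ``<outdir>/report.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    seeds = cfg.stage_seeds()
    cfg.to_yaml(outdir / "config.yaml")
    try:
        stage = "simulate/load"
        if cfg.fasta and cfg.labels:
            ds = dio.read_dataset(cfg.fasta, cfg.labels)
        else:
            p = cfg.simulate
            syn = sim.SyntheticConfig(
                joint=sim.chain_joint(),
                motifs=sim.default_motifs(copies=p.copies),
                n=p.n,
                length_range=(p.length_min, p.length_max),
                background_gc=p.background_gc,
                seed=seeds["simulate"],
                tokenizer_k=cfg.k,
            )
            ds = sim.simulate_dataset(syn)
        dio.write_dataset(ds, outdir / "data.fasta", outdir / "data.tsv")
        dio.summarize(ds).to_json(outdir / "summary.json")
        logger.info("stage %s: %d records", stage, len(ds))

        stage = "split"
        train_ds, test_ds = dio.split_train_test(
            ds, dio.SplitSpec(test_fraction=cfg.test_fraction, seed=seeds["split"])
        )
        dio.write_dataset(train_ds, outdir / "train.fasta", outdir / "train.tsv")
        dio.write_dataset(test_ds, outdir / "test.fasta", outdir / "test.tsv")
        logger.info("stage split: %d train / %d test", len(train_ds), len(test_ds))

        stage = "embed"
        tok = TokenizerConfig(k=cfg.k)
        corpus = [segment(rec.sequence, tok) for rec in ds.records]
        sg = dataclasses.replace(cfg.skipgram, seed=seeds["skipgram"])
        table = train_skipgram(corpus, sg, k=cfg.k)
        table.save(outdir / "embedding")
        logger.info("stage embed: vocab %d, dim %d", len(table.vocabulary), table.dim)

        stage = "fit-priors"
        coocc = fit_cooccurrence(
            train_ds.label_matrix, alpha=cfg.alpha, universe=ds.universe
        )
        coocc.to_json(outdir / "cooccurrence.json")

        stage = "train"
        mcfg = dataclasses.replace(cfg.model, seed=seeds["model"])
        predictor = train(train_ds, table, coocc, mcfg)
        predictor.save(outdir / "model")
        logger.info("stage train: final loss %.4f", predictor.loss_history[-1])

        stage = "predict"
        scores = predictor.predict_scores(test_ds)
        decisions = decide_labels(scores, mcfg.threshold)
        write_predictions(
            test_ds.ids, scores, decisions, list(ds.universe.labels),
            outdir / "predictions.tsv",
        )

        stage = "evaluate"
        report = evaluate_predictions(outdir / "predictions.tsv", test_ds)
        report.to_json(outdir / "report.json")
        logger.info(
            "stage evaluate: acc_exam %.3f hamming %.3f",
            report.acc_exam, report.hamming_loss,
        )
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
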