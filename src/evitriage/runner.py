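"""Experiment orchestration: configs in, seeded runs, reports out.

A run is described by a flat key/value config (YAML). Every
under-specified default that matters to reproduction — optimizer, layer
sizes, the split policy — is snapshotted into the report, and a rerun with
the same config yields an identical report apart from timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import yaml

from . import synth
from .methods import PassageClassifierConfig, evaluate_multirestart
from .triage import (TriageConfig, classify_document,
                     evaluate_triage_multirestart, select_passages)

__all__ = ["accuracy", "ExperimentReport", "run_experiment",
           "reports_equal", "ConfigError"]


def accuracy(predictions: Sequence, labels: Sequence) -> float:
    """Fraction of exact matches."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError(
            f"length mismatch: {predictions.shape} vs {labels.shape}")
    if predictions.size == 0:
        raise ValueError("empty prediction list")
    return float((predictions == labels).mean())


class ConfigError(ValueError):
    """Schema violation; message lists the offending keys."""


@dataclass
class ExperimentReport:
    task: str
    config: dict
    seeds: list[int]
    accuracies: list[float]
    mean: float
    std: float
    confusion: list[list[int]]
    classes: list[str]
    defaults_recorded: dict
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentReport":
        return cls(**json.loads(text))

    def validate(self):
        if not np.isclose(self.mean, float(np.mean(self.accuracies))):
            raise ValueError("mean not recomputable from per-restart list")
        expect_std = (0.0 if len(self.accuracies) < 2
                      else float(np.std(self.accuracies, ddof=1)))
        if not np.isclose(self.std, expect_std):
            raise ValueError("std not recomputable from per-restart list")


def reports_equal(a: ExperimentReport, b: ExperimentReport) -> bool:
    """Equality modulo timestamps (the determinism contract)."""
    da, db = dataclasses.asdict(a), dataclasses.asdict(b)
    for d in (da, db):
        d.pop("started"), d.pop("finished")
    return da == db


_COMMON_KEYS = {"task", "n_restarts", "seed", "outdir", "embedding_dim",
                "oov_policy", "embedding_path"}
_TRIAGE_KEYS = _COMMON_KEYS | {
    f"synth_{f.name}" for f in dataclasses.fields(synth.SynthConfig)
} | {f"model_{f.name}" for f in dataclasses.fields(TriageConfig)}
_METHOD_KEYS = _COMMON_KEYS | {
    f"synth_{f.name}" for f in dataclasses.fields(synth.MethodSynthConfig)
} | {f"model_{f.name}" for f in dataclasses.fields(PassageClassifierConfig)}


def _check_schema(cfg: dict):
    task = cfg.get("task")
    if task not in ("triage", "method"):
        raise ConfigError("config key 'task' must be 'triage' or 'method'")
    allowed = _TRIAGE_KEYS if task == "triage" else _METHOD_KEYS
    bad = sorted(set(cfg) - allowed)
    if bad:
        raise ConfigError(f"unknown config keys for task {task!r}: {bad}")


def _sub(cfg: dict, prefix: str) -> dict:
    out = {}
    for k, v in cfg.items():
        if k.startswith(prefix):
            if isinstance(v, list):
                v = tuple(v)
            out[k[len(prefix):]] = v
    return out


def run_experiment(config: Union[str, Path, dict],
                   outdir: Union[str, Path, None] = None) -> ExperimentReport:
    """Run one fully seeded experiment from a flat config; persist artifacts.

    Artifacts (when an outdir is given): ``report.json``, a Table-style
    ``results.tsv`` row, and for triage an ``attention.jsonl`` dump of
    per-passage weights on the held-out documents.
    """
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict):
            raise ConfigError("config file must hold a flat mapping")
    else:
        cfg = dict(config)
    _check_schema(cfg)

    seed = int(cfg.get("seed", 0))
    n_restarts = int(cfg.get("n_restarts", 3))
    dim = int(cfg.get("embedding_dim", 16))
    oov = cfg.get("oov_policy", "zero")
    outdir = Path(outdir or cfg.get("outdir", "")) if (outdir or cfg.get("outdir")) else None
    started = time.strftime("%Y-%m-%dT%H:%M:%S")

    emb_path = cfg.get("embedding_path")
    if emb_path is not None and not Path(emb_path).exists():
        raise FileNotFoundError(f"embedding file not found: {emb_path}")

    if cfg["task"] == "triage":
        scfg = synth.SynthConfig(**{"seed": seed, **_sub(cfg, "synth_")})
        mcfg = TriageConfig(**{"seed": seed, **_sub(cfg, "model_")})
        docs, labels = synth.generate_triage_corpus(scfg)
        if emb_path is not None:
            from .embeddings import load_word_vectors
            table = load_word_vectors(emb_path, oov_policy=oov)
        else:
            table = synth.toy_embedding_table(synth.triage_vocabulary(scfg),
                                              dim, seed + 7, oov_policy=oov)
        result, models, (tr_idx, te_idx) = evaluate_triage_multirestart(
            docs, labels, mcfg, n_restarts, table, return_models=True)
        classes = ["negative", "positive"]
        model_name = result.model_configuration
        defaults = {
            "optimizer": "adam", "learning_rate": mcfg.learning_rate,
            "batch_size": mcfg.batch_size,
            "early_stopping_patience": mcfg.early_stopping_patience,
            "split": "stratified 70/15/15 by document, seeded",
            "encoder": mcfg.effective_encoder,
            "conv_filters": mcfg.conv_filters, "lstm_units": mcfg.lstm_units,
            "attention_width": mcfg.attention_width,
            "max_passages": mcfg.max_passages, "max_len": mcfg.max_len,
            "embedding_dim": dim, "embeddings_trainable": False,
        }
        accs, seeds = result.accuracies, result.seeds
        confusion = result.confusion
        if outdir:
            outdir.mkdir(parents=True, exist_ok=True)
            with open(outdir / "attention.jsonl", "w", encoding="utf-8") as fh:
                model = models[-1]
                for i in te_idx:
                    _, att = classify_document(model, docs[i])
                    passages = select_passages(docs[i], mcfg.text_source,
                                               max_passages=mcfg.max_passages)
                    for j, (p, w) in enumerate(zip(passages, att.weights)):
                        fh.write(json.dumps({
                            "doc_id": docs[i].doc_id, "passage_index": j,
                            "kind": p.kind.value, "weight": float(w)}) + "\n")
    else:
        scfg = synth.MethodSynthConfig(**{"seed": seed, **_sub(cfg, "synth_")})
        mcfg = PassageClassifierConfig(**{"seed": seed, **_sub(cfg, "model_")})
        dataset, scheme = synth.generate_method_corpus(scfg)
        if emb_path is not None:
            from .embeddings import load_word_vectors
            table = load_word_vectors(emb_path, oov_policy=oov)
        else:
            table = synth.toy_embedding_table(synth.method_vocabulary(scfg),
                                              dim, seed + 7, oov_policy=oov)
        result = evaluate_multirestart(dataset, mcfg, n_restarts, table)
        classes = result.classes
        model_name = mcfg.arch.upper()
        defaults = {
            "optimizer": "adam", "learning_rate": mcfg.learning_rate,
            "batch_size": mcfg.batch_size,
            "early_stopping_patience": mcfg.early_stopping_patience,
            "split": "stratified 70/15/15 by passage, seeded",
            "conv_filters": mcfg.conv_filters,
            "conv_filter_widths": list(mcfg.conv_filter_widths),
            "lstm_units": mcfg.lstm_units, "dense_width": mcfg.dense_width,
            "max_len": mcfg.max_len, "embedding_dim": dim,
            "embeddings_trainable": mcfg.trainable_embeddings,
            "label_scheme": scheme.name,
        }
        accs, seeds = result.accuracies, result.seeds
        confusion = result.confusion

    report = ExperimentReport(
        task=cfg["task"], config={k: (list(v) if isinstance(v, tuple) else v)
                                  for k, v in cfg.items()},
        seeds=list(seeds), accuracies=[float(a) for a in accs],
        mean=float(np.mean(accs)),
        std=0.0 if len(accs) < 2 else float(np.std(accs, ddof=1)),
        confusion=np.asarray(confusion).tolist(), classes=list(classes),
        defaults_recorded=defaults, started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"))
    report.validate()

    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(report.to_json(), encoding="utf-8")
        source = (mcfg.text_source.value if cfg["task"] == "triage"
                  else "captions")
        with open(outdir / "results.tsv", "w", encoding="utf-8") as fh:
            fh.write("text_source\tmodel_configuration\taccuracy_mean\t"
                     "accuracy_std\tn_restarts\n")
            fh.write(f"{source}\t{model_name}\t{report.mean:.4f}\t"
                     f"{report.std:.4f}\t{len(accs)}\n")
    return report
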