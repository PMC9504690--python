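"""End-to-end pipeline: train -> validate -> refine -> screen -> rank.

Fully ligand-based automation with explicit sanity gates: a QPhAR model
is trained on a labelled training set, validated on a held-out test set
against configurable thresholds (minimum R², maximum RMSE), the
refinement hyperparameter space is searched with top-5 test validation,
the best query screens the library, and hits are ranked by predicted
activity.  Every stage logs its inputs, a config hash and outputs as
JSON lines; all artifacts are pure functions of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import screen_metrics as sm
from .pharm_core import read_samples, write_pharmacophore
from .qphar_model import QpharRegressor
from .refine import grid_search

__all__ = ["WorkflowConfig", "GateFailure", "run_end_to_end", "load_config"]


class GateFailure(RuntimeError):
    """A sanity gate rejected the pipeline state; carries the gate report."""

    def __init__(self, stage: str, report: dict):
        super().__init__(f"gate failure at stage {stage!r}: {report}")
        self.stage = stage
        self.report = report


@dataclass
class WorkflowConfig:
    train_path: str
    test_path: str
    library_path: str
    out_dir: str
    min_r2: float = 0.5
    max_rmse: float = 2.0
    beta: float = 0.5
    percentile: float = 20.0
    top_k: int = 5
    seed: int = 0
    rf_n_estimators: int = 100
    merge_radius: float = 1.5
    library_labels_path: str | None = None  # optional ground-truth flags (JSON list)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path) -> WorkflowConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return WorkflowConfig(**raw)


class _StageLogger:
    def __init__(self, path: Path, config_hash: str):
        self.path = path
        self.config_hash = config_hash
        self.path.write_text("")

    def log(self, stage: str, **payload) -> None:
        rec = {"stage": stage, "config_hash": self.config_hash, **payload}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")


def run_end_to_end(cfg: WorkflowConfig) -> dict:
    """Run the full pipeline; returns a manifest of produced artifacts.

    Raises :class:`GateFailure` when model validation misses the
    configured thresholds; stage errors propagate annotated with the
    stage name.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _StageLogger(out / "run_log.jsonl", cfg.config_hash())

    def stage(name):
        log.log(name, event="start", t=time.time())

    try:
        stage("load")
        train = read_samples(cfg.train_path)
        test = read_samples(cfg.test_path)
        library = read_samples(cfg.library_path)
        log.log("load", event="done", n_train=len(train), n_test=len(test), n_library=len(library))

        stage("train")
        model = QpharRegressor(
            merge_radius=cfg.merge_radius,
            n_estimators=cfg.rf_n_estimators,
            random_state=cfg.seed,
        ).fit(train)
        model.save(out / "model_bundle")
        log.log("train", event="done", n_model_features=len(model.model_features_))

        stage("validate")
        scores = model.score_report(test)
        (out / "validation.json").write_text(json.dumps(scores, indent=2) + "\n")
        log.log("validate", event="done", **scores)
        if scores["r2"] < cfg.min_r2 or scores["rmse"] > cfg.max_rmse:
            report = {
                "r2": scores["r2"],
                "rmse": scores["rmse"],
                "min_r2": cfg.min_r2,
                "max_rmse": cfg.max_rmse,
            }
            (out / "gate_report.json").write_text(json.dumps(report, indent=2) + "\n")
            log.log("validate", event="gate_failure", **report)
            raise GateFailure("validate", report)

        stage("gridsearch")
        audit = grid_search(
            train, test, model, percentile=cfg.percentile, beta=cfg.beta, top_k=cfg.top_k
        )
        queries = audit.attrs["queries"]
        audit.to_csv(out / "gridsearch_audit.csv", index=False)
        validated = audit[audit["rank_train"] <= cfg.top_k]
        best_row = validated.sort_values(
            by=["f_composite_test", "rank_train"], ascending=[False, True], kind="stable"
        ).iloc[0]
        best_query = queries[int(best_row["order"])]
        if not best_query.non_xv():
            report = {"reason": "selected refined query has no features"}
            (out / "gate_report.json").write_text(json.dumps(report, indent=2) + "\n")
            raise GateFailure("gridsearch", report)
        write_pharmacophore(best_query, out / "refined.json")
        log.log(
            "gridsearch",
            event="done",
            selected_order=int(best_row["order"]),
            f_composite_test=float(best_row["f_composite_test"]),
        )

        stage("screen")
        labels = None
        if cfg.library_labels_path:
            labels = [bool(x) for x in json.loads(Path(cfg.library_labels_path).read_text())]
        report = sm.screen_report(best_query, library, labels=labels, model=model, beta=cfg.beta)
        screen_payload = {
            "query": report.query_name,
            "n_library": len(library),
            "n_hits": sum(report.flags),
            "counts": asdict(report.counts) if labels is not None else None,
            "f_beta": report.f_beta if labels is not None else None,
            "f_specificity": report.f_specificity if labels is not None else None,
            "f_composite": report.f_composite if labels is not None else None,
        }
        (out / "screen_report.json").write_text(json.dumps(screen_payload, indent=2) + "\n")
        log.log("screen", event="done", n_hits=sum(report.flags))

        stage("rank")
        with open(out / "ranked_hits.csv", "w") as fh:
            fh.write("rank,ligand_id,predicted_activity\n")
            for rank, (lid, pred) in enumerate(report.ranked_hits, start=1):
                fh.write(f"{rank},{lid},{pred:.6f}\n")
        log.log("rank", event="done", n_ranked=len(report.ranked_hits))

    except GateFailure:
        raise
    except Exception as exc:
        raise RuntimeError(f"workflow stage failed: {exc}") from exc

    manifest = {
        "config_hash": cfg.config_hash(),
        "artifacts": [
            "model_bundle",
            "validation.json",
            "gridsearch_audit.csv",
            "refined.json",
            "screen_report.json",
            "ranked_hits.csv",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
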