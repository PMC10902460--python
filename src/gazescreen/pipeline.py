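"""End-to-end orchestration: simulate -> extract -> select -> train -> evaluate.

A single master seed determines every stage's randomness: per-stage seeds
are derived as ``sha256(f"{master_seed}:{stage}") mod 2**31``, so stages
can be re-run independently and the whole pipeline is byte-reproducible.
Every command writes its artifacts plus a manifest (config, derived seeds,
package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__ as _version
from .features import FeatureTable
from .io import write_subject_table
from .paradigms import build_timeline, timeline_to_json
from .qc import filter_cohort
from .screening import ScreeningModel
from .selection import select_all_tasks
from .synth import CohortSpec, packaged_params, sample_feature_table, sample_subject_records
from .tables import ENROLLMENT_LEDGER, STAGE_SCHEMAS, STAGE1_TASK_COUNTS

__all__ = ["PipelineConfig", "stage_seed", "run", "COMMANDS"]

log = logging.getLogger(__name__)

COMMANDS = ("simulate", "extract", "select", "train", "evaluate",
            "replicate-tables", "all")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    out_dir: str = "gazescreen_out"
    master_seed: int = 0
    n_adhd: int = 56
    n_tdc: int = 79
    stages: tuple = ("stage1", "ata_only", "stroop_only", "ata_stroop", "stage3")
    selection: dict = field(default_factory=lambda: {
        "replicate": True, "n_trees": 400, "step": 1, "folds": 5})
    modeling: dict = field(default_factory=lambda: {
        "folds": 5, "n_estimators": 400, "max_depth": 5})
    correlation: str = "independent"
    factor_loading: float = 0.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["stages"] = list(data["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _write_manifest(out: Path, config: PipelineConfig, stages_run: list[str]) -> None:
    manifest = {
        "version": _version,
        "master_seed": config.master_seed,
        "stage_seeds": {s: stage_seed(config.master_seed, s) for s in
                        ("simulate", "select", "train", "evaluate")},
        "config": dataclasses.asdict(config) | {"stages": list(config.stages)},
        "commands": stages_run,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _simulate(config: PipelineConfig, out: Path) -> None:
    seed = stage_seed(config.master_seed, "simulate")
    spec = CohortSpec(params=packaged_params(), seed=seed,
                      correlation=config.correlation,
                      factor_loading=config.factor_loading,
                      n_per_group={"ADHD": config.n_adhd, "TDC": config.n_tdc})
    table = sample_feature_table(spec)
    records = sample_subject_records(spec)
    table.to_csv(out / "features.csv")
    write_subject_table(records, out / "subjects.csv")
    for task in ("PST", "AST", "MGST", "CDT", "STROOP"):
        tl = build_timeline(task, stage_seed(config.master_seed, f"timeline:{task}"))
        (out / f"timeline_{task}.json").write_text(timeline_to_json(tl))
    log.info("simulate: %d subjects x 5 tasks", config.n_adhd + config.n_tdc)


def _extract(config: PipelineConfig, out: Path) -> None:
    # in the synthetic features-only pipeline, extraction is the identity on
    # the simulated feature table; kept as a stage so stream-based cohorts
    # can slot in (see gazescreen.synth.simulate_cohort_streams)
    src = out / "features.csv"
    if not src.exists():
        raise FileNotFoundError("run 'simulate' before 'extract'")
    FeatureTable.from_csv(src).wide().to_csv(out / "features_wide.csv")


def _select(config: PipelineConfig, out: Path) -> None:
    seed = stage_seed(config.master_seed, "select")
    table = FeatureTable.from_csv(out / "features.csv")
    wide = table.wide()
    y = table.labels.reindex(wide.index).map({"ADHD": 1, "TDC": 0}).to_numpy()
    sel = config.selection
    schema, traces = select_all_tasks(
        wide, y, replicate=sel.get("replicate", True), step=sel.get("step", 1),
        n_trees=sel.get("n_trees", 400), folds=sel.get("folds", 5), seed=seed)
    (out / "schema_stage1.json").write_text(json.dumps(
        {"schema": list(schema), "seed": seed, "replicate": sel.get("replicate", True)},
        indent=1))
    for task, tr in traces.items():
        tr.to_frame().to_csv(out / f"selection_trace_{task}.csv", index=False)


def _train_evaluate(config: PipelineConfig, out: Path, evaluate: bool) -> None:
    from .screening import default_members
    from .io import read_subject_table

    seed = stage_seed(config.master_seed, "train")
    table = FeatureTable.from_csv(out / "features.csv")
    records = read_subject_table(out / "subjects.csv")
    rows = []
    preds_by_stage = {}
    members_cfg = config.modeling
    for stage in config.stages:
        members = default_members(members_cfg.get("n_estimators", 400),
                                  members_cfg.get("max_depth", 5))
        model = ScreeningModel.from_feature_table(
            stage, table, records, members=members,
            folds=members_cfg.get("folds", 5))
        res = model.fit(seed=seed)
        preds_by_stage[stage] = res
        res.predictions.to_frame().to_csv(out / f"predictions_{stage}.csv", index=False)
        rows.append({"stage": stage, "n": res.predictions.labels.size,
                     "dummy_accuracy": res.dummy_accuracy, **res.metrics.to_dict()})
        log.info("train: stage %s fitted (n=%d)", stage, res.predictions.labels.size)
    pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
    if evaluate and "stage1" in preds_by_stage:
        base = preds_by_stage["stage1"]
        comp_rows = []
        for stage, res in preds_by_stage.items():
            if stage == "stage1":
                continue
            try:
                c = res.compare(base)
            except ValueError:
                continue   # different complete-case subjects
            comp_rows.append({"stage": stage, "vs": "stage1", "U": c.statistic,
                              "p_value": c.p_value, "auc": c.auc_a,
                              "auc_stage1": c.auc_b, "method": c.method})
        pd.DataFrame(comp_rows).to_csv(out / "stage_comparisons.csv", index=False)
        base.roc_curve().to_csv(out / "roc_stage1.csv", index=False)


def _replicate_tables(config: PipelineConfig, out: Path) -> None:
    """Regenerate the structural worked examples from packaged transcriptions."""
    payload = {
        "stage_widths": {k: len(v) for k, v in STAGE_SCHEMAS.items()},
        "per_task_selected": dict(STAGE1_TASK_COUNTS),
        "candidate_features_per_task": 20,
        "enrollment": filter_cohort(dict(ENROLLMENT_LEDGER)),
        "trial_counts": {"PST": 30, "AST": 48, "MGST": 36, "CDT": 15, "STROOP": 40},
    }
    (out / "replicated_tables.json").write_text(json.dumps(payload, indent=1, sort_keys=True))


def run(command: str, config: PipelineConfig) -> Path:
    """Execute one pipeline command (or ``all``); returns the output dir."""
    if command not in COMMANDS:
        raise ValueError(f"unknown command {command!r}; choose from {COMMANDS}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    steps = (["simulate", "extract", "select", "train", "evaluate"]
             if command == "all" else [command])
    t0 = time.time()
    for step in steps:
        ts = time.time()
        if step == "simulate":
            _simulate(config, out)
        elif step == "extract":
            _extract(config, out)
        elif step == "select":
            _select(config, out)
        elif step == "train":
            _train_evaluate(config, out, evaluate=False)
        elif step == "evaluate":
            _train_evaluate(config, out, evaluate=True)
        elif step == "replicate-tables":
            _replicate_tables(config, out)
        log.info("%s finished in %.1fs", step, time.time() - ts)
    config.to_yaml(out / "config.yaml")
    _write_manifest(out, config, steps)
    log.info("pipeline done in %.1fs", time.time() - t0)
    return out
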