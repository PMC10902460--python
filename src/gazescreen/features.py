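"""The 20 per-task eye-tracking features and the staged model schemas.

Units are artifact conventions chosen so that packaged cohort parameters and
extracted values live on the same scale: event durations, latencies and
screen times in seconds; saccade amplitude ("degree") in visual degrees;
gaze coordinates in pixels centred on the screen centre.  Standard
deviations use the sample (n-1) convention throughout, consistent with the
synthetic generator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from .events import EventTrain, trial_latencies
from .geometry import degrees_to_pixels
from .io import GazeRecording, SubjectRecord, TASK_IDS
from .paradigms import TaskTimeline
from .tables import FEATURE_NAMES, STAGE_SCHEMAS

__all__ = ["FeatureVector", "FeatureTable", "extract_features",
           "build_feature_table", "assemble_stage", "stage_schema"]

log = logging.getLogger(__name__)


@dataclass
class FeatureVector:
    """The 20 canonical eye-tracking features for one subject x task."""

    saccade_degree_mean: float = 0.0
    saccade_degree_sd: float = 0.0
    saccade_degree_total: float = 0.0
    saccade_latency_mean: float = math.nan   # NaN when no trial recovered a latency
    saccade_latency_sd: float = math.nan
    saccade_latency_total: float = 0.0
    saccade_count: float = 0.0
    saccade_mean: float = 0.0
    saccade_duration: float = 0.0
    saccade_time_max: float = 0.0
    fixation_count: float = 0.0
    fixation_mean: float = 0.0
    fixation_duration: float = 0.0
    fixation_time_max: float = 0.0
    coordinate_x_mean: float = 0.0
    coordinate_y_mean: float = 0.0
    screen_duration_mean: float = 0.0
    screen_duration_total: float = 0.0
    hit_count: float = 0.0
    total_elapsed_time: float = 0.0
    diagnostics: dict = field(default_factory=dict, compare=False)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)
                if f.name != "diagnostics"}


def _agg(values: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, sample sd, total, max) of a non-empty array; zeros if empty."""
    if values.size == 0:
        return 0.0, 0.0, 0.0, 0.0
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd, float(values.sum()), float(values.max())


def _screen_segments(rec: GazeRecording) -> np.ndarray:
    """Durations (ms) of on-screen valid-gaze segments.

    A segment is a maximal run of valid, on-screen samples; invalid or
    off-screen samples break segments.  A segment's duration is the span
    from its first to its last sample (interior sample-free gaps included).
    """
    g = rec.geometry
    ok = rec.valid & (rec.x >= 0) & (rec.x < g.width_px) & (rec.y >= 0) & (rec.y < g.height_px)
    if not ok.any():
        return np.empty(0)
    idx = np.flatnonzero(np.diff(ok.astype(np.int8)))
    bounds = np.concatenate(([0], idx + 1, [ok.size]))
    durs = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if ok[s]:
            durs.append(rec.t[e - 1] - rec.t[s])
    return np.asarray(durs, dtype=float)


def extract_features(rec: GazeRecording, events: EventTrain, timeline: TaskTimeline,
                     aoi_radius_px: float | None = None,
                     hit_aoi_deg: float = 2.5) -> FeatureVector:
    """Compute the 20 features from a recording's detected event train.

    ``hit_count`` counts trials during which some fixation centroid fell
    within the trial's hit AOI (the target for PST/MGST, the mirrored
    location for AST, the correct-answer location for CDT/Stroop).
    """
    fv = FeatureVector()
    fix = events.fixations
    sac = events.saccades

    fd = np.array([f.duration_ms for f in fix]) / 1000.0
    fv.fixation_count = float(len(fix))
    fv.fixation_mean, _, fv.fixation_duration, fv.fixation_time_max = _agg(fd)

    sd_ = np.array([s.duration_ms for s in sac]) / 1000.0
    fv.saccade_count = float(len(sac))
    fv.saccade_mean, _, fv.saccade_duration, fv.saccade_time_max = _agg(sd_)

    amps = np.array([s.amplitude_deg for s in sac])
    fv.saccade_degree_mean, fv.saccade_degree_sd, fv.saccade_degree_total, _ = _agg(amps)

    lats_ms = trial_latencies(events, timeline, aoi_radius_px)
    lats = np.array([v for v in lats_ms if v is not None], dtype=float) / 1000.0
    if lats.size:
        fv.saccade_latency_mean = float(lats.mean())
        fv.saccade_latency_sd = float(lats.std(ddof=1)) if lats.size > 1 else 0.0
        fv.saccade_latency_total = float(lats.sum())
    fv.diagnostics["n_latency_trials"] = int(lats.size)
    fv.diagnostics["n_missing_latency"] = sum(1 for v in lats_ms if v is None)

    if rec.valid.any():
        cx, cy = rec.geometry.center
        fv.coordinate_x_mean = float(rec.x[rec.valid].mean()) - cx
        fv.coordinate_y_mean = float(rec.y[rec.valid].mean()) - cy

    segs = _screen_segments(rec) / 1000.0
    fv.screen_duration_mean, _, fv.screen_duration_total, _ = _agg(segs)

    hit_r = degrees_to_pixels(hit_aoi_deg, rec.geometry)
    hits = 0
    for info in timeline.trial_info():
        pos = info["hit_pos"]
        if pos is None:
            continue
        hx, hy = pos
        for f in fix:
            if f.end_ms < info["gov_onset"] or f.start_ms >= info["window_end"]:
                continue
            if (f.cx - hx) ** 2 + (f.cy - hy) ** 2 <= hit_r * hit_r:
                hits += 1
                break
    fv.hit_count = float(hits)

    fv.total_elapsed_time = rec.span_ms / 1000.0
    return fv


# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Long-format table: one row per (subject, task), the 20 feature columns,
    plus the per-subject group label."""

    data: pd.DataFrame                 # MultiIndex (subject_id, task_id)
    labels: pd.Series                  # subject_id -> group

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate (subject, task) rows")

    def wide(self) -> pd.DataFrame:
        """Pivot to one row per subject, columns named ``{task}__{feature}``."""
        w = self.data.unstack("task_id")
        w.columns = [f"{task}__{feat}" for feat, task in w.columns]
        order = [f"{t}__{f}" for t in TASK_IDS for f in FEATURE_NAMES
                 if f"{t}__{f}" in w.columns]
        return w[order]

    def to_csv(self, path) -> None:
        out = self.data.reset_index()
        out["group"] = out["subject_id"].map(self.labels)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path)
        labels = df.drop_duplicates("subject_id").set_index("subject_id")["group"]
        data = df.drop(columns=["group"]).set_index(["subject_id", "task_id"])
        return cls(data[list(FEATURE_NAMES)], labels)

    @classmethod
    def from_vectors(cls, rows: dict[tuple[str, str], FeatureVector],
                     labels: dict[str, str]) -> "FeatureTable":
        idx = pd.MultiIndex.from_tuples(rows.keys(), names=["subject_id", "task_id"])
        data = pd.DataFrame([fv.as_dict() for fv in rows.values()], index=idx,
                            columns=list(FEATURE_NAMES))
        return cls(data, pd.Series(labels, name="group"))


def build_feature_table(cohort, labels: dict[str, str]) -> FeatureTable:
    """Extract features for a cohort of ``(recording, events, timeline)``
    triples.  Subjects missing a task simply lack that row (logged)."""
    rows: dict[tuple[str, str], FeatureVector] = {}
    for rec, events, timeline in cohort:
        key = (rec.subject_id, rec.task_id)
        if key in rows:
            raise ValueError(f"duplicate subject-task pair {key}")
        rows[key] = extract_features(rec, events, timeline)
    by_subject: dict[str, set[str]] = {}
    for sid, task in rows:
        by_subject.setdefault(sid, set()).add(task)
    for sid, tasks in by_subject.items():
        missing = set(TASK_IDS) - tasks
        if missing:
            log.warning("subject %s missing tasks %s", sid, sorted(missing))
    return FeatureTable.from_vectors(rows, labels)


def stage_schema(stage) -> tuple[str, ...]:
    """Resolve a stage identifier to its ordered feature-name schema."""
    aliases = {1: "stage1", "1": "stage1", 3: "stage3", "3": "stage3",
               "ATA_ONLY": "ata_only", "STROOP_ONLY": "stroop_only",
               "ATA_STROOP": "ata_stroop"}
    key = aliases.get(stage, stage)
    if key not in STAGE_SCHEMAS:
        raise ValueError(f"unknown stage {stage!r}; choose from {sorted(STAGE_SCHEMAS)}")
    return tuple(STAGE_SCHEMAS[key])


def assemble_stage(stage, eye_table: FeatureTable | pd.DataFrame | None,
                   subject_records: list[SubjectRecord] | None = None,
                   complete_case: bool = True):
    """Build the model-ready matrix and labels for one analysis stage.

    Stage 1 uses the 33 retained eye-tracking features; the stage-2 variants
    use ATA and/or Stroop T-scores; stage 3 concatenates eye-tracking,
    demographic (age, sex with M=1/F=0, IQ), behavioral and clinical
    features (width 75).  For stages that need scores, subjects with any
    missing required score are dropped casewise when ``complete_case``
    (mirroring the published complete-case subsample).

    Returns ``(X, y)``: a DataFrame with exactly the stage's schema width
    and a Series of group labels (ADHD=1, TDC=0).
    """
    schema = stage_schema(stage)
    needs_eye = any("__" in c for c in schema)
    needs_scores = any("__" not in c for c in schema)

    parts = []
    labels = None
    if needs_eye:
        if eye_table is None:
            raise ValueError(f"stage {stage!r} requires an eye-tracking feature table")
        wide = eye_table.wide() if isinstance(eye_table, FeatureTable) else eye_table
        missing = [c for c in schema if "__" in c and c not in wide.columns]
        if missing:
            raise ValueError(f"eye table lacks required columns {missing[:5]}...")
        parts.append(wide[[c for c in schema if "__" in c]])
        if isinstance(eye_table, FeatureTable):
            labels = eye_table.labels
    if needs_scores:
        if not subject_records:
            raise ValueError(f"stage {stage!r} requires subject records")
        rows = {}
        for r in subject_records:
            row = {}
            for name in schema:
                if "__" in name:
                    continue
                if name == "age":
                    row[name] = r.age
                elif name == "sex":
                    row[name] = 1.0 if r.sex == "M" else 0.0
                elif name == "iq":
                    row[name] = r.iq
                else:
                    row[name] = r.score(name)
            rows[r.subject_id] = row
        parts.append(pd.DataFrame.from_dict(rows, orient="index"))
    if labels is None:
        if not subject_records:
            raise ValueError("labels unavailable: provide subject_records or a FeatureTable")
        labels = pd.Series({r.subject_id: r.group for r in subject_records})

    X = pd.concat(parts, axis=1, join="inner")
    X = X[list(schema)]
    assert X.shape[1] == len(schema), "stage schema width mismatch"
    if complete_case:
        X = X.dropna(axis=0, how="any")
    y = labels.reindex(X.index).map({"ADHD": 1, "TDC": 0}).astype(int)
    return X, y
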