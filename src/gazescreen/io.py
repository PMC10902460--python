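"""Core data containers and delimited-text readers/writers.

A gaze recording is stored as parallel NumPy arrays (timestamps in
milliseconds, x/y in screen pixels, a validity flag per sample) rather than
per-sample objects, so that event detection over recordings with hundreds of
thousands of samples stays vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import DEFAULT_GEOMETRY, ScreenGeometry

__all__ = [
    "TASK_IDS",
    "GazeRecording",
    "SubjectRecord",
    "GazeFormatError",
    "EmptyRecordingError",
    "read_gaze_stream",
    "write_gaze_stream",
    "read_subject_table",
    "write_subject_table",
]

#: The five serial task paradigms, in administration order.
TASK_IDS = ("PST", "AST", "MGST", "CDT", "STROOP")

GAZE_COLUMNS = ("t_ms", "x_px", "y_px", "valid")


class GazeFormatError(ValueError):
    """Raised when a delimited gaze file does not have the expected columns."""


class EmptyRecordingError(ValueError):
    """Raised when a gaze file contains no samples."""


@dataclass
class GazeRecording:
    """Time-ordered 2D gaze samples for one subject performing one task.

    Invariants: timestamps strictly increasing; at least 2 samples are
    required by downstream event detection; ``task_id`` drawn from
    :data:`TASK_IDS`.
    """

    subject_id: str
    task_id: str
    t: np.ndarray          # milliseconds from recording start, float64
    x: np.ndarray          # pixels
    y: np.ndarray
    valid: np.ndarray      # bool
    geometry: ScreenGeometry = field(default_factory=lambda: DEFAULT_GEOMETRY)
    nominal_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        if self.task_id not in TASK_IDS:
            raise ValueError(f"unknown task_id {self.task_id!r}; expected one of {TASK_IDS}")
        self.t = np.asarray(self.t, dtype=np.float64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t.size
        if not (self.x.size == self.y.size == self.valid.size == n):
            raise ValueError("sample arrays must have equal length")
        if n and self.t[0] < 0:
            raise ValueError("timestamps must be non-negative")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def span_ms(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def shifted(self, offset_ms: float) -> "GazeRecording":
        """Copy with all timestamps uniformly translated by ``offset_ms``."""
        return GazeRecording(self.subject_id, self.task_id, self.t + offset_ms,
                             self.x.copy(), self.y.copy(), self.valid.copy(),
                             self.geometry, self.nominal_rate_hz)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_ms": self.t, "x_px": self.x, "y_px": self.y,
                             "valid": self.valid.astype(int)})


@dataclass
class SubjectRecord:
    """Per-subject metadata, clinical scale scores and behavioral T-scores.

    ``clinical_scores`` and ``behavioral_scores`` may be partially missing
    (``NaN``); missingness is preserved and handled casewise at model time,
    never silently imputed.
    """

    subject_id: str
    group: str                       # "ADHD" or "TDC"
    age: float
    sex: str                         # "M" or "F"
    iq: float
    clinical_scores: dict[str, float] = field(default_factory=dict)
    behavioral_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("ADHD", "TDC"):
            raise ValueError(f"group must be ADHD or TDC, got {self.group!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M or F, got {self.sex!r}")

    def score(self, name: str) -> float:
        if name in self.behavioral_scores:
            return self.behavioral_scores[name]
        return self.clinical_scores.get(name, float("nan"))

    def is_complete(self, names) -> bool:
        return all(np.isfinite(self.score(n)) for n in names)


def read_gaze_stream(path, geometry: ScreenGeometry | None = None, *,
                     subject_id: str = "", task_id: str = "PST",
                     nominal_rate_hz: float | None = None) -> GazeRecording:
    """Read a delimited gaze stream (columns ``t_ms,x_px,y_px,valid``).

    Rows are sorted by timestamp; duplicate timestamps are collapsed to the
    last-occurring value.  The nominal sampling rate, if not given, is
    estimated from the median inter-sample interval.
    """
    geometry = geometry or DEFAULT_GEOMETRY
    df = pd.read_csv(path)
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise GazeFormatError(f"gaze stream {path!r} is missing columns {missing}")
    if df.empty:
        raise EmptyRecordingError(f"gaze stream {path!r} contains no samples")
    df = df.sort_values("t_ms", kind="stable").drop_duplicates("t_ms", keep="last")
    t = df["t_ms"].to_numpy(float)
    if nominal_rate_hz is None:
        dt = np.median(np.diff(t)) if t.size > 1 else np.nan
        nominal_rate_hz = float(1000.0 / dt) if np.isfinite(dt) and dt > 0 else 30.0
    return GazeRecording(subject_id=subject_id, task_id=task_id, t=t,
                         x=df["x_px"].to_numpy(float), y=df["y_px"].to_numpy(float),
                         valid=df["valid"].to_numpy().astype(bool),
                         geometry=geometry, nominal_rate_hz=nominal_rate_hz)


def write_gaze_stream(rec: GazeRecording, path) -> None:
    rec.to_frame().to_csv(path, index=False)


# -- subject metadata tables -------------------------------------------------

_META_FIXED = ("subject_id", "group", "age", "sex", "iq")


def write_subject_table(records: list[SubjectRecord], path) -> None:
    """Write subject metadata + scores as one CSV row per subject."""
    score_names: list[str] = []
    for r in records:
        for name in list(r.behavioral_scores) + list(r.clinical_scores):
            if name not in score_names:
                score_names.append(name)
    rows = []
    for r in records:
        row: dict[str, object] = {"subject_id": r.subject_id, "group": r.group,
                                  "age": r.age, "sex": r.sex, "iq": r.iq}
        for name in score_names:
            row[name] = r.score(name)
        rows.append(row)
    pd.DataFrame(rows, columns=list(_META_FIXED) + score_names).to_csv(path, index=False)


def read_subject_table(path, behavioral_names=None) -> list[SubjectRecord]:
    """Inverse of :func:`write_subject_table`.

    ``behavioral_names`` lists which score columns belong in
    ``behavioral_scores``; all other score columns are treated as clinical.
    """
    from .tables import BEHAVIORAL_SCORE_NAMES  # local import avoids a cycle

    behavioral_names = set(behavioral_names or BEHAVIORAL_SCORE_NAMES)
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        behav = {c: float(row[c]) for c in df.columns if c in behavioral_names}
        clin = {c: float(row[c]) for c in df.columns
                if c not in behavioral_names and c not in _META_FIXED}
        records.append(SubjectRecord(str(row["subject_id"]), row["group"],
                                     float(row["age"]), row["sex"], float(row["iq"]),
                                     clinical_scores=clin, behavioral_scores=behav))
    return records
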