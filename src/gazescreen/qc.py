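"""Recording-level quality control and cohort enrollment accounting.

Mirrors the study's exclusion rules: recordings whose coordinates remain
stalled at a fixed point (frozen tracker) and recordings whose gaze
reference is off-screen are excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GazeRecording

__all__ = ["QCResult", "qc_recording", "filter_cohort", "write_qc_report",
           "LedgerInconsistencyError"]

QC_FLAGS = ("STALLED_COORDINATES", "OFFSCREEN_REFERENCE", "INCOMPLETE")


@dataclass
class QCResult:
    subject_id: str
    task_id: str
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def excluded(self) -> bool:
        return bool(self.flags)


def _has_stalled_window(t: np.ndarray, x: np.ndarray, y: np.ndarray,
                        window_ms: float, eps_px: float) -> bool:
    """True if some contiguous sample run spanning >= window_ms has both
    coordinate ranges <= eps_px."""
    n = t.size
    i = 0
    while i < n:
        # extend j while the bounding box of [i..j] stays within eps
        xlo = xhi = x[i]
        ylo = yhi = y[i]
        j = i
        while j + 1 < n:
            nx, ny = x[j + 1], y[j + 1]
            if (max(xhi, nx) - min(xlo, nx) > eps_px
                    or max(yhi, ny) - min(ylo, ny) > eps_px):
                break
            j += 1
            xlo, xhi = min(xlo, nx), max(xhi, nx)
            ylo, yhi = min(ylo, ny), max(yhi, ny)
        if t[j] - t[i] >= window_ms:
            return True
        i = j + 1
    return False


def qc_recording(rec: GazeRecording, stall_window_ms: float = 2000.0,
                 stall_epsilon_px: float = 1.0) -> QCResult:
    """Flag a recording that a human rater would have discarded.

    ``STALLED_COORDINATES``: some contiguous window of at least
    ``stall_window_ms`` during which both coordinates move by at most
    ``stall_epsilon_px`` (a frozen tracker; real fixational gaze jitters by
    more than a pixel).  ``OFFSCREEN_REFERENCE``: the centroid of the valid
    samples lies outside the screen bounds.  Degenerate recordings (fewer
    than 2 samples, or no valid samples) are flagged ``INCOMPLETE``.
    """
    flags = set()
    valid = rec.valid
    if len(rec) < 2 or not valid.any():
        return QCResult(rec.subject_id, rec.task_id, frozenset({"INCOMPLETE"}))
    if _has_stalled_window(rec.t, rec.x, rec.y, stall_window_ms, stall_epsilon_px):
        flags.add("STALLED_COORDINATES")
    cx = float(rec.x[valid].mean())
    cy = float(rec.y[valid].mean())
    g = rec.geometry
    if not (0 <= cx < g.width_px and 0 <= cy < g.height_px):
        flags.add("OFFSCREEN_REFERENCE")
    return QCResult(rec.subject_id, rec.task_id, frozenset(flags))


def write_qc_report(results: list[QCResult], path) -> None:
    """One CSV row per subject x task with flags and the exclusion verdict."""
    import pandas as pd

    rows = [{"subject_id": r.subject_id, "task_id": r.task_id,
             "flags": "|".join(sorted(r.flags)), "excluded": r.excluded}
            for r in results]
    pd.DataFrame(rows, columns=["subject_id", "task_id", "flags", "excluded"]
                 ).to_csv(path, index=False)


class LedgerInconsistencyError(ValueError):
    """Raised when exclusion counts exceed the available participants."""


def filter_cohort(enrollment_ledger: dict[str, int],
                  qc_results: list[QCResult] | None = None) -> dict[str, int]:
    """Summarise an enrollment flow: recruited, per-category exclusions,
    and the completing count (recruited minus all exclusions).

    ``qc_results``, if given, contributes an additional ``qc_excluded``
    category counting excluded recordings' subjects.
    """
    ledger = dict(enrollment_ledger)
    if any(v < 0 for v in ledger.values()):
        raise LedgerInconsistencyError("ledger counts must be non-negative")
    if "recruited" not in ledger:
        raise LedgerInconsistencyError("ledger must contain a 'recruited' count")
    if qc_results is not None:
        excluded_subjects = {r.subject_id for r in qc_results if r.excluded}
        ledger.setdefault("qc_excluded", len(excluded_subjects))
    recruited = ledger["recruited"]
    remaining = recruited
    for key, count in ledger.items():
        if key == "recruited":
            continue
        remaining -= count
        if remaining < 0:
            raise LedgerInconsistencyError(
                f"exclusions through {key!r} exceed recruited count ({recruited})")
    out = dict(ledger)
    out["completing"] = remaining
    return out
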