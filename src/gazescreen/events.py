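"""Gaze-event detection: fixations, saccades, and trial-locked latencies.

Fixations follow a dispersion-threshold definition: a maximal run of
consecutive valid samples whose bounding-box diagonal stays within
``dispersion_px`` and whose temporal span is at least ``min_fixation_ms``
(70 ms by default) becomes one fixation, with its centroid at the mean of
the member coordinates.  Invalid samples break runs.  A saccade is the
movement between two consecutive fixations: it spans the inter-fixation
gap and its amplitude is the visual angle between the two centroids.

The scan is greedy and left-to-right (earliest start, maximal extension),
so fixations are pairwise non-overlapping by construction.  The inner
extension loop is chunked over NumPy accumulations so recordings with
hundreds of thousands of samples stay fast.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .geometry import degrees_to_pixels, pixel_to_degrees
from .io import GazeRecording
from .paradigms import TaskTimeline

__all__ = [
    "Fixation", "Saccade", "EventTrain",
    "detect_fixations", "detect_saccades", "detect_events",
    "trial_latencies", "default_dispersion_px", "default_aoi_radius_px",
]

_CHUNK = 4096


@dataclass
class Fixation:
    start_ms: float
    end_ms: float
    cx: float
    cy: float

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.cx, self.cy)


@dataclass
class Saccade:
    start_ms: float
    end_ms: float
    origin: tuple[float, float]
    destination: tuple[float, float]
    amplitude_deg: float
    latency_ms: float | None = None

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass
class EventTrain:
    recording: GazeRecording
    fixations: list[Fixation] = field(default_factory=list)
    saccades: list[Saccade] = field(default_factory=list)

    def to_frame(self):
        """One typed row per event, time-ordered, for inspection/CSV export."""
        import pandas as pd

        rows = []
        for f in self.fixations:
            rows.append({"event": "fixation", "start_ms": f.start_ms,
                         "end_ms": f.end_ms, "x": f.cx, "y": f.cy,
                         "amplitude_deg": np.nan, "latency_ms": np.nan})
        for s in self.saccades:
            rows.append({"event": "saccade", "start_ms": s.start_ms,
                         "end_ms": s.end_ms, "x": s.destination[0],
                         "y": s.destination[1], "amplitude_deg": s.amplitude_deg,
                         "latency_ms": s.latency_ms if s.latency_ms is not None
                         else np.nan})
        df = pd.DataFrame(rows, columns=["event", "start_ms", "end_ms", "x", "y",
                                         "amplitude_deg", "latency_ms"])
        return df.sort_values("start_ms", kind="stable").reset_index(drop=True)


def default_dispersion_px(geometry) -> float:
    """Dispersion threshold equivalent to 1 degree of visual angle."""
    return degrees_to_pixels(1.0, geometry)


def default_aoi_radius_px(geometry) -> float:
    """Fixation-point AOI radius equivalent to 2 degrees of visual angle."""
    return degrees_to_pixels(2.0, geometry)


def _extend_run(x: np.ndarray, y: np.ndarray, i: int, end: int, disp: float) -> int:
    """Largest j in [i, end) with bbox diagonal of samples i..j <= disp."""
    xlo = xhi = x[i]
    ylo = yhi = y[i]
    disp2 = disp * disp
    pos = i + 1
    j = i
    while pos < end:
        hi = min(end, pos + _CHUNK)
        cxhi = np.maximum.accumulate(np.maximum(x[pos:hi], xhi))
        cxlo = np.minimum.accumulate(np.minimum(x[pos:hi], xlo))
        cyhi = np.maximum.accumulate(np.maximum(y[pos:hi], yhi))
        cylo = np.minimum.accumulate(np.minimum(y[pos:hi], ylo))
        dx = cxhi - cxlo
        dy = cyhi - cylo
        bad = dx * dx + dy * dy > disp2
        if bad.any():
            k = int(np.argmax(bad))          # first violating sample
            return pos + k - 1
        j = hi - 1
        xhi, xlo = float(cxhi[-1]), float(cxlo[-1])
        yhi, ylo = float(cyhi[-1]), float(cylo[-1])
        pos = hi
    return j


def detect_fixations(rec: GazeRecording, dispersion_px: float | None = None,
                     min_fixation_ms: float = 70.0) -> list[Fixation]:
    """Dispersion-based fixation detection (greedy maximal-run scan)."""
    if dispersion_px is None:
        dispersion_px = default_dispersion_px(rec.geometry)
    t, x, y, valid = rec.t, rec.x, rec.y, rec.valid
    n = t.size
    fixations: list[Fixation] = []
    # maximal runs of valid samples; invalid samples break runs
    if n == 0 or not valid.any():
        return fixations
    idx = np.flatnonzero(np.diff(valid.astype(np.int8)))
    bounds = np.concatenate(([0], idx + 1, [n]))
    for s, e in zip(bounds[:-1], bounds[1:]):
        if not valid[s]:
            continue
        i = int(s)
        while i < e:
            j = _extend_run(x, y, i, int(e), dispersion_px)
            if t[j] - t[i] >= min_fixation_ms:
                seg = slice(i, j + 1)
                fixations.append(Fixation(float(t[i]), float(t[j]),
                                          float(x[seg].mean()), float(y[seg].mean())))
                i = j + 1
            else:
                i += 1
    return fixations


def detect_saccades(rec: GazeRecording, fixations: list[Fixation]) -> list[Saccade]:
    """One saccade per consecutive fixation pair (k fixations -> k-1 saccades)."""
    saccades = []
    for a, b in zip(fixations[:-1], fixations[1:]):
        amp = pixel_to_degrees(a.centroid, b.centroid, rec.geometry)
        saccades.append(Saccade(a.end_ms, b.start_ms, a.centroid, b.centroid, amp))
    return saccades


def detect_events(rec: GazeRecording, dispersion_px: float | None = None,
                  min_fixation_ms: float = 70.0) -> EventTrain:
    fixations = detect_fixations(rec, dispersion_px, min_fixation_ms)
    return EventTrain(rec, fixations, detect_saccades(rec, fixations))


def trial_latencies(events: EventTrain, timeline: TaskTimeline,
                    aoi_radius_px: float | None = None) -> list[float | None]:
    """Saccade latency per trial, in milliseconds.

    For each trial, the latency is the onset of the first saccade that
    departs the fixation-point AOI (origin inside, destination outside)
    at or after the governing stimulus onset and before the trial window
    closes, minus that onset.  Trials without a qualifying saccade yield
    ``None`` (excluded from aggregates but counted).

    Matching saccades have their ``latency_ms`` field set as a side effect.
    """
    if events.recording.task_id != timeline.task_id:
        raise ValueError("timeline task does not match recording task")
    if aoi_radius_px is None:
        aoi_radius_px = default_aoi_radius_px(events.recording.geometry)
    r2 = aoi_radius_px * aoi_radius_px
    starts = [s.start_ms for s in events.saccades]
    out: list[float | None] = []
    for info in timeline.trial_info():
        fx, fy = info["fp_pos"]
        lat: float | None = None
        k = bisect.bisect_left(starts, info["gov_onset"])
        while k < len(events.saccades):
            s = events.saccades[k]
            if s.start_ms >= info["window_end"]:
                break
            ox, oy = s.origin
            dx_, dy_ = s.destination
            inside = (ox - fx) ** 2 + (oy - fy) ** 2 <= r2
            outside = (dx_ - fx) ** 2 + (dy_ - fy) ** 2 > r2
            if inside and outside:
                lat = s.start_ms - info["gov_onset"]
                s.latency_ms = lat
                break
            k += 1
        out.append(lat)
    return out
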