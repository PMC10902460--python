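"""Stimulus timelines for the five oculomotor task paradigms.

Each builder is deterministic given its seed and reproduces the published
task structure: a 30-trial pro-saccade task with gap/overlap conditions
(200 ms gap), a 48-trial anti-saccade task with trials 5 s apart, a
36-trial memory-guided saccade task (FP 1000 ms, target 500 ms, memory
delay 1000 ms), a 15-pair change detection task (240 ms images separated
by 80 ms blanks, 20 s penalty wait), and a 40-trial Stroop task (5000 ms
stimulus, 2000 ms inter-trial fixation point).

Timings the source protocol leaves open (response windows, condition
ratios, target eccentricities) are configuration defaults, documented in
the methods note.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import DEFAULT_GEOMETRY, ScreenGeometry

__all__ = [
    "StimulusEvent", "TaskTimeline",
    "build_pst", "build_ast", "build_mgst", "build_cdt", "build_stroop",
    "build_timeline", "timeline_to_json", "timeline_from_json",
]

EVENT_KINDS = ("FIXATION_POINT", "TARGET", "IMAGE_PAIR", "STROOP_STIMULUS", "BLANK")

STROOP_COLORS = ("red", "blue", "green", "yellow")


@dataclass
class StimulusEvent:
    kind: str
    onset_ms: float
    duration_ms: float
    trial_index: int
    position: tuple[float, float] | None = None
    side: str | None = None                     # "LEFT" / "RIGHT" where applicable
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.onset_ms < 0:
            raise ValueError("onset_ms must be non-negative")
        if self.duration_ms < 0 or (self.duration_ms == 0 and self.kind != "BLANK"):
            raise ValueError("duration_ms must be positive (BLANK may be 0)")

    @property
    def offset_ms(self) -> float:
        return self.onset_ms + self.duration_ms


@dataclass
class TaskTimeline:
    """Ordered stimulus events for one paradigm run, with provenance."""

    task_id: str
    events: list[StimulusEvent]
    total_duration_ms: float
    config: dict = field(default_factory=dict)
    seed: int | None = None
    geometry: ScreenGeometry = field(default_factory=lambda: DEFAULT_GEOMETRY)

    def __post_init__(self) -> None:
        onsets = [e.onset_ms for e in self.events]
        if onsets != sorted(onsets):
            raise ValueError("events must be ordered by onset")

    @property
    def n_trials(self) -> int:
        return len({e.trial_index for e in self.events})

    def events_of(self, kind: str) -> list[StimulusEvent]:
        return [e for e in self.events if e.kind == kind]

    def trial_starts(self) -> list[float]:
        starts: dict[int, float] = {}
        for e in self.events:
            starts.setdefault(e.trial_index, e.onset_ms)
            starts[e.trial_index] = min(starts[e.trial_index], e.onset_ms)
        return [starts[k] for k in sorted(starts)]

    def governing_events(self) -> list[StimulusEvent]:
        """Per trial, the stimulus whose onset anchors saccade latency.

        PST/AST: the peripheral target; MGST: the GO marker (fixation-point
        offset ending the memory delay); CDT: the first image of the pair;
        Stroop: the word stimulus.
        """
        per_trial: dict[int, StimulusEvent] = {}
        for e in self.events:
            if self.task_id in ("PST", "AST") and e.kind == "TARGET":
                per_trial.setdefault(e.trial_index, e)
            elif self.task_id == "MGST" and e.kind == "BLANK" and e.attributes.get("go"):
                per_trial.setdefault(e.trial_index, e)
            elif self.task_id == "CDT" and e.kind == "IMAGE_PAIR":
                per_trial.setdefault(e.trial_index, e)
            elif self.task_id == "STROOP" and e.kind == "STROOP_STIMULUS":
                per_trial.setdefault(e.trial_index, e)
        return [per_trial[k] for k in sorted(per_trial)]

    def trial_info(self) -> list[dict]:
        """Per-trial scheduling summary: start, governing onset, window end,
        fixation-point position and hit-target position (correct-answer AOI
        for CDT/Stroop, mirrored side for AST)."""
        starts = self.trial_starts()
        governing = self.governing_events()
        cx, cy = self.geometry.center
        out = []
        for i, (start, gov) in enumerate(zip(starts, governing)):
            window_end = starts[i + 1] if i + 1 < len(starts) else self.total_duration_ms
            hit_pos = gov.attributes.get("hit_position", gov.position)
            out.append({"trial": i, "start": start, "gov_onset": gov.onset_ms,
                        "window_end": window_end, "fp_pos": (cx, cy),
                        "hit_pos": hit_pos})
        return out


# ---------------------------------------------------------------------------

def _target_position(side: str, geometry: ScreenGeometry, eccentricity_frac: float):
    cx, cy = geometry.center
    dx = eccentricity_frac * geometry.width_px
    return (cx - dx, cy) if side == "LEFT" else (cx + dx, cy)


def _peripheral_position(rng: np.random.Generator, geometry: ScreenGeometry,
                         min_frac: float = 0.25, margin_px: float = 80.0):
    """Uniform draw from the peripheral annulus (>= min_frac of screen width
    from the centre), rejection-sampled onto the screen."""
    cx, cy = geometry.center
    r_min = min_frac * geometry.width_px
    r_max = 0.5 * geometry.diagonal_px - margin_px
    while True:
        r = rng.uniform(r_min, r_max)
        theta = rng.uniform(0, 2 * math.pi)
        x, y = cx + r * math.cos(theta), cy + r * math.sin(theta)
        if margin_px <= x < geometry.width_px - margin_px and \
                margin_px <= y < geometry.height_px - margin_px:
            return (x, y)


def build_pst(seed: int, n_trials: int = 30, gap_ms: float = 200.0,
              fp_ms: float = 1000.0, target_ms: float = 1000.0,
              response_ms: float = 1500.0, gap_probability: float = 0.5,
              eccentricity_frac: float = 0.35,
              geometry: ScreenGeometry | None = None) -> TaskTimeline:
    """Pro-saccade task: central FP, then a peripheral target left or right.

    Each trial is either a GAP trial (FP extinguished, 200 ms blank, then the
    target) or an OVERLAP trial (FP remains lit alongside the target for
    1000 ms), assigned by a seeded coin flip.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    geometry = geometry or DEFAULT_GEOMETRY
    rng = np.random.default_rng(seed)
    cx, cy = geometry.center
    events, t = [], 0.0
    for i in range(n_trials):
        gap = bool(rng.random() < gap_probability)
        side = "LEFT" if rng.random() < 0.5 else "RIGHT"
        pos = _target_position(side, geometry, eccentricity_frac)
        cond = "GAP" if gap else "OVERLAP"
        if gap:
            events.append(StimulusEvent("FIXATION_POINT", t, fp_ms, i, (cx, cy),
                                        attributes={"condition": cond}))
            events.append(StimulusEvent("BLANK", t + fp_ms, gap_ms, i,
                                        attributes={"condition": cond}))
            target_onset = t + fp_ms + gap_ms
        else:
            events.append(StimulusEvent("FIXATION_POINT", t, fp_ms + target_ms, i, (cx, cy),
                                        attributes={"condition": cond}))
            target_onset = t + fp_ms
        events.append(StimulusEvent("TARGET", target_onset, target_ms, i, pos, side,
                                    attributes={"condition": cond}))
        t = target_onset + target_ms + response_ms
    cfg = dict(n_trials=n_trials, gap_ms=gap_ms, fp_ms=fp_ms, target_ms=target_ms,
               response_ms=response_ms, gap_probability=gap_probability,
               eccentricity_frac=eccentricity_frac)
    return TaskTimeline("PST", events, t, cfg, seed, geometry)


def build_ast(seed: int, n_trials: int = 48, trial_period_ms: float = 5000.0,
              fp_ms: float = 1000.0, target_ms: float = 1000.0,
              eccentricity_frac: float = 0.35,
              geometry: ScreenGeometry | None = None) -> TaskTimeline:
    """Anti-saccade task: look away from the peripheral stimulus.

    48 trials, 5 s apart; the stimulus side is a seeded coin flip and the
    correct response side is its mirror image across the vertical meridian.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    geometry = geometry or DEFAULT_GEOMETRY
    rng = np.random.default_rng(seed)
    cx, cy = geometry.center
    events = []
    for i in range(n_trials):
        t = i * trial_period_ms
        side = "LEFT" if rng.random() < 0.5 else "RIGHT"
        correct = "RIGHT" if side == "LEFT" else "LEFT"
        pos = _target_position(side, geometry, eccentricity_frac)
        mirror = (geometry.width_px - pos[0], pos[1])
        events.append(StimulusEvent("FIXATION_POINT", t, fp_ms, i, (cx, cy)))
        events.append(StimulusEvent("TARGET", t + fp_ms, target_ms, i, pos, side,
                                    attributes={"correct_side": correct,
                                                "hit_position": mirror}))
    total = n_trials * trial_period_ms
    cfg = dict(n_trials=n_trials, trial_period_ms=trial_period_ms, fp_ms=fp_ms,
               target_ms=target_ms, eccentricity_frac=eccentricity_frac)
    return TaskTimeline("AST", events, total, cfg, seed, geometry)


def build_mgst(seed: int, n_trials: int = 36, fp_ms: float = 1000.0,
               target_ms: float = 500.0, delay_ms: float = 1000.0,
               response_ms: float = 2500.0,
               geometry: ScreenGeometry | None = None) -> TaskTimeline:
    """Memory-guided saccade task.

    Phase order per trial: fixation 1000 ms; peripheral target flash 500 ms
    at a seeded random position (gaze stays on the FP); 1000 ms memory
    delay; then the GO marker (FP offset) cues a saccade to the remembered
    location.  The GO onset is fp_ms + target_ms + delay_ms after trial
    start under this serialisation.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    geometry = geometry or DEFAULT_GEOMETRY
    rng = np.random.default_rng(seed)
    cx, cy = geometry.center
    events = []
    period = fp_ms + target_ms + delay_ms + response_ms
    for i in range(n_trials):
        t = i * period
        pos = _peripheral_position(rng, geometry)
        go_onset = t + fp_ms + target_ms + delay_ms
        events.append(StimulusEvent("FIXATION_POINT", t, fp_ms + target_ms + delay_ms,
                                    i, (cx, cy)))
        events.append(StimulusEvent("TARGET", t + fp_ms, target_ms, i, pos))
        events.append(StimulusEvent("BLANK", go_onset, 0.0, i,
                                    attributes={"go": True, "hit_position": pos}))
    total = n_trials * period
    cfg = dict(n_trials=n_trials, fp_ms=fp_ms, target_ms=target_ms,
               delay_ms=delay_ms, response_ms=response_ms)
    return TaskTimeline("MGST", events, total, cfg, seed, geometry)


def build_cdt(seed: int, n_pairs: int = 15, image_ms: float = 240.0,
              blank_ms: float = 80.0, penalty_wait_ms: float = 20000.0,
              geometry: ScreenGeometry | None = None) -> TaskTimeline:
    """Change detection task: two images alternate (240 ms each, 80 ms blank
    between) until the simulated response or the 20 s penalty wait elapses."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    geometry = geometry or DEFAULT_GEOMETRY
    rng = np.random.default_rng(seed)
    events, t = [], 0.0
    for i in range(n_pairs):
        diff_pos = _peripheral_position(rng, geometry, min_frac=0.1)
        # simulated response time: lognormal around ~6 s, capped by penalty wait
        response_ms = min(float(rng.lognormal(math.log(6000.0), 0.5)), penalty_wait_ms)
        trial_start, elapsed, img = t, 0.0, "A"
        while elapsed < response_ms and elapsed < penalty_wait_ms:
            events.append(StimulusEvent("IMAGE_PAIR", trial_start + elapsed, image_ms, i,
                                        diff_pos, attributes={"image": img,
                                                              "hit_position": diff_pos}))
            elapsed += image_ms
            if elapsed < response_ms and elapsed < penalty_wait_ms:
                events.append(StimulusEvent("BLANK", trial_start + elapsed, blank_ms, i))
                elapsed += blank_ms
            img = "B" if img == "A" else "A"
        t = trial_start + min(max(elapsed, response_ms), penalty_wait_ms)
    cfg = dict(n_pairs=n_pairs, image_ms=image_ms, blank_ms=blank_ms,
               penalty_wait_ms=penalty_wait_ms)
    return TaskTimeline("CDT", events, t, cfg, seed, geometry)


def build_stroop(seed: int, n_trials: int = 40, stimulus_ms: float = 5000.0,
                 fp_ms: float = 2000.0, error_gap_ms: float = 5000.0,
                 congruent_ratio: float = 0.5,
                 geometry: ScreenGeometry | None = None) -> TaskTimeline:
    """Color-word Stroop task with four answer buttons on the lower screen.

    Each trial shows a color word in a colored rectangle for 5000 ms
    followed by a 2000 ms fixation point signalling the trial change.
    Congruency (word == ink color) is assigned at ``congruent_ratio`` by a
    seeded draw.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    geometry = geometry or DEFAULT_GEOMETRY
    rng = np.random.default_rng(seed)
    cx, cy = geometry.center
    # four answer buttons spread across the lower screen
    ys = geometry.height_px * 0.88
    xs = [(k + 0.5) * geometry.width_px / 4 for k in range(4)]
    buttons = {c: (x, ys) for c, x in zip(STROOP_COLORS, xs)}
    events = []
    period = stimulus_ms + fp_ms
    for i in range(n_trials):
        t = i * period
        ink = STROOP_COLORS[rng.integers(4)]
        if rng.random() < congruent_ratio:
            word = ink
        else:
            others = [c for c in STROOP_COLORS if c != ink]
            word = others[rng.integers(3)]
        events.append(StimulusEvent(
            "STROOP_STIMULUS", t, stimulus_ms, i, (cx, cy * 0.6),
            attributes={"word": word, "ink": ink, "congruent": word == ink,
                        "buttons": {c: list(p) for c, p in buttons.items()},
                        "hit_position": buttons[ink]}))
        events.append(StimulusEvent("FIXATION_POINT", t + stimulus_ms, fp_ms, i, (cx, cy)))
    total = n_trials * period
    cfg = dict(n_trials=n_trials, stimulus_ms=stimulus_ms, fp_ms=fp_ms,
               error_gap_ms=error_gap_ms, congruent_ratio=congruent_ratio)
    return TaskTimeline("STROOP", events, total, cfg, seed, geometry)


_BUILDERS = {"PST": build_pst, "AST": build_ast, "MGST": build_mgst,
             "CDT": build_cdt, "STROOP": build_stroop}


def build_timeline(task_id: str, seed: int, geometry: ScreenGeometry | None = None,
                   **kwargs) -> TaskTimeline:
    """Dispatch to the builder for ``task_id``."""
    try:
        builder = _BUILDERS[task_id]
    except KeyError:
        raise ValueError(f"unknown task_id {task_id!r}") from None
    return builder(seed, geometry=geometry, **kwargs)


# -- JSON serialization ------------------------------------------------------

def timeline_to_json(tl: TaskTimeline) -> str:
    payload = {
        "task_id": tl.task_id,
        "seed": tl.seed,
        "config": tl.config,
        "total_duration_ms": tl.total_duration_ms,
        "geometry": asdict(tl.geometry),
        "events": [
            {"kind": e.kind, "onset_ms": e.onset_ms, "duration_ms": e.duration_ms,
             "trial_index": e.trial_index,
             "position": list(e.position) if e.position else None,
             "side": e.side, "attributes": e.attributes}
            for e in tl.events
        ],
    }
    return json.dumps(payload, indent=1)


def timeline_from_json(text: str) -> TaskTimeline:
    d = json.loads(text)
    events = [StimulusEvent(e["kind"], e["onset_ms"], e["duration_ms"], e["trial_index"],
                            tuple(e["position"]) if e["position"] else None,
                            e["side"], e["attributes"])
              for e in d["events"]]
    geom = ScreenGeometry(**d["geometry"])
    return TaskTimeline(d["task_id"], events, d["total_duration_ms"],
                        d["config"], d["seed"], geom)
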