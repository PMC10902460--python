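"""Synthetic ADHD/TDC cohorts calibrated to the published group statistics.

Two output modes:

* ``features_only`` — draw per-subject feature vectors directly from
  per-group truncated normals whose moments match the packaged parameters
  (fast; used for feature-selection and classification experiments);
* ``gaze_streams`` — realise each subject's target features as an actual
  gaze sample stream via the dwell/jump planner, so the full detection and
  extraction pipeline can be exercised end to end.

Distribution choice: the published tables report mean ± SD only, so each
feature is modelled as a truncated normal (truncation at 0 for non-negative
features); the underlying parameters are moment-matched so the truncated
distribution reproduces the printed mean and SD (the raw truncation bias is
corrected whenever it exceeds 0.5%).  Features are independent by default —
no covariance is published — with an optional one-factor within-task
correlation model to stress collinearity handling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._plan import InfeasibleTargetsError, PlanReport, plan_recording
from .features import FeatureTable
from .geometry import DEFAULT_GEOMETRY, ScreenGeometry
from .io import GazeRecording, SubjectRecord, TASK_IDS
from .paradigms import TaskTimeline, build_timeline
from .tables import (ADHD_RS_SCALES, BEHAVIORAL_SCORE_NAMES, CLINICAL_SCORE_NAMES,
                     COMPLETE_CASE_COUNTS, DEMOGRAPHICS, FEATURE_NAMES, TABLE3)

__all__ = [
    "GroupParams", "CohortSpec", "packaged_params", "truncnorm_matched",
    "sample_feature_table", "sample_subject_records", "generate_gaze_recording",
    "sample_task_targets", "InfeasibleTargetsError",
]

#: Features that may take negative values (no truncation at zero).
_SIGNED_FEATURES = {"coordinate_x_mean", "coordinate_y_mean"}
_COUNT_FEATURES = {"fixation_count", "saccade_count", "hit_count"}

#: Neutral defaults for (task, feature) cells without packaged parameters:
#: identical in both groups, so they carry no diagnostic signal.
DEFAULT_FEATURE_PARAMS: dict[str, tuple[float, float]] = {
    "saccade_degree_mean": (12.0, 3.0),
    "saccade_degree_sd": (6.0, 1.5),
    "saccade_degree_total": (900.0, 250.0),
    "saccade_latency_mean": (0.45, 0.15),
    "saccade_latency_sd": (0.25, 0.08),
    "saccade_latency_total": (10.0, 3.0),
    "saccade_count": (80.0, 20.0),
    "saccade_mean": (0.12, 0.04),
    "saccade_duration": (9.0, 3.0),
    "saccade_time_max": (1.2, 0.4),
    "fixation_count": (80.0, 20.0),
    "fixation_mean": (0.5, 0.12),
    "fixation_duration": (40.0, 10.0),
    "fixation_time_max": (3.0, 1.0),
    "coordinate_x_mean": (0.0, 60.0),
    "coordinate_y_mean": (0.0, 60.0),
    "screen_duration_mean": (2.0, 0.6),
    "screen_duration_total": (45.0, 12.0),
    "hit_count": (20.0, 6.0),
    "total_elapsed_time": (120.0, 20.0),
}


@dataclass(frozen=True)
class GroupParams:
    """Per-group generative parameters.

    ``eye``: (task, feature) -> (mean, sd) per group, transcribed from the
    published group comparison for the 33 selected features and filled with
    neutral defaults elsewhere.  ``clinical``: score name -> (mean, sd) per
    group.  Demographics: sizes, sex counts, age moments.
    """

    eye: dict
    clinical: dict
    sizes: dict
    males: dict
    age: dict

    def eye_cell(self, group: str, task: str, feature: str) -> tuple[float, float]:
        return self.eye[group].get((task, feature),
                                   DEFAULT_FEATURE_PARAMS[feature])


def packaged_params() -> GroupParams:
    """The packaged verbatim transcription of the published group statistics."""
    eye = {"ADHD": {}, "TDC": {}}
    for task, feat, _imp, am, asd, tm, tsd, _p, _nn in TABLE3:
        eye["ADHD"][(task, feat)] = (am, asd)
        eye["TDC"][(task, feat)] = (tm, tsd)
    clinical = {"ADHD": {}, "TDC": {}}
    for grp in ("ADHD", "TDC"):
        demo = DEMOGRAPHICS[grp]
        for name in ADHD_RS_SCALES:
            clinical[grp][name] = tuple(demo[name])
        base = 60.0 if grp == "ADHD" else 50.0   # artifact default T-scores
        for name in BEHAVIORAL_SCORE_NAMES + CLINICAL_SCORE_NAMES:
            clinical[grp][name] = (base, 10.0)
        clinical[grp]["iq"] = (105.0, 12.0)      # artifact default; groups matched
    sizes = {g: DEMOGRAPHICS[g]["n"] for g in ("ADHD", "TDC")}
    males = {g: DEMOGRAPHICS[g]["males"] for g in ("ADHD", "TDC")}
    age = {g: (DEMOGRAPHICS[g]["age_mean"], DEMOGRAPHICS[g]["age_sd"])
           for g in ("ADHD", "TDC")}
    return GroupParams(eye=eye, clinical=clinical, sizes=sizes, males=males, age=age)


@dataclass
class CohortSpec:
    params: GroupParams = field(default_factory=packaged_params)
    seed: int = 0
    correlation: str = "independent"       # or "factor"
    factor_loading: float = 0.0
    output_mode: str = "features_only"     # or "gaze_streams"
    n_per_group: dict | None = None        # override group sizes
    complete_case_counts: dict | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.factor_loading < 1.0):
            raise ValueError("factor loading must be in [0, 1)")
        if self.correlation not in ("independent", "factor"):
            raise ValueError("correlation must be 'independent' or 'factor'")

    def size(self, group: str) -> int:
        if self.n_per_group and group in self.n_per_group:
            return int(self.n_per_group[group])
        return int(self.params.sizes[group])


# ---------------------------------------------------------------------------
# truncated-normal moment matching

from functools import lru_cache


@lru_cache(maxsize=4096)
def truncnorm_matched(mean: float, sd: float, lower: float = 0.0):
    """A ``scipy.stats`` truncated-normal frozen distribution whose
    *truncated* mean and SD equal the requested values.

    The naive parameterisation N(mean, sd) truncated at ``lower`` is biased
    upward; when that bias exceeds 0.5% of the mean the underlying
    parameters are solved numerically so the realised moments match.
    """
    if sd <= 0:
        return stats.uniform(loc=mean, scale=0.0)

    def frozen(mu, sigma):
        a = (lower - mu) / sigma
        return stats.truncnorm(a, np.inf, loc=mu, scale=sigma)

    naive = frozen(mean, sd)
    bias = abs(naive.mean() - mean)
    if bias <= 0.005 * max(abs(mean), 1e-12):
        return naive

    def resid(p):
        mu, log_sigma = p
        d = frozen(mu, math.exp(log_sigma))
        return [d.mean() - mean, d.std() - sd]

    sol = optimize.root(resid, x0=[mean, math.log(sd)], method="hybr")
    mu, sigma = sol.x[0], math.exp(sol.x[1])
    if not sol.success:       # heavy truncation: fall back to the naive form
        return naive
    return frozen(mu, sigma)


def _draw_feature(rng, mean, sd, feature, n, z=None):
    lower = None if feature in _SIGNED_FEATURES else 0.0
    if sd <= 0:
        vals = np.full(n, mean)
    elif lower is None:
        vals = rng.normal(mean, sd, n) if z is None else mean + sd * z
    else:
        dist = truncnorm_matched(mean, sd, lower)
        if z is None:
            vals = dist.ppf(rng.uniform(1e-12, 1 - 1e-12, n))
        else:
            vals = dist.ppf(np.clip(stats.norm.cdf(z), 1e-12, 1 - 1e-12))
    if feature in _COUNT_FEATURES:
        vals = np.round(np.maximum(vals, 0))
    return vals


def sample_feature_table(spec: CohortSpec, seed: int | None = None) -> FeatureTable:
    """Draw a cohort feature table directly from the group distributions."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows: dict[tuple[str, str], dict] = {}
    labels: dict[str, str] = {}
    for group in ("ADHD", "TDC"):
        n = spec.size(group)
        sids = [f"{group}{i:04d}" for i in range(n)]
        for sid in sids:
            labels[sid] = group
        for task in TASK_IDS:
            g_lat = rng.standard_normal(n) if spec.correlation == "factor" else None
            for feature in FEATURE_NAMES:
                mean, sd = spec.params.eye_cell(group, task, feature)
                z = None
                if spec.correlation == "factor":
                    lam = spec.factor_loading
                    z = lam * g_lat + math.sqrt(1 - lam * lam) * rng.standard_normal(n)
                vals = _draw_feature(rng, mean, sd, feature, n, z)
                for sid, v in zip(sids, vals):
                    rows.setdefault((sid, task), {})[feature] = float(v)
    idx = pd.MultiIndex.from_tuples(rows.keys(), names=["subject_id", "task_id"])
    data = pd.DataFrame([rows[k] for k in rows.keys()], index=idx,
                        columns=list(FEATURE_NAMES))
    return FeatureTable(data, pd.Series(labels, name="group"))


def sample_subject_records(spec: CohortSpec, seed: int | None = None
                           ) -> list[SubjectRecord]:
    """Demographics plus clinical/behavioral scores for one cohort.

    Group sizes and sex ratios follow the packaged counts exactly
    (deterministic allocation, not sampling); ages and scores are drawn
    from the per-group distributions.  The complete-case pattern (which
    subjects carry full behavioral + clinical batteries) is allocated
    deterministically to mirror the published complete-case subsample.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    params = spec.params
    cc = spec.complete_case_counts
    if cc is None:
        cc = dict(COMPLETE_CASE_COUNTS)
    records = []
    for group in ("ADHD", "TDC"):
        n = spec.size(group)
        n_m = int(round(params.males[group] * n / params.sizes[group]))
        age_m, age_sd = params.age[group]
        ages = np.clip(rng.normal(age_m, age_sd, n), 6.0, 12.99)
        n_complete = min(int(cc.get(group, n)), n)
        for i in range(n):
            sid = f"{group}{i:04d}"
            sex = "M" if i < n_m else "F"
            iq_m, iq_sd = params.clinical[group]["iq"]
            iq = float(np.clip(rng.normal(iq_m, iq_sd), 70.0, None))
            complete = i < n_complete
            behav, clin = {}, {}
            for name in BEHAVIORAL_SCORE_NAMES:
                m, s = params.clinical[group][name]
                behav[name] = float(rng.normal(m, s)) if complete else math.nan
            for name in ADHD_RS_SCALES:
                m, s = params.clinical[group][name]
                clin[name] = float(max(rng.normal(m, s), 0.0))
            for name in CLINICAL_SCORE_NAMES:
                m, s = params.clinical[group][name]
                clin[name] = float(rng.normal(m, s)) if complete else math.nan
            records.append(SubjectRecord(sid, group, float(ages[i]), sex, iq,
                                         clinical_scores=clin,
                                         behavioral_scores=behav))
    return records


# ---------------------------------------------------------------------------
# gaze-stream generation

def sample_task_targets(params: GroupParams, group: str, task: str,
                        rng: np.random.Generator, rate_hz: float = 30.0,
                        amp_cap_deg: float = 33.0) -> dict[str, float]:
    """Draw one subject's target vector for the features packaged for
    ``task`` (the published selected-feature cells).

    Independent marginal draws can be mutually impossible for a physical
    gaze stream (e.g. a large total saccade amplitude with almost no total
    saccade time, since every saccade consumes at least one sample period
    and spans at most the screen diagonal).  The generator requires
    internally consistent targets, so the mechanical couplings are enforced
    here; the corrections bind only in the distribution tails (~1% of the
    marginal means).
    """
    targets = {}
    for (t, feature), (mean, sd) in params.eye[group].items():
        if t != task:
            continue
        targets[feature] = float(_draw_feature(rng, mean, sd, feature, 1)[0])
    deg_total = targets.get("saccade_degree_total")
    if deg_total is not None and "saccade_duration" in targets:
        # each saccade moves at most amp_cap degrees and lasts at least one
        # sample period
        t_s_min = deg_total / (amp_cap_deg * rate_hz * 0.9) + 2.0
        targets["saccade_duration"] = max(targets["saccade_duration"], t_s_min)
    if "saccade_time_max" in targets and "saccade_duration" in targets:
        targets["saccade_time_max"] = min(targets["saccade_time_max"],
                                          0.8 * targets["saccade_duration"])
    if "fixation_time_max" in targets and "fixation_duration" in targets:
        targets["fixation_time_max"] = min(targets["fixation_time_max"],
                                           0.9 * targets["fixation_duration"])
    return targets


def generate_gaze_recording(targets: dict[str, float], timeline: TaskTimeline,
                            geometry: ScreenGeometry | None = None,
                            seed: int = 0, subject_id: str = "synthetic",
                            rate_hz: float = 30.0,
                            jitter_px: float | None = None,
                            dispersion_px: float | None = None,
                            on_infeasible: str = "error"
                            ) -> tuple[GazeRecording, PlanReport]:
    """Emit a gaze stream realising ``targets``; see the planner's module
    docstring for the recovery guarantee.

    ``on_infeasible="error"`` raises :class:`InfeasibleTargetsError` when an
    explicit target had to be adjusted; ``"adjust"`` keeps the clipped plan
    and reports the adjustments.
    """
    geometry = geometry or DEFAULT_GEOMETRY
    if on_infeasible not in ("error", "adjust"):
        raise ValueError("on_infeasible must be 'error' or 'adjust'")
    plan = plan_recording(targets, timeline, geometry, seed, rate_hz=rate_hz,
                          dispersion_px=dispersion_px, jitter_px=jitter_px)
    if on_infeasible == "error" and plan.report.adjustments:
        raise InfeasibleTargetsError(plan.report.adjustments)

    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0xE317]))
    unit = plan.unit_ms
    counts = (plan.span_u + 1).astype(np.int64)
    total = int(counts.sum())
    offsets = np.concatenate(([0], np.cumsum(counts)[:-1]))
    u = np.repeat(plan.start_u, counts) + (np.arange(total) - np.repeat(offsets, counts))
    if jitter_px is None:
        from .events import default_dispersion_px
        disp = dispersion_px if dispersion_px is not None else default_dispersion_px(geometry)
        j = min(8.0, 0.08 * disp)
    else:
        j = jitter_px
    x = np.repeat(plan.x, counts) + rng.uniform(-j, j, total)
    y = np.repeat(plan.y, counts) + rng.uniform(-j, j, total)
    t = u.astype(np.float64) * unit
    valid = np.ones(total, dtype=bool)

    # invalid marker samples inside designated gaps split viewing segments
    marks = np.flatnonzero(plan.break_after[:-1]) if plan.break_after.size else []
    if len(marks):
        ends = plan.start_u[marks] + plan.span_u[marks]
        nxts = plan.start_u[np.asarray(marks) + 1]
        mt = (ends.astype(np.float64) + nxts.astype(np.float64)) / 2.0 * unit
        mx = plan.x[marks]
        my = plan.y[marks]
        ins = np.searchsorted(t, mt)
        t = np.insert(t, ins, mt)
        x = np.insert(x, ins, mx)
        y = np.insert(y, ins, my)
        valid = np.insert(valid, ins, False)

    rec = GazeRecording(subject_id=subject_id, task_id=timeline.task_id,
                        t=t, x=x, y=y, valid=valid, geometry=geometry,
                        nominal_rate_hz=rate_hz)
    return rec, plan.report


def simulate_cohort_streams(params: GroupParams, group: str, task: str,
                            n: int, seed: int, geometry: ScreenGeometry | None = None,
                            rate_hz: float = 30.0, timeline_seed: int | None = None):
    """Yield ``(recording, timeline, targets)`` for ``n`` subjects whose
    target features are drawn from the packaged group column.

    All subjects share one timeline draw (the paradigm is fixed within a
    study); per-subject randomness covers targets, schedules and jitter.
    """
    geometry = geometry or DEFAULT_GEOMETRY
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, TASK_IDS.index(task),
                                 0 if group == "ADHD" else 1])
    child_seeds = ss.generate_state(2 * n + 1)
    timeline = build_timeline(task, int(child_seeds[-1]) & 0x7FFFFFFF
                              if timeline_seed is None else timeline_seed,
                              geometry=geometry)
    for i in range(n):
        rng = np.random.default_rng(child_seeds[2 * i])
        targets = sample_task_targets(params, group, task, rng, rate_hz=rate_hz)
        rec, report = generate_gaze_recording(
            targets, timeline, geometry, seed=int(child_seeds[2 * i + 1]) & 0x7FFFFFFF,
            subject_id=f"{group}{i:04d}", rate_hz=rate_hz, on_infeasible="adjust")
        yield rec, timeline, targets, report
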