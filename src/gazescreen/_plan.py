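"""Dwell/jump planning for synthetic gaze streams.

Given a target feature vector (any subset of the 20 canonical features), a
task timeline and a screen geometry, the planner constructs an explicit
schedule of fixation dwells (start, span, position) and inter-dwell gaps
(the saccades), aligned to the sample grid of the nominal recording rate,
so that running the event detector and feature extractor on the emitted
stream recovers the planned quantities essentially exactly:

* dwell boundaries are snapped to the sample grid, so detected durations,
  counts and totals equal the planned integer-unit values;
* per-trial latencies are planted by ending the trial's fixation-point
  dwell exactly at ``governing onset + latency``;
* amplitudes are realised by placing consecutive dwell centroids at the
  planned pixel distance (sample jitter perturbs centroids by a few px);
* samples are emitted only during dwells, so slow large "saccades" cannot
  masquerade as fixations, and a single invalid marker sample placed in a
  gap splits an on-screen viewing segment without touching any dwell.

Not every target combination is geometrically or temporally realisable
(a per-saccade amplitude above the angle subtended by the screen diagonal,
or a fixation count whose minimum dwell time exceeds the total fixation
duration).  Conflicts are resolved by a fixed priority — duration and
latency totals first, then degree totals, then counts, then means, then
maxima, then SDs — clipping lower-priority targets to the feasible range
and recording every adjustment in the returned :class:`PlanReport`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import ScreenGeometry, degrees_to_pixels, pixel_to_degrees

__all__ = ["PlanReport", "GazePlan", "plan_recording", "InfeasibleTargetsError"]

MIN_DWELL_MS = 100.0       # shortest plannable fixation; > the 70 ms threshold
EDGE_MARGIN_PX = 24.0      # keeps jittered samples on-screen (3x max jitter)


class InfeasibleTargetsError(ValueError):
    """Raised (in ``on_infeasible="error"`` mode) when explicit targets are
    not realisable; ``adjustments`` lists (feature, target, planned)."""

    def __init__(self, adjustments):
        self.adjustments = list(adjustments)
        msg = "; ".join(f"{a[0]}: target {a[1]:g} -> planned {a[2]:g}" for a in adjustments)
        super().__init__(f"infeasible feature targets: {msg}")


@dataclass
class PlanReport:
    adjustments: list[tuple[str, float, float]] = field(default_factory=list)
    planned: dict[str, float] = field(default_factory=dict)
    n_planted_trials: int = 0

    def adjusted_features(self) -> set[str]:
        return {a[0] for a in self.adjustments}


@dataclass
class GazePlan:
    """Resolved schedule: parallel arrays over fixation slots (grid units)."""

    start_u: np.ndarray
    span_u: np.ndarray
    x: np.ndarray
    y: np.ndarray
    break_after: np.ndarray
    unit_ms: float
    report: PlanReport


# ---------------------------------------------------------------------------
# allocation helpers

def _largest_remainder(vals: np.ndarray, total: int, lo: int, hi: int) -> np.ndarray:
    """Round ``vals`` to integers in [lo, hi] summing exactly to ``total``."""
    n = vals.size
    v = np.clip(np.floor(vals).astype(np.int64), lo, hi)
    deficit = int(total - v.sum())
    guard = 0
    while deficit != 0 and guard < 64:
        guard += 1
        if deficit > 0:
            room = np.flatnonzero(v < hi)
            if room.size == 0:
                break
            take = room[:deficit]
            add = min(deficit // max(1, take.size) + 1, 1_000_000)
            inc = np.minimum(hi - v[take], max(1, deficit // take.size))
            v[take] += inc
            deficit = int(total - v.sum())
        else:
            room = np.flatnonzero(v > lo)
            if room.size == 0:
                break
            take = room[:(-deficit)]
            dec = np.minimum(v[take] - lo, max(1, (-deficit) // take.size))
            v[take] -= dec
            deficit = int(total - v.sum())
    return v


def _alloc_int(total: int, n: int, lo: int, hi: float, rng: np.random.Generator,
               sd: float | None = None, reserve_max: int | None = None) -> np.ndarray:
    """n integers in [lo, hi] summing to ``total``; optionally one element
    pinned at ``reserve_max`` (the intended family maximum).

    ``total`` must lie in the feasible band (callers pre-clip).
    """
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    total = int(total)
    head = None
    if reserve_max is not None:
        head = int(min(max(reserve_max, lo), total - (n - 1) * lo))
        total -= head
        n -= 1
        hi = min(hi, head)
        if n == 0:
            return np.array([head], dtype=np.int64)
    hi_i = int(min(hi, total - (n - 1) * lo)) if math.isfinite(hi) else total - (n - 1) * lo
    hi_i = max(hi_i, lo)
    mean = total / n
    spread = sd if sd is not None else max(0.5, 0.15 * mean)
    vals = rng.normal(mean, spread, n)
    for _ in range(4):
        vals = np.clip(vals, lo, hi_i)
        vals = vals + (total - vals.sum()) / n
    v = _largest_remainder(np.clip(vals, lo, hi_i), total, lo, hi_i)
    if head is not None:
        v = np.concatenate([[head], v])
    return v


def _alloc_float(total: float, n: int, lo: float, hi: float,
                 rng: np.random.Generator, sd: float | None = None) -> np.ndarray:
    """n floats in [lo, hi] summing (approximately exactly) to ``total``."""
    if n <= 0:
        return np.zeros(0)
    total = min(max(total, n * lo), n * hi)
    mean = total / n
    spread = sd if sd is not None else 0.15 * max(mean, 1e-9)
    vals = rng.normal(mean, spread, n)
    for _ in range(8):
        vals = np.clip(vals, lo, hi)
        resid = total - vals.sum()
        if abs(resid) < 1e-9 * max(1.0, abs(total)):
            break
        vals = vals + resid / n
    return np.clip(vals, lo, hi)


def _sd_bound(mean: float, lo: float, hi: float) -> float:
    """Bhatia-Davis bound on the SD of values in [lo, hi] with given mean."""
    if not (lo < mean < hi):
        return 0.0
    return math.sqrt((mean - lo) * (hi - mean))


# ---------------------------------------------------------------------------

class _Planner:
    def __init__(self, targets, timeline, geometry: ScreenGeometry, seed,
                 rate_hz, dispersion_px, fp_aoi_px, jitter_px):
        self.targets = {k: float(v) for k, v in dict(targets).items() if v is not None}
        self.timeline = timeline
        self.geom = geometry
        self.rng = np.random.default_rng(seed)
        self.unit = 1000.0 / rate_hz
        self.disp = dispersion_px
        self.aoi = fp_aoi_px
        self.jitter = jitter_px if jitter_px is not None else min(8.0, 0.08 * dispersion_px)
        self.report = PlanReport()
        # amplitude bounds follow the margin-adjusted box actually available
        # to dwell centroids, not the full screen diagonal
        inner = pixel_to_degrees(
            (EDGE_MARGIN_PX, EDGE_MARGIN_PX),
            (geometry.width_px - EDGE_MARGIN_PX, geometry.height_px - EDGE_MARGIN_PX),
            geometry)
        self.amp_max = geometry.max_amplitude_deg()
        self.amp_cap = 0.995 * inner
        self.mean_cap = 0.97 * inner
        self.amp_min = max(2.0, pixel_to_degrees((0, 0), (1.8 * dispersion_px, 0), geometry))
        self.min_dwell = max(3, int(math.ceil(MIN_DWELL_MS / self.unit)))
        self.min_gap = 1

    def _t(self, name):
        return self.targets.get(name)

    def _u(self, seconds: float) -> int:
        return max(0, int(round(seconds * 1000.0 / self.unit)))

    def _s(self, units: float) -> float:
        return units * self.unit / 1000.0

    def _note(self, feature: str, target: float, planned: float, tol: float = 0.015):
        denom = abs(target) if target else 1.0
        if abs(planned - target) / denom > tol:
            self.report.adjustments.append((feature, float(target), float(planned)))

    # ------------------------------------------------------------------
    def solve(self) -> GazePlan:
        md, mg = self.min_dwell, self.min_gap

        infos = self.timeline.trial_info() if self.timeline is not None else []
        trials = []
        for info in infos:
            trials.append({
                "start": int(round(info["start"] / self.unit)),
                "gov": int(round(info["gov_onset"] / self.unit)),
                "win": int(round(info["window_end"] / self.unit)),
                "fp_pos": tuple(info["fp_pos"]),
                "hit_pos": tuple(info["hit_pos"]) if info["hit_pos"] is not None else None,
            })
        reserve = 2 * md + 3 * mg
        lat_max_u = [max(2, t["win"] - t["gov"] - reserve) for t in trials]

        fix_total_u = self._u(self._t("fixation_duration")) \
            if self._t("fixation_duration") is not None else None
        sac_total_u = self._u(self._t("saccade_duration")) \
            if self._t("saccade_duration") is not None else None
        fix_max_u = self._u(self._t("fixation_time_max")) \
            if self._t("fixation_time_max") is not None else None
        sac_max_u = self._u(self._t("saccade_time_max")) \
            if self._t("saccade_time_max") is not None else None
        fix_mean_s = self._t("fixation_mean")
        sac_mean_s = self._t("saccade_mean")
        elapsed_u = self._u(self._t("total_elapsed_time")) \
            if self._t("total_elapsed_time") is not None else None
        seg_mean_s = self._t("screen_duration_mean")
        lat_total_s = self._t("saccade_latency_total")
        lat_mean_s = self._t("saccade_latency_mean")
        lat_sd_s = self._t("saccade_latency_sd")
        deg_total = self._t("saccade_degree_total")
        deg_mean = self._t("saccade_degree_mean")
        deg_sd = self._t("saccade_degree_sd")

        deg_mean_c = None
        if deg_mean is not None:
            deg_mean_c = min(max(deg_mean, self.amp_min), self.mean_cap)

        # --- preferred saccade count ---
        n_count = None
        if self._t("saccade_count") is not None:
            n_count = max(1, int(round(self._t("saccade_count"))))
        elif self._t("fixation_count") is not None:
            n_count = max(1, int(round(self._t("fixation_count"))) - 1)

        def pinned_amp_sum(n_plant: int) -> float:
            """Estimated degrees consumed by the 2*n_plant pinned slots."""
            total = 0.0
            cx, cy = self.geom.center
            for t in trials[:n_plant]:
                hit = t["hit_pos"] or (cx + 3 * self.aoi, cy)
                ecc = pixel_to_degrees((cx, cy), hit, self.geom)
                total += 2 * max(ecc, self.amp_min)
            return total

        def n_preferred(n_plant: int) -> int:
            k = 2 * n_plant
            n_pref = n_count if n_count is not None else 0
            if deg_total is not None:
                m = deg_mean_c if deg_mean_c is not None else 0.5 * self.mean_cap
                rest = max(0.0, deg_total - pinned_amp_sum(n_plant))
                n_pref = max(n_pref,
                             int(math.ceil(rest / self.amp_cap)) + max(0, k - 1),
                             int(round(rest / m)) + max(0, k - 1))
            return n_pref if n_pref else 64

        def duration_caps(n_plant: int, with_reserves: bool = True) -> list[int]:
            k = 2 * n_plant
            windows = sum(t["win"] - t["start"] for t in trials[:n_plant])
            resv_f = fix_max_u if (with_reserves and (fix_max_u or 0) > md) else 0
            resv_s = sac_max_u if (with_reserves and (sac_max_u or 0) > mg) else 0
            caps = []
            if fix_total_u is not None:
                caps.append(k - 1 + max(1, (fix_total_u - k * md - resv_f) // md))
            if sac_total_u is not None:
                caps.append(k + max(1, (sac_total_u - 2 * k * mg - resv_s) // mg))
            if fix_total_u is not None and sac_total_u is not None and windows:
                joint = ((fix_total_u - resv_f) + (sac_total_u - resv_s) - windows)
                caps.append(k - 1 + max(1, joint // (md + mg)))
            return caps

        def n_s_at(n_plant: int) -> int:
            caps = duration_caps(n_plant)
            n_pref = n_preferred(n_plant)
            n_s = max(2 * n_plant + 1, min([n_pref] + caps) if caps else n_pref)
            if deg_total is not None:
                # the degree total outranks the duration maxima: when the
                # max-reserves squeeze the slot budget below the minimum the
                # amplitude total needs, the reserves yield (recorded later
                # by the gap/dwell allocators)
                k = 2 * n_plant
                rest = max(0.0, deg_total - pinned_amp_sum(n_plant))
                n_deg_min = int(math.ceil(rest / self.amp_cap)) + max(0, k - 1)
                if n_s < n_deg_min:
                    caps_wo = duration_caps(n_plant, with_reserves=False)
                    relaxed = min([n_deg_min] + caps_wo) if caps_wo else n_deg_min
                    n_s = max(n_s, min(n_deg_min, relaxed))
            return n_s

        # --- how many trials can we plant? ---
        plant_cap = len(trials)
        if n_count is not None:
            plant_cap = max(0, (n_count - 1) // 2)   # k = 2*n_plant dwells fit
        n_plant = self._search_n_plant(trials[:plant_cap], fix_total_u, sac_total_u,
                                       fix_max_u, sac_max_u)
        # planting every trial can starve the amplitude budget: prefer the
        # largest prefix that still covers the latency demand and maximises
        # the achievable total saccade amplitude
        if deg_total is not None and n_plant > 1:
            lat_need = 0
            if lat_total_s is not None and lat_max_u:
                cap_typ = max(1, int(np.median(lat_max_u[:n_plant])))
                lat_need = min(n_plant, int(math.ceil(self._u(lat_total_s) / cap_typ)))
            elif lat_mean_s is not None or lat_sd_s is not None:
                lat_need = min(n_plant, 3)

            def achievable(np_):
                n_s_ = n_s_at(np_)
                b = n_s_ - max(0, 2 * np_ - 1)
                return min(deg_total, pinned_amp_sum(np_) + b * self.amp_cap)

            best_np, best_deg = n_plant, achievable(n_plant)
            for cand in range(n_plant - 1, max(lat_need, 1) - 1, -1):
                got = achievable(cand)
                if got > best_deg * 1.001:
                    best_np, best_deg = cand, got
                if best_deg >= deg_total * 0.999:
                    break
            n_plant = best_np

        trials = trials[:n_plant]
        lat_max_u = lat_max_u[:n_plant]
        k = 2 * n_plant
        self.report.n_planted_trials = n_plant
        n_s = n_s_at(n_plant)
        caps = duration_caps(n_plant)
        resv_f = fix_max_u if (fix_max_u or 0) > md else 0
        windows_u = sum(t["win"] - t["start"] for t in trials)

        # bumps that need more slots (only when the relevant total is free)
        if fix_mean_s is not None and fix_total_u is None:
            m_f = self._u(fix_mean_s)
            S_pf_est = max(0, windows_u - 3 * mg * n_plant)
            M = fix_max_u
            Mp = int(0.98 * M) if M else None
            if Mp is not None and m_f >= Mp:
                Mp = int(1.1 * m_f) + 1
            if Mp is not None and k and Mp > m_f:
                need = int(math.ceil((k * Mp - S_pf_est) / (Mp - m_f)))
                n_s = max(n_s, min([need - 1] + caps) if caps else need - 1)
        if deg_mean_c is not None and deg_total is None and k:
            headroom = self.amp_cap - deg_mean_c
            if headroom > 0.3:
                need = k + max(8, int(math.ceil(k * deg_mean_c / headroom)))
                n_s = max(n_s, min([need] + caps) if caps else need)
        if elapsed_u is not None and sac_max_u is not None and sac_total_u is None:
            # gaps stretched to meet the elapsed-time target must each stay
            # below the saccade-duration maximum
            per_dwell = self._u(fix_mean_s) if fix_mean_s is not None else 12
            need = int(math.ceil(elapsed_u / (sac_max_u * 0.95 + per_dwell)))
            n_s = max(n_s, min([need] + caps) if caps else need)
        n_s = max(n_s, k + 1)
        n_f = n_s + 1
        b_f = n_f - k

        if n_count is not None:
            self._note("fixation_count" if self._t("fixation_count") is not None
                       else "saccade_count",
                       self._t("fixation_count") or self._t("saccade_count"),
                       n_f if self._t("fixation_count") is not None else n_s)

        # --- latencies ---
        lats = self._plan_latencies(trials, lat_max_u, lat_total_s, lat_mean_s, lat_sd_s)

        # --- pinned dwells + reconciliation ---
        pinned = self._plan_pinned(trials, lats, fix_total_u, fix_max_u,
                                   seg_mean_s, b_f, resv_f)
        S_pf = sum(p["span"] for p in pinned)
        pinned_gaps = [b["start"] - (a["start"] + a["span"])
                       for a, b in zip(pinned[:-1], pinned[1:])]

        # --- bulk fixation durations ---
        bulk_spans = self._plan_bulk_fix(b_f, S_pf, pinned, fix_total_u,
                                         fix_mean_s, fix_max_u, n_f, seg_mean_s)

        # --- bulk gaps ---
        b_s = n_s - max(0, k - 1)          # one gap precedes each bulk dwell,
        if k == 0:                          # except the very first when no
            b_s = n_s                       # pinned dwell exists
            b_gap_slots = b_f - 1
        else:
            b_gap_slots = b_f
        bulk_gaps = self._plan_bulk_gaps(b_gap_slots, pinned_gaps, sac_total_u,
                                         sac_mean_s, sac_max_u, n_s, elapsed_u,
                                         S_pf + int(bulk_spans.sum()))

        # --- positions ---
        fx, fy = self._plan_positions(pinned, n_f, n_s, k, deg_total, deg_mean,
                                      deg_mean_c, deg_sd)

        # --- absolute schedule ---
        start_u = np.zeros(n_f, dtype=np.int64)
        span_u = np.zeros(n_f, dtype=np.int64)
        for i, p in enumerate(pinned):
            start_u[i], span_u[i] = p["start"], p["span"]
        if k == 0:
            start_u[0] = 0
            span_u[0] = int(bulk_spans[0])
            cursor = int(bulk_spans[0])
            for j in range(1, b_f):
                cursor += int(bulk_gaps[j - 1])
                start_u[j] = cursor
                cursor += int(bulk_spans[j])
                span_u[j] = int(bulk_spans[j])
        else:
            cursor = pinned[-1]["start"] + pinned[-1]["span"]
            for j in range(b_f):
                cursor += int(bulk_gaps[j])
                start_u[k + j] = cursor
                span_u[k + j] = int(bulk_spans[j])
                cursor += int(bulk_spans[j])

        self._shift_coordinates(fx, fy, span_u, k)
        break_after = self._plan_breaks(start_u, span_u, seg_mean_s)
        self._fill_planned(start_u, span_u, fx, fy, lats, break_after)
        return GazePlan(start_u, span_u, fx, fy, break_after, self.unit, self.report)

    # ------------------------------------------------------------------
    def _search_n_plant(self, trials, fix_total_u, sac_total_u,
                        fix_max_u, sac_max_u) -> int:
        """Largest trial-prefix whose pinned schedule fits the duration
        budgets (totals take priority over latency coverage)."""
        md, mg = self.min_dwell, self.min_gap
        for with_reserves in (True, False):   # duration maxima yield if needed
            resv_f = fix_max_u if (with_reserves and (fix_max_u or 0) > md) else 0
            resv_s = sac_max_u if (with_reserves and (sac_max_u or 0) > mg) else 0
            for n_plant in range(len(trials), 0, -1):
                k = 2 * n_plant
                windows = sum(t["win"] - t["start"] for t in trials[:n_plant])
                if fix_total_u is not None and sac_total_u is not None:
                    if (fix_total_u - resv_f - md) + (sac_total_u - resv_s - mg) < windows:
                        continue
                if fix_total_u is not None:
                    if fix_total_u < (k + 1) * md + resv_f:
                        continue
                if sac_total_u is not None:
                    if sac_total_u < (2 * k + 1) * mg + resv_s:
                        continue
                return n_plant
        return 0

    # ------------------------------------------------------------------
    def _plan_latencies(self, trials, lat_max_u, lat_total_s, lat_mean_s, lat_sd_s):
        n = len(trials)
        if n == 0:
            return []
        if lat_total_s is not None:
            total = self._u(lat_total_s)
        elif lat_mean_s is not None:
            total = self._u(lat_mean_s) * n
        else:
            total = self._u(0.3) * n
        cap = np.asarray(lat_max_u, dtype=np.int64)
        # the trial's FP dwell must end at gov+latency and still fit a full
        # dwell after t=0, so very early governing onsets bound latency below
        lo = np.array([max(1, self.min_dwell - t["gov"]) for t in trials],
                      dtype=np.int64)
        lo = np.minimum(lo, cap)
        total_c = int(min(max(total, int(lo.sum())), cap.sum()))
        if lat_total_s is not None:
            self._note("saccade_latency_total", lat_total_s, self._s(total_c))
        elif lat_mean_s is not None:
            self._note("saccade_latency_mean", lat_mean_s, self._s(total_c) / n)
        sd_u = self._u(lat_sd_s) if lat_sd_s is not None else None
        vals = self.rng.normal(total_c / n, sd_u if sd_u else 0.2 * total_c / n, n)
        for _ in range(6):
            vals = np.minimum(np.maximum(vals, lo), cap)
            vals = vals + (total_c - vals.sum()) / n
        lats = _largest_remainder(np.minimum(np.maximum(vals, lo), cap),
                                  total_c, int(lo.min()), int(cap.max()))
        lats = np.minimum(np.maximum(lats, lo), cap)
        if lat_sd_s is not None:
            got = float(np.std(lats, ddof=1)) if n > 1 else 0.0
            self._note("saccade_latency_sd", lat_sd_s, self._s(got), tol=0.05)
        return [int(v) for v in lats]

    # ------------------------------------------------------------------
    def _plan_pinned(self, trials, lats, fix_total_u, fix_max_u, seg_mean_s,
                     b_f, resv_f):
        md, mg = self.min_dwell, self.min_gap
        pinned = []
        if not trials:
            return pinned
        seg_cap = None
        if seg_mean_s is not None and fix_total_u is None:
            seg_cap = max(md, self._u(seg_mean_s))
        naturals = []
        for t, l in zip(trials, lats):
            fp_nat = max(md, t["gov"] + l - t["start"])
            away_nat = max(md, t["win"] - (t["gov"] + l) - 2 * mg)
            if seg_cap is not None:
                fp_nat, away_nat = min(fp_nat, seg_cap), min(away_nat, seg_cap)
            naturals.append((fp_nat, away_nat))
        nat_total = sum(a + b for a, b in naturals)
        k = 2 * len(trials)
        if fix_total_u is not None:
            budget = max(k * md, fix_total_u - b_f * md - resv_f)
            D_p = min(nat_total, budget)
        else:
            D_p = nat_total
        scale = D_p / nat_total if nat_total else 1.0

        cursor = max(0, trials[0]["start"])
        for t, l, (fp_nat, away_nat) in zip(trials, lats, naturals):
            fp_end = t["gov"] + l
            fp_span = int(max(md, min(round(fp_nat * scale), fp_end - cursor)))
            fp_start = fp_end - fp_span
            if fp_start < cursor:        # squeeze against the previous dwell
                fp_span = max(md, fp_end - cursor)
                fp_start = max(0, fp_end - fp_span)
                fp_span = fp_end - fp_start
            away_start = fp_end + mg
            away_span = int(max(md, min(round(away_nat * scale),
                                        t["win"] - mg - away_start)))
            pinned.append({"start": fp_start, "span": fp_span, "kind": "fp", "trial": t})
            pinned.append({"start": away_start, "span": away_span, "kind": "away",
                           "trial": t})
            cursor = away_start + away_span + mg
        # reconcile any residual overlaps (tight windows)
        for a, b in zip(pinned[:-1], pinned[1:]):
            overlap = (a["start"] + a["span"] + mg) - b["start"]
            if overlap > 0:
                a["span"] = max(md, a["span"] - overlap)
        return pinned

    # ------------------------------------------------------------------
    def _plan_bulk_fix(self, b_f, S_pf, pinned, fix_total_u, fix_mean_s,
                       fix_max_u, n_f, seg_mean_s):
        md = self.min_dwell
        if b_f <= 0:
            if fix_total_u is not None:
                self._note("fixation_duration", self._s(fix_total_u), self._s(S_pf))
            return np.zeros(0, dtype=np.int64)
        if fix_total_u is not None:
            total = fix_total_u
        elif fix_mean_s is not None:
            total = self._u(fix_mean_s) * n_f
        else:
            per = (self._t("screen_duration_mean") or 0) * 1000.0 / self.unit \
                if seg_mean_s is not None else 12.0
            total = S_pf + int(round(b_f * max(per, md)))
        bulk_total = max(b_f * md, total - S_pf)
        if fix_total_u is not None:
            self._note("fixation_duration", self._s(fix_total_u),
                       self._s(S_pf + bulk_total))

        pinned_max = max((p["span"] for p in pinned), default=0)
        resv, hi = None, float("inf")
        if fix_max_u is not None:
            if fix_max_u < pinned_max:
                self._note("fixation_time_max", self._s(fix_max_u), self._s(pinned_max))
                hi = pinned_max
            else:
                target_max = min(fix_max_u, bulk_total - (b_f - 1) * md)
                if target_max < fix_max_u:
                    self._note("fixation_time_max", self._s(fix_max_u),
                               self._s(max(target_max, pinned_max)))
                resv = max(target_max, md)
                if bulk_total > b_f * resv:   # the mean outranks the maximum
                    resv = int(math.ceil(bulk_total / b_f * 1.03)) + 1
                    self._note("fixation_time_max", self._s(fix_max_u), self._s(resv))
                hi = resv
        spans = _alloc_int(bulk_total, b_f, md, hi, self.rng, reserve_max=resv)
        if fix_mean_s is not None:
            self._note("fixation_mean", fix_mean_s,
                       self._s(S_pf + int(spans.sum())) / n_f)
        return spans

    # ------------------------------------------------------------------
    def _plan_bulk_gaps(self, b_slots, pinned_gaps, sac_total_u, sac_mean_s,
                        sac_max_u, n_s, elapsed_u, fix_total_planned):
        mg = self.min_gap
        S_pg = sum(pinned_gaps)
        if b_slots <= 0:
            if sac_total_u is not None:
                self._note("saccade_duration", self._s(sac_total_u), self._s(S_pg))
            return np.zeros(0, dtype=np.int64)
        if sac_total_u is not None:
            total = sac_total_u
        elif sac_mean_s is not None:
            total = self._u(sac_mean_s) * n_s
        elif elapsed_u is not None:
            total = max(S_pg + b_slots * mg, elapsed_u - fix_total_planned)
        else:
            total = S_pg + b_slots * 2
        bulk_total = max(b_slots * mg, total - S_pg)
        if sac_total_u is not None:
            self._note("saccade_duration", self._s(sac_total_u),
                       self._s(S_pg + bulk_total))
        if elapsed_u is not None:
            self._note("total_elapsed_time", self._s(elapsed_u),
                       self._s(fix_total_planned + S_pg + bulk_total))

        pinned_max = max(pinned_gaps, default=0)
        resv, hi = None, float("inf")
        if sac_max_u is not None:
            if sac_max_u < pinned_max:
                self._note("saccade_time_max", self._s(sac_max_u), self._s(pinned_max))
                hi = pinned_max
            else:
                target_max = min(sac_max_u, bulk_total - (b_slots - 1) * mg)
                if target_max < sac_max_u:
                    self._note("saccade_time_max", self._s(sac_max_u),
                               self._s(max(target_max, pinned_max)))
                resv = max(target_max, mg)
                if bulk_total > b_slots * resv:   # the mean outranks the maximum
                    resv = int(math.ceil(bulk_total / b_slots * 1.03)) + 1
                    self._note("saccade_time_max", self._s(sac_max_u), self._s(resv))
                hi = resv
        gaps = _alloc_int(bulk_total, b_slots, mg, hi, self.rng, reserve_max=resv)
        if sac_mean_s is not None:
            self._note("saccade_mean", sac_mean_s,
                       self._s(S_pg + int(gaps.sum())) / max(n_s, 1))
        return gaps

    # ------------------------------------------------------------------
    def _plan_positions(self, pinned, n_f, n_s, k, deg_total, deg_mean,
                        deg_mean_c, deg_sd):
        g = self.geom
        cx, cy = g.center
        rng = self.rng
        fx = np.zeros(n_f)
        fy = np.zeros(n_f)

        off_r = min(0.4 * self.aoi, 90.0)
        for i, p in enumerate(pinned):
            if p["kind"] == "fp":
                ang = (i // 2) * 2.4
                fx[i] = cx + off_r * math.cos(ang)
                fy[i] = cy + off_r * math.sin(ang)
            else:
                hit = p["trial"]["hit_pos"] or (cx + 3.0 * self.aoi, cy)
                hx, hy = float(hit[0]), float(hit[1])
                d = math.hypot(hx - cx, hy - cy)
                if d < 1.4 * self.aoi:
                    s = (1.6 * self.aoi) / max(d, 1.0)
                    hx, hy = cx + (hx - cx) * s, cy + (hy - cy) * s
                fx[i], fy[i] = hx, hy
        pinned_amps = [pixel_to_degrees((fx[i], fy[i]), (fx[i + 1], fy[i + 1]), g)
                       for i in range(max(0, k - 1))]
        S_pa = float(np.sum(pinned_amps))

        b_amp = n_s - max(0, k - 1)
        lo, hi = self.amp_min, self.amp_cap
        if deg_total is not None:
            bulk_sum = max(b_amp * lo, min(deg_total - S_pa, b_amp * hi))
            self._note("saccade_degree_total", deg_total, S_pa + bulk_sum)
        elif deg_mean_c is not None:
            bulk_sum = max(b_amp * lo, min(deg_mean_c * n_s - S_pa, b_amp * hi))
        else:
            bulk_sum = b_amp * min(12.0, hi)
        mu_b = bulk_sum / max(b_amp, 1)
        sd_req = None
        if deg_sd is not None:
            bound = 0.95 * _sd_bound(mu_b, lo, hi)
            sd_req = min(deg_sd, bound)
            self._note("saccade_degree_sd", deg_sd, sd_req, tol=0.05)
        amps = _alloc_float(bulk_sum, b_amp, lo, hi, rng, sd=sd_req)
        if deg_mean is not None and n_s:
            self._note("saccade_degree_mean", deg_mean,
                       (S_pa + float(amps.sum())) / n_s)

        margin = EDGE_MARGIN_PX
        w, h = g.width_px, g.height_px
        base = k if k else 1
        if k:
            px, py = fx[k - 1], fy[k - 1]
        else:
            px, py = cx + 3.0 * self.aoi, cy
            fx[0], fy[0] = px, py
        corners = [(margin, margin), (w - margin, margin),
                   (margin, h - margin), (w - margin, h - margin)]
        aoi_excl = 1.3 * self.aoi
        angles = rng.uniform(0, 2 * math.pi, size=max(8, 4 * b_amp))
        ai = 0
        deficit = 0.0    # degrees lost to reach limits, repaid by later slots
        for j in range(b_amp):
            want_deg = min(max(float(amps[j]) + deficit, lo), self.amp_cap)
            d_px = degrees_to_pixels(want_deg, g)
            nx = ny = None
            for _ in range(10):
                th = angles[ai % angles.size]
                ai += 1
                tx_, ty_ = px + d_px * math.cos(th), py + d_px * math.sin(th)
                if (margin <= tx_ <= w - margin and margin <= ty_ <= h - margin
                        and math.hypot(tx_ - cx, ty_ - cy) > aoi_excl):
                    nx, ny = tx_, ty_
                    break
            if nx is None:
                fc = max(corners, key=lambda c: math.hypot(c[0] - px, c[1] - py))
                reach = math.hypot(fc[0] - px, fc[1] - py)
                step = min(d_px, reach)
                nx = px + (fc[0] - px) * step / max(reach, 1.0)
                ny = py + (fc[1] - py) * step / max(reach, 1.0)
                if math.hypot(nx - cx, ny - cy) <= aoi_excl:
                    nx += math.copysign(aoi_excl + 40.0, (nx - cx) or 1.0)
                    nx = min(max(nx, margin), w - margin)
            realized = pixel_to_degrees((px, py), (nx, ny), g)
            deficit += float(amps[j]) - realized
            fx[base + j] = nx
            fy[base + j] = ny
            px, py = nx, ny
        return fx, fy

    # ------------------------------------------------------------------
    def _shift_coordinates(self, fx, fy, span_u, k):
        tx = self._t("coordinate_x_mean")
        ty = self._t("coordinate_y_mean")
        if tx is None and ty is None:
            return
        g = self.geom
        cx, cy = g.center
        n_f = span_u.size
        # fixation-point dwells stay put (the AOI anchors latency planting);
        # departure dwells and the bulk walk absorb the shift
        free = np.zeros(n_f, dtype=bool)
        free[k:] = True
        free[1:k:2] = True
        wgt = span_u.astype(float) + 1.0
        W = wgt.sum()
        Wb = wgt[free].sum()
        if Wb <= 0:
            return
        margin = EDGE_MARGIN_PX
        for _ in range(3):       # clipping and AOI pushes leave a residual
            if tx is not None:
                cur = float(np.average(fx - cx, weights=wgt))
                fx[free] = np.clip(fx[free] + (tx - cur) * W / Wb, margin,
                                   g.width_px - margin)
            if ty is not None:
                cur = float(np.average(fy - cy, weights=wgt))
                fy[free] = np.clip(fy[free] + (ty - cur) * W / Wb, margin,
                                   g.height_px - margin)
            # keep movable dwells out of the fixation-point AOI
            d = np.hypot(fx[free] - cx, fy[free] - cy)
            close = d < 1.15 * self.aoi
            if close.any():
                scale = (1.3 * self.aoi) / np.maximum(d[close], 1.0)
                xs = fx[free]
                ys = fy[free]
                xs[close] = cx + (xs[close] - cx) * scale
                ys[close] = cy + (ys[close] - cy) * scale
                fx[free] = xs
                fy[free] = ys

    # ------------------------------------------------------------------
    def _plan_breaks(self, start_u, span_u, seg_mean_s) -> np.ndarray:
        n_f = start_u.size
        breaks = np.zeros(n_f, dtype=bool)
        if seg_mean_s is None or n_f < 2:
            return breaks
        m_u = max(1.0, seg_mean_s * 1000.0 / self.unit)
        med_span = float(np.median(span_u))
        if med_span >= 0.8 * m_u:
            breaks[:-1] = True      # one dwell per viewing segment
            return breaks
        # deficit-tracking greedy: at each gap, break or continue so the
        # running sum of (segment span - target) stays near zero; a one-dwell
        # lookahead lets short dwells merge across small gaps while long
        # dwells stand alone, so the segment-mean self-corrects
        deficit = 0.0
        acc_start = float(start_u[0])
        for j in range(n_f - 1):
            end_j = float(start_u[j] + span_u[j])
            cur = end_j - acc_start
            nxt = float(start_u[j + 1] + span_u[j + 1]) - acc_start
            if abs(deficit + (cur - m_u)) <= abs(deficit + (nxt - m_u)):
                breaks[j] = True
                deficit += cur - m_u
                acc_start = float(start_u[j + 1])
        return breaks

    # ------------------------------------------------------------------
    def _fill_planned(self, start_u, span_u, fx, fy, lats, break_after):
        u = self.unit / 1000.0
        spans = span_u.astype(float) * u
        n_f = start_u.size
        gaps = (start_u[1:] - (start_u[:-1] + span_u[:-1])).astype(float) * u
        amps = np.array([pixel_to_degrees((fx[i], fy[i]), (fx[i + 1], fy[i + 1]),
                                          self.geom) for i in range(n_f - 1)])
        p = self.report.planned
        p["fixation_count"] = float(n_f)
        p["fixation_duration"] = float(spans.sum())
        p["fixation_mean"] = float(spans.mean()) if n_f else 0.0
        p["fixation_time_max"] = float(spans.max()) if n_f else 0.0
        p["saccade_count"] = float(n_f - 1)
        p["saccade_duration"] = float(gaps.sum())
        p["saccade_mean"] = float(gaps.mean()) if gaps.size else 0.0
        p["saccade_time_max"] = float(gaps.max()) if gaps.size else 0.0
        p["saccade_degree_total"] = float(amps.sum())
        p["saccade_degree_mean"] = float(amps.mean()) if amps.size else 0.0
        p["saccade_degree_sd"] = float(amps.std(ddof=1)) if amps.size > 1 else 0.0
        lat_s = np.array(lats, dtype=float) * u
        p["saccade_latency_total"] = float(lat_s.sum())
        p["saccade_latency_mean"] = float(lat_s.mean()) if lat_s.size else math.nan
        p["saccade_latency_sd"] = float(lat_s.std(ddof=1)) if lat_s.size > 1 else 0.0
        p["total_elapsed_time"] = float((start_u[-1] + span_u[-1] - start_u[0]) * u)
        seg_spans = []
        seg_start = start_u[0]
        for i in range(n_f):
            end_i = start_u[i] + span_u[i]
            if i == n_f - 1 or break_after[i]:
                seg_spans.append((end_i - seg_start) * u)
                if i < n_f - 1:
                    seg_start = start_u[i + 1]
        seg = np.asarray(seg_spans)
        p["screen_duration_total"] = float(seg.sum())
        p["screen_duration_mean"] = float(seg.mean()) if seg.size else 0.0


def plan_recording(targets, timeline, geometry: ScreenGeometry, seed,
                   rate_hz: float = 30.0, dispersion_px: float | None = None,
                   fp_aoi_px: float | None = None,
                   jitter_px: float | None = None) -> GazePlan:
    """Resolve a feature-target vector into an explicit dwell/jump schedule."""
    from .events import default_aoi_radius_px, default_dispersion_px

    if dispersion_px is None:
        dispersion_px = default_dispersion_px(geometry)
    if fp_aoi_px is None:
        fp_aoi_px = default_aoi_radius_px(geometry)
    planner = _Planner(targets, timeline, geometry, seed, rate_hz,
                       dispersion_px, fp_aoi_px, jitter_px)
    return planner.solve()
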