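"""Fixation/saccade detection against the brute-force oracle, and latencies."""

import math

import numpy as np
import pytest

from gazescreen import (build_mgst, build_pst, detect_events, detect_fixations,
                        detect_saccades, trial_latencies, generate_gaze_recording)

from conftest import make_recording
from oracles import fixations_bruteforce


class TestFixations:
    def test_constant_gaze_single_fixation(self):
        t = np.arange(0, 1000 + 1, 33.0)
        rec = make_recording(t, np.full(t.size, 400.0), np.full(t.size, 400.0))
        fx = detect_fixations(rec, dispersion_px=50)
        assert len(fx) == 1
        f = fx[0]
        assert f.duration_ms == pytest.approx(t[-1] - t[0])
        assert (f.cx, f.cy) == (400.0, 400.0)

    def test_sub_threshold_dwells_excluded(self):
        # two 60 ms dwells separated by a jump: both below the 70 ms minimum
        t = np.array([0, 30, 60, 100, 130, 160.0])
        x = np.array([100, 100, 100, 600, 600, 600.0])
        rec = make_recording(t, x, np.full(6, 300.0))
        assert detect_fixations(rec, dispersion_px=50) == []

    def test_k_planted_dwells_recovered(self):
        rng = np.random.default_rng(0)
        t_list, x_list, y_list = [], [], []
        t0 = 0.0
        centers = [(100, 100), (600, 150), (300, 500), (700, 450), (150, 550)]
        for cx, cy in centers:
            n = 8   # 8 samples at 33 ms -> 231 ms dwell
            t_list.append(t0 + np.arange(n) * 33.0)
            x_list.append(cx + rng.uniform(-5, 5, n))
            y_list.append(cy + rng.uniform(-5, 5, n))
            t0 += n * 33.0 + 100.0
        rec = make_recording(np.concatenate(t_list), np.concatenate(x_list),
                             np.concatenate(y_list))
        fx = detect_fixations(rec, dispersion_px=40)
        assert len(fx) == len(centers)
        for f, (cx, cy) in zip(fx, centers):
            assert math.hypot(f.cx - cx, f.cy - cy) < 6

    def test_invalid_samples_break_runs(self):
        t = np.arange(0, 20) * 33.0
        valid = np.ones(20, bool)
        valid[10] = False
        rec = make_recording(t, np.full(20, 100.0), np.full(20, 100.0), valid=valid)
        fx = detect_fixations(rec, dispersion_px=10)
        assert len(fx) == 2

    def test_all_invalid_gives_empty(self):
        t = np.arange(0, 10) * 33.0
        rec = make_recording(t, np.zeros(10), np.zeros(10), valid=np.zeros(10, bool))
        assert detect_fixations(rec, dispersion_px=10) == []

    @pytest.mark.parametrize("seed", range(60))
    def test_oracle_equivalence_random_streams(self, seed):
        """Greedy dispersion detector equals the exhaustive maximal-run scan."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        t = np.cumsum(rng.uniform(20, 45, n))
        # mixture of dwells and noise so qualifying runs actually appear
        x = np.where(rng.random(n) < 0.6, rng.normal(300, 8, n),
                     rng.uniform(0, 800, n))
        y = np.where(rng.random(n) < 0.6, rng.normal(300, 8, n),
                     rng.uniform(0, 600, n))
        valid = rng.random(n) > 0.05
        rec = make_recording(t, x, y, valid=valid)
        disp = float(rng.uniform(20, 120))
        got = [(f.start_ms, f.end_ms, f.cx, f.cy)
               for f in detect_fixations(rec, dispersion_px=disp)]
        expect = fixations_bruteforce(t, x, y, valid, disp)
        assert len(got) == len(expect)
        for g, e in zip(got, expect):
            assert g[0] == pytest.approx(e[0]) and g[1] == pytest.approx(e[1])
            assert g[2] == pytest.approx(e[2]) and g[3] == pytest.approx(e[3])


class TestSaccades:
    def test_zero_displacement_zero_amplitude(self, geometry):
        from gazescreen.events import Fixation

        rec = make_recording([0, 33], [0, 0], [0, 0])
        fx = [Fixation(0, 100, 200, 200), Fixation(150, 300, 200, 200)]
        sc = detect_saccades(rec, fx)
        assert len(sc) == 1 and sc[0].amplitude_deg == 0.0

    def test_constructed_ten_degree_amplitude(self, geometry):
        from gazescreen.events import Fixation
        from gazescreen import degrees_to_pixels

        d = degrees_to_pixels(10.0, geometry)
        rec = make_recording([0, 33], [0, 0], [0, 0], geometry=geometry)
        fx = [Fixation(0, 100, 100, 100), Fixation(150, 300, 100 + d, 100)]
        sc = detect_saccades(rec, fx)
        assert sc[0].amplitude_deg == pytest.approx(10.0, abs=1e-6)

    def test_k_fixations_give_k_minus_1_saccades(self):
        from gazescreen.events import Fixation

        rec = make_recording([0, 33], [0, 0], [0, 0])
        fx = [Fixation(i * 200.0, i * 200.0 + 100, 100 + 200 * i, 100)
              for i in range(6)]
        sc = detect_saccades(rec, fx)
        assert len(sc) == 5
        for a, b, s in zip(fx[:-1], fx[1:], sc):
            assert s.start_ms == a.end_ms and s.end_ms == b.start_ms

    def test_partition_inequality_on_synthetic_stream(self):
        tl = build_pst(seed=2)
        rec, _ = generate_gaze_recording({"fixation_mean": 0.5}, tl, seed=9,
                                         on_infeasible="adjust")
        ev = detect_events(rec)
        total = sum(f.duration_ms for f in ev.fixations) \
            + sum(s.duration_ms for s in ev.saccades)
        assert total <= rec.span_ms + 1e-6


class TestLatencies:
    def test_planted_latencies_recovered(self):
        tl = build_mgst(seed=4)
        targets = {"saccade_latency_total": 36 * 0.4}
        rec, report = generate_gaze_recording(targets, tl, seed=10,
                                              on_infeasible="adjust")
        ev = detect_events(rec)
        lats = trial_latencies(ev, tl)
        got = [l for l in lats if l is not None]
        assert len(got) == 36
        assert sum(got) / 1000.0 == pytest.approx(36 * 0.4, rel=0.01)

    def test_known_latency_values(self):
        """Mean of planted {200, 300, 400} ms latencies is recovered."""
        tl = build_mgst(seed=4, n_trials=3)
        rec, report = generate_gaze_recording({"saccade_latency_total": 0.9}, tl,
                                              seed=11, on_infeasible="adjust")
        ev = detect_events(rec)
        lats = [l for l in trial_latencies(ev, tl) if l is not None]
        assert len(lats) == 3
        assert np.mean(lats) == pytest.approx(300.0, rel=0.05)

    def test_no_departure_gives_missing(self):
        # gaze never leaves the FP: every trial's latency is missing
        tl = build_pst(seed=3, n_trials=3)
        t = np.arange(0, tl.total_duration_ms, 33.0)
        cx, cy = tl.geometry.center
        rng = np.random.default_rng(0)
        rec = make_recording(t, cx + rng.uniform(-5, 5, t.size),
                             cy + rng.uniform(-5, 5, t.size), geometry=tl.geometry)
        ev = detect_events(rec)
        lats = trial_latencies(ev, tl)
        assert lats == [None, None, None]

    def test_task_mismatch_raises(self):
        tl = build_pst(seed=1, n_trials=2)
        rec = make_recording([0, 33, 66], [1, 2, 3], [1, 2, 3], task_id="AST")
        ev = detect_events(rec)
        with pytest.raises(ValueError):
            trial_latencies(ev, tl)


def test_event_train_to_frame():
    tl = build_pst(seed=5)
    rec, _ = generate_gaze_recording({"fixation_count": 6, "fixation_mean": 0.4},
                                     tl, seed=3, on_infeasible="adjust")
    ev = detect_events(rec)
    df = ev.to_frame()
    assert (df["event"] == "fixation").sum() == len(ev.fixations)
    assert (df["event"] == "saccade").sum() == len(ev.saccades)
    assert df["start_ms"].is_monotonic_increasing
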