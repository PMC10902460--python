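"""Feature extraction arithmetic, table assembly, and stage schemas."""

import numpy as np
import pandas as pd
import pytest

from gazescreen import (FeatureTable, assemble_stage, build_feature_table,
                        build_pst, detect_events, extract_features,
                        generate_gaze_recording, stage_schema)
from gazescreen.synth import CohortSpec, sample_feature_table, sample_subject_records
from gazescreen.tables import FEATURE_NAMES, STAGE1_TASK_COUNTS


@pytest.fixture(scope="module")
def pst_example():
    tl = build_pst(seed=7)
    targets = {"fixation_count": 12, "fixation_duration": 12.0,
               "saccade_degree_total": 150.0}
    rec, report = generate_gaze_recording(targets, tl, seed=21,
                                          on_infeasible="adjust")
    ev = detect_events(rec)
    return rec, ev, tl, extract_features(rec, ev, tl)


class TestExtraction:
    def test_constructed_fixation_family(self):
        tl = build_pst(seed=7)
        rec, _ = generate_gaze_recording(
            {"fixation_count": 3, "fixation_duration": 3.0, "fixation_mean": 1.0},
            tl, seed=2, on_infeasible="adjust")
        fv = extract_features(rec, detect_events(rec), tl)
        assert fv.fixation_count == 3
        assert fv.fixation_duration == pytest.approx(3.0, rel=1e-6)
        assert fv.fixation_mean == pytest.approx(1.0, rel=1e-6)

    def test_degree_family_closed_form(self, geometry):
        """Two saccades of 10 and 20 degrees: mean 15, total 30, sample SD."""
        from gazescreen.events import EventTrain, Fixation, Saccade
        from gazescreen import GazeRecording, build_pst

        tl = build_pst(seed=1, n_trials=1)
        t = np.arange(4) * 33.0
        rec = GazeRecording("s", "PST", t, np.zeros(4), np.zeros(4),
                            np.ones(4, bool), geometry, 30.0)
        fx = [Fixation(0, 100, 0, 0), Fixation(150, 250, 0, 0), Fixation(300, 400, 0, 0)]
        sc = [Saccade(100, 150, (0, 0), (1, 1), 10.0),
              Saccade(250, 300, (0, 0), (1, 1), 20.0)]
        fv = extract_features(rec, EventTrain(rec, fx, sc), tl)
        assert fv.saccade_degree_mean == pytest.approx(15.0)
        assert fv.saccade_degree_total == pytest.approx(30.0)
        assert fv.saccade_degree_sd == pytest.approx(np.std([10, 20], ddof=1))

    def test_totals_means_maxima_consistent(self, pst_example):
        _, _, _, fv = pst_example
        assert fv.fixation_duration >= fv.fixation_time_max >= fv.fixation_mean >= 0
        assert fv.saccade_duration >= fv.saccade_time_max >= fv.saccade_mean >= 0
        assert fv.fixation_count == int(fv.fixation_count) >= 0
        assert fv.saccade_degree_sd >= 0

    def test_time_translation_invariance(self, pst_example):
        rec, ev, tl, fv = pst_example
        shifted = rec.shifted(5000.0)
        ev2 = detect_events(shifted)
        fv2 = extract_features(shifted, ev2, tl)
        d1, d2 = fv.as_dict(), fv2.as_dict()
        for name in FEATURE_NAMES:
            if "latency" in name or name == "hit_count":
                continue   # trial-locked features reference the timeline clock
            assert d2[name] == pytest.approx(d1[name], rel=1e-9, abs=1e-9), name

    def test_empty_event_train_zero_vector(self, geometry):
        from gazescreen.events import EventTrain
        from gazescreen import GazeRecording, build_pst

        tl = build_pst(seed=1, n_trials=1)
        t = np.arange(3) * 33.0
        rec = GazeRecording("s", "PST", t, np.zeros(3), np.zeros(3),
                            np.zeros(3, bool), geometry, 30.0)
        fv = extract_features(rec, EventTrain(rec, [], []), tl)
        assert fv.fixation_count == 0 and fv.saccade_count == 0
        assert np.isnan(fv.saccade_latency_mean)
        assert fv.diagnostics["n_latency_trials"] == 0


class TestFeatureTable:
    def test_build_and_shape(self):
        spec = CohortSpec(seed=1, n_per_group={"ADHD": 3, "TDC": 4})
        table = sample_feature_table(spec)
        assert table.data.shape == (7 * 5, 20)
        wide = table.wide()
        assert wide.shape == (7, 100)

    def test_duplicate_subject_task_rejected(self):
        tl = build_pst(seed=7)
        rec, _ = generate_gaze_recording({"fixation_mean": 0.4}, tl, seed=5,
                                         on_infeasible="adjust")
        ev = detect_events(rec)
        with pytest.raises(ValueError, match="duplicate"):
            build_feature_table([(rec, ev, tl), (rec, ev, tl)], {"s0": "ADHD"})

    def test_csv_roundtrip(self, tmp_path):
        spec = CohortSpec(seed=2, n_per_group={"ADHD": 3, "TDC": 3})
        table = sample_feature_table(spec)
        path = tmp_path / "ft.csv"
        table.to_csv(path)
        back = FeatureTable.from_csv(path)
        pd.testing.assert_frame_equal(back.data, table.data, check_like=True)
        assert dict(back.labels) == dict(table.labels)


class TestStageSchemas:
    @pytest.mark.parametrize("stage,width", [
        ("stage1", 33), ("ata_only", 8), ("stroop_only", 4),
        ("ata_stroop", 12), ("stage3", 75),
    ])
    def test_schema_widths(self, stage, width):
        assert len(stage_schema(stage)) == width

    def test_per_task_selected_counts(self):
        assert dict(STAGE1_TASK_COUNTS) == {"PST": 7, "AST": 11, "MGST": 8,
                                            "CDT": 4, "STROOP": 3}
        assert sum(STAGE1_TASK_COUNTS.values()) == 33

    def test_stage3_width_decomposition(self):
        # 33 eye + 3 demographic + 12 behavioral + 13 CBCL + 3 DBDRS
        # + CDI + BDI + 6 SCARED + 3 FACES = 75
        assert 33 + 3 + 12 + 13 + 3 + 1 + 1 + 6 + 3 == len(stage_schema("stage3"))

    def test_assemble_stage1_matrix(self):
        spec = CohortSpec(seed=3, n_per_group={"ADHD": 8, "TDC": 9})
        table = sample_feature_table(spec)
        X, y = assemble_stage("stage1", table)
        assert X.shape == (17, 33)
        assert y.sum() == 8

    def test_assemble_stage3_complete_cases_and_sex_coding(self):
        spec = CohortSpec(seed=4, n_per_group={"ADHD": 6, "TDC": 6},
                          complete_case_counts={"ADHD": 4, "TDC": 3})
        table = sample_feature_table(spec)
        records = sample_subject_records(spec)
        X, y = assemble_stage("stage3", table, records)
        assert X.shape == (7, 75)          # casewise-complete subjects only
        assert set(X["sex"].unique()) <= {0.0, 1.0}

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError):
            stage_schema("stage9")
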