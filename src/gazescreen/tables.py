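"""Packaged transcriptions of the published cohort statistics.

These constants transcribe the group-level statistics printed in the source
study (per-group mean ± SD of the 33 selected eye-tracking features, cohort
demographics, the enrollment ledger, and the staged feature schemas).  They
drive the synthetic cohort generator and the worked-example replications;
they are immutable reference data, not fitted values.

Feature-name convention: staged schema columns are ``{TASK}__{feature}``
(for example ``MGST__saccade_degree_total``).
"""

from __future__ import annotations

from types import MappingProxyType

__all__ = [
    "FEATURE_NAMES",
    "TABLE3",
    "table3_row",
    "STAGE1_SCHEMA",
    "STAGE1_TASK_COUNTS",
    "ATA_SCORE_NAMES",
    "STROOP_SCORE_NAMES",
    "BEHAVIORAL_SCORE_NAMES",
    "CBCL_SCALES",
    "DBDRS_SCALES",
    "SCARED_SCALES",
    "FACES_SCALES",
    "ADHD_RS_SCALES",
    "CLINICAL_SCORE_NAMES",
    "STAGE_SCHEMAS",
    "DEMOGRAPHICS",
    "ENROLLMENT_LEDGER",
    "GROUP_SIZES",
]

#: The 20 candidate eye-tracking features extracted from every task.
#: Units are artifact conventions chosen to match the printed magnitudes:
#: durations/latencies in seconds, saccade amplitudes ("degree") in visual
#: degrees, coordinates in pixels centred on the screen centre.
FEATURE_NAMES = (
    "saccade_degree_mean",
    "saccade_degree_sd",
    "saccade_degree_total",
    "saccade_latency_mean",
    "saccade_latency_sd",
    "saccade_latency_total",
    "saccade_count",
    "saccade_mean",            # mean per-saccade duration, s
    "saccade_duration",        # total saccade duration, s
    "saccade_time_max",        # longest single saccade, s
    "fixation_count",
    "fixation_mean",           # mean per-fixation duration, s
    "fixation_duration",       # total fixation duration, s
    "fixation_time_max",       # longest single fixation, s
    "coordinate_x_mean",       # centred px
    "coordinate_y_mean",       # centred px
    "screen_duration_mean",    # mean on-screen valid-gaze segment, s
    "screen_duration_total",   # total on-screen valid-gaze span, s
    "hit_count",
    "total_elapsed_time",      # last minus first sample time, s
)

#: Per-group comparison of the 33 features retained by recursive feature
#: elimination: (task, feature) -> (importance, adhd_mean, adhd_sd,
#: tdc_mean, tdc_sd, p_value, nonnormal).  ``nonnormal`` marks rows where the
#: published comparison fell back to the Mann-Whitney U test.
#: Ordered as printed (by importance rank within task).
TABLE3: tuple[tuple[str, str, float, float, float, float, float, float, bool], ...] = (
    # task, feature, importance, ADHD mean, ADHD sd, TDC mean, TDC sd, p, nonnormal
    ("PST", "fixation_duration",     0.038, 64.57, 19.70, 71.79, 16.90, 0.030, True),
    ("PST", "saccade_degree_mean",   0.025, 39.13, 7.23, 37.33, 8.20, 0.189, False),
    ("PST", "saccade_latency_mean",  0.021, 1.21, 0.75, 1.08, 0.36, 0.932, True),
    ("PST", "saccade_mean",          0.021, 8.98, 3.04, 8.95, 2.82, 0.830, True),
    ("PST", "saccade_degree_sd",     0.022, 29.10, 8.24, 29.41, 7.78, 0.630, True),
    ("PST", "saccade_degree_total",  0.021, 7808.41, 3444.85, 7217.25, 3230.01, 0.233, True),
    ("PST", "fixation_time_max",     0.020, 26.81, 4.87, 27.97, 4.08, 0.213, True),
    ("AST", "saccade_degree_mean",   0.033, 42.92, 5.98, 40.82, 8.63, 0.119, False),
    ("AST", "saccade_duration",      0.029, 52.44, 13.73, 48.18, 18.77, 0.151, False),
    ("AST", "saccade_degree_total",  0.028, 20869.22, 7520.73, 18612.54, 8268.31, 0.061, True),
    ("AST", "fixation_duration",     0.024, 104.47, 33.88, 103.06, 30.69, 0.918, True),
    ("AST", "coordinate_y_mean",     0.025, 20.20, 94.26, 10.44, 108.63, 0.588, False),
    ("AST", "saccade_degree_sd",     0.028, 35.70, 8.52, 35.76, 8.43, 0.967, False),
    ("AST", "fixation_count",        0.019, 1131.79, 236.06, 1168.73, 241.93, 0.379, False),
    ("AST", "screen_duration_mean",  0.023, 3.77, 4.91, 3.18, 3.51, 0.768, True),
    ("AST", "saccade_latency_sd",    0.020, 0.85, 0.36, 0.93, 0.62, 0.520, True),
    ("AST", "saccade_time_max",      0.025, 24.68, 6.58, 22.19, 7.41, 0.047, False),
    ("AST", "saccade_latency_total", 0.020, 76.85, 13.23, 77.54, 17.02, 0.799, True),
    ("MGST", "saccade_degree_total", 0.048, 14201.95, 6935.07, 10647.83, 4475.26, 0.005, True),
    ("MGST", "saccade_degree_mean",  0.033, 40.88, 6.05, 37.48, 8.45, 0.032, True),
    ("MGST", "saccade_time_max",     0.035, 17.91, 6.64, 14.96, 5.47, 0.007, True),
    ("MGST", "fixation_time_max",    0.036, 32.41, 7.17, 35.54, 4.78, 0.020, True),
    ("MGST", "fixation_mean",        0.039, 28.71, 8.09, 32.27, 6.36, 0.013, True),
    ("MGST", "saccade_latency_total", 0.033, 51.14, 12.20, 55.75, 10.84, 0.022, False),
    ("MGST", "saccade_duration",     0.029, 42.41, 17.58, 35.11, 14.18, 0.011, True),
    ("MGST", "coordinate_x_mean",    0.023, 1.78, 88.28, -13.09, 90.57, 0.198, True),
    ("CDT", "saccade_degree_sd",     0.057, 24.67, 4.76, 27.47, 6.61, 0.008, False),
    ("CDT", "total_elapsed_time",    0.038, 5658.91, 1333.01, 5172.72, 1088.88, 0.051, True),
    ("CDT", "saccade_degree_mean",   0.024, 34.38, 7.12, 34.06, 7.25, 0.805, False),
    ("CDT", "saccade_time_max",      0.025, 12.36, 5.08, 13.27, 5.03, 0.219, True),
    ("STROOP", "saccade_degree_mean", 0.052, 33.67, 6.43, 30.54, 6.35, 0.003, True),
    ("STROOP", "screen_duration_mean", 0.037, 0.42, 0.32, 0.33, 0.34, 0.019, True),
    ("STROOP", "saccade_latency_total", 0.043, 2.66, 0.75, 2.33, 0.65, 0.012, True),
)


def table3_row(task: str, feature: str):
    """Return the transcription row for one (task, feature) cell."""
    for row in TABLE3:
        if row[0] == task and row[1] == feature:
            return row
    raise KeyError(f"({task}, {feature}) is not one of the 33 selected features")


#: Stage-1 schema: the 33 retained eye-tracking features in printed order.
STAGE1_SCHEMA: tuple[str, ...] = tuple(f"{task}__{feat}" for task, feat, *_ in TABLE3)

#: Features retained per task (7 PST + 11 AST + 8 MGST + 4 CDT + 3 Stroop = 33).
STAGE1_TASK_COUNTS = MappingProxyType(
    {t: sum(1 for row in TABLE3 if row[0] == t) for t in ("PST", "AST", "MGST", "CDT", "STROOP")}
)

# -- behavioral / clinical score inventories ---------------------------------

ATA_SCORE_NAMES = (
    "ata_visual_omission", "ata_visual_commission", "ata_visual_rt", "ata_visual_rt_var",
    "ata_auditory_omission", "ata_auditory_commission", "ata_auditory_rt", "ata_auditory_rt_var",
)
STROOP_SCORE_NAMES = ("stroop_word", "stroop_color", "stroop_color_word", "stroop_interference")
BEHAVIORAL_SCORE_NAMES = ATA_SCORE_NAMES + STROOP_SCORE_NAMES

CBCL_SCALES = (
    "cbcl_anxious_depressed", "cbcl_withdrawn_depressed", "cbcl_somatic_complaints",
    "cbcl_social_problems", "cbcl_thought_problems", "cbcl_attention_problems",
    "cbcl_rule_breaking", "cbcl_aggressive_behavior", "cbcl_internalizing",
    "cbcl_externalizing", "cbcl_total_problems", "cbcl_obsessive_compulsive",
    "cbcl_posttraumatic_stress",
)
DBDRS_SCALES = ("dbdrs_odd", "dbdrs_conduct", "dbdrs_adhd")
SCARED_SCALES = ("scared_panic", "scared_generalized", "scared_separation",
                 "scared_social", "scared_school", "scared_total")
FACES_SCALES = ("faces_cohesion", "faces_flexibility", "faces_communication")
ADHD_RS_SCALES = ("adhd_rs_total", "adhd_rs_inattention", "adhd_rs_hyperactivity")

CLINICAL_SCORE_NAMES = CBCL_SCALES + DBDRS_SCALES + ("cdi", "bdi") + SCARED_SCALES + FACES_SCALES

#: Staged model schemas.  Widths: stage 1 = 33, ATA-only = 8, Stroop-only = 4,
#: combined = 12, stage 3 = 33 + 3 demographics + 12 behavioral + 28 clinical = 75.
STAGE_SCHEMAS = MappingProxyType({
    "stage1": STAGE1_SCHEMA,
    "ata_only": ATA_SCORE_NAMES,
    "stroop_only": STROOP_SCORE_NAMES,
    "ata_stroop": BEHAVIORAL_SCORE_NAMES,
    "stage3": STAGE1_SCHEMA + ("age", "sex", "iq") + BEHAVIORAL_SCORE_NAMES
              + CBCL_SCALES + DBDRS_SCALES + ("cdi", "bdi") + SCARED_SCALES + FACES_SCALES,
})

# -- demographics and enrollment ---------------------------------------------

#: Cohort demographics: per group (n, males, females, age mean, age sd) and
#: ADHD-RS scale (mean, sd) per group.
DEMOGRAPHICS = MappingProxyType({
    "ADHD": MappingProxyType({
        "n": 56, "males": 45, "females": 11, "age_mean": 8.38, "age_sd": 1.58,
        "adhd_rs_total": (26.27, 8.46),
        "adhd_rs_inattention": (14.88, 4.82),
        "adhd_rs_hyperactivity": (11.39, 5.31),
    }),
    "TDC": MappingProxyType({
        "n": 79, "males": 33, "females": 46, "age_mean": 8.80, "age_sd": 1.82,
        "adhd_rs_total": (9.77, 5.71),
        "adhd_rs_inattention": (6.16, 3.87),
        "adhd_rs_hyperactivity": (3.61, 2.62),
    }),
})

GROUP_SIZES = MappingProxyType({"ADHD": 56, "TDC": 79})

#: Enrollment flow: 250 recruited, 7 excluded pre-enrollment (3 withdrawals,
#: 4 screening failures), 108 excluded for eye-tracking collection errors
#: (5 gaze off-screen, 4 incomplete experiment, 99 tracking failure),
#: 135 completing (56 ADHD / 79 TDC).
ENROLLMENT_LEDGER = MappingProxyType({
    "recruited": 250,
    "pre_enrollment": 7,
    "eye_tracking_errors": 108,
})

#: Subjects with complete clinical + behavioral batteries (stage 2/3 sample).
COMPLETE_CASE_COUNTS = MappingProxyType({"ADHD": 50, "TDC": 23})
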