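# Methods

This note documents the models and procedures implemented in `gazescreen`,
the parameter defaults and why they were chosen, the design of the
synthetic cohort generator, and the known limits of what passing tests
demonstrate.

## Screen geometry and units

Screen coordinates use a top-left origin, x rightward, y downward, in
continuous 0-based pixels.  The default display is a 1752×2800 px tablet
panel at 266 ppi (10.47 px/mm) viewed from 500 mm — the tablet-on-a-desk
setup the task battery targets.  All three values are configurable on
`ScreenGeometry`.

Visual angle between two screen points uses the exact chord formula
`2·atan(d_mm / 2D)`; under the default geometry the full screen diagonal
subtends ≈ 35.0°, which bounds any single saccade's amplitude.  Feature
units are artifact conventions chosen to live on the same scale as the
packaged cohort parameters: durations, latencies and screen times in
seconds; amplitudes ("degree" features) in visual degrees; coordinate
means in pixels centred on the screen centre.  All standard deviations are
sample (n−1) SDs, used consistently by the extractor and the generator.

## Task paradigms

Each builder emits a deterministic-given-seed `TaskTimeline`:

| task | trials | per-trial structure | defaults chosen here |
|------|--------|---------------------|----------------------|
| PST  | 30 | FP 1000 ms; GAP (200 ms blank) or OVERLAP (FP stays lit 1000 ms with the target); target 1000 ms left/right at ±35 % screen width | 50/50 gap ratio; 1500 ms response window |
| AST  | 48 | trials 5000 ms apart; FP 1000 ms then a 1000 ms peripheral stimulus; correct response side is the mirror image | eccentricity as PST |
| MGST | 36 | FP 1000 ms → target flash 500 ms at a random peripheral position → 1000 ms memory delay → GO marker (FP offset) | 2500 ms response window; peripheral annulus ≥ 25 % screen width from centre |
| CDT  | 15 pairs | images alternate 240 ms each with 80 ms blanks until a simulated response, capped at 20 s | response times lognormal around 6 s |
| STROOP | 40 | color word in a colored rectangle 5000 ms, then 2000 ms FP; four answer buttons on the lower screen | 50 % congruent trials |

The Stroop congruent/incongruent counts are deliberately parameterised:
the protocol literature states 40 trials alongside a 50/50 count that
cannot both hold, so the trial count and the congruent ratio are separate
knobs.  The PST and MGST response windows are not part of the published
timing; they were sized once so that saccade latencies of the magnitude
reported for these tasks (≈ 1.2–1.4 s) fit inside the trial windows, and
are config-level choices.  The MGST phase serialisation (FP → target →
delay → GO at +2500 ms) is one consistent reading of an elliptical
protocol description and is likewise configurable.

## Event detection

Fixations use a dispersion-threshold definition: a maximal run of
consecutive valid samples whose bounding-box diagonal stays within
`dispersion_px` and whose temporal span is ≥ 70 ms becomes one fixation
(centroid = mean of member coordinates); invalid samples break runs; the
scan is greedy left-to-right, so fixations never overlap.  **The
dispersion threshold is the single most consequential parameter in the
pipeline** — every downstream feature depends on it — and defaults to the
pixel equivalent of 1.0° under the recording's geometry (≈ 91 px on the
default display).

A saccade is simply the movement between two consecutive fixations: it
spans the inter-fixation gap (noisy in-between samples are attributed to
the saccade; there is no separate noise-event class), its amplitude is the
visual angle between the two centroids, and k fixations always yield k−1
saccades.  Velocity-based detection, microsaccades and blink
reconstruction are out of scope.

Trial-locked latency: for each trial, the latency is the onset of the
first saccade that departs the fixation-point AOI (origin inside,
destination outside; AOI radius defaults to 2.0°) at or after the
governing stimulus onset — the peripheral target for PST/AST, the GO
marker for MGST, the first image for CDT, the word stimulus for Stroop —
minus that onset.  Trials without a qualifying saccade yield a missing
latency, which is excluded from the latency aggregates and counted in the
diagnostics.

## The 20 features and staged schemas

Per task: amplitude mean/SD/total; latency mean/SD/total; saccade count,
mean duration, total duration, longest saccade; fixation count, mean
duration, total duration, longest fixation; centred coordinate x/y means
over valid samples; mean and total on-screen viewing-segment span (a
segment is a maximal run of valid on-screen samples, broken by invalid or
off-screen samples, spanning first to last sample time); hit count (trials
whose hit AOI — target, mirrored side, difference location or correct
answer button, radius 2.5° — was entered by a fixation centroid during the
trial window); and total elapsed time (last minus first sample).

"Saccade Mean" is read as mean per-saccade duration and "Saccade
Duration" as total saccade duration, mirroring the unambiguous fixation
family.  Several published feature magnitudes (a ~28 s mean fixation
duration, a ~5700 s elapsed time) are irreconcilable with literal
task-clock seconds; the package treats all duration features as
artifact-defined seconds and keeps generator and extractor unit-consistent
rather than guessing the original instrumentation's units.

Staged schemas: stage 1 = the 33 retained eye-tracking features
(7 PST + 11 AST + 8 MGST + 4 CDT + 3 Stroop); stage 2 = ATA T-scores (8),
Stroop T-scores (4), or both (12); stage 3 = 33 + age/sex/IQ + 12
behavioral + 13 CBCL + 3 DBDRS + CDI + BDI + 6 SCARED + 3 FACES-IV = 75.
Sex is coded M = 1, F = 0.  Stages that need clinical/behavioral scores
drop incomplete subjects casewise (the published analysis used the 73
complete cases); nothing is imputed.

## Feature selection

Per task, a random forest (2000 trees by default) is fitted on each of 5
stratified CV folds; features are eliminated one at a time in order of
lowest fold-averaged impurity importance, recording the mean CV accuracy
of every surviving set; the best set maximises mean accuracy with ties
broken toward the smaller set, and equal importances drop the
lexicographically last name.  Folds are fixed per seed across steps so
accuracy differences reflect feature sets rather than fold noise.

Two deliberate reproductions of the source design, documented rather than
corrected: elimination is importance-ordered with accuracy used only to
pick the best set (the only reading that yields a well-defined algorithm),
and selection shares its CV with the accuracy estimate (no outer loop), an
optimistically biased design.  `select_all_tasks(replicate=True)` returns
the packaged 33-feature schema instead of re-selecting.

## Screening models

The dummy baseline classifies everyone as TDC; its stratified 5-fold CV
accuracy on a 56/79 cohort is ≈ 0.585 (the whole-sample rate 79/135; the
originally reported 0.583 differs in the third decimal because the exact
fold layout is not recoverable).  A candidate is "superior" when its mean
CV accuracy beats the dummy by ≥ 0.10.  The screening roster spans the
standard families (tree ensembles, linear, kernel, neighbor, boosting,
naive Bayes); the soft-voting ensemble combines the two tree ensembles
(random forest + extremely randomised trees), each depth-capped (default
5) to curb overfitting on n ≈ 135, with grids {500, 1000, 2000} trees ×
depth {3, 5, 8, none} available to `tune`.  A subject's ensemble
probability is the unweighted mean of the members' probabilities from the
one fold where the subject was held out; no training computation touches
held-out rows.  Threshold metrics use 0.5; AUC is the Mann-Whitney rank
statistic.

Stage comparison offers two methods.  `rank_sum_probs` runs a two-sample
Wilcoxon rank-sum test on the two models' out-of-fold probability vectors;
it reproduces the scale of the published U statistics (≈ n²/2 under the
null for n = 73) but its inferential target — "are the two probability
distributions shifted?" — is not a standard AUC-difference test, so it is
the default for comparability, while the paired DeLong test (`delong`,
implemented here since no installed package provides it) is recommended
for actual inference.  Univariate group comparisons are normality-gated:
t-test only when Lilliefors and Shapiro-Wilk are both non-significant
(p > 0.05) in both groups, Mann-Whitney otherwise; categorical variables
use chi-square without continuity correction; Pearson correlations are
casewise-complete with per-cell n, uncorrected by default (a
Benjamini-Hochberg option exists behind a flag).

## Synthetic cohort generator

The generator's defaults are the study conditions: 56 ADHD / 79 TDC, sex
ratios 45:11 and 33:46 (deterministic allocation), ages 8.38 ± 1.58 vs
8.80 ± 1.82 years, ADHD-RS scale parameters per group, and per-group
mean ± SD for each of the 33 selected eye-tracking features.  Feature
cells without published parameters get neutral defaults identical in both
groups (no diagnostic signal); clinical/behavioral instruments without
published distributions default to T-scores 60 ± 10 (ADHD) vs 50 ± 10
(TDC) — synthetic placeholders, clearly not published values.  73 subjects
(50 ADHD / 23 TDC) carry complete clinical/behavioral batteries,
mirroring the published complete-case pattern.

Distributions are truncated normals (truncation at 0 for non-negative
features; counts rounded), with the underlying parameters moment-matched
whenever naive truncation would bias the mean by more than 0.5 %.
Features are independent by default — no covariance was published — with a
one-factor within-task option to stress collinearity handling.  Because
independent draws add their group separations more cleanly than correlated
real features would, synthetic classification performance is optimistic;
passing tests show the pipeline is correct and self-consistent, not that
real-cohort accuracy would reach the same level.

### Gaze-stream realisation and its guarantee

In `gaze_streams` mode each subject's target vector is realised as an
explicit dwell/jump schedule (see `gazescreen._plan`): dwell boundaries
snapped to the 30 Hz sample grid so detected durations and counts are
exact; per-trial latencies planted by ending the trial's FP dwell at
`governing onset + latency`; amplitudes realised by placing consecutive
dwell centroids at the planned pixel distance (uniform jitter ≤ 8 px
perturbs centroids by a few pixels); samples emitted only during dwells so
slow large movements cannot masquerade as fixations; single invalid
marker samples placed in chosen gaps to split viewing segments.  The 30 Hz
default simulation rate is a recording property, not a claim about the
original hardware (whose rate is unpublished).

Running detection + extraction on the emitted stream recovers every
planned quantity to within sampling-grid rounding (sub-percent).  What is
*not* always recoverable is the published target itself: some target
combinations are geometrically or mutually impossible, and the planner
resolves them by a fixed priority — duration/latency totals, then degree
totals, then counts, then means, then maxima, then SDs — recording every
adjustment in its `PlanReport` (`generate_gaze_recording` raises on
adjusted targets unless `on_infeasible="adjust"`).  The structural
infeasibilities under the default geometry are worth listing because they
bound what the cohort-level calibration can reproduce:

* per-saccade amplitude means of 37–43° exceed the ≈ 35° screen diagonal,
  so the degree-mean cells for PST, AST and MGST are clipped to ≈ 33°;
  amplitude SDs near 30° exceed the Bhatia-Davis bound for bounded values
  with such high means;
* the AST cells are jointly over-constrained: 1132 fixations × the 100 ms
  grid minimum exceeds the 104 s total fixation duration, and covering 48
  five-second trial windows is impossible within the fixation + saccade
  duration budgets, so the planner plants the trial prefix that preserves
  the latency total and trades away fixation count and degree total;
* independently drawn per-subject targets can conflict in the tails
  (a large degree total with a tiny saccade-duration total); the cohort
  sampler enforces the mechanical couplings (each saccade costs at least
  one sample period and spans at most the screen diagonal) before
  planning, which perturbs the affected marginals by ≈ 1 %.

Totals and duration-family features — including the two cohort
calibration cells recomputed by `scripts/acceptance.py` (the MGST total
saccade amplitude in the ADHD column and the PST total fixation duration
in the TDC column) — are unaffected and reproduce their published group
means within sampling error at n = 500 per group.

## Quality control and enrollment

A recording is excluded when its coordinates stay within 1 px for ≥ 2 s
(a frozen tracker; real fixational jitter exceeds a pixel, so steady
fixation is not flagged) or when the valid-sample centroid lies off
screen; degenerate recordings are marked incomplete.  The enrollment
helper reproduces the published flow arithmetic: 250 recruited − 7
pre-enrollment − 108 eye-tracking exclusions = 135 completing (56/79).

## Problem sizes and numerical choices

Simulation-based tests run at sizes chosen to keep the default suite
practical while leaving the statistics interpretable: forests of 40–100
trees in unit tests and 48 trees in the selection-recovery study (the
2000-tree default remains the analysis setting), 500 subjects per group
for cohort calibration, 1000 random streams for the detector/oracle
equivalence sweep, and 300–500 replicates for null-calibration checks.
Integer allocation uses largest-remainder rounding so totals are exact on
the sample grid; ties in selection and tuning resolve deterministically
(documented above); every stochastic component takes an explicit seed, and
the pipeline derives per-stage seeds as `sha256(master_seed:stage) mod
2³¹`, making end-to-end runs byte-reproducible.

## Known limitations

* Synthetic gaze has no main-sequence kinematics, no head movement, and
  no blink structure; saccade gaps are sample-free rather than showing
  in-flight samples.
* Independent feature draws overstate multivariate separability (see
  above); classification metrics on synthetic cohorts are upper bounds.
* The degree-family unit convention cannot reconcile every published
  magnitude with the physical display; the affected cells are clipped and
  reported, never silently rescaled.
* The selection procedure's shared-CV optimism is reproduced by design;
  use an outer loop before trusting its accuracy estimates on real data.
  A related caveat: because the best set maximises a noisy CV accuracy,
  weakly informative features (d ≈ 0.6 at n = 135) are not reliably
  retained — replicates exist where the accuracy-argmax set omits one of
  two planted signal features even with large forests.  Treat retained
  sets as candidate, not definitive, biomarker panels.
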