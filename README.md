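# poseform

Computational core of an on-device AI exercise coach, rebuilt as a
testable Python library and CLI: pose-landmark-stream smoothing,
joint-angle form assessment with misalignment detection and repetition
counting, rule-based corrective and periodized exercise prescription,
IPAQ-SF / FMS / GXT scoring, and the pre/post statistics of a
single-arm training trial. Everything runs on synthetic landmark
streams and synthetic cohorts — no video, camera, or clinical data
needed.

## Who this is for

Researchers and engineers building or evaluating markerless
exercise-feedback systems (digital health, sports science,
physiotherapy tech) who need the *analysis* layer — what happens after
a pose estimator has produced 33 named 3-D body landmarks per frame —
as reproducible, unit-tested code.

## What it computes

**Form assessment.** A joint angle is the interior angle at a vertex
landmark, `θ = arccos( û·v̂ )`, between rays toward a proximal and a
distal landmark (hip: shoulder–hip–knee; knee: hip–knee–ankle; ankle:
knee–ankle–foot-index). Each monitored joint carries a reference angle
and tolerance band (squat bottom: hip 90°, knee 90°, ankle 75°, ±10°);
a joint is *green* when |measured − reference| ≤ tolerance, *red*
otherwise, and form accuracy maps the excess deviation to a [0, 100]%
score. Repetitions are counted by a hysteretic three-state machine on
the primary joint's angle (standing → descending → bottom → standing).
Landmark trajectories are denoised causally by a per-coordinate
constant-velocity Kalman filter followed by an EMA
(`y_t = α·x_t + (1−α)·y_{t−1}`, α = 0.3).

**Prescription.** A 16-week, 48-session plan (3 non-consecutive days
per week, 30-min sessions, 09:00–22:00) with phase bands 60–70% 1RM
(weeks 1–4), 70–80% (5–8), 75–85% (9–16); Brzycki initial loads
(`1RM × (37 − reps)/36`, 0.80 × 1RM at 8 reps); progression of +2% load
per set completed beyond the prescription, gated on form quality.

**Questionnaire scoring.** IPAQ-SF MET-minutes
(`MET × days/week × min/day`; 8.0 / 4.0 / 3.3 METs) with the standard
cleaning rules (drop bouts < 10 min, 960 min/day cap, 10,000
MET-min/week cap) and Low / Moderate / High categories; FMS composite
(best of three attempts per movement, pain ⇒ 0, max 21); GXT
maximal-effort criteria (VO₂ plateau, RER ≥ 1.10, HR ≥ 90% of 220 −
age; ≥ 2 required).

**Trial statistics.** Shapiro–Wilk-gated paired t / Wilcoxon
signed-rank tests, Cohen's d (pooled-SD and difference-SD variants),
Wilcoxon effect size r = |Z|/√N, ICC(2,1) rater agreement, and cohort
attrition/adherence accounting.

**Synthetic data.** A sagittal four-segment squat generator with exact
kinematic ground truth and controllable form-error modes
(insufficient depth, knee valgus, trunk lean, heel rise), jitter and
occlusion; and a paired pre/post cohort generator with configurable
effect structure and attrition.

## Worked example

Generate a jittered 5-repetition squat stream and analyze it:

```bash
poseform simulate squat --seed 7 --reps 5 --jitter-sd 0.005 --out .
poseform analyze squat_stream.jsonl --exercise barbell_squat --out report
```

`report/session_report.json` contains:

```json
{
  "exercise": "barbell_squat",
  "n_reps": 5,
  "session_accuracy": 100.0,
  "deficiencies": [],
  "muscles": ["quadriceps", "gluteus maximus", "hamstrings"]
}
```

All five repetitions were detected despite the landmark jitter, and the
bottom-of-rep posture stayed inside every tolerance band
(`rep_report.csv` shows, e.g., rep 1 hip 90.43° vs reference 90°,
deviation +0.43°, green). Injecting a form error changes the diagnosis:

```bash
poseform simulate squat --seed 7 --reps 5 --error insufficient_depth=25 --out shallow
poseform analyze shallow/squat_stream.jsonl --level beginner --out shallow_report
```

now reports `"n_reps": 0` (the lifter never reaches the counting
depth), flags `insufficient_depth`, and recommends the beginner
corrective drill *box squat to parallel* (12-s demo). Other
subcommands: `prescribe`, `ipaq-score`, `fms-score`, `stats`,
`simulate cohort`.

## Layout

- `src/poseform/pose_io.py` — landmark-stream model, JSONL/CSV dialects, gap filling
- `src/poseform/smoothing.py` — Kalman + EMA cascade
- `src/poseform/kinematics.py` — joint angles, exercise configs, extraction
- `src/poseform/form_engine.py` — misalignment, accuracy, rep FSM, recommendations
- `src/poseform/prescription.py` — scheduling, phases, loads, progression
- `src/poseform/questionnaire.py` — IPAQ-SF, FMS, GXT scoring
- `src/poseform/outcome_stats.py` — paired tests, effect sizes, ICC, cohort accounting
- `src/poseform/synth.py` — squat and cohort generators with ground truth
- `src/poseform/cli.py` — `poseform` command
- `docs/methods.md` — models, assumptions, numerical choices, limitations
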