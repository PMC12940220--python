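# Methods

This note records the models implemented in `poseform`, the assumptions
behind them, the defaults and why they were chosen, and what the
synthetic-data tests do and do not demonstrate.

## Landmark streams

A stream is a time-ordered sequence of frames, each carrying the full
33-landmark full-body topology (nose through foot-index points) as
`(x, y, z, visibility)`. Coordinates are image-normalized with origin
top-left, x right, y down (camera convention) and z a signed depth in
the same scale, toward-camera negative. Upstream estimators do not
always document their normalization; this is our assumption, stated
here and in the format schema, not a property we can verify against any
published contract.

Two dialects are supported. JSONL is primary: a versioned header record
(`schema`, `version`, `fps_nominal`, `metadata`), then one record per
frame with a 33 × 4 landmark array in canonical topology order —
stream-appendable and diff-friendly. The wide CSV dialect
(`frame_index`, `timestamp_ms`, 33 × 4 named columns) is for
spreadsheet inspection and drops free-form metadata. All floats are
serialized with 17 significant digits so round trips are bit-exact;
decimal separators are locale-independent. Timestamps are optional on
input and synthesized from `frame_index / fps_nominal` (default 30 fps)
when absent.

**Gap filling.** A gap is a maximal run of frames where a landmark's
visibility falls below `min_visibility` (default 0.5). Gaps up to
`max_gap_frames` (default 10 ≈ 0.33 s at 30 fps) bracketed by visible
frames are filled by timestamp-weighted linear interpolation and
flagged imputed; longer or boundary gaps are reported untouched.
Imputed samples are assigned visibility exactly `min_visibility`, which
makes the operation idempotent. The defaults are our choice of a
conservative occlusion-bridging window; no published values exist.

## Temporal smoothing

Each coordinate channel passes through a causal 1-D constant-velocity
Kalman filter, then an EMA with the conventional weight-on-new-sample
reading of α = 0.3. The filter state is (position, velocity) with
unit-step transition; defaults are measurement variance 1e-4 and
process variance 1e-5 (normalized units², i.e. sub-pixel estimator
jitter over smooth limb motion), both configurable. The order is fixed
Kalman → EMA and no backward pass is used, mirroring a real-time
feedback loop.

Two different claims must be kept apart:

* the **jitter metric** (mean frame-to-frame landmark displacement)
  never increases under smoothing for jittered streams — this holds
  across noise levels and is tested over 20 seeded replicates;
* the **mean squared deviation from the clean reference** shrinks only
  when the noise floor exceeds the filter's lag error. At squat-speed
  motion the EMA's ~2-frame lag costs roughly 0.01–0.02 normalized
  units at peak velocity, so the MSD test uses a heavy-jitter condition
  (σ = 0.02); at small σ the causal cascade trades accuracy for
  stability, which is the intended real-time behavior, not a defect.

No tracking-stability percentage is reported: that metric has no
defined formula here, so the suite reports the jitter ratio instead.

## Joint angles and exercise presets

The joint angle at vertex *b* between rays *b→a* and *b→c* is computed
from the normalized dot product, clamped to [−1, 1] before arccos;
results lie in [0, 180]°. Angles are invariant under rigid rotation,
translation, uniform scaling, and the a↔c swap (property-tested).
Computation is 3-D by default with a planar (x, y) mode per exercise
config for streams with unreliable depth.

Triplets follow standard sagittal conventions — hip:
shoulder–hip–knee; knee: hip–knee–ankle; ankle:
knee–ankle–foot-index — since the joints, not the triplets, are what a
reference posture names. Squat references (hip 90°, knee 90°,
ankle 75°) are evaluated at the detected bottom-of-rep frame; the
tolerance is ±10° by default. That band is our documented default for
"predetermined angular thresholds" that are never printed anywhere.
Bilateral chains are averaged (`side="mean"`) by default; unilateral
analysis is available per side. A joint whose triplet falls below the
visibility floor on both sides is flagged missing for that frame rather
than guessed.

The seven-exercise catalog (squat, bench press, deadlift, row, military
press, pull-up, dips) ships as a YAML resource with per-exercise
joints, FSM thresholds and the 2–3 primary target muscles. The squat is
the fully modeled archetype; the other lifts are threshold-level
presets on their primary flexion joint (elbow for presses, rows, dips
and pull-ups; knee for the deadlift), sufficient for rep counting and
single-joint reference checks.

## Form engine

**Misalignment.** Deviation = measured − reference; green iff
|deviation| ≤ tolerance. **Form accuracy** per joint is
`100 · max(0, 1 − max(0, |dev| − tol)/tol)`: full credit inside the
band, linear decay to zero at twice the tolerance; the frame score is
the mean over assessed joints. The formula is ours — any monotone
mapping would do; this one is continuous, equals 100 exactly on
in-tolerance frames, and floors at 0. Accuracy is reported per rep
(bottom frame) and as the session mean, since an aggregation level is
not prescribed anywhere.

**Repetition counting.** Three-state hysteretic machine on the primary
joint angle: standing → descending when the angle drops below the
descent threshold (squat default 150°), → bottom below the bottom
threshold (default 100°), rep emitted on recovery above descent +
hysteresis (default 5°). A single sample may advance several
transitions, so dips faster than the sampling rate are not lost; NaN
samples (missing joint) are skipped without changing state. Descents
that never reach the bottom threshold are discarded by the counter but
retained as *attempts* for diagnosis, so a consistently-too-shallow set
yields zero reps **and** an insufficient-depth finding. The counter is
equivalence-tested against an independent crossing oracle on 500 random
piecewise-linear series.

**Deficiency codes** are derived from the direction of deviation at
each attempt's deepest frame: knee angle above reference + tolerance →
`insufficient_depth`; hip angle below reference − tolerance →
`trunk_lean`; ankle angle above reference + tolerance → `heel_rise`;
mediolateral knee offset from the hip–ankle line beyond 0.04 normalized
units → `knee_valgus`. The corrective rule table (YAML resource) maps
each code deterministically to one recommendation per difficulty level
(beginner / intermediate / advanced) with 10–15 s demo durations.

## Prescription

The plan is 16 weeks × 3 sessions on a fixed weekday pattern whose
cyclic pairwise gaps are ≥ 2 days (24-h recovery; consecutive days
rejected), each session 5 + 20 + 5 min starting inside 09:00–22:00
(sessions must also *end* by 22:00). Two phase encodings ship: the
default intensity table (1–4 / 5–8 / 9–16, i.e. 60–70 / 70–80 / 75–85
%1RM with 12–15 / 8–12 / 6–10 reps at RPE 13–14 / 15–16 / 16–17) and a
narrative variant (1–4 / 5–12 / 13–16); the two appear side by side in
the source material and disagree, so the intensity table is the default
and the other is selectable.

Initial loads use the Brzycki relation `1RM × (37 − reps)/36` with the
conventional 0.80 × 1RM anchor at an 8-rep target, rounded to an
equipment increment (default 2 kg, disableable). Progression implements
the "2%-for-1-set" rule as +2% load per set completed **beyond** the
prescription, gated on session form accuracy ≥ 80% (our default for
"form quality maintenance"); loads never decrease and never move when
the gate fails. Under this reading, exceeding the prescription by one
set yields exactly a 2% increment, which is the printed constant; an
alternative reading (+2% already for meeting the prescription) exists
but would make the per-extra-set increment 4%.

## Questionnaire scoring

**IPAQ-SF.** Cleaning first: bouts < 10 min dropped; each day's summed
minutes across classes capped at 960, truncating walking first, then
moderate, preserving vigorous (the priority is configurable; some
scoring services cap per class instead). Scoring uses
`MET × active days × mean min/active day` per class (the product equals
MET × weekly minutes), METs 8.0 / 4.0 / 3.3, and a 10,000 MET-min/week
cap on the total, with every action logged. `min/day` as the mean over
active days after cleaning follows the IPAQ committee convention; the
source protocol does not say.

Categories: High = 1500 MET-min/week with vigorous activity on ≥ 3
days, or 3000 with any combination on ≥ 7 days; Moderate = ≥ 600
MET-min/week over ≥ 5 active days of any combination. The official
short-form protocol lists further Moderate combinations (e.g. ≥ 3
vigorous days of ≥ 20 min, or ≥ 5 moderate/walking days of ≥ 30 min)
that the material we follow mentions only by example; they are
deliberately **not** implemented, and such diaries fall to Low. This is
a completion choice, enumerated here so the boundary
(600 MET-min/week at 5 active days) is exact and testable. Threshold
comparisons absorb float accumulation with a 1e-9 epsilon.

**FMS.** Seven movements, up to three attempts each scored 0–3, best
attempt recorded, reported pain forcing 0 for that movement; composite
is the sum, range [0, 21]. **GXT.** Maximal effort holds when ≥ 2 of:
VO₂ plateau (accepted as an input flag; breath-by-breath processing is
out of scope), RER ≥ 1.10, HR ≥ 90% of the age-predicted maximum, taken
as 220 − age since no formula is specified.

## Outcome statistics

Differences (post − pre, pairwise deletion) are gated by Shapiro–Wilk
at α = 0.05: normal → paired t, else Wilcoxon signed-rank. The Wilcoxon
p is exact by full sign-flip enumeration with midranks up to n = 12
(ties make the classical exact distribution inapplicable), scipy's
exact distribution up to n = 25 without ties, and a
continuity-corrected normal approximation above; zero differences are
dropped. The mean-difference CI is t-based on the differences
(df = n − 1).

Effect sizes: Cohen's d is reported in both the pooled-SD form
(`mean_diff / sqrt((sd_pre² + sd_post²)/2)`) and the difference-SD form
(`mean_diff / sd_diff`), because published pre/post studies mix the two
— the validation study defines the pooled form but its printed d for
the strength outcome (1.148) is only consistent with the difference-SD
form, which the suite verifies by back-computing sd from the printed CI
([3.76, 5.01], n = 146 → d ≈ 1.149). The Wilcoxon effect size is
r = |Z|/√N from the normal-approximation Z; the |Z|/N form that appears
in print is dimensionally inconsistent with its own values (r = 0.797
at N = 146 would need Z ≈ 116) and is treated as a typo.

ICC is the two-way random-effects, absolute-agreement, single-measure
ICC(2,1), computed directly from the ANOVA decomposition
`(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)` so that degenerate
but legitimate inputs (perfect agreement) return exactly 1.0; it
matches pingouin's ICC(A,1) to 1e-10 on non-degenerate data (tested).

Cohort accounting reports counts, 1-decimal percentages, retention, and
adherence as mean ± SD sessions and percent of the 48-session
prescription.

## Synthetic generators

**Squat streams.** A sagittal four-segment linkage (foot 0.15, shank
0.25, thigh 0.25, trunk 0.30 of image height — round-number
anthropometric mean ratios; only angles matter downstream) driven by a
raised-cosine knee-angle trajectory between standing (175°) and bottom
(90°) at 3 s/rep and 30 fps, with 0.5-s standing holds. The trunk is
held parallel to the shank (standard deep-squat cue), making the hip
angle equal the knee angle by construction, and the foot pitch ramps
with shank rotation so the full-depth posture is exactly hip 90 /
knee 90 / ankle 75. Non-leg landmarks ride rigidly on the trunk with
arms held forward. Error modes perturb the linkage: insufficient depth
raises the bottom knee angle; trunk lean tilts the trunk beyond the
shank-parallel cue (closing the hip angle); heel rise adds foot pitch
(opening the ankle angle); knee valgus pulls the knees toward the
midline, growing with depth like the real deficiency. Gaussian jitter
and visibility-based occlusion are applied last. The paired truth
object carries the exact angle series and rep windows.

What the generator does **not** emulate: estimator-correlated noise
(real keypoint error is structured, not i.i.d. Gaussian), soft-tissue
and clothing artifacts, camera perspective and lens distortion,
anthropometric variation, and non-squat movement archetypes beyond
single-joint threshold behavior. Passing tests therefore demonstrate
algorithmic correctness on known kinematics, not field accuracy on real
video.

**Cohorts.** Per subject and outcome, pre ~ N(pre mean, pre SD) and
change ~ N(change mean, change SD); defaults mirror the validation
trial's effect structure (e.g. strength change 4.39 ± 3.85 kg on a
34.67 ± 11.34 kg baseline, n = 216 enrolled). Dropout counts are the
rounded category fractions of enrollment (0.181 / 0.106 / 0.037 →
39 / 23 / 8 of 216, leaving 146 completers); which subjects drop is
randomized under the seed, and dropouts carry missing post values.
Real cohorts have skewed, bounded, correlated outcomes; the normal
model is deliberately simple because the tests target estimator
calibration (type-I error, CI coverage, parameter recovery), not
distributional realism.

## Problem sizes and runtimes

The suite's stochastic checks use: 2,000 null replicates of n = 30 for
the type-I error band [0.03, 0.07]; 100 replicates of n = 146 for
parameter recovery (± 0.8 kg in ≥ 95); 500 random series for the
rep-counter oracle; 20 replicates for the jitter property; n = 10,000
for generator moment convergence (2%). These sizes put every Monte
Carlo estimate's standard error well inside the asserted band while
keeping the full suite under a minute of compute.

## Known limitations

* Exercise presets other than the squat are single-joint stubs; no
  multi-joint reference postures for presses or hinges.
* The valgus metric uses the depth axis as a mediolateral proxy, which
  assumes a roughly frontal camera; a side-on recording would need a
  different axis convention.
* IPAQ Moderate sub-rules beyond the 600 MET-min / 5-day clause are
  intentionally absent (see above); diaries qualifying only under those
  official sub-rules are classified Low here.
* The smoothing cascade is tuned for stability, not minimum-lag
  tracking; fast ballistic movements will be underestimated at the
  turnaround.
* Statistical routines assume exchangeable subjects; no clustering,
  covariates or multiplicity handling (single-arm, five outcomes,
  reported as-is).
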