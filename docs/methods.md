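# Methods

`saccscreen` reproduces, end to end and on synthetic data, a saccadic
eye-movement screening study for primary open-angle glaucoma (POAG): gaze
traces are simulated for three cohorts (healthy controls, preperimetric POAG,
moderate POAG), saccades are detected with a velocity-threshold algorithm,
the standard saccadic parameters are extracted and aggregated per subject,
and a nested cross-validated Random Forest discriminates patients from
controls. This note documents the generative model, the measurement pipeline,
the statistical machinery, and the design choices that were genuinely open.

## Oculomotor tasks

Two paradigms are generated at 1000 Hz (monocular, degrees of visual angle,
screen-centre origin, +x rightward, +y upward), with the trial clock starting
at fixation onset and the target appearing after a uniform 1000–1500 ms
fixation period:

* **Static task** — a target at 10° eccentricity at one of eight polar angles
  (0°, 45°, …, 315°), visible for 1000 ms; 64 trials per session, 8 per
  location, shuffled under a no-immediate-repeat constraint on location.
  Traces run 1200 ms past target onset so late corrective saccades are
  captured.
* **Moving task** — a target appears at 15° eccentricity and moves
  centripetally at 5, 10 or 15 °/s along one of three axes (0°, 120°, 240°),
  continuing through the centre to the opposite side; the fixation cross
  disappears 200 ms after motion onset. 72 trials per session, 8 per
  speed × axis cell, fully shuffled. Traces run 3000 ms past motion onset,
  which covers the centre crossing at all three speeds.

The three motion axes are a design choice (the protocol fixes their number,
not their directions); a rotationally symmetric set avoids direction bias.
The static task is treated as a step paradigm (fixation cross replaced by the
target); the moving task is a 200 ms-overlap/gap design as described.

## Subject model

Each cohort is described by a `GroupProfile`: between-subject means and SDs
of static/moving latency, static gain, peak velocity at the group's mean
static amplitude, endpoint error, intercept error at the 10 °/s reference
speed, plus clinical covariates (visual-field mean deviation MD in dB,
peripapillary RNFL thickness in µm) and speed-dependence slopes. The default
profiles carry the published group values (e.g. control static latency
221 ± 24 ms, moderate gain 0.83 ± 0.09, moderate intercept error
3.64 ± 1.12°, moderate MD −8.56 dB). Printed SDs are interpreted as
between-subject SDs of subject means; within-subject trial noise is separate
(latency SD 25 ms per trial, fixation jitter 0.08° per axis).

A single latent severity factor z couples a subject's deficits: every trait
mean is realized as

    m_i = μ_g + σ_g · (√f · s · z_i + √(1−f) · ε_i),

with s = +1 for latencies and errors, s = −1 for gain, peak velocity, MD and
RNFL, and f = `shared_severity_fraction`. f controls how redundant the
feature space is: f = 1 collapses all deficits onto one axis, f = 0 makes
them independent and makes multi-feature classification unrealistically
easy, and the clinical correlation |r(intercept error, MD)| grows with f.
The default **f = 0.2** was fixed by a single calibration pass against the
published operating points (the three classification AUCs and the r ≈ −0.7
clinical correlations); see "Calibration" below. Positive-only traits are
floored (gain ≥ 0.3, latency ≥ 120 ms, peak velocity ≥ 120 °/s).

**Moment-matched cohorts.** When a cohort is drawn, the latent-factor and
residual columns are orthonormalized across subjects (exact sample mean 0,
SD 1, zero sample cross-correlation; marginals unchanged). Realized cohort
moments then equal the profile values exactly rather than fluctuating with
the seed, so parameter-recovery checks measure pipeline bias, not
Monte-Carlo luck. Subjects are consequently weakly exchangeably dependent,
as in standard moment-matched simulation designs; for n ≤ 10 the sampler
falls back to per-column standardization, and `moment_match=False` restores
i.i.d. draws.

## Saccade kinematics

Saccades use a raised-cosine velocity profile, for which displacement is
exactly the amplitude A and peak velocity exactly V = 2A/D (A in deg, D in
s). Peak velocity follows a main-sequence law V(A) = K·A^0.6 with K set per
subject so that the subject's drawn peak velocity is realized at the group's
mean static amplitude; durations then come out near 50 ms for 8–10°
saccades and do not differ systematically between groups, while small
corrective saccades get realistically short durations (~20 ms at 1°).

**Latency semantics.** Saccade latency is operationally defined — here and
in the measurement convention the printed values come from — as the time
the 2-D speed first exceeds 30 °/s. The generator therefore places each
primary saccade so that its analytic 30 °/s crossing falls at the drawn
latency (movement starts earlier by the closed-form crossing offset,
≈4–5 ms for a 9°/50 ms saccade). Trial latency draws are
N(subject mean, 25 ms) floored at 90 ms, with the moving-task mean shifted
linearly with target speed around the 10 °/s reference (faster targets
elicit earlier saccades; slopes −2.2/−1.5/−0.8 ms per °/s for
control/preperimetric/moderate, so the group gap widens at high speed).

**Landing points.** Static: landing = gain · target + isotropic Gaussian
scatter. The expected Euclidean endpoint error of such a landing is the mean
of a Rice distribution with bias b = 10·|1−gain|; the scatter σ is obtained
per subject by numerically inverting the Rice mean to hit the subject's
drawn endpoint-error mean. Because a Rice mean can never fall below its
bias, subjects whose hypometria alone exceeds their drawn error are floored
at e = b + 0.02°; a one-time Gauss–Hermite recalibration of the
endpoint-error draw centre keeps the cohort mean on the published group
value despite this floor. Moving: the landing sits v·L/1000 degrees behind
the target's position at (estimated) saccade completion plus isotropic
scatter (set to 0.35 of the expected error); the aiming lag L is calibrated
per subject and per speed by the same Rice inversion so that the expected
intercept error equals the subject's drawn value at 10 °/s and grows
linearly with speed (slopes 0.05/0.135/0.24 ° per °/s for
control/preperimetric/moderate — the speed dependence is qualitative in the
source, these slopes are part of the package's calibration, see below). A
speed-varying lag is required: a single lag per subject would force slopes
of e/10 per °/s, far steeper than any plausible calibration.

**Corrective saccades.** Poisson-many per trial (rates 0.3/0.7/1.4 for
control/preperimetric/moderate — chosen to match the qualitative
"occasional" vs "multiple corrective saccades" description), each starting
150–250 ms after the previous saccade ends and covering 80% of the
then-current residual error toward the (possibly moving) target; correctives
below 0.25° are dropped.

**Fixation jitter** is Gaussian white noise filtered with a 20 ms Gaussian
kernel and analytically rescaled to 0.08° SD per axis; its velocity stays
far below the 30 °/s detection threshold. Blinks, drift, smooth pursuit
after target acquisition, and measurement dropouts are not simulated — the
modelled recordings correspond to artifact-free accepted trials. Passing
tests therefore demonstrate correctness of the pipeline under clean
oculomotor signals, not robustness to recording artifacts.

## Saccade detection

Per-axis central differences (one-sided at the boundaries) give a 2-D
velocity; its magnitude is smoothed with a centred 5 ms moving average.
Saccades are maximal runs of smoothed speed above 30 °/s: onset = first
sample above threshold, offset = first sample back below. Runs separated by
< 20 ms are merged; runs shorter than 10 ms or with displacement < 0.3° are
discarded as jitter. The 5 ms window attenuates a 50 ms raised-cosine peak
by < 1%, and peak velocity is reported from the smoothed speed, consistent
with detection. Event positions are read from the trace at the last
quiescent sample before onset and at the offset sample, so the sub-threshold
takeoff displacement is not lost; detected amplitudes match injected ones to
< 0.1° on noise-free traces. The threshold is the published value; the
differentiation scheme, smoothing window and noise-rejection margins are
conventional choices for 1000 Hz data and are exposed as parameters.

The primary saccade of a trial is the first detected event with onset
80–600 ms after the latency reference (target onset for static trials,
motion onset — not the 200 ms-later gap cue — for moving trials), amplitude
≥ 1°, and direction within ±90° of the instantaneous target direction.
Trials without one are invalid; subjects with fewer than half their trials
valid per task are flagged for exclusion.

## Features

Per valid trial: latency, amplitude, gain (= amplitude / eccentricity), peak
velocity, duration, endpoint error (static; Euclidean distance from landing
to target) or intercept error (moving; distance from landing to the target's
position at saccade completion), and the count of later events. Subject
vectors are arithmetic means over valid trials; the moving-task latency and
intercept error are additionally binned per target speed, since the high
speed conditions separate the groups best. The classifier uses 13 features
(5 static, 8 moving); the corrective-saccade rate is extracted but excluded
by default since its role in the original feature set is unclear.

## Statistics and classification

* Group contrasts: Welch t tests on subject means with Holm–Bonferroni
  adjustment across the three pairwise contrasts per feature. Subjects
  contribute balanced trial counts and analysis operates on subject means,
  so this replaces the original random-intercept mixed models without
  changing the estimand; age is not simulated and therefore not adjusted
  for.
* ROC: rank (Mann–Whitney) AUC with ties counted ½; stratified percentile
  bootstrap 95% CI (2000 resamples); Youden-optimal operating point with
  ties broken toward higher sensitivity.
* Classification: Random Forest, subject-level nested CV. Outer loop:
  stratified 10-fold over subjects (the CV unit is always the subject, never
  the trial, so no leakage between training and test). Inner loop:
  stratified 2-fold grid search over trees {100, 200, 500} × max depth
  {3, 5, 7, 10} × min samples per split {2, 5, 10}, selecting by inner-CV
  accuracy, ties toward the earliest grid cell. The inner evaluator grows
  one bootstrap forest per (depth, min-split) cell with bare decision trees
  (sqrt feature subsampling, averaged probabilities — the standard RF
  recipe) and scores it at 100/200/500 trees, so the whole 36-cell grid is
  priced at twelve 500-tree builds per fold; the outer-fold model refit uses
  scikit-learn's `RandomForestClassifier` with the selected parameters.
  Out-of-fold class probabilities are pooled into a single ROC per contrast
  (one AUC + CI per contrast, as reported), with per-fold AUCs and their SD
  as a stability check.
* Permutation importance: mean drop in out-of-fold AUC when one feature
  column is shuffled within a fold's test subjects, averaged over 50 repeats
  and the outer folds.
* Three binary contrasts are evaluated against controls: both patient groups
  pooled ("any glaucoma"), moderate only, preperimetric only.

## Calibration

The published group tables fix the marginal means and SDs but not the joint
structure; three quantities were fixed by numeric calibration against the
published operating points (the three classification AUCs — 0.92 any
glaucoma, 0.97 moderate, 0.87 preperimetric — and the r ≈ −0.7 clinical
correlations), then frozen:

* `shared_severity_fraction` f: a grid {0.1, 0.2, 0.3, 0.4} at 100
  subjects/group shows AUC rising only weakly as f falls while the MD/RNFL
  correlations weaken from −0.61 to −0.53; f = 0.2 keeps the correlations
  inside the plausible band.
* The speed-dependence slopes. With the Random Forest protocol fixed, the
  high-speed moving-task features carry the classification: slope sets were
  evaluated once on a coarse grid and frozen at intercept-error slopes
  0.05/0.135/0.24 ° per °/s and latency slopes −2.2/−1.5/−0.8 ms per °/s,
  which reproduce the published AUC ordering and levels with a few points
  of margin. (Notably, a linear model on the same features exceeds the
  forest here — the synthetic feature space is additive-Gaussian by
  construction, whereas on the original data the forest was the strongest
  classifier; matching the printed forest performance therefore requires
  the high-speed group differences to do more of the work, exactly as the
  original feature-importance analysis reports.)
* The endpoint-error draw centre per group (Gauss–Hermite root-finding, see
  above), which is fully determined by the published means/SDs and the
  hypometria-floor geometry.

Group means are unaffected by the slope calibration (speed bins are
symmetric around the 10 °/s reference), so parameter recovery and the
clinical-correlation structure do not depend on it.

## Problem sizes

Parameter-recovery checks run at 50 subjects per group (the between-subject
2-SE band at n = 50 is the acceptance yardstick); classification checks run
at 100 subjects per group with three independent replicate cohorts and a
majority/median rule, which keeps the pooled-AUC Monte-Carlo spread near
±0.01–0.02. The analysis scripts under `analysis/` run the study-sized
cohort (16 per group) for illustration; at that size AUC estimates carry
bootstrap CIs several points wide, exactly as in the original cohort.

## Numerical choices and degenerate inputs

* Rice-mean evaluations use exponentially scaled Bessel functions (no
  overflow); inversions use Brent root-finding to 1e-10.
* Velocity smoothing windows must be odd; traces must be uniformly sampled
  at 1 ms and at least 3 samples long.
* `target_position` refuses query times before target onset; zero-variance
  inputs to `pearson_r` and single-class inputs to AUC/CV raise errors
  rather than returning NaN.
* All randomness flows from explicit seeds through counter-based
  `SeedSequence` fan-out (per stage, group, subject), so cohorts are
  bit-reproducible; trial streams are independent of cohort size, while
  moment matching makes parameter draws cohort-dependent by construction.

## Known limitations

* The generator reproduces first- and second-moment structure and one
  latent severity axis; real oculomotor data have richer trial-level
  dynamics (sequential effects, fatigue, learning) and artifact structure.
* The speed dependence of latency and intercept error, the corrective-
  saccade rates, and f are calibrated, not measured — only their qualitative
  direction is anchored in the published results.
* Age is not simulated, so the original age-covariate adjustment has no
  counterpart here.
* Mixed-effects trial-level inference is intentionally out of scope; all
  inference is on subject means.
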