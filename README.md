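# saccscreen

Saccadic eye movements degrade early in primary open-angle glaucoma (POAG):
latencies lengthen, saccades become hypometric, and interception of moving
targets suffers — measurably even in *preperimetric* patients whose standard
visual fields are still normal. `saccscreen` is a complete, tested pipeline
for studying these effects in silico: it simulates 1000-Hz gaze recordings
for the two standard oculomotor tasks (saccades to static targets at 10°,
saccades to targets moving centripetally from 15° at 5/10/15 °/s), detects
saccades with the classical 30 °/s velocity-threshold algorithm, extracts
the per-trial saccadic parameters, and evaluates their diagnostic value with
nested cross-validated Random Forest classification and ROC analysis.

It is aimed at oculomotor/visual-psychophysics researchers who want a
ground-truth-annotated testbed for saccade detectors and for subject-level
diagnostic classifiers on small clinical cohorts.

## The model in brief

* **Cohorts.** Three groups (control, preperimetric POAG, moderate POAG)
  with published-value profiles: e.g. static latency 221/237/256 ms, gain
  0.94/0.91/0.83, peak velocity 371/352/336 °/s, intercept error
  1.95/2.78/3.64°, MD −0.23/−0.87/−8.56 dB, RNFL 96.2/82.7/68.3 µm. A
  latent severity factor (loading fraction f = 0.2) couples each subject's
  deficits and clinical covariates.
* **Saccades.** Raised-cosine velocity profiles (peak velocity exactly
  2A/D) on a main sequence V(A) = K·A^0.6; latency is defined — in the
  generator and the detector alike — as the 30 °/s threshold crossing.
  Landing-point scatter is calibrated by Rice-mean inversion so each
  subject's expected endpoint/intercept error equals their drawn value;
  moving-target interception uses a per-speed aiming lag (error = v·L/1000).
* **Detection.** Central-difference velocity, 5 ms moving-average smoothing,
  30 °/s threshold, 20 ms merge gap, 10 ms / 0.3° noise rejection.
* **Analysis.** Subject-mean features (latency, gain, peak velocity,
  endpoint/intercept error, overall and per target speed); Welch tests with
  Holm adjustment; rank AUC with stratified bootstrap CIs and Youden
  operating points; Random Forest with subject-level nested CV (outer
  stratified 10-fold, inner grid over trees {100,200,500} × depth
  {3,5,7,10} × min-split {2,5,10}) and permutation importance.

See `docs/methods.md` for assumptions, calibration and limitations.

## Worked example

The `analysis/` scripts run the study-sized experiment (16 subjects per
group) end to end and write their tables under `results/cohort/`:

```sh
python analysis/01_simulate_cohort.py   # cohort + ground-truth sidecars
python analysis/02_detect_saccades.py   # detection vs. ground truth audit
python analysis/03_extract_features.py  # per-trial and per-subject features
python analysis/04_group_stats.py       # group contrasts + clinical correlations
python analysis/05_classify.py          # nested-CV classification + importances
```

Output from this run (abridged):

```
02: detected 10502 events over 6528 injected (recall 1.0000, precision 1.0000)
    primary onset error vs threshold crossing: +0.25 +/- 0.39 ms
03:                static_latency_mean  ...  intercept_err_mean
    control                     222.68  ...                1.93
    preperimetric               235.73  ...                2.76
    moderate                    255.97  ...                3.59
04: moving_latency_mean  control vs preperimetric  +37.8 ms  p_adj 0.0044
    moving_latency_mean  control vs moderate       +79.1 ms  p_adj <0.0001
    intercept_err_mean   control vs moderate       +1.66 deg p_adj 0.0001
    correlations: intercept error vs MD r = -0.556, vs RNFL r = -0.581
05: any_glaucoma_vs_control:   AUC 0.871 (95% CI 0.742-0.969), sens 0.75, spec 0.875
    moderate_vs_control:       AUC 0.941 (95% CI 0.836-1.0),   sens 0.938, spec 0.938
    preperimetric_vs_control:  AUC 0.805 (95% CI 0.633-0.945)
    top features: intercept_err_15, moving_latency_15, intercept_err_mean, ...
```

Reading: the detector recovers every injected primary saccade with
sub-millisecond mean onset agreement; measured group means of the saccadic
parameters land on the generating profiles (e.g. moderate-group intercept
error 3.59° vs the generating 3.64°); moving-task latency and intercept
error separate the groups most cleanly and correlate with the clinical
severity metrics; and at n = 16/group the classifier's AUCs carry wide
bootstrap CIs — the acceptance script below reruns the protocol at a scale
where they stabilize near 0.95/0.99/0.90.

A one-command variant of the same pipeline (with a YAML config) is also
available:

```sh
saccscreen run-all --n-per-group 4 --seed 7 --out results/demo
```

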