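# tugait

Metric-scale Timed Up and Go (TUG) gait analysis from a single
**uncalibrated** consumer camera.

The TUG test — rise from a chair, walk ~3 m, turn 180°, walk back, turn
and sit — is a clinical workhorse for assessing mobility and, under
dual-task cognitive load, for screening early Parkinsonian risk. Automating
it at home runs into one physical obstacle: a single camera without
calibration cannot measure distance. `tugait` is for researchers and
engineers who have per-frame *pose keypoints* (2D pixels plus a
scale-ambiguous 3D skeleton from any off-the-shelf pose network) and want
metric gait parameters out of them, with nothing more than two tape-measure
numbers: the subject's height and the camera's mounting height.

## What it computes

1. **Self-calibration.** A pinhole camera with unknown vertical FOV and
   pitch θ is recovered by nonlinear least squares on upright frames: under
   the ground-plane constraint, an ankle pixel at row v maps to depth
   `Z = h_cam / tan(θ + arctan((v − c_y)/f))`, and the back-projected body
   height must match the known stature `H` at every calibration frame.
2. **Noise-adaptive depth fusion.** The metric-but-jittery geometric depth
   `Z_geo(t)` is blended with the smooth-but-scale-free 3D-pose depth
   `Z_dl(t)`: a windowed jitter level η(t) drives a piecewise-linear
   confidence `w(t) ∈ [0.1, 1]`, the prior is scale-aligned by
   `s = std(Z_geo)/std(Z_dl)` and mean-anchored, and
   `Z_final = w·Z_geo + (1 − w)·Z_dl′`.
3. **Phase segmentation.** A state machine on the pelvis-to-ankle vertical
   signal (sit-to-stand / stand-to-sit threshold crossings) and the
   shoulder depth difference `|Z_Lsh − Z_Rsh|` (each 180° turn is a
   prominent peak) labels Sit, Sit-to-Stand, Walk-1, Turn-1, Walk-2,
   Turn-2, Stand-to-Sit, Sit.
4. **Gait state vector.** Step events are prominent extrema of the fused
   foot depth difference `D(t) = Z_left − Z_right`, phase-restricted to the
   walks; the session is summarized as
   `x = [T_total, V_walk, T_turn, T_sts, N_total, N_walk, SL_mean, CV]`,
   with stride-length proxy `SL_k = |D(t_k)|` and variability
   `CV = 100·σ_SL/μ_SL` (a gait-automaticity biomarker).
5. **Hierarchical screening.** A two-stage L1-logistic cascade (Stage 1
   screens Normal vs abnormal with cross-validated penalty selection;
   Stage 2 grades Mild vs Parkinsonian-like at a fixed penalty), z-scored
   per training fold and evaluated by leave-one-out cross-validation.

A built-in simulator generates ground-truthed synthetic TUG sessions
(articulated stick figure, exact pinhole projection, pixel noise, burst
jitter, scale-ambiguous 3D stream) and labeled feature cohorts, so the
whole chain is testable without any recordings. See `docs/methods.md` for
the models, defaults and limitations.

## Worked example

Simulate a living-room session (camera 0.9 m, chair 4.6 m out, turn point
at 1.6 m, subject 1.76 m) and analyze it:

```bash
tug simulate --preset living_room --seed 7 --subject-height 1.76 --out demo/
tug analyze --kp2d demo/kp2d.json --kp3d demo/kp3d.json \
    --subject-height 1.76 --cam-height 0.9 \
    --truth demo/truth.json --out demo/report.json
```

Key numbers from `demo/report.json` (this exact invocation):

```
calibration:   fov 83.1 deg, pitch 12.4 deg, height residual 0.008 m
walking path:  near 1.51 m, far 4.51 m  ->  distance 2.994 m
state vector:  T_total 12.13 s, V_walk 0.538 m/s, T_turn 0.80 s,
               N_total 14, N_walk 14, SL_mean 0.466 m, CV 6.11 %
truth errors:  near 0.088 m, far 0.094 m, walking distance 0.006 m
```

Reading this: from 2 px-noisy keypoints alone the pipeline recovered the
camera (true preset: FOV 80°, pitch 12°), rebuilt the 3.0 m walking path to
within 6 mm, counted all 14 walking steps, and measured a mean stride proxy
of 0.47 m with 6% variability — the kind of quantity a timing-only
stopwatch system cannot produce. The per-phase table and per-step table are
in the same JSON.

For classification, generate a labeled cohort and evaluate the cascade:

```bash
tug simulate-cohort --seed 1 --out cohort.csv
tug classify --cohort cohort.csv --out eval.json --sweep
```

## Library use

Everything the CLI does is a thin wrapper:

```python
from tugait import (PipelineConfig, run_session, simulate_trial,
                    living_room, HierarchicalLassoClassifier)

trial = simulate_trial(living_room(subject_height_m=1.76, seed=7))
report = run_session(trial.kp2d, trial.kp3d,
                     PipelineConfig(subject_height_m=1.76, cam_height_m=0.9))
print(report.state_vector.to_table())
```

`HierarchicalLassoClassifier` is a scikit-learn estimator (`fit` /
`predict` / `get_params`) and composes with sklearn model selection.

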