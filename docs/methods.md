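# Methods

This note records the models, conventions, numerical choices and known
limitations behind `tugait`. It is written for a reader who wants to know
*why* the pipeline is built the way it is, not just what it computes.

## Problem setting

A Timed Up and Go (TUG) session — rise from a chair, walk ~3 m, turn 180°,
walk back, turn and sit — is observed by a single uncalibrated consumer
camera on a fixed mount. Upstream pose estimators provide two streams per
frame: 2D pixel keypoints `P_uv(t)` and camera-centered, *scale-ambiguous*
3D keypoints `P_dl(t)`. A single camera cannot recover absolute distances;
the pipeline's job is to restore metric scale from two easily measured
scalars — the subject's stature `H` and the camera mounting height — and
then turn the metric trajectories into clinically interpretable gait
parameters and a screening decision.

## Camera model and ground-plane geometry

The camera is a minimal pinhole: vertical field of view (FOV), downward
pitch θ, principal point at the image center, zero skew and distortion.
The world frame sits on the floor under the optical center, y up, z along
the ground. For a pixel imaging a floor-contact point (the ankle midpoint),

    Z = h_cam / tan(θ + arctan((v − c_y) / f)),    f = (H_img/2) / tan(FOV/2),

and the head height follows by intersecting the head ray with the vertical
line at that ground distance. `project_pinhole` is the exact forward model;
every inverse formula in the package is tested against it (identity below
10⁻⁶ m across the parameter box).

### Self-calibration

FOV and θ are recovered by nonlinear least squares (Trust Region
Reflective, bounds FOV ∈ [20°, 120°], θ ∈ [−30°, 30°], multi-start over
FOV ∈ {40°, 60°, 80°}) on the residuals `back_projected_height(t) − H` over
k = 5 upright calibration frames. A single frame leaves one equation for
two unknowns, so frames are required to be at least 10 frames apart —
walking between them spans different depths, which makes the pair jointly
identifiable. Upright frames are screened three ways: largest vertical
pixel extent (ankle-to-head), pixel collinearity of ankle–pelvis–head
(tolerance 10°), and mid-stance (ankle pixels vertically aligned within
6 px) — a frame with the feet split in depth biases the ankle-midpoint
ground anchor. A calibration attempt whose selected frames span less than
5 px of vertical ankle travel is rejected outright: at a single depth the
two parameters are not jointly observable, which is also how a
seated-only/static recording fails fast.

**Known limitation — zero pitch.** At θ = 0 the back-projected height is
exactly `h_cam·(v_ankle − v_head)/(v_ankle − c_y)`: the focal length
cancels, so FOV is unobservable from height residuals no matter how many
frames or depths are used. Any real tilt restores identifiability (and
tripod mounts always have some); `calibrate` flags |θ| < 0.5° as
FOV-unidentifiable in its diagnostics. Recovered pitch is unaffected.

## Noise-adaptive depth fusion

Ground-plane depth `Z_geo` is metric but inherits keypoint jitter — the
depth resolution decays like `(h² + Z²)/(h·f)` per pixel, i.e. roughly
quadratically with distance. The 3D-pose depth `Z_dl` is smooth but has
arbitrary scale and offset. Fusion:

1. jitter level η(t): centered moving-window (W = 15 frames ≈ 0.5 s) mean
   absolute residual of `Z_geo` around a moving-median baseline (median
   because it is robust to the very spikes being measured; a low-pass
   baseline is selectable);
2. confidence w(t): piecewise linear, w = 1 for η ≤ τ_stable = 0.05 m,
   down to a 0.1 floor at η ≥ τ_jitter = 0.15 m. The floor preserves weak
   metric anchoring under severe jitter. τ_stable is of the order of the
   smoothed per-frame depth noise at far range under ~2 px keypoint noise;
   τ_jitter sits where jitter is an order of magnitude above that, which is
   the level a 15 px detector glitch produces at ~4 m — so the floor
   engages for genuine glitches and never in clean operation;
3. scale s = std(Z_geo)/std(Z_dl) (population SDs) over stable (w = 1)
   frames;
4. blend `Z_final = w·Z_geo + (1 − w)·Z_dl′` where the prior is *affinely*
   anchored: scaled by s about its stable-frame mean and shifted onto the
   stable-frame mean of `Z_geo`. A pure scale product would leave the
   camera-centered prior's arbitrary offset in the blend and corrupt the
   metric track.

Weights and η are computed per foot; s is shared (computed on the two-foot
mean) so the left/right difference signal is not distorted by independent
scale estimates. Shoulder depths, needed for turn detection, come from the
scale-aligned prior — the ground-plane constraint is only valid for joints
touching the floor.

## Phase segmentation

Two signals drive a small state machine:

* `h_foot(t)` = |y_pelvis − mean(y_ankles)| from the 3D stream. It is
  scale-free; thresholds are fractions of its robust range (5th–95th
  percentiles, so noise extremes cannot inflate them): T_high at 80%,
  T_low at 30%. Sit-to-Stand *ends* at the first frame with
  h_foot ≥ T_high and *starts* at the last preceding frame with
  h_foot ≤ T_low; Stand-to-Sit *begins* at the first frame after the
  second turn with h_foot ≤ T_low and *ends* when the forward 0.5 s window
  deviates from the final seated value by at most 15% of the range on
  average (a windowed-mean rule; an every-frame-in-band rule is fragile
  exactly where the descent flattens).
* `dZ_shoulder(t)` = |Z_left_sh − Z_right_sh| in meters. Near zero facing
  the camera; at the 90° instant of a turn it equals the full biacromial
  breadth (~0.4 m), so each 180° turn is a prominent peak. The two most
  prominent peaks (prominence ≥ 0.15 m ≈ a shoulder half-width) are the
  turns; each interval is the contiguous region above half-prominence.

Intervals are half-open `[start, end)`, 0-based, and tile the analyzed
span. The turn-and-sit transition may begin descending during the second
turn; Turn2 is extended to the Stand-to-Sit start crossing so the phases
stay contiguous (reported turn duration uses Turn1 only). Velocity-based
segmentation was deliberately avoided: thresholded postural geometry is
far more robust to measurement noise than differentiated signals.

## Step events and the gait state vector

`D(t) = Z_final_left − Z_final_right` oscillates once per stride during
steady walking. A *step event* is a peak or valley of D with

* prominence ≥ 0.5 × std(D over the walking phases) — the reference is the
  gait amplitude, deliberately not the whole-session std, which noise
  floors outside the walks would dilute;
* |D| at the event ≥ the same floor — |D| is the stride proxy, and a
  near-zero foot separation is a stance crossing or transitional shuffle,
  not a step;
* a 0.36 s refractory gap enforced across peak/valley polarity by
  non-maximum suppression (successive heel events cannot physically occur
  faster than the cadence bound; 0.36 s admits up to ~2.8 events/s).

The pipeline optionally band-limits D at 3 Hz (zero-phase, order 4) before
detection; cadence harmonics (~1–2 Hz) pass untouched. `S_walk` restricts
events to Walk-1 ∪ Walk-2, which is the sole mechanism excluding turn
shuffles and pre-seat adjustments from the stride statistics.

The state vector is
`x = [T_total, V_walk, T_turn, T_sts, N_total, N_walk, SL_mean, CV]` with
`T_total` from Sit-to-Stand start to Stand-to-Sit end, `SL_mean` the mean
|D| over walking events, `CV = 100·σ/μ` of the same (population SD by
default; a `ddof` switch is provided), and
`V_walk = SL_mean·N_walk/T_total`. The divisor is deliberately the *full*
TUG duration (including sit and turn time), which understates free walking
speed; it is kept because it is the convention the rest of the pipeline
and its downstream thresholds assume. The identity
`V_walk·T_total = SL_mean·N_walk` holds to machine precision by
construction. Note SL_mean is a depth-separation proxy, not anatomical
stride length; reports label it "Avg Stride" with that caveat here.

## Hierarchical risk classification

Three conditions: N (normal), M (mild cognitive burden), P (severe /
Parkinsonian-like). A flat 3-class model is fragile at cohort sizes of a
few dozen trials, so classification cascades:

* Stage 1 (screening, N vs {M, P}) on `[T_total, V_walk, T_turn, N_total,
  CV]`, inverse penalty selected on a 7-point log grid over 10⁻²…10² by
  stratified 3-fold CV inside the training data;
* Stage 2 (grading, M vs P) on `[V_walk, N_walk, SL_mean, T_total, T_turn,
  T_sts, CV]` at fixed C = 1.0 (moderate sparsity — stable behavior
  matters more than per-fold tuning at these sample sizes; configurable).

Both stages z-score with training statistics only and fit L1-penalized
logistic regression (liblinear). Ties at p = 0.5 resolve to "abnormal":
for a screening instrument, a missed case costs more than a false alarm.
Leave-one-out evaluation refits everything — scaler, strength selection,
both stages — inside every fold. The report carries the 3×3 confusion
matrix, per-class precision/recall/F1, overall accuracy, and a screening
accuracy (correctness of the N vs abnormal split); a per-subject screening
figure can be derived by aggregating the stored per-trial predictions. No
class reweighting is applied by default (a `class_weight` flag exposes
it). The regularization sweep reports selected-feature counts and CV
accuracy across the grid plus the sparsest strength within one standard
error of the best.

## The synthetic TUG simulator

The simulator is the package's test bed and defines its study conditions.
A kinematic stick figure (head at 1.00, shoulders at 0.82, pelvis at 0.53
of stature standing and 0.45 seated; biacromial half-width 0.1225 of
stature; hips ±0.055 of stature; ankles on the floor, stance half-width
0.05 m) executes: sit 2 s → rise 1.5 s → walk 3.5 s → turn 1.5 s → walk
3.5 s → turn 1.5 s → sit down 1.5 s → sit 2 s, between the far and near
points of one of two preset geometries (conference room: camera 1.1 m,
far 4.2 m, near 1.2 m; living room: 0.9 m, 4.6 m, 1.6 m), at 30 fps,
1920×1080. Transitions are smoothstep; the foot depth split is a 0.5 m,
1 Hz sinusoid windowed with 0.35 s ramps; torso yaw rotates 180° per turn.
The camera preset uses vertical FOV 80° and pitch 12°, chosen so the
ankles remain in frame down to the 1.2 m near point; the head leaves the
frame near the turn, exactly as a detector would lose it, and the
calibration-frame selector skips those frames.

Observations: exact pinhole projection, Gaussian pixel noise (default
σ = 2 px), optional burst jitter (the ablation default is 15 px for 1.3 s
late in the walk back, where depth noise amplifies most); off-frame joints
are dropped to NaN, surviving coordinates are clipped to the image. The 3D
stream is the truth geometry divided by a per-trial log-uniform scale in
[0.5, 2] (so scale alignment is never vacuously exercised at 1) plus
smooth noise of 0.004 m std — these networks' outputs are characteristically
smooth, which is the entire reason they are worth fusing.

**Ground truth.** Truth phase boundaries are obtained by applying the
segmentation definitions (threshold crossings, half-prominence regions) to
the *noise-free* kinematic signals: the boundary definitions are the
crossings, so this is the exact segmentation of the clean session, and
recovery tests measure robustness of the noisy 2D/3D chain against it. The
configured schedule is stored separately as `protocol_bounds`. Truth step
events use the detector's event definition on the clean foot split with a
prominence floor of 0.25 × stride.

**What the simulator does not model** — and hence what passing tests do
not show about real recordings: joint detection outages from occlusion or
clothing, detector biases that vary with viewpoint, body-shape deviations
from the stick-figure anthropometry, foot sliding vs true swing-phase
lift-off (simulated ankles never leave the floor, so the ground-plane
constraint is exact at every frame), lens distortion, rolling shutter,
multi-person scenes, and non-Gaussian heavy-tailed noise. The cohort
generator draws labeled feature vectors directly (per-subject baselines ×
condition multipliers × trial noise: mild load slows the walk ~15% and
raises stride CV ~50%; severe load ~35% and ~120% plus turning and
sit-to-stand penalties); it does not simulate full sessions per row, so
classifier results speak to the feature-space geometry, not to end-to-end
video variability.

## Problem sizes and tolerances in the shipped checks

Batch checks use 20 simulated trials per condition and 5–7 seeds where a
median over seeds is asserted; these sizes make the default suite and the
reproduction script complete in a few minutes on one core while leaving
the stochastic margins comfortable (walking-step counts matched truth on
60 plain + 20 burst seeds during development). Phase-boundary recovery is
asserted at ±5 frames (0.17 s at 30 fps); spatial-error IQRs at ≤ 0.1 m;
noise-free calibration at <1° FOV / <0.5° pitch away from the zero-pitch
degeneracy described above.
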