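# Methods

This note documents the models, conventions and numerical choices behind
`gaitlab`, in the order data flows through the pipeline.

## Coordinate conventions and data model

Trajectories are `(n_frames, 17, 3)` arrays in millimetres with a fixed joint
registry (`gaitlab.skeleton.JOINT_NAMES`): a spine column (sacrum, thoracic
and cervical markers, nose, head top) plus bilateral hip/knee/ankle and
shoulder/elbow/wrist centres — the common monocular 2D-to-3D lifting layout.
The lab frame is +x walking direction, +z up; frames are 0-based with time
`t = i/f`. CSV files carry one row per frame with columns
`frame, <joint>_<axis>` (axes x, y, z); JSON mirrors this and stores the
frame rate.

## Preprocessing

**Centering** subtracts the sacrum from every joint per frame; it is exactly
idempotent and preserves all pairwise distances.

**Metric scaling** multiplies each frame by
`(L_left + L_right) / (‖K_l − F_l‖ + ‖K_r − F_r‖)`, the measured over the
keypoint-derived shank-length sum. The ratio is computed *per frame* by
default, because keypoint-derived limb lengths fluctuate frame to frame; a
`mode="median"` variant applies one trajectory-median ratio when a smoother
overall scale is preferred. Frames with a zero shank-length sum raise a
degenerate-geometry error naming the frame.

**Resampling** (e.g. optical-lab 100 Hz down to 30 Hz) is per-coordinate
linear interpolation onto the uniform grid `t = k/f_target` spanning the
original duration. Linear interpolation is adequate at these rates because
gait kinematics are band-limited well below 15 Hz.

**Temporal alignment** of two same-rate scalar series (knee angles, in the
validation workflow) maximises the discrete cross-correlation
`C(τ) = Σ_t x(t)·y(t+τ)` of the mean-removed series over all integer lags
with at least 50% overlap of the shorter series; ties break toward the
smallest `|τ|`. Sign convention: `shift > 0` means y *lags* x by `shift`
samples — a test series delayed by 3 frames yields `shift = +3`, and the
aligned pair is `(x[:n], y[shift:shift+n])`. All-zero inputs raise an
undefined-alignment error.

## Knee kinematics

The knee angle is the included angle at the knee between the knee→hip and
knee→ankle rays, in degrees (180° = fully extended, so it is invariant under
rigid motion and uniform scaling). Angular velocity is the frame-rate-scaled
backward difference `ω_i = f(θ_i − θ_{i−1})`, indexed to the later frame; the
series is one sample shorter than the angle series (no zero padding). No
filtering is applied before differencing — the unfiltered definition is the
reference behaviour — but `knee_angle_series(..., smooth_window=k)` exposes
an optional centred moving average (odd `k`, default off) for noisy
keypoints. Ranges of motion are max − min of the respective series.

## Step detection and labelling

Steps are peaks of the 3-D inter-ankle distance `D_i = ‖A_li − A_ri‖`
(the printed definition; a ground-plane projection would differ only by the
small vertical term and is not applied). `detect_step_peaks` keeps strict
local maxima with value ≥ `threshold_fraction × max(D)`
(`threshold_fraction = 0.5` by default, exposed as a knob) and thins peaks
closer than `min_separation` frames keeping the larger. The pipeline calls it
with a minimum separation of 0.3 s of frames — an a priori physiological
cadence bound (adults do not exceed ≈3.3 steps/s) that suppresses duplicate
maxima from keypoint noise on the broad peak of slow gait.

Step side uses the body's anatomical planes at the peak frame: the sagittal
plane through the sacrum (SV), thoracic (TV) and cervical (CV) markers
(normal = unit cross product of SV→TV and SV→CV) and the coronal plane
through SV with normal = unit cross(sagittal normal, unit SV→CV),
perpendicular to both by construction. The step belongs to the foot whose
ankle lies anterior to the coronal plane; "anterior" is the horizontal unit
direction of sacrum travel over the enclosing step interval, falling back to
whole-walk travel when the local displacement is under 10 mm (near-standing),
and finally to +x. A near-tie (< 1 mm separation of the signed distances)
emits a warning and picks the larger absolute distance. Because centering
erases sacrum travel, the pipeline assigns sides on the scaled-but-uncentered
trajectory (scaling and centering commute, so all other measures are
unaffected).

Periods and speeds are `p_i = T_i − T_{i−1}` and
`v_i = (S_i + S_{i−1})/(2 p_i)` over the full step sequence, each labelled
with the side of step *i*; the first detected step has no predecessor and
carries neither (boundary policy: first/last events never yield differenced
quantities).

## Gait phases from knee angular velocity

Per leg: all strict local extrema of `ω` are found; maxima at or above the
80th percentile and minima at or below the 20th percentile of the sorted `ω`
values are retained (linear-interpolation percentiles; both cut-offs are
arguments). Runs of same-type retained extrema with no opposite-type event
between them are collapsed to the single most extreme one — a clean stride
has exactly one retained maximum between consecutive minima, and keypoint
noise can only split one extremum into adjacent ripples, so this merge
removes duplicates without inventing events. Each retained minimum is a
toe-off; from each retained maximum the first later sample with `ω` below
10°/s (signed by default; an absolute-value variant is available) is a
heel-strike. Swing is heel-strike minus the preceding toe-off; support is
toe-off minus the preceding heel-strike; cycles lacking a predecessor (and a
final toe-off with no later heel-strike in the data) are omitted.

## Segmental centre of mass and balance

The body model has exactly 11 segments — head (neck→head top), upper trunk
(cervical→thoracic), lower trunk (thoracic→sacrum), and bilateral upper
arms, forearms, thighs and shanks — excluding the hands and feet as the
lightest parts. Default mass fractions follow published adult segmental
tables (head 0.081, upper trunk 0.216, lower trunk 0.281, upper arm 0.028,
forearm 0.016, thigh 0.100, shank 0.0465; sum 0.959) with the segment COM at
fraction 0.5 along the proximal→distal axis; the table ships as an editable
JSON data file (`gaitlab/data/segments.json`) so a population-specific
standard can be substituted.

The default whole-body COM is the normalized weighted centroid
`Σ m_i COM_i / Σ m_i` — the standard segmental method. A literal
`variant="printed"` computes `(1/N)·Σ COM_i·m_i/m_w` instead; with only 11
of the body's segments summed that expression is not a centroid, and it is
retained purely for fidelity comparisons, never as the default.

RCOMV is `f·‖COM_a − COM_{a−1}‖` after the COM is expressed relative to a
reference point: the hip/sacrum centre in the measurement workflow (so the
measure reflects body-relative balance motion) or the left ankle in the
validation workflow (where an optical marker sits most reliably). COM
deviations are per-frame unsigned point-to-plane distances to the sagittal
and coronal planes; the reported ranges are max − min of those series.

## The synthetic gait simulator

The simulator is a parametric kinematic model, **not** a biomechanical one:
its purpose is to give every extractor a known programmed answer.

* Feet alternate stance and swing with a cosine profile; consecutive
  landings are `step_period` apart and the 3-D inter-ankle distance at each
  landing equals `step_length` exactly (forward separation
  `√(S² − w²)` at stance width `w = min(100 mm, S/3)`; swing clearance
  vanishes at landing). The walk ends with a closing step and quiet standing
  so the final landing stays an interior distance peak.
* Each leg's knee performs one cosine flexion pulse per 2-step stride,
  from 180° down to `180° − knee_rom` and back, over a window
  `W = (8p/3)/(1 + stance_swing_ratio)` from swing onset
  (`stance_swing_ratio` default 1.5 ≈ the physiological 60:40 stance:swing
  split). Ground-truth toe-off and heel-strike are the *continuous* model's
  angular-velocity landmarks in closed form — the velocity minimum at 1/4 of
  the pulse and the first crossing below 10°/s after the maximum at
  `W·(1 − arcsin(10/A)/2π)`, `A = knee_rom·π/W` — matching the convention
  the detector estimates, while never touching the sampled/detection code.
* The trunk column is generated on the corridor midline (y = 0), so the
  trunk-defined sagittal plane is exactly the vertical x–z plane; lateral
  balance motion is imposed on the upper body and scaled by a numerically
  probed COM-attenuation factor so that the whole-body COM's distance to
  that plane oscillates with exactly `lateral_sway_amplitude` about a
  1.5×-amplitude standing offset (unsigned-deviation range = 2×amplitude by
  construction).
* Keypoint noise is isotropic i.i.d. Gaussian per joint per frame
  (`noise_sd`, mm), seeded; ground truth always describes the noise-free
  motion.
* Sit-to-stand traces sit (1 s) – rise – stand (1 s) – sit by driving the
  knee angle 90°→180°→90° with a monotone cosine ramp; the sacrum height
  follows through the leg geometry, and rise onset/offset times are stored.

Default study conditions: 30 Hz, 10 s trials, 600 mm steps at 0.6 s,
knee ROM 60–74°, 10 mm sway, shank 400 mm, thigh 450 mm, trunk 500 mm —
typical adult self-paced walking. What the simulator does **not** emulate:
turning, double support, pose-estimator error structure (occlusion,
temporally correlated drift, outliers), soft-tissue artefact, or
pathology-specific waveforms — patients are emulated only through the
parameter directions (shorter, slower, lower-ROM, swaying gait). Tests that
pass on this simulator therefore verify the *extraction mathematics*, not
clinical validity on real video.

## Statistics

ICC(2,k) is computed from the two-way ANOVA mean squares,
`(MS_R − MS_E)/(MS_R + (MS_C − MS_E)/n)` (rows = targets, columns =
raters/systems), banded per Cicchetti (<0.40 poor, 0.40–0.60 fair,
0.60–0.75 good, ≥0.75 excellent; half-open on the left edges). In the
validation workflow, trials are targets and the two systems are raters.
Pearson r uses the conventional strength bands on |r| (<0.30 negligible,
0.30–0.50 low, 0.50–0.70 moderate, 0.70–0.90 high, ≥0.90 very high).
Welch's t supports both group summaries (mean, SD, n; Welch–Satterthwaite
df) and raw tables. Constant inputs raise undefined-statistic errors rather
than returning NaN.

The validation report covers the validation parameter set — step period,
walking speed, knee ROMs, knee angular-velocity ranges, RCOMV. Step length
and the COM plane-deviation ranges belong to the measurement workflow; the
deviation range in particular is an extreme-value statistic whose
between-system agreement under one-sided keypoint noise is structurally poor
(see limitations).

K-means++ uses k = 3 by default on z-scored columns (gait parameters mix mm,
s and °/s scales, which would otherwise dominate the Euclidean distance;
standardization can be disabled), Lloyd iterations to centroid-shift
convergence (tol 1e-8) or 300 iterations, deterministic per seed; clusters
are ordered by descending centroid walking speed so "higher-function" labels
are assigned mechanically rather than by hand.

The bundled reference tables (`gaitlab.datasets`) hold group-level summary
statistics — a validation experiment comparing an optical system against a
smartphone markerless system, and a measurement cohort of 13 healthy adults
and 12 musculoskeletal patients with 4 gait segments each (52/48 analysis
rows). `synthetic_cohort_table` draws independent per-column Gaussians at
those statistics; real between-parameter correlations are not reproduced,
which slightly *understates* cluster separability relative to a real cohort.

## Numerical choices and degenerate inputs

* Percentiles use numpy's linear interpolation; band edges are half-open
  exactly as printed above.
* Cross-correlation tie-break: smallest |τ| (with a 1e-12 comparison guard).
* Collinear spine markers, zero-length limb segments and zero shank sums
  raise degenerate-geometry errors carrying the frame index.
* Constant distance series yield *no* steps (empty result, not an error);
  a constant ω series raises no-gait-detected.
* The first detected step and boundary gait cycles never contribute
  differenced quantities (periods, speeds, swing/support).
* `arccos` arguments are clipped to [−1, 1] to absorb rounding.

## Known limitations

* Range-of-motion and deviation-range estimators are max − min extremes and
  therefore noise-inflating: 2 mm keypoint noise adds ≈0.5° angle noise,
  hence ≈20°/s per-sample ω noise and ≈+90°/s inflation of the unfiltered
  angular-velocity range over a 10 s trial. When only one arm of a
  gold-vs-test comparison carries that noise, the systematic inflation caps
  the velocity-range ICC near 0.9 regardless of sample size — consistent
  with the bundled validation reference, whose own left-knee velocity-range
  ICC is 0.843. The same mechanism makes the COM plane-deviation range
  (lever-armed additionally by per-frame plane jitter) unsuitable for
  between-system ICC entirely.
* Heel-strike detection scans for a signed threshold crossing; under noise
  the crossing fires early by up to a few frames at the slowest cadences
  (shallow ω slope). Event-time accuracy is therefore characterised as a
  mean absolute error over detected events.
* Segment mass fractions and COM-position fractions are population averages;
  the printed-variant COM and per-frame scaling are faithful to their
  definitions, not claims about optimality.
* Pre-edited straight-walk segments are assumed; turning is neither
  simulated nor segmented automatically.
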