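# gaitlab

Markerless gait and balance analysis from 3D keypoint trajectories.

Monocular (single-camera) human pose estimation delivers per-frame 3D
coordinates of 17 body joints, cheaply and without markers — but those raw
keypoints are not yet clinically meaningful. `gaitlab` turns them into the
quantities a rehabilitation assessment needs: spatiotemporal gait parameters
(step length, step period, walking speed), knee kinematics (flexion angle and
angular velocity ranges), segmental centre-of-mass (COM) balance measures,
gold-standard reliability/validity statistics, and k-means++ stratification of
subjects by balance level. It is written for movement scientists and
rehabilitation engineers who have keypoint trajectories (from any pose
estimator) plus basic subject anthropometry, and who want a reproducible,
testable pipeline rather than a camera system.

Because recorded motion-capture data cannot be redistributed, the package
includes a parametric 17-joint gait/sit-to-stand simulator with exact ground
truth, so every stage of the pipeline is verifiable end to end.

## The method

Given per-frame joint positions `P_i` (mm) at frame rate `f` (30 Hz default):

1. **Centering & metric scaling.** All joints are translated so the sacrum is
   the per-frame origin, then each frame is rescaled by
   `(L_left + L_right) / (‖K_l F_l‖ + ‖K_r F_r‖)` — the subject's measured
   shank lengths over the keypoint-derived ones — resolving the scale
   ambiguity of monocular 3D poses.
2. **Knee kinematics.** The knee angle is the included angle at the knee,
   `θ_i = arccos[(K_iH_i · K_iA_i) / (‖K_iH_i‖‖K_iA_i‖)]` (180° = fully
   extended); angular velocity is `ω_i = f·(θ_i − θ_{i−1})`; ranges of motion
   are max − min.
3. **Steps.** The inter-ankle distance `D_i = ‖A_li A_ri‖` peaks once per
   step; threshold-filtered local maxima give step lengths `S_i` and times
   `T_i`, whence periods `p_i = T_i − T_{i−1}` and speeds
   `v_i = (S_i + S_{i−1}) / (2p_i)`. Step side comes from which ankle lies
   anterior to the body's coronal plane (built, with the sagittal plane, from
   the sacrum/thoracic/cervical markers).
4. **Gait phases.** Toe-off is the time of each retained minimum of `ω`
   (percentile-filtered extrema); heel-strike is the first sample after each
   retained maximum where `ω` drops below 10°/s; swing and support times
   follow by differencing consecutive events.
5. **Balance.** An 11-segment body model (hands/feet excluded) gives the
   whole-body COM `Σ m_i·COM_i / Σ m_i`; the relative COM velocity is
   `RCOMV_a = f·‖COM_a − COM_{a−1}‖` after referencing to the hip (or left
   foot), and COM deviation ranges from the sagittal/coronal planes quantify
   lateral/fore-aft stability.
6. **Statistics.** System agreement uses ICC(2,k) — two-way random effects,
   absolute agreement, average measures, `(MS_R − MS_E)/(MS_R + (MS_C −
   MS_E)/n)` — with Cicchetti bands, Pearson r with conventional strength
   bands, and Welch's unequal-variance t-test; cohorts are stratified with
   k-means++ (k = 3) on z-scored parameters.

## Worked example

Simulate a walk with known ground truth and run the full extraction chain:

```python
from gaitlab import (GaitSimConfig, SubjectProfile, generate_walk,
                     extract_parameters)

cfg = GaitSimConfig(duration=10.0, step_length=600.0, step_period=0.6,
                    knee_rom=74.0, lateral_sway_amplitude=10.0,
                    noise_sd=1.0, seed=42)
traj, truth = generate_walk(cfg)

profile = SubjectProfile(shank_length_left=400.0, shank_length_right=400.0,
                         body_mass=70.0, subject_id="demo")
result = extract_parameters(traj, profile)

print(f"steps detected: {result.n_steps} (simulated: {truth.n_steps})")
for name, value in result.parameters.items():
    print(f"{name:35s} {value:10.3f}")
```

prints

```
steps detected: 15 (simulated: 15)
step_period_s                            0.602
step_length_mm                         599.111
walking_speed_mm_s                     994.842
knee_rom_right_deg                      74.216
knee_rom_left_deg                       74.109
knee_velocity_range_right_deg_s        784.156
knee_velocity_range_left_deg_s         763.522
rcomv_mm_s                             200.501
sagittal_deviation_range_mm             25.631
coronal_deviation_range_mm              33.628
```

Every programmed quantity is recovered through the full pipeline under 1 mm
keypoint noise: all 15 steps, step length within 0.15%, period within a tenth
of a frame, knee ROM within 0.25°. The sagittal COM deviation range (2 × the
10 mm sway amplitude by construction, inflated ~5 mm by noise extremes) and
the hip-referenced RCOMV describe the walker's lateral balance.

The same stages are available from the shell:

```bash
gaitlab simulate --out sim/ --step-length 600 --seed 42
gaitlab extract sim/walk_trajectory.csv --profile profile.json --out results/
gaitlab validate --gold g0.csv --test t0.csv --gold g1.csv --test t1.csv \
    --profile profile.json --out validation/
gaitlab cluster parameters.csv --k 3 --out clusters/
```

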