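# hipclear

Subject-specific prediction of **anterior femoroacetabular clearance** — the
beta angle — from bone point clouds, anatomical landmarks and motion-capture
hip kinematics.

## The problem

Cam and pincer morphologies (an aspherical femoral head-neck junction;
acetabular over-coverage) can cause the femoral head-neck contour to abut the
acetabular rim in deep hip flexion — femoroacetabular impingement, a proposed
precursor of hip pain and osteoarthritis. Whether a given hip actually
impinges depends on both its bony shape *and* how it moves, so a useful model
must combine subject-specific anatomy (from imaging) with subject-specific
kinematics (from motion capture).

`hipclear` implements such a model for researchers in musculoskeletal
biomechanics. On the alpha-plane slice stack through the hip it computes, per
motion frame, the **beta angle**: the angle at the femoral head centre
between

* the ray to the most lateral bony margin of the acetabular rim, and
* the ray to the starting point of deviation from sphericity of the femoral
  head-neck contour,

with β > 0 meaning clearance and β < 0 meaning the aspherical region sits
under acetabular coverage (overlap/impingement). The minimum beta over the
plane stack is the per-frame outcome.

## The pipeline

1. **Geometry** — least-squares sphere fits of the femoral head and the
   acetabular lunate surface (linear Coope solve + geometric refinement);
   principal-axis fits; plane slicing and in-plane projection
   (`hipclear.geometry`).
2. **Registration** — point-to-point ICP (KD-tree correspondences, SVD rigid
   updates with reflection guard) to move bone models between postures
   (`hipclear.registration`).
3. **Joint frames** — ISB pelvis and femur coordinate systems from ASIS/PSIS
   and epicondyle landmarks plus the fitted head centre; hip angles by the
   Grood–Suntay convention (e₁ = pelvis Z, flexion; e₂ = femur y, internal
   rotation; e₃ = e₁ × e₂ floating, ab/adduction) (`hipclear.frames`).
4. **Motion capture** — standing calibration binds the anatomical frames to
   marker clusters; per-frame cluster poses by Kabsch fits propagate the
   frames through a trial; a statically imaged posture is matched to the
   motion frame minimising the least-squares error (LSQE) in hip angles,
   ‖Δ(flexion, ab/adduction, rotation)‖₂ (`hipclear.mocap`).
5. **Clearance** — the supine bone models are posed at the matched frame, the
   femur translated to restore the supine centre-to-centre distance, and beta
   computed on planes parallel to the alpha plane spaced 2.5 mm apart using
   points within 0.5 mm of each plane (`hipclear.clearance`).
6. **Validation statistics** — absolute-error summaries (mean, SD, RMSE),
   Pearson r, absolute-agreement ICC(2,1), and the LSQE threshold-inclusion
   procedure (`hipclear.stats`), plus the bundled reference validation
   tables (`hipclear.datasets`).
7. **Synthetic ground truth** — a parametric hip phantom (spherical head,
   neck cylinder, Gaussian cam bump, acetabular cup with a defined rim) with
   closed-form clearance, and simulated squat/FADIR trials with known
   rigid-body poses (`hipclear.synthetic`).

## Worked example

```python
from hipclear import *
from hipclear.synthetic import MotionScenario, simulate_motion
from hipclear.pipeline import predict_beta

spec = HipPhantomSpec(seed=42, cam_amplitude=3.0)       # 3 mm cam bump
phantom = generate_phantom(spec)
scenario = MotionScenario(kind="squat",
                          peak_angles=HipJointAngles(80.0, 4.0, 6.0),
                          duration=2.0, rate=60.0, seed=42)
motion, truth = simulate_motion(scenario, phantom)

imaged = truth.angles[100]            # plays the role of the static scan posture
report = predict_beta(phantom.femur, phantom.head, phantom.acetabulum,
                      phantom.landmarks, phantom.neck_axis, phantom.shaft_axis,
                      motion, (imaged.flexion, imaged.adduction, imaged.internal_rotation))

print(f"matched frame      : {report['matched_frame']} (LSQE {report['matched_lsqe']:.2f} deg)")
print(f"head sphere        : r = {report['head_fit']['radius']:.2f} mm")
print(f"minimum beta angle : {report['min_beta']:.1f} deg on plane {report['min_plane_index']}")
```

prints

```
matched frame      : 100 (LSQE 0.00 deg)
head sphere        : r = 25.00 mm
minimum beta angle : 37.5 deg on plane 2
```

The noise-free markers make the frame match exact; the predicted minimum
beta of 37.5° sits on the plane through the cam and agrees with the
phantom's analytic clearance at that pose (35.8°) to within the angular
sampling resolution of the point cloud. With a cam under the rim the same
number comes out negative — impingement.

The same chain is available from the shell:

```bash
hipclear synth --preset cam-moderate --seed 5 --out fx/
hipclear angles --motion fx/motion.trc --landmarks fx/landmarks.json \
                --head fx/head.ply --acetabulum fx/acetabulum.ply --out angles.csv
hipclear match-frame --angles angles.csv --target "60.1,2.9,4.0"
hipclear beta --femur fx/femur.ply --acetab fx/acetabulum.ply \
              --head fx/head.ply --landmarks fx/landmarks.json --out beta.csv
```

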