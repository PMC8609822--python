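# Methods

This note records the model, its assumptions, the numerical choices and the
defaults, in the package's own words. Nothing here states an empirical result
that the tests or `scripts/acceptance.py` do not themselves compute.

## The clearance model

The quantity of interest is the beta angle: on a slice through the hip
parallel to the femoral neck, the angle at the femoral head centre between
the ray to the most lateral bony margin of the acetabular rim and the ray to
the onset of deviation from sphericity of the head-neck contour. Positive
beta is clearance; negative beta means the aspherical region lies under
acetabular coverage. The model's per-frame prediction is the *minimum* beta
over a stack of parallel slices, mimicking how the angle is read from an
oblique imaging stack.

Assumptions baked into the chain:

* **Rigid bodies.** Pelvis and femur are rigid; bone models segmented supine
  remain valid in deep flexion. Soft tissue enters only through marker noise.
* **Sphere-like head.** "Deviation from sphericity" is defined against a
  least-squares sphere fitted to the head surface; the onset is where the
  contour's 3D distance from that fitted centre first exceeds
  radius + tolerance.
* **Concentric-ish joint.** The femur is translated along the line joining
  the fitted head centre and the acetabular-sphere centre so that their
  distance equals the supine reference distance, compensating tracking drift
  without touching rotation.

## Geometric conventions

* Millimetres everywhere; degrees at API boundaries, radians internally.
* **Alpha plane**: through the fitted head centre with normal
  unit(neck × shaft) — the plane containing both the neck and shaft axis
  directions. Reslices are parallel planes at k·spacing (default 2.5 mm),
  k ∈ [−c, c] with c = ceil(head radius / spacing), each realised as the
  closed slab of points within 0.5 mm of the plane (the slice thickness of
  the emulated stack). Slabs must not overlap (half-thickness ≤ spacing/2).
* **Marching coordinate.** Within a section, points are parameterised by the
  angle φ about the projected head centre, φ = 0 opposite the projected neck
  direction (deepest inside the acetabulum), increasing toward the neck
  (φ = π) through the half-plane of v = normal × neck. Deriving the basis
  from the neck projection makes onset/rim/beta signs reproducible without
  manual input and invariant under rigid motion of the whole scene.
* **Onset detection.** Candidate points are femur section points on the
  marching path within a radial *contour band* (default 2.5 mm) above the
  fitted sphere — the head-neck contour. The band is what the measurement
  marches along; without it, the shaft or trochanter silhouette, which
  overlaps the same angular range at several times the head radius, would
  pre-empt the true onset. The onset is the first band point (by φ) whose 3D
  distance from the head centre exceeds radius + tolerance (default 0.5 mm)
  and that begins a run of ≥ 3 consecutive supra-threshold points (noise
  guard). A plane whose contour stays spherical through the slab is
  *non-informative* and never contributes to the minimum.
* **Rim.** The acetabular section point with the largest marching angle —
  the free edge of the cup on the head-neck side.
* The asphericity tolerance is configurable and echoed into every output:
  the onset concept is operationalised here (a reading convention), so its
  threshold must be visible and sensitivity-testable rather than hidden.

## Joint coordinate systems

Pelvis (ISB): Z along the inter-ASIS line toward the subject's right, X
anterior in the plane of the ASIS and the PSIS midpoint, Y = Z × X superior;
origin at the acetabular-sphere centre. Femur: y from the epicondyle
midpoint to the head centre, z perpendicular to y in the plane of head and
epicondyles pointing toward the subject's right — the *lateral* epicondyle
on the right side and the *medial* one on the left — and x = y × z anterior;
origin at the head centre. Building z toward the subject's right on both
sides is what makes one set of Grood–Suntay sign rules mean the same
clinically for left and right hips; the mirror-symmetry property test pins
this down. Right-handedness is enforced by construction (the floating-axis
triad is y = Z × X, x = y × z); "anterior/superior/lateral" are resolved by
dot-product checks against landmark-derived directions, never by assuming a
scanner orientation.

Angles follow Grood–Suntay (e₁ = pelvis Z, e₂ = femur y, e₃ = e₁ × e₂),
equivalent to an intrinsic Z-X-Y factorisation of the pelvis-to-femur
rotation; extraction uses atan2 on direction cosines so signs are correct
near zero. Poses with |e₁·e₂| > 0.999 (ab/adduction near ±90°) set a gimbal
warning but still return angles — the maneuvers this model targets stay far
from that region.

## Registration and tracking

ICP is plain point-to-point: nearest neighbours via a KD-tree, closed-form
SVD update with reflection guard, iterated until the RMS change drops below
1e-4 mm (default) or 200 iterations. No trimming by default (an optional
worst-fraction trim serves partial-overlap scans); initialisation defaults
to identity, with a landmark-correspondence pre-alignment helper for large
posture changes. The defaults are far below the sub-degree accuracy the
validation needs; the RMS history is recorded and is non-increasing.

Cluster tracking uses all markers of a cluster in a centroid + SVD (Kabsch)
fit rather than a 3-marker frame construction — it uses the full cluster and
tolerates one noisy marker. No gap-filling and no filtering by default (a
deliberate "do not invent preprocessing" stance); frames with fewer than 3
visible markers per cluster are reported as gaps, never interpolated.

LSQE — the Euclidean norm of the three angle differences — has one home
(`stats.lsqe`) and is used identically for frame matching and for the
inclusion analysis.

## Statistics

Accuracy is summarised as mean, SD (sample, n−1) and RMSE of absolute
errors; RMSE ≥ mean by the power-mean inequality (property-tested). Pearson
r carries the two-sided t-distribution p-value. The ICC is fixed to the
two-way, absolute-agreement, single-measure form (ICC(2,1) from ANOVA mean
squares) and the choice is echoed in output metadata. The threshold-inclusion
procedure is formalised as: sort by ascending LSQE, return the largest
prefix (≥ 3) whose LSQE-accuracy correlation is non-significant at α = 0.05,
with an undefined (zero-variance) correlation counting as non-significant.
On the bundled reference tables this reproduces the published inclusion
counts (10 squat, 7 FADIR). All statistics run on unrounded values; rounding
to one decimal happens only in reports.

## The synthetic phantom and what it does (not) show

The phantom is a right hip in a neutral standing pose: spherical head
(radius R, default 25 mm), neck cylinder (radius default 14 mm) meeting the
sphere at the analytic junction angle arcsin(r_neck/R), shaft stub, optional
Gaussian radial cam bump (amplitude, angular centre, width σ) centred in the
alpha plane, and an acetabular cup: a spherical-cap shell of radius
R + clearance whose pole opposes the neck, with a small (1.5 mm) cup-centre
offset so the two sphere centres are distinct (the centre-to-centre
adjustment needs a direction). Landmarks sit at generic adult pelvis/femur
positions chosen so both anatomical frames are exactly axis-aligned at
neutral, which makes simulated joint angles equal to the Grood–Suntay
forward composition directly.

Surfaces are sampled on jittered quasi-regular lattices (Fibonacci sphere,
cylinder grids) at a default 2 points/mm². This emulates segmentation of
gridded images, where sampling is near-regular; independent uniform sampling
would leave angular gaps several times the mean spacing and make onset
localisation error unbounded relative to the mean step at any density. The
*angular sampling step* quoted in tests is (1/√density)/R — the mean
inter-point spacing seen from the head centre; measured-vs-analytic beta
comparisons use 2× this step as their resolution limit.

Simulated trials ramp the angle triple from standing to the peak with a
half-cosine over 1.5–2 s; the pelvis descends and tilts slightly during
squats so tracking is non-trivial. The thigh segment is tracked by a
4-marker cluster plate plus greater-trochanter and lateral-epicondyle
markers (the trial marker set keeps these on); the long epicondyle lever is
what conditions axial rotation. Marker noise is isotropic Gaussian,
independent per frame — there is no autocorrelated soft-tissue artifact
model, no marker occlusion model, and the phantom has no cartilage or
labrum. Passing tests therefore demonstrate the *computational* chain
(registration, frames, tracking, matching, reslicing, angle reading) at
known geometry; they do not certify accuracy against real soft-tissue
artifact, segmentation error, or non-spherical (e.g. dysplastic) heads.

### Analytic oracle

The oracle never touches the point-cloud pipeline. Femoral onset per plane
comes from closed forms: the neck-cylinder crossing of radius + tolerance
(at the slab depth farthest from the axis plane — a detected run must be
supra-threshold across the whole slab, so the worst depth binds) and the
cam's tolerance-crossing boundary Δ* = σ√(2 ln(A/tol)). The rim per plane is
the maximum marching angle over the cup cap's intersection with the slab,
enumerated on a dense grid of the plane-circle with the cap condition, over
several slab sub-offsets. Per-frame analytic beta evaluates these with the
cup rigidly moved into the femur frame by the simulated relative pose. Two
conventions coexist deliberately: `beta_true` (ideal, junction-angle onset)
and the detection-aware oracle used for end-to-end comparisons — they differ
by well under a degree because the measurement itself defines onset through
the tolerance level. Planes where only part of the slab depth can cross
threshold are treated as non-informative by the oracle (conservative); such
planes yield large betas near the neck and never decide the minimum.

## Problem sizes

Defaults were chosen so a full subject-level run is interactive: ~40 k femur
points at 2 points/mm², 21 reslice planes, 61–121 motion frames; one
end-to-end prediction takes a fraction of a second, and the 20-draw
synthetic validation in `scripts/acceptance.py` completes in seconds.

## Known limitations

* The onset rule (tolerance + run guard + contour band) is one defensible
  operationalisation of "deviation from sphericity"; readings on real images
  may follow other conventions, which is why the tolerance is exposed.
* How neck and shaft axes are derived from images is not standardised here:
  `fit_axis` (principal direction) is a stand-in, and the fixture bundles
  carry explicit axes instead.
* Left hips are supported throughout the frame/angle layer, but the phantom
  generator builds right hips only.
* C3D marker files are not read (TRC and CSV are); no kinetics, no
  gap-filling, no soft-tissue-artifact compensation.
* Beta can wrap for extreme cup poses (rim beyond the neck); the maneuvers
  modelled here stay far from that regime.
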