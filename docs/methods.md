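# Methods

This note records the models, conventions, numerical choices, and known
limitations behind `ndtsurf`. Axis convention throughout: x = lateral,
y = longitudinal, z = vertical; lengths in mm, angles in degrees.

## Rigid pose model

A pose is a translation t ∈ ℝ³ plus intrinsic Z-Y-X Euler angles
(rx, ry, rz); the rotation acts about the coordinate origin, so
p ↦ R(rz, ry, rx)·p + t. Euler order and rotation centre are package
conventions: the evaluation metrics use only the translation component
(treatment couches translate without rotating), so no reported quantity
depends on them, but they are fixed and documented so poses compose
predictably. Composition and inversion are exact (matrix form); the
Euler↔matrix round trip is stable away from ±90° pitch, far outside the
sub-degree regime registration operates in.

The registration pose is the *correction*: it maps the current surface
onto the reference. A phantom physically shifted by +s registers with
translation ≈ −s, and the measured couch shift is the negated correction.

## Preprocessing

Both surfaces pass identically through (1) statistical outlier removal —
drop points whose mean distance to their k nearest neighbours exceeds the
global mean + m·std of that statistic (defaults k = 20, m = 2) — and
(2) an axis-aligned closed-box region-of-interest crop, default
600 × 380 × 160 mm centred on the reference centroid (an abdomen-sized
patch). Ties on the box boundary are kept. The crop is idempotent and
commutes with translations of the box; the outlier filter is *not*
idempotent on bounded patches — once gross outliers are gone the
recomputed statistics tighten and a second pass can peel edge points. It
is applied once, by design.

## ICP

Point-to-point ICP: k-d-tree nearest neighbours (current → reference),
Kabsch/SVD least-squares pose with reflection correction, increment
composed onto the pose, from the zero transform, stopping when the
increment falls below 0.1 mm translation norm and 0.1° largest angle, or
at 100 iterations. An optional maximum correspondence distance gate exists
but defaults off: post-ROI phantom surfaces overlap fully. The mean
correspondence distance is non-increasing across iterations and noiseless
fully-overlapping clouds with displacements small relative to the point
spacing are recovered to ≤ 1e-6 mm (both tested).

## NDT

### Grid

Reference points are binned by floor((p − origin)/cell_size) with origin
at the cloud's minimum corner; cells with fewer than `min_points_per_cell`
(default 5) points are inactive. Per active cell the sample mean and
covariance (n−1 denominator) are stored. Covariance eigenvalues are
floored at `eig_floor_ratio` (default 0.001) times the largest eigenvalue,
with a small absolute floor of (0.001·cell_size)² for fully degenerate
cells — surface patches are near-planar, so without flooring Σ would be
singular in essentially every cell. Larger floors were evaluated and
rejected: they widen the basin slightly but blur the optimum, costing
0.2–1 mm of recovery accuracy on the phantom fixtures.

The default cell edge is 100 mm, the scale appropriate to whole-torso
clinical surfaces; the bundled phantom fixtures use 30 mm cells so that
the grid holds a few hundred active cells at ~5000 points. Single fixed
grid; no multi-resolution schedule and no trilinear interpolation between
cells.

### Score

Within a cell the point likelihood is modelled as a Gaussian-inlier /
uniform-outlier mixture c₁·exp(−q/2) + c₂ with q the Mahalanobis square,
c₂ = outlier_mass / cell_volume and Gaussian amplitude c₁ =
10·(1 − outlier_mass), outlier_mass defaulting to 0.55. The negative log
of the mixture is approximated by a single exponential d₃ − d₁·exp(−d₂q/2)
fitted at q = 0, 1, ∞, giving

    d₁ = log((c₁+c₂)/c₂),   d₂ = −2·log( log((c₁·e^{−1/2}+c₂)/c₂) / d₁ ).

The additive constant d₃ is dropped; points landing in inactive cells sit
at the uniform-outlier baseline and contribute exactly zero, so the score
is ≤ 0 and bounded below by −d₁·n. Gradient and Hessian with respect to
the six pose parameters are fully analytic: per-point Jacobians combine
the identity (translation block) with ∂R/∂angle·p terms, and the Hessian
adds the ∂²R/∂angle² curvature of the Euler parameterisation; degree
units are folded in via π/180 factors. These derivatives are the module's
central correctness oracle — they match central finite differences to
better than 1e-4 (gradient) and 1e-3 (Hessian) on randomized fixtures,
in practice to ~1e-9.

### Optimisation

Newton's method on the 6-parameter chart from the zero transform. Each
iteration: shift the Hessian by λI when not positive definite
(λ = |λ_min| + 1e-6·max(1, |λ_max|)), cap the step at cell_size/2
translation and 5° rotation (an uncapped Newton step overshoots by 2–3×
early on, when the quadratic model is poor), then backtrack by halving
down to 1/64, keeping the best-scoring candidate. Convergence is declared
when a *full* (uncapped, unbacktracked) Newton increment falls below
0.1 mm / 0.1° — during damping a small step does not indicate
stationarity, and stopping on any small step was measured to leave
0.3–0.5 mm of recoverable error. If no candidate improves the score the
optimiser has hit the resolution floor created by cell-boundary
discontinuities; the run reports converged if even the smallest probed
step (1/64 of the proposal) was below the thresholds, and a divergence
(converged = False, best-so-far pose) otherwise. The optimiser contains
no randomness: identical inputs give identical results.

## CT-to-surface conversion

Three steps: binarise the volume at a threshold (default −300 HU, the
soft-tissue/air boundary; synthetic 0/1 volumes use 0.5), mark as contour
every foreground voxel with at least one background face-neighbour
(6-connectivity, volume borders count as background), and emit each
contour voxel's centre at origin + index·spacing (0-based indices, voxel
centres). DICOM series are read with pydicom: slices sorted by table
position, rescaled to HU, slice gaps required uniform to 1%. The boundary
operator makes the output invariant under background padding, and counts
are exactly predictable on filled blocks (a k³ block yields k³ − (k−2)³
surface voxels).

## Synthetic phantom

The generator stands in for a physical torso phantom observed by
ceiling-mounted depth cameras; it emulates the study conditions, not the
hardware. The torso is a superellipse cylinder (|x/a|^e + |z/b|^e = 1,
e = 2.5, chest half-axes a = 300, b = 200 mm, length 600 mm) resting on
the couch plane, with the half-axes tapering linearly by 25% from chest
to waist. The taper is essential, not cosmetic: a straight extrusion
leaves longitudinal translation unobservable to distribution matching
(the cell statistics are y-invariant), which showed up as ~0.8 mm NDT
y-bias; real torsos are not extrusions either. Surfaces are sampled
uniformly in (arc length × length) at 0.01 points/mm² (~5000 points,
~10 mm spacing — sparse-depth-camera scale). A capture applies the couch
shift, keeps the top 60% of the cloud's own height range (ceiling-camera
visibility), adds iid Gaussian noise (default σ = 0.5 mm, a mid-range
consumer-depth-camera figure at ~1.5 m), and optionally drops points.
All randomness flows from explicit seeds. The embedded 450 × 450 × 400 mm
cube phantom's centre serves as the treatment target.

The CT counterpart voxelises the solid torso into a binary volume padded
with background; its extracted surface lies within one voxel diagonal of
the analytic boundary (tested at 2 and 4 mm pitch).

What the generator does **not** model: multi-camera calibration error,
speckle, perspective-dependent occlusion, resampling between captures
(the same material points are re-observed, which flatters ICP slightly),
respiratory motion, and deformation. Consequences: (1) passing recovery
tests demonstrate algorithmic correctness under the stated noise, not
clinical accuracy; (2) the registration error does *not* grow with couch
shift here — both algorithms converge fully at every shift in 2–10 mm, so
per-shift errors sit at the noise floor, whereas on real hardware larger
shifts degrade the capture itself and errors climb.

## Evaluation

Registration error is the signed per-axis difference ground-truth minus
measured translation; RMS is its Euclidean norm. Aggregation uses
absolute per-axis errors (mean ± STD, n−1 denominator), the grand mean is
the arithmetic mean of the three per-axis means, and the "average RMS"
is the mean of per-trial RMS values (not the RMS of means). Report tables
round to two decimals, ties away from zero; the percent reduction between
methods is computed from the rounded grand means, matching how such
tables are read. The paired two-sided Student's t-test (scipy, df = n−1)
compares methods per trial and refuses zero-variance differences. Single
trials aggregate with STD = 0 and a warning. The three experiment runners
(reposition, target, surface-model) share the capture pipeline; target
accuracy transports the estimated correction to the cube centre and
reports its residual displacement from the planned position — a geometric
surrogate for a film-based beam-centre measurement. Registration failures
are counted and excluded from aggregates.

## Problem sizes

Defaults used by the test suite and the acceptance script: ~5000-point
surfaces, 30 mm NDT cells, 12 reposition trials (3 axes × 4 shifts),
2–3 repetitions for target and surface-model runs, 4–5 mm CT pitch. These
sizes put every statistic well past its convergence scale for a rigid
phantom while keeping the full suite under ten seconds; density, shifts,
repetitions and pitch are all exposed for larger studies.

## Known limitations

- Rigid transforms only; soft-tissue deformation is out of scope.
- Rotation accuracy is untested by design (metrics use ΔT only); the
  rotation conventions are internally consistent but not validated
  against an external system.
- Single-grid NDT retains a cell-quantisation bias of roughly 0.1–0.4 mm
  at 30 mm cells on noisy fixtures; interpolation or multi-resolution
  schedules would reduce it but are deliberately not implemented.
- The PLY codec reads vertex-only ASCII / binary-little-endian files and
  skips extra scalar properties; list properties (meshes) are rejected.
- DICOM support covers single-frame axial CT series with uniform spacing;
  enhanced multi-frame objects and RT structure sets are not read.
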