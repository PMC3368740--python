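# Methods

This note records the model, the numerical scheme, the synthetic phantom
design, and the design decisions taken where the method leaves room —
in enough detail that every number in the test suite and acceptance
script can be traced to a choice made here.

## Segmentation model

The corpus callosum is segmented as the region swept by an expanding
implicit surface. The boundary is the zero level set of φ(r, t)
(negative inside), evolved by

    ∂φ/∂t + F |∇φ| = w κ |∇φ|,

where F ≥ 0 is a tensor-similarity speed and κ the mean curvature. The
speed at a boundary voxel r is

    F(r) = Σ_{n_r} FA(r) FA(n_r) tr(D(r) D(n_r)) / (tr D(r) tr D(n_r)),

summed over 26-neighborhood voxels n_r whose offset direction lies
within 60° of the outward surface normal (cos cutoff 0.5, so the face
neighbor, its four edge diagonals and four corner diagonals in the
propagation direction participate). The summand is the trace inner
product of the two tensors normalized by the product of their traces —
a scale-free shape-and-orientation similarity in [0, 1] for PSD tensors
— weighted by the FA pair so low-anisotropy tissue contributes little.
A neighbor is admitted only if

1. |PDD(r) · PDD(n_r)| > 0.7 (orientation coherence),
2. FA(n_r) > 0.1 (anisotropic tissue),
3. |PDD_x(r)| > 0.55 (left–right oriented surface voxel),

and the summed speed is floored to zero at F ≤ 0.05. Eigenvectors are
sign-indeterminate, so PDDs are stored sign-canonicalized (x ≥ 0, ties
broken by y then z) and both orientation tests use absolute dot
products; without this the gates would depend on an unphysical sign
convention. Only the neighbor's FA is gated (not the surface voxel's),
following the printed form of the admission rule.

All four thresholds are `SpeedParams` fields; the defaults above are the
operating point found optimal for callosal segmentation and are used
everywhere unless a sweep varies one of them.

### Speed extension and stopping behavior

Speeds are evaluated on the hyper-surface voxels (inside voxels with an
outside face-neighbor), each with its own normal. The speed is then
extended to the voxels those surface points *admit through the gates*:
a claimed neighbor inherits the speed of its claiming surface voxel
(maximum over claimants). This gives the upwind stencil a speed on both
sides of the zero crossing — so the front can claim the last tissue
layer — while voxels no surface point admits keep speed zero and freeze
the front exactly at the anatomical boundary. Extending instead to all
nearby band voxels (e.g. nearest-surface-voxel lookup) lets diagonal
ties bleed speed into inadmissible tissue and the front creeps; the
gate-restricted extension is sharp.

### Numerics

* Advection uses a Godunov scheme with 5th-order WENO one-sided
  differences (the standard high-order upwind discretization for
  level-set transport); curvature uses central differences with an
  ε = 1e-8 guard on |∇φ| and values clamped to ±1 voxel⁻¹, since finer
  curvature is not resolvable on the grid and unclamped spikes only
  throttle the time step.
* Explicit Euler steps with CFL bound Δt = 0.5 / max(F + 6 w max|κ|),
  in voxel units.
* **Curvature coupling.** In the driver the regularizer multiplies the
  speed, F·(1 − wκ) clamped at zero (w = 0.1 default), rather than
  acting as an independent additive term. An always-on curvature term
  expands any concavity it finds — on a C-shaped structure it slowly
  fills the inner bend long after the gates have frozen the front, and
  the evolution never converges. Speed-modulated smoothing regularizes
  the moving front and leaves a gate-frozen boundary frozen. The
  independent-term PDE form remains available in
  `levelset.evolve_step` and is exercised directly by the unit tests
  (e.g. curvature-only flow shrinking a sphere).
* **Reinitialization** every 20 iterations: sub-cell anchored
  sign-preserving redistancing. Voxels adjacent to the zero crossing
  are pinned at φ₀/|∇φ₀| (so the interface cannot move), the rest relax
  under ∂φ/∂τ = sgn(φ₀)(1 − |∇φ|) with first-order upwind differences,
  and no voxel may change sign. Accuracy is exact at the interface and
  within ≈0.15 voxel nearby; the first-order scheme has an O(h·κ)
  fixed-point offset away from the interface, which is irrelevant to
  the front.
* **Convergence**: the zero-level-set voxel set unchanged for at least
  5 consecutive iterations spanning ≥ 4 time units. CFL steps are small
  (Δt ≈ 0.13 at typical speeds), so an iteration count alone can
  declare victory while the front is still creeping at ≈0.05 voxel per
  step; the time window makes the test mean "nothing moved for long
  enough that the slowest admissible speed would have crossed a voxel".
* Evolution and redistancing are restricted to the bounding box of the
  active band (|φ| < 6, padded): identical results (speed is zero
  outside the band) at a fraction of the arithmetic.
* Inside is φ < 0 strictly; exact zeros are outside (deterministic
  tie-break).

### Tensor fitting and I/O

Tensors are fit per voxel by plain log-linear least squares on
log(S_i/S0) = −b gᵀDg (no weighting or outlier rejection — the fit is
standard and not where this package adds value); negative eigenvalues
are clamped to zero so the speed function is defined everywhere, and
voxels with nonpositive signal get the zero tensor (FA 0, PDD
undefined, never admitted). Resampling to the isotropic working grid
(default 1.9 mm) is component-wise trilinear with re-symmetrization;
fitting precedes resampling by default (both orders are reachable
through the API). Tensors are stored as 6-component NIfTI volumes in
lower-triangular order (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz); gradient tables
as FSL-style bval/bvec text files. Axis convention everywhere: 0-based
voxel indices, axis 0 = left–right (x), axis 1 = anterior–posterior
(y), axis 2 = inferior–superior (z).

## Witelson parcellation

The anterior–posterior extent L of the mask (whole-mask bounding box —
identical to the mid-sagittal extent for untilted anatomy but robust
when the structure is rotated out of the slice plane) is cut at
anterior fractions 1/3, 1/2, 2/3, 4/5:

| strip | region(s) |
|---|---|
| [0, L/3) | rostrum + genu + rostral body |
| [L/3, L/2) | anterior mid-body |
| [L/2, 2L/3) | posterior mid-body |
| [2L/3, 4L/5) | isthmus |
| [4L/5, L] | splenium |

Within the anterior third, the rostrum is the tissue inferior to the
genu/rostrum critical point, and the remainder splits at the strip's
own midpoint (L/6) into genu (anterior) and rostral body (posterior);
that internal boundary is anatomical rather than fractional in the
original scheme, and the midpoint is the simplest deterministic proxy.
Every 3D voxel inherits the label of its anterior-posterior bin (labels
extend uniformly along x). Labels exactly partition the mask by
construction.

The mid-sagittal plane is the sagittal slice maximizing the normalized
cross-correlation between the FA volume and its left-right reflection,
searched over the central third of the x-range; a user override wins.
The critical point is found on the mid-sagittal boundary contour:
uniform-arclength resampling, circular Gaussian smoothing (σ = 4 of 256
points), signed curvature, then the most concave point (κ < −0.1) in
the anterior-inferior quadrant. Rasterization jitter on smooth convex
boundaries stays above ≈ −0.06 after smoothing, so a convex mask (no
recurve) correctly raises and asks for a manual point.

## Rotation experiment

A rigid rotation R = R_x(azimuth)·R_y(elevation)·R_z(skew) is applied
to the baseline segmentation plus a 5-voxel margin about the mask
centroid: output voxels sample the input at the inverse-rotated
coordinate (nearest neighbor — no tensor interpolation, hence no
swelling artifacts) and tensors reorient as T′ = R T Rᵀ, which rotates
the PDD consistently and preserves eigenvalues exactly. Seeds follow
the rotation. The reference is the **baseline parcellation carried
through the same rotation** (subdivide-then-rotate); the re-segmentation
of the rotated volume is parcellated in the fixed image frame. At zero
angle this compares a deterministic pipeline against itself, so Dice is
exactly 1, and at nonzero angles the comparison captures both gate
failures (orientation gates are frame-locked to the left-right axis)
and the parcellation's sensitivity to the structure leaving its
canonical pose. Outer (rostrum, genu, splenium) vs inner subdivision
means are compared per angle with the exact paired Wilcoxon signed-rank
test (two-sided; zero differences dropped, ties mid-ranked; exact
distribution by dynamic programming for n ≤ 25 nonzero pairs, normal
approximation with continuity and tie corrections above; p < 0.01
flagged). No multiple-testing correction across cells — each cell is
reported on its own.

## The phantom

The generator builds the study conditions; its defaults are fixed and
not tuned per experiment.

* Grid 64×96×64 voxels at 1.9 mm (reduced 48×72×48 for the sweep and
  rotation experiments; see *Problem sizes*). Arch radius 0.23·n_y,
  tube radius 3, lateral half-width 0.07·n_x.
* Bundle tensors are axially symmetric with eigenvalues
  (1.7, 0.3, 0.3)×10⁻³ mm²/s — FA = 0.799 — and the background is
  isotropic 0.8×10⁻³ (FA 0), bracketing the FA gate decisively.
* The arch spans ±100° of a circle in the sagittal plane. Through the
  body the PDD is left–right; beyond 25% of the half-angle it tilts
  toward a fixed oblique fan direction (25% anterior-posterior, 75%
  inferior dorsoventral), reaching 52° at the arch end — |PDD_x| =
  0.616, still inside the gate. A rostral arm recurves
  posterior-inferiorly from the genu tip, its orientation bending
  smoothly back to left-right.
* The fan **continues smoothly** past the arch end at 2° of tilt per
  degree of arc: tissue whose tilt still passes the default |PDD_x|
  gate (up to ≈102°) is deliberately labeled neither bundle nor
  distractor — it models the partial-volume transition that makes the
  real callosum/forceps boundary hard — and the forceps label starts at
  108° (tilt 68°, |PDD_x| = 0.37), beyond the front's one-voxel claim
  horizon. This graded interface is what gives the threshold sweep its
  characteristic false-positive rise at low |PDD_x| thresholds, with
  the orientation-coherence gate playing no role there — so the
  collinearity sweep is flat by design, mirroring which gate does the
  work at each boundary.
* Distractors: a straight anterior-posterior cingulum tube 2 voxels
  above the arch apex (orthogonal PDD: fails collinearity and PDD_x); a
  low-FA tapetum sheet (eigenvalues (0.85, 0.775, 0.775)×10⁻³, FA
  0.054: fails the FA gate) with callosal orientation; and the forceps
  fans above. A 2-voxel zone around the rostral arm where it crosses
  the fan ring stays unlabeled (orientations grade between arm and
  fan).
* Noise: optional zero-mean Gaussian perturbation of the six tensor
  components (default off; replicate experiments use σ = 5×10⁻⁵ mm²/s,
  which perturbs PDDs by ≈2° and FA by a few percent), then eigenvalue
  re-clamping to keep tensors PSD. Everything is reproducible from the
  integer seed.
* Suggested seeds: five points along the arch centerline at
  θ ∈ {−80°, −40°, 0°, 40°, 80°} on the mid-sagittal slice, radius-2
  spheres.

The fan geometry encodes the anatomy that produces the rotation
result: rotations about the left-right axis (azimuth) never change
PDD_x, so their cost is purely the parcellation leaving its canonical
pose; rotations about the anterior-posterior axis (elevation) drive the
dorsoventrally-tilted fan out of the |PDD_x| gate over a wide band at
both ends; in-plane (skew) rotations affect only the small
anterior-posterior fan component on one end plus a modest bin shear —
hence skew is the least disruptive axis, azimuth and elevation the
more disruptive ones.

**What the phantom does not model:** partial-volume mixing at the
signal level, Rician noise, susceptibility distortion, fiber crossing
within a voxel, non-rigid tumor deformation (infiltration, tearing,
mass effect beyond rotation), and inter-subject anatomical variability.
Tests passing on the phantom demonstrate the algorithm's mechanics —
gate selectivity, convergence, parcellation arithmetic, rotation
equivariance — not clinical accuracy.

## Problem sizes

Full segmentations run on the 64×96×64 default phantom (≈25 s on one
CPU). The threshold sweeps (12 segmentations) and the rotation
experiment (3 noise replicates × 3 axes × angles {0°, 10°, 30°}, with
the zero-angle cell computed once per replicate) use the 48×72×48
phantom so the whole analysis completes in minutes; the full
6-angle/5-replicate experiment is available through the same API and
CLI. Sweep grids cover [0.3, 0.8] in steps of 0.1.

## Known limitations

* The front claims admissible tissue one voxel past the last admissible
  surface voxel (the claim horizon), so masks can carry a sub-voxel
  overshoot into transition tissue; on the phantom this is confined to
  the unlabeled fan transition.
* Threshold sweeps show ≈1% non-monotonic wobble in raw TP counts from
  front-propagation discretization (corner-filling differences between
  runs); the curves' shape is unaffected.
* Seed placement is manual by design; `suggest_seeds` ranks
  |PDD_x|·FA candidates on a chosen slice but is an optional helper,
  off the main path.
* The exact Wilcoxon needs ≥5 nonzero paired differences; with fewer
  replicates the inner/outer comparison reports NA.
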