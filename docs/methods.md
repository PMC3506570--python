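# Methods

This note documents the models, conventions and numerical choices behind
`cardiotract`, and what the synthetic phantom does and does not establish
about real data.

## Coordinate conventions

All tract geometry lives in world millimeters; voxel centers sit at
(i + 0.5)·spacing with 0-based indices, so a world point p belongs to
voxel floor(p / spacing). The LV local frame at a wall point is the
orthonormal triad (ĉ, l̂, r̂): r̂ the outward in-plane offset from the LV
centerline, l̂ the long axis, ĉ = l̂ × r̂ the circumferential direction.
For real masks the long axis is the principal axis of the voxel-center
covariance and the centerline is the per-slice centroid binned along the
axis at one-voxel resolution and linearly interpolated; phantoms carry
their analytic frame.

The helix angle of a fiber direction f is atan2(f·l̂, f·ĉ) after folding f
so that f·ĉ ≥ 0, giving HA ∈ (−90°, 90°] with HA(f) = HA(−f). One module
constant (`GLOBAL_HA_SIGN`) controls the global sign; with the default +1
and ĉ circulating counterclockwise viewed from the base, subendocardial
right-handed helices are positive. HA is invariant to the (arbitrary) sign
of the fitted long axis, because flipping l̂ flips ĉ too and the fold
restores the angle. Fibers within 1e-9 of radial have no defined HA and
are excluded from statistics rather than imputed. The same axial-angle
convention, with the same sign constant, maps microscopy orientations onto
the MR frame.

## Tensor fit

The fit is unweighted log-linear least squares on
ln(S_i/S_0) = −b_i g_iᵀ D g_i, with multiple baselines averaged before the
log. It is exact on noiseless signals (used as a round-trip oracle at
1e-10) and adequate at phantom noise levels; no positivity constraint is
imposed. Non-SPD or non-positive-signal voxels are flagged, not clamped —
clamping eigenvalues would silently distort HA. A rank-deficient gradient
scheme (fewer than six independent directions) is rejected outright.

## Tracking

Streamlines integrate the ê₁ field with classical RK4 at a step of
¼ voxel (`step_fraction`, default 0.25). Because ê₁ is axial, every field
evaluation aligns each contributing voxel's vector with the incoming
direction (dot ≥ 0) before component-wise trilinear interpolation and
renormalization; out-of-mask corners get zero weight. The RK4 increment is
*not* rescaled to the nominal step: rescaling would trade the observed
fourth-order convergence (verified on the analytic circular field: ≥ 8×
endpoint-error reduction per step halving, radial drift < 1e-3 R per
revolution) for cosmetic spacing exactness, and for smooth fields the
increment norm already equals the step to O(h³·curvature²).

Growth is bidirectional (the backward branch integrates −ê₁; the seed's
initial sign is fixed to the positive hemisphere by first nonzero
component), and termination is per branch: propagation angle > 35° between
consecutive segments, mask exit, invalid (NaN) field, or the length
policy. Under `pi_r` each branch is capped at πR/2 so the *total* tract
length is at most half the LV circumference; `roi_clip` stops growth at
the ROI boundary; a hard step cap (default 2000/branch, flagged when hit)
guarantees no streamline is infinite. Tracts with fewer than 3 vertices
are discarded and counted. R is the mean in-plane distance from the long
axis over mask voxels in the central third of the axial extent.

One consequence of trilinear interpolation deserves emphasis: a
discontinuity in the field is smeared over one voxel, so at ¼-voxel steps
even a 90° interface produces only ~20°/segment and does *not* trigger the
35° criterion; the criterion catches step-scale direction noise, not
smoothly resolved turns. The termination tests therefore exercise an 80°
interface at one-voxel steps, where the per-segment angle genuinely
exceeds the threshold.

## Transmural curves, TCI, histogram

Each classified tract deposits its (min, med, max) HA into every ROI voxel
its polyline traverses (once per voxel) — deposition per traversed voxel,
not per seed, makes the curves independent of seeding density. ROI voxels
are binned on the local frame at the ROI centroid (transmural = radial,
base-apex = long axis, anterior-posterior = circumferential arc length) at
one-voxel resolution; deposits are averaged along base-apex per column,
then across anterior-posterior, and the resulting three curves are sampled
on x = layer index / (layers − 1), endo → epi. By default the statistics
come from the full tract even when it extends beyond the ROI (only the
deposition is ROI-limited); `pi_r` versus `roi_clip` tracking reproduces
the two fiber-length analyses.

TCI = ∫HA_med²dx / [∫(HA_max−HA_med)²dx + ∫(HA_min−HA_med)²dx], both
integrals trapezoidal on normalized depth so the index is a pure ratio
(degrees² cancel). At least 3 valid samples are required; a denominator
below 1e-12 of the numerator returns +inf with a "perfectly coherent"
flag, and an all-zero 0/0 raises. The mean-HA classification is computed
but never enters the TCI.

The variance ratio is the (n−1) sample variance of strictly negative tract
median HAs over that of strictly positive ones; values exactly 0 are
excluded from both sides, fewer than 2 values on either side leaves the
ratio undefined. Binning (5° default) affects display only. The
zero-crossing of HA_med(x) is linearly interpolated between bracketing
samples; multiple crossings are all returned and flagged.

## Phantom

The phantom is an annular cylinder segment — the mid-ventricular lateral
wall, where the LV is locally cylindrical — not a truncated ellipsoid:
all quantification here happens in such an ROI. Defaults: inner radius
24 mm, outer 34 mm (10 mm wall, sheep-scale), height 75 mm, isotropic
1.25 mm voxels (8 transmural layers on a ~64³ grid), eigenvalues
(1.0, 0.7, 0.5)×10⁻³ mm²/s (physiologic-order anisotropy; the values are
irrelevant to HA), linear transmural HA profile between `alpha_endo` and
`alpha_epi`, and per-voxel orientation noise of Normal(0, 5°) about a
uniformly random axis in the study configuration. The voxel size is chosen
so the transmural profile is well resolved: at coarser resolution (e.g. a
5-layer wall) the lumpy radial volume element of the voxelized annulus
alone distorts depth-weighted statistics such as the variance ratio by
~10%, independent of any tracking. The transmural depth coordinate is
x = (r − r_inner)/(r_outer − r_inner).

Presets encode the studied architectures as configuration, not code:
`normal-human` ±60°, `normal-sheep` ±50°, `remote-zone` +60/−37.5° (the
epicardial value anchored to subepicardial histology of remodeled hearts;
the endocardial side, where remodeling differences are not significant, is
left unchanged). Optional features, both off by default: a quadratic
axial taper of |HA| emulating apex/base flattening, and an elevated-noise
subendocardial band (x < 0.15) standing in for papillary/trabecular
incoherence. Forward-simulated DWI uses S_i = S₀ exp(−b g_iᵀ D g_i) with
Rician (default) or Gaussian noise; the noiseless signal round-trips
through the tensor fit exactly.

What the phantom does not emulate: real whole-heart anatomy (apex, base,
right ventricle), papillary muscles and trabeculations as structures,
infarct core, strain/motion, susceptibility or eddy-current artifacts, and
any nonlinear transmural profile (the profile rule is pluggable but only
linear ships). Passing tests on the phantom therefore validates the
*estimators* — tracking accuracy, classification, curve construction,
index algebra — under controlled geometry and noise; it does not by itself
establish accuracy on scanner data.

On this idealized symmetric phantom the expected variance ratio is 1.0
(real normal hearts sit slightly below 1);
measured study values are ≈ 0.97, and the remote-zone preset drives the
ratio to ≈ 0.4 with the zero-crossing moving to ≈ 0.62, reproducing the
direction and rough magnitude of the remodeling signature while TCI stays
far above the 0.1 floor — the computed numbers come from the test suite
and `scripts/acceptance.py`, not from fits to any external data.

## Histology orientation

Ridges are detected on the Gaussian-smoothed image (scale σ, default 2 px)
as pixels whose principal Hessian curvature exceeds a threshold (default:
half the image RMS principal curvature — adaptive and scale-free) *and*
whose smoothed intensity is extremal one pixel away along the
principal-curvature eigenvector; bright ridges (fibers) and dark valleys
(interstitial spaces) both carry orientation and both are kept. The ridge
mask is skeletonized to single-pixel 8-connected chains (idempotent),
chains shorter than `min_segment_length` (default 10 px) are dropped, and
each segment's angle is the principal axis of its pixel chain — more
robust than an endpoint chord for curved segments. The section mean is the
length-weighted circular mean on the half-circle (angles doubled, averaged
as vectors, halved; an unweighted switch exists since the reference
procedure's weighting is not specified): ±80° average to ±90°, not 0, as
axial data require. Structureless (constant) images return an empty,
flagged result.

## Degenerate inputs and tie-breaks

Eigenvalue ties are broken by the symmetric solver's deterministic output;
no re-orientation is applied at decomposition time (the tracker's sign
alignment handles antipodality). Seeds outside the mask are skipped and
counted. A wall thinner than two voxels is rejected at phantom
construction (profile unresolvable). An ROI spanning fewer than two
transmural depths is rejected; empty averaging columns are dropped with
zero counts. HA exactly 0 is excluded from both sides of the variance
ratio (documented tie-break). Discrete HA jumps above 90° along a tract
set a wrap flag rather than being unwrapped.

## Problem sizes

The default study runs a ~64³ phantom with ≈ 70,000 wall voxels, seeds
≈ 6,000 tracts from a 90° × 24 mm transmural sector ROI, and tracks
πR ≈ 92 mm tracts at 0.3125 mm steps; one full pipeline run takes ≈ 10 s
and the five-seed acceptance study ≈ 1 min on one CPU. Tracking is
batched: all active streamlines advance one RK4 step per iteration, so
cost scales with steps × front size, not with streamline count.

## Determinism

Every stochastic stage (orientation noise, DWI noise, seed jitter) is
driven by an explicit integer seed through `numpy.random.default_rng`;
identical configuration including seeds gives bitwise-identical phantoms
and identical metrics JSON. CLI outputs carry a provenance block (config
hash, seed, package version).
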