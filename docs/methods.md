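# Methods

This package implements a geometric-morphometric pipeline for postnatal
craniofacial ontogeny (0–48 months) and a synthetic growing-skull
generator with closed-form ground truth, so that every stage —
semilandmark templating and sliding, superimposition, form-space
ordination, trajectory comparison, shape–volume covariation and cavity
volumetry — can be validated without clinical data.

## The synthetic cohort generator

**Geometry.** A cranium is a superellipsoid shell
|x/A|^p + |y/B|^p + |z/C|^p = 1 (default p = 2, i.e. an ellipsoid with
semi-axes 82 × 68 × 62 mm at the 12-month reference; the exponent is
configurable and the enclosed volume stays closed-form,
8ABC·Γ(1+1/p)³/Γ(1+3/p)). Meshes are icosphere subdivisions mapped
radially onto the implicit surface, so they are watertight and genus 0 by
construction. Four internal cavities — intracranial (ICV), left orbital
(LOV), nasal (NCV) and upper intraoral (UIV) — are axis-aligned
ellipsoids strictly inside the shell and mutually disjoint (worst-case
margins across 0–48 months: ≈1.9 mm to the shell, ≈2.6 % relative
between cavities, checked numerically when the layout was fixed). Each
cavity surface carries a small polar aperture (spherical-cap cut, cone
cosine 0.95, ≈2.5 % of area) whose rim is an ordered vertex loop; true
volumes are 4/3·π·abc exactly.

The cavity placement is schematic: volumes follow realistic growth
dynamics and rank order, but the ICV is scaled down relative to real
anatomy so four disjoint analytic ellipsoids fit inside one convex
shell. Sutures, teeth, sinuses and surface relief are absent; linear
dimensions and indices are therefore internally consistent rather than
normative.

**Landmarks.** The 88-landmark roster (16 + 2 midline points, 35
bilateral pairs; standard craniometric names) ships as package data with
each point's placement direction; positions are the radial map of those
directions onto the shell. The paired Euryon points are flagged and
excluded from superimposition (their position depends on overall vault
shape), leaving 86 landmarks for GPA while both remain available for
maximum cranial breadth.

**Growth.** Ages use 1 month = 30.41 days. Centroid size follows
cs(t) = S·(a + b(1 − e^{−ct})) with a = 0.72, b = 0.38, c = 0.13/month:
strictly increasing, fast in the first 18 months, slowing thereafter
(48-month/birth size ratio ≈ 1.53). Males are a constant size-for-age
factor 1.03 above females (heterochrony by size only). Shape change is a
single allometric displacement field v over the 88 landmarks — unit
Frobenius norm, orthogonalised against translations, rotations and
scaling of the template so it is identifiable — applied in unit-shape
space as `allometric_scale · v · (Ln CS − Ln CS_ref)` with
allometric_scale = 0.18. That magnitude makes size dominate form
variation (form-space PC1 loads ≈ 0.98 on Ln CS), the regime the method
is designed for. The default pattern expands anterior-inferior (facial)
regions relative to the vault. A `trajectory_divergence_deg` knob
rotates the male vector towards an orthogonal secondary field for power
experiments only; the default is 0 (fully shared trajectory).

Mesh vertices follow the landmarks through a 3D thin-plate-spline warp
anchored on the noise-free landmarks; i.i.d. Gaussian measurement noise
(default sd 0.5 mm per coordinate) is then added to the landmarks only.
ICV/LOV follow logistic volume curves (rapid early growth that
saturates), NCV/UIV affine ones; cavity semi-axes are rescaled each age
so analytic volumes equal the curves exactly. One seed sequence is
spawned per specimen by counter, so cohorts are bitwise reproducible and
insensitive to construction order. The default age sampler is uniform on
0–1460 days; a skewed sampler mimicking a clinical age distribution
(dense in year 1) is provided. Sex counts are deterministic:
round(n · male fraction), default fraction 123/217.

## Thin-plate splines and sliding

The 3D TPS uses kernel U(r) = r with the sign convention U(r) = −r, under
which the bending-energy matrix (top-left block of the inverted bordered
system) is symmetric positive semidefinite with the affine fields as null
space; the interpolant is identical under either sign. A Tikhonov jitter
of 1e-10 on the kernel block guards near-degenerate configurations while
preserving interpolation to well below 1e-8 mm at cranial scales.

Surface semilandmarks are seeded on one side of the reference by
farthest-point thinning of a dense area-weighted candidate pool on each
labelled patch (midfacial / calvarial / lower occipital; one-sided
counts 100/1000/52 by default), mirrored across the least-squares
midsagittal plane of the midline landmarks, and projected back to the
surface — 2304 points, 200 mid-facial, 2104 neurocranial. On each target
the template semilandmarks are carried by a TPS anchored on the
landmarks, projected to the surface (KD-tree-prefiltered exact
point-to-triangle projection), then slid: each iteration solves the
tangent-plane-restricted minimisation of the reference-to-target TPS
bending energy in closed form (the quadratic programme in the 2m tangent
coefficients), re-projects to the surface, and accepts the step only if
energy did not increase (1e-9 relative), so the energy trace is
nonincreasing. Tangent frames interpolate area-weighted vertex normals
at the projected point. Landmarks stay fixed; default 3 iterations,
relative tolerance 1e-6. Sliding uses the 86 superimposition landmarks
as anchors; an optional second pass re-slides against the GPA mean
(off by default — with a synthetic template there is no template-choice
bias to remove, and the single-pass result is already stable).

The per-iteration solve is dense and cubic in the semilandmark count, so
cohort-scale runs default to a few hundred semilandmarks; the full
2304-point configuration is exercised where only templating is needed.

## Superimposition and form space

GPA scales every configuration to unit centroid size (full Procrustes —
size is removed and re-attached as Ln CS, which is what the form-space
construction expects), aligns by SVD rotations with a determinant
correction so reflections are impossible, and iterates to the updating
mean until the relative mean change is < 1e-10 (max 100 iterations).
The converged mean is rotated to its principal axes with a fixed sign
convention, making the output frame invariant to how inputs were posed.
The form matrix appends the Ln CS column, unweighted, to the shape
coordinates.

## Statistics

* **PCA** is covariance PCA via SVD of the centred matrix.
* **Multivariate regression** of a response block on one covariate is
  per-column OLS; R² is trace-based (Goodall): explained over total
  centred sums of squares. Permutation p-values permute the covariate
  rows and use (1 + #{perm ≥ obs})/(1 + n_perm), so p at 1000
  permutations bottoms out at ≈0.001.
* **Trajectory comparison**: the angle between the two groups' unit
  coefficient vectors (arccos of the dot product); the null pools
  specimens and permutes group labels preserving group sizes, refitting
  both vectors each time.
* **Two-block PLS**: SVD of the cross-covariance of the centred blocks;
  per axis the score correlation r and the squared singular value as a
  percentage of their sum. The reported %Var(Block 1) is the variance of
  block 1 explained by regression on its own axis-1 scores (the
  alternative — prediction from block-2 scores — can be derived from the
  returned scores). The permutation null shuffles block-2 rows; the
  statistic is the axis-1 score correlation.
* **Age groups**: default edges {0,1,3,6,9,12,18,24,36,48} months — nine
  bins, dense in the first year where growth is fastest. Bins are
  lower-exclusive/upper-inclusive (12.0 months falls in 9–12), the first
  bin closed below. Edges are configurable.
* **Warps**: the mean shape is moved along a regression vector to a
  covariate value and rescaled by exp(Ln CS); prediction is affine in
  the covariate. Surface visualisation warps the template mesh by TPS to
  the predicted configuration and reports per-triangle percent area
  change (reference in the denominator; positive = expansion), by face
  index — meshes share topology by construction, so no proximity
  matching is ever used. Out-of-range covariates warn (extrapolation)
  rather than fail.

## Volumetry

`cavity_volume` is cap-and-enclose: each aperture loop is closed by a
triangle fan about its centroid, oriented against the directed boundary
edges so the capped shell remains consistently wound; connected
components are split, and the smallest watertight component containing
the seed point (generalized-winding-number test) is measured by the
divergence-theorem volume. The "smallest enclosing" rule makes the
function work on combined scenes where the outer shell also contains the
seed. A fan cap slightly underestimates the missing spherical cap; with
the default ≈2.5 %-area apertures, total recovery error is ≈1 % at the
default resolutions, dominated by the inscribed-polyhedron bias of the
icosphere (cavity meshes use at least subdivision 3 for that reason).
Cube-root volumes (CVols) and their percentage contributions to the sum
of cube roots (CPVols, summing to 100) are derived views.

## Calibration and recovery experiments

Run on landmark-only cohorts (the generating vector is defined over the
landmarks; meshes add runtime, not information): type-I error of the
regression permutation test over 200 null replicates (n = 50, 200
permutations) lands inside the binomial band around 0.05; with a shared
allometric vector the sex-trajectory test is non-significant in ≥ 90 %
of replicates, and with a 45° divergence at low noise it rejects in
≥ 90 %; the estimated allometric vector (after rotating the GPA frame
onto the template by ordinary Procrustes) recovers the truth to ≈1° at
n = 200, low noise.

## Problem sizes and numerical choices

Default driver sizes: cohorts of 40 at mesh subdivision 3 with ≈280
semilandmarks for the full battery; subdivision 4 and the full 2304-point
template for templating and volumetry checks; 200/100 replicates for
calibration. These sizes were chosen so the whole battery runs
interactively on a laptop-class single core while every qualitative
conclusion is already stable. Other constants: GPA tolerance 1e-10; TPS
jitter 1e-10; sliding acceptance 1e-9 relative; PCA/PLS rank cutoffs at
1e-12 of the leading singular value.

## What passing tests do and do not show

The generator produces exactly the structure the statistics assume: a
single shared allometric vector, monotone growth, Gaussian landmark
noise, bilaterally symmetric shells, exact ellipsoid cavities. Passing
recovery and calibration tests therefore validates the implementation —
superimposition, sliding, regression, PLS and volumetry do what they
claim — not the biological adequacy of any particular model of human
growth. Real crania add landmarking error structure, asymmetry,
non-ellipsoidal cavities with ill-defined aperture boundaries, suture
gaps needing hole-filling, and sampling imbalance, none of which are
emulated beyond the optional skewed age sampler.
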