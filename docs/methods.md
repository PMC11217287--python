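# Methods

This note documents the models implemented in `seedmech`, the assumptions
behind them, the parameters that matter, and what the synthetic-data tests
do and do not establish about real data.

## Shell model

**Membrane statics.** The seed coat is modelled as a thin elastic shell
under uniform internal pressure.  `solve_membrane_stress` computes the
small-strain linear membrane solution with constant-strain triangles in
plane stress: per-face stiffness t·A·BᵀDB assembled into a global system,
a dead pressure load p·A/3 along the outward face normal lumped to the
vertices, and the six rigid-body modes removed by Lagrange constraints
(zero mean translation and rotation).  Because the pressure load on a
closed surface is self-equilibrated, the constraint choice only fixes the
rigid motion; the stress field is unaffected.  Per-face stress tensors are
rotated to the global frame, optionally area-averaged within each cell,
projected onto the local tangent plane and eigen-decomposed into principal
stresses σ₁ ≥ σ₂, principal axes and the anisotropy (σ₁−σ₂)/(σ₁+σ₂)
(stated whenever σ₁+σ₂ > 0; the formula itself is a package convention —
the source analyses never print one).

A closed convex membrane is statically determinate to leading order:
stresses depend on pressure, thickness and geometry but not on the elastic
constants.  The test suite exploits this (Young's-modulus invariance,
exact linearity in p, invariance under joint scaling of lengths and
thickness) and validates the solver against two closed forms: the sphere
(σ = pR/(2t)) and the spheroid of revolution, for which
`spheroid_stress_oracle` evaluates σ_m = pR₂/(2t) and
σ_h = (pR₂/t)(1 − R₂/(2R₁)) with R₁ = w³/(ab), R₂ = bw/a,
w = √(a²cos²u + b²sin²u) at parametric latitude u.  At the poles
R₁ = R₂ = b²/a and both stresses equal pb²/(2ta).

**Inflated configuration.** Membrane statics hold on whatever shape the
shell actually assumes under load.  On a *fixed* flattened ellipsoid the
flatter faces turn out to be nearly isotropic in stress, so the principal
direction there is not meaningful; a real pressurized shell, however, does
not stay at its unloaded shape — its flattened faces bulge and the
cross-section rounds up, which makes the hoop direction dominate
everywhere away from the tips.  `inflate_shell` therefore computes the
pressurized equilibrium shape of a St. Venant–Kirchhoff membrane (plane
stress, Ψ = λ_ps/2 (tr E)² + μ tr E² on the Green strain of each triangle)
by minimizing total potential Π = Σ t·A_ref·Ψ − p·V with L-BFGS, ramping
the pressure over four load steps; −p·V is the exact potential of a
uniform follower pressure on a closed surface.  The default prediction
pipeline treats the seed-ratio ellipsoid as the unloaded reference,
inflates it, and evaluates stress and curvature on the inflated shape
(`inflate: false` in the run configuration gives the fixed-shape solve).
Region labels (tips, flanks, flat faces) are assigned on the reference
geometry, where the ellipsoid axes are exact.

**Default material.** E = 100 MPa, ν = 0.3, t = 1 µm, p = 0.2 MPa.  The
directional and anisotropy outputs the package is used for are ratios, so
these defaults act only through the degree of inflation (strain scale
≈ pR/(2tE) ≈ 10% at R = 100 µm), which is of the order expected for a
turgid plant wall.

## Curvature estimation

`estimate_curvature` fits, for each cell, the quadric
h = ½(Aξ² + 2Bξη + Cη²) + Dξ + Eη + h₀ in the cell's tangent frame to all
mesh vertices within a given surface distance of the cell centroid, then
eigen-decomposes the shape operator S = (I + ggᵀ)⁻¹H/√(1+|g|²) (H the
fitted Hessian, g the fitted slope).  Curvature is positive for a convex
surface with outward normals (a sphere has κ = +1/R).  Distances are
shortest paths on the mesh edge graph — the geodesic convention matches
how "neighbourhood" is meant on a curved organ; a Euclidean-ball mode is
available behind a flag and agrees closely on smooth surfaces.  The
neighbourhood radius is a physical scale, 30 µm by default (appropriate
when cells are ~10–20 µm across; a 60 µm radius suits proportionally
larger cells); it must exceed twice the mean edge length or the fit is
refused.  Fewer than six in-radius vertices raise an error naming the
cell.  A fixed radius is used throughout; an adaptive per-cell radius
(e.g. to the far edge of the direct neighbours) would be a natural
extension but is not implemented.

The analytic oracle `ellipsoid_curvature_oracle` evaluates the exact
principal curvatures of the triaxial ellipsoid from its implicit form
(shape operator EᵀHE/|∇F| on the tangent basis E), giving the estimator a
ground truth on spheres, spheroids and the seed shape.  Estimator error at
a fixed physical radius has two parts: vertex-sampling error, which falls
with mesh refinement, and a patch-size bias from approximating the surface
by one quadric over the whole neighbourhood, which does not.  The
convergence test operates in the sampling-limited regime (coarse meshes,
65 µm radius); at fine meshes the bias floor (well below 3% on the sphere
at 30 µm) dominates.

## CMT–curvature angle statistic

Both the per-cell CMT orientation and the maximum-curvature direction are
sign-free (axial) tangent unit vectors, so their disagreement is
θ = arccos(|u·v|) ∈ [0°, 90°] — symmetric, invariant under independent
sign flips, 45° on average for unrelated axes.
`correlate_orientation_with_curvature` joins the two fields on cell ids
(cells missing from either side, or carrying non-finite values, are
excluded and counted), computes θ per cell and a histogram (default 18
bins of 5°), and reports median (robust), mean and the fraction below 30°.
`orientation_relative_to_point` is the 2D variant used for ablation-style
analyses: the deviation of each cell's axis from the circumferential
direction around a focus point, 0° meaning perfectly circumferential.

## Fibril analysis

`fibril_tensor` implements the gradient nematic tensor: Gaussian
pre-smoothing (σ = 1 px by default, exposed as a parameter), central-
difference gradients, fibril axis = gradient rotated 90°, and the weighted
mean tensor N = Σ w (û ûᵀ − I/2)/Σ w with w = |∇I|² (unit weights behind a
flag for sensitivity analysis).  The mean orientation is the principal
eigenvector angle, reported modulo 180° in image coordinates (x = columns,
y = rows); the organization score is the eigenvalue gap λ₁ − λ₂ ∈ [0, 1].
A constant ROI yields score 0 with the orientation flagged undefined; ROIs
under 64 px are refused.  Organization scores depend on the imaging and
preprocessing route, so they should only be compared between measurements
made the same way; every measurement records its preprocessing parameters.
`roi_batch_measure` applies the tensor per labelled region and can report
orientations relative to an organ axis (90° = circumferential hoops).

Central differences underestimate the direction of obliquely sampled high
frequencies (the sin k vs k distortion), which biases recovered
orientations toward the image diagonals by a few tenths of a degree at an
8–20 px fibril spacing.  The synthetic texture's default spacing (20 px)
keeps this sampling bias small; orientation-recovery checks average a few
replicate textures so they measure the estimator's accuracy rather than
single-realization scatter.

## Morphometry

**Segmentation.** `segment_seeds` binarizes with the Huang minimum-
fuzziness threshold (entropy of fuzzy class memberships minimized over a
256-bin histogram, as in the ImageJ implementation), fills holes, and
separates touching objects by watershed seeded at the maxima of the
smoothed Euclidean distance transform.  Objects below 100 px² are
discarded; objects with solidity < 0.8 are kept but flagged with a warning
— the automated stand-in for the manual curation such macros receive.  A
contrast gate (foreground/background mean separation of at least 3
background SDs) prevents a foreground-free noise image from being split
spuriously; such images return zero labels with a warning.

**Shape.** `measure_seed` offers two conventions: `ellipse` (major/minor
axes of the second-moment-matched ellipse — the mature-seed convention)
and `axes` (longest chord along the principal axis and the perpendicular
extent through its midpoint — an automated proxy for hand-drawn
length/width lines on developing seeds, where those lines were drawn by
eye in practice).  Aspect ratio is L/W; both modes agree within ~1% on
clean ellipses and are rotation- and scale-invariant at the pixel level.

**Growth series.** `growth_derivative_series` applies exactly
rate_{n→n+1} = (mean_{n+1} − mean_n)/mean_n and
sd_{n→n+1} = √((sd_{n+1}/mean_{n+1})² + (sd_n/mean_n)²), to area (growth
rate) and to aspect ratio (growth anisotropy).  The derivative formula is
stated for area; its application to aspect ratio follows the way the two
series are used side by side, and is flagged here as an inference.

**Cell growth.** `cell_growth_map` takes two tessellations with matched
face indexing plus a parent→offspring lineage.  Areal growth is
Σ offspring areas / parent area − 1.  Growth anisotropy comes from the
least-squares linear map between the parent's face centroids at the two
timepoints (the later set rigidly rotated to align cell normals, both
projected to the parent tangent plane): the singular values λ₁ ≥ λ₂ give
the anisotropy λ₁/λ₂ (isotropic = 1) and the λ₁ direction the main axis
(axial angle from the in-plane x direction).  Matched face centroids stand
in for matched boundary points; for tessellation pairs produced by the
affine generator the two are equivalent.  Cells with fewer than three
non-collinear points are flagged rather than fitted.

**Dimension changes.** `dimension_change_stats` computes per-cell percent
changes in length, width and thickness between paired tables and
summarizes each seed by the *median* across its cells — deliberately not
the mean, because a few mis-segmented cells otherwise dominate.

## Synthetic data: what it emulates, and what it does not

The generators provide every input with known ground truth:

- `make_ellipsoid_mesh` — icosahedral subdivision mapped radially to the
  ellipsoid (near-uniform triangles, no pole artifacts).  The default
  seed shape is (a, b, c) = (170, 100, 85) µm: aspect ratio 1.7 with
  thickness 15% below width, the proportions of a seed two days post
  anthesis; the absolute scale cancels in all direction and anisotropy
  outputs.  An ovule-like shape (aspect ≈ 0.8) can be generated but has no
  validated reference values.
- `tessellate_surface` — Lloyd-relaxed Voronoi-like cells: seeds drawn
  from face centroids, faces assigned to the nearest seed (Euclidean
  distance, a geodesic approximation at cell scale), seeds re-projected to
  the surface each iteration; minority components are reattached so every
  cell is face-connected, and the result is bitwise-reproducible per seed.
- `make_fibril_image` — white noise filtered by a Gabor-like band (pass
  band at 1/20 px⁻¹ across the fibril axis, coherence 10 px along it)
  blended with ring-spectrum isotropic noise of the same spatial scale, so
  the anisotropy level varies angular order at fixed fibril spacing.
- `sample_cmt_field` — axial von Mises sampling (von Mises on doubled
  angles, then halved — the standard axial-statistics device) around the
  maximum-curvature axis rotated by a chosen offset in the tangent plane;
  κ = 0 gives the uniform axial field, large κ a tightly aligned one.
- `make_silhouette_image` — filled ellipses with optional smooth boundary
  perturbations and Gaussian intensity noise on a darker background.
- `make_growth_observations` — lognormal per-seed scatter around given
  daily means with a chosen coefficient of variation (0.1 is typical of
  the seed-to-seed spread in organ-size data).
- `make_paired_tessellation` — the same mesh under an in-plane affine
  stretch, with cells split in two (median cut along a random tangent
  direction) with a chosen probability, and the lineage recorded.

These emulate the *geometry and statistics* the analyzers consume, not the
imaging physics: no optical point-spread function, no depth attenuation or
reporter variability, no real cell-shape irregularity, no segmentation
errors in the tessellations.  Passing the loop-back suite therefore shows
that each analyzer correctly inverts its generator under controlled
conditions — it does not certify performance on real micrographs, where
preprocessing quality dominates.

## Reproducibility and numerical choices

- Every stochastic function takes an explicit integer seed and is bitwise
  reproducible.  Pipelines derive per-stage seeds by hashing the root seed
  with the stage name (always < 2³¹), so adding a stage never perturbs the
  draws of existing ones; the run manifest records config, derived seeds
  and library versions, and reruns produce byte-identical CSVs.
- Degenerate inputs are errors, not silent results: zero axes in the angle
  statistic, open meshes in the shell solver, over-capacity tessellations,
  mismatched lineages, constant images for thresholding.
- Eigen-decompositions use symmetric solvers; principal axes are
  normalized, re-orthogonalized against the local normal, and reported as
  sign-free axes.  Ties in tessellation assignment are broken by stable
  nearest-neighbour queries, making results deterministic.
- Default problem sizes — mesh refinement 4 (5120 faces), 200 cells for
  region statistics, 1000 cells for distributional checks, 256–512 px
  textures, 10 replicate seeds for recovery statistics — give sampling
  errors comfortably below the tolerances being tested while keeping the
  full validation suite and acceptance script to a few minutes on one CPU.

## Known limitations

- The shell model is membrane-only: no bending stiffness, no wrinkling or
  compressive instability, no wall-layer heterogeneity, no growth
  mechanics; the inflation solve assumes a stress-free reference shape.
- Curvature estimation assumes a mesh fine enough that a 30 µm
  neighbourhood spans several vertices, and a fixed radius for all cells.
- The fibril analyzer supports the 2D-image route only; scores from other
  projection routes are not comparable.
- Real-data ingestion (confocal stacks, 2.5D projection, 3D cell
  segmentation) is out of scope; the package consumes meshes, images and
  tables that such pipelines produce.
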