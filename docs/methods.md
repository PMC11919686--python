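# Methods

This note documents the models, estimators and numerical choices behind
memcurve, and what the synthetic benchmarks do and do not demonstrate.

## Coordinate and unit conventions

Grids are indexed `[ix, iy, iz]`; physical positions are Angstroms at
voxel centers, `physical = origin + index · voxel_size`. Curvatures and
curvedness are reported in nm⁻¹ (1 nm⁻¹ = 10 Å⁻¹; the single conversion
lives in the curvature estimator). The curvedness of a point with
principal curvatures k₁ ≥ k₂ is C = √((k₁² + k₂²)/2); a sphere of
radius r has C = 1/r, a cylinder C = 1/(r√2), a plane C = 0. Particle
orientations are ZYZ Euler angles in degrees, `Rz(rot)·Ry(tilt)·Rz(psi)`
carrying the reference +z onto the membrane normal; the in-plane angle
is a free parameter of downstream alignment and defaults to 0.

## Segmentation cleanup

Connected components are computed per class with 26-connectivity
(segmented membranes are thin shells; 6-connectivity fragments them) and
components of fewer than 150 voxels are set to background. The threshold
is a strict "fewer than": a 150-voxel component survives.

## Membrane surface representation

A segmented membrane is a slab of voxels a few voxels thick. Its 0.5
isosurface (after a Gaussian smoothing pass of the binary mask)
therefore consists of **two** closely spaced sheets whose curvedness on
a vesicle differs systematically (1/(r∓t/2)). The pipeline collapses the
sheets to a single **mid-surface**: each marching-cubes vertex probes
along its inward normal for the nearest opposite-normal vertex, and the
pair is replaced by its midpoint. Vertices without a partner (hole rims
created by segmentation noise, ragged edges) are discarded, which also
acts as an artifact filter. This follows the field's practice of
building one surface per membrane; the raw two-sheet point set remains
available (`mode="isosurface"`) and is the right choice for solid masks,
whose isosurface is a single closed surface.

Normals are oriented locally down the smoothed-mask gradient (away from
the segmented material), then made globally consistent by breadth-first
propagation over a neighbor graph; closed clusters are flipped to point
away from their centroid. For open sheets the global sign is inherently
ambiguous — only consistency matters downstream, as the occupancy
analysis is sign-free and particle priors restrain only the out-of-plane
search.

Point sets are downsampled to an approximately uniform spacing of one
voxel by keeping, per cubic cell, the vertex nearest the cell center.
Each retained point carries an equal share of the total mesh area as its
`area_weight`; points within `edge_margin` (default 50 Å, equal to the
proximity threshold so edge artifacts cannot masquerade as coat) of a
volume face are flagged `near_edge` and excluded from the analysis.

Mask smoothing defaults are mode-dependent: 1.5 voxels for thin slabs
(heavier smoothing erases the isosurface of a ~3-voxel shell) and 2.5
voxels for solid masks, where the extra smoothing suppresses staircase
jitter and its systematic effect is corrected downstream (below).

## Curvature estimation

Per point, neighbors within 2.5× the sampling step (opposing-normal
neighbors excluded, so the fit never bridges the two sheets of a slab)
are expressed in the frame of the point normal, and a quadratic height
function h(u,v) = a u² + b uv + c v² + d u + e v + f is fitted by least
squares. k₁, k₂ are the eigenvalues of the shape operator of the fitted
Monge patch. Points with fewer than 6 neighbors are flagged unreliable
and never binned. Three corrections address the known biases of quadric
fitting on rasterized surfaces:

1. **Jitter debias.** Mesh jitter inflates |k| because C sums squares.
   The least-squares covariance of (a, b, c), scaled by the residual
   variance of the fit, gives an estimate of that noise contribution,
   and (k₁, k₂) are shrunk so that k₁² + k₂² loses it.
2. **Smoothing-shrink compensation.** Gaussian smoothing of a solid
   mask displaces the 0.5 level set along the normal by δ ≈ σ²H (mean
   curvature flow), so the measured surface of a sphere is slightly
   smaller than the mask's. The estimator inverts this with
   k ← k/(1 + σ²·H·k), with σ the physical smoothing width recorded at
   extraction. For mid-surface point sets the two sheets shift toward
   each other and the midpoint is unmoved, so the correction is skipped.
3. **Median smoothing.** Principal curvatures are median-filtered over
   same-sheet neighbors within 2× the fit radius, suppressing pointwise
   fit noise while preserving steps between regions — the same idea as
   the curvature vote averaging used on membrane morphometrics meshes.

On rasterized test surfaces at 10 Å voxels the estimator recovers the
closed-form curvedness within ~2% for spheres of 10–40 voxel radius
(error decreasing with radius), ~3% for a 17.7-voxel cylinder, and
|C| < 0.001 nm⁻¹ for a plane.

## Occupancy analysis

A surface point is **coat-proximal** when its Euclidean distance to the
nearest coat-voxel center is ≤ 50 Å (point-to-center rather than
point-to-voxel-surface: simpler, uniformly applied, and different by at
most half a voxel diagonal). Retained (non-edge, reliable) points are
sorted into fixed curvedness bins of 0.004 nm⁻¹ — narrow enough for ≥10
bins across the 0.02–0.06 nm⁻¹ regime of interest — and the per-bin
proximal fraction is the occupancy.

The saturation summary fits O(C) = α + β·min(C, c*) with bin centers
weighted by their counts; c* is scanned over bin edges and chosen by
minimum weighted RSS, ties going to the smallest candidate. Hence a flat
profile reports c* at the start of the observed range and a purely
linear one at its end. The piecewise fit is this package's
quantification of the saturation behavior; the plateau is clipped to
[0, 1]. The companion readout d = 2/c* converts the breakpoint into the
sphere diameter at which coat binding saturates.

## Particle preparation

Minimum spacing (default 15 Å) is enforced greedily in input order
(surface-extraction order): a point is kept unless within the threshold
of an already kept point, which guarantees both pairwise spacing and
maximality. Orientation priors set (rot, tilt) from the membrane normal
with psi = 0 (optionally randomized with a seed). Curvedness clustering
uses scikit-learn k-means on the 1-D values, with labels relabeled by
ascending cluster mean for determinism. Orientation outliers are points
whose normal deviates by more than 30° from the renormalized
component-wise median of their neighbors within 100 Å; points with
fewer than 3 neighbors are kept and flagged `isolated`. The outlier
thresholds are package defaults, recorded in run provenance, not
field-calibrated constants.

## Cyclic-symmetry search

`apply_cn` averages the n copies of a map rotated by k·360/n about a
z-parallel axis through (center_x + offset, center_y), with bilinear
(z-separable trilinear) interpolation; voxels whose pre-image leaves the
grid are excluded per copy via a support mask. The search maximizes the
Pearson correlation between the map and its symmetrized copies in two
stages: offset scans along x at 1 Å per candidate order, then a rotation
scan at 0.5° at the winning (n, offset).

Three choices matter for noisy inputs and are defaults, each with an
escape hatch:

* the **identity copy is excluded** from the average being correlated —
  correlating a map's noise with itself contributes a term ∝ 1/n that
  otherwise always favors the smallest candidate order;
* the map is **low-pass filtered** (Gaussian, 1.5 voxels) first — the
  structural features are broader than a voxel, so this acts as a
  matched filter against white noise without moving the optimum;
* the correlation is evaluated on an **automatic molecular mask**
  (smoothed map thresholded at 2 robust SDs above the median, dilated),
  intersected with the rotational support. The mask depends only on the
  input map, identically for every candidate, so it cannot bias the
  argmax; without it, the ghost ring that symmetrization spreads outside
  an off-axis patch dominates the statistic.

A `low_confidence` flag marks ambiguous searches: best correlation
below 0.7, or a winning-order margin over the runner-up below 0.3% of
the best correlation — the signature of a true symmetry outside the
candidate range. Both thresholds are heuristics and configurable.

For patches, candidate orders close together lie on a near-degeneracy
ridge n·d ≈ const (equal subunit arc spacing); discrimination comes from
the arc curvature across the patch, so wider patches separate orders
better. The benchmark uses 150° wedges (≈8 subunits).

## Tube profiles

Radial profiles average density over annuli (bin width = voxel size)
about the chosen grid axis; a center-of-mass drift above 2 voxels along
the stack triggers a misalignment warning. Binning conserves total
density to numerical precision by construction (means are ratios of
per-annulus sums and counts).

Leaflets are the two innermost peaks with prominence ≥ 3% of the
profile's dynamic range. The low threshold is deliberate: radial
profiles are angle-averaged and essentially noise-free, while at leaflet
width σ = 15 Å and 35 Å separation the inter-peak dip is only ~4% of
the range. Peak positions are refined by a two-Gaussian component fit
between the first minima flanking the pair (the window bound keeps the
outer protein wall out of the fit); for broad leaflets the raw maxima of
the summed profile are pulled toward each other by several Å, which the
component fit undoes. Thickness is the center-to-center distance.

The outer diameter is twice the radius where the density falls through
50% of the outermost peak's background-subtracted height, linearly
interpolated on the outward side. Note this is a half-maximum crossing:
for a Gaussian shell at radius r with width σ it sits at
r + σ√(2 ln 2), not at r.

Axial traces run the leaflet detection per 2-slice slab; slabs without
two qualifying peaks leave gaps. The kink angle at a constriction is the
angle enclosed by straight-line fits of r(z) over 30 Å flanking windows
on either side of the trace minimum, measured at the vertex — a straight
tube reports 180°, and flanks with slope tan(30°) report 120°.

## Synthetic scenes: what they emulate, and what they do not

`make_vesicle_scene` renders non-overlapping spherical membrane shells
(35 Å thick, 12 Å voxels by default) with coat patches in a thin band
outside the shell. Coverage follows the ramp model
clamp((C − c_lo)/(c_hi − c_lo), 0, 1) at each vesicle's true curvedness,
with defaults c_lo = 0.02, c_hi = 0.06 nm⁻¹. Coverage is realized as a
small number (3) of contiguous spherical caps — the "patch" regime the
proximity analysis actually faces, where boundary dilation matters —
and the caps are drawn *smaller* than the target by the geodesic width
of the 50 Å proximity dilation (corrected for the radial mid-surface→
coat gap and half a voxel of rendering discretization), so that the
ground-truth coverage is defined in the measurement's own terms. The
cap half-angle solves the resulting area equation by bisection.
Segmentation error is emulated by flipping 2% of non-background voxels
to background; real U-Net errors are spatially structured, so this is a
stand-in, not a claim about real segmentations.

`make_tube_map` sums Gaussian annular shells (two leaflets 35 Å apart
plus a protein wall); `make_hourglass_map` bends the leaflet pair to an
analytic 120° flank geometry; `make_cn_map` builds rings of subunits,
each a seeded cluster of 3–4 Å Gaussian blobs spread over ~14 Å (the
scale of secondary-structure density), optionally rendering only a wedge
— the off-axis patch geometry of a subtomogram average of part of a
larger ring. Noise is additive white Gaussian; `snr` sets it by the
variance-based convention, noise σ = sd(signal within the molecular
envelope)/SNR. Same seed ⇒ bit-identical volumes.

What passing these benchmarks shows: the measurement chain (surface →
curvature → proximity → binning → fit; symmetry search; profile
metrology) recovers known ground truth through realistic rasterization,
patch-boundary and noise effects. What it does not show: robustness to
structured segmentation errors, missing-wedge anisotropy, CTF effects or
crowded multi-organelle scenes, none of which the generators model.

## Benchmark problem sizes

The standard validation scene uses 30 vesicles with true curvedness
evenly spaced over 0.016–0.088 nm⁻¹ (radii 114–625 Å) in a ~333³ grid
of 12 Å voxels (~2×10⁵ retained surface points; ~25 s). The symmetry
sweep uses 20 wedge-patch maps (96×96×48 at 2 Å) over orders
{6, 12, 18, 20, 22} at SNR 1, with ring radius drawn from a constant
subunit arc spacing of 32–42.5 Å — ring diameter grows with symmetry
order, as it does for the rings these assemblies form — and offsets up
to ~150 Å. Tube benchmarks use 128×128×48 grids at 3 Å voxels with
leaflet widths 5–15 Å.

## Known limitations

* The mid-surface construction assumes a slab thin enough for
  probe-pairing (≤ ~6 voxels); thicker compartments should use
  isosurface mode per closed surface.
* Curvedness carries a residual positive bias of a few percent at radii
  near 10 voxels; at the default scene scale this shifts the measured
  breakpoint by up to one bin width.
* The occupancy profile is a per-point, not per-area, fraction by
  default (area weights are carried but uniform after downsampling).
* The symmetry search assumes the ring axis is parallel to z (a
  pre-alignment helper rotates a map given an axis guess); it does not
  search helical rise/twist.
* The saturation fit's breakpoint granularity is the bin width; no
  sub-bin refinement is attempted.
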