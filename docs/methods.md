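# Methods

This note documents the models, conventions, parameter choices and known
limitations behind each analysis stage, and what the synthetic generators
do and do not emulate.

## Conventions

Pixel coordinates are 0-based, x rightward (array axis 1), y downward
(array axis 0), pixel centers at integer coordinates. All µm↔px
conversion goes through `core_io.um_to_px` / `px_to_um`. Z ranges in µm
are half-open `[start, stop)` so consecutive sections tile a stack
without double counting; slice *i* occupies `[i·z_step, (i+1)·z_step)`.
Rectangle ROIs are half-open pixel boxes (corners `(x0,y0),(x1,y1)`
select `image[y0:y1, x0:x1]`), so a "10 × 10 pixel square" has corners
ten apart and covers exactly 100 pixels.

Where a protocol calls for two *distinct* 5 µm projections per spheroid
but does not say where they were placed, the pair is placed at fixed
fractions (25% and 60%) of the Z extent, shifted down as needed so both
sections fit without overlap. The fractions are a reproducible stand-in
for an unstated manual choice, and are configurable.

## Fiber alignment (AFT)

Each overlapping square window (default 25 px, 50% overlap) is
mean-subtracted, tapered with a 2D Hann window, and Fourier transformed.
An oriented texture concentrates spectral power perpendicular to the
fiber direction, so the fiber angle is the principal axis of the
spectrum's second-moment tensor rotated by 90°, reported in [0, π).
Windows whose total spectral power falls below 5% of the strongest
window are marked invalid — blank matrix regions otherwise contribute
noise angles. The floor is configurable.

Neighborhood co-alignment is the 2D nematic order parameter
S = ⟨cos 2θᵢⱼ⟩ = 2(⟨cos²θᵢⱼ⟩ − ½), averaged over the 24 neighbors of each
window in a 5×5 neighborhood, defined only where the full neighborhood
fits and every member is valid. The scalar summary is the **median** over
defined windows (robust to boundary windows); the mean is also exposed.
S → 1 for co-aligned neighborhoods, 0 for random, −1 for perpendicular.

Radial alignment about a spheroid center bins windows into 8 angular
sectors (cardinal + intercardinal) and reports ⟨cos 2φ⟩ per sector, φ
being the deviation of each fiber from its radial direction: +1 radial,
−1 circumferential. Sectors are unweighted by distance; empty sectors
are NaN.

Two statistics that must not be conflated:

- the **neighborhood order parameter S** measures pairwise co-alignment
  of *measured window vectors*;
- the **axial alignment to the mean**, E[cos 2(θ−μ)], measures the
  angular dispersion of *individual fibers* and has the closed form
  I₁(κ)/I₀(κ) under the generator's von Mises model.

These coincide only in the limits (both → 1 when aligned; both → 0 for
i.i.d. uniform *vectors*). In between they differ by construction: for
i.i.d. window angles the pairwise statistic equals the *square* of the
axial alignment, and on rendered images each window aggregates several
fibers, which sharpens the measured orientation distribution relative to
the single-fiber marginal. Accordingly the test suite asserts the two
limits and strict monotonicity of S in κ on the image pipeline, and the
Bessel closed form on the generator's sampled angles, where it is exact.
A related artifact: with 50% window overlap, neighboring windows share
texture, so S on a *rendered* random (κ=0) image is slightly positive
(≈0.1) rather than 0; i.i.d. orientation fields (`gen_orientation_field`)
give the exact null.

## PIV

Source windows (5 µm, ~31 px at the default 0.16 µm/px) tile frame A
with 50% overlap and are matched against co-centered 10 µm search
windows in frame B by zero-normalized cross-correlation
(`skimage.feature.match_template`), making the 0.3 retain threshold
contrast-invariant. The peak is refined to sub-pixel precision by a
3-point parabolic fit per axis; ties between equal peaks break toward
the smaller displacement. Windows without texture (zero variance) are
dropped. Retained matches are interpolated with a normalized Gaussian
kernel (σ = 10 µm, truncated at 25 µm radius, i.e. 50 µm support); grid
points with zero support are NaN. Speeds are |displacement|/Δt with a
5 min default frame interval.

Rejection of decorrelated frames depends on the pixel count of the
source window: the correlation-noise scale is ~N⁻¹², so the 0.3
threshold discriminates real matches only when the 5 µm window spans
tens of pixels. The generator's default pixel size (0.16 µm/px,
high-NA spinning-disk geometry) reflects the acquisition regime in
which that threshold is meaningful.

No multi-pass or window-deformation PIV, no optical flow.

## Nuclear:cytoplasmic ratios

value = (mean nuclear − background) / (mean of two cytoplasmic means −
background), with background taken as the mean of an off-spheroid ROI.
Correction is subtractive because the ratio divides background-corrected
signals. Degenerate measurements (non-positive numerator or denominator)
are excluded and logged, never clipped — clipping biases group means. The
KTR readout is the reciprocal on the same squares. Two identities hold
bit-for-bit on integer-valued data and are tested as such: adding a
constant to image and background, or scaling both, leaves every ratio
unchanged.

Outer cells are those whose centroid lies within `boundary_depth_um`
(default 15 µm ≈ one cell radius) of the mask boundary, measured by the
Euclidean distance transform (distance to the nearest off-mask pixel);
inner otherwise; centroids off the mask are flagged and excluded. The
depth operationalizes "in contact with the matrix" — the original
assignment was manual, and the parameter is configurable. The sampling
plan (≥24 cells per compartment, from ≥2 distinct projections, per
spheroid) is audited with named deficiencies rather than enforced by
exception.

## Invasion, protrusions, filopodia

Invasion projections are thresholded (Otsu by default; triangle and
fixed selectable, and the method is recorded in the output), connected
components (8-connectivity) below 20,000 µm² are discarded as debris,
and the retained area is normalized to hour 0. Whether the original
thresholding was global or per-timepoint is unknown; thresholds here are
computed per projection.

The broad-protrusion proxy opens the mask with a disk (default 40 µm),
takes connected components of mask − body that touch the body, and
counts those larger than `min_cells × cell_area_um2` (default 3 cells).
The opening radius must sit well above the protrusion half-width —
otherwise the structuring disk intrudes into each lobe and the residue
underestimates its area — and below the spheroid radius. The proxy is an
explicit approximation of a manual count; annotated counts can be used
instead.

Filopodia: body mask from a high threshold (largest component, holes
filled, then a 2 µm opening so filopodium-width appendages are not
absorbed into the body); candidate thin structures from a lower
threshold (default half the body threshold) outside the body; a 1 px
dilation regularizes 1–2 px wide structures (a bare diagonal staircase
collapses under skeletonization); skeletonize; per-component geodesic
length as the sum of 8-connected inter-pixel steps (1 or √2 px).
Components shorter than the minimum length (default 2 µm; the original
protocol's numeric floor is unpublished) are discarded. Reported:
per-filopodium length, count per µm of body-boundary perimeter, mean
length.

## Nuclei and packing

Nuclei are detected as Laplacian-of-Gaussian blobs at the expected
nuclear scale (σ = d/(2√2)), local maxima with a minimum separation
(default half the diameter) above a relative response floor, refined to
intensity-weighted centroids. This is a declared substitute for
interactive cell detection, validated on synthetic ground truth.

Packing metrics come from the Delaunay triangulation of centroids
(scipy.spatial): per nucleus, neighbor distance = mean incident-edge
length and neighbor count = degree; the reported metrics average both
over nuclei. Convex-hull edges inflate distances; `max_edge_um` prunes
long edges (default none, mirroring the unstated original setting; ~30 µm
is a reasonable choice for epithelial packing) and the choice is recorded
in the output. Fewer than three non-collinear points fall back to the
all-pairs graph with a warning. The triangulation is tested for exact
agreement with an all-triangle circumcircle oracle on ≤50 points.

## AFM Hertz fitting

The contact point of an extension curve is found by fitting a line to
the first half of the curve and locating the first z where the force
exceeds the baseline by 3 residual SDs for ≥5 consecutive samples.
Because a δ^{3/2} contact rises gently, that crossing is systematically
late under noise, so the estimate is refined by exploiting the Hertz
form: F^{2/3} is linear in (z − F/k), and extrapolating it to zero
excess force gives the contact point. The refinement is accepted only
when it lands at or before the crossing.

Indentation is deflection-corrected, δ = (z − z₀) − F/k, when a spring
constant is available (default 0.013 N/m; skipped with a warning
otherwise). The modulus comes from a through-origin least-squares fit of
F on δ^{3/2} over the deepest 10% of the indentation range of the
extension curve — the depth reading of "top 10%", which avoids shallow
regions where the probe is still breaking through softer layers;
selection by force is also available and coincides on noiseless curves.
Poisson ratio defaults to 0.5 (incompressible hydrogel). Units: z in nm,
F in nN, R in µm, E in Pa; a hand-computed single-point test guards the
conversion chain. No thermal calibration, no viscoelastic models.

## Junction linescans

Lines (default 10 µm) are sampled by bilinear interpolation at one-pixel
spacing, from the first annotated vertex toward the second, and
normalized by the value at distance 0 — interpreted as the first sample
of the annotated line. Perpendicularity to the junction is the
annotator's responsibility. Aggregation reports the pointwise mean and
25/75th percentile band and flags sets of fewer than 12 junctions.

## Statistics

Normality routing: Shapiro-Wilk for n ≤ 50 (n = 50 exactly is routed to
Shapiro-Wilk as a declared tie-break), Kolmogorov–Smirnov against a
normal fitted to the sample for n > 50. Two groups: two-sided t-test —
Welch by default (robust to unequal variances; the classic Student
variant is selectable and the choice recorded). More groups: one-way
ANOVA, then all-pairs t-tests with Sidak adjustment
p_adj = 1 − (1−p)^m. A failed normality check flags the result but does
not switch tests — silent switching would make the routing
data-dependent in a way the analysis plan does not specify. Percentiles
use linear interpolation between order statistics. Empirical size of the
two-group route is verified on 2000 null simulations.

## Synthetic generators: what they emulate, and what they do not

All generators are seeded and bit-reproducible, and each returns a
`GroundTruth` record sufficient to compute the expected downstream
metric without re-reading the image. Rendering is 2D; 3D stacks are
emulated as stacks of 2D sections, because every analyzed quantity is
computed on 2D projections.

- **Fiber fields**: anti-aliased line segments with axial von Mises
  dispersion (2θ ~ VM(2μ, κ)), giving the closed-form expected alignment
  I₁(κ)/I₀(κ). Defaults (800 fibers of 60 px on 512 px at 0.5 µm/px)
  render a dense meshwork with texture in ~90% of windows, as in
  sparsely labelled collagen; sparser fields leave blank windows that
  fail the validity floor. Not emulated: fiber curvature, bundling,
  depth-dependent blur.
- **Flow pairs**: smoothed uniform speckle, frame B resampled from frame
  A by a constant or dense sub-pixel displacement (cubic spline), plus
  optional Gaussian noise. Not emulated: out-of-plane motion,
  photobleaching, deforming cell boundaries.
- **Two-compartment cells**: cytoplasm disks with nuclear cores at an
  exact intensity ratio over a flat background, plus the 10×10 px
  sampling squares. Not emulated: crowded/touching cells, intensity
  gradients across the spheroid.
- **Nuclei fields**: hexagonal lattices (exact spacing) or Poisson
  scatters, rendered as Gaussian blobs. Not emulated: nuclear shape
  variation, overlap in dense cores.
- **Spheroid series**: growing disks with half-disk protrusion lobes of
  prescribed cell-equivalent area and thin radial filopodia spurs;
  analytic areas recorded. Not emulated: irregular boundaries, texture
  inside the body.
- **Force curves**: exact Hertz ramps with cantilever-deflection
  geometry (z = z₀ + δ + F/k), a long pre-contact baseline (4 µm of a
  ~10 µm sweep, so half-curve baseline fits see only baseline), optional
  tilt and force noise. Not emulated: adhesion on retraction,
  viscoelastic hysteresis, substrate bottom effects.
- **Junction ridges**: Gaussian ridge of set amplitude/width on a flat
  background; FWHM = 2.355·w recorded.

Passing tests on these generators demonstrates correctness of the
measurement chain on data satisfying each model's assumptions; they do
not certify performance on real images with segmentation ambiguity,
debris, or drift.

## Problem sizes

Default test and benchmark sizes: 512 px fiber fields, 192–256 px flow
frames, 100-cell ratio fields, ≤50-point triangulations, 1024-sample
force curves, 200-field null ensembles, 2000-replicate size simulations.
These sizes give Monte-Carlo error well inside each stated tolerance
while keeping the full suite fast on a single CPU.
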