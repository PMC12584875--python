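# Methods

## Measurement model

The pipeline treats a membrane instance segmentation as a noisy sampling of
two parallel surfaces — the two sides of a bilayer as delineated by a
segmentation network — and estimates the local distance between them.

**Coordinates and units.** Volumes are indexed `[z, y, x]` with x the
fastest storage axis (MRC2014 convention); z is the beam axis and therefore
the missing-wedge axis. Voxel indices are 0-based at voxel centers;
physical position = index × voxel size + origin, in Å. Point coordinates
are (x, y, z) Å triples; all thickness values are reported in nm.

**Surface reconstruction.** The binarized instance mask is isosurfaced with
marching cubes at level 0.5. Two numerical choices matter here and are the
package's own:

* The mask is first smoothed with a 1-voxel Gaussian. The 0.5-level of the
  smoothed step function coincides exactly with the segmentation boundary
  mid-plane for a flat boundary, so the measured quantity is unchanged, but
  the voxel staircase amplitude drops by roughly an order of magnitude.
  Without this, the tight 1° pairing cone preferentially matches protruding
  stair corners of the jagged binary isosurface and inflates planar
  thickness estimates by over half a voxel.
* Provisional normals are the negated gradient of a 2-voxel-Gaussian
  smoothed mask, sampled at the vertices. A tilted plane's voxel staircase
  has lateral period 1/tan(tilt) voxels — typically 4–5 voxels — which a
  1-voxel kernel cannot average away; the wider support reduces systematic
  normal wobble from ~9° to ~1°. For curved surfaces the induced position
  bias scales as σ²/R and is a few hundredths of a voxel at vesicle scales;
  because both bilayer surfaces shift in the same radial direction, the
  bias largely cancels in the thickness difference.

A 26-connectivity boundary test (3×3×3 dilation of the background) retains
only vertices whose nearest voxel touches true background, removing
vertices generated where two instances touch. Vertices closer than 1e-3 Å
are deduplicated. Normals are then refined by Gaussian-weighted averaging
over neighbors within a radius of 3 voxel widths (weight exp(−d²/2σ²),
σ = radius/2, self included); when side labels are not yet available,
"same side" is approximated by a positive normal dot product, which stops
the two opposing surfaces from canceling each other on thin instances.
Side assignment uses PCA of the normal directions (side = sign of the
projection on the first principal axis). Closed surfaces — where the
normal covariance is nearly isotropic, detected by an eigenvalue ratio
λ₁/λ₃ < 2 — are routed to a fallback that classifies each point by the
sign of its normal against the outward gradient of the filled-instance
distance transform.

**Pairing.** For each side-1 query point, opposite-side candidates must lie
within `max_distance` (default 8 nm, above any plausible bilayer) and
within `cone_half_angle` (default 1°) of the query's normal *axis* (the
cone test uses |cos|, so the normal's sign convention is immaterial). Up to
`candidates_per_query` (default 5) candidates per query, sorted by
distance, enter a single global list sorted by (distance, query id, target
id); one greedy traversal accepts a candidate only when both endpoints are
still unused. The total tie-break makes the result independent of input
ordering and of the chunk decomposition used for parallel candidate
search — the test suite asserts element-wise equality across chunk counts
and against a brute-force O(N²) reference. Thickness is the exact
Euclidean distance between paired points; the orientation angle
θ = arccos(|n · ẑ|) ∈ [0°, 90°] measures each pair against the
missing-wedge axis, and Pearson r(θ, t) quantifies orientation bias.

**Profile filtering.** The tomogram is sampled by trilinear interpolation
along each pair axis, extended outward by `extension_fraction` (default
0.30) of the pair separation on each end, at `samples_per_voxel` (default
3) samples per voxel. In cryo-ET contrast, dense structures are dark, so a
bilayer crossing shows two minima (phosphate headgroup layers) separated
by a central maximum (acyl-chain core); an `invert_contrast` flag handles
the opposite convention. A profile is accepted if it has two local minima
with prominence at least `prominence_min` (default 0.05) of the profile's
dynamic range, a central maximum rising above the higher minimum by the
same threshold, and both minima inside the extended measurement window.
The checks run in a fixed order, so each rejection names the first
violated criterion: `one_minimum`, `low_prominence`, `no_central_max`,
`minima_outside` (plus `edge` when the extended segment leaves the
volume). When more than two qualifying minima exist the two most prominent
are used; a third within 80% of the second's prominence is flagged.
Filtering only toggles validity — thickness values are never altered.

**Leaflet asymmetry.** Accepted profiles are grouped into thickness bins
(default 0.1 nm; bins under 20 profiles omitted), averaged on a common
grid, and the bin's score is a = max(ΔI₁, ΔI₂)/min(ΔI₁, ΔI₂) ≥ 1 with
ΔIᵢ the depth of minimum i below the central maximum; percent asymmetry is
(a − 1) × 100. Because the score reads single extremum values off an
averaged noisy curve, the bin mean is lightly Savitzky–Golay smoothed
(window 5, order 2) and each extremum value is refined by a local
parabolic fit. Both operations scale a trough's depth proportionally to
its amplitude, so the depth *ratio* is preserved while the read-off noise
drops by roughly a third. The score is invariant under any positive affine
transform of the intensities.

**Alternative readout.** The minima-to-minima distance (headgroup peak
separation) is available per accepted profile. It is systematically
smaller than the boundary-to-boundary readout because segmentation
boundaries sit near the profile inflection points, outside the minima.

## Simulated density maps (`mdmap`)

Atoms become normalized 3D Gaussian blobs with σ = FWHM/2.35 (default FWHM
1.6 Å), truncated at 4σ and renormalized so each atom's discrete map
integral equals its scattering amplitude exactly; blobs wrap periodically
(MD boxes are periodic). Amplitude mode weights each atom by a per-element
amplitude ∝ Z^(4/3) normalized to carbon; weak-phase mode takes the
imaginary part of A·exp(i·0.2·φ) with φ ∝ Z. Only relative contrast
reaches any readout, so the absolute scale of both tables is immaterial
and both are configurable. Default map voxel: 0.8 Å, fine enough to
resolve the σ ≈ 0.68 Å blobs.

The protein footprint is the XY convex hull of the protein atoms (center
of mass as reference point, equivalent radius = √(area/π)). Annular
distance bins are measured from the hull *edge* (0 at the boundary,
negative inside, excluded from non-negative bins) — this keeps the 0–1 nm
ring meaningful for non-circular proteins; a center-of-mass mode is
available, and protein-free controls use a degenerate point footprint.
Per-ring z-profiles are the XY mean of the map; simulated maps hold
physical density (dense = bright), so feature detection runs with
inverted contrast. Thickness is reported both as minima-to-minima and as
the distance between the first density-gradient extrema found outward
from each headgroup minimum (the profile inflection points, computed by
central differences); the inflection readout is strictly the larger of
the two.

## Phantom generator

Phantoms evaluate the intensity model
I(s) = baseline − d₁G(s + dₘ; σ_t) − d₂G(s − dₘ; σ_t) + c·G(s; σ_c)
on the signed distance s to a mid-surface (slab, sphere, tube or
sine-sheet). Defaults are the package's study conditions: voxel 7.84 Å
(bin4), thickness 5.0 nm (4.6–6.0 across geometry tests), trough σ 0.5 nm,
trough depths 1.0, core ridge height 0.3 and σ 0.8 nm, sphere radius 40 nm,
tube radius 20 nm. The label covers |s| ≤ thickness/2 with the trough
centers at dₘ = thickness/2 − σ_t, so the label edge coincides with the
troughs' outward inflection surfaces — where segmentation networks place
membrane boundaries — and the nominal thickness is directly comparable to
the pipeline output. The slab is tilted 12° by default: an exactly
axis-aligned plane locks the label quantization to a single phase and
biases the boundary readout by up to half a voxel, a degenerate
configuration that generic orientations (and all real membranes) average
away. The sine sheet uses a first-order perpendicular-distance correction
(vertical offset × local slope cosine); its default amplitude 3 nm /
period 50 nm keep the curvature radius ≈ 21 nm, large against the
membrane thickness, so the constant-thickness truth stays exact.

Noise is additive Gaussian, seeded; "SNR" in the tests means trough depth
over noise σ (amplitude SNR). The optional missing wedge is a hard
conjugate-symmetric Fourier mask zeroing directions within the half-angle
(default 30°, i.e. a ±60° tilt range about y) of the z axis in the x–z
plane, preserving the kx = kz = 0 line; output stays real and total power
never increases.

What the phantoms do *not* emulate: projection/reconstruction artifacts
beyond the hard wedge mask, CTF modulation, structured (non-white) noise,
membrane proteins, segmentation errors, or spatially varying thickness.
Passing phantom tests therefore demonstrates the geometric and
signal-processing correctness of the pipeline, not its robustness to
segmentation quality — on real data the segmentation is the dominant
error source.

## Statistics

Group comparisons are two-sided paired or unpaired t tests on
instance-level mean thicknesses (each membrane instance is one biological
replicate), annotated with the conventional star thresholds (ns > 0.05,
\* < 0.05, ** < 0.01, *** < 0.001). Degenerate inputs (zero-variance
paired differences) are flagged explicitly rather than returning NaN. No
multiple-testing correction is applied by default; a Holm step-down
helper is provided.

## Problem sizes used by the test suite

The end-to-end checks run on 48×64×64 (slab), 120³ (sphere, r = 40 nm),
80×64×80 (tube) and 64×48×96 (sine) voxel grids at 7.84 Å/voxel —
5·10⁴–10⁵ surface points and 10³–5·10³ accepted pairs per geometry, enough
for sub-0.1-nm mean recovery while keeping the full suite under a few
minutes on one CPU core. Pairing-oracle equivalence uses 500 points per
side across 20 random configurations; asymmetry recovery uses 100 noisy
profiles per bin at amplitude SNR 10.

## Known limitations

* Thickness is only measured where the 1° cone finds an opposite-surface
  vertex; on coarse voxel grids this yields sparse (few-percent) but
  unbiased coverage. Increase `interpolation_factor` or the cone angle for
  denser coverage.
* Instances thinner than ~4 voxels interact with the smoothing kernels;
  below 2 voxels extraction refuses outright. At bin4 this corresponds to
  membranes thinner than ~3 nm, below the biological range.
* The sub-voxel minima localization is limited to one sample spacing
  (voxel/3 by default); minima-to-minima distances inherit it.
* PCA side separation assumes sheet-like geometry; the automatic fallback
  handles closed surfaces but self-intersecting or multi-lamellar
  instances should be split upstream.
* The weak-phase element potentials are single per-element constants, not
  tabulated scattering potentials; only relative contrast trends between
  modes are meaningful.
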