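# tomothick

Local membrane thickness morphometrics for cryo-electron tomography.

Cellular membranes are not uniformly thick: lipid composition varies between
and within organelles, and bilayer thickness tracks it. Cryo-ET images
membranes directly in situ, and segmentation networks label each membrane as
a voxel instance — but turning a voxel segmentation into quantitative,
curvature-aware thickness measurements takes a dedicated pipeline. This
package provides one, for structural cell biologists working from tomogram
instance segmentations:

1. **Surface reconstruction** — marching cubes on each labeled instance
   yields oriented boundary points; a boundary-detection kernel keeps only
   true membrane/background vertices; normals **n** are refined by
   Gaussian-weighted neighbor averaging and the two bilayer surfaces are
   separated by PCA of the normal directions (with a distance-transform
   fallback for closed surfaces such as vesicles).
2. **Point pairing** — for each query point a parallelizable cone search
   (half-angle 1°, about the normal axis) finds opposite-surface candidates
   within a distance cutoff; candidates are pooled globally, sorted by
   distance and paired greedily one-to-one. Local thickness is the Euclidean
   distance **t = ‖P₂ − P₁‖** between paired points, so curvature is handled
   natively in 3D.
3. **Intensity-profile filtering** — the tomogram is sampled along each pair
   axis (extended 30% outward); a valid trans-membrane profile shows two
   headgroup minima separated by a central (hydrophobic-core) maximum, with
   sufficient prominence and position inside the measurement window.
   Failures are rejected with enumerated reasons.
4. **Analysis** — per-instance summaries, thickness maps, particle
   colocalization, orientation-bias statistics θ = arccos(|**n** · **ẑ**|)
   against the missing-wedge axis, minima-to-minima as an alternative
   thickness readout, and thickness-binned leaflet-asymmetry scores
   a = max(ΔI₁, ΔI₂) / min(ΔI₁, ΔI₂) ≥ 1, reported as (a − 1) × 100 %.

Two supporting modules make every step testable without microscope data:

* **`phantom`** — matched (tomogram, segmentation, ground truth) triplets
  for slab / sphere / tube / sine-sheet geometries with known thickness,
  leaflet asymmetry, noise level and an optional Fourier missing wedge.
* **`mdmap`** — converts atomistic membrane–protein systems (PDB/GRO) into
  resolution-limited density maps (Gaussian blobs, σ = FWHM/2.35; amplitude
  or weak-phase-object contrast) and measures bilayer profiles in annular
  rings around the protein footprint, with both minima-to-minima and
  inflection-point thickness readouts and phosphate-position projection.

## Worked example

Measure a noisy hollow-vesicle phantom with known 4.6 nm thickness:

```python
import numpy as np
from tomothick import phantom, surface, pairing, profiles

spec = phantom.PhantomSpec(geometry="sphere", shape=(96, 96, 96),
                           sphere_radius_nm=30.0, thickness_nm=4.6,
                           noise_sigma=0.2, seed=1)
tomo, labels, truth = phantom.generate(spec)

sps = surface.reconstruct_surface(labels, instance_label=1)
print(f"surface points: {len(sps)} "
      f"(side 1: {(sps.sides == 1).sum()}, side 2: {(sps.sides == 2).sum()})")

pairs = pairing.pair_surfaces(sps)
result = profiles.filter_pairs(pairs, tomo)
valid = pairs.thickness_nm[pairs.valid]
print(f"pairs: {int(pairs.matched.sum())} matched, {len(valid)} retained")
print(f"thickness: {valid.mean():.3f} +/- {valid.std():.3f} nm "
      f"(ground truth {truth.thickness_nm} nm)")
print(f"orientation bias r(theta, t) = {pairing.orientation_bias(pairs):.4f}")
```

```
surface points: 55536 (side 1: 32088, side 2: 23448)
pairs: 1776 matched, 1776 retained
thickness: 4.607 +/- 0.060 nm (ground truth 4.6 nm)
orientation bias r(theta, t) = 0.0129
```

The mean recovered thickness is within 0.01 nm of truth (well under the
half-voxel bound at 7.84 Å/voxel), the spread reflects voxel quantization,
and the near-zero Pearson correlation between orientation angle and
thickness shows no direction-dependent bias on this isotropic geometry.

The same pipeline runs from the shell on MRC volumes:

```bash
tomothick phantom --geometry slab --out-prefix demo       # or your own data
tomothick measure --tomogram demo_tomo.mrc --labels demo_labels.mrc --out-dir out/
tomothick analyze --measurements out/measurements.csv \
                  --summaries-out out/summaries.csv --map-out out/map.csv
```

`out/` then contains per-instance surface CSVs (point, side, position,
normal), a measurements CSV (paired coordinates, normals, thickness in nm,
θ in degrees, validity and rejection reason), profile/feature tables, a
per-instance summary CSV and a thickness-map CSV for external renderers.
Other subcommands: `surface`, `filter`, `colocalize`, `mdmap`, `compare`
(instance-level two-sided t tests with the usual star convention).

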