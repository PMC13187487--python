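# vistaz

Automated quantification of embryonic zebrafish vasculature from confocal
fluorescence imaging.

Zebrafish embryos carrying endothelial reporters (e.g. *Tg(kdrl:EGFP)*) are
the workhorse of developmental vascular biology, but extracting comparable
numbers from their images is hard: signal-to-noise is low, reporter
expression is heterogeneous, and hand tracing does not scale. `vistaz`
turns calibrated 3D z-stacks (or pre-computed 2D maximum-intensity
projections) into per-embryo vascular metrics — network length, vessel
density, branchpoint count and density, and vessel diameter — with
optional region-of-interest analysis (left/right brain, midbrain vs
hindbrain, trunk thirds) and a benchmarking module for choosing the
segmentation and skeletonisation algorithms.

## Method

For each channel of each image the pipeline runs:

1. **Maximum-intensity projection** of the (z, y, x) stack, carrying the
   physical calibration (default 0.83 µm/px ≡ 1.2 px/µm in XY, 5 µm
   z-step).
2. **Pre-processing** — linear normalisation to 8-bit, CLAHE local contrast
   enhancement (clip limit 2.0, 4×4 tile grid), and an initial Otsu
   threshold mask.
3. **Segmentation** — multiscale Meijering neuriteness filtering
   (σ ∈ {3…8} px, threshold 10 on the [0, 255] response; Frangi, Sato and
   Jerman available), intersected with the Otsu mask, then morphological
   clean-up (remove objects < 50 px, fill holes < 200 px). Connected
   segments get stable integer IDs so misidentified structures can be
   removed by ID and the map relabelled — scriptable, reproducible
   curation.
4. **Skeleton analysis** — thinning to a 1-px centreline (Lee, or
   Zhang–Suen), branchpoint detection (≥ 3 centreline branches meeting in
   the 3×3 neighbourhood), distance-based de-clustering (greedy
   raster-order retention at ≥ 30 px separation), decomposition into
   segments between junctions, and per-pixel diameters as twice the
   Euclidean distance transform (maximum inscribed circle).
5. **Metrics** — total network length L (skeleton pixel count), tiled
   vessel density (mean vessel-pixel fraction over 100 µm² windows),
   branchpoint count/density, mean segment diameter; conversion to microns
   via the px/µm scale; normalised network length
   L̂ = L[µm] / z-depth[µm]; asymmetric MAD outlier filtering of the
   per-segment diameter and length distributions
   (median − 1·MAD ≤ x ≤ median + 3·MAD); export to Excel + CSV with full
   parameter provenance.

Segmentation quality is scored with the Jaccard index
J = |A∩B| / |A∪B|; skeleton quality with
**Q = connectivity × length × area**, each factor in [0, 1]
(component-count penalty; tolerance-dilated overlap of candidate against
reference and vice versa). `run_grid` evaluates all filter ×
skeletonisation combinations on one image.

Every stage is testable without microscope data through the `phantom`
module, which renders ladder-, tree-, plus- and bar-topology vessel
networks with exact analytic ground truth (centrelines, widths, junction
coordinates) under controlled blur and noise.

## Worked example

```python
from vistaz import PhantomSpec, analyze_mask, generate, segment_projection

truth = generate(PhantomSpec(seed=1))          # ladder: 10 rungs, width 5 px
mask, _ = segment_projection(truth.projection())
record, segments, skeleton = analyze_mask(mask, px_per_um=1.2, z_depth_um=100.0)
print(f"junctions     truth={len(truth.junctions)}  measured={record.branchpoint_count}")
print(f"length_px     truth={truth.total_centreline_px}  measured={record.network_length_px:.0f}")
print(f"length_um     {record.network_length_um:.1f}")
print(f"normalised    {record.normalised_network_length:.2f}")
print(f"diameter_px   {record.mean_diameter_px:.2f}")
```

prints

```
junctions     truth=20  measured=20
length_px     truth=3006  measured=2982
length_um     2485.0
normalised    24.85
diameter_px   6.00
```

All 20 junctions are recovered; the measured skeleton is within 1% of the
true centreline length; 2982 px at 1.2 px/µm is 2485 µm of vasculature,
i.e. 24.85 µm of vessel per µm of imaged depth. The mean diameter of
6.00 px reflects the maximum-inscribed-circle convention, which reads a
5-px-wide vessel as 6 px (distances are measured between pixel centres).

Command-line equivalents: `vistaz phantom`, `vistaz segment`,
`vistaz benchmark`, and `vistaz run --config run.yaml` for batch
processing.

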