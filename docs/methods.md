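# Methods

## Scope and data model

`vistaz` quantifies 2D maximum-intensity projections of 3D confocal
z-stacks of fluorescently labelled zebrafish vasculature. The analysis is
deliberately 2D: projections are the standard readout for embryo-scale
vascular phenotyping, and all metrics are defined on the projected image,
with the stack contributing only its physical depth (slice count × z-step)
for normalisation. Axis order is (z, y, x), origin top-left, 0-based pixel
coordinates.

Calibration precedence is explicit configuration > embedded file metadata >
package defaults. The defaults encode the reference acquisition: XY scale
1.2 px/µm (0.8333 µm/px) and 5 µm z-step. Both the µm/px and px/µm forms
are exposed; the px/µm form (1.2) is the one used for unit conversion.
Projections supplied without a source stack carry `z_depth_um = 0` and the
depth-normalised metric is reported as 0 rather than silently guessed.

## Pre-processing

Intensities are linearly rescaled to 8 bits (min → 0, max → 255,
round-half-to-even; constant images map to zero). The map is invariant to
affine intensity changes, so gain/offset differences between acquisitions
do not alter downstream masks.

CLAHE uses the OpenCV-style parameterisation so the conventional clip
limit of 2.0 is meaningful: per tile (4×4 grid), the 256-bin histogram is
capped at `clip_limit × tile_area / 256` counts, the clipped excess is
redistributed uniformly, and the equalisation mapping is the rescaled CDF;
per-pixel output bilinearly interpolates the four surrounding tile
mappings. Images not divisible by the grid are reflection-padded and
cropped back. CLAHE is implemented in-package; it is the OpenCV
convention, written against the published parameter values.

Otsu thresholding maximises between-class variance over the 256-bin
histogram (vectorised cumulative moments); ties take the lowest threshold
so output is deterministic. Foreground is strictly above the threshold. By
default Otsu runs on the CLAHE-enhanced image (the numbered stage order:
normalise → CLAHE → Otsu); `otsu_on_enhanced=False` switches it to the raw
8-bit image.

## Segmentation

The tubularity response is the per-pixel maximum of a multiscale
Hessian-based ridge filter over σ ∈ {3, 4, …, 8} px, rescaled to
[0, 255] so the segmentation threshold of 10 has a defined scale.
Meijering neuriteness is the default; Frangi, Sato, and an in-package
Jerman (ratio-of-eigenvalues with τ = 0.5 regularisation and γ-normalised
scales) are provided for benchmarking. The thresholded response is
combined with the Otsu mask by intersection by default — the ridge filter
suppresses blobs but halos into the background, the Otsu mask is crude but
photometrically grounded, and their intersection keeps the agreement set.
Union and filter-only modes are selectable.

Morphological clean-up removes 8-connected foreground objects with area
< 50 px and fills 4-connected background holes (components not touching
the border) with area < 200 px. Both operations use strict inequalities
and are implemented directly over labelled components so the printed
bounds mean exactly what they say.

Connected components are labelled 1..n in raster order of first pixel.
Curation is scriptable rather than interactive: a JSON sidecar lists
segment IDs to remove (plus an optional minimum segment size); survivors
are relabelled contiguously and the removed IDs recorded, so a curated
analysis is reproducible from its artefacts alone.

## Skeleton analysis

Thinning uses Lee's method by default (Zhang–Suen selectable); the two are
benchmarked, not mixed. A **branchpoint** is a skeleton pixel where at
least three centreline branches meet, counted as connected neighbour
groups (0→1 transitions walking the 8-neighbourhood in circular order).
This crossing-number rule flags exactly one pixel at a plus-crossing and
the centre of a T-junction, where a naive neighbour count would flag the
whole cluster of pixels around a junction (diagonal contacts inflate
per-pixel neighbour counts next to a junction). A strict variant
(≥ 4 branches, i.e. crossings only) is available. An **endpoint** has
exactly one skeleton neighbour.

Even with the crossing-number rule, thinning artefacts in noisy masks
produce clusters of nearby branchpoints. De-clustering is greedy in raster
order: a branchpoint is retained iff it is ≥ 30 px (≈ the mean vessel
length in the reference data) from every previously retained point. The
retained set is deterministic and its minimum pairwise distance is
guaranteed ≥ the threshold. Filtering is a counting correction only:
segment decomposition cuts at the *raw* branchpoints so segments never
span a junction.

Decomposition removes branchpoint pixels and takes components of the rest
under 8-adjacency, with one refinement: two pixels flanking the same
removed branchpoint are not considered adjacent. Without it, the arms of a
junction remain diagonally connected around the excised pixel and a
plus-junction would decompose into one segment instead of four. Segment
length is the pixel count (the pipeline's convention); a √2-weighted
length is reported as a clearly-labelled secondary column. Pixel
conservation holds exactly: Σ segment lengths + #raw branchpoints =
#skeleton pixels.

Per-pixel diameter is 2 × the Euclidean distance transform of the mask at
the skeleton pixel — the maximum inscribed circle diameter. Note the
convention's discretisation bias: distances are between pixel centres, so
an ideal w-px-wide band reads as w + 1 (a single isolated pixel reads as
2). Mean network diameter averages segment means by default
(`diameter_pixel_weighted=True` averages over all skeleton pixels
instead).

Vessel density is the mean vessel-pixel fraction over non-overlapping
square tiles sized to 100 µm² (side = round(√100 × 1.2) = 12 px at the
default scale); partial edge tiles are dropped. The tile area is
configurable — 100 µm² is a small window, and density estimates at other
scales differ. Branchpoint density divides the de-clustered count by the
image (or ROI bounding) area in µm².

## Units, normalisation, outlier filtering

Lengths and diameters divide by the px/µm scale; areal densities by its
square. Normalised network length divides µm of skeleton by µm of stack
depth (slice count × z-step), making embryos imaged with different stack
extents comparable; dividing by slice count instead is available as a
flag.

Outlier removal uses the raw median absolute deviation
(no 1.4826 normal-consistency factor — the small printed multipliers are
read in raw-MAD units; a consistency-factor option exists). Values in the
closed interval [median − 1·MAD, median + 3·MAD] are retained; the
asymmetry drops implausibly small fragments aggressively while tolerating
genuinely wide or long vessels. MAD = 0 retains exactly the ties at the
median. The filter acts on the per-segment diameter and length
distributions before image-level means; the network length total is not
recomputed from the filtered set, since outlier filtering is a statistical
correction, not a skeleton edit. Filtering is scale-equivariant, so
applying it before or after unit conversion is equivalent.

## ROI analysis

ROIs are polygons (even–odd rule, pixel-centre containment, boundary
inclusive), boxes, or half-planes, serialised as JSON in (y, x) pixel
coordinates. The vessel mask is intersected with the region and the whole
skeleton chain is recomputed inside it, rather than cropping an existing
skeleton — cropping would manufacture branchpoints and endpoints at the
ROI boundary. The full-image ROI therefore reproduces whole-image metrics
exactly, and metrics are monotone under ROI nesting up to
skeleton-boundary effects.

## Benchmarking

Jaccard scores mask overlap; two empty masks score 1.0 (identical sets)
with a warning. The Q-score multiplies three [0, 1] factors:
connectivity = 1 − min(1, |ΔC| / |ref|) penalising the component-count
difference relative to reference skeleton size; length = fraction of
candidate pixels within a 2-px tolerance of the reference; area = the same
with roles swapped. This is the standard connectivity–area–length
construction for curvilinear segmentation quality; the tolerance is
configurable and recorded. The selection grid evaluates
{Meijering, Frangi, Sato, Jerman} × {Lee, Zhang} with shared
pre-processing and deterministic ordering (Q, then Jaccard, descending).

## Synthetic phantoms

Phantoms exist so every stage has exact ground truth. Geometry is drawn
first: branches are analytic polylines with per-branch stroke widths; the
truth skeleton is the rasterised centreline (never a thinning of the
rendered mask, so thinning artefacts cannot leak into ground truth); the
truth mask is the set of pixels within (w−1)/2 of the centreline. The
ladder topology emulates the trunk ISV pattern — two longitudinal vessels
joined by evenly spaced rungs, two T-junctions per rung; the longitudinal
vessels overhang the outer rungs by ≥ 4 vessel widths so every declared
junction is a genuine T-junction after thinning. Tree, plus and bar
topologies cover branching, crossing and degenerate cases.

Rendering applies background (flat or ramp), vessel level, Gaussian PSF
blur, and noise after blur (Gaussian, or Poisson scaled with signal to
mimic photon statistics), into a 16-bit image. Defaults emulate the
reference acquisition: vessel/background 200/30 (≈ 6.7, a moderately
bright reporter over autofluorescence), and PSF σ = 0.5 px derived from
the imaging optics (0.61·λ/NA with λ = 510 nm and NA 0.3 gives
FWHM ≈ 1.04 µm ≈ 1.25 px at 0.83 µm/px, σ ≈ 0.5 px). Everything is
deterministic given the seed; the seed changes only noise, never geometry.

What phantoms do not emulate: real embryo anatomy, depth-dependent
attenuation, reporter mosaicism, motion, or the double-line artefact of
membrane-localised reporters. Passing recovery tests on phantoms
demonstrates the correctness of the measurement chain, not segmentation
performance on real embryos — that is what the benchmarking module and
reference masks are for.

## Numerical choices and limitations

- Otsu ties take the lowest threshold; MAD bounds are closed intervals;
  greedy branchpoint retention uses raster order — all tie-breaks are
  deterministic.
- The diameter convention (2 × EDT) systematically reads an ideal
  w-px-wide vessel as w + 1; consumers comparing absolute diameters
  across tools should account for the half-pixel-per-side bias.
- Meijering neuriteness has no scale-selective peak: its centreline
  response grows monotonically and saturates with σ on ridges wider than
  the smallest scale. Scale-selection sanity (response peaking near
  width/2) holds for Frangi and Sato and is tested there.
- Hessian filtering near the image border is not exactly symmetric under
  transposition (boundary handling of the underlying derivatives);
  symmetry holds to tight tolerance in the interior.
- Problem sizes in the test and acceptance suites (512² ladder phantoms,
  256² benchmark grids, 100-image oracle sweeps) were chosen as the
  smallest sizes at which every geometric regime of the method (junction
  separation above and below the de-clustering threshold, multi-scale
  widths, partial tiles) is exercised.
- CZI reading requires the optional `czifile` dependency; TIFF is the
  fully supported interchange format.
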