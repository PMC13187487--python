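"""Vessel segmentation: multiscale tubularity filtering, mask refinement,
connected-component labelling and scriptable curation.

The refined vessel mask is produced by thresholding a multiscale ridge
response (Meijering by default; Frangi, Sato and Jerman available for
benchmarking), combining it with the Otsu mask, removing small artefacts
(< 50 px by default) and filling small background holes (< 200 px).
Each connected vascular segment then receives a unique integer identifier,
so that misidentified structures can be removed by ID and the map relabelled
— a scriptable, reproducible replacement for interactive curation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.filters import frangi, meijering, sato

logger = logging.getLogger("vistaz")

_STRUCT_8 = np.ones((3, 3), dtype=bool)  # 8-connectivity (foreground)
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)  # 4-connectivity (holes)


@dataclass
class VesselMask:
    """Binary vessel mask with a record of the stages that produced it."""

    pixels: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())


@dataclass
class LabelMap:
    """Connected-component labelling of a vessel mask.

    Positive labels are contiguous 1..n_segments after any relabelling;
    0 is background. ``removed_ids`` records identifiers excised by curation
    or size-based exclusion (in the labelling they were removed from).
    """

    labels: np.ndarray
    n_segments: int
    removed_ids: set[int] = field(default_factory=set)

    def segment_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def as_mask(self) -> VesselMask:
        return VesselMask(self.labels > 0, provenance=["labelled"])


@dataclass
class SegmentationParams:
    """Segmentation defaults as published: Meijering threshold 10 on the
    [0, 255]-rescaled response, sigma range 3–8 px step 1, artefacts < 50 px
    removed, holes < 200 px filled."""

    meijering_threshold: float = 10.0
    sigma_min: float = 3.0
    sigma_max: float = 8.0
    sigma_step: float = 1.0
    min_object_px: int = 50
    max_hole_px: int = 200
    filter_name: str = "meijering"
    combine_with_otsu: str = "intersection"

    def __post_init__(self) -> None:
        if self.sigma_min > self.sigma_max:
            raise ValueError("sigma_min must be <= sigma_max")
        if self.sigma_step <= 0:
            raise ValueError("sigma_step must be > 0")
        if self.filter_name not in ("meijering", "frangi", "sato", "jerman"):
            raise ValueError(f"unknown filter {self.filter_name!r}")
        if self.combine_with_otsu not in ("intersection", "union", "meijering_only"):
            raise ValueError(f"unknown combination mode {self.combine_with_otsu!r}")

    @property
    def sigmas(self) -> np.ndarray:
        n = int(np.floor((self.sigma_max - self.sigma_min) / self.sigma_step + 1e-9)) + 1
        return self.sigma_min + self.sigma_step * np.arange(n)


def jerman_filter(image: np.ndarray, sigmas, tau: float = 0.5) -> np.ndarray:
    """Jerman's ratio-of-eigenvalues vesselness for bright 2D ridges.

    At each scale the Hessian eigenvalues are sorted by magnitude
    (|λ1| ≤ |λ2|); with λ = −λ2 (positive on bright ridges) the regularised
    λρ replaces small responses by τ·max(λ) and the enhancement is
    λ²·λρ·(3/(λ+λρ))³, capped at 1 where λ ≥ λρ/2. The multiscale response
    is the per-pixel maximum over scales.
    """
    img = np.asarray(image, dtype=np.float64)
    out = np.zeros_like(img)
    for sigma in sigmas:
        H = hessian_matrix(img, sigma=sigma, order="rc", use_gaussian_derivatives=False)
        ev = hessian_matrix_eigvals(H)  # (2, y, x), sorted descending by value
        # sort by absolute value: lam2 = larger magnitude
        idx = np.argmax(np.abs(ev), axis=0)
        lam2 = np.take_along_axis(ev, idx[None], axis=0)[0]
        lam = -lam2 * sigma**2  # gamma-normalised; positive on bright ridges
        lam[lam < 0] = 0.0
        mx = lam.max()
        if mx == 0:
            continue
        lam_rho = np.where(lam > tau * mx, lam, tau * mx)
        lam_rho[lam == 0] = 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            resp = lam**2 * lam_rho * (3.0 / (lam + lam_rho)) ** 3
        resp = np.nan_to_num(resp)
        resp[lam >= lam_rho / 2.0] = 1.0
        resp[lam == 0] = 0.0
        np.maximum(out, resp, out=out)
    return out


def tubularity_filter(image, params: SegmentationParams | None = None) -> np.ndarray:
    """Multiscale ridge (tubularity) response, rescaled to [0, 255].

    The chosen Hessian-based filter (Meijering neuriteness by default) is
    evaluated at sigmas {sigma_min, sigma_min+step, …, sigma_max} with
    bright-ridge polarity; the per-pixel maximum over scales is linearly
    rescaled so the printed segmentation threshold (10) is meaningful.
    """
    params = params or SegmentationParams()
    px = getattr(image, "pixels", image)
    img = np.asarray(px, dtype=np.float64)
    sigmas = params.sigmas
    if params.filter_name == "meijering":
        resp = meijering(img, sigmas=sigmas, black_ridges=False)
    elif params.filter_name == "frangi":
        resp = frangi(img, sigmas=sigmas, black_ridges=False)
    elif params.filter_name == "sato":
        resp = sato(img, sigmas=sigmas, black_ridges=False)
    else:
        resp = jerman_filter(img, sigmas=sigmas)
    mx = resp.max()
    if mx > 0:
        resp = resp * (255.0 / mx)
    return resp


def remove_small_objects_strict(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Delete 8-connected foreground components with area < min_px."""
    labels, n = ndimage.label(mask, structure=_STRUCT_8)
    if n == 0:
        return mask.copy()
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def fill_small_holes_strict(mask: np.ndarray, max_px: int) -> np.ndarray:
    """Fill 4-connected background holes (not touching the border) with area < max_px."""
    bg = ~mask
    labels, n = ndimage.label(bg, structure=_STRUCT_4)
    if n == 0:
        return mask.copy()
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    touching = np.unique(labels[border & bg])
    sizes = np.bincount(labels.ravel())
    fill = (sizes < max_px) & (np.arange(sizes.size) > 0)
    fill[touching] = False
    return mask | fill[labels]


def refine_mask(
    response: np.ndarray,
    otsu: VesselMask | None,
    params: SegmentationParams | None = None,
) -> VesselMask:
    """Refined vessel mask from the ridge response and the Otsu mask.

    The response is thresholded (strictly greater than the segmentation
    threshold), combined with the Otsu mask (intersection by default), then
    morphologically cleaned: 8-connected objects below ``min_object_px`` are
    removed and 4-connected holes below ``max_hole_px`` filled.
    """
    params = params or SegmentationParams()
    thresholded = np.asarray(response) > params.meijering_threshold
    mode = params.combine_with_otsu
    if mode != "meijering_only" and otsu is not None:
        if otsu.pixels.shape != thresholded.shape:
            raise ValueError("response and Otsu mask shapes differ")
        combined = thresholded & otsu.pixels if mode == "intersection" else thresholded | otsu.pixels
    else:
        combined = thresholded
    cleaned = remove_small_objects_strict(combined, params.min_object_px)
    filled = fill_small_holes_strict(cleaned, params.max_hole_px)
    prov = (otsu.provenance if otsu is not None else []) + [
        f"{params.filter_name}>{params.meijering_threshold:g}",
        mode,
        f"rm<{params.min_object_px}px",
        f"fill<{params.max_hole_px}px",
    ]
    return VesselMask(filled, provenance=prov)


def label_segments(mask: VesselMask) -> LabelMap:
    """Label 8-connected components 1..n in raster order of first pixel."""
    labels, n = ndimage.label(mask.pixels, structure=_STRUCT_8)
    return LabelMap(labels=labels, n_segments=int(n))


def curate(
    labelmap: LabelMap,
    remove_ids: set[int] | None = None,
    min_segment_px: int | None = None,
) -> LabelMap:
    """Remove segments by ID and/or size, then relabel contiguously.

    Unknown IDs are ignored with a warning. Surviving segments are
    relabelled 1..m preserving raster order; removed IDs (in the input
    labelling) are recorded on the result.
    """
    remove_ids = set(remove_ids or ())
    present = set(np.unique(labelmap.labels[labelmap.labels > 0]).tolist())
    unknown = remove_ids - present
    if unknown:
        logger.warning("curate: ignoring unknown segment IDs %s", sorted(unknown))
    to_remove = remove_ids & present
    if min_segment_px is not None:
        sizes = labelmap.segment_sizes()
        to_remove |= {sid for sid, sz in sizes.items() if sz < min_segment_px}

    labels = labelmap.labels.copy()
    if to_remove:
        labels[np.isin(labels, list(to_remove))] = 0
    # relabel contiguously, preserving raster order of original IDs
    survivors = np.unique(labels[labels > 0])
    mapping = np.zeros(labelmap.labels.max() + 1, dtype=labels.dtype)
    mapping[survivors] = np.arange(1, survivors.size + 1)
    return LabelMap(
        labels=mapping[labels],
        n_segments=int(survivors.size),
        removed_ids=labelmap.removed_ids | to_remove,
    )


def render_pseudocolour(labelmap: LabelMap) -> np.ndarray:
    """Deterministic pseudo-colour rendering (uint8 RGB), background black.

    Colours come from a fixed-seed permutation of an HSV wheel so adjacent
    labels get visually distinct hues; the same label map always renders to
    the identical image.
    """
    n = labelmap.n_segments
    h, w = labelmap.labels.shape
    out = np.zeros((h, w, 3), dtype=np.uint8)
    if n == 0:
        return out
    rng = np.random.default_rng(8421)
    hues = (np.arange(n) * 0.6180339887498949) % 1.0  # golden-ratio spacing
    sat = 0.65 + 0.35 * rng.random(n)
    val = 0.75 + 0.25 * rng.random(n)
    import colorsys

    palette = np.zeros((n + 1, 3), dtype=np.uint8)
    for i in range(n):
        r, g, b = colorsys.hsv_to_rgb(hues[i], sat[i], val[i])
        palette[i + 1] = np.rint(np.array([r, g, b]) * 255)
    return palette[labelmap.labels]
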