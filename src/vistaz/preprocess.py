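"""Projection pre-processing: 8-bit normalisation, CLAHE, Otsu masking.

Stage order follows the pipeline: pixel intensity normalisation, then
contrast-limited adaptive histogram equalisation (CLAHE), then Otsu
threshold-based masking. CLAHE locally improves vessel visibility in
low-signal regions without amplifying background noise; Otsu gives an
unbiased initial vessel/background split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .image_io import ProjectionImage
from .segmentation import VesselMask


@dataclass
class PreprocessParams:
    """CLAHE parameters. Defaults: clip limit 2.0, 4×4 tile grid."""

    clahe_clip_limit: float = 2.0
    clahe_tile_grid: tuple[int, int] = (4, 4)
    otsu_enabled: bool = True
    #: Threshold the CLAHE-enhanced image (True) or the raw 8-bit image.
    otsu_on_enhanced: bool = True

    def __post_init__(self) -> None:
        if self.clahe_clip_limit <= 0:
            raise ValueError("clahe_clip_limit must be > 0")
        gy, gx = self.clahe_tile_grid
        if gy < 1 or gx < 1:
            raise ValueError("tile grid dimensions must be >= 1")


def normalize_to_8bit(image: ProjectionImage) -> ProjectionImage:
    """Linearly rescale intensities to the full 8-bit range.

    The minimum input value maps to 0 and the maximum to 255, linear in
    between with round-half-to-even; constant images map to all zeros. The
    map is invariant to affine intensity changes a·x + b with a > 0.
    """
    px = image.pixels
    if px.size == 0:
        raise ValueError("cannot normalise an empty image")
    lo = float(px.min())
    hi = float(px.max())
    if hi == lo:
        out = np.zeros(px.shape, dtype=np.uint8)
    else:
        scaled = (px.astype(np.float64) - lo) * (255.0 / (hi - lo))
        out = np.rint(scaled).astype(np.uint8)
    return replace(image, pixels=out, bit_depth=8)


def _tile_lut(tile: np.ndarray, clip_limit: float) -> np.ndarray:
    """Clipped-histogram equalisation LUT for one tile (OpenCV convention).

    The per-bin cap is clip_limit × tile_area / 256 (at least 1); clipped
    excess is redistributed uniformly over all 256 bins before building the
    cumulative mapping scaled to [0, 255].
    """
    n = tile.size
    hist = np.bincount(tile.ravel(), minlength=256).astype(np.float64)
    cap = max(clip_limit * n / 256.0, 1.0)
    excess = np.clip(hist - cap, 0.0, None).sum()
    hist = np.minimum(hist, cap) + excess / 256.0
    cdf = np.cumsum(hist)
    return np.rint(cdf * (255.0 / n)).astype(np.uint8)


def apply_clahe(image: ProjectionImage, params: PreprocessParams | None = None) -> ProjectionImage:
    """Contrast-limited adaptive histogram equalisation on an 8-bit image.

    The image is divided into a tile grid (default 4×4); each tile gets a
    clipped-histogram equalisation mapping, and per-pixel output is the
    bilinear interpolation of the four surrounding tile mappings. Images not
    divisible by the grid are padded by edge reflection and cropped back.
    """
    params = params or PreprocessParams()
    if image.bit_depth != 8 or image.pixels.dtype != np.uint8:
        raise ValueError("CLAHE requires an 8-bit image; run normalize_to_8bit first")
    gy, gx = params.clahe_tile_grid
    px = image.pixels
    h, w = px.shape
    if gy > h or gx > w:
        raise ValueError("tile grid exceeds image dimensions")

    th = -(-h // gy)  # tile height (ceil), pad to a multiple
    tw = -(-w // gx)
    pad_y, pad_x = th * gy - h, tw * gx - w
    padded = np.pad(px, ((0, pad_y), (0, pad_x)), mode="reflect") if (pad_y or pad_x) else px
    ph, pw = padded.shape

    luts = np.empty((gy, gx, 256), dtype=np.uint8)
    for iy in range(gy):
        for ix in range(gx):
            tile = padded[iy * th : (iy + 1) * th, ix * tw : (ix + 1) * tw]
            luts[iy, ix] = _tile_lut(tile, params.clahe_clip_limit)

    # Bilinear interpolation between tile-centre mappings, clamped at borders.
    yy = (np.arange(ph) + 0.5) / th - 0.5
    xx = (np.arange(pw) + 0.5) / tw - 0.5
    y0 = np.clip(np.floor(yy).astype(int), 0, gy - 1)
    x0 = np.clip(np.floor(xx).astype(int), 0, gx - 1)
    y1 = np.minimum(y0 + 1, gy - 1)
    x1 = np.minimum(x0 + 1, gx - 1)
    wy = np.clip(yy - y0, 0.0, 1.0)[:, None]
    wx = np.clip(xx - x0, 0.0, 1.0)[None, :]

    Y0, X0 = y0[:, None], x0[None, :]
    Y1, X1 = y1[:, None], x1[None, :]
    v00 = luts[Y0, X0, padded].astype(np.float64)
    v01 = luts[Y0, X1, padded].astype(np.float64)
    v10 = luts[Y1, X0, padded].astype(np.float64)
    v11 = luts[Y1, X1, padded].astype(np.float64)
    out = (1 - wy) * ((1 - wx) * v00 + wx * v01) + wy * ((1 - wx) * v10 + wx * v11)
    out = np.rint(out).astype(np.uint8)[:h, :w]
    return replace(image, pixels=out, bit_depth=8)


def otsu_threshold(pixels: np.ndarray) -> int:
    """Otsu threshold over the 256-bin histogram of an 8-bit image.

    Returns the integer t maximising between-class variance, where the split
    is background ≤ t < foreground. Ties take the lowest t.
    """
    hist = np.bincount(pixels.ravel(), minlength=256).astype(np.float64)
    n = hist.sum()
    w0 = np.cumsum(hist)  # class counts for thresholds t = 0..255
    w1 = n - w0
    mu = np.cumsum(hist * np.arange(256))
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = mu / w0
        m1 = (mu_t - mu) / w1
        var_between = w0 * w1 * (m0 - m1) ** 2
    var_between = np.nan_to_num(var_between, nan=-1.0)
    return int(np.argmax(var_between[:-1]))  # t = 255 is not a valid split


def otsu_mask(image: ProjectionImage) -> VesselMask:
    """Initial binary vessel mask by Otsu thresholding (foreground = pixels > t)."""
    if image.bit_depth != 8 or image.pixels.dtype != np.uint8:
        raise ValueError("Otsu masking requires an 8-bit image")
    px = image.pixels
    if px.min() == px.max():
        warnings.warn("constant image: no variance to split; returning empty mask", stacklevel=2)
        return VesselMask(np.zeros(px.shape, dtype=bool), provenance=["otsu"])
    t = otsu_threshold(px)
    return VesselMask(px > t, provenance=["otsu"])
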