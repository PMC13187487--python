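"""Reading calibrated z-stacks and producing maximum-intensity projections.

The pipeline's entry point: confocal z-stacks (multi-page TIFF, or CZI when
the optional ``czifile`` dependency is installed) are loaded together with
their physical calibration (XY pixel size in µm, z-step in µm), collapsed to
2D maximum-intensity projections, and split into single-channel stacks for
independent processing.

Axis order is fixed as (z, y, x) for stacks and (y, x) for projections,
origin top-left, 0-based integer pixel coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger("vistaz")

#: Default XY calibration: 1.2 pixels per micron, i.e. 0.8333 µm per pixel.
DEFAULT_PX_PER_UM = 1.2
DEFAULT_PIXEL_SIZE_UM = 1.0 / DEFAULT_PX_PER_UM
#: Default z-step between confocal slices, in microns.
DEFAULT_Z_STEP_UM = 5.0


@dataclass
class CalibratedStack:
    """A 3D fluorescence stack with per-axis physical calibration.

    ``voxels`` is (z, y, x) for a single channel or (c, z, y, x) for a
    multi-channel acquisition; ``channel_names`` has one entry per channel.
    """

    voxels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float = DEFAULT_Z_STEP_UM
    channel_names: list[str] = field(default_factory=lambda: ["ch0"])

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 3:
            if len(self.channel_names) != 1:
                raise ValueError("3D voxels imply exactly one channel")
        elif self.voxels.ndim == 4:
            if self.voxels.shape[0] != len(self.channel_names):
                raise ValueError("channel axis does not match channel_names")
        else:
            raise ValueError("voxels must be (z, y, x) or (c, z, y, x)")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("calibration values must be positive")
        if self.n_slices == 0:
            raise ValueError("stack has zero slices")

    @property
    def n_channels(self) -> int:
        return 1 if self.voxels.ndim == 3 else self.voxels.shape[0]

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0] if self.voxels.ndim == 3 else self.voxels.shape[1]

    @property
    def z_depth_um(self) -> float:
        """Physical depth of the stack: slice count × z-step."""
        return self.n_slices * self.z_step_um

    def channel_voxels(self, channel: int) -> np.ndarray:
        if channel < 0 or channel >= self.n_channels:
            raise IndexError(f"channel {channel} out of range (n={self.n_channels})")
        return self.voxels if self.voxels.ndim == 3 else self.voxels[channel]


@dataclass
class ProjectionImage:
    """A 2D projection with calibration and stack provenance.

    ``z_depth_um`` is the physical depth of the source stack; 0 is allowed
    only for images with no stack provenance (depth-normalised metrics are
    then unavailable).
    """

    pixels: np.ndarray
    bit_depth: int = 16
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_depth_um: float = 0.0
    channel: str = "ch0"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("projection pixels must be 2D (y, x)")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def px_per_um(self) -> float:
        return 1.0 / self.pixel_size_um

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def read_stack(
    path: str | Path,
    format_hint: str = "auto",
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
    channel_names: list[str] | None = None,
) -> CalibratedStack:
    """Read a CZI or multi-page TIFF z-stack with calibration metadata.

    Calibration precedence: explicit arguments > embedded metadata > package
    defaults (0.8333 µm/px ≡ 1.2 px/µm, 5 µm z-step). Missing metadata is
    filled from the defaults with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read stack: no such file {path}")
    fmt = format_hint
    if fmt == "auto":
        fmt = "czi" if path.suffix.lower() == ".czi" else "tiff"
    if fmt == "czi":
        voxels, meta_px, meta_z = _read_czi(path)
    elif fmt == "tiff":
        voxels, meta_px, meta_z = _read_tiff(path)
    else:
        raise ValueError(f"unknown format hint {fmt!r}")
    if voxels.ndim == 2:
        voxels = voxels[None, :, :]
    n_slices = voxels.shape[0] if voxels.ndim == 3 else voxels.shape[1]
    if n_slices == 0:
        raise ValueError(f"stack {path} has zero slices")

    px = _resolve_calibration("pixel_size_um", pixel_size_um, meta_px, DEFAULT_PIXEL_SIZE_UM, path)
    dz = _resolve_calibration("z_step_um", z_step_um, meta_z, DEFAULT_Z_STEP_UM, path)
    n_ch = 1 if voxels.ndim == 3 else voxels.shape[0]
    names = channel_names if channel_names is not None else [f"ch{i}" for i in range(n_ch)]
    return CalibratedStack(voxels=voxels, pixel_size_um=px, z_step_um=dz, channel_names=names)


def _resolve_calibration(
    name: str, explicit: float | None, embedded: float | None, default: float, path: Path
) -> float:
    if explicit is not None:
        if embedded is not None and not np.isclose(explicit, embedded):
            logger.warning(
                "%s: config %s=%g overrides embedded metadata %g", path, name, explicit, embedded
            )
        return float(explicit)
    if embedded is not None:
        return float(embedded)
    logger.warning("%s: %s missing from metadata; using default %g", path, name, default)
    return float(default)


def _read_tiff(path: Path) -> tuple[np.ndarray, float | None, float | None]:
    try:
        with tifffile.TiffFile(path) as tf:
            voxels = tf.asarray()
            meta_px = None
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if res is not None and unit is not None:
                num, den = res.value
                if num > 0 and den > 0:
                    px_per_unit = num / den
                    unit_um = {2: 25400.0, 3: 10000.0}.get(int(unit.value))  # inch / cm
                    if unit_um is not None and px_per_unit > 0:
                        meta_px = unit_um / px_per_unit
    except (tifffile.TiffFileError, ValueError) as exc:
        raise IOError(f"cannot parse {path} as TIFF: {exc}") from exc
    return voxels, meta_px, None


def _read_czi(path: Path) -> tuple[np.ndarray, float | None, float | None]:
    try:
        import czifile
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "CZI support requires the optional 'czifile' dependency "
            "(pip install vistaz[czi]); alternatively convert to TIFF"
        ) from exc
    with czifile.CziFile(path) as czi:  # pragma: no cover - optional dependency
        data = np.squeeze(czi.asarray())
        return data, None, None


def max_project(stack: CalibratedStack, channel: int = 0) -> ProjectionImage:
    """Maximum-intensity projection of one channel along z.

    Each output pixel is the maximum over z of the corresponding voxel
    column; bit depth and calibration are carried over, and ``z_depth_um``
    records the source stack depth for downstream normalisation.
    """
    vox = stack.channel_voxels(channel)
    proj = vox.max(axis=0)
    bit_depth = 8 if proj.dtype == np.uint8 else 16
    return ProjectionImage(
        pixels=proj,
        bit_depth=bit_depth,
        pixel_size_um=stack.pixel_size_um,
        z_depth_um=stack.z_depth_um,
        channel=stack.channel_names[channel],
    )


def split_channels(stack: CalibratedStack) -> list[CalibratedStack]:
    """Split a multi-channel stack into single-channel stacks, order preserved."""
    out = []
    for i, name in enumerate(stack.channel_names):
        out.append(
            CalibratedStack(
                voxels=stack.channel_voxels(i).copy(),
                pixel_size_um=stack.pixel_size_um,
                z_step_um=stack.z_step_um,
                channel_names=[name],
            )
        )
    return out


def write_projection(image: ProjectionImage, path: str | Path) -> None:
    """Write a projection to TIFF, preserving bit depth exactly."""
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    tifffile.imwrite(str(path), image.pixels.astype(dtype))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as 8-bit TIFF with foreground 255."""
    tifffile.imwrite(str(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_projection(
    path: str | Path,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    z_depth_um: float = 0.0,
    channel: str = "ch0",
) -> ProjectionImage:
    """Read a pre-computed 2D projection from TIFF/PNG.

    Projections supplied directly have no stack provenance, so ``z_depth_um``
    must be given explicitly for depth-normalised metrics to be meaningful.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read projection: no such file {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        pixels = np.asarray(iio.imread(str(path)))
    if pixels.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2D image")
    bit_depth = 8 if pixels.dtype == np.uint8 else 16
    if z_depth_um == 0.0:
        warnings.warn(
            f"{path}: projection has no z-depth; depth-normalised metrics unavailable",
            stacklevel=2,
        )
    return ProjectionImage(
        pixels=pixels,
        bit_depth=bit_depth,
        pixel_size_um=pixel_size_um,
        z_depth_um=z_depth_um,
        channel=channel,
    )
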