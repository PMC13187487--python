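"""Physical-unit conversion, z-depth normalisation, MAD outlier filtering
and result export.

Pixel metrics become microns via the pixel-to-micron scale factor
(1.2 px/µm by default, the calibration of the source microscope at 10×);
network length is additionally normalised by the physical z-depth of the
source stack so embryos imaged at different depths are comparable. Outliers
in the per-segment diameter and length distributions are removed with an
asymmetric median-absolute-deviation filter (lower = 1 × MAD,
upper = 3 × MAD) before image-level means are computed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_SCALE_PX_PER_UM = 1.2

#: Normal consistency factor 1/Φ⁻¹(3/4); OFF by default — the published
#: multipliers (1×, 3×) are read in raw-MAD units.
MAD_CONSISTENCY = 1.4826022185056018


@dataclass
class MadParams:
    """Asymmetric MAD filter bounds: [median − lower·MAD, median + upper·MAD]."""

    lower_mult: float = 1.0
    upper_mult: float = 3.0
    targets: tuple[str, ...] = ("diameter", "length")
    use_consistency_factor: bool = False

    def __post_init__(self) -> None:
        if self.lower_mult <= 0 or self.upper_mult <= 0:
            raise ValueError("MAD multipliers must be > 0")


@dataclass
class MetricsRecord:
    """Per-image (or per-ROI) vascular metrics with normalisation provenance."""

    image_id: str = ""
    roi_id: str = "full"
    channel: str = "ch0"
    network_length_px: float = 0.0
    network_length_um: float = 0.0
    normalised_network_length: float = 0.0
    vessel_density: float = 0.0
    branchpoint_count: int = 0
    branchpoint_density_per_um2: float = 0.0
    mean_diameter_px: float = 0.0
    mean_diameter_um: float = 0.0
    mean_segment_length_px: float = 0.0
    mean_segment_length_um: float = 0.0
    n_segments_pre_mad: int = 0
    n_segments_post_mad: int = 0
    scale_px_per_um: float = DEFAULT_SCALE_PX_PER_UM
    z_depth_um: float = 0.0
    image_area_px: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def mad_filter(values, params: MadParams | None = None) -> tuple[np.ndarray, tuple[float, float]]:
    """Asymmetric MAD outlier filter.

    With m = median(values) and MAD = median(|values − m|), values inside
    the closed interval [m − lower·MAD, m + upper·MAD] are retained; the
    bounds are returned for audit. MAD = 0 retains only values equal to the
    median. Scale-equivariant: filtering a·x retains the scaled versions of
    exactly the values retained for x.
    """
    params = params or MadParams()
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("mad_filter requires at least one value")
    m = float(np.median(values))
    mad = float(np.median(np.abs(values - m)))
    if params.use_consistency_factor:
        mad *= MAD_CONSISTENCY
    lo = m - params.lower_mult * mad
    hi = m + params.upper_mult * mad
    retained = values[(values >= lo) & (values <= hi)]
    return retained, (lo, hi)


def mad_inlier_flags(values, params: MadParams | None = None) -> np.ndarray:
    """Boolean inlier flags under the same bounds as :func:`mad_filter`."""
    params = params or MadParams()
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return np.zeros(0, dtype=bool)
    m = float(np.median(values))
    mad = float(np.median(np.abs(values - m)))
    if params.use_consistency_factor:
        mad *= MAD_CONSISTENCY
    return (values >= m - params.lower_mult * mad) & (values <= m + params.upper_mult * mad)


def to_physical_units(
    record: MetricsRecord,
    scale_px_per_um: float | None = None,
    z_depth_um: float | None = None,
) -> MetricsRecord:
    """Convert pixel metrics to microns and normalise by z-depth.

    Lengths and diameters divide by the scale (px/µm); areal densities
    divide by scale²; ``normalised_network_length`` is µm of skeleton per
    µm of stack depth. A record with no stack provenance (depth 0) keeps
    normalised length at 0.
    """
    scale = scale_px_per_um if scale_px_per_um is not None else record.scale_px_per_um
    depth = z_depth_um if z_depth_um is not None else record.z_depth_um
    if scale <= 0:
        raise ValueError("scale_px_per_um must be > 0")
    if depth < 0:
        raise ValueError("z_depth_um must be >= 0")
    record.scale_px_per_um = scale
    record.z_depth_um = depth
    record.network_length_um = record.network_length_px / scale
    record.mean_diameter_um = record.mean_diameter_px / scale
    record.mean_segment_length_um = record.mean_segment_length_px / scale
    area_um2 = record.image_area_px / scale**2
    record.branchpoint_density_per_um2 = (
        record.branchpoint_count / area_um2 if area_um2 > 0 else 0.0
    )
    record.normalised_network_length = (
        record.network_length_um / depth if depth > 0 else 0.0
    )
    return record


def segment_table(segments, mad_params: MadParams | None = None) -> pd.DataFrame:
    """Per-segment table with MAD inlier flags for diameter and length."""
    mad_params = mad_params or MadParams()
    rows = [
        {
            "segment_id": s.segment_id,
            "n_pixels": int(s.length_px),
            "length_px": s.length_px,
            "length_px_weighted": s.length_px_weighted,
            "mean_diameter_px": s.mean_diameter_px,
        }
        for s in segments
    ]
    df = pd.DataFrame(
        rows,
        columns=["segment_id", "n_pixels", "length_px", "length_px_weighted", "mean_diameter_px"],
    )
    if len(df):
        diam_ok = (
            mad_inlier_flags(df["mean_diameter_px"], mad_params)
            if "diameter" in mad_params.targets
            else np.ones(len(df), bool)
        )
        len_ok = (
            mad_inlier_flags(df["length_px"], mad_params)
            if "length" in mad_params.targets
            else np.ones(len(df), bool)
        )
        df["diameter_inlier"] = diam_ok
        df["length_inlier"] = len_ok
        df["mad_retained"] = diam_ok & len_ok
    else:
        df["diameter_inlier"] = df["length_inlier"] = df["mad_retained"] = pd.Series(dtype=bool)
    return df


def apply_mad_to_record(
    record: MetricsRecord, segments, mad_params: MadParams | None = None
) -> MetricsRecord:
    """Recompute image-level means over MAD-retained segments.

    The filter acts on the per-segment diameter and length distributions;
    the network length total is not recomputed from the filtered set (the
    skeleton itself is not edited by outlier removal).
    """
    mad_params = mad_params or MadParams()
    record.n_segments_pre_mad = len(segments)
    if not segments:
        record.n_segments_post_mad = 0
        return record
    table = segment_table(segments, mad_params)
    kept = table[table["mad_retained"]]
    record.n_segments_post_mad = int(len(kept))
    if len(kept):
        record.mean_diameter_px = float(kept["mean_diameter_px"].mean())
        record.mean_segment_length_px = float(kept["length_px"].mean())
    return record


SUMMARY_COLUMNS = [f.name for f in MetricsRecord.__dataclass_fields__.values()]


def export_results(
    records: list[MetricsRecord],
    segment_tables: dict[str, pd.DataFrame] | None,
    path: str | Path,
) -> None:
    """Export results as an Excel workbook with a CSV mirror.

    The summary sheet has one row per image×ROI with all metric fields in a
    stable column order; each per-segment table becomes its own sheet with
    MAD inlier flags. Identical content is mirrored to CSV files next to
    the workbook, so re-export of identical records is byte-identical.
    """
    if not records:
        raise ValueError("export_results requires at least one record")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    summary = pd.DataFrame([r.to_dict() for r in records], columns=SUMMARY_COLUMNS)
    segment_tables = segment_tables or {}
    with pd.ExcelWriter(path, engine="openpyxl") as xl:
        summary.to_excel(xl, sheet_name="summary", index=False)
        for name, df in segment_tables.items():
            df.to_excel(xl, sheet_name=f"segments_{name}"[:31], index=False)
    summary.to_csv(path.with_suffix(".summary.csv"), index=False, lineterminator="\n")
    for name, df in segment_tables.items():
        df.to_csv(
            path.parent / f"{path.stem}.segments_{name}.csv", index=False, lineterminator="\n"
        )
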