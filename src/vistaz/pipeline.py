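"""End-to-end pipeline orchestration.

Fixed stage order: read → project → per-channel [normalise → CLAHE → Otsu →
tubularity → refine → label → curate → (per ROI) skeletonise → branchpoints
→ distance filter → segments → diameters → metrics → unit conversion and
z-normalisation → MAD filtering → export]. A run's effective configuration
is written beside the outputs so every number in the summary sheet is
reproducible from the saved config and inputs alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .image_io import (
    CalibratedStack,
    DEFAULT_PIXEL_SIZE_UM,
    ProjectionImage,
    max_project,
    read_stack,
    split_channels,
    write_mask,
    write_projection,
)
from .metrics import (
    MadParams,
    MetricsRecord,
    apply_mad_to_record,
    export_results,
    segment_table,
    to_physical_units,
)
from .preprocess import PreprocessParams, apply_clahe, normalize_to_8bit, otsu_mask
from .roi import ROISpec, load_roi_file, restrict_mask
from .segmentation import (
    SegmentationParams,
    VesselMask,
    curate,
    label_segments,
    refine_mask,
    render_pseudocolour,
    tubularity_filter,
)
from .skeleton_analysis import (
    SkeletonParams,
    decompose_segments,
    detect_branchpoints,
    estimate_diameters,
    filter_branchpoints,
    network_metrics,
    skeletonize,
)

logger = logging.getLogger("vistaz")


@dataclass
class RunConfig:
    """Fully serialisable run configuration; written beside the outputs."""

    inputs: list[str] = field(default_factory=list)
    output_dir: str = "vistaz_out"
    channels: list[int] | None = None
    pixel_size_um: float | None = None
    z_step_um: float | None = None
    z_depth_um: float | None = None  # required for bare projections
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    skeleton: SkeletonParams = field(default_factory=SkeletonParams)
    mad: MadParams = field(default_factory=MadParams)
    roi_file: str | None = None
    curation_file: str | None = None  # JSON {"removed_ids": [...], "min_segment_px": N}
    min_segment_px: int | None = None
    save_intermediates: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        for key, sub in (
            ("preprocess", PreprocessParams),
            ("segmentation", SegmentationParams),
            ("skeleton", SkeletonParams),
            ("mad", MadParams),
        ):
            if key in data and isinstance(data[key], dict):
                sub_data = dict(data[key])
                if key == "preprocess" and "clahe_tile_grid" in sub_data:
                    sub_data["clahe_tile_grid"] = tuple(sub_data["clahe_tile_grid"])
                if key == "mad" and "targets" in sub_data:
                    sub_data["targets"] = tuple(sub_data["targets"])
                data[key] = sub(**sub_data)
        return cls(**data)


def segment_projection(
    projection: ProjectionImage,
    preprocess_params: PreprocessParams | None = None,
    segmentation_params: SegmentationParams | None = None,
) -> tuple[VesselMask, ProjectionImage]:
    """Pre-process one projection and produce the refined vessel mask.

    Returns the mask and the CLAHE-enhanced 8-bit image (useful for
    overlays and benchmarking).
    """
    pp = preprocess_params or PreprocessParams()
    sp = segmentation_params or SegmentationParams()
    img8 = normalize_to_8bit(projection)
    enhanced = apply_clahe(img8, pp)
    otsu = otsu_mask(enhanced if pp.otsu_on_enhanced else img8) if pp.otsu_enabled else None
    response = tubularity_filter(enhanced, sp)
    mask = refine_mask(response, otsu, sp)
    return mask, enhanced


def analyze_mask(
    mask: VesselMask,
    px_per_um: float,
    z_depth_um: float,
    skeleton_params: SkeletonParams | None = None,
    mad_params: MadParams | None = None,
    image_id: str = "",
    roi_id: str = "full",
    channel: str = "ch0",
):
    """Skeletonise a vessel mask and compute the full metrics record.

    Runs thinning, branchpoint detection and de-clustering, segment
    decomposition, diameter estimation, network metrics, MAD filtering and
    physical-unit conversion. Returns (MetricsRecord, segments, skeleton).
    """
    sk = skeleton_params or SkeletonParams()
    mp = mad_params or MadParams()
    skel = skeletonize(mask, sk)
    skel = detect_branchpoints(skel, sk)
    skel = filter_branchpoints(skel, sk)
    segments = decompose_segments(skel)
    segments = estimate_diameters(mask, segments)
    net = network_metrics(skel, segments, mask, px_per_um, sk)
    record = MetricsRecord(
        image_id=image_id,
        roi_id=roi_id,
        channel=channel,
        network_length_px=net["network_length_px"],
        vessel_density=net["vessel_density"],
        branchpoint_count=net["branchpoint_count"],
        mean_diameter_px=net["mean_diameter_px"],
        mean_segment_length_px=(
            float(np.mean([s.length_px for s in segments])) if segments else 0.0
        ),
        scale_px_per_um=px_per_um,
        z_depth_um=z_depth_um,
        image_area_px=int(mask.pixels.size),
    )
    record = apply_mad_to_record(record, segments, mp)
    record = to_physical_units(record)
    return record, segments, skel


def _load_curation(config: RunConfig) -> tuple[set[int], int | None]:
    removed: set[int] = set()
    min_px = config.min_segment_px
    if config.curation_file:
        with open(config.curation_file) as fh:
            data = json.load(fh)
        removed = set(data.get("removed_ids", []))
        if min_px is None:
            min_px = data.get("min_segment_px")
    return removed, min_px


def process_projection(
    projection: ProjectionImage,
    config: RunConfig,
    image_id: str,
    rois: list[ROISpec] | None = None,
    out_dir: Path | None = None,
):
    """Run segmentation, curation and (per-ROI) analysis for one projection."""
    mask, enhanced = segment_projection(projection, config.preprocess, config.segmentation)
    labelmap = label_segments(mask)
    removed, min_px = _load_curation(config)
    labelmap = curate(labelmap, removed, min_px)
    curated_mask = labelmap.as_mask()
    curated_mask.provenance = mask.provenance + ["curated"]

    if out_dir is not None and config.save_intermediates:
        write_projection(enhanced, out_dir / f"{image_id}_enhanced.tif")
        write_mask(curated_mask.pixels, out_dir / f"{image_id}_mask.tif")
        import tifffile

        tifffile.imwrite(
            str(out_dir / f"{image_id}_labels.tif"), labelmap.labels.astype(np.uint16)
        )
        tifffile.imwrite(
            str(out_dir / f"{image_id}_labels_rgb.tif"), render_pseudocolour(labelmap)
        )

    z_depth = config.z_depth_um if config.z_depth_um else projection.z_depth_um
    records, tables = [], {}
    targets: list[tuple[str, VesselMask]] = [("full", curated_mask)]
    for spec in rois or []:
        targets.append((spec.roi_id, restrict_mask(curated_mask, spec)))
    for roi_id, target_mask in targets:
        record, segments, skel = analyze_mask(
            target_mask,
            px_per_um=projection.px_per_um,
            z_depth_um=z_depth,
            skeleton_params=config.skeleton,
            mad_params=config.mad,
            image_id=image_id,
            roi_id=roi_id,
            channel=projection.channel,
        )
        records.append(record)
        tables[f"{image_id}_{roi_id}"] = segment_table(segments, config.mad)
        if out_dir is not None and config.save_intermediates:
            write_mask(skel.skeleton, out_dir / f"{image_id}_{roi_id}_skeleton.tif")
    return records, tables


def run_pipeline(config: RunConfig) -> list[MetricsRecord]:
    """Run the full pipeline for every input file in the configuration.

    Each input is read, projected, and each channel processed
    independently; per-image failures are logged and skipped so one poor
    acquisition does not abort a batch. Results are exported as an Excel
    workbook with CSV mirrors, and the effective config is saved beside
    them.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    rois = load_roi_file(config.roi_file) if config.roi_file else None

    all_records: list[MetricsRecord] = []
    all_tables: dict = {}
    for input_path in config.inputs:
        path = Path(input_path)
        try:
            stack = read_stack(
                path, pixel_size_um=config.pixel_size_um, z_step_um=config.z_step_um
            )
            channels = config.channels or list(range(stack.n_channels))
            for ch_stack in [split_channels(stack)[c] for c in channels]:
                projection = max_project(ch_stack, 0)
                image_id = f"{path.stem}_{ch_stack.channel_names[0]}"
                records, tables = process_projection(
                    projection, config, image_id, rois, out_dir
                )
                all_records.extend(records)
                all_tables.update(tables)
        except Exception:
            logger.exception("skipping %s after stage failure", path)
            continue

    if all_records:
        export_results(all_records, all_tables, out_dir / "results.xlsx")
    with open(out_dir / "run_config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, default=str)
    return all_records
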