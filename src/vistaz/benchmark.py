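"""Segmentation and skeletonisation benchmarking.

Candidate vessel masks are scored against reference masks with the Jaccard
similarity index; candidate skeletons are scored against reference
skeletons with a Q-score, the product of three [0, 1] factors:

* connectivity — penalises fragmentation via the difference in connected
  component counts, relative to the reference skeleton size;
* length — the fraction of candidate pixels within a pixel tolerance of the
  reference (no spurious centreline);
* area — the fraction of reference pixels within the tolerance of the
  candidate (no missing centreline).

``run_grid`` evaluates the full filter × skeletoniser cartesian product
(Meijering/Frangi/Sato/Jerman × Lee/Zhang by default) with shared
pre-processing, for algorithm selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .image_io import ProjectionImage
from .preprocess import PreprocessParams, apply_clahe, normalize_to_8bit, otsu_mask
from .segmentation import SegmentationParams, _STRUCT_8, refine_mask, tubularity_filter
from .skeleton_analysis import SkeletonParams, skeletonize

DEFAULT_FILTERS = ("meijering", "frangi", "sato", "jerman")
DEFAULT_METHODS = ("lee", "zhang")


@dataclass
class BenchmarkResult:
    filter_name: str
    skeleton_method: str
    jaccard: float
    q_connectivity: float = 0.0
    q_length: float = 0.0
    q_area: float = 0.0
    q_score: float = 0.0


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Jaccard similarity |A ∩ B| / |A ∪ B| of two binary masks.

    Two empty masks are identical sets, scored 1.0 with a warning.
    """
    a = np.asarray(getattr(mask_a, "pixels", mask_a), dtype=bool)
    b = np.asarray(getattr(mask_b, "pixels", mask_b), dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        warnings.warn("both masks empty; Jaccard defined as 1.0", stacklevel=2)
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def _count_components(mask: np.ndarray) -> int:
    return int(ndimage.label(mask, structure=_STRUCT_8)[1])


def _within_tolerance(pixels_of: np.ndarray, near: np.ndarray, tol: int) -> float:
    """Fraction of ``pixels_of`` lying within Euclidean distance tol of ``near``."""
    n = int(pixels_of.sum())
    if n == 0:
        return 0.0
    if not near.any():
        return 0.0
    dist = ndimage.distance_transform_edt(~near)
    return float(((dist <= tol) & pixels_of).sum() / n)


def q_score(
    candidate: np.ndarray,
    reference: np.ndarray,
    tolerance_px: int = 2,
    filter_name: str = "",
    skeleton_method: str = "",
) -> BenchmarkResult:
    """Skeleton quality Q = connectivity × length × area against a reference."""
    cand = np.asarray(getattr(candidate, "skeleton", candidate), dtype=bool)
    ref = np.asarray(getattr(reference, "skeleton", reference), dtype=bool)
    if cand.shape != ref.shape:
        raise ValueError("candidate and reference shapes differ")
    n_ref = int(ref.sum())
    if n_ref == 0:
        raise ValueError("reference skeleton is empty")
    conn = 1.0 - min(1.0, abs(_count_components(cand) - _count_components(ref)) / n_ref)
    length = _within_tolerance(cand, ref, tolerance_px)
    area = _within_tolerance(ref, cand, tolerance_px)
    return BenchmarkResult(
        filter_name=filter_name,
        skeleton_method=skeleton_method,
        jaccard=0.0,
        q_connectivity=conn,
        q_length=length,
        q_area=area,
        q_score=conn * length * area,
    )


def run_grid(
    image: ProjectionImage,
    reference_mask: np.ndarray,
    reference_skeleton: np.ndarray,
    filters: tuple[str, ...] = DEFAULT_FILTERS,
    methods: tuple[str, ...] = DEFAULT_METHODS,
    preprocess_params: PreprocessParams | None = None,
    segmentation_params: SegmentationParams | None = None,
    tolerance_px: int = 2,
) -> list[BenchmarkResult]:
    """Evaluate every filter × skeletoniser combination on one image.

    Pre-processing (8-bit normalisation, CLAHE, Otsu) is shared across the
    grid; each filter produces its own refined mask scored by Jaccard, and
    each skeletonisation of that mask is scored by Q against the reference.
    Results are sorted by Q-score then Jaccard, descending; ties keep the
    grid order, so repeated runs are identical.
    """
    ref_mask = np.asarray(getattr(reference_mask, "pixels", reference_mask), dtype=bool)
    ref_skel = np.asarray(getattr(reference_skeleton, "skeleton", reference_skeleton), dtype=bool)
    if ref_mask.shape != image.shape or ref_skel.shape != image.shape:
        raise ValueError("references must match the image shape")
    pp = preprocess_params or PreprocessParams()
    sp = segmentation_params or SegmentationParams()
    img8 = normalize_to_8bit(image)
    enhanced = apply_clahe(img8, pp)
    otsu = otsu_mask(enhanced if pp.otsu_on_enhanced else img8)

    results: list[BenchmarkResult] = []
    for filt in filters:
        fparams = replace(sp, filter_name=filt)
        response = tubularity_filter(enhanced, fparams)
        mask = refine_mask(response, otsu, fparams)
        jac = jaccard(mask.pixels, ref_mask)
        for method in methods:
            skel = skeletonize(mask, SkeletonParams(method=method))
            res = q_score(
                skel.skeleton, ref_skel, tolerance_px, filter_name=filt, skeleton_method=method
            )
            res.jaccard = jac
            results.append(res)
    results.sort(key=lambda r: (-r.q_score, -r.jaccard))
    return results
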