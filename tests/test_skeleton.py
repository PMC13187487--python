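"""Skeletonisation, branchpoint detection/filtering, segment decomposition
and distance-transform diameter estimation."""

import numpy as np
import pytest
from scipy import ndimage

from vistaz import (
    SkeletonGraph,
    SkeletonParams,
    VesselMask,
    decompose_segments,
    detect_branchpoints,
    estimate_diameters,
    filter_branchpoints,
    network_metrics,
    skeletonize,
    vessel_density,
)


def plus_skeleton(arm=10, size=25):
    """Plus-shaped skeleton: centre pixel with 4 arms of `arm` pixels each."""
    c = size // 2
    sk = np.zeros((size, size), bool)
    sk[c, c - arm : c + arm + 1] = True
    sk[c - arm : c + arm + 1, c] = True
    return sk


def graph_from(sk):
    g = SkeletonGraph(sk)
    return detect_branchpoints(g)


class TestSkeletonize:
    @pytest.mark.parametrize("method", ["lee", "zhang"])
    def test_thin_line_is_fixed_point(self, method):
        mask = np.zeros((20, 20), bool)
        mask[10, 3:17] = True
        out = skeletonize(VesselMask(mask), SkeletonParams(method=method))
        np.testing.assert_array_equal(out.skeleton, mask)

    def test_empty_mask_gives_empty_skeleton(self):
        out = skeletonize(VesselMask(np.zeros((10, 10), bool)))
        assert out.n_pixels == 0

    def test_filled_square_reduces_to_small_connected_core(self):
        mask = np.zeros((15, 15), bool)
        mask[4:11, 4:11] = True  # 7×7 square
        out = skeletonize(VesselMask(mask))
        assert 1 <= out.n_pixels <= 13
        _, n = ndimage.label(out.skeleton, structure=np.ones((3, 3)))
        assert n == 1

    @pytest.mark.parametrize("method", ["lee", "zhang"])
    def test_bar_skeleton_is_single_path_spanning_bar(self, method):
        mask = np.zeros((20, 70), bool)
        mask[8:13, 10:60] = True  # 50×5 bar
        out = skeletonize(VesselMask(mask), SkeletonParams(method=method))
        labelled, n = ndimage.label(out.skeleton, structure=np.ones((3, 3)))
        assert n == 1
        xs = np.argwhere(out.skeleton)[:, 1]
        assert xs.min() <= 13 and xs.max() >= 56  # endpoints near short edges

    def test_skeleton_subset_of_mask(self, grid_phantom):
        mask = VesselMask(grid_phantom.true_mask)
        out = skeletonize(mask)
        assert not (out.skeleton & ~mask.pixels).any()

    def test_zhang_skeleton_has_no_2x2_blocks(self, grid_phantom):
        out = skeletonize(VesselMask(grid_phantom.true_mask), SkeletonParams(method="zhang"))
        s = out.skeleton.astype(int)
        blocks = s[:-1, :-1] + s[1:, :-1] + s[:-1, 1:] + s[1:, 1:]
        assert not (blocks == 4).any()


class TestDetectBranchpoints:
    def test_plus_has_one_branchpoint_four_endpoints(self):
        g = graph_from(plus_skeleton())
        assert len(g.branchpoints_raw) == 1
        assert g.branchpoints_raw[0] == (12, 12)
        assert len(g.endpoints) == 4

    def test_straight_line_has_no_branchpoints_two_endpoints(self):
        sk = np.zeros((10, 20), bool)
        sk[5, 2:18] = True
        g = graph_from(sk)
        assert g.branchpoints_raw == []
        assert len(g.endpoints) == 2

    def test_t_junction_detected_by_default_but_not_strict(self):
        sk = np.zeros((15, 15), bool)
        sk[7, 2:13] = True
        sk[2:8, 7] = True  # T: centre (7,7) has 3 neighbours
        g = SkeletonGraph(sk)
        default = detect_branchpoints(g, SkeletonParams())
        assert (7, 7) in default.branchpoints_raw
        strict = detect_branchpoints(
            SkeletonGraph(sk), SkeletonParams(strict_branch_neighbours=True)
        )
        assert (7, 7) not in strict.branchpoints_raw


class TestFilterBranchpoints:
    def _graph_with_points(self, pts):
        g = SkeletonGraph(np.zeros((200, 200), bool))
        g.branchpoints_raw = pts
        return g

    def test_close_pair_keeps_raster_first(self):
        g = self._graph_with_points([(10, 10), (10, 20)])  # 10 px apart
        out = filter_branchpoints(g, SkeletonParams(min_branch_dist_px=30))
        assert out.branchpoints_filtered == [(10, 10)]

    def test_distant_pair_keeps_both(self):
        g = self._graph_with_points([(10, 10), (10, 50)])  # 40 px apart
        out = filter_branchpoints(g, SkeletonParams(min_branch_dist_px=30))
        assert len(out.branchpoints_filtered) == 2

    def test_empty_set(self):
        out = filter_branchpoints(self._graph_with_points([]))
        assert out.branchpoints_filtered == []

    def test_retained_pairwise_distances_and_subset(self, rng):
        # exhaustive assertion over many random sets
        for _ in range(200):
            pts = [tuple(p) for p in rng.integers(0, 200, size=(rng.integers(1, 30), 2))]
            g = self._graph_with_points(pts)
            out = filter_branchpoints(g, SkeletonParams(min_branch_dist_px=30))
            kept = out.branchpoints_filtered
            assert set(kept) <= set(pts)
            arr = np.asarray(kept, float)
            for i in range(len(kept)):
                for j in range(i + 1, len(kept)):
                    assert np.hypot(*(arr[i] - arr[j])) >= 30

    def test_deterministic(self, rng):
        pts = [tuple(p) for p in rng.integers(0, 100, size=(20, 2))]
        a = filter_branchpoints(self._graph_with_points(list(pts)))
        b = filter_branchpoints(self._graph_with_points(list(reversed(pts))))
        assert a.branchpoints_filtered == b.branchpoints_filtered


class TestDecomposeSegments:
    def test_plus_decomposes_into_four_equal_arms(self):
        g = graph_from(plus_skeleton(arm=10))
        segments = decompose_segments(g)
        assert len(segments) == 4
        assert all(s.length_px == 10 for s in segments)

    def test_line_is_single_segment(self):
        sk = np.zeros((10, 30), bool)
        sk[5, 2:27] = True
        segments = decompose_segments(graph_from(sk))
        assert len(segments) == 1
        assert segments[0].length_px == 25

    def test_empty_skeleton(self):
        assert decompose_segments(graph_from(np.zeros((5, 5), bool))) == []

    def test_decomposition_conserves_pixels(self, grid_phantom):
        g = graph_from(grid_phantom.true_skeleton)
        segments = decompose_segments(g)
        total = sum(s.length_px for s in segments) + len(g.branchpoints_raw)
        assert total == g.n_pixels


class TestEstimateDiameters:
    def _segments_for(self, mask, skeleton):
        g = graph_from(skeleton)
        return estimate_diameters(VesselMask(mask), decompose_segments(g))

    def test_straight_band_diameter_within_1px(self):
        mask = np.zeros((30, 60), bool)
        mask[13:18, :] = True  # width 5, full-width band (no end effects)
        sk = np.zeros_like(mask)
        sk[15, 10:50] = True
        segs = self._segments_for(mask, sk)
        assert abs(segs[0].mean_diameter_px - 5) <= 1

    def test_single_pixel_mask(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 4] = True
        segs = self._segments_for(mask, mask)
        assert segs[0].diameters_px[0] == pytest.approx(2.0)

    def test_disc_centre_diameter(self):
        yy, xx = np.mgrid[0:31, 0:31]
        mask = (yy - 15) ** 2 + (xx - 15) ** 2 <= 10**2
        sk = np.zeros_like(mask)
        sk[15, 15] = True
        segs = self._segments_for(mask, sk)
        assert abs(segs[0].mean_diameter_px - 20) <= 2  # 2×EDT ≈ 22 at centre

    def test_matches_brute_force_nearest_background(self, rng):
        mask = ndimage.binary_dilation(rng.random((40, 40)) > 0.9, iterations=2)
        skeleton = np.zeros_like(mask)
        fg = np.argwhere(mask)
        pick = fg[rng.choice(len(fg), size=min(15, len(fg)), replace=False)]
        skeleton[pick[:, 0], pick[:, 1]] = True
        segs = self._segments_for(mask, skeleton)
        bg = np.argwhere(~mask)
        for seg in segs:
            for (y, x), d in zip(seg.pixel_coords, seg.diameters_px):
                nearest = np.sqrt(((bg - [y, x]) ** 2).sum(axis=1)).min()
                assert d == pytest.approx(2 * nearest)

    def test_skeleton_outside_mask_raises(self):
        mask = np.zeros((10, 10), bool)
        mask[2:5, 2:5] = True
        sk = np.zeros_like(mask)
        sk[8, 8] = True
        with pytest.raises(ValueError, match="outside mask"):
            self._segments_for(mask, sk)


class TestNetworkMetrics:
    def test_all_vessel_mask_has_density_one(self):
        mask = VesselMask(np.ones((48, 48), bool))
        g = graph_from(np.zeros((48, 48), bool))
        net = network_metrics(g, [], mask, px_per_um=1.2)
        assert net["vessel_density"] == pytest.approx(1.0)
        assert net["tile_side_px"] == 12  # round(√100 µm² × 1.2 px/µm)

    def test_empty_skeleton_all_zero(self):
        mask = VesselMask(np.zeros((48, 48), bool))
        g = graph_from(np.zeros((48, 48), bool))
        g = filter_branchpoints(g)
        net = network_metrics(g, [], mask, px_per_um=1.2)
        assert net["network_length_px"] == 0
        assert net["branchpoint_count"] == 0
        assert net["mean_diameter_px"] == 0

    def test_tile_side_below_one_pixel_rejected(self):
        mask = VesselMask(np.zeros((48, 48), bool))
        g = graph_from(np.zeros((48, 48), bool))
        with pytest.raises(ValueError):
            network_metrics(g, [], mask, px_per_um=0.05,
                            params=SkeletonParams(density_tile_um2=1.0))

    def test_translation_invariance_up_to_tile_phase(self, grid_phantom):
        from vistaz import analyze_mask

        base = grid_phantom.true_mask
        h, w = base.shape
        shifted = np.zeros_like(base)
        shifted[7:, 3:] = base[: h - 7, : w - 3]
        rec_a, _, _ = analyze_mask(VesselMask(base), px_per_um=1.2, z_depth_um=100)
        rec_b, _, _ = analyze_mask(VesselMask(shifted), px_per_um=1.2, z_depth_um=100)
        assert rec_a.network_length_px == rec_b.network_length_px
        assert rec_a.branchpoint_count == rec_b.branchpoint_count
        assert rec_a.mean_diameter_px == pytest.approx(rec_b.mean_diameter_px)
        assert rec_a.vessel_density == pytest.approx(rec_b.vessel_density, abs=0.02)


def test_vessel_density_counts_full_tiles_only():
    mask = np.zeros((25, 25), bool)
    mask[:12, :12] = True  # exactly the first 12×12 tile
    assert vessel_density(mask, 12) == pytest.approx(0.25)  # 1 of 4 tiles full
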