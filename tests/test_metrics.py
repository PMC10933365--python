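import numpy as np
import pytest

from angioquant.binarize import BinaryMap
from angioquant.errors import ValidationError
from angioquant.graph import (
    GraphEdge,
    SkeletonMap,
    VesselGraph,
    build_graph,
    classify_elements,
    diameter_map,
    skeletonize,
)
from angioquant.metrics import (
    box_count,
    branchpoint_density,
    compile_metrics,
    diameter_stats,
    fractal_dimension,
    length_stats,
    tortuosity_stats,
    vessel_area_density,
    vessel_length_density,
)
from angioquant.phantom import arc_phantom, cross_phantom, square_calibration, straight_bar_phantom
from angioquant.regions import nine_squares, whole_image

PITCH = 3.0


def bmap(mask, pitch=PITCH):
    mask = np.asarray(mask, bool)
    return BinaryMap(mask, "synthetic", {}, square_calibration(mask.shape[0], pitch))


def smap(mask, pitch=PITCH):
    mask = np.asarray(mask, bool)
    return SkeletonMap(mask, square_calibration(mask.shape[0], pitch))


def manual_graph(edges, n=64, pitch=PITCH):
    return VesselGraph(nodes=[], edges=edges, calibration=square_calibration(n, pitch))


def manual_edge(length_mm, chord_mm=None, path=None):
    if path is None:
        path = np.array([[1, 1], [1, 2]])
    return GraphEdge(
        node_a=None, node_b=None, path=np.asarray(path),
        path_length_mm=length_mm,
        chord_length_mm=length_mm if chord_mm is None else chord_mm,
        cls="isolated",
    )


class TestDensities:
    def test_checkerboard_half(self):
        m = np.indices((32, 32)).sum(0) % 2 == 0
        assert vessel_area_density(bmap(m), np.ones((32, 32), bool)) == pytest.approx(50.0)

    def test_all_vessel(self):
        m = np.ones((16, 16), bool)
        assert vessel_area_density(bmap(m), m) == pytest.approx(100.0)

    def test_counting(self):
        m = np.zeros((10, 10), bool)
        m.flat[:37] = True
        assert vessel_area_density(bmap(m), np.ones((10, 10), bool)) == pytest.approx(37.0)

    def test_empty_region_rejected(self):
        with pytest.raises(ValidationError):
            vessel_area_density(bmap(np.ones((8, 8), bool)), np.zeros((8, 8), bool))

    def test_vld_line(self):
        m = np.zeros((100, 100), bool)
        m[50, :] = True
        assert vessel_length_density(smap(m), np.ones((100, 100), bool)) == pytest.approx(1.0)

    def test_vld_empty_skeleton(self):
        assert vessel_length_density(
            smap(np.zeros((10, 10), bool)), np.ones((10, 10), bool)
        ) == 0.0

    def test_vld_never_exceeds_vad(self, clean_pipeline_products):
        _, _, bin_map, skel, _, _ = clean_pipeline_products
        region = np.ones(bin_map.mask.shape, bool)
        assert vessel_length_density(skel, region) <= vessel_area_density(bin_map, region)


class TestLengthStats:
    def test_straight_edge_length(self):
        m = np.zeros((110, 110), bool)
        m[55, 5:105] = True  # 100 px -> 99 axial steps
        g = build_graph(smap(m))
        total, mean, med = length_stats(g, np.ones((110, 110), bool))
        assert 0.297 <= total <= 0.300
        assert mean == pytest.approx(total)

    def test_two_edges_mean_median(self):
        g = manual_graph([manual_edge(0.1), manual_edge(0.3)])
        # region covers the tiny dummy paths
        region = np.ones((64, 64), bool)
        total, mean, med = length_stats(g, region)
        assert total == pytest.approx(0.4)
        assert mean == pytest.approx(0.2)
        assert med == pytest.approx(0.2)

    def test_edge_clipped_to_region(self):
        m = np.zeros((110, 110), bool)
        m[55, 5:105] = True
        g = build_graph(smap(m))
        half = np.zeros((110, 110), bool)
        half[:, :55] = True
        total_half, _, _ = length_stats(g, half)
        total_full, _, _ = length_stats(g, np.ones((110, 110), bool))
        assert total_half == pytest.approx(total_full / 2, rel=0.05)

    def test_no_edges_flagged(self):
        g = manual_graph([])
        total, mean, med = length_stats(g, np.ones((64, 64), bool))
        assert total == 0.0 and mean is None and med is None


class TestDiameterStats:
    def test_uniform_bar(self):
        m = np.zeros((30, 30), bool)
        m[10:17, :] = True
        b = bmap(m)
        sk = skeletonize(b)
        d = diameter_map(b, sk)
        mean, med = diameter_stats(d, np.ones((30, 30), bool))
        assert mean == pytest.approx(21.0)
        assert med == pytest.approx(21.0)

    def test_median_of_two_bar_populations_matches_multiset(self):
        m = np.zeros((40, 40), bool)
        m[5:8, :] = True   # width 3 -> 9 um
        m[20:25, :] = True  # width 5 -> 15 um
        b = bmap(m)
        sk = skeletonize(b)
        d = diameter_map(b, sk)
        mean, med = diameter_stats(d, np.ones((40, 40), bool))
        vals = d.values[sk.mask]
        assert med == pytest.approx(np.median(vals))
        assert mean == pytest.approx(vals.mean())

    def test_none_when_region_misses_skeleton(self):
        m = np.zeros((20, 20), bool)
        m[10, :] = True
        b = bmap(m)
        d = diameter_map(b, skeletonize(b))
        region = np.zeros((20, 20), bool)
        region[0, 0] = True
        assert diameter_stats(d, region) == (None, None)


class TestBranchpointDensity:
    def test_plus_sign_value(self):
        cross, _ = cross_phantom(10, grid_px=41)
        sk = skeletonize(cross)
        g = classify_elements(build_graph(sk))
        bd = branchpoint_density(g, np.ones((41, 41), bool))
        # 1 node over 4 arms x 9 steps x 3 um = 0.108 mm
        assert bd == pytest.approx(1 / 0.108, rel=1e-6)

    def test_straight_vessel_zero(self):
        m = np.zeros((40, 40), bool)
        m[20, 5:35] = True
        g = classify_elements(build_graph(smap(m)))
        assert branchpoint_density(g, np.ones((40, 40), bool)) == 0.0

    def test_halving_with_doubled_pitch(self):
        cross, _ = cross_phantom(10, grid_px=41)
        g1 = classify_elements(build_graph(skeletonize(cross)))
        cross2, _ = cross_phantom(10, grid_px=41, pitch_um=6.0)
        g2 = classify_elements(build_graph(skeletonize(cross2)))
        region = np.ones((41, 41), bool)
        assert branchpoint_density(g2, region) == pytest.approx(
            branchpoint_density(g1, region) / 2
        )


class TestTortuosity:
    def test_straight_edge_unity(self):
        m = np.zeros((50, 50), bool)
        m[25, 5:45] = True
        g = build_graph(smap(m))
        assert tortuosity_stats(g, np.ones((50, 50), bool)) == pytest.approx(1.0, abs=1e-6)

    def test_semicircular_arc(self):
        arc, truth = arc_phantom(50)
        sk = skeletonize(arc)
        g = build_graph(sk)
        tau = tortuosity_stats(g, np.ones(arc.mask.shape, bool))
        assert tau == pytest.approx(np.pi / 2, abs=0.05)

    def test_mean_of_edges(self):
        g = manual_graph([manual_edge(1.0, 1.0), manual_edge(1.2, 1.0)])
        assert tortuosity_stats(g, np.ones((64, 64), bool)) == pytest.approx(1.1)

    def test_loops_excluded(self):
        g = manual_graph([manual_edge(1.0, 0.0), manual_edge(1.2, 1.0)])
        assert tortuosity_stats(g, np.ones((64, 64), bool)) == pytest.approx(1.2)


def brute_force_box_count(mask, size):
    count = 0
    for r0 in range(0, mask.shape[0], size):
        for c0 in range(0, mask.shape[1], size):
            if mask[r0:r0 + size, c0:c0 + size].any():
                count += 1
    return count


class TestFractalDimension:
    def test_straight_line_dimension_one(self):
        m = np.zeros((256, 256), bool)
        m[128, :] = True
        fd = fractal_dimension(smap(m), np.ones((256, 256), bool))
        assert fd == pytest.approx(1.0, abs=0.05)

    def test_filled_square_dimension_two(self):
        m = np.ones((256, 256), bool)
        fd = fractal_dimension(smap(m), np.ones((256, 256), bool))
        assert fd == pytest.approx(2.0, abs=0.05)

    def test_too_few_pixels(self):
        m = np.zeros((64, 64), bool)
        m[10, 10] = True
        with pytest.raises(ValidationError):
            fractal_dimension(smap(m), np.ones((64, 64), bool))

    @pytest.mark.parametrize("size", [2, 4, 8, 16])
    def test_box_count_matches_brute_force(self, size):
        rng = np.random.default_rng(13)
        m = rng.random((100, 100)) > 0.9
        assert box_count(m, size) == brute_force_box_count(m, size)


class TestCompile:
    def test_whole_image_only(self, clean_pipeline_products):
        _, _, bin_map, skel, dmap, graph = clean_pipeline_products
        recs = compile_metrics(bin_map, skel, dmap, graph, whole_image(bin_map.mask.shape))
        assert [r.region_name for r in recs] == ["whole image", "whole image"]

    def test_deterministic(self, clean_pipeline_products):
        _, _, bin_map, skel, dmap, graph = clean_pipeline_products
        rs = nine_squares(bin_map.mask.shape)
        a = compile_metrics(bin_map, skel, dmap, graph, rs)
        b = compile_metrics(bin_map, skel, dmap, graph, rs)
        assert [(r.region_name, r.vad_percent, r.total_vl_mm) for r in a] == [
            (r.region_name, r.vad_percent, r.total_vl_mm) for r in b
        ]

    def test_nine_square_area_additivity(self, clean_pipeline_products):
        _, _, bin_map, skel, dmap, graph = clean_pipeline_products
        rs = nine_squares(bin_map.mask.shape)
        recs = compile_metrics(bin_map, skel, dmap, graph, rs)
        whole = recs[0]
        total_px = bin_map.mask.size
        acc = sum(r.vad_percent * r_.mask.sum() for r, r_ in zip(recs[1:], rs.regions))
        assert acc / total_px == pytest.approx(whole.vad_percent, abs=1e-9)

    def test_invariants_on_phantom(self, clean_pipeline_products):
        _, _, bin_map, skel, dmap, graph = clean_pipeline_products
        recs = compile_metrics(bin_map, skel, dmap, graph, whole_image(bin_map.mask.shape))
        r = recs[0]
        assert 0 <= r.vld_percent <= r.vad_percent <= 100
        assert r.tortuosity_mean >= 1.0
        assert 0 <= r.fd <= 2.0
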