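import numpy as np
import pytest

from angioquant.binarize import BinaryMap
from angioquant.errors import ConsistencyError, ValidationError
from angioquant.graph import (
    SkeletonMap,
    build_graph,
    classify_elements,
    diameter_map,
    prune_twigs,
    skeletonize,
)
from angioquant.metrics import length_stats
from angioquant.phantom import square_calibration

PITCH = 3.0


def bmap(mask, pitch=PITCH):
    mask = np.asarray(mask, bool)
    return BinaryMap(mask, "synthetic", {}, square_calibration(mask.shape[0], pitch))


def smap(mask, pitch=PITCH):
    mask = np.asarray(mask, bool)
    return SkeletonMap(mask, square_calibration(mask.shape[0], pitch))


def plus_sign(n=41, arm=10):
    m = np.zeros((n, n), bool)
    c = n // 2
    m[c, c - arm: c + arm + 1] = True
    m[c - arm: c + arm + 1, c] = True
    return m


def brute_force_graph_counts(mask):
    """Independent graph-decomposition oracle by pure-python flood fill.

    Nodes: connected components of {skeleton pixels with >= 3 8-neighbours}
    merged through a 1-px halo, plus pixels with exactly one neighbour.
    Edges: connected components of the remaining path pixels, plus directly
    adjacent distinct junction clusters.
    """
    pix = set(map(tuple, np.argwhere(mask)))
    nbr = {
        p: [q for q in [(p[0] + dr, p[1] + dc)
                        for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                        if (dr, dc) != (0, 0)] if q in pix]
        for p in pix
    }
    branch = {p for p in pix if len(nbr[p]) >= 3}
    ends = {p for p in pix if len(nbr[p]) == 1}

    def components(points, adjacency):
        seen, comps = set(), []
        for start in sorted(points):
            if start in seen:
                continue
            comp, stack = [], [start]
            seen.add(start)
            while stack:
                p = stack.pop()
                comp.append(p)
                for q in adjacency(p):
                    if q in points and q not in seen:
                        seen.add(q)
                        stack.append(q)
            comps.append(comp)
        return comps

    def halo_adj(p):
        # dilating each cluster by 1 px and labelling 8-connected merges
        # junction pixels up to a Chebyshev distance of 3
        return [
            (p[0] + dr, p[1] + dc)
            for dr in range(-3, 4) for dc in range(-3, 4)
            if max(abs(dr), abs(dc)) in (1, 2, 3)
        ]

    clusters = components(branch, halo_adj)
    path_pixels = pix - branch
    paths = components(path_pixels, lambda p: nbr[p])
    # direct cluster-cluster adjacency without intervening path pixels
    label_of = {}
    for i, comp in enumerate(clusters):
        for p in comp:
            label_of[p] = i
    adj_pairs = set()
    for p in branch:
        for q in nbr[p]:
            if q in branch and label_of[p] != label_of[q]:
                adj_pairs.add((min(label_of[p], label_of[q]), max(label_of[p], label_of[q])))
    # endpoints are path-component ends not adjacent to any cluster
    n_endpoints = 0
    for comp in paths:
        comp_set = set(comp)
        free_ends = [p for p in comp if len([q for q in nbr[p] if q in comp_set]) <= 1]
        if not free_ends and len(comp) > 2:  # cycle
            continue
        for p in (free_ends if len(comp) > 1 else comp):
            if not any(q in branch for q in nbr[p]):
                n_endpoints += 1
    return {
        "branch_nodes": len(clusters),
        "edges": len(paths) + len(adj_pairs),
        "endpoints": n_endpoints,
    }


class TestSkeletonize:
    def test_single_pixel_preserved(self):
        m = np.zeros((9, 9), bool)
        m[4, 4] = True
        assert skeletonize(bmap(m)).mask.sum() == 1

    def test_bar_thins_to_centre_row(self):
        m = np.zeros((104, 104), bool)
        m[50:55, 2:102] = True
        sk = skeletonize(bmap(m)).mask
        rows = np.unique(np.argwhere(sk)[:, 0])
        assert len(rows) == 1 and 50 <= rows[0] <= 54
        assert 96 <= sk.sum() <= 100

    def test_disc_collapses_to_centre(self):
        m = np.zeros((31, 31), bool)
        yy, xx = np.mgrid[0:31, 0:31]
        m[(yy - 15) ** 2 + (xx - 15) ** 2 <= 100] = True
        sk = skeletonize(bmap(m)).mask
        assert sk.sum() <= 5
        rr, cc = np.nonzero(sk)
        assert np.all(np.hypot(rr - 15, cc - 15) < 4)

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning):
            sk = skeletonize(bmap(np.zeros((8, 8), bool)))
        assert not sk.mask.any()

    def test_topology_preserved(self, clean_phantom):
        from scipy import ndimage as ndi

        img, truth = clean_phantom
        b = bmap(truth.vessel_mask)
        sk = skeletonize(b)
        s8 = np.ones((3, 3), int)
        # components of >= 2 px survive thinning one-to-one
        _, n_mask = ndi.label(truth.vessel_mask, structure=s8)
        _, n_skel = ndi.label(sk.mask, structure=s8)
        assert n_skel == n_mask


class TestDiameterMap:
    def test_bar_width_seven(self):
        m = np.zeros((30, 30), bool)
        m[10:17, :] = True  # spans edge to edge: no end effects
        b = bmap(m)
        sk = skeletonize(b)
        d = diameter_map(b, sk)
        np.testing.assert_allclose(d.values[sk.mask], 21.0)

    def test_single_pixel_line(self):
        m = np.zeros((20, 20), bool)
        m[10, :] = True
        b = bmap(m)
        d = diameter_map(b, skeletonize(b))
        np.testing.assert_allclose(d.values[m], 3.0)

    def test_disc_centre_diameter(self):
        r = 10
        m = np.zeros((31, 31), bool)
        yy, xx = np.mgrid[0:31, 0:31]
        m[(yy - 15) ** 2 + (xx - 15) ** 2 <= r * r] = True
        b = bmap(m)
        sk = skeletonize(b)
        d = diameter_map(b, sk)
        centre_d = d.values[sk.mask].max()
        assert centre_d == pytest.approx((2 * r - 1) * PITCH, abs=PITCH)

    def test_skeleton_outside_mask_rejected(self):
        m = np.zeros((10, 10), bool)
        m[5, 5] = True
        s = np.zeros((10, 10), bool)
        s[2, 2] = True
        with pytest.raises(ConsistencyError):
            diameter_map(bmap(m), smap(s))

    def test_values_at_least_pitch(self, clean_pipeline_products):
        _, _, bin_map, skel, dmap, _ = clean_pipeline_products
        vals = dmap.values[skel.mask]
        assert vals.min() >= bin_map.calibration.um_per_px - 1e-9


class TestBuildGraph:
    def test_plus_sign(self):
        g = classify_elements(build_graph(smap(plus_sign())))
        assert len(g.branchpoints()) == 1
        assert sum(1 for n in g.nodes if n.kind == "endpoint") == 4
        assert len(g.edges) == 4
        assert all(e.cls == "branch" for e in g.edges)
        # arms of 10 px = 9 geodesic steps each at 3 um pitch
        for e in g.edges:
            assert e.path_length_mm == pytest.approx(0.027, abs=1e-9)

    def test_straight_path(self):
        m = np.zeros((60, 60), bool)
        m[30, 5:55] = True
        g = classify_elements(build_graph(smap(m)))
        assert len(g.branchpoints()) == 0
        assert len(g.edges) == 1
        assert g.edges[0].cls == "isolated"
        assert g.edges[0].tortuosity == pytest.approx(1.0)

    def test_h_shape(self):
        m = np.zeros((40, 40), bool)
        m[5:26, 10] = True
        m[5:26, 20] = True
        m[15, 10:21] = True
        g = classify_elements(build_graph(smap(m)))
        assert len(g.branchpoints()) == 2
        assert len(g.edges) == 5
        assert sorted(e.cls for e in g.edges) == ["branch"] * 4 + ["segment"]

    def test_pixel_bijection(self, clean_pipeline_products):
        _, _, _, skel, _, graph = clean_pipeline_products
        covered = set()
        for e in graph.edges:
            covered.update(map(tuple, e.path))
        for n in graph.nodes:
            covered.update(n.pixels)
        skeleton = set(map(tuple, np.argwhere(skel.mask)))
        assert covered == skeleton

    def test_path_at_least_chord(self, clean_pipeline_products):
        _, _, _, _, _, graph = clean_pipeline_products
        for e in graph.edges:
            assert e.path_length_mm >= e.chord_length_mm - 1e-9

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = np.zeros((64, 64), bool)
        for _ in range(6):
            r0, c0 = rng.integers(4, 60, 2)
            r1, c1 = rng.integers(4, 60, 2)
            npts = max(abs(r1 - r0), abs(c1 - c0)) + 1
            rr = np.linspace(r0, r1, npts).round().astype(int)
            cc = np.linspace(c0, c1, npts).round().astype(int)
            m[rr, cc] = True
        sk = skeletonize(bmap(m))  # re-thin to unit width
        g = build_graph(sk)
        oracle = brute_force_graph_counts(sk.mask)
        assert len([n for n in g.nodes if n.kind == "branchpoint"]) == oracle["branch_nodes"]
        assert len(g.edges) == oracle["edges"]
        assert len([n for n in g.nodes if n.kind == "endpoint"]) == oracle["endpoints"]


class TestPruneTwigs:
    def test_twig_zero_is_identity(self):
        g = classify_elements(build_graph(smap(plus_sign())))
        g2, _ = prune_twigs(g, 0)
        assert len(g2.edges) == len(g.edges)
        assert g2.total_length_mm == pytest.approx(g.total_length_mm)

    def test_h_with_short_legs(self):
        # legs (branches) below the threshold go; the crossbar (a segment)
        # stays and is re-classified isolated without being re-tested
        m = np.zeros((40, 40), bool)
        m[10:21, 8] = True
        m[10:21, 28] = True
        m[15, 8:29] = True
        g = classify_elements(build_graph(smap(m)))
        g2, sk2 = prune_twigs(g, 8)
        assert len(g2.edges) == 1
        assert g2.edges[0].cls == "isolated"
        assert len(g2.branchpoints()) == 0

    def test_plus_arms_retained_at_default_twig(self):
        g = classify_elements(build_graph(smap(plus_sign(arm=10))))
        g2, _ = prune_twigs(g, 8)
        assert len(g2.edges) == 4  # 9-step arms are >= 8 px

    def test_negative_twig_rejected(self):
        g = build_graph(smap(plus_sign()))
        with pytest.raises(ValidationError):
            prune_twigs(g, -1)

    def test_total_length_monotone_in_twig(self, clean_pipeline_products):
        _, _, _, _, dmap, graph = clean_pipeline_products
        region = np.ones(dmap.values.shape, bool)
        totals = []
        for twig in (0, 4, 8, 12, 16, 20):
            g, _ = prune_twigs(graph, twig, dmap)
            totals.append(length_stats(g, region)[0])
        assert all(b <= a + 1e-9 for a, b in zip(totals, totals[1:]))
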