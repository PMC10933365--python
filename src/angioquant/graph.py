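"""Skeleton-graph representation of the vessel network.

The binary vessel map is thinned to 1-px-wide centrelines, per-pixel vessel
diameters are read off the Euclidean distance transform, and the skeleton is
converted to an undirected graph:

* skeleton pixels with >= 3 8-neighbours form **branchpoint** nodes (thinning
  emits 2-3 px junction clumps, so adjacent such pixels are merged into one
  node — counting each pixel separately would inflate branchpoint density);
* pixels with exactly one neighbour are **endpoints**;
* maximal pixel paths between nodes become edges, each carrying its ordered
  pixel polyline, geodesic path length (1 px per axial step, √2 per diagonal,
  times the pixel pitch) and straight-line chord length.

Edges are classified by their attachment: *segment* (junction to junction),
*branch* (junction to free end), *isolated* (free at both ends).  Short
branches and isolated elements ("twigs") are usually noise — broken
binarisation, speckle — and are pruned below a length threshold, after which
the skeleton and graph are rebuilt once (no iterative re-pruning, so a
segment that becomes isolated by losing its legs is not re-tested against the
length filter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize as _thin

from .binarize import BinaryMap
from .errors import ConsistencyError, ValidationError
from .imagery import Calibration

__all__ = [
    "SkeletonMap",
    "DiameterMap",
    "GraphNode",
    "GraphEdge",
    "VesselGraph",
    "skeletonize",
    "diameter_map",
    "build_graph",
    "classify_elements",
    "prune_twigs",
]

_N8 = np.ones((3, 3), dtype=int)
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class SkeletonMap:
    """1-px-wide centreline mask."""

    mask: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class DiameterMap:
    """Per-skeleton-pixel vessel diameter in µm (0 off the skeleton)."""

    values: np.ndarray
    calibration: Calibration


@dataclass
class GraphNode:
    id: int
    kind: str  # "branchpoint" | "endpoint"
    pixel: tuple[int, int]  # representative pixel (row, col)
    pixels: list = field(default_factory=list)  # member pixels (branch clusters only)


@dataclass
class GraphEdge:
    node_a: int | None
    node_b: int | None
    path: np.ndarray  # ordered (k, 2) polyline incl. junction attach pixels
    path_length_mm: float
    chord_length_mm: float
    cls: str = "unclassified"  # "segment" | "branch" | "isolated"
    mean_diameter_um: float = float("nan")

    @property
    def tortuosity(self) -> float:
        """Arc-to-chord ratio; NaN for closed loops (zero chord)."""
        if self.chord_length_mm <= 0:
            return float("nan")
        return self.path_length_mm / self.chord_length_mm


@dataclass
class VesselGraph:
    nodes: list[GraphNode]
    edges: list[GraphEdge]
    calibration: Calibration

    def branchpoints(self) -> list[GraphNode]:
        return [n for n in self.nodes if n.kind == "branchpoint"]

    @property
    def total_length_mm(self) -> float:
        return float(sum(e.path_length_mm for e in self.edges))


def skeletonize(bin_map: BinaryMap) -> SkeletonMap:
    """Homotopic thinning to unit-width 8-connected centrelines.

    Uses Lee's thinning (the 3-D algorithm restricted to a planar image),
    which preserves the topology of the mask.  An empty mask yields an empty
    skeleton with a warning rather than an error.
    """
    if not bin_map.mask.any():
        warnings.warn("empty binary mask: skeleton is empty", stacklevel=2)
        return SkeletonMap(np.zeros_like(bin_map.mask), bin_map.calibration)
    skel = _thin(bin_map.mask, method="lee").astype(bool)
    return SkeletonMap(skel, bin_map.calibration)


def diameter_map(bin_map: BinaryMap, skel: SkeletonMap) -> DiameterMap:
    """Vessel diameter at each centreline pixel from the distance transform.

    D = (2·d_EDT − 1) · pitch, where d_EDT is the Euclidean distance (px) to
    the nearest background pixel centre.  The −1 calibrates the discrete
    transform so that a w-px-wide bar reports exactly w·pitch.  Anisotropic
    grids use the mean of the x/y pitches.
    """
    if np.any(skel.mask & ~bin_map.mask):
        raise ConsistencyError("skeleton contains pixels outside the binary mask")
    pitch = bin_map.calibration.um_per_px
    edt = ndi.distance_transform_edt(bin_map.mask)
    values = np.where(skel.mask, (2.0 * edt - 1.0) * pitch, 0.0)
    return DiameterMap(values=values, calibration=bin_map.calibration)


def _polyline_length_px(poly: np.ndarray) -> float:
    """Geodesic length of a pixel path, in pixels.

    Raw 8-connected step sums overestimate smooth curves by several percent
    (the staircase effect), so the polyline is lightly smoothed with a
    5-point moving average before measuring.  The end points are pinned, and
    a collinear (straight) path is left exactly unchanged, so axial paths
    still measure one pitch per step.
    """
    if len(poly) < 2:
        return 0.0
    pts = poly.astype(float)
    if len(pts) >= 3:
        padded = np.vstack([pts[:1], pts[:1], pts, pts[-1:], pts[-1:]])
        kernel = np.ones(5) / 5.0
        sm = np.column_stack([
            np.convolve(padded[:, 0], kernel, "valid"),
            np.convolve(padded[:, 1], kernel, "valid"),
        ])
        sm[0], sm[-1] = pts[0], pts[-1]
        pts = sm
    steps = np.diff(pts, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def _make_edge(
    poly: np.ndarray,
    node_a: int | None,
    node_b: int | None,
    pitch_mm: float,
    dmap: DiameterMap | None,
    free_ends: tuple[bool, bool] = (False, False),
) -> GraphEdge:
    path_mm = _polyline_length_px(poly) * pitch_mm
    chord_px = float(np.hypot(*(poly[0].astype(float) - poly[-1].astype(float))))
    mean_d = float("nan")
    if dmap is not None and len(poly):
        mean_d = float(dmap.values[poly[:, 0], poly[:, 1]].mean())
        # thinning erodes each free vessel end by about the local radius;
        # compensate from the distance transform (d_EDT = (D/pitch + 1)/2).
        # The chord grows by the same amount: the virtual extension runs
        # along the end direction, so tortuosity is unaffected by it.
        pitch_um = pitch_mm * 1000.0
        for is_free, end in zip(free_ends, (poly[0], poly[-1])):
            if is_free:
                edt_px = (dmap.values[end[0], end[1]] / pitch_um + 1.0) / 2.0
                ext = max(0.0, edt_px - 1.0) * pitch_mm
                path_mm += ext
                chord_px += ext / pitch_mm
    return GraphEdge(
        node_a=node_a,
        node_b=node_b,
        path=poly,
        path_length_mm=path_mm,
        chord_length_mm=chord_px * pitch_mm,
        mean_diameter_um=mean_d,
    )


def build_graph(skel: SkeletonMap, dmap: DiameterMap | None = None) -> VesselGraph:
    """Convert a unit-width skeleton into an undirected vessel graph.

    Every skeleton pixel ends up either in exactly one edge polyline or in
    exactly one branchpoint cluster (endpoint nodes reference a pixel that
    belongs to their edge's polyline).
    """
    S = skel.mask
    pitch_mm = skel.calibration.um_per_px / 1000.0
    nodes: list[GraphNode] = []
    edges: list[GraphEdge] = []
    if not S.any():
        return VesselGraph(nodes, edges, skel.calibration)

    nbr_count = ndi.correlate(S.astype(int), _N8, mode="constant") - S.astype(int)
    nbr_count[~S] = 0
    branch_px = S & (nbr_count >= 3)
    # thinning can split one anatomical junction into two >=3-degree pixels a
    # knight's move apart; cluster junction pixels through a 1-px halo so such
    # twins collapse into a single branchpoint node
    halo_lab, n_raw = ndi.label(
        ndi.binary_dilation(branch_px, structure=np.ones((3, 3), bool)), structure=_N8
    )
    cluster_lab = np.where(branch_px, halo_lab, 0)

    # in wide vessels one junction can thin into two Y-clusters several px
    # apart but still inside the junction's own footprint; when diameters are
    # known, merge clusters closer than the sum of their local vessel radii
    if dmap is not None and n_raw > 1:
        pitch_um = skel.calibration.um_per_px
        pix_by_lab: dict[int, np.ndarray] = {}
        rad_by_lab: dict[int, float] = {}
        brr, bcc = np.nonzero(branch_px)
        labs_flat = cluster_lab[brr, bcc]
        for lab in range(1, n_raw + 1):
            sel = labs_flat == lab
            pix = np.column_stack([brr[sel], bcc[sel]]).astype(float)
            pix_by_lab[lab] = pix
            rad_by_lab[lab] = float(
                dmap.values[brr[sel], bcc[sel]].max() / (2.0 * pitch_um)
            )
        parent = {lab: lab for lab in range(1, n_raw + 1)}

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        labs_sorted = sorted(pix_by_lab)
        for i, la in enumerate(labs_sorted):
            for lb in labs_sorted[i + 1:]:
                # the +2 px covers thinning displacement beyond the radii
                # at asymmetric junctions
                limit = rad_by_lab[la] + rad_by_lab[lb] + 2.0
                pa, pb = pix_by_lab[la], pix_by_lab[lb]
                d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1)
                if d2.min() <= limit * limit:
                    ra, rb = find(la), find(lb)
                    if ra != rb:
                        parent[max(ra, rb)] = min(ra, rb)
        remap = {}
        new_id = 0
        for lab in labs_sorted:
            root = find(lab)
            if root not in remap:
                new_id += 1
                remap[root] = new_id
        lut = np.zeros(n_raw + 1, dtype=int)
        for lab in labs_sorted:
            lut[lab] = remap[find(lab)]
        cluster_lab = lut[cluster_lab]
        n_clusters = new_id
    else:
        n_clusters = n_raw

    cluster_node: dict[int, int] = {}
    for lab in range(1, n_clusters + 1):
        rr, cc = np.nonzero(cluster_lab == lab)
        cy, cx = rr.mean(), cc.mean()
        rep = int(np.argmin((rr - cy) ** 2 + (cc - cx) ** 2))
        nid = len(nodes)
        nodes.append(
            GraphNode(
                id=nid,
                kind="branchpoint",
                pixel=(int(rr[rep]), int(cc[rep])),
                pixels=list(zip(rr.tolist(), cc.tolist())),
            )
        )
        cluster_node[lab] = nid

    def adjacent_clusters(px: tuple[int, int]) -> list[int]:
        r, c = px
        labs = []
        for dr, dc in _OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < S.shape[0] and 0 <= cc < S.shape[1]:
                lab = cluster_lab[rr, cc]
                if lab > 0 and lab not in labs:
                    labs.append(lab)
        return labs

    def attach_pixel(px: tuple[int, int], lab: int) -> tuple[int, int]:
        r, c = px
        best, best_d = None, np.inf
        for dr, dc in _OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < S.shape[0] and 0 <= cc < S.shape[1] and cluster_lab[rr, cc] == lab:
                d = dr * dr + dc * dc
                if d < best_d:
                    best, best_d = (rr, cc), d
        assert best is not None
        return best

    def new_endpoint(px: tuple[int, int]) -> int:
        nid = len(nodes)
        nodes.append(GraphNode(id=nid, kind="endpoint", pixel=px, pixels=[]))
        return nid

    # --- trace maximal paths on the skeleton minus junction clusters -------
    path_mask = S & ~branch_px
    path_set = set(zip(*np.nonzero(path_mask)))

    def path_neighbours(px: tuple[int, int]) -> list[tuple[int, int]]:
        r, c = px
        return [(r + dr, c + dc) for dr, dc in _OFFSETS if (r + dr, c + dc) in path_set]

    visited: set[tuple[int, int]] = set()
    comp_lab, n_comp = ndi.label(path_mask, structure=_N8)
    comp_pixels: dict[int, list[tuple[int, int]]] = {}
    for px in path_set:
        comp_pixels.setdefault(comp_lab[px], []).append(px)

    def walk(start: tuple[int, int]) -> list[tuple[int, int]]:
        """Follow the path from an end (or around a cycle) pixel by pixel."""
        order = [start]
        visited.add(start)
        cur, prev = start, None
        while True:
            nxt = [p for p in path_neighbours(cur) if p not in visited]
            if not nxt:
                break
            # prefer axial continuation when a diagonal shortcut coexists
            nxt.sort(key=lambda p: (abs(p[0] - cur[0]) + abs(p[1] - cur[1])))
            cur, prev = nxt[0], cur
            order.append(cur)
            visited.add(cur)
        return order

    for lab in range(1, n_comp + 1):
        pix = comp_pixels.get(lab, [])
        ends = [p for p in pix if len(path_neighbours(p)) <= 1]
        start = min(ends) if ends else min(pix)  # min() keeps ordering deterministic
        order = walk(start)
        is_cycle = not ends and len(order) > 2
        first, last = order[0], order[-1]
        labs_a = adjacent_clusters(first)
        labs_b = adjacent_clusters(last)
        poly = order
        if len(order) == 1:
            # single pixel: may bridge up to two clusters, or be isolated
            labs = labs_a
            a_lab = labs[0] if labs else None
            b_lab = labs[1] if len(labs) > 1 else None
        else:
            a_lab = labs_a[0] if labs_a else None
            if is_cycle:
                b_lab = a_lab  # loop closes on the same junction (or on itself)
                poly = order + [order[0]] if a_lab is None else order
            else:
                b_lab = labs_b[0] if labs_b else None
        full = []
        if a_lab is not None:
            full.append(attach_pixel(poly[0], a_lab))
        full.extend(poly)
        if b_lab is not None:
            full.append(attach_pixel(poly[-1], b_lab))
        node_a = cluster_node[a_lab] if a_lab is not None else None
        node_b = cluster_node[b_lab] if b_lab is not None else None
        free_a = a_lab is None and not is_cycle
        free_b = b_lab is None and not is_cycle
        if node_a is None and not is_cycle:
            node_a = new_endpoint(first)
        if node_b is None and not is_cycle and not (len(order) == 1 and node_a is not None):
            node_b = new_endpoint(last)
        edges.append(
            _make_edge(np.array(full, dtype=int), node_a, node_b, pitch_mm, dmap,
                       free_ends=(free_a, free_b))
        )

    # --- directly adjacent junction clusters (no path pixels between) ------
    seen_pairs: set[tuple[int, int]] = set()
    brr, bcc = np.nonzero(branch_px)
    for r, c in zip(brr.tolist(), bcc.tolist()):
        la = cluster_lab[r, c]
        for dr, dc in _OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < S.shape[0] and 0 <= cc < S.shape[1]:
                lb = cluster_lab[rr, cc]
                if lb > 0 and lb != la:
                    pair = (min(la, lb), max(la, lb))
                    if pair not in seen_pairs:
                        seen_pairs.add(pair)
                        poly = np.array([(r, c), (rr, cc)], dtype=int)
                        edges.append(
                            _make_edge(poly, cluster_node[la], cluster_node[lb], pitch_mm, dmap)
                        )

    return VesselGraph(nodes, edges, skel.calibration)


def classify_elements(graph: VesselGraph) -> VesselGraph:
    """Label each edge segment / branch / isolated from its attachments."""
    kind = {n.id: n.kind for n in graph.nodes}
    for e in graph.edges:
        a = kind.get(e.node_a, "endpoint") if e.node_a is not None else "endpoint"
        b = kind.get(e.node_b, "endpoint") if e.node_b is not None else "endpoint"
        n_branch = (a == "branchpoint") + (b == "branchpoint")
        e.cls = ("isolated", "branch", "segment")[n_branch]
    return graph


def prune_twigs(
    graph: VesselGraph,
    twig_px: int,
    dmap: DiameterMap | None = None,
    shape: tuple[int, int] | None = None,
) -> tuple[VesselGraph, SkeletonMap]:
    """Remove noise twigs and rebuild the graph once.

    Isolated elements and branches whose geodesic length is below
    ``twig_px`` pixels (converted to mm at the current pitch) are dropped;
    segments are never length-filtered.  The skeleton is rebuilt from the
    surviving polylines plus the junction clusters that still join at least
    two edges, then the graph is rebuilt and re-classified exactly once —
    an element whose class changes during the rebuild is not re-tested.
    """
    if twig_px < 0:
        raise ValidationError("twig size must be non-negative")
    if graph.edges and graph.edges[0].cls == "unclassified":
        classify_elements(graph)
    pitch_mm = graph.calibration.um_per_px / 1000.0
    thr_mm = twig_px * pitch_mm
    keep = [
        e
        for e in graph.edges
        if e.cls == "segment" or e.path_length_mm >= thr_mm
    ]
    if shape is None:
        if dmap is not None:
            shape = dmap.values.shape
        else:
            cal = graph.calibration
            shape = (cal.px_y, cal.px_x)
    mask = np.zeros(shape, dtype=bool)
    incident: dict[int, int] = {}
    for e in keep:
        if len(e.path):
            mask[e.path[:, 0], e.path[:, 1]] = True
        for nid in (e.node_a, e.node_b):
            if nid is not None:
                incident[nid] = incident.get(nid, 0) + 1
    # A cluster that still joins >= 2 edges keeps all its pixels (it remains a
    # junction); a cluster left with a single edge contributes only the attach
    # pixel already inside that edge's polyline, so no stub pixels survive.
    for n in graph.nodes:
        if n.kind == "branchpoint" and incident.get(n.id, 0) >= 2:
            for r, c in n.pixels:
                mask[r, c] = True
    skel = SkeletonMap(mask, graph.calibration)
    rebuilt = classify_elements(build_graph(skel, dmap))
    return rebuilt, skel
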