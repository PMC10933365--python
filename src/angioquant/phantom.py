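"""Synthetic OCTA-like phantoms with exact ground truth.

No public OCTA dataset ships with this package, so every pipeline stage is
validated against phantoms: bright curvilinear vessel trees of known
geometry drawn as hard-edged (non-anti-aliased) thick polylines on a dark
background, an optional central avascular disc standing in for the FAZ, and
image degradation by multiplicative speckle followed by additive Gaussian
noise — the dominant noise structure of OCTA decorrelation maps.

Vessel centrelines are sinusoidally perturbed straight runs; trees never
touch each other or the avascular disc (candidate paths are truncated at a
clearance distance and retried), so the rendered mask, per-path lengths,
arc-chord tortuosities, and the branch-point count are exact bookkeeping,
not estimates.  Identical spec + seed reproduces the image bit for bit.

Short "spur" artefacts (noise-like twigs below the pruning threshold) can be
injected deliberately to exercise twig pruning.

Deterministic analytic fixtures (bars, arcs, crosses) used throughout the
test suite live here as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt

from .binarize import BinaryMap
from .errors import ValidationError
from .imagery import Calibration, RasterImage

__all__ = [
    "PhantomSpec",
    "PathTruth",
    "GroundTruth",
    "generate_phantom",
    "straight_bar_phantom",
    "arc_phantom",
    "cross_phantom",
    "square_calibration",
]


def square_calibration(grid_px: int, pitch_um: float = 3.0) -> Calibration:
    """Convenience: square grid with the given isotropic pitch."""
    mm = pitch_um * grid_px / 1000.0
    return Calibration(width_mm=mm, height_mm=mm, px_x=grid_px, px_y=grid_px)


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for a synthetic angiogram.

    Defaults emulate a 3×3 mm macular scan rendered on a 512-px grid
    (5.86 µm/px): branching vessel trees plus a dense capillary-bed fill
    with capillary-scale calibres (2–5 px ≈ 12–30 µm), a 0.25-mm-radius
    avascular centre ringed by a terminal capillary arcade, and noise levels
    that visually mimic OCTA decorrelation speckle.
    """

    grid_px: int = 512
    field_mm: float = 3.0
    n_trees: int = 14
    branch_depth: int = 3
    diameter_px: tuple[int, int] = (2, 5)
    trunk_diameter_px: tuple[int, int] = (3, 6)
    tortuosity_amp_px: float = 6.0
    fill_attempts: int = 1500
    junction_min_sep_px: float = 12.0
    faz_radius_mm: float = 0.25
    # noise set so vessel contrast-to-noise is ~3-4, the good-quality regime
    # OCTA studies screen for before quantitative analysis
    speckle_variance: float = 0.05
    gaussian_sigma: float = 0.03
    background: float = 0.12
    vessel_level: float = 0.85
    n_spurs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diameter_px[0] < 1:
            raise ValidationError("vessel diameters must be >= 1 px")
        faz_px = self.faz_radius_mm * 1000.0 / (1000.0 * self.field_mm / self.grid_px)
        if 2 * faz_px >= self.grid_px:
            raise ValidationError("avascular disc does not fit inside the field")

    @property
    def calibration(self) -> Calibration:
        return Calibration(
            width_mm=self.field_mm, height_mm=self.field_mm,
            px_x=self.grid_px, px_y=self.grid_px,
        )

    @property
    def faz_radius_px(self) -> float:
        return self.faz_radius_mm * 1000.0 / self.calibration.um_per_px


@dataclass
class PathTruth:
    """Exact geometry of one drawn centreline."""

    points: np.ndarray  # (k, 2) float (row, col)
    diameter_px: float
    length_mm: float
    chord_mm: float
    tortuosity: float
    depth: int  # 0 = trunk


@dataclass
class GroundTruth:
    vessel_mask: np.ndarray
    paths: list[PathTruth]
    branchpoint_count: int
    faz_centre_px: tuple[float, float] | None
    faz_radius_px: float
    target_vad_percent: float
    spur_masks: list[np.ndarray] = field(default_factory=list)
    # one probe point per spur: the free tip (attached spurs) or the middle
    # of the dash (isolated spurs); a spur counts as present/surviving in a
    # skeleton when skeleton pixels lie within 2 px of its probe point
    spur_tips: list[tuple[float, float]] = field(default_factory=list)

    @property
    def total_length_mm(self) -> float:
        return float(sum(p.length_mm for p in self.paths))


def _stamp_polyline(mask: np.ndarray, pts: np.ndarray, half_width: float) -> None:
    """Set mask pixels within ``half_width`` of the polyline (hard edges)."""
    ny, nx = mask.shape
    pad = int(np.ceil(half_width)) + 1
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rlo = max(int(np.floor(min(r0, r1))) - pad, 0)
        rhi = min(int(np.ceil(max(r0, r1))) + pad + 1, ny)
        clo = max(int(np.floor(min(c0, c1))) - pad, 0)
        chi = min(int(np.ceil(max(c0, c1))) + pad + 1, nx)
        if rhi <= rlo or chi <= clo:
            continue
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        vr, vc = r1 - r0, c1 - c0
        seg2 = vr * vr + vc * vc
        if seg2 == 0:
            d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        else:
            t = np.clip(((rr - r0) * vr + (cc - c0) * vc) / seg2, 0.0, 1.0)
            d2 = (rr - r0 - t * vr) ** 2 + (cc - c0 - t * vc) ** 2
        mask[rlo:rhi, clo:chi] |= d2 <= half_width * half_width
    # polylines always contain >= 1 point: ensure single points stamp too
    if len(pts) == 1:
        r0, c0 = pts[0]
        rr, cc = np.mgrid[0:ny, 0:nx]
        mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= half_width * half_width


def _polyline_truth(pts: np.ndarray, diameter_px: float, pitch_um: float, depth: int) -> PathTruth:
    d = np.diff(pts, axis=0)
    arc_px = float(np.hypot(d[:, 0], d[:, 1]).sum())
    chord_px = float(np.hypot(*(pts[-1] - pts[0])))
    return PathTruth(
        points=pts,
        diameter_px=diameter_px,
        length_mm=arc_px * pitch_um / 1000.0,
        chord_mm=chord_px * pitch_um / 1000.0,
        tortuosity=arc_px / chord_px if chord_px > 0 else float("inf"),
        depth=depth,
    )


def _grow_path(
    rng: np.random.Generator,
    start: np.ndarray,
    heading: float,
    target_len: float,
    half_width: float,
    amp_px: float,
    occ_dist: np.ndarray,
    faz_centre: np.ndarray | None,
    faz_clear_px: float,
    margin: float,
    junction_free_px: float = 0.0,
    min_len_px: float = 30.0,
) -> np.ndarray | None:
    """March a sinusoidally perturbed centreline until blocked.

    Returns the (k, 2) polyline, or None when it stalls before a useful
    length (30 px).  Clearance tests use the distance map of already
    committed vessels, skipped within ``junction_free_px`` of the start so
    that branches may leave their parent.
    """
    ny, nx = occ_dist.shape
    step = 1.5
    wavelength = rng.uniform(70.0, 160.0)
    phase = rng.uniform(0.0, 2 * np.pi)
    u = np.array([np.sin(heading), np.cos(heading)])  # (dr, dc)
    n_vec = np.array([u[1], -u[0]])
    pts = [start.astype(float)]
    t = 0.0
    while t < target_len:
        t += step
        p = start + u * t + n_vec * amp_px * np.sin(2 * np.pi * t / wavelength + phase)
        r, c = p
        if not (margin <= r < ny - margin and margin <= c < nx - margin):
            break
        if faz_centre is not None and np.hypot(*(p - faz_centre)) < faz_clear_px:
            break
        if np.hypot(*(p - start)) > junction_free_px:
            ri, ci = int(round(r)), int(round(c))
            if occ_dist[ri, ci] < half_width + 2.0:
                break
        pts.append(p)
    poly = np.array(pts)
    if len(poly) < 2:
        return None
    d = np.diff(poly, axis=0)
    if np.hypot(d[:, 0], d[:, 1]).sum() < min_len_px:
        return None
    return poly


def generate_phantom(spec: PhantomSpec) -> tuple[RasterImage, GroundTruth]:
    """Render a seeded synthetic angiogram and its exact ground truth.

    Raises a :class:`ValidationError` when no vessel tree can be placed
    (e.g. an avascular disc so large that nothing fits) after bounded
    retries.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.grid_px
    cal = spec.calibration
    pitch = cal.um_per_px
    faz_centre = None
    faz_r = 0.0
    if spec.faz_radius_mm > 0:
        faz_centre = np.array([(n - 1) / 2.0, (n - 1) / 2.0])
        faz_r = spec.faz_radius_px
    mask = np.zeros((n, n), dtype=bool)
    occ_dist = np.full((n, n), np.inf)
    paths: list[PathTruth] = []
    tree_of_path: list[int] = []
    junctions: list[np.ndarray] = []
    branchpoints = 0
    margin = 4.0

    def commit(poly: np.ndarray, half_width: float) -> None:
        # incremental occupancy-distance update: the exact distance to the
        # new stamp is computed in a window padded by R; outside it the true
        # distance exceeds R, far above any clearance threshold in use
        R = 24
        pad = int(np.ceil(half_width)) + 2 + R
        rlo = max(int(np.floor(poly[:, 0].min())) - pad, 0)
        rhi = min(int(np.ceil(poly[:, 0].max())) + pad + 1, n)
        clo = max(int(np.floor(poly[:, 1].min())) - pad, 0)
        chi = min(int(np.ceil(poly[:, 1].max())) + pad + 1, n)
        sub = np.zeros((rhi - rlo, chi - clo), dtype=bool)
        _stamp_polyline(sub, poly - [rlo, clo], half_width)
        mask[rlo:rhi, clo:chi] |= sub
        occ_dist[rlo:rhi, clo:chi] = np.minimum(
            occ_dist[rlo:rhi, clo:chi], distance_transform_edt(~sub)
        )

    d_lo, d_hi = spec.diameter_px
    t_lo, t_hi = spec.trunk_diameter_px
    if faz_centre is not None:
        # terminal capillary arcade: a closed ring bordering the avascular
        # disc, as in the real perifoveal plexus; its inner edge sits at the
        # disc boundary so the FAZ is a well-defined hole in the mesh
        ring_w = float(d_lo)
        ring_r = faz_r + ring_w / 2.0 + 0.2
        theta = np.linspace(0.0, 2 * np.pi, max(64, int(4 * np.pi * ring_r)))
        ring = np.column_stack([
            faz_centre[0] + ring_r * np.sin(theta),
            faz_centre[1] + ring_r * np.cos(theta),
        ])
        commit(ring, ring_w / 2.0)
        paths.append(_polyline_truth(ring, ring_w, pitch, depth=0))
        tree_of_path.append(-2)
    for tree in range(spec.n_trees):
        # trunks at arteriole/venule calibre; daughters taper to capillaries
        diam = float(rng.integers(t_lo, t_hi + 1))
        trunk = None
        for _ in range(40):
            start = rng.uniform(margin + 2, n - margin - 2, size=2)
            if faz_centre is not None and np.hypot(*(start - faz_centre)) < faz_r + diam:
                continue
            if occ_dist[int(start[0]), int(start[1])] < diam + 4:
                continue
            heading = rng.uniform(0, 2 * np.pi)
            trunk = _grow_path(
                rng, start, heading, rng.uniform(0.45, 0.85) * n, diam / 2.0,
                spec.tortuosity_amp_px, occ_dist, faz_centre,
                faz_r + diam / 2.0 + 0.5, margin,
            )
            if trunk is not None:
                break
        if trunk is None:
            continue
        commit(trunk, diam / 2.0)
        paths.append(_polyline_truth(trunk, diam, pitch, depth=0))
        tree_of_path.append(tree)
        parents = [(trunk, diam)]
        for depth in range(1, spec.branch_depth + 1):
            children = []
            for parent_poly, parent_d in parents:
                used: list[float] = []
                n_kids = int(rng.integers(1, 3))
                for _ in range(n_kids):
                    for _try in range(15):
                        arc = np.r_[0.0, np.cumsum(np.hypot(*np.diff(parent_poly, axis=0).T))]
                        # keep the spawn point well away from the parent's
                        # ends, or the junction degenerates into a corner
                        # inside the joint footprint instead of a true Y
                        end_margin = 12.0 + parent_d
                        if arc[-1] < 2 * end_margin + 6.0:
                            break
                        pos = rng.uniform(end_margin, arc[-1] - end_margin)
                        if any(abs(pos - u) < 18.0 for u in used):
                            continue
                        idx = int(np.searchsorted(arc, pos))
                        idx = min(max(idx, 1), len(parent_poly) - 2)
                        p0 = parent_poly[idx]
                        # keep anatomically distinct junctions resolvable:
                        # no two branch points closer than the minimum
                        # separation anywhere in the phantom
                        if any(
                            np.hypot(*(p0 - j)) < spec.junction_min_sep_px
                            for j in junctions
                        ):
                            continue
                        tang = parent_poly[idx + 1] - parent_poly[idx - 1]
                        base = np.arctan2(tang[0], tang[1])
                        sign = rng.choice([-1.0, 1.0])
                        heading = base + sign * np.deg2rad(rng.uniform(35, 70))
                        child_d = max(float(d_lo), parent_d - 2.0)
                        child = _grow_path(
                            rng, p0, heading, rng.uniform(0.25, 0.5) * n, child_d / 2.0,
                            spec.tortuosity_amp_px * 0.7, occ_dist, faz_centre,
                            faz_r + child_d / 2.0 + 0.5, margin,
                            junction_free_px=parent_d / 2.0 + child_d / 2.0 + 3.0,
                        )
                        if child is None:
                            continue
                        used.append(pos)
                        commit(child, child_d / 2.0)
                        paths.append(_polyline_truth(child, child_d, pitch, depth=depth))
                        tree_of_path.append(tree)
                        junctions.append(p0.copy())
                        branchpoints += 1
                        children.append((child, child_d))
                        break
            parents = children
    if not paths:
        raise ValidationError("could not place any vessel tree; relax the phantom spec")

    # capillary-bed fill: short unbranched vessels packed greedily into the
    # largest remaining gap, emulating the dense perifoveal mesh so that the
    # avascular disc is actually enclosed by capillaries and inter-vessel
    # gaps shrink to a few pixels (the regime FAZ segmentation relies on)
    if spec.fill_attempts > 0:
        rr, cc = np.mgrid[0:n, 0:n]
        allowed = (
            (rr > margin + 2) & (rr < n - margin - 2)
            & (cc > margin + 2) & (cc < n - margin - 2)
        )
        if faz_centre is not None:
            allowed &= (rr - faz_centre[0]) ** 2 + (cc - faz_centre[1]) ** 2 > (faz_r + 4.0) ** 2
        blocked = np.zeros((n, n), dtype=bool)
        gap_target = 5.0
        for _ in range(spec.fill_attempts):
            cand = np.where(allowed & ~blocked, occ_dist, 0.0)
            flat = int(np.argmax(cand))
            if cand.flat[flat] < gap_target:
                break
            start = np.array(np.unravel_index(flat, cand.shape), dtype=float)
            diam = float(d_lo)
            fill = None
            for _try in range(8):
                heading = rng.uniform(0, 2 * np.pi)
                fill = _grow_path(
                    rng, start, heading, rng.uniform(20.0, 90.0), diam / 2.0,
                    spec.tortuosity_amp_px * 0.5, occ_dist, faz_centre,
                    faz_r + diam / 2.0 + 0.5, margin, min_len_px=8.0,
                )
                if fill is not None:
                    break
            if fill is None:
                blocked[int(start[0]), int(start[1])] = True
                continue
            commit(fill, diam / 2.0)
            paths.append(_polyline_truth(fill, diam, pitch, depth=0))
            tree_of_path.append(-1)

    spur_masks: list[np.ndarray] = []
    spur_tips: list[tuple[float, float]] = []
    for k in range(spec.n_spurs):
        spur = np.zeros_like(mask)
        tip = None
        for _try in range(30):
            if k % 2 == 0 and paths:  # attached spur
                # twig length is measured from the junction on the host
                # centreline, so the whole protrusion (host radius included)
                # stays below the 8-px pruning threshold
                path = paths[int(rng.integers(0, len(paths)))]
                # attach away from the host's ends: a spur at a vessel end
                # reads as the vessel's own continuation (a corner, not a
                # junction) and is not a twig in any meaningful sense
                arc = np.r_[0.0, np.cumsum(np.hypot(*np.diff(path.points, axis=0).T))]
                if arc[-1] < 24.0:
                    continue
                pos = rng.uniform(8.0, arc[-1] - 8.0)
                idx = min(max(int(np.searchsorted(arc, pos)), 1), len(path.points) - 2)
                p0 = path.points[idx]
                length = path.diameter_px / 2.0 + rng.uniform(1.5, 3.5)
                tang = path.points[min(idx + 1, len(path.points) - 1)] - path.points[idx - 1]
                base = np.arctan2(tang[0], tang[1]) + rng.choice([-1, 1]) * np.pi / 2
                p1 = p0 + np.array([np.sin(base), np.cos(base)]) * length
                tip = p1
                # the tip must dangle freely: in the packed mesh a spur that
                # reaches a neighbouring vessel bridges it (becoming a
                # segment no length filter may touch) instead of being a twig
                lo = max(idx - 10, 0)
                hi = min(idx + 11, len(path.points))
                w0 = max(int(tip[0]) - 8, 0); w1 = min(int(tip[0]) + 9, n)
                v0 = max(int(tip[1]) - 8, 0); v1 = min(int(tip[1]) + 9, n)
                host_stamp = np.zeros((w1 - w0, v1 - v0), dtype=bool)
                _stamp_polyline(
                    host_stamp, path.points[lo:hi] - [w0, v0],
                    path.diameter_px / 2.0 + 0.7,
                )
                others = mask[w0:w1, v0:v1] & ~host_stamp
                if others.any():
                    orr, occ_ = np.nonzero(others)
                    d2o = (orr + w0 - tip[0]) ** 2 + (occ_ + v0 - tip[1]) ** 2
                    if d2o.min() < 3.0**2:
                        continue
            else:  # isolated dash
                length = rng.uniform(3.0, 5.5)
                p0 = rng.uniform(margin, n - margin, size=2)
                if occ_dist[int(p0[0]), int(p0[1])] < 10.0:
                    continue
                ang = rng.uniform(0, 2 * np.pi)
                p1 = p0 + np.array([np.sin(ang), np.cos(ang)]) * length
                tip = 0.5 * (p0 + p1)
            if not (0 <= p1[0] < n and 0 <= p1[1] < n):
                continue
            _stamp_polyline(spur, np.array([p0, p1]), 0.8)
            break
        if spur.any():
            # record only the pixels the spur adds beyond existing vessels,
            # so tests can tell spur skeleton from host-vessel skeleton
            spur_masks.append(spur & ~mask)
            spur_tips.append((float(tip[0]), float(tip[1])))
            mask |= spur

    if faz_centre is not None:
        rr, cc = np.mgrid[0:n, 0:n]
        inside = (rr - faz_centre[0]) ** 2 + (cc - faz_centre[1]) ** 2 <= faz_r**2
        mask &= ~inside  # safety net: clearance already keeps vessels out

    target_vad = 100.0 * float(mask.mean())
    img = spec.background + (spec.vessel_level - spec.background) * mask.astype(float)
    if spec.speckle_variance > 0:
        img = img * rng.normal(1.0, np.sqrt(spec.speckle_variance), size=img.shape)
    if spec.gaussian_sigma > 0:
        img = img + rng.normal(0.0, spec.gaussian_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    raster = RasterImage(pixels=img, calibration=cal, source_path=f"phantom(seed={spec.seed})")
    truth = GroundTruth(
        vessel_mask=mask,
        paths=paths,
        branchpoint_count=branchpoints,
        faz_centre_px=tuple(faz_centre) if faz_centre is not None else None,
        faz_radius_px=faz_r,
        target_vad_percent=target_vad,
        spur_masks=spur_masks,
        spur_tips=spur_tips,
    )
    return raster, truth


# ---------------------------------------------------------------------------
# deterministic analytic fixtures
# ---------------------------------------------------------------------------


def _fixture_truth(mask, pts, diameter_px, pitch_um, branchpoints=0, extra_paths=()):
    paths = [_polyline_truth(np.asarray(p, float), diameter_px, pitch_um, 0)
             for p in ([pts] if pts is not None else [])]
    for p, d in extra_paths:
        paths.append(_polyline_truth(np.asarray(p, float), d, pitch_um, 0))
    return GroundTruth(
        vessel_mask=mask,
        paths=paths,
        branchpoint_count=branchpoints,
        faz_centre_px=None,
        faz_radius_px=0.0,
        target_vad_percent=100.0 * float(mask.mean()),
    )


def straight_bar_phantom(
    width_px: int,
    length_px: int | None = None,
    grid_px: int = 128,
    pitch_um: float = 3.0,
) -> tuple[BinaryMap, GroundTruth]:
    """Horizontal bar of exact width; ``length_px=None`` spans edge to edge."""
    if width_px < 1:
        raise ValidationError("bar width must be >= 1 px")
    full = length_px is None
    length_px = grid_px if full else length_px
    if width_px > grid_px or length_px > grid_px:
        raise ValidationError("bar does not fit in the grid")
    mask = np.zeros((grid_px, grid_px), dtype=bool)
    r0 = grid_px // 2 - width_px // 2
    c0 = 0 if full else (grid_px - length_px) // 2
    mask[r0: r0 + width_px, c0: c0 + length_px] = True
    row = r0 + width_px // 2
    pts = np.array([[row, c0], [row, c0 + length_px - 1]], float)
    cal = square_calibration(grid_px, pitch_um)
    return (
        BinaryMap(mask, method="synthetic", threshold_info={}, calibration=cal),
        _fixture_truth(mask, pts, float(width_px), pitch_um),
    )


def arc_phantom(
    radius_px: int,
    width_px: int = 3,
    grid_px: int | None = None,
    pitch_um: float = 3.0,
) -> tuple[BinaryMap, GroundTruth]:
    """Semicircular arc: ground-truth tortuosity is exactly π/2."""
    if grid_px is None:
        grid_px = 2 * radius_px + 6 * width_px + 10
    if 2 * radius_px + width_px >= grid_px:
        raise ValidationError("arc does not fit in the grid")
    centre = np.array([grid_px * 0.62, (grid_px - 1) / 2.0])
    theta = np.linspace(np.pi, 0.0, max(64, 8 * radius_px))
    pts = np.column_stack([centre[0] - radius_px * np.sin(theta),
                           centre[1] + radius_px * np.cos(theta)])
    mask = np.zeros((grid_px, grid_px), dtype=bool)
    _stamp_polyline(mask, pts, width_px / 2.0)
    cal = square_calibration(grid_px, pitch_um)
    truth = _fixture_truth(mask, pts, float(width_px), pitch_um)
    truth.paths[0].tortuosity = np.pi / 2.0  # analytic, not polyline-sampled
    return BinaryMap(mask, method="synthetic", threshold_info={}, calibration=cal), truth


def cross_phantom(
    arm_px: int,
    width_px: int = 1,
    grid_px: int | None = None,
    pitch_um: float = 3.0,
) -> tuple[BinaryMap, GroundTruth]:
    """Plus sign with four arms of ``arm_px`` pixels; one branchpoint."""
    if grid_px is None:
        grid_px = 2 * arm_px + 2 * width_px + 9
    c = grid_px // 2
    if arm_px + width_px >= grid_px // 2:
        raise ValidationError("cross does not fit in the grid")
    mask = np.zeros((grid_px, grid_px), dtype=bool)
    h = width_px // 2
    mask[c - h: c + h + 1, c - arm_px: c + arm_px + 1] = True
    mask[c - arm_px: c + arm_px + 1, c - h: c + h + 1] = True
    cal = square_calibration(grid_px, pitch_um)
    arms = [
        [[c, c], [c, c - arm_px]],
        [[c, c], [c, c + arm_px]],
        [[c, c], [c - arm_px, c]],
        [[c, c], [c + arm_px, c]],
    ]
    truth = _fixture_truth(
        mask, None, float(width_px), pitch_um, branchpoints=1,
        extra_paths=[(a, float(width_px)) for a in arms],
    )
    return BinaryMap(mask, method="synthetic", threshold_info={}, calibration=cal), truth
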