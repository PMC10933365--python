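"""Analysis region masks: ETDRS sectors, nine squares, custom rectangles.

The ETDRS macular grid here comprises the structures that fit inside a
3×3 mm field: the central 1-mm-diameter "fovea" disc and the 1–3-mm
parafoveal annulus split into four quadrants by the ±45° diagonals through
the grid centre.  The grid is centred on the FAZ centroid (falling back to
the image centre when no FAZ is available); the nine-square grid is always
centred on the image.

Quadrant naming follows ocular laterality: the horizontal quadrants are
nasal/temporal when the eye is known (nasal is the right side of the image
for a right eye, OD, and the left side for a left eye, OS), otherwise the
geometric names left/right are used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .imagery import Calibration

__all__ = ["Region", "RegionSet", "whole_image", "etdrs_grid", "nine_squares", "custom_region"]


@dataclass
class Region:
    name: str
    mask: np.ndarray


@dataclass
class RegionSet:
    regions: list[Region]
    scheme: str  # "whole" | "etdrs" | "squares" | "custom"
    centre: tuple[float, float] | None = None  # (row, col) used, if any

    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def __iter__(self):
        return iter(self.regions)


def whole_image(shape: tuple[int, int]) -> RegionSet:
    return RegionSet([Region("whole image", np.ones(shape, dtype=bool))], scheme="whole")


def etdrs_grid(
    shape: tuple[int, int],
    cal: Calibration,
    centre: tuple[float, float],
    eye: str = "unknown",
) -> RegionSet:
    """Fovea disc (1 mm diameter) + four parafoveal quadrants (1–3 mm).

    ``centre`` is the (row, col) pixel position of the grid centre — normally
    the FAZ centroid.  Masks are clipped to the image.
    """
    cy, cx = centre
    if not (0 <= cy < shape[0] and 0 <= cx < shape[1]):
        raise ValidationError(f"grid centre {centre} lies outside the image")
    if eye not in ("OD", "OS", "unknown"):
        raise ValidationError("eye must be 'OD', 'OS' or 'unknown'")
    rows, cols = np.mgrid[: shape[0], : shape[1]]
    dy_mm = (rows - cy) * cal.um_per_px_y / 1000.0
    dx_mm = (cols - cx) * cal.um_per_px_x / 1000.0
    r_mm = np.hypot(dx_mm, dy_mm)
    fovea = r_mm <= 0.5
    annulus = (r_mm > 0.5) & (r_mm <= 1.5)
    vertical = np.abs(dy_mm) > np.abs(dx_mm)  # superior/inferior wedges
    superior = annulus & vertical & (dy_mm < 0)  # row 0 is the top of the image
    inferior = annulus & vertical & (dy_mm >= 0)
    right = annulus & ~vertical & (dx_mm >= 0)
    left = annulus & ~vertical & (dx_mm < 0)
    if eye == "OD":
        right_name, left_name = "nasal", "temporal"
    elif eye == "OS":
        right_name, left_name = "temporal", "nasal"
    else:
        right_name, left_name = "right", "left"
    regions = [
        Region("fovea", fovea),
        Region("parafovea superior", superior),
        Region("parafovea inferior", inferior),
        Region(f"parafovea {right_name}", right),
        Region(f"parafovea {left_name}", left),
    ]
    return RegionSet(regions, scheme="etdrs", centre=(float(cy), float(cx)))


def nine_squares(shape: tuple[int, int]) -> RegionSet:
    """3×3 tiling with integer boundaries floor(i·N/3), names r{0..2}c{0..2}."""
    ny, nx = shape
    if ny < 3 or nx < 3:
        raise ValidationError("image must be at least 3x3 for the nine-square grid")
    rb = [ny * i // 3 for i in range(4)]
    cb = [nx * i // 3 for i in range(4)]
    regions = []
    for i in range(3):
        for j in range(3):
            mask = np.zeros(shape, dtype=bool)
            mask[rb[i]: rb[i + 1], cb[j]: cb[j + 1]] = True
            regions.append(Region(f"r{i}c{j}", mask))
    return RegionSet(regions, scheme="squares", centre=(ny / 2, nx / 2))


def custom_region(rect: tuple[int, int, int, int], shape: tuple[int, int]) -> RegionSet:
    """Single rectangular mask with half-open bounds (row0, col0, row1, col1).

    Rectangles extending beyond the image are clipped; an empty intersection
    is an error.
    """
    r0, c0, r1, c1 = rect
    r0c, c0c = max(r0, 0), max(c0, 0)
    r1c, c1c = min(r1, shape[0]), min(c1, shape[1])
    if r1c <= r0c or c1c <= c0c:
        raise ValidationError(f"custom rectangle {rect} has empty intersection with image")
    mask = np.zeros(shape, dtype=bool)
    mask[r0c:r1c, c0c:c1c] = True
    return RegionSet(
        [Region(f"rect({r0c},{c0c},{r1c},{c1c})", mask)], scheme="custom"
    )
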