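"""Vessel/background segmentation of the enhanced angiogram.

Two methods, matching common OCTA practice:

* **fuzzy thresholding** — two-cluster fuzzy c-means (fuzziness m = 2) run on
  the 256-bin intensity histogram.  For a scalar feature the histogram
  formulation is exactly equivalent to per-pixel FCM but costs O(bins) per
  iteration.  With m = 2 the equal-membership point of two clusters is the
  midpoint of their centres, which is used as the global threshold.
* **adaptive thresholding** — pixel is vessel iff its intensity exceeds the
  local mean over a square window plus a fixed offset; included for
  comparison with studies that use local-mean binarisation.

No morphological cleanup is applied here: spurious specks are dealt with
later by twig pruning on the skeleton graph, and cleaning twice would bias
the density metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import DegenerateImageError, ValidationError
from .imagery import Calibration, RasterImage

__all__ = ["BinaryMap", "fuzzy_threshold", "adaptive_threshold", "fcm_histogram_centres"]


@dataclass
class BinaryMap:
    """Boolean vessel mask with provenance of how it was thresholded."""

    mask: np.ndarray
    method: str  # "fuzzy" | "adaptive" | synthetic provenance strings
    threshold_info: dict
    calibration: Calibration

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError("BinaryMap mask must be 2-D")


def fcm_histogram_centres(
    values: np.ndarray,
    weights: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[float, float]:
    """Two-cluster fuzzy c-means (m = 2) on a weighted 1-D sample.

    Centres are initialised at (min, max) of the support and iterated until
    the largest centre shift is below ``tol``.  Returns the sorted centres.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    support = values[weights > 0]
    if support.size < 2:
        raise DegenerateImageError("need at least two distinct intensity values")
    centres = np.array([support.min(), support.max()], dtype=float)
    for _ in range(max_iter):
        d = np.abs(values[:, None] - centres[None, :])  # (n, 2)
        # membership u_ik = 1 / sum_j (d_ik/d_jk)^2  for m = 2
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / d**2
            u = inv / inv.sum(axis=1, keepdims=True)
        exact = d == 0.0  # a sample sitting on a centre belongs to it fully
        if exact.any():
            rows = exact.any(axis=1)
            u[rows] = exact[rows].astype(float)
            u[rows] /= u[rows].sum(axis=1, keepdims=True)
        w2 = weights[:, None] * u**2
        new = (w2 * values[:, None]).sum(axis=0) / w2.sum(axis=0)
        shift = float(np.max(np.abs(new - centres)))
        centres = new
        if shift < tol:
            break
    return tuple(np.sort(centres))


def fuzzy_threshold(img: RasterImage, bins: int = 256) -> BinaryMap:
    """Segment vessels by histogram fuzzy c-means.

    The threshold is the midpoint of the two converged cluster centres (the
    exact equal-membership intensity for fuzziness m = 2); vessel pixels are
    those strictly above it.
    """
    pix = img.pixels
    lo, hi = float(pix.min()), float(pix.max())
    if hi <= lo:
        raise DegenerateImageError("constant image cannot be fuzzy-thresholded")
    hist, edges = np.histogram(pix, bins=bins, range=(lo, hi))
    mids = 0.5 * (edges[:-1] + edges[1:])
    c0, c1 = fcm_histogram_centres(mids, hist)
    thr = 0.5 * (c0 + c1)
    return BinaryMap(
        mask=pix > thr,
        method="fuzzy",
        threshold_info={"threshold": thr, "centres": (c0, c1)},
        calibration=img.calibration,
    )


def default_adaptive_window(image_px: int) -> int:
    """Default window: image_size / 8, rounded up to the next odd integer."""
    w = int(np.ceil(image_px / 8))
    return w + 1 if w % 2 == 0 else w


def adaptive_threshold(
    img: RasterImage, window_px: int | None = None, offset: float = 0.02
) -> BinaryMap:
    """Segment vessels by a local-mean threshold.

    A pixel is vessel iff its intensity exceeds the mean of its
    ``window_px`` × ``window_px`` neighbourhood (reflect boundary) by more
    than ``offset``.  A positive offset suppresses flat background.
    """
    if window_px is None:
        window_px = default_adaptive_window(max(img.shape))
    if window_px < 3 or window_px % 2 == 0:
        raise ValidationError("adaptive window must be an odd integer >= 3")
    local_mean = ndi.uniform_filter(img.pixels, size=window_px, mode="reflect")
    mask = img.pixels > local_mean + offset
    return BinaryMap(
        mask=mask,
        method="adaptive",
        threshold_info={"window_px": window_px, "offset": offset},
        calibration=img.calibration,
    )
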