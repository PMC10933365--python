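"""Image input/output and physical calibration.

En-face OCT angiography (OCTA) maximum-intensity projections are exported by
clinical instruments as plain 8- or 16-bit grayscale raster files (PNG, TIFF,
BMP, JPEG) at instrument-native pixel counts (304x304 ... 1000x1000 for a
typical 3x3 mm macular field).  The user supplies the physical field of view
in millimetres (already corrected for transverse magnification); everything
downstream works on a :class:`RasterImage` whose :class:`Calibration` converts
pixels to micrometres.

All images are analysed on a common square grid (default 1000 px) so that
kernel-based filters act consistently across instruments; see
:func:`resample_to_grid`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.measure import find_contours
from skimage.transform import resize

from .errors import DecodeError, ValidationError

__all__ = [
    "Calibration",
    "RasterImage",
    "load_grayscale",
    "resample_to_grid",
    "save_intermediates",
    "write_report",
]

_SUPPORTED_SUFFIXES = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class Calibration:
    """Physical calibration of a raster grid.

    Attributes
    ----------
    width_mm, height_mm : float
        Physical field of view in millimetres.
    px_x, px_y : int
        Pixel counts along x (columns) and y (rows).
    """

    width_mm: float
    height_mm: float
    px_x: int
    px_y: int

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValidationError("physical field size must be strictly positive")
        if self.px_x < 1 or self.px_y < 1:
            raise ValidationError("pixel counts must be strictly positive")

    @property
    def um_per_px_x(self) -> float:
        """Pixel pitch along x in micrometres."""
        return 1000.0 * self.width_mm / self.px_x

    @property
    def um_per_px_y(self) -> float:
        """Pixel pitch along y in micrometres."""
        return 1000.0 * self.height_mm / self.px_y

    @property
    def um_per_px(self) -> float:
        """Isotropic pitch: mean of the x and y pitches (µm/px)."""
        return 0.5 * (self.um_per_px_x + self.um_per_px_y)

    @property
    def px_area_mm2(self) -> float:
        """Physical area of one pixel in mm²."""
        return (self.um_per_px_x / 1000.0) * (self.um_per_px_y / 1000.0)


@dataclass
class RasterImage:
    """A calibrated 2-D intensity grid with values in [0, 1].

    ``pixels[row, col]``; row (y) increases downward, 0-based indices,
    physical positions at pixel centres.
    """

    pixels: np.ndarray
    calibration: Calibration
    source_path: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValidationError("RasterImage requires a 2-D pixel grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("RasterImage pixels must be finite")
        ny, nx = self.pixels.shape
        if (nx, ny) != (self.calibration.px_x, self.calibration.px_y):
            raise ValidationError(
                f"pixel grid {self.pixels.shape} does not match calibration "
                f"({self.calibration.px_y}, {self.calibration.px_x})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _collapse_rgb(arr: np.ndarray) -> np.ndarray:
    """Collapse an (H, W, C) array to grayscale.

    Instrument exports are frequently grayscale stored as RGB; if the three
    channels are identical the first one is returned untouched, otherwise the
    Rec.601 luma combination is used.
    """
    if arr.shape[2] >= 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.shape[2] == 1:
        return arr[:, :, 0]
    r, g, b = arr[:, :, 0], arr[:, :, 1], arr[:, :, 2]
    if np.array_equal(r, g) and np.array_equal(g, b):
        return r
    return 0.299 * r.astype(float) + 0.587 * g.astype(float) + 0.114 * b.astype(float)


def load_grayscale(path: str | os.PathLike, width_mm: float, height_mm: float) -> RasterImage:
    """Read an angiogram file and attach its physical calibration.

    Intensities are rescaled to [0, 1] by the bit-depth maximum (255 for
    8-bit, 65535 for 16-bit).  RGB inputs are collapsed to a single channel.

    Parameters
    ----------
    path : path-like
        PNG/TIFF/BMP/JPEG file, 8- or 16-bit, grayscale or RGB.
    width_mm, height_mm : float
        Physical field of view, corrected for transverse magnification.
    """
    path = Path(path)
    if width_mm <= 0 or height_mm <= 0:
        raise ValidationError("physical image size must be positive (mm)")
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise DecodeError(f"unsupported image format: {path.suffix!r}")
    try:
        arr = iio.imread(path)
    except (OSError, ValueError, RuntimeError) as exc:
        raise DecodeError(f"cannot decode {path}: {exc}") from exc
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    elif np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
    else:  # float input assumed already normalised
        scale = 1.0
    if arr.ndim == 3:
        arr = _collapse_rgb(arr)
    if arr.ndim != 2:
        raise DecodeError(f"{path} is not a 2-D image (shape {arr.shape})")
    pix = np.clip(arr.astype(float) / scale, 0.0, 1.0)
    ny, nx = pix.shape
    cal = Calibration(width_mm=width_mm, height_mm=height_mm, px_x=nx, px_y=ny)
    return RasterImage(pixels=pix, calibration=cal, source_path=str(path))


def resample_to_grid(img: RasterImage, target_px: int) -> RasterImage:
    """Bicubically resample to a ``target_px`` × ``target_px`` analysis grid.

    The physical field is unchanged; the pixel pitch is recomputed.  When the
    image is already on the target grid it is returned pixel-identical.
    """
    if target_px < 2:
        raise ValidationError("target_px must be >= 2")
    ny, nx = img.shape
    if (ny, nx) == (target_px, target_px):
        return replace(img, pixels=img.pixels.copy())
    out = resize(
        img.pixels,
        (target_px, target_px),
        order=3,
        mode="reflect",
        anti_aliasing=target_px < min(ny, nx),
        preserve_range=True,
    )
    out = np.clip(out, 0.0, 1.0)
    cal = Calibration(
        width_mm=img.calibration.width_mm,
        height_mm=img.calibration.height_mm,
        px_x=target_px,
        px_y=target_px,
    )
    return RasterImage(pixels=out, calibration=cal, source_path=img.source_path)


def _overlay_contour(gray: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Render a mask outline in red on top of a grayscale image (uint8 RGB)."""
    base = np.clip(gray * 255.0, 0, 255).astype(np.uint8)
    rgb = np.stack([base, base, base], axis=-1)
    for cont in find_contours(np.pad(mask, 1).astype(float), 0.5):
        rr = np.clip(np.round(cont[:, 0] - 1).astype(int), 0, gray.shape[0] - 1)
        cc = np.clip(np.round(cont[:, 1] - 1).astype(int), 0, gray.shape[1] - 1)
        rgb[rr, cc] = (255, 0, 0)
    return rgb


def save_intermediates(
    bundle: dict,
    out_dir: str | os.PathLike,
    stem: str = "image",
) -> list[Path]:
    """Write intermediate maps as losslessly compressed PNG files.

    ``bundle`` may contain any of the keys ``binary`` and ``skeleton``
    (boolean arrays) and ``faz_overlay`` (a ``(grayscale, faz_mask)`` pair,
    rendered as the contour drawn on the image).  File names are derived
    deterministically from ``stem``.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc
    written: list[Path] = []
    for key in ("binary", "skeleton"):
        if key in bundle and bundle[key] is not None:
            arr = (np.asarray(bundle[key], dtype=bool) * np.uint8(255))
            p = out_dir / f"{stem}_{key}.png"
            iio.imwrite(p, arr, extension=".png")
            written.append(p)
    if bundle.get("faz_overlay") is not None:
        gray, mask = bundle["faz_overlay"]
        p = out_dir / f"{stem}_faz.png"
        iio.imwrite(p, _overlay_contour(np.asarray(gray, float), np.asarray(mask, bool)),
                    extension=".png")
        written.append(p)
    return written


def write_report(records: list[dict], out_path: str | os.PathLike) -> Path:
    """Write per-image/per-region metric rows to XLSX plus a sibling CSV.

    All rows must share one column schema.  The CSV is UTF-8 with '.' decimal
    and full float precision so that values round-trip through text.
    """
    out_path = Path(out_path)
    if records:
        schema = list(records[0].keys())
        for rec in records[1:]:
            if list(rec.keys()) != schema:
                raise ValidationError("all report rows must share one column schema")
        df = pd.DataFrame(records, columns=schema)
    else:
        df = pd.DataFrame()
    out_path.parent.mkdir(parents=True, exist_ok=True)
    df.to_excel(out_path, index=False)
    df.to_csv(out_path.with_suffix(".csv"), index=False)
    return out_path
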