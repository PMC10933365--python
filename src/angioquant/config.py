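"""Pipeline configuration: plain-text (TOML) and programmatic.

Defaults are the recommended settings for retinal OCTA at the common
analysis grid: 1000-px grid, no median filter, Frangi maximum kernel 4 px,
fuzzy thresholding, twig size 8 px, rapid FAZ segmentation at neutral
stringency, ETDRS regions.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ValidationError

__all__ = ["PipelineConfig"]

_METHODS = ("fuzzy", "adaptive")
_FAZ_METHODS = ("rapid", "rapid_tuned", "manual", "drawn", "none")
_REGION_SCHEMES = ("whole", "etdrs", "squares", "custom")
_EYES = ("OD", "OS", "unknown")


@dataclass
class PipelineConfig:
    """Every tunable of the single-image / batch pipeline.

    ``median_kernel = 0`` disables the median filter; ``frangi_max_kernel =
    0`` disables vesselness enhancement (thresholding then runs on the raw
    image).  ``faz_contour_csv`` points at a sidecar CSV of (row, col)
    vertices for the manual/drawn FAZ methods.
    """

    target_grid_px: int = 1000
    field_width_mm: float = 3.0
    field_height_mm: float = 3.0
    median_kernel: int = 0
    frangi_max_kernel: int = 4
    method: str = "fuzzy"
    adaptive_window: int = 0  # 0 = automatic (image/8 rounded up to odd)
    adaptive_offset: float = 0.02
    twig_size_px: int = 8
    faz_method: str = "rapid"
    stringency: float = 0.5
    tune_iterations: int = 100
    faz_contour_csv: str = ""
    regions: str = "etdrs"
    custom_rect: tuple[int, int, int, int] = (0, 0, 0, 0)
    eye: str = "unknown"
    output_dir: str = "angioquant_out"
    seed: int = 0  # phantom generation only

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValidationError(f"method must be one of {_METHODS}")
        if self.faz_method not in _FAZ_METHODS:
            raise ValidationError(f"faz_method must be one of {_FAZ_METHODS}")
        if self.regions not in _REGION_SCHEMES:
            raise ValidationError(f"regions must be one of {_REGION_SCHEMES}")
        if self.eye not in _EYES:
            raise ValidationError(f"eye must be one of {_EYES}")
        if self.target_grid_px < 2:
            raise ValidationError("target_grid_px must be >= 2")
        if self.median_kernel < 0 or (self.median_kernel > 0 and self.median_kernel % 2 == 0):
            raise ValidationError("median_kernel must be 0 (off) or an odd integer")
        if not 0.0 <= self.stringency <= 1.0:
            raise ValidationError("stringency must lie in [0, 1]")
        self.custom_rect = tuple(int(v) for v in self.custom_rect)

    # -- plain-text round trip ---------------------------------------------

    def to_toml(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, str):
                lines.append(f'{f.name} = "{v}"')
            elif isinstance(v, bool):
                lines.append(f"{f.name} = {str(v).lower()}")
            elif isinstance(v, tuple):
                lines.append(f"{f.name} = [{', '.join(str(x) for x in v)}]")
            else:
                lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(self.to_toml(), encoding="utf-8")
        return path

    @classmethod
    def from_toml(cls, text: str) -> "PipelineConfig":
        data = tomllib.loads(text)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "custom_rect" in data:
            data["custom_rect"] = tuple(data["custom_rect"])
        return cls(**data)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_toml(Path(path).read_text(encoding="utf-8"))

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["custom_rect"] = list(self.custom_rect)
        return d
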