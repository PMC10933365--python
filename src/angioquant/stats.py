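"""Method-agreement and test–retest statistics.

These are the statistics used to compare metric sets produced by two
software pipelines on the same images, and to quantify intrasession
repeatability of one pipeline:

* **Bland–Altman**: for paired values (a_i, b_i), the bias d̄ = mean(a − b),
  the sample SD of the differences s_d, and the 95% limits of agreement
  d̄ ± 1.96·s_d.  The paired t statistic t = d̄ / (s_d/√n) is referred to a
  Student t distribution with n − 1 degrees of freedom; Spearman's ρ (with
  average-rank ties) summarises monotone association.
* **Coefficient of repeatability**: CR = 2.77 · S_w, where S_w is the
  within-subject SD.  For a duplicate design (two replicates per subject)
  S_w = √(Σ_i d_i² / 2m) over m subjects — the one-way-ANOVA within-subject
  estimate.  |test − retest| is expected to stay below CR for 95% of pairs.
* **VLD rescaling**: instruments that report vessel length density in
  mm/mm² are converted to total in-region length by multiplying with the
  region's physical area (9 mm² whole image, π·0.5² mm² fovea,
  π(1.5² − 0.5²) mm² parafovea, for a 3×3 mm scan).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "PairedSamples",
    "AgreementStats",
    "RepeatabilityResult",
    "bland_altman",
    "repeatability_cr",
    "vld_to_total_length",
]

_REGION_AREA_MM2 = {
    "whole": 9.0,
    "fovea": np.pi * 0.5**2,
    "parafovea": np.pi * (1.5**2 - 0.5**2),
}


@dataclass(frozen=True)
class PairedSamples:
    """Two same-length series of one metric measured by two methods."""

    method_a: np.ndarray
    method_b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.method_a, dtype=float)
        b = np.asarray(self.method_b, dtype=float)
        object.__setattr__(self, "method_a", a)
        object.__setattr__(self, "method_b", b)
        if a.shape != b.shape or a.ndim != 1:
            raise ValidationError("paired samples must be two equal-length 1-D series")
        if a.size < 2:
            raise ValidationError("need at least two pairs")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValidationError("paired samples must be finite")

    @property
    def n(self) -> int:
        return self.method_a.size


@dataclass
class AgreementStats:
    bias: float
    sd_diff: float
    la_low: float
    la_high: float
    se: float
    t_stat: float | None  # None when s_d = 0 (t undefined)
    p_value: float | None
    spearman_rho: float


@dataclass
class RepeatabilityResult:
    s_w: float
    cr: float  # always 2.77 * s_w
    n_subjects: int


def bland_altman(pairs: PairedSamples) -> AgreementStats:
    """Bland–Altman agreement of two methods with paired t test and ρ."""
    d = pairs.method_a - pairs.method_b
    n = pairs.n
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / np.sqrt(n)
    if sd > 0:
        t = bias / se
        p = 2.0 * float(sps.t.sf(abs(t), df=n - 1))
    else:
        t = p = None
    rho = float(sps.spearmanr(pairs.method_a, pairs.method_b).statistic)
    return AgreementStats(
        bias=bias,
        sd_diff=sd,
        la_low=bias - 1.96 * sd,
        la_high=bias + 1.96 * sd,
        se=float(se),
        t_stat=t,
        p_value=p,
        spearman_rho=rho,
    )


def repeatability_cr(replicates) -> RepeatabilityResult:
    """Coefficient of repeatability from per-subject duplicate measurements.

    ``replicates`` is an (m, 2) array-like: two replicate values per subject.
    """
    reps = np.asarray(replicates, dtype=float)
    if reps.ndim != 2 or reps.shape[1] != 2 or reps.shape[0] < 2:
        raise ValidationError("need an (m >= 2, 2) array of duplicate measurements")
    d = reps[:, 0] - reps[:, 1]
    m = reps.shape[0]
    s_w = float(np.sqrt(np.sum(d**2) / (2.0 * m)))
    return RepeatabilityResult(s_w=s_w, cr=2.77 * s_w, n_subjects=m)


def vld_to_total_length(vld_value: float, region: str) -> float:
    """Convert a vessel length density (mm/mm², 3×3 mm scan) to total mm."""
    if region not in _REGION_AREA_MM2:
        raise ValidationError(
            f"unknown region {region!r}; expected one of {sorted(_REGION_AREA_MM2)}"
        )
    return float(vld_value) * _REGION_AREA_MM2[region]
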