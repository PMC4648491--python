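"""Method-agreement statistics: Lin's CCC, Bland-Altman, Sanger proportions.

Used to compare copy-number estimates from two assays (droplet PCR vs MLPA
probe ratios) and allele proportions from droplet PCR vs Sanger peak
heights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError


@dataclass(frozen=True)
class PairedMeasurements:
    """Jointly indexed measurements of the same samples by two methods."""

    sample_ids: tuple[str, ...]
    x: tuple[float, ...]
    y: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.sample_ids) == len(self.x) == len(self.y)):
            raise ValidationError("sample_ids, x and y must have equal lengths")
        if len(self.x) < 2:
            raise ValidationError("need at least 2 paired measurements")
        if not all(math.isfinite(v) for v in self.x + self.y):
            raise ValidationError("paired measurements must be finite")

    @classmethod
    def from_arrays(cls, x, y, sample_ids=None) -> "PairedMeasurements":
        x = tuple(float(v) for v in x)
        y = tuple(float(v) for v in y)
        if sample_ids is None:
            sample_ids = tuple(str(i) for i in range(len(x)))
        return cls(sample_ids=tuple(sample_ids), x=x, y=y)


@dataclass(frozen=True)
class ConcordanceResult:
    ccc: float
    ci_low: float
    ci_high: float
    pearson_r: float
    r_squared: float


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int


def lins_ccc(p: PairedMeasurements) -> ConcordanceResult:
    """Lin's concordance correlation coefficient with a Fisher-z 95% CI.

    Uses population (divide-by-n) moments per Lin's original estimator:
    ``ccc = 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2)``.  The CI uses
    the Fisher z transform with Lin's (1989) variance; it degenerates to
    the point estimate when the data sit exactly on the identity line.
    """
    x = np.asarray(p.x, dtype=float)
    y = np.asarray(p.y, dtype=float)
    n = x.size
    mx, my = x.mean(), y.mean()
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        raise ValidationError("both methods constant with equal means: CCC undefined")
    ccc = 2.0 * sxy / denom

    if sx2 > 0 and sy2 > 0:
        r = float(sxy / math.sqrt(sx2 * sy2))
    else:
        r = 0.0

    ci_low = ci_high = ccc
    if n >= 3 and abs(ccc) < 1.0 and r != 0.0:
        u = (mx - my) / (sx2 * sy2) ** 0.25 if sx2 > 0 and sy2 > 0 else 0.0
        one_m_c2 = 1.0 - ccc**2
        var_z = (
            (1.0 - r**2) * ccc**2 / (one_m_c2 * r**2)
            + 2.0 * ccc**3 * (1.0 - ccc) * u**2 / (r * one_m_c2**2)
            - ccc**4 * u**4 / (2.0 * r**2 * one_m_c2**2)
        ) / (n - 2)
        if var_z > 0:
            z = math.atanh(ccc)
            half = stats.norm.ppf(0.975) * math.sqrt(var_z)
            ci_low, ci_high = math.tanh(z - half), math.tanh(z + half)
    return ConcordanceResult(
        ccc=ccc, ci_low=ci_low, ci_high=ci_high, pearson_r=r, r_squared=r**2
    )


def bland_altman(p: PairedMeasurements) -> BlandAltmanResult:
    """Bias and 95% limits of agreement for differences x - y."""
    d = np.asarray(p.x, dtype=float) - np.asarray(p.y, dtype=float)
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd_diff=sd,
        n=int(d.size),
    )


def sanger_proportion(
    forward: tuple[float, float], reverse: tuple[float, float]
) -> float:
    """Mean risk-allele peak-height proportion across the two strands.

    Each strand contributes peak_risk / (peak_risk + peak_prot); a strand
    whose peaks sum to zero is dropped with a warning, and the proportion is
    undefined when both strands are empty.
    """
    per_strand = []
    for name, (risk, prot) in (("forward", forward), ("reverse", reverse)):
        if risk < 0 or prot < 0:
            raise ValidationError(f"{name} strand: peak heights must be non-negative")
        total = risk + prot
        if total > 0:
            per_strand.append(risk / total)
        else:
            warnings.warn(
                f"{name} strand has zero total peak height; dropped", stacklevel=2
            )
    if not per_strand:
        raise ValidationError("zero total peak height on both strands")
    return math.fsum(per_strand) / len(per_strand)


def sanger_proportions(
    strands: Sequence[tuple[str, float, float]]
) -> float:
    """Proportion from an arbitrary set of (strand, peak_risk, peak_prot) rows."""
    by_strand: dict[str, tuple[float, float]] = {}
    for strand, risk, prot in strands:
        by_strand[strand] = (risk, prot)
    fwd = by_strand.get("forward", (0.0, 0.0))
    rev = by_strand.get("reverse", (0.0, 0.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sanger_proportion(fwd, rev)
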