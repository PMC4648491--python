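"""Allelic-imbalance calling against three-sigma constitutional thresholds.

Replicate wells are merged into per-sample mean allele concentrations, the
risk-allele proportion is taken against the allele total, thresholds are
calibrated as mean +/- 3 SD of constitutional heterozygote proportions, and
tumor samples outside the band are called imbalanced.
"""

from __future__ import annotations

import math
import statistics
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .droplet import ChannelConcentration
from .errors import (
    DegenerateThresholdsWarning,
    InsufficientCalibrationError,
    UndefinedProportionError,
    ValidationError,
)

#: Samples whose combined allele concentration falls below this many
#: copies/uL are excluded from calling (the cutoff itself is a convention).
DEFAULT_MIN_TOTAL_CONC = 5.0

STATUS_AI_RISK = "AI_risk"
STATUS_AI_PROTECTIVE = "AI_protective"
STATUS_NO_AI = "no_AI"
STATUS_EXCLUDED = "excluded"


@dataclass(frozen=True)
class SampleMeasurement:
    """Replicate-merged allele concentrations for one sample."""

    sample_id: str
    tissue: str  # "constitutional" or "tumor"
    mean_conc_risk: float
    mean_conc_prot: float
    sem_proportion: float
    n_replicates: int

    def __post_init__(self) -> None:
        if self.tissue not in ("constitutional", "tumor"):
            raise ValidationError(f"unknown tissue {self.tissue!r}")
        if self.mean_conc_risk < 0 or self.mean_conc_prot < 0:
            raise ValidationError("mean concentrations must be non-negative")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.sem_proportion < 0:
            raise ValidationError("sem_proportion must be non-negative")


@dataclass(frozen=True)
class AIThresholds:
    mean_constitutional: float
    sd_constitutional: float
    upper: float
    lower: float
    n_constitutional_measurements: int


@dataclass(frozen=True)
class AICall:
    sample_id: str
    proportion: float
    status: str


def _conc(value: float | ChannelConcentration) -> float:
    if isinstance(value, ChannelConcentration):
        return value.concentration_copies_per_ul
    return float(value)


def merge_replicates(
    replicates: Sequence[tuple[float | ChannelConcentration, float | ChannelConcentration]],
    *,
    sample_id: str = "",
    tissue: str = "tumor",
) -> SampleMeasurement:
    """Merge per-replicate (risk, protective) concentrations for one sample.

    Means are taken per allele; ``sem_proportion`` is the standard error of
    the per-replicate proportions (sample SD over sqrt(n); 0 for a single
    replicate).  Replicates with zero total concentration contribute to the
    means but not to the proportion SEM.
    """
    if len(replicates) == 0:
        raise ValidationError(f"sample {sample_id!r}: no replicates to merge")
    risks = [_conc(r) for r, _ in replicates]
    prots = [_conc(p) for _, p in replicates]
    mean_risk = math.fsum(risks) / len(risks)
    mean_prot = math.fsum(prots) / len(prots)
    proportions = [r / (r + p) for r, p in zip(risks, prots) if r + p > 0]
    if len(proportions) >= 2:
        sem = statistics.stdev(proportions) / math.sqrt(len(proportions))
    else:
        sem = 0.0
    return SampleMeasurement(
        sample_id=sample_id,
        tissue=tissue,
        mean_conc_risk=mean_risk,
        mean_conc_prot=mean_prot,
        sem_proportion=sem,
        n_replicates=len(replicates),
    )


def risk_allele_proportion(m: SampleMeasurement) -> float:
    """Risk-allele share of the total allele concentration (0.5 = balanced)."""
    total = m.mean_conc_risk + m.mean_conc_prot
    if total <= 0:
        raise UndefinedProportionError(
            f"sample {m.sample_id!r}: both allele concentrations are zero"
        )
    return m.mean_conc_risk / total


def calibrate_thresholds(
    constitutional_proportions: Sequence[float],
    sigma_multiplier: float = 3.0,
) -> AIThresholds:
    """Three-sigma band from constitutional heterozygote proportions.

    Uses the sample SD (n-1 denominator).  A zero SD yields coinciding
    thresholds and a :class:`DegenerateThresholdsWarning`.
    """
    values = list(constitutional_proportions)
    if len(values) < 2:
        raise InsufficientCalibrationError(
            f"need >= 2 constitutional proportions, got {len(values)}"
        )
    for v in values:
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"proportion {v} outside [0, 1]")
    mean = math.fsum(values) / len(values)
    sd = statistics.stdev(values)
    if sd == 0.0:
        warnings.warn(
            "constitutional proportions are constant: upper and lower thresholds coincide",
            DegenerateThresholdsWarning,
            stacklevel=2,
        )
    return AIThresholds(
        mean_constitutional=mean,
        sd_constitutional=sd,
        upper=mean + sigma_multiplier * sd,
        lower=mean - sigma_multiplier * sd,
        n_constitutional_measurements=len(values),
    )


def qc_exclude_low_concentration(
    m: SampleMeasurement, min_total_conc: float = DEFAULT_MIN_TOTAL_CONC
) -> bool:
    """True when both alleles together fall below the concentration cutoff."""
    return (m.mean_conc_risk + m.mean_conc_prot) < min_total_conc


def call_ai(
    proportion: float,
    thresholds: AIThresholds,
    qc_excluded: bool = False,
    *,
    sample_id: str = "",
) -> AICall:
    """Call AI status with strict threshold inequalities; QC exclusion wins."""
    if qc_excluded:
        status = STATUS_EXCLUDED
    elif proportion > thresholds.upper:
        status = STATUS_AI_RISK
    elif proportion < thresholds.lower:
        status = STATUS_AI_PROTECTIVE
    else:
        status = STATUS_NO_AI
    return AICall(sample_id=sample_id, proportion=proportion, status=status)


def call_sample(
    m: SampleMeasurement,
    thresholds: AIThresholds,
    min_total_conc: float = DEFAULT_MIN_TOTAL_CONC,
) -> AICall:
    """QC-check then call one merged sample measurement."""
    excluded = qc_exclude_low_concentration(m, min_total_conc)
    if excluded:
        return AICall(sample_id=m.sample_id, proportion=float("nan"), status=STATUS_EXCLUDED)
    return call_ai(risk_allele_proportion(m), thresholds, sample_id=m.sample_id)


def constitutional_proportions(measurements: Iterable[SampleMeasurement]) -> list[float]:
    """Pool proportions from constitutional measurements for calibration."""
    return [
        risk_allele_proportion(m)
        for m in measurements
        if m.tissue == "constitutional" and (m.mean_conc_risk + m.mean_conc_prot) > 0
    ]
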