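"""Exact binomial test for preferential allelic imbalance and cohort summaries.

Under the null each imbalanced sample is equally likely to favor either
allele (p = q = 0.5).  The one-sided p-value is the exact upper tail taken
from the majority direction: P(X >= max(k_risk, k_prot)) for
X ~ Binomial(k_risk + k_prot, 1/2), computed by integer summation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .ai import STATUS_AI_PROTECTIVE, STATUS_AI_RISK, STATUS_EXCLUDED, AICall
from .errors import UndefinedTestError, ValidationError

DIRECTION_MAJORITY = "majority"
DIRECTION_RISK = "risk"


@dataclass(frozen=True)
class PAIResult:
    k_risk: int
    k_prot: int
    n_ai: int
    p_value: float
    direction_tested: str
    tie: bool = False


@dataclass(frozen=True)
class CohortSummary:
    snp_id: str
    n_heterozygotes: int
    n_ai: int
    pct_ai: float
    k_risk: int
    k_prot: int
    p_value: float | None


def _exact_upper_tail(k: int, n: int) -> float:
    """P(X >= k) for X ~ Binomial(n, 1/2), exact integer summation."""
    numerator = sum(math.comb(n, i) for i in range(k, n + 1))
    return float(Fraction(numerator, 2**n))


def binomial_pai_test(
    k_risk: int, k_prot: int, direction: str = DIRECTION_MAJORITY
) -> PAIResult:
    """Exact one-sided binomial test of direction preference among AI samples.

    ``direction="majority"`` (default) takes the tail from whichever allele
    holds the majority; this is the convention that reproduces reported
    two-direction cohorts, including ties at p = P(X >= k).  Pass
    ``direction="risk"`` for a strict a-priori risk-direction tail.
    """
    if k_risk < 0 or k_prot < 0:
        raise ValidationError("counts must be non-negative")
    n = k_risk + k_prot
    if n == 0:
        raise UndefinedTestError("no AI samples: binomial test undefined")
    tie = k_risk == k_prot
    if direction == DIRECTION_MAJORITY:
        k = max(k_risk, k_prot)
        direction_tested = "risk" if k_risk >= k_prot else "protective"
    elif direction == DIRECTION_RISK:
        k = k_risk
        direction_tested = "risk"
    else:
        raise ValidationError(f"unknown direction {direction!r}")
    return PAIResult(
        k_risk=k_risk,
        k_prot=k_prot,
        n_ai=n,
        p_value=_exact_upper_tail(k, n),
        direction_tested=direction_tested,
        tie=tie,
    )


def summarize_counts(
    snp_id: str, n_heterozygotes: int, k_risk: int, k_prot: int
) -> CohortSummary:
    """Table-style cohort summary straight from direction counts."""
    n_ai = k_risk + k_prot
    if n_heterozygotes < n_ai:
        raise ValidationError(
            f"{snp_id}: n_heterozygotes={n_heterozygotes} < n_ai={n_ai}"
        )
    p_value = binomial_pai_test(k_risk, k_prot).p_value if n_ai > 0 else None
    pct = round(100.0 * n_ai / n_heterozygotes, 1) if n_heterozygotes else 0.0
    return CohortSummary(
        snp_id=snp_id,
        n_heterozygotes=n_heterozygotes,
        n_ai=n_ai,
        pct_ai=pct,
        k_risk=k_risk,
        k_prot=k_prot,
        p_value=p_value,
    )


def summarize_cohort(
    calls: Sequence[AICall], n_heterozygotes: int, snp_id: str = ""
) -> CohortSummary:
    """Count AI directions over calls and attach the exact binomial p-value.

    Excluded calls do not count toward AI; ``n_heterozygotes`` must cover
    every non-excluded call.
    """
    non_excluded = [c for c in calls if c.status != STATUS_EXCLUDED]
    if n_heterozygotes < len(non_excluded):
        raise ValidationError(
            f"{snp_id}: n_heterozygotes={n_heterozygotes} below "
            f"{len(non_excluded)} non-excluded calls"
        )
    k_risk = sum(1 for c in non_excluded if c.status == STATUS_AI_RISK)
    k_prot = sum(1 for c in non_excluded if c.status == STATUS_AI_PROTECTIVE)
    return summarize_counts(snp_id, n_heterozygotes, k_risk, k_prot)
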