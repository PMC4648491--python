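"""Droplet partition simulation and Poisson quantitation.

A duplexed assay reads two fluorescence channels (FAM for the risk allele,
VIC for the protective allele) over 10-20k water-in-oil droplets.  A droplet
is channel-positive when it received at least one template molecule of that
allele, so the negative-droplet fraction estimates ``exp(-lambda)`` and the
absolute concentration follows from the Poisson occupancy model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .errors import SaturationError, ValidationError

#: Volume of one droplet in microlitres (QX100-era convention, configurable).
DEFAULT_DROPLET_VOLUME_UL = 0.00085


@dataclass(frozen=True)
class DropletWell:
    """Accepted-droplet counts for one well of one duplexed assay."""

    well_id: str
    sample_id: str
    assay_id: str
    n_total: int
    n_fam_pos: int
    n_vic_pos: int
    droplet_volume_ul: float = DEFAULT_DROPLET_VOLUME_UL
    extras: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValidationError(
                f"well {self.well_id!r}: n_total must be positive, got {self.n_total}"
            )
        for name in ("n_fam_pos", "n_vic_pos"):
            value = getattr(self, name)
            if not 0 <= value <= self.n_total:
                raise ValidationError(
                    f"well {self.well_id!r}: {name}={value} outside [0, n_total={self.n_total}]"
                )
        if not self.droplet_volume_ul > 0:
            raise ValidationError(
                f"well {self.well_id!r}: droplet_volume_ul must be > 0"
            )


@dataclass(frozen=True)
class ChannelConcentration:
    """Absolute concentration for one channel with a 95% interval."""

    concentration_copies_per_ul: float
    ci_low: float
    ci_high: float
    lambda_hat: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.concentration_copies_per_ul <= self.ci_high:
            raise ValidationError("concentration must lie inside its interval")


@dataclass(frozen=True)
class Clone:
    """One tumor (sub)clone: its cell fraction and per-cell copy counts."""

    fraction: float
    copies_risk: int
    copies_prot: int
    copies_control: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValidationError(f"clone fraction {self.fraction} outside [0, 1]")
        if self.copies_risk < 0 or self.copies_prot < 0:
            raise ValidationError("allele copy counts must be non-negative")
        if self.copies_control <= 0:
            raise ValidationError("control copy count must be positive")


@dataclass(frozen=True)
class ClonePopulation:
    """Mixture of clones plus the total genomic-control concentration.

    The control assay targets a region not somatically altered, so the
    control concentration anchors the absolute scale: each allele's expected
    concentration is the control concentration times the copy-weighted
    allele share of the mixture.
    """

    clones: tuple[Clone, ...]
    total_control_conc: float

    def __post_init__(self) -> None:
        if len(self.clones) == 0:
            raise ValidationError("a clone population needs at least one clone")
        total = math.fsum(c.fraction for c in self.clones)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"clone fractions sum to {total}, expected 1")
        if not self.total_control_conc >= 0:
            raise ValidationError("total_control_conc must be non-negative")

    def expected_allele_concentrations(self) -> tuple[float, float]:
        """Expected (risk, protective) concentrations in copies/uL."""
        w_control = math.fsum(c.fraction * c.copies_control for c in self.clones)
        if w_control <= 0:
            raise ValidationError("all-zero control copies: mixture scale undefined")
        w_risk = math.fsum(c.fraction * c.copies_risk for c in self.clones)
        w_prot = math.fsum(c.fraction * c.copies_prot for c in self.clones)
        scale = self.total_control_conc / w_control
        return w_risk * scale, w_prot * scale

    def expected_proportion(self) -> float:
        risk, prot = self.expected_allele_concentrations()
        if risk + prot == 0:
            raise ValidationError("both allele concentrations are zero")
        return risk / (risk + prot)

    def expected_normalized_cn(self) -> float:
        """Expected SNP-locus copy number relative to the diploid control."""
        risk, prot = self.expected_allele_concentrations()
        if self.total_control_conc == 0:
            raise ValidationError("zero control concentration")
        return (risk + prot) / self.total_control_conc


def clone_population(
    clones: Sequence[tuple[float, int, int, int]], total_control_conc: float
) -> ClonePopulation:
    """Build a :class:`ClonePopulation` from plain tuples."""
    return ClonePopulation(
        clones=tuple(Clone(*c) for c in clones),
        total_control_conc=total_control_conc,
    )


def estimate_channel_concentration(
    n_pos: int,
    n_total: int,
    droplet_volume_ul: float = DEFAULT_DROPLET_VOLUME_UL,
) -> ChannelConcentration:
    """Poisson estimate of copies/uL from positive-droplet counts.

    ``lambda_hat = -ln(n_neg / n_total)`` and concentration is
    ``lambda_hat / droplet_volume_ul``.  The 95% interval is a Wilson score
    interval on the negative-droplet fraction pushed through the same
    monotone transform, which stays stable at very low and very high
    occupancy.
    """
    if n_total <= 0:
        raise ValidationError(f"n_total must be positive, got {n_total}")
    if n_pos < 0 or n_pos > n_total:
        raise ValidationError(f"n_pos={n_pos} outside [0, n_total={n_total}]")
    if not droplet_volume_ul > 0:
        raise ValidationError("droplet_volume_ul must be > 0")
    if n_pos == n_total:
        raise SaturationError(
            f"all {n_total} droplets positive: concentration unbounded; dilute and re-run"
        )
    n_neg = n_total - n_pos
    lam = -math.log(n_neg / n_total)
    conc = lam / droplet_volume_ul
    # Wilson interval on the negative fraction; -ln is decreasing, so the
    # lower bound on p_neg maps to the upper concentration bound.
    p_neg_low, p_neg_high = proportion_confint(n_neg, n_total, alpha=0.05, method="wilson")
    ci_high = -math.log(p_neg_low) / droplet_volume_ul
    ci_low = 0.0 if p_neg_high >= 1.0 else -math.log(p_neg_high) / droplet_volume_ul
    ci_low = min(ci_low, conc)
    ci_high = max(ci_high, conc)
    return ChannelConcentration(
        concentration_copies_per_ul=conc, ci_low=ci_low, ci_high=ci_high, lambda_hat=lam
    )


def quantify_well(well: DropletWell) -> tuple[ChannelConcentration, ChannelConcentration]:
    """Per-channel concentrations (FAM, VIC) for one well."""
    fam = estimate_channel_concentration(well.n_fam_pos, well.n_total, well.droplet_volume_ul)
    vic = estimate_channel_concentration(well.n_vic_pos, well.n_total, well.droplet_volume_ul)
    return fam, vic


def _as_rng(seed: int | np.random.SeedSequence | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_droplet_classes(
    conc_fam: float,
    conc_vic: float,
    n_droplets: int,
    droplet_volume_ul: float = DEFAULT_DROPLET_VOLUME_UL,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    cross_reactivity: float = 0.0,
) -> tuple[int, int, int, int]:
    """Simulate per-droplet occupancy; return (neg, fam-only, vic-only, double).

    Molecule counts of the two targets are drawn as independent Poissons per
    droplet.  ``cross_reactivity`` is the probability that a molecule of the
    other target also fires this channel's probe (0 = fully specific).
    """
    if n_droplets <= 0:
        raise ValidationError("n_droplets must be positive")
    if conc_fam < 0 or conc_vic < 0:
        raise ValidationError("concentrations must be non-negative")
    if not 0.0 <= cross_reactivity <= 1.0:
        raise ValidationError("cross_reactivity must lie in [0, 1]")
    rng = _as_rng(seed)
    lam_fam = conc_fam * droplet_volume_ul
    lam_vic = conc_vic * droplet_volume_ul
    mol_fam = rng.poisson(lam_fam, n_droplets)
    mol_vic = rng.poisson(lam_vic, n_droplets)
    pos_fam = mol_fam > 0
    pos_vic = mol_vic > 0
    if cross_reactivity > 0.0:
        pos_fam = pos_fam | (rng.binomial(mol_vic, cross_reactivity) > 0)
        pos_vic = pos_vic | (rng.binomial(mol_fam, cross_reactivity) > 0)
    n_double = int(np.count_nonzero(pos_fam & pos_vic))
    n_fam_only = int(np.count_nonzero(pos_fam & ~pos_vic))
    n_vic_only = int(np.count_nonzero(pos_vic & ~pos_fam))
    n_neg = n_droplets - n_double - n_fam_only - n_vic_only
    return n_neg, n_fam_only, n_vic_only, n_double


def simulate_well(
    conc_risk: float,
    conc_prot: float,
    n_droplets: int,
    droplet_volume_ul: float = DEFAULT_DROPLET_VOLUME_UL,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    *,
    well_id: str = "sim",
    sample_id: str = "sim",
    assay_id: str = "snp",
    cross_reactivity: float = 0.0,
) -> DropletWell:
    """Draw one synthetic well for a duplexed assay (risk=FAM, prot=VIC)."""
    n_neg, n_fam_only, n_vic_only, n_double = simulate_droplet_classes(
        conc_risk,
        conc_prot,
        n_droplets,
        droplet_volume_ul,
        seed,
        cross_reactivity=cross_reactivity,
    )
    return DropletWell(
        well_id=well_id,
        sample_id=sample_id,
        assay_id=assay_id,
        n_total=n_droplets,
        n_fam_pos=n_fam_only + n_double,
        n_vic_pos=n_vic_only + n_double,
        droplet_volume_ul=droplet_volume_ul,
    )


def simulate_sample(
    pop: ClonePopulation,
    n_droplets: int,
    droplet_volume_ul: float = DEFAULT_DROPLET_VOLUME_UL,
    n_replicates: int = 2,
    seed: int | np.random.SeedSequence = 0,
    *,
    sample_id: str = "sim",
    snp_assay_id: str = "snp",
    control_assay_id: str = "control",
) -> tuple[list[DropletWell], list[DropletWell]]:
    """Simulate replicate SNP-assay and control-assay wells for one sample.

    Expected allele concentrations come from the clone mixture; the control
    assay is simulated at ``pop.total_control_conc`` (FAM channel only).
    Per-replicate seeds are spawned deterministically from ``seed``.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    conc_risk, conc_prot = pop.expected_allele_concentrations()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_replicates)
    snp_wells: list[DropletWell] = []
    control_wells: list[DropletWell] = []
    for rep in range(n_replicates):
        snp_wells.append(
            simulate_well(
                conc_risk,
                conc_prot,
                n_droplets,
                droplet_volume_ul,
                children[2 * rep],
                well_id=f"{sample_id}:{snp_assay_id}:{rep + 1}",
                sample_id=sample_id,
                assay_id=snp_assay_id,
            )
        )
        control_wells.append(
            simulate_well(
                pop.total_control_conc,
                0.0,
                n_droplets,
                droplet_volume_ul,
                children[2 * rep + 1],
                well_id=f"{sample_id}:{control_assay_id}:{rep + 1}",
                sample_id=sample_id,
                assay_id=control_assay_id,
            )
        )
    return snp_wells, control_wells
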