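"""Well-table pipelines shared by the CLI and tests.

These functions connect the quantitation, merging, calibration, calling and
classification primitives into the end-to-end flows the subcommands expose.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Mapping, Sequence

from . import ai, copystate
from .droplet import DropletWell, quantify_well
from .errors import ValidationError


def group_wells(
    wells: Sequence[DropletWell], assay_id: str
) -> dict[str, list[DropletWell]]:
    """Replicate wells of one assay keyed by sample, in input order."""
    groups: dict[str, list[DropletWell]] = defaultdict(list)
    for well in wells:
        if well.assay_id == assay_id:
            groups[well.sample_id].append(well)
    if not groups:
        raise ValidationError(f"no wells found for assay {assay_id!r}")
    return dict(groups)


def measure_samples(
    wells: Sequence[DropletWell],
    tissues: Mapping[str, str],
    assay_id: str,
) -> dict[str, ai.SampleMeasurement]:
    """Quantify and replicate-merge SNP-assay wells into per-sample means."""
    measurements = {}
    for sample_id, sample_wells in group_wells(wells, assay_id).items():
        pairs = [quantify_well(w) for w in sample_wells]
        measurements[sample_id] = ai.merge_replicates(
            [(fam, vic) for fam, vic in pairs],
            sample_id=sample_id,
            tissue=tissues.get(sample_id, "tumor"),
        )
    return measurements


def control_concentrations(
    wells: Sequence[DropletWell], control_assay_id: str
) -> dict[str, float]:
    """Mean genomic-control concentration per sample (FAM channel)."""
    out = {}
    for sample_id, sample_wells in group_wells(wells, control_assay_id).items():
        concs = [quantify_well(w)[0].concentration_copies_per_ul for w in sample_wells]
        out[sample_id] = sum(concs) / len(concs)
    return out


def call_cohort(
    wells: Sequence[DropletWell],
    tissues: Mapping[str, str],
    snp_assay_id: str,
    *,
    min_total_conc: float = ai.DEFAULT_MIN_TOTAL_CONC,
    sigma_multiplier: float = 3.0,
) -> tuple[ai.AIThresholds, list[dict]]:
    """Calibrate thresholds on constitutional samples, call the tumors.

    Returns the thresholds and one output row per tumor sample with the
    proportion, replicate SEM, call status and the thresholds applied.
    """
    measurements = measure_samples(wells, tissues, snp_assay_id)
    constitutional = ai.constitutional_proportions(measurements.values())
    thresholds = ai.calibrate_thresholds(constitutional, sigma_multiplier)
    rows = []
    for sample_id, m in measurements.items():
        if m.tissue != "tumor":
            continue
        call = ai.call_sample(m, thresholds, min_total_conc)
        rows.append(
            {
                "sample_id": sample_id,
                "proportion": call.proportion,
                "sem": m.sem_proportion,
                "status": call.status,
                "upper": thresholds.upper,
                "lower": thresholds.lower,
            }
        )
    return thresholds, rows


def copy_states(
    wells: Sequence[DropletWell],
    snp_assay_id: str,
    control_assay_id: str,
    *,
    tissues: Mapping[str, str] | None = None,
    ambiguity_margin: float = copystate.DEFAULT_AMBIGUITY_MARGIN,
    min_total_conc: float = ai.DEFAULT_MIN_TOTAL_CONC,
) -> list[dict]:
    """Classify the somatic copy state of every sample with both assays."""
    tissues = tissues or {}
    measurements = measure_samples(wells, tissues, snp_assay_id)
    controls = control_concentrations(wells, control_assay_id)
    rows = []
    for sample_id, m in measurements.items():
        if sample_id not in controls:
            continue
        if ai.qc_exclude_low_concentration(m, min_total_conc):
            continue
        cn = copystate.normalized_copy_number(m, controls[sample_id])
        proportion = ai.risk_allele_proportion(m)
        call = copystate.classify_alteration(
            proportion, cn, ambiguity_margin, sample_id=sample_id
        )
        rows.append(
            {
                "sample_id": sample_id,
                "proportion": proportion,
                "normalized_cn": cn.normalized_cn,
                "model": call.model,
                "clonal_fraction": call.clonal_fraction,
                "residual": call.residual,
                "ambiguous_flag": call.ambiguous,
            }
        )
    return rows
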