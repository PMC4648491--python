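"""Packaged fixtures: published cohort counts, candidate loci, demo cohort."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import io as sio
from .droplet import DropletWell, clone_population, simulate_sample
from .errors import ValidationError
from .scan import GwasSnp, PaiCandidate, ScnaRegion

FIXTURES = ("table1_counts", "table2_loci", "demo_cohort")


@dataclass(frozen=True)
class CohortCounts:
    """Published per-SNP AI counts: (n_het, n_ai, k_risk, k_prot)."""

    snp_id: str
    gene: str
    genomic_location: str
    n_heterozygotes: int
    n_ai: int
    k_risk: int
    k_prot: int


def _data_path(name: str) -> Path:
    return Path(resources.files("smartddpcr") / "data" / name)


def load_table1_counts() -> dict[str, CohortCounts]:
    df = pd.read_csv(_data_path("table1_counts.tsv"), sep="\t", dtype=str)
    out = {}
    for _, row in df.iterrows():
        rec = CohortCounts(
            snp_id=row["snp_id"],
            gene=row["gene"],
            genomic_location=row["genomic_location"],
            n_heterozygotes=int(row["n_heterozygotes"]),
            n_ai=int(row["n_ai"]),
            k_risk=int(row["k_risk"]),
            k_prot=int(row["k_prot"]),
        )
        if rec.k_risk + rec.k_prot != rec.n_ai:
            raise ValidationError(f"{rec.snp_id}: k_risk + k_prot != n_ai")
        out[rec.snp_id] = rec
    return out


def load_table2_regions() -> list[ScnaRegion]:
    return sio.read_regions_tsv(_data_path("table2_loci.tsv"))


def load_cancer_vocab() -> dict[str, tuple[str, ...]]:
    return sio.read_vocab_tsv(_data_path("cancer_vocab.tsv"))


def table2_candidates() -> list[PaiCandidate]:
    """Candidate loci with one synthetic overlapping SNP per trait phrase.

    The fixture records which cancer-association traits overlap each locus;
    the synthetic SNPs are positioned at the region start so positional
    overlap holds by construction.
    """
    df = pd.read_csv(_data_path("table2_loci.tsv"), sep="\t", dtype=str)
    regions = load_table2_regions()
    candidates = []
    for region, (_, row) in zip(regions, df.iterrows()):
        traits = [t.strip() for t in row["assoc_cancer_traits"].split(";") if t.strip()]
        snps = tuple(
            GwasSnp(
                rsid=f"fixture:{region.peak_name}:{i}",
                chrom=region.chrom,
                pos=region.start,
                trait=trait,
            )
            for i, trait in enumerate(traits)
        )
        candidates.append(PaiCandidate(region=region, snps=snps))
    return candidates


def load_demo_config() -> dict:
    return yaml.safe_load(_data_path("demo_cohort.yaml").read_text())


def simulate_demo_cohort(seed: int | None = None) -> list[DropletWell]:
    """Simulate the packaged demo cohort; deterministic for a fixed seed."""
    cfg = load_demo_config()
    wells: list[DropletWell] = []
    base_seed = cfg["seed"] if seed is None else seed
    for i, sample in enumerate(cfg["samples"]):
        pop = clone_population(
            [tuple(c) for c in sample["clones"]], sample["control_conc"]
        )
        snp_wells, control_wells = simulate_sample(
            pop,
            n_droplets=cfg["n_droplets"],
            droplet_volume_ul=cfg["droplet_volume_ul"],
            n_replicates=cfg["n_replicates"],
            seed=base_seed + 7919 * i,
            sample_id=sample["sample_id"],
            snp_assay_id=cfg["snp_assay_id"],
            control_assay_id=cfg["control_assay_id"],
        )
        wells.extend(snp_wells)
        wells.extend(control_wells)
    return wells


def load_fixture(name: str):
    """Uniform entry point for the packaged fixtures.

    ``table1_counts`` -> dict of per-SNP published AI counts;
    ``table2_loci`` -> candidate loci with overlapping-trait SNPs;
    ``demo_cohort`` -> deterministic wells-CSV text for the demo cohort.
    """
    if name == "table1_counts":
        return load_table1_counts()
    if name == "table2_loci":
        return table2_candidates()
    if name == "demo_cohort":
        return sio.wells_to_csv_text(simulate_demo_cohort())
    raise ValidationError(
        f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}"
    )
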