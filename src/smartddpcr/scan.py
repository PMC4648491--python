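"""Overlap recurrent SCNA peak regions with cancer-associated GWAS SNPs.

A SNP joins a peak region when its position falls inside the region's
1-based inclusive interval on the same chromosome, or when one of its
mapped genes is listed among the peak genes.  A candidate locus is a
"match" when a controlled-vocabulary mapping of the SNP trait phrases
shares at least one tumor-type code with the cancer types in which the
SCNA was found recurrent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .errors import UnmappedTraitWarning, ValidationError

SCNA_AMPLIFICATION = "amplification"
SCNA_DELETION = "deletion"

#: Tumor-type codes grouped into the cancer labels used for reporting
#: (both lung codes count as the single cancer "lung").
CODE_LABELS: Mapping[str, str] = {
    "BLCA": "bladder",
    "BRCA": "breast",
    "GBM": "glioma",
    "LUAD": "lung",
    "LUSC": "lung",
    "CRC": "colorectal",
    "UCEC": "endometrial",
    "OV": "ovarian",
    "KIRC": "kidney",
    "HNSC": "head_and_neck",
}


def normalize_chrom(chrom: str) -> str:
    chrom = str(chrom).strip()
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def normalize_trait(phrase: str) -> str:
    return " ".join(str(phrase).replace("’", "'").lower().split())


@dataclass(frozen=True)
class ScnaRegion:
    peak_name: str
    cytoband: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    scna_type: str
    peak_genes: tuple[str, ...]
    tumor_types: tuple[str, ...]
    build: str = "hg19"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"region {self.peak_name}: start > end")
        if self.scna_type not in (SCNA_AMPLIFICATION, SCNA_DELETION):
            raise ValidationError(
                f"region {self.peak_name}: unknown scna_type {self.scna_type!r}"
            )
        if not self.tumor_types:
            raise ValidationError(f"region {self.peak_name}: no tumor types")

    def contains(self, chrom: str, pos: int) -> bool:
        return normalize_chrom(chrom) == normalize_chrom(self.chrom) and (
            self.start <= pos <= self.end
        )


@dataclass(frozen=True)
class GwasSnp:
    rsid: str
    chrom: str
    pos: int  # 1-based
    trait: str
    cancer_types: tuple[str, ...] = ()
    mapped_genes: tuple[str, ...] = ()
    build: str = "hg19"

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValidationError(f"SNP {self.rsid}: position must be positive")


@dataclass(frozen=True)
class PaiCandidate:
    region: ScnaRegion
    snps: tuple[GwasSnp, ...]
    matched: bool = False
    matched_types: tuple[str, ...] = ()


def overlap_snps(
    regions: Sequence[ScnaRegion], snps: Sequence[GwasSnp]
) -> list[PaiCandidate]:
    """Join SNPs to regions by position or shared gene; drop empty regions."""
    builds = {r.build for r in regions} | {s.build for s in snps}
    if len(builds) > 1:
        raise ValidationError(
            f"mixed genome builds in overlap inputs: {', '.join(sorted(builds))}"
        )
    candidates: list[PaiCandidate] = []
    for region in regions:
        genes = {g.upper() for g in region.peak_genes}
        hits = tuple(
            snp
            for snp in snps
            if region.contains(snp.chrom, snp.pos)
            or (genes and genes.intersection(g.upper() for g in snp.mapped_genes))
        )
        if hits:
            candidates.append(PaiCandidate(region=region, snps=hits))
    return candidates


def map_traits(
    trait: str, vocab: Mapping[str, Sequence[str]]
) -> tuple[tuple[str, ...], list[str]]:
    """Map a (possibly ';'-separated) trait string to tumor-type codes.

    Returns the mapped codes and the list of phrases missing from the
    vocabulary.
    """
    codes: list[str] = []
    unmapped: list[str] = []
    for phrase in str(trait).split(";"):
        phrase = normalize_trait(phrase)
        if not phrase:
            continue
        if phrase in vocab:
            codes.extend(vocab[phrase])
        else:
            unmapped.append(phrase)
    return tuple(dict.fromkeys(codes)), unmapped


def match_cancer_types(
    candidate: PaiCandidate, vocab: Mapping[str, Sequence[str]]
) -> PaiCandidate:
    """Set the matched flag from the SNP-trait vs SCNA tumor-type overlap.

    Trait phrases missing from the vocabulary raise an
    :class:`UnmappedTraitWarning` rather than being silently dropped.
    """
    snp_codes: list[str] = []
    all_unmapped: list[str] = []
    mapped_snps = []
    for snp in candidate.snps:
        codes, unmapped = map_traits(snp.trait, vocab)
        codes = tuple(dict.fromkeys(tuple(snp.cancer_types) + codes))
        mapped_snps.append(replace(snp, cancer_types=codes))
        snp_codes.extend(codes)
        all_unmapped.extend(unmapped)
    if all_unmapped:
        warnings.warn(
            "trait phrases missing from vocabulary: "
            + ", ".join(sorted(set(all_unmapped))),
            UnmappedTraitWarning,
            stacklevel=2,
        )
    matched_types = tuple(
        code for code in dict.fromkeys(snp_codes) if code in candidate.region.tumor_types
    )
    return replace(
        candidate,
        snps=tuple(mapped_snps),
        matched=bool(matched_types),
        matched_types=matched_types,
    )


def summarize_candidates(
    candidates: Iterable[PaiCandidate],
    code_labels: Mapping[str, str] = CODE_LABELS,
) -> dict:
    """Counts of matched loci overall, by SCNA type, and by cancer label.

    A locus counts once per cancer label it matches (so a locus matching
    several cancers appears under each, and label counts can sum to more
    than the total).
    """
    total = 0
    by_scna = {SCNA_AMPLIFICATION: 0, SCNA_DELETION: 0}
    by_cancer: dict[str, int] = {}
    for cand in candidates:
        if not cand.matched:
            continue
        total += 1
        by_scna[cand.region.scna_type] += 1
        labels = {code_labels.get(code, code) for code in cand.matched_types}
        for label in sorted(labels):
            by_cancer[label] = by_cancer.get(label, 0) + 1
    return {
        "total_matched": total,
        "by_scna_type": by_scna,
        "by_cancer_type": dict(sorted(by_cancer.items())),
    }
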