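import random

import pytest

from smartddpcr import (
    GwasSnp,
    ScnaRegion,
    match_cancer_types,
    overlap_snps,
    summarize_candidates,
)
from smartddpcr.errors import UnmappedTraitWarning, ValidationError
from smartddpcr.scan import PaiCandidate

CDKN2A_REGION = ScnaRegion(
    peak_name="CDKN2A",
    cytoband="9p21.3",
    chrom="9",
    start=21865498,
    end=22448737,
    scna_type="deletion",
    peak_genes=("CDKN2A", "CDKN2B"),
    tumor_types=("BLCA", "BRCA", "GBM"),
)


class TestOverlapSnps:
    def test_position_overlap(self):
        snp = GwasSnp(rsid="rs3731217", chrom="chr9", pos=21984661, trait="ALL")
        cands = overlap_snps([CDKN2A_REGION], [snp])
        assert len(cands) == 1
        assert cands[0].snps == (snp,)

    def test_inclusive_end_boundary(self):
        at_end = GwasSnp(rsid="rs_end", chrom="9", pos=CDKN2A_REGION.end, trait="x")
        past_end = GwasSnp(rsid="rs_past", chrom="9", pos=CDKN2A_REGION.end + 1, trait="x")
        cands = overlap_snps([CDKN2A_REGION], [at_end, past_end])
        assert [s.rsid for s in cands[0].snps] == ["rs_end"]

    def test_inclusive_start_boundary(self):
        at_start = GwasSnp(rsid="rs_start", chrom="9", pos=CDKN2A_REGION.start, trait="x")
        assert overlap_snps([CDKN2A_REGION], [at_start])

    def test_gene_rule_disjunction(self):
        outside = GwasSnp(
            rsid="rs_gene",
            chrom="9",
            pos=30000000,
            trait="x",
            mapped_genes=("CDKN2B",),
        )
        cands = overlap_snps([CDKN2A_REGION], [outside])
        assert len(cands) == 1

    def test_no_overlap_region_omitted(self):
        far = GwasSnp(rsid="rs_far", chrom="2", pos=100, trait="x")
        assert overlap_snps([CDKN2A_REGION], [far]) == []

    def test_chrom_normalization(self):
        snp = GwasSnp(rsid="rs1", chrom="chr9", pos=21984661, trait="x")
        assert overlap_snps([CDKN2A_REGION], [snp])

    def test_mixed_builds_rejected(self):
        snp = GwasSnp(rsid="rs1", chrom="9", pos=21984661, trait="x", build="hg38")
        with pytest.raises(ValidationError, match="build"):
            overlap_snps([CDKN2A_REGION], [snp])

    def test_shuffle_invariance(self, table2_candidates):
        regions = [c.region for c in table2_candidates]
        snps = [s for c in table2_candidates for s in c.snps]
        baseline = {c.region.peak_name: {s.rsid for s in c.snps} for c in overlap_snps(regions, snps)}
        rng = random.Random(0)
        for _ in range(3):
            r2, s2 = regions[:], snps[:]
            rng.shuffle(r2)
            rng.shuffle(s2)
            shuffled = {c.region.peak_name: {s.rsid for s in c.snps} for c in overlap_snps(r2, s2)}
            assert shuffled == baseline

    def test_removing_gene_rule_only_decreases(self):
        inside = GwasSnp(rsid="rs_in", chrom="9", pos=21984661, trait="x")
        by_gene = GwasSnp(rsid="rs_gene", chrom="9", pos=30000000, trait="x", mapped_genes=("CDKN2A",))
        with_genes = overlap_snps([CDKN2A_REGION], [inside, by_gene])
        no_gene_region = ScnaRegion(
            peak_name="CDKN2A",
            cytoband="9p21.3",
            chrom="9",
            start=CDKN2A_REGION.start,
            end=CDKN2A_REGION.end,
            scna_type="deletion",
            peak_genes=(),
            tumor_types=CDKN2A_REGION.tumor_types,
        )
        without_genes = overlap_snps([no_gene_region], [inside, by_gene])
        assert len(without_genes[0].snps) <= len(with_genes[0].snps)


class TestMatchCancerTypes:
    def test_bladder_matches_blca(self, cancer_vocab):
        snp = GwasSnp(rsid="rs1", chrom="9", pos=21984661, trait="Bladder cancer")
        cand = match_cancer_types(PaiCandidate(region=CDKN2A_REGION, snps=(snp,)), cancer_vocab)
        assert cand.matched
        assert cand.matched_types == ("BLCA",)

    def test_glioma_does_not_match_foreign_types(self, cancer_vocab):
        region = ScnaRegion(
            peak_name="x", cytoband="", chrom="1", start=1, end=10,
            scna_type="deletion", peak_genes=(), tumor_types=("BLCA", "BRCA"),
        )
        snp = GwasSnp(rsid="rs1", chrom="1", pos=5, trait="Glioma")
        cand = match_cancer_types(PaiCandidate(region=region, snps=(snp,)), cancer_vocab)
        assert not cand.matched

    def test_empty_cancer_types_no_match(self, cancer_vocab):
        snp = GwasSnp(rsid="rs1", chrom="9", pos=21984661, trait="")
        cand = match_cancer_types(PaiCandidate(region=CDKN2A_REGION, snps=(snp,)), cancer_vocab)
        assert not cand.matched

    def test_unmapped_phrase_warns(self, cancer_vocab):
        snp = GwasSnp(rsid="rs1", chrom="9", pos=21984661, trait="Moon dust exposure")
        with pytest.warns(UnmappedTraitWarning, match="moon dust"):
            match_cancer_types(PaiCandidate(region=CDKN2A_REGION, snps=(snp,)), cancer_vocab)


@pytest.fixture(scope="module")
def matched(table2_candidates, cancer_vocab):
    return [match_cancer_types(c, cancer_vocab) for c in table2_candidates]


class TestSummarizeCandidates:

    def test_total_and_by_scna_type(self, matched):
        summary = summarize_candidates(matched)
        assert summary["total_matched"] == 16
        assert summary["by_scna_type"] == {"amplification": 8, "deletion": 8}

    def test_per_cancer_counts(self, matched):
        by_cancer = summarize_candidates(matched)["by_cancer_type"]
        assert by_cancer["bladder"] == 6
        assert by_cancer["breast"] == 4
        assert by_cancer["glioma"] == 3
        assert by_cancer["lung"] == 3
        assert by_cancer["colorectal"] == 2
        assert by_cancer["endometrial"] == 2
        assert by_cancer["ovarian"] == 1
        assert by_cancer["kidney"] == 1

    def test_counts_against_brute_force_double_loop(self, matched):
        # oracle: loop over every (locus, cancer label) pair independently
        from smartddpcr.scan import CODE_LABELS

        labels = sorted(set(CODE_LABELS.values()))
        oracle = {}
        for label in labels:
            count = 0
            for cand in matched:
                codes = {c for s in cand.snps for c in s.cancer_types}
                hit = False
                for code in codes:
                    if CODE_LABELS.get(code) == label and code in cand.region.tumor_types:
                        hit = True
                if hit:
                    count += 1
            if count:
                oracle[label] = count
        assert summarize_candidates(matched)["by_cancer_type"] == oracle
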