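"""Region classification, ts/tv, coding effects and gene fusions."""

import numpy as np
import pytest

from popdiv.annotation import (
    CONS_DEL,
    CONS_INS,
    DISR_DEL,
    DISR_INS,
    FRAMESHIFT,
    FUSION_BI,
    MISSENSE,
    START_LOST,
    STOP_GAINED,
    STOP_LOST,
    SYNONYMOUS,
    EffectCall,
    IMPACT,
    RegionCall,
    annotate_matrix,
    classify_region,
    coding_effect,
    detect_gene_fusion,
    normalize_indel,
    region_summary,
    syn_nonsyn_ratio,
    transition_transversion,
    tstv_ratio,
)
from popdiv.model import GeneModel, VariantSite

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s):
    return s.translate(_COMP)[::-1]


# A hand-built plus-strand gene: 20 kb chromosome, CDS at [10000, 10030)
# (10 codons: ATG + 8 sense codons + TAA), 5'UTR and 3'UTR of 50 bp.
CDS = "ATG" + "GCT" + "AAA" + "TGG" + "CTT" + "GAC" + "CCT" + "ACT" + "GGA" + "TAA"


def plus_gene(chrom_len=20_000, cds_start=10_000):
    pre = "".join("ACGT"[(i * 7 + 3) % 4] for i in range(cds_start - 50))
    seq = pre + "T" * 50 + CDS + "G" * 50
    seq += "".join("ACGT"[(i * 5 + 1) % 4] for i in range(chrom_len - len(seq)))
    gene = GeneModel(
        gene_id="gX",
        chrom="c",
        strand="+",
        cds_segments=[(cds_start, cds_start + len(CDS))],
        utr5_segments=[(cds_start - 50, cds_start)],
        utr3_segments=[(cds_start + len(CDS), cds_start + len(CDS) + 50)],
    )
    return gene, {"c": seq}


class TestClassifyRegion:
    def setup_method(self):
        self.gene, self.genome = plus_gene()

    def snp(self, pos0, alt="G"):
        ref = self.genome["c"][pos0]
        alt = "G" if ref != "G" else "A"
        return VariantSite("c", pos0 + 1, ref, (alt,))

    def test_upstream_within_flank_of_start_codon(self):
        call = classify_region(self.snp(10_000 - 3_000), [self.gene])
        assert call == RegionCall("upstream", "gX")

    def test_intergenic_beyond_flank(self):
        call = classify_region(self.snp(10_000 - 6_000), [self.gene])
        assert call.label == "intergenic"

    def test_exonic_utr_intron_downstream(self):
        assert classify_region(self.snp(10_010), [self.gene]).label == "exonic"
        assert classify_region(self.snp(10_000 - 10), [self.gene]).label == "utr5"
        assert classify_region(self.snp(10_030 + 10), [self.gene]).label == "utr3"
        assert (
            classify_region(self.snp(10_030 + 50 + 100), [self.gene]).label
            == "downstream"
        )

    def test_exonic_wins_over_neighbouring_flank(self):
        # second gene 2 kb downstream whose flank covers the first's CDS
        other = GeneModel(
            gene_id="gY", chrom="c", strand="+", cds_segments=[(12_000, 12_030)]
        )
        call = classify_region(self.snp(10_010), [self.gene, other])
        assert call == RegionCall("exonic", "gX")

    def test_strand_symmetry_under_mirroring(self):
        # mirror the genome: position p -> L-1-p, strand flips; labels of
        # mirrored sites must be identical
        gene, genome = plus_gene()
        L = len(genome["c"])
        mirrored = GeneModel(
            gene_id="gX",
            chrom="c",
            strand="-",
            cds_segments=[(L - e, L - s) for s, e in gene.cds_segments],
            utr5_segments=[(L - e, L - s) for s, e in gene.utr5_segments],
            utr3_segments=[(L - e, L - s) for s, e in gene.utr3_segments],
        )
        mirror_genome = {"c": _revcomp(genome["c"])}
        for pos0 in [10_010, 9_990, 10_035, 7_000, 12_500, 4_000, 16_000]:
            ref = genome["c"][pos0]
            site = VariantSite("c", pos0 + 1, ref, ("A" if ref != "A" else "C",))
            mref = mirror_genome["c"][L - 1 - pos0]
            msite = VariantSite(
                "c", L - pos0, mref, ("A" if mref != "A" else "C",)
            )
            assert (
                classify_region(site, [gene]).label
                == classify_region(msite, [mirrored]).label
            ), pos0


class TestTsTv:
    def test_purine_purine_is_transition(self):
        assert transition_transversion(VariantSite("c", 1, "A", ("G",))) == "ts"
        assert transition_transversion(VariantSite("c", 1, "C", ("T",))) == "ts"
        assert transition_transversion(VariantSite("c", 1, "A", ("C",))) == "tv"

    def test_six_class_enumeration(self):
        pairs = [("A", "G"), ("C", "T"), ("G", "A"), ("A", "C"), ("A", "T"), ("C", "G")]
        sites = [VariantSite("c", i + 1, r, (a,)) for i, (r, a) in enumerate(pairs)]
        classes = [transition_transversion(s) for s in sites]
        assert classes.count("ts") + classes.count("tv") == len(sites)
        assert tstv_ratio(sites) == pytest.approx(1.0)

    def test_all_transversions(self):
        sites = [VariantSite("c", 1, "A", ("T",)), VariantSite("c", 2, "C", ("G",))]
        assert tstv_ratio(sites) == 0

    def test_zero_transversions_flagged_not_raised(self):
        sites = [VariantSite("c", 1, "A", ("G",))]
        with pytest.warns(UserWarning, match="ts/tv undefined"):
            assert np.isnan(tstv_ratio(sites))


def _snp_effect(cds_offset, alt_tx, gene, genome):
    cds_start = gene.cds_segments[0][0]
    pos0 = cds_start + cds_offset
    site = VariantSite("c", pos0 + 1, genome["c"][pos0], (alt_tx,))
    return coding_effect(site, gene, genome)


class TestCodingEffectSNPs:
    def setup_method(self):
        self.gene, self.genome = plus_gene()

    @pytest.mark.parametrize(
        "offset,alt,term",
        [
            (3 + 2, "C", SYNONYMOUS),  # GCT -> GCC, Ala -> Ala
            (6 + 1, "G", MISSENSE),  # AAA -> AGA, Lys -> Arg
            (9 + 2, "A", STOP_GAINED),  # TGG -> TGA
            (27 + 2, "C", STOP_LOST),  # TAA -> TAC
            (0, "G", START_LOST),  # ATG -> GTG
        ],
    )
    def test_snp_classification(self, offset, alt, term):
        effect = _snp_effect(offset, alt, self.gene, self.genome)
        assert effect.term == term
        assert effect.impact == IMPACT[term]

    def test_malformed_cds_skipped_with_warning(self):
        bad = GeneModel(
            gene_id="bad", chrom="c", strand="+", cds_segments=[(10_000, 10_004)]
        )
        site = VariantSite("c", 10_001, self.genome["c"][10_000], ("C",))
        with pytest.warns(UserWarning, match="not divisible by 3"):
            assert coding_effect(site, bad, self.genome) is None


class TestCodingEffectInDels:
    def setup_method(self):
        self.gene, self.genome = plus_gene()
        self.cds_start = self.gene.cds_segments[0][0]
        self.seq = self.genome["c"]

    def deletion(self, cds_offset, k):
        anchor = self.cds_start + cds_offset - 1
        ref = self.seq[anchor : anchor + 1 + k]
        return VariantSite("c", anchor + 1, ref, (ref[0],))

    def test_single_base_deletion_frameshift(self):
        eff = coding_effect(self.deletion(13, 1), self.gene, self.genome)
        assert eff.term == FRAMESHIFT

    def test_full_codon_deletion_conservative(self):
        eff = coding_effect(self.deletion(12, 3), self.gene, self.genome)
        assert eff.term == CONS_DEL

    def test_codon_straddling_deletion_disruptive(self):
        eff = coding_effect(self.deletion(13, 3), self.gene, self.genome)
        assert eff.term == DISR_DEL

    def test_insertion_on_codon_boundary_conservative(self):
        anchor = self.cds_start + 11  # last base of codon 3; boundary offset 12
        ref = self.seq[anchor]
        site = VariantSite("c", anchor + 1, ref, (ref + "GAC",))
        eff = coding_effect(site, self.gene, self.genome)
        assert eff.term == CONS_INS

    def test_insertion_mid_codon_disruptive(self):
        # inserted sequence chosen so left-alignment cannot slide it onto
        # a codon boundary
        anchor = self.cds_start + 13
        ref = self.seq[anchor]
        site = VariantSite("c", anchor + 1, ref, (ref + "GGG",))
        eff = coding_effect(site, self.gene, self.genome)
        assert eff.term == DISR_INS

    def test_frameshift_secondary_stop_gained_recorded(self):
        eff = coding_effect(self.deletion(13, 1), self.gene, self.genome)
        assert set(eff.secondary) <= {STOP_GAINED, STOP_LOST, START_LOST}


class TestNormalizeIndel:
    def test_left_alignment_of_homopolymer_deletion(self):
        #        0123456789
        seq = "GGTCAAAAGT"
        # deleting the last A (pos 8, ref "AA"->"A") left-aligns to pos 4
        pos, ref, alt = normalize_indel(seq, 7, "AA", "A")
        assert (pos, ref, alt) == (4, "CA", "C")

    def test_already_canonical_untouched(self):
        seq = "GGTCATGCGT"
        assert normalize_indel(seq, 4, "CAT", "C") == (4, "CAT", "C")


class TestGeneFusion:
    def test_intergenic_deletion_is_not_fusion(self, toy):
        site = VariantSite("ChrF", 10, toy.genome["ChrF"][9:14], (toy.genome["ChrF"][9],))
        assert detect_gene_fusion(site, toy.genes, toy.genome) is None

    def test_bidirectional_fusion_on_toy_pair(self, toy):
        fus = [t for t in toy.truth if t.term == FUSION_BI][0]
        site = VariantSite(fus.chrom, fus.pos, fus.ref, (fus.alt,))
        eff = detect_gene_fusion(site, toy.genes, toy.genome)
        assert eff is not None and eff.term == FUSION_BI
        assert set(eff.gene_ids) == {"GeneFusA", "GeneFusB"}
        assert eff.impact == "HIGH"

    def test_deletion_inside_one_gene_is_not_fusion(self, toy):
        gene = [g for g in toy.genes if g.gene_id == "GeneFusA"][0]
        lo, _ = gene.cds_span0
        anchor = lo + 4
        ref = toy.genome["ChrF"][anchor : anchor + 4]
        site = VariantSite("ChrF", anchor + 1, ref, (ref[0],))
        assert detect_gene_fusion(site, toy.genes, toy.genome) is None


class TestSummaries:
    def test_syn_nonsyn_ratio(self):
        effects = [EffectCall(SYNONYMOUS, ("g",), "LOW")] * 8 + [
            EffectCall(MISSENSE, ("g",), "MODERATE")
        ] * 3 + [EffectCall(STOP_GAINED, ("g",), "HIGH")] * 2
        assert syn_nonsyn_ratio(effects) == pytest.approx(8 / 5)

    def test_syn_nonsyn_undefined_without_nonsyn(self):
        effects = [EffectCall(SYNONYMOUS, ("g",), "LOW")] * 3
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(syn_nonsyn_ratio(effects))

    def test_region_summary_percentages(self):
        calls = [RegionCall("intergenic")] * 6 + [RegionCall("exonic", "g")] * 2
        s = region_summary(calls)
        assert s["exonic"] == pytest.approx(25.0)
        assert s.sum() == pytest.approx(100.0)
        assert region_summary([RegionCall("intergenic")]).to_dict() == {
            "intergenic": 100.0
        }


class TestToyFixtureSanity:
    def test_reference_cds_translate_without_internal_stops(self, toy):
        from popdiv.annotation import _cds_context, _translate

        for gene in toy.genes:
            cds, _ = _cds_context(gene, toy.genome)
            prot = _translate(cds)
            assert prot.endswith("*") and "*" not in prot[:-1], gene.gene_id
            assert cds.startswith("ATG")

    def test_effect_calls_match_truth_on_both_strands(self, toy):
        table = annotate_matrix(toy.matrix, toy.genes, toy.genome)
        truth = {(t.chrom, t.pos, t.ref, t.alt): t for t in toy.truth}
        seen_strands = set()
        for _, row in table.iterrows():
            t = truth[(row.chrom, row.pos, row.ref, row.alt)]
            assert row.effect == t.term, (row.pos, t.term, row.effect)
            seen_strands.add(t.strand)
        assert {"+", "-"} <= seen_strands
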