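"""Variant annotation: genomic-region classification and coding-effect
calls in sequence-ontology (SO) terms.

Region labels follow the precedence exonic > UTR > intronic >
upstream/downstream > intergenic, with up/downstream defined as a
configurable flank (default 5 kb) measured from the start codon
(upstream) or stop codon (downstream), strand-aware.

Coding effects compare the reference and mutated CDS under the standard
nuclear genetic code: SNPs yield synonymous/missense/stop_gained/
stop_lost/start_lost; InDels whose length difference is not a multiple
of 3 are frameshift_variant (with secondary start/stop consequences
recomputed from the shifted ORF), in-frame InDels are conservative or
disruptive inframe insertions/deletions depending on codon-boundary
alignment; and a deletion bridging the coding spans of two genes is a
gene fusion ("bidirectional" when the genes lie on opposite strands).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .model import GeneModel, GenotypeMatrix, VariantSite

__all__ = [
    "RegionCall",
    "EffectCall",
    "classify_region",
    "transition_transversion",
    "tstv_ratio",
    "normalize_indel",
    "coding_effect",
    "detect_gene_fusion",
    "syn_nonsyn_ratio",
    "region_summary",
    "annotate_matrix",
    "IMPACT",
]

REGION_RANK = {
    "exonic": 6,
    "utr5": 5,
    "utr3": 5,
    "intronic": 4,
    "upstream": 3,
    "downstream": 3,
    "intergenic": 0,
}

SYNONYMOUS = "synonymous_variant"
MISSENSE = "missense_variant"
STOP_GAINED = "stop_gained"
STOP_LOST = "stop_lost"
START_LOST = "start_lost"  # aka initiator_codon_variant
FRAMESHIFT = "frameshift_variant"
CONS_INS = "conservative_inframe_insertion"
CONS_DEL = "conservative_inframe_deletion"
DISR_INS = "disruptive_inframe_insertion"
DISR_DEL = "disruptive_inframe_deletion"
FUSION_BI = "bidirectional_gene_fusion"
FUSION = "gene_fusion"

#: Impact grade per SO term.
IMPACT = {
    STOP_GAINED: "HIGH",
    STOP_LOST: "HIGH",
    START_LOST: "HIGH",
    FRAMESHIFT: "HIGH",
    FUSION: "HIGH",
    FUSION_BI: "HIGH",
    MISSENSE: "MODERATE",
    CONS_INS: "MODERATE",
    CONS_DEL: "MODERATE",
    DISR_INS: "MODERATE",
    DISR_DEL: "MODERATE",
    SYNONYMOUS: "LOW",
}

NONSYNONYMOUS_SNP_TERMS = {MISSENSE, STOP_GAINED, STOP_LOST, START_LOST}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RegionCall:
    label: str
    gene_id: str | None = None


@dataclass(frozen=True)
class EffectCall:
    """One primary SO term per (variant, transcript), plus secondaries."""

    term: str
    gene_ids: tuple[str, ...]
    impact: str
    secondary: tuple[str, ...] = ()


# ----------------------------------------------------------------- regions
def classify_region(
    site: VariantSite, genes: list[GeneModel], flank: int = 5_000
) -> RegionCall:
    """Label a site by genomic region under the documented precedence."""
    pos0 = site.pos0
    best = RegionCall("intergenic", None)
    best_rank = 0
    for gene in genes:
        if gene.chrom != site.chrom:
            continue
        label = None
        if gene.contains(pos0, gene.cds_segments):
            label = "exonic"
        elif gene.contains(pos0, gene.utr5_segments):
            label = "utr5"
        elif gene.contains(pos0, gene.utr3_segments):
            label = "utr3"
        else:
            lo, hi = gene.span0
            if lo <= pos0 < hi:
                label = "intronic"
            else:
                start_a = gene.start_codon_anchor0
                stop_a = gene.stop_codon_anchor0
                if gene.strand == "+":
                    up = start_a - flank <= pos0 < start_a
                    down = stop_a < pos0 <= stop_a + flank
                else:
                    up = start_a < pos0 <= start_a + flank
                    down = stop_a - flank <= pos0 < stop_a
                if up:
                    label = "upstream"
                elif down:
                    label = "downstream"
        if label is not None and REGION_RANK[label] > best_rank:
            best = RegionCall(label, gene.gene_id)
            best_rank = REGION_RANK[label]
    return best


# ----------------------------------------------------- transitions/transversions
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def transition_transversion(site: VariantSite) -> str:
    """Classify a biallelic SNP as 'ts' or 'tv'."""
    if not site.is_snp or len(site.alts) != 1:
        raise ValueError("ts/tv is defined for biallelic SNPs only")
    return "ts" if frozenset((site.ref, site.alts[0])) in _TRANSITIONS else "tv"


def tstv_ratio(sites) -> float:
    """#transitions / #transversions; NaN (with a warning) when tv = 0."""
    ts = tv = 0
    for site in sites:
        if transition_transversion(site) == "ts":
            ts += 1
        else:
            tv += 1
    if tv == 0:
        warnings.warn("no transversions observed; ts/tv undefined")
        return float("nan")
    return ts / tv


# ------------------------------------------------------------ indel helpers
def normalize_indel(chrom_seq: str, pos: int, ref: str, alt: str):
    """Left-align and trim an indel against the reference sequence.

    ``pos`` is 1-based.  Returns the canonical (pos, ref, alt) with a
    shared single leading anchor base for pure insertions/deletions.
    """
    pos0 = pos - 1
    assert chrom_seq[pos0 : pos0 + len(ref)].upper() == ref.upper(), (
        f"REF mismatch at {pos}: genome has "
        f"{chrom_seq[pos0 : pos0 + len(ref)]!r}, record says {ref!r}"
    )
    ref, alt = ref.upper(), alt.upper()
    # trim common suffix (keep at least one base each)
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim common prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos0 += 1
    # left-shift while the representation is ambiguous
    while (
        len(ref) != len(alt)
        and ref[-1] == alt[-1]
        and min(len(ref), len(alt)) == 1
        and pos0 > 0
    ):
        prev = chrom_seq[pos0 - 1].upper()
        ref = prev + ref[:-1]
        alt = prev + alt[:-1]
        pos0 -= 1
    return pos0 + 1, ref, alt


# ------------------------------------------------------------ coding effects
def _cds_context(gene: GeneModel, genome: dict[str, str]):
    if gene.chrom not in genome:
        raise KeyError(f"gene {gene.gene_id}: unknown chromosome {gene.chrom}")
    seq = genome[gene.chrom]
    positions = gene.cds_positions()
    if gene.strand == "+":
        cds = "".join(seq[p] for p in positions)
    else:
        cds = "".join(seq[p].translate(_COMPLEMENT) for p in positions)
    return cds.upper(), {p: i for i, p in enumerate(positions)}


def _translate(cds: str) -> str:
    usable = len(cds) - len(cds) % 3
    return str(Seq(cds[:usable]).translate())


def _orf_secondary(ref_cds: str, mut_cds: str) -> tuple[str, ...]:
    """Start/stop consequences of a frameshifted ORF."""
    sec = []
    if mut_cds[:3] != "ATG":
        sec.append(START_LOST)
    prot = _translate(mut_cds)
    if "*" not in prot:
        sec.append(STOP_LOST)
    else:
        first = prot.index("*")
        ref_prot = _translate(ref_cds)
        ref_stop = ref_prot.index("*") if "*" in ref_prot else len(ref_prot)
        # a stop strictly earlier (in codons) than the reference stop truncates
        if first < min(ref_stop, len(prot) - 1):
            sec.append(STOP_GAINED)
    return tuple(sec)


def coding_effect(
    site: VariantSite,
    gene: GeneModel,
    genome: dict[str, str],
    alt_index: int = 0,
) -> EffectCall | None:
    """Effect of one ALT allele on a gene's CDS; None when non-coding.

    The variant is left-aligned first.  Genes whose CDS length is not a
    multiple of 3 are skipped with a warning.
    """
    if not gene.is_well_formed:
        warnings.warn(
            f"gene {gene.gene_id}: CDS length {gene.cds_length} not divisible by 3; "
            "annotation skipped"
        )
        return None
    cds, pos_to_idx = _cds_context(gene, genome)
    alt = site.alts[alt_index]
    ref = site.ref
    minus = gene.strand == "-"

    if len(ref) == 1 == len(alt):  # SNP
        idx = pos_to_idx.get(site.pos0)
        if idx is None:
            return None
        codon_i = idx // 3
        offset = idx % 3
        ref_codon = cds[3 * codon_i : 3 * codon_i + 3]
        alt_base = alt.translate(_COMPLEMENT) if minus else alt
        alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
        aa_ref = _translate(ref_codon)
        aa_alt = _translate(alt_codon)
        if codon_i == 0 and alt_codon != "ATG":
            term = START_LOST
        elif aa_ref == "*" and aa_alt != "*":
            term = STOP_LOST
        elif aa_alt == "*" and aa_ref != "*":
            term = STOP_GAINED
        elif aa_ref == aa_alt:
            term = SYNONYMOUS
        else:
            term = MISSENSE
        return EffectCall(term, (gene.gene_id,), IMPACT[term])

    pos, ref, alt = normalize_indel(genome[site.chrom], site.pos, ref, alt)
    pos0 = pos - 1
    if len(ref) > len(alt):  # deletion; ref = anchor + deleted
        deleted = range(pos0 + len(alt), pos0 + len(ref))
        idxs = [pos_to_idx.get(p) for p in deleted]
        in_cds = [i for i in idxs if i is not None]
        if not in_cds:
            return None
        k = len(in_cds)
        if k % 3 != 0:
            mut = _apply_cds_deletion(cds, in_cds)
            sec = _orf_secondary(cds, mut)
            return EffectCall(FRAMESHIFT, (gene.gene_id,), IMPACT[FRAMESHIFT], sec)
        term = CONS_DEL if min(in_cds) % 3 == 0 else DISR_DEL
        return EffectCall(term, (gene.gene_id,), IMPACT[term])
    if len(alt) > len(ref):  # insertion; alt = anchor + inserted
        anchor_idx = pos_to_idx.get(pos0)
        neighbor_idx = pos_to_idx.get(pos0 + 1)
        if anchor_idx is None or neighbor_idx is None:
            return None  # insertion not flanked by CDS on both sides
        ins = alt[len(ref) :]
        if minus:
            boundary = anchor_idx  # inserted before tx index of the anchor
            ins_tx = _revcomp(ins)
        else:
            boundary = anchor_idx + 1
            ins_tx = ins
        k = len(ins)
        if k % 3 != 0:
            mut = cds[:boundary] + ins_tx + cds[boundary:]
            sec = _orf_secondary(cds, mut)
            return EffectCall(FRAMESHIFT, (gene.gene_id,), IMPACT[FRAMESHIFT], sec)
        term = CONS_INS if boundary % 3 == 0 else DISR_INS
        return EffectCall(term, (gene.gene_id,), IMPACT[term])
    return None  # same-length after normalization: not an indel effect


def _apply_cds_deletion(cds: str, idxs: list[int]) -> str:
    drop = set(idxs)
    return "".join(b for i, b in enumerate(cds) if i not in drop)


# --------------------------------------------------------------- gene fusion
def detect_gene_fusion(
    site: VariantSite,
    genes: list[GeneModel],
    genome: dict[str, str] | None = None,
    alt_index: int = 0,
) -> EffectCall | None:
    """Fusion call for a deletion bridging the coding spans of two genes."""
    alt = site.alts[alt_index]
    if len(site.ref) <= len(alt):
        return None
    pos0, ref = site.pos0, site.ref
    if genome is not None:
        pos, ref, alt = normalize_indel(genome[site.chrom], site.pos, ref, alt)
        pos0 = pos - 1
    dstart = pos0 + len(alt)
    dend = pos0 + len(ref)  # deleted interval [dstart, dend), 0-based
    hit = []
    for gene in genes:
        if gene.chrom != site.chrom:
            continue
        lo, hi = gene.cds_span0
        if dstart < hi and dend > lo:
            hit.append(gene)
    if len(hit) < 2:
        return None
    hit.sort(key=lambda g: g.cds_span0[0])
    a, b = hit[0], hit[1]
    term = FUSION_BI if a.strand != b.strand else FUSION
    return EffectCall(term, (a.gene_id, b.gene_id), IMPACT[term])


# ------------------------------------------------------------------ summaries
def syn_nonsyn_ratio(effects: list[EffectCall]) -> float:
    """#synonymous / #(missense + stop_gained + stop_lost + start_lost)."""
    syn = sum(1 for e in effects if e.term == SYNONYMOUS)
    nonsyn = sum(1 for e in effects if e.term in NONSYNONYMOUS_SNP_TERMS)
    if nonsyn == 0:
        warnings.warn("no non-synonymous calls; syn/nonsyn undefined")
        return float("nan")
    return syn / nonsyn


def region_summary(calls: list[RegionCall]) -> pd.Series:
    """Percentage of sites per region label (sums to 100 up to rounding)."""
    if not calls:
        return pd.Series(dtype=float)
    labels = pd.Series([c.label for c in calls])
    return labels.value_counts().sort_index() / len(labels) * 100.0


# ----------------------------------------------------------- whole-matrix run
def annotate_matrix(
    matrix: GenotypeMatrix,
    genes: list[GeneModel],
    genome: dict[str, str],
    flank: int = 5_000,
) -> pd.DataFrame:
    """Region + effect annotation table for every (site, first ALT)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    for site in matrix.sites:
        cgenes = by_chrom.get(site.chrom, [])
        region = classify_region(site, cgenes, flank=flank)
        effect = None
        if not site.is_snp:
            effect = detect_gene_fusion(site, cgenes, genome)
        if effect is None:
            for gene in cgenes:
                lo, hi = gene.cds_span0
                if site.pos0 < hi and site.end0 > lo and gene.is_well_formed:
                    effect = coding_effect(site, gene, genome)
                    if effect is not None:
                        break
        rows.append(
            {
                "chrom": site.chrom,
                "pos": site.pos,
                "ref": site.ref,
                "alt": site.alts[0],
                "variant_class": site.variant_class,
                "region": region.label,
                "gene": ",".join(effect.gene_ids) if effect else (region.gene_id or ""),
                "effect": effect.term if effect else "",
                "secondary": "&".join(effect.secondary) if effect else "",
                "impact": effect.impact if effect else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "variant_class",
            "region", "gene", "effect", "secondary", "impact",
        ],
    )
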