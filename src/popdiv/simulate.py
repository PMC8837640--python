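"""Synthetic-data generation with a fully known truth ledger.

Three generators cover the three statistical regimes the pipeline is
tested against:

* linkage-free Hardy-Weinberg genotypes at configurable allele-frequency
  laws (fixed p, uniform, or a neutral site-frequency spectrum ∝ 1/i),
  with MCAR missingness — the substrate of the filter and diversity
  stages;
* a copying-Markov haplotype model whose allele correlation between
  sites at distance d is exp(−d/(2L)), so dosage r²(d) ≈ exp(−d/L) with
  an analytically known half-decay distance of L·ln 2 — the substrate
  of the LD stage;
* a toy genome (FASTA + GFF3 + VCF) with designed genes on both strands
  and one implanted variant per sequence-ontology effect class, each
  recorded in a truth ledger — the substrate of the annotation stage.

All randomness flows from a single seed; outputs are byte-identical
across runs with the same configuration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import annotation as ann
from .io_formats import (
    DEFAULT_YEAR_BINS,
    write_fasta,
    write_gff3,
    write_sample_meta,
    write_vcf,
)
from .model import MISSING, GeneModel, GenotypeMatrix, SampleMeta, VariantSite

__all__ = [
    "SubpopSpec",
    "SimConfig",
    "simulate_frequencies",
    "simulate_sites",
    "simulate_genotypes",
    "simulate_ld_haplotypes",
    "haplotypes_to_matrix",
    "simulate_subpops",
    "TruthRecord",
    "ToyGenome",
    "make_toy_genome",
    "write_toy_genome",
    "simulate_population_dataset",
    "PopulationDataset",
]

_BASES = np.array(list("ACGT"))
_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
#: Default probability that a simulated substitution is a transition;
#: chosen so the simulated genome-wide ts/tv ratio is ≈ 1.89.
DEFAULT_TS_PROB = 1.89 / 2.89


# ------------------------------------------------------------------ config
@dataclass
class SubpopSpec:
    """One sub-population: size, frequency law and release-year bin."""

    n_samples: int
    law: str = "sfs"  # fixed | uniform | sfs
    p: float = 0.3  # for law == "fixed"
    p_range: tuple[float, float] = (0.0, 1.0)  # for law == "uniform"
    year_range: tuple[int, int] = (1963, 2017)


@dataclass
class SimConfig:
    """Study-scale defaults for the population simulator.

    Sub-population sizes and year bins mirror a 181-accession cultivar
    panel split into five breeding eras; the genome is represented at
    desk scale by two 1 Mb chromosomes carrying ~3000 SNP sites with an
    LD length scale of 100 kb.
    """

    subpops: dict[str, SubpopSpec] = field(
        default_factory=lambda: {
            name: SubpopSpec(n_samples=n, law="sfs", year_range=DEFAULT_YEAR_BINS[name])
            for name, n in [("SA", 12), ("SB", 8), ("SC", 7), ("SD", 90), ("SE", 64)]
        }
    )
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"Chr01": 1_000_000, "Chr02": 1_000_000}
    )
    n_sites: int = 3_000
    missing_rate: float = 0.02
    #: inbreeding-style F; P(het) = 2pq(1-F).  High by default: the panels
    #: this emulates are self-pollinating cultivar lines, nearly homozygous.
    het_deficit: float = 0.95
    ld_length_scale: int = 100_000  # L (bp) of the copying-Markov model
    genes_per_chrom: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.missing_rate, self.het_deficit):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.ld_length_scale <= 0:
            raise ValueError("ld_length_scale must be positive")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# -------------------------------------------------------------- frequencies
def simulate_frequencies(
    n_sites: int,
    law: str = "sfs",
    *,
    p: float = 0.3,
    p_range: tuple[float, float] = (0.0, 1.0),
    n_chromosome_copies: int = 100,
    rng=None,
) -> np.ndarray:
    """Draw i.i.d. per-site ALT-allele frequencies.

    ``fixed``: all sites at ``p``;  ``uniform``: U(p_range);
    ``sfs``: a neutral spectrum, allele count i in 1..n−1 with
    P(i) ∝ 1/i over n = ``n_chromosome_copies`` sequences, frequency i/n.
    """
    rng = _rng(rng)
    if law == "fixed":
        return np.full(n_sites, float(p))
    if law == "uniform":
        lo, hi = p_range
        return rng.uniform(lo, hi, n_sites)
    if law == "sfs":
        n = n_chromosome_copies
        i = np.arange(1, n)
        w = 1.0 / i
        counts = rng.choice(i, size=n_sites, p=w / w.sum())
        return counts / n
    raise ValueError(f"unknown frequency law {law!r}")


def simulate_sites(
    positions: np.ndarray,
    chrom: str = "Chr01",
    rng=None,
    ts_prob: float = DEFAULT_TS_PROB,
    ref_bases: str | None = None,
) -> list[VariantSite]:
    """Biallelic SNP sites at given 1-based positions with ts-biased ALTs."""
    rng = _rng(rng)
    sites = []
    for j, pos in enumerate(np.asarray(positions)):
        ref = ref_bases[j] if ref_bases is not None else str(rng.choice(_BASES))
        if rng.random() < ts_prob:
            alt = _TS_PARTNER[ref]
        else:
            choices = [b for b in "ACGT" if b != ref and b != _TS_PARTNER[ref]]
            alt = str(rng.choice(choices))
        sites.append(VariantSite(chrom, int(pos), ref, (alt,)))
    return sites


# ---------------------------------------------------------------- genotypes
def simulate_genotypes(
    frequencies: np.ndarray,
    n_samples: int,
    missing_rate: float = 0.0,
    rng=None,
    *,
    sites: list[VariantSite] | None = None,
    chrom: str = "Chr01",
    positions: np.ndarray | None = None,
    chrom_length: int | None = None,
    het_deficit: float = 0.0,
    exact_frequency: bool = False,
    sample_prefix: str = "S",
    samples: list[str] | None = None,
) -> GenotypeMatrix:
    """Linkage-free Hardy-Weinberg diploid genotypes.

    By default each allele of each call is an independent Bernoulli(p)
    draw (with an optional inbreeding-style heterozygote deficit F that
    copies one allele with probability F).  ``exact_frequency=True``
    instead *conditions on the sample allele count*: exactly
    ``round(2N·p)`` ALT alleles are dealt at random among the 2N allele
    slots, i.e. random mating at the realised frequency — the sampling
    scheme under which per-site diversity equals
    2p(1−p)·2N/(2N−1) in closed form.  Missing calls are MCAR at
    ``missing_rate``.
    """
    rng = _rng(rng)
    freqs = np.asarray(frequencies, dtype=float)
    S = len(freqs)
    if sites is None:
        if positions is None:
            length = chrom_length or max(100 * S, 1000)
            positions = np.sort(rng.choice(np.arange(1, length + 1), size=S, replace=False))
        sites = simulate_sites(positions, chrom=chrom, rng=rng)
    if exact_frequency:
        slots = np.arange(2 * n_samples)
        pool = slots[None, :] < np.rint(freqs * 2 * n_samples)[:, None]
        pool = rng.permuted(pool, axis=1)
        a = pool[:, :n_samples]
        b = pool[:, n_samples:]
    else:
        a = rng.random((S, n_samples)) < freqs[:, None]
        b = rng.random((S, n_samples)) < freqs[:, None]
        if het_deficit > 0:
            copy = rng.random((S, n_samples)) < het_deficit
            b = np.where(copy, a, b)
    calls = np.stack([a, b], axis=2).astype(np.int16)
    if missing_rate > 0:
        miss = rng.random((S, n_samples)) < missing_rate
        calls[miss] = MISSING
    if samples is None:
        samples = [f"{sample_prefix}{j:03d}" for j in range(n_samples)]
    return GenotypeMatrix(sites, samples, calls)


# --------------------------------------------------------------- LD process
def simulate_ld_haplotypes(
    positions: np.ndarray, L: float, n_haplotypes: int, rng=None
) -> np.ndarray:
    """0/1 haplotypes with allele correlation exp(−d/(2L)) between sites.

    A symmetric two-state Markov chain runs along each haplotype: the
    first site is Bernoulli(1/2) and each subsequent site copies the
    previous allele with probability (1+ρ)/2, ρ = exp(−Δd/(2L)).  The
    chain's correlation telescopes, so sites at distance d have allele
    correlation exp(−d/(2L)) and expected dosage r²(d) = exp(−d/L).
    """
    rng = _rng(rng)
    positions = np.asarray(positions, dtype=np.int64)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    if L <= 0:
        raise ValueError("L must be positive")
    S = len(positions)
    H = n_haplotypes
    hap = np.empty((H, S), dtype=np.int8)
    hap[:, 0] = rng.random(H) < 0.5
    rho = np.exp(-np.diff(positions) / (2.0 * L))
    u = rng.random((H, S - 1))
    flip = u >= (1.0 + rho)[None, :] / 2.0
    for k in range(1, S):
        hap[:, k] = hap[:, k - 1] ^ flip[:, k - 1]
    return hap


def haplotypes_to_matrix(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    chrom: str = "Chr01",
    rng=None,
    sample_prefix: str = "S",
) -> GenotypeMatrix:
    """Pair consecutive haplotypes into diploids (random mating)."""
    rng = _rng(rng)
    H, S = haplotypes.shape
    if H % 2:
        raise ValueError("need an even number of haplotypes to form diploids")
    sites = simulate_sites(np.asarray(positions), chrom=chrom, rng=rng)
    a = haplotypes[0::2].T  # (S, N)
    b = haplotypes[1::2].T
    calls = np.stack([a, b], axis=2).astype(np.int16)
    samples = [f"{sample_prefix}{j:03d}" for j in range(H // 2)]
    return GenotypeMatrix(sites, samples, calls)


# ------------------------------------------------------------- sub-populations
def simulate_subpops(
    specs: dict[str, SubpopSpec],
    n_sites: int,
    missing_rate: float = 0.0,
    rng=None,
    *,
    chrom: str = "Chr01",
    chrom_length: int = 1_000_000,
) -> tuple[GenotypeMatrix, list[SampleMeta], dict]:
    """Genotypes with sub-population-specific frequency laws at shared sites.

    Returns the combined matrix, metadata with years drawn inside each
    sub-population's bin, and a truth dict holding the per-sub-population
    frequency vectors.
    """
    if len(specs) < 2:
        raise ValueError("need at least two sub-populations")
    rng = _rng(rng)
    positions = np.sort(
        rng.choice(np.arange(1, chrom_length + 1), size=n_sites, replace=False)
    )
    sites = simulate_sites(positions, chrom=chrom, rng=rng)
    blocks = []
    samples: list[str] = []
    meta: list[SampleMeta] = []
    truth: dict = {"frequencies": {}, "laws": {}}
    for name in specs:
        spec = specs[name]
        freqs = simulate_frequencies(
            n_sites,
            spec.law,
            p=spec.p,
            p_range=spec.p_range,
            n_chromosome_copies=2 * spec.n_samples,
            rng=rng,
        )
        sub = simulate_genotypes(
            freqs, spec.n_samples, missing_rate, rng, sites=sites,
            sample_prefix=f"{name}_",
        )
        blocks.append(sub.calls)
        samples += sub.samples
        lo, hi = spec.year_range
        yrs = rng.integers(lo, hi + 1, size=spec.n_samples)
        meta += [
            SampleMeta(sample=s, release_year=int(y), subpop=name)
            for s, y in zip(sub.samples, yrs)
        ]
        truth["frequencies"][name] = freqs
        truth["laws"][name] = asdict(spec)
    calls = np.concatenate(blocks, axis=1)
    return GenotypeMatrix(sites, samples, calls), meta, truth


# ------------------------------------------------------------- toy genome
@dataclass(frozen=True)
class TruthRecord:
    """Ledger entry for one implanted variant."""

    chrom: str
    pos: int
    ref: str
    alt: str
    term: str
    gene_ids: tuple[str, ...]
    strand: str


@dataclass
class ToyGenome:
    genome: dict[str, str]
    genes: list[GeneModel]
    matrix: GenotypeMatrix
    truth: list[TruthRecord]


_SAFE_CODONS = [
    c
    for c in (
        a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT"
    )
    if c not in ("TAA", "TAG", "TGA", "ATG")
]


class _GeneDesign:
    """A designed two-exon gene in transcription space, with implants.

    The coding sequence is ATG + fixed implant codons + random filler +
    TAA, split into two CDS exons by an intron, flanked by UTRs.  Implant
    specs are expressed in CDS coordinates and mapped to genomic
    coordinates for either strand.
    """

    UTR5 = 120
    UTR3 = 120
    INTRON = 150
    N_CODONS = 40  # incl. start and stop
    EXON1_CODONS = 25  # multiple-of-3 split keeps downstream phases simple

    # implant layout (codon indices, all interior to their exon)
    SYN_CODON = 5
    MIS_CODON = 8
    STOPG_CODON = 11
    FS_CODON = 14
    DEL_CODON = 17
    INS_CODON = 20
    START_CODON = 0
    STOP_CODON = N_CODONS - 1  # the TAA itself, in exon 2

    def __init__(self, gene_id: str, strand: str, rng: np.random.Generator):
        self.gene_id = gene_id
        self.strand = strand
        codons = ["ATG"]
        for _ in range(1, self.N_CODONS - 1):
            codons.append(str(rng.choice(_SAFE_CODONS)))
        codons.append("TAA")
        # designed implant codons
        codons[self.SYN_CODON] = "GCT"  # Ala; 3rd-position T->C stays Ala
        codons[self.MIS_CODON] = "AAA"  # Lys; mid A->G gives Arg
        codons[self.STOPG_CODON] = "TGG"  # Trp; 3rd G->A gives TGA stop
        self.codons = codons
        cds = self.cds
        e1 = 3 * self.EXON1_CODONS
        self.tx_seq = (
            _random_dna(self.UTR5, rng)
            + cds[:e1]
            + _random_dna(self.INTRON, rng)
            + cds[e1:]
            + _random_dna(self.UTR3, rng)
        )

    @property
    def cds(self) -> str:
        return "".join(self.codons)

    # -- coordinate mapping ---------------------------------------------
    def cds_to_tx(self, o: int) -> int:
        e1 = 3 * self.EXON1_CODONS
        if o < e1:
            return self.UTR5 + o
        return self.UTR5 + e1 + self.INTRON + (o - e1)

    def region_len(self) -> int:
        return len(self.tx_seq)

    def genomic(self, region_start: int, t: int) -> int:
        """Genomic 0-based position of tx offset t."""
        if self.strand == "+":
            return region_start + t
        return region_start + self.region_len() - 1 - t

    # -- implant spec ----------------------------------------------------
    def implants(self):
        """(term, kind, payload) tuples in CDS coordinates."""
        cds = self.cds
        return [
            (ann.SYNONYMOUS, "snp", (3 * self.SYN_CODON + 2, "C")),
            (ann.MISSENSE, "snp", (3 * self.MIS_CODON + 1, "G")),
            (ann.STOP_GAINED, "snp", (3 * self.STOPG_CODON + 2, "A")),
            (ann.START_LOST, "snp", (0, "G")),  # ATG -> GTG
            (ann.STOP_LOST, "snp", (3 * self.STOP_CODON + 2, "C")),  # TAA -> TAC
            (ann.FRAMESHIFT, "del", (3 * self.FS_CODON + 1, 1)),
            (ann.CONS_DEL, "del", (3 * self.DEL_CODON, 3)),
            (ann.CONS_INS, "ins", (3 * self.INS_CODON, "GAA")),
        ]


def _random_dna(n: int, rng) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _genotype_pattern(n_samples: int, rng) -> np.ndarray:
    """A polymorphic diploid pattern with hom-ref, het and hom-alt calls."""
    gts = [(0, 0)] * (n_samples - 4) + [(0, 1), (0, 1), (1, 1), (1, 1)]
    rng.shuffle(gts)
    return np.array(gts, dtype=np.int16)


def make_toy_genome(seed: int = 0, n_samples: int = 8) -> ToyGenome:
    """FASTA + gene models + VCF matrix with one implant per SO class.

    Chromosome ``ChrS`` carries one gene per strand, each receiving the
    full set of single-gene implants (synonymous, missense, stop_gained,
    start_lost, stop_lost, frameshift, conservative inframe deletion and
    insertion); chromosome ``ChrF`` carries an opposite-strand gene pair
    bridged by a deletion implanted as a bidirectional gene fusion.
    Every implant is recorded in the truth ledger exactly once.
    """
    rng = _rng(seed)
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    truth: list[TruthRecord] = []
    sites: list[VariantSite] = []
    call_rows: list[np.ndarray] = []

    # ------------------------------------------------------------- ChrS
    seq = _random_dna(600, rng)  # leading intergenic spacer
    for strand, gid in [("+", "GenePlus"), ("-", "GeneMinus")]:
        # redraw the design until every implanted indel is already in its
        # left-aligned canonical VCF representation (no ambiguity shifts)
        for _ in range(200):
            design = _GeneDesign(gid, strand, rng)
            region_start = len(seq)
            region = design.tx_seq if strand == "+" else ann._revcomp(design.tx_seq)
            trial = seq + region
            implanted = []
            for term, kind, payload in design.implants():
                site = _implant_variant(trial, design, region_start, kind, payload, "ChrS")
                if not site.is_snp:
                    norm = ann.normalize_indel(trial, site.pos, site.ref, site.alts[0])
                    if norm != (site.pos, site.ref, site.alts[0]):
                        implanted = None
                        break
                implanted.append((term, site))
            if implanted is not None:
                break
        else:  # pragma: no cover - redraw converges quickly in practice
            raise RuntimeError("could not build a left-align-stable gene design")
        seq = trial + _random_dna(700, rng)
        R = design.region_len()

        # gene model segments (genomic 0-based half-open)
        def tx_iv(a: int, b: int) -> tuple[int, int]:
            if strand == "+":
                return (region_start + a, region_start + b)
            return (region_start + R - b, region_start + R - a)

        u5 = tx_iv(0, design.UTR5)
        e1 = tx_iv(design.UTR5, design.UTR5 + 3 * design.EXON1_CODONS)
        e2a = design.UTR5 + 3 * design.EXON1_CODONS + design.INTRON
        e2 = tx_iv(e2a, e2a + 3 * (design.N_CODONS - design.EXON1_CODONS))
        u3 = tx_iv(e2a + 3 * (design.N_CODONS - design.EXON1_CODONS), R)
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom="ChrS",
                strand=strand,
                cds_segments=[e1, e2],
                utr5_segments=[u5],
                utr3_segments=[u3],
            )
        )

        for term, site in implanted:
            sites.append(site)
            call_rows.append(_genotype_pattern(n_samples, rng))
            truth.append(
                TruthRecord(
                    "ChrS", site.pos, site.ref, site.alts[0], term, (gid,), strand
                )
            )
    genome["ChrS"] = seq

    # ------------------------------------------------------------- ChrF
    fseq = _random_dna(400, rng)
    gap = 20
    fus_genes = []
    for strand, gid in [("+", "GeneFusA"), ("-", "GeneFusB")]:
        n_codons = 30
        codons = ["ATG"] + [str(rng.choice(_SAFE_CODONS)) for _ in range(n_codons - 2)] + ["TAA"]
        cds = "".join(codons)
        region_start = len(fseq)
        region = cds if strand == "+" else ann._revcomp(cds)
        fseq += region
        fus_genes.append(
            GeneModel(
                gene_id=gid,
                chrom="ChrF",
                strand=strand,
                cds_segments=[(region_start, region_start + len(cds))],
            )
        )
        if strand == "+":
            fseq += _random_dna(gap, rng)
    fseq += _random_dna(400, rng)
    genes += fus_genes
    # deletion from inside GeneFusA's CDS across the gap into GeneFusB's CDS
    a_end = fus_genes[0].cds_span0[1]
    b_start = fus_genes[1].cds_span0[0]
    danchor = a_end - 10 - 1  # anchor base inside gene A
    dlen = 10 + gap + 9  # 10 bp of A, the gap, 9 bp of B (39 < 50)
    ref = fseq[danchor : danchor + 1 + dlen]
    alt = fseq[danchor]
    fsite = VariantSite("ChrF", danchor + 1, ref, (alt,))
    sites.append(fsite)
    call_rows.append(_genotype_pattern(n_samples, rng))
    truth.append(
        TruthRecord(
            "ChrF", fsite.pos, ref, alt, ann.FUSION_BI, ("GeneFusA", "GeneFusB"), "+-"
        )
    )
    assert b_start > danchor + 1 and danchor + 1 + dlen > b_start
    genome["ChrF"] = fseq

    samples = [f"T{j:02d}" for j in range(n_samples)]
    calls = np.stack(call_rows)
    matrix = GenotypeMatrix(sites, samples, calls)
    # the ledger must cover every emitted variant exactly once
    assert len({(t.chrom, t.pos, t.ref, t.alt) for t in truth}) == len(truth) == len(sites)
    return ToyGenome(genome=genome, genes=genes, matrix=matrix, truth=truth)


def _implant_variant(
    seq: str,
    design: _GeneDesign,
    region_start: int,
    kind: str,
    payload,
    chrom: str,
) -> VariantSite:
    """Map a CDS-space implant spec to a genomic VCF-style variant."""
    strand = design.strand
    R = design.region_len()
    if kind == "snp":
        o, alt_tx = payload
        t = design.cds_to_tx(o)
        g = design.genomic(region_start, t)
        ref = seq[g]
        alt = alt_tx if strand == "+" else alt_tx.translate(ann._COMPLEMENT)
        assert ref != alt
        return VariantSite(chrom, g + 1, ref, (alt,))
    if kind == "del":
        o, k = payload
        t = design.cds_to_tx(o)
        if strand == "+":
            gstart = region_start + t
        else:
            gstart = region_start + R - t - k
        anchor = gstart - 1
        ref = seq[anchor : anchor + 1 + k]
        alt = seq[anchor]
        return VariantSite(chrom, anchor + 1, ref, (alt,))
    if kind == "ins":
        o, ins_tx = payload
        t = design.cds_to_tx(o)  # insertion before this tx offset
        if strand == "+":
            anchor = region_start + t - 1
            ins = ins_tx
        else:
            anchor = region_start + R - 1 - t
            ins = ann._revcomp(ins_tx)
        ref = seq[anchor]
        return VariantSite(chrom, anchor + 1, ref, (ref + ins,))
    raise ValueError(kind)


def write_toy_genome(toy: ToyGenome, outdir) -> dict[str, Path]:
    """Write FASTA/GFF3/VCF/metadata/truth files; returns path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "toy.fasta",
        "gff3": outdir / "toy.gff3",
        "vcf": outdir / "toy.vcf",
        "meta": outdir / "toy_meta.tsv",
        "truth": outdir / "toy_truth.json",
    }
    write_fasta(toy.genome, paths["fasta"])
    write_gff3(toy.genes, paths["gff3"])
    write_vcf(toy.matrix, paths["vcf"])
    metas = [
        SampleMeta(sample=s, release_year=2001 + (j % 10), subpop="SD")
        for j, s in enumerate(toy.matrix.samples)
    ]
    write_sample_meta(metas, paths["meta"])
    paths["truth"].write_text(
        json.dumps([asdict(t) for t in toy.truth], indent=1) + "\n"
    )
    return paths


# -------------------------------------------------- full population dataset
@dataclass
class PopulationDataset:
    """Simulated inputs for an end-to-end pipeline run."""

    matrix: GenotypeMatrix
    meta: list[SampleMeta]
    genome: dict[str, str]
    genes: list[GeneModel]
    truth: dict


def _random_gene(gene_id, chrom, strand, start0, rng, n_codons=250) -> tuple[GeneModel, str]:
    codons = ["ATG"] + [str(rng.choice(_SAFE_CODONS)) for _ in range(n_codons - 2)] + ["TAA"]
    cds = "".join(codons)
    region = cds if strand == "+" else ann._revcomp(cds)
    model = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        cds_segments=[(start0, start0 + len(cds))],
    )
    return model, region


def simulate_population_dataset(config: SimConfig) -> PopulationDataset:
    """Genome + genes + LD-structured sub-population genotypes + metadata.

    Chromosome sequences are random DNA with single-exon genes placed at
    regular intervals; SNP REF alleles are taken from the genome so that
    effect annotation is internally consistent.  Haplotypes carry the
    copying-Markov LD structure with length scale ``ld_length_scale``;
    sub-population allele-frequency differences are induced by drawing
    each sub-population's haplotype pool independently.
    """
    rng = _rng(config.seed)
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    for chrom, length in config.chrom_lengths.items():
        seq = _random_dna(length, rng)
        spacing = length // (config.genes_per_chrom + 1)
        for gi in range(config.genes_per_chrom):
            strand = "+" if gi % 2 == 0 else "-"
            start0 = spacing * (gi + 1)
            model, region = _random_gene(
                f"{chrom}.G{gi + 1:02d}", chrom, strand, start0, rng
            )
            seq = seq[:start0] + region + seq[start0 + len(region) :]
            genes.append(model)
        genome[chrom] = seq

    chroms = list(config.chrom_lengths)
    per_chrom = np.full(len(chroms), config.n_sites // len(chroms))
    per_chrom[: config.n_sites % len(chroms)] += 1
    all_sites: list[VariantSite] = []
    blocks: list[np.ndarray] = []
    truth: dict = {"ld_length_scale": config.ld_length_scale, "positions": {}}
    samples: list[str] = []
    meta: list[SampleMeta] = []
    first = True
    for chrom, n_s in zip(chroms, per_chrom):
        length = config.chrom_lengths[chrom]
        positions = np.sort(
            rng.choice(np.arange(1, length + 1), size=int(n_s), replace=False)
        )
        refs = [genome[chrom][p - 1] for p in positions]
        csites = simulate_sites(positions, chrom=chrom, rng=rng, ref_bases=refs)
        truth["positions"][chrom] = positions
        col_blocks = []
        for name, spec in config.subpops.items():
            hap = simulate_ld_haplotypes(
                positions, config.ld_length_scale, 2 * spec.n_samples, rng
            )
            a = hap[0::2].T
            b = hap[1::2].T
            if config.het_deficit > 0:  # autozygosity: copy the first gamete
                auto = rng.random(a.shape) < config.het_deficit
                b = np.where(auto, a, b)
            calls = np.stack([a, b], axis=2).astype(np.int16)
            if config.missing_rate > 0:
                miss = rng.random(calls.shape[:2]) < config.missing_rate
                calls[miss] = MISSING
            col_blocks.append(calls)
            if first:
                subsamples = [f"{name}_{j:03d}" for j in range(spec.n_samples)]
                samples += subsamples
                lo, hi = spec.year_range
                yrs = rng.integers(lo, hi + 1, size=spec.n_samples)
                meta += [
                    SampleMeta(sample=s, release_year=int(y), subpop=name)
                    for s, y in zip(subsamples, yrs)
                ]
        first = False
        all_sites += csites
        blocks.append(np.concatenate(col_blocks, axis=1))
    calls = np.concatenate(blocks, axis=0)
    matrix = GenotypeMatrix(all_sites, samples, calls)
    return PopulationDataset(matrix=matrix, meta=meta, genome=genome, genes=genes, truth=truth)
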