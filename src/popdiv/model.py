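"""Core in-memory containers for a resequencing variant panel.

The central object is :class:`GenotypeMatrix`: an ordered set of variant
sites by an ordered set of diploid samples, with each call stored as an
unordered pair of allele indices (``-1`` marks a missing call).  All
statistics in this package (site filters, nucleotide diversity, PIC,
dosage r²) are computed from this matrix; phase is deliberately not
represented because every statistic in scope is phase-free.

Coordinates: variant and feature positions are 1-based on the public
surface (as in VCF/GFF3); internal interval arithmetic is 0-based
half-open, and conversion happens only at parse/serialize boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

MISSING = -1
_DNA = frozenset("ACGT")
#: InDels longer than this are out of scope ("small" insertions/deletions).
MAX_INDEL_LEN = 50

SNP = "SNP"
INDEL = "InDel"


@dataclass(frozen=True)
class VariantSite:
    """One variant record: chromosome, 1-based position, REF and ALT alleles."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not isinstance(self.alts, tuple):
            object.__setattr__(self, "alts", tuple(self.alts))
        for allele in (self.ref, *self.alts):
            if not allele or set(allele) - _DNA:
                raise ValueError(f"invalid allele {allele!r} at {self.chrom}:{self.pos}")
        if not self.alts:
            raise ValueError(f"site {self.chrom}:{self.pos} has no ALT allele")
        lengths = [len(self.ref)] + [len(a) for a in self.alts]
        max_diff = max(lengths) - min(lengths)
        if max_diff == 0 and max(lengths) > 1:
            raise ValueError(
                f"multi-nucleotide substitution at {self.chrom}:{self.pos} is unsupported"
            )
        if max_diff >= MAX_INDEL_LEN:
            raise ValueError(
                f"InDel at {self.chrom}:{self.pos} has length difference "
                f"{max_diff} >= {MAX_INDEL_LEN} bp"
            )

    @property
    def pos0(self) -> int:
        """0-based start of the REF allele."""
        return self.pos - 1

    @property
    def end0(self) -> int:
        """0-based half-open end of the REF allele."""
        return self.pos - 1 + len(self.ref)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def variant_class(self) -> str:
        return SNP if self.is_snp else INDEL

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref, *self.alts)

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alts)


class GenotypeMatrix:
    """Samples x sites diploid genotype matrix.

    Parameters
    ----------
    sites
        Variant sites; re-sorted by (chrom, pos) on construction.
    samples
        Sample identifiers, order preserved.
    calls
        Integer array of shape ``(n_sites, n_samples, 2)`` of allele
        indices into ``site.alleles``; ``-1`` marks a missing allele.
        A call with any missing allele is normalised to fully missing,
        and the two alleles of a call are stored sorted (unordered pair).
    """

    def __init__(self, sites, samples, calls, *, sort: bool = True):
        sites = list(sites)
        samples = list(samples)
        calls = np.asarray(calls, dtype=np.int16)
        if calls.shape != (len(sites), len(samples), 2):
            raise ValueError(
                f"calls shape {calls.shape} != ({len(sites)}, {len(samples)}, 2)"
            )
        calls = calls.copy()
        # partial calls (one missing allele) become fully missing
        partial = (calls == MISSING).any(axis=2)
        calls[partial] = MISSING
        calls.sort(axis=2)  # unordered pair, canonical order; (-1,-1) stays put
        if sort:
            order = sorted(range(len(sites)), key=lambda i: (sites[i].chrom, sites[i].pos))
            if order != list(range(len(sites))):
                sites = [sites[i] for i in order]
                calls = calls[order]
        keys = [s.key for s in sites]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chrom, pos, ref, alts) records")
        for i, site in enumerate(sites):
            if calls[i].max(initial=MISSING) >= 1 + len(site.alts):
                raise ValueError(f"allele index out of range at {site.chrom}:{site.pos}")
        self.sites: list[VariantSite] = sites
        self.samples: list[str] = samples
        self.calls: np.ndarray = calls

    # ------------------------------------------------------------------ size
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    # ------------------------------------------------------------- per-site
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_sites, n_samples): True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def allele_counts(self, i: int) -> np.ndarray:
        """Counts of each allele (length ``1 + n_alts``) over non-missing calls."""
        site = self.sites[i]
        flat = self.calls[i].ravel()
        flat = flat[flat >= 0]
        return np.bincount(flat, minlength=1 + len(site.alts))

    def dosages(self, i: int) -> np.ndarray:
        """Per-sample count of the ALT allele at a biallelic site.

        Returns a float vector with ``nan`` for missing calls.
        """
        site = self.sites[i]
        if len(site.alts) != 1:
            raise ValueError(
                f"dosages are defined for biallelic sites; {site.chrom}:{site.pos} "
                f"has {len(site.alts)} ALT alleles"
            )
        c = self.calls[i]
        d = (c == 1).sum(axis=1).astype(float)
        d[c[:, 0] == MISSING] = np.nan
        return d

    def dosage_matrix(self) -> np.ndarray:
        """(n_sites, n_samples) ALT-dosage matrix; requires all sites biallelic."""
        for site in self.sites:
            if len(site.alts) != 1:
                raise ValueError("dosage_matrix requires all sites biallelic")
        d = (self.calls == 1).sum(axis=2).astype(float)
        d[self.missing_mask()] = np.nan
        return d

    # ------------------------------------------------------------- subsets
    def take_sites(self, indices) -> "GenotypeMatrix":
        indices = np.asarray(indices, dtype=int)
        sites = [self.sites[i] for i in indices]
        return GenotypeMatrix(sites, self.samples, self.calls[indices], sort=False)

    def take_samples(self, which) -> "GenotypeMatrix":
        """Subset columns by sample names or integer indices (order preserved)."""
        if len(which) and isinstance(next(iter(which)), str):
            lookup = {s: j for j, s in enumerate(self.samples)}
            idx = [lookup[name] for name in which]
        else:
            idx = list(which)
        samples = [self.samples[j] for j in idx]
        return GenotypeMatrix(self.sites, samples, self.calls[:, idx], sort=False)

    def replace_sites(self, sites, calls=None) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sites, self.samples, self.calls if calls is None else calls
        )

    # ------------------------------------------------------------ equality
    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and [s.key for s in self.sites] == [s.key for s in other.sites]
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GenotypeMatrix({self.n_sites} sites x {self.n_samples} samples)"


@dataclass
class SampleMeta:
    """Accession metadata: id, year of release, and sub-population label."""

    sample: str
    release_year: int
    subpop: str | None = None


@dataclass
class GeneModel:
    """Strand-aware single-transcript gene model.

    Segment lists hold 0-based half-open genomic intervals in
    *transcription* order (for a '-' strand gene the first CDS segment is
    the genomically last one).
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    cds_segments: list[tuple[int, int]]
    utr5_segments: list[tuple[int, int]] = field(default_factory=list)
    utr3_segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.cds_segments:
            raise ValueError(f"gene {self.gene_id} has no CDS segments")
        genomic = sorted(self.cds_segments)
        for (a0, a1), (b0, b1) in zip(genomic, genomic[1:]):
            if b0 < a1:
                raise ValueError(f"gene {self.gene_id}: overlapping CDS segments")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    @property
    def is_well_formed(self) -> bool:
        """CDS length divisible by 3 (a translatable ORF)."""
        return self.cds_length % 3 == 0

    @property
    def span0(self) -> tuple[int, int]:
        """Genomic 0-based half-open span over all annotated segments."""
        segs = self.cds_segments + self.utr5_segments + self.utr3_segments
        return min(s for s, _ in segs), max(e for _, e in segs)

    @property
    def cds_span0(self) -> tuple[int, int]:
        return (
            min(s for s, _ in self.cds_segments),
            max(e for _, e in self.cds_segments),
        )

    @property
    def start_codon_anchor0(self) -> int:
        """0-based genomic position of the first base of the start codon."""
        s, e = self.cds_segments[0]
        return s if self.strand == "+" else e - 1

    @property
    def stop_codon_anchor0(self) -> int:
        """0-based genomic position of the last base of the stop codon."""
        s, e = self.cds_segments[-1]
        return e - 1 if self.strand == "+" else s

    def cds_positions(self) -> list[int]:
        """Genomic 0-based positions of CDS bases in transcription order."""
        out: list[int] = []
        for s, e in self.cds_segments:
            rng = range(s, e) if self.strand == "+" else range(e - 1, s - 1, -1)
            out.extend(rng)
        return out

    def contains(self, pos0: int, segments) -> bool:
        return any(s <= pos0 < e for s, e in segments)


def flag_malformed_genes(genes: list[GeneModel]) -> list[GeneModel]:
    """Warn about gene models whose CDS length is not divisible by 3."""
    bad = [g.gene_id for g in genes if not g.is_well_formed]
    if bad:
        warnings.warn(f"CDS length not divisible by 3 for: {', '.join(bad)}")
    return genes
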