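"""Readers and writers for the standard formats the pipeline touches.

VCF v4.2 (genotypes only), GFF3 gene annotation, FASTA genome sequence
and a TSV sample-metadata table (``sample<TAB>year``).  Parsing is
delegated to cyvcf2, gffutils and Biopython; the VCF writer emits a
minimal GT-only v4.2 file whose round trip through :func:`read_vcf` is
lossless.

Coordinates arriving from VCF/GFF3 are 1-based inclusive and are
converted to the package's 0-based half-open convention here and only
here.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

from .model import MISSING, GeneModel, GenotypeMatrix, SampleMeta, VariantSite

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_gff3",
    "write_gff3",
    "read_fasta",
    "write_fasta",
    "read_sample_meta",
    "write_sample_meta",
    "assign_subpop",
    "DEFAULT_YEAR_BINS",
    "VcfFormatError",
]


class VcfFormatError(ValueError):
    """Raised when a VCF cannot be parsed into a GenotypeMatrix."""


# --------------------------------------------------------------------- VCF
def read_vcf(path) -> GenotypeMatrix:
    """Load a VCF v4.2 with GT fields into a :class:`GenotypeMatrix`.

    Multi-allelic records are preserved; ``./.`` and partial calls map to
    missing; sites emerge sorted by (chrom, pos) regardless of input order.
    """
    path = str(path)
    try:
        vcf = VCF(path, gts012=False)
        samples = list(vcf.samples)
        sites: list[VariantSite] = []
        rows: list[np.ndarray] = []
        for lineno, var in enumerate(vcf, start=1):
            try:
                site = VariantSite(var.CHROM, var.POS, var.REF, tuple(var.ALT))
                gts = np.array(
                    [g[:2] for g in var.genotypes], dtype=np.int16
                ).reshape(len(samples), 2)
            except Exception as exc:  # noqa: BLE001 - rewrap with record number
                raise VcfFormatError(f"{path}: record {lineno}: {exc}") from exc
            sites.append(site)
            rows.append(gts)
    except VcfFormatError:
        raise
    except Exception as exc:  # malformed header, truncated file, ...
        raise VcfFormatError(f"{path}: {exc}") from exc
    calls = (
        np.stack(rows) if rows else np.empty((0, len(samples), 2), dtype=np.int16)
    )
    return GenotypeMatrix(sites, samples, calls)


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Serialize a matrix as VCF v4.2 (unphased GT only, het as ``0/1``)."""
    chroms = list(dict.fromkeys(s.chrom for s in matrix.sites))
    lines = ["##fileformat=VCFv4.2", "##source=popdiv"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples)
    )
    for i, site in enumerate(matrix.sites):
        gts = [
            "./." if a == MISSING else f"{a}/{b}" for a, b in matrix.calls[i]
        ]
        lines.append(
            "\t".join(
                [
                    site.chrom,
                    str(site.pos),
                    ".",
                    site.ref,
                    ",".join(site.alts),
                    ".",
                    ".",
                    ".",
                    "GT",
                ]
                + gts
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# -------------------------------------------------------------------- GFF3
def read_gff3(path) -> list[GeneModel]:
    """Assemble single-transcript gene models from a GFF3 file.

    Expects gene/mRNA/CDS/five_prime_UTR/three_prime_UTR features with
    Parent links.  CDS segments are returned in transcription order
    (genomically descending for '-' strand genes).
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        parent = mrna.attributes.get("Parent", [mrna.id])[0]

        def segs(ftype: str) -> list[tuple[int, int]]:
            feats = sorted(
                db.children(mrna, featuretype=ftype), key=lambda f: f.start
            )
            if mrna.strand == "-":
                feats = feats[::-1]
            return [(f.start - 1, f.end) for f in feats]  # 1-based closed -> 0-based half-open

        cds = segs("CDS")
        if not cds:
            warnings.warn(f"transcript {mrna.id} has no CDS; skipped")
            continue
        genes.append(
            GeneModel(
                gene_id=parent,
                chrom=mrna.seqid,
                strand=mrna.strand,
                cds_segments=cds,
                utr5_segments=segs("five_prime_UTR"),
                utr3_segments=segs("three_prime_UTR"),
            )
        )
    return genes


def write_gff3(genes: list[GeneModel], path) -> None:
    """Write gene models as GFF3 (gene/mRNA/UTR/CDS rows, 1-based closed)."""
    out = ["##gff-version 3"]
    for g in genes:
        s0, e0 = g.span0
        out.append(
            f"{g.chrom}\tpopdiv\tgene\t{s0 + 1}\t{e0}\t.\t{g.strand}\t.\tID={g.gene_id}"
        )
        tid = f"{g.gene_id}.t1"
        out.append(
            f"{g.chrom}\tpopdiv\tmRNA\t{s0 + 1}\t{e0}\t.\t{g.strand}\t.\t"
            f"ID={tid};Parent={g.gene_id}"
        )
        for ftype, segs in [
            ("five_prime_UTR", g.utr5_segments),
            ("CDS", g.cds_segments),
            ("three_prime_UTR", g.utr3_segments),
        ]:
            # CDS phase: cumulative length of preceding CDS segments mod 3
            done = 0
            for a0, a1 in (sorted(segs, reverse=g.strand == "-") if ftype == "CDS" else sorted(segs)):
                col8 = str((3 - done % 3) % 3) if ftype == "CDS" else "."
                out.append(
                    f"{g.chrom}\tpopdiv\t{ftype}\t{a0 + 1}\t{a1}\t.\t{g.strand}\t"
                    f"{col8}\tParent={tid}"
                )
                done += a1 - a0
    Path(path).write_text("\n".join(out) + "\n")


# ------------------------------------------------------------------- FASTA
def read_fasta(path) -> dict[str, str]:
    """Chromosome id -> uppercase sequence."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ----------------------------------------------------------- sample metadata
#: Breeding-era bins (inclusive year ranges) used to label sub-populations.
DEFAULT_YEAR_BINS: dict[str, tuple[int, int]] = {
    "SA": (1963, 1980),
    "SB": (1983, 1988),
    "SC": (1991, 2000),
    "SD": (2001, 2010),
    "SE": (2011, 2017),
}


def assign_subpop(year: int, bins: dict[str, tuple[int, int]] | None = None) -> str | None:
    """Map a release year to its sub-population label, or None if unbinned."""
    bins = DEFAULT_YEAR_BINS if bins is None else bins
    for label, (lo, hi) in bins.items():
        if lo <= year <= hi:
            return label
    return None


def read_sample_meta(path, bins=None) -> list[SampleMeta]:
    """Read ``sample<TAB>year`` TSV (header optional) and bin years."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two tab-separated columns")
    first_year = df.iloc[0, 1]
    if not str(first_year).strip().lstrip("-").isdigit():  # header row
        df = df.iloc[1:]
    metas = []
    for _, row in df.iterrows():
        year = int(row.iloc[1])
        sub = assign_subpop(year, bins)
        if sub is None:
            warnings.warn(f"sample {row.iloc[0]}: year {year} outside all bins; unassigned")
        metas.append(SampleMeta(sample=str(row.iloc[0]), release_year=year, subpop=sub))
    return metas


def write_sample_meta(metas: list[SampleMeta], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tyear\n")
        for m in metas:
            fh.write(f"{m.sample}\t{m.release_year}\n")
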