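"""Site-level quality statistics and SNP-subset filters.

Two SNP subsets are produced from a raw call set:

* a *simply filtered* set — biallelic, polymorphic SNPs (monomorphic
  sites and sites with more than two alleles removed); and
* a *core* set — the simply filtered sites that additionally satisfy
  missing rate <= 10%, heterozygosity rate <= 10% and minor allele
  frequency >= 2% (all thresholds inclusive and configurable).

A separate detector flags sites "mutated in all samples": missing rate
strictly below 10% and every non-missing call carrying at least one
alternate allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MISSING, GenotypeMatrix, VariantSite

__all__ = [
    "SiteStats",
    "site_stats",
    "matrix_stats",
    "split_snps_indels",
    "simple_filter",
    "core_filter",
    "chrom_counts",
    "mutated_in_all",
    "filter_report",
]


@dataclass
class SiteStats:
    """Quality statistics of one site over the sample panel.

    ``het_rate`` and ``maf`` are computed over non-missing calls only;
    ``maf`` is the frequency of the second most common allele (NaN when
    no call is available).
    """

    n_called: int
    missing_rate: float
    het_rate: float
    maf: float
    n_alleles: int


def _stat_arrays(matrix: GenotypeMatrix):
    calls = matrix.calls
    called = calls[:, :, 0] != MISSING  # (S, N)
    n_called = called.sum(axis=1)
    n_samples = matrix.n_samples
    # computed from the integer missing count so threshold comparisons at
    # printed boundaries (e.g. exactly 10%) are exact
    missing_rate = (
        (n_samples - n_called) / n_samples if n_samples else np.ones(len(calls))
    )
    het = called & (calls[:, :, 0] != calls[:, :, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        het_rate = np.where(n_called > 0, het.sum(axis=1) / n_called, np.nan)
    maf = np.full(matrix.n_sites, np.nan)
    n_alleles = np.zeros(matrix.n_sites, dtype=int)
    for i in range(matrix.n_sites):
        counts = matrix.allele_counts(i)
        n = counts.sum()
        n_alleles[i] = int((counts > 0).sum())
        if n > 0:
            top2 = np.sort(counts)[::-1][:2]
            maf[i] = (top2[1] / n) if len(top2) > 1 else 0.0
    return n_called, missing_rate, het_rate, maf, n_alleles


def site_stats(matrix: GenotypeMatrix, i: int) -> SiteStats:
    """Statistics for one site; ``maf`` is NaN when every call is missing."""
    sub = matrix.take_sites([i])
    n_called, miss, het, maf, n_alleles = _stat_arrays(sub)
    if n_called[0] == 0:
        warnings.warn(f"site {matrix.sites[i].chrom}:{matrix.sites[i].pos}: all calls missing")
    return SiteStats(
        n_called=int(n_called[0]),
        missing_rate=float(miss[0]),
        het_rate=float(het[0]) if n_called[0] else float("nan"),
        maf=float(maf[0]),
        n_alleles=int(n_alleles[0]),
    )


def matrix_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-site statistics table (chrom, pos, n_called, missing_rate, het_rate, maf)."""
    n_called, miss, het, maf, n_alleles = _stat_arrays(matrix)
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in matrix.sites],
            "pos": [s.pos for s in matrix.sites],
            "n_called": n_called,
            "missing_rate": miss,
            "het_rate": het,
            "maf": maf,
            "n_alleles": n_alleles,
        }
    )


def split_snps_indels(matrix: GenotypeMatrix) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Split a matrix into its SNP and InDel streams."""
    snp_idx = [i for i, s in enumerate(matrix.sites) if s.is_snp]
    indel_idx = [i for i, s in enumerate(matrix.sites) if not s.is_snp]
    return matrix.take_sites(snp_idx), matrix.take_sites(indel_idx)


def _recode_biallelic(site: VariantSite, calls: np.ndarray, alt_index: int):
    """Collapse a site to REF + one observed ALT, remapping call indices."""
    new_site = VariantSite(site.chrom, site.pos, site.ref, (site.alts[alt_index - 1],))
    new_calls = calls.copy()
    new_calls[calls == alt_index] = 1
    return new_site, new_calls


def simple_filter(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Biallelic polymorphic SNPs only.

    A site is retained iff it is a SNP and the alleles observed in
    non-missing calls are exactly {REF, one ALT}: monomorphic sites and
    sites with more than two alleles (REF plus two or more observed
    ALTs) are removed.  Retained sites are recoded so the single
    observed ALT becomes allele 1.  InDels are not part of the output;
    use :func:`split_snps_indels` to carry them as a separate stream.
    """
    kept_sites: list[VariantSite] = []
    kept_calls: list[np.ndarray] = []
    for i, site in enumerate(matrix.sites):
        if not site.is_snp:
            continue
        counts = matrix.allele_counts(i)
        observed = np.flatnonzero(counts)
        if len(observed) != 2 or observed[0] != 0:
            continue  # monomorphic, >2 alleles, or REF never observed
        new_site, new_calls = _recode_biallelic(site, matrix.calls[i], int(observed[1]))
        kept_sites.append(new_site)
        kept_calls.append(new_calls)
    calls = (
        np.stack(kept_calls)
        if kept_calls
        else np.empty((0, matrix.n_samples, 2), dtype=np.int16)
    )
    return GenotypeMatrix(kept_sites, matrix.samples, calls, sort=False)


def core_filter(
    matrix: GenotypeMatrix,
    max_missing: float = 0.10,
    max_het: float = 0.10,
    min_maf: float = 0.02,
) -> GenotypeMatrix:
    """High-quality subset of an already simply-filtered matrix.

    Retained iff missing_rate <= max_missing AND het_rate <= max_het AND
    maf >= min_maf (all inclusive, as printed thresholds).
    """
    for name, v in [("max_missing", max_missing), ("max_het", max_het), ("min_maf", min_maf)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be within [0, 1], got {v}")
    _, miss, het, maf, _ = _stat_arrays(matrix)
    with np.errstate(invalid="ignore"):
        keep = (miss <= max_missing) & (het <= max_het) & (maf >= min_maf)
    keep &= ~np.isnan(het) & ~np.isnan(maf)
    return matrix.take_sites(np.flatnonzero(keep))


def chrom_counts(matrix: GenotypeMatrix) -> pd.Series:
    """Per-chromosome site counts (sums to the total site count)."""
    chroms = [s.chrom for s in matrix.sites]
    return pd.Series(chroms, dtype=object).value_counts().sort_index().rename("n_sites")


def mutated_in_all(
    matrix: GenotypeMatrix,
    max_missing_exclusive: float = 0.10,
    hom_alt_only: bool = False,
) -> np.ndarray:
    """Indices of sites mutated in every genotyped sample.

    A site qualifies iff its missing rate is *strictly* below
    ``max_missing_exclusive`` and every non-missing call carries at
    least one alternate allele (``hom_alt_only=True`` demands both
    alleles alternate).
    """
    calls = matrix.calls
    called = calls[:, :, 0] != MISSING
    miss = (matrix.n_samples - called.sum(axis=1)) / matrix.n_samples
    if hom_alt_only:
        mutated = (calls >= 1).all(axis=2)
    else:
        mutated = (calls >= 1).any(axis=2)
    all_mut = np.where(called, mutated, True).all(axis=1) & (called.sum(axis=1) > 0)
    return np.flatnonzero((miss < max_missing_exclusive) & all_mut)


def filter_report(
    matrix: GenotypeMatrix,
    max_missing: float = 0.10,
    max_het: float = 0.10,
    min_maf: float = 0.02,
) -> pd.DataFrame:
    """Per-site TSV-ready report with the core-filter verdict."""
    df = matrix_stats(matrix)
    with np.errstate(invalid="ignore"):
        keep = (
            (df["missing_rate"] <= max_missing)
            & (df["het_rate"] <= max_het)
            & (df["maf"] >= min_maf)
        )
    df["verdict"] = np.where(keep.fillna(False), "retained", "removed")
    return df
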