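"""Nucleotide diversity (π) and polymorphic information content (PIC).

π treats each non-missing allele call of a diploid panel as one sampled
sequence.  At a site with allele counts c₁..c_k (n = Σc), the default
estimator is the mean pairwise difference *without replacement*,

    π_site = Σ_{u<v} c_u c_v / C(n, 2)  =  (n² − Σ c²) / (n(n−1)),

which for a biallelic site equals 2pq·n/(n−1).  The plain
with-replacement form Σ xᵢxⱼπᵢⱼ = 1 − Σp² is available via
``estimator="raw"``.  Windowed π divides the summed per-site values by
the window length in bp; the population value is the unweighted mean
over windows.

PIC for a locus with allele frequencies p_u is the Botstein-type
measure

    PIC = 1 − Σ_u p_u² − Σ_u Σ_{v>u} 2 p_u² p_v²,

and the population PIC is the unweighted mean over loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import GenotypeMatrix, SampleMeta

__all__ = [
    "site_pi",
    "matrix_site_pi",
    "windowed_pi",
    "population_pi",
    "locus_pic",
    "population_pic",
    "subpop_diversity",
    "WindowStat",
]


def site_pi(counts, estimator: str = "unbiased") -> float:
    """Per-site nucleotide diversity from allele counts.

    Parameters
    ----------
    counts
        Integer allele counts at one site (over non-missing calls).
    estimator
        ``"unbiased"`` (without replacement, n/(n−1) correction; default)
        or ``"raw"`` (Σ xᵢxⱼπᵢⱼ with replacement).

    Returns NaN when fewer than two alleles were sampled.
    """
    counts = np.asarray(counts, dtype=np.int64)
    n = int(counts.sum())
    if n < 2:
        warnings.warn("site_pi undefined for fewer than 2 sampled alleles")
        return float("nan")
    sq = int((counts.astype(object) ** 2).sum())
    if estimator == "unbiased":
        return (n * n - sq) / (n * (n - 1))
    if estimator == "raw":
        return (n * n - sq) / (n * n)
    raise ValueError(f"unknown estimator {estimator!r}")


def matrix_site_pi(matrix: GenotypeMatrix, estimator: str = "unbiased") -> np.ndarray:
    """Vector of per-site π over a matrix (NaN where undefined)."""
    out = np.empty(matrix.n_sites)
    for i in range(matrix.n_sites):
        counts = matrix.allele_counts(i)
        n = counts.sum()
        if n < 2:
            out[i] = np.nan
            continue
        sq = float((counts.astype(np.float64) ** 2).sum())
        denom = n * (n - 1) if estimator == "unbiased" else n * n
        if estimator not in ("unbiased", "raw"):
            raise ValueError(f"unknown estimator {estimator!r}")
        out[i] = (n * n - sq) / denom
    return out


@dataclass
class WindowStat:
    """π of one genomic window (0-based half-open coordinates, per-bp π)."""

    chrom: str
    start: int
    end: int
    n_sites: int
    pi: float


def windowed_pi(
    matrix: GenotypeMatrix,
    window: int = 100_000,
    step: int | None = 10_000,
    chrom_lengths: dict[str, int] | None = None,
    estimator: str = "unbiased",
) -> list[WindowStat]:
    """Per-window π along each chromosome.

    ``step=None`` (or ``step == window``) gives non-overlapping tiling
    windows; the default is a 100 kb window sliding by 10 kb.  Window π
    is the sum of per-site π divided by the window length in bp; empty
    windows report 0.
    """
    if step is None:
        step = window
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    pis = matrix_site_pi(matrix, estimator=estimator)
    pos0 = np.array([s.pos0 for s in matrix.sites], dtype=np.int64)
    chroms = np.array([s.chrom for s in matrix.sites], dtype=object)
    out: list[WindowStat] = []
    chrom_list = (
        sorted(chrom_lengths) if chrom_lengths else list(dict.fromkeys(chroms))
    )
    for chrom in chrom_list:
        mask = chroms == chrom
        cpos = pos0[mask]
        cpi = np.nan_to_num(pis[mask], nan=0.0)
        if chrom_lengths is not None:
            length = chrom_lengths[chrom]
        elif len(cpos):
            length = int(cpos[-1]) + 1
        else:
            continue
        start = 0
        while start < length:
            end = min(start + window, length)
            lo, hi = np.searchsorted(cpos, [start, end])
            n_sites = int(hi - lo)
            pi = float(cpi[lo:hi].sum() / (end - start)) if n_sites else 0.0
            out.append(WindowStat(chrom, start, end, n_sites, pi))
            if start + window >= length:
                break
            start += step
    return out


def population_pi(windows: list[WindowStat]) -> float:
    """Unweighted mean of window π values over the genome."""
    if not windows:
        raise ValueError("population_pi requires at least one window")
    return float(np.mean([w.pi for w in windows]))


def locus_pic(counts) -> float:
    """PIC of one locus from allele counts (or frequencies).

    Evaluates 1 − Σp² − Σ_{v>u} 2 p_u² p_v²; returns NaN when no allele
    was sampled.
    """
    counts = np.asarray(counts, dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        warnings.warn("locus_pic undefined with no sampled alleles")
        return float("nan")
    p = counts / total
    s2 = float((p**2).sum())
    s4 = float((p**4).sum())
    return 1.0 - s2 - (s2 * s2 - s4)


def population_pic(matrix: GenotypeMatrix) -> float:
    """Unweighted mean locus PIC over all loci with at least one call."""
    vals = []
    for i in range(matrix.n_sites):
        counts = matrix.allele_counts(i)
        if counts.sum() > 0:
            vals.append(locus_pic(counts))
    if not vals:
        raise ValueError("population_pic requires at least one usable locus")
    return float(np.mean(vals))


def subpop_diversity(
    matrix: GenotypeMatrix,
    meta: list[SampleMeta],
    window: int = 100_000,
    step: int | None = 10_000,
    chrom_lengths: dict[str, int] | None = None,
    min_samples: int = 2,
    estimator: str = "unbiased",
) -> pd.DataFrame:
    """Per-sub-population π and PIC report.

    Statistics are computed on each sub-population's columns only, with
    sub-population-specific allele counts.  Sub-populations with fewer
    than ``min_samples`` members are excluded with a warning.  The
    ``pi_x1e3`` column carries the conventional ×10⁻³ display scale.
    """
    by_sub: dict[str, list[str]] = {}
    years: dict[str, list[int]] = {}
    sample_set = set(matrix.samples)
    for m in meta:
        if m.subpop is None or m.sample not in sample_set:
            continue
        by_sub.setdefault(m.subpop, []).append(m.sample)
        years.setdefault(m.subpop, []).append(m.release_year)
    rows = []
    for sub in sorted(by_sub):
        names = by_sub[sub]
        if len(names) < min_samples:
            warnings.warn(
                f"sub-population {sub} has {len(names)} sample(s) < {min_samples}; excluded"
            )
            continue
        sm = matrix.take_samples(names)
        windows = windowed_pi(sm, window=window, step=step,
                              chrom_lengths=chrom_lengths, estimator=estimator)
        pi = population_pi(windows) if windows else 0.0
        try:
            pic = population_pic(sm)
        except ValueError:
            warnings.warn(f"sub-population {sub}: no usable locus for PIC")
            pic = float("nan")
        rows.append(
            {
                "subpop": sub,
                "years": f"{min(years[sub])}-{max(years[sub])}",
                "n_accessions": len(names),
                "pi": pi,
                "pi_x1e3": pi * 1e3,
                "pic": pic,
            }
        )
    return pd.DataFrame(rows, columns=["subpop", "years", "n_accessions", "pi", "pi_x1e3", "pic"])
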