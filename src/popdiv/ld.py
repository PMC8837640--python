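"""Linkage-disequilibrium decay: dosage r², distance-binned curves and
the half-decay distance.

r² between two sites is the squared Pearson correlation of per-sample
ALT-allele dosages over pairwise-complete samples (composite,
genotype-based LD — no phase required).  Pairs on different chromosomes
are ignored; pairs farther apart than ``max_dist`` (default 1 Mb) are
ignored.  The decay curve bins pairs by physical distance and the
half-decay distance is where the binned mean first falls to half of the
maximum level (by default, the mean r² of the shortest-distance bin),
linearly interpolated between bin midpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import GenotypeMatrix

__all__ = ["pairwise_r2", "ld_curve", "half_decay_distance", "LDCurve"]


def pairwise_r2(dosages_a, dosages_b) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing values (NaN) are dropped pairwise; returns NaN when fewer
    than two complete pairs remain or either site is monomorphic within
    the complete subset.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if len(a) < 2:
        return float("nan")
    va = a.var()
    vb = b.var()
    if va == 0.0 or vb == 0.0:
        return float("nan")
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


@dataclass
class LDCurve:
    """Distance-binned mean r² (bins left-closed, in bp)."""

    bin_left: np.ndarray
    bin_right: np.ndarray
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    bin_width: int
    max_dist: int

    @property
    def midpoints(self) -> np.ndarray:
        return (self.bin_left + self.bin_right) / 2.0

    @property
    def max_r2(self) -> float:
        """Reference level: mean r² of the first populated bin."""
        pop = np.flatnonzero(self.n_pairs > 0)
        return float(self.mean_r2[pop[0]]) if len(pop) else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_left,
                "bin_end": self.bin_right,
                "n_pairs": self.n_pairs,
                "mean_r2": self.mean_r2,
            }
        )


def _pair_r2_block(D: np.ndarray, i: int, js: np.ndarray) -> np.ndarray:
    """r² between row i and rows js of dosage matrix D, pairwise-complete."""
    a = D[i]
    B = D[js]
    valid = ~np.isnan(a)[None, :] & ~np.isnan(B)
    A = np.where(valid, a[None, :], 0.0)
    Bv = np.where(valid, B, 0.0)
    n = valid.sum(axis=1).astype(float)
    sx = A.sum(axis=1)
    sy = Bv.sum(axis=1)
    sxx = (A * A).sum(axis=1)
    syy = (Bv * Bv).sum(axis=1)
    sxy = (A * Bv).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sy
        den = (n * sxx - sx * sx) * (n * syy - sy * sy)
        r2 = np.where((n >= 2) & (den > 0), num * num / den, np.nan)
    return r2


def ld_curve(
    matrix: GenotypeMatrix,
    max_dist: int = 1_000_000,
    bin_width: int = 1_000,
) -> LDCurve:
    """Distance-binned mean r² over all same-chromosome site pairs.

    Every pair of biallelic sites on the same chromosome with separation
    in (0, max_dist] contributes its r² (when defined) to the bin of its
    distance; per-bin means are over defined r² values only.
    """
    if max_dist <= 0 or bin_width <= 0:
        raise ValueError("max_dist and bin_width must be positive")
    n_bins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    chroms = np.array([s.chrom for s in matrix.sites], dtype=object)
    pos = np.array([s.pos for s in matrix.sites], dtype=np.int64)
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        if len(idx) < 2:
            continue
        D = matrix.take_sites(idx).dosage_matrix()
        cpos = pos[idx]
        for k in range(len(idx) - 1):
            hi = np.searchsorted(cpos, cpos[k] + max_dist, side="right")
            js = np.arange(k + 1, hi)
            if not len(js):
                continue
            dist = cpos[js] - cpos[k]
            keep = dist > 0  # co-located duplicates carry no distance
            js, dist = js[keep], dist[keep]
            if not len(js):
                continue
            r2 = _pair_r2_block(D, k, js)
            ok = ~np.isnan(r2)
            if not ok.any():
                continue
            bins = (dist[ok] - 1) // bin_width
            np.add.at(sums, bins, r2[ok])
            np.add.at(counts, bins, 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    edges = np.arange(n_bins + 1, dtype=np.int64) * bin_width
    edges[-1] = min(edges[-1], max_dist)
    return LDCurve(
        bin_left=edges[:-1],
        bin_right=edges[1:],
        mean_r2=means,
        n_pairs=counts,
        bin_width=bin_width,
        max_dist=max_dist,
    )


def half_decay_distance(curve: LDCurve, reference: str = "first_bin") -> float | None:
    """Distance (bp) where the binned curve first crosses half its maximum.

    ``reference`` selects the maximum level: ``"first_bin"`` (default)
    uses the shortest-distance populated bin; ``"global_max"`` uses the
    largest binned mean.  Crossing is linearly interpolated between bin
    midpoints; returns None when the curve never reaches half-maximum
    within ``max_dist``.
    """
    pop = np.flatnonzero(curve.n_pairs > 0)
    if len(pop) == 0:
        warnings.warn("empty LD curve; half-decay undefined")
        return None
    x = curve.midpoints[pop]
    y = curve.mean_r2[pop]
    if reference == "first_bin":
        top = y[0]
    elif reference == "global_max":
        top = float(np.max(y))
    else:
        raise ValueError(f"unknown reference {reference!r}")
    half = top / 2.0
    below = np.flatnonzero(y <= half)
    if len(below) == 0:
        warnings.warn("LD curve never decays to half-maximum within max_dist")
        return None
    j = below[0]
    if j == 0:
        return float(x[0])
    x0, y0, x1, y1 = x[j - 1], y[j - 1], x[j], y[j]
    if y1 == y0:
        return float(x1)
    return float(x0 + (y0 - half) * (x1 - x0) / (y0 - y1))
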