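"""Filter predicates, their boundary behaviour, and brute-force oracles."""

from fractions import Fraction

import numpy as np
import pytest

from popdiv.model import MISSING, GenotypeMatrix, VariantSite
from popdiv.site_filters import (
    chrom_counts,
    core_filter,
    matrix_stats,
    mutated_in_all,
    simple_filter,
    site_stats,
    split_snps_indels,
)
from popdiv.simulate import simulate_frequencies, simulate_genotypes

from conftest import matrix_from_genotypes


# ------------------------------------------------------- independent oracle
def oracle_stats(calls_row, n_samples):
    """Hand tally of missing/het/maf (exact rationals) from raw call pairs."""
    called = [c for c in calls_row if c[0] >= 0]
    missing_rate = Fraction(n_samples - len(called), n_samples)
    het_rate = (
        Fraction(sum(1 for c in called if c[0] != c[1]), len(called))
        if called
        else None
    )
    alleles = [a for c in called for a in c]
    maf = None
    if alleles:
        counts = sorted(
            (alleles.count(a) for a in set(alleles)), reverse=True
        )
        maf = Fraction(counts[1], len(alleles)) if len(counts) > 1 else Fraction(0)
    return missing_rate, het_rate, maf


class TestSiteStats:
    def test_hand_tally_example(self):
        # 10 samples: 1 missing, 5 hom-ref, 3 het, 1 hom-alt
        gts = [None] + [(0, 0)] * 5 + [(0, 1)] * 3 + [(1, 1)]
        m = matrix_from_genotypes([gts])
        s = site_stats(m, 0)
        assert s.missing_rate == pytest.approx(0.1)
        assert s.het_rate == pytest.approx(3 / 9)
        assert s.maf == pytest.approx(5 / 18)
        assert s.n_called == 9

    def test_all_hom_ref(self):
        s = site_stats(matrix_from_genotypes([[(0, 0)] * 6]), 0)
        assert s.maf == 0 and s.het_rate == 0 and s.n_alleles == 1

    def test_all_het(self):
        s = site_stats(matrix_from_genotypes([[(0, 1)] * 6]), 0)
        assert s.het_rate == 1 and s.maf == 0.5

    def test_all_missing_flagged(self):
        with pytest.warns(UserWarning, match="all calls missing"):
            s = site_stats(matrix_from_genotypes([[None, None]]), 0)
        assert s.n_called == 0 and np.isnan(s.maf)


class TestSimpleFilter:
    def test_three_observed_alleles_removed(self):
        site = VariantSite("c", 1, "A", ("T", "G"))
        calls = np.array([[[0, 1], [0, 2], [0, 0]]], dtype=np.int16)
        m = GenotypeMatrix([site], ["a", "b", "c"], calls)
        assert simple_filter(m).n_sites == 0

    def test_monomorphic_removed(self):
        m = matrix_from_genotypes([[(0, 0)] * 4])
        assert simple_filter(m).n_sites == 0
        m_alt = matrix_from_genotypes([[(1, 1)] * 4])
        assert simple_filter(m_alt).n_sites == 0

    def test_single_het_retained(self):
        m = matrix_from_genotypes([[(0, 0), (0, 1), (0, 0)]])
        assert simple_filter(m).n_sites == 1

    def test_indels_not_in_snp_stream(self):
        sites = [
            VariantSite("c", 1, "AT", ("A",)),
            VariantSite("c", 5, "A", ("G",)),
        ]
        calls = np.array([[[0, 1]], [[0, 1]]], dtype=np.int16)
        m = GenotypeMatrix(sites, ["a"], calls)
        snps, indels = split_snps_indels(m)
        assert [s.pos for s in snps.sites] == [5]
        assert [s.pos for s in indels.sites] == [1]
        assert [s.pos for s in simple_filter(m).sites] == [5]

    def test_multiallelic_record_with_one_observed_alt_recoded(self):
        site = VariantSite("c", 1, "A", ("T", "G"))
        calls = np.array([[[0, 2], [0, 0], [2, 2]]], dtype=np.int16)
        m = GenotypeMatrix([site], ["a", "b", "c"], calls)
        out = simple_filter(m)
        assert out.sites[0].alts == ("G",)
        assert out.calls.max() == 1


class TestCoreFilter:
    def test_boundaries_inclusive(self):
        # missing rate exactly 10% -> retained (<= is inclusive)
        gts_boundary = [None] + [(0, 0)] * 5 + [(1, 1)] * 4
        # maf below 2% -> removed
        gts_low_maf = [(0, 1)] + [(0, 0)] * 49
        m = matrix_from_genotypes([gts_boundary])
        assert core_filter(m).n_sites == 1
        m2 = matrix_from_genotypes([gts_low_maf])  # maf = 1/100 = 1%
        assert core_filter(m2).n_sites == 0

    def test_maf_just_below_threshold_removed(self):
        # 500 samples, 19 ALT alleles of 1000 -> maf 1.9%
        gts = [(0, 1)] * 19 + [(0, 0)] * 481
        m = matrix_from_genotypes([gts])
        stats = site_stats(m, 0)
        assert stats.maf == pytest.approx(0.019)
        assert core_filter(m, max_het=1.0).n_sites == 0
        # and 20 ALT alleles (2.0%) passes
        gts = [(0, 1)] * 20 + [(0, 0)] * 480
        assert core_filter(matrix_from_genotypes([gts]), max_het=1.0).n_sites == 1

    def test_threshold_validation(self):
        m = matrix_from_genotypes([[(0, 1), (0, 0)]])
        with pytest.raises(ValueError, match="max_missing"):
            core_filter(m, max_missing=1.5)

    def test_idempotence_and_containment(self):
        rng = np.random.default_rng(11)
        m = simulate_genotypes(
            simulate_frequencies(300, "uniform", rng=rng),
            30,
            missing_rate=0.12,
            rng=rng,
            het_deficit=0.8,
        )
        simple = simple_filter(m)
        core = core_filter(simple)
        keys = lambda x: [s.key for s in x.sites]
        assert set(keys(core)) <= set(keys(simple))
        assert simple_filter(simple).equals(simple)
        assert core_filter(core).equals(core)

    def test_matches_brute_force_predicates(self):
        rng = np.random.default_rng(42)
        m = simulate_genotypes(
            simulate_frequencies(500, "uniform", rng=rng),
            25,
            missing_rate=0.15,
            rng=rng,
            het_deficit=0.7,
        )
        simple = simple_filter(m)
        core = core_filter(simple)
        expected = []
        for i, site in enumerate(simple.sites):
            miss, het, maf = oracle_stats(
                [tuple(c) for c in simple.calls[i]], simple.n_samples
            )
            if (
                miss <= Fraction(1, 10)
                and het is not None
                and het <= Fraction(1, 10)
                and maf >= Fraction(1, 50)
            ):
                expected.append(site.key)
        assert [s.key for s in core.sites] == expected


class TestChromCounts:
    def test_empty(self):
        m = GenotypeMatrix([], ["a"], np.empty((0, 1, 2), dtype=np.int16))
        assert chrom_counts(m).sum() == 0

    def test_two_chromosomes(self):
        sites = [VariantSite("c1", p, "A", ("G",)) for p in (1, 5, 9)]
        sites += [VariantSite("c2", p, "A", ("G",)) for p in (2, 4, 6, 8, 10)]
        calls = np.tile(np.array([[0, 1]], dtype=np.int16), (8, 1, 1))
        m = GenotypeMatrix(sites, ["a"], calls)
        counts = chrom_counts(m)
        assert counts.to_dict() == {"c1": 3, "c2": 5}
        assert counts.sum() == m.n_sites

    def test_recount_by_grouping(self):
        rng = np.random.default_rng(3)
        parts = []
        for chrom, n in [("cA", 17), ("cB", 5)]:
            parts.append(
                simulate_genotypes(
                    simulate_frequencies(n, "uniform", rng=rng), 4, rng=rng, chrom=chrom
                )
            )
        m = GenotypeMatrix(
            parts[0].sites + parts[1].sites,
            parts[0].samples,
            np.concatenate([parts[0].calls, parts[1].calls]),
        )
        counts = chrom_counts(m)
        for chrom in ("cA", "cB"):
            assert counts[chrom] == sum(1 for s in m.sites if s.chrom == chrom)


class TestMutatedInAll:
    def test_included_when_every_called_sample_mutated(self):
        gts = [None] + [(1, 1)] * 15 + [(0, 1)] * 4  # 5% missing
        m = matrix_from_genotypes([gts])
        assert list(mutated_in_all(m)) == [0]

    def test_strict_missing_boundary(self):
        gts = [None] + [(1, 1)] * 9  # exactly 10% missing -> excluded
        m = matrix_from_genotypes([gts])
        assert list(mutated_in_all(m)) == []

    def test_hom_ref_call_excludes(self):
        gts = [(0, 0)] + [(1, 1)] * 19
        assert list(mutated_in_all(matrix_from_genotypes([gts]))) == []

    def test_hom_alt_only_mode(self):
        gts = [(0, 1)] * 10
        m = matrix_from_genotypes([gts])
        assert list(mutated_in_all(m)) == [0]
        assert list(mutated_in_all(m, hom_alt_only=True)) == []

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(7)
        m = simulate_genotypes(
            simulate_frequencies(200, "uniform", p_range=(0.5, 1.0), rng=rng),
            12,
            missing_rate=0.08,
            rng=rng,
        )
        perm = rng.permutation(m.n_samples)
        got = mutated_in_all(m)
        got_perm = mutated_in_all(m.take_samples(list(perm)))
        assert np.array_equal(got, got_perm)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        m = simulate_genotypes(
            simulate_frequencies(400, "uniform", p_range=(0.6, 1.0), rng=rng),
            20,
            missing_rate=0.12,
            rng=rng,
        )
        expected = []
        for i in range(m.n_sites):
            row = [tuple(c) for c in m.calls[i]]
            called = [c for c in row if c[0] >= 0]
            miss = Fraction(m.n_samples - len(called), m.n_samples)
            if called and miss < Fraction(1, 10) and all(max(c) >= 1 for c in called):
                expected.append(i)
        assert list(mutated_in_all(m)) == expected
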