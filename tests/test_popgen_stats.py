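"""Allele counts, Reich F_ST, diversity measures, LD and IBS distances.

Each statistic is checked against an independently coded oracle: direct
formula evaluation for F_ST and H_E, exhaustive subsample enumeration for
rarefaction allelic richness, and naive per-genotype loops for counts,
LD r^2 and allele sharing.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lsblscan import (
    MISSING,
    AlleleCount,
    allele_counts,
    allele_sharing_distance,
    allelic_richness,
    diversity_summary,
    expected_heterozygosity,
    genomewide_fst,
    ld_prune,
    ld_r2,
    proportion_polymorphic,
    reich_fst,
    reich_fst_arrays,
)
from lsblscan.popgen_stats import AlleleCountArray, _window_r2

from conftest import make_matrix


def oracle_fst(a1, n1, a2, n2):
    """Independent transcription of the unbiased estimator."""
    h1 = a1 * (n1 - a1) / (n1 * (n1 - 1))
    h2 = a2 * (n2 - a2) / (n2 * (n2 - 1))
    num = (a1 / n1 - a2 / n2) ** 2 - h1 / n1 - h2 / n2
    den = num + h1 + h2
    if den == 0:
        return 0.0
    return num / den


class TestAlleleCounts:
    def test_direct_count_with_missing(self):
        g = make_matrix([[2], [1], [MISSING]])
        c = allele_counts(g, g.samples)
        assert (c.a[0], c.n[0]) == (3, 4)

    def test_all_missing_gives_zero_zero(self):
        g = make_matrix([[MISSING], [MISSING]])
        c = allele_counts(g, g.samples)
        assert (c.a[0], c.n[0]) == (0, 0)

    def test_matches_naive_loop(self, random_matrix):
        members = random_matrix.samples[3:15]
        c = allele_counts(random_matrix, members)
        idx = random_matrix.sample_index(members)
        for j in range(random_matrix.n_snps):
            a = n = 0
            for i in idx:
                d = random_matrix.dosage[i, j]
                if d != MISSING:
                    a += d
                    n += 2
            assert (c.a[j], c.n[j]) == (a, n)

    def test_empty_members_rejected(self, random_matrix):
        with pytest.raises(ValueError):
            allele_counts(random_matrix, [])


class TestReichFst:
    def test_fixed_difference_is_one(self):
        f = reich_fst(AlleleCount(20, 20), AlleleCount(0, 20))
        assert f.clipped == pytest.approx(1.0)

    def test_identical_frequencies_clip_to_zero(self):
        f = reich_fst(AlleleCount(10, 20), AlleleCount(10, 20))
        assert f.raw <= 0.0
        assert f.clipped == 0.0

    def test_same_fixed_allele_is_zero_by_convention(self):
        f = reich_fst(AlleleCount(20, 20), AlleleCount(20, 20))
        assert f.raw == 0.0

    def test_matches_oracle_formula(self):
        f = reich_fst(AlleleCount(10, 20), AlleleCount(2, 20))
        assert f.raw == pytest.approx(oracle_fst(10, 20, 2, 20), rel=1e-12)

    def test_ten_thousand_random_pairs_match_oracle(self):
        rng = np.random.default_rng(17)
        n1 = rng.integers(2, 200, 10_000)
        n2 = rng.integers(2, 200, 10_000)
        a1 = rng.integers(0, n1 + 1)
        a2 = rng.integers(0, n2 + 1)
        raw, clipped, valid = reich_fst_arrays(a1, n1, a2, n2)
        assert valid.all()
        for k in range(10_000):
            assert raw[k] == pytest.approx(
                oracle_fst(a1[k], n1[k], a2[k], n2[k]), rel=1e-10, abs=1e-12
            )
        assert (clipped >= 0).all() and (clipped <= 1).all()

    def test_undefined_below_two_chromosomes(self):
        with pytest.raises(ValueError):
            reich_fst(AlleleCount(0, 1), AlleleCount(5, 10))

    @given(
        n1=st.integers(2, 60),
        n2=st.integers(2, 60),
        f1=st.floats(0, 1),
        f2=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetry_and_allele_relabeling(self, n1, n2, f1, f2):
        a1, a2 = round(f1 * n1), round(f2 * n2)
        c1, c2 = AlleleCount(a1, n1), AlleleCount(a2, n2)
        assert reich_fst(c1, c2).raw == pytest.approx(reich_fst(c2, c1).raw, abs=1e-12)
        swapped = reich_fst(AlleleCount(n1 - a1, n1), AlleleCount(n2 - a2, n2))
        assert reich_fst(c1, c2).raw == pytest.approx(swapped.raw, abs=1e-12)

    def test_clipped_one_only_for_fixed_difference(self):
        rng = np.random.default_rng(2)
        n = rng.integers(2, 50, 2000)
        a = rng.integers(0, n + 1)
        m = rng.integers(2, 50, 2000)
        b = rng.integers(0, m + 1)
        _, clipped, _ = reich_fst_arrays(a, n, b, m)
        is_one = np.isclose(clipped, 1.0)
        fixed_diff = ((a == 0) & (b == m)) | ((a == n) & (b == 0))
        assert np.array_equal(is_one, fixed_diff)


class TestDiversity:
    def test_h_e_fixed_and_forced_values(self):
        assert expected_heterozygosity(AlleleCount(4, 4)) == 0.0
        assert expected_heterozygosity(AlleleCount(1, 2)) == pytest.approx(1.0)

    def test_h_e_matches_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            n = int(rng.integers(2, 100))
            a = int(rng.integers(0, n + 1))
            p = a / n
            assert expected_heterozygosity(AlleleCount(a, n)) == pytest.approx(
                2 * p * (1 - p) * n / (n - 1)
            )

    def test_proportion_polymorphic_extremes_and_mixture(self):
        assert proportion_polymorphic(
            AlleleCountArray(a=np.array([0, 10]), n=np.array([10, 10]))
        ) == 0.0
        assert proportion_polymorphic(
            AlleleCountArray(a=np.array([3, 7]), n=np.array([10, 10]))
        ) == 1.0
        rng = np.random.default_rng(4)
        n = np.full(500, 20)
        a = rng.integers(0, 21, 500)
        got = proportion_polymorphic(AlleleCountArray(a=a, n=n))
        assert got == pytest.approx(np.mean((a > 0) & (a < 20)))

    def test_allelic_richness_trivial_cases(self):
        assert allelic_richness(AlleleCount(6, 6), 4) == pytest.approx(1.0)
        assert allelic_richness(AlleleCount(3, 6), 6) == pytest.approx(2.0)

    def test_allelic_richness_exhaustive_enumeration(self):
        # n=6 chromosomes, a=2 copies of allele A, subsamples of g=4
        n, a, g = 6, 2, 4
        chroms = ["A"] * a + ["B"] * (n - a)
        counts = []
        for combo in itertools.combinations(range(n), g):
            counts.append(len({chroms[i] for i in combo}))
        expected = sum(counts) / len(counts)
        assert allelic_richness(AlleleCount(a, n), g) == pytest.approx(expected)

    def test_allelic_richness_g2_closed_form(self):
        # at g=2 the expected allele count is 1 + 2p(1-p) n/(n-1) = 1 + H_E
        for a, n in [(1, 8), (4, 8), (7, 16)]:
            assert allelic_richness(AlleleCount(a, n), 2) == pytest.approx(
                1.0 + expected_heterozygosity(AlleleCount(a, n))
            )

    def test_g_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            allelic_richness(AlleleCount(2, 4), 6)

    def test_diversity_summary_bounds(self, sim_small):
        g, assign, _ = sim_small
        rows = diversity_summary(g, assign, rarefaction_g=10)
        assert {r.population for r in rows} == {"popA", "popB", "popC"}
        for r in rows:
            # per-SNP unbiased H_E tops out at 0.5 n/(n-1); the mean stays below
            assert 0.0 <= r.h_e <= 0.55
            assert 0.0 <= r.p_n <= 1.0
            assert 1.0 <= r.a_r <= 2.0


class TestLd:
    def test_identical_vectors_r2_one(self):
        g = make_matrix(np.array([[0, 0], [1, 1], [2, 2], [1, 1]], dtype=np.int8))
        assert ld_r2(g, 0, 1) == pytest.approx(1.0)

    def test_orthogonal_contrast_r2_zero(self):
        g = make_matrix(np.array([[0, 1], [1, 0], [1, 2], [2, 1]], dtype=np.int8))
        assert ld_r2(g, 0, 1) == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_correlation(self, random_matrix):
        d = random_matrix.dosage
        for i, j in [(0, 1), (5, 20), (10, 47)]:
            ok = (d[:, i] != MISSING) & (d[:, j] != MISSING)
            x, y = d[ok, i].astype(float), d[ok, j].astype(float)
            if x.var() == 0 or y.var() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            assert ld_r2(random_matrix, i, j) == pytest.approx(r * r)

    def test_zero_variance_is_nan(self):
        g = make_matrix(np.array([[1, 0], [1, 1], [1, 2]], dtype=np.int8))
        assert math.isnan(ld_r2(g, 0, 1))

    def test_window_r2_matches_pairwise_calls(self, random_matrix):
        r2 = _window_r2(random_matrix.dosage[:, :10])
        for i in range(10):
            for j in range(i + 1, 10):
                want = ld_r2(random_matrix, i, j)
                if math.isnan(want):
                    assert math.isnan(r2[i, j])
                else:
                    assert r2[i, j] == pytest.approx(want, rel=1e-9)


class TestLdPrune:
    def test_perfectly_correlated_pair_keeps_one(self):
        base = np.array([0, 1, 2, 0, 1, 2, 1, 0], dtype=np.int8)
        g = make_matrix(np.stack([base, base], axis=1))
        out = ld_prune(g, r2_max=0.3, window_snps=10, step_snps=5)
        assert out.n_snps == 1

    def test_uncorrelated_panel_unchanged(self):
        rng = np.random.default_rng(21)
        d = rng.integers(0, 3, size=(200, 12)).astype(np.int8)
        g = make_matrix(d)
        out = ld_prune(g, r2_max=0.9, window_snps=12, step_snps=3)
        # high threshold, independent SNPs: nothing should exceed it
        assert out.snp_ids() == g.snp_ids()

    def test_all_pairs_property_on_ld_block(self):
        # build a 50-SNP block with heavy correlation: copies of few haplotypes
        rng = np.random.default_rng(30)
        base = rng.integers(0, 3, size=(60, 5)).astype(np.int8)
        cols = [base[:, rng.integers(0, 5)] for _ in range(50)]
        noise = rng.random((60, 50)) < 0.05
        d = np.stack(cols, axis=1)
        d[noise] = rng.integers(0, 3)
        g = make_matrix(d.astype(np.int8))
        out = ld_prune(g, r2_max=0.3, window_snps=50, step_snps=5)
        kept = [g.snp_ids().index(s) for s in out.snp_ids()]
        # exhaustive recheck over all retained pairs
        for x, y in itertools.combinations(kept, 2):
            r2 = ld_r2(g, x, y)
            assert math.isnan(r2) or r2 < 0.3

    def test_idempotent(self):
        rng = np.random.default_rng(31)
        d = rng.integers(0, 3, size=(50, 30)).astype(np.int8)
        g = make_matrix(d)
        once = ld_prune(g, 0.3, 15, 5)
        twice = ld_prune(once, 0.3, 15, 5)
        assert once.snp_ids() == twice.snp_ids()

    def test_unsorted_input_rejected(self):
        g = make_matrix(np.zeros((4, 2), dtype=np.int8), positions=[500, 100])
        with pytest.raises(ValueError, match="sort"):
            ld_prune(g, 0.3, 10, 5)


class TestAlleleSharing:
    def test_identical_and_opposite_samples(self):
        g = make_matrix(np.array([[0, 2, 1], [0, 2, 1], [2, 0, 1]], dtype=np.int8))
        dm = allele_sharing_distance(g)
        assert dm.matrix[0, 1] == 0.0
        # s1 vs s3: two opposite homozygotes and one identical het
        assert dm.matrix[0, 2] == pytest.approx((1 + 1 + 0) / 3)

    def test_opposite_homozygotes_distance_one(self):
        g = make_matrix(np.array([[0, 0], [2, 2]], dtype=np.int8))
        assert allele_sharing_distance(g).matrix[0, 1] == 1.0

    def test_matches_per_snp_ibs_loop(self, random_matrix):
        dm = allele_sharing_distance(random_matrix)
        d = random_matrix.dosage
        for i, j in [(0, 1), (2, 19), (7, 11)]:
            ibs_sum = m = 0
            for k in range(random_matrix.n_snps):
                if d[i, k] == MISSING or d[j, k] == MISSING:
                    continue
                m += 1
                shared = 2 - abs(int(d[i, k]) - int(d[j, k]))
                ibs_sum += shared
            assert dm.matrix[i, j] == pytest.approx(1 - ibs_sum / (2 * m))

    def test_no_overlap_rejected(self):
        g = make_matrix(np.array([[0, MISSING], [MISSING, 2]], dtype=np.int8))
        with pytest.raises(ValueError, match="share no genotyped"):
            allele_sharing_distance(g)


class TestCalibration:
    def test_genomewide_fst_recovers_drift(self):
        """Balding-Nichols with drift F in both populations: the estimator's
        genome-wide value (summed numerators over summed denominators) is F."""
        from lsblscan import PopulationConfig, SimConfig, simulate_panel

        for F in (0.05, 0.1, 0.2):
            cfg = SimConfig(
                n_snps=6_000,
                populations=(
                    PopulationConfig("a", 25, F),
                    PopulationConfig("b", 25, F),
                ),
                missing_rate=0.02,
                seed=101,
            )
            g, assign, _ = simulate_panel(cfg)
            ca = allele_counts(g, assign.samples_in("a"))
            cb = allele_counts(g, assign.samples_in("b"))
            got = genomewide_fst(ca.a, ca.n, cb.a, cb.n)
            assert abs(got - F) / F < 0.2
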