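"""Count matrix construction and the three null models."""

import math
from fractions import Fraction

import numpy as np
import pytest

import regulome as r
from regulome.enrichment import significance_flags

from conftest import brute_force_segments_hit, regulome_from_sim


def hyper_tail_over(N, m, n, b):
    denom = math.comb(N, n)
    return float(
        sum(
            Fraction(math.comb(m, i) * math.comb(N - m, n - i), denom)
            for i in range(b, min(m, n) + 1)
        )
    )


def hyper_tail_under(N, m, n, b):
    denom = math.comb(N, n)
    lo = max(0, n - (N - m))
    return float(
        sum(
            Fraction(math.comb(m, i) * math.comb(N - m, n - i), denom)
            for i in range(lo, b + 1)
        )
    )


def small_fixture(genome, rng, n_tfs=5, n_diseases=4, n_genes=60):
    """Small gene-centric fixture: one possible point per gene (TSS style)."""
    starts = np.sort(rng.choice(900_000 // 1000, size=n_genes, replace=False)) * 1000
    genes = [
        r.GenomicSegment("chr1", int(s), int(s) + 800, "+", f"g{i}")
        for i, s in enumerate(starts)
    ]
    tf_tracks = []
    for t in range(n_tfs):
        targets = rng.choice(n_genes, size=rng.integers(10, 30), replace=False)
        pts = [r.GenomicPoint("chr1", genes[i].start) for i in targets]
        tf_tracks.append(r.PointTrack(f"tf{t}", pts, genome))
    disease_tracks = []
    for d in range(n_diseases):
        members = rng.choice(n_genes, size=rng.integers(15, 35), replace=False)
        disease_tracks.append(
            r.SegmentTrack(f"dis{d}", [genes[i] for i in members], genome)
        )
    return r.TrackSet("tfs", tf_tracks), r.TrackSet("diseases", disease_tracks)


class TestBuildCountMatrix:
    def test_empty_tf_row_is_zero(self, genome):
        tf = r.PointTrack("tf0", [], genome)
        segs = r.SegmentTrack(
            "d0", [r.GenomicSegment("chr1", 0, 100, "+", "g")], genome
        )
        other = r.PointTrack("tf1", [r.GenomicPoint("chr1", 10)], genome)
        cm = r.build_count_matrix(
            r.TrackSet("tfs", [tf, other]), r.TrackSet("dis", [segs])
        )
        assert cm.observed[0, 0] == 0 and cm.observed[1, 0] == 1

    def test_perfect_overlap_hits_every_gene(self, genome):
        genes = [
            r.GenomicSegment("chr1", i * 1000, i * 1000 + 500, "+", f"g{i}")
            for i in range(10)
        ]
        tf = r.PointTrack("tf", [r.GenomicPoint("chr1", g.start) for g in genes], genome)
        cm = r.build_count_matrix(
            r.TrackSet("tfs", [tf]),
            r.TrackSet("dis", [r.SegmentTrack("d", genes, genome)]),
        )
        assert cm.observed[0, 0] == len(genes) == cm.n_t[0]

    def test_matches_per_cell_brute_force(self, genome, rng):
        tfs, diseases = small_fixture(genome, rng)
        cm = r.build_count_matrix(tfs, diseases)
        for ti, tf in enumerate(tfs):
            for di, dis in enumerate(diseases):
                assert cm.observed[ti, di] == brute_force_segments_hit(dis, tf)
        # m_d: universe positions inside >= 1 region, counted once
        uni = r.universe_positions(tfs)
        for di, dis in enumerate(diseases):
            m = sum(
                1
                for (chrom, pos) in uni.as_set()
                if any(s.chrom == chrom and s.start <= pos < s.end for s in dis)
            )
            assert cm.m_d[di] == m


class TestHypergeometricNull:
    def test_derived_example_tails_and_z(self):
        N, m, n, b = 20, 5, 8, 4
        cm = r.CountMatrix(["t"], ["d"], [[b]], [n], N, [m])
        mat = r.hypergeometric_null(cm)
        assert mat.expected[0, 0] == pytest.approx(n * m / N)
        var = n * m * (N - m) * (N - n) / (N**2 * (N - 1))
        assert mat.variance[0, 0] == pytest.approx(var)
        assert mat.z[0, 0] == pytest.approx((b - 2.0) / math.sqrt(var))
        assert mat.p_over[0, 0] == pytest.approx(hyper_tail_over(N, m, n, b), rel=1e-10)
        assert mat.p_under[0, 0] == pytest.approx(hyper_tail_under(N, m, n, b), rel=1e-10)

    def test_tf_occupying_whole_universe_degenerates(self):
        N = m = 12
        cm = r.CountMatrix(["t"], ["d"], [[5]], [N], N, [5])
        mat = r.hypergeometric_null(cm)
        assert mat.expected[0, 0] == pytest.approx(5)
        assert mat.variance[0, 0] == pytest.approx(0)
        assert np.isnan(mat.z[0, 0])
        assert mat.p_over[0, 0] == pytest.approx(1.0)
        assert mat.p_under[0, 0] == pytest.approx(1.0)

    def test_observation_at_expectation_gives_z_zero(self):
        # N=100, m=20, n=25 -> E = 5 exactly
        cm = r.CountMatrix(["t"], ["d"], [[5]], [25], 100, [20])
        assert r.hypergeometric_null(cm).z[0, 0] == pytest.approx(0.0)

    def test_inconsistent_count_rejected(self):
        cm = r.CountMatrix(["t"], ["d"], [[6]], [10], 100, [5])
        with pytest.raises(ValueError, match="inconsisten"):
            r.hypergeometric_null(cm)

    def test_expected_margin_linearity(self, genome, rng):
        tfs, diseases = small_fixture(genome, rng)
        cm = r.build_count_matrix(tfs, diseases)
        mat = r.hypergeometric_null(cm)
        col_sums = mat.expected.sum(axis=0)
        want = cm.m_d * cm.n_t.sum() / cm.N
        np.testing.assert_allclose(col_sums, want, rtol=1e-12)

    def test_z_invariant_under_axis_relabeling(self, genome, rng):
        tfs, diseases = small_fixture(genome, rng)
        cm = r.build_count_matrix(tfs, diseases)
        z = r.hypergeometric_null(cm).z
        perm_t = rng.permutation(len(tfs))
        perm_d = rng.permutation(len(diseases))
        tfs2 = r.TrackSet("tfs", [tfs.tracks[i] for i in perm_t])
        dis2 = r.TrackSet("dis", [diseases.tracks[i] for i in perm_d])
        z2 = r.hypergeometric_null(r.build_count_matrix(tfs2, dis2)).z
        np.testing.assert_allclose(z2, z[np.ix_(perm_t, perm_d)], rtol=1e-12)


class TestBinomialNull:
    def binom_tail_over(self, n, p, b):
        return float(
            sum(
                math.comb(n, i) * (p**i) * ((1 - p) ** (n - i))
                for i in range(b, n + 1)
            )
        )

    def test_row_sum_conservation(self, genome, rng):
        tfs, diseases = small_fixture(genome, rng)
        cm = r.build_count_matrix(tfs, diseases)
        mat = r.binomial_null(cm)
        np.testing.assert_allclose(
            mat.expected.sum(axis=1), cm.observed.sum(axis=1), rtol=1e-9
        )

    def test_all_zero_row_is_undefined(self, genome):
        genes = [
            r.GenomicSegment("chr1", i * 1000, i * 1000 + 500, "+", f"g{i}")
            for i in range(5)
        ]
        quiet = r.PointTrack("quiet", [r.GenomicPoint("chr2", 99)], genome)
        active = r.PointTrack(
            "active", [r.GenomicPoint("chr1", g.start) for g in genes], genome
        )
        cm = r.build_count_matrix(
            r.TrackSet("tfs", [quiet, active]),
            r.TrackSet("dis", [
                r.SegmentTrack("d1", genes[:3], genome),
                r.SegmentTrack("d2", genes[2:], genome),
            ]),
        )
        mat = r.binomial_null(cm)
        assert mat.expected[0, 0] == 0
        assert mat.variance[0, 0] == 0
        assert np.isnan(mat.z[0, 0])
        assert not np.isnan(mat.z[1, 0])

    def test_matches_direct_formula_reimplementation(self, genome, rng):
        tfs, diseases = small_fixture(genome, rng)
        cm = r.build_count_matrix(tfs, diseases)
        mat = r.binomial_null(cm)
        sum_m = cm.m_d.sum()
        for ti in range(len(tfs)):
            for di in range(len(diseases)):
                n = int(cm.n_t[ti])
                p = cm.m_d[di] * cm.observed[ti].sum() / (n * sum_m)
                b = int(cm.observed[ti, di])
                assert mat.expected[ti, di] == pytest.approx(n * p, rel=1e-12)
                assert mat.variance[ti, di] == pytest.approx(n * p * (1 - p), rel=1e-12)
                assert mat.p_over[ti, di] == pytest.approx(
                    self.binom_tail_over(n, p, b), rel=1e-9
                )


class TestPermutationNull:
    def test_fixed_seed_is_deterministic(self, genome, rng):
        tfs, diseases = small_fixture(genome, rng, n_tfs=2, n_diseases=2)
        a = r.permutation_null(tfs, diseases, n_reps=150, seed=9)
        b = r.permutation_null(tfs, diseases, n_reps=150, seed=9)
        np.testing.assert_array_equal(a.expected, b.expected)
        np.testing.assert_array_equal(a.p_over, b.p_over)
        c = r.permutation_null(tfs, diseases, n_reps=150, seed=10)
        assert not np.array_equal(a.expected, c.expected)

    def test_agrees_with_hypergeometric_analytics(self, genome, rng):
        # TSS-style fixture: every region holds at most one universe position,
        # so the hypergeometric model is exact and the permutation null must
        # reproduce its mean within Monte-Carlo standard error.
        tfs, diseases = small_fixture(genome, rng, n_tfs=3, n_diseases=3)
        n_reps = 2000
        perm = r.permutation_null(tfs, diseases, n_reps=n_reps, seed=11)
        hyper = r.hypergeometric_null(
            r.build_count_matrix(tfs, diseases)
        )
        mc_se = np.sqrt(hyper.variance / n_reps)
        assert np.all(np.abs(perm.expected - hyper.expected) <= 3 * mc_se + 1e-12)
        # exact tail within binomial sampling error of the MC estimate
        p = hyper.p_over
        se_p = np.sqrt(p * (1 - p) / n_reps)
        assert np.all(np.abs(perm.p_over - p) <= 4 * se_p + 2 / n_reps)

    def test_rejects_too_few_reps(self, genome, rng):
        tfs, diseases = small_fixture(genome, rng, n_tfs=2, n_diseases=2)
        with pytest.raises(ValueError):
            r.permutation_null(tfs, diseases, n_reps=50, seed=1)


class TestSignificanceFlags:
    def make_matrix(self, p_over, p_under):
        p_over = np.asarray(p_over, dtype=float)
        T, D = p_over.shape
        cm = r.CountMatrix(
            [f"t{i}" for i in range(T)],
            [f"d{j}" for j in range(D)],
            np.zeros((T, D), int),
            np.zeros(T, int),
            10,
            np.zeros(D, int),
        )
        return r.RegulomeMatrix(
            cm, "hypergeometric", np.zeros((T, D)), np.ones((T, D)),
            np.zeros((T, D)), p_over, np.asarray(p_under, dtype=float),
        )

    def test_alpha_one_without_correction_flags_everything(self):
        mat = self.make_matrix([[0.5, 1.0]], [[1.0, 0.2]])
        out = significance_flags(mat, alpha=1.0, correction="none")
        assert out.sig_over.all() and out.sig_under.all()

    def test_alpha_zero_flags_nothing(self):
        mat = self.make_matrix([[0.5, 0.001]], [[0.9, 0.2]])
        out = significance_flags(mat, alpha=0.0, correction="none")
        assert not out.sig_over.any() and not out.sig_under.any()

    def test_bonferroni_threshold_matches_hand_computation(self):
        rng = np.random.default_rng(0)
        p_over = rng.uniform(size=(4, 5))
        p_under = rng.uniform(size=(4, 5))
        alpha = 0.05
        out = significance_flags(self.make_matrix(p_over, p_under),
                                 alpha=alpha, correction="bonferroni")
        thresh = alpha / (2 * 4 * 5)
        np.testing.assert_array_equal(out.sig_over, p_over <= thresh)
        np.testing.assert_array_equal(out.sig_under, p_under <= thresh)

    def test_bh_pools_both_tails(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p_over = rng.uniform(size=(3, 4)) ** 3
        p_under = rng.uniform(size=(3, 4))
        out = significance_flags(self.make_matrix(p_over, p_under),
                                 alpha=0.1, correction="bh")
        pooled = np.concatenate([p_over.ravel(), p_under.ravel()])
        reject, *_ = multipletests(pooled, alpha=0.1, method="fdr_bh")
        np.testing.assert_array_equal(out.sig_over.ravel(), reject[:12])
        np.testing.assert_array_equal(out.sig_under.ravel(), reject[12:])


def test_tail_pvalues_cover_at_least_unity(planted_sim):
    # p_over + p_under >= 1 for any discrete statistic (tails share pmf at b)
    mat = regulome_from_sim(planted_sim)
    assert np.all(mat.p_over + mat.p_under >= 1 - 1e-12)
    assert np.all((mat.p_over > 0) & (mat.p_over <= 1))
    assert np.all((mat.p_under > 0) & (mat.p_under <= 1))
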