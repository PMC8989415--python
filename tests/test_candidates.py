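"""Candidate enumeration, fields, couplings, and top-|h| selection."""

import itertools

import numpy as np
import pytest

from ubia import (
    BinaryDataset,
    CandidateConfig,
    WordSupport,
    enumerate_candidates,
    compute_field,
    compute_coupling,
    select_top_candidates,
    build_system,
)
from ubia.moments import CandidateStat, candidate_stat, column_frequencies, null_covariance
from .conftest import exact_loglik, richardson_first, richardson_second


class TestEnumeration:
    def test_all_zero_data_yields_no_candidates(self):
        data = BinaryDataset(np.zeros((5, 4), dtype=np.uint8))
        assert enumerate_candidates(data, CandidateConfig(k_max=3)) == []

    def test_single_sample_111_yields_all_subsets(self):
        data = BinaryDataset(np.ones((1, 3), dtype=np.uint8))
        # constant columns (n_i = M) carry no signal and are excluded
        assert enumerate_candidates(data, CandidateConfig(k_max=3)) == []
        # with a second, empty sample every unit is informative again
        data = BinaryDataset(np.array([[1, 1, 1], [0, 0, 0]], dtype=np.uint8))
        stats = enumerate_candidates(data, CandidateConfig(k_max=3))
        assert {tuple(s.support) for s in stats} == {
            (0,), (1,), (2,), (0, 1), (0, 2), (1, 2), (0, 1, 2)
        }

    def test_absent_word_threshold(self):
        # q = 0.2 uniform, M = 100: absent order-3 word has <n> = 0.8 kept;
        # with k_max clipped large, an absent order-6 word (<n> = 0.0064) not.
        rng = np.random.default_rng(0)
        vals = np.zeros((100, 7), dtype=np.uint8)
        for j in range(7):
            vals[rng.choice(100, 20, replace=False), j] = 1
        data = BinaryDataset(vals)
        stats = enumerate_candidates(data, CandidateConfig(k_max=6))
        by_support = {tuple(s.support): s for s in stats}
        absent3 = [
            s for s in stats if s.order == 3 and s.n_mu == 0
        ]
        assert absent3, "some order-3 words should be absent yet retained"
        for s in absent3:
            assert s.null_mean * 100 >= 0.02
        absent6 = [
            sup for sup in itertools.combinations(range(7), 6)
            if sup not in by_support
        ]
        assert absent6, "absent order-6 words must be discarded (<n> < 0.02)"

    def test_k_max_clipped_with_warning(self, tiny_data):
        with pytest.warns(UserWarning, match="clipping"):
            enumerate_candidates(tiny_data, CandidateConfig(k_max=10))

    def test_exhaustive_against_bruteforce(self, small_random_data):
        """The vectorized path returns exactly the brute-force candidate set
        with identical statistics."""
        config = CandidateConfig(k_max=3)
        data = small_random_data
        stats = {tuple(s.support): s for s in enumerate_candidates(data, config)}
        n = column_frequencies(data)
        expected = {}
        for k in range(1, 4):
            for sup in itertools.combinations(range(data.N), k):
                ref = candidate_stat(data, sup, n)
                if ref.n_mu > 0 or ref.null_mean * data.M >= config.absent_threshold:
                    expected[sup] = ref
        assert set(stats) == set(expected)
        for sup, ref in expected.items():
            got = stats[sup]
            assert got.n_mu == ref.n_mu
            assert got.null_mean == pytest.approx(ref.null_mean, rel=1e-12)


class TestFields:
    def test_expected_frequency_gives_negative_field(self):
        st = CandidateStat(WordSupport([0]), n_mu=20, sigma_bar=0.2,
                           null_mean=0.2, null_var=0.16)
        h = compute_field(st, 100)
        assert h == pytest.approx(-100 * 0.16 / 2)
        assert h < 0

    def test_worked_example(self):
        st = CandidateStat(WordSupport([0, 1]), n_mu=20, sigma_bar=0.2,
                           null_mean=0.1, null_var=0.09)
        assert compute_field(st, 100) == pytest.approx(45.5)

    def test_over_and_under_representation_symmetric(self):
        over = CandidateStat(WordSupport([0]), 30, 0.3, 0.2, 0.16)
        under = CandidateStat(WordSupport([0]), 10, 0.1, 0.2, 0.16)
        assert compute_field(over, 100) == pytest.approx(compute_field(under, 100))

    def test_field_increases_with_sample_size(self):
        st = CandidateStat(WordSupport([0]), 0, 0.3, 0.2, 0.16)
        hs = [compute_field(st, M) for M in (50, 100, 200, 400)]
        assert all(a < b for a, b in zip(hs, hs[1:]))

    def test_matches_loglik_derivatives(self, small_random_data):
        """h_mu = (1/2)[d2L/dtheta2 + (dL/dtheta)^2] at the null anchor,
        via exact state enumeration and numerical differentiation."""
        data = small_random_data
        for sup in [(0,), (0, 3), (1, 2, 4)]:
            st = candidate_stat(data, sup)
            f = lambda d: exact_loglik(data, {sup: d})
            h_num = 0.5 * (richardson_second(f) + richardson_first(f) ** 2)
            assert compute_field(st, data.M) == pytest.approx(h_num, rel=1e-6)


class TestCouplings:
    def test_disjoint_supports_zero(self):
        a = CandidateStat(WordSupport([0, 1]), 10, 0.1, 0.2, 0.16)
        b = CandidateStat(WordSupport([2, 3]), 10, 0.1, 0.2, 0.16)
        assert compute_coupling(a, b, 0.0, 100) == 0.0

    def test_worked_example_zero_deviation(self):
        a = CandidateStat(WordSupport([0, 1]), 25, 0.25, 0.25, 0.1875)
        b = CandidateStat(WordSupport([1, 2]), 25, 0.25, 0.25, 0.1875)
        assert compute_coupling(a, b, 0.0625, 100) == pytest.approx(
            2500 * 0.0625 ** 2
        )

    def test_expected_cooccurrence_with_positive_codeviation_negative(self):
        a = CandidateStat(WordSupport([0, 1]), 40, 0.4, 0.25, 0.1875)
        b = CandidateStat(WordSupport([1, 2]), 40, 0.4, 0.25, 0.1875)
        assert compute_coupling(a, b, 0.0625, 100) < 0

    def test_matches_loglik_mixed_derivative(self, small_random_data):
        """J from Eq.-level closed form equals the numerical mixed second
        derivative construction (confirming the 2M deviation term)."""
        data = small_random_data
        n = column_frequencies(data)
        sa, sb = (0, 3), (1, 3, 5)
        sta, stb = candidate_stat(data, sa), candidate_stat(data, sb)
        d = 1e-3

        def f(da, db):
            return exact_loglik(data, {sa: da, sb: db})

        Hab = (f(d, d) - f(d, -d) - f(-d, d) + f(-d, -d)) / (4 * d * d)
        ba = richardson_first(lambda x: f(x, 0.0), d)
        bb = richardson_first(lambda x: f(0.0, x), d)
        J_num = 0.25 * Hab * (Hab + 2.0 * ba * bb)
        cov = null_covariance(n, data.M, sa, sb)
        assert compute_coupling(sta, stb, cov, data.M) == pytest.approx(
            J_num, rel=1e-4
        )


class TestSelection:
    def test_fewer_candidates_than_n_max_all_kept(self, small_random_data):
        stats = enumerate_candidates(small_random_data, CandidateConfig(k_max=2))
        system = select_top_candidates(stats, CandidateConfig(k_max=2, n_max=5000),
                                       small_random_data.M)
        assert system.size == len(stats)

    def test_top_by_absolute_field(self, small_random_data):
        config = CandidateConfig(k_max=3, n_max=10)
        stats = enumerate_candidates(small_random_data, config)
        system = select_top_candidates(stats, config, small_random_data.M)
        all_h = sorted((abs(compute_field(s, small_random_data.M)) for s in stats),
                       reverse=True)
        assert sorted(np.abs(system.h), reverse=True) == pytest.approx(all_h[:10])

    def test_deterministic_selection(self, small_random_data):
        config = CandidateConfig(k_max=3, n_max=20)
        s1 = build_system(small_random_data, config)
        s2 = build_system(small_random_data, config)
        assert s1.supports == s2.supports
        assert np.array_equal(s1.h, s2.h)
        assert np.array_equal(s1.J, s2.J)

    def test_fast_path_matches_object_path(self, small_random_data):
        config = CandidateConfig(k_max=3, n_max=15)
        stats = enumerate_candidates(small_random_data, config)
        via_stats = select_top_candidates(stats, config, small_random_data.M)
        via_arrays = build_system(small_random_data, config)
        assert via_stats.supports == via_arrays.supports
        np.testing.assert_allclose(via_stats.h, via_arrays.h, rtol=1e-12)
        np.testing.assert_allclose(via_stats.J, via_arrays.J, rtol=1e-9, atol=1e-12)


class TestSystemInvariants:
    def test_coupling_matrix_symmetric_zero_for_disjoint(self, small_random_data):
        system = build_system(small_random_data, CandidateConfig(k_max=3, n_max=30))
        np.testing.assert_allclose(system.J, system.J.T)
        for a in range(system.size):
            for b in range(a + 1, system.size):
                if not set(system.supports[a]) & set(system.supports[b]):
                    assert system.J[a, b] == 0.0
        assert np.all(np.diag(system.J) == 0.0)

    def test_coupling_matrix_matches_scalar_formula(self, small_random_data):
        data = small_random_data
        system = build_system(data, CandidateConfig(k_max=3, n_max=25))
        n = column_frequencies(data)
        for a in range(system.size):
            for b in range(a + 1, system.size):
                sa, sb = system.supports[a], system.supports[b]
                sta = candidate_stat(data, sa, n)
                stb = candidate_stat(data, sb, n)
                cov = null_covariance(n, data.M, sa, sb)
                assert system.J[a, b] == pytest.approx(
                    compute_coupling(sta, stb, cov, data.M), rel=1e-9, abs=1e-12
                )
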