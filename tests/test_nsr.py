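import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pyuntb import (compute_stochasticity, normalized_sr,
                    null_expected_similarity, pairwise_ruzicka,
                    ruzicka_similarity, simulate_metacommunity,
                    stochasticity_ratio, to_relative_abundance)

from conftest import make_cm, null_process_metacommunity


class TestRuzicka:
    def test_hand_value(self):
        assert ruzicka_similarity([0.5, 0.5, 0], [0.25, 0.25, 0.5]) == \
            pytest.approx(1 / 3)

    def test_identical_and_disjoint(self):
        assert ruzicka_similarity([0.2, 0.8], [0.2, 0.8]) == 1.0
        assert ruzicka_similarity([1, 0], [0, 1]) == 0.0

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            ruzicka_similarity([0, 0], [0, 0])

    def test_reduces_to_jaccard_on_binary(self):
        p = np.array([1, 1, 0, 0, 1.0])
        q = np.array([1, 0, 1, 0, 1.0])
        assert ruzicka_similarity(p, q) == pytest.approx(2 / 4)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(arrays(np.float64, 6, elements=st.floats(0, 10)),
           arrays(np.float64, 6, elements=st.floats(0, 10)))
    def test_symmetric_and_bounded(self, p, q):
        if p.sum() == 0 or q.sum() == 0:
            return
        s = ruzicka_similarity(p, q)
        assert s == ruzicka_similarity(q, p)
        assert 0 <= s <= 1


class TestNullExpectation:
    def test_identity_null_equals_observed(self, wide_cm):
        from pyuntb import filter_min_reads
        cm = filter_min_reads(wide_cm, 1)
        E = null_expected_similarity(cm, n_null=5, null_algorithm="identity",
                                     seed=0)
        C = pairwise_ruzicka(to_relative_abundance(cm))
        np.testing.assert_allclose(E, C)

    def test_seed_determinism_and_range(self):
        cm = null_process_metacommunity(3, n_samples=8)
        E1 = null_expected_similarity(cm, n_null=20, seed=5)
        E2 = null_expected_similarity(cm, n_null=20, seed=5)
        np.testing.assert_array_equal(E1, E2)
        assert ((E1 >= 0) & (E1 <= 1)).all()

    def test_unknown_algorithm_raises(self, small_cm):
        with pytest.raises(ValueError):
            null_expected_similarity(small_cm, n_null=5, null_algorithm="?")


class TestStochasticityRatio:
    def test_single_pair_type_a(self):
        C = np.array([[1.0, 1.0], [1.0, 1.0]])
        E = np.array([[1.0, 0.2], [0.2, 1.0]])
        SR, n_A, n_B, _ = stochasticity_ratio(C, E)
        assert SR == pytest.approx(0.2)
        assert (n_A, n_B) == (1, 0)

    def test_single_pair_type_b(self):
        C = np.array([[1.0, 0.1], [0.1, 1.0]])
        E = np.array([[1.0, 0.5], [0.5, 1.0]])
        SR, n_A, n_B, _ = stochasticity_ratio(C, E)
        assert SR == pytest.approx(0.5 / 0.9)
        assert (n_A, n_B) == (0, 1)

    def test_all_ties_warns_and_returns_one(self):
        C = np.full((3, 3), 0.4)
        with pytest.warns(UserWarning):
            SR, n_A, n_B, _ = stochasticity_ratio(C, C)
        assert SR == 1.0 and n_A == n_B == 0

    def test_sample_reordering_invariance(self):
        cm = null_process_metacommunity(11, n_samples=10)
        res = compute_stochasticity(cm, n_null=30, seed=2)
        perm = np.random.default_rng(1).permutation(cm.n_samples)
        C2 = res.C[np.ix_(perm, perm)]
        E2 = res.E_bar[np.ix_(perm, perm)]
        SR2, *_ = stochasticity_ratio(C2, E2)
        assert SR2 == pytest.approx(res.SR)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_sr_in_unit_interval_on_random_configs(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 8)
        C = rng.random((n, n))
        E = rng.random((n, n))
        C = (C + C.T) / 2
        E = (E + E.T) / 2
        SR, *_ = stochasticity_ratio(C, E)
        assert 0 <= SR <= 1


class TestNSR:
    def test_null_coincident_maps_to_one(self):
        # every pair an epsilon away from its expectation in either direction
        C = np.array([[1, 0.5 + 1e-9, 0.5 - 1e-9],
                      [0.5 + 1e-9, 1, 0.5 + 1e-9],
                      [0.5 - 1e-9, 0.5 + 1e-9, 1]])
        E = np.full((3, 3), 0.5)
        np.fill_diagonal(E, 1)
        assert normalized_sr(C, E) == pytest.approx(1.0, abs=1e-6)

    def test_deterministic_fixture_near_zero(self):
        counts = np.zeros((1, 12), dtype=int)
        counts[0] = 1000
        cm = make_cm(counts)
        res = compute_stochasticity(cm, n_null=300,
                                    null_algorithm="richness_uniform",
                                    seed=4, pool_size=1000)
        assert res.SR <= 0.01
        assert res.NSR < 0.01

    def test_nsr_clipped_to_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(3, 7)
            C = rng.random((n, n))
            C = (C + C.T) / 2
            E = rng.random((n, n))
            E = (E + E.T) / 2
            assert 0 <= normalized_sr(C, E) <= 1

    def test_from_null_draws(self):
        cm = null_process_metacommunity(21, n_samples=8)
        E, draws = null_expected_similarity(cm, n_null=25, seed=9,
                                            return_draws=True)
        C = pairwise_ruzicka(to_relative_abundance(cm))
        assert normalized_sr(C, null_draws=draws) == \
            pytest.approx(normalized_sr(C, E))


class TestCalibration:
    def test_self_null_data_give_high_sr(self):
        """Observed data generated by the null process itself sit at the
        stochastic limit: SR close to 1."""
        srs = [compute_stochasticity(null_process_metacommunity((31, r)),
                                     n_null=100, seed=(32, r)).SR
               for r in range(5)]
        assert np.mean(srs) >= 0.9
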