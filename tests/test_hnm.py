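import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pyuntb import (EtienneLikelihood, SADSample, ewens_loglik, fit_hnm,
                    hnm_neutrality_test, neutral_loglik, passing_rate_curve,
                    simulate_local_neutral, simulate_metacommunity,
                    simulate_neutral_sad)
from pyuntb.hnm import log_stirling_row

from _oracles import enumerate_sad_probs, ewens_prob


def partitions(n, cap=None):
    """All unordered SADs (integer partitions) of n."""
    cap = cap or n
    if n == 0:
        yield ()
        return
    for first in range(min(n, cap), 0, -1):
        for rest in partitions(n - first, first):
            yield (first,) + rest


class TestLikelihood:
    def test_single_individual_probability_one(self):
        for theta, I in [(0.5, 1.0), (7.0, 300.0)]:
            assert abs(neutral_loglik(SADSample([1]), theta, I)) < 1e-12

    def test_matches_enumeration_oracle_small_J(self):
        """The sampling-formula likelihood equals exhaustive history
        enumeration for every SAD with J <= 8 on a (theta, I) grid."""
        grid = [(0.7, 1.3), (2.0, 5.0), (10.0, 0.5)]
        for theta, I in grid:
            for J in range(2, 9):
                probs = enumerate_sad_probs(theta, I, J)
                assert abs(sum(probs.values()) - 1) < 1e-12
                for sad, p in probs.items():
                    ll = neutral_loglik(SADSample(list(sad)), theta, I)
                    assert abs(ll - np.log(p)) <= 1e-9, (theta, I, sad)

    def test_specific_value_vs_oracle(self):
        probs = enumerate_sad_probs(2.0, 5.0, 3)
        expected = np.log(probs[(1, 2)])
        assert abs(neutral_loglik(SADSample([2, 1]), 2.0, 5.0)
                   - expected) < 1e-9

    def test_ewens_limit_large_I(self):
        """As I -> infinity the formula converges to the Ewens closed form."""
        for sad in ([5, 3, 1, 1], [10, 10], [7, 2, 2, 1, 1, 1]):
            for theta in (0.5, 3.0, 25.0):
                full = neutral_loglik(SADSample(sad), theta, 1e8)
                ew = np.log(ewens_prob(sad, theta))
                assert abs(full - ew) / abs(ew) <= 1e-6
                assert abs(ewens_loglik(SADSample(sad), theta) - ew) < 1e-9

    def test_normalization_over_partitions(self):
        """Likelihood sums to 1 over all SADs of fixed J."""
        theta, I, J = 3.0, 2.0, 7
        total = sum(np.exp(neutral_loglik(SADSample(list(p)), theta, I))
                    for p in partitions(J))
        assert abs(total - 1) < 1e-9

    def test_stirling_rows_small_values(self):
        # s(4, .) = (6, 11, 6, 1)
        np.testing.assert_allclose(np.exp(log_stirling_row(4)),
                                   [6, 11, 6, 1], rtol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 30), min_size=2, max_size=8),
           st.floats(0.1, 50.0), st.floats(0.1, 1e4))
    def test_loglik_finite_and_negative(self, abund, theta, I):
        ll = neutral_loglik(SADSample(abund), theta, I)
        assert np.isfinite(ll)
        assert ll <= 1e-12


class TestFit:
    def test_parameter_recovery(self):
        """Median theta over replicate fits near the generating value, and
        every fit dominates the generating parameters in likelihood.

        m is deliberately not checked here: for a single SAD the likelihood
        has a shallow ridge joining a low-m/high-theta and a high-m/
        low-theta mode, so the exact MLE of m alone is unreliable (the
        multi-site model exists precisely to pool this information)."""
        thetas = []
        for i in range(20):
            meta = simulate_metacommunity("stick_breaking", 20.0, 2000,
                                          seed=(50, i))
            sad = simulate_local_neutral(meta, 2000, 0.3, seed=(51, i))
            fit = fit_hnm(sad)
            thetas.append(fit.theta)
            I_true = 0.3 * (sad.J - 1) / 0.7
            assert fit.loglik >= neutral_loglik(sad, 20.0, I_true) - 1e-6
        assert 10 <= np.median(thetas) <= 40

    def test_deterministic(self):
        meta = simulate_metacommunity("stick_breaking", 10.0, 300, seed=1)
        sad = simulate_local_neutral(meta, 600, 0.5, seed=2)
        f1, f2 = fit_hnm(sad), fit_hnm(sad)
        assert (f1.theta, f1.m) == (f2.theta, f2.m)

    def test_degenerate_sads_flagged(self):
        with pytest.warns(UserWarning):
            fit = fit_hnm(SADSample([500]))
        assert fit.boundary
        with pytest.warns(UserWarning):
            fit = fit_hnm(SADSample([1] * 12))
        assert fit.boundary and fit.theta == pytest.approx(1e5)

    def test_loglik_at_optimum_beats_neighbors(self):
        meta = simulate_metacommunity("stick_breaking", 15.0, 300, seed=4)
        sad = simulate_local_neutral(meta, 500, 0.4, seed=5)
        fit = fit_hnm(sad)
        lik = EtienneLikelihood(sad)
        for ft, fm in itertools.product((0.5, 2.0), repeat=2):
            I = (fm * fit.m) * (sad.J - 1) / (1 - min(fm * fit.m, 0.999))
            assert lik.loglik(ft * fit.theta, I) <= fit.loglik + 1e-6


class TestNeutralityTest:
    def test_deterministic_given_seed(self):
        meta = simulate_metacommunity("stick_breaking", 20.0, 300, seed=6)
        sad = simulate_local_neutral(meta, 300, 0.5, seed=7)
        r1 = hnm_neutrality_test(sad, n_sim=50, seed=123)
        r2 = hnm_neutrality_test(sad, n_sim=50, seed=123)
        assert r1.pseudo_p == r2.pseudo_p

    def test_even_sad_rejected(self):
        """A perfectly even 20-species SAD is an extreme departure from
        neutral expectations."""
        sad = SADSample([50] * 20)
        res = hnm_neutrality_test(sad, n_sim=100, seed=11)
        assert res.pseudo_p < 0.05
        assert res.verdict == "rejected"

    def test_pseudo_p_bounds_and_smoothing(self):
        meta = simulate_metacommunity("stick_breaking", 20.0, 300, seed=8)
        sad = simulate_local_neutral(meta, 200, 0.5, seed=9)
        res = hnm_neutrality_test(sad, n_sim=40, seed=10)
        assert 1 / 41 <= res.pseudo_p <= 1.0

    def test_n_sim_floor(self):
        with pytest.raises(ValueError):
            hnm_neutrality_test(SADSample([5, 3, 1]), n_sim=10, seed=1)

    def test_subsampling_preserves_composition(self):
        """Deep samples are thinned without replacement; proportions are
        approximately preserved and the total hits the cap exactly."""
        from pyuntb.hnm import _subsample_sad
        sad = SADSample([40_000, 20_000, 5], sample_id="deep")
        sub = _subsample_sad(sad, 30_000, np.random.default_rng(0))
        assert sub.J == 30_000
        assert abs(sub.abundances[0] / sub.J - 2 / 3) < 0.01

    def test_simulator_conserves_J(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            sad = simulate_neutral_sad(5.0, 30.0, 250, rng)
            assert sad.J == 250

    def test_simulator_matches_formula_distribution(self):
        """Empirical SAD frequencies from the sampling-formula simulator
        match the analytic probabilities (chi-square on J=4 partitions)."""
        from scipy.stats import chisquare
        theta, I, J, n = 2.0, 3.0, 4, 4000
        rng = np.random.default_rng(42)
        keys = list(enumerate_sad_probs(theta, I, J).keys())
        expected = np.array([enumerate_sad_probs(theta, I, J)[k]
                             for k in keys])
        obs = dict.fromkeys(keys, 0)
        for _ in range(n):
            sad = tuple(sorted(simulate_neutral_sad(theta, I, J,
                                                    rng).abundances))
            obs[sad] += 1
        counts = np.array([obs[k] for k in keys], dtype=float)
        _, p = chisquare(counts, f_exp=expected * n)
        assert p > 1e-3


class TestPassingRateCurve:
    def test_direct_counts(self):
        rates = passing_rate_curve([0.2, 0.6, 0.9], [0.05, 0.5])
        np.testing.assert_allclose(rates, [1.0, 2 / 3])

    def test_extremes(self):
        assert passing_rate_curve([0.3, 0.7], [0.0])[0] == 1.0
        assert passing_rate_curve([0.3, 0.7], [1.0])[0] == 0.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            passing_rate_curve([], [0.5])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_monotone_non_increasing(self, pvals):
        t = np.linspace(0, 1, 11)
        rates = passing_rate_curve(pvals, t)
        assert (np.diff(rates) <= 1e-12).all()
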