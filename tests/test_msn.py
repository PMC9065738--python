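import numpy as np
import pytest

from pyuntb import (CommunityMatrix, SimConfig, antoniak_pmf, extract_sad,
                    fit_hnm, fit_msn, msn_neutrality_test,
                    simulate_metacommunity, simulate_msn_dataset,
                    simulate_treatment)
from pyuntb.hnm import EtienneLikelihood

from conftest import make_cm


def neutral_treatment(theta, m, J, n_sites, seed):
    meta = simulate_metacommunity("stick_breaking", theta, 4 * J, seed=(seed, 0))
    return simulate_treatment(meta, SimConfig(J=J, m=m, n_sites=n_sites,
                                              seed=(seed, 1)))


class TestAntoniak:
    def test_single_draw(self):
        for theta in (0.1, 1.0, 42.0):
            np.testing.assert_allclose(antoniak_pmf(theta, 1), [1.0])

    def test_two_draws_hand_value(self):
        # s(2,1) = s(2,2) = 1: P(S=1) = 1/(theta+1), P(S=2) = theta/(theta+1)
        np.testing.assert_allclose(antoniak_pmf(1.0, 2), [0.5, 0.5],
                                   atol=1e-12)
        np.testing.assert_allclose(antoniak_pmf(3.0, 2), [0.25, 0.75],
                                   atol=1e-12)

    @pytest.mark.parametrize("theta", [0.1, 1.0, 10.0, 100.0])
    def test_normalization_up_to_N50(self, theta):
        for N in (2, 5, 10, 25, 50):
            assert abs(antoniak_pmf(theta, N).sum() - 1) <= 1e-10

    def test_mode_shifts_right_with_theta(self):
        """S is stochastically larger at larger theta (cdf comparison)."""
        N = 40
        cdf_small = np.cumsum(antoniak_pmf(0.5, N))
        cdf_large = np.cumsum(antoniak_pmf(20.0, N))
        assert (cdf_large <= cdf_small + 1e-12).all()

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            antoniak_pmf(0.0, 5)
        with pytest.raises(ValueError):
            antoniak_pmf(1.0, 0)


class TestFit:
    def test_deterministic_chains(self):
        cm = neutral_treatment(20.0, 0.5, 400, 4, seed=3)
        f1 = fit_msn(cm, n_gibbs=200, burn_in=100, seed=9)
        f2 = fit_msn(cm, n_gibbs=200, burn_in=100, seed=9)
        np.testing.assert_array_equal(f1.traces["theta"], f2.traces["theta"])
        np.testing.assert_array_equal(f1.traces["I"], f2.traces["I"])

    def test_beta_post_normalized(self):
        cm = neutral_treatment(15.0, 0.5, 300, 3, seed=4)
        fit = fit_msn(cm, n_gibbs=300, burn_in=100, seed=1)
        assert abs(fit.beta_post.sum() - 1) <= 1e-9
        assert len(fit.traces["theta"]) == 200

    def test_posterior_interval_covers_truth(self):
        """Central 90% interval for theta contains the generating value in
        most replicate fits (loose calibration at small scale)."""
        hits = 0
        for rep in range(8):
            cm = neutral_treatment(30.0, 0.5, 800, 6, seed=(60, rep))
            fit = fit_msn(cm, n_gibbs=500, burn_in=200, seed=rep)
            lo, hi = np.percentile(fit.traces["theta"], [5, 95])
            hits += lo <= 30.0 <= hi
        assert hits >= 5

    def test_single_site_lands_on_mle_likelihood_ridge(self):
        """For one SAD, (theta, I) are jointly weakly identified along a
        likelihood ridge; the Bayesian fit and the MLE must agree in
        likelihood even when the parameter points differ."""
        cm = neutral_treatment(20.0, 0.5, 1000, 1, seed=77)
        sad = extract_sad(cm, cm.sample_ids[0])
        mle = fit_hnm(sad)
        fit = fit_msn(cm, n_gibbs=600, burn_in=300, seed=5)
        lik = EtienneLikelihood(sad)
        post_ll = lik.loglik(fit.theta, fit.I[0])
        assert mle.loglik - post_ll < 5.0

    def test_requires_gibbs_beyond_burnin(self):
        cm = neutral_treatment(10.0, 0.5, 200, 2, seed=6)
        with pytest.raises(ValueError):
            fit_msn(cm, n_gibbs=100, burn_in=100)


class TestNeutralityTest:
    def test_self_consistency_neutral_data(self):
        """Data simulated from (approximately) the fitted model should not
        be rejected at the metacommunity level."""
        passes = 0
        for rep in range(5):
            cm = neutral_treatment(30.0, 0.5, 600, 5, seed=(70, rep))
            fit = fit_msn(cm, n_gibbs=400, burn_in=150, seed=rep)
            t = msn_neutrality_test(fit, cm, n_sim=60, seed=rep)
            passes += t.P_M > 0.05
        assert passes >= 4

    def test_even_identical_sites_rejected(self):
        """Deterministically identical, perfectly even sites are an extreme
        violation of neutral sampling noise."""
        S, n_sites, J = 20, 6, 1000
        cm = make_cm(np.tile(np.full((S, 1), J // S), (1, n_sites)))
        fit = fit_msn(cm, n_gibbs=400, burn_in=150, seed=0)
        t = msn_neutrality_test(fit, cm, n_sim=60, seed=1)
        assert t.P_M <= 0.05

    def test_outputs_in_unit_interval_and_relabel_invariance(self):
        cm = neutral_treatment(10.0, 0.6, 300, 4, seed=8)
        fit = fit_msn(cm, n_gibbs=300, burn_in=100, seed=2)
        t = msn_neutrality_test(fit, cm, n_sim=30, seed=3)
        assert 0 <= t.P_M <= 1
        assert ((t.P_L >= 0) & (t.P_L <= 1)).all()
        # reversing site order permutes P_L and leaves P_M unchanged
        rev = CommunityMatrix(cm.otu_ids, cm.sample_ids[::-1],
                              cm.counts[:, ::-1])
        fit_r = fit_msn(rev, n_gibbs=300, burn_in=100, seed=2)
        t_r = msn_neutrality_test(fit_r, rev, n_sim=30, seed=3)
        assert abs(t_r.P_M - t.P_M) <= 0.2  # same statistic, fresh chains

    def test_n_sim_floor(self):
        cm = neutral_treatment(10.0, 0.6, 200, 3, seed=9)
        fit = fit_msn(cm, n_gibbs=200, burn_in=100, seed=4)
        with pytest.raises(ValueError):
            msn_neutrality_test(fit, cm, n_sim=10)


class TestSimulator:
    def test_site_sizes_and_determinism(self):
        rng1 = np.random.default_rng(5)
        rng2 = np.random.default_rng(5)
        J = np.array([100, 250, 60])
        I = np.array([10.0, 50.0, 5.0])
        s1 = simulate_msn_dataset(8.0, I, J, rng1)
        s2 = simulate_msn_dataset(8.0, I, J, rng2)
        for a, b, j in zip(s1, s2, J):
            assert a.J == j
            assert np.array_equal(a.abundances, b.abundances)
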