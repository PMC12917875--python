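"""Five-parameter combination BLRM: model function, sampler, EWOC, selection."""

import numpy as np
import pytest
from scipy.special import expit

from doseinsert import BLRMPriors, blrm_fit, joint_tox_prob, pipe_prior
from doseinsert.blrm_design import (blrm_next_dose, blrm_select_final,
                                    ewoc_admissible, standardized_doses)
from doseinsert.state import DesignConfig, TrialState


def make_state(n=None, y=None):
    means, ss, _ = pipe_prior((3, 3))
    st = TrialState.from_prior(means, ss)
    if n is not None:
        st.n = np.array(n)
        st.y = np.array(y)
    return st


class TestJointToxProb:
    def test_hand_worked_example(self):
        # alpha1=beta1=0, alpha2=beta2=1, doses 0, eta=1:
        # psi=0.5 each, p_dagger=0.75, odds 3 * exp(log 2) = 6 -> 6/7
        assert joint_tox_prob((0, 1, 0, 1, 1), 0.0, 0.0) == pytest.approx(6 / 7)

    def test_no_interaction_factorizes(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a1, b1 = rng.normal(-1, 2, 2)
            a2, b2 = rng.lognormal(0, 0.7, 2)
            da, db = rng.uniform(-1, 2, 2)
            p = joint_tox_prob((a1, a2, b1, b2, 0.0), da, db)
            psi_a = expit(a1 + a2 * da)
            psi_b = expit(b1 + b2 * db)
            assert p == pytest.approx(1 - (1 - psi_a) * (1 - psi_b), abs=1e-12)

    def test_vanishing_single_agent_probabilities(self):
        assert joint_tox_prob((-60, 1, -60, 1, 0.5), 0.0, 0.0) == pytest.approx(0.0,
                                                                                abs=1e-20)

    def test_monotone_in_both_doses_for_positive_params(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            params = (rng.normal(-2, 1), rng.lognormal(0.5, 0.5),
                      rng.normal(-2, 1), rng.lognormal(0.5, 0.5),
                      abs(rng.normal(0, 0.5)))
            d = np.sort(rng.uniform(-0.5, 1.5, 5))
            p_a = joint_tox_prob(params, d, 0.3)
            p_b = joint_tox_prob(params, 0.3, d)
            assert np.all(np.diff(p_a) >= -1e-12)
            assert np.all(np.diff(p_b) >= -1e-12)

    def test_reduces_to_single_agent_logistic(self):
        # eta=0 and agent B impossible to cause toxicity: two-parameter logistic
        a1, a2 = -1.3, 2.1
        d = np.linspace(-0.5, 1.0, 7)
        p = joint_tox_prob((a1, a2, -60.0, 1.0, 0.0), d, 0.2)
        np.testing.assert_allclose(p, expit(a1 + a2 * d), atol=1e-10)

    def test_classical_interaction_form(self):
        p = joint_tox_prob((0, 1, 0, 1, 1.0), 0.5, 0.5, classical_interaction=True)
        odds = 3 * np.exp(1.0 * 0.25)  # p_dagger=0.75 at psi=expit(0.5)? no:
        psi = expit(0.5)
        pd = 1 - (1 - psi) ** 2
        odds = pd / (1 - pd) * np.exp(0.25)
        assert p == pytest.approx(odds / (1 + odds))


class TestStandardizedDoses:
    def test_compatibility_with_prior_probabilities(self):
        pri = BLRMPriors()
        da = np.asarray(pri.std_doses_a)
        slope = np.exp(pri.mu_alpha[1] + pri.sd_alpha[1] ** 2 / 2)
        np.testing.assert_allclose(expit(pri.mu_alpha[0] + slope * da),
                                   [0.10, 0.25, 0.40], atol=1e-12)

    def test_inserted_levels_interpolated(self):
        pri = BLRMPriors()
        st = make_state()
        from doseinsert import InsertionPlan, expand_state
        st2 = expand_state(st, InsertionPlan(frozenset({0}), frozenset()))
        da, db = standardized_doses(pri, st2.grid)
        assert da[1] == pytest.approx((pri.std_doses_a[0] + pri.std_doses_a[1]) / 2)
        np.testing.assert_allclose(db, pri.std_doses_b)


class TestFit:
    def test_prior_predictive_mean_at_lowest_combination(self):
        # no data: plug-in estimate should sit near the direct prior construction
        rng = np.random.default_rng(0)
        pri = BLRMPriors()
        post = blrm_fit(make_state(), pri, 2000, rng, burn_in=500)
        draws = rng.standard_normal((20000, 5))
        mu = np.array([pri.mu_alpha[0], pri.mu_alpha[1], pri.mu_beta[0],
                       pri.mu_beta[1], pri.mu_eta])
        sd = np.array([pri.sd_alpha[0], pri.sd_alpha[1], pri.sd_beta[0],
                       pri.sd_beta[1], pri.sd_eta])
        x = mu + sd * draws
        mean_params = (x[:, 0].mean(), np.exp(x[:, 1]).mean(), x[:, 2].mean(),
                       np.exp(x[:, 3]).mean(), x[:, 4].mean())
        oracle = joint_tox_prob(mean_params, pri.std_doses_a[0], pri.std_doses_b[0])
        assert post.pi_mean[0, 0] == pytest.approx(oracle, abs=0.1)

    def test_sharp_toxicity_jump_is_smoothed(self):
        # 0/12 at d11, 9/12 at d12, 8/12 at d21: the rigid surface overestimates
        # the lowest combination and underestimates the two toxic ones
        st = make_state(n=[[12, 12, 0], [12, 0, 0], [0, 0, 0]],
                        y=[[0, 9, 0], [8, 0, 0], [0, 0, 0]])
        post = blrm_fit(st, BLRMPriors(), 2000, np.random.default_rng(1))
        assert post.pi_mean[0, 0] > 0.10          # >> its empirical 0%
        assert post.pi_mean[0, 1] < 9 / 12        # < empirical 75%
        assert post.pi_mean[1, 0] < 8 / 12 + 0.05  # <~ empirical 67%
        assert np.all(np.diff(post.pi_mean, axis=0) >= -1e-9)
        assert np.all(np.diff(post.pi_mean, axis=1) >= -1e-9)

    def test_mcmc_reproducible_and_consistent(self):
        st = make_state(n=[[6, 3, 0], [3, 0, 0], [0, 0, 0]],
                        y=[[0, 1, 0], [2, 0, 0], [0, 0, 0]])
        p1 = blrm_fit(st, BLRMPriors(), 1000, np.random.default_rng(3), burn_in=500)
        p2 = blrm_fit(st, BLRMPriors(), 1000, np.random.default_rng(3), burn_in=500)
        np.testing.assert_array_equal(p1.samples, p2.samples)
        p3 = blrm_fit(st, BLRMPriors(), 2000, np.random.default_rng(4), burn_in=500)
        assert np.abs(p1.pi_mean - p3.pi_mean).max() < 0.08

    def test_parameter_recovery_at_large_n(self):
        # truth inside the model family; n=480 per combination
        pri = BLRMPriors()
        truth_params = (-2.0, 3.0, -2.0, 3.0, 0.3)
        DA, DB = np.meshgrid(pri.std_doses_a, pri.std_doses_b, indexing="ij")
        pi_true = joint_tox_prob(truth_params, DA, DB)
        rng = np.random.default_rng(12)
        n = np.full((3, 3), 480)
        y = rng.binomial(n, pi_true)
        st = make_state(n=n, y=y)
        post = blrm_fit(st, pri, 2000, np.random.default_rng(13))
        assert np.abs(post.pi_mean - pi_true).max() < 0.05


class TestEwocAndEscalation:
    def test_ewoc_boundary_is_inclusive(self):
        pri = BLRMPriors()
        post = blrm_fit(make_state(), pri, 500, np.random.default_rng(0),
                        burn_in=200)
        post.pi_exceed = np.array([[0.40, 1.0], [0.0, 0.39]])
        adm = ewoc_admissible(post, pri)
        np.testing.assert_array_equal(adm, [[True, False], [True, True]])

    def test_patient_gain_picks_closest_from_below(self):
        pri = BLRMPriors()
        st = make_state()
        st.treat((0, 0), 3, 0)
        post = blrm_fit(st, pri, 500, np.random.default_rng(0), burn_in=200)
        post.pi_mean = np.array([[0.10, 0.25, 0.45]] * 3)
        post.pi_exceed = np.zeros((3, 3))
        nxt = blrm_next_dose(post, st, DesignConfig(), pri)
        assert nxt == (0, 1)

    def test_all_inadmissible_terminates(self):
        pri = BLRMPriors()
        st = make_state()
        st.treat((0, 0), 3, 3)
        post = blrm_fit(st, pri, 500, np.random.default_rng(0), burn_in=200)
        post.pi_exceed = np.ones((3, 3))
        assert blrm_next_dose(post, st, DesignConfig(), pri) is None

    def test_final_selection_requires_six_patients(self):
        pri = BLRMPriors()
        st = make_state()
        st.treat((0, 0), 21, 4)
        post = blrm_fit(st, pri, 500, np.random.default_rng(0), burn_in=200)
        assert blrm_select_final(post, st, DesignConfig()) == (0, 0)
        st2 = make_state()
        st2.treat((0, 0), 5, 1)
        post2 = blrm_fit(st2, pri, 500, np.random.default_rng(0), burn_in=200)
        assert blrm_select_final(post2, st2, DesignConfig()) is None
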