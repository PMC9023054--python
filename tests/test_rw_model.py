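"""Delta-rule updates, the response rule, and the session likelihood."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualsource import (RWParams, TrialSequence, advice_weighted_value,
                        choice_probability, combine_values,
                        negative_log_likelihood, run_model, update_value)
from dualsource.rw_model import replace_choices

probs = st.floats(0.01, 0.99)


class TestElementaryOperations:
    @pytest.mark.parametrize("v,r,alpha,expected", [
        (0.5, 1, 0.5, 0.75),
        (0.2, 0, 0.1, 0.18),
        (0.3, 1, 0.0, 0.3),   # zero learning rate is the identity
        (0.9, 0, 1.0, 0.0),   # full learning rate jumps to the outcome
    ])
    def test_update_value(self, v, r, alpha, expected):
        assert update_value(v, r, alpha) == pytest.approx(expected)

    @pytest.mark.parametrize("advice,v,expected", [
        (0, 0.8, 0.8),   # advice endorses the reference option
        (1, 0.8, 0.2),
        (0, 0.5, 0.5),   # uninformative belief about advice accuracy
    ])
    def test_advice_weighted_value(self, advice, v, expected):
        assert advice_weighted_value(advice, v) == pytest.approx(expected)

    @pytest.mark.parametrize("vp,vaw,zeta,expected", [
        (0.6, 0.8, 0.0, 0.6),
        (0.6, 0.8, 1.0, 0.8),
        (0.6, 0.8, 0.5, 0.7),
    ])
    def test_combine_values(self, vp, vaw, zeta, expected):
        assert combine_values(vp, vaw, zeta) == pytest.approx(expected)

    @pytest.mark.parametrize("v,beta,expected", [
        (0.5, 7.3, 0.5),
        (0.7, 1.0, 0.7),                   # beta = 1 is the identity map
        (0.8, 2.0, 0.64 / 0.68),
    ])
    def test_choice_probability(self, v, beta, expected):
        assert choice_probability(v, beta) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("call", [
        lambda: update_value(1.5, 1, 0.5),
        lambda: update_value(0.5, 2, 0.5),
        lambda: advice_weighted_value(2, 0.5),
        lambda: combine_values(0.5, 0.5, 1.5),
        lambda: choice_probability(0.5, 0.0),
    ])
    def test_domain_errors(self, call):
        with pytest.raises(ValueError):
            call()

    @given(v=probs, beta=st.floats(0.1, 20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_sigmoid_antisymmetry(self, v, beta):
        assert choice_probability(v, beta) == pytest.approx(
            1 - choice_probability(1 - v, beta), abs=1e-9)

    @given(v=probs, beta=st.floats(0.1, 20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_sigmoid_monotone(self, v, beta):
        assert choice_probability(min(v + 0.005, 0.995), beta) >= \
            choice_probability(v, beta)


def tiny_sequence():
    """Five hand-checkable trials, one per combination of interest."""
    return TrialSequence(
        r=[1, 1, 0, 1, 0],
        advice=[0, 1, 0, 0, 1],
        phase_primary=np.array(["stable", "stable", "volatile", "volatile",
                                "stable"]),
        phase_secondary=np.array(["volatile", "stable", "stable", "volatile",
                                  "stable"]),
        y=[1, 1, 0, 1, 1],
    )


class TestRunModel:
    def test_hand_rolled_five_trial_trajectory(self):
        """Step-by-step application of the three model equations."""
        params = RWParams(alpha_primary_stable=0.1, alpha_primary_volatile=0.4,
                          alpha_secondary_stable=0.2,
                          alpha_secondary_volatile=0.3, zeta=0.6, beta=2.0)
        tr = tiny_sequence()
        traj = run_model(params, tr)

        vp, vs = 0.5, 0.5
        a_pri = {"stable": 0.1, "volatile": 0.4}
        a_sec = {"stable": 0.2, "volatile": 0.3}
        for t in range(5):
            adv = tr.advice[t]
            c = tr.r[t] ^ adv          # advice correctness inferred from feedback
            vaw = abs(adv - vs)
            comb = 0.6 * vaw + 0.4 * vp
            pch = comb ** 2 / (comb ** 2 + (1 - comb) ** 2)
            assert traj.v_primary[t] == pytest.approx(vp, abs=1e-12)
            assert traj.v_secondary[t] == pytest.approx(vs, abs=1e-12)
            assert traj.v_advice_weighted[t] == pytest.approx(vaw, abs=1e-12)
            assert traj.v_combined[t] == pytest.approx(comb, abs=1e-12)
            assert traj.p_choice[t] == pytest.approx(pch, abs=1e-9)
            assert traj.pe_primary[t] == pytest.approx(tr.r[t] - vp, abs=1e-12)
            vp = vp + a_pri[tr.phase_primary[t]] * (tr.r[t] - vp)
            vs = vs + a_sec[tr.phase_secondary[t]] * (c - vs)

    def test_frozen_beliefs_with_zero_learning_rates(self, default_trials):
        params = RWParams(alpha_primary_stable=0, alpha_primary_volatile=0,
                          alpha_secondary_stable=0, alpha_secondary_volatile=0)
        traj = run_model(params, default_trials)
        assert np.all(traj.v_primary == 0.5)
        assert np.all(traj.v_secondary == 0.5)
        assert np.all(traj.v_advice_weighted == 0.5)
        assert np.all(traj.p_choice == 0.5)

    def test_unused_phase_alphas_are_inert(self):
        tr = tiny_sequence()
        tr.phase_primary = np.array(["stable"] * 5)
        tr.phase_secondary = np.array(["stable"] * 5)
        a = run_model(RWParams(alpha_primary_stable=0.2,
                               alpha_primary_volatile=0.9,
                               alpha_secondary_stable=0.3,
                               alpha_secondary_volatile=0.9), tr)
        b = run_model(RWParams(alpha_primary_stable=0.2,
                               alpha_primary_volatile=0.2,
                               alpha_secondary_stable=0.3,
                               alpha_secondary_volatile=0.3), tr)
        assert np.allclose(a.p_choice, b.p_choice, atol=0)

    @given(aps=probs, apv=probs, ass=probs, asv=probs, zeta=probs,
           beta=st.floats(0.1, 30))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_trajectory_probabilities_stay_in_bounds(
            self, default_trials, aps, apv, ass, asv, zeta, beta):
        params = RWParams(alpha_primary_stable=aps, alpha_primary_volatile=apv,
                          alpha_secondary_stable=ass,
                          alpha_secondary_volatile=asv, zeta=zeta, beta=beta)
        traj = run_model(params, default_trials)
        for arr in (traj.v_primary, traj.v_secondary, traj.v_combined,
                    traj.p_choice):
            assert np.all(arr > 0) and np.all(arr < 1)
        assert np.all(np.abs(traj.pe_primary) < 1)


class TestLikelihood:
    def test_closed_form_at_chance(self):
        n = 120
        tr = TrialSequence(
            r=np.zeros(n, dtype=int), advice=np.zeros(n, dtype=int),
            phase_primary=np.array(["stable"] * n),
            phase_secondary=np.array(["stable"] * n),
            y=np.ones(n))
        params = RWParams(alpha_primary_stable=0, alpha_primary_volatile=0,
                          alpha_secondary_stable=0, alpha_secondary_volatile=0)
        assert negative_log_likelihood(params, tr) == pytest.approx(
            n * math.log(2), rel=1e-12)

    def test_matches_per_trial_sum_from_run_model(self, agent_trials):
        params, tr = agent_trials
        traj = run_model(params, tr)
        y = tr.y
        expected = -np.sum(y * np.log(traj.p_choice)
                           + (1 - y) * np.log(1 - traj.p_choice))
        assert negative_log_likelihood(params, tr) == pytest.approx(
            expected, rel=1e-9)

    def test_greedy_self_consistent_choices_at_high_beta(self, default_trials):
        params = RWParams(alpha_primary_stable=0.2, alpha_primary_volatile=0.2,
                          alpha_secondary_stable=0.2,
                          alpha_secondary_volatile=0.2, zeta=0.4, beta=1e5)
        traj = run_model(params, default_trials)
        tr = replace_choices(default_trials, (traj.v_combined > 0.5).astype(float))
        # choices follow the model's own beliefs; only the first trial (an
        # exact tie at 0.5) contributes its ln 2 to the likelihood
        assert negative_log_likelihood(params, tr) < math.log(2) + 0.05

    def test_relabelling_symmetry(self, agent_trials):
        params, tr = agent_trials
        flipped = TrialSequence(
            r=1 - tr.r, advice=1 - tr.advice,
            phase_primary=tr.phase_primary, phase_secondary=tr.phase_secondary,
            y=1 - tr.y)
        assert negative_log_likelihood(params, flipped) == pytest.approx(
            negative_log_likelihood(params, tr), rel=1e-9)

    def test_missing_choices_skipped_but_updated(self, agent_trials):
        params, tr = agent_trials
        y = tr.y.copy()
        y[10:20] = np.nan
        partial = replace_choices(tr, y)
        traj = run_model(params, tr)
        mask = ~np.isnan(y)
        expected = -np.sum(y[mask] * np.log(traj.p_choice[mask])
                           + (1 - y[mask]) * np.log(1 - traj.p_choice[mask]))
        assert negative_log_likelihood(params, partial) == pytest.approx(
            expected, rel=1e-9)

    def test_all_missing_rejected(self, default_trials):
        with pytest.raises(ValueError):
            negative_log_likelihood(RWParams(), default_trials)

    def test_single_alpha_reduction(self, default_trials):
        """With both split flags off the model is a plain one-alpha learner."""
        full = RWParams(alpha_primary_stable=0.25, alpha_primary_volatile=0.25,
                        alpha_secondary_stable=0.25,
                        alpha_secondary_volatile=0.25, zeta=0.4, beta=3.0)
        reduced = RWParams(alpha_primary_stable=0.25, alpha_primary_volatile=0.25,
                           alpha_secondary_stable=0.25,
                           alpha_secondary_volatile=0.25, zeta=0.4, beta=3.0,
                           split_alpha_by_source=False,
                           split_alpha_by_volatility=False)
        a = run_model(full, default_trials)
        b = run_model(reduced, default_trials)
        assert np.array_equal(a.p_choice, b.p_choice)
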