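import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from relieflearn.models import (HMMAgent, ModelNumericalError, compile_subject,
                                hmm_choice_and_entropy, hmm_step,
                                hybrid_action_step, hybrid_state_step,
                                make_agent, run_model, rw_step, softmax_policy,
                                td_step, wsls_policy)
from oracles import hmm_forward_enumeration


class TestSoftmax:
    @pytest.mark.parametrize("values,tau,expected", [
        ((0.0, 0.0), 5.0, (0.5, 0.5)),
        ((1.0, -3.0), 0.0, (0.5, 0.5)),
        ((1.0, 0.0), 1.0, (math.e / (math.e + 1), 1 / (math.e + 1))),
    ])
    def test_known_values(self, values, tau, expected):
        np.testing.assert_allclose(softmax_policy(values, tau), expected,
                                   atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            softmax_policy([], 1.0)

    @given(st.lists(st.floats(-20, 20), min_size=1, max_size=5),
           st.floats(0, 10), st.floats(-5, 5))
    def test_sums_to_one_and_shift_invariant(self, values, tau, shift):
        p = softmax_policy(values, tau)
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p > 0)
        p2 = softmax_policy([v + shift for v in values], tau)
        np.testing.assert_allclose(p, p2, atol=1e-9)


class TestValueUpdates:
    def test_td_step(self):
        Q = np.zeros((2, 2))
        Q1, d = td_step(Q, (0, 1), 1, 0.5)
        assert d == 1.0 and Q1[0, 1] == 0.5
        assert Q1[0, 0] == 0 and Q1[1, 0] == 0  # untouched entries
        Q2, _ = td_step(Q1, (0, 1), 0, 0.0)
        np.testing.assert_array_equal(Q2, Q1)  # no learning at alpha = 0

    def test_td_step_group_mean_learning_rate(self):
        # one update from zero with the static-paradigm group-mean rate
        Q1, _ = td_step(np.zeros((1, 1)), (0, 0), 1, 0.401)
        assert Q1[0, 0] == pytest.approx(0.401)

    def test_rw_step(self):
        V1, d = rw_step(np.array([0.5]), 0, 0, 0.5)
        assert d == -0.5 and V1[0] == 0.25
        V2, d2 = rw_step(np.array([1.0]), 0, 1, 0.9)
        assert d2 == 0.0 and V2[0] == 1.0

    def test_rw_tracks_bernoulli_rate(self):
        rng = np.random.default_rng(0)
        V = np.array([0.0])
        vals = []
        for r in (rng.random(4000) < 0.7).astype(int):
            V, _ = rw_step(V, 0, int(r), 0.1)
            vals.append(V[0])
        assert abs(np.mean(vals[500:]) - 0.7) < 0.05

    def test_hybrid_state_step(self):
        V, A, d = hybrid_state_step(np.array([0.0]), np.array([1.0]), 0, 1,
                                    0.5, 0.5)
        assert d == 1.0 and V[0] == 0.5 and A[0] == 1.0
        # eta = 1: associability jumps to |delta|
        _, A1, _ = hybrid_state_step(np.array([0.3]), np.array([0.9]), 0, 0,
                                     0.5, 1.0)
        assert A1[0] == pytest.approx(0.3)
        # eta = 0: associability frozen
        _, A0, _ = hybrid_state_step(np.array([0.3]), np.array([0.9]), 0, 0,
                                     0.5, 0.0)
        assert A0[0] == 0.9

    def test_hybrid_action_step(self):
        Q, A, d = hybrid_action_step(np.full((1, 1), 0.5),
                                     np.full((1, 1), 0.4), (0, 0), 1,
                                     0.5, 0.25)
        assert d == 0.5
        assert Q[0, 0] == pytest.approx(0.6)
        assert A[0, 0] == pytest.approx(0.425)

    def test_hybrid_reduces_to_rw_when_eta_zero(self):
        # with eta = 0 and alpha0 = 1, kappa plays the role of the RW rate
        rng = np.random.default_rng(3)
        outcomes = (rng.random(100) < 0.6).astype(int)
        V_rw = np.array([0.0])
        V_h, A_h = np.array([0.0]), np.array([1.0])
        for r in outcomes:
            V_rw, _ = rw_step(V_rw, 0, int(r), 0.35)
            V_h, A_h, _ = hybrid_state_step(V_h, A_h, 0, int(r), 0.35, 0.0)
            assert V_h[0] == pytest.approx(V_rw[0], abs=1e-12)

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=60),
           st.floats(0, 1), st.floats(0, 1))
    def test_associability_bounded(self, outcomes, kappa, eta):
        V, A = np.array([0.0]), np.array([1.0])
        for r in outcomes:
            V, A, _ = hybrid_state_step(V, A, 0, r, kappa, eta)
            assert -1e-12 <= A[0] <= 1.0 + 1e-12


class TestWSLS:
    def test_win_stay(self):
        p = wsls_policy((0, 1), 1.0)
        assert p[0] == pytest.approx(math.e / (math.e + math.exp(-1)), abs=1e-4)

    def test_zero_scaling_uniform(self):
        np.testing.assert_allclose(wsls_policy((0, 1), 0.0), [0.5, 0.5])

    def test_lose_shift(self):
        p = wsls_policy((0, 0), 0.7)
        assert p[1] > p[0]

    def test_first_encounter_uniform(self):
        np.testing.assert_allclose(wsls_policy(None, 0.9), [0.5, 0.5])


class TestHMM:
    def test_identity_transition(self):
        assert hmm_step(0.73, None, 0.0, 0.5, 0.5) == pytest.approx(0.73)

    def test_maximal_mixing(self):
        assert hmm_step(0.9, None, 0.5, 0.5, 0.5) == pytest.approx(0.5)

    def test_uninformative_likelihood(self):
        prior = hmm_step(0.6, None, 0.2, 0.0, 0.0)
        post = hmm_step(0.6, 1, 0.2, 0.0, 0.0)
        assert post == pytest.approx(prior)

    def test_degenerate_normalisation_flagged(self):
        # belief pinned at the relief state, then an impossible no-relief
        # outcome under d = 1 zeroes the posterior
        with pytest.raises(ModelNumericalError):
            hmm_step(1.0, 0, 0.0, 0.5, 1.0)

    def test_filter_matches_enumeration_on_all_length6_sequences(self):
        import itertools
        beta, c, d = 0.1, 0.6, 0.1
        for seq in itertools.product((0, 1), repeat=6):
            agent = HMMAgent(beta, c, d, 0.0, n_cues=1)
            for r in seq:
                agent.update(0, 0, r)
            oracle = hmm_forward_enumeration(list(seq), beta, c, d)
            assert agent.q[0] == pytest.approx(oracle, abs=1e-10)

    def test_choice_and_entropy(self):
        p_relief, probs, H = hmm_choice_and_entropy([0.5, 0.5, 0.5], 0.0, 2.0)
        np.testing.assert_allclose(p_relief, 0.5)
        np.testing.assert_allclose(probs, 1 / 3)
        np.testing.assert_allclose(H, math.log(2), atol=1e-12)
        p_relief, _, H = hmm_choice_and_entropy([1.0], 0.0, 1.0)
        assert p_relief[0] == pytest.approx(1 / (1 + math.exp(-1)), abs=1e-4)
        assert H[0] == 0.0
        p_relief, _, _ = hmm_choice_and_entropy([0.1, 0.9], 50.0, 1.0)
        assert np.all(p_relief > 0.999)  # large shift dominates


class TestHGF:
    def _run(self, outcomes, kappa=0.5, omega=-2.0, theta=0.2):
        agent = make_agent("hgf", {"kappa": kappa, "omega": omega,
                                   "theta": theta}, "exp2")
        preds = []
        for r in outcomes:
            preds.append(agent.action_values(0)[0])
            agent.update(0, 0, r)
        return np.array(preds)

    def test_volatility_off_limit_changes_slowly(self):
        rng = np.random.default_rng(1)
        outcomes = (rng.random(60) < 0.5).astype(int)
        slow = self._run(outcomes, omega=-8.0, theta=1e-4)
        fast = self._run(outcomes, omega=-1.0, theta=0.3)
        # after burn-in of the initial estimation uncertainty
        assert np.abs(np.diff(slow[10:])).max() < np.abs(np.diff(fast[10:])).max()
        assert np.abs(np.diff(slow[10:])).max() < 0.05

    def test_constant_relief_belief_increases(self):
        preds = self._run([1] * 40)
        assert np.all(np.diff(preds[5:]) >= -1e-12)
        assert preds[-1] > 0.8

    def test_prior_mean_convention(self):
        # latent prior means (kappa, omega, theta) = (0, -2, 0)
        from relieflearn.fitting import default_choice_priors
        pr = default_choice_priors("hgf", 1)
        mus = {p.name: p.mu0 for p in pr.params}
        assert (mus["kappa"], mus["omega"], mus["theta"]) == (0.0, -2.0, 0.0)


class TestRunModel:
    def test_uniform_at_initialisation(self, exp1_cohort):
        trials = [t for t in exp1_cohort.trials["s01"]
                  if t.paradigm == "exp1_instrumental"][:1]
        traj = run_model("td", {"alpha": 0.3}, trials, taus=[2.0])
        assert traj.variables["choice_prob"][0] == pytest.approx(0.5)

    @pytest.mark.parametrize("model,params", [
        ("td", {"alpha": 0.4}),
        ("hybrid_action", {"kappa": 0.5, "eta": 0.3}),
        ("rw", {"alpha": 0.4}),
        ("hybrid_state", {"kappa": 0.5, "eta": 0.3}),
        ("wsls", {"p1": 0.4, "p2": 0.6}),
    ])
    def test_trajectory_aligned_with_trials(self, exp1_cohort, model, params):
        trials = exp1_cohort.trials["s01"]
        traj = run_model(model, params, trials)
        assert len(traj) == len(trials)
        for arr in traj.variables.values():
            assert len(arr) == len(trials)

    def test_yoked_state_trajectories_identical(self, exp1_cohort):
        trials = exp1_cohort.trials["s01"]
        ins = [t for t in trials if t.paradigm == "exp1_instrumental"]
        pav = [t for t in trials if t.paradigm == "exp1_pavlovian"]
        params = {"kappa": 0.5, "eta": 0.5}
        ti = run_model("hybrid_state", params, ins)
        tp = run_model("hybrid_state", params, pav)
        np.testing.assert_allclose(ti.variables["value_pre"],
                                   tp.variables["value_pre"], atol=1e-14)
        np.testing.assert_allclose(ti.variables["assoc_pre"],
                                   tp.variables["assoc_pre"], atol=1e-14)

    def test_pavlovian_contributes_no_choice_likelihood(self, exp1_cohort):
        trials = [t for t in exp1_cohort.trials["s01"]
                  if t.paradigm == "exp1_pavlovian"]
        traj = run_model("td", {"alpha": 0.4}, trials, taus=[1.0] * 3)
        assert traj.loglik == 0.0
        assert np.all(np.isnan(traj.variables["loglik"]))

    def test_exp2_models_reject_exp1(self, exp1_cohort):
        with pytest.raises(ValueError):
            run_model("hmm", {"beta": 0.2, "c": 0.5, "d": 0.1},
                      exp1_cohort.trials["s01"])

    def test_unknown_model_rejected(self, exp1_cohort):
        with pytest.raises(ValueError):
            run_model("nope", {}, exp1_cohort.trials["s01"])

    def test_softmax_rows_normalised_every_trial(self, exp2_cohort):
        trials = exp2_cohort.trials["s01"]
        for model, params in [("td", {"alpha": 0.5}),
                              ("hmm", {"beta": 0.2, "c": 0.5, "d": 0.1}),
                              ("hgf", {"kappa": 0.4, "omega": -2.0,
                                       "theta": 0.3})]:
            sd = compile_subject(trials)
            agent = make_agent(model, params, "exp2")
            for sess in sd.sessions:
                agent.reset()
                for s, opt, r in zip(sess.state_idx, sess.opt_idx, sess.r):
                    p = softmax_policy(agent.action_values(s), 2.0)
                    assert abs(p.sum() - 1.0) < 1e-12
                    agent.update(s, opt, r)

    def test_greedy_limit_prefers_learned_action(self):
        # after convergence on a static 0.8/0.2 cue, a near-greedy policy
        # picks the high-relief action essentially always
        agent = make_agent("td", {"alpha": 0.2}, "exp1")
        for _ in range(50):
            agent.update(0, 0, 1)  # left rewarded
            agent.update(0, 1, 0)  # right not
        p = softmax_policy(agent.action_values(0), 1000.0)
        assert p[0] > 0.999
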