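import math

import numpy as np
import pytest
from scipy import stats

from relieflearn.fitting import (ParamPrior, PriorSpec, choice_nll,
                                 default_choice_priors, fit_choice_model,
                                 fit_map, fit_scr, inverse_transform,
                                 laplace_evidence, preprocess_scr, transform)
from relieflearn.models import compile_subject
from relieflearn.task import TrialRecord
from oracles import gaussian_conjugate_log_marginal


class TestTransforms:
    @pytest.mark.parametrize("kind,latent,native", [
        ("sigmoid", 0.0, 0.5),
        ("exp", 0.0, 1.0),
        ("identity", -1.7, -1.7),
    ])
    def test_fixed_points(self, kind, latent, native):
        assert transform(latent, kind) == pytest.approx(native)

    @pytest.mark.parametrize("kind", ["sigmoid", "exp", "identity"])
    def test_round_trip(self, kind):
        for x in np.linspace(-5, 5, 21):
            assert inverse_transform(transform(x, kind), kind) == \
                pytest.approx(x, abs=1e-12)

    def test_inverse_domain_errors(self):
        with pytest.raises(ValueError):
            inverse_transform(1.2, "sigmoid")
        with pytest.raises(ValueError):
            inverse_transform(-0.1, "exp")

    def test_tight_prior_concentrates_near_half(self):
        # latent N(0, 0.05^2) through the sigmoid puts 95% of prior mass
        # within about (0.476, 0.524) — why SCR-fit parameters cluster at 0.5
        lo = transform(stats.norm.ppf(0.025, 0, 0.05), "sigmoid")
        hi = transform(stats.norm.ppf(0.975, 0, 0.05), "sigmoid")
        assert lo == pytest.approx(0.476, abs=0.002)
        assert hi == pytest.approx(0.524, abs=0.002)


class TestChoiceNLL:
    def test_uniform_choice_term(self, exp1_cohort):
        # WSLS with p1 = p2 = 0 is uniform on every trial, so the choice
        # term is n ln 2 on the instrumental trials
        trials = [t for t in exp1_cohort.trials["s01"]
                  if t.paradigm == "exp1_instrumental"]
        sd = compile_subject(trials)
        priors = default_choice_priors("wsls", len(sd.sessions))
        x = np.array([inverse_transform(1e-12, "sigmoid")] * 2)
        nll = choice_nll("wsls", x, sd, priors)
        choice_term = nll - priors.neg_log_prior(x)
        assert choice_term == pytest.approx(len(trials) * math.log(2), rel=1e-6)

    def test_likelihood_dominates_near_truth(self, exp2_cohort):
        # the nll at the generating learning rate is lower than with the
        # rate perturbed by +-0.3 (averaged over subjects)
        diffs = []
        for sid in exp2_cohort.subjects:
            gt = exp2_cohort.truths[sid]
            sd = compile_subject(exp2_cohort.trials[sid])
            priors = default_choice_priors("td", len(sd.sessions))
            tau_lat = [math.log(gt.params["tau"])] * len(sd.sessions)
            def nll_at(alpha):
                x = np.array([inverse_transform(np.clip(alpha, 0.02, 0.98),
                                                "sigmoid")] + tau_lat)
                return choice_nll("td", x, sd, priors)
            a = gt.params["alpha"]
            diffs.append(min(nll_at(a + 0.3), nll_at(a - 0.3)) - nll_at(a))
        assert np.mean(diffs) > 0


class TestFitMap:
    def test_quadratic_mode_recovered(self):
        priors = PriorSpec([ParamPrior("a", 0.0, 10.0, "identity"),
                            ParamPrior("b", 0.0, 10.0, "identity")], 2)
        target = np.array([0.7, -1.2])
        res = fit_map(lambda x: float(np.sum((x - target) ** 2)), priors,
                      n_starts=3, seed=0, tol=1e-8)
        np.testing.assert_allclose(res.mode, target, atol=1e-4)

    def test_prior_dominance_at_tiny_variance(self, exp2_cohort):
        sd = compile_subject(exp2_cohort.trials["s01"])
        fr = fit_choice_model("td", sd, n_starts=2, seed=0,
                              priors=default_choice_priors(
                                  "td", len(sd.sessions),
                                  sigma_evolution=1e-5))
        assert fr.native["alpha"] == pytest.approx(0.5, abs=1e-3)

    def test_deterministic_given_seed(self, exp2_cohort):
        sd = compile_subject(exp2_cohort.trials["s02"])
        f1 = fit_choice_model("td", sd, n_starts=2, seed=5, tol=1e-4)
        f2 = fit_choice_model("td", sd, n_starts=2, seed=5, tol=1e-4)
        np.testing.assert_array_equal(f1.latent_mode, f2.latent_mode)
        assert f1.free_energy == f2.free_energy


class TestLaplaceEvidence:
    def _nll(self, y, sigma, mu0, sigma0):
        def f(x):
            th = float(np.asarray(x).ravel()[0])
            return (float(np.sum(0.5 * ((y - th) / sigma) ** 2
                                 + 0.5 * math.log(2 * math.pi * sigma**2)))
                    + 0.5 * ((th - mu0) / sigma0) ** 2
                    + 0.5 * math.log(2 * math.pi * sigma0**2))
        return f

    def test_matches_conjugate_closed_form(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0.3, 0.8, size=12)
        f = self._nll(y, 0.8, 0.1, 1.5)
        # analytic posterior mode of the Gaussian-Gaussian model
        prec = 12 / 0.8**2 + 1 / 1.5**2
        mode = (y.sum() / 0.8**2 + 0.1 / 1.5**2) / prec
        F = laplace_evidence(f, np.array([mode]))
        exact = gaussian_conjugate_log_marginal(y, 0.8, 0.1, 1.5)
        assert F == pytest.approx(exact, abs=1e-6)

    def test_occam_penalty_for_flat_parameter(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0.0, 1.0, size=10)
        f1 = self._nll(y, 1.0, 0.0, 1.0)
        # add a second parameter the likelihood ignores (prior only)
        def f2(x):
            return f1(x[:1]) + 0.5 * x[1] ** 2 + 0.5 * math.log(2 * math.pi)
        mode = np.array([y.sum() / (10 + 1)])
        F1 = laplace_evidence(f1, mode)
        F2 = laplace_evidence(f2, np.array([mode[0], 0.0]))
        assert F2 < F1

    def test_duplicated_data_doubles_data_term(self):
        y = np.array([0.4, -0.2, 0.9])
        f1 = self._nll(y, 1.0, 0.0, 1.0)
        f2 = self._nll(np.concatenate([y, y]), 1.0, 0.0, 1.0)
        x = np.array([0.1])
        prior = 0.5 * x[0] ** 2 + 0.5 * math.log(2 * math.pi)
        assert f2(x) - prior == pytest.approx(2 * (f1(x) - prior), rel=1e-12)


def _scr_trials(amps, paradigm="exp1_instrumental", session=1):
    out = []
    for i, a in enumerate(amps):
        out.append(TrialRecord(
            subject="x", paradigm=paradigm, session=session, trial=i + 1,
            cues_shown=("easy",), chosen="left", outcome=int(i % 2 == 0),
            scr_left=a))
    return out


class TestPreprocessSCR:
    def test_quarter_bad_session_excluded(self):
        amps = [0.01] * 5 + [0.5] * 15  # 25% below threshold
        scr = preprocess_scr(_scr_trials(amps))
        assert not scr.usable["left"].any()
        assert scr.report

    def test_exp2_boundary_fractions(self):
        # 5/24 ~ 20.8% excluded; 4/24 ~ 16.7% kept
        bad5 = _scr_trials([0.01] * 5 + [0.5] * 19)
        bad4 = _scr_trials([0.01] * 4 + [0.5] * 20)
        assert not preprocess_scr(bad5).usable["left"].any()
        assert preprocess_scr(bad4).usable["left"].any()

    def test_clean_session_keeps_all_but_first_two(self):
        amps = [0.5] * 20
        scr = preprocess_scr(_scr_trials(amps))
        assert scr.usable["left"].sum() == 18  # startle exclusion only
        np.testing.assert_allclose(scr.y["left"], math.log(0.5))

    def test_log_transform(self):
        scr = preprocess_scr(_scr_trials([1.0, math.e, math.e**2] + [0.5] * 17))
        np.testing.assert_allclose(scr.y["left"][:3], [0.0, 1.0, 2.0])


class TestFitSCR:
    def test_noiseless_offset_recovered(self, exp1_cohort):
        from relieflearn.models import run_model
        from relieflearn.simulate import fill_scr, simulate_scr
        trials = [t for t in exp1_cohort.trials["s01"]]
        traj = run_model("hybrid_state", {"kappa": 0.5, "eta": 0.5}, trials)
        amps = simulate_scr(traj, "associability", 0.2, 0.0, seed=0)
        fill_scr(trials, amps)
        fr = fit_scr("hybrid_assoc", trials, n_starts=2, seed=0)
        for bs in fr.extras["b"]["left"]:
            assert bs == pytest.approx(0.2, abs=0.02)
        assert fr.extras["sigma2"]["left"] < 1e-3

    def test_evidence_ranking_shift_invariant(self, exp2_cohort):
        # adding a constant to all log amplitudes is absorbed by b and
        # leaves the model ranking unchanged
        import copy
        sid = exp2_cohort.subjects[0]
        trials = copy.deepcopy(exp2_cohort.trials[sid])
        models = ["rw_value", "hybrid_assoc"]
        def ranking(tr):
            Fs = {m: fit_scr(m, tr, sources=("left", "right"),
                             exclusion_source="right", n_starts=2,
                             seed=0).free_energy for m in models}
            return sorted(Fs, key=Fs.get)
        base = ranking(trials)
        for t in trials:
            t.scr_left *= math.e  # +1 on the log scale
            t.scr_right *= math.e
        assert ranking(trials) == base

    def test_too_few_trials_rejected(self):
        trials = _scr_trials([0.5] * 5)
        with pytest.raises(ValueError):
            fit_scr("rw_value", trials)
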