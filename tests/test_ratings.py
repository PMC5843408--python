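import math

import numpy as np
import pytest

from relieflearn.models import run_model
from relieflearn.ratings import (axiomatic_bins, build_rating_design,
                                 fit_rating_regression, relief_logtrial,
                                 subject_correlation_stats)
from relieflearn.task import TrialRecord


def _trials(outcomes, ratings=None, paradigm="exp2", session=1):
    out = []
    for i, r in enumerate(outcomes):
        rec = TrialRecord(subject="x", paradigm=paradigm, session=session,
                          trial=i + 1, cues_shown=("A", "B", "C"), chosen="A",
                          outcome=int(r))
        if ratings is not None and ratings[i] is not None:
            rec.rating = ratings[i]
            rec.rating_type = "pain"
        out.append(rec)
    return out


class TestReliefLogTrial:
    def test_counter_resets_at_relief(self):
        trials = _trials([0, 1, 0, 0, 1, 0])
        relief, logtrial = relief_logtrial(trials)
        # trial immediately after a relief outcome -> Relief = 1
        np.testing.assert_array_equal(relief, [1, 2, 1, 2, 3, 1])
        assert logtrial[0] == 0.0
        assert logtrial[3] == pytest.approx(math.log(4))

    def test_counter_resets_at_session_start(self):
        trials = _trials([1, 0], session=1) + _trials([0, 0], session=2)
        relief, _ = relief_logtrial(trials)
        np.testing.assert_array_equal(relief, [1, 1, 1, 2])


class TestBuildDesign:
    def test_rows_only_for_rated_trials(self):
        trials = _trials([0, 1, 0, 0], ratings=[None, None, 5.0, 6.0])
        d = build_rating_design(trials, None, "none")
        assert d.X.shape == (2, 2)
        np.testing.assert_array_equal(d.y, [5.0, 6.0])

    def test_surprise_uses_previous_trial_pe(self):
        trials = _trials([1, 0, 0, 0], ratings=[None, 4.0, None, None])
        traj = run_model("td", {"alpha": 0.5}, trials)
        d = build_rating_design(trials, traj, "surprise")
        # at trial 2, |delta_1| = |1 - 0| = 1
        assert d.X[0, 2] == pytest.approx(1.0)

    def test_row_order_invariance(self):
        trials = _trials([0, 1, 0, 1, 0, 0],
                         ratings=[None, 3.0, None, 4.0, 5.0, None])
        traj = run_model("hybrid_state", {"kappa": 0.5, "eta": 0.5}, trials)
        d1 = build_rating_design(trials, traj, "associability")
        shuffled = [trials[i] for i in (3, 0, 5, 2, 4, 1)]
        d2 = build_rating_design(shuffled, traj, "associability")
        np.testing.assert_array_equal(d1.X, d2.X)
        np.testing.assert_array_equal(d1.y, d2.y)

    def test_missing_stream_rejected(self):
        trials = _trials([0, 1, 0, 0], ratings=[1.0, 2.0, 3.0, 4.0])
        traj = run_model("rw", {"alpha": 0.4}, trials)  # no associability
        with pytest.raises(ValueError):
            build_rating_design(trials, traj, "associability")


class TestRegression:
    def test_exact_relief_coefficient(self):
        trials = _trials([0, 1, 0, 0, 1, 0, 0, 0])
        relief, _ = relief_logtrial(trials)
        for i, t in enumerate(trials):
            t.rating = min(2.0 * relief[i], 10.0)
            t.rating_type = "pain"
        d = build_rating_design(trials, None, "none")
        fit = fit_rating_regression(d)
        assert fit.coef[0] == pytest.approx(2.0, abs=1e-10)
        assert fit.sigma2 < 1e-20

    def test_too_few_rows_rejected(self):
        trials = _trials([0, 1, 0], ratings=[1.0, 2.0, None])
        d = build_rating_design(trials, None, "none")
        with pytest.raises(ValueError):
            fit_rating_regression(d)

    def test_rank_deficient_design_flagged(self):
        trials = _trials([0] * 6, ratings=[1, 2, 3, 4, 5, 6.0])
        d = build_rating_design(trials, None, "none")
        d.X[:, 1] = d.X[:, 0]  # duplicate column
        with pytest.raises(ValueError):
            fit_rating_regression(d)


class TestExclusionRule:
    def test_subject_with_95pc_identical_ratings_excluded(self):
        from relieflearn.ratings import compare_rating_models
        rng = np.random.default_rng(0)
        designs = {"a": {}, "none": {}}
        for s in range(4):
            n = 20
            outcomes = (rng.random(n) < 0.4).astype(int)
            if s == 0:  # 19/20 identical ratings
                ratings = [7.0] * 19 + [5.0]
            else:
                ratings = list(rng.uniform(3, 9, n))
            trials = _trials(outcomes, ratings=ratings)
            traj = run_model("hybrid_state", {"kappa": 0.5, "eta": 0.5},
                             trials)
            designs["a"][f"s{s}"] = build_rating_design(trials, traj,
                                                        "associability")
            designs["none"][f"s{s}"] = build_rating_design(trials, None,
                                                           "none")
        res, table, excluded = compare_rating_models(designs, seed=0,
                                                     n_samples=10_000)
        assert any(e["subject"] == "s0" for e in excluded)
        assert set(table.subject) == {"s1", "s2", "s3"}


class TestCorrelationStats:
    def test_perfect_anticorrelation_guarded(self):
        pairs = {f"s{i}": ([1, 2, 3, 4], [4, 3, 2, 1]) for i in range(5)}
        rep = subject_correlation_stats(pairs)
        assert rep["mean_rho"] == pytest.approx(-1.0)
        assert rep["statistic"] < 0
        assert rep["p"] < 1e-6

    def test_zero_variance_subject_excluded(self):
        pairs = {"s1": ([1, 1, 1], [1, 2, 3]),
                 "s2": ([1, 2, 3], [2, 1, 3]),
                 "s3": ([3, 1, 2], [1, 3, 2])}
        rep = subject_correlation_stats(pairs)
        assert rep["n"] == 2
        assert rep["excluded"][0]["subject"] == "s1"

    def test_paired_t_zero_for_identical_conditions(self):
        pairs = {f"s{i}": ([4.0 + i], [4.0 + i]) for i in range(6)}
        rep = subject_correlation_stats(pairs, test="paired_t")
        assert rep["statistic"] == pytest.approx(0.0)

    def test_group_test_detects_negative_correlation(self):
        # power check at a modest true within-subject rank correlation
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            pairs = {}
            for s in range(19):
                x = rng.normal(size=8)
                y = -0.35 * x + rng.normal(scale=math.sqrt(1 - 0.35**2),
                                           size=8)
                pairs[f"s{s}"] = (x, y)
            rep = subject_correlation_stats(pairs)
            hits += (rep["p"] < 0.05 and rep["mean_rho"] < 0)
        assert hits / n_rep >= 0.6


class TestAxiomaticBins:
    def _setup(self, n):
        rng = np.random.default_rng(1)
        outcomes = [0] * n + [1] * n
        trials = _trials(outcomes)
        traj = run_model("td", {"alpha": 0.5}, trials)
        return trials, traj

    def test_median_split_equal_bins(self):
        trials, traj = self._setup(10)
        labels = axiomatic_bins(trials, traj, n_bins=2)
        counts = labels.groupby(["outcome", "bin"]).size()
        assert set(counts) == {5}

    def test_three_bins_of_three(self):
        trials, traj = self._setup(9)
        labels = axiomatic_bins(trials, traj, n_bins=3)
        counts = labels.groupby(["outcome", "bin"]).size()
        assert set(counts) == {3}

    def test_labels_partition_trials(self):
        trials, traj = self._setup(10)
        labels = axiomatic_bins(trials, traj, n_bins=2)
        assert len(labels) == len(trials)
        assert labels.groupby(["session", "trial"]).size().max() == 1

    def test_fewer_trials_than_bins_rejected(self):
        trials = _trials([0, 0, 0, 1])  # one relief trial only
        traj = run_model("td", {"alpha": 0.5}, trials)
        with pytest.raises(ValueError):
            axiomatic_bins(trials, traj, n_bins=3)

    def test_deterministic_tie_break(self):
        trials = _trials([0] * 8)
        traj = run_model("td", {"alpha": 0.0}, trials)  # all values equal
        a = axiomatic_bins(trials, traj, n_bins=2)
        b = axiomatic_bins(trials, traj, n_bins=2)
        assert a.equals(b)
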