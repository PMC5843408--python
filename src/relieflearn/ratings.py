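"""Trial-by-trial pain-rating analysis.

Ratings are modelled per subject with the linear design

    Rating = b1 * Relief + b2 * log(Trial) + b3 * Predictor

where Relief counts trials since the previous relief outcome (since
session start before any relief), log(Trial) is the log of the
within-session trial number, and Predictor is a model-derived
uncertainty stream — Pearce-Hall associability (hybrid state model),
HMM belief entropy, or surprise (|prediction error| from the previous
trial of the TD model); the null model drops the Predictor column.
Predictors are computed over all trials from group-mean parameters,
but only rated trials enter the regression.  Per-subject Gaussian log
likelihoods feed random-effects BMS to compare predictor models.

The static-paradigm analyses correlate pain ratings with uncertainty
streams within subject (Spearman), then test the Fisher-z transformed
coefficients against zero at the group level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import LatentTrajectory
from .simulate import _predictor_stream
from .task import TrialRecord

__all__ = ["RatingDesign", "RegressionFit", "relief_logtrial",
           "build_rating_design", "fit_rating_regression",
           "compare_rating_models", "subject_correlation_stats",
           "axiomatic_bins", "identical_rating_fraction"]


def relief_logtrial(ordered_trials: Sequence[TrialRecord]):
    """Relief counter and log within-session trial number for every trial.

    Relief_t counts trials since the last relief outcome strictly before
    trial t (resets at relief outcomes and at session starts: before any
    relief the counter equals the trial number).  logTrial = ln(trial),
    0 at trial 1.
    """
    n = len(ordered_trials)
    relief = np.empty(n)
    logtrial = np.empty(n)
    last_relief = 0
    prev_key = None
    for i, rec in enumerate(ordered_trials):
        key = (rec.paradigm, rec.session)
        if key != prev_key:
            last_relief = 0
            prev_key = key
        relief[i] = rec.trial - last_relief
        logtrial[i] = math.log(rec.trial)
        if rec.outcome == 1:
            last_relief = rec.trial
    return relief, logtrial


@dataclass
class RatingDesign:
    """Design rows for one subject's rated trials."""

    subject: str
    predictor: str
    X: np.ndarray  # columns: Relief, logTrial[, Predictor]
    y: np.ndarray
    columns: list
    trial_index: list


@dataclass
class RegressionFit:
    subject: str
    predictor: str
    coef: np.ndarray
    columns: list
    sigma2: float
    loglik: float
    n: int


def build_rating_design(trials: Sequence[TrialRecord],
                        trajectory: Optional[LatentTrajectory],
                        predictor: str, subject: str = "?",
                        intercept: bool = False,
                        rating_type: Optional[str] = "pain") -> RatingDesign:
    """Assemble the rating regression design for one subject.

    Predictors are computed over *all* trials (the trajectory must align
    with the subject's full trial sequence); rows are emitted only for
    rated trials, optionally restricted to one rating type.
    """
    ordered = sorted(trials, key=lambda t: (t.paradigm, t.session, t.trial))
    relief, logtrial = relief_logtrial(ordered)
    if predictor == "none":
        pred = np.zeros(len(ordered))
    else:
        if trajectory is None:
            raise ValueError(f"predictor {predictor!r} needs a trajectory")
        pred = _predictor_stream(trajectory, predictor)
        if len(pred) != len(ordered):
            raise ValueError("trajectory / trial length mismatch")
    rows, y, idx = [], [], []
    for i, rec in enumerate(ordered):
        if rec.rating is None:
            continue
        if rating_type is not None and rec.rating_type != rating_type:
            continue
        row = [relief[i], logtrial[i]]
        if predictor != "none":
            row.append(pred[i])
        if intercept:
            row.append(1.0)
        rows.append(row)
        y.append(rec.rating)
        idx.append((rec.paradigm, rec.session, rec.trial))
    columns = ["Relief", "logTrial"]
    if predictor != "none":
        columns.append("Predictor")
    if intercept:
        columns.append("Intercept")
    return RatingDesign(subject=subject, predictor=predictor,
                        X=np.asarray(rows, dtype=float),
                        y=np.asarray(y, dtype=float),
                        columns=columns, trial_index=idx)


def fit_rating_regression(design: RatingDesign) -> RegressionFit:
    """Least squares with Gaussian log likelihood at the ML variance."""
    X, y = design.X, design.y
    n, p = X.shape
    if n < max(4, p + 1):
        raise ValueError(f"too few rated trials (n={n}) for regression")
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise ValueError(f"rank-deficient rating design for {design.subject}")
    resid = y - X @ coef
    sigma2 = float(np.mean(resid**2))
    if sigma2 <= 0:
        sigma2 = 1e-12
    loglik = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    return RegressionFit(subject=design.subject, predictor=design.predictor,
                         coef=coef, columns=design.columns, sigma2=sigma2,
                         loglik=float(loglik), n=n)


def identical_rating_fraction(trials: Sequence[TrialRecord]) -> float:
    """Fraction of a subject's ratings equal to their modal value."""
    vals = [t.rating for t in trials if t.rating is not None]
    if not vals:
        return 1.0
    _, counts = np.unique(np.round(vals, 6), return_counts=True)
    return counts.max() / len(vals)


def compare_rating_models(designs: dict, seed: int = 0,
                          n_samples: int = 1_000_000,
                          exclude_identical_above: float = 0.9,
                          evidence: str = "bic"):
    """RFX-BMS over per-subject rating-regression evidences.

    ``designs`` maps predictor name -> {subject: RatingDesign}.  Subjects
    whose fraction of identical ratings exceeds the threshold (default
    90%), or whose design is rank-deficient for any predictor, are
    excluded listwise.  Returns (BMSResult, fits table, exclusion list).

    ``evidence`` selects the per-subject model evidence: ``"bic"``
    (default) penalises the Gaussian log likelihood by (p/2) ln n — the
    standard large-n approximation to the log marginal likelihood, kept
    consistent with the free-energy evidences used elsewhere in the
    pipeline; ``"loglik"`` uses the raw maximum log likelihood, under
    which a nested null design can never attain the highest evidence
    (adding a regressor never lowers the ML fit).
    """
    from .bms import rfx_bms
    predictors = list(designs)
    if len(predictors) < 2:
        raise ValueError("need at least 2 predictor models")
    subjects = set.intersection(*(set(d) for d in designs.values()))
    excluded = []
    fits: dict = {p: {} for p in predictors}
    for s in sorted(subjects):
        d0 = designs[predictors[0]][s]
        frac = _modal_fraction(d0.y)
        if frac > exclude_identical_above:
            excluded.append({"subject": s,
                             "reason": f"{frac:.0%} identical ratings"})
            continue
        try:
            for p in predictors:
                fits[p][s] = fit_rating_regression(designs[p][s])
        except ValueError as e:
            excluded.append({"subject": s, "reason": str(e)})
            for p in predictors:
                fits[p].pop(s, None)
    kept = sorted(set.intersection(*(set(fits[p]) for p in predictors)))
    if len(kept) < 2:
        raise ValueError("fewer than 2 subjects after exclusion")
    if evidence == "bic":
        def ev(f):
            return f.loglik - 0.5 * len(f.columns) * math.log(f.n)
    elif evidence == "loglik":
        def ev(f):
            return f.loglik
    else:
        raise ValueError(f"unknown evidence {evidence!r}")
    lme = pd.DataFrame(
        [[ev(fits[p][s]) for p in predictors] for s in kept],
        index=kept, columns=predictors)
    res = rfx_bms(lme, seed=seed, n_samples=n_samples)
    rows = []
    for p in predictors:
        for s in kept:
            f = fits[p][s]
            rec = {"subject": s, "predictor": p, "loglik": f.loglik, "n": f.n}
            rec.update({c: float(v) for c, v in zip(f.columns, f.coef)})
            rows.append(rec)
    return res, pd.DataFrame(rows), excluded


def _modal_fraction(y: np.ndarray) -> float:
    if y.size == 0:
        return 1.0
    _, counts = np.unique(np.round(y, 6), return_counts=True)
    return counts.max() / y.size


# ---------------------------------------------------------------------------
# group statistics for the static paradigm
# ---------------------------------------------------------------------------

def subject_correlation_stats(pairs: dict, test: str = "spearman_fisher_t",
                              clip: float = 1.0 - 1e-12) -> dict:
    """Group tests over per-subject paired series.

    ``pairs`` maps subject -> (x, y) series.  ``spearman_fisher_t``
    computes per-subject Spearman rho, Fisher-z transforms them
    (|rho| clipped just below 1 to keep atanh finite) and runs a
    one-sample t-test of the z values against zero.  ``paired_t`` and
    ``one_sample_t`` treat the per-subject series as condition means.
    """
    report: dict = {"test": test, "excluded": []}
    if test == "spearman_fisher_t":
        rhos, zs = [], []
        for s, (x, y) in pairs.items():
            x = np.asarray(x, dtype=float)
            y = np.asarray(y, dtype=float)
            if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
                report["excluded"].append(
                    {"subject": s, "reason": "zero variance or n < 3"})
                continue
            rho = stats.spearmanr(x, y).statistic
            rhos.append(rho)
            zs.append(math.atanh(float(np.clip(rho, -clip, clip))))
        if len(zs) < 2:
            raise ValueError("fewer than 2 usable subjects")
        if np.std(zs) == 0:  # degenerate: all subjects identical
            mean_z = float(np.mean(zs))
            t = math.copysign(math.inf, mean_z) if mean_z != 0 else 0.0
            p = 0.0 if mean_z != 0 else 1.0
        else:
            t, p = stats.ttest_1samp(zs, 0.0)
        report.update(mean_rho=float(np.mean(rhos)), statistic=float(t),
                      df=len(zs) - 1, p=float(p), n=len(zs))
    elif test in ("paired_t", "one_sample_t"):
        a = np.array([np.mean(v[0]) for v in pairs.values()], dtype=float)
        if test == "paired_t":
            b = np.array([np.mean(v[1]) for v in pairs.values()], dtype=float)
            if np.all(a == b):  # identical conditions: t defined as 0
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(a, b)
            report.update(mean_diff=float(np.mean(a - b)))
        else:
            t, p = stats.ttest_1samp(a, 0.0)
            report.update(mean=float(np.mean(a)))
        report.update(statistic=float(t), df=a.size - 1, p=float(p), n=int(a.size))
    else:
        raise ValueError(f"unknown test {test!r}")
    return report


def axiomatic_bins(trials: Sequence[TrialRecord], trajectory: LatentTrajectory,
                   n_bins: int = 2, value_key: str = "value_pre"
                   ) -> pd.DataFrame:
    """Outcome x predicted-value bin labels for the axiomatic analysis.

    Trials are split by outcome (relief / no relief) and then into
    ``n_bins`` equal-size bins of ascending predicted relief value
    (median split at n_bins = 2); ties at bin boundaries are resolved by
    stable sort order.  Returns one labelled row per trial.
    """
    if n_bins not in (2, 3):
        raise ValueError("n_bins must be 2 or 3")
    ordered = sorted(trials, key=lambda t: (t.paradigm, t.session, t.trial))
    values = np.asarray(trajectory.variables[value_key], dtype=float)
    if len(values) != len(ordered):
        raise ValueError("trajectory / trial length mismatch")
    rows = []
    for outcome in (0, 1):
        idx = [i for i, t in enumerate(ordered) if t.outcome == outcome]
        if 0 < len(idx) < n_bins:
            raise ValueError(f"fewer trials than bins for outcome {outcome}")
        order = np.array(idx)[np.argsort(values[idx], kind="stable")]
        for b, chunk in enumerate(np.array_split(order, n_bins)):
            for i in chunk:
                t = ordered[i]
                rows.append({"paradigm": t.paradigm, "session": t.session,
                             "trial": t.trial, "outcome": outcome,
                             "value": values[i], "bin": b + 1})
    return pd.DataFrame(rows).sort_values(
        ["paradigm", "session", "trial"]).reset_index(drop=True)
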