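"""Synthetic cohorts for both escape-learning paradigms.

Subjects are simulated by running a learning model generatively:
choices are sampled from the model's softmax policy and relief outcomes
from the task contingencies (fixed 80/20 and 60/40 pairs for the static
paradigm; bounded random walks for the dynamic one).  SCR-like trial
amplitudes and 0-10 pain/relief ratings are generated from the model's
latent trajectory, so ground truth is known for every downstream stage.

SCR amplitudes are generated on the log scale (amplitude fitting
consumes within-subject log-transformed SCRs) and stored in trial
records after exponentiation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .models import LatentTrajectory, make_agent, run_model, softmax_policy
from .task import (EXP1_ACTIONS, EXP1_CUES, EXP2_CUES, TaskConfig, TrialRecord,
                   make_exp2_walk, yoke_pavlovian)

__all__ = ["GroundTruth", "simulate_subject", "simulate_exp1_subject",
           "simulate_scr", "fill_scr", "simulate_ratings"]

SCR_SOURCES = {"state_value": "value_pre", "associability": "assoc_pre"}
RATING_PREDICTORS = ("associability", "entropy", "surprise", "none")


@dataclass
class GroundTruth:
    """Generating model, parameters and trajectory for one simulated subject."""

    subject: str
    model: str
    params: dict
    seed: int
    trajectory: LatentTrajectory
    walk: Optional[np.ndarray] = None  # (n_cues, n_trials) relief probabilities


def _derive_seed(seed: int, *salt: int) -> int:
    return int(np.random.SeedSequence([seed, *salt]).generate_state(1)[0] % (2**31))


def simulate_subject(config: TaskConfig, model: str, params: dict, seed: int,
                     subject: str = "sim") -> tuple[list[TrialRecord], GroundTruth]:
    """Simulate one subject's sessions under a generating model.

    ``params`` holds the model's native evolution parameters plus
    ``tau`` (inverse temperature) for choice models.  The same seed
    regenerates the identical cohort bit-for-bit.
    """
    rng = np.random.default_rng(seed)
    fam = "exp1" if config.paradigm.startswith("exp1") else "exp2"
    agent = make_agent(model, params, fam)
    if not agent.has_choice:
        raise ValueError(f"model {model!r} has no choice rule; cannot act")
    tau = agent.fixed_tau if agent.fixed_tau is not None else params["tau"]

    trials: list[TrialRecord] = []
    walk = None
    if fam == "exp2":
        n_total = config.n_sessions * config.n_trials_per_session
        wp = config.walk_params
        walk = make_exp2_walk(n_total, wp["step"], wp["lower"], wp["upper"],
                              seed=_derive_seed(seed, 1), n_cues=3)
    g = 0  # global trial counter (walk column)
    for sess in range(1, config.n_sessions + 1):
        agent.reset()
        if fam == "exp1":
            half = config.n_trials_per_session // 2
            cue_seq = [0] * half + [1] * (config.n_trials_per_session - half)
            rng.shuffle(cue_seq)
        for t in range(1, config.n_trials_per_session + 1):
            if fam == "exp1":
                s = cue_seq[t - 1]
                probs = softmax_policy(agent.action_values(s), tau)
                a = int(rng.choice(2, p=probs))
                p_relief = config.contingency[(EXP1_CUES[s], EXP1_ACTIONS[a])]
                r = int(rng.random() < p_relief)
                agent.update(s, a, r)
                trials.append(TrialRecord(
                    subject=subject, paradigm=config.paradigm, session=sess,
                    trial=t, cues_shown=(EXP1_CUES[s],), chosen=EXP1_ACTIONS[a],
                    outcome=r))
            else:
                probs = softmax_policy(agent.action_values(0), tau)
                a = int(rng.choice(3, p=probs))
                r = int(rng.random() < walk[a, g])
                agent.update(0, a, r)
                trials.append(TrialRecord(
                    subject=subject, paradigm="exp2", session=sess, trial=t,
                    cues_shown=EXP2_CUES, chosen=EXP2_CUES[a], outcome=r))
            g += 1
    taus = [tau] * config.n_sessions
    traj = run_model(model, params, trials, taus=taus)
    return trials, GroundTruth(subject=subject, model=model, params=dict(params),
                               seed=seed, trajectory=traj, walk=walk)


def simulate_exp1_subject(config: TaskConfig, model: str, params: dict,
                          seed: int, subject: str = "sim"
                          ) -> tuple[list[TrialRecord], GroundTruth]:
    """Instrumental sessions plus their yoked Pavlovian counterparts."""
    trials, gt = simulate_subject(config, model, params, seed, subject)
    pav = []
    for sess in range(1, config.n_sessions + 1):
        ins = [t for t in trials if t.session == sess]
        pav.extend(yoke_pavlovian(ins, seed=_derive_seed(seed, 2, sess)))
    return trials + pav, gt


def simulate_scr(trajectory: LatentTrajectory, source: str, b,
                 noise_sd: float, seed: int, n_sources: int = 1) -> np.ndarray:
    """Log-scale SCR amplitudes: predictor + b + Gaussian noise.

    ``source`` selects the latent stream ("state_value" or
    "associability").  With ``n_sources=2`` (bilateral recording) the
    two columns share the predictor but get per-source offsets
    ``b = (b1, b2)`` and independent noise, which makes them correlated
    through the common predictor.
    """
    key = SCR_SOURCES.get(source)
    if key is None:
        raise ValueError(f"unknown SCR source {source!r}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    pred = np.asarray(trajectory.variables[key], dtype=float)
    rng = np.random.default_rng(seed)
    offsets = np.atleast_1d(np.asarray(b, dtype=float))
    if offsets.size != n_sources:
        raise ValueError("need one offset per source")
    out = pred[:, None] + offsets[None, :]
    out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return out[:, 0] if n_sources == 1 else out


def fill_scr(trials: Sequence[TrialRecord], log_left: np.ndarray,
             log_right: Optional[np.ndarray] = None) -> None:
    """Store raw (exponentiated) amplitudes into trial records in place."""
    ordered = sorted(trials, key=lambda t: (t.paradigm, t.session, t.trial))
    for i, rec in enumerate(ordered):
        rec.scr_left = float(np.exp(log_left[i]))
        if log_right is not None:
            rec.scr_right = float(np.exp(log_right[i]))


def _schedule_for(config: TaskConfig, n_sessions: int, rng) -> dict:
    """Per-session rated-trial indices (1-based)."""
    sched = {}
    for sess in range(1, n_sessions + 1):
        if config.rating_schedule:
            sched[sess] = sorted(config.rating_schedule)
        else:
            k = min(config.n_ratings_per_session, config.n_trials_per_session)
            sched[sess] = sorted(
                rng.choice(config.n_trials_per_session, size=k, replace=False) + 1)
    return sched


def simulate_ratings(trials: Sequence[TrialRecord], trajectory: LatentTrajectory,
                     betas: tuple, predictor: str, noise_sd: float, seed: int,
                     config: TaskConfig, intercept: float = 7.0,
                     round_to_int: bool = False) -> None:
    """Fill 0-10 ratings on scheduled trials, in place.

    rating = b1*Relief + b2*log(Trial) + b3*Predictor + intercept + noise,
    truncated to [0, 10].  ``Relief`` counts trials since the previous
    relief outcome (since session start before any relief) and
    ``log(Trial)`` is the log of the within-session trial number,
    exactly as in the rating regression design.  For the static paradigm
    ratings are post-outcome (pain after no relief, relief otherwise);
    for the dynamic paradigm they are pre-outcome pain ratings.
    """
    from .ratings import relief_logtrial  # shared definition
    if predictor not in RATING_PREDICTORS:
        raise ValueError(f"unknown predictor {predictor!r}")
    ordered = sorted(trials, key=lambda t: (t.paradigm, t.session, t.trial))
    pred = _predictor_stream(trajectory, predictor)
    relief, logtrial = relief_logtrial(ordered)
    rng = np.random.default_rng(seed)
    sched = _schedule_for(config, max(t.session for t in ordered), rng)
    b1, b2, b3 = betas
    for i, rec in enumerate(ordered):
        if rec.trial not in sched.get(rec.session, ()):
            continue
        val = (b1 * relief[i] + b2 * logtrial[i] + b3 * pred[i] + intercept
               + rng.normal(0.0, noise_sd))
        val = float(np.clip(val, 0.0, 10.0))
        if round_to_int:
            val = float(round(val))
        rec.rating = val
        if rec.paradigm == "exp2":
            rec.rating_type = "pain"
        else:
            rec.rating_type = "relief" if rec.outcome == 1 else "pain"


def _predictor_stream(trajectory: LatentTrajectory, predictor: str) -> np.ndarray:
    n = len(trajectory)
    if predictor == "none":
        return np.zeros(n)
    if predictor == "associability":
        key = "assoc_pre"
    elif predictor == "entropy":
        key = "entropy_pre"
    elif predictor == "surprise":
        # |prediction error| from the previous trial; 0 at session starts
        pe = np.abs(trajectory.variables["pe"])
        out = np.zeros(n)
        for i in range(1, n):
            same = trajectory.trial_index[i][:2] == trajectory.trial_index[i - 1][:2]
            out[i] = pe[i - 1] if same else 0.0
        return out
    else:
        raise ValueError(predictor)
    if key not in trajectory.variables:
        raise ValueError(
            f"trajectory of model {trajectory.model!r} lacks {key!r} "
            f"needed for predictor {predictor!r}")
    return np.asarray(trajectory.variables[key], dtype=float)
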