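"""Candidate learning models for tonic-pain escape behaviour.

Seven models are implemented, each as a per-trial *agent* exposing
``action_values`` (mapped to choice probabilities through a softmax) and
``update`` (latent-state evolution given the observed relief outcome):

* ``wsls`` — win-stay-lose-shift with per-cue pseudo-Q scalings p1, p2;
* ``td`` — temporal-difference action learning, Q(s, a) updated by a
  delta rule with fixed learning rate alpha;
* ``rw`` — Rescorla-Wagner state (cue) value learning, V(s);
* ``hybrid_state`` / ``hybrid_action`` — Pearce-Hall hybrids in which
  the learning rate is kappa times a running associability, itself a
  recency-weighted average of absolute prediction errors (weight eta);
* ``hmm`` — per-cue two-state hidden Markov filter with symmetric
  transition probability beta and outcome biases c (relief) and
  d (no relief); relief belief is mapped through a shifted sigmoid;
* ``hgf`` — three-level binary hierarchical Gaussian filter per cue
  (coupling kappa, tonic log-volatility omega, third-level volatility
  theta), whose level-2 expectation approximates the relief probability.

Binary outcomes: r = 1 is relief (cooling of the tonic heat stimulus),
r = 0 is continued pain.  Initial states follow the fitting convention
V0 = Q0 = 0, associability alpha0 = 1, HMM relief belief 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .task import TrialRecord

__all__ = [
    "softmax_policy", "td_step", "rw_step", "hybrid_state_step",
    "hybrid_action_step", "wsls_policy", "hmm_step", "hmm_choice_and_entropy",
    "run_model", "make_agent", "compile_subject", "LatentTrajectory",
    "SubjectData", "SessionData", "MODEL_INFO", "ModelNumericalError",
]


class ModelNumericalError(RuntimeError):
    """Raised when a filter update degenerates (zero normaliser, diverging
    precision); fitting treats this as a large-penalty evaluation."""


# ---------------------------------------------------------------------------
# pure per-trial operations
# ---------------------------------------------------------------------------

def softmax_policy(values: Sequence[float], tau: float) -> np.ndarray:
    """Softmax choice probabilities p_i ∝ exp(tau * v_i).

    tau = 0 gives a uniform policy; the output is invariant to adding a
    constant to all values.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("softmax needs at least one option")
    if tau < 0:
        raise ValueError("inverse temperature must be >= 0")
    z = tau * values
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def td_step(Q: np.ndarray, chosen: tuple, r: int, alpha: float):
    """One delta-rule update of the state-action value table.

    Returns ``(Q', delta)`` with delta = r - Q(s, a); only the chosen
    entry changes: Q'(s, a) = Q(s, a) + alpha * delta.
    """
    s, a = chosen
    Q = np.array(Q, dtype=float)
    delta = r - Q[s, a]
    Q[s, a] += alpha * delta
    return Q, delta


def rw_step(V: np.ndarray, s: int, r: int, alpha: float):
    """Rescorla-Wagner state-value update (action-independent)."""
    V = np.array(V, dtype=float)
    delta = r - V[s]
    V[s] += alpha * delta
    return V, delta


def hybrid_state_step(V: np.ndarray, assoc: np.ndarray, s: int, r: int,
                      kappa: float, eta: float):
    """Pearce-Hall hybrid state update.

    V'(s) = V(s) + kappa * assoc(s) * delta;
    assoc'(s) = eta * |delta| + (1 - eta) * assoc(s).
    """
    V = np.array(V, dtype=float)
    assoc = np.array(assoc, dtype=float)
    delta = r - V[s]
    V[s] += kappa * assoc[s] * delta
    assoc[s] = eta * abs(delta) + (1.0 - eta) * assoc[s]
    return V, assoc, delta


def hybrid_action_step(Q: np.ndarray, assoc: np.ndarray, chosen: tuple, r: int,
                       kappa: float, eta: float):
    """Pearce-Hall hybrid extended to instrumental (s, a) learning."""
    s, a = chosen
    Q = np.array(Q, dtype=float)
    assoc = np.array(assoc, dtype=float)
    delta = r - Q[s, a]
    Q[s, a] += kappa * assoc[s, a] * delta
    assoc[s, a] = eta * abs(delta) + (1.0 - eta) * assoc[s, a]
    return Q, assoc, delta


def wsls_policy(previous: Optional[tuple], p_cue: float,
                n_actions: int = 2) -> np.ndarray:
    """Win-stay-lose-shift pseudo-Q policy for one cue.

    ``previous`` is ``(action_index, outcome)`` from the last trial of
    this cue or None.  After relief the previously chosen action gets
    pseudo-Q +p_cue and all others -p_cue; after no relief the signs
    flip.  Probabilities come from a softmax with fixed tau = 1, so the
    first encounter of a cue is uniform.
    """
    if previous is None:
        return np.full(n_actions, 1.0 / n_actions)
    act, r = previous
    sign = 1.0 if r == 1 else -1.0
    q = np.full(n_actions, -sign * p_cue)
    q[act] = sign * p_cue
    return softmax_policy(q, 1.0)


def hmm_step(belief: float, observed_r: Optional[int],
             beta: float, c: float, d: float) -> float:
    """Propagate one cue's relief belief through the two-state HMM.

    ``belief`` is P(state = relief).  The symmetric transition matrix
    [[1-beta, beta], [beta, 1-beta]] is applied first; if an outcome was
    observed for this cue the belief is reweighted by the observation
    row 0.5*(1+c, 1-c) for relief or 0.5*(1-d, 1+d) for no relief and
    renormalised.  Pass ``observed_r=None`` for transition-only updates
    (unchosen cues).
    """
    prior = (1.0 - beta) * belief + beta * (1.0 - belief)
    if observed_r is None:
        return prior
    if observed_r == 1:
        num = (1.0 + c) * prior
        den = num + (1.0 - c) * (1.0 - prior)
    else:
        num = (1.0 - d) * prior
        den = num + (1.0 + d) * (1.0 - prior)
    if den <= 0.0 or not math.isfinite(den):
        raise ModelNumericalError("degenerate HMM posterior normalisation")
    return num / den


def hmm_choice_and_entropy(beliefs: Sequence[float], m: float, tau: float):
    """Observation side of the HMM.

    Relief probability per cue is sigmoid(x) with
    x = P(relief) - P(no relief) + m; choice probabilities are a softmax
    over those relief probabilities scaled by tau; H is the natural-log
    entropy of each cue's two-state belief (bounded by ln 2).
    """
    beliefs = np.asarray(beliefs, dtype=float)
    x = 2.0 * beliefs - 1.0 + m
    p_relief = 1.0 / (1.0 + np.exp(-x))
    probs = softmax_policy(p_relief, tau)
    H = np.array([_entropy2(b) for b in beliefs])
    return p_relief, probs, H


def _entropy2(q: float) -> float:
    if q <= 0.0 or q >= 1.0:
        return 0.0
    return -(q * math.log(q) + (1.0 - q) * math.log(1.0 - q))


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


# ---------------------------------------------------------------------------
# agents: incremental model state shared by fitting and simulation
# ---------------------------------------------------------------------------

class _Agent:
    """Per-session incremental model state.

    ``action_values(s)`` returns the value vector the softmax acts on
    for the available options; ``update(s, opt, r)`` evolves the latent
    state after outcome ``r`` and returns the prediction error (or None
    for models without one).  ``fixed_tau`` overrides the fitted inverse
    temperature when not None (WSLS uses tau = 1).
    """

    fixed_tau: Optional[float] = None
    has_choice = True

    def reset(self):  # new session: re-apply initial states
        raise NotImplementedError

    def action_values(self, s: int):
        raise NotImplementedError

    def update(self, s: int, opt: Optional[int], r: int):
        raise NotImplementedError

    def snapshot(self, s: int, opt: Optional[int]) -> dict:
        """Pre-update latent quantities for trajectory recording."""
        return {}


class TDAgent(_Agent):
    def __init__(self, alpha, n_states, n_options):
        self.alpha = alpha
        self.shape = (n_states, n_options)
        self.reset()

    def reset(self):
        self.Q = [[0.0] * self.shape[1] for _ in range(self.shape[0])]

    def action_values(self, s):
        return self.Q[s]

    def update(self, s, opt, r):
        row = self.Q[s]
        delta = r - row[opt]
        row[opt] += self.alpha * delta
        return delta

    def snapshot(self, s, opt):
        return {"value_pre": self.Q[s][opt]}


class HybridActionAgent(_Agent):
    def __init__(self, kappa, eta, n_states, n_options):
        self.kappa, self.eta = kappa, eta
        self.shape = (n_states, n_options)
        self.reset()

    def reset(self):
        self.Q = [[0.0] * self.shape[1] for _ in range(self.shape[0])]
        self.A = [[1.0] * self.shape[1] for _ in range(self.shape[0])]

    def action_values(self, s):
        return self.Q[s]

    def update(self, s, opt, r):
        q, a = self.Q[s], self.A[s]
        delta = r - q[opt]
        q[opt] += self.kappa * a[opt] * delta
        a[opt] = self.eta * abs(delta) + (1.0 - self.eta) * a[opt]
        return delta

    def snapshot(self, s, opt):
        return {"value_pre": self.Q[s][opt], "assoc_pre": self.A[s][opt]}


class RWAgent(_Agent):
    """State (cue) value learning; no choice model."""

    has_choice = False

    def __init__(self, alpha, n_cues):
        self.alpha = alpha
        self.n_cues = n_cues
        self.reset()

    def reset(self):
        self.V = [0.0] * self.n_cues

    def action_values(self, s):
        return self.V

    def update(self, s, opt, r):
        delta = r - self.V[s]
        self.V[s] += self.alpha * delta
        return delta

    def snapshot(self, s, opt):
        return {"value_pre": self.V[s]}


class HybridStateAgent(_Agent):
    has_choice = False

    def __init__(self, kappa, eta, n_cues):
        self.kappa, self.eta = kappa, eta
        self.n_cues = n_cues
        self.reset()

    def reset(self):
        self.V = [0.0] * self.n_cues
        self.A = [1.0] * self.n_cues

    def action_values(self, s):
        return self.V

    def update(self, s, opt, r):
        delta = r - self.V[s]
        self.V[s] += self.kappa * self.A[s] * delta
        self.A[s] = self.eta * abs(delta) + (1.0 - self.eta) * self.A[s]
        return delta

    def snapshot(self, s, opt):
        return {"value_pre": self.V[s], "assoc_pre": self.A[s]}


class WSLSAgent(_Agent):
    """Win-stay-lose-shift over two cues; softmax with fixed tau = 1."""

    fixed_tau = 1.0

    def __init__(self, p1, p2, n_states=2, n_options=2):
        self.p = [p1, p2]
        self.n_options = n_options
        self.reset()

    def reset(self):
        self.last: list[Optional[tuple]] = [None] * len(self.p)

    def action_values(self, s):
        prev = self.last[s]
        if prev is None:
            return [0.0] * self.n_options
        act, r = prev
        sign = 1.0 if r == 1 else -1.0
        vals = [-sign * self.p[s]] * self.n_options
        vals[act] = sign * self.p[s]
        return vals

    def update(self, s, opt, r):
        self.last[s] = (opt, r)
        return None


class HMMAgent(_Agent):
    """Per-cue two-state hidden Markov filter (dynamic paradigm).

    The belief for every cue is propagated through the transition matrix
    each trial; only the chosen cue's belief is reweighted by the
    observation likelihood (the outcome is observed for that cue only).
    """

    def __init__(self, beta, c, d, m, n_cues):
        self.beta, self.c, self.d, self.m = beta, c, d, m
        self.n_cues = n_cues
        self.reset()

    def reset(self):
        self.q = [0.5] * self.n_cues
        self._advanced = False

    def _advance(self):
        # transition applies once per trial, before choice
        if not self._advanced:
            b = self.beta
            self.q = [(1.0 - b) * q + b * (1.0 - q) for q in self.q]
            self._advanced = True

    def action_values(self, s):
        self._advance()
        m = self.m
        return [_sigmoid(2.0 * q - 1.0 + m) for q in self.q]

    def update(self, s, opt, r):
        self._advance()
        q = self.q[opt]
        p_pre = _sigmoid(2.0 * q - 1.0 + self.m)
        if r == 1:
            num = (1.0 + self.c) * q
            den = num + (1.0 - self.c) * (1.0 - q)
        else:
            num = (1.0 - self.d) * q
            den = num + (1.0 + self.d) * (1.0 - q)
        if den <= 0.0 or not math.isfinite(den):
            raise ModelNumericalError("degenerate HMM posterior normalisation")
        self.q[opt] = num / den
        self._advanced = False
        return r - p_pre

    def snapshot(self, s, opt):
        self._advance()
        q = self.q[opt]
        return {
            "value_pre": _sigmoid(2.0 * q - 1.0 + self.m),
            "belief_pre": q,
            "entropy_pre": _entropy2(q),
        }


class HGFAgent(_Agent):
    """Three-level binary hierarchical Gaussian filter, one per cue.

    Level 2 tracks the log-odds of relief (expectation mu2, variance
    sigma2); level 3 tracks log-volatility (mu3, sigma3) coupled through
    kappa with tonic component omega; theta is the level-3 random-walk
    variance.  Only the chosen cue's means are updated; every cue's
    variances inflate by the volatility prediction each trial.
    Initial states: mu2 = 0 (relief belief 0.5), sigma2 = 1, mu3 = 1,
    sigma3 = 1, re-applied at each session start.
    """

    def __init__(self, kappa, omega, theta, n_cues):
        self.kappa, self.omega, self.theta = kappa, omega, theta
        self.n_cues = n_cues
        self.reset()

    def reset(self):
        n = self.n_cues
        self.mu2 = [0.0] * n
        self.s2 = [1.0] * n
        self.mu3 = [1.0] * n
        self.s3 = [1.0] * n
        self._advanced = False
        self._s2hat = [0.0] * n

    def _advance(self):
        # prediction step: inflate variances with the volatility estimate
        if not self._advanced:
            k, w, th = self.kappa, self.omega, self.theta
            for i in range(self.n_cues):
                self._s2hat[i] = self.s2[i] + math.exp(k * self.mu3[i] + w)
            self._advanced = True

    def action_values(self, s):
        self._advance()
        return [_sigmoid(m) for m in self.mu2]

    def update(self, s, opt, r):
        self._advance()
        k, w, th = self.kappa, self.omega, self.theta
        j = opt
        mu1hat = _sigmoid(self.mu2[j])
        delta1 = r - mu1hat
        s2hat = self._s2hat[j]
        s2_old = self.s2[j]
        pi2 = 1.0 / s2hat + mu1hat * (1.0 - mu1hat)
        if pi2 <= 0.0 or not math.isfinite(pi2):
            raise ModelNumericalError("HGF level-2 precision degenerated")
        s2_new = 1.0 / pi2
        mu2_new = self.mu2[j] + s2_new * delta1
        # volatility prediction error and level-3 update
        expo = math.exp(k * self.mu3[j] + w)
        delta2 = (s2_new + (mu2_new - self.mu2[j]) ** 2) / s2hat - 1.0
        w2 = expo / s2hat
        r2 = (expo - s2_old) / s2hat
        s3hat = self.s3[j] + th
        pi3 = 1.0 / s3hat + 0.5 * k * k * w2 * (w2 + r2 * delta2)
        if pi3 <= 0.0 or not math.isfinite(pi3):
            raise ModelNumericalError("HGF level-3 precision diverged")
        s3_new = 1.0 / pi3
        mu3_new = self.mu3[j] + 0.5 * k * s3_new * w2 * delta2
        # commit: chosen cue gets posterior, others keep inflated variances
        for i in range(self.n_cues):
            if i == j:
                self.mu2[i], self.s2[i] = mu2_new, s2_new
                self.mu3[i], self.s3[i] = mu3_new, s3_new
            else:
                self.s2[i] = self._s2hat[i]
                self.s3[i] = self.s3[i] + th
        self._advanced = False
        return delta1

    def snapshot(self, s, opt):
        self._advance()
        return {"value_pre": _sigmoid(self.mu2[opt]), "mu3_pre": self.mu3[opt]}


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelInfo:
    name: str
    evolution_params: tuple  # (name, transform) pairs; transforms from fitting
    has_choice: bool
    paradigms: tuple  # "exp1" and/or "exp2" families


MODEL_INFO = {
    "wsls": ModelInfo("wsls", (("p1", "sigmoid"), ("p2", "sigmoid")), True, ("exp1",)),
    "td": ModelInfo("td", (("alpha", "sigmoid"),), True, ("exp1", "exp2")),
    "rw": ModelInfo("rw", (("alpha", "sigmoid"),), False, ("exp1", "exp2")),
    "hybrid_state": ModelInfo(
        "hybrid_state", (("kappa", "sigmoid"), ("eta", "sigmoid")), False,
        ("exp1", "exp2")),
    "hybrid_action": ModelInfo(
        "hybrid_action", (("kappa", "sigmoid"), ("eta", "sigmoid")), True,
        ("exp1", "exp2")),
    "hmm": ModelInfo(
        "hmm", (("beta", "sigmoid"), ("c", "sigmoid"), ("d", "sigmoid")), True,
        ("exp2",)),
    "hgf": ModelInfo(
        "hgf", (("kappa", "sigmoid"), ("omega", "identity"), ("theta", "sigmoid")),
        True, ("exp2",)),
}

# models whose choice rule uses a fitted inverse temperature
TAU_MODELS = {"td", "hybrid_action", "hmm", "hgf"}


def make_agent(model: str, params: dict, paradigm_family: str,
               n_cues: int = None, n_actions: int = 2) -> _Agent:
    """Instantiate an agent with native-scale parameters."""
    info = MODEL_INFO.get(model)
    if info is None:
        raise ValueError(f"unknown model {model!r}")
    if paradigm_family not in info.paradigms:
        raise ValueError(f"model {model!r} is not defined for {paradigm_family}")
    if n_cues is None:
        n_cues = 2 if paradigm_family == "exp1" else 3
    for pname, tr in info.evolution_params:
        v = params[pname]
        if tr == "sigmoid" and not 0.0 <= v <= 1.0:
            raise ValueError(f"{model} parameter {pname}={v} outside [0, 1]")
    if model == "td":
        if paradigm_family == "exp1":
            return TDAgent(params["alpha"], n_cues, n_actions)
        return TDAgent(params["alpha"], 1, n_cues)
    if model == "hybrid_action":
        if paradigm_family == "exp1":
            return HybridActionAgent(params["kappa"], params["eta"], n_cues, n_actions)
        return HybridActionAgent(params["kappa"], params["eta"], 1, n_cues)
    if model == "wsls":
        return WSLSAgent(params["p1"], params["p2"], n_cues, n_actions)
    if model == "rw":
        return RWAgent(params["alpha"], n_cues)
    if model == "hybrid_state":
        return HybridStateAgent(params["kappa"], params["eta"], n_cues)
    if model == "hmm":
        return HMMAgent(params["beta"], params["c"], params["d"],
                        params.get("m", 0.0), n_cues)
    if model == "hgf":
        return HGFAgent(params["kappa"], params["omega"], params["theta"], n_cues)
    raise ValueError(model)


# ---------------------------------------------------------------------------
# running a model over recorded trials
# ---------------------------------------------------------------------------

@dataclass
class SessionData:
    """Compact per-session encoding of one subject's trials."""

    state_idx: list  # exp1: cue index; exp2: always 0 (single state)
    opt_idx: list  # exp1: action index; exp2: chosen-cue index
    cue_idx: list  # cue whose outcome was observed (exp1 cue / exp2 chosen)
    r: list
    free_choice: bool
    paradigm: str
    session: int


@dataclass
class SubjectData:
    paradigm_family: str  # "exp1" | "exp2"
    sessions: list
    n_cues: int
    n_options: int

    @property
    def n_trials(self):
        return sum(len(s.r) for s in self.sessions)


def compile_subject(trials: Sequence[TrialRecord]) -> SubjectData:
    """Group a subject's trials into ordered sessions of index arrays."""
    if not trials:
        raise ValueError("no trials")
    fams = {t.paradigm.split("_")[0] for t in trials}
    if len(fams) != 1:
        raise ValueError("mixed exp1/exp2 trials for one subject")
    fam = fams.pop()
    from .task import EXP1_ACTIONS, EXP1_CUES, EXP2_CUES
    sessions = {}
    for t in sorted(trials, key=lambda t: (t.paradigm, t.session, t.trial)):
        sessions.setdefault((t.paradigm, t.session), []).append(t)
    out = []
    for (paradigm, sess), recs in sessions.items():
        if [t.trial for t in recs] != list(range(1, len(recs) + 1)):
            raise ValueError(f"ragged session {paradigm}/{sess}")
        if fam == "exp1":
            state = [EXP1_CUES.index(t.cues_shown[0]) for t in recs]
            opt = [EXP1_ACTIONS.index(t.chosen) for t in recs]
            cue = state
        else:
            state = [0] * len(recs)
            opt = [EXP2_CUES.index(t.chosen) for t in recs]
            cue = opt
        out.append(SessionData(
            state_idx=state, opt_idx=opt, cue_idx=cue, r=[t.outcome for t in recs],
            free_choice=paradigm != "exp1_pavlovian", paradigm=paradigm,
            session=sess))
    return SubjectData(
        paradigm_family=fam, sessions=out,
        n_cues=2 if fam == "exp1" else 3,
        n_options=2 if fam == "exp1" else 3)


@dataclass
class LatentTrajectory:
    """Per-trial model internals aligned 1:1 with the subject's trials."""

    model: str
    variables: dict  # name -> np.ndarray over trials (flattened session order)
    loglik: float  # summed choice log-likelihood (free-choice trials only)
    trial_index: list = field(default_factory=list)  # (paradigm, session, trial)

    def __len__(self):
        return len(self.trial_index)

    def to_tidy(self, subject: str):
        import pandas as pd
        rows = []
        for name, arr in self.variables.items():
            for (paradigm, sess, trial), v in zip(self.trial_index, arr):
                rows.append((subject, paradigm, sess, trial, name, v))
        return pd.DataFrame(
            rows, columns=["subject", "paradigm", "session", "trial",
                           "variable", "value"])


def model_loglik(model: str, params: dict, sd: SubjectData,
                 taus: Optional[Sequence[float]] = None) -> float:
    """Summed choice log-likelihood (fast path, no trajectory)."""
    agent = make_agent(model, params, sd.paradigm_family,
                       n_cues=sd.n_cues, n_actions=sd.n_options)
    total = 0.0
    exp_ = math.exp
    log_ = math.log
    for i, sess in enumerate(sd.sessions):
        agent.reset()
        tau = agent.fixed_tau
        if tau is None:
            tau = taus[i] if taus is not None else 1.0
        collect = agent.has_choice and sess.free_choice
        for s, opt, r in zip(sess.state_idx, sess.opt_idx, sess.r):
            if collect:
                vals = agent.action_values(s)
                mx = max(vals)
                den = 0.0
                for v in vals:
                    den += exp_(tau * (v - mx))
                total += tau * (vals[opt] - mx) - log_(den)
            agent.update(s, opt, r)
    return total


def run_model(model: str, params: dict, trials: Sequence[TrialRecord],
              taus: Optional[Sequence[float]] = None) -> LatentTrajectory:
    """Run a model over recorded trials, returning the full latent trajectory.

    Latent states reset to their initial values at each session start.
    Choice log-likelihood accumulates only on free-choice (instrumental)
    trials; Pavlovian sessions contribute state learning only.  ``taus``
    gives the per-session inverse temperature for choice models (a single
    value is broadcast).
    """
    sd = compile_subject(trials)
    agent = make_agent(model, params, sd.paradigm_family,
                       n_cues=sd.n_cues, n_actions=sd.n_options)
    if taus is None:
        taus = [1.0] * len(sd.sessions)
    elif np.isscalar(taus):
        taus = [float(taus)] * len(sd.sessions)
    elif len(taus) == 1:
        taus = [float(taus[0])] * len(sd.sessions)

    names = None
    cols: dict = {}
    index = []
    total_ll = 0.0
    for i, sess in enumerate(sd.sessions):
        agent.reset()
        tau = agent.fixed_tau if agent.fixed_tau is not None else taus[i]
        for t, (s, opt, r) in enumerate(
                zip(sess.state_idx, sess.opt_idx, sess.r)):
            snap = agent.snapshot(s, opt)
            vals = agent.action_values(s)
            probs = softmax_policy(vals, tau)
            snap["choice_prob"] = probs[opt]
            if agent.has_choice and sess.free_choice:
                ll = math.log(probs[opt])
                snap["loglik"] = ll
                total_ll += ll
            else:
                snap["loglik"] = np.nan
            delta = agent.update(s, opt, r)
            snap["pe"] = np.nan if delta is None else delta
            if isinstance(agent, HMMAgent):
                snap["belief_post"] = agent.q[opt]
                snap["entropy_post"] = _entropy2(agent.q[opt])
            if names is None:
                names = list(snap)
                cols = {k: [] for k in names}
            for k in names:
                cols[k].append(snap.get(k, np.nan))
            index.append((sess.paradigm, sess.session, t + 1))
    variables = {k: np.asarray(v, dtype=float) for k, v in cols.items()}
    return LatentTrajectory(model=model, variables=variables,
                            loglik=total_ll, trial_index=index)
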