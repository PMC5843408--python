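"""MAP fitting with Laplace model evidence.

Each subject's model is fitted by maximum-a-posteriori estimation over
Gaussian latent parameters (sigmoid-, exp- or identity-transformed to
their native ranges), and the log model evidence is approximated at the
mode by the Laplace method:

    F = -nll(mode) + (d/2) ln(2 pi) - 0.5 ln det H,

with ``nll`` the negative log joint (likelihood plus Gaussian prior)
and H its finite-difference Hessian at the mode.  This is the one
intentional methodological substitution of the pipeline: the reference
analyses used full variational-Bayes updates, which are asymptotically
equivalent for model-selection purposes; MAP + Laplace is deterministic
and unit-testable against conjugate closed forms.

Conventions mirrored from the reference fitting setup: evolution
(learning) parameters and initial states are shared across sessions
while observation parameters (inverse temperature tau for choice fits,
offset b for SCR fits) are instantiated per session; choice-fit priors
are N(0, 1) on the latent scale and SCR-fit evolution priors are
N(0, 0.05) — tight enough that sigmoid-transformed parameters stay
within a few hundredths of 0.5.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize

from .models import (MODEL_INFO, TAU_MODELS, ModelNumericalError, SubjectData,
                     compile_subject, model_loglik)

__all__ = [
    "ParamPrior", "PriorSpec", "transform", "inverse_transform",
    "default_choice_priors", "choice_nll", "fit_map", "laplace_evidence",
    "FitResult", "fit_choice_model", "preprocess_scr", "fit_scr",
    "SCR_MODELS", "ScrData",
]

_BIG = 1e8  # sentinel for numerically failed evaluations


# ---------------------------------------------------------------------------
# latent-parameter transforms and priors
# ---------------------------------------------------------------------------

def transform(x, kind: str):
    """Latent -> native. sigmoid maps to (0,1), exp to (0,inf)."""
    x = np.asarray(x, dtype=float)
    if kind == "sigmoid":
        out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                       np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        return out if out.ndim else float(out)
    if kind == "exp":
        return np.exp(x) if x.ndim else float(np.exp(x))
    if kind == "identity":
        return x if x.ndim else float(x)
    raise ValueError(f"unknown transform {kind!r}")


def inverse_transform(y, kind: str):
    y = np.asarray(y, dtype=float)
    if kind == "sigmoid":
        if np.any((y <= 0) | (y >= 1)):
            raise ValueError("sigmoid inverse needs values in (0, 1)")
        return np.log(y / (1.0 - y)) if y.ndim else float(np.log(y / (1.0 - y)))
    if kind == "exp":
        if np.any(y <= 0):
            raise ValueError("exp inverse needs positive values")
        return np.log(y) if y.ndim else float(np.log(y))
    if kind == "identity":
        return y if y.ndim else float(y)
    raise ValueError(f"unknown transform {kind!r}")


@dataclass(frozen=True)
class ParamPrior:
    name: str
    mu0: float
    sigma0: float
    kind: str  # transform

    def logpdf(self, x: float) -> float:
        z = (x - self.mu0) / self.sigma0
        return -0.5 * (z * z + math.log(2.0 * math.pi) ) - math.log(self.sigma0)


@dataclass
class PriorSpec:
    """Ordered latent priors: evolution parameters first, then observation."""

    params: list  # of ParamPrior
    n_evolution: int

    def __len__(self):
        return len(self.params)

    @property
    def mu0(self):
        return np.array([p.mu0 for p in self.params])

    def neg_log_prior(self, x: np.ndarray) -> float:
        return -sum(p.logpdf(v) for p, v in zip(self.params, x))

    def draw(self, rng) -> np.ndarray:
        return np.array([rng.normal(p.mu0, p.sigma0) for p in self.params])

    def to_native(self, x: np.ndarray) -> dict:
        return {p.name: transform(v, p.kind) for p, v in zip(self.params, x)}


# latent prior means per evolution parameter (0 unless stated otherwise;
# the hierarchical filter's tonic volatility has prior mean -2)
_EVOLUTION_MU0 = {("hgf", "omega"): -2.0}


def default_choice_priors(model: str, n_sessions: int,
                          per_session_obs: bool = True,
                          sigma_evolution: float = 1.0,
                          fit_m: bool = False) -> PriorSpec:
    """N(0, 1) latent priors; tau (exp-transformed) per session."""
    info = MODEL_INFO[model]
    params = [ParamPrior(name, _EVOLUTION_MU0.get((model, name), 0.0),
                         sigma_evolution, kind)
              for name, kind in info.evolution_params]
    if model == "hmm" and fit_m:
        params.append(ParamPrior("m", 0.0, sigma_evolution, "identity"))
    n_evo = len(params)
    if model in TAU_MODELS:
        n_tau = n_sessions if per_session_obs else 1
        params += [ParamPrior(f"tau_{i + 1}", 0.0, 1.0, "exp")
                   for i in range(n_tau)]
    return PriorSpec(params=params, n_evolution=n_evo)


# ---------------------------------------------------------------------------
# choice objective
# ---------------------------------------------------------------------------

def _split_latents(x: np.ndarray, priors: PriorSpec, model: str,
                   n_sessions: int):
    native = priors.to_native(np.asarray(x, dtype=float))
    evo = {p.name: native[p.name] for p in priors.params[:priors.n_evolution]}
    taus = None
    if model in TAU_MODELS:
        tau_vals = [native[p.name] for p in priors.params[priors.n_evolution:]]
        taus = tau_vals * n_sessions if len(tau_vals) == 1 else tau_vals
    return evo, taus


def choice_nll(model: str, latents: np.ndarray, sd: SubjectData,
               priors: PriorSpec) -> float:
    """Negative log joint of choices and latent priors.

    Only free-choice (instrumental) trials contribute likelihood.  A
    numerically failed model evaluation returns a large penalty rather
    than raising, so optimisation can continue.
    """
    x = np.asarray(latents, dtype=float)
    if not np.all(np.isfinite(x)):
        return _BIG
    evo, taus = _split_latents(x, priors, model, len(sd.sessions))
    try:
        ll = model_loglik(model, evo, sd, taus=taus)
    except (ModelNumericalError, OverflowError, ZeroDivisionError):
        return _BIG * (1.0 + float(np.sum(x * x)))
    if not math.isfinite(ll):
        return _BIG
    return -ll + priors.neg_log_prior(x)


# ---------------------------------------------------------------------------
# optimisation and evidence
# ---------------------------------------------------------------------------

@dataclass
class MapResult:
    mode: np.ndarray
    fun: float
    start_funs: list
    success: bool
    message: str = ""


def fit_map(objective: Callable, priors: PriorSpec, n_starts: int = 8,
            seed: int = 0, tol: float = 1e-6,
            maxfev: Optional[int] = None) -> MapResult:
    """Multistart gradient-free (Nelder-Mead) MAP optimisation.

    The first start is the prior mean; the remaining ``n_starts - 1``
    are prior draws.  Deterministic given (objective, seed, n_starts,
    tol).
    """
    rng = np.random.default_rng(seed)
    d = len(priors)
    starts = [priors.mu0]
    for _ in range(n_starts - 1):
        starts.append(priors.draw(rng))
    if not math.isfinite(objective(starts[0])):
        raise ValueError("objective not finite at the prior mean")
    best = None
    funs = []
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": tol, "fatol": tol, "adaptive": d > 4,
                     "maxfev": maxfev or 200 * d * 2})
        funs.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not math.isfinite(best.fun):
        raise RuntimeError(f"all {n_starts} starts failed: {funs}")
    return MapResult(mode=np.asarray(best.x, dtype=float), fun=float(best.fun),
                     start_funs=funs, success=bool(best.success),
                     message=str(best.message))


def _fd_hessian(f: Callable, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian."""
    x = np.asarray(x, dtype=float)
    d = x.size
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d); ei[i] = step
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / step**2
        for j in range(i + 1, d):
            ej = np.zeros(d); ej[j] = step
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej)
                + f(x - ei - ej)) / (4.0 * step**2)
    return H


def laplace_evidence(objective: Callable, mode: np.ndarray,
                     step: float = 1e-4) -> float:
    """Laplace approximation to the log model evidence at a MAP mode.

    F = -nll(mode) + (d/2) ln(2 pi) - 0.5 ln det H.  A non-positive-
    definite Hessian is repaired by flooring its eigenvalues (with a
    warning); this happens only for likelihood-flat directions.
    """
    mode = np.asarray(mode, dtype=float)
    H = _fd_hessian(objective, mode, step=step)
    H = 0.5 * (H + H.T)
    eigvals, eigvecs = np.linalg.eigh(H)
    if np.any(eigvals <= 0):
        warnings.warn("non-positive-definite Hessian repaired at the mode")
        eigvals = np.clip(eigvals, 1e-8, None)
    logdet = float(np.sum(np.log(eigvals)))
    d = mode.size
    return float(-objective(mode) + 0.5 * d * math.log(2.0 * math.pi)
                 - 0.5 * logdet)


@dataclass
class FitResult:
    """Per-subject fit: posterior-mode parameters and Laplace free energy."""

    subject: str
    model: str
    latent_mode: np.ndarray
    native: dict  # evolution parameters on the native scale
    taus: Optional[list]  # per-session inverse temperatures (choice fits)
    free_energy: float
    diagnostics: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_record(self) -> dict:
        rec = {"subject": self.subject, "model": self.model,
               "free_energy": self.free_energy}
        rec.update({k: float(v) for k, v in self.native.items()})
        return rec


def fit_choice_model(model: str, trials, subject: str = "?",
                     n_starts: int = 8, seed: int = 0, tol: float = 1e-6,
                     per_session_obs: bool = True,
                     priors: Optional[PriorSpec] = None,
                     maxfev: Optional[int] = None) -> FitResult:
    """MAP-fit a choice model to one subject's instrumental choices."""
    sd = trials if isinstance(trials, SubjectData) else compile_subject(trials)
    if priors is None:
        priors = default_choice_priors(model, len(sd.sessions), per_session_obs)

    def obj(x):
        return choice_nll(model, x, sd, priors)

    mres = fit_map(obj, priors, n_starts=n_starts, seed=seed, tol=tol,
                   maxfev=maxfev)
    F = laplace_evidence(obj, mres.mode)
    evo, taus = _split_latents(mres.mode, priors, model, len(sd.sessions))
    return FitResult(
        subject=subject, model=model, latent_mode=mres.mode, native=evo,
        taus=taus, free_energy=F,
        diagnostics={"nll": mres.fun, "start_funs": mres.start_funs,
                     "converged": mres.success})


# ---------------------------------------------------------------------------
# SCR preprocessing and fitting
# ---------------------------------------------------------------------------

# predictor streams for the three SCR observation models
SCR_MODELS = {
    "rw_value": ("rw", "value_pre"),
    "hybrid_value": ("hybrid_state", "value_pre"),
    "hybrid_assoc": ("hybrid_state", "assoc_pre"),
}


@dataclass
class ScrData:
    """Log-transformed SCR series with exclusion masks, per source.

    ``y[source]`` is the log-amplitude over the subject's flattened trial
    order; ``usable[source]`` marks trials that enter the fit (session
    kept, amplitude at/above threshold, and not among the first two
    trials of a session).  ``report`` lists exclusions.
    """

    y: dict
    usable: dict
    session_of: np.ndarray  # flattened trial -> session slot index
    n_sessions: int
    report: list


def preprocess_scr(trials, threshold: float = 0.02,
                   max_bad_fraction: float = 0.2,
                   sources: Sequence[str] = ("left",),
                   exclusion_source: Optional[str] = None) -> ScrData:
    """Session exclusion and within-subject log transform.

    A session is excluded for a source iff the fraction of its trials
    with amplitude below ``threshold`` exceeds ``max_bad_fraction``
    (strictly more than 20% by default).  Surviving amplitudes are
    log-transformed; the first two trials of each session are flagged
    for exclusion from fitting (startle effects).  With bilateral
    recordings one source's exclusion decisions can be applied to both
    via ``exclusion_source``.
    """
    ordered = sorted(trials, key=lambda t: (t.paradigm, t.session, t.trial))
    sess_keys = sorted({(t.paradigm, t.session) for t in ordered})
    slot = {k: i for i, k in enumerate(sess_keys)}
    session_of = np.array([slot[(t.paradigm, t.session)] for t in ordered])
    n = len(ordered)
    report = []
    y, usable, sess_keep = {}, {}, {}
    for src in sources:
        amp = np.array([getattr(t, f"scr_{src}") if getattr(t, f"scr_{src}")
                        is not None else np.nan for t in ordered])
        keep = np.ones(len(sess_keys), dtype=bool)
        for k, i in slot.items():
            a = amp[session_of == i]
            if np.all(np.isnan(a)):
                keep[i] = False
                report.append({"source": src, "session": k,
                               "reason": "no amplitudes"})
                continue
            bad = np.mean(np.nan_to_num(a, nan=0.0) < threshold)
            if bad > max_bad_fraction:
                keep[i] = False
                report.append({"source": src, "session": k,
                               "reason": f"{bad:.1%} trials below {threshold}"})
        sess_keep[src] = keep
        with np.errstate(divide="ignore", invalid="ignore"):
            y[src] = np.where(amp >= threshold, np.log(amp), np.nan)
    for src in sources:
        keep = sess_keep[exclusion_source or src]
        first_two = np.zeros(n, dtype=bool)
        for i in range(len(sess_keys)):
            idx = np.flatnonzero(session_of == i)
            first_two[idx[:2]] = True
        usable[src] = (keep[session_of] & ~first_two
                       & np.isfinite(y[src]))
    if all(not sess_keep[exclusion_source or s].any() for s in sources):
        report.append({"source": "all", "session": None,
                       "reason": "subject dropped: every session excluded"})
    return ScrData(y=y, usable=usable, session_of=session_of,
                   n_sessions=len(sess_keys), report=report)


def _state_predictor_stream(model: str, params: dict, sd: SubjectData,
                            key: str) -> np.ndarray:
    """Fast pre-outcome V / associability stream for the state models."""
    out = np.empty(sd.n_trials)
    i = 0
    if model == "rw":
        alpha = params["alpha"]
        for sess in sd.sessions:
            V = [0.0] * sd.n_cues
            for c, r in zip(sess.cue_idx, sess.r):
                out[i] = V[c]
                V[c] += alpha * (r - V[c])
                i += 1
    elif model == "hybrid_state":
        kappa, eta = params["kappa"], params["eta"]
        want_assoc = key == "assoc_pre"
        for sess in sd.sessions:
            V = [0.0] * sd.n_cues
            A = [1.0] * sd.n_cues
            for c, r in zip(sess.cue_idx, sess.r):
                out[i] = A[c] if want_assoc else V[c]
                delta = r - V[c]
                V[c] += kappa * A[c] * delta
                A[c] = eta * abs(delta) + (1.0 - eta) * A[c]
                i += 1
    else:
        raise ValueError(model)
    return out


def _scr_profile_nll(pred: np.ndarray, scr: ScrData, b: dict,
                     prior_b_sigma: float = 1.0):
    """Data + offset-prior terms with per-source profiled noise variance.

    Given the predictor stream and per-session offsets ``b[source]``,
    the Gaussian noise variance of each source is set to its profile
    (ML) value sigma^2 = RSS / n.
    """
    total = 0.0
    for src, yv in scr.y.items():
        m = scr.usable[src]
        if not m.any():
            continue
        resid = yv[m] - pred[m] - b[src][scr.session_of[m]]
        n = resid.size
        s2 = max(float(np.mean(resid * resid)), 1e-12)
        total += 0.5 * n * (math.log(2.0 * math.pi * s2) + 1.0)
        bs = b[src]
        total += float(np.sum(
            0.5 * (bs / prior_b_sigma) ** 2
            + 0.5 * math.log(2.0 * math.pi) + math.log(prior_b_sigma)))
    return total


def _solve_offsets(pred: np.ndarray, scr: ScrData,
                   prior_b_sigma: float = 1.0, n_iter: int = 40):
    """Coordinate MAP for per-session offsets with profiled variance."""
    b = {}
    for src, yv in scr.y.items():
        m = scr.usable[src]
        bs = np.zeros(scr.n_sessions)
        if not m.any():
            b[src] = bs
            continue
        resid0 = yv[m] - pred[m]
        sess = scr.session_of[m]
        counts = np.bincount(sess, minlength=scr.n_sessions).astype(float)
        sums = np.bincount(sess, weights=resid0, minlength=scr.n_sessions)
        s2 = max(float(np.var(resid0)), 1e-8)
        for _ in range(n_iter):
            bs_new = (sums / s2) / (counts / s2 + 1.0 / prior_b_sigma**2)
            bs_new = np.where(counts > 0, bs_new, 0.0)
            resid = resid0 - bs_new[sess]
            s2_new = max(float(np.mean(resid * resid)), 1e-12)
            if np.max(np.abs(bs_new - bs)) < 1e-12 and abs(s2_new - s2) < 1e-14:
                bs, s2 = bs_new, s2_new
                break
            bs, s2 = bs_new, s2_new
        b[src] = bs
    return b


def fit_scr(scr_model: str, trials, subject: str = "?",
            sources: Sequence[str] = ("left",),
            exclusion_source: Optional[str] = None,
            sigma_evolution: float = 0.05, n_starts: int = 4, seed: int = 0,
            tol: float = 1e-6, threshold: float = 0.02,
            max_bad_fraction: float = 0.2,
            scr_data: Optional[ScrData] = None,
            sd: Optional[SubjectData] = None) -> FitResult:
    """Fit an SCR observation model g(x) = Predictor + b to log amplitudes.

    ``scr_model`` is one of ``rw_value``, ``hybrid_value`` or
    ``hybrid_assoc``; the predictor is the model's pre-outcome state
    value or associability, unscaled.  Offsets b are per session and
    per source (bilateral sources are fitted simultaneously against the
    same predictor); noise variance is profiled per source.  Evolution
    priors are N(0, sigma_evolution^2) on the latent scale with
    sigma = 0.05 by default.
    """
    if scr_model not in SCR_MODELS:
        raise ValueError(f"unknown SCR model {scr_model!r}")
    model, key = SCR_MODELS[scr_model]
    if sd is None:
        sd = compile_subject(trials)
    if scr_data is None:
        scr_data = preprocess_scr(trials, threshold=threshold,
                                  max_bad_fraction=max_bad_fraction,
                                  sources=sources,
                                  exclusion_source=exclusion_source)
    n_usable = min(int(scr_data.usable[s].sum()) for s in scr_data.y)
    if n_usable < 4:
        raise ValueError(f"fewer than 4 usable SCR trials for {subject}")

    info = MODEL_INFO[model]
    evo_priors = PriorSpec(
        params=[ParamPrior(name, 0.0, sigma_evolution, kind)
                for name, kind in info.evolution_params],
        n_evolution=len(info.evolution_params))

    def evo_obj(x):
        if not np.all(np.isfinite(x)):
            return _BIG
        native = evo_priors.to_native(np.asarray(x, dtype=float))
        pred = _state_predictor_stream(model, native, sd, key)
        b = _solve_offsets(pred, scr_data)
        return (_scr_profile_nll(pred, scr_data, b)
                + evo_priors.neg_log_prior(np.asarray(x, dtype=float)))

    mres = fit_map(evo_obj, evo_priors, n_starts=n_starts, seed=seed, tol=tol)
    native = evo_priors.to_native(mres.mode)
    pred = _state_predictor_stream(model, native, sd, key)
    b_hat = _solve_offsets(pred, scr_data)
    src_names = list(scr_data.y)
    n_evo = len(evo_priors)

    def full_obj(xfull):
        x = np.asarray(xfull, dtype=float)
        nat = evo_priors.to_native(x[:n_evo])
        p = _state_predictor_stream(model, nat, sd, key)
        b = {}
        off = n_evo
        for s in src_names:
            b[s] = x[off:off + scr_data.n_sessions]
            off += scr_data.n_sessions
        return (_scr_profile_nll(p, scr_data, b)
                + evo_priors.neg_log_prior(x[:n_evo]))

    xfull = np.concatenate([mres.mode] + [b_hat[s] for s in src_names])
    F = laplace_evidence(full_obj, xfull)
    sigma2 = {}
    for s in src_names:
        m = scr_data.usable[s]
        resid = scr_data.y[s][m] - pred[m] - b_hat[s][scr_data.session_of[m]]
        sigma2[s] = float(np.mean(resid**2)) if m.any() else float("nan")
    return FitResult(
        subject=subject, model=scr_model, latent_mode=xfull, native=native,
        taus=None, free_energy=F,
        diagnostics={"nll": mres.fun, "start_funs": mres.start_funs,
                     "converged": mres.success,
                     "exclusions": scr_data.report},
        extras={"b": {s: b_hat[s].tolist() for s in src_names},
                "sigma2": sigma2})
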