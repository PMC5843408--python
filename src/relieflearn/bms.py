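"""Random-effects Bayesian model selection over subjects.

Given a subjects x models matrix of log evidences, a variational
Dirichlet-multinomial scheme estimates the population frequency of each
model, the exceedance probability XP_k (posterior probability that
model k is the most frequent), the Bayes omnibus risk BOR (posterior
probability that all frequencies are equal, i.e. observed differences
are due to chance) and the protected exceedance probability
PXP_k = (1 - BOR) * XP_k + BOR / K.

The variational update with a uniform Dirichlet prior (concentration 1
per model) iterates, until convergence of the concentrations alpha:

    g_nk  ∝ exp( lme_nk + psi(alpha_k) - psi(sum_j alpha_j) )
    alpha = alpha0 + sum_n g_n

BOR is computed from the free energies of the alternative (random
frequencies) and null (fixed equal frequencies) hypotheses:

    F1 = sum_nk g_nk [lme_nk + E ln r_k - ln g_nk]
         + ln B(alpha0) terms - ln B(alpha) terms  (Dirichlet KL)
    F0 = sum_n [ logsumexp_k(lme_nk) - ln K ]      (exact null evidence)
    BOR = 1 / (1 + exp(F1 - F0))
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp

__all__ = ["BMSResult", "rfx_bms", "protected_exceedance", "compare_models"]


@dataclass
class BMSResult:
    """Group-level model-selection summary."""

    models: list
    alpha: np.ndarray  # posterior Dirichlet concentrations
    frequencies: np.ndarray  # E[r_k]
    exceedance: np.ndarray  # XP_k
    bor: float
    protected_exceedance: np.ndarray  # PXP_k
    attributions: Optional[np.ndarray] = None  # subjects x models g_nk
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "models": list(self.models),
            "alpha": self.alpha.tolist(),
            "frequencies": self.frequencies.tolist(),
            "exceedance": self.exceedance.tolist(),
            "bor": self.bor,
            "protected_exceedance": self.protected_exceedance.tolist(),
        }


def _check_evidence(evidence) -> tuple[np.ndarray, list]:
    if isinstance(evidence, pd.DataFrame):
        models = list(evidence.columns)
        lme = evidence.to_numpy(dtype=float)
    else:
        lme = np.asarray(evidence, dtype=float)
        models = [f"m{k + 1}" for k in range(lme.shape[1])]
    if lme.ndim != 2 or lme.shape[1] < 2:
        raise ValueError("evidence must be subjects x (>= 2) models")
    if not np.all(np.isfinite(lme)):
        raise ValueError("evidence matrix contains non-finite entries")
    return lme, models


def _vb_dirichlet(lme: np.ndarray, alpha0: np.ndarray, tol: float = 1e-8,
                  max_iter: int = 10_000):
    n, K = lme.shape
    alpha = alpha0.copy()
    g = np.full((n, K), 1.0 / K)
    for _ in range(max_iter):
        elog_r = digamma(alpha) - digamma(alpha.sum())
        logu = lme + elog_r
        logu -= logu.max(axis=1, keepdims=True)
        g = np.exp(logu)
        g /= g.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    else:
        raise RuntimeError("RFX-BMS did not converge in 10,000 iterations")
    return alpha, g


def _exceedance_mc(alpha: np.ndarray, seed: int, n_samples: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    K = alpha.size
    counts = np.zeros(K)
    # sample in blocks to bound memory
    left = int(n_samples)
    while left > 0:
        block = min(left, 200_000)
        r = rng.dirichlet(alpha, size=block)
        winners = np.argmax(r, axis=1)
        counts += np.bincount(winners, minlength=K)
        left -= block
    return counts / n_samples


def _free_energy_alt(lme: np.ndarray, alpha0: np.ndarray, alpha: np.ndarray,
                     g: np.ndarray) -> float:
    elog_r = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        glng = np.where(g > 0, g * np.log(g), 0.0)
    F = float(np.sum(g * (lme + elog_r)) - np.sum(glng))
    # E_q[ln p(r)] - E_q[ln q(r)]
    F += float(gammaln(alpha0.sum()) - gammaln(alpha0).sum()
               + np.dot(alpha0 - 1.0, elog_r))
    F -= float(gammaln(alpha.sum()) - gammaln(alpha).sum()
               + np.dot(alpha - 1.0, elog_r))
    return F


def _free_energy_null(lme: np.ndarray) -> float:
    n, K = lme.shape
    return float(np.sum(logsumexp(lme, axis=1) - math.log(K)))


def rfx_bms(evidence, seed: int = 0, n_samples: int = 1_000_000,
            alpha0: Optional[np.ndarray] = None, tol: float = 1e-8,
            with_bor: bool = True) -> BMSResult:
    """Random-effects BMS with exceedance and protected exceedance.

    ``evidence`` is a subjects x models array or DataFrame of log
    evidences (free energies for learning models, log likelihoods for
    rating regressions).  XP is estimated by seeded Monte-Carlo sampling
    of the posterior Dirichlet.
    """
    lme, models = _check_evidence(evidence)
    K = lme.shape[1]
    a0 = np.ones(K) if alpha0 is None else np.asarray(alpha0, dtype=float)
    alpha, g = _vb_dirichlet(lme, a0, tol=tol)
    freq = alpha / alpha.sum()
    xp = _exceedance_mc(alpha, seed, n_samples)
    if with_bor:
        F1 = _free_energy_alt(lme, a0, alpha, g)
        F0 = _free_energy_null(lme)
        bor = 1.0 / (1.0 + math.exp(min(F1 - F0, 700.0)))
    else:
        bor = float("nan")
    pxp = (1.0 - bor) * xp + bor / K if with_bor else np.full(K, np.nan)
    return BMSResult(models=models, alpha=alpha, frequencies=freq,
                     exceedance=xp, bor=bor, protected_exceedance=pxp,
                     attributions=g)


def protected_exceedance(evidence, seed: int = 0,
                         n_samples: int = 1_000_000) -> tuple[float, np.ndarray]:
    """Bayes omnibus risk and protected exceedance probabilities."""
    res = rfx_bms(evidence, seed=seed, n_samples=n_samples)
    return res.bor, res.protected_exceedance


def compare_models(fits: dict, seed: int = 0,
                   n_samples: int = 1_000_000) -> tuple[BMSResult, pd.DataFrame]:
    """Assemble an evidence matrix from per-model fit collections and run BMS.

    ``fits`` maps model name -> list of FitResult.  Subjects missing any
    model (failed fits) are dropped listwise.  Returns the BMS result
    plus a per-model parameter summary table (group mean and std of the
    native evolution parameters).
    """
    if len(fits) < 2:
        raise ValueError("model comparison needs at least 2 models")
    per_model = {m: {f.subject: f for f in fl} for m, fl in fits.items()}
    shared = set.intersection(*(set(d) for d in per_model.values()))
    dropped = set.union(*(set(d) for d in per_model.values())) - shared
    if len(shared) < 2:
        raise ValueError("fewer than 2 subjects shared across all models")
    subjects = sorted(shared)
    models = list(fits)
    lme = pd.DataFrame(
        [[per_model[m][s].free_energy for m in models] for s in subjects],
        index=subjects, columns=models)
    res = rfx_bms(lme, seed=seed, n_samples=n_samples)
    res.extras["dropped_subjects"] = sorted(dropped)
    res.extras["evidence"] = lme
    rows = []
    for m in models:
        pnames = sorted({k for s in subjects for k in per_model[m][s].native})
        for p in pnames:
            vals = np.array([per_model[m][s].native[p] for s in subjects])
            rows.append({"model": m, "parameter": p,
                         "mean": float(vals.mean()),
                         "std": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0})
    return res, pd.DataFrame(rows)
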