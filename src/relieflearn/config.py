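"""Pipeline configuration.

Every constant the pipeline uses is explicit in the serialised config:
the static contingencies (0.8/0.2 and 0.6/0.4), the random-walk step
0.1 and bounds [0.2, 0.8], the SCR amplitude threshold 0.02 and 20%
session-exclusion fraction, the 90% identical-ratings exclusion, and
the latent priors (choice fits sigma = 1; SCR evolution sigma = 0.05).
Runs are reproducible from config + data + seeds alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    paradigm: str = "exp2"
    # static paradigm
    exp1_n_sessions: int = 3
    exp1_n_trials: int = 20
    exp1_easy_probs: tuple = (0.8, 0.2)
    exp1_hard_probs: tuple = (0.6, 0.4)
    exp1_rating_trials: tuple = (2, 10, 18)
    # dynamic paradigm
    exp2_n_sessions: int = 8
    exp2_n_trials: int = 24
    walk_step: float = 0.1
    walk_lower: float = 0.2
    walk_upper: float = 0.8
    exp2_ratings_per_session: int = 10
    # cohort
    n_subjects: int = 20
    seed: int = 0
    # fitting
    model_set: tuple = ("td", "hybrid_action", "hmm", "hgf")
    scr_model_set: tuple = ("rw_value", "hybrid_value", "hybrid_assoc")
    rating_predictors: tuple = ("associability", "entropy", "surprise", "none")
    n_starts: int = 8
    fit_tol: float = 1e-6
    per_session_obs: bool = True
    prior_sigma_choice: float = 1.0
    prior_sigma_scr_evolution: float = 0.05
    # exclusions
    scr_amplitude_threshold: float = 0.02
    scr_max_bad_fraction: float = 0.2
    identical_ratings_exclusion: float = 0.9
    # BMS
    bms_n_samples: int = 1_000_000
    # ratings
    rating_intercept_in_fit: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def save_config(cfg: PipelineConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    for k, v in d.items():
        if not hasattr(cfg, k):
            raise ValueError(f"unknown config key {k!r}")
        cur = getattr(cfg, k)
        if isinstance(cur, tuple) and isinstance(v, list):
            v = tuple(v)
        setattr(cfg, k, v)
    return cfg
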