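"""Task paradigms and trial-level data containers.

Two escape-learning paradigms are modelled. In the static paradigm
("exp1") subjects under tonic thermal pain see one of two fractal cues
per trial and choose a left/right button press; one cue carries 80/20
relief contingencies over the two actions ("easy"), the other 60/40
("hard").  Instrumental sessions alternate with yoked Pavlovian
sessions that replay the cue/outcome sequence with instructed presses.
In the dynamic paradigm ("exp2") three cues are shown simultaneously
and each cue's relief probability follows an independent bounded random
walk, forcing continual exploration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

PARADIGMS = ("exp1_instrumental", "exp1_pavlovian", "exp2")

EXP1_ACTIONS = ("left", "right")
EXP1_CUES = ("easy", "hard")
EXP2_CUES = ("A", "B", "C")


@dataclass(frozen=True)
class TaskConfig:
    """Paradigm definition: contingencies or walk parameters plus schedule.

    ``contingency`` maps ``(cue, action) -> relief probability`` for the
    static paradigm; ``walk_params`` holds the random-walk step and bounds
    for the dynamic paradigm.  ``rating_schedule`` lists 1-based trial
    indices (per session) on which a 0-10 rating is collected: post-outcome
    for exp1 (pain after no-relief, relief after relief), pre-outcome pain
    for exp2.  ``relief_duration_s`` is metadata only.
    """

    paradigm: str
    n_sessions: int
    n_trials_per_session: int
    contingency: Optional[dict] = None
    walk_params: Optional[dict] = None
    rating_schedule: tuple = ()
    n_ratings_per_session: int = 0
    relief_duration_s: float = 4.0

    def __post_init__(self):
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.n_sessions < 1 or self.n_trials_per_session < 1:
            raise ValueError("session/trial counts must be >= 1")
        if self.contingency is not None:
            for key, p in self.contingency.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"contingency {key} = {p} outside [0, 1]")
        if self.walk_params is not None:
            lo, hi = self.walk_params["lower"], self.walk_params["upper"]
            if not 0.0 < lo < hi < 1.0:
                raise ValueError("walk bounds must satisfy 0 < lower < upper < 1")

    @property
    def cues(self) -> tuple:
        return EXP1_CUES if self.paradigm.startswith("exp1") else EXP2_CUES


@dataclass
class TrialRecord:
    """One trial of one subject.

    ``outcome`` is binary relief (1 = relief, 0 = no relief).  SCR
    amplitudes are raw (non-negative) trial amplitudes; ``rating`` is a
    0-10 value present only on scheduled trials.
    """

    subject: str
    paradigm: str
    session: int  # 1-based
    trial: int  # 1-based within session
    cues_shown: tuple
    chosen: str
    outcome: int
    scr_left: Optional[float] = None
    scr_right: Optional[float] = None
    rating: Optional[float] = None
    rating_type: Optional[str] = None

    def __post_init__(self):
        if self.outcome not in (0, 1):
            raise ValueError(f"outcome must be 0/1, got {self.outcome!r}")
        if self.paradigm.startswith("exp1"):
            if self.chosen not in EXP1_ACTIONS:
                raise ValueError(f"exp1 chosen must be left/right, got {self.chosen!r}")
        elif self.chosen not in self.cues_shown:
            raise ValueError(f"chosen {self.chosen!r} not among cues {self.cues_shown}")
        if self.rating is not None and not 0.0 <= self.rating <= 10.0:
            raise ValueError(f"rating {self.rating} outside [0, 10]")

    @property
    def cue(self) -> str:
        """The single cue (exp1) or the chosen cue (exp2)."""
        if self.paradigm.startswith("exp1"):
            return self.cues_shown[0]
        return self.chosen


def make_exp1_config(n_sessions: int = 3, n_trials: int = 20,
                     rating_trials: Sequence[int] = (2, 10, 18),
                     instrumental: bool = True) -> TaskConfig:
    """Static-contingency escape task: 2 cues x 2 actions.

    The "easy" cue gives 80% relief for one press and 20% for the other;
    the "hard" cue gives 60%/40%.  Each session presents equal numbers of
    easy and hard cue trials, and 3 post-outcome ratings are scheduled
    near the beginning, middle and end of the session.
    """
    if n_sessions < 1 or n_trials < 1:
        raise ValueError("counts must be >= 1")
    contingency = {
        ("easy", "left"): 0.8, ("easy", "right"): 0.2,
        ("hard", "left"): 0.6, ("hard", "right"): 0.4,
    }
    rating_trials = tuple(t for t in rating_trials if 1 <= t <= n_trials)
    return TaskConfig(
        paradigm="exp1_instrumental" if instrumental else "exp1_pavlovian",
        n_sessions=n_sessions,
        n_trials_per_session=n_trials,
        contingency=contingency,
        rating_schedule=rating_trials,
        n_ratings_per_session=len(rating_trials),
        relief_duration_s=4.0,
    )


def make_exp2_config(n_sessions: int = 8, n_trials: int = 24,
                     step: float = 0.1, lower: float = 0.2, upper: float = 0.8,
                     n_ratings_per_session: int = 10) -> TaskConfig:
    """Dynamic-contingency escape task: 3 cues, random-walk relief probabilities.

    Relief probabilities change with step size 0.1 and are bounded
    between 0.2 and 0.8; 10 pre-outcome pain ratings are collected in
    random trials per 24-trial session (schedule drawn at simulation
    time from the subject's seed).
    """
    return TaskConfig(
        paradigm="exp2",
        n_sessions=n_sessions,
        n_trials_per_session=n_trials,
        walk_params={"step": step, "lower": lower, "upper": upper},
        n_ratings_per_session=n_ratings_per_session,
        relief_duration_s=3.0,
    )


def make_exp2_walk(n_trials_total: int, step: float = 0.1,
                   lower: float = 0.2, upper: float = 0.8,
                   seed: int = 0, n_cues: int = 3) -> np.ndarray:
    """Bounded random-walk relief-probability traces, one row per cue.

    Each trace starts uniformly at random in [lower, upper] and moves
    +-step once per trial; a proposal beyond a bound is clipped to the
    bound.  Returns an (n_cues, n_trials_total) array.
    """
    if not lower < upper:
        raise ValueError("lower must be < upper")
    if step < 0:
        raise ValueError("step must be >= 0")
    if step > upper - lower:
        raise ValueError("step larger than the bound range")
    rng = np.random.default_rng(seed)
    traces = np.empty((n_cues, n_trials_total))
    p = rng.uniform(lower, upper, size=n_cues)
    for t in range(n_trials_total):
        traces[:, t] = p
        if t < n_trials_total - 1:
            moves = rng.choice([-step, step], size=n_cues)
            p = np.clip(p + moves, lower, upper)
    return traces


def yoke_pavlovian(instrumental: Sequence[TrialRecord],
                   seed: int = 0) -> list[TrialRecord]:
    """Yoke a Pavlovian session to an instrumental one.

    The cue and outcome sequences are copied element-wise; actions are
    replaced by instructed (random-arrow) presses carrying no
    contingency, and the paradigm is relabelled.
    """
    out = []
    rng = np.random.default_rng(seed)
    for rec in instrumental:
        if rec.paradigm != "exp1_instrumental":
            raise ValueError("yoking requires an exp1 instrumental session")
        out.append(replace(
            rec,
            paradigm="exp1_pavlovian",
            chosen=EXP1_ACTIONS[rng.integers(2)],
            scr_left=None, scr_right=None, rating=None, rating_type=None,
        ))
    return out
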