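"""Probabilistic reward/punishment categorisation task.

Four visual stimuli are each mapped to one of two responses (A or B).  Two
stimuli (I1, I2) probe reward learning: the optimal response pays +25 points
with probability 0.8 and nothing otherwise, while the non-optimal response
pays +25 with probability only 0.2.  The other two stimuli (I3, I4) probe
punishment learning: the optimal response loses -25 points with probability
only 0.2, the non-optimal one with probability 0.8.  A session is 160 trials
with each stimulus shown equally often in a seeded pseudorandom order.

The model consumes rewards on the unit scale r in {-1, 0, +1}; the mapping
from points lives here so that empirical and simulated records share units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

STIMULI = ("I1", "I2", "I3", "I4")
RESPONSES = ("A", "B")
GROUPS = ("HC", "PD-ON-ICD", "PD-ON-nonICD", "PD-OFF")

#: points -> unit reward consumed by the learning rules
POINTS_TO_REWARD = {25: 1.0, 0: 0.0, -25: -1.0}

_DEFAULT_OPTIMAL = {"I1": "A", "I2": "B", "I3": "A", "I4": "B"}


def _default_schedule() -> dict:
    """Outcome schedule: (stimulus, response) -> [(points, probability), ...]."""
    sched = {}
    for stim in ("I1", "I2"):  # reward stimuli
        opt = _DEFAULT_OPTIMAL[stim]
        for resp in RESPONSES:
            p_win = 0.8 if resp == opt else 0.2
            sched[(stim, resp)] = [(25, p_win), (0, 1.0 - p_win)]
    for stim in ("I3", "I4"):  # punishment stimuli
        opt = _DEFAULT_OPTIMAL[stim]
        for resp in RESPONSES:
            p_loss = 0.2 if resp == opt else 0.8
            sched[(stim, resp)] = [(-25, p_loss), (0, 1.0 - p_loss)]
    return sched


@dataclass
class TaskConfig:
    """Task structure: stimuli, responses, optimal map and outcome schedule."""

    stimuli: tuple = STIMULI
    responses: tuple = RESPONSES
    optimal_map: dict = field(default_factory=lambda: dict(_DEFAULT_OPTIMAL))
    schedule: dict = field(default_factory=_default_schedule)
    n_trials: int = 160

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for stim in self.stimuli:
            if stim not in self.optimal_map:
                raise ValueError(f"stimulus {stim!r} missing from optimal_map")
            if self.optimal_map[stim] not in self.responses:
                raise ValueError(f"optimal response for {stim!r} not a known response")
            for resp in self.responses:
                key = (stim, resp)
                if key not in self.schedule:
                    raise ValueError(f"schedule missing entry for {key}")
                pairs = self.schedule[key]
                total = sum(p for _, p in pairs)
                if not np.isclose(total, 1.0):
                    raise ValueError(f"probabilities for {key} sum to {total}, not 1")
                for points, p in pairs:
                    if points not in POINTS_TO_REWARD:
                        raise ValueError(f"illegal points value {points} for {key}")
                    if p < 0:
                        raise ValueError(f"negative probability for {key}")

    # -- convenience ------------------------------------------------------
    @property
    def reward_stimuli(self) -> tuple:
        """Stimuli whose outcome support contains positive points."""
        out = []
        for stim in self.stimuli:
            pts = {pt for resp in self.responses for pt, p in self.schedule[(stim, resp)] if p > 0}
            if any(pt > 0 for pt in pts):
                out.append(stim)
        return tuple(out)

    @property
    def punishment_stimuli(self) -> tuple:
        out = []
        for stim in self.stimuli:
            pts = {pt for resp in self.responses for pt, p in self.schedule[(stim, resp)] if p > 0}
            if any(pt < 0 for pt in pts):
                out.append(stim)
        return tuple(out)

    def stimulus_index(self, stimulus: str) -> int:
        try:
            return self.stimuli.index(stimulus)
        except ValueError:
            raise KeyError(f"unknown stimulus {stimulus!r}") from None

    def response_index(self, response: str) -> int:
        try:
            return self.responses.index(response)
        except ValueError:
            raise KeyError(f"unknown response {response!r}") from None

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "stimuli": list(self.stimuli),
            "responses": list(self.responses),
            "optimal_map": dict(self.optimal_map),
            "schedule": {
                f"{s}/{r}": [[int(pt), float(p)] for pt, p in pairs]
                for (s, r), pairs in self.schedule.items()
            },
            "n_trials": int(self.n_trials),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        sched = {}
        for key, pairs in d["schedule"].items():
            s, r = key.split("/")
            sched[(s, r)] = [(int(pt), float(p)) for pt, p in pairs]
        return cls(
            stimuli=tuple(d["stimuli"]),
            responses=tuple(d["responses"]),
            optimal_map=dict(d["optimal_map"]),
            schedule=sched,
            n_trials=int(d["n_trials"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "TaskConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class TrialRecord:
    """One trial of behavioural data, empirical or simulated."""

    subject_id: str
    group: str
    trial_index: int
    stimulus: str
    response: str
    optimal: bool
    points: int
    rt_ms: Optional[float] = None  # None for purely accuracy-level data

    def __post_init__(self) -> None:
        if self.rt_ms is not None and not np.isnan(self.rt_ms) and self.rt_ms < 0:
            raise ValueError("rt_ms must be non-negative")


def generate_trial_sequence(config: TaskConfig, seed: int) -> list:
    """Balanced seeded pseudorandom stimulus order.

    Each stimulus appears exactly ``n_trials / n_stimuli`` times; the order is
    a seeded permutation, so the same seed always yields the same sequence.
    """
    n_stim = len(config.stimuli)
    if config.n_trials % n_stim != 0:
        raise ValueError(
            f"n_trials={config.n_trials} not divisible by {n_stim} stimuli"
        )
    reps = config.n_trials // n_stim
    seq = np.repeat(np.arange(n_stim), reps)
    rng = np.random.default_rng(seed)
    rng.shuffle(seq)
    return [config.stimuli[i] for i in seq]


def sample_outcome(
    config: TaskConfig, stimulus: str, response: str, rng: np.random.Generator
) -> int:
    """Draw the points outcome for (stimulus, response) from the schedule."""
    if stimulus not in config.stimuli:
        raise KeyError(f"unknown stimulus {stimulus!r}")
    if response not in config.responses:
        raise KeyError(f"unknown response {response!r}")
    pairs = config.schedule[(stimulus, response)]
    u = rng.random()
    acc = 0.0
    for points, p in pairs:
        acc += p
        if u < acc:
            return points
    return pairs[-1][0]  # guard against floating-point shortfall


def points_to_reward(points: int) -> float:
    """Map task points to the unit reward scale used by the model."""
    try:
        return POINTS_TO_REWARD[points]
    except KeyError:
        raise ValueError(f"points {points} not on the task scale") from None
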