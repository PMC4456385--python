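"""Canonical behavioural CSV and synthetic cohort generation.

The canonical trial-record schema has the columns
``subject_id, group, trial_index, stimulus, response, optimal, points,
rt_ms`` with a 0-based trial index, RT in milliseconds (empty when absent)
and the group labels HC, PD-ON-ICD, PD-ON-nonICD, PD-OFF.  Deposited
datasets in other layouts are mapped onto this schema by a one-off adapter
before analysis.

The synthetic cohort generator emulates the structure of the empirical
study — four groups of the published sizes performing 160 trials — from a
per-group profile of optimality and RT distributions, so every downstream
analysis is testable without any download.  Profile defaults are the
package's stand-in for the clinical cohort: group sizes are the published
ones; optimality and RT levels are chosen to express the qualitative group
pattern (reward optimality highest in PD-ON-ICD, punishment optimality
highest in PD-OFF, RT shortest in PD-OFF and longest in PD-ON-nonICD) at
within-group spreads typical of such studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .task import GROUPS, TaskConfig, TrialRecord, generate_trial_sequence, sample_outcome

CSV_COLUMNS = [
    "subject_id",
    "group",
    "trial_index",
    "stimulus",
    "response",
    "optimal",
    "points",
    "rt_ms",
]


def write_behavior_csv(records, path) -> None:
    """Write trial records in the canonical column order (stable output)."""
    rows = [
        {
            "subject_id": r.subject_id,
            "group": r.group,
            "trial_index": r.trial_index,
            "stimulus": r.stimulus,
            "response": r.response,
            "optimal": bool(r.optimal),
            "points": r.points,
            "rt_ms": "" if r.rt_ms is None or np.isnan(r.rt_ms) else repr(float(r.rt_ms)),
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    df.to_csv(path, index=False)


def load_behavior_csv(path, task: TaskConfig | None = None) -> list:
    """Read and validate canonical trial records; errors name the CSV row."""
    task = task or TaskConfig()
    df = pd.read_csv(path, dtype={"rt_ms": float})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    records = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        stim, resp = row.stimulus, row.response
        if stim not in task.stimuli:
            raise ValueError(f"row {pos}: unknown stimulus {stim!r}")
        if resp not in task.responses:
            raise ValueError(f"row {pos}: unknown response {resp!r}")
        rt = None if pd.isna(row.rt_ms) else float(row.rt_ms)
        if rt is not None and rt < 0:
            raise ValueError(f"row {pos}: negative rt_ms")
        optimal = bool(row.optimal)
        if optimal != (resp == task.optimal_map[stim]):
            raise ValueError(f"row {pos}: optimal flag inconsistent with optimal map")
        records.append(
            TrialRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                trial_index=int(row.trial_index),
                stimulus=stim,
                response=resp,
                optimal=optimal,
                points=int(row.points),
                rt_ms=rt,
            )
        )
    return records


@dataclass
class GroupProfile:
    """Latent per-subject distributions for one group."""

    n_subjects: int
    reward_optimality: tuple  # (mean, sd) of per-subject proportion, in [0, 1]
    punishment_optimality: tuple
    rt_ms: tuple  # (mean, sd) of per-subject mean RT
    rt_outlier_rate: float = 0.0  # chance of an inflated-RT subject

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        for name in ("reward_optimality", "punishment_optimality"):
            mean, sd = getattr(self, name)
            if not (0.0 <= mean <= 1.0) or sd < 0:
                raise ValueError(f"invalid {name} profile ({mean}, {sd})")
        if self.rt_ms[0] <= 0 or self.rt_ms[1] < 0:
            raise ValueError("invalid rt_ms profile")
        if not (0.0 <= self.rt_outlier_rate <= 1.0):
            raise ValueError("rt_outlier_rate must be a probability")


@dataclass
class CohortProfile:
    """Per-group latent profiles keyed by group label."""

    groups: dict = field(default_factory=dict)

    @classmethod
    def default(cls) -> "CohortProfile":
        """Stand-in for the empirical cohort (synthetic; see module docstring)."""
        return cls(
            groups={
                "HC": GroupProfile(20, (0.75, 0.12), (0.75, 0.12), (600.0, 35.0), 0.05),
                "PD-ON-ICD": GroupProfile(16, (0.85, 0.10), (0.60, 0.13), (595.0, 35.0), 0.05),
                "PD-ON-nonICD": GroupProfile(14, (0.70, 0.12), (0.70, 0.12), (650.0, 35.0), 0.05),
                "PD-OFF": GroupProfile(26, (0.55, 0.13), (0.82, 0.10), (560.0, 35.0), 0.05),
            }
        )

    def to_dict(self) -> dict:
        return {
            g: {
                "n_subjects": p.n_subjects,
                "reward_optimality": list(p.reward_optimality),
                "punishment_optimality": list(p.punishment_optimality),
                "rt_ms": list(p.rt_ms),
                "rt_outlier_rate": p.rt_outlier_rate,
            }
            for g, p in self.groups.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortProfile":
        return cls(
            groups={
                g: GroupProfile(
                    n_subjects=int(v["n_subjects"]),
                    reward_optimality=tuple(v["reward_optimality"]),
                    punishment_optimality=tuple(v["punishment_optimality"]),
                    rt_ms=tuple(v["rt_ms"]),
                    rt_outlier_rate=float(v.get("rt_outlier_rate", 0.0)),
                )
                for g, v in d.items()
            }
        )


def _truncnorm01(mean: float, sd: float, rng: np.random.Generator) -> float:
    if sd == 0:
        return mean
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return float(sps.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def synthesize_cohort(
    profile: CohortProfile | None = None,
    task: TaskConfig | None = None,
    seed: int = 0,
) -> list:
    """Generate trial records for a full synthetic cohort.

    Each subject draws a latent optimality per valence (truncated normal on
    [0, 1]) and responds optimally with that probability on every trial of
    the matching valence; outcomes follow the task schedule.  Trial RTs are
    lognormal around a subject-level mean drawn from the group profile;
    with probability ``rt_outlier_rate`` a subject's RT level is inflated,
    emulating the occasional slow responder that outlier screening removes.
    """
    profile = profile or CohortProfile.default()
    task = task or TaskConfig()
    rng = np.random.default_rng(seed)
    rew = set(task.reward_stimuli)
    records = []
    for group, gp in profile.groups.items():
        for j in range(gp.n_subjects):
            sid = f"{group}-e{j:02d}"
            p_rew = _truncnorm01(*gp.reward_optimality, rng)
            p_pun = _truncnorm01(*gp.punishment_optimality, rng)
            rt_mean = max(float(rng.normal(*gp.rt_ms)), 1.0)
            if rng.random() < gp.rt_outlier_rate:
                rt_mean *= 1.0 + rng.uniform(0.5, 1.5)
            seq_seed = int(rng.integers(0, 2**31 - 1))
            sequence = generate_trial_sequence(task, seq_seed)
            # lognormal with the subject's mean and a fixed within-subject CV
            cv = 0.25
            sigma = np.sqrt(np.log(1.0 + cv**2))
            mu = np.log(rt_mean) - sigma**2 / 2.0
            for t, stim in enumerate(sequence):
                p_opt = p_rew if stim in rew else p_pun
                optimal = rng.random() < p_opt
                opt_resp = task.optimal_map[stim]
                if optimal:
                    resp = opt_resp
                else:
                    resp = next(r for r in task.responses if r != opt_resp)
                points = sample_outcome(task, stim, resp, rng)
                rt = float(rng.lognormal(mu, sigma))
                records.append(
                    TrialRecord(
                        subject_id=sid,
                        group=group,
                        trial_index=t,
                        stimulus=stim,
                        response=resp,
                        optimal=optimal,
                        points=points,
                        rt_ms=rt,
                    )
                )
    return records
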