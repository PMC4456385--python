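"""Behavioural statistics applied identically to empirical and simulated data.

Per subject: proportions of optimal responding to reward stimuli (I1/I2) and
punishment stimuli (I3/I4), and the mean reaction time over trials where an
RT was recorded.  Group comparisons use a fixed-effects one-way ANOVA on the
per-subject summaries, preceded (for RT) by iterative two-sided Grubbs
outlier removal, and followed by pairwise two-tailed t-tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from .task import TaskConfig


@dataclass
class SubjectSummary:
    subject_id: str
    group: str
    reward_optimality: float
    punishment_optimality: float
    mean_rt_ms: Optional[float]


@dataclass
class AnovaResult:
    """One-way fixed-effects decomposition with all the usual table columns."""

    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    df_total: int
    ms_between: float
    ms_within: float
    F: float
    p: float
    f_crit: float

    def to_dict(self) -> dict:
        return {
            "SS_between": self.ss_between,
            "SS_within": self.ss_within,
            "SS_total": self.ss_total,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "df_total": self.df_total,
            "MS_between": self.ms_between,
            "MS_within": self.ms_within,
            "F": self.F,
            "p": self.p,
            "F_crit": self.f_crit,
        }


def summarize_subject(records, task: Optional[TaskConfig] = None) -> SubjectSummary:
    """Collapse one subject's trial records to the three per-subject measures."""
    if not records:
        raise ValueError("no records")
    ids = {r.subject_id for r in records}
    if len(ids) != 1:
        raise ValueError(f"records mix subjects: {sorted(ids)}")
    task = task or TaskConfig()
    rew = set(task.reward_stimuli)
    pun = set(task.punishment_stimuli)
    rew_ok = [r.optimal for r in records if r.stimulus in rew]
    pun_ok = [r.optimal for r in records if r.stimulus in pun]
    rts = [r.rt_ms for r in records if r.rt_ms is not None and not np.isnan(r.rt_ms)]
    return SubjectSummary(
        subject_id=records[0].subject_id,
        group=records[0].group,
        reward_optimality=float(np.mean(rew_ok)) if rew_ok else np.nan,
        punishment_optimality=float(np.mean(pun_ok)) if pun_ok else np.nan,
        mean_rt_ms=float(np.mean(rts)) if rts else None,
    )


def summarize_cohort(records, task: Optional[TaskConfig] = None) -> list:
    """Per-subject summaries for a mixed-subject record collection."""
    by_subject: dict = {}
    for r in records:
        by_subject.setdefault(r.subject_id, []).append(r)
    return [summarize_subject(recs, task) for recs in by_subject.values()]


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value at level alpha for sample size n."""
    if n < 3:
        return np.inf
    t2 = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2) ** 2
    return (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))


def grubbs_iterative(values, alpha: float = 0.05) -> tuple:
    """Repeated two-sided Grubbs test; returns (retained, removed).

    The statistic G = max|x - mean| / sd is compared with the critical value
    at ``alpha``; the most extreme point is removed while significant,
    stopping when nothing is significant, fewer than 3 points remain, or the
    sample is constant (sd = 0 treated as outlier-free).
    """
    retained = [float(v) for v in values]
    removed: list = []
    if len(retained) < 3:
        warnings.warn("fewer than 3 values: Grubbs test not applicable", stacklevel=2)
        return retained, removed
    while len(retained) >= 3:
        arr = np.asarray(retained)
        sd = arr.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(arr - arr.mean())
        idx = int(np.argmax(dev))
        g = dev[idx] / sd
        if g > grubbs_critical(len(arr), alpha):
            removed.append(retained.pop(idx))
        else:
            break
    return retained, removed


def one_way_anova(groups) -> AnovaResult:
    """Standard fixed-effects one-way decomposition over k groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(groups):
        if g.size < 1:
            raise ValueError(f"group {i} is empty")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ss_total = ((all_vals - grand) ** 2).sum()
    k, n = len(groups), all_vals.size
    df_b, df_w = k - 1, n - k
    if df_w < 1:
        raise ValueError("no within-group degrees of freedom")
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    f = ms_b / ms_w if ms_w > 0 else np.inf
    return AnovaResult(
        ss_between=float(ss_between),
        ss_within=float(ss_within),
        ss_total=float(ss_total),
        df_between=df_b,
        df_within=df_w,
        df_total=n - 1,
        ms_between=float(ms_b),
        ms_within=float(ms_w),
        F=float(f),
        p=float(sps.f.sf(f, df_b, df_w)),
        f_crit=float(sps.f.ppf(0.95, df_b, df_w)),
    )


def anova_from_table(
    ss_between: float, ss_within: float, df_between: int, df_within: int
) -> AnovaResult:
    """Rebuild a full one-way ANOVA row from its sums of squares and df.

    Useful for checking the internal consistency of a published ANOVA table:
    mean squares, F, p and the critical F are all recomputed from the four
    quantities that determine them.
    """
    ms_b = ss_between / df_between
    ms_w = ss_within / df_within
    f = ms_b / ms_w
    return AnovaResult(
        ss_between=float(ss_between),
        ss_within=float(ss_within),
        ss_total=float(ss_between + ss_within),
        df_between=int(df_between),
        df_within=int(df_within),
        df_total=int(df_between + df_within),
        ms_between=float(ms_b),
        ms_within=float(ms_w),
        F=float(f),
        p=float(sps.f.sf(f, df_between, df_within)),
        f_crit=float(sps.f.ppf(0.95, df_between, df_within)),
    )


def posthoc_ttests(groups: dict, equal_var: bool = True) -> dict:
    """Pairwise two-tailed two-sample t-tests.

    Pooled-variance (Student) form by default; ``equal_var=False`` switches
    to Welch.  Returns {(label_a, label_b): (t, p)}; a pair where both
    groups are degenerate (zero variance and equal means handled by t = 0)
    with zero pooled variance yields p = nan and a warning.
    """
    labels = list(groups)
    for lab in labels:
        if len(groups[lab]) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 values")
    out = {}
    for a, b in itertools.combinations(labels, 2):
        xa = np.asarray(groups[a], dtype=float)
        xb = np.asarray(groups[b], dtype=float)
        if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
            if xa.mean() == xb.mean():
                out[(a, b)] = (0.0, 1.0)
            else:
                warnings.warn(f"degenerate variances for pair ({a}, {b})", stacklevel=2)
                out[(a, b)] = (np.nan, np.nan)
            continue
        t, p = sps.ttest_ind(xa, xb, equal_var=equal_var)
        out[(a, b)] = (float(t), float(p))
    return out


def group_anova(
    summaries,
    measure: str,
    grubbs_alpha: Optional[float] = None,
    group_order=None,
) -> tuple:
    """ANOVA over per-subject summaries for one measure.

    ``measure`` is one of ``reward_optimality``, ``punishment_optimality``
    (analysed on the percentage scale) or ``mean_rt_ms``.  When
    ``grubbs_alpha`` is given, iterative Grubbs removal is applied within
    each group before the decomposition (the convention for RT).  Returns
    (AnovaResult, {group: values used}).
    """
    by_group: dict = {}
    for s in summaries:
        val = getattr(s, measure)
        if val is None or (isinstance(val, float) and np.isnan(val)):
            continue
        if measure in ("reward_optimality", "punishment_optimality"):
            val = 100.0 * val
        by_group.setdefault(s.group, []).append(float(val))
    if group_order is not None:
        by_group = {g: by_group[g] for g in group_order if g in by_group}
    if grubbs_alpha is not None:
        by_group = {g: grubbs_iterative(v, grubbs_alpha)[0] for g, v in by_group.items()}
    result = one_way_anova(list(by_group.values()))
    return result, by_group
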