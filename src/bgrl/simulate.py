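"""Per-trial pipeline and session/group runners.

Each trial runs the full loop: read out the striatal responses for the
current stimulus, form per-action utilities, compute the utility-difference
dopamine signal, gate the direct and indirect pathway drives, race the
thalamic integrators to threshold (choice + reaction time), sample the
outcome, and update the cortico-striatal weights through the
dopamine-conditioned TD error.

Two equivalent execution paths are provided: :func:`run_trial` /
:func:`run_session` (readable, one subject at a time) and a vectorised
engine used by :func:`run_group` that advances many independent session
instances in lockstep.  Both consume the per-instance random streams in the
same order (circuit initial noise, then the outcome draw), so a group run
reproduces the single-session results seed for seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .circuit import CircuitParams, SelectionResult, random_state, select_action
from .striatum import (
    LEARNING_GAINS,
    SELECTION_GAINS,
    StriatalWeights,
    SubjectCondition,
    UtilityTrace,
    apply_da_condition,
    compute_utility,
    gain,
    td_error,
    update_weights,
    utility_difference,
)
from .task import TaskConfig, TrialRecord, generate_trial_sequence, points_to_reward, sample_outcome


@dataclass(frozen=True)
class SimOptions:
    """Pipeline switches that the model description leaves open.

    delta_u_mode
        "max": the dopamine burst anticipates the best available option --
        the utility difference uses the maximum-utility candidate of the
        current trial (default).  "chosen": the signal realised at the
        previous selection (utility of the chosen action minus its
        predecessor) gates the current trial.
    u_prev_mode
        "stored": the previous utility is the scalar realised at the last
        selection (default).  "reevaluate": the previous action is re-scored
        in the current state with current weights.
    risk_transform
        "linear" (as the utility is written here) or "sqrt" (the precursor
        lumped model's convention).
    uncrossed_rt
        "deadline": a trial whose race never crosses the threshold is a
        response at the iteration cap and contributes that RT (default).
        "missing": such trials carry no RT and drop out of RT averages.
    weight_bound
        Saturation bound b on cortico-striatal weights (clipped to [-b, b]
        after each update); None disables saturation.
    ms_per_iter
        Linear scale from race iterations to milliseconds; presentation
        only.
    """

    delta_u_mode: str = "max"
    u_prev_mode: str = "stored"
    risk_transform: str = "linear"
    uncrossed_rt: str = "deadline"
    weight_bound: Optional[float] = None
    ms_per_iter: float = 1.0

    def __post_init__(self) -> None:
        if self.delta_u_mode not in ("max", "chosen"):
            raise ValueError("delta_u_mode must be 'max' or 'chosen'")
        if self.u_prev_mode not in ("stored", "reevaluate"):
            raise ValueError("u_prev_mode must be 'stored' or 'reevaluate'")
        if self.uncrossed_rt not in ("deadline", "missing"):
            raise ValueError("uncrossed_rt must be 'deadline' or 'missing'")


def task_circuit_params(**overrides) -> CircuitParams:
    """Circuit parameters used for the behavioural simulations.

    The thalamic units run as pure accumulators (leak 0, unit step): the
    cortico-striatal weights learned over a 160-trial session keep the
    pathway drives well below the selection threshold, which a leaky
    integrator (asymptote = drive) could then never reach.  Accumulation
    preserves the race semantics and puts reaction times in the
    tens-to-hundreds of iterations.
    """
    kw = dict(thal_leak=0.0, dt_thal=1.0)
    kw.update(overrides)
    return CircuitParams(**kw)


@dataclass
class _Trace(UtilityTrace):
    """Session-carried trace; extends the scalar trace with the last action."""

    prev_action: Optional[int] = None


@dataclass
class SessionResult:
    records: list
    final_weights: StriatalWeights
    seed: int
    condition: SubjectCondition


@dataclass
class GroupSummary:
    """Across-instance aggregate of one simulated cohort."""

    group: str
    n_instances: int
    reward_optimality: float  # mean of per-instance proportions on I1/I2
    reward_optimality_sd: float
    punishment_optimality: float
    punishment_optimality_sd: float
    mean_rt_ms: float  # across instances, non-crossing trials excluded
    mean_rt_ms_sd: float
    rt_by_trial: np.ndarray  # per-trial mean RT over instances (ms)
    per_instance: dict = field(default_factory=dict)  # arrays keyed by measure


# ---------------------------------------------------------------------------
# scalar reference path
# ---------------------------------------------------------------------------

def _pathway_drives(y1, y2, y12, delta_u, cond: SubjectCondition):
    """Direct and indirect pathway drives for all candidate actions."""
    lam1 = gain("D1", delta_u, SELECTION_GAINS)
    lam2 = gain("D2", delta_u, SELECTION_GAINS)
    lam12 = gain("D1D2", delta_u, SELECTION_GAINS)
    x_dp = cond.alpha_d1 * lam1 * y1
    x_ip = cond.alpha_d2 * lam2 * y2 + cond.alpha_d1d2 * np.sign(y1) * lam12 * y12
    return x_dp, x_ip


def run_trial(
    weights: StriatalWeights,
    cond: SubjectCondition,
    task: TaskConfig,
    circuit_params: CircuitParams,
    trace: _Trace,
    stimulus: str,
    rng: np.random.Generator,
    options: SimOptions = SimOptions(),
    trial_index: int = 0,
    subject_id: str = "sim",
) -> tuple:
    """One full trial; returns (TrialRecord, new weights, new trace)."""
    s = task.stimulus_index(stimulus)
    y1 = weights.w_d1[s].copy()
    y2 = weights.w_d2[s].copy()
    y12 = weights.w_d1d2[s].copy()
    q, h = y1, y12
    u = compute_utility(q, h, cond.alpha_d1d2, options.risk_transform)

    if options.delta_u_mode == "max":
        if options.u_prev_mode == "reevaluate" and trace.prev_action is not None:
            u_prev = float(u[trace.prev_action])
        else:
            u_prev = trace.u_prev
        delta_u = utility_difference(float(np.max(u)), u_prev)
    else:  # realised at the previous selection
        delta_u = trace.delta_u

    x_dp, x_ip = _pathway_drives(y1, y2, y12, delta_u, cond)
    sel: SelectionResult = select_action(x_dp, x_ip, circuit_params, rng=rng)
    a = sel.action
    response = task.responses[a]

    points = sample_outcome(task, stimulus, response, rng)
    r = points_to_reward(points)
    delta = apply_da_condition(td_error(r, float(q[a])), cond)
    new_weights = update_weights(weights, s, a, delta, cond, LEARNING_GAINS)
    if options.weight_bound is not None:
        b = options.weight_bound
        for w in (new_weights.w_d1, new_weights.w_d2, new_weights.w_d1d2):
            np.clip(w, -b, b, out=w)

    new_trace = _Trace(
        u_prev=float(u[a]),
        delta_u=utility_difference(float(u[a]), trace.u_prev),
        prev_action=a,
    )
    record = TrialRecord(
        subject_id=subject_id,
        group=cond.group,
        trial_index=trial_index,
        stimulus=stimulus,
        response=response,
        optimal=(response == task.optimal_map[stimulus]),
        points=points,
        rt_ms=(
            sel.rt_iters * options.ms_per_iter
            if (sel.crossed or options.uncrossed_rt == "deadline")
            else None
        ),
    )
    return record, new_weights, new_trace


def _session_streams(seed: int):
    """Derive the sequence seed and the trial-level generator from one seed."""
    ss = np.random.SeedSequence(seed)
    seq_ss, trial_ss = ss.spawn(2)
    seq_seed = int(seq_ss.generate_state(1)[0])
    return seq_seed, np.random.default_rng(trial_ss)


def run_session(
    cond: SubjectCondition,
    task: TaskConfig,
    circuit_params: CircuitParams,
    seed: int,
    options: SimOptions = SimOptions(),
    subject_id: Optional[str] = None,
) -> SessionResult:
    """One simulated subject: a full trial sequence with carried weights."""
    seq_seed, rng = _session_streams(seed)
    sequence = generate_trial_sequence(task, seq_seed) if task.n_trials else []
    weights = StriatalWeights(n_states=len(task.stimuli), n_actions=len(task.responses))
    trace = _Trace()
    sid = subject_id if subject_id is not None else f"{cond.group}-s{seed}"
    records = []
    for t, stim in enumerate(sequence):
        rec, weights, trace = run_trial(
            weights, cond, task, circuit_params, trace, stim, rng,
            options=options, trial_index=t, subject_id=sid,
        )
        records.append(rec)
    return SessionResult(records=records, final_weights=weights, seed=seed, condition=cond)


# ---------------------------------------------------------------------------
# vectorised engine (instances in lockstep)
# ---------------------------------------------------------------------------

def _select_actions_batch(x_dp, x_ip, init_stn, init_gpe, params: CircuitParams):
    """Race all instances at once; returns (action, rt_iters, crossed)."""
    m, n = x_dp.shape
    ws, wg = params.w_stn.T, params.w_gpe.T
    its, itg = params.inv_tau_s, params.inv_tau_g
    lam, w_gpi = params.lambda_stn, params.w_stn_gpi
    dt, leak, thr = params.dt_thal, params.thal_leak, params.threshold

    x_stn = init_stn.copy()
    x_gpe = init_gpe.copy()
    y_stn = np.tanh(lam * x_stn)
    y_thal = np.zeros((m, n))

    action = np.zeros(m, dtype=int)
    rt = np.full(m, params.max_iters, dtype=int)
    crossed = np.zeros(m, dtype=bool)
    alive = np.ones(m, dtype=bool)

    for k in range(1, params.max_iters + 1):
        x_stn = x_stn + its * (-x_stn + y_stn @ ws - x_gpe)
        y_stn = np.tanh(lam * x_stn)
        x_gpe = x_gpe + itg * (-x_gpe + x_gpe @ wg + y_stn - x_ip)
        x_thal = x_dp - w_gpi * y_stn
        y_thal = y_thal + dt * (-leak * y_thal + x_thal)

        over = y_thal >= thr
        newly = alive & over.any(axis=1)
        if newly.any():
            masked = np.where(over[newly], y_thal[newly], -np.inf)
            action[newly] = np.argmax(masked, axis=1)
            rt[newly] = k
            crossed[newly] = True
            alive[newly] = False
            if not alive.any():
                break
    if alive.any():
        action[alive] = np.argmax(y_thal[alive], axis=1)
    return action, rt, crossed


def _run_sessions_batch(
    cond: SubjectCondition,
    task: TaskConfig,
    circuit_params: CircuitParams,
    seeds,
    options: SimOptions = SimOptions(),
) -> list:
    """Run independent sessions in lockstep; equivalent to mapping
    :func:`run_session` over ``seeds``."""
    seeds = list(seeds)
    m = len(seeds)
    n_s, n_a = len(task.stimuli), len(task.responses)
    n_trials = task.n_trials
    a_init = circuit_params.init_scale

    rngs, sequences = [], []
    for sd in seeds:
        seq_seed, rng = _session_streams(sd)
        rngs.append(rng)
        seq = generate_trial_sequence(task, seq_seed) if n_trials else []
        sequences.append(np.array([task.stimulus_index(s) for s in seq], dtype=int))
    stim_idx = np.stack(sequences) if n_trials else np.zeros((m, 0), dtype=int)

    w1 = np.zeros((m, n_s, n_a))
    w2 = np.zeros((m, n_s, n_a))
    w12 = np.zeros((m, n_s, n_a))
    u_prev = np.zeros(m)
    have_prev = np.zeros(m, dtype=bool)
    delta_u_stored = np.zeros(m)
    prev_action = np.zeros(m, dtype=int)

    opt_resp = np.array([task.response_index(task.optimal_map[s]) for s in task.stimuli])
    all_records = [[] for _ in range(m)]
    rows = np.arange(m)

    for t in range(n_trials):
        s = stim_idx[:, t]
        y1 = w1[rows, s, :]
        y2 = w2[rows, s, :]
        y12 = w12[rows, s, :]
        u = compute_utility(y1, y12, cond.alpha_d1d2, options.risk_transform)

        if options.delta_u_mode == "max":
            if options.u_prev_mode == "reevaluate":
                prev_u = np.where(have_prev, u[rows, prev_action], 0.0)
            else:
                prev_u = u_prev
            delta_u = np.where(have_prev, u.max(axis=1) - prev_u, 0.0)
        else:
            delta_u = delta_u_stored

        lam1 = gain("D1", delta_u, SELECTION_GAINS)[:, None]
        lam2 = gain("D2", delta_u, SELECTION_GAINS)[:, None]
        lam12 = gain("D1D2", delta_u, SELECTION_GAINS)[:, None]
        x_dp = cond.alpha_d1 * lam1 * y1
        x_ip = cond.alpha_d2 * lam2 * y2 + cond.alpha_d1d2 * np.sign(y1) * lam12 * y12

        init_stn = np.empty((m, n_a))
        init_gpe = np.empty((m, n_a))
        for i, rng in enumerate(rngs):
            init_stn[i] = rng.uniform(-a_init, a_init, n_a)
            init_gpe[i] = rng.uniform(-a_init, a_init, n_a)

        act, rt, crossed = _select_actions_batch(x_dp, x_ip, init_stn, init_gpe, circuit_params)

        points = np.empty(m, dtype=int)
        for i, rng in enumerate(rngs):
            stim_lab = task.stimuli[s[i]]
            resp_lab = task.responses[act[i]]
            points[i] = sample_outcome(task, stim_lab, resp_lab, rng)
        r = np.array([points_to_reward(p) for p in points])

        q_sel = y1[rows, act]
        delta = apply_da_condition(r - q_sel, cond)
        w1[rows, s, act] += cond.eta_d1 * gain("D1", delta, LEARNING_GAINS)
        w2[rows, s, act] += cond.eta_d2 * gain("D2", delta, LEARNING_GAINS)
        w12[rows, s, act] += cond.eta_d1d2 * gain("D1D2", delta, LEARNING_GAINS)
        if options.weight_bound is not None:
            b = options.weight_bound
            w1[rows, s, act] = np.clip(w1[rows, s, act], -b, b)
            w2[rows, s, act] = np.clip(w2[rows, s, act], -b, b)
            w12[rows, s, act] = np.clip(w12[rows, s, act], -b, b)

        u_sel = u[rows, act]
        delta_u_stored = np.where(have_prev, u_sel - u_prev, 0.0)
        u_prev = u_sel
        prev_action = act
        have_prev[:] = True

        for i in range(m):
            stim_lab = task.stimuli[s[i]]
            resp_lab = task.responses[act[i]]
            all_records[i].append(
                TrialRecord(
                    subject_id=f"{cond.group}-s{seeds[i]}",
                    group=cond.group,
                    trial_index=t,
                    stimulus=stim_lab,
                    response=resp_lab,
                    optimal=(act[i] == opt_resp[s[i]]),
                    points=int(points[i]),
                    rt_ms=(
                        float(rt[i]) * options.ms_per_iter
                        if (crossed[i] or options.uncrossed_rt == "deadline")
                        else None
                    ),
                )
            )

    out = []
    for i, sd in enumerate(seeds):
        weights = StriatalWeights(n_states=n_s, n_actions=n_a, w_d1=w1[i], w_d2=w2[i], w_d1d2=w12[i])
        out.append(SessionResult(records=all_records[i], final_weights=weights, seed=sd, condition=cond))
    return out


# ---------------------------------------------------------------------------
# group runner
# ---------------------------------------------------------------------------

def _session_measures(records, task: TaskConfig):
    """(reward optimality, punishment optimality, mean crossed RT, rt series)."""
    rew = set(task.reward_stimuli)
    pun = set(task.punishment_stimuli)
    rew_ok = [r.optimal for r in records if r.stimulus in rew]
    pun_ok = [r.optimal for r in records if r.stimulus in pun]
    rts = np.array([np.nan if r.rt_ms is None else r.rt_ms for r in records], dtype=float)
    return (
        float(np.mean(rew_ok)) if rew_ok else np.nan,
        float(np.mean(pun_ok)) if pun_ok else np.nan,
        float(np.nanmean(rts)) if np.any(np.isfinite(rts)) else np.nan,
        rts,
    )


def run_group(
    cond: SubjectCondition,
    task: TaskConfig,
    circuit_params: CircuitParams,
    n_instances: int = 100,
    base_seed: int = 0,
    options: SimOptions = SimOptions(),
    return_sessions: bool = False,
):
    """n independent session instances (seeds base_seed..base_seed+n-1).

    Reaction-time averages exclude trials whose race never crossed the
    threshold (their ``rt_ms`` is missing); choices from those trials are
    still counted for optimality.
    """
    if n_instances < 1:
        raise ValueError("n_instances must be at least 1")
    sessions = _run_sessions_batch(
        cond, task, circuit_params, range(base_seed, base_seed + n_instances), options
    )
    rew = np.empty(n_instances)
    pun = np.empty(n_instances)
    rt = np.empty(n_instances)
    rt_series = np.empty((n_instances, task.n_trials))
    for i, sess in enumerate(sessions):
        rew[i], pun[i], rt[i], rt_series[i] = _session_measures(sess.records, task)
    summary = GroupSummary(
        group=cond.group,
        n_instances=n_instances,
        reward_optimality=float(np.mean(rew)),
        reward_optimality_sd=float(np.std(rew, ddof=1)) if n_instances > 1 else 0.0,
        punishment_optimality=float(np.mean(pun)),
        punishment_optimality_sd=float(np.std(pun, ddof=1)) if n_instances > 1 else 0.0,
        mean_rt_ms=float(np.nanmean(rt)),
        mean_rt_ms_sd=float(np.nanstd(rt, ddof=1)) if n_instances > 1 else 0.0,
        rt_by_trial=np.nanmean(rt_series, axis=0) if task.n_trials else np.array([]),
        per_instance={"reward_optimality": rew, "punishment_optimality": pun, "mean_rt_ms": rt},
    )
    if return_sessions:
        return summary, sessions
    return summary


def calibrate_ms_per_iter(
    task: TaskConfig,
    circuit_params: CircuitParams,
    target_hc_ms: float = 600.0,
    n_instances: int = 20,
    base_seed: int = 0,
) -> float:
    """Scale factor mapping race iterations to ms so that the healthy-control
    mean RT lands at ``target_hc_ms``.  Presentation only; group orderings
    are invariant to this common factor."""
    hc = SubjectCondition.from_group("HC")
    summary = run_group(hc, task, circuit_params, n_instances=n_instances, base_seed=base_seed)
    return target_hc_ms / summary.mean_rt_ms
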