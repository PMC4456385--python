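"""STN-GPe-GPi-thalamus action selection dynamics.

The subthalamic nucleus (STN) and external pallidum (GPe) form a coupled
excitatory-inhibitory loop with one unit per candidate action: STN units
excite their GPe partner one-to-one and themselves laterally (strength
eps_s), GPe units inhibit each other (strength eps_g = -eps_s) and their STN
partner.  Striatal indirect-pathway input inhibits GPe.  The loop sustains
oscillatory activity that acts as an exploration drive.

The internal pallidum (GPi) combines direct-pathway drive with STN
excitation, x_gpi = -x_dp + w * y_stn, and projects inhibitorily to
thalamus, so the thalamic afferent is its negation, x_thal = x_dp - w *
y_stn.  Each thalamic unit integrates its afferent; the first unit to cross
a fixed threshold names the chosen action and the number of iterations taken
is the reaction time (race to threshold).

Integration is explicit Euler with the per-iteration coefficients 1/tau_s
and 1/tau_g applied directly.  The thalamic update is
``y += dt_thal * (-leak * y + x_thal)``: with ``thal_leak = 1`` this is the
standard leaky integrator; with ``thal_leak = 0`` it is a pure accumulator.
The simulation pipeline runs the accumulator form because the task's learned
pathway drives are an order of magnitude below the selection threshold
(1.815), which a leaky unit can therefore never reach; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass(frozen=True)
class CircuitParams:
    """Connectivity, rates and race parameters of the selection circuit."""

    n: int = 2
    eps_s: float = 0.12
    eps_g: Optional[float] = None  # defaults to -eps_s
    inv_tau_s: float = 0.1
    inv_tau_g: float = 0.033
    lambda_stn: float = 3.0
    w_stn_gpi: float = 1.0
    threshold: float = 1.815
    dt_thal: float = 0.1
    thal_leak: float = 1.0
    max_iters: int = 1000
    init_scale: float = 0.01  # uniform half-width of STN/GPe initial state

    def __post_init__(self) -> None:
        if self.eps_g is None:
            object.__setattr__(self, "eps_g", -self.eps_s)
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.max_iters <= 0:
            raise ValueError("max_iters must be positive")
        if self.n < 1:
            raise ValueError("need at least one action channel")

    @property
    def w_stn(self) -> np.ndarray:
        """STN lateral weights: 1 + eps_s on the diagonal, eps_s elsewhere."""
        return np.full((self.n, self.n), self.eps_s) + np.eye(self.n)

    @property
    def w_gpe(self) -> np.ndarray:
        """GPe lateral weights: eps_g everywhere, including self-connections."""
        return np.full((self.n, self.n), self.eps_g)


@dataclass
class CircuitState:
    """Instantaneous circuit state; vectors have one entry per action."""

    x_stn: np.ndarray
    x_gpe: np.ndarray
    y_thal: np.ndarray
    y_stn: np.ndarray = None
    iter: int = 0

    def __post_init__(self) -> None:
        self.x_stn = np.asarray(self.x_stn, dtype=float)
        self.x_gpe = np.asarray(self.x_gpe, dtype=float)
        self.y_thal = np.asarray(self.y_thal, dtype=float)
        if self.y_stn is None:
            self.y_stn = np.tanh(3.0 * self.x_stn)
        else:
            self.y_stn = np.asarray(self.y_stn, dtype=float)

    def copy(self) -> "CircuitState":
        return CircuitState(
            x_stn=self.x_stn.copy(),
            x_gpe=self.x_gpe.copy(),
            y_thal=self.y_thal.copy(),
            y_stn=self.y_stn.copy(),
            iter=self.iter,
        )


def zero_state(params: CircuitParams) -> CircuitState:
    n = params.n
    return CircuitState(x_stn=np.zeros(n), x_gpe=np.zeros(n), y_thal=np.zeros(n))


def random_state(params: CircuitParams, rng: np.random.Generator) -> CircuitState:
    """Per-trial initial state: small uniform noise on STN and GPe.

    The oscillator needs symmetry breaking between otherwise identical
    action channels; the thalamic integrators start at zero.
    """
    a = params.init_scale
    return CircuitState(
        x_stn=rng.uniform(-a, a, params.n),
        x_gpe=rng.uniform(-a, a, params.n),
        y_thal=np.zeros(params.n),
    )


@dataclass
class SelectionResult:
    action: int
    rt_iters: int
    crossed: bool
    #: (iters, 3n) per-iteration record of [y_thal, x_stn, x_gpe], or None
    trajectories: Optional[np.ndarray] = None

    def trajectory_table(self) -> "object":
        """Trajectory as a DataFrame (iter, y_thal_i.., x_stn_i.., x_gpe_i..)."""
        if self.trajectories is None:
            raise ValueError("selection was run without record=True")
        import pandas as pd

        n = self.trajectories.shape[1] // 3
        cols = (
            [f"y_thal_{i}" for i in range(n)]
            + [f"x_stn_{i}" for i in range(n)]
            + [f"x_gpe_{i}" for i in range(n)]
        )
        df = pd.DataFrame(self.trajectories, columns=cols)
        df.insert(0, "iter", np.arange(1, len(df) + 1))
        return df


def _check_len(vec: np.ndarray, n: int, name: str) -> np.ndarray:
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (n,):
        raise ValueError(f"{name} has shape {vec.shape}, expected ({n},)")
    return vec


def step_stn_gpe(state: CircuitState, x_ip: np.ndarray, params: CircuitParams) -> CircuitState:
    """One Euler update of the STN-GPe loop (returns a new state)."""
    x_ip = _check_len(x_ip, params.n, "x_ip")
    s = state.copy()
    x_stn = s.x_stn + params.inv_tau_s * (-s.x_stn + params.w_stn @ s.y_stn - s.x_gpe)
    y_stn = np.tanh(params.lambda_stn * x_stn)  # updated before the GPe line
    x_gpe = s.x_gpe + params.inv_tau_g * (-s.x_gpe + params.w_gpe @ s.x_gpe + y_stn - x_ip)
    s.x_stn, s.y_stn, s.x_gpe = x_stn, y_stn, x_gpe
    s.iter += 1
    return s


def gpi_input(x_dp: np.ndarray, y_stn: np.ndarray, params: CircuitParams) -> np.ndarray:
    """Read-only GPi afferent: -x_dp + w_stn_gpi * y_stn."""
    x_dp = _check_len(x_dp, params.n, "x_dp")
    return -x_dp + params.w_stn_gpi * np.asarray(y_stn, dtype=float)


def step_thalamus(state: CircuitState, x_dp: np.ndarray, params: CircuitParams) -> CircuitState:
    """One thalamic integration step of the sign-inverted GPi signal."""
    x_dp = _check_len(x_dp, params.n, "x_dp")
    s = state.copy()
    x_thal = x_dp - params.w_stn_gpi * s.y_stn
    s.y_thal = s.y_thal + params.dt_thal * (-params.thal_leak * s.y_thal + x_thal)
    return s


def thalamic_crossing_iter(x: float, params: CircuitParams) -> float:
    """Closed-form first-crossing iteration for constant afferent x, STN silent.

    For the leaky unit (leak 1) the recursion y_k = x * (1 - (1 - dt)^k)
    crosses the threshold at ceil(log(1 - thr/x) / log(1 - dt)); below the
    threshold it never crosses (inf).  For the accumulator it is thr/(dt*x).
    """
    thr, dt = params.threshold, params.dt_thal
    if params.thal_leak == 0.0:
        if x <= 0:
            return np.inf
        return np.ceil(thr / (dt * x))
    if x * params.thal_leak <= thr:
        return np.inf
    return np.ceil(np.log(1.0 - thr * params.thal_leak / x) / np.log(1.0 - dt * params.thal_leak))


def select_action(
    x_dp: np.ndarray,
    x_ip: np.ndarray,
    params: CircuitParams,
    init: Optional[CircuitState] = None,
    rng: Optional[np.random.Generator] = None,
    record: bool = False,
) -> SelectionResult:
    """Race-to-threshold selection given pathway drives held fixed in-trial.

    The STN-GPe loop and the thalamic integrators co-evolve, one Euler step
    each per iteration, until some thalamic unit reaches the threshold or
    ``max_iters`` elapses.  The first crosser is the chosen action;
    simultaneous crossers are broken by maximum y_thal then lowest index.
    Without a crossing, ``crossed`` is False and the action is the argmax of
    y_thal at the cap.
    """
    x_dp = _check_len(x_dp, params.n, "x_dp")
    x_ip = _check_len(x_ip, params.n, "x_ip")
    if not (np.all(np.isfinite(x_dp)) and np.all(np.isfinite(x_ip))):
        raise ValueError("pathway drives must be finite")
    if init is not None:
        state = init.copy()
    elif rng is not None:
        state = random_state(params, rng)
    else:
        state = zero_state(params)

    traj = [] if record else None
    for k in range(1, params.max_iters + 1):
        state = step_stn_gpe(state, x_ip, params)
        state = step_thalamus(state, x_dp, params)
        if record:
            traj.append(np.concatenate([state.y_thal, state.x_stn, state.x_gpe]))
        over = state.y_thal >= params.threshold
        if over.any():
            # among simultaneous crossers pick max y_thal (argmax breaks
            # exact ties toward the lowest index)
            masked = np.where(over, state.y_thal, -np.inf)
            action = int(np.argmax(masked))
            return SelectionResult(
                action=action,
                rt_iters=k,
                crossed=True,
                trajectories=np.array(traj) if record else None,
            )
    action = int(np.argmax(state.y_thal))
    return SelectionResult(
        action=action,
        rt_iters=params.max_iters,
        crossed=False,
        trajectories=np.array(traj) if record else None,
    )
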