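"""Striatal value/risk computation and dopamine-gated learning.

The striatum is modelled as three pools of medium spiny neurons (MSNs):
D1-receptor expressing (value, Q), D2-receptor expressing (punishment), and
D1R-D2R co-expressing (risk, h).  Cortical input is one-hot on the current
state, so each pool's response to a (state, action) pair equals the
corresponding cortico-striatal weight.

Dopamine enters in two forms.  The TD error delta = r - Q drives weight
updates through receptor-specific sigmoid gains: the D1 gain increases with
delta, the D2 gain decreases, and the co-expressing pool's gain is the sum of
two half-height sigmoids, giving a U-shape that responds to |delta|.  The
utility-difference signal (computed in :mod:`bgrl.simulate`) gates the direct
and indirect pathways with a second set of gain constants.

Serotonin enters as the static coefficients alpha_d1, alpha_d2, alpha_d1d2
scaling each pool's pathway output, and as the risk sensitivity in the
utility U = Q - alpha_d1d2 * sign(Q) * h (risk-averse for gains, risk-seeking
for losses).

Parkinsonian dopamine availability is modelled on the TD error itself: an
upper clamp delta_lim (cell loss, OFF medication) and an additive constant
delta_med (medication, ON groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional

import numpy as np
import yaml

GAIN_KINDS = ("D1", "D2", "hD1", "hD2", "D1D2")


def _load_packaged(name: str) -> dict:
    with resources.files("bgrl.configs").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class GainParams:
    """Sigmoid constants (c1, c2, c3) per gain kind, for one context."""

    context: str  # "learning" or "selection"
    constants: dict  # kind -> (c1, c2, c3)

    def coeffs(self, kind: str) -> tuple:
        if kind not in self.constants:
            raise KeyError(f"unknown gain kind {kind!r}")
        return self.constants[kind]


def _gain_params_from_config(context: str) -> GainParams:
    raw = _load_packaged("gains.yaml")[context]
    constants = {k: (v["c1"], v["c2"], v["c3"]) for k, v in raw.items()}
    return GainParams(context=context, constants=constants)


LEARNING_GAINS = _gain_params_from_config("learning")
SELECTION_GAINS = _gain_params_from_config("selection")


def gain(kind: str, delta, params: GainParams):
    """Receptor-specific sigmoid gain evaluated at the dopamine signal.

    Full-height form (D1, D2): 2*c1 / (1 + exp(c2*(delta + c3))) - 1, range
    (-c1, c1).  Half-height form (hD1, hD2): c1 / (1 + exp(c2*(delta + c3))).
    The co-expressing pool's gain is the sum of the two half-height sigmoids
    (one increasing, one decreasing), yielding a U-shape in delta.

    Accepts scalar or ndarray ``delta``.
    """
    delta = np.asarray(delta, dtype=float)
    if kind == "D1D2":
        out = np.asarray(gain("hD1", delta, params)) + np.asarray(gain("hD2", delta, params))
    elif kind in ("D1", "D2"):
        c1, c2, c3 = params.coeffs(kind)
        out = 2.0 * c1 / (1.0 + np.exp(c2 * (delta + c3))) - 1.0
    elif kind in ("hD1", "hD2"):
        c1, c2, c3 = params.coeffs(kind)
        out = c1 / (1.0 + np.exp(c2 * (delta + c3)))
    else:
        raise KeyError(f"unknown gain kind {kind!r}")
    return out if out.ndim else float(out)


@dataclass
class StriatalWeights:
    """Cortico-striatal weight matrices over (state, action) for each pool."""

    n_states: int = 4
    n_actions: int = 2
    w_d1: np.ndarray = None
    w_d2: np.ndarray = None
    w_d1d2: np.ndarray = None

    def __post_init__(self) -> None:
        shape = (self.n_states, self.n_actions)
        for name in ("w_d1", "w_d2", "w_d1d2"):
            w = getattr(self, name)
            if w is None:
                # zero start: Q = h = 0, U = 0, unbiased first choices
                setattr(self, name, np.zeros(shape))
            else:
                w = np.asarray(w, dtype=float)
                if w.shape != shape:
                    raise ValueError(f"{name} has shape {w.shape}, expected {shape}")
                if not np.all(np.isfinite(w)):
                    raise ValueError(f"{name} contains non-finite entries")
                setattr(self, name, w)

    def copy(self) -> "StriatalWeights":
        return StriatalWeights(
            n_states=self.n_states,
            n_actions=self.n_actions,
            w_d1=self.w_d1.copy(),
            w_d2=self.w_d2.copy(),
            w_d1d2=self.w_d1d2.copy(),
        )

    def _check(self, state: int, action: int) -> None:
        if not (0 <= state < self.n_states):
            raise IndexError(f"state {state} out of range [0, {self.n_states})")
        if not (0 <= action < self.n_actions):
            raise IndexError(f"action {action} out of range [0, {self.n_actions})")


@dataclass(frozen=True)
class SubjectCondition:
    """Group label plus serotonin coefficients and dopamine condition."""

    group: str
    alpha_d1: float
    alpha_d2: float
    alpha_d1d2: float
    delta_lim: Optional[float] = None
    delta_med: Optional[float] = None
    eta_d1: float = 0.01
    eta_d2: float = 0.1
    eta_d1d2: float = 0.1

    def __post_init__(self) -> None:
        if self.delta_med is not None and self.delta_lim is None:
            raise ValueError("delta_med requires delta_lim (medication on top of deficit)")
        for name in ("alpha_d1", "alpha_d2", "alpha_d1d2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_group(cls, group: str, **overrides) -> "SubjectCondition":
        """Load a named group's parameters from the packaged table."""
        table = _load_packaged("subjects.yaml")
        if group not in table:
            raise KeyError(f"unknown group {group!r}; known: {sorted(table)}")
        kw = dict(table[group])
        kw.update(overrides)
        return cls(group=group, **kw)

    def replace(self, **changes) -> "SubjectCondition":
        return replace(self, **changes)


def all_conditions() -> dict:
    """The four study groups keyed by label."""
    return {g: SubjectCondition.from_group(g) for g in _load_packaged("subjects.yaml")}


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def msn_response(weights: StriatalWeights, state: int, action: int) -> tuple:
    """(y_d1, y_d2, y_d1d2) for a (state, action) pair.

    Cortical input is one-hot on the current state, so each pool's response
    equals its weight.
    """
    weights._check(state, action)
    return (
        float(weights.w_d1[state, action]),
        float(weights.w_d2[state, action]),
        float(weights.w_d1d2[state, action]),
    )


def td_error(r: float, q: float) -> float:
    """Classical temporal-difference error for the immediate-reward task."""
    return r - q


def apply_da_condition(delta, cond: SubjectCondition):
    """Dopamine availability: clamp from above, then add medication.

    Healthy controls pass delta through unchanged; PD-OFF clamps at
    delta_lim; PD-ON clamps then adds delta_med.  Accepts scalars or arrays.
    """
    delta = np.asarray(delta, dtype=float)
    out = delta
    if cond.delta_lim is not None:
        out = np.minimum(delta, cond.delta_lim)
        if cond.delta_med is not None:
            out = out + cond.delta_med
    return out if out.ndim else float(out)


def compute_utility(q, h, alpha_d1d2: float, risk_transform: str = "linear"):
    """U = Q - alpha * sign(Q) * h, with sign(0) := 0.

    ``risk_transform="sqrt"`` applies a signed square root to the risk
    response (the convention of the precursor lumped model); the default is
    the linear form.
    """
    q = np.asarray(q, dtype=float)
    h = np.asarray(h, dtype=float)
    if risk_transform == "linear":
        hterm = h
    elif risk_transform == "sqrt":
        hterm = np.sign(h) * np.sqrt(np.abs(h))
    else:
        raise ValueError(f"unknown risk_transform {risk_transform!r}")
    out = q - alpha_d1d2 * np.sign(q) * hterm
    return out if out.ndim else float(out)


def utility_difference(u_now: float, u_prev: Optional[float]) -> float:
    """Trial-to-trial utility difference; 0 on the first trial of a session."""
    if u_prev is None:
        return 0.0
    return u_now - u_prev


def update_weights(
    weights: StriatalWeights,
    state: int,
    action: int,
    delta: float,
    cond: SubjectCondition,
    params: GainParams = LEARNING_GAINS,
) -> StriatalWeights:
    """One learning step at (state, action); all other entries untouched.

    ``delta`` must already have passed through :func:`apply_da_condition`.
    Returns a new :class:`StriatalWeights`; the input is not mutated.
    """
    weights._check(state, action)
    out = weights.copy()
    out.w_d1[state, action] += cond.eta_d1 * gain("D1", delta, params)
    out.w_d2[state, action] += cond.eta_d2 * gain("D2", delta, params)
    out.w_d1d2[state, action] += cond.eta_d1d2 * gain("D1D2", delta, params)
    return out


@dataclass
class UtilityTrace:
    """Carried between trials: the utility realised at the last selection."""

    u_prev: Optional[float] = None  # None marks the first trial
    delta_u: float = 0.0  # last computed utility difference
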