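"""Two-step parameter estimation for the subject-group model.

Step 1 finds serotonin/dopamine parameter sets whose simulated behaviour
matches a group's reward and punishment action-selection optimality: a
coarse grid search seeds a real-coded genetic algorithm on the squared-error
cost.  Step 2 filters the near-optimal step-1 candidates by agreement with
the group's mean reaction time and returns the best survivor.  Simulated
costs use common random numbers (the same session seeds for every candidate)
so that candidate ranking is stable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .circuit import CircuitParams
from .simulate import SimOptions, run_group, task_circuit_params
from .striatum import SubjectCondition
from .task import TaskConfig

PARAM_NAMES = ("alpha_d1", "alpha_d2", "alpha_d1d2", "delta_lim", "delta_med")

#: box bounds covering all fitted group values
DEFAULT_BOUNDS = {
    "alpha_d1": (0.0, 1.2),
    "alpha_d2": (0.0, 1.2),
    "alpha_d1d2": (0.0, 1.2),
    "delta_lim": (1e-4, 1.0),
    "delta_med": (0.0, 0.5),
}


@dataclass(frozen=True)
class FitBudget:
    grid_points: int = 5  # per free parameter
    pop_size: int = 50
    generations: int = 100
    n_instances: int = 100  # sessions per cost evaluation

    @classmethod
    def small(cls) -> "FitBudget":
        return cls(grid_points=3, pop_size=12, generations=8, n_instances=8)


@dataclass
class FitSpec:
    """What to fit: free parameters with bounds, the rest fixed."""

    group: str
    free_params: dict  # name -> (lo, hi)
    fixed_params: dict  # name -> value (None where the group has no such term)
    target: tuple  # (reward_optimality, punishment_optimality)
    budget: FitBudget = field(default_factory=FitBudget)
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.free_params) & set(self.fixed_params)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
        covered = set(self.free_params) | set(self.fixed_params)
        if covered != set(PARAM_NAMES):
            raise ValueError(f"free+fixed must cover {PARAM_NAMES}, got {sorted(covered)}")
        for name, (lo, hi) in self.free_params.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"infeasible bounds for {name}: ({lo}, {hi})")

    @property
    def free_names(self) -> tuple:
        return tuple(sorted(self.free_params))

    def condition(self, values: dict) -> SubjectCondition:
        kw = dict(self.fixed_params)
        kw.update(values)
        return SubjectCondition(group=self.group, **kw)


@dataclass
class FitResult:
    best_params: SubjectCondition
    best_values: dict
    step1_cost: float
    step2_cost: Optional[float]
    candidate_set: list  # (step1 cost, values) survivors of step 1
    provenance: dict


def group_schedule(group: str) -> tuple:
    """The published free/fixed split per group: controls fit the three
    serotonin coefficients; PD-OFF adds the dopamine clamp; PD-ON-ICD adds
    the medication constant with the clamp carried over; PD-ON-nonICD fits
    the serotonin coefficients with clamp and medication both carried over."""
    alphas = {k: DEFAULT_BOUNDS[k] for k in ("alpha_d1", "alpha_d2", "alpha_d1d2")}
    if group == "HC":
        return alphas, {"delta_lim": None, "delta_med": None}
    if group == "PD-OFF":
        return {**alphas, "delta_lim": DEFAULT_BOUNDS["delta_lim"]}, {"delta_med": None}
    if group == "PD-ON-ICD":
        return {**alphas, "delta_med": DEFAULT_BOUNDS["delta_med"]}, {"delta_lim": 0.001}
    if group == "PD-ON-nonICD":
        return alphas, {"delta_lim": 0.001, "delta_med": 0.06}
    raise KeyError(f"unknown group {group!r}")


# ---------------------------------------------------------------------------
# costs
# ---------------------------------------------------------------------------

def optimality_cost(
    cond: SubjectCondition,
    target: tuple,
    task: Optional[TaskConfig] = None,
    circuit_params: Optional[CircuitParams] = None,
    n_instances: int = 100,
    base_seed: int = 0,
    options: SimOptions = SimOptions(),
) -> float:
    """Squared error between simulated and target optimality proportions."""
    task = task or TaskConfig()
    circuit_params = circuit_params or task_circuit_params()
    summary = run_group(
        cond, task, circuit_params, n_instances=n_instances, base_seed=base_seed, options=options
    )
    return float(
        (summary.reward_optimality - target[0]) ** 2
        + (summary.punishment_optimality - target[1]) ** 2
    )


def mean_rt_iters(
    cond: SubjectCondition,
    task: Optional[TaskConfig] = None,
    circuit_params: Optional[CircuitParams] = None,
    n_instances: int = 100,
    base_seed: int = 0,
    options: SimOptions = SimOptions(),
) -> float:
    task = task or TaskConfig()
    circuit_params = circuit_params or task_circuit_params()
    summary = run_group(
        cond, task, circuit_params, n_instances=n_instances, base_seed=base_seed, options=options
    )
    return summary.mean_rt_ms / options.ms_per_iter


# ---------------------------------------------------------------------------
# step 1: grid search + genetic algorithm
# ---------------------------------------------------------------------------

def grid_search(spec: FitSpec, cost: Callable[[dict], float]) -> list:
    """Evaluate the Cartesian grid over the free parameters; sorted by cost."""
    names = spec.free_names
    if not names:
        values: dict = {}
        return [(cost(values), values)]
    axes = []
    for name in names:
        lo, hi = spec.free_params[name]
        if spec.budget.grid_points < 2:
            raise ValueError("grid resolution must be at least 2 per free parameter")
        axes.append(np.linspace(lo, hi, spec.budget.grid_points))
    out = []
    for point in itertools.product(*axes):
        values = dict(zip(names, (float(v) for v in point)))
        out.append((cost(values), values))
    out.sort(key=lambda cv: cv[0])
    return out


def ga_optimize(
    spec: FitSpec,
    cost: Callable[[dict], float],
    init_population: Optional[list] = None,
) -> tuple:
    """Real-coded GA: tournament selection (3), blend crossover (p=0.9),
    per-gene Gaussian mutation (p=0.1, sigma = 10% of range), elitism 1.

    Returns (best values dict, best cost, per-generation best-cost trace).
    """
    names = spec.free_names
    if not names:
        values: dict = {}
        return values, cost(values), []
    lo = np.array([spec.free_params[n][0] for n in names])
    hi = np.array([spec.free_params[n][1] for n in names])
    rng = np.random.default_rng(spec.seed)
    pop_size, n_gen = spec.budget.pop_size, spec.budget.generations
    d = len(names)

    pop = rng.uniform(lo, hi, size=(pop_size, d))
    if init_population:
        for i, values in enumerate(init_population[:pop_size]):
            pop[i] = [values[n] for n in names]

    def vec_cost(v: np.ndarray) -> float:
        return cost(dict(zip(names, (float(x) for x in v))))

    fitness = np.array([vec_cost(v) for v in pop])
    trace = [float(fitness.min())]
    for _ in range(n_gen):
        order = np.argsort(fitness)
        elite = pop[order[0]].copy()
        elite_cost = float(fitness[order[0]])
        new_pop = [elite]
        while len(new_pop) < pop_size:
            # tournament selection, size 3
            parents = []
            for _ in range(2):
                idx = rng.integers(0, pop_size, 3)
                parents.append(pop[idx[np.argmin(fitness[idx])]].copy())
            p1, p2 = parents
            if rng.random() < 0.9:  # blend (BLX-0.5) crossover
                gamma = rng.uniform(-0.5, 1.5, d)
                c1 = gamma * p1 + (1 - gamma) * p2
            else:
                c1 = p1
            mutate = rng.random(d) < 0.1
            c1 = c1 + mutate * rng.normal(0.0, 0.1 * (hi - lo), d)
            new_pop.append(np.clip(c1, lo, hi))
        pop = np.array(new_pop)
        fitness = np.array([elite_cost] + [vec_cost(v) for v in pop[1:]])
        trace.append(float(fitness.min()))
    best = int(np.argmin(fitness))
    values = dict(zip(names, (float(x) for x in pop[best])))
    return values, float(fitness[best]), trace


# ---------------------------------------------------------------------------
# step 2: reaction-time filter
# ---------------------------------------------------------------------------

def two_step_fit(
    spec: FitSpec,
    rt_target: Optional[float] = None,
    task: Optional[TaskConfig] = None,
    circuit_params: Optional[CircuitParams] = None,
    options: SimOptions = SimOptions(),
    survivor_tolerance: float = 0.10,
) -> FitResult:
    """Optimality fit (grid + GA), then RT filtering of near-optimal sets.

    ``rt_target`` is the group's mean RT in race iterations; survivors of
    step 1 (cost within ``survivor_tolerance`` of the best) are ranked by
    the normalised squared RT error.  Candidate evaluations share one set of
    session seeds (common random numbers).
    """
    task = task or TaskConfig()
    circuit_params = circuit_params or task_circuit_params()
    base_seed = spec.seed
    cache: dict = {}

    def cost(values: dict) -> float:
        key = tuple(round(values[n], 12) for n in spec.free_names)
        if key not in cache:
            cache[key] = optimality_cost(
                spec.condition(values),
                spec.target,
                task,
                circuit_params,
                n_instances=spec.budget.n_instances,
                base_seed=base_seed,
                options=options,
            )
        return cache[key]

    ranked = grid_search(spec, cost)
    n_seed = max(2, spec.budget.pop_size // 4)
    init = [values for _, values in ranked[:n_seed]]
    ga_values, ga_cost, trace = ga_optimize(spec, cost, init_population=init)

    evaluated = {tuple(round(v[n], 12) for n in spec.free_names): (c, v) for c, v in ranked}
    evaluated[tuple(round(ga_values[n], 12) for n in spec.free_names)] = (ga_cost, ga_values)
    best_cost = min(c for c, _ in evaluated.values())
    threshold = best_cost * (1.0 + survivor_tolerance) + 1e-12
    survivors = sorted(
        ((c, v) for c, v in evaluated.values() if c <= threshold), key=lambda cv: cv[0]
    )
    if not survivors:
        raise RuntimeError("step 1 produced no survivors")

    step2_cost = None
    best_c, best_v = survivors[0]
    if rt_target is not None and len(survivors) > 1:
        rt_costs = []
        for c, v in survivors:
            rt = mean_rt_iters(
                spec.condition(v),
                task,
                circuit_params,
                n_instances=spec.budget.n_instances,
                base_seed=base_seed,
                options=options,
            )
            rt_costs.append(((rt - rt_target) / rt_target) ** 2)
        j = int(np.argmin(rt_costs))
        best_c, best_v = survivors[j]
        step2_cost = float(rt_costs[j])

    return FitResult(
        best_params=spec.condition(best_v),
        best_values=best_v,
        step1_cost=float(best_c),
        step2_cost=step2_cost,
        candidate_set=survivors,
        provenance={
            "seed": spec.seed,
            "budget": spec.budget.__dict__,
            "ga_trace": trace,
            "rt_target": rt_target,
        },
    )
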