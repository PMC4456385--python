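import numpy as np
import pytest

from bgrl import (
    FitBudget,
    FitSpec,
    SubjectCondition,
    ga_optimize,
    grid_search,
    group_schedule,
    optimality_cost,
    run_group,
    two_step_fit,
)

ALL_FIXED = {"alpha_d1": 1.0, "alpha_d2": 0.5, "alpha_d1d2": 0.5,
             "delta_lim": None, "delta_med": None}


def _spec(free, fixed=None, budget=None, seed=0, target=(0.7, 0.7)):
    fixed = dict(ALL_FIXED if fixed is None else fixed)
    for k in free:
        fixed.pop(k, None)
    return FitSpec(group="HC", free_params=free, fixed_params=fixed,
                   target=target, budget=budget or FitBudget.small(), seed=seed)


class TestFitSpec:
    def test_overlap_and_coverage_validation(self):
        with pytest.raises(ValueError, match="both free and fixed"):
            FitSpec(group="HC", free_params={"alpha_d2": (0, 1)},
                    fixed_params=ALL_FIXED, target=(0.5, 0.5))
        with pytest.raises(ValueError, match="cover"):
            FitSpec(group="HC", free_params={}, fixed_params={"alpha_d1": 1.0},
                    target=(0.5, 0.5))

    def test_infeasible_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            _spec({"alpha_d2": (1.0, 0.5)})

    def test_published_schedules_cover_parameters(self):
        for g in ("HC", "PD-OFF", "PD-ON-ICD", "PD-ON-nonICD"):
            free, fixed = group_schedule(g)
            assert set(free) | set(fixed) == {
                "alpha_d1", "alpha_d2", "alpha_d1d2", "delta_lim", "delta_med"}
            assert "alpha_d2" in free and "alpha_d1d2" in free


class TestOptimalityCost:
    def test_self_target_has_zero_cost(self, task, circuit):
        cond = SubjectCondition.from_group("PD-OFF")
        summary = run_group(cond, task, circuit, n_instances=4, base_seed=3)
        cost = optimality_cost(cond, (summary.reward_optimality,
                                      summary.punishment_optimality),
                               task, circuit, n_instances=4, base_seed=3)
        assert cost == pytest.approx(0.0, abs=1e-12)

    def test_chance_level_model_against_perfect_target(self, task, circuit):
        # all serotonin coefficients zero silences both pathways: the race is
        # pure noise and both optimalities sit at chance, so the squared
        # error against a perfect learner is ~2 * 0.25
        cond = SubjectCondition(group="chance", alpha_d1=0.0, alpha_d2=0.0, alpha_d1d2=0.0)
        cost = optimality_cost(cond, (1.0, 1.0), task, circuit,
                               n_instances=20, base_seed=0)
        assert cost == pytest.approx(0.5, abs=0.06)
        assert cost >= 0


class TestGridSearch:
    def test_quadratic_cost_recovers_minimiser(self):
        spec = _spec({"alpha_d2": (0.0, 1.0)},
                     budget=FitBudget(grid_points=11, pop_size=4, generations=1))
        ranked = grid_search(spec, lambda v: (v["alpha_d2"] - 0.3) ** 2)
        assert ranked[0][1]["alpha_d2"] == pytest.approx(0.3)
        assert ranked == sorted(ranked, key=lambda cv: cv[0])

    def test_deterministic_ranking(self):
        spec = _spec({"alpha_d2": (0.0, 1.0), "alpha_d1d2": (0.0, 1.0)})
        cost = lambda v: (v["alpha_d2"] - 0.4) ** 2 + (v["alpha_d1d2"] - 0.6) ** 2
        assert grid_search(spec, cost) == grid_search(spec, cost)

    def test_too_coarse_grid_rejected(self):
        spec = _spec({"alpha_d2": (0.0, 1.0)},
                     budget=FitBudget(grid_points=1, pop_size=4, generations=1))
        with pytest.raises(ValueError, match="resolution"):
            grid_search(spec, lambda v: 0.0)


class TestGa:
    def test_sphere_cost_minimised(self):
        spec = _spec({"alpha_d2": (0.0, 1.2), "alpha_d1d2": (0.0, 1.2)},
                     budget=FitBudget(pop_size=30, generations=40), seed=1)
        cost = lambda v: (v["alpha_d2"] - 0.5) ** 2 + (v["alpha_d1d2"] - 0.5) ** 2
        best, best_cost, trace = ga_optimize(spec, cost)
        assert best_cost < 1e-3

    def test_fixed_seed_reproducible(self):
        spec = _spec({"alpha_d2": (0.0, 1.0)}, seed=5)
        cost = lambda v: abs(v["alpha_d2"] - 0.25)
        a = ga_optimize(spec, cost)
        b = ga_optimize(spec, cost)
        assert a[0] == b[0] and a[1] == b[1] and a[2] == b[2]

    def test_elitism_makes_best_cost_non_increasing(self):
        spec = _spec({"alpha_d2": (0.0, 1.0), "alpha_d1d2": (0.0, 1.0)},
                     budget=FitBudget(pop_size=10, generations=15), seed=2)
        rng = np.random.default_rng(0)
        noisy = lambda v: (v["alpha_d2"] - 0.7) ** 2 + 0.01 * rng.random()
        _, _, trace = ga_optimize(spec, noisy)
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_respects_box_bounds(self):
        spec = _spec({"alpha_d2": (0.2, 0.4)},
                     budget=FitBudget(pop_size=8, generations=10), seed=3)
        seen = []
        def cost(v):
            seen.append(v["alpha_d2"])
            return 0.0
        ga_optimize(spec, cost)
        assert all(0.2 <= x <= 0.4 for x in seen)


class TestTwoStep:
    def test_no_free_parameters_returns_fixed(self, task, circuit):
        spec = FitSpec(group="HC", free_params={},
                       fixed_params={"alpha_d1": 1.0, "alpha_d2": 0.185,
                                     "alpha_d1d2": 0.997, "delta_lim": None,
                                     "delta_med": None},
                       target=(0.7, 0.6),
                       budget=FitBudget(grid_points=2, pop_size=2,
                                        generations=1, n_instances=2))
        res = two_step_fit(spec, task=task, circuit_params=circuit)
        assert res.best_values == {}
        assert res.best_params.alpha_d2 == 0.185
        assert res.step2_cost is None

    def test_monotone_improvement_over_grid(self, task, circuit):
        cond = SubjectCondition.from_group("PD-ON-ICD")
        target = run_group(cond, task, circuit, n_instances=3, base_seed=1)
        spec = FitSpec(group="PD-ON-ICD",
                       free_params={"alpha_d2": (0.0, 1.2)},
                       fixed_params={"alpha_d1": 1.0, "alpha_d1d2": 0.001,
                                     "delta_lim": 0.001, "delta_med": 0.06},
                       target=(target.reward_optimality, target.punishment_optimality),
                       budget=FitBudget(grid_points=3, pop_size=6,
                                        generations=3, n_instances=3),
                       seed=1)
        cache = {}
        def cost(values):
            key = values["alpha_d2"]
            if key not in cache:
                cache[key] = optimality_cost(spec.condition(values), spec.target,
                                             task, circuit, n_instances=3, base_seed=1)
            return cache[key]
        grid_best = grid_search(spec, cost)[0][0]
        res = two_step_fit(spec, task=task, circuit_params=circuit)
        assert res.step1_cost <= grid_best + 1e-12

    def test_rt_filter_picks_among_survivors(self, task, circuit):
        spec = _spec({"alpha_d2": (0.0, 1.0)},
                     budget=FitBudget(grid_points=3, pop_size=4,
                                      generations=2, n_instances=2), seed=4)
        res = two_step_fit(spec, rt_target=150.0, task=task, circuit_params=circuit)
        assert any(res.best_values == v for _, v in res.candidate_set)
        assert res.step1_cost <= min(c for c, _ in res.candidate_set) * 1.1 + 1e-9
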