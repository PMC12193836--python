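import numpy as np
import pytest

from levywolf import benchmarks
from levywolf.gwo import GWOConfig, gwo_optimize
from levywolf.lgwo import (
    LGWOConfig,
    StagnationState,
    contraction_update,
    drift_update,
    greedy_levy_update,
    hho_mutation,
    lgwo_optimize,
    opposition,
    weight_factor,
)


def sphere(x):
    return float(np.sum(x * x))


class TestWeightFactor:
    def test_start_value_with_defaults(self):
        cfg = LGWOConfig(dim=2, max_iter=30)
        # arctan(1) = pi/4 -> bracket 1.5 - 1.4*0.5 = 0.8; (28/30)*0.64
        assert weight_factor(0, cfg) == pytest.approx(0.5973333333, rel=1e-9)

    def test_large_t_limit_approaches_we_squared(self):
        cfg = LGWOConfig(dim=2, max_iter=30)
        limit = (28 / 30) * cfg.we**2
        assert weight_factor(10_000_000, cfg) == pytest.approx(limit, rel=1e-3)

    def test_strictly_decreasing_with_defaults(self):
        cfg = LGWOConfig(dim=2, max_iter=500)
        vals = [weight_factor(t, cfg) for t in range(0, 500, 10)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_literal_reading_escapes_weight_band(self):
        cfg = LGWOConfig(dim=2, max_iter=30, literal_weight=True)
        assert not 0 <= weight_factor(0, cfg) <= (28 / 30) * cfg.ws**2


class TestOperators:
    def test_levy_jump_identities(self):
        x = np.array([1.0, -2.0])
        assert np.allclose(greedy_levy_update(x, x, 0.5, 2.0), x)
        assert np.allclose(greedy_levy_update(x, np.zeros(2), 0.5, 0.0), x)
        # scalar case: 1 + 0.5*2*(1-0) = 2
        assert greedy_levy_update(np.array([1.0]), np.array([0.0]), 0.5, 2.0)[0] == 2.0

    def test_opposition_cases(self):
        cfg = LGWOConfig(dim=2, lower=-1, upper=1)
        assert np.allclose(opposition(np.array([0.3, -0.7]), cfg, 1.0), [-0.3, 0.7])
        assert np.allclose(opposition(np.array([0.3, -0.7]), cfg, 0.0), [0.0, 0.0])
        cfg = LGWOConfig(dim=1, lower=0, upper=1)
        assert opposition(np.array([0.25]), cfg, 1.0)[0] == pytest.approx(0.75)

    def test_drift_cases(self):
        x, xb = np.array([2.0, 4.0]), np.array([1.0, 1.0])
        assert np.allclose(drift_update(x, xb, 1.0), xb)
        assert np.allclose(drift_update(x, xb, 0.0), x)
        assert np.allclose(drift_update(xb, xb, 7.3), xb)

    def test_contraction_cases(self):
        assert np.allclose(contraction_update(np.array([2.0, -4.0]), 0.5), [1.0, -2.0])
        assert np.allclose(contraction_update(np.array([2.0, -4.0]), 1.0), [2.0, -4.0])
        assert np.allclose(contraction_update(np.array([2.0, -4.0]), 0.0), [0.0, 0.0])

    def test_mutation_zero_rand_limits(self, cycling_rng):
        cfg = LGWOConfig(dim=2, lower=-1, upper=1)
        x = np.array([0.5, 0.5])
        x_r = np.array([-0.25, 0.75])
        x_best = np.array([0.1, 0.2])
        x_mean = np.array([0.0, 0.1])
        x3, x4 = hho_mutation(x, x_r, x_best, x_mean, cfg, cycling_rng([0.0]))
        assert np.allclose(x3, x_r)
        assert np.allclose(x4, x_best - x_mean)

    def test_mutation_hand_worked_scalar_case(self, cycling_rng):
        cfg = LGWOConfig(dim=1, lower=-65, upper=65)
        x3, _ = hho_mutation(
            np.array([1.0]), np.array([2.0]), np.array([0.0]), np.array([0.0]),
            cfg, cycling_rng([0.5]),
        )
        # 2 - 0.5*|2 - 2*0.5*1| = 1.5
        assert x3[0] == pytest.approx(1.5)


class TestStagnation:
    def test_triggers_only_after_full_flat_window(self):
        s = StagnationState(window=3, tol=1e-12)
        for v in (10.0, 5.0, 4.0, 3.9):
            assert not s.update(v)
        assert not s.update(3.9)  # improvement from 5 still inside the window
        assert not s.update(3.9)  # improvement from 4 still inside the window
        assert s.update(3.9)  # flat across the whole window now
        assert s.update(3.9)

    def test_scale_guard_below_machine_scale(self):
        s = StagnationState(window=2, tol=1e-12)
        # improvements huge in relative terms but below absolute tolerance
        for v in (1e-20, 1e-30, 1e-40):
            s.update(v)
        assert s.triggered


class TestOptimizer:
    def test_reduction_to_canonical_gwo_is_bitwise(self):
        for fid in ("f1", "f9"):
            fn = benchmarks.get_function(fid)
            obj = benchmarks.make_objective(fn)
            for seed in range(1, 6):
                g = gwo_optimize(
                    obj,
                    GWOConfig(dim=fn.dim, lower=fn.lower, upper=fn.upper,
                              n_agents=20, max_iter=60, seed=seed),
                )
                l = lgwo_optimize(
                    obj,
                    LGWOConfig(dim=fn.dim, lower=fn.lower, upper=fn.upper,
                               n_agents=20, max_iter=60, seed=seed,
                               mutation_prob=0.0, stagnation_window=60),
                )
                assert g.best_fitness == l.best_fitness
                assert np.array_equal(g.best_position, l.best_position)
                assert np.array_equal(g.curve, l.curve)
                assert g.n_evals == l.n_evals

    def test_sphere_collapses_to_exact_zero(self):
        fn = benchmarks.get_function("f1")
        cfg = LGWOConfig(dim=30, lower=-100, upper=100, n_agents=30,
                         max_iter=500, seed=1)
        res = lgwo_optimize(benchmarks.make_objective(fn), cfg)
        assert res.best_fitness == 0.0

    def test_ackley_reaches_double_precision_floor(self):
        fn = benchmarks.get_function("f9")
        cfg = LGWOConfig(dim=30, lower=-32, upper=32, n_agents=30,
                         max_iter=500, seed=1)
        res = lgwo_optimize(benchmarks.make_objective(fn), cfg)
        assert res.best_fitness == 4.440892098500626e-16

    def test_best_fitness_curve_never_increases(self):
        cfg = LGWOConfig(dim=10, lower=-5, upper=5, n_agents=12,
                         max_iter=120, seed=7)
        res = lgwo_optimize(sphere, cfg)
        assert np.all(np.diff(res.curve) <= 0)
        assert res.curve[-1] == res.best_fitness

    def test_same_seed_identical_results(self):
        cfg = LGWOConfig(dim=6, lower=-2, upper=2, n_agents=10,
                         max_iter=80, seed=3)
        a = lgwo_optimize(sphere, cfg)
        b = lgwo_optimize(sphere, cfg)
        assert a.best_fitness == b.best_fitness
        assert np.array_equal(a.curve, b.curve)
        assert a.n_evals == b.n_evals

    def test_config_validation(self):
        with pytest.raises(ValueError):
            LGWOConfig(dim=2, ws=0.1, we=0.5).validate()
        with pytest.raises(ValueError):
            LGWOConfig(dim=2, mutation_prob=1.5).validate()
        with pytest.raises(ValueError):
            LGWOConfig(dim=2, stagnation_window=0).validate()
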