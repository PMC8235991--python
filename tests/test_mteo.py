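"""Optimizer unit tests: operation examples, invariants and a full
straight-line transcription oracle replaying the documented RNG order."""

import math

import numpy as np
import pytest

from dermopt.mteo import (
    CHAOS_CEIL,
    CHAOS_FLOOR,
    Individual,
    OptimizerConfig,
    OptimizeResult,
    chaos_step,
    component_reset,
    cooling_coefficient,
    env_temperature,
    initialize,
    opposite,
    optimize,
    update_position,
)


def sphere(x):
    return float(np.sum(x * x))


def bounds(lo, hi, d):
    return (np.full(d, float(lo)), np.full(d, float(hi)))


class TestInitialize:
    def test_within_bounds_and_deterministic(self):
        cfg = OptimizerConfig(pop_size=8, max_iter=1, bounds=bounds(0, 1, 3), seed=5, tm_size=2)
        pop1 = initialize(sphere, cfg)
        pop2 = initialize(sphere, cfg)
        for a, b in zip(pop1, pop2):
            np.testing.assert_array_equal(a.position, b.position)
            assert 0 <= a.position.min() and a.position.max() <= 1

    def test_obl_keeps_better_of_pair(self):
        cfg = OptimizerConfig(
            pop_size=10, max_iter=1, bounds=bounds(-1, 1, 4), seed=2, use_obl=True
        )
        for ind in initialize(sphere, cfg):
            opp = opposite(ind.position, cfg.bounds)
            assert ind.cost <= sphere(opp) + 1e-12

    def test_pop4_matches_scripted_transcription(self):
        cfg = OptimizerConfig(
            pop_size=4, max_iter=1, bounds=bounds(-2, 3, 1), seed=11,
            use_obl=True, tm_size=2,
        )
        rng = np.random.default_rng(11)
        pop = initialize(sphere, cfg, rng)
        # independent transcription of the init + opposition equations
        oracle_rng = np.random.default_rng(11)
        delta = oracle_rng.random((4, 1))
        lo, hi = -2.0, 3.0
        for i in range(4):
            x = lo + delta[i] * (hi - lo)
            x_hat = hi + lo - x
            kept = x if sphere(x) <= sphere(x_hat) else x_hat
            np.testing.assert_allclose(pop[i].position, kept, atol=1e-15)

    def test_nonfinite_objective_raises(self):
        cfg = OptimizerConfig(pop_size=4, max_iter=1, bounds=bounds(0, 1, 2), seed=0, tm_size=2)
        with pytest.raises(ValueError, match="non-finite"):
            initialize(lambda x: float("nan"), cfg)


class TestOpposite:
    def test_examples(self):
        b = bounds(0, 1, 1)
        assert opposite(np.array([0.3]), b)[0] == pytest.approx(0.7)
        assert opposite(np.array([0.5]), b)[0] == pytest.approx(0.5)

    def test_involution(self, rng):
        b = bounds(-3, 7, 5)
        for _ in range(50):
            x = -3 + 10 * rng.random(5)
            np.testing.assert_allclose(opposite(opposite(x, b), b), x, atol=1e-12)


class TestChaosStep:
    def test_endpoints(self):
        assert chaos_step(0.0) == 0.0
        assert chaos_step(1.0) == pytest.approx(0.0, abs=1e-12)

    def test_half(self):
        assert chaos_step(0.5, 2.3) == pytest.approx(0.575)

    def test_iterates_bounded_by_map_maximum(self):
        # numeric maximum of the map on [0, 1]
        grid = np.linspace(0, 1, 1_000_001)
        map_max = float(np.max(2.3 * grid**2 * np.sin(np.pi * grid)))
        k = 0.7
        for _ in range(1000):
            k = chaos_step(k, 2.3)
            assert 0.0 <= k <= map_max + 1e-12
        assert map_max < CHAOS_CEIL + 0.01


class TestEnvTemperature:
    def test_zero_controls_identity(self, rng):
        x = rng.random(4)
        np.testing.assert_array_equal(env_temperature(x, 0.3, 0.9, 0.0, 0.0), x)

    def test_t_one_drops_m2(self, rng):
        x = rng.random(4)
        r = 0.37
        np.testing.assert_allclose(
            env_temperature(x, 1.0, r, 1.0, 5.0), (1 - r) * x, atol=1e-12
        )

    def test_hand_computation(self):
        x = np.array([2.0, -1.0])
        t, r = 0.25, 0.6
        expected = (1 - (1 + 1 * 0.75) * 0.6) * x
        np.testing.assert_allclose(env_temperature(x, t, r, 1.0, 1.0), expected)


class TestUpdatePosition:
    def test_gamma_zero_keeps_old(self):
        b = bounds(-10, 10, 2)
        old = np.array([1.0, 2.0])
        np.testing.assert_array_equal(update_position(old, np.zeros(2), 0.0, 0.5, b), old)

    def test_large_gamma_reaches_env(self):
        b = bounds(-10, 10, 2)
        env = np.array([3.0, -1.0])
        out = update_position(np.array([9.0, 9.0]), env, 1e6, 1.0, b)
        np.testing.assert_allclose(out, env, atol=1e-9)

    def test_scalar_example(self):
        b = bounds(-10, 10, 1)
        out = update_position(np.array([2.0]), np.array([1.0]), 0.5, 0.4, b)
        assert out[0] == pytest.approx(1.0 + math.exp(-0.2))
        assert out[0] == pytest.approx(1.8187307530779818)

    def test_clamped_to_bounds(self):
        b = bounds(0, 1, 1)
        out = update_position(np.array([0.9]), np.array([5.0]), 1e6, 1.0, b)
        assert out[0] == 1.0


class TestCoolingCoefficient:
    def test_zero_worst(self):
        assert cooling_coefficient(1.0, 0.0) == 0.0

    def test_ratio_and_clamping(self):
        assert cooling_coefficient(1.0, 2.0) == 0.5
        assert cooling_coefficient(-1.0, 2.0) == 0.0
        assert cooling_coefficient(1e9, 1.0) == 50.0


class TestComponentReset:
    def test_pr_zero_never_changes(self, rng):
        b = bounds(0, 1, 3)
        x = rng.random(3)
        for _ in range(100):
            np.testing.assert_array_equal(component_reset(x, 0.5, 0.5, 0.0, b, rng), x)

    def test_pr_one_always_rewrites_within_bounds(self, rng):
        b = bounds(-2, 2, 1)
        x = np.array([1.5])
        for _ in range(100):
            out = component_reset(x, 0.5, 0.5, 1.0, b, rng)
            assert -2 <= out[0] <= 2

    def test_reset_frequency_monte_carlo(self, rng):
        b = bounds(0, 1, 4)
        x = np.full(4, 0.5)
        n, hits = 10_000, 0
        for _ in range(n):
            out = component_reset(x, 1.0, 0.5, 0.3, b, rng)
            hits += not np.array_equal(out, x)
        assert hits / n == pytest.approx(0.3, abs=0.02)


class TestOptimize:
    def test_sphere_convergence(self):
        cfg = OptimizerConfig(
            pop_size=100, max_iter=200, bounds=bounds(-100, 100, 10), seed=3
        )
        res = optimize(sphere, cfg)
        assert res.best_cost < 1e-3
        assert np.all(np.diff(res.history) <= 0)
        assert res.best_cost == res.history.min()

    def test_corner_minimum_stays_in_bounds(self):
        cfg = OptimizerConfig(
            pop_size=20, max_iter=50, bounds=bounds(0, 1, 3), seed=4
        )
        res = optimize(lambda x: float(-np.sum(x)), cfg)
        assert np.all(res.best_position >= 0) and np.all(res.best_position <= 1)
        assert res.best_cost <= -2.0

    def test_seed_determinism(self):
        cfg = OptimizerConfig(pop_size=10, max_iter=20, bounds=bounds(-5, 5, 4), seed=9)
        r1, r2 = optimize(sphere, cfg), optimize(sphere, cfg)
        assert r1.best_cost == r2.best_cost
        np.testing.assert_array_equal(r1.best_position, r2.best_position)
        np.testing.assert_array_equal(r1.history, r2.history)

    def test_positions_within_bounds_for_offset_optimum(self):
        # optimum outside the box pushes agents against the bound
        cfg = OptimizerConfig(pop_size=10, max_iter=30, bounds=bounds(0, 1, 2), seed=6)
        res = optimize(lambda x: float(np.sum((x - 5) ** 2)), cfg)
        assert np.all(res.best_position <= 1.0)

    def test_two_iterations_match_straight_line_transcription(self):
        """Full two-iteration replay with an independent procedural oracle."""
        n, d, iters, seed = 4, 2, 2, 21
        lo, hi = np.zeros(d), np.ones(d)
        pr, tm, alpha = 0.3, 2, 2.3

        cfg = OptimizerConfig(
            pop_size=n, max_iter=iters, bounds=(lo, hi), seed=seed,
            pr=pr, tm_size=tm, chaos_alpha=alpha, use_obl=True, use_chaos=True,
        )
        res = optimize(sphere, cfg)

        # ---- oracle: plain arrays, documented RNG order ----
        rng = np.random.default_rng(seed)
        delta = rng.random((n, d))
        pos = lo + delta * (hi - lo)
        cost = np.empty(n)
        for i in range(n):
            opp = hi + lo - pos[i]
            if sphere(opp) < sphere(pos[i]):
                pos[i] = opp
            cost[i] = sphere(pos[i])
        k = rng.random()
        if k < CHAOS_FLOOR:
            k = CHAOS_FLOOR + rng.random() * (CHAOS_CEIL - CHAOS_FLOOR)
        order = np.argsort(cost, kind="stable")
        pos, cost = pos[order], cost[order]
        mem_p, mem_c = pos[:tm].copy(), cost[:tm].copy()
        best_p, best_c = pos[0].copy(), cost[0]
        hist = []
        half = n // 2
        for it in range(1, iters + 1):
            t = it / iters
            order = np.argsort(cost, kind="stable")
            pos, cost = pos[order], cost[order]
            for slot in range(tm):
                pos[-1 - slot], cost[-1 - slot] = mem_p[slot].copy(), mem_c[slot]
            order = np.argsort(cost, kind="stable")
            pos, cost = pos[order], cost[order]
            worst = cost[-1]
            for idx in range(half):
                g = min(max(cost[half + idx] / worst if worst else 0.0, 0.0), 50.0)
                m1 = float(rng.integers(0, 2))
                m2 = float(rng.integers(0, 2))
                k = alpha * k * k * math.sin(math.pi * k)
                if k < CHAOS_FLOOR:
                    k = CHAOS_FLOOR + rng.random() * (CHAOS_CEIL - CHAOS_FLOOR)
                te = (1 - (m1 + m2 * (1 - t)) * k) * pos[idx]
                new = np.clip(te + (pos[half + idx] - te) * math.exp(-g * t), lo, hi)
                if rng.random() < pr:
                    j = int(rng.integers(d))
                    new = new.copy()
                    new[j] = lo[j] + rng.random() * (hi[j] - lo[j]) * math.exp(-g * t)
                nc = sphere(new)
                opp = np.clip(hi + lo - new, lo, hi)
                if sphere(opp) < nc:
                    new, nc = opp, sphere(opp)
                if nc < cost[half + idx]:
                    pos[half + idx], cost[half + idx] = new, nc
            allp = np.vstack([mem_p, pos])
            allc = np.concatenate([mem_c, cost])
            order = np.argsort(allc, kind="stable")
            mem_p, mem_c = allp[order[:tm]].copy(), allc[order[:tm]].copy()
            if mem_c[0] < best_c:
                best_p, best_c = mem_p[0].copy(), mem_c[0]
            hist.append(best_c)

        np.testing.assert_allclose(res.best_position, best_p, atol=1e-12)
        assert res.best_cost == pytest.approx(best_c, abs=1e-12)
        np.testing.assert_allclose(res.history, hist, atol=1e-12)


class TestConfigValidation:
    def test_odd_pop_rejected(self):
        with pytest.raises(ValueError):
            OptimizerConfig(pop_size=5, bounds=bounds(0, 1, 2))

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            OptimizerConfig(pop_size=4, bounds=bounds(1, 0, 2))

    def test_bad_pr_rejected(self):
        with pytest.raises(ValueError):
            OptimizerConfig(pop_size=4, bounds=bounds(0, 1, 2), pr=1.5)
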