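"""ABER optimizer: step formulas, elitism, bounds, reproducibility."""

import math

import numpy as np
import pytest

from mammober import ber
from mammober.ber import (OptimizerConfig, Solution, StepDraws,
                          around_leader, earth_radius_coefficient,
                          elitism_radius, exploit_move, explore_move,
                          group_sizes, multi_run, mutate,
                          random_search_baseline, run)

B = (0.0, 1.0)


def _draws(dim=3, h=1.0, x=90.0, r1=None, r2=None, r3=None, z=0.5):
    one = np.ones(dim)
    return StepDraws(h=h, x=x,
                     r1=one * 0.5 if r1 is None else np.asarray(r1, float),
                     r2=one * 0.5 if r2 is None else np.asarray(r2, float),
                     r3=one * 0.5 if r3 is None else np.asarray(r3, float),
                     z=z)


class TestEarthRadiusCoefficient:
    @pytest.mark.parametrize(
        "h,x,expected",
        [(1.0, 90.0, 0.0), (2.0, 60.0, 2.0), (1.0, 180.0, -0.5)],
    )
    def test_closed_forms(self, h, x, expected):
        assert earth_radius_coefficient(_draws(h=h, x=x)) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            earth_radius_coefficient(_draws(x=-5.0))
        with pytest.raises(ValueError):
            earth_radius_coefficient(_draws(x=1e-9))


class TestExploreMove:
    def test_all_ones_position_is_fixed_point(self):
        p = np.ones(4)
        out = explore_move(p, _draws(4, h=1.5, x=30.0), B)
        np.testing.assert_allclose(out, p)

    def test_centered_r2_freezes_member(self):
        p = np.array([0.2, 0.7, 0.4])
        out = explore_move(p, _draws(3, r2=[0.5, 0.5, 0.5]), B)
        np.testing.assert_allclose(out, p)

    def test_matches_hand_recomputation(self, rng):
        p = rng.uniform(size=5)
        d = StepDraws(h=1.3, x=40.0, r1=rng.uniform(size=5),
                      r2=rng.uniform(size=5), r3=rng.uniform(size=5), z=0.3)
        r = d.h * math.cos(math.radians(d.x)) / (1 - math.cos(math.radians(d.x)))
        c = min(abs(r), 1.0) * d.r1
        expected = np.clip(p + c * (p - 1.0) * (2 * d.r2 - 1.0), 0, 1)
        np.testing.assert_allclose(explore_move(p, d, B), expected)


class TestExploitMove:
    def test_difference_term_vanishes(self, rng):
        p1 = rng.uniform(size=4)
        p2 = rng.uniform(size=4)
        leader = rng.uniform(size=4)
        d = _draws(4, z=1.0)
        out = exploit_move(p1, p2, p2, leader, d, B)
        np.testing.assert_allclose(out, np.clip(d.r1 * p1, 0, 1))

    def test_leader_term_vanishes_when_p1_is_leader(self, rng):
        leader = rng.uniform(size=4)
        p2, p3 = rng.uniform(size=4), rng.uniform(size=4)
        d = _draws(4, z=0.0)
        out = exploit_move(leader, p2, p3, leader, d, B)
        np.testing.assert_allclose(out, np.clip(d.r1 * leader, 0, 1))

    def test_matches_hand_recomputation(self, rng):
        p1, p2, p3, lead = (rng.uniform(size=6) for _ in range(4))
        d = StepDraws(h=1.0, x=70.0, r1=rng.uniform(size=6),
                      r2=rng.uniform(size=6), r3=rng.uniform(size=6), z=0.42)
        expected = np.clip(
            d.r1 * p1 + d.z * d.r2 * (p2 - p3) + (1 - d.z) * d.r3 * (lead - p1),
            0, 1,
        )
        np.testing.assert_allclose(exploit_move(p1, p2, p3, lead, d, B), expected)


class TestElitismRadius:
    @pytest.mark.parametrize("t,T,expected", [(0, 100, 1.0), (100, 100, 3.0),
                                              (50, 100, 1.5)])
    def test_endpoints_and_midpoint(self, t, T, expected):
        assert elitism_radius(t, T) == pytest.approx(expected)


class TestAroundLeader:
    def test_identity_limit(self):
        lead = np.array([0.3, 0.6])
        d = _draws(2, r1=[1.0, 1.0])
        np.testing.assert_allclose(around_leader(lead, 0.0, d, B), lead)

    def test_annihilation_clips_to_lower_bound(self):
        lead = np.array([0.3, 0.6])
        d = _draws(2, r1=[0.0, 0.0])
        np.testing.assert_allclose(around_leader(lead, 1.0, d, (0.1, 1.0)),
                                   [0.1, 0.1])


class TestMutate:
    def test_z_zero_is_plain_sum(self):
        p = np.full(3, 0.1)
        out = mutate(p, p, p, k=0.2, z=0.0, bounds=(0.0, 10.0))
        np.testing.assert_allclose(out, 0.2 + 0.3)

    def test_zero_peers_give_k(self):
        z3 = np.zeros(3)
        out = mutate(z3, z3, z3, k=1.5, z=0.7, bounds=(0.0, 10.0))
        np.testing.assert_allclose(out, 1.5)

    def test_large_zk_decays_to_k(self):
        p = np.full(3, 0.5)
        out = mutate(p, p, p, k=2.0, z=400.0, bounds=(0.0, 10.0))
        np.testing.assert_allclose(out, 2.0, atol=1e-12)


class TestGroupSizes:
    @pytest.mark.parametrize("t,expected", [(0, (21, 9)), (500, (9, 21)),
                                            (250, (15, 15))])
    def test_schedule_endpoints(self, t, expected):
        assert group_sizes(t, 500, 30) == expected

    def test_sizes_always_sum_and_exploration_nonincreasing(self):
        prev = 31
        for t in range(0, 501, 10):
            ne, nx = group_sizes(t, 500, 30)
            assert ne + nx == 30
            assert ne <= prev
            prev = ne

    def test_classic_mode_is_frozen(self):
        cfg = OptimizerConfig(classic_mode=True)
        assert group_sizes(0, 500, 30, cfg) == group_sizes(500, 500, 30, cfg) == (21, 9)


def sphere(p):
    return float(np.sum(p * p))


class TestRun:
    def test_constant_objective_flat_history(self):
        cfg = OptimizerConfig(population_size=6, max_iterations=10, seed=0)
        best, hist = run(lambda p: 1.0, cfg, dimension=3)
        assert best.fitness == 1.0
        assert hist == [1.0] * 10

    def test_elitism_monotone_and_bounds_respected(self):
        cfg = OptimizerConfig(population_size=8, max_iterations=40,
                              bounds=(-5.0, 5.0), seed=3)
        traced = []

        def objective(p):
            traced.append(p.copy())
            return sphere(p)

        _, hist = run(objective, cfg, dimension=3)
        assert all(b <= a + 1e-15 for a, b in zip(hist, hist[1:]))
        for p in traced:
            assert (p >= -5.0).all() and (p <= 5.0).all()

    def test_classic_mode_still_monotone(self):
        cfg = OptimizerConfig(population_size=8, max_iterations=30,
                              classic_mode=True, bounds=(-2.0, 2.0), seed=1)
        _, hist = run(sphere, cfg, dimension=2)
        assert all(b <= a + 1e-15 for a, b in zip(hist, hist[1:]))

    def test_reproducible_trajectory(self):
        cfg = OptimizerConfig(population_size=6, max_iterations=15, seed=11,
                              bounds=(-1.0, 1.0))
        b1, h1 = run(sphere, cfg, dimension=4)
        b2, h2 = run(sphere, cfg, dimension=4)
        assert h1 == h2
        np.testing.assert_array_equal(b1.position, b2.position)

    def test_nonfinite_objective_raises(self):
        cfg = OptimizerConfig(population_size=4, max_iterations=2, seed=0)
        with pytest.raises(ValueError, match="non-finite"):
            run(lambda p: float("nan"), cfg, dimension=2)

    def test_one_d_sphere_converges_tightly(self):
        """Leader-shrinking exploitation drives the 1-D sphere below 1e-6."""
        hits = 0
        for seed in range(10):
            cfg = OptimizerConfig(population_size=30, max_iterations=500,
                                  bounds=(-1.0, 1.0), seed=seed)
            best, _ = run(sphere, cfg, dimension=1)
            hits += best.fitness <= 1e-6
        assert hits >= 9

    def test_multi_run_returns_best_restart(self):
        cfg = OptimizerConfig(population_size=6, max_iterations=10, n_runs=3,
                              bounds=(-1.0, 1.0), seed=5)
        best, hists = multi_run(sphere, cfg, dimension=2)
        assert len(hists) == 3
        assert best.fitness <= min(h[-1] for h in hists) + 1e-15


class TestRandomSearch:
    def test_budget_one_returns_single_sample(self):
        rng = np.random.default_rng(9)
        sol = random_search_baseline(sphere, 1, (-1.0, 1.0), 3, seed=9)
        expected = np.random.default_rng(9).uniform(-1.0, 1.0, 3)
        np.testing.assert_array_equal(sol.position, expected)

    def test_budget_zero_is_error(self):
        with pytest.raises(ValueError, match="budget"):
            random_search_baseline(sphere, 0, B, 2)

    def test_deterministic_under_seed(self):
        a = random_search_baseline(sphere, 50, (-2.0, 2.0), 4, seed=3)
        b = random_search_baseline(sphere, 50, (-2.0, 2.0), 4, seed=3)
        assert a.fitness == b.fitness


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            ({"population_size": 3}, "population_size"),
            ({"max_iterations": 0}, "max_iterations"),
            ({"exploration_fraction_start": 1.0}, "fraction"),
            ({"mutation_probability": 1.5}, "mutation_probability"),
            ({"stagnation_limit": 0}, "stagnation_limit"),
            ({"bounds": (1.0, 1.0)}, "bounds"),
        ],
    )
    def test_invalid(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            OptimizerConfig(**kwargs)
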