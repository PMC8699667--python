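"""Inverse solver: bounds, exact recovery, oracle equivalence, scans."""

import math

import numpy as np
import pytest

from heatrr.blocks import DEFAULT_REGISTRY, BlockLevel, Blocktype, LevelSpec
from heatrr.mavb import MAVBParams, forward_simulate, objective
from heatrr.solver import (
    SolverConfig,
    brute_force_solve,
    delta_a_bounds_for,
    sensitivity_scan,
    solve,
)
from conftest import draw_on_grid_params


def _fixed_ratio_blocktype(block_type, pattern):
    return Blocktype(9, "test", (LevelSpec(block_type, (pattern,)),))


class TestDeltaABounds:
    def test_2_1_block_against_mean_rr(self):
        bt = _fixed_ratio_blocktype("II", ((2, 1),))
        rng = delta_a_bounds_for(bt, [400.0] * 10)
        assert rng is not None
        lo, hi = rng
        assert lo >= 175 and hi <= 250
        assert lo <= 200 <= hi

    def test_identity_ratio_contains_mean(self):
        bt = _fixed_ratio_blocktype("I", ((1, 1),))
        lo, hi = delta_a_bounds_for(bt, [240.0] * 10)
        assert lo <= 240 <= hi

    def test_empty_when_exceeding_physiological_cap(self):
        # rho * mean RR = 900 is far above the 400 ms upper bound
        bt = _fixed_ratio_blocktype("I", ((1, 1),))
        assert delta_a_bounds_for(bt, [900.0] * 10) is None

    def test_true_delta_a_always_inside(self, rng):
        # exhaustive check: generating simulations land inside the range
        for bt_id in DEFAULT_REGISTRY.ids:
            for _ in range(3):
                p = draw_on_grid_params(rng, bt_id)
                rr = forward_simulate(p, 22).ventricular_rr
                lo, hi = delta_a_bounds_for(DEFAULT_REGISTRY[bt_id], rr)
                assert lo <= p.delta_a <= hi


class TestSolve:
    def test_noiseless_recovery_is_exact(self):
        truth = MAVBParams(200, 2, (BlockLevel("II", ((2, 1),), 60),))
        obs = forward_simulate(truth, 22).ventricular_rr
        sol = solve(obs)
        assert sol.objective_value == 0.0
        assert sol.params.delta_a == 200.0
        assert sol.feasible

    def test_single_perturbed_interval(self):
        truth = MAVBParams(200, 2, (BlockLevel("II", ((2, 1),), 60),))
        obs = forward_simulate(truth, 22).ventricular_rr.copy()
        obs[7] += 2.0
        sol = solve(obs)
        assert sol.objective_value == 2.0
        assert sol.params.delta_a == 200.0

    def test_sentinel_on_empty_search_space(self):
        cfg = SolverConfig(blocktype_ids=())
        sol = solve([400.0, 410.0, 390.0], cfg)
        assert sol.params is None and not sol.feasible
        assert math.isinf(sol.objective_value)

    def test_prune_toggle_never_changes_solution(self, rng, coarse_config):
        from dataclasses import replace

        for _ in range(6):
            obs = np.round(rng.uniform(250, 900, 12))
            a = solve(obs, replace(coarse_config, prune=True))
            b = solve(obs, replace(coarse_config, prune=False))
            assert a.objective_value == b.objective_value
            assert (a.params is None) == (b.params is None)
            if a.params is not None:
                assert a.params.delta_a == b.params.delta_a
                assert a.params.blocktype_id == b.params.blocktype_id
                assert a.params.oc_vector() == b.params.oc_vector()

    def test_returned_objective_lower_bounds_user_params(self, rng):
        # the optimum is at least as good as any feasible candidate
        for bt_id in (1, 2, 3):
            p = draw_on_grid_params(rng, bt_id)
            clean = forward_simulate(p, 22).ventricular_rr
            obs = np.round(clean + rng.normal(0, 4, clean.size))
            sol = solve(obs)
            f_user, _, feasible = objective(p, obs)
            if feasible:
                assert sol.objective_value <= f_user


def _assert_same_solution(a, b):
    assert a.objective_value == b.objective_value
    assert (a.params is None) == (b.params is None)
    if a.params is not None:
        assert a.params.blocktype_id == b.params.blocktype_id
        assert a.params.delta_a == b.params.delta_a
        assert a.params.oc_vector() == b.params.oc_vector()


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed,bt_ids", [
        (11, (1, 2)), (12, (2, 3)), (13, (1, 4)), (14, (3, 4)), (15, (2, 5)),
    ])
    def test_random_instances_match_brute_force(self, seed, bt_ids):
        rng = np.random.default_rng(seed)
        cfg = SolverConfig(grid_step=5.0, blocktype_ids=bt_ids)
        obs = np.round(rng.uniform(300, 1400, 12))
        _assert_same_solution(solve(obs, cfg), brute_force_solve(obs, cfg))

    def test_near_fit_instance_matches_brute_force(self, rng):
        # a feasible instance (not everything clipped) exercises tie-breaks
        cfg = SolverConfig(grid_step=5.0, blocktype_ids=(1, 2))
        truth = MAVBParams(250, 2, (BlockLevel("II", ((3, 2),), 0),))
        obs = forward_simulate(truth, 12).ventricular_rr.copy()
        obs += np.round(rng.normal(0, 6, obs.size))
        a, b = solve(obs, cfg), brute_force_solve(obs, cfg)
        assert math.isfinite(a.objective_value)
        _assert_same_solution(a, b)

    def test_brute_force_trivial_cases(self):
        cfg = SolverConfig(blocktype_ids=())
        sol = brute_force_solve([400.0, 400.0, 400.0], cfg)
        assert sol.params is None and math.isinf(sol.objective_value)


class TestSensitivityScan:
    def test_point_count_and_identity_offset(self, fast_config):
        truth = MAVBParams(240, 2, (BlockLevel("II", ((2, 1),), 0),))
        obs = forward_simulate(truth, 10).ventricular_rr
        points = sensitivity_scan(obs, 5, -20, 20, 1.0, fast_config)
        assert len(points) == 41
        centre = next(p for p in points if p.offset == 0)
        assert centre.objective == solve(obs, fast_config).objective_value

    def test_nonpositive_perturbation_is_infeasible(self, fast_config):
        obs = np.full(10, 300.0)
        points = sensitivity_scan(obs, 0, -400, 0, 100.0, fast_config)
        assert math.isinf(points[0].objective)  # offset -400 kills interval 0

    def test_piecewise_quadratic_segments(self, fast_config):
        # while the argmin stays put, F^2 is exactly quadratic in the offset
        truth = MAVBParams(250, 2, (BlockLevel("II", ((2, 1),), 0),))
        obs = forward_simulate(truth, 10).ventricular_rr
        points = sensitivity_scan(obs, 4, -60, 60, 1.0, fast_config)
        segments = _constant_argmin_segments(points)
        assert any(len(seg) >= 4 for seg in segments)
        for seg in segments:
            if len(seg) < 4:
                continue
            f_sq = np.array([p.objective**2 for p in seg])
            third_diff = np.diff(f_sq, n=3)
            assert np.max(np.abs(third_diff)) < 1e-6


def _constant_argmin_segments(points):
    segments, current, current_key = [], [], object()
    for p in points:
        if p.params is None:
            key = None
        else:
            key = (p.params.blocktype_id, p.params.delta_a,
                   tuple(p.params.oc_vector()))
        if key != current_key:
            if current:
                segments.append(current)
            current, current_key = [], key
        if key is not None:
            current.append(p)
    if current:
        segments.append(current)
    return segments
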