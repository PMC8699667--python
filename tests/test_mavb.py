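"""Forward model: block levels, cascades, RR intervals and the objective."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heatrr.blocks import (
    DEFAULT_REGISTRY,
    BlockLevel,
    BlocktypeRegistry,
    conducted_fraction,
    decision_cycle,
)
from heatrr.mavb import (
    InfeasibleParametersError,
    MAVBParams,
    RRSeries,
    atrial_train,
    conduct_level,
    forward_simulate,
    objective,
)
from conftest import draw_on_grid_params


class TestAtrialTrain:
    @pytest.mark.parametrize(
        "delta_a,t_start,count,expected",
        [
            (250, 0, 4, [0, 250, 500, 750]),
            (182, 0, 3, [0, 182, 364]),  # typical AFib atrial cycle
            (1, 5, 2, [5, 6]),
        ],
    )
    def test_values(self, delta_a, t_start, count, expected):
        out = atrial_train(delta_a, t_start, count)
        assert out.tolist() == expected
        assert np.all(np.diff(out) > 0)

    @pytest.mark.parametrize("bad", [(0, 0, 3), (-5, 0, 3), (250, 0, 0)])
    def test_invalid_arguments(self, bad):
        with pytest.raises(ValueError):
            atrial_train(*bad)


class TestConductLevel:
    def test_fixed_2_1_mobitz(self):
        lv = BlockLevel("II", ((2, 1),), base_delay_c=60)
        out, flags = conduct_level([0, 200, 400, 600], lv)
        assert out.tolist() == [60, 460]
        assert flags.tolist() == [True, False, True, False]

    def test_wenckebach_4_3_delay_ramp(self):
        # delays ramp 50, 70, 90 within each cycle and reset after the drop
        lv = BlockLevel("I", ((4, 3),), base_delay_c=50, increment_delta=20)
        out, flags = conduct_level(np.arange(8) * 250.0, lv)
        assert out.tolist() == [50, 320, 590, 1050, 1320, 1590]
        assert flags.sum() == 6

    def test_identity_passthrough(self):
        lv = BlockLevel("I", ((1, 1),))
        incoming = np.array([3.0, 400.0, 555.0])
        out, flags = conduct_level(incoming, lv)
        assert out.tolist() == incoming.tolist()
        assert flags.all()

    def test_phase_offset_shifts_pattern(self):
        lv = BlockLevel("II", ((2, 1),), phase_offset_o=1)
        out, flags = conduct_level([0, 200, 400, 600], lv)
        assert flags.tolist() == [False, True, False, True]
        assert out.tolist() == [200, 600]

    def test_excessive_increment_is_infeasible(self):
        # 300 ms ramp on a 250 ms cycle drives outgoing times backwards
        lv = BlockLevel("I", ((4, 3),), increment_delta=300)
        with pytest.raises(InfeasibleParametersError):
            conduct_level(np.arange(8) * 250.0, lv)

    def test_non_monotone_incoming_rejected(self):
        lv = BlockLevel("II", ((2, 1),))
        with pytest.raises(ValueError):
            conduct_level([0, 200, 100], lv)


class TestForwardSimulate:
    def test_passthrough_keeps_cycle(self):
        p = MAVBParams(250, 1, (BlockLevel("I", ((1, 1),)),))
        rr = forward_simulate(p, 5).ventricular_rr
        assert rr.tolist() == [250] * 5

    def test_2_1_block_halves_rate(self):
        p = MAVBParams(200, 2, (BlockLevel("II", ((2, 1),), 60),))
        rr = forward_simulate(p, 2).ventricular_rr
        assert rr.tolist() == [400, 400]

    def test_wenckebach_closed_form(self):
        p = MAVBParams(250, 1, (BlockLevel("I", ((4, 3),), 50, 20),))
        rr = forward_simulate(p, 6).ventricular_rr
        assert rr.tolist() == [270, 270, 460, 270, 270, 460]

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5])
    def test_wenckebach_closed_form_general(self, n):
        # (n-1) intervals of delta_a + delta, then 2*delta_a - (n-1)*delta
        delta_a, delta = 300.0, 15.0
        p = MAVBParams(
            delta_a, 1, (BlockLevel("I", ((n + 1, n),), 0.0, delta),)
        )
        rr = forward_simulate(p, 3 * n).ventricular_rr
        expected = ([delta_a + delta] * (n - 1) + [2 * delta_a - (n - 1) * delta]) * 3
        assert rr.tolist() == expected[: 3 * n]

    def test_level0_spacing_is_exact(self):
        p = MAVBParams(241, 4, _bt4_levels())
        trace = forward_simulate(p, 10)
        assert np.all(np.diff(trace.times_per_level[0]) == 241)

    def test_signal_conservation_per_level(self):
        p = MAVBParams(241, 4, _bt4_levels())
        trace = forward_simulate(p, 10)
        for level_in, flags, level_out in zip(
            trace.times_per_level, trace.conducted_flags,
            trace.times_per_level[1:]
        ):
            assert flags.size == level_in.size
            assert flags.sum() == level_out.size

    def test_long_run_conducted_fraction(self):
        lv = BlockLevel("II", ((2, 1), (3, 2)))
        incoming = np.arange(5000) * 200.0
        _, flags = conduct_level(incoming, lv)
        assert flags.mean() == pytest.approx(
            float(conducted_fraction(((2, 1), (3, 2)))), abs=1e-3
        )


def _bt4_levels():
    return (
        BlockLevel("II", ((2, 1), (3, 2))),
        BlockLevel("II", ((1, 1), (2, 1))),
        BlockLevel("II", ((1, 1), (2, 1))),
    )


class TestObjective:
    def test_self_match_is_zero(self):
        p = MAVBParams(250, 1, (BlockLevel("I", ((4, 3),), 50, 20),))
        rr = forward_simulate(p, 8).ventricular_rr
        f, res, feasible = objective(p, rr)
        assert f == 0.0 and feasible and np.all(res == 0)

    def test_euclidean_norm_of_residuals(self):
        p = MAVBParams(250, 1, (BlockLevel("I", ((4, 3),), 50, 20),))
        f, res, feasible = objective(p, [270, 280, 460])
        assert res.tolist() == [0, -10, 0]
        assert f == 10.0 and feasible

    def test_clipping_beyond_150ms(self):
        p = MAVBParams(250, 1, (BlockLevel("I", ((4, 3),), 50, 20),))
        f, res, feasible = objective(p, [270, 270, 660])
        assert not feasible and math.isinf(f)
        assert res.tolist() == [0, 0, -200]

    def test_translation_invariance(self, rng):
        for bt_id in DEFAULT_REGISTRY.ids:
            p = draw_on_grid_params(rng, bt_id)
            shifted = MAVBParams(p.delta_a, p.blocktype_id, p.levels,
                                 t_start=137.0)
            rr = forward_simulate(p, 12).ventricular_rr
            rr_shifted = forward_simulate(shifted, 12).ventricular_rr
            assert rr.tolist() == rr_shifted.tolist()
            assert objective(shifted, rr)[0] == 0.0

    def test_forward_inverse_consistency_all_presets(self, rng):
        # objective(params, forward_simulate(params)) == 0 identically
        for bt_id in DEFAULT_REGISTRY.ids:
            for _ in range(5):
                p = draw_on_grid_params(rng, bt_id)
                rr = forward_simulate(p, 22).ventricular_rr
                f, _, feasible = objective(p, rr)
                assert f == 0.0 and feasible


class TestRRSeries:
    def test_validation(self):
        with pytest.raises(ValueError):
            RRSeries(np.array([500.0]))
        with pytest.raises(ValueError):
            RRSeries(np.array([500.0, -1.0]))
        with pytest.raises(ValueError):
            RRSeries(np.array([500.0, 400.0]), label="sinus")

    def test_window(self):
        s = RRSeries(np.arange(1, 11, dtype=float), label="AFib", age=70)
        w = s.window(2, 7)
        assert w.intervals.tolist() == [3, 4, 5, 6, 7]
        assert w.label == "AFib" and w.age == 70


@settings(deadline=None, max_examples=25)
@given(
    n=st.integers(min_value=1, max_value=5),
    offset=st.integers(min_value=0, max_value=10),
)
def test_decision_cycle_structure(n, offset):
    """One blocked signal per n+1:n pair; multipliers ramp 0..n-1."""
    cycle = decision_cycle(((n + 1, n),))
    assert len(cycle) == n + 1
    assert [m for c, m in cycle if c] == list(range(n))
    assert sum(1 for c, _ in cycle if not c) == 1


def test_registry_round_trip():
    reg = BlocktypeRegistry.from_dict(DEFAULT_REGISTRY.to_dict())
    assert reg.ids == DEFAULT_REGISTRY.ids
    for i in reg.ids:
        assert reg[i] == DEFAULT_REGISTRY[i]
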