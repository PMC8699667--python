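"""Feature generation: windows, N-grams, moving-horizon series, scaling."""

import numpy as np
import pytest

from heatrr.blocks import BlockLevel
from heatrr.features import (
    FeatureVector,
    apply_standardizer,
    basic_features,
    feature_table,
    fit_standardizer,
    heat_features,
    heat_series,
    inverse_standardizer,
    moving_windows,
    ngram_features,
    saturated_objective,
    series_avg,
)
from heatrr.mavb import MAVBParams, RRSeries, forward_simulate
from heatrr.solver import SolverConfig


def _series(values, **kw):
    return RRSeries(np.asarray(values, dtype=float), **kw)


class TestBasicFeatures:
    def test_constant_series(self):
        mean, var = basic_features(_series([400, 400, 400]))
        assert (mean, var) == (400.0, 0.0)

    def test_sample_variance(self):
        mean, var = basic_features(_series([270, 270, 460]))
        assert mean == pytest.approx(333.3333, abs=1e-3)
        assert var == pytest.approx(12033.3333, abs=1e-3)

    def test_too_short(self):
        with pytest.raises(ValueError):
            RRSeries(np.array([200.0]))


class TestMovingWindows:
    @pytest.mark.parametrize(
        "n_rr,n_sub,count", [(22, 17, 6), (22, 22, 1), (12, 10, 3)]
    )
    def test_window_counts(self, n_rr, n_sub, count):
        wc = moving_windows(_series(np.arange(1, n_rr + 1)), n_sub)
        assert len(wc) == count
        assert wc.windows[0] == (0, n_sub)
        assert wc.windows[-1] == (n_rr - n_sub, n_rr)
        for (s1, e1), (s2, e2) in zip(wc.windows, wc.windows[1:]):
            assert s2 - s1 == 1 and e1 - s1 == n_sub

    @pytest.mark.parametrize("n_sub", [9, 23])
    def test_out_of_range(self, n_sub):
        with pytest.raises(ValueError):
            moving_windows(_series(np.arange(1, 23)), n_sub)


class TestNgramFeatures:
    def test_exhaustive_enumeration_n3(self):
        fv = ngram_features([1, 2, 3])
        assert len(fv) == 9
        means = fv.values[:6]
        sds = fv.values[6:]
        # ordered by start index, then length
        assert means.tolist() == [1, 1.5, 2, 2, 2.5, 3]
        assert sds == pytest.approx([0.70711, 1.0, 0.70711], abs=1e-4)

    @pytest.mark.parametrize("n,count", [(22, 484), (10, 100), (2, 4)])
    def test_square_feature_count(self, n, count):
        fv = ngram_features(np.arange(1, n + 1, dtype=float))
        assert len(fv) == count
        assert len(set(fv.names)) == count

    def test_too_short(self):
        with pytest.raises(ValueError):
            ngram_features([5.0])


class TestHeatFeatures:
    def test_nine_features_and_recovery(self):
        truth = MAVBParams(200, 2, (BlockLevel("II", ((2, 1),), 0),))
        rr = _series(forward_simulate(truth, 22).ventricular_rr,
                     sample_id="s0")
        fv = heat_features(rr)
        assert len(fv) == 9  # 18 standardisation parameters
        assert fv.feature_set == "heatSolution"
        vals = dict(zip(fv.names, fv.values))
        assert vals["heat_obj"] == 0.0
        assert vals["delta_a"] == 200.0
        assert vals["rr_var"] == 0.0
        assert vals["rr_mean"] == 400.0

    def test_infeasible_sample_saturates(self):
        cfg = SolverConfig(blocktype_ids=())
        rr = _series([400, 800, 300, 900] * 3)
        fv = heat_features(rr, cfg)
        vals = dict(zip(fv.names, fv.values))
        assert vals["heat_obj"] == saturated_objective(12)
        assert vals["delta_a"] == 0.0 and vals["blocktype"] == 0.0


class TestHeatSeries:
    def test_stationary_noiseless_series(self, fast_config):
        truth = MAVBParams(240, 2, (BlockLevel("II", ((2, 1),), 0),))
        rr = _series(forward_simulate(truth, 14).ventricular_rr)
        hs = heat_series(rr, 10, fast_config)
        assert len(hs.window_config) == 5
        assert np.all(hs.heatobj == 0.0)
        assert np.all(hs.heatfit == 0.0)  # solutions generalise across windows
        assert np.all(hs.heatsol[:, 0] == 240.0)
        comps = hs.components()
        assert len(comps) == 8
        for arr in comps.values():
            assert arr.size == 5

    def test_six_windows_at_study_defaults(self, fast_config):
        truth = MAVBParams(250, 2, (BlockLevel("II", ((3, 2),), 0),))
        rr = _series(forward_simulate(truth, 22).ventricular_rr)
        hs = heat_series(rr, 17, fast_config)
        assert hs.heatobj.size == 6
        assert hs.heatfit.size == 6
        assert hs.heatsol.shape == (6, 6)


class TestSeriesAvg:
    def _dummy_series(self, component):
        from heatrr.features import HeatSeries, WindowConfig

        n = len(component)
        return HeatSeries(
            WindowConfig(n + 9, 10),
            np.asarray(component, dtype=float),
            np.zeros((n, 6)),
            np.zeros(n),
        )

    def test_constant_component(self):
        fv = series_avg(self._dummy_series([7, 7, 7]))
        vals = dict(zip(fv.names, fv.values))
        assert vals["heat_obj_mean"] == 7.0
        assert vals["heat_obj_sd"] == 0.0
        assert len(fv) == 16  # 2 per component series

    def test_mean_and_sample_sd(self):
        fv = series_avg(self._dummy_series([0, 0, 0, 0, 0, 6]))
        vals = dict(zip(fv.names, fv.values))
        assert vals["heat_obj_mean"] == pytest.approx(1.0)
        assert vals["heat_obj_sd"] == pytest.approx(2.449, abs=1e-3)

    def test_age_appended(self):
        fv = series_avg(self._dummy_series([1, 2]), age=64)
        assert fv.feature_set == "heatSerAvgAge"
        assert fv.names[-1] == "age" and fv.values[-1] == 64.0
        assert len(fv) == 17

    def test_single_window_sd_warns(self):
        with pytest.warns(UserWarning):
            fv = series_avg(self._dummy_series([5]))
        assert dict(zip(fv.names, fv.values))["heat_obj_sd"] == 0.0


class TestStandardizer:
    def test_two_point_column(self):
        params = fit_standardizer(np.array([[1.0], [3.0]]))
        assert params.mean[0] == 2.0
        assert params.scale[0] == pytest.approx(1.0)  # population sd of {1,3}
        assert apply_standardizer(params, np.array([[2.0]]))[0, 0] == 0.0

    def test_train_columns_become_standard(self, rng):
        X = rng.normal(50, 9, size=(40, 5))
        params = fit_standardizer(X)
        Z = apply_standardizer(params, X)
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(Z.std(axis=0), 1, atol=1e-12)

    def test_no_leakage_on_held_out(self, rng):
        train, test = rng.normal(0, 1, (30, 3)), rng.normal(2, 1, (30, 3))
        params = fit_standardizer(train)
        Z = apply_standardizer(params, test)
        assert np.all(np.abs(Z.mean(axis=0)) > 0.5)

    def test_round_trip(self, rng):
        X = rng.normal(10, 4, (20, 4))
        params = fit_standardizer(X)
        back = inverse_standardizer(params, apply_standardizer(params, X))
        assert np.allclose(back, X, atol=1e-9)

    def test_constant_column_scale_one(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.warns(UserWarning):
            params = fit_standardizer(X)
        assert params.scale[1] == 1.0


class TestFeatureTable:
    def test_determinism_and_shapes(self, fast_config):
        truth = MAVBParams(250, 2, (BlockLevel("II", ((2, 1),), 0),))
        samples = [
            _series(forward_simulate(truth, 12).ventricular_rr,
                    label="AFlu", age=60.0, sample_id=f"s{i}")
            for i in range(3)
        ]
        t1 = feature_table(samples, "heatSolution", fast_config)
        t2 = feature_table(samples, "heatSolution", fast_config)
        assert t1.equals(t2)
        assert t1.shape == (3, 3 + 9)
        raw = feature_table(samples, "rawRR", fast_config, n_sub=10)
        assert raw.shape == (3, 3 + 100)

    def test_feature_vector_validation(self):
        with pytest.raises(ValueError):
            FeatureVector(["a"], np.array([1.0, 2.0]), "rawRR")
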