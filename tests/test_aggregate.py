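"""Electrode weighting, aggregate time course, slope statistic, projection."""

import numpy as np
import pandas as pd
import pytest

from driftband import aggregate as agg
from driftband import layout as lay
from driftband import synth
from driftband.aggregate import (AggregateTimecourse, ElectrodeWeights,
                                 difficulty_labels, median_hard_rt,
                                 scalp_projection, slope_statistic)


class TestDifficultyLabels:
    def test_mapping_total_on_six_conditions(self):
        out = difficulty_labels([1, 2, 3, 4, 5, 6])
        np.testing.assert_array_equal(out, [0, 0, -1, -1, 1, 1])

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            difficulty_labels([7])


class TestMedianHardRT:
    def _trials(self, rts, conds):
        return pd.DataFrame({"subject": ["a"] * len(rts),
                             "condition": conds, "rt_s": rts})

    def test_odd_count_median(self):
        t = self._trials([0.6, 0.8, 1.0], [1, 1, 2])
        assert median_hard_rt(t)["a"] == pytest.approx(800.0)

    def test_midpoint_convention(self):
        t = self._trials([0.6, 1.0], [1, 2])
        assert median_hard_rt(t)["a"] == pytest.approx(800.0)

    def test_snapping_to_grid(self):
        t = self._trials([0.83], [1])
        grid = np.arange(0.0, 1001.0, 50.0)
        assert median_hard_rt(t, grid_ms=grid)["a"] == 850.0

    def test_no_hard_trials_errors(self):
        t = self._trials([0.6, 0.7], [5, 6])
        with pytest.raises(ValueError, match="hard"):
            median_hard_rt(t)


def _mk_weights(coef, channels):
    """Weights container with identity scaler (coef: (draws, channels))."""
    coef = np.asarray(coef, dtype=float)[None, :, :]  # 1 chain
    nch = coef.shape[-1]
    return ElectrodeWeights(group_coef=coef, channels=tuple(channels),
                            scaler_mean=np.zeros(nch), scaler_sd=np.ones(nch),
                            subjects=["a"], diagnostics={})


def _mk_tensor(power, conds, channels, times):
    return synth.BandPowerTensor(
        power=power, subjects=["a"], conditions=conds,
        channels=tuple(channels), times_ms=np.asarray(times, dtype=float),
        band="gamma")


class TestApplyWeights:
    times = np.arange(-200.0, 901.0, 50.0)

    def _tensor(self, rng, n_ch=3, n_tr=12):
        power = rng.normal(size=(1, n_tr, n_ch, self.times.size))
        conds = np.tile(np.arange(1, 7), n_tr // 6)[None, :]
        chans = [f"c{i}" for i in range(n_ch)]
        return _mk_tensor(power, conds, chans, self.times)

    def test_zero_weights_zero_aggregate(self, rng):
        tensor = self._tensor(rng)
        w = _mk_weights(np.zeros((5, 3)), tensor.channels)
        out = agg.apply_weights(w, tensor, standardize=False)
        np.testing.assert_allclose(out.values, 0.0)

    def test_single_channel_linearity(self, rng):
        tensor = self._tensor(rng)
        coef = np.zeros((4, 3))
        coef[:, 1] = 2.5
        w = _mk_weights(coef, tensor.channels)
        out = agg.apply_weights(w, tensor, standardize=False)
        cond_mask = tensor.conditions[0] == 3
        expect = 2.5 * tensor.power[0, cond_mask, 1, :].mean(axis=0)
        np.testing.assert_allclose(out.values[0, 0, 2], expect, atol=1e-12)

    def test_matches_brute_force_nested_loops(self, rng):
        tensor = self._tensor(rng)
        coef = rng.normal(size=(6, 3))
        w = _mk_weights(coef, tensor.channels)
        out = agg.apply_weights(w, tensor, standardize=False)
        for d in range(6):
            for ci, cond in enumerate(range(1, 7)):
                m = tensor.conditions[0] == cond
                brute = np.zeros(self.times.size)
                for tr in np.flatnonzero(m):
                    for ch in range(3):
                        brute += coef[d, ch] * tensor.power[0, tr, ch]
                brute /= m.sum()
                np.testing.assert_allclose(out.values[d, 0, ci], brute,
                                           atol=1e-10)

    def test_linearity_in_power(self, rng):
        t1 = self._tensor(rng)
        t2 = self._tensor(rng)
        coef = rng.normal(size=(3, 3))
        w = _mk_weights(coef, t1.channels)
        mix = _mk_tensor(2.0 * t1.power + 0.5 * t2.power, t1.conditions,
                         t1.channels, self.times)
        out = agg.apply_weights(w, mix, standardize=False)
        a = agg.apply_weights(w, t1, standardize=False)
        b = agg.apply_weights(w, t2, standardize=False)
        np.testing.assert_allclose(out.values, 2.0 * a.values + 0.5 * b.values,
                                   atol=1e-10)

    def test_channel_mismatch_errors(self, rng):
        tensor = self._tensor(rng)
        w = _mk_weights(np.zeros((2, 3)), ["x", "y", "z"])
        with pytest.raises(ValueError):
            agg.apply_weights(w, tensor)


class TestSlopeStatistic:
    times = np.arange(-200.0, 1001.0, 50.0)

    def _course(self, values):
        return AggregateTimecourse(values=values, subjects=["a"],
                                   conditions=tuple(range(1, 7)),
                                   times_ms=self.times, band="gamma")

    def test_linear_ramp_recovers_increment(self):
        y = 2.0 + 0.004 * self.times
        vals = np.tile(y, (2, 1, 6, 1))
        est = slope_statistic(self._course(vals))
        np.testing.assert_allclose(est.values, 0.2, atol=1e-12)
        np.testing.assert_allclose(est.point, 0.2, atol=1e-12)

    def test_telescoping_identity(self, rng):
        vals = rng.normal(size=(3, 2, 6, self.times.size))
        est = slope_statistic(self._course(vals))
        i300 = np.flatnonzero(self.times == 300.0)[0]
        i800 = np.flatnonzero(self.times == 800.0)[0]
        expect = (vals[..., i800] - vals[..., i300]) / 10.0
        np.testing.assert_allclose(est.values, expect, atol=1e-12)

    def test_unbiased_under_noise(self, rng):
        true = 0.2
        reps = 1000
        y = true * (self.times / 50.0)
        vals = y[None, None, None, :] + 0.5 * rng.standard_normal(
            (reps, 1, 1, self.times.size))
        est = slope_statistic(AggregateTimecourse(
            values=vals, subjects=["a"], conditions=(1,),
            times_ms=self.times, band="beta"))
        assert est.values.mean() == pytest.approx(true, abs=0.01)

    def test_missing_grid_point_errors(self):
        times = np.arange(-200.0, 1001.0, 100.0)
        vals = np.zeros((1, 1, 6, times.size))
        course = AggregateTimecourse(values=vals, subjects=["a"],
                                     conditions=tuple(range(1, 7)),
                                     times_ms=times, band="gamma")
        with pytest.raises(ValueError):
            slope_statistic(course)


class TestScalpProjection:
    def test_identical_channel_projects_to_one(self, rng):
        T, D = 20, 4
        Y = rng.normal(size=(1, T, D))
        X = np.tile(Y[0, :, 0], (3, 1))[None, :, :]
        X[0, 1] = rng.normal(size=T)  # make other channels arbitrary
        X[0, 0] = Y[0, :, 0]
        m, _ = scalp_projection(X, Y[..., :1])
        assert m[0] == pytest.approx(1.0)

    def test_orthogonal_channel_projects_to_zero(self):
        T = 8
        y = np.zeros((1, T, 1))
        y[0, :, 0] = np.sin(2 * np.pi * np.arange(T) / T)
        x = np.zeros((1, 1, T))
        x[0, 0] = np.cos(2 * np.pi * np.arange(T) / T)
        m, _ = scalp_projection(x, y)
        assert m[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_regression_through_origin(self, rng):
        T = 30
        X = rng.normal(size=(1, 5, T))
        Y = rng.normal(size=(1, T, 1))
        m, _ = scalp_projection(X, Y)
        for ch in range(5):
            beta = np.dot(X[0, ch], Y[0, :, 0]) / np.dot(Y[0, :, 0], Y[0, :, 0])
            assert m[ch] == pytest.approx(beta, rel=1e-10)

    def test_zero_norm_column_flagged_nan(self, rng):
        X = rng.normal(size=(1, 2, 5))
        Y = np.zeros((1, 5, 2))
        Y[0, :, 1] = rng.normal(size=5)
        med, per_draw = scalp_projection(X, Y)
        assert np.isnan(per_draw[:, 0]).all()
        assert np.isfinite(med).all()  # median over remaining draws


class TestExcludeFrontal:
    def test_64_to_48(self, rng):
        layout = lay.default_layout()
        power = rng.normal(size=(1, 4, 64, 5))
        tensor = _mk_tensor(power, np.array([[1, 2, 5, 6]]), layout.names,
                            np.arange(5.0))
        red = agg.exclude_frontal_tensor(tensor, layout)
        assert red.power.shape[2] == 48
        assert set(red.channels).isdisjoint(lay.FRONTAL16)

    def test_no_frontal_flag_is_identity(self, rng):
        layout = lay.ChannelLayout(names=("a", "b"), is_frontal=(False, False))
        power = rng.normal(size=(1, 2, 2, 3))
        tensor = _mk_tensor(power, np.array([[1, 5]]), ("a", "b"),
                            np.arange(3.0))
        red = agg.exclude_frontal_tensor(tensor, layout)
        np.testing.assert_array_equal(red.power, tensor.power)

    def test_layout_mismatch_errors(self, rng):
        layout = lay.default_layout()
        power = rng.normal(size=(1, 2, 3, 3))
        tensor = _mk_tensor(power, np.array([[1, 5]]), ("a", "b", "c"),
                            np.arange(3.0))
        with pytest.raises(ValueError):
            agg.exclude_frontal_tensor(tensor, layout)


class TestFrontalExclusionRobustness:
    def test_slope_estimates_survive_frontal_exclusion(self, tiny_dataset):
        """With planted posterior-channel signal, the aggregate slope
        estimates barely change when the 16 frontal channels are dropped."""
        ds = tiny_dataset
        layout = lay.default_layout()
        tensor = synth.generate_power(ds["cohort"], ds["trials"], layout,
                                      ds["truth"], ds["slopes"], "gamma",
                                      seed=21)
        trials = ds["trials"]
        grid = tensor.times_ms
        rt_ms = agg.median_hard_rt(trials, grid_ms=grid)

        def slopes_for(t):
            x, y, si, subs = agg.power_at_timepoint(t, rt_ms)
            w = agg.fit_electrode_weights(x, y, si, subs, t.channels,
                                          chains=2, warmup=150, iters=200,
                                          seed=4)
            course = agg.apply_weights(w, t, n_draws=40, seed=4)
            return agg.slope_statistic(course).point.ravel()

        full = slopes_for(tensor)
        reduced = slopes_for(agg.exclude_frontal_tensor(tensor, layout))
        r = np.corrcoef(full, reduced)[0, 1]
        assert r > 0.8
        truth = (ds["slopes"][ds["slopes"]["band"] == "gamma"]
                 .pivot(index="subject", columns="condition", values="slope")
                 .loc[tensor.subjects].to_numpy().ravel())
        assert np.corrcoef(truth, reduced)[0, 1] > 0.7


class TestHDF5RoundTrips:
    def test_weights(self, rng, tmp_path):
        w = _mk_weights(rng.normal(size=(5, 3)), ["a", "b", "c"])
        p = tmp_path / "w.h5"
        w.to_hdf5(p)
        back = ElectrodeWeights.from_hdf5(p)
        np.testing.assert_array_equal(back.group_coef, w.group_coef)
        assert back.channels == w.channels

    def test_timecourse(self, rng, tmp_path):
        times = np.arange(-200.0, 901.0, 50.0)
        course = AggregateTimecourse(
            values=rng.normal(size=(3, 2, 6, times.size)),
            subjects=["a", "b"], conditions=tuple(range(1, 7)),
            times_ms=times, band="beta")
        p = tmp_path / "agg.h5"
        course.to_hdf5(p)
        back = AggregateTimecourse.from_hdf5(p)
        np.testing.assert_array_equal(back.values, course.values)
        assert back.band == "beta"


class TestElectrodeWeightFit:
    def _planted(self, rng, sep=2.0, n_ch=6, n_sub=5, n_tr=40):
        xs, ys, si = [], [], []
        for s in range(n_sub):
            y = rng.integers(0, 2, n_tr)
            x = rng.standard_normal((n_tr, n_ch))
            x[:, 2] += sep * y          # planted signal channel
            xs.append(x)
            ys.append(y)
            si.append(np.full(n_tr, s))
        return (np.concatenate(xs), np.concatenate(ys), np.concatenate(si),
                [f"s{k}" for k in range(n_sub)])

    def test_planted_channel_ranked_first(self, rng):
        x, y, si, subs = self._planted(rng)
        w = agg.fit_electrode_weights(x, y, si, subs,
                                      [f"c{i}" for i in range(6)],
                                      chains=2, warmup=200, iters=300, seed=0)
        med = np.abs(np.median(w.flat_coef(), axis=0))
        assert np.argmax(med) == 2

    def test_relabeling_flips_signs(self, rng):
        x, y, si, subs = self._planted(rng)
        chans = [f"c{i}" for i in range(6)]
        w1 = agg.fit_electrode_weights(x, y, si, subs, chans, chains=2,
                                       warmup=200, iters=300, seed=3)
        w2 = agg.fit_electrode_weights(x, 1 - y, si, subs, chans, chains=2,
                                       warmup=200, iters=300, seed=3)
        m1 = np.median(w1.flat_coef(), axis=0)
        m2 = np.median(w2.flat_coef(), axis=0)
        assert np.all(np.sign(m1[np.abs(m1) > 0.1])
                      == -np.sign(m2[np.abs(m1) > 0.1]))

    def test_single_class_subject_dropped(self, rng):
        x, y, si, subs = self._planted(rng, n_sub=3)
        y[si == 2] = 1  # subject 3 has one class
        with pytest.warns(RuntimeWarning, match="single difficulty class"):
            w = agg.fit_electrode_weights(x, y, si, subs,
                                          [f"c{i}" for i in range(6)],
                                          chains=2, warmup=50, iters=50,
                                          seed=1)
        assert w.subjects == ["s0", "s1"]
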