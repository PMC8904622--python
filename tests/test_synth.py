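"""Synthetic cohort, behavior, and power generators."""

import numpy as np
import pandas as pd
import pytest

from driftband import layout as lay
from driftband import synth


class TestCohort:
    def test_full_design_bin_counts(self):
        cohort = synth.generate_cohort(67, (19, 18, 15, 15), seed=0)
        padua = np.array([p.padua for p in cohort])
        assert len(cohort) == 67
        assert (padua <= 16).sum() == 19
        assert ((padua >= 17) & (padua <= 33)).sum() == 18
        assert ((padua >= 34) & (padua <= 50)).sum() == 15
        assert (padua >= 51).sum() == 15

    def test_single_bin(self):
        cohort = synth.generate_cohort(1, (1, 0, 0, 0), seed=0)
        assert len(cohort) == 1
        assert 0 <= cohort[0].padua <= 16

    def test_mismatched_totals_error(self):
        with pytest.raises(ValueError):
            synth.generate_cohort(10, (1, 1, 1, 1), seed=0)

    def test_same_seed_identical(self):
        a = synth.generate_cohort(12, (3, 3, 3, 3), seed=42)
        b = synth.generate_cohort(12, (3, 3, 3, 3), seed=42)
        assert a == b

    def test_worry_correlated_and_skewed(self):
        cohort = synth.generate_cohort(200, (50, 50, 50, 50), seed=7)
        padua = np.array([p.padua for p in cohort], dtype=float)
        worry = np.array([p.worry for p in cohort], dtype=float)
        assert np.corrcoef(padua, worry)[0, 1] > 0.15
        # right skew: mean above the midpoint of the 16-80 range
        assert worry.mean() > 48
        from scipy.stats import skew
        assert skew(worry) < 0  # mass piled toward the upper range


class TestBehavior:
    def test_720_trials_per_subject(self):
        cohort = synth.generate_cohort(2, (1, 1, 0, 0), seed=0)
        trials = synth.generate_behavior(cohort, synth.GroundTruth(),
                                         n_trials_per_condition=120, seed=0)
        per = trials.groupby("subject").size()
        assert (per == 720).all()

    def test_direction_fair_coin(self):
        cohort = synth.generate_cohort(2, (1, 1, 0, 0), seed=1)
        trials = synth.generate_behavior(cohort, synth.GroundTruth(),
                                         n_trials_per_condition=120, seed=1)
        frac = (trials["direction"] == 1).mean()
        assert 0.45 < frac < 0.55

    def test_huge_drift_gives_perfect_accuracy(self):
        truth = synth.GroundTruth(drift_c=(0.5, 1, 2, 3, 4, 30.0),
                                  subj_drift_sd=0.01)
        cohort = synth.generate_cohort(2, (1, 1, 0, 0), seed=2, truth=truth)
        trials = synth.generate_behavior(cohort, truth, 60, seed=2)
        easy = trials[trials["condition"] == 6]
        assert (easy["choice"] == easy["direction"]).mean() > 0.999

    def test_accuracy_monotone_in_coherence(self):
        # expectation check over replicate cohorts
        accs = np.zeros(6)
        for rep in range(5):
            ds = synth.generate_dataset(8, n_trials_per_condition=30,
                                        seed=100 + rep)
            t = ds["trials"]
            correct = t["choice"] == t["direction"]
            accs += np.array([correct[t["condition"] == c].mean()
                              for c in range(1, 7)])
        assert np.all(np.diff(accs) > -0.02 * 5)  # non-decreasing up to noise

    def test_negative_padua_effect_shows_in_easy_accuracy(self):
        # planted drift_padua = -0.3 for the easy conditions: sample
        # correlation between padua and easy accuracy is negative across
        # replicate cohorts
        truth = synth.GroundTruth(
            drift_padua=(0, 0, 0, 0, -0.3, -0.3),
            drift_gamma=(0.0,) * 6, drift_beta=(0.0,) * 6)
        corrs = []
        for rep in range(20):
            cohort = synth.generate_cohort(40, (10, 10, 10, 10),
                                           seed=300 + rep, truth=truth)
            trials = synth.generate_behavior(cohort, truth, 20, seed=300 + rep)
            easy = trials[trials["condition"].isin([5, 6])]
            acc = easy.assign(ok=(easy["choice"] == easy["direction"])) \
                      .groupby("subject")["ok"].mean()
            padua = pd.Series({p.subject_id: p.padua for p in cohort})
            corrs.append(np.corrcoef(padua[acc.index], acc)[0, 1])
        assert np.mean(corrs) < -0.1

    def test_nonpositive_boundary_errors(self):
        truth = synth.GroundTruth(boundary_padua=(-9.0,) * 6)
        cohort = synth.generate_cohort(4, (1, 1, 1, 1), seed=3, truth=truth)
        with pytest.raises(ValueError):
            synth.generate_behavior(cohort, truth, 5, seed=3)

    def test_same_seed_identical_trials(self):
        ds1 = synth.generate_dataset(4, n_trials_per_condition=10, seed=9)
        ds2 = synth.generate_dataset(4, n_trials_per_condition=10, seed=9)
        pd.testing.assert_frame_equal(ds1["trials"], ds2["trials"])
        pd.testing.assert_frame_equal(ds1["slopes"], ds2["slopes"])


class TestNeuralSlopes:
    def test_planted_padua_effect_recovers_in_correlation(self):
        truth = synth.GroundTruth(beta=synth.BandTruth(
            b0=(0.1,) * 6, b_padua=(-0.3,) * 6, b_worry=(0.0,) * 6,
            eps_sd=0.2))
        corrs = []
        for rep in range(20):
            cohort = synth.generate_cohort(40, (10, 10, 10, 10), seed=rep,
                                           truth=truth)
            slopes = synth.generate_neural_slopes(cohort, truth, seed=rep)
            beta = slopes[slopes["band"] == "beta"]
            padua = pd.Series({p.subject_id: p.padua for p in cohort})
            per_subj = beta.groupby("subject")["slope"].mean()
            corrs.append(np.corrcoef(padua[per_subj.index], per_subj)[0, 1])
        assert np.mean(corrs) < -0.5


class TestPower:
    def test_null_channel_effects_give_no_signal(self, tiny_dataset):
        ds = tiny_dataset
        layout = lay.default_layout()
        tensor = synth.generate_power(
            ds["cohort"], ds["trials"], layout, ds["truth"], ds["slopes"],
            "gamma", seed=0, channel_effects=np.zeros(64))
        post = tensor.power[..., tensor.times_ms > 0]
        assert abs(post.mean()) < 0.01  # pure noise

    def test_baseline_has_no_ramp(self, tiny_dataset):
        ds = tiny_dataset
        layout = lay.default_layout()
        tensor = synth.generate_power(
            ds["cohort"], ds["trials"], layout, ds["truth"], ds["slopes"],
            "gamma", seed=1, noise_sd=0.0)
        base = tensor.power[..., tensor.times_ms <= 0]
        np.testing.assert_allclose(base, 0.0, atol=1e-12)

    def test_ramp_matches_planted_slope(self, tiny_dataset):
        ds = tiny_dataset
        layout = lay.default_layout()
        tensor = synth.generate_power(
            ds["cohort"], ds["trials"], layout, ds["truth"], ds["slopes"],
            "gamma", seed=1, noise_sd=0.0)
        eff = lay.channel_effect_map(layout, "gamma")
        ch = int(np.argmax(eff))
        sid = tensor.subjects[0]
        cond = tensor.conditions[0][0]
        truth_slope = ds["slopes"].query(
            "subject == @sid and condition == @cond and band == 'gamma'"
        )["slope"].item()
        t1 = np.flatnonzero(tensor.times_ms == 300.0)[0]
        t2 = np.flatnonzero(tensor.times_ms == 350.0)[0]
        inc = tensor.power[0, 0, ch, t2] - tensor.power[0, 0, ch, t1]
        assert inc == pytest.approx(eff[ch] * truth_slope, rel=1e-9)

    def test_time_grid_must_cover_baseline(self, tiny_dataset):
        ds = tiny_dataset
        layout = lay.default_layout()
        with pytest.raises(ValueError):
            synth.generate_power(ds["cohort"], ds["trials"], layout,
                                 ds["truth"], ds["slopes"], "gamma",
                                 time_grid_ms=np.arange(0, 900, 50.0))

    def test_same_seed_identical_tensor(self, tiny_dataset):
        ds = tiny_dataset
        layout = lay.default_layout()
        kw = dict(time_grid_ms=np.arange(-200, 901, 50.0), seed=5)
        a = synth.generate_power(ds["cohort"], ds["trials"], layout,
                                 ds["truth"], ds["slopes"], "beta", **kw)
        b = synth.generate_power(ds["cohort"], ds["trials"], layout,
                                 ds["truth"], ds["slopes"], "beta", **kw)
        np.testing.assert_array_equal(a.power, b.power)

    def test_hdf5_round_trip(self, tiny_dataset, tmp_path):
        ds = tiny_dataset
        layout = lay.default_layout()
        tensor = synth.generate_power(
            ds["cohort"], ds["trials"], layout.subset(range(4)), ds["truth"],
            ds["slopes"], "gamma", seed=2,
            channel_effects=np.ones(4))
        path = tmp_path / "power.h5"
        tensor.to_hdf5(path)
        back = synth.BandPowerTensor.from_hdf5(path)
        np.testing.assert_array_equal(back.power, tensor.power)
        assert back.band == "gamma"
        assert back.channels == tensor.channels


class TestRawOscillations:
    def _small(self, tiny_dataset, n=4):
        ds = tiny_dataset
        layout = lay.default_layout().subset(range(2))
        trials = ds["trials"].head(n)
        return ds, layout, trials

    def test_shapes_and_determinism(self, tiny_dataset):
        ds, layout, trials = self._small(tiny_dataset)
        kw = dict(band="beta", sampling_rate=500.0, seed=3,
                  channel_effects=np.ones(2))
        a, ta = synth.generate_raw_oscillations(trials, layout, ds["truth"],
                                                ds["slopes"], **kw)
        b, _ = synth.generate_raw_oscillations(trials, layout, ds["truth"],
                                               ds["slopes"], **kw)
        assert a.shape == (4, 2, ta.size)
        np.testing.assert_array_equal(a, b)

    def test_nyquist_violation_rejected(self, tiny_dataset):
        ds, layout, trials = self._small(tiny_dataset)
        with pytest.raises(ValueError, match="Nyquist"):
            synth.generate_raw_oscillations(trials, layout, ds["truth"],
                                            ds["slopes"], band="gamma",
                                            sampling_rate=500.0,
                                            carrier_hz=300.0)

    def test_low_sampling_rate_rejected(self, tiny_dataset):
        ds, layout, trials = self._small(tiny_dataset)
        with pytest.raises(ValueError):
            synth.generate_raw_oscillations(trials, layout, ds["truth"],
                                            ds["slopes"], band="beta",
                                            sampling_rate=100.0)

    def test_flat_envelope_when_ramp_gain_zero(self, tiny_dataset):
        ds, layout, trials = self._small(tiny_dataset, n=2)
        sig, t_ms = synth.generate_raw_oscillations(
            trials, layout, ds["truth"], ds["slopes"], band="beta",
            seed=1, ramp_gain=0.0, noise_sd=0.0, channel_effects=np.ones(2))
        # constant-amplitude carrier: RMS equal pre and post stimulus
        pre = sig[0, 0, t_ms < 0]
        post = sig[0, 0, t_ms > 500]
        assert np.std(post) == pytest.approx(np.std(pre), rel=0.05)


class TestLayout:
    def test_64_channels_16_frontal(self):
        layout = lay.default_layout()
        assert layout.n_channels == 64
        assert len(layout.frontal_indices) == 16
        assert set(np.array(layout.names)[layout.frontal_indices]) == set(lay.FRONTAL16)

    def test_exclude_frontal_keeps_48(self):
        layout = lay.default_layout()
        reduced, keep = lay.exclude_frontal(layout)
        assert reduced.n_channels == 48
        assert not any(reduced.is_frontal)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            lay.ChannelLayout(names=("a", "a"), is_frontal=(False, False))

    def test_csv_round_trip(self, tmp_path):
        layout = lay.default_layout()
        p = tmp_path / "layout.csv"
        layout.to_csv(p)
        assert lay.ChannelLayout.from_csv(p) == layout

    def test_effect_map_signs(self):
        layout = lay.default_layout()
        g = lay.channel_effect_map(layout, "gamma")
        b = lay.channel_effect_map(layout, "beta")
        assert g[layout.index("Pz")] > 0 and g[layout.index("Fp1")] < 0
        assert b[layout.index("POz")] < 0 and b[layout.index("Fp1")] > 0
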