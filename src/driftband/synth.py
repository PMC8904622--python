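"""Synthetic cohorts, behavior, and EEG band power with known ground truth.

The generator reproduces the statistical structure the analysis pipeline
assumes: a cohort covering four obsessive-compulsive (Padua) score bins
with positively correlated, right-skewed worry scores; per-subject neural
ramp slopes generated from the slope-on-symptoms regression; dot-motion
choices and RTs simulated from a drift-diffusion model whose drift and
boundary are assembled from the same linear model the sampler fits; and
per-trial band-power time series whose within-trial ramp carries each
subject/condition slope through a spatial channel-effect map.

Ground-truth parameters travel with the outputs so recovery tests never
re-derive them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _wfpt
from .layout import ChannelLayout, channel_effect_map, default_layout

COHERENCES = (0.025, 0.05, 0.15, 0.25, 0.45, 0.7)
PADUA_BINS = ((0, 16), (17, 33), (34, 50), (51, 80))
N_CONDITIONS = 6


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    padua: int
    worry: int
    true_drift_offset: float
    true_boundary_offset: float
    true_ndt: float

    def __post_init__(self):
        if self.padua < 0 or self.worry < 0:
            raise ValueError("symptom scores must be non-negative")
        if not (np.isfinite(self.true_drift_offset)
                and np.isfinite(self.true_boundary_offset)):
            raise ValueError("subject offsets must be finite")


@dataclass(frozen=True)
class BandTruth:
    """Slope-on-symptoms regression truth for one band (per condition)."""
    b0: tuple
    b_padua: tuple
    b_worry: tuple
    eps_sd: float


@dataclass(frozen=True)
class GroundTruth:
    coherences: tuple = COHERENCES
    drift_c: tuple = (0.4, 0.7, 1.4, 2.1, 3.2, 4.2)
    boundary_c: tuple = (1.7, 1.7, 1.6, 1.6, 1.5, 1.5)
    drift_padua: tuple = (0.0, 0.0, -0.05, -0.1, -0.25, -0.35)
    drift_worry: tuple = (0.0,) * 6
    drift_gamma: tuple = (0.25,) * 6
    drift_beta: tuple = (0.25,) * 6
    boundary_padua: tuple = (0.0,) * 6
    boundary_worry: tuple = (0.0,) * 6
    boundary_gamma: tuple = (0.0,) * 6
    boundary_beta: tuple = (0.0,) * 6
    subj_drift_sd: float = 0.3
    subj_boundary_sd: float = 0.15
    ndt_mean: float = 0.4
    ndt_sd: float = 0.05
    # Band slopes are on the scale of the aggregate whole-brain measure
    # (which ramps upward in both bands); the channel-effect map carries
    # the sign of the underlying raw ramps (negative parieto-occipital
    # ramps for beta, positive posterior/lateral ramps for gamma).
    gamma: BandTruth = field(default_factory=lambda: BandTruth(
        b0=(0.05, 0.08, 0.12, 0.18, 0.26, 0.32),
        b_padua=(0.0,) * 6, b_worry=(0.0,) * 6, eps_sd=0.08))
    beta: BandTruth = field(default_factory=lambda: BandTruth(
        b0=(0.05, 0.08, 0.12, 0.18, 0.26, 0.32),
        b_padua=(-0.04,) * 6, b_worry=(0.0,) * 6, eps_sd=0.08))

    def __post_init__(self):
        if np.any(np.asarray(self.boundary_c) <= 0):
            raise ValueError("boundary separations must be positive")
        if self.ndt_mean <= 0:
            raise ValueError("non-decision time must be positive")

    def band(self, name: str) -> BandTruth:
        if name not in ("gamma", "beta"):
            raise ValueError(f"unknown band: {name!r}")
        return getattr(self, name)


def null_truth() -> GroundTruth:
    """Study conditions with every symptom and neural effect removed."""
    z = (0.0,) * 6
    b0 = (0.05, 0.08, 0.12, 0.18, 0.26, 0.32)
    return GroundTruth(
        drift_padua=z, drift_worry=z, drift_gamma=z, drift_beta=z,
        gamma=BandTruth(b0=b0, b_padua=z, b_worry=z, eps_sd=0.08),
        beta=BandTruth(b0=b0, b_padua=z, b_worry=z, eps_sd=0.08))


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def generate_cohort(n_subjects, bin_targets=(19, 18, 15, 15), seed=0,
                    worry_corr=0.4, worry_skew=(5.0, 2.0),
                    truth: GroundTruth | None = None):
    """Cohort of subject profiles with Padua scores hitting the requested
    per-bin counts and worry scores positively correlated + right-skewed.

    worry scores are drawn through a Gaussian copula (correlation
    ``worry_corr`` with the Padua latent) with a Beta(*worry_skew*) marginal
    mapped onto the 16-80 questionnaire range, giving the documented skew
    toward the upper range.
    """
    from scipy import stats

    if len(bin_targets) != 4:
        raise ValueError("bin_targets must have length 4")
    if sum(bin_targets) != n_subjects:
        raise ValueError(
            f"n_subjects ({n_subjects}) must equal sum of bin_targets "
            f"({sum(bin_targets)})")
    truth = truth or GroundTruth()
    rng = np.random.default_rng(seed)
    profiles = []
    k = 0
    for (lo, hi), count in zip(PADUA_BINS, bin_targets):
        for _ in range(count):
            padua = int(rng.integers(lo, hi + 1))
            # latent copula: correlate worry with the padua bin position
            z_pad = (padua - 40.0) / 25.0
            z_lat = worry_corr * z_pad + np.sqrt(1 - worry_corr ** 2) * rng.standard_normal()
            u = stats.norm.cdf(z_lat)
            w01 = stats.beta.ppf(u, *worry_skew)
            worry = int(np.clip(np.round(16 + 64 * w01), 16, 80))
            ndt = -1.0
            while ndt <= 0.05:
                ndt = truth.ndt_mean + truth.ndt_sd * rng.standard_normal()
            profiles.append(SubjectProfile(
                subject_id=f"s{k:03d}", padua=padua, worry=worry,
                true_drift_offset=truth.subj_drift_sd * rng.standard_normal(),
                true_boundary_offset=truth.subj_boundary_sd * rng.standard_normal(),
                true_ndt=ndt))
            k += 1
    return profiles


def cohort_frame(cohort) -> pd.DataFrame:
    return pd.DataFrame({
        "subject": [p.subject_id for p in cohort],
        "padua_raw": [p.padua for p in cohort],
        "worry_raw": [p.worry for p in cohort],
    })


def _zscore(x):
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in scores")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# neural slopes (slope-on-symptoms regression structure)
# ---------------------------------------------------------------------------


def generate_neural_slopes(cohort, truth: GroundTruth, seed=0,
                           bands=("gamma", "beta")) -> pd.DataFrame:
    """Per subject x condition x band ramp slopes (units: normalized power
    per 50 ms), generated from the slope-on-symptoms linear model with
    Gaussian residuals."""
    rng = np.random.default_rng(seed)
    padua_z = _zscore([p.padua for p in cohort])
    worry_z = _zscore([p.worry for p in cohort])
    rows = []
    for band in bands:
        bt = truth.band(band)
        for c in range(N_CONDITIONS):
            eps = bt.eps_sd * rng.standard_normal(len(cohort))
            sl = (bt.b0[c] + bt.b_padua[c] * padua_z
                  + bt.b_worry[c] * worry_z + eps)
            for i, p in enumerate(cohort):
                rows.append((p.subject_id, c + 1, band, sl[i]))
    return pd.DataFrame(rows, columns=["subject", "condition", "band", "slope"])


def _slopes_z_by_condition(slopes: pd.DataFrame, band: str, subjects):
    """(S, C) matrix of slopes z-scored across subjects within condition."""
    sub = slopes[slopes["band"] == band]
    mat = (sub.pivot(index="subject", columns="condition", values="slope")
           .loc[list(subjects)].to_numpy())
    sd = mat.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero variance in neural slopes within a condition")
    return (mat - mat.mean(axis=0)) / sd


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------


def assemble_true_drift(cohort, truth: GroundTruth, slopes=None):
    """True (S, C) drift and boundary matrices under the generating model."""
    padua_z = _zscore([p.padua for p in cohort])
    worry_z = _zscore([p.worry for p in cohort])
    subjects = [p.subject_id for p in cohort]
    S, C = len(cohort), N_CONDITIONS
    if slopes is not None:
        gz = _slopes_z_by_condition(slopes, "gamma", subjects)
        bz = _slopes_z_by_condition(slopes, "beta", subjects)
    else:
        gz = bz = np.zeros((S, C))
    drift = np.empty((S, C))
    bound = np.empty((S, C))
    for s, p in enumerate(cohort):
        for c in range(C):
            drift[s, c] = (truth.drift_c[c] + p.true_drift_offset
                           + truth.drift_padua[c] * padua_z[s]
                           + truth.drift_worry[c] * worry_z[s]
                           + truth.drift_gamma[c] * gz[s, c]
                           + truth.drift_beta[c] * bz[s, c])
            bound[s, c] = (truth.boundary_c[c] + p.true_boundary_offset
                           + truth.boundary_padua[c] * padua_z[s]
                           + truth.boundary_worry[c] * worry_z[s]
                           + truth.boundary_gamma[c] * gz[s, c]
                           + truth.boundary_beta[c] * bz[s, c])
    return drift, bound


def generate_behavior(cohort, truth: GroundTruth, n_trials_per_condition=120,
                      seed=0, slopes: pd.DataFrame | None = None,
                      dt=0.001) -> pd.DataFrame:
    """Simulate the dot-motion trial table from the drift-diffusion model.

    Motion direction is a fair coin; the drift toward the correct boundary
    for subject s in condition c is assembled from the ground-truth linear
    model (symptom scores z-scored across the cohort, neural slopes z-scored
    within condition when supplied).  RTs include the subject's non-decision
    time; trials that fail to absorb within 10 s are kept with the censoring
    cap and fall to the RT filter downstream.
    """
    drift, bound = assemble_true_drift(cohort, truth, slopes)
    if np.any(bound <= 0):
        raise ValueError("assembled boundary separation is non-positive")
    rng = np.random.default_rng(seed)
    rows = []
    for s, p in enumerate(cohort):
        if p.true_ndt <= 0:
            raise ValueError("non-decision time must be positive")
        for c in range(N_CONDITIONS):
            sub_seed = int(rng.integers(0, 2 ** 31 - 1))
            rt, up, cen = _wfpt.simulate_trials(
                n_trials_per_condition, drift[s, c], bound[s, c],
                p.true_ndt, 0.5, dt, sub_seed)
            direction = rng.choice([-1, 1], size=n_trials_per_condition)
            # upper boundary = correct response under accuracy coding
            choice = np.where(up == 1, direction, -direction)
            conf = rng.integers(1, 4, size=n_trials_per_condition)
            for i in range(n_trials_per_condition):
                rows.append((p.subject_id, c + 1, truth.coherences[c],
                             int(direction[i]), int(choice[i]),
                             float(rt[i]), int(conf[i])))
    return pd.DataFrame(rows, columns=[
        "subject", "condition", "coherence", "direction", "choice",
        "rt_s", "confidence"])


# ---------------------------------------------------------------------------
# band power and raw oscillations
# ---------------------------------------------------------------------------


@dataclass
class BandPowerTensor:
    """Normalized band power: power[subject, trial, channel, time]."""
    power: np.ndarray
    subjects: list
    conditions: np.ndarray       # (n_subjects, n_trials) condition labels 1..6
    channels: tuple
    times_ms: np.ndarray
    band: str
    baseline_ms: tuple = (-200.0, 0.0)

    def __post_init__(self):
        if self.power.shape[2] != len(self.channels):
            raise ValueError("channel axis mismatch")
        if self.power.shape[3] != len(self.times_ms):
            raise ValueError("time axis mismatch")

    def to_hdf5(self, path):
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("power", data=self.power)
            f.create_dataset("conditions", data=self.conditions)
            f.create_dataset("times_ms", data=self.times_ms)
            f.attrs["band"] = self.band
            f.attrs["baseline_ms"] = self.baseline_ms
            f.attrs["subjects"] = [str(s) for s in self.subjects]
            f.attrs["channels"] = [str(c) for c in self.channels]

    @classmethod
    def from_hdf5(cls, path):
        import h5py
        with h5py.File(path, "r") as f:
            return cls(power=f["power"][()],
                       subjects=[str(s) for s in f.attrs["subjects"]],
                       conditions=f["conditions"][()],
                       channels=tuple(str(c) for c in f.attrs["channels"]),
                       times_ms=f["times_ms"][()],
                       band=str(f.attrs["band"]),
                       baseline_ms=tuple(f.attrs["baseline_ms"]))


def generate_power(cohort, trials: pd.DataFrame, layout: ChannelLayout,
                   truth: GroundTruth, slopes: pd.DataFrame, band: str,
                   time_grid_ms=None, seed=0, noise_sd=1.0,
                   channel_effects=None) -> BandPowerTensor:
    """Per-trial normalized band power: baseline noise plus a post-stimulus
    ramp whose slope is (channel effect) x (subject/condition slope).

    Slopes are in normalized-power units per 50 ms; the baseline window
    carries no ramp, emulating z-normalization against pre-stimulus power.
    """
    if time_grid_ms is None:
        time_grid_ms = np.arange(-200.0, 1001.0, 50.0)
    time_grid_ms = np.asarray(time_grid_ms, dtype=float)
    if time_grid_ms[0] > -200.0 or time_grid_ms[-1] < 800.0:
        raise ValueError("time grid must cover the -200 ms baseline and "
                         "the 300-800 ms analysis window")
    if channel_effects is None:
        channel_effects = channel_effect_map(layout, band)
    rng = np.random.default_rng(seed)
    subjects = [p.subject_id for p in cohort]
    slope_mat = (slopes[slopes["band"] == band]
                 .pivot(index="subject", columns="condition", values="slope")
                 .loc[subjects].to_numpy())
    per_subj = trials.groupby("subject", sort=False).size()
    n_trials = int(per_subj.iloc[0])
    if not (per_subj == n_trials).all():
        raise ValueError("generate_power expects equal trial counts per subject")
    ramp = np.clip(time_grid_ms, 0.0, None) / 50.0   # slope units: per 50 ms
    power = np.empty((len(subjects), n_trials, layout.n_channels,
                      time_grid_ms.size))
    conditions = np.empty((len(subjects), n_trials), dtype=np.int64)
    for s, sid in enumerate(subjects):
        tsub = trials[trials["subject"] == sid]
        cond = tsub["condition"].to_numpy()
        conditions[s] = cond
        sl = slope_mat[s, cond - 1]                      # (n_trials,)
        signal = (sl[:, None, None] * channel_effects[None, :, None]
                  * ramp[None, None, :])
        noise = noise_sd * rng.standard_normal(signal.shape)
        power[s] = signal + noise
    return BandPowerTensor(power=power, subjects=subjects,
                           conditions=conditions, channels=layout.names,
                           times_ms=time_grid_ms, band=band)


BAND_RANGES_HZ = {"gamma": (32.0, 100.0), "beta": (12.0, 28.0)}
BAND_CARRIER_HZ = {"gamma": 60.0, "beta": 20.0}


def generate_raw_oscillations(trials: pd.DataFrame, layout: ChannelLayout,
                              truth: GroundTruth, slopes: pd.DataFrame,
                              band: str, sampling_rate=500.0, seed=0,
                              epoch_ms=(-350.0, 1150.0), carrier_hz=None,
                              base_amp=1.0, noise_sd=0.5, ramp_gain=0.5,
                              channel_effects=None):
    """Band-limited oscillations whose amplitude envelope ramps with the
    trial's true slope, plus broadband noise.

    Returns (signal[trial, channel, time], times_ms).  Intended for
    end-to-end tests of the multitaper stage; one subject's trials at a
    time keeps arrays small.
    """
    if sampling_rate < 250.0:
        raise ValueError("sampling_rate must be at least 250 Hz")
    lo, hi = BAND_RANGES_HZ[band]
    carrier = BAND_CARRIER_HZ[band] if carrier_hz is None else carrier_hz
    if carrier >= sampling_rate / 2.0:
        raise ValueError("carrier frequency exceeds the Nyquist limit")
    if channel_effects is None:
        channel_effects = channel_effect_map(layout, band)
    rng = np.random.default_rng(seed)
    times_ms = np.arange(epoch_ms[0], epoch_ms[1] + 1e-9, 1000.0 / sampling_rate)
    t_s = times_ms / 1000.0
    subjects = trials["subject"].unique()
    slope_lut = (slopes[slopes["band"] == band]
                 .set_index(["subject", "condition"])["slope"])
    n_tr = len(trials)
    sig = np.empty((n_tr, layout.n_channels, times_ms.size))
    ramp = np.clip(times_ms, 0.0, None) / 50.0
    for i, (_, row) in enumerate(trials.iterrows()):
        sl = slope_lut[(row["subject"], row["condition"])]
        phase = rng.uniform(0, 2 * np.pi)
        for ch in range(layout.n_channels):
            # envelope on the amplitude scale; power tracks its square
            env = base_amp * np.sqrt(np.clip(
                1.0 + ramp_gain * channel_effects[ch] * sl * ramp, 0.05, None))
            sig[i, ch] = (env * np.sin(2 * np.pi * carrier * t_s + phase)
                          + noise_sd * rng.standard_normal(times_ms.size))
    return sig, times_ms


def generate_dataset(n_subjects=12, bin_targets=None, n_trials_per_condition=40,
                     seed=0, truth: GroundTruth | None = None):
    """Convenience bundle: cohort, neural slopes, and trial table under one
    seed, with the ground truth attached."""
    truth = truth or GroundTruth()
    if bin_targets is None:
        base = n_subjects // 4
        rem = n_subjects - 4 * base
        bin_targets = tuple(base + (1 if i < rem else 0) for i in range(4))
    ss = np.random.SeedSequence(seed).spawn(3)
    cohort = generate_cohort(n_subjects, bin_targets, seed=ss[0], truth=truth)
    slopes = generate_neural_slopes(cohort, truth, seed=ss[1])
    trials = generate_behavior(cohort, truth, n_trials_per_condition,
                               seed=ss[2], slopes=slopes)
    return {"cohort": cohort, "slopes": slopes, "trials": trials,
            "truth": truth}
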