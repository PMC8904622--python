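"""Multitaper time-frequency power, log transform, baseline z-normalization.

Band power is estimated with DPSS (Slepian) multitapers on a fixed 250 ms
sliding window with +/-8 Hz of spectral smoothing (time-bandwidth product 4,
hence 3 tapers), log-transformed, z-normalized against the 200 ms
pre-stimulus baseline per subject/condition/channel/frequency, and averaged
across the frequencies of each band (gamma: 32-100 Hz in 4 Hz steps, beta:
12-28 Hz in 4 Hz steps).

The spectrogram itself is delegated to mne's multitaper implementation;
output is sampled on a 50 ms grid, and windows that would extend past the
epoch edges are dropped rather than zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TFSpec:
    band: str
    freqs: tuple
    window_s: float = 0.25
    smoothing_hz: float = 8.0
    baseline_ms: tuple = (-200.0, 0.0)

    def __post_init__(self):
        if self.smoothing_hz <= 1.0 / self.window_s:
            raise ValueError("spectral smoothing must exceed the Rayleigh "
                             "resolution of the window")

    @property
    def time_bandwidth(self) -> float:
        """Window length times full smoothing bandwidth (2W)."""
        return 2.0 * self.window_s * self.smoothing_hz

    @property
    def n_tapers(self) -> int:
        return int(np.floor(self.time_bandwidth - 1.0))


def gamma_spec() -> TFSpec:
    return TFSpec(band="gamma", freqs=tuple(np.arange(32.0, 101.0, 4.0)))


def beta_spec() -> TFSpec:
    return TFSpec(band="beta", freqs=tuple(np.arange(12.0, 29.0, 4.0)))


def default_power_grid_ms(epoch_ms=(-350.0, 1150.0), window_s=0.25,
                          step_ms=50.0):
    """50 ms output grid restricted to times whose full analysis window
    fits inside the epoch."""
    half = 1000.0 * window_s / 2.0
    lo = np.ceil((epoch_ms[0] + half) / step_ms) * step_ms
    hi = np.floor((epoch_ms[1] - half) / step_ms) * step_ms
    return np.arange(lo, hi + 1e-9, step_ms)


def multitaper_power(epochs, times_ms, sampling_rate, spec: TFSpec,
                     out_times_ms=None):
    """DPSS multitaper spectrogram power.

    epochs: array (n_trials, n_channels, n_times) of epoched signal.
    Returns (power[trial, channel, freq, time], out_times_ms); power is
    taper-averaged and non-negative.  Output times whose window would
    extend past the epoch are rejected with an error.
    """
    from mne.time_frequency import tfr_array_multitaper

    epochs = np.asarray(epochs, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    if epochs.shape[-1] != times_ms.size:
        raise ValueError("time axis mismatch between epochs and times_ms")
    freqs = np.asarray(spec.freqs, dtype=float)
    if freqs.max() > sampling_rate / 2.0:
        raise ValueError("frequencies of interest exceed the Nyquist limit")
    win_ms = 1000.0 * spec.window_s
    if times_ms[-1] - times_ms[0] < win_ms:
        raise ValueError("analysis window is longer than the epoch")
    if out_times_ms is None:
        out_times_ms = default_power_grid_ms(
            (times_ms[0], times_ms[-1]), spec.window_s)
    out_times_ms = np.asarray(out_times_ms, dtype=float)
    half = win_ms / 2.0
    if (out_times_ms[0] - half < times_ms[0] - 1e-6
            or out_times_ms[-1] + half > times_ms[-1] + 1e-6):
        raise ValueError("output grid requires windows outside the epoch; "
                         "extend the epoch or trim the grid")
    n_cycles = freqs * spec.window_s   # fixed 250 ms window at every freq
    tfr = tfr_array_multitaper(
        epochs, sfreq=sampling_rate, freqs=freqs, n_cycles=n_cycles,
        time_bandwidth=spec.time_bandwidth, output="power", zero_mean=True)
    idx = np.array([int(np.argmin(np.abs(times_ms - t))) for t in out_times_ms])
    return tfr[:, :, :, idx], out_times_ms


def log_baseline_normalize(power, times_ms, conditions, spec: TFSpec):
    """z-score log power against the pre-stimulus baseline.

    power: (n_trials, n_channels, n_freqs, n_times) raw power for ONE
    subject; conditions: per-trial labels defining the normalization
    strata.  For each condition x channel x frequency stratum, the mean and
    SD of log power are pooled over that stratum's trials and baseline time
    points, then applied to every sample of those trials.
    """
    power = np.asarray(power, dtype=float)
    if np.any(power < 0):
        raise ValueError("power must be non-negative")
    times_ms = np.asarray(times_ms, dtype=float)
    conditions = np.asarray(conditions)
    logp = np.log(power)
    bmask = (times_ms >= spec.baseline_ms[0]) & (times_ms <= spec.baseline_ms[1])
    if not bmask.any():
        raise ValueError("no samples in the baseline window")
    out = np.empty_like(logp)
    for cond in np.unique(conditions):
        tmask = conditions == cond
        base = logp[tmask][:, :, :, bmask]          # (trials, ch, freq, bt)
        m = base.mean(axis=(0, 3))
        sd = base.std(axis=(0, 3), ddof=0)
        if np.any(sd == 0):
            ch, fr = np.argwhere(sd == 0)[0]
            raise ValueError(
                f"zero baseline SD in stratum condition={cond}, "
                f"channel index {ch}, frequency index {fr}")
        out[tmask] = (logp[tmask] - m[None, :, :, None]) / sd[None, :, :, None]
    return out


def band_average(norm_power, freqs, band_freqs):
    """Unweighted mean of normalized power over the band's frequencies.

    norm_power: (..., n_freqs, n_times); freqs: frequency axis labels;
    band_freqs: frequencies to average (all must be present).
    """
    freqs = np.asarray(freqs, dtype=float)
    band_freqs = np.asarray(band_freqs, dtype=float)
    idx = []
    for f in band_freqs:
        hit = np.flatnonzero(np.isclose(freqs, f))
        if hit.size == 0:
            raise ValueError(f"frequency {f} Hz missing from the power tensor")
        idx.append(hit[0])
    return np.asarray(norm_power)[..., idx, :].mean(axis=-2)
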