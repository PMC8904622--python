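"""Aggregate whole-brain band-power measure and its slope statistic.

A multi-level Bayesian logistic regression predicts trial difficulty
(hard = lowest two coherences, easy = highest two; the middle two are left
out) from band power at all electrodes, read out at each subject's median
hard-trial reaction time.  The posterior distribution of group-level
channel coefficients then weights every electrode, trial, and time point,
giving a scalar aggregate time course per draw, subject, and condition.
Its slope over 300-800 ms (mean of ten consecutive 50 ms increments) is
the per-subject evidence-integration statistic, and the aggregate can be
projected back to the scalp via X.Y with per-draw Y'Y normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import models, sampler
from .synth import BandPowerTensor

HARD_CONDITIONS = (1, 2)
EASY_CONDITIONS = (5, 6)
EXCLUDED_CONDITIONS = (3, 4)


def difficulty_labels(conditions):
    """Map condition labels 1..6 to hard=0 / easy=1 / excluded=-1."""
    conditions = np.asarray(conditions)
    out = np.full(conditions.shape, -1, dtype=np.int64)
    out[np.isin(conditions, HARD_CONDITIONS)] = 0
    out[np.isin(conditions, EASY_CONDITIONS)] = 1
    bad = ~np.isin(conditions, HARD_CONDITIONS + EASY_CONDITIONS
                   + EXCLUDED_CONDITIONS)
    if bad.any():
        raise ValueError(f"unknown condition labels: "
                         f"{np.unique(conditions[bad])}")
    return out


def median_hard_rt(trials: pd.DataFrame, grid_ms=None):
    """Per-subject median RT over hard trials, optionally snapped to the
    nearest power-grid time point (ms)."""
    hard = trials[trials["condition"].isin(HARD_CONDITIONS)]
    out = {}
    for subject, grp in trials.groupby("subject", sort=True):
        h = hard[hard["subject"] == subject]
        if len(h) == 0:
            raise ValueError(f"subject {subject!r} has no hard trials")
        rt_ms = 1000.0 * float(np.median(h["rt_s"]))
        if grid_ms is not None:
            grid_ms_arr = np.asarray(grid_ms, dtype=float)
            rt_ms = float(grid_ms_arr[np.argmin(np.abs(grid_ms_arr - rt_ms))])
        out[subject] = rt_ms
    return out


@dataclass
class ElectrodeWeights:
    """Posterior draws of the logistic electrode weighting.

    group_coef: (chains, iters, n_channels) group-level channel
    coefficients on the standardized-predictor scale; scaler_mean/scaler_sd
    hold the per-channel standardization used at fit time.
    """
    group_coef: np.ndarray
    channels: tuple
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    subjects: list
    diagnostics: dict

    @property
    def n_draws(self):
        return self.group_coef.shape[0] * self.group_coef.shape[1]

    def flat_coef(self):
        return self.group_coef.reshape(-1, self.group_coef.shape[-1])

    def coef_summary(self) -> pd.DataFrame:
        flat = self.flat_coef()
        lo, med, hi = np.quantile(flat, [0.025, 0.5, 0.975], axis=0)
        return pd.DataFrame({"channel": self.channels, "median": med,
                             "ci_low": lo, "ci_high": hi})

    def to_hdf5(self, path):
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("group_coef", data=self.group_coef)
            f.create_dataset("scaler_mean", data=self.scaler_mean)
            f.create_dataset("scaler_sd", data=self.scaler_sd)
            f.attrs["channels"] = [str(c) for c in self.channels]
            f.attrs["subjects"] = [str(s) for s in self.subjects]

    @classmethod
    def from_hdf5(cls, path):
        import h5py
        with h5py.File(path, "r") as f:
            return cls(group_coef=f["group_coef"][()],
                       channels=tuple(str(c) for c in f.attrs["channels"]),
                       scaler_mean=f["scaler_mean"][()],
                       scaler_sd=f["scaler_sd"][()],
                       subjects=[str(s) for s in f.attrs["subjects"]],
                       diagnostics={})


def power_at_timepoint(tensor: BandPowerTensor, rt_ms_by_subject):
    """Band power at each subject's analysis time point.

    Returns (xmat[trial_total, channels], labels, subj_idx) over the
    hard/easy trials of all subjects, plus the subject id list.
    """
    xs, ys, si = [], [], []
    subjects = []
    for s, sid in enumerate(tensor.subjects):
        t_ms = rt_ms_by_subject[sid]
        ti = int(np.argmin(np.abs(tensor.times_ms - t_ms)))
        lab = difficulty_labels(tensor.conditions[s])
        keep = lab >= 0
        if keep.sum() == 0:
            continue
        xs.append(tensor.power[s, keep, :, ti])
        ys.append(lab[keep])
        si.append(np.full(keep.sum(), len(subjects)))
        subjects.append(sid)
    return (np.concatenate(xs), np.concatenate(ys),
            np.concatenate(si), subjects)


def fit_electrode_weights(xmat, labels, subj_idx, subjects, channels,
                          chains=4, warmup=1000, iters=3000, seed=0,
                          target_accept=0.8, coef_sd=2.5,
                          tau_sd=1.0) -> ElectrodeWeights:
    """Hierarchical logistic regression of easy-vs-hard on channel power.

    Predictors are standardized per channel before fitting (weakly
    informative Normal(0, 2.5) priors on the group coefficients assume
    unit-scale inputs); per-subject coefficient deviations are pooled
    through half-normal scales.  Subjects with a single label class are
    dropped with a warning.
    """
    from .inference import PosteriorDraws, diagnose

    xmat = np.asarray(xmat, dtype=float)
    labels = np.asarray(labels, dtype=float)
    subj_idx = np.asarray(subj_idx, dtype=np.int64)
    keep_subj = []
    for s in range(len(subjects)):
        m = subj_idx == s
        classes = np.unique(labels[m])
        if classes.size < 2:
            warnings.warn(f"subject {subjects[s]!r} has a single difficulty "
                          "class and was dropped", RuntimeWarning)
        else:
            keep_subj.append(s)
    remap = {s: i for i, s in enumerate(keep_subj)}
    mask = np.isin(subj_idx, keep_subj)
    xmat = xmat[mask]
    labels = labels[mask]
    subj_idx = np.array([remap[s] for s in subj_idx[mask]], dtype=np.int64)
    kept_subjects = [subjects[s] for s in keep_subj]

    mean = xmat.mean(axis=0)
    sd = xmat.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant power predictor; cannot standardize")
    xstd = (xmat - mean) / sd

    S, Ch = len(kept_subjects), xmat.shape[1]
    off = models.logistic_param_layout(Ch, S)
    args = (xstd, labels, subj_idx, Ch, S, coef_sd, tau_sd)

    def logp_grad(theta):
        return models.logistic_logp_grad(theta, *args)

    inits = []
    for chain in range(chains):
        rng = np.random.default_rng(np.random.SeedSequence(
            [int(seed), 613, chain]))
        th = np.zeros(off["n"])
        th[off["log_tau"]:off["log_tau"] + Ch] = np.log(0.1)
        th[off["log_alpha_tau"]] = np.log(0.1)
        th += 0.05 * rng.standard_normal(off["n"])
        inits.append(th)
    draws, chain_stats = sampler.run_chains(
        logp_grad, inits, warmup, iters, seed, target_accept=target_accept)
    group = draws[:, :, off["mu"]:off["mu"] + Ch]
    pdraws = PosteriorDraws({"coef": group}, meta={
        "divergences": [cs.divergences for cs in chain_stats]})
    diag = diagnose(pdraws)
    return ElectrodeWeights(group_coef=group, channels=tuple(channels),
                            scaler_mean=mean, scaler_sd=sd,
                            subjects=kept_subjects, diagnostics=diag)


@dataclass
class AggregateTimecourse:
    """values[draw, subject, condition, time]; linear in the power tensor."""
    values: np.ndarray
    subjects: list
    conditions: tuple
    times_ms: np.ndarray
    band: str

    def mean_over_subjects(self):
        return self.values.mean(axis=1)

    def to_hdf5(self, path):
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.create_dataset("times_ms", data=self.times_ms)
            f.attrs["subjects"] = [str(s) for s in self.subjects]
            f.attrs["conditions"] = list(self.conditions)
            f.attrs["band"] = self.band

    @classmethod
    def from_hdf5(cls, path):
        import h5py
        with h5py.File(path, "r") as f:
            return cls(values=f["values"][()],
                       subjects=[str(s) for s in f.attrs["subjects"]],
                       conditions=tuple(int(c) for c in f.attrs["conditions"]),
                       times_ms=f["times_ms"][()], band=str(f.attrs["band"]))


def apply_weights(weights: ElectrodeWeights, tensor: BandPowerTensor,
                  n_draws=None, seed=0, standardize=True) -> AggregateTimecourse:
    """Weight every electrode, trial, and time point by the posterior
    coefficient draws, then average within subject x condition.

    The intercept plays no role (slopes-only projection).  When
    ``standardize`` the power is divided per channel by the fit-time SD so
    weights act on the scale they were estimated on; the fit-time channel
    means are NOT subtracted — a mean offset belongs to the intercept, and
    carrying it into the aggregate would shift the whole time course by a
    constant (harmless for the slope statistic, but it breaks the
    through-the-origin scalp projection).  n_draws subsamples the
    posterior (without replacement) for tractability.
    """
    if tuple(weights.channels) != tuple(tensor.channels):
        raise ValueError("channel axes of weights and power do not align")
    coef = weights.flat_coef()
    if n_draws is not None and n_draws < coef.shape[0]:
        rng = np.random.default_rng(seed)
        coef = coef[rng.choice(coef.shape[0], n_draws, replace=False)]
    conds = tuple(range(1, 7))
    S = len(tensor.subjects)
    nt = tensor.times_ms.size
    mean_power = np.zeros((S, len(conds), tensor.power.shape[2], nt))
    for s in range(S):
        for ci, cond in enumerate(conds):
            m = tensor.conditions[s] == cond
            if m.sum() == 0:
                mean_power[s, ci] = np.nan
                continue
            mp = tensor.power[s, m].mean(axis=0)
            if standardize:
                mp = mp / weights.scaler_sd[:, None]
            mean_power[s, ci] = mp
    # aggregate[draw, s, c, t] = sum_ch coef[draw, ch] * mean_power[s, c, ch, t]
    values = np.tensordot(coef, mean_power, axes=([1], [2]))
    return AggregateTimecourse(values=values, subjects=list(tensor.subjects),
                               conditions=conds, times_ms=tensor.times_ms,
                               band=tensor.band)


@dataclass
class SlopeEstimate:
    """Mean 50 ms increment of the aggregate over 300-800 ms.

    values: (draws, subjects, conditions); point: (subjects, conditions)
    marginal medians used as downstream covariates.
    """
    values: np.ndarray
    point: np.ndarray
    subjects: list
    band: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, sid in enumerate(self.subjects):
            for c in range(self.point.shape[1]):
                rows.append((sid, c + 1, self.band, self.point[s, c]))
        return pd.DataFrame(rows, columns=["subject", "condition", "band",
                                           "slope"])


def slope_statistic(agg: AggregateTimecourse, window_ms=(300.0, 800.0),
                    step_ms=50.0) -> SlopeEstimate:
    """Mean of consecutive ``step_ms`` increments across ``window_ms``;
    by telescoping this equals (y(end) - y(start)) / n_increments."""
    want = np.arange(window_ms[0], window_ms[1] + 1e-9, step_ms)
    idx = []
    for t in want:
        hit = np.flatnonzero(np.isclose(agg.times_ms, t))
        if hit.size == 0:
            raise ValueError(f"time grid lacks the {t:.0f} ms point needed "
                             "for the slope statistic")
        idx.append(hit[0])
    series = agg.values[..., idx]
    vals = np.diff(series, axis=-1).mean(axis=-1)
    point = np.median(vals, axis=0)
    return SlopeEstimate(values=vals, point=point, subjects=agg.subjects,
                         band=agg.band)


def scalp_projection(X, Y):
    """Back-project the aggregate to channels.

    X: (subjects, channels, times) power; Y: (subjects, times, draws)
    aggregate.  Per subject and draw j the map is (X @ Y)[:, j] / (Y_j'Y_j);
    maps are averaged across subjects and reduced by the median across
    draws.  Returns (per-channel map, per-draw maps[channels, draws]).
    Zero-norm aggregate columns are flagged as NaN for that draw.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0] or X.shape[2] != Y.shape[1]:
        raise ValueError("subject/time axes of X and Y do not align")
    nsub, nch, _ = X.shape
    ndraw = Y.shape[2]
    maps = np.zeros((nsub, nch, ndraw))
    for s in range(nsub):
        num = X[s] @ Y[s]                      # (channels, draws)
        den = np.sum(Y[s] * Y[s], axis=0)      # (draws,)
        zero = den == 0
        den = np.where(zero, np.nan, den)
        maps[s] = num / den[None, :]
    mean_map = maps.mean(axis=0)
    return np.nanmedian(mean_map, axis=1), mean_map


def exclude_frontal_tensor(tensor: BandPowerTensor, layout) -> BandPowerTensor:
    """Drop the flagged frontal channels from a power tensor."""
    if tuple(layout.names) != tuple(tensor.channels):
        raise ValueError("layout does not match the tensor's channels")
    keep = layout.nonfrontal_indices
    return BandPowerTensor(power=tensor.power[:, :, keep, :],
                           subjects=tensor.subjects,
                           conditions=tensor.conditions,
                           channels=tuple(tensor.channels[i] for i in keep),
                           times_ms=tensor.times_ms, band=tensor.band,
                           baseline_ms=tensor.baseline_ms)
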