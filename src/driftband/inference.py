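"""Hierarchical Bayesian estimation of the drift-diffusion regression.

The model, for subject s and condition c (all covariates standardized):

    drift[s,c]    = drift_c[c] + drift_s[s]
                    + drift_padua[c]*padua_z[s] + drift_worry[c]*worry_z[s]
                    + drift_gamma[c]*gamma_z[s,c] + drift_beta[c]*beta_z[s,c]
    boundary[s,c] = analogous
    ndt[s]        shared across conditions, pooled via a group Gaussian
    start point   fixed at half the boundary separation

Condition-level locations and every regression-coefficient block are
sampled on a cumulative scale (value for condition 1 plus per-condition
increments) to reduce posterior correlation; all reported draws are on the
original scale.  Four reduced/full variants differ only in which covariate
blocks exist.  Sampling is gradient-based MCMC (NUTS) on the exact Wiener
first-passage-time likelihood; split R-hat and ESS come from arviz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models, sampler
from .behavior import Covariates

VARIANT_COVARIATES = {
    "behavior_only": (),
    "symptoms": ("padua", "worry"),
    "neural": ("gamma", "beta"),
    "full": ("padua", "worry", "gamma", "beta"),
}

RHAT_THRESHOLD = 1.05


@dataclass(frozen=True)
class ModelSpec:
    variant: str = "full"
    n_conditions: int = 6

    def __post_init__(self):
        if self.variant not in VARIANT_COVARIATES:
            raise ValueError(f"unknown variant {self.variant!r}; choose from "
                             f"{sorted(VARIANT_COVARIATES)}")

    @property
    def covariates(self):
        return VARIANT_COVARIATES[self.variant]


@dataclass(frozen=True)
class PriorConfig:
    """Broad priors on the sampled (cumulative) scale.

    coef_sd applies to condition locations and every regression
    coefficient; the condition-1 boundary location is centered at
    ``boundary1_mean`` (biased positive, since separation must be > 0).
    Scale parameters carry half-normal priors.
    """
    coef_sd: float = 20.0
    boundary1_mean: float = 1.0
    ndt_mu_loc: float = 0.5
    ndt_mu_sd: float = 1.0
    ndt_sd_sd: float = 1.0
    subj_sd_sd: float = 20.0


@dataclass(frozen=True)
class MCMCConfig:
    chains: int = 4
    warmup: int = 1000
    iters: int = 3000
    seed: int = 0
    max_treedepth: int = 10
    target_accept: float = 0.8


class PosteriorDraws:
    """Labeled MCMC draws: dict of name -> array (chains, iters[, extra]).

    Vector-valued parameters keep a trailing axis (e.g. ``drift_c`` has
    shape (chains, iters, 6)).  Diagnostics and sampler metadata ride along
    in ``.diagnostics`` and ``.meta``.
    """

    def __init__(self, params: dict, meta: dict | None = None):
        self.params = params
        self.meta = meta or {}
        self.diagnostics: dict = {}

    def __contains__(self, name):
        return name in self.params

    def names(self):
        return list(self.params)

    @property
    def n_chains(self):
        return next(iter(self.params.values())).shape[0]

    @property
    def n_iters(self):
        return next(iter(self.params.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws pooled across chains: shape (chains*iters[, extra])."""
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])

    def median(self, name: str):
        return np.median(self.stacked(name), axis=0)

    def quantile(self, name: str, q):
        return np.quantile(self.stacked(name), q, axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (chain, iter, parameter, value) table; vector parameters
        are expanded with 1-based bracket indices."""
        recs = []
        for name, arr in self.params.items():
            nc, ni = arr.shape[:2]
            flat = arr.reshape(nc, ni, -1)
            k = flat.shape[2]
            for j in range(k):
                label = name if (arr.ndim == 2) else f"{name}[{j + 1}]"
                for c in range(nc):
                    recs.append(pd.DataFrame({
                        "chain": c, "iter": np.arange(ni),
                        "parameter": label, "value": flat[c, :, j]}))
        return pd.concat(recs, ignore_index=True)

    def to_dataset(self):
        import arviz as az
        return az.convert_to_dataset(
            {k: v for k, v in self.params.items()})

    def save(self, path_csv, path_json=None):
        self.to_frame().to_csv(path_csv, index=False)
        if path_json is not None:
            import json
            payload = {"meta": _jsonable(self.meta),
                       "diagnostics": _jsonable(self.diagnostics)}
            with open(path_json, "w") as f:
                json.dump(payload, f, indent=1)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# cumulative reparameterization
# ---------------------------------------------------------------------------


def cumulative_transform(primed, axis=-1):
    """Map sampled increments to condition-scale values: the condition-1
    entry is shared, later entries add their own increment to it."""
    out = np.moveaxis(np.array(primed, dtype=float), axis, -1)
    out[..., 1:] += out[..., :1]
    return np.moveaxis(out, -1, axis)


def inverse_cumulative_transform(actual, axis=-1):
    """Exact inverse of :func:`cumulative_transform`."""
    out = np.moveaxis(np.array(actual, dtype=float), axis, -1)
    out[..., 1:] -= out[..., :1]
    return np.moveaxis(out, -1, axis)


def assemble_drift(condition_value, subject_effect, coefficients=None,
                   covariate_values=None):
    """Linear drift (or boundary) assembly for one subject x condition."""
    total = condition_value + subject_effect
    if coefficients:
        for name, coef in coefficients.items():
            if covariate_values is None or name not in covariate_values:
                raise ValueError(f"missing covariate {name!r}")
            total += coef * covariate_values[name]
    return total


# ---------------------------------------------------------------------------
# data packing
# ---------------------------------------------------------------------------


def _pack_trials(trials: pd.DataFrame, subjects, C):
    sidx = {s: i for i, s in enumerate(subjects)}
    s = trials["subject"].map(sidx).to_numpy()
    c = trials["condition"].to_numpy() - 1
    order = np.lexsort((c, s))
    rt = trials["rt_s"].to_numpy(dtype=float)[order]
    upper = (trials["choice"].to_numpy() == trials["direction"].to_numpy())
    upper = upper[order].astype(np.int8)
    cell = s[order] * C + c[order]
    cell_ptr = np.zeros(len(subjects) * C + 1, dtype=np.int64)
    np.add.at(cell_ptr, cell + 1, 1)
    cell_ptr = np.cumsum(cell_ptr)
    min_rt = np.array([rt[(s[order] == i)].min() for i in range(len(subjects))])
    return rt, upper, cell_ptr, min_rt


def _covariate_tensor(cov: Covariates | None, names, subjects, C):
    P = len(names)
    S = len(subjects)
    X = np.zeros((S, C, P))
    for p, name in enumerate(names):
        if cov is None:
            raise ValueError(f"variant requires covariate {name!r} but no "
                             "covariates were supplied")
        X[:, :, p] = cov.block(name, C)
    return X


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit(trials: pd.DataFrame, covariates: Covariates | None = None,
        model: ModelSpec = ModelSpec("behavior_only"),
        priors: PriorConfig = PriorConfig(),
        mcmc: MCMCConfig = MCMCConfig()) -> PosteriorDraws:
    """Fit the hierarchical drift-diffusion regression by NUTS.

    Returns reported-scale posterior draws with split R-hat/ESS attached;
    a max split R-hat above 1.05 sets ``diagnostics['converged']`` False
    (the run completes either way).
    """
    C = model.n_conditions
    subjects = sorted(trials["subject"].unique())
    if len(subjects) < 2:
        raise ValueError("need at least two subjects for the hierarchy")
    if covariates is not None and list(covariates.subjects) != subjects:
        covariates = _reindex_covariates(covariates, subjects)
    names = model.covariates
    X = _covariate_tensor(covariates, names, subjects, C)
    S, P = len(subjects), len(names)
    rt, upper, cell_ptr, min_rt = _pack_trials(trials, subjects, C)
    off = models.ddm_param_layout(C, P, S)
    args = (rt, upper, cell_ptr, X, min_rt, C, P, S,
            priors.coef_sd, priors.boundary1_mean, priors.ndt_mu_loc,
            priors.ndt_mu_sd, priors.ndt_sd_sd, priors.subj_sd_sd)

    def logp_grad(theta):
        return models.ddm_logp_grad(theta, *args)

    inits = []
    for chain in range(mcmc.chains):
        rng = np.random.default_rng(np.random.SeedSequence(
            [int(mcmc.seed), 977, chain]))
        th = np.zeros(off["n"])
        th[off["drift_c"]] = 1.0
        th[off["boundary_c"]] = 1.5
        th[off["ndt_mu"]] = 0.3
        th[off["log_ndt_sd"]] = np.log(0.1)
        th[off["log_sigma_drift"]] = np.log(0.2)
        th[off["log_sigma_boundary"]] = np.log(0.1)
        th += 0.05 * rng.standard_normal(off["n"])
        inits.append(th)

    draws, chain_stats = sampler.run_chains(
        logp_grad, inits, mcmc.warmup, mcmc.iters, mcmc.seed,
        max_treedepth=mcmc.max_treedepth, target_accept=mcmc.target_accept)

    params = _unpack_ddm_draws(draws, off, names, C, P, S, min_rt)
    pd_out = PosteriorDraws(params, meta={
        "variant": model.variant,
        "subjects": subjects,
        "mcmc": {"chains": mcmc.chains, "warmup": mcmc.warmup,
                 "iters": mcmc.iters, "seed": mcmc.seed},
        "divergences": [cs.divergences for cs in chain_stats],
        "step_size": [cs.step_size for cs in chain_stats],
        "mean_accept": [cs.mean_accept for cs in chain_stats],
    })
    pd_out.diagnostics = diagnose(pd_out)
    if not pd_out.diagnostics["converged"]:
        warnings.warn(
            f"fit flagged non-converged: max split R-hat = "
            f"{pd_out.diagnostics['max_rhat']:.3f}", RuntimeWarning)
    return pd_out


def _reindex_covariates(cov: Covariates, subjects):
    idx = [list(cov.subjects).index(s) for s in subjects]
    def take(v):
        return None if v is None else np.asarray(v)[idx]
    return Covariates(subjects=list(subjects), padua_z=take(cov.padua_z),
                      worry_z=take(cov.worry_z), gamma_z=take(cov.gamma_z),
                      beta_z=take(cov.beta_z))


def _unpack_ddm_draws(draws, off, names, C, P, S, min_rt):
    nc, ni, _ = draws.shape
    params = {}
    d_primed = draws[:, :, off["drift_c"]:off["drift_c"] + C]
    b_primed = draws[:, :, off["boundary_c"]:off["boundary_c"] + C]
    params["drift_c"] = cumulative_transform(d_primed)
    params["boundary_c"] = cumulative_transform(b_primed)
    for p, name in enumerate(names):
        dblk = draws[:, :, off["drift_coef"] + p * C:off["drift_coef"] + (p + 1) * C]
        bblk = draws[:, :, off["boundary_coef"] + p * C:off["boundary_coef"] + (p + 1) * C]
        params[f"drift_{name}"] = cumulative_transform(dblk)
        params[f"boundary_{name}"] = cumulative_transform(bblk)
    sig_d = np.exp(draws[:, :, off["log_sigma_drift"]])
    sig_b = np.exp(draws[:, :, off["log_sigma_boundary"]])
    params["sigma_drift"] = sig_d
    params["sigma_boundary"] = sig_b
    params["drift_subj"] = (draws[:, :, off["eta_drift"]:off["eta_drift"] + S]
                            * sig_d[:, :, None])
    params["boundary_subj"] = (draws[:, :, off["eta_boundary"]:off["eta_boundary"] + S]
                               * sig_b[:, :, None])
    x = draws[:, :, off["x_ndt"]:off["x_ndt"] + S]
    params["ndt"] = (0.999 * min_rt)[None, None, :] / (1.0 + np.exp(-x))
    params["ndt_mu"] = draws[:, :, off["ndt_mu"]]
    params["ndt_sd"] = np.exp(draws[:, :, off["log_ndt_sd"]])
    return params


# ---------------------------------------------------------------------------
# slope-on-symptoms regression
# ---------------------------------------------------------------------------


def fit_neural_regression(slopes, covariates: Covariates,
                          priors: PriorConfig = PriorConfig(),
                          mcmc: MCMCConfig = MCMCConfig()) -> PosteriorDraws:
    """Per-condition Gaussian regression of neural slopes on z-scored
    symptom scores, with hierarchically pooled intercepts.

    slopes: (S, C) array aligned with ``covariates.subjects``.
    """
    y = np.asarray(slopes, dtype=float)
    S, C = y.shape
    if S < 3:
        raise ValueError("need at least three subjects")
    f = models.slope_logp_grad_factory(
        y, np.asarray(covariates.padua_z, dtype=float),
        np.asarray(covariates.worry_z, dtype=float), C,
        coef_sd=priors.coef_sd)
    off = models.slope_param_layout(C)
    inits = []
    for chain in range(mcmc.chains):
        rng = np.random.default_rng(np.random.SeedSequence(
            [int(mcmc.seed), 431, chain]))
        th = np.zeros(off["n"])
        th[3 * C:4 * C] = np.log(max(y.std(), 0.1))
        th[4 * C + 1] = np.log(max(y.std(), 0.1))
        th += 0.05 * rng.standard_normal(off["n"])
        inits.append(th)
    draws, chain_stats = sampler.run_chains(
        f, inits, mcmc.warmup, mcmc.iters, mcmc.seed,
        max_treedepth=mcmc.max_treedepth, target_accept=mcmc.target_accept)
    params = {
        "b0": draws[:, :, 0:C],
        "b_padua": draws[:, :, C:2 * C],
        "b_worry": draws[:, :, 2 * C:3 * C],
        "resid_sd": np.exp(draws[:, :, 3 * C:4 * C]),
        "b0_mu": draws[:, :, 4 * C],
        "b0_sd": np.exp(draws[:, :, 4 * C + 1]),
    }
    out = PosteriorDraws(params, meta={
        "subjects": list(covariates.subjects),
        "divergences": [cs.divergences for cs in chain_stats]})
    out.diagnostics = diagnose(out)
    return out


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def diagnose(draws: PosteriorDraws) -> dict:
    """Split R-hat and effective sample size per parameter (via arviz)."""
    if draws.n_chains < 2:
        raise ValueError("split R-hat needs at least two chains")
    import arviz as az
    ds = draws.to_dataset()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(ds, method="split")
        ess = az.ess(ds)
    rhat_map, ess_map = {}, {}
    max_rhat = 0.0
    degenerate = []
    for name in rhat.data_vars:
        vals = np.atleast_1d(rhat[name].values)
        rhat_map[name] = vals
        ess_map[name] = np.atleast_1d(ess[name].values)
        finite = vals[np.isfinite(vals)]
        if finite.size < vals.size:
            degenerate.append(str(name))
        if finite.size:
            max_rhat = max(max_rhat, float(finite.max()))
    return {
        "rhat": rhat_map,
        "ess": ess_map,
        "max_rhat": max_rhat,
        "degenerate_parameters": degenerate,
        "converged": bool(max_rhat <= RHAT_THRESHOLD) and not degenerate,
    }
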