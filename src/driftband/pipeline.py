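"""End-to-end pipeline: synthetic study -> band power -> electrode
weighting -> aggregate slopes -> regressions -> mediation comparison.

Each stage is the public function from its module; this orchestration adds
seed bookkeeping, a manifest with convergence diagnostics, and the tidy
result tables.  Any stage's hard error aborts the run with the stage named;
convergence problems only flag the manifest.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import aggregate as agg
from . import behavior, effects, inference, synth
from .config import StudyConfig
from .layout import default_layout


@dataclass
class PipelineResult:
    config: StudyConfig
    truth: synth.GroundTruth
    cohort: list
    trials: pd.DataFrame
    true_slopes: pd.DataFrame
    est_slopes: pd.DataFrame
    weights: dict
    scalp_maps: dict
    slope_fits: dict
    ddm_fits: dict
    summaries: pd.DataFrame
    mediation: pd.DataFrame
    manifest: dict

    def save(self, outdir):
        import os
        os.makedirs(outdir, exist_ok=True)
        self.trials.to_csv(f"{outdir}/trials.csv", index=False)
        self.est_slopes.to_csv(f"{outdir}/slopes.csv", index=False)
        self.summaries.to_csv(f"{outdir}/summaries.csv", index=False)
        self.mediation.to_csv(f"{outdir}/mediation.csv", index=False)
        if self.scalp_maps:
            bands = sorted(self.scalp_maps)
            channels = self.weights[bands[0]].channels
            pd.DataFrame({"channel": channels,
                          **{b: self.scalp_maps[b] for b in bands}}
                         ).to_csv(f"{outdir}/scalp_maps.csv", index=False)
        with open(f"{outdir}/manifest.json", "w") as f:
            json.dump(self.manifest, f, indent=1, default=str)


def _stage(manifest, name):
    manifest["stages"].append(name)


def run_pipeline(config: StudyConfig, truth: synth.GroundTruth | None = None,
                 use_true_slopes: bool = False) -> PipelineResult:
    """Run the whole analysis on a synthetic study drawn under ``config``.

    ``use_true_slopes`` bypasses the EEG stages and feeds the generator's
    subject/condition slopes straight into the regressions (useful when
    only the behavioral machinery is under study).
    """
    truth = truth or synth.GroundTruth()
    manifest = {"stages": [], "seed": config.seed, "diagnostics": {},
                "converged": True}
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31 - 1)) for s in ss.spawn(8)]

    # --- synthetic study -------------------------------------------------
    ds = synth.generate_dataset(
        n_subjects=config.n_subjects, bin_targets=config.bin_targets,
        n_trials_per_condition=config.n_trials_per_condition,
        seed=seeds[0], truth=truth)
    cohort, true_slopes = ds["cohort"], ds["slopes"]
    _stage(manifest, "generate")

    trials, _ = behavior.filter_trials(ds["trials"], config.min_rt_s,
                                       config.max_rt_s)
    _stage(manifest, "filter")

    layout = default_layout()
    if config.n_channels < layout.n_channels:
        layout = layout.subset(range(config.n_channels))

    weights, scalp_maps, slope_fits = {}, {}, {}
    scores = synth.cohort_frame(cohort)
    if use_true_slopes:
        est_slopes = true_slopes.copy()
        _stage(manifest, "slopes:ground-truth")
    else:
        grid = np.arange(-200.0, 1001.0, config.power_step_ms)
        est_frames = []
        for bi, band in enumerate(config.bands):
            tensor = synth.generate_power(
                cohort, trials, layout, truth, true_slopes, band,
                time_grid_ms=grid, seed=seeds[1] + bi)
            if config.exclude_frontal:
                tensor = agg.exclude_frontal_tensor(tensor, layout)
            _stage(manifest, f"power:{band}")
            rt_ms = agg.median_hard_rt(trials, grid_ms=grid)
            xmat, labels, sidx, subs = agg.power_at_timepoint(tensor, rt_ms)
            w = agg.fit_electrode_weights(
                xmat, labels, sidx, subs, tensor.channels,
                chains=config.chains, warmup=config.warmup,
                iters=config.iters, seed=seeds[2] + bi,
                target_accept=config.target_accept)
            weights[band] = w
            manifest["diagnostics"][f"weights:{band}"] = {
                "max_rhat": w.diagnostics["max_rhat"],
                "converged": w.diagnostics["converged"]}
            _stage(manifest, f"weights:{band}")
            course = agg.apply_weights(
                w, tensor, n_draws=config.weight_draws_applied,
                seed=seeds[3] + bi)
            slope = agg.slope_statistic(
                course, window_ms=config.slope_window_ms,
                step_ms=config.power_step_ms)
            est_frames.append(slope.to_frame())
            _stage(manifest, f"slope:{band}")
            # scalp back-projection: per-subject mean power vs aggregate
            X = tensor.power.mean(axis=1)                     # (S, ch, t)
            Y = np.moveaxis(course.values.mean(axis=2), 0, -1)  # (S, t, draw)
            scalp_maps[band], _ = agg.scalp_projection(X, Y)
            _stage(manifest, f"projection:{band}")
        est_slopes = pd.concat(est_frames, ignore_index=True)

    # --- covariates and regressions --------------------------------------
    subjects = sorted(trials["subject"].unique())
    cov = behavior.zscore_covariates(scores, est_slopes, subjects=subjects)
    _stage(manifest, "covariates")

    mcmc = inference.MCMCConfig(chains=config.chains, warmup=config.warmup,
                                iters=config.iters, seed=seeds[4],
                                target_accept=config.target_accept)
    for band in config.bands:
        zmat = cov.block(band, 6)
        fitres = inference.fit_neural_regression(zmat, cov, mcmc=mcmc)
        slope_fits[band] = fitres
        manifest["diagnostics"][f"slope_regression:{band}"] = {
            "max_rhat": fitres.diagnostics["max_rhat"],
            "converged": fitres.diagnostics["converged"]}
        _stage(manifest, f"slope_regression:{band}")

    ddm_fits = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for variant in ("symptoms", "neural", "full"):
            fitres = inference.fit(
                trials, cov, model=inference.ModelSpec(variant),
                mcmc=inference.MCMCConfig(
                    chains=config.chains, warmup=config.warmup,
                    iters=config.iters, seed=seeds[5],
                    target_accept=config.target_accept))
            ddm_fits[variant] = fitres
            manifest["diagnostics"][f"ddm:{variant}"] = {
                "max_rhat": fitres.diagnostics["max_rhat"],
                "converged": fitres.diagnostics["converged"]}
            _stage(manifest, f"ddm:{variant}")

    # --- summaries, contrasts, mediation ---------------------------------
    frames = []
    sym = effects.summarize_all(ddm_fits["symptoms"],
                                ["drift_padua", "drift_worry",
                                 "boundary_padua", "boundary_worry"])
    sym["source"] = "ddm:symptoms"
    frames.append(sym)
    neu = effects.summarize_all(ddm_fits["neural"],
                                ["drift_gamma", "drift_beta"])
    neu["source"] = "ddm:neural"
    frames.append(neu)
    ful = effects.summarize_all(ddm_fits["full"],
                                ["drift_padua", "drift_worry",
                                 "drift_gamma", "drift_beta"])
    ful["source"] = "ddm:full"
    frames.append(ful)
    for band in config.bands:
        sf = effects.summarize_all(slope_fits[band], ["b_padua", "b_worry"])
        sf["source"] = f"slope_regression:{band}"
        frames.append(sf)
    summaries = pd.concat(frames, ignore_index=True)
    _stage(manifest, "summaries")

    med_rows = []
    for c in range(1, 7):
        ch = effects.mediation_change(ddm_fits["full"], ddm_fits["symptoms"],
                                      "drift_padua", condition=c,
                                      seed=seeds[6])
        med_rows.append({**ch.__dict__, "reduced": "symptoms"})
        for band_param in ("drift_gamma", "drift_beta"):
            ch = effects.mediation_change(ddm_fits["full"],
                                          ddm_fits["neural"], band_param,
                                          condition=c, seed=seeds[6])
            med_rows.append({**ch.__dict__, "reduced": "neural"})
    mediation = pd.DataFrame(med_rows)
    _stage(manifest, "mediation")

    manifest["converged"] = all(
        d.get("converged", True) for d in manifest["diagnostics"].values())
    return PipelineResult(config=config, truth=truth, cohort=cohort,
                          trials=trials, true_slopes=true_slopes,
                          est_slopes=est_slopes, weights=weights,
                          scalp_maps=scalp_maps,
                          slope_fits=slope_fits, ddm_fits=ddm_fits,
                          summaries=summaries, mediation=mediation,
                          manifest=manifest)
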