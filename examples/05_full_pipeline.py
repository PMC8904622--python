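"""The whole analysis end to end on a reduced synthetic study.

Cohort -> behavior -> band power -> logistic electrode weighting ->
aggregate slopes -> slope-on-symptoms regressions -> reduced and full
drift-diffusion regressions -> mediation (coefficient-change) comparison.
Prints the headline pattern: OCD score lowers drift in easy conditions,
relates negatively to the aggregate beta slope, and the OCD coefficient
barely moves when the neural slopes join the model.
"""

import numpy as np

from driftband import StudyConfig, run_pipeline

cfg = StudyConfig().small(n_subjects=12, n_trials_per_condition=30,
                          chains=2, warmup=250, iters=400)
res = run_pipeline(cfg)

print("stages:", " -> ".join(res.manifest["stages"]), "\n")
print("convergence:",
      {k: round(v["max_rhat"], 3) for k, v in
       res.manifest["diagnostics"].items()}, "\n")

sym = res.summaries.query("source == 'ddm:symptoms' and parameter == 'drift_padua'")
print("OCD-score effect on drift (controlling worry), per condition:")
print(sym[["condition", "median", "ci_low", "ci_high", "significant"]]
      .round(2).to_string(index=False))

for band in ("gamma", "beta"):
    bp = res.summaries.query(
        f"source == 'slope_regression:{band}' and parameter == 'b_padua'")
    print(f"\nOCD-score effect on the aggregate {band} slope: "
          f"median of condition medians = {bp['median'].median():+.2f}")

med = res.mediation.query("parameter == 'change[drift_padua]'")
print("\nchange in the OCD coefficient when controlling for the neural "
      "slopes\n(full minus symptoms-only model), per condition:")
print(med[["condition", "median", "ci_low", "ci_high", "significant"]]
      .round(2).to_string(index=False))
print("\nWith the default generator the change intervals straddle zero: the "
      "\nbeta-slope pathway does not absorb the direct OCD-drift effect.")
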