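"""Trial filtering, descriptive summaries, and covariate standardization.

These are the steps between the raw trial table and model fitting: remove
implausibly fast/slow responses, summarize accuracy and correct-trial RT
per difficulty condition, and z-score the symptom scores (once, across
subjects) and the neural ramp slopes (across subjects, separately within
each condition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("subject", "condition", "rt_s", "choice", "direction")


def filter_trials(trials: pd.DataFrame, min_rt: float = 0.25,
                  max_rt: float = 10.0):
    """Drop trials with RT outside [min_rt, max_rt] (boundaries retained:
    only responses strictly faster/slower than the cutoffs are removed).

    Returns (filtered table, removal report).  The report lists retained
    and removed counts per subject x condition.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    if not min_rt < max_rt:
        raise ValueError("min_rt must be below max_rt")
    keep = (trials["rt_s"] >= min_rt) & (trials["rt_s"] <= max_rt)
    kept = trials[keep].reset_index(drop=True)
    report = (trials.assign(kept=keep.astype(int))
              .groupby(["subject", "condition"], sort=True)
              .agg(n_total=("kept", "size"), n_kept=("kept", "sum"))
              .reset_index())
    report["n_removed"] = report["n_total"] - report["n_kept"]
    return kept, report


def summarize_behavior(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean accuracy and mean correct-trial RT (and log-RT).

    Accuracy counts a trial correct when the chosen direction matches the
    true motion direction.  RT summaries use correct trials only; a
    condition with no correct trials gets NaN RT columns.
    """
    df = trials.assign(correct=(trials["choice"] == trials["direction"]))
    out = []
    for cond, grp in df.groupby("condition", sort=True):
        correct = grp[grp["correct"]]
        out.append({
            "condition": cond,
            "accuracy": grp["correct"].mean(),
            "mean_rt_correct": correct["rt_s"].mean() if len(correct) else np.nan,
            "mean_log_rt_correct": (np.log(correct["rt_s"]).mean()
                                    if len(correct) else np.nan),
            "n_trials": len(grp),
        })
    return pd.DataFrame(out)


@dataclass
class Covariates:
    """Standardized covariates keyed to a fixed subject order.

    padua_z / worry_z: (S,) z-scored symptom scores (across subjects, once).
    gamma_z / beta_z: (S, C) neural slopes z-scored within each condition,
    or None for variants without neural terms.
    """
    subjects: list
    padua_z: np.ndarray | None = None
    worry_z: np.ndarray | None = None
    gamma_z: np.ndarray | None = None
    beta_z: np.ndarray | None = None

    def block(self, name: str, n_conditions: int) -> np.ndarray:
        """(S, C) matrix for a named covariate; symptom scores broadcast
        across conditions."""
        val = getattr(self, f"{name}_z")
        if val is None:
            raise ValueError(f"covariate {name!r} is not available")
        val = np.asarray(val, dtype=float)
        if val.ndim == 1:
            return np.repeat(val[:, None], n_conditions, axis=1)
        return val


def _zscore_strict(x, name):
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"zero variance in covariate {name!r}")
    return (x - x.mean()) / sd


def zscore_covariates(scores: pd.DataFrame,
                      slopes: pd.DataFrame | None = None,
                      subjects=None) -> Covariates:
    """Standardize symptom scores and (optionally) neural slopes.

    scores: DataFrame with columns subject, padua_raw, worry_raw.
    slopes: tidy DataFrame (subject, condition, band, slope) or None.
    Symptom scores are z-scored once across subjects; slopes are z-scored
    across subjects separately within each condition (and band).
    """
    if subjects is None:
        subjects = list(scores["subject"])
    if len(subjects) < 2:
        raise ValueError("need at least two subjects to standardize")
    sc = scores.set_index("subject").loc[list(subjects)]
    cov = Covariates(
        subjects=list(subjects),
        padua_z=_zscore_strict(sc["padua_raw"].to_numpy(), "padua"),
        worry_z=_zscore_strict(sc["worry_raw"].to_numpy(), "worry"),
    )
    if slopes is not None:
        for band in ("gamma", "beta"):
            sub = slopes[slopes["band"] == band]
            if len(sub) == 0:
                continue
            mat = (sub.pivot(index="subject", columns="condition",
                             values="slope").loc[list(subjects)].to_numpy())
            zs = np.empty_like(mat)
            for c in range(mat.shape[1]):
                zs[:, c] = _zscore_strict(mat[:, c], f"{band} slope, condition {c + 1}")
            setattr(cov, f"{band}_z", zs)
    return cov


def score_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Raw + z-scored symptom scores in one table."""
    cov = zscore_covariates(scores)
    out = scores.copy()
    out["padua_z"] = cov.padua_z
    out["worry_z"] = cov.worry_z
    return out
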