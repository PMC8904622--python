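"""Posterior summaries, condition contrasts, and the coefficient-change
(mediation) comparison between full and reduced model fits.

Conventions follow the analysis they serve: central 95% credible
intervals, posterior medians, and a reporting flag that calls an effect
"significant" when more than 95% of its posterior mass lies on one side of
zero.  The flag never drives control flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import PosteriorDraws


@dataclass(frozen=True)
class EffectSummary:
    parameter: str
    condition: object
    median: float
    ci_low: float
    ci_high: float
    p_positive: float
    significant: bool

    def __post_init__(self):
        if not self.ci_low <= self.ci_high:
            raise ValueError("credible-interval bounds out of order")


def _extract(draws: PosteriorDraws, parameter, condition=None):
    if parameter not in draws:
        raise KeyError(f"parameter {parameter!r} not present in the draws")
    flat = draws.stacked(parameter)
    if flat.ndim == 2:
        if condition is None:
            raise ValueError(f"{parameter!r} is per-condition; pass condition")
        flat = flat[:, condition - 1]
    return flat


def _summary(vals, parameter, condition):
    lo, med, hi = np.quantile(vals, [0.025, 0.5, 0.975])
    p_pos = float(np.mean(vals > 0))
    p_neg = float(np.mean(vals < 0))
    return EffectSummary(parameter=parameter, condition=condition,
                         median=float(med), ci_low=float(lo),
                         ci_high=float(hi), p_positive=p_pos,
                         significant=bool(p_pos >= 0.975 or p_neg >= 0.975))


def summarize(draws: PosteriorDraws, parameter: str,
              condition=None) -> EffectSummary:
    """Median, central 95% credible interval, and sign probability."""
    return _summary(_extract(draws, parameter, condition), parameter,
                    condition)


def summarize_all(draws: PosteriorDraws, parameters=None) -> pd.DataFrame:
    """Tidy summary table over (parameter, condition) cells."""
    rows = []
    for name in (parameters or draws.names()):
        arr = draws.stacked(name)
        if arr.ndim == 1:
            rows.append(summarize(draws, name).__dict__)
        else:
            for c in range(arr.shape[1]):
                rows.append(summarize(draws, name, condition=c + 1).__dict__)
    return pd.DataFrame(rows)


def condition_contrast(draws: PosteriorDraws, parameter: str,
                       pair) -> EffectSummary:
    """Draw-wise difference between two conditions of one coefficient
    block (pair = (c_a, c_b) gives c_a minus c_b)."""
    a = _extract(draws, parameter, pair[0])
    b = _extract(draws, parameter, pair[1])
    if a.shape != b.shape:
        raise ValueError("mismatched draw counts between conditions")
    return _summary(a - b, f"{parameter}[{pair[0]}-{pair[1]}]", None)


def parameter_contrast(draws: PosteriorDraws, param_a: str, param_b: str,
                       condition=None) -> EffectSummary:
    """Draw-wise difference between two parameters in the same fit (e.g.
    the OCD-score vs worry coefficient within a condition)."""
    a = _extract(draws, param_a, condition)
    b = _extract(draws, param_b, condition)
    return _summary(a - b, f"{param_a}-{param_b}", condition)


def mediation_change(full_draws: PosteriorDraws, reduced_draws: PosteriorDraws,
                     parameter: str, condition=None, seed=0) -> EffectSummary:
    """Change in a coefficient between independently fitted full and
    reduced models.

    The two posteriors are independent, so their draws are paired by index
    after a random permutation of the reduced fit's draws; the summarized
    distribution is (full - reduced).
    """
    a = _extract(full_draws, parameter, condition)
    b = _extract(reduced_draws, parameter, condition)
    n = min(a.shape[0], b.shape[0])
    rng = np.random.default_rng(seed)
    a = a[rng.permutation(a.shape[0])[:n]]
    b = b[rng.permutation(b.shape[0])[:n]]
    return _summary(a - b, f"change[{parameter}]", condition)
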