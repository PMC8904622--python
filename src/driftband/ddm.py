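"""User-facing drift-diffusion primitives.

A thin, validated layer over the numba kernels in :mod:`driftband._wfpt`:
the exact first-passage density of the simple model (no trial-to-trial
parameter variability, within-trial diffusion SD fixed at 1), the
closed-form absorption probability, and a path simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _wfpt


@dataclass(frozen=True)
class DDMParams:
    """drift: evidence/s (signed toward the upper boundary); boundary:
    separation a > 0; ndt: non-decision seconds; start_frac: starting
    point as a fraction of a, fixed at 0.5 throughout the analyses."""
    drift: float
    boundary: float
    ndt: float = 0.0
    start_frac: float = 0.5

    def __post_init__(self):
        if self.boundary <= 0:
            raise ValueError("boundary separation must be positive")
        if not 0.0 < self.start_frac < 1.0:
            raise ValueError("start_frac must lie strictly inside (0, 1)")
        if self.ndt < 0:
            raise ValueError("non-decision time must be non-negative")


def wfpt_log_density(rt_s, boundary_hit: str, params: DDMParams,
                     eps: float = 1e-10):
    """Log density of an observed (choice, RT) pair.

    boundary_hit: "upper" or "lower".  Returns -inf (not an exception)
    for rt_s <= ndt so that samplers can reject such proposals.
    """
    if boundary_hit not in ("upper", "lower"):
        raise ValueError("boundary_hit must be 'upper' or 'lower'")
    rt = np.asarray(rt_s, dtype=float)
    scalar = rt.ndim == 0
    rt = np.atleast_1d(rt)
    out = np.empty(rt.shape)
    for i, t in enumerate(rt):
        td = t - params.ndt
        if boundary_hit == "upper":
            out[i] = _wfpt.wfpt_logpdf(td, -params.drift, params.boundary,
                                       1.0 - params.start_frac, eps)
        else:
            out[i] = _wfpt.wfpt_logpdf(td, params.drift, params.boundary,
                                       params.start_frac, eps)
    return float(out[0]) if scalar else out


def choice_probability(params: DDMParams) -> float:
    """Closed-form probability of absorption at the upper boundary."""
    return float(_wfpt.upper_probability(params.drift, params.boundary,
                                         params.start_frac))


def simulate_trial(params: DDMParams, seed: int, dt: float = 0.001,
                   t_max: float = 10.0):
    """One Euler-Maruyama path (1 ms default step, bridge-corrected
    crossings).  Returns (boundary_hit, rt_s, censored)."""
    if dt > 0.001 + 1e-12:
        raise ValueError("step size must be at most 1 ms")
    rt, up, cen = _wfpt.simulate_trials(1, params.drift, params.boundary,
                                        params.ndt, params.start_frac, dt,
                                        seed, t_max)
    return ("upper" if up[0] else "lower", float(rt[0]), bool(cen[0]))


def simulate_trials(n, params: DDMParams, seed: int, dt: float = 0.001,
                    t_max: float = 10.0):
    """Vectorized simulator: (rt_s, upper, censored) arrays of length n."""
    if dt > 0.001 + 1e-12:
        raise ValueError("step size must be at most 1 ms")
    return _wfpt.simulate_trials(n, params.drift, params.boundary,
                                 params.ndt, params.start_frac, dt, seed,
                                 t_max)
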