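"""Numba kernels for the Wiener first-passage-time (WFPT) density.

The simple drift-diffusion model: evidence X(t) starts at w*a, drifts at
rate v with unit diffusion SD, and is absorbed at 0 (lower boundary) or a
(upper boundary).  The first-passage density at the *lower* boundary in
normalized time u = t / a**2 admits two series expansions (small-time and
large-time); we evaluate whichever needs fewer terms for a given absolute
tolerance and switch adaptively, following the standard term-count bounds.

All gradients are hand-derived term-by-term so that gradient-based MCMC can
run on the exact likelihood.  Upper-boundary densities are obtained from the
reflection identity f_upper(t | v, a, w) = f_lower(t | -v, a, 1 - w).
"""

import math

import numpy as np
from numba import njit

_SQRT_2PI = math.sqrt(2.0 * math.pi)
_PISQ = math.pi * math.pi


@njit(cache=True)
def _f1_terms(u, w, eps):
    """Density f1(u, w) of lower-boundary passage in normalized time, and
    its derivative d f1 / d u.  Returns (f1, df1_du)."""
    # term counts needed by each expansion (absolute tolerance eps)
    if 2.0 * math.sqrt(2.0 * math.pi * u) * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * u * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * u)))
        if ks < math.sqrt(u) + 1.0:
            ks = math.sqrt(u) + 1.0
    else:
        ks = 2.0
    if math.pi * u * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * u * eps) / (_PISQ * u))
        if kl < 1.0 / (math.pi * math.sqrt(u)):
            kl = 1.0 / (math.pi * math.sqrt(u))
    else:
        kl = 1.0 / (math.pi * math.sqrt(u))

    f1 = 0.0
    df = 0.0
    if ks < kl:
        # small-time expansion over image charges w + 2k
        K = int(math.ceil(ks)) + 2
        lo = -((K - 1) // 2)
        hi = (K - 1) // 2 + 1
        s = 0.0
        sd = 0.0
        for k in range(lo, hi + 1):
            q = w + 2.0 * k
            e = math.exp(-q * q / (2.0 * u))
            s += q * e
            sd += q * e * (q * q / (2.0 * u * u))
        inv = 1.0 / (_SQRT_2PI * math.pow(u, 1.5))  # (2 pi u^3)^{-1/2}
        f1 = s * inv
        # d/du [s * u^{-3/2}] = s' u^{-3/2} - 1.5 s u^{-5/2}
        df = sd * inv - 1.5 * f1 / u
    else:
        K = int(math.ceil(kl)) + 2
        for k in range(1, K + 1):
            e = math.exp(-k * k * _PISQ * u / 2.0)
            sn = math.sin(k * math.pi * w)
            f1 += k * e * sn
            df += -0.5 * _PISQ * k * k * k * e * sn
        f1 *= math.pi
        df *= math.pi
    return f1, df


@njit(cache=True)
def wfpt_logpdf(t, v, a, w, eps=1e-10):
    """Log density of absorption at the LOWER boundary after decision time t.

    t is decision time (RT minus non-decision time), in seconds.
    Returns -inf for t <= 0 or numerically vanishing density.
    """
    if t <= 0.0 or a <= 0.0:
        return -np.inf
    u = t / (a * a)
    f1, _ = _f1_terms(u, w, eps)
    if f1 <= 0.0:
        return -np.inf
    return -2.0 * math.log(a) - v * a * w - v * v * t / 2.0 + math.log(f1)


@njit(cache=True)
def wfpt_logpdf_grad(t, v, a, w, eps=1e-10):
    """(logf, dlogf/dv, dlogf/da, dlogf/dt) for the lower-boundary density."""
    if t <= 0.0 or a <= 0.0:
        return -np.inf, 0.0, 0.0, 0.0
    u = t / (a * a)
    f1, df = _f1_terms(u, w, eps)
    if f1 <= 0.0:
        return -np.inf, 0.0, 0.0, 0.0
    logf = -2.0 * math.log(a) - v * a * w - v * v * t / 2.0 + math.log(f1)
    r = df / f1
    dv = -a * w - v * t
    dt = -v * v / 2.0 + r / (a * a)
    da = -2.0 / a - v * w - r * 2.0 * t / (a * a * a)
    return logf, dv, da, dt


@njit(cache=True)
def wfpt_trial_logpdf_grad(rt, upper, v, a, ndt, w, eps=1e-10):
    """Log density and gradient for an observed (choice, RT) trial.

    upper=True means the accumulator was absorbed at the upper boundary.
    Gradients are with respect to (v, a, ndt) on the trial's own scale.
    """
    t = rt - ndt
    if upper:
        logf, dv, da, dt = wfpt_logpdf_grad(t, -v, a, 1.0 - w, eps)
        dv = -dv
    else:
        logf, dv, da, dt = wfpt_logpdf_grad(t, v, a, w, eps)
    return logf, dv, da, -dt


@njit(cache=True)
def upper_probability(v, a, w):
    """Closed-form probability of absorption at the upper boundary."""
    # P(hit a before 0 | start w*a) = (1 - exp(-2 v a w)) / (1 - exp(-2 v a))
    x = -2.0 * v * a
    if abs(x) < 1e-9:
        return w
    num = math.expm1(x * w)
    den = math.expm1(x)
    return num / den


@njit(cache=True)
def simulate_trials(n, v, a, ndt, w, dt, seed, t_max=10.0):
    """Euler-Maruyama first-passage simulation with Brownian-bridge
    crossing correction (removes the O(sqrt(dt)) boundary-overshoot bias).

    Returns (rt, upper, censored) arrays; censored trials carry rt = t_max+ndt.
    """
    np.random.seed(seed)
    rt = np.empty(n)
    upper = np.zeros(n, dtype=np.int8)
    censored = np.zeros(n, dtype=np.int8)
    sq = math.sqrt(dt)
    for i in range(n):
        x = w * a
        t = 0.0
        absorbed = False
        while t < t_max:
            xn = x + v * dt + sq * np.random.randn()
            t += dt
            if xn >= a:
                upper[i] = 1
                absorbed = True
            elif xn <= 0.0:
                absorbed = True
            else:
                # bridge crossing probabilities within the step
                pu = math.exp(-2.0 * (a - x) * (a - xn) / dt)
                pl = math.exp(-2.0 * x * xn / dt)
                if np.random.random() < pu:
                    upper[i] = 1
                    absorbed = True
                elif np.random.random() < pl:
                    absorbed = True
            if absorbed:
                break
            x = xn
        if not absorbed:
            censored[i] = 1
        rt[i] = t + ndt
    return rt, upper, censored
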