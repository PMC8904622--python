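"""A self-contained No-U-Turn sampler (NUTS) with Stan-style adaptation.

The sampler operates on an arbitrary differentiable log posterior supplied
as a callable ``logp_grad(q) -> (float, ndarray)``.  Warmup adapts the step
size by dual averaging toward a target acceptance statistic and a diagonal
mass matrix from expanding memory windows; both are frozen for sampling.

Non-finite log posteriors are treated as divergent proposals and rejected,
so constrained models can simply return -inf outside their support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["nuts_sample", "run_chains", "ChainResult"]

_MAX_DELTA_H = 1000.0  # energy error beyond which a trajectory is divergent


@dataclass
class ChainResult:
    draws: np.ndarray            # (n_iter, dim)
    divergences: int = 0
    step_size: float = float("nan")
    mean_accept: float = float("nan")
    treedepths: np.ndarray = field(default=None)


class _State:
    __slots__ = ("q", "p", "logp", "grad")

    def __init__(self, q, p, logp, grad):
        self.q = q
        self.p = p
        self.logp = logp
        self.grad = grad


def _leapfrog(logp_grad, state, eps, inv_mass):
    p = state.p + 0.5 * eps * state.grad
    q = state.q + eps * inv_mass * p
    logp, grad = logp_grad(q)
    p = p + 0.5 * eps * grad
    return _State(q, p, logp, grad)


def _hamiltonian(state, inv_mass):
    return -state.logp + 0.5 * np.dot(state.p * inv_mass, state.p)


def _find_initial_step(logp_grad, q0, logp0, grad0, inv_mass, rng):
    eps = 1.0
    p0 = rng.standard_normal(q0.size) / np.sqrt(inv_mass)
    s0 = _State(q0, p0, logp0, grad0)
    h0 = _hamiltonian(s0, inv_mass)
    s1 = _leapfrog(logp_grad, s0, eps, inv_mass)
    h1 = _hamiltonian(s1, inv_mass)
    if not np.isfinite(h1):
        ratio = 0.0
    else:
        ratio = math.exp(min(0.0, h0 - h1))
    direction = 1.0 if ratio > 0.5 else -1.0
    for _ in range(60):
        eps *= 2.0 ** direction
        s1 = _leapfrog(logp_grad, s0, eps, inv_mass)
        h1 = _hamiltonian(s1, inv_mass)
        ratio = math.exp(min(0.0, h0 - h1)) if np.isfinite(h1) else 0.0
        if (direction > 0 and ratio <= 0.5) or (direction < 0 and ratio >= 0.5):
            break
    return max(eps, 1e-8)


def _build_tree(logp_grad, state, log_u, direction, depth, eps, inv_mass, h0, rng, stats):
    """Recursive doubling of the trajectory (slice-sampling variant)."""
    if depth == 0:
        s1 = _leapfrog(logp_grad, state, direction * eps, inv_mass)
        h1 = _hamiltonian(s1, inv_mass)
        if not np.isfinite(h1):
            h1 = np.inf
        n_valid = 1 if log_u <= -h1 else 0
        diverged = (log_u - 1000.0) > -h1 if np.isfinite(h1) else True
        if h1 == np.inf:
            diverged = True
        stats["accept_sum"] += math.exp(min(0.0, h0 - h1)) if np.isfinite(h1) else 0.0
        stats["accept_n"] += 1
        return s1, s1, s1, n_valid, not diverged, diverged
    # build left/right subtrees
    s_minus, s_plus, s_prop, n1, cont, div = _build_tree(
        logp_grad, state, log_u, direction, depth - 1, eps, inv_mass, h0, rng, stats)
    if cont:
        if direction == -1:
            s_minus, _, s_prop2, n2, cont2, div2 = _build_tree(
                logp_grad, s_minus, log_u, direction, depth - 1, eps, inv_mass, h0, rng, stats)
        else:
            _, s_plus, s_prop2, n2, cont2, div2 = _build_tree(
                logp_grad, s_plus, log_u, direction, depth - 1, eps, inv_mass, h0, rng, stats)
        if n1 + n2 > 0 and rng.random() < n2 / (n1 + n2):
            s_prop = s_prop2
        dq = s_plus.q - s_minus.q
        no_uturn = (np.dot(dq, inv_mass * s_minus.p) >= 0.0) and (np.dot(dq, inv_mass * s_plus.p) >= 0.0)
        cont = cont2 and no_uturn
        n1 += n2
        div = div or div2
    return s_minus, s_plus, s_prop, n1, cont, div


def _nuts_step(logp_grad, q, logp, grad, eps, inv_mass, rng, max_treedepth):
    p0 = rng.standard_normal(q.size) / np.sqrt(inv_mass)
    s0 = _State(q, p0, logp, grad)
    h0 = _hamiltonian(s0, inv_mass)
    log_u = -h0 + math.log(max(rng.random(), 1e-300))
    s_minus = s_plus = s_prop = s0
    n = 1
    depth = 0
    diverged = False
    stats = {"accept_sum": 0.0, "accept_n": 0}
    while depth < max_treedepth:
        direction = -1 if rng.random() < 0.5 else 1
        if direction == -1:
            s_minus, _, s_prop2, n2, cont, div = _build_tree(
                logp_grad, s_minus, log_u, direction, depth, eps, inv_mass, h0, rng, stats)
        else:
            _, s_plus, s_prop2, n2, cont, div = _build_tree(
                logp_grad, s_plus, log_u, direction, depth, eps, inv_mass, h0, rng, stats)
        diverged = diverged or div
        if cont and n2 > 0 and rng.random() < min(1.0, n2 / n):
            s_prop = s_prop2
        n += n2
        depth += 1
        if not cont:
            break
        dq = s_plus.q - s_minus.q
        if (np.dot(dq, inv_mass * s_minus.p) < 0.0) or (np.dot(dq, inv_mass * s_plus.p) < 0.0):
            break
    accept_stat = stats["accept_sum"] / max(stats["accept_n"], 1)
    return s_prop.q, s_prop.logp, s_prop.grad, accept_stat, diverged, depth


def _adaptation_schedule(n_warmup):
    """(step-size-only head, variance windows, step-size-only tail)."""
    init_buf, term_buf, base = 75, 50, 25
    if n_warmup < init_buf + term_buf + base:
        init_buf = max(int(0.15 * n_warmup), 1)
        term_buf = max(int(0.10 * n_warmup), 1)
        base = max(n_warmup - init_buf - term_buf, 1)
    windows = []
    pos = init_buf
    w = base
    while pos + w < n_warmup - term_buf:
        nxt = w * 2
        if pos + w + nxt >= n_warmup - term_buf:
            w = n_warmup - term_buf - pos
        windows.append((pos, pos + w))
        pos += w
        w *= 2
    if not windows and n_warmup - term_buf > init_buf:
        windows.append((init_buf, n_warmup - term_buf))
    return windows


def nuts_sample(logp_grad, init, n_warmup, n_iter, rng, *, max_treedepth=10,
                target_accept=0.8):
    """Run one NUTS chain; returns a :class:`ChainResult` of post-warmup draws."""
    q = np.asarray(init, dtype=float).copy()
    dim = q.size
    logp, grad = logp_grad(q)
    if not np.isfinite(logp):
        raise ValueError("log posterior is not finite at the initial point")
    inv_mass = np.ones(dim)

    eps = _find_initial_step(logp_grad, q, logp, grad, inv_mass, rng)
    mu = math.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    windows = _adaptation_schedule(n_warmup)
    win_idx = 0
    wsum = np.zeros(dim)
    wsum2 = np.zeros(dim)
    wn = 0

    draws = np.empty((n_iter, dim))
    depths = np.empty(n_iter, dtype=np.int8)
    divergences = 0
    accept_accum = 0.0

    total = n_warmup + n_iter
    for it in range(total):
        warming = it < n_warmup
        q, logp, grad, astat, div, depth = _nuts_step(
            logp_grad, q, logp, grad, eps, inv_mass, rng, max_treedepth)
        if warming:
            da_count += 1
            h_bar = (1.0 - 1.0 / (da_count + t0)) * h_bar + (target_accept - astat) / (da_count + t0)
            log_eps = mu - math.sqrt(da_count) / gamma * h_bar
            frac = da_count ** (-kappa)
            log_eps_bar = frac * log_eps + (1.0 - frac) * log_eps_bar
            eps = math.exp(log_eps)
            if win_idx < len(windows):
                lo, hi = windows[win_idx]
                if lo <= it < hi:
                    wsum += q
                    wsum2 += q * q
                    wn += 1
                if it == hi - 1 and wn > 1:
                    var = (wsum2 - wsum * wsum / wn) / (wn - 1)
                    var = (wn / (wn + 5.0)) * var + 1e-3 * (5.0 / (wn + 5.0))
                    inv_mass = np.maximum(var, 1e-10)
                    wsum[:] = 0.0
                    wsum2[:] = 0.0
                    wn = 0
                    win_idx += 1
                    # restart step-size adaptation around the current value
                    eps = _find_initial_step(logp_grad, q, logp, grad, inv_mass, rng)
                    mu = math.log(10.0 * eps)
                    log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = math.exp(log_eps_bar)
        else:
            j = it - n_warmup
            draws[j] = q
            depths[j] = depth
            divergences += int(div)
            accept_accum += astat
    return ChainResult(draws=draws, divergences=divergences, step_size=eps,
                       mean_accept=accept_accum / max(n_iter, 1), treedepths=depths)


def run_chains(logp_grad, inits, n_warmup, n_iter, seed, *, max_treedepth=10,
               target_accept=0.8):
    """Run several chains sequentially with independent substreams of `seed`.

    inits: sequence of initial parameter vectors, one per chain.
    Returns (draws[chain, iter, dim], list of ChainResult).
    """
    results = []
    all_draws = []
    for c, init in enumerate(inits):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), c]))
        res = nuts_sample(logp_grad, init, n_warmup, n_iter, rng,
                          max_treedepth=max_treedepth, target_accept=target_accept)
        results.append(res)
        all_draws.append(res.draws)
    return np.stack(all_draws), results
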