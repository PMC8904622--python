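"""Log-posterior kernels (value + analytic gradient) for the model stack.

Three models are implemented on unconstrained parameter vectors so that the
NUTS sampler in :mod:`driftband.sampler` can run on them directly:

* the hierarchical drift-diffusion regression — condition-level drift and
  boundary locations (sampled on the cumulative "primed" scale to reduce
  posterior correlation), per-condition regression coefficients on z-scored
  covariates, Gaussian subject effects (non-centered), and subject
  non-decision times constrained below each subject's fastest RT via a
  scaled-logistic transform;
* a hierarchical logistic regression of trial difficulty on multichannel
  band power (partial pooling of per-subject channel coefficients);
* the per-condition Gaussian regression of neural slopes on symptom scores
  with hierarchically pooled intercepts.

Scale parameters are sampled on the log scale with half-normal priors and
the log-|Jacobian| included.  Hard constraint violations (e.g. non-positive
boundary separation, RT below non-decision time) return -inf, which the
sampler treats as a rejected/divergent proposal.
"""

import math

import numpy as np
from numba import njit

from ._wfpt import wfpt_trial_logpdf_grad

# ---------------------------------------------------------------------------
# hierarchical DDM regression
# ---------------------------------------------------------------------------


def ddm_param_layout(C, P, S):
    """Offsets of each block in the packed parameter vector."""
    off = {}
    off["drift_c"] = 0
    off["boundary_c"] = C
    off["drift_coef"] = 2 * C            # P x C, row-major by covariate
    off["boundary_coef"] = 2 * C + P * C
    off["eta_drift"] = 2 * C + 2 * P * C
    off["eta_boundary"] = off["eta_drift"] + S
    off["x_ndt"] = off["eta_boundary"] + S
    off["ndt_mu"] = off["x_ndt"] + S
    off["log_ndt_sd"] = off["ndt_mu"] + 1
    off["log_sigma_drift"] = off["ndt_mu"] + 2
    off["log_sigma_boundary"] = off["ndt_mu"] + 3
    off["n"] = off["ndt_mu"] + 4
    return off


@njit(cache=True)
def ddm_logp_grad(theta, rt, upper, cell_ptr, X, min_rt, C, P, S,
                  coef_sd, bound1_mean, ndt_mu_loc, ndt_mu_sd, ndt_sd_sd,
                  subj_sd_sd):
    n = theta.size
    g = np.zeros(n)
    o_d = 0
    o_b = C
    o_dc = 2 * C
    o_bc = 2 * C + P * C
    o_ed = 2 * C + 2 * P * C
    o_eb = o_ed + S
    o_x = o_eb + S
    o_mu = o_x + S
    o_lsn = o_mu + 1
    o_lsd = o_mu + 2
    o_lsb = o_mu + 3

    # cumulative ("primed") -> reported parameters
    drift_c = np.empty(C)
    bound_c = np.empty(C)
    drift_c[0] = theta[o_d]
    bound_c[0] = theta[o_b]
    for c in range(1, C):
        drift_c[c] = theta[o_d] + theta[o_d + c]
        bound_c[c] = theta[o_b] + theta[o_b + c]
    dcoef = np.empty((P, C))
    bcoef = np.empty((P, C))
    for p in range(P):
        dcoef[p, 0] = theta[o_dc + p * C]
        bcoef[p, 0] = theta[o_bc + p * C]
        for c in range(1, C):
            dcoef[p, c] = theta[o_dc + p * C] + theta[o_dc + p * C + c]
            bcoef[p, c] = theta[o_bc + p * C] + theta[o_bc + p * C + c]

    mu_ndt = theta[o_mu]
    sig_ndt = math.exp(theta[o_lsn])
    sig_d = math.exp(theta[o_lsd])
    sig_b = math.exp(theta[o_lsb])

    logp = 0.0
    cv = coef_sd * coef_sd

    # priors on the primed scale
    for c in range(C):
        logp += -theta[o_d + c] * theta[o_d + c] / (2.0 * cv)
        g[o_d + c] += -theta[o_d + c] / cv
        m = bound1_mean if c == 0 else 0.0
        logp += -(theta[o_b + c] - m) * (theta[o_b + c] - m) / (2.0 * cv)
        g[o_b + c] += -(theta[o_b + c] - m) / cv
    for k in range(2 * P * C):
        logp += -theta[o_dc + k] * theta[o_dc + k] / (2.0 * cv)
        g[o_dc + k] += -theta[o_dc + k] / cv
    for s in range(S):
        logp += -0.5 * (theta[o_ed + s] ** 2 + theta[o_eb + s] ** 2)
        g[o_ed + s] += -theta[o_ed + s]
        g[o_eb + s] += -theta[o_eb + s]
    # hyperpriors
    logp += -(mu_ndt - ndt_mu_loc) ** 2 / (2.0 * ndt_mu_sd * ndt_mu_sd)
    g[o_mu] += -(mu_ndt - ndt_mu_loc) / (ndt_mu_sd * ndt_mu_sd)
    # half-normal scales, sampled as logs (Jacobian = +log sigma each)
    logp += -sig_ndt * sig_ndt / (2.0 * ndt_sd_sd * ndt_sd_sd) + theta[o_lsn]
    g[o_lsn] += -sig_ndt * sig_ndt / (ndt_sd_sd * ndt_sd_sd) + 1.0
    sv = subj_sd_sd * subj_sd_sd
    logp += -sig_d * sig_d / (2.0 * sv) + theta[o_lsd]
    g[o_lsd] += -sig_d * sig_d / sv + 1.0
    logp += -sig_b * sig_b / (2.0 * sv) + theta[o_lsb]
    g[o_lsb] += -sig_b * sig_b / sv + 1.0

    # subject non-decision times: ndt_s = 0.999 * min_rt_s * sigmoid(x_s)
    ndt = np.empty(S)
    dndt_dx = np.empty(S)
    dndt_like = np.zeros(S)
    for s in range(S):
        m = 0.999 * min_rt[s]
        sgm = 1.0 / (1.0 + math.exp(-theta[o_x + s]))
        ndt[s] = m * sgm
        dndt_dx[s] = m * sgm * (1.0 - sgm)
        # prior N(mu_ndt, sig_ndt) on the constrained value + log Jacobian
        d = ndt[s] - mu_ndt
        logp += -d * d / (2.0 * sig_ndt * sig_ndt) - theta[o_lsn]
        logp += math.log(dndt_dx[s])
        dndt_like[s] += -d / (sig_ndt * sig_ndt)
        g[o_mu] += d / (sig_ndt * sig_ndt)
        g[o_lsn] += d * d / (sig_ndt * sig_ndt) - 1.0
        g[o_x + s] += 1.0 - 2.0 * sgm  # d/dx log|dndt/dx|

    # likelihood over subject x condition cells
    g_drift = np.zeros(C)
    g_bound = np.zeros(C)
    g_dcoef = np.zeros((P, C))
    g_bcoef = np.zeros((P, C))
    for s in range(S):
        for c in range(C):
            v = drift_c[c] + sig_d * theta[o_ed + s]
            a = bound_c[c] + sig_b * theta[o_eb + s]
            for p in range(P):
                v += dcoef[p, c] * X[s, c, p]
                a += bcoef[p, c] * X[s, c, p]
            if a < 1e-3:
                return -np.inf, np.zeros(n)
            dv_acc = 0.0
            da_acc = 0.0
            cell = s * C + c
            for i in range(cell_ptr[cell], cell_ptr[cell + 1]):
                lf, dvi, dai, dni = wfpt_trial_logpdf_grad(
                    rt[i], upper[i] == 1, v, a, ndt[s], 0.5)
                if lf == -np.inf:
                    return -np.inf, np.zeros(n)
                logp += lf
                dv_acc += dvi
                da_acc += dai
                dndt_like[s] += dni
            g_drift[c] += dv_acc
            g_bound[c] += da_acc
            g[o_ed + s] += dv_acc * sig_d
            g[o_eb + s] += da_acc * sig_b
            g[o_lsd] += dv_acc * theta[o_ed + s] * sig_d
            g[o_lsb] += da_acc * theta[o_eb + s] * sig_b
            for p in range(P):
                g_dcoef[p, c] += dv_acc * X[s, c, p]
                g_bcoef[p, c] += da_acc * X[s, c, p]
    for s in range(S):
        g[o_x + s] += dndt_like[s] * dndt_dx[s]

    # fold reported-scale gradients back to the primed parameters
    for c in range(C):
        g[o_d] += g_drift[c]
        g[o_b] += g_bound[c]
        if c > 0:
            g[o_d + c] += g_drift[c]
            g[o_b + c] += g_bound[c]
    for p in range(P):
        for c in range(C):
            g[o_dc + p * C] += g_dcoef[p, c]
            g[o_bc + p * C] += g_bcoef[p, c]
            if c > 0:
                g[o_dc + p * C + c] += g_dcoef[p, c]
                g[o_bc + p * C + c] += g_bcoef[p, c]
    return logp, g


# ---------------------------------------------------------------------------
# hierarchical logistic regression (electrode weighting)
# ---------------------------------------------------------------------------


def logistic_param_layout(Ch, S):
    off = {}
    off["mu"] = 0
    off["log_tau"] = Ch
    off["eta"] = 2 * Ch                  # S x Ch row-major
    off["alpha_mu"] = 2 * Ch + S * Ch
    off["log_alpha_tau"] = off["alpha_mu"] + 1
    off["eta_alpha"] = off["alpha_mu"] + 2
    off["n"] = off["eta_alpha"] + S
    return off


@njit(cache=True)
def logistic_logp_grad(theta, xmat, y, subj, Ch, S, coef_sd, tau_sd):
    n = theta.size
    g = np.zeros(n)
    o_mu = 0
    o_lt = Ch
    o_e = 2 * Ch
    o_am = 2 * Ch + S * Ch
    o_lat = o_am + 1
    o_ea = o_am + 2

    logp = 0.0
    cv = coef_sd * coef_sd
    tau = np.empty(Ch)
    for ch in range(Ch):
        tau[ch] = math.exp(theta[o_lt + ch])
        logp += -theta[o_mu + ch] ** 2 / (2.0 * cv)
        g[o_mu + ch] += -theta[o_mu + ch] / cv
        logp += -tau[ch] * tau[ch] / (2.0 * tau_sd * tau_sd) + theta[o_lt + ch]
        g[o_lt + ch] += -tau[ch] * tau[ch] / (tau_sd * tau_sd) + 1.0
    a_tau = math.exp(theta[o_lat])
    logp += -theta[o_am] ** 2 / (2.0 * cv)
    g[o_am] += -theta[o_am] / cv
    logp += -a_tau * a_tau / (2.0 * tau_sd * tau_sd) + theta[o_lat]
    g[o_lat] += -a_tau * a_tau / (tau_sd * tau_sd) + 1.0
    for k in range(S * Ch):
        logp += -0.5 * theta[o_e + k] ** 2
        g[o_e + k] += -theta[o_e + k]
    for s in range(S):
        logp += -0.5 * theta[o_ea + s] ** 2
        g[o_ea + s] += -theta[o_ea + s]

    beta = np.empty((S, Ch))
    alpha = np.empty(S)
    for s in range(S):
        alpha[s] = theta[o_am] + a_tau * theta[o_ea + s]
        for ch in range(Ch):
            beta[s, ch] = theta[o_mu + ch] + tau[ch] * theta[o_e + s * Ch + ch]

    g_beta = np.zeros((S, Ch))
    g_alpha = np.zeros(S)
    N = y.size
    for i in range(N):
        s = subj[i]
        lin = alpha[s]
        for ch in range(Ch):
            lin += beta[s, ch] * xmat[i, ch]
        # log-likelihood: y*lin - log(1 + exp(lin)), numerically stable
        if lin > 0.0:
            logp += y[i] * lin - lin - math.log1p(math.exp(-lin))
            pr = 1.0 / (1.0 + math.exp(-lin))
        else:
            logp += y[i] * lin - math.log1p(math.exp(lin))
            pr = math.exp(lin) / (1.0 + math.exp(lin))
        r = y[i] - pr
        g_alpha[s] += r
        for ch in range(Ch):
            g_beta[s, ch] += r * xmat[i, ch]

    for s in range(S):
        g[o_am] += g_alpha[s]
        g[o_lat] += g_alpha[s] * theta[o_ea + s] * a_tau
        g[o_ea + s] += g_alpha[s] * a_tau
        for ch in range(Ch):
            g[o_mu + ch] += g_beta[s, ch]
            g[o_lt + ch] += g_beta[s, ch] * theta[o_e + s * Ch + ch] * tau[ch]
            g[o_e + s * Ch + ch] += g_beta[s, ch] * tau[ch]
    return logp, g


# ---------------------------------------------------------------------------
# per-condition Gaussian regression of neural slopes on symptom scores
# ---------------------------------------------------------------------------


def slope_param_layout(C):
    off = {"b0": 0, "b_padua": C, "b_worry": 2 * C, "log_sd": 3 * C,
           "b0_mu": 4 * C, "log_b0_sd": 4 * C + 1, "n": 4 * C + 2}
    return off


def slope_logp_grad_factory(y, padua, worry, C, coef_sd=20.0):
    """Closure for the Eq-style slope regression; y is (S, C)."""
    S = y.shape[0]
    cv = coef_sd * coef_sd

    def logp_grad(theta):
        g = np.zeros_like(theta)
        b0 = theta[0:C]
        bp = theta[C:2 * C]
        bw = theta[2 * C:3 * C]
        sd = np.exp(theta[3 * C:4 * C])
        b0_mu = theta[4 * C]
        b0_sd = math.exp(theta[4 * C + 1])

        logp = -np.sum(bp ** 2 + bw ** 2) / (2.0 * cv)
        g[C:2 * C] += -bp / cv
        g[2 * C:3 * C] += -bw / cv
        # half-normal on residual SDs and on the intercept-pool SD (+ Jacobians)
        logp += np.sum(-sd ** 2 / (2.0 * cv) + theta[3 * C:4 * C])
        g[3 * C:4 * C] += -sd ** 2 / cv + 1.0
        logp += -b0_mu ** 2 / (2.0 * cv)
        g[4 * C] += -b0_mu / cv
        logp += -b0_sd ** 2 / (2.0 * cv) + theta[4 * C + 1]
        g[4 * C + 1] += -b0_sd ** 2 / cv + 1.0
        # hierarchical intercepts
        d0 = b0 - b0_mu
        logp += np.sum(-d0 ** 2 / (2.0 * b0_sd ** 2) - math.log(b0_sd))
        g[0:C] += -d0 / b0_sd ** 2
        g[4 * C] += np.sum(d0) / b0_sd ** 2
        g[4 * C + 1] += np.sum(d0 ** 2) / b0_sd ** 2 - C
        # likelihood
        mu = b0[None, :] + bp[None, :] * padua[:, None] + bw[None, :] * worry[:, None]
        resid = y - mu
        logp += np.sum(-resid ** 2 / (2.0 * sd[None, :] ** 2) - np.log(sd)[None, :])
        rs = resid / sd[None, :] ** 2
        g[0:C] += rs.sum(axis=0)
        g[C:2 * C] += (rs * padua[:, None]).sum(axis=0)
        g[2 * C:3 * C] += (rs * worry[:, None]).sum(axis=0)
        g[3 * C:4 * C] += (resid ** 2 / sd[None, :] ** 2 - 1.0).sum(axis=0)
        return logp, g

    return logp_grad
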