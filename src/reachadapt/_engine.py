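"""Numerical core: exact marginal likelihood and the MCMC chain loop.

The dual-rate dynamics with Gaussian state and output noise form a
linear-Gaussian state-space model, so the likelihood of the observed
adaptation indices (the outputs at error-clamp probes) is computed exactly
with a Kalman filter — no latent per-trial noise needs to be sampled.

Error feedback is folded into the transition matrix.  On field/null trials
the error e = f - y = f - (xf + xs) - eps_out, so

    x(n+1) = A x(n) + L f(n) + w(n),
    A = [[Rf - Lf, -Lf], [-Ls, Rs - Ls]],
    Cov w = sigma_state^2 I + sigma_output^2 L L^T,

while on error-clamp trials the error is clamped to zero: A = diag(Rf, Rs)
and Cov w = sigma_state^2 I.  Observations y = xf + xs + eps_out occur at EC
probes only; there the output noise does not enter the dynamics, so process
and observation noise stay uncorrelated.

Sampling is adaptive random-walk Metropolis-within-Gibbs: one 6-d block per
participant (its parameters, against the Kalman likelihood and its
truncated-normal priors) and one 2-d block per group-level (mu, sigma) pair
(cheap: prior terms only).  Proposal covariances and scales adapt during
warmup (Haario-style empirical covariance + Robbins-Monro scale tuning) and
are frozen afterwards, so the post-warmup chain is a valid Markov chain.

Parameter vector layout (P participants):
  theta[6p : 6p+6] = (Rf, Rs, Lf, Ls, sigma_state, sigma_output) of participant p
  theta[6P + 2j], theta[6P + 2j + 1] = (mu_j, sigma_j) for parameter j
with j in the same order.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

LOG2PI = math.log(2.0 * math.pi)
SQRT1_2 = 1.0 / math.sqrt(2.0)

# hyperprior constants, parameter order (Rf, Rs, Lf, Ls, ss, so):
# truncated-normal hyperpriors on the rate group means,
HYPER_MU_M0 = np.array([0.85, 0.998, 0.1, 0.1])
HYPER_MU_S0 = np.array([0.5, 0.01, 0.5, 0.5])
# half-Cauchy scales: group SDs of all parameters, group means of noise SDs
HC_SCALE_SD = 0.5
HC_SCALE_NOISE_MU = 1.0


@njit(cache=True)
def _phi(z):
    return 0.5 * (1.0 + math.erf(z * SQRT1_2))


@njit(cache=True)
def kalman_loglik(th, f, is_ec, obs, y):
    """Exact log-likelihood of one participant's probe AIs.

    th: (Rf, Rs, Lf, Ls, sigma_state, sigma_output); f, is_ec, obs are
    per-trial arrays; y holds the observed AI at the obs-flagged trials,
    in trial order.
    """
    Rf, Rs, Lf, Ls = th[0], th[1], th[2], th[3]
    ss2 = th[4] * th[4]
    so2 = th[5] * th[5]
    m1 = 0.0
    m2 = 0.0
    p11 = 0.0
    p12 = 0.0
    p22 = 0.0
    ll = 0.0
    j = 0
    for n in range(f.shape[0]):
        if obs[n]:
            s = p11 + 2.0 * p12 + p22 + so2
            if s < 1e-300:
                return -np.inf
            v = y[j] - (m1 + m2)
            ll += -0.5 * (LOG2PI + math.log(s) + v * v / s)
            c1 = p11 + p12
            c2 = p12 + p22
            k1 = c1 / s
            k2 = c2 / s
            m1 += k1 * v
            m2 += k2 * v
            p11 -= k1 * c1
            p12 -= k1 * c2
            p22 -= k2 * c2
            j += 1
        if is_ec[n]:
            m1n = Rf * m1
            m2n = Rs * m2
            p11n = Rf * Rf * p11 + ss2
            p12n = Rf * Rs * p12
            p22n = Rs * Rs * p22 + ss2
        else:
            a11 = Rf - Lf
            a12 = -Lf
            a21 = -Ls
            a22 = Rs - Ls
            m1n = a11 * m1 + a12 * m2 + Lf * f[n]
            m2n = a21 * m1 + a22 * m2 + Ls * f[n]
            t11 = a11 * p11 + a12 * p12
            t12 = a11 * p12 + a12 * p22
            t21 = a21 * p11 + a22 * p12
            t22 = a21 * p12 + a22 * p22
            p11n = t11 * a11 + t12 * a12 + ss2 + so2 * Lf * Lf
            p12n = t11 * a21 + t12 * a22 + so2 * Lf * Ls
            p22n = t21 * a21 + t22 * a22 + ss2 + so2 * Ls * Ls
        m1, m2 = m1n, m2n
        p11, p12, p22 = p11n, p12n, p22n
    return ll


@njit(cache=True)
def _support_ok(th):
    return (
        0.0 < th[0] < th[1] < 1.0
        and 0.0 < th[3] < th[2] < 1.0
        and th[4] > 0.0
        and th[5] > 0.0
    )


@njit(cache=True)
def participant_logprior(th, hyp):
    """Participant-level prior, dropping terms constant in th (normalising
    constants of the truncations depend only on the hypers and cancel in
    participant-block Metropolis ratios)."""
    if not _support_ok(th):
        return -np.inf
    lp = 0.0
    for j in range(6):
        mu = hyp[2 * j]
        sd = hyp[2 * j + 1]
        z = (th[j] - mu) / sd
        lp += -0.5 * z * z
    return lp


@njit(cache=True)
def hyper_logdens(j, mu, sd, th_col, m0, s0):
    """Log-density terms involving the (mu_j, sigma_j) hyperparameter pair:
    hyperprior plus the participant-level truncated-normal prior terms
    (including their truncation normalisers, which depend on mu and sd)."""
    if sd <= 0.0:
        return -np.inf
    is_rate = j < 4
    if is_rate:
        if not (0.0 < mu < 1.0):
            return -np.inf
        z0 = (mu - m0[j]) / s0[j]
        lp = -0.5 * z0 * z0
        zc = _phi((1.0 - mu) / sd) - _phi((0.0 - mu) / sd)
    else:
        if mu <= 0.0:
            return -np.inf
        r = mu / HC_SCALE_NOISE_MU
        lp = -math.log1p(r * r)
        zc = 1.0 - _phi((0.0 - mu) / sd)
    rs = sd / HC_SCALE_SD
    lp += -math.log1p(rs * rs)
    if zc < 1e-300:
        return -np.inf
    n = th_col.shape[0]
    lp += -n * (math.log(sd) + math.log(zc))
    for p in range(n):
        z = (th_col[p] - mu) / sd
        lp += -0.5 * z * z
    return lp


@njit(cache=True)
def hierarchical_logpost(theta, n_part, f, is_ec, obs, y_mat, m0, s0):
    """Full joint log-density (up to constants): for tests and diagnostics."""
    hyp = theta[6 * n_part :]
    lp = 0.0
    for j in range(6):
        lp_j = hyper_logdens(j, hyp[2 * j], hyp[2 * j + 1], theta[j : 6 * n_part : 6], m0, s0)
        if not np.isfinite(lp_j):
            return -np.inf
        lp += lp_j
    for p in range(n_part):
        th = theta[6 * p : 6 * p + 6]
        if not _support_ok(th):
            return -np.inf
        lp += kalman_loglik(th, f, is_ec, obs, y_mat[p])
    return lp


@njit(cache=True)
def _col_support_ok(j, col, partner, mu):
    """Support of one parameter column after a group move: truncation plus
    the ordering against its partner column (Rf<Rs, Ls<Lf)."""
    if j < 4 and not (0.0 < mu < 1.0):
        return False
    if j >= 4 and mu <= 0.0:
        return False
    for p in range(col.shape[0]):
        v = col[p]
        if j == 0:  # Rf
            if not (0.0 < v < partner[p]):
                return False
        elif j == 1:  # Rs
            if not (partner[p] < v < 1.0):
                return False
        elif j == 2:  # Lf
            if not (partner[p] < v < 1.0):
                return False
        elif j == 3:  # Ls
            if not (0.0 < v < partner[p]):
                return False
        else:
            if v <= 0.0:
                return False
    return True


@njit(cache=True)
def _tri_solve_mul(ch, z, d):
    out = np.zeros(d)
    for i in range(d):
        acc = 0.0
        for k in range(i + 1):
            acc += ch[i, k] * z[k]
        out[i] = acc
    return out


@njit(cache=True)
def run_chain(y_mat, f, is_ec, obs, theta0, n_warmup, n_iter, seed, m0, s0, init_sd):
    """One MCMC chain; returns (post-warmup draws, per-block acceptance rates).

    y_mat: (P, M) observed AIs; theta0: initial parameter vector;
    init_sd: initial proposal SD for each of the 6 participant-level
    coordinates followed by the 12 hyper coordinates.
    """
    np.random.seed(seed)
    n_part = y_mat.shape[0]
    dim = 6 * n_part + 12
    theta = theta0.copy()

    # cached likelihoods
    lik = np.empty(n_part)
    for p in range(n_part):
        lik[p] = kalman_loglik(theta[6 * p : 6 * p + 6], f, is_ec, obs, y_mat[p])

    n_blocks = n_part + 6
    # proposal state per block
    chol_p = np.zeros((n_part, 6, 6))
    for p in range(n_part):
        for i in range(6):
            chol_p[p, i, i] = init_sd[i]
    chol_h = np.zeros((6, 2, 2))
    for j in range(6):
        chol_h[j, 0, 0] = init_sd[6 + 2 * j]
        chol_h[j, 1, 1] = init_sd[6 + 2 * j + 1]
    ls = np.zeros(n_blocks)  # log proposal scale per block

    # Welford accumulators (participant blocks share one, being exchangeable
    # would be wrong — keep per block)
    mean_p = np.zeros((n_part, 6))
    m2_p = np.zeros((n_part, 6, 6))
    mean_h = np.zeros((6, 2))
    m2_h = np.zeros((6, 2, 2))
    n_acc = np.zeros(n_blocks)
    n_try = np.zeros(n_blocks)
    cov_switched = False

    # group-move proposal log-scales: per parameter, (translation, log-scale)
    gls = np.empty(12)
    trans0 = np.array([0.02, 0.002, 0.01, 0.003, 0.005, 0.01])
    for j in range(6):
        gls[2 * j] = math.log(trans0[j])
        gls[2 * j + 1] = math.log(0.2)
    partner_of = np.array([1, 0, 3, 2, -1, -1])

    total = n_warmup + n_iter
    draws = np.empty((n_iter, dim))
    target = 0.27

    for it in range(total):
        adapt = it < n_warmup
        gamma = 1.0 / (1.0 + 0.1 * it) ** 0.6 if adapt else 0.0

        for p in range(n_part):
            cur = theta[6 * p : 6 * p + 6]
            z = np.random.standard_normal(6)
            step = _tri_solve_mul(chol_p[p], z, 6)
            prop = cur + math.exp(ls[p]) * step
            hyp = theta[6 * n_part :]
            lp_new = participant_logprior(prop, hyp)
            alpha = 0.0
            if np.isfinite(lp_new):
                ll_new = kalman_loglik(prop, f, is_ec, obs, y_mat[p])
                num = lp_new + ll_new
                if not math.isnan(num) and num > -np.inf:
                    den = participant_logprior(cur, hyp) + lik[p]
                    if math.isnan(den) or den == -np.inf:
                        alpha = 1.0  # escape an invalid current state
                    else:
                        alpha = math.exp(min(0.0, num - den))
                    if np.random.random() < alpha:
                        for i in range(6):
                            theta[6 * p + i] = prop[i]
                        lik[p] = ll_new
                        n_acc[p] += 1.0
            n_try[p] += 1.0
            if adapt:
                ls[p] += gamma * (alpha - target)

        for j in range(6):
            b = n_part + j
            i0 = 6 * n_part + 2 * j
            mu_c, sd_c = theta[i0], theta[i0 + 1]
            z2 = np.random.standard_normal(2)
            d0 = math.exp(ls[b]) * (chol_h[j, 0, 0] * z2[0])
            d1 = math.exp(ls[b]) * (chol_h[j, 1, 0] * z2[0] + chol_h[j, 1, 1] * z2[1])
            mu_n, sd_n = mu_c + d0, sd_c + d1
            col = theta[j : 6 * n_part : 6].copy()
            lp_new = hyper_logdens(j, mu_n, sd_n, col, m0, s0)
            alpha = 0.0
            if np.isfinite(lp_new):
                den = hyper_logdens(j, mu_c, sd_c, col, m0, s0)
                if math.isnan(den) or den == -np.inf:
                    alpha = 1.0
                else:
                    alpha = math.exp(min(0.0, lp_new - den))
                if np.random.random() < alpha:
                    theta[i0] = mu_n
                    theta[i0 + 1] = sd_n
                    n_acc[b] += 1.0
            n_try[b] += 1.0
            if adapt:
                ls[b] += gamma * (alpha - target)

        # group moves: jointly shift or rescale one parameter's hyper pair
        # and all its participant values — breaks the funnel coupling
        # between group SDs and participant-level parameters
        for _rep in range(2):
            j = np.random.randint(6)
            use_scale = np.random.random() < 0.5
            i0h = 6 * n_part + 2 * j
            mu_c, sd_c = theta[i0h], theta[i0h + 1]
            col = theta[j : 6 * n_part : 6].copy()
            if partner_of[j] >= 0:
                partner = theta[partner_of[j] : 6 * n_part : 6].copy()
            else:
                partner = col
            col_n = np.empty(n_part)
            if use_scale:
                eps = math.exp(gls[2 * j + 1]) * np.random.standard_normal()
                s = math.exp(eps)
                mu_n, sd_n = mu_c, sd_c * s
                for p in range(n_part):
                    col_n[p] = mu_c + s * (col[p] - mu_c)
                jac = (n_part + 1.0) * eps
            else:
                dlt = math.exp(gls[2 * j]) * np.random.standard_normal()
                mu_n, sd_n = mu_c + dlt, sd_c
                for p in range(n_part):
                    col_n[p] = col[p] + dlt
                jac = 0.0
            alpha = 0.0
            if sd_n > 0.0 and _col_support_ok(j, col_n, partner, mu_n):
                lp_new = hyper_logdens(j, mu_n, sd_n, col_n, m0, s0)
                if np.isfinite(lp_new):
                    dll = 0.0
                    ll_new = np.empty(n_part)
                    ok = True
                    for p in range(n_part):
                        th_try = theta[6 * p : 6 * p + 6].copy()
                        th_try[j] = col_n[p]
                        ll = kalman_loglik(th_try, f, is_ec, obs, y_mat[p])
                        if math.isnan(ll):
                            ok = False
                            break
                        ll_new[p] = ll
                        dll += ll - lik[p]
                    if ok:
                        den = hyper_logdens(j, mu_c, sd_c, col, m0, s0)
                        logr = lp_new - den + dll + jac
                        if not math.isnan(logr):
                            alpha = math.exp(min(0.0, logr))
                            if np.random.random() < alpha:
                                theta[i0h] = mu_n
                                theta[i0h + 1] = sd_n
                                for p in range(n_part):
                                    theta[6 * p + j] = col_n[p]
                                    lik[p] = ll_new[p]
            if adapt:
                gls[2 * j + (1 if use_scale else 0)] += gamma * (alpha - target)

        if adapt:
            # Welford update of empirical covariances
            k = it + 1
            for p in range(n_part):
                x = theta[6 * p : 6 * p + 6]
                for i in range(6):
                    d_i = x[i] - mean_p[p, i]
                    mean_p[p, i] += d_i / k
                    for q in range(6):
                        m2_p[p, i, q] += d_i * (x[q] - mean_p[p, q])
            for j in range(6):
                i0 = 6 * n_part + 2 * j
                for i in range(2):
                    d_i = theta[i0 + i] - mean_h[j, i]
                    mean_h[j, i] += d_i / k
                    for q in range(2):
                        m2_h[j, i, q] += d_i * (theta[i0 + q] - mean_h[j, q])
            if k >= 200 and k % 100 == 0:
                for p in range(n_part):
                    cov = m2_p[p] / (k - 1)
                    tr = 0.0
                    for i in range(6):
                        tr += cov[i, i]
                    if tr > 1e-18:
                        for i in range(6):
                            cov[i, i] += 1e-14 + 1e-8 * cov[i, i]
                        chol_p[p] = np.linalg.cholesky(cov)
                        if not cov_switched:
                            ls[p] = math.log(2.38 / math.sqrt(6.0))
                for j in range(6):
                    cov2 = m2_h[j] / (k - 1)
                    if cov2[0, 0] + cov2[1, 1] > 1e-18:
                        for i in range(2):
                            cov2[i, i] += 1e-14 + 1e-8 * cov2[i, i]
                        chol_h[j] = np.linalg.cholesky(cov2)
                        if not cov_switched:
                            ls[n_part + j] = math.log(2.38 / math.sqrt(2.0))
                cov_switched = True
        else:
            draws[it - n_warmup] = theta

    return draws, n_acc / n_try
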