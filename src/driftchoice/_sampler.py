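"""Numba kernel: adaptive Metropolis-within-Gibbs for the hierarchical
drift-regression diffusion model.

Parameterization (per context c, participant p): the unconstrained
vector U[c, p, :] holds (log a, logit z, log t_nd, beta_0..beta_B).
Participant values are exchangeable draws from Normal(mu[c,k],
sigma[c,k]^2) on the unconstrained scale; group means get conjugate
Gibbs updates under Normal(m0, tau0^2) hyperpriors, group SDs get
adaptive random-walk Metropolis on the log scale under a Half-Normal(1)
prior.  Participant parameters mix through two complementary moves:
single-site adaptive random-walk Metropolis (targeting 44% acceptance)
and full-vector multivariate proposals whose covariance is estimated
from the chain's own burn-in history (Haario-style, scaled 2.38^2/K,
targeting ~25% acceptance) — the joint moves carry the sampler along
the correlated ridges (e.g. starting point vs baseline drift) that
defeat purely coordinate-wise updates.

Because weakly-identified participant parameters couple tightly to
their group SD under the centered parameterization (the hierarchical
funnel), each iteration also interweaves two non-centered group moves
per (context, parameter): a scale move that proposes a new sigma and
rescales every participant deviation with it, and a translation move
that shifts mu together with all participant values.  All adaptation
happens during burn-in only; proposal scales and covariances are frozen
afterwards.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ._wfpt import loglik_block


@njit(cache=True)
def _natural(Urow):
    a = math.exp(Urow[0])
    z = 1.0 / (1.0 + math.exp(-Urow[1]))
    t = math.exp(Urow[2])
    return a, z, t


@njit(cache=True)
def _block_ll(rt, upper, X, s, e, Urow):
    if e <= s:
        return 0.0
    a, z, t = _natural(Urow)
    return loglik_block(rt[s:e], upper[s:e], X[s:e], a, z, t, Urow[3:])


@njit(cache=True)
def _cholesky(A, L):
    """In-place lower Cholesky of small SPD matrix; False if not SPD."""
    K = A.shape[0]
    for i in range(K):
        for j in range(i + 1):
            s = A[i, j]
            for m in range(j):
                s -= L[i, m] * L[j, m]
            if i == j:
                if s <= 0.0:
                    return False
                L[i, i] = math.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
        for j in range(i + 1, K):
            L[i, j] = 0.0
    return True


@njit(cache=True)
def _prior_lp(Urow, mu_c, sig_c):
    lp = 0.0
    K = Urow.shape[0]
    for k in range(K):
        d = (Urow[k] - mu_c[k]) / sig_c[k]
        lp += -0.5 * d * d
    return lp


@njit(cache=True)
def _nc_scale_target(rt, upper, X, start, end, U, mu, c, k, e_buf, ls,
                     prop, ll_buf):
    """Log joint of the non-centered scale coordinate: likelihood at the
    rescaled participant deviations + Half-Normal(1) prior + Jacobian."""
    s = math.exp(ls)
    C, P, K = U.shape
    tot = 0.0
    for p in range(P):
        for kk in range(K):
            prop[kk] = U[c, p, kk]
        prop[k] = mu[c, k] + e_buf[p] * s
        nl = _block_ll(rt, upper, X, start[c, p], end[c, p], prop)
        if nl == -np.inf:
            return -np.inf
        ll_buf[p] = nl
        tot += nl
    return tot - s * s / 2.0 + ls


@njit(cache=True)
def _nc_shift_target(rt, upper, X, start, end, U, mu, c, k, m0, tau0, shift,
                     prop, ll_buf):
    """Log joint of the non-centered location shift: likelihood with all
    participant values translated + Normal hyperprior on the group mean."""
    C, P, K = U.shape
    tot = 0.0
    for p in range(P):
        for kk in range(K):
            prop[kk] = U[c, p, kk]
        prop[k] = U[c, p, k] + shift
        nl = _block_ll(rt, upper, X, start[c, p], end[c, p], prop)
        if nl == -np.inf:
            return -np.inf
        ll_buf[p] = nl
        tot += nl
    d = (mu[c, k] + shift - m0[k]) / tau0[k]
    return tot - 0.5 * d * d


@njit(cache=True)
def run_chain(rt, upper, X, start, end, n_iter, n_burn, n_sweeps, n_block,
              m0, tau0, U0, mu0, sig0, seed):
    """One MCMC chain; returns post-burn-in draws.

    rt/upper/X: trial data sorted so block (c, p) occupies rows
    [start[c,p], end[c,p]).  m0/tau0: (K,) hyperprior location/scale for
    group means.  n_sweeps single-site scans and n_block multivariate
    proposals per participant per iteration.  Returns
    (U_draws, mu_draws, sig_draws, deviance) with the draw axis first.
    """
    np.random.seed(seed)
    C, P, K = U0.shape
    U = U0.copy()
    mu = mu0.copy()
    sig = sig0.copy()

    cur_ll = np.empty((C, P))
    for c in range(C):
        for p in range(P):
            cur_ll[c, p] = _block_ll(rt, upper, X, start[c, p], end[c, p], U[c, p])

    # single-site proposal scales
    log_step_u = np.full((C, P, K), math.log(0.15))
    acc_u = np.zeros((C, P, K))
    try_u = np.zeros((C, P, K))
    # group-SD proposal scales
    log_step_s = np.full((C, K), math.log(0.3))
    acc_s = np.zeros((C, K))
    try_s = np.zeros((C, K))
    # fixed slice widths for the interweaved (non-centered) group moves
    log_step_nc = np.full((C, K), math.log(0.2))
    log_step_tr = np.full((C, K), math.log(0.1))
    new_ll_buf = np.empty(P)
    e_buf = np.empty(P)
    # block-proposal state: running moments, Cholesky factors, scales
    msum = np.zeros((C, P, K))
    osum = np.zeros((C, P, K, K))
    n_mom = 0
    chol = np.zeros((C, P, K, K))
    chol_ok = np.zeros((C, P), np.uint8)
    log_scale_b = np.full((C, P), math.log(2.38 / math.sqrt(K)))
    acc_b = np.zeros((C, P))
    try_b = np.zeros((C, P))

    adapt_start = n_burn // 4
    n_keep = n_iter - n_burn
    U_out = np.empty((n_keep, C, P, K))
    mu_out = np.empty((n_keep, C, K))
    sig_out = np.empty((n_keep, C, K))
    dev_out = np.empty(n_keep)

    prop = np.empty(K)
    eps = np.empty(K)
    batch = 0
    for it in range(n_iter):
        for c in range(C):
            for p in range(P):
                # single-site scans
                for sweep in range(n_sweeps):
                    for k in range(K):
                        for kk in range(K):
                            prop[kk] = U[c, p, kk]
                        step = math.exp(log_step_u[c, p, k])
                        prop[k] = U[c, p, k] + step * np.random.normal()
                        new_ll = _block_ll(rt, upper, X, start[c, p], end[c, p], prop)
                        try_u[c, p, k] += 1.0
                        if new_ll == -np.inf:
                            continue
                        d_new = (prop[k] - mu[c, k]) / sig[c, k]
                        d_old = (U[c, p, k] - mu[c, k]) / sig[c, k]
                        dprior = -0.5 * d_new * d_new + 0.5 * d_old * d_old
                        if math.log(np.random.random()) < new_ll - cur_ll[c, p] + dprior:
                            U[c, p, k] = prop[k]
                            cur_ll[c, p] = new_ll
                            acc_u[c, p, k] += 1.0
                # independence proposals from the current group law: these
                # are the mode-jumping moves — a chain whose block settles
                # in a poor local mode (e.g. a spurious non-decision-time
                # basin) re-enters the population-typical region through
                # them.  With q = prior, the MH ratio is the likelihood
                # ratio alone.
                for b in range(2):
                    for k in range(K):
                        prop[k] = mu[c, k] + sig[c, k] * np.random.normal()
                    new_ll = _block_ll(rt, upper, X, start[c, p], end[c, p], prop)
                    if new_ll == -np.inf:
                        continue
                    if math.log(np.random.random()) < new_ll - cur_ll[c, p]:
                        for k in range(K):
                            U[c, p, k] = prop[k]
                        cur_ll[c, p] = new_ll
                # coordinate-wise independence proposals: near-rejection-free
                # for weakly likelihood-identified coordinates (e.g. the
                # starting point), whose conditionals are prior-dominated
                for k in range(K):
                    for kk in range(K):
                        prop[kk] = U[c, p, kk]
                    prop[k] = mu[c, k] + sig[c, k] * np.random.normal()
                    new_ll = _block_ll(rt, upper, X, start[c, p], end[c, p], prop)
                    if new_ll == -np.inf:
                        continue
                    if math.log(np.random.random()) < new_ll - cur_ll[c, p]:
                        U[c, p, k] = prop[k]
                        cur_ll[c, p] = new_ll
                # joint multivariate moves along the adapted covariance
                if chol_ok[c, p] == 1:
                    for b in range(n_block):
                        sc = math.exp(log_scale_b[c, p])
                        for k in range(K):
                            eps[k] = np.random.normal()
                        for k in range(K):
                            s = 0.0
                            for m in range(k + 1):
                                s += chol[c, p, k, m] * eps[m]
                            prop[k] = U[c, p, k] + sc * s
                        new_ll = _block_ll(rt, upper, X, start[c, p], end[c, p], prop)
                        try_b[c, p] += 1.0
                        if new_ll == -np.inf:
                            continue
                        dprior = (_prior_lp(prop, mu[c], sig[c])
                                  - _prior_lp(U[c, p], mu[c], sig[c]))
                        if math.log(np.random.random()) < new_ll - cur_ll[c, p] + dprior:
                            for k in range(K):
                                U[c, p, k] = prop[k]
                            cur_ll[c, p] = new_ll
                            acc_b[c, p] += 1.0
            # group means: conjugate Gibbs
            for k in range(K):
                s2 = sig[c, k] * sig[c, k]
                prec = P / s2 + 1.0 / (tau0[k] * tau0[k])
                su = 0.0
                for p in range(P):
                    su += U[c, p, k]
                mean = (su / s2 + m0[k] / (tau0[k] * tau0[k])) / prec
                mu[c, k] = mean + np.random.normal() / math.sqrt(prec)
            # group SDs: Metropolis on log scale, Half-Normal(1) prior
            for rep in range(3):
                for k in range(K):
                    ls = math.log(sig[c, k])
                    ls_new = ls + math.exp(log_step_s[c, k]) * np.random.normal()
                    s_new = math.exp(ls_new)
                    ss = 0.0
                    for p in range(P):
                        d = U[c, p, k] - mu[c, k]
                        ss += d * d
                    # log target + log-Jacobian of the log transform
                    lp_new = (-P * ls_new - ss / (2.0 * s_new * s_new)
                              - s_new * s_new / 2.0 + ls_new)
                    lp_old = (-P * ls - ss / (2.0 * sig[c, k] * sig[c, k])
                              - sig[c, k] * sig[c, k] / 2.0 + ls)
                    try_s[c, k] += 1.0
                    if math.log(np.random.random()) < lp_new - lp_old:
                        sig[c, k] = s_new
                        acc_s[c, k] += 1.0
            # interweaved non-centered moves (funnel escape): slice-sampled
            # in the non-centered parameterization.  These are the binding
            # constraint on group-SD mixing; slice sampling is
            # rejection-free and self-tuning, so each call makes a full
            # conditional draw at the price of a handful of likelihood
            # sweeps over the participants.
            for _nc_rep in range(2):
              for k in range(K):
                # --- scale move: log sigma with deviations rescaled -------
                for p in range(P):
                    e_buf[p] = (U[c, p, k] - mu[c, k]) / sig[c, k]
                ls0 = math.log(sig[c, k])
                g0 = 0.0
                for p in range(P):
                    g0 += cur_ll[c, p]
                g0 += -sig[c, k] * sig[c, k] / 2.0 + ls0
                y_slice = g0 + math.log(np.random.random())
                w = math.exp(log_step_nc[c, k]) * 2.0
                L = ls0 - w * np.random.random()
                R = L + w
                # step out (bounded)
                for _so in range(5):
                    gl = _nc_scale_target(rt, upper, X, start, end, U, mu, c, k,
                                          e_buf, L, prop, new_ll_buf)
                    if gl <= y_slice:
                        break
                    L -= w
                for _so in range(5):
                    gr = _nc_scale_target(rt, upper, X, start, end, U, mu, c, k,
                                          e_buf, R, prop, new_ll_buf)
                    if gr <= y_slice:
                        break
                    R += w
                # shrink
                for _sh in range(20):
                    ls_new = L + (R - L) * np.random.random()
                    g_new = _nc_scale_target(rt, upper, X, start, end, U, mu,
                                             c, k, e_buf, ls_new, prop,
                                             new_ll_buf)
                    if g_new > y_slice:
                        s_new = math.exp(ls_new)
                        for p in range(P):
                            U[c, p, k] = mu[c, k] + e_buf[p] * s_new
                            cur_ll[c, p] = new_ll_buf[p]
                        sig[c, k] = s_new
                        break
                    if ls_new < ls0:
                        L = ls_new
                    else:
                        R = ls_new
                # --- translation move: shift mu with all participants -----
                g0 = 0.0
                for p in range(P):
                    g0 += cur_ll[c, p]
                d0 = (mu[c, k] - m0[k]) / tau0[k]
                g0 += -0.5 * d0 * d0
                y_slice = g0 + math.log(np.random.random())
                w = math.exp(log_step_tr[c, k]) * 2.0
                L = -w * np.random.random()
                R = L + w
                for _so in range(5):
                    gl = _nc_shift_target(rt, upper, X, start, end, U, mu, c, k,
                                          m0, tau0, L, prop, new_ll_buf)
                    if gl <= y_slice:
                        break
                    L -= w
                for _so in range(5):
                    gr = _nc_shift_target(rt, upper, X, start, end, U, mu, c, k,
                                          m0, tau0, R, prop, new_ll_buf)
                    if gr <= y_slice:
                        break
                    R += w
                for _sh in range(20):
                    shift = L + (R - L) * np.random.random()
                    g_new = _nc_shift_target(rt, upper, X, start, end, U, mu,
                                             c, k, m0, tau0, shift, prop,
                                             new_ll_buf)
                    if g_new > y_slice:
                        for p in range(P):
                            U[c, p, k] += shift
                            cur_ll[c, p] = new_ll_buf[p]
                        mu[c, k] += shift
                        break
                    if shift < 0.0:
                        L = shift
                    else:
                        R = shift
        # burn-in adaptation
        if it < n_burn:
            if it >= adapt_start:
                n_mom += 1
                for c in range(C):
                    for p in range(P):
                        for k in range(K):
                            msum[c, p, k] += U[c, p, k]
                            for m in range(K):
                                osum[c, p, k, m] += U[c, p, k] * U[c, p, m]
            if (it + 1) % 25 == 0:
                batch += 1
                delta = min(0.25, 1.0 / math.sqrt(batch))
                for c in range(C):
                    for p in range(P):
                        for k in range(K):
                            if try_u[c, p, k] > 0:
                                r = acc_u[c, p, k] / try_u[c, p, k]
                                log_step_u[c, p, k] += delta if r > 0.44 else -delta
                            acc_u[c, p, k] = 0.0
                            try_u[c, p, k] = 0.0
                        if try_b[c, p] > 0:
                            r = acc_b[c, p] / try_b[c, p]
                            log_scale_b[c, p] += delta if r > 0.25 else -delta
                        acc_b[c, p] = 0.0
                        try_b[c, p] = 0.0
                    for k in range(K):
                        if try_s[c, k] > 0:
                            r = acc_s[c, k] / try_s[c, k]
                            log_step_s[c, k] += delta if r > 0.44 else -delta
                        acc_s[c, k] = 0.0
                        try_s[c, k] = 0.0
                # refresh proposal covariance from accumulated moments
                if n_mom >= 50:
                    A = np.empty((K, K))
                    L = np.empty((K, K))
                    for c in range(C):
                        for p in range(P):
                            for k in range(K):
                                for m in range(K):
                                    A[k, m] = (osum[c, p, k, m] / n_mom
                                               - (msum[c, p, k] / n_mom)
                                               * (msum[c, p, m] / n_mom))
                                A[k, k] += 1e-6
                            if _cholesky(A, L):
                                for k in range(K):
                                    for m in range(K):
                                        chol[c, p, k, m] = L[k, m]
                                chol_ok[c, p] = 1
        if it >= n_burn:
            j = it - n_burn
            U_out[j] = U
            mu_out[j] = mu
            sig_out[j] = sig
            tot = 0.0
            for c in range(C):
                for p in range(P):
                    tot += cur_ll[c, p]
            dev_out[j] = -2.0 * tot
    return U_out, mu_out, sig_out, dev_out


@njit(cache=True)
def total_loglik(rt, upper, X, start, end, U):
    """Summed log-likelihood of all blocks at unconstrained parameters U."""
    C, P, K = U.shape
    tot = 0.0
    for c in range(C):
        for p in range(P):
            tot += _block_ll(rt, upper, X, start[c, p], end[c, p], U[c, p])
    return tot
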