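"""Numba kernels: Wiener first-passage-time density and Euler simulation.

Conventions (within-trial noise sigma = 1):
  * boundaries at 0 (sooner/immediate) and a (later/delayed);
  * start at z*a with relative start z in (0, 1);
  * positive drift v pushes toward the upper (later) boundary;
  * decision time t excludes the non-decision time.

The density uses the classic dual series expansion with automatic
small-time / large-time regime selection at absolute truncation error
ERR; the lower-boundary density under (v, w) equals the upper-boundary
density under (-v, 1-w).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

ERR = 1e-7



@njit(cache=True)
def _ftt01w(tt: float, w: float) -> float:
    """FPT density at the lower boundary for v=0, a=1, at scaled time tt."""
    if tt <= 0.0:
        return 0.0
    # number of terms needed in each expansion for truncation error ERR
    if math.pi * tt * ERR < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt * ERR) / (math.pi**2 * tt))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(tt)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt))
    if 2.0 * math.sqrt(2.0 * math.pi * tt) * ERR < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(2.0 * math.sqrt(2.0 * math.pi * tt) * ERR))
        ks = max(ks, math.sqrt(tt) + 1.0)
    else:
        ks = 2.0
    p = 0.0
    if ks < kl:  # small-time expansion
        K = int(math.ceil(ks))
        lo = -int(math.floor((K - 1) / 2.0))
        hi = int(math.ceil((K - 1) / 2.0))
        for k in range(lo, hi + 1):
            y = w + 2.0 * k
            p += y * math.exp(-y * y / (2.0 * tt))
        p /= math.sqrt(2.0 * math.pi * tt**3)
    else:  # large-time expansion
        K = int(math.ceil(kl))
        for k in range(1, K + 1):
            p += k * math.exp(-(k * k) * (math.pi**2) * tt / 2.0) * math.sin(k * math.pi * w)
        p *= math.pi
    return p


@njit(cache=True)
def wfpt_logp(rt: float, upper: int, a: float, v: float, z: float, t_nd: float) -> float:
    """Log WFPT density at the given boundary (upper=1 later, 0 sooner)."""
    t = rt - t_nd
    if t <= 0.0 or a <= 0.0 or z <= 0.0 or z >= 1.0:
        return -np.inf
    if upper == 1:
        vv = -v
        w = 1.0 - z
    else:
        vv = v
        w = z
    tt = t / (a * a)
    p = _ftt01w(tt, w)
    if p <= 0.0:
        return -np.inf
    return math.log(p) - vv * a * w - vv * vv * t / 2.0 - 2.0 * math.log(a)


@njit(cache=True)
def loglik_block(rt, upper, X, a, z, t_nd, beta) -> float:
    """Summed trial log-likelihood for one participant-context block.

    X is (n, B) with intercept in column 0; beta is (B,).
    """
    total = 0.0
    n = rt.shape[0]
    B = beta.shape[0]
    for i in range(n):
        v = 0.0
        for j in range(B):
            v += X[i, j] * beta[j]
        lp = wfpt_logp(rt[i], upper[i], a, v, z, t_nd)
        if lp == -np.inf:
            return -np.inf
        total += lp
    return total


@njit(cache=True)
def simulate_kernel(a, z, t_nd, v, dt, max_t, seed):
    """Euler-Maruyama first-passage simulation for an array of drifts.

    Returns (choice, rt) with choice 1=upper/later, 0=lower/sooner,
    -1=timeout; rt includes t_nd (NaN on timeout).  Between Euler steps
    the Brownian-bridge boundary-crossing probability
    exp(-2 d0 d1 / dt) (d0, d1 the endpoint distances to the boundary)
    decides latent within-step absorptions, removing the leading-order
    discretization bias of the naive first-exit test.
    """
    np.random.seed(seed)
    n = v.shape[0]
    choice = np.empty(n, dtype=np.int8)
    rt = np.empty(n, dtype=np.float64)
    sdt = math.sqrt(dt)
    max_steps = int(max_t / dt)
    for i in range(n):
        x = z * a
        done = False
        for step in range(1, max_steps + 1):
            x_new = x + v[i] * dt + sdt * np.random.normal()
            if x_new >= a:
                choice[i] = 1
                rt[i] = step * dt + t_nd
                done = True
                break
            if x_new <= 0.0:
                choice[i] = 0
                rt[i] = step * dt + t_nd
                done = True
                break
            # bridge crossing of either boundary within the step
            p_up = math.exp(-2.0 * (a - x) * (a - x_new) / dt)
            if np.random.random() < p_up:
                choice[i] = 1
                rt[i] = step * dt + t_nd
                done = True
                break
            p_lo = math.exp(-2.0 * x * x_new / dt)
            if np.random.random() < p_lo:
                choice[i] = 0
                rt[i] = step * dt + t_nd
                done = True
                break
            x = x_new
        if not done:
            choice[i] = -1
            rt[i] = np.nan
    return choice, rt
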