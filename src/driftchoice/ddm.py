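"""Two-boundary drift-diffusion process: drift regression, simulation,
closed-form absorption probability, and the Wiener first-passage-time
(WFPT) likelihood.

The accumulator starts at ``z * a`` between absorbing boundaries 0 and
``a`` and evolves as ``dX = v dt + dW`` (unit within-trial noise).  The
upper boundary is the later/delayed option in both gain and loss
contexts; the first boundary hit fixes the choice, and the response time
is the first-passage time plus the non-decision time ``t_nd``.

Drift is a linear function of standardized trial covariates:

    v = beta0 + beta_reward * money_diff_z + beta_time * delay_diff_z
              + beta_base * baseline_z
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _wfpt

__all__ = [
    "DDMParams",
    "compute_drift",
    "hit_probability",
    "simulate_trial",
    "simulate_trials",
    "wfpt_log_density",
]


@dataclass(frozen=True)
class DDMParams:
    """Diffusion parameters for one participant in one context."""

    a: float  # boundary separation, evidence units
    z: float  # relative starting point in (0, 1)
    t_nd: float  # non-decision time, seconds
    beta0: float  # baseline drift, evidence/s
    beta_reward: float = 0.0  # drift per standardized money-difference unit
    beta_time: float = 0.0  # drift per standardized delay-difference unit
    beta_base: float = 0.0  # drift per standardized baseline unit
    context: str = "gain"

    def __post_init__(self):
        if not (self.a > 0):
            raise ValueError(f"boundary separation must be positive, got {self.a}")
        if not (0.0 < self.z < 1.0):
            raise ValueError(f"relative start must lie in (0, 1), got {self.z}")
        if self.t_nd < 0:
            raise ValueError(f"non-decision time must be >= 0, got {self.t_nd}")

    def with_(self, **kw) -> "DDMParams":
        return replace(self, **kw)


def compute_drift(params: DDMParams, covariates) -> float:
    """Trial drift rate from standardized covariates.

    ``covariates`` is the triple (money_diff_z, delay_diff_z, baseline_z).
    Positive drift moves toward the upper boundary (the later option).
    """
    cov = np.asarray(covariates, dtype=float)
    if cov.shape != (3,) or not np.all(np.isfinite(cov)):
        raise ValueError("covariates must be a finite triple")
    return float(
        params.beta0
        + params.beta_reward * cov[0]
        + params.beta_time * cov[1]
        + params.beta_base * cov[2]
    )


def hit_probability(a: float, v: float, z: float) -> float:
    """Probability that the diffusion absorbs at the upper boundary.

    Closed form for unit noise: ``(1 - exp(-2 v a z)) / (1 - exp(-2 v a))``,
    reducing to ``z`` as v -> 0.  z may take the degenerate values 0 or 1.
    """
    if a <= 0:
        raise ValueError("boundary separation must be positive")
    if not (0.0 <= z <= 1.0):
        raise ValueError("relative start must lie in [0, 1]")
    x = 2.0 * v * a
    if abs(x) < 1e-9:
        return float(z)
    # expm1 keeps precision for small exponents
    return float(math.expm1(-x * z) / math.expm1(-x))


def simulate_trials(params: DDMParams, drifts, dt: float = 1e-3,
                    max_t: float = 10.0, rng=None):
    """Simulate one trial per drift value by the Euler-Maruyama scheme.

    Within-step boundary crossings are resolved by the Brownian-bridge
    crossing probability, cancelling the leading-order discretization
    bias so the dt=1 ms default matches the analytic first-passage law.
    Returns ``(choice, rt)`` arrays with choice
    1=later, 0=sooner, -1=timeout (rt NaN); rt includes ``t_nd``.
    Timeout means total elapsed time (passage + t_nd) would exceed
    ``max_t``.
    """
    if dt <= 0 or max_t <= 0:
        raise ValueError("dt and max_t must be positive")
    rng = np.random.default_rng(rng)
    seed = int(rng.integers(0, 2**31 - 1))
    drifts = np.ascontiguousarray(drifts, dtype=float)
    # the decision window is max_t total, so passage time budget excludes t_nd
    budget = max_t - params.t_nd
    if budget <= 0:
        raise ValueError("max_t must exceed the non-decision time")
    return _wfpt.simulate_kernel(params.a, params.z, params.t_nd,
                                 drifts, dt, budget, seed)


def simulate_trial(params: DDMParams, covariates, dt: float = 1e-3,
                   max_t: float = 10.0, rng=None):
    """Simulate a single trial; returns ``("later"|"sooner"|"timeout", rt)``."""
    v = compute_drift(params, covariates)
    choice, rt = simulate_trials(params, np.array([v]), dt=dt, max_t=max_t, rng=rng)
    label = {1: "later", 0: "sooner", -1: "timeout"}[int(choice[0])]
    return label, float(rt[0])


def wfpt_log_density(rt: float, boundary: str, a: float, v: float,
                     z: float, t_nd: float) -> float:
    """Log WFPT density of absorbing at ``boundary`` ("upper"/"lower") at rt.

    Returns -inf (zero likelihood) for rt <= t_nd so samplers can reject
    gracefully.  The lower-boundary density is the upper-boundary density
    under the reflection (v -> -v, z -> 1 - z).
    """
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    if a <= 0 or not (0.0 < z < 1.0) or t_nd < 0:
        raise ValueError("invalid diffusion parameters")
    return float(_wfpt.wfpt_logp(float(rt), 1 if boundary == "upper" else 0,
                                 float(a), float(v), float(z), float(t_nd)))
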