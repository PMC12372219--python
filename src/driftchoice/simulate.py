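"""Synthetic two-group intertemporal-choice studies.

Generates complete datasets — control-like and SUD-like groups, each
participant performing all 144 design cells — from a hierarchical
drift-diffusion generative process, plus hyperbolic-discounting agents
for testing the discount-rate estimator in isolation.

Default group centers encode the study conditions the analysis targets:
the SUD-like group has a lower decision boundary in the loss context,
weaker reward/time drift sensitivity in gains, and near-zero contextual
modulation of its baseline drift, while the control-like group shifts
strongly between contexts.  Per-participant heterogeneity defaults to
20% of each center's magnitude with small floors for near-zero
coefficients (the underlying study reports only group means, so spreads
are assumptions of the generator and are documented as such).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .ddm import DDMParams
from . import _wfpt
from .task_design import standardize_covariates, covariate_matrix

TIMEOUT_RT = -1  # rt_ms marker for timed-out trials in the file format

PARAM_NAMES = ("a", "z", "t_nd", "beta0", "beta_reward", "beta_time", "beta_base")

# valid ranges enforced on sampled participant parameters (by resampling)
_BOUNDS = {
    "a": (0.3, np.inf),
    "z": (0.05, 0.95),
    "t_nd": (0.05, 2.0),
    "beta0": (-np.inf, np.inf),
    "beta_reward": (-np.inf, np.inf),
    "beta_time": (-np.inf, np.inf),
    "beta_base": (-np.inf, np.inf),
}


def _default_sds(means: DDMParams) -> dict[str, float]:
    """20% of |center| with floors for scale-free or near-zero parameters."""
    sds = {}
    for name in PARAM_NAMES:
        m = abs(getattr(means, name))
        if name == "a":
            sds[name] = 0.2 * m
        elif name == "z":
            sds[name] = 0.04
        elif name == "t_nd":
            sds[name] = 0.08
        else:
            sds[name] = max(0.2 * m, 0.03)
    return sds


@dataclass
class GroupSpec:
    """Population-level description of one simulated group."""

    label: str  # "control" or "sud"
    n_participants: int
    means: dict[str, DDMParams]  # per context
    sds: dict[str, dict[str, float]] = field(default_factory=dict)  # per context
    rng_seed: int = 0

    def __post_init__(self):
        for ctx, m in self.means.items():
            if ctx not in self.sds:
                self.sds[ctx] = _default_sds(m)
            for name, s in self.sds[ctx].items():
                if s < 0:
                    raise ValueError(f"negative spread for {name} in {ctx}")


def control_like_spec(n_participants: int = 86, rng_seed: int = 10) -> GroupSpec:
    means = {
        "gain": DDMParams(a=3.168, z=0.512, t_nd=0.5, beta0=0.33,
                          beta_reward=0.191, beta_time=-0.170, context="gain"),
        "loss": DDMParams(a=3.450, z=0.484, t_nd=0.5, beta0=-0.42,
                          beta_reward=-0.086, beta_time=0.083, context="loss"),
    }
    return GroupSpec("control", n_participants, means, rng_seed=rng_seed)


def sud_like_spec(n_participants: int = 100, rng_seed: int = 20) -> GroupSpec:
    means = {
        "gain": DDMParams(a=3.168, z=0.512, t_nd=0.5, beta0=-0.10,
                          beta_reward=0.130, beta_time=-0.131, context="gain"),
        "loss": DDMParams(a=3.100, z=0.484, t_nd=0.5, beta0=-0.10,
                          beta_reward=-0.051, beta_time=0.083, context="loss"),
    }
    return GroupSpec("sud", n_participants, means, rng_seed=rng_seed)


def draw_participant_params(spec: GroupSpec, rng: np.random.Generator) -> dict[str, DDMParams]:
    """Draw one participant's per-context parameters from the group law.

    Truncated-normal draws (by resampling) keep a > 0, z in (0, 1),
    t_nd >= 0.  With all spreads zero the group means are returned
    exactly, independent of the rng.
    """
    out = {}
    for ctx, m in spec.means.items():
        vals = {}
        for name in PARAM_NAMES:
            mu = getattr(m, name)
            sd = spec.sds[ctx][name]
            lo, hi = _BOUNDS[name]
            if sd == 0.0:
                vals[name] = mu
                continue
            for _ in range(1000):
                x = rng.normal(mu, sd)
                if lo < x < hi:
                    break
            else:  # pragma: no cover - pathological spec
                raise RuntimeError(f"could not draw {name} within bounds")
            vals[name] = x
        out[ctx] = DDMParams(context=ctx, **vals)
    return out


def _simulate_records(pid: str, group: str, params_by_ctx, design_df,
                      rng: np.random.Generator, dt: float, max_t: float):
    rows = []
    for ctx, params in params_by_ctx.items():
        sub = design_df[design_df["context"] == ctx]
        X = covariate_matrix(design_df, sub.index, ("money", "time", "baseline"))
        beta = np.array([params.beta0, params.beta_reward,
                         params.beta_time, params.beta_base])
        drifts = X @ beta
        seed = int(rng.integers(0, 2**31 - 1))
        budget = max_t - params.t_nd
        choice, rt = _wfpt.simulate_kernel(params.a, params.z, params.t_nd,
                                           np.ascontiguousarray(drifts),
                                           dt, budget, seed)
        for cid, ch, r in zip(sub.index, choice, rt):
            if ch == -1:
                rows.append((pid, group, cid, ctx, "timeout", TIMEOUT_RT))
            else:
                rows.append((pid, group, cid, ctx,
                             "later" if ch == 1 else "sooner",
                             int(round(r * 1000))))
    return rows


def simulate_participant(spec: GroupSpec, design_df: pd.DataFrame,
                         participant_index: int, rng=None,
                         dt: float = 1e-3, max_t: float = 10.0):
    """Simulate all 144 trials for one participant.

    Returns ``(trials, params_by_context)``.  The participant's
    parameters are drawn from the group distributions with a stream
    derived from ``spec.rng_seed`` and ``participant_index`` unless an
    explicit ``rng`` is given.
    """
    if rng is None:
        rng = np.random.default_rng([spec.rng_seed, participant_index])
    rng = np.random.default_rng(rng)
    params = draw_participant_params(spec, rng)
    pid = f"{spec.label}_{participant_index:03d}"
    rows = _simulate_records(pid, spec.label, params, design_df, rng, dt, max_t)
    trials = pd.DataFrame(rows, columns=["participant_id", "group", "condition_id",
                                         "context", "choice", "rt_ms"])
    return trials, params


def simulate_study(control_spec: GroupSpec | None = None,
                   sud_spec: GroupSpec | None = None,
                   rng_seed: int = 0,
                   contaminate: float = 0.01,
                   dt: float = 1e-3, max_t: float = 10.0):
    """Simulate a complete two-group study.

    Returns ``(trials, truth)`` where ``truth`` holds one row per
    participant per context with the generative diffusion parameters
    (for recovery testing).  A ``contaminate`` fraction of trials is
    replaced by fast guesses (rt < 100 ms, random choice) to exercise
    the exclusion filter; set 0 to disable.
    """
    control_spec = control_spec or control_like_spec()
    sud_spec = sud_spec or sud_like_spec()
    design_df = standardize_covariates()
    master = np.random.default_rng(rng_seed)
    all_trials, truth_rows = [], []
    for spec in (control_spec, sud_spec):
        for i in range(spec.n_participants):
            rng = np.random.default_rng([rng_seed, spec.rng_seed, i])
            trials, params = simulate_participant(spec, design_df, i, rng=rng,
                                                  dt=dt, max_t=max_t)
            all_trials.append(trials)
            for ctx, p in params.items():
                truth_rows.append({"participant_id": trials["participant_id"].iloc[0],
                                   "group": spec.label, "context": ctx,
                                   **{k: getattr(p, k) for k in PARAM_NAMES}})
    trials = pd.concat(all_trials, ignore_index=True)
    if contaminate > 0:
        n = len(trials)
        k = int(round(contaminate * n))
        idx = master.choice(n, size=k, replace=False)
        trials.loc[idx, "rt_ms"] = master.integers(30, 100, size=k)
        trials.loc[idx, "choice"] = master.choice(["later", "sooner"], size=k)
    truth = pd.DataFrame(truth_rows)
    return trials, truth


def simulate_hyperbolic_agent(k_gain: float, k_loss: float,
                              choice_temperature: float,
                              design_df: pd.DataFrame | None = None,
                              rng=None,
                              participant_id: str = "agent_000",
                              group: str = "control",
                              rt_lognorm: tuple[float, float] = (7.3, 0.4)):
    """Choices from a hyperbolic value maximizer with a logistic link.

    Each option's subjective value is its signed amount discounted by
    ``V = A / (1 + k D)`` over its own delivery delay (baseline for the
    sooner option, baseline + delay for the later one); the agent picks
    the later option with probability
    ``sigmoid((V_later - V_sooner) / choice_temperature)``.  Response
    times are generative nuisance, drawn log-normal in milliseconds
    (the discounting analysis ignores them).
    """
    if k_gain <= 0 or k_loss <= 0 or choice_temperature <= 0:
        raise ValueError("k values and choice temperature must be positive")
    if design_df is None:
        design_df = standardize_covariates()
    rng = np.random.default_rng(rng)
    ks = {"gain": k_gain, "loss": k_loss}
    rows = []
    for cid, row in design_df.iterrows():
        k = ks[row["context"]]
        d_soon = row["baseline_days"]
        d_late = row["baseline_days"] + row["delay_days"]
        v_soon = row["sooner_amount"] / (1.0 + k * d_soon)
        v_late = row["later_amount"] / (1.0 + k * d_late)
        p_later = expit((v_late - v_soon) / choice_temperature)
        choice = "later" if rng.random() < p_later else "sooner"
        rt = int(round(np.exp(rng.normal(*rt_lognorm))))
        rt = min(max(rt, 100), 10000)
        rows.append((participant_id, group, cid, row["context"], choice, rt))
    return pd.DataFrame(rows, columns=["participant_id", "group", "condition_id",
                                       "context", "choice", "rt_ms"])
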