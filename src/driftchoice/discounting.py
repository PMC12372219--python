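"""Hyperbolic delay-discounting estimation and group comparison.

Each option's subjective value is V = A / (1 + k D) (amount A delayed by
D days, discount rate k per day).  Both options of a trial are
discounted over their own delivery delay — sooner at the baseline, later
at baseline + delay — so the 100-day-baseline cells discount both
options.  Because a deterministic value comparison has zero gradient in
k, the nonlinear least-squares fit targets a logistic choice rule:

    P(later) = sigmoid((V_later - V_sooner) / tau)

with the temperature tau profiled per participant, minimizing the sum of
squared residuals between the binary choice (later=1) and P(later).

k is log-transformed for group tests (lnk).  The fitted lnk is reported
natively (ln of the per-day rate, typically negative) and as an
affine-shifted variant ``lnk_shifted = lnk + LNK_SHIFT`` on the positive
scale some reports use; every monotone affine choice yields identical
group test statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .task_design import standardize_covariates

__all__ = ["subjective_value", "DiscountFit", "fit_k", "HyperbolicDiscounter",
           "compare_groups_lnk", "LNK_SHIFT"]

LNK_SHIFT = 9.0  # documentation-scale offset; group tests are invariant to it


def subjective_value(A: float, k: float, D: float) -> float:
    """Hyperbolically discounted value V = A / (1 + k D).

    A may be signed (negative for losses); k and D must be non-negative.
    """
    if k < 0 or D < 0:
        raise ValueError("k and D must be non-negative")
    return A / (1.0 + k * D)


@dataclass
class DiscountFit:
    participant_id: str
    context: str
    k: float
    lnk: float
    lnk_shifted: float
    temperature: float
    sse: float
    converged: bool
    boundary_flag: bool
    n_trials_used: int

    def to_dict(self):
        return asdict(self)


def _value_diff(df: pd.DataFrame, k: float) -> np.ndarray:
    d_soon = df["baseline_days"].to_numpy(float)
    d_late = d_soon + df["delay_days"].to_numpy(float)
    v_soon = df["sooner_amount"].to_numpy(float) / (1.0 + k * d_soon)
    v_late = df["later_amount"].to_numpy(float) / (1.0 + k * d_late)
    return v_late - v_soon


def _sse(df, y, k, tau):
    p = expit(_value_diff(df, k) / tau)
    r = y - p
    return float(r @ r)


def fit_k(trials: pd.DataFrame, design_df: pd.DataFrame | None = None,
          k_min: float = 1e-5, k_max: float = 10.0, n_grid: int = 50) -> DiscountFit:
    """Fit the discount rate for one participant-context block of trials.

    ``trials`` carries retained records for a single participant and
    context; amounts and delays are joined from the design via
    condition_id.  Multi-start optimization over a log-spaced k grid
    (temperature profiled at each start) followed by joint refinement;
    all-identical choice patterns pin k to the bound the pattern implies
    and set the boundary flag.
    """
    if len(trials) == 0:
        raise ValueError("no trials to fit")
    pid = str(trials["participant_id"].iloc[0])
    ctx = str(trials["context"].iloc[0])
    if trials["context"].nunique() != 1 or trials["participant_id"].nunique() != 1:
        raise ValueError("fit_k expects trials from one participant and context")
    if design_df is None:
        design_df = standardize_covariates()
    df = design_df.loc[trials["condition_id"]]
    y = (trials["choice"] == "later").to_numpy(float)
    n = len(y)

    def _boundary_fit(kb):
        # the pinned k predicts the observed all-one-way pattern exactly
        # in the zero-temperature limit, so the residual objective is 0
        lnk = np.log(kb)
        return DiscountFit(pid, ctx, kb, lnk, lnk + LNK_SHIFT, np.nan,
                           0.0, True, True, n)

    if y.min() == y.max():
        # no discounting signal; pin to the bound that predicts this pattern
        prefers_later_at = {kb: np.mean(_value_diff(df, kb) > 0) for kb in (k_min, k_max)}
        if y[0] == 1.0:
            kb = max(prefers_later_at, key=prefers_later_at.get)
        else:
            kb = min(prefers_later_at, key=prefers_later_at.get)
        return _boundary_fit(kb)

    grid = np.geomspace(k_min, k_max, n_grid)
    scale = float(np.abs(_value_diff(df, np.median(grid))).mean()) or 1.0

    def profiled(k):
        res = optimize.minimize_scalar(
            lambda lt: _sse(df, y, k, np.exp(lt)),
            bounds=(np.log(scale * 1e-3), np.log(scale * 1e3)), method="bounded")
        return res.fun, np.exp(res.x)

    grid_obj = []
    for k in grid:
        f, tau = profiled(k)
        grid_obj.append((f, k, tau))
    grid_obj.sort()
    best = None
    for f0, k0, tau0 in grid_obj[:3]:
        res = optimize.minimize(
            lambda p: _sse(df, y, np.exp(p[0]), np.exp(p[1])),
            x0=[np.log(k0), np.log(tau0)], method="L-BFGS-B",
            bounds=[(np.log(k_min), np.log(k_max)), (None, None)])
        cand = (res.fun, float(np.exp(res.x[0])), float(np.exp(res.x[1])), res.success)
        if best is None or cand[0] < best[0]:
            best = cand
    sse_val, k_hat, tau_hat, ok = best
    at_bound = k_hat <= k_min * 1.01 or k_hat >= k_max * 0.99
    lnk = float(np.log(k_hat))
    return DiscountFit(pid, ctx, k_hat, lnk, lnk + LNK_SHIFT, tau_hat,
                       float(sse_val), bool(ok), bool(at_bound), n)


class HyperbolicDiscounter:
    """Per-participant, per-context hyperbolic discount-rate estimator.

    scikit-learn style: configure in the constructor, ``fit`` on a
    retained trial table, read results from ``fits_`` (a DataFrame with
    one row per participant-context).
    """

    def __init__(self, k_min: float = 1e-5, k_max: float = 10.0, n_grid: int = 50):
        self.k_min = k_min
        self.k_max = k_max
        self.n_grid = n_grid

    # minimal get/set_params so the estimator composes with sklearn tooling
    def get_params(self, deep: bool = True) -> dict:
        return {"k_min": self.k_min, "k_max": self.k_max, "n_grid": self.n_grid}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, trials: pd.DataFrame, design_df: pd.DataFrame | None = None):
        if design_df is None:
            design_df = standardize_covariates()
        rows = []
        for (pid, ctx), sub in trials.groupby(["participant_id", "context"], sort=True):
            f = fit_k(sub, design_df, self.k_min, self.k_max, self.n_grid)
            row = f.to_dict()
            row["group"] = sub["group"].iloc[0]
            rows.append(row)
        self.fits_ = pd.DataFrame(rows)
        return self


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with pooled SD."""
    nx, ny = len(x), len(y)
    sp = np.sqrt(((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1))
                 / (nx + ny - 2))
    if sp == 0:
        return 0.0
    return float((np.mean(x) - np.mean(y)) / sp)


def compare_groups_lnk(fits: pd.DataFrame, context: str,
                       welch: bool = False) -> dict:
    """Two-sample t-test on lnk between groups within one context.

    Boundary/non-converged fits are excluded (and counted).  Default is
    the pooled-variance t (matching conventional df reporting); set
    ``welch=True`` for the unequal-variance form.
    """
    sub = fits[(fits["context"] == context) & fits["converged"]
               & ~fits["boundary_flag"]]
    groups = sorted(sub["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    x = sub.loc[sub["group"] == groups[0], "lnk"].to_numpy()
    y = sub.loc[sub["group"] == groups[1], "lnk"].to_numpy()
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 converged fits per group")
    t, p = stats.ttest_ind(x, y, equal_var=not welch)
    return {
        "context": context,
        "groups": groups,
        "n": [int(len(x)), int(len(y))],
        "n_excluded": int(len(fits[fits["context"] == context]) - len(sub)),
        "mean": [float(np.mean(x)), float(np.mean(y))],
        "sd": [float(np.std(x, ddof=1)), float(np.std(y, ddof=1))],
        "t": float(t),
        "df": float(len(x) + len(y) - 2) if not welch else float(
            stats.ttest_ind(x, y, equal_var=False).df),
        "p": float(p),
        "cohen_d": cohens_d(x, y),
        "welch": welch,
    }
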