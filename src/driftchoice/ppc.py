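"""Posterior predictive checks: simulate replicate datasets from
posterior draws and compare choice/RT statistics to the observed data
per group x context cell.

For each thinned posterior draw the full design is re-simulated with the
drawn participant-level parameters; the report pairs every observed
statistic (later-choice proportion and RT quantiles per boundary) with
its predictive interval and a two-sided predictive p-value (fraction of
replicates at least as extreme, min-tail doubled and capped at 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _wfpt
from .task_design import covariate_matrix
from .inference import HierarchicalDDM

RT_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)


def posterior_predictive(fit: HierarchicalDDM, n_rep: int = 100, seed: int = 0,
                         dt: float = 1e-3, max_t: float = 10.0,
                         group_of: dict[str, str] | None = None) -> list[pd.DataFrame]:
    """Simulate ``n_rep`` replicate datasets from the fitted posterior.

    Draws are thinned evenly across chains and iterations.  Returns a
    list of trial tables in the standard format.  ``group_of`` maps
    participant ids to group labels (defaults to everything "all").
    """
    if not hasattr(fit, "trace_"):
        raise ValueError("fit the model before posterior prediction")
    U = fit._U_draws  # (chain, keep, C, P, K)
    nchain, nkeep = U.shape[0], U.shape[1]
    total = nchain * nkeep
    if n_rep > total:
        raise ValueError(f"n_rep={n_rep} exceeds available draws ({total})")
    flat = U.reshape(total, *U.shape[2:])
    sel = np.linspace(0, total - 1, n_rep).astype(int)
    rng = np.random.default_rng(seed)
    design_df = fit.design_df_
    reps = []
    for j, idx in enumerate(sel):
        Ud = flat[idx]
        rows = []
        for ci, ctx in enumerate(fit.contexts_):
            sub = design_df[design_df["context"] == ctx]
            X = covariate_matrix(design_df, sub.index, fit.spec_.drift_terms)
            for pi, pid in enumerate(fit.participants_):
                u = Ud[ci, pi]
                a, z, t_nd = np.exp(u[0]), 1 / (1 + np.exp(-u[1])), np.exp(u[2])
                drifts = X @ u[3:]
                budget = max_t - t_nd
                if budget <= 0:
                    continue
                ch, rt = _wfpt.simulate_kernel(
                    a, z, t_nd, np.ascontiguousarray(drifts), dt, budget,
                    int(rng.integers(0, 2**31 - 1)))
                g = (group_of or {}).get(pid, "all")
                for cid, c, r in zip(sub.index, ch, rt):
                    if c == -1:
                        continue  # timeouts are dropped, as in preprocessing
                    rows.append((pid, g, cid, ctx,
                                 "later" if c == 1 else "sooner",
                                 int(round(r * 1000))))
        reps.append(pd.DataFrame(rows, columns=["participant_id", "group",
                                                "condition_id", "context",
                                                "choice", "rt_ms"]))
    return reps


def _cell_stats(df: pd.DataFrame) -> dict[str, float]:
    out = {"p_later": float((df["choice"] == "later").mean())}
    for ch in ("later", "sooner"):
        rts = df.loc[df["choice"] == ch, "rt_ms"]
        for q in RT_QUANTILES:
            key = f"rt_q{int(q*100)}_{ch}"
            out[key] = float(rts.quantile(q)) if len(rts) else np.nan
    return out


def _pvalue(obs: float, sims: np.ndarray) -> float:
    sims = sims[~np.isnan(sims)]
    if np.isnan(obs) or len(sims) == 0:
        return np.nan
    lo = np.mean(sims <= obs)
    hi = np.mean(sims >= obs)
    return float(min(1.0, 2.0 * min(lo, hi)))


@dataclass
class PPCReport:
    cells: dict = field(default_factory=dict)  # (group, context) -> stats
    n_rep: int = 0

    def to_dict(self) -> dict:
        return {"n_rep": self.n_rep,
                "cells": {f"{g}|{c}": v for (g, c), v in self.cells.items()}}

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(s)
        return s

    def to_text(self) -> str:
        lines = []
        for (g, c), stats in self.cells.items():
            lines.append(f"== {g} / {c} ==")
            if stats.get("missing"):
                lines.append("  (no observed trials)")
                continue
            for name, e in stats.items():
                lines.append(f"  {name:<16} obs={e['observed']:<9.3f} "
                             f"pred=[{e['pred2.5']:.3f}, {e['pred97.5']:.3f}] "
                             f"p={e['p_value']:.3f}"
                             + ("  *" if e["extreme"] else ""))
        return "\n".join(lines)

    def n_extreme(self, alpha: float = 0.05) -> int:
        n = 0
        for stats in self.cells.values():
            if stats.get("missing"):
                continue
            n += sum(1 for e in stats.values()
                     if isinstance(e, dict) and e.get("extreme"))
        return n


def ppc_summary(observed: pd.DataFrame, simulated: list[pd.DataFrame],
                alpha: float = 0.05) -> PPCReport:
    """Pair observed statistics with predictive intervals per cell.

    A statistic is flagged ``extreme`` when its two-sided predictive
    p-value falls below ``alpha``.  Cells with no observed trials are
    marked missing.
    """
    if not simulated:
        raise ValueError("need at least one simulated dataset")
    groups = sorted(observed["group"].unique())
    contexts = sorted(observed["context"].unique())
    report = PPCReport(n_rep=len(simulated))
    for g in groups:
        for c in contexts:
            obs_cell = observed[(observed["group"] == g) & (observed["context"] == c)]
            if obs_cell.empty:
                report.cells[(g, c)] = {"missing": True}
                continue
            obs_stats = _cell_stats(obs_cell)
            sim_stats = {k: [] for k in obs_stats}
            for rep in simulated:
                cell = rep[(rep["group"].isin([g, "all"])) & (rep["context"] == c)]
                s = _cell_stats(cell) if len(cell) else {k: np.nan for k in obs_stats}
                for k in obs_stats:
                    sim_stats[k].append(s.get(k, np.nan))
            entry = {}
            for k, obs_val in obs_stats.items():
                sims = np.asarray(sim_stats[k], float)
                ok = sims[~np.isnan(sims)]
                p = _pvalue(obs_val, sims)
                entry[k] = {
                    "observed": obs_val,
                    "pred2.5": float(np.quantile(ok, 0.025)) if len(ok) else np.nan,
                    "pred97.5": float(np.quantile(ok, 0.975)) if len(ok) else np.nan,
                    "p_value": p,
                    "extreme": bool(p < alpha) if not np.isnan(p) else False,
                }
            report.cells[(g, c)] = entry
    return report
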