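"""Group-contrast statistics on fitted diffusion parameters.

The analysis layer the study's reporting implies: per-parameter 2
(group, between-subjects) x 2 (context, within-subjects) mixed-design
ANOVA with partial eta-squared, plus simple-effect two-sample t
contrasts with pooled-SD Cohen's d, Bonferroni-corrected within the
recorded family.  Inputs are participant-level point estimates
(posterior means) of the diffusion parameters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

import pingouin as pg

from .discounting import cohens_d

__all__ = ["mixed_anova", "simple_effects", "stats_report", "format_report"]


def mixed_anova(table: pd.DataFrame, value: str = "value") -> dict:
    """2x2 mixed ANOVA: group between subjects, context within.

    ``table`` has columns participant_id, group, context and the value
    column.  Participants missing either context are dropped (counted in
    the result).  Returns per-effect F, df, p and partial eta-squared.
    """
    counts = table.groupby("participant_id")["context"].nunique()
    complete = counts[counts == 2].index
    n_dropped = int(len(counts) - len(complete))
    sub = table[table["participant_id"].isin(complete)]
    if sub["group"].nunique() != 2:
        raise ValueError("mixed ANOVA requires exactly 2 group levels, "
                         f"found {sorted(sub['group'].unique())}")
    if sub.groupby("group")["participant_id"].nunique().min() < 2:
        raise ValueError("need at least 2 complete participants per group")
    if np.allclose(sub[value].var(), 0.0):
        zero = {"F": 0.0, "df1": 1, "df2": len(complete) - 2, "p": 1.0, "np2": 0.0}
        return {"group": dict(zero), "context": dict(zero),
                "interaction": dict(zero), "n_dropped": n_dropped,
                "n_per_group": sub.groupby("group")["participant_id"].nunique().to_dict(),
                "degenerate": True}
    aov = pg.mixed_anova(data=sub, dv=value, within="context",
                         subject="participant_id", between="group")
    out = {"n_dropped": n_dropped, "degenerate": False,
           "n_per_group": sub.groupby("group")["participant_id"].nunique().to_dict()}
    names = {"group": "group", "context": "context", "Interaction": "interaction"}
    for _, row in aov.iterrows():
        key = names.get(str(row["Source"]), str(row["Source"]))
        out[key] = {"F": float(row["F"]), "df1": int(row["DF1"]),
                    "df2": int(row["DF2"]), "p": float(row["p_unc"]),
                    "np2": float(row["np2"])}
    return out


def simple_effects(table: pd.DataFrame, slicer: str = "context",
                   value: str = "value") -> list[dict]:
    """Two-sample t contrasts within each level of ``slicer``.

    slicer="context": group contrast within each context (the study's
    headline simple effects).  slicer="group": context contrast within
    each group.  Bonferroni family = number of contrasts emitted.
    """
    if slicer == "context":
        between = "group"
    elif slicer == "group":
        between = "context"
    else:
        raise ValueError("slicer must be 'context' or 'group'")
    contrasts = []
    for level, sub in table.groupby(slicer, sort=True):
        sides = sorted(sub[between].unique())
        if len(sides) != 2:
            contrasts.append({"slice": str(level), "skipped": True,
                              "note": f"need 2 {between} levels, found {sides}"})
            continue
        x = sub.loc[sub[between] == sides[0], value].to_numpy()
        y = sub.loc[sub[between] == sides[1], value].to_numpy()
        t, p = stats.ttest_ind(x, y, equal_var=True)
        contrasts.append({
            "slice": str(level), "contrast": f"{sides[0]} - {sides[1]}",
            "n": [int(len(x)), int(len(y))],
            "mean": [float(np.mean(x)), float(np.mean(y))],
            "t": float(t), "df": int(len(x) + len(y) - 2), "p": float(p),
            "cohen_d": cohens_d(x, y), "skipped": False,
        })
    family = sum(1 for c in contrasts if not c.get("skipped"))
    for c in contrasts:
        if not c.get("skipped"):
            c["p_bonferroni"] = min(1.0, c["p"] * family)
            c["family_size"] = family
    return contrasts


def stats_report(param_table: pd.DataFrame,
                 parameters: tuple[str, ...] = ("a", "z", "t_nd", "beta0",
                                                "beta_reward", "beta_time")) -> dict:
    """Full report: mixed ANOVA + simple effects for each parameter.

    ``param_table`` holds one row per participant-context with one
    column per diffusion parameter.  The Bonferroni family for the ANOVA
    p-values is the number of parameters tested.
    """
    report = {"parameters": {}, "family_size": len(parameters)}
    for par in parameters:
        t = param_table[["participant_id", "group", "context", par]].rename(
            columns={par: "value"})
        entry = {"anova": mixed_anova(t),
                 "by_context": simple_effects(t, "context"),
                 "by_group": simple_effects(t, "group")}
        for eff in ("group", "context", "interaction"):
            raw = entry["anova"][eff]["p"]
            entry["anova"][eff]["p_bonferroni"] = min(1.0, raw * len(parameters))
        report["parameters"][par] = entry
    return report


def report_frame(report: dict) -> pd.DataFrame:
    """Flatten a stats report to one row per effect (CSV export)."""
    rows = []
    for par, entry in report["parameters"].items():
        for eff in ("group", "context", "interaction"):
            e = entry["anova"][eff]
            rows.append({"parameter": par, "effect": eff, "type": "F",
                         "stat": e["F"], "df1": e["df1"], "df2": e["df2"],
                         "p": e["p"], "p_bonferroni": e["p_bonferroni"],
                         "effect_size": e["np2"], "effect_size_kind": "np2"})
        for c in entry["by_context"]:
            if not c.get("skipped"):
                rows.append({"parameter": par, "effect": f"group @ {c['slice']}",
                             "type": "t", "stat": c["t"], "df1": c["df"],
                             "df2": np.nan, "p": c["p"],
                             "p_bonferroni": c["p_bonferroni"],
                             "effect_size": c["cohen_d"], "effect_size_kind": "d"})
    return pd.DataFrame(rows)


def format_report(report: dict) -> str:
    """Text table echoing the conventional F(df1, df2)/t(df) style."""
    lines = []
    for par, entry in report["parameters"].items():
        lines.append(f"== {par} ==")
        for eff in ("group", "context", "interaction"):
            e = entry["anova"][eff]
            lines.append(f"  {eff:<12} F({e['df1']}, {e['df2']}) = {e['F']:.3f}, "
                         f"p = {e['p']:.3g}, partial eta2 = {e['np2']:.3f}")
        for c in entry["by_context"]:
            if not c.get("skipped"):
                lines.append(f"  {c['slice']:<6} {c['contrast']}: "
                             f"t({c['df']}) = {c['t']:.3f}, p = {c['p']:.3g}, "
                             f"d = {c['cohen_d']:.3f}")
    return "\n".join(lines)
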