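"""Factorial intertemporal-choice task design.

The task crosses 2 outcome contexts (gain, loss) x 2 time baselines (now,
100 days) x 2 delay lengths (7, 30 days) x 3 magnitudes (100, 400, 1000
tokens) x 6 premium rates (5%..30%), giving 144 distinct decision cells.
In every cell the sooner option delivers the base magnitude at the
baseline and the later option delivers the base magnitude plus the
premium ``magnitude * rate`` after the additional delay.  In the loss
context both amounts are negative: the sooner option is a smaller loss
paid earlier, the later option a larger loss paid later.

Drift-rate covariates (money difference, delay difference, baseline
indicator) are z-scored across the 144 design cells with the population
standard deviation so regression coefficients are comparable across
covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

CONTEXTS = ("gain", "loss")
BASELINES_DAYS = (0, 100)
DELAYS_DAYS = (7, 30)
MAGNITUDES = (100, 400, 1000)
RATES = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)

#: covariates carried by every design cell, in canonical order
COVARIATES = ("money_diff", "delay_diff", "baseline")


@dataclass(frozen=True)
class TaskCondition:
    """One cell of the factorial design.

    Amounts are signed tokens (negative in the loss context); the money
    difference is the unsigned magnitude gap ``|later| - |sooner|``.
    """

    context: str
    baseline_days: int
    delay_days: int
    magnitude: int
    rate: float

    @property
    def sooner_amount(self) -> float:
        sign = 1.0 if self.context == "gain" else -1.0
        return sign * self.magnitude

    @property
    def later_amount(self) -> float:
        sign = 1.0 if self.context == "gain" else -1.0
        return sign * self.magnitude * (1.0 + self.rate)

    @property
    def money_diff(self) -> float:
        return self.magnitude * self.rate

    @property
    def delay_diff(self) -> int:
        return self.delay_days

    @property
    def condition_id(self) -> str:
        return (
            f"{self.context}|{self.baseline_days}|{self.delay_days}"
            f"|{self.magnitude}|{self.rate:.2f}"
        )


def build_design() -> list[TaskCondition]:
    """Enumerate all 144 task conditions in a deterministic order.

    Ordering is lexicographic in (context, baseline, delay, magnitude,
    rate), which also sorts ``condition_id``; repeated calls are
    bit-stable.
    """
    design = [
        TaskCondition(ctx, t0, dt, m, r)
        for ctx in CONTEXTS
        for t0 in BASELINES_DAYS
        for dt in DELAYS_DAYS
        for m in MAGNITUDES
        for r in RATES
    ]
    ids = [c.condition_id for c in design]
    if len(set(ids)) != len(ids):  # pragma: no cover - structural guarantee
        raise RuntimeError("duplicate condition ids in design")
    return design


def design_frame(design: Iterable[TaskCondition] | None = None) -> pd.DataFrame:
    """Tabulate the design, one row per condition, indexed by condition_id."""
    design = list(design) if design is not None else build_design()
    rows = [
        {
            "condition_id": c.condition_id,
            "context": c.context,
            "baseline_days": c.baseline_days,
            "delay_days": c.delay_days,
            "magnitude": c.magnitude,
            "rate": c.rate,
            "sooner_amount": c.sooner_amount,
            "later_amount": c.later_amount,
            "money_diff": c.money_diff,
            "delay_diff": c.delay_diff,
        }
        for c in design
    ]
    cols = ["condition_id", "context", "baseline_days", "delay_days",
            "magnitude", "rate", "sooner_amount", "later_amount",
            "money_diff", "delay_diff"]
    return pd.DataFrame(rows, columns=cols).set_index("condition_id")


def standardize_covariates(design: Iterable[TaskCondition] | None = None) -> pd.DataFrame:
    """z-score the drift covariates across design cells.

    The baseline is coded {0, 1} (now vs 100 days) before scaling.  Uses
    the population SD (ddof=0); each standardized column has mean 0 and
    SD 1 across cells.  Raises ``ValueError`` if a covariate is constant
    across the supplied cells.

    Returns the design table with ``money_diff_z``, ``delay_diff_z`` and
    ``baseline_z`` columns appended.
    """
    df = design_frame(design)
    if df.empty:
        raise ValueError("empty design")
    raw = pd.DataFrame(
        {
            "money_diff": df["money_diff"].astype(float),
            "delay_diff": df["delay_diff"].astype(float),
            "baseline": (df["baseline_days"] > 0).astype(float),
        },
        index=df.index,
    )
    out = df.copy()
    for name in COVARIATES:
        x = raw[name].to_numpy()
        sd = float(np.std(x))
        if sd == 0.0:
            raise ValueError(f"covariate {name!r} is constant across design cells")
        out[f"{name}_z"] = (x - x.mean()) / sd
    return out


def covariate_matrix(design_df: pd.DataFrame, condition_ids: Iterable[str],
                     terms: tuple[str, ...]) -> np.ndarray:
    """Drift-regression design matrix for a sequence of trials.

    ``terms`` is a subset of {"money", "time", "baseline", "time_x_base"};
    column 0 is always the intercept.  The interaction column is the
    product of the standardized delay and baseline covariates.
    """
    sub = design_df.loc[list(condition_ids)]
    cols = [np.ones(len(sub))]
    for t in terms:
        if t == "money":
            cols.append(sub["money_diff_z"].to_numpy())
        elif t == "time":
            cols.append(sub["delay_diff_z"].to_numpy())
        elif t == "baseline":
            cols.append(sub["baseline_z"].to_numpy())
        elif t == "time_x_base":
            cols.append(sub["delay_diff_z"].to_numpy() * sub["baseline_z"].to_numpy())
        else:
            raise ValueError(f"unknown drift term {t!r}")
    return np.column_stack(cols)


def export_design(path) -> pd.DataFrame:
    """Write the standardized design table to CSV and return it."""
    df = standardize_covariates().reset_index()
    df.to_csv(path, index=False)
    return df
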