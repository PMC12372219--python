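"""Trial-table I/O, validation, and exclusion rules.

The file contract is a comma-delimited UTF-8 CSV with header
``participant_id,group,condition_id,context,choice,rt_ms`` where group is
control/sud, context gain/loss, choice later/sooner/timeout, and rt_ms
integer milliseconds (-1 marks a timeout row).

Exclusions follow the study's two rules with strict inequalities:
response times *below* 100 ms are removed as fast guesses, and trials
whose decision time *exceeded* the 10 s response window (or that carry
the timeout marker) are removed; 100 ms and 10000 ms exactly are kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

REQUIRED_COLUMNS = ["participant_id", "group", "condition_id",
                    "context", "choice", "rt_ms"]
_CHOICES = {"later", "sooner", "timeout"}


def _round2(x: float) -> float:
    """Round half-up to two decimals (report convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ExclusionReport:
    n_total: int
    n_retained: int
    n_fast_excluded: int
    n_timeout_excluded: int
    min_rt_ms: int
    max_rt_ms: int
    by_group: dict = field(default_factory=dict)
    by_context: dict = field(default_factory=dict)

    @property
    def pct_excluded(self) -> float:
        if self.n_total == 0:
            return 0.0
        return _round2(100.0 * (self.n_fast_excluded + self.n_timeout_excluded)
                       / self.n_total)

    @property
    def pct_fast_excluded(self) -> float:
        if self.n_total == 0:
            return 0.0
        return _round2(100.0 * self.n_fast_excluded / self.n_total)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pct_excluded"] = self.pct_excluded
        d["pct_fast_excluded"] = self.pct_fast_excluded
        return d

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(s)
        return s


def load_trials(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a trial CSV; returns ``(records, rejects)``.

    Missing required columns raise immediately; rows with unparseable
    rt_ms or unknown choice labels are collected into the rejects table
    (with their 1-based data row number and a reason) rather than
    silently dropped.  Duplicated (participant_id, condition_id) pairs
    are a hard error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    df = df[REQUIRED_COLUMNS].copy()
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    bad_rt = rt.isna()
    bad_choice = ~df["choice"].isin(_CHOICES)
    bad = bad_rt | bad_choice
    rejects = df[bad].copy()
    rejects["row"] = rejects.index + 2  # 1-based, after the header line
    rejects["reason"] = ["unparseable rt_ms" if b else "unknown choice"
                         for b in bad_rt[bad]]
    records = df[~bad].copy()
    records["rt_ms"] = rt[~bad].astype(int)
    dup = records.duplicated(subset=["participant_id", "condition_id"], keep=False)
    if dup.any():
        pairs = records.loc[dup, ["participant_id", "condition_id"]]
        listing = ", ".join(f"({p}, {c})" for p, c in
                            pairs.drop_duplicates().itertuples(index=False))
        raise ValueError(f"duplicated (participant_id, condition_id): {listing}")
    return records.reset_index(drop=True), rejects.reset_index(drop=True)


def save_trials(df: pd.DataFrame, path) -> None:
    df[REQUIRED_COLUMNS].to_csv(path, index=False)


def apply_exclusions(records: pd.DataFrame, min_rt_ms: int = 100,
                     max_rt_ms: int = 10000) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the fast-guess and timeout rules; returns (retained, report).

    Retains non-timeout trials with ``min_rt_ms <= rt_ms <= max_rt_ms``
    (both boundaries inclusive, matching the strict wording of the
    exclusion rules).  Counts always reconcile:
    retained + fast + timeout = total.
    """
    n_total = len(records)
    if n_total == 0:
        return records.copy(), ExclusionReport(0, 0, 0, 0, min_rt_ms, max_rt_ms)
    is_timeout = (records["choice"] == "timeout") | (records["rt_ms"] > max_rt_ms)
    is_fast = ~is_timeout & (records["rt_ms"] < min_rt_ms)
    keep = ~is_timeout & ~is_fast
    report = ExclusionReport(
        n_total=n_total,
        n_retained=int(keep.sum()),
        n_fast_excluded=int(is_fast.sum()),
        n_timeout_excluded=int(is_timeout.sum()),
        min_rt_ms=min_rt_ms,
        max_rt_ms=max_rt_ms,
    )
    for col, dest in (("group", report.by_group), ("context", report.by_context)):
        for level, sub in records.groupby(col):
            t = is_timeout[sub.index].sum()
            f = is_fast[sub.index].sum()
            dest[str(level)] = {"n_total": len(sub), "n_fast_excluded": int(f),
                                "n_timeout_excluded": int(t),
                                "n_retained": int(len(sub) - f - t)}
    return records[keep].reset_index(drop=True), report
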