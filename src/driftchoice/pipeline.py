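"""End-to-end pipeline orchestration with reproducible seeds.

Stages: simulate (or load) -> preprocess -> discounting -> fit ->
compare (DIC) -> ppc -> stats -> report.  Every run directory contains a
frozen copy of the resolved config, per-stage child seeds, and a
manifest with sha256 checksums of all written artifacts.  File writes
are atomic (write to a temp name, then rename).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from . import preprocessing, ppc as ppc_mod
from .discounting import HyperbolicDiscounter, compare_groups_lnk
from .inference import HierarchicalDDM, compare_models, dic, MODEL_TERMS
from .group_stats import stats_report, report_frame, format_report
from .task_design import standardize_covariates

log = logging.getLogger("driftchoice")


@dataclass
class RunConfig:
    """Resolved configuration for one pipeline run."""

    output_dir: str = "run"
    input_trials: str = "simulate"  # path to a trial CSV, or "simulate"
    seed: int = 0
    n_control: int = 8
    n_sud: int = 8
    contaminate: float = 0.01
    models: list = field(default_factory=lambda: ["M1", "M2", "M3"])
    n_draws: int = 2000
    n_burn: int = 1000
    n_chains: int = 4
    n_sweeps: int = 3
    min_rt_ms: int = 100
    max_rt_ms: int = 10000
    k_min: float = 1e-5
    k_max: float = 10.0
    n_ppc_rep: int = 100
    verbosity: str = "INFO"

    def validate(self) -> None:
        unknown = [m for m in self.models if m not in MODEL_TERMS]
        if unknown:
            raise ValueError(f"unknown model id(s): {unknown}")
        if self.n_burn >= self.n_draws:
            raise ValueError("n_burn must be smaller than n_draws")
        if self.input_trials != "simulate" and not Path(self.input_trials).exists():
            raise ValueError(f"input trials file not found: {self.input_trials}")

    def to_yaml(self, path=None) -> str:
        s = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path:
            atomic_write_text(Path(path), s)
        return s

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config key(s): {sorted(bad)}")
        return cls(**data)


def atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    os.replace(tmp, path)


def _atomic_to_csv(df: pd.DataFrame, path: Path, **kw) -> None:
    tmp = path.with_name(path.name + ".tmp")
    df.to_csv(tmp, **kw)
    os.replace(tmp, path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def child_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Partial failure leaves completed-stage outputs in place and records
    the failing stage in the manifest before re-raising.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), 20),
                        format="%(asctime)s %(name)s %(message)s")
    manifest: dict = {"stages": {}, "seeds": {}, "started": time.strftime("%F %T")}
    config.to_yaml(out / "config.yaml")

    def record(stage, *paths):
        manifest["stages"][stage] = {
            "artifacts": {p.name: _sha256(p) for p in paths}, "status": "ok"}
        atomic_write_text(out / "manifest.json", json.dumps(manifest, indent=2))

    stage = "design"
    try:
        design_df = standardize_covariates()
        _atomic_to_csv(design_df.reset_index(), out / "design.csv", index=False)
        record(stage, out / "design.csv")

        stage = "simulate"
        seed = child_seed(config.seed, stage)
        manifest["seeds"][stage] = seed
        if config.input_trials == "simulate":
            log.info("simulating study: %d control, %d sud", config.n_control,
                     config.n_sud)
            trials, truth = sim.simulate_study(
                sim.control_like_spec(config.n_control),
                sim.sud_like_spec(config.n_sud),
                rng_seed=seed, contaminate=config.contaminate)
            _atomic_to_csv(truth, out / "ground_truth.csv", index=False)
            _atomic_to_csv(trials, out / "trials.csv", index=False)
            record(stage, out / "trials.csv", out / "ground_truth.csv")
        else:
            trials, rejects = preprocessing.load_trials(config.input_trials)
            if len(rejects):
                _atomic_to_csv(rejects, out / "rejects.csv", index=False)
            _atomic_to_csv(trials, out / "trials.csv", index=False)
            record(stage, out / "trials.csv")

        stage = "preprocess"
        retained, report = preprocessing.apply_exclusions(
            trials, config.min_rt_ms, config.max_rt_ms)
        _atomic_to_csv(retained, out / "retained.csv", index=False)
        atomic_write_text(out / "exclusions.json", report.to_json())
        log.info("retained %d/%d trials (%.2f%% excluded)", report.n_retained,
                 report.n_total, report.pct_excluded)
        record(stage, out / "retained.csv", out / "exclusions.json")

        stage = "discounting"
        hd = HyperbolicDiscounter(k_min=config.k_min, k_max=config.k_max)
        hd.fit(retained, design_df)
        _atomic_to_csv(hd.fits_, out / "discount_fits.csv", index=False)
        lnk_tests = {}
        for ctx in sorted(retained["context"].unique()):
            try:
                lnk_tests[ctx] = compare_groups_lnk(hd.fits_, ctx)
            except ValueError as e:
                lnk_tests[ctx] = {"error": str(e)}
        atomic_write_text(out / "lnk_tests.json", json.dumps(lnk_tests, indent=2))
        record(stage, out / "discount_fits.csv", out / "lnk_tests.json")

        stage = "fit"
        seed = child_seed(config.seed, stage)
        manifest["seeds"][stage] = seed
        fits = {}
        for group, sub in retained.groupby("group"):
            log.info("fitting M3-family models for group %s", group)
            comp = compare_models(sub, models=config.models, design_df=design_df,
                                  n_draws=config.n_draws, n_burn=config.n_burn,
                                  n_chains=config.n_chains,
                                  n_sweeps=config.n_sweeps, seed=seed)
            fits[group] = comp
            _atomic_to_csv(comp, out / f"dic_{group}.csv", index=False)
            best = comp.attrs["fits"][comp["model_id"].iloc[0]]
            best.trace_.save(str(out / f"trace_{group}"))
        record(stage, *[out / f"dic_{g}.csv" for g in fits])

        stage = "ppc"
        seed = child_seed(config.seed, stage)
        manifest["seeds"][stage] = seed
        ppc_texts = {}
        for group, comp in fits.items():
            best = comp.attrs["fits"][comp["model_id"].iloc[0]]
            reps = ppc_mod.posterior_predictive(
                best, n_rep=min(config.n_ppc_rep, best.trace_.n_chains
                                * best.trace_.n_keep), seed=seed)
            obs = retained[retained["group"] == group]
            rep = ppc_mod.ppc_summary(obs, [r.assign(group=group) for r in reps])
            rep.to_json(out / f"ppc_{group}.json")
            ppc_texts[group] = rep.to_text()
        record(stage, *[out / f"ppc_{g}.json" for g in fits])

        stage = "stats"
        tables = []
        for group, comp in fits.items():
            best = comp.attrs["fits"][comp["model_id"].iloc[0]]
            t = best.participant_params_()
            t["group"] = group
            tables.append(t)
        params = pd.concat(tables, ignore_index=True)
        _atomic_to_csv(params, out / "participant_params.csv", index=False)
        common = [p for p in ("a", "z", "t_nd", "beta0", "beta_reward", "beta_time")
                  if p in params.columns and params[p].notna().all()]
        rep = stats_report(params, tuple(common))
        _atomic_to_csv(report_frame(rep), out / "stats_report.csv", index=False)
        atomic_write_text(out / "stats_report.txt", format_report(rep))
        record(stage, out / "participant_params.csv", out / "stats_report.csv")

        manifest["finished"] = time.strftime("%F %T")
        atomic_write_text(out / "manifest.json", json.dumps(manifest, indent=2))
    except Exception as e:
        manifest["stages"][stage] = {"status": "failed", "error": str(e)}
        atomic_write_text(out / "manifest.json", json.dumps(manifest, indent=2))
        raise RuntimeError(f"stage {stage!r} failed: {e}") from e
    return out


def render_report(run_dir) -> str:
    """Render the run's result sections into one human-readable document."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {run_dir}")
    sections = []

    def section(title, path, loader):
        if path.exists():
            try:
                sections.append(f"# {title}\n\n{loader(path)}")
                return
            except Exception as e:  # pragma: no cover - defensive
                sections.append(f"# {title}\n\n[unreadable: {e}]")
                return
        sections.append(f"# {title}\n\n[unavailable]")

    for group in ("control", "sud"):
        section(f"Model comparison (DIC), {group}", run_dir / f"dic_{group}.csv",
                lambda p: pd.read_csv(p).to_string(index=False))
    section("Discount-rate group tests (lnk)", run_dir / "lnk_tests.json",
            lambda p: p.read_text())
    section("Parameter contrasts", run_dir / "stats_report.txt",
            lambda p: p.read_text())
    for group in ("control", "sud"):
        section(f"Posterior predictive checks, {group}",
                run_dir / f"ppc_{group}.json",
                lambda p: json.dumps(json.loads(p.read_text()), indent=2)[:4000])
    doc = "\n\n".join(sections)
    atomic_write_text(run_dir / "report.md", doc)
    return doc
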