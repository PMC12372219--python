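"""Hierarchical Bayesian estimation of the drift-regression diffusion
model, convergence diagnostics, DIC, and nested-model comparison.

Five nested drift regressions are compared:

    M1: v = b0 + b_money * money_diff_z
    M2: v = b0 + b_time  * delay_diff_z
    M3: v = b0 + b_money + b_time
    M4: M3 + b_base * baseline_z
    M5: M4 + b_txb * (delay_diff_z * baseline_z)

Boundary separation, relative start and non-decision time are always
estimated.  Contexts present in the data are estimated independently;
each parameter has a group-level Normal(mu, sigma) law on the
unconstrained scale (log a, logit z, log t_nd, identity betas) with
participant-level draws, weakly-informative hyperpriors, and the Wiener
first-passage density as the trial likelihood.  Sampling is adaptive
Metropolis-within-Gibbs (see ``_sampler``); ``n_draws`` counts total
iterations per chain of which the first ``n_burn`` are discarded,
mirroring the samples/burn-in convention of hierarchical-DDM tooling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _sampler
from .task_design import standardize_covariates, covariate_matrix

__all__ = ["MODEL_TERMS", "ModelSpec", "PosteriorTrace", "HierarchicalDDM",
           "split_rhat", "rhat", "DICResult", "dic", "compare_models"]

MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "M1": ("money",),
    "M2": ("time",),
    "M3": ("money", "time"),
    "M4": ("money", "time", "baseline"),
    "M5": ("money", "time", "baseline", "time_x_base"),
}

_TERM_BETA = {"money": "beta_reward", "time": "beta_time",
              "baseline": "beta_base", "time_x_base": "beta_txb"}

#: convergence gate applied before downstream tables are trusted
RHAT_THRESHOLD = 1.01


@dataclass(frozen=True)
class ModelSpec:
    model_id: str
    drift_terms: tuple[str, ...]

    @classmethod
    def from_id(cls, model_id: str) -> "ModelSpec":
        if model_id not in MODEL_TERMS:
            raise ValueError(f"unknown model id {model_id!r}; "
                             f"choose from {sorted(MODEL_TERMS)}")
        return cls(model_id, MODEL_TERMS[model_id])

    @property
    def param_names(self) -> tuple[str, ...]:
        return ("a", "z", "t_nd", "beta0") + tuple(
            _TERM_BETA[t] for t in self.drift_terms)


@dataclass
class PosteriorTrace:
    """Post-burn-in MCMC draws with (chain, draw) indexing.

    ``draws`` maps fully-qualified parameter names to (n_chains, n_keep)
    arrays.  Participant-level diffusion parameters are stored on their
    natural scales; group-level mu/sigma on the unconstrained sampling
    scale.  ``deviance`` is -2 * log-likelihood per retained iteration.
    """

    draws: dict[str, np.ndarray]
    deviance: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return int(self.deviance.shape[0])

    @property
    def n_keep(self) -> int:
        return int(self.deviance.shape[1])

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, x in self.draws.items():
            flat = x.reshape(-1)
            rows.append({"parameter": name, "mean": float(flat.mean()),
                         "sd": float(flat.std(ddof=1)),
                         "hdi2.5": float(np.quantile(flat, 0.025)),
                         "hdi97.5": float(np.quantile(flat, 0.975)),
                         "rhat": split_rhat(x)})
        return pd.DataFrame(rows).set_index("parameter")

    def max_rhat(self) -> float:
        return float(max(split_rhat(x) for x in self.draws.values()))

    def to_inference_data(self):
        import arviz as az
        return az.from_dict(posterior={k: v for k, v in self.draws.items()},
                            sample_stats={"deviance": self.deviance})

    def save(self, path_prefix: str) -> None:
        """Persist as an .npz array container plus a JSON metadata sidecar."""
        np.savez_compressed(f"{path_prefix}.npz", deviance=self.deviance,
                            **self.draws)
        with open(f"{path_prefix}.json", "w", encoding="utf-8") as fh:
            json.dump(self.meta, fh, indent=2, default=str)

    @classmethod
    def load(cls, path_prefix: str) -> "PosteriorTrace":
        with np.load(f"{path_prefix}.npz") as z:
            draws = {k: z[k] for k in z.files if k != "deviance"}
            deviance = z["deviance"]
        with open(f"{path_prefix}.json", encoding="utf-8") as fh:
            meta = json.load(fh)
        return cls(draws, deviance, meta)


def split_rhat(x: np.ndarray) -> float:
    """Split-chain Gelman-Rubin statistic for one (chain, draw) array.

    Each chain is split in half; R-hat compares between- and
    within-half-chain variance.  Constant series return 1.0.
    """
    x = np.asarray(x, float)
    if x.ndim != 2 or x.shape[0] < 1 or x.shape[1] < 4:
        raise ValueError("need a (chain, draw) array with >= 4 draws")
    n = x.shape[1] // 2
    halves = np.concatenate([x[:, :n], x[:, n:2 * n]], axis=0)
    W = halves.var(axis=1, ddof=1).mean()
    if W == 0.0:
        return 1.0
    B_over_n = halves.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def rhat(trace: PosteriorTrace) -> pd.Series:
    """Per-parameter split-chain R-hat (requires >= 2 chains)."""
    if trace.n_chains < 2:
        raise ValueError("R-hat requires at least 2 chains")
    return pd.Series({k: split_rhat(v) for k, v in trace.draws.items()},
                     name="rhat")


def _prepare(trials: pd.DataFrame, design_df: pd.DataFrame,
             terms: tuple[str, ...]):
    """Pack retained trials into sorted arrays with per-block slices."""
    t = trials[trials["choice"].isin(["later", "sooner"])].copy()
    if t.empty:
        raise ValueError("no decision trials to fit")
    contexts = sorted(t["context"].unique())
    participants = sorted(t["participant_id"].unique())
    cidx = {c: i for i, c in enumerate(contexts)}
    pidx = {p: i for i, p in enumerate(participants)}
    t["_c"] = t["context"].map(cidx)
    t["_p"] = t["participant_id"].map(pidx)
    t = t.sort_values(["_c", "_p"], kind="mergesort").reset_index(drop=True)
    rt = np.ascontiguousarray(t["rt_ms"].to_numpy(float) / 1000.0)
    upper = np.ascontiguousarray((t["choice"] == "later").to_numpy(np.int8))
    X = np.ascontiguousarray(covariate_matrix(design_df, t["condition_id"], terms))
    C, P = len(contexts), len(participants)
    start = np.zeros((C, P), np.int64)
    end = np.zeros((C, P), np.int64)
    pos = 0
    groups = t.groupby(["_c", "_p"]).size()
    for (c, p), sz in groups.items():
        start[c, p] = pos
        end[c, p] = pos + sz
        pos += sz
    return rt, upper, X, start, end, contexts, participants, t


def _hyperpriors(K: int):
    """(m0, tau0) for group means on the unconstrained scale."""
    m0 = np.zeros(K)
    tau0 = np.full(K, 3.0)  # betas: Normal(0, 3^2)
    m0[0], tau0[0] = np.log(2.0), 1.5   # log a
    m0[1], tau0[1] = 0.0, 1.0           # logit z
    m0[2], tau0[2] = np.log(0.4), 1.5   # log t_nd
    return m0, tau0


class HierarchicalDDM:
    """Hierarchical drift-regression DDM estimator (scikit-learn style).

    Parameters
    ----------
    model : str
        One of M1..M5 (drift-term sets, see module docstring).
    n_draws, n_burn, n_chains : int
        Total iterations per chain, burn-in iterations, chain count.
    n_sweeps : int
        Metropolis scans per recorded iteration (internal thinning that
        improves mixing at fixed output size).
    seed : int
        Master seed; per-chain streams are spawned deterministically.

    Fitted attributes: ``trace_`` (PosteriorTrace), ``contexts_``,
    ``participants_``, ``spec_``, ``converged_`` (max R-hat <= 1.01).
    """

    def __init__(self, model: str = "M3", n_draws: int = 2000,
                 n_burn: int = 1000, n_chains: int = 4, n_sweeps: int = 2,
                 n_block: int = 24, seed: int = 0):
        self.model = model
        self.n_draws = n_draws
        self.n_burn = n_burn
        self.n_chains = n_chains
        self.n_sweeps = n_sweeps
        self.n_block = n_block
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"model": self.model, "n_draws": self.n_draws,
                "n_burn": self.n_burn, "n_chains": self.n_chains,
                "n_sweeps": self.n_sweeps, "n_block": self.n_block,
                "seed": self.seed}

    def set_params(self, **params):
        known = self.get_params()
        for k, v in params.items():
            if k not in known:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- model construction -------------------------------------------------
    def build(self, trials: pd.DataFrame, design_df: pd.DataFrame | None = None):
        """Validate data against the model spec and pack arrays."""
        self.spec_ = ModelSpec.from_id(self.model)
        if design_df is None:
            design_df = standardize_covariates()
        needed = {"money": "money_diff_z", "time": "delay_diff_z",
                  "baseline": "baseline_z", "time_x_base": "delay_diff_z"}
        for term in self.spec_.drift_terms:
            if needed[term] not in design_df.columns:
                raise ValueError(f"design table lacks covariate for term {term!r}")
        (self._rt, self._upper, self._X, self._start, self._end,
         self.contexts_, self.participants_, self._sorted) = _prepare(
            trials, design_df, self.spec_.drift_terms)
        self.design_df_ = design_df
        return self

    def manifest(self) -> list[str]:
        """Fully-qualified names of every sampled parameter."""
        names = []
        K = 4 + len(self.spec_.drift_terms)
        unames = ("log_a", "logit_z", "log_t_nd") + self.spec_.param_names[3:]
        for c in self.contexts_:
            for k in range(K):
                names.append(f"mu_{unames[k]}[{c}]")
                names.append(f"sigma_{unames[k]}[{c}]")
        for c in self.contexts_:
            for p in self.participants_:
                for nat in self.spec_.param_names:
                    names.append(f"{nat}[{p},{c}]")
        return names

    def log_likelihood(self, U: np.ndarray) -> float:
        """Total data log-likelihood at unconstrained parameters U (C,P,K)."""
        return float(_sampler.total_loglik(self._rt, self._upper, self._X,
                                           self._start, self._end,
                                           np.ascontiguousarray(U)))

    # -- sampling -----------------------------------------------------------
    def fit(self, trials: pd.DataFrame, design_df: pd.DataFrame | None = None):
        self.build(trials, design_df)
        if self.n_burn >= self.n_draws:
            raise ValueError("n_burn must be smaller than n_draws")
        C, P = len(self.contexts_), len(self.participants_)
        K = 4 + len(self.spec_.drift_terms)
        m0, tau0 = _hyperpriors(K)
        ss = np.random.SeedSequence(self.seed)
        chains = []
        min_rt = float(self._rt.min())
        for chain_seed in ss.spawn(self.n_chains):
            rng = np.random.default_rng(chain_seed)
            # overdispersed but sane initial state; t_nd starts safely
            # below the fastest observed response
            mu0 = m0 + rng.normal(0, 0.2, K)
            mu0[2] = np.log(0.4 * min_rt) + rng.normal(0, 0.1)
            mu0[3:] = rng.normal(0, 0.1, K - 3)
            sig0 = np.abs(rng.normal(0.2, 0.05, (C, K))) + 0.05
            U0 = np.empty((C, P, K))
            for c in range(C):
                U0[c] = mu0 + rng.normal(0, 0.05, (P, K))
            mu_init = np.tile(mu0, (C, 1))
            out = _sampler.run_chain(
                self._rt, self._upper, self._X, self._start, self._end,
                self.n_draws, self.n_burn, self.n_sweeps, self.n_block,
                m0, tau0, U0, mu_init, sig0,
                int(rng.integers(0, 2**31 - 1)))
            chains.append(out)
        self.trace_ = self._collect(chains)
        self.converged_ = self.trace_.max_rhat() <= RHAT_THRESHOLD
        return self

    def _collect(self, chains) -> PosteriorTrace:
        n_keep = self.n_draws - self.n_burn
        nchain = len(chains)
        unames = ("log_a", "logit_z", "log_t_nd") + self.spec_.param_names[3:]
        nat = self.spec_.param_names
        draws: dict[str, np.ndarray] = {}
        dev = np.stack([ch[3] for ch in chains])
        U = np.stack([ch[0] for ch in chains])      # (chain, keep, C, P, K)
        MU = np.stack([ch[1] for ch in chains])     # (chain, keep, C, K)
        SIG = np.stack([ch[2] for ch in chains])
        Unat = np.empty_like(U)
        Unat[..., 0] = np.exp(U[..., 0])
        Unat[..., 1] = 1.0 / (1.0 + np.exp(-U[..., 1]))
        Unat[..., 2] = np.exp(U[..., 2])
        Unat[..., 3:] = U[..., 3:]
        for ci, c in enumerate(self.contexts_):
            for k, un in enumerate(unames):
                draws[f"mu_{un}[{c}]"] = MU[:, :, ci, k]
                draws[f"sigma_{un}[{c}]"] = SIG[:, :, ci, k]
            for pi, p in enumerate(self.participants_):
                for k, name in enumerate(nat):
                    draws[f"{name}[{p},{c}]"] = Unat[:, :, ci, pi, k]
        meta = {"model": self.model, "n_draws": self.n_draws,
                "n_burn": self.n_burn, "n_chains": nchain,
                "n_sweeps": self.n_sweeps, "n_block": self.n_block,
                "seed": self.seed,
                "contexts": list(self.contexts_),
                "participants": list(self.participants_),
                "param_names": list(nat),
                "priors": "mu ~ N(m0, tau0^2) on unconstrained scale; "
                          "sigma ~ HalfNormal(1); see inference._hyperpriors"}
        self._U_draws = U  # unconstrained, for DIC
        return PosteriorTrace(draws, dev, meta)

    # -- posterior summaries ------------------------------------------------
    def participant_params_(self) -> pd.DataFrame:
        """Posterior means of natural-scale parameters per participant-context."""
        rows = []
        for c in self.contexts_:
            for p in self.participants_:
                row = {"participant_id": p, "context": c}
                for name in self.spec_.param_names:
                    row[name] = float(self.trace_.draws[f"{name}[{p},{c}]"].mean())
                rows.append(row)
        return pd.DataFrame(rows)

    def group_mean_draws(self, param: str, context: str) -> np.ndarray:
        """Draws of the across-participant mean of a natural parameter."""
        k = self.spec_.param_names.index(param)
        ci = self.contexts_.index(context)
        U = self._U_draws[:, :, ci, :, k]
        if param == "a":
            U = np.exp(U)
        elif param == "z":
            U = 1.0 / (1.0 + np.exp(-U))
        elif param == "t_nd":
            U = np.exp(U)
        return U.mean(axis=2)

    def group_mean_summary(self) -> pd.DataFrame:
        rows = []
        for c in self.contexts_:
            for name in self.spec_.param_names:
                g = self.group_mean_draws(name, c).reshape(-1)
                rows.append({"context": c, "parameter": name,
                             "mean": float(g.mean()),
                             "sd": float(g.std(ddof=1)),
                             "ci2.5": float(np.quantile(g, 0.025)),
                             "ci97.5": float(np.quantile(g, 0.975))})
        return pd.DataFrame(rows)


@dataclass
class DICResult:
    model_id: str
    dic: float
    mean_deviance: float
    p_d: float
    converged: bool
    max_rhat: float

    def to_dict(self):
        return {"model_id": self.model_id, "dic": self.dic,
                "mean_deviance": self.mean_deviance, "p_d": self.p_d,
                "converged": self.converged, "max_rhat": self.max_rhat}


def dic(fit: HierarchicalDDM) -> DICResult:
    """Deviance information criterion: DIC = D_bar + p_D.

    p_D = D_bar - D(theta_bar) with theta_bar the posterior mean of the
    natural-scale participant parameters (mapped back to the sampling
    scale for evaluation).
    """
    if not hasattr(fit, "trace_"):
        raise ValueError("fit the model before computing DIC")
    d_bar = float(fit.trace_.deviance.mean())
    U = fit._U_draws  # (chain, keep, C, P, K)
    Unat = U.copy()
    Unat[..., 0] = np.exp(U[..., 0])
    Unat[..., 1] = 1.0 / (1.0 + np.exp(-U[..., 1]))
    Unat[..., 2] = np.exp(U[..., 2])
    mean_nat = Unat.mean(axis=(0, 1))  # (C, P, K)
    Ubar = mean_nat.copy()
    Ubar[..., 0] = np.log(mean_nat[..., 0])
    zc = np.clip(mean_nat[..., 1], 1e-9, 1 - 1e-9)
    Ubar[..., 1] = np.log(zc / (1 - zc))
    Ubar[..., 2] = np.log(mean_nat[..., 2])
    d_hat = -2.0 * fit.log_likelihood(Ubar)
    p_d = d_bar - d_hat
    mr = fit.trace_.max_rhat()
    return DICResult(fit.model, d_bar + p_d, d_bar, p_d,
                     mr <= RHAT_THRESHOLD, mr)


def compare_models(trials: pd.DataFrame, models=("M1", "M2", "M3", "M4", "M5"),
                   design_df: pd.DataFrame | None = None,
                   **sampler_kw) -> pd.DataFrame:
    """Fit each model on identical data and rank by DIC.

    Reports two delta conventions: against the best (minimum-DIC) model
    and against the predecessor in the nested M1..M5 order.  Models
    whose max R-hat exceeds the convergence gate are included but
    flagged ``converged=False``.
    """
    results = []
    fits = {}
    for mid in models:
        f = HierarchicalDDM(model=mid, **sampler_kw).fit(trials, design_df)
        fits[mid] = f
        results.append(dic(f).to_dict())
    df = pd.DataFrame(results)
    order = [m for m in ("M1", "M2", "M3", "M4", "M5") if m in set(df["model_id"])]
    df["_ord"] = df["model_id"].map({m: i for i, m in enumerate(order)})
    df = df.sort_values("_ord").reset_index(drop=True)
    df["delta_dic_prev"] = df["dic"].diff() * -1  # improvement over predecessor
    df["delta_dic_min"] = df["dic"] - df["dic"].min()
    df = df.sort_values("dic").reset_index(drop=True).drop(columns="_ord")
    df.attrs["fits"] = fits
    return df
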