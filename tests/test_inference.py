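import numpy as np
import pandas as pd
import pytest

from driftchoice.ddm import wfpt_log_density
from driftchoice.inference import (MODEL_TERMS, DICResult, HierarchicalDDM,
                                   ModelSpec, PosteriorTrace, dic, rhat,
                                   split_rhat)


class TestModelSpec:
    def test_nested_term_sets(self):
        assert MODEL_TERMS["M1"] == ("money",)
        assert MODEL_TERMS["M2"] == ("time",)
        assert set(MODEL_TERMS["M3"]) < set(MODEL_TERMS["M4"]) < set(MODEL_TERMS["M5"])

    def test_unknown_id(self):
        with pytest.raises(ValueError):
            ModelSpec.from_id("M9")


class TestManifestAndLikelihood:
    def test_manifest_arithmetic_two_participants_gain_only(self, retained_small,
                                                            design_df):
        sub = retained_small[(retained_small["group"] == "control")
                             & (retained_small["context"] == "gain")]
        ids = sorted(sub["participant_id"].unique())[:2]
        sub = sub[sub["participant_id"].isin(ids)]
        m = HierarchicalDDM(model="M3").build(sub, design_df)
        names = m.manifest()
        # group-level (mu, sigma) for 6 parameters + 2 participants x 6
        assert len(names) == 12 + 12
        assert sum(n.startswith("mu_") for n in names) == 6

    def test_missing_covariate_is_error(self, retained_small, design_df):
        broken = design_df.drop(columns="delay_diff_z")
        with pytest.raises(ValueError):
            HierarchicalDDM(model="M3").build(retained_small, broken)

    def test_total_loglik_equals_sum_of_wfpt_terms(self, retained_small, design_df):
        sub = retained_small[(retained_small["group"] == "control")
                             & (retained_small["context"] == "gain")]
        pid = sorted(sub["participant_id"].unique())[0]
        sub = sub[sub["participant_id"] == pid]
        m = HierarchicalDDM(model="M3").build(sub, design_df)
        rng = np.random.default_rng(0)
        U = np.zeros((1, 1, 6))
        U[0, 0] = [np.log(3.0), 0.1, np.log(0.4), 0.2, 0.1, -0.1]
        total = m.log_likelihood(U)
        a, z, t_nd = 3.0, 1 / (1 + np.exp(-0.1)), 0.4
        manual = 0.0
        d = design_df.loc[sub["condition_id"]]
        for (_, row), cid in zip(sub.iterrows(), sub["condition_id"]):
            cov = design_df.loc[cid]
            v = 0.2 + 0.1 * cov["money_diff_z"] - 0.1 * cov["delay_diff_z"]
            manual += wfpt_log_density(row["rt_ms"] / 1000.0,
                                       "upper" if row["choice"] == "later" else "lower",
                                       a, v, z, t_nd)
        assert total == pytest.approx(manual, abs=1e-8)


class TestSplitRhat:
    def test_identical_chains_near_one(self):
        # between-chain variance is zero; only the within-chain split halves
        # contribute, leaving the statistic at 1 up to white-noise jitter
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 500))
        chains = np.vstack([x, x])
        assert split_rhat(chains) <= 1.005

    def test_separated_chains_match_hand_formula(self):
        rng = np.random.default_rng(2)
        c1 = rng.normal(0, 1, 400)
        c2 = rng.normal(10, 1, 400)
        x = np.vstack([c1, c2])
        r = split_rhat(x)
        assert r > 1.1
        # hand computation from the split-chain definition
        n = 200
        halves = np.array([c1[:n], c1[n:], c2[:n], c2[n:]])
        W = halves.var(axis=1, ddof=1).mean()
        B_over_n = halves.mean(axis=1).var(ddof=1)
        expected = np.sqrt(((n - 1) / n * W + B_over_n) / W)
        assert r == pytest.approx(expected, abs=1e-12)

    def test_constant_series(self):
        assert split_rhat(np.ones((2, 100))) == 1.0

    def test_requires_enough_draws(self):
        with pytest.raises(ValueError):
            split_rhat(np.ones((2, 2)))

    def test_agrees_with_arviz_split_implementation(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        x = rng.normal(size=(4, 300)) + rng.normal(0, 0.2, size=(4, 1))
        ours = split_rhat(x)
        theirs = float(az.rhat(az.convert_to_dataset(x[:, :, None]),
                               method="split")["x"].values.ravel()[0])
        assert ours == pytest.approx(theirs, abs=1e-6)


class TestSampling:
    def test_same_seed_identical_traces(self, retained_small, design_df):
        sub = retained_small[(retained_small["group"] == "sud")
                             & (retained_small["context"] == "gain")]
        kw = dict(model="M1", n_draws=80, n_burn=40, n_chains=2, seed=5)
        f1 = HierarchicalDDM(**kw).fit(sub, design_df)
        f2 = HierarchicalDDM(**kw).fit(sub, design_df)
        for k in f1.trace_.draws:
            np.testing.assert_array_equal(f1.trace_.draws[k], f2.trace_.draws[k])
        np.testing.assert_array_equal(f1.trace_.deviance, f2.trace_.deviance)

    def test_rhat_requires_two_chains(self, retained_small, design_df):
        sub = retained_small[retained_small["group"] == "sud"]
        f = HierarchicalDDM(model="M1", n_draws=60, n_burn=30, n_chains=1,
                            seed=1).fit(sub, design_df)
        with pytest.raises(ValueError):
            rhat(f.trace_)

    def test_burn_must_be_smaller_than_draws(self, retained_small):
        with pytest.raises(ValueError):
            HierarchicalDDM(n_draws=100, n_burn=100).fit(retained_small)

    def test_fitted_attributes_and_summaries(self, tiny_fit):
        assert tiny_fit.trace_.n_chains == 2
        s = tiny_fit.trace_.summary()
        assert {"mean", "sd", "rhat"} <= set(s.columns)
        pp = tiny_fit.participant_params_()
        assert set(pp["context"]) == {"gain", "loss"}
        assert len(pp) == 2 * len(tiny_fit.participants_)
        gm = tiny_fit.group_mean_summary()
        a_gain = gm[(gm["parameter"] == "a") & (gm["context"] == "gain")]
        assert 1.0 < float(a_gain["mean"].iloc[0]) < 6.0

    def test_trace_roundtrip(self, tiny_fit, tmp_path):
        prefix = str(tmp_path / "trace")
        tiny_fit.trace_.save(prefix)
        loaded = PosteriorTrace.load(prefix)
        assert loaded.meta["model"] == "M3"
        np.testing.assert_array_equal(loaded.deviance, tiny_fit.trace_.deviance)

    def test_sklearn_param_interface(self):
        m = HierarchicalDDM()
        params = m.get_params()
        assert params["model"] == "M3"
        m.set_params(n_chains=2)
        assert m.n_chains == 2
        with pytest.raises(ValueError):
            m.set_params(nonsense=1)


class TestDIC:
    def test_point_mass_posterior_has_zero_complexity(self, tiny_fit):
        import copy
        frozen = copy.deepcopy(tiny_fit)
        point = frozen._U_draws[:1, :1].copy()
        frozen._U_draws = np.broadcast_to(point, frozen._U_draws.shape).copy()
        d_at_point = -2.0 * frozen.log_likelihood(point[0, 0])
        frozen.trace_.deviance = np.full_like(frozen.trace_.deviance, d_at_point)
        res = dic(frozen)
        assert res.p_d == pytest.approx(0.0, abs=1e-6)
        assert res.dic == pytest.approx(d_at_point, abs=1e-6)

    def test_unfitted_model_rejected(self):
        with pytest.raises(ValueError):
            dic(HierarchicalDDM())

    def test_dic_fields_consistent(self, tiny_fit):
        res = dic(tiny_fit)
        assert res.dic == pytest.approx(res.mean_deviance + res.p_d)
        assert res.p_d > 0
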