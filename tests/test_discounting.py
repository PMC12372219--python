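import numpy as np
import pandas as pd
import pytest
from scipy import stats

from driftchoice import simulate
from driftchoice.discounting import (HyperbolicDiscounter, compare_groups_lnk,
                                     cohens_d, fit_k, subjective_value)


class TestSubjectiveValue:
    def test_no_discounting_limits(self):
        assert subjective_value(500, 0.0, 30) == 500
        assert subjective_value(500, 0.3, 0) == 500

    def test_direct_formula(self):
        assert subjective_value(1000, 0.1, 30) == pytest.approx(250.0)

    def test_signed_amounts_pass_through(self):
        assert subjective_value(-1000, 0.1, 30) == pytest.approx(-250.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            subjective_value(100, -0.1, 5)
        with pytest.raises(ValueError):
            subjective_value(100, 0.1, -5)


def _all_choice_trials(design_df, context, choice):
    sub = design_df[design_df["context"] == context]
    return pd.DataFrame({
        "participant_id": "p0", "group": "control",
        "condition_id": sub.index, "context": context,
        "choice": choice, "rt_ms": 800})


class TestFitK:
    def test_always_later_in_gain_pins_low(self, design_df):
        f = fit_k(_all_choice_trials(design_df, "gain", "later"), design_df)
        assert f.boundary_flag and f.converged
        assert f.k == pytest.approx(1e-5)

    def test_always_sooner_in_gain_pins_high(self, design_df):
        f = fit_k(_all_choice_trials(design_df, "gain", "sooner"), design_df)
        assert f.boundary_flag
        assert f.k == pytest.approx(10.0)

    def test_recovery_from_hyperbolic_agent(self, design_df):
        ks = []
        for seed in range(5):
            trials = simulate.simulate_hyperbolic_agent(
                0.05, 0.05, 20.0, design_df, rng=seed)
            gain = trials[trials["context"] == "gain"]
            ks.append(fit_k(gain, design_df).k)
        assert 0.03 < np.median(ks) < 0.08

    def test_bias_shrinks_as_choices_become_deterministic(self, design_df):
        errs = {}
        for temp in (200.0, 2.0):
            e = []
            for seed in range(8):
                trials = simulate.simulate_hyperbolic_agent(
                    0.05, 0.05, temp, design_df, rng=100 + seed)
                gain = trials[trials["context"] == "gain"]
                e.append(abs(np.log(fit_k(gain, design_df).k / 0.05)))
            errs[temp] = np.median(e)
        assert errs[2.0] <= errs[200.0] + 1e-9

    def test_multistart_dominance(self, design_df):
        trials = simulate.simulate_hyperbolic_agent(0.1, 0.1, 10.0, design_df, rng=3)
        gain = trials[trials["context"] == "gain"]
        fit = fit_k(gain, design_df)
        df = design_df.loc[gain["condition_id"]]
        y = (gain["choice"] == "later").to_numpy(float)

        def sse(k, tau):
            d_soon = df["baseline_days"].to_numpy(float)
            d_late = d_soon + df["delay_days"].to_numpy(float)
            dv = (df["later_amount"].to_numpy(float) / (1 + k * d_late)
                  - df["sooner_amount"].to_numpy(float) / (1 + k * d_soon))
            from scipy.special import expit
            p = expit(dv / tau)
            return float(((y - p) ** 2).sum())

        for k in np.geomspace(1e-5, 10, 50):
            assert fit.sse <= sse(k, fit.temperature) + 1e-9


class TestGroupComparison:
    def _fits(self, lnk_by_group):
        rows = []
        for g, vals in lnk_by_group.items():
            for i, v in enumerate(vals):
                rows.append({"participant_id": f"{g}{i}", "group": g,
                             "context": "gain", "k": np.exp(v), "lnk": v,
                             "converged": True, "boundary_flag": False})
        return pd.DataFrame(rows)

    def test_identical_groups_null(self):
        fits = self._fits({"control": [1, 2, 3], "sud": [1, 2, 3]})
        res = compare_groups_lnk(fits, "gain")
        assert res["t"] == pytest.approx(0.0)
        assert res["cohen_d"] == pytest.approx(0.0)

    def test_shifted_sample_matches_pooled_t_formula(self):
        fits = self._fits({"control": [1, 2, 3], "sud": [2, 3, 4]})
        res = compare_groups_lnk(fits, "gain")
        # hand-computed pooled t on 3+3 samples
        sp = np.sqrt(((2) * 1.0 + (2) * 1.0) / 4)
        t_manual = (2.0 - 3.0) / (sp * np.sqrt(1 / 3 + 1 / 3))
        p_manual = 2 * stats.t.sf(abs(t_manual), 4)
        assert res["t"] == pytest.approx(t_manual, abs=1e-12)
        assert res["df"] == 4
        assert res["p"] == pytest.approx(p_manual, abs=1e-12)
        assert res["cohen_d"] == pytest.approx(-1.0, abs=1e-12)

    def test_label_swap_flips_sign(self):
        fits = self._fits({"a_grp": [1.0, 1.5, 2.0], "b_grp": [2.0, 2.5, 3.1]})
        res = compare_groups_lnk(fits, "gain")
        swapped = fits.copy()
        swapped["group"] = swapped["group"].map({"a_grp": "b_grp", "b_grp": "a_grp"})
        res2 = compare_groups_lnk(swapped, "gain")
        assert res2["t"] == pytest.approx(-res["t"])
        assert res2["p"] == pytest.approx(res["p"])

    def test_too_few_fits_is_error(self):
        fits = self._fits({"control": [1], "sud": [1, 2, 3]})
        with pytest.raises(ValueError):
            compare_groups_lnk(fits, "gain")


def test_estimator_fits_study_and_separates_contexts(design_df):
    frames = []
    for i, (kg, kl) in enumerate([(0.02, 0.1), (0.03, 0.08)]):
        t = simulate.simulate_hyperbolic_agent(kg, kl, 10.0, design_df, rng=i,
                                               participant_id=f"p{i}")
        frames.append(t)
    trials = pd.concat(frames, ignore_index=True)
    est = HyperbolicDiscounter().fit(trials, design_df)
    assert set(est.fits_["context"]) == {"gain", "loss"}
    assert len(est.fits_) == 4
    assert est.get_params()["k_max"] == 10.0
    est.set_params(k_max=5.0)
    assert est.k_max == 5.0
    with pytest.raises(ValueError):
        est.set_params(bogus=1)
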