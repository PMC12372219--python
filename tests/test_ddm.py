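import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from driftchoice.ddm import (DDMParams, compute_drift, hit_probability,
                             simulate_trial, simulate_trials, wfpt_log_density)


@pytest.fixture(scope="module")
def base_params():
    return DDMParams(a=2.0, z=0.5, t_nd=0.3, beta0=0.5)


class TestComputeDrift:
    @pytest.mark.parametrize("params,cov,expected", [
        (dict(beta0=0.5), (0.7, -1.2, 0.3), 0.5),
        (dict(beta0=0.0, beta_reward=0.1), (2.0, 0.0, 0.0), 0.2),
        # group-mean coefficients: 0.101 + 0.161 - 0.150 at covariates (1,1,0)
        (dict(beta0=0.101, beta_reward=0.161, beta_time=-0.150), (1, 1, 0), 0.112),
    ])
    def test_linear_combination(self, params, cov, expected):
        p = DDMParams(a=2, z=0.5, t_nd=0.3, **params)
        assert compute_drift(p, cov) == pytest.approx(expected)

    def test_nonfinite_covariates_rejected(self, base_params):
        with pytest.raises(ValueError):
            compute_drift(base_params, (np.nan, 0, 0))

    @pytest.mark.parametrize("bad", [dict(a=-1), dict(z=0.0), dict(z=1.2),
                                     dict(t_nd=-0.1)])
    def test_invalid_params_rejected(self, bad):
        kw = dict(a=2.0, z=0.5, t_nd=0.3, beta0=0.0)
        kw.update(bad)
        with pytest.raises(ValueError):
            DDMParams(**kw)


class TestHitProbability:
    def test_unbiased_zero_drift(self):
        assert hit_probability(2.0, 0.0, 0.5) == pytest.approx(0.5)

    def test_degenerate_starts(self):
        for v in (-1.0, 0.0, 2.0):
            assert hit_probability(1.5, v, 1.0) == pytest.approx(1.0)
            assert hit_probability(1.5, v, 0.0) == pytest.approx(0.0)

    def test_invalid_boundary(self):
        with pytest.raises(ValueError):
            hit_probability(0.0, 0.5, 0.5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(a=st.floats(0.5, 4), v=st.floats(-2, 2), z=st.floats(0.05, 0.95))
    def test_in_unit_interval_and_monotone_in_z(self, a, v, z):
        p = hit_probability(a, v, z)
        assert 0.0 <= p <= 1.0
        assert hit_probability(a, v, min(z + 0.02, 0.96)) >= p - 1e-12


class TestWfptDensity:
    def test_reflection_symmetry(self):
        for rt in np.linspace(0.35, 5.0, 40):
            up = wfpt_log_density(rt, "upper", 2.0, 0.7, 0.4, 0.3)
            lo = wfpt_log_density(rt, "lower", 2.0, -0.7, 0.6, 0.3)
            assert up == pytest.approx(lo, abs=1e-10)

    def test_normalizes_and_matches_hit_probability(self):
        a, v, z, tnd = 2.0, 0.5, 0.5, 0.3
        Iu = quad(lambda t: np.exp(wfpt_log_density(t, "upper", a, v, z, tnd)),
                  tnd, 60, limit=200)[0]
        Il = quad(lambda t: np.exp(wfpt_log_density(t, "lower", a, v, z, tnd)),
                  tnd, 60, limit=200)[0]
        assert Iu + Il == pytest.approx(1.0, abs=1e-3)
        assert Iu == pytest.approx(hit_probability(a, v, z), abs=1e-3)

    def test_zero_likelihood_before_nondecision_time(self):
        assert wfpt_log_density(0.29, "upper", 2.0, 0.5, 0.5, 0.3) == -np.inf
        assert wfpt_log_density(0.3, "lower", 2.0, 0.5, 0.5, 0.3) == -np.inf

    def test_density_nonnegative_and_vanishes_in_tails(self):
        lp_near = wfpt_log_density(0.301, "upper", 2.0, 0.5, 0.5, 0.3)
        lp_far = wfpt_log_density(59.0, "upper", 2.0, 0.5, 0.5, 0.3)
        lp_mid = wfpt_log_density(1.0, "upper", 2.0, 0.5, 0.5, 0.3)
        assert lp_near < lp_mid and lp_far < lp_mid


class TestSimulator:
    def test_rt_includes_nondecision_time(self, base_params):
        ch, rt = simulate_trials(base_params, np.full(200, 0.5), rng=0)
        assert np.nanmin(rt) >= base_params.t_nd

    def test_symmetry_at_zero_drift(self):
        p = DDMParams(a=2.0, z=0.5, t_nd=0.3, beta0=0.0)
        ch, rt = simulate_trials(p, np.zeros(20000), rng=1)
        frac = (ch == 1).mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 20000)

    def test_stronger_drift_is_faster(self):
        p = DDMParams(a=2.0, z=0.5, t_nd=0.3, beta0=0.0)
        _, rt_weak = simulate_trials(p, np.full(20000, 0.2), rng=7)
        _, rt_strong = simulate_trials(p, np.full(20000, 0.8), rng=7)
        assert np.nanmean(rt_strong) < np.nanmean(rt_weak)

    def test_dt_refinement_bias_within_mc_error(self):
        p = DDMParams(a=2.0, z=0.5, t_nd=0.3, beta0=0.4)
        n = 60_000
        _, rt1 = simulate_trials(p, np.full(n, 0.4), dt=1e-3, rng=3)
        _, rt2 = simulate_trials(p, np.full(n, 0.4), dt=5e-4, rng=4)
        se = np.nanstd(rt1) / np.sqrt(n)
        assert abs(np.nanmean(rt1) - np.nanmean(rt2)) < 3 * se

    def test_single_trial_interface_and_timeout(self):
        p = DDMParams(a=2.0, z=0.5, t_nd=0.3, beta0=0.2)
        label, rt = simulate_trial(p, (0.5, -0.5, 0.0), rng=0)
        assert label in ("later", "sooner", "timeout")
        # enormous boundary with no drift: certain timeout
        slow = DDMParams(a=200.0, z=0.5, t_nd=0.3, beta0=0.0)
        label, rt = simulate_trial(slow, (0, 0, 0), max_t=1.0, rng=0)
        assert label == "timeout" and np.isnan(rt)

    def test_invalid_step_sizes(self, base_params):
        with pytest.raises(ValueError):
            simulate_trials(base_params, np.ones(2), dt=0.0)
        with pytest.raises(ValueError):
            simulate_trials(base_params, np.ones(2), max_t=-1.0)
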