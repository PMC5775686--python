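import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import gpvreg as g
from gpvreg.km import KaplanMeierCurve

from conftest import naive_loo_survival, random_survival_sample, subjects_frame


def naive_pseudo(time, event, t_star):
    n = len(time)
    s = g.fit_km(time, event).survival_at(t_star)
    return n * s - (n - 1) * naive_loo_survival(time, event, t_star)


class TestMarginal:
    def test_uncensored_values_are_event_indicators(self):
        time = np.array([1.0, 2.0, 3.0, 6.0, 7.0])
        event = np.ones(5, dtype=int)
        vals = g.marginal_pseudo_values(time, event, 5.0)
        np.testing.assert_allclose(vals, [0, 0, 0, 1, 1], atol=1e-12)

    def test_censored_case_equals_naive_jackknife(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 0, 1, 0])
        vals = g.marginal_pseudo_values(time, event, 3.5)
        np.testing.assert_array_equal(vals, naive_pseudo(time, event, 3.5))

    @pytest.mark.parametrize("seed", range(5))
    def test_jackknife_identity(self, seed):
        rng = np.random.default_rng(seed)
        time, event = random_survival_sample(rng)
        t_star = float(np.median(time))
        vals = g.marginal_pseudo_values(time, event, t_star)
        s = g.fit_km(time, event).survival_at(t_star)
        assert np.mean(vals) == pytest.approx(s, abs=1e-12)

    def test_empty_risk_set_raises(self):
        with pytest.raises(ValueError, match="9"):
            g.marginal_pseudo_values([1.0, 2.0], [1, 1], 9.0)

    def test_values_outside_unit_interval_not_clipped(self):
        # heavy censoring pushes individual values below 0 / above 1
        time = np.array([1.0, 1.5, 2.0, 6.0, 6.0, 6.0])
        event = np.array([0, 0, 1, 1, 0, 0])
        vals = g.marginal_pseudo_values(time, event, 5.0)
        assert np.max(vals) > 1.0


class TestDirect02:
    def test_without_transitions_reduces_to_marginal(self):
        rng = np.random.default_rng(2)
        time, event = random_survival_sample(rng, n=20)
        df = subjects_frame(time, event)
        tab, _ = g.direct02_pseudo_values(df, 3.0)
        np.testing.assert_array_equal(
            tab["value"].to_numpy(),
            g.marginal_pseudo_values(time, event, 3.0))

    def test_transition_subject_censored_at_w(self):
        # donors censored at w=1; oracle = naive jackknife on modified sample
        df = subjects_frame([2.0, 6.0, 4.0], [1, 0, 1], [np.nan, np.nan, 1.0])
        tab, curve = g.direct02_pseudo_values(df, 5.0)
        mod_t, mod_e = np.array([2.0, 6.0, 1.0]), np.array([1, 0, 0])
        np.testing.assert_array_equal(tab["value"].to_numpy(),
                                      naive_pseudo(mod_t, mod_e, 5.0))
        assert curve.survival_at(5.0) == g.fit_km(mod_t, mod_e).survival_at(5.0)

    def test_mean_is_modified_sample_estimate(self):
        rng = np.random.default_rng(9)
        time, event = random_survival_sample(rng, n=30)
        w = np.where(rng.random(30) < 0.3, np.minimum(time, 1.0) * 0.5, np.nan)
        df = subjects_frame(time, event, w)
        tab, curve = g.direct02_pseudo_values(df, 3.0)
        assert tab["value"].mean() == pytest.approx(curve.survival_at(3.0),
                                                    abs=1e-12)


class TestConditional12:
    def test_uncensored_shared_w_group(self):
        df = subjects_frame([2.0, 3.0, 7.0], [1, 1, 0],
                            [1.0, 1.0, 1.0])
        tab = g.conditional12_pseudo_values(df, 5.0)
        np.testing.assert_allclose(np.sort(tab["value"]), [0, 0, 1], atol=1e-12)
        assert set(tab["risk_set_size"]) == {3}

    def test_censoring_inside_window_equals_naive(self):
        df = subjects_frame([2.0, 3.5, 7.0, 4.0], [1, 0, 0, 1],
                            [1.0, 1.0, 1.0, 1.0])
        tab = g.conditional12_pseudo_values(df, 5.0)
        time_shift = df["time"].to_numpy() - 1.0
        np.testing.assert_array_equal(
            tab["value"].to_numpy(),
            naive_pseudo(time_shift, df["event"].to_numpy(), 4.0))

    def test_group_mean_identity(self):
        df = subjects_frame([2.0, 3.5, 7.0, 4.0], [1, 0, 0, 1],
                            [1.0, 1.0, 1.0, 1.0])
        tab = g.conditional12_pseudo_values(df, 5.0)
        cond_km = g.fit_km(df["time"] - 1.0, df["event"]).survival_at(4.0)
        assert tab["value"].mean() == pytest.approx(cond_km, abs=1e-12)

    def test_singleton_group_is_indicator(self, caplog):
        df = subjects_frame([2.0, 7.0], [1, 0], [1.0, 2.0])
        tab = g.conditional12_pseudo_values(df, 5.0)
        assert tab["value"].tolist() == [0.0, 1.0]

    def test_state1_risk_set_mode(self):
        # continuous waiting times: each subject's risk set = transitioned
        # subjects still at risk at its own w, clock restarted at w
        df = subjects_frame([2.0, 3.5, 7.0], [1, 1, 0], [0.5, 3.0, 4.0])
        tab = g.conditional12_pseudo_values(df, 5.0, grouping="state1-risk-set")
        assert tab["risk_set_size"].tolist() == [3, 2, 1]
        # first subject: KM on all three, clock from 0.5, jackknife entry 0
        time_shift = df["time"].to_numpy() - 0.5
        expected = naive_pseudo(time_shift, df["event"].to_numpy(), 4.5)
        assert tab["value"].iloc[0] == expected[0]


class TestComposite:
    def test_identity_factor(self):
        df = subjects_frame([2.0, 3.0, 7.0], [1, 1, 0], [1.0, 1.0, 1.0])
        cond = g.conditional12_pseudo_values(df, 5.0)
        curve = KaplanMeierCurve(np.array([]), np.array([]), np.array([]),
                                 np.array([]), np.array([]), n=3)
        comp = g.composite012_pseudo_values(curve, cond)
        np.testing.assert_array_equal(comp["value"], cond["value"])

    def test_direct_product(self):
        cond = pd.DataFrame({"subject_id": [0], "kind": "conditional12",
                             "value": [0.9], "waiting_time": [1.0],
                             "risk_set_size": [3]})
        curve = KaplanMeierCurve(np.array([0.5]), np.array([0.8]),
                                 np.array([5]), np.array([1]),
                                 np.array([0.01]), n=5)
        comp = g.composite012_pseudo_values(curve, cond)
        assert comp["value"].iloc[0] == pytest.approx(0.72)


def _fixed_curve(s0, var):
    return KaplanMeierCurve(np.array([0.5]), np.array([s0]), np.array([10]),
                            np.array([2]), np.array([var]), n=10)


def _unit_cond(m):
    return pd.DataFrame({"subject_id": np.arange(m), "kind": "conditional12",
                         "value": np.ones(m), "waiting_time": np.ones(m),
                         "risk_set_size": np.full(m, m)})


class TestImputation:
    def test_degenerate_variance_gives_plain_bernoulli(self):
        m = 100_000
        out = g.impute_composite012(_fixed_curve(0.7, 0.0), _unit_cond(m),
                                    np.random.default_rng(0))
        mc_se = np.sqrt(0.7 * 0.3 / m)
        assert np.mean(out["value"]) == pytest.approx(0.7, abs=3 * mc_se)

    def test_mean_matches_numerical_integration(self):
        # E[B] = int exp(-exp(p)) dN(p; mu, sd^2), delta-method variance
        s0, var = 0.5, 0.002
        mu = np.log(-np.log(s0))
        sd = np.sqrt(var) / abs(s0 * np.log(s0))
        target, _ = integrate.quad(
            lambda p: np.exp(-np.exp(p)) * stats.norm.pdf(p, mu, sd),
            mu - 8 * sd, mu + 8 * sd)
        m = 100_000
        out = g.impute_composite012(_fixed_curve(s0, var), _unit_cond(m),
                                    np.random.default_rng(1))
        mc_se = np.sqrt(target * (1 - target) / m)
        assert np.mean(out["value"]) == pytest.approx(target, abs=3 * mc_se)

    def test_mean_preserving_vs_plain_composite(self):
        s0, var = 0.6, 0.004
        m = 100_000
        curve, cond = _fixed_curve(s0, var), _unit_cond(m)
        plain = g.composite012_pseudo_values(curve, cond)["value"].mean()
        imputed = g.impute_composite012(curve, cond,
                                        np.random.default_rng(2))
        assert abs(imputed["value"].mean() - plain) < 0.01

    def test_seed_reproducibility(self):
        curve, cond = _fixed_curve(0.5, 0.003), _unit_cond(50)
        a = g.impute_composite012(curve, cond, np.random.default_rng(42))
        b = g.impute_composite012(curve, cond, np.random.default_rng(42))
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_s0_falls_back_with_warning(self, caplog):
        curve = _fixed_curve(1.0, 0.0)
        cond = _unit_cond(5)
        import logging
        with caplog.at_level(logging.WARNING):
            out = g.impute_composite012(curve, cond, np.random.default_rng(3))
        assert "degenerate" in caplog.text
        np.testing.assert_array_equal(out["value"], np.ones(5))
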