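"""Estimator correctness: direct standardisation identities, Aalen-Johansen
against enumeration and lifelines, Cox recovery, g-computation reductions,
and adjusted mean home-time."""

import numpy as np
import pandas as pd
import pytest

from stroketrace import (aalen_johansen, adjusted_cif, direct_standardised_rate,
                         fit_cox_cause_specific, mean_home_time)
from stroketrace.estimators import ModelFit, _breslow_baseline


class TestDirectStandardisation:
    def test_single_stratum_identity(self):
        strata = pd.DataFrame({"age_band": ["60-64"], "events": [2], "person_years": [1000.0]})
        rp = direct_standardised_rate(strata, {"60-64": 6000})
        assert rp.rate == pytest.approx(200.0)
        assert rp.crude_rate == pytest.approx(200.0)
        assert rp.ci_low < 200.0 < rp.ci_high

    def test_hand_computed_two_strata(self):
        strata = pd.DataFrame({"age_band": ["a", "b"], "events": [1, 3],
                               "person_years": [100.0, 300.0]})
        rp = direct_standardised_rate(strata, {"a": 1, "b": 3})
        # both stratum rates are 0.01/py, so any weighting gives 1000 per 100k
        assert rp.rate == pytest.approx(1000.0)

    def test_structure_proportional_to_standard_gives_crude(self):
        weights = {"a": 2000, "b": 3000, "c": 5000}
        py = pd.Series({"a": 400.0, "b": 600.0, "c": 1000.0})  # proportional
        events = pd.Series({"a": 3, "b": 10, "c": 40})
        strata = pd.DataFrame({"age_band": list(weights),
                               "events": events.values, "person_years": py.values})
        rp = direct_standardised_rate(strata, weights)
        assert abs(rp.rate - rp.crude_rate) < 1e-9

    def test_splitting_a_stratum_in_half_changes_nothing(self):
        one = pd.DataFrame({"age_band": ["a", "b"], "events": [4, 6],
                            "person_years": [200.0, 300.0]})
        split = pd.DataFrame({"age_band": ["a", "a", "b"], "events": [2, 2, 6],
                              "person_years": [100.0, 100.0, 300.0]})
        w = {"a": 1000, "b": 2000}
        assert direct_standardised_rate(one, w).rate == pytest.approx(
            direct_standardised_rate(split, w).rate)

    def test_zero_person_time_with_weight_names_the_stratum(self):
        strata = pd.DataFrame({"age_band": ["a", "b"], "events": [1, 0],
                               "person_years": [100.0, 0.0]})
        with pytest.raises(ValueError, match="b"):
            direct_standardised_rate(strata, {"a": 1, "b": 1})

    def test_gamma_interval_is_positive_at_zero_events(self):
        strata = pd.DataFrame({"age_band": ["a"], "events": [0], "person_years": [100.0]})
        rp = direct_standardised_rate(strata, {"a": 1})
        assert rp.rate == 0.0
        assert rp.ci_low == 0.0
        assert rp.ci_high > 0.0


def enumerate_cif(subjects, t_max, cause="dispensed"):
    """Risk-set walker independent of the estimator implementation."""
    subjects = sorted(subjects)
    cif, surv = 0.0, 1.0
    for t in sorted({t for t, e in subjects if e != "censored"}):
        if t > t_max:
            break
        at_risk = sum(1 for ti, _ in subjects if ti >= t)
        d_cause = sum(1 for ti, e in subjects if ti == t and e == cause)
        d_all = sum(1 for ti, e in subjects if ti == t and e != "censored")
        cif += surv * d_cause / at_risk
        surv *= 1 - d_all / at_risk
    return cif


class TestAalenJohansen:
    def test_four_subject_enumeration(self):
        times = [1, 2, 3, 4]
        events = ["dispensed", "death", "censored", "dispensed"]
        curve = aalen_johansen(times, events)
        # walk: t=1 cif 1/4; t=2 death 1/4; t=4 one at risk, cif += 1/2
        assert curve.cif_at("dispensed", 4) == pytest.approx(0.75, abs=1e-12)
        assert curve.cif_at("death", 4) == pytest.approx(0.25, abs=1e-12)
        assert curve.cif_at("dispensed", 4) == pytest.approx(
            enumerate_cif(list(zip(times, events)), 4), abs=1e-12)

    def test_matches_enumeration_on_random_data(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = rng.integers(3, 30)
            times = rng.integers(0, 15, size=n).astype(float)
            events = rng.choice(["dispensed", "death", "censored"], size=n)
            curve = aalen_johansen(times, events)
            for t in (3, 7, 14):
                assert curve.cif_at("dispensed", t) == pytest.approx(
                    enumerate_cif(list(zip(times, events)), t), abs=1e-12)

    def test_without_competing_deaths_cif_is_one_minus_km(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(2)
        times = rng.exponential(50, size=200).round()
        events = np.where(rng.random(200) < 0.7, "dispensed", "censored")
        curve = aalen_johansen(times, events)
        km = KaplanMeierFitter().fit(times, events == "dispensed")
        for t in (10, 40, 90):
            assert curve.cif_at("dispensed", t) == pytest.approx(
                1 - km.survival_function_at_times(t).iloc[0], abs=1e-12)

    def test_agrees_with_lifelines_aalen_johansen(self):
        from lifelines import AalenJohansenFitter
        rng = np.random.default_rng(3)
        times = rng.exponential(100, size=300) + 1  # continuous, so no ties
        codes = rng.choice([0, 1, 2], size=300, p=[0.2, 0.5, 0.3])
        events = np.array(["censored", "dispensed", "death"])[codes]
        curve = aalen_johansen(times, events)
        ajf = AalenJohansenFitter(calculate_variance=False, seed=0)
        ajf.fit(times, codes, event_of_interest=1)
        for t in (50, 150, 400):
            ours = curve.cif_at("dispensed", t)
            theirs = float(ajf.cumulative_density_.loc[:t].iloc[-1, 0])
            assert ours == pytest.approx(theirs, abs=1e-9)

    def test_additivity_on_every_dataset(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = rng.integers(5, 200)
            times = rng.integers(0, 50, size=n).astype(float)
            events = rng.choice(["dispensed", "death", "censored"], size=n)
            tab = aalen_johansen(times, events).table
            if len(tab):
                total = tab["surv"] + tab["cif_dispensed"] + tab["cif_death"]
                assert np.allclose(total, 1.0, atol=1e-10)

    def test_all_censored_gives_flat_zero(self):
        curve = aalen_johansen([1.0, 2.0], ["censored", "censored"])
        assert curve.cif_at("dispensed", 100) == 0.0

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            aalen_johansen([], [])


def _simulate_competing(rng, n, h1, h2, beta1=0.0, horizon=365):
    x = rng.integers(0, 2, size=n)
    t1 = rng.exponential(1.0 / (h1 * np.exp(beta1 * x)))
    t2 = rng.exponential(1.0 / h2, size=n)
    t = np.minimum(np.minimum(t1, t2), horizon)
    events = np.where(t >= horizon, "censored", np.where(t1 <= t2, "dispensed", "death"))
    return pd.DataFrame({"x": x}), t, events


class TestCauseSpecificCox:
    def test_null_effect_recovered_within_three_se(self):
        rng = np.random.default_rng(5)
        X, t, e = _simulate_competing(rng, 2000, 0.004, 0.001, beta1=0.0)
        fit = fit_cox_cause_specific(X, t, e, "dispensed")
        assert fit.converged
        assert abs(fit.params["x"]) <= 3 * fit.se["x"]

    def test_subject_order_does_not_change_the_estimate(self):
        rng = np.random.default_rng(6)
        X, t, e = _simulate_competing(rng, 500, 0.004, 0.001, beta1=0.5)
        fit1 = fit_cox_cause_specific(X, t, e, "dispensed")
        perm = rng.permutation(len(t))
        fit2 = fit_cox_cause_specific(X.iloc[perm].reset_index(drop=True), t[perm], e[perm], "dispensed")
        assert fit1.params["x"] == pytest.approx(fit2.params["x"], abs=1e-6)

    def test_complete_separation_is_flagged_not_estimated(self):
        n = 40
        x = np.repeat([0, 1], n // 2)
        t = np.concatenate([1000.0 + np.arange(n // 2), 1.0 + np.arange(n // 2)])
        e = np.where(x == 1, "dispensed", "censored")
        fit = fit_cox_cause_specific(pd.DataFrame({"x": x}), t.astype(float), e, "dispensed")
        assert not fit.converged
        assert len(fit.params) == 0

    def test_no_events_of_the_cause_is_flagged(self):
        fit = fit_cox_cause_specific(pd.DataFrame({"x": [0, 1]}),
                                     np.array([1.0, 2.0]),
                                     np.array(["censored", "censored"]), "dispensed")
        assert not fit.converged


class TestAdjustedCif:
    def test_zero_coefficients_reduce_to_aalen_johansen(self):
        rng = np.random.default_rng(7)
        X, t, e = _simulate_competing(rng, 400, 0.004, 0.001)
        fits = {}
        for cause in ("dispensed", "death"):
            base = _breslow_baseline(t, e == cause, np.ones_like(t))
            fits[cause] = ModelFit(cause=cause, converged=True,
                                   params=pd.Series({"x": 0.0}), baseline=base)
        adj = adjusted_cif(fits, X)
        aj = aalen_johansen(t, e)
        for q in (50, 150, 300):
            assert adj.cif_at("dispensed", q) == pytest.approx(
                aj.cif_at("dispensed", q), abs=1e-6)
            assert adj.cif_at("death", q) == pytest.approx(aj.cif_at("death", q), abs=1e-6)

    def test_empty_covariate_set_is_identical_to_aalen_johansen(self):
        rng = np.random.default_rng(8)
        X, t, e = _simulate_competing(rng, 300, 0.004, 0.001)
        fits = {c: fit_cox_cause_specific(X[[]], t, e, c) for c in ("dispensed", "death")}
        adj = adjusted_cif(fits, X[[]])
        aj = aalen_johansen(t, e)
        assert adj.cif_at("dispensed", 365) == pytest.approx(aj.cif_at("dispensed", 365), abs=1e-10)

    def test_per_level_curves_match_stratified_estimator(self):
        rng = np.random.default_rng(9)
        X, t, e = _simulate_competing(rng, 5000, 0.004, 0.001, beta1=np.log(2))
        fits = {c: fit_cox_cause_specific(X, t, e, c) for c in ("dispensed", "death")}
        for level in (0, 1):
            X_level = pd.DataFrame({"x": np.full(len(X), level)})
            adj = adjusted_cif(fits, X_level)
            sel = X["x"].to_numpy() == level
            strat = aalen_johansen(t[sel], e[sel])
            assert adj.cif_at("dispensed", 300) == pytest.approx(
                strat.cif_at("dispensed", 300), abs=0.03)

    def test_non_convergent_fit_propagates(self):
        fits = {"dispensed": ModelFit(cause="dispensed", converged=False),
                "death": ModelFit(cause="death", converged=True)}
        with pytest.raises(ValueError, match="converge"):
            adjusted_cif(fits, pd.DataFrame({"x": [0, 1]}))


class TestMeanHomeTime:
    def test_constant_stratum_has_zero_width_interval(self):
        df = pd.DataFrame({"home_days": [180] * 8, "g": ["a"] * 8})
        out = mean_home_time(df, "g")
        assert out.loc[0, "crude_mean"] == 180
        assert out.loc[0, "ci_low"] == out.loc[0, "ci_high"] == 180

    def test_balanced_design_adjusted_equals_crude(self):
        # covariate distribution identical in both strata -> collapsible
        df = pd.DataFrame({
            "g": ["a"] * 4 + ["b"] * 4,
            "z": [0, 0, 1, 1] * 2,
            "home_days": [170, 172, 150, 152, 160, 162, 140, 142.0],
        })
        out = mean_home_time(df, "g", adjust_for=["z"])
        assert np.allclose(out["adjusted_mean"], out["crude_mean"], atol=1e-9)

    def test_confounded_effect_recovered_within_three_se(self):
        rng = np.random.default_rng(10)
        n = 4000
        z = rng.integers(0, 2, size=n)
        g = np.where(rng.random(n) < 0.2 + 0.6 * z, "exposed", "reference")
        noise = rng.normal(0, 8, size=n)
        y = 170 - 10.0 * (g == "exposed") - 15.0 * z + noise
        df = pd.DataFrame({"g": g, "z": z, "home_days": y})
        out = mean_home_time(df, "g", adjust_for=["z"]).set_index("g")
        diff = out.loc["exposed", "adjusted_mean"] - out.loc["reference", "adjusted_mean"]
        se = 8 / np.sqrt(n / 4)
        assert abs(diff - (-10.0)) <= 3 * se
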