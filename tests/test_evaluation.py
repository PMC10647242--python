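"""C-index, time-dependent AUC, bootstrap comparison, Youden threshold,
Kaplan-Meier / log-rank and Schoenfeld power."""

import numpy as np
import pandas as pd
import pytest

from deltarad.evaluation import (
    UndefinedMetricError,
    bootstrap_compare,
    concordance_index,
    evaluate_model,
    km_logrank,
    schoenfeld_power,
    time_dependent_auc,
    youden_threshold,
)


def brute_cindex(risk, time, event):
    """Exhaustive Harrell pair enumeration with censoring rules."""
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # usable pair: i has the earlier time and an observed event
            if event[i] and time[i] < time[j]:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


class TestConcordance:
    def test_perfect_ranking(self):
        out = pd.DataFrame({"time_days": [10.0, 20, 30, 40], "event": [1, 1, 1, 1]})
        assert concordance_index(-out["time_days"], out) == 1.0
        assert concordance_index(out["time_days"], out) == 0.0

    def test_censored_toy_matches_pair_enumeration_oracle(self, outcomes_frame, rng):
        risk = rng.normal(size=len(outcomes_frame))
        got = concordance_index(risk, outcomes_frame)
        expect = brute_cindex(
            risk,
            outcomes_frame["time_days"].to_numpy(),
            outcomes_frame["event"].to_numpy(),
        )
        assert got == pytest.approx(expect, abs=1e-12)

    def test_negated_risk_complements(self, outcomes_frame, rng):
        risk = rng.normal(size=len(outcomes_frame))  # continuous: no ties
        c1 = concordance_index(risk, outcomes_frame)
        c2 = concordance_index(-risk, outcomes_frame)
        assert c1 + c2 == pytest.approx(1.0, abs=1e-12)

    def test_monotone_transform_invariance(self, outcomes_frame, rng):
        risk = rng.normal(size=len(outcomes_frame))
        c1 = concordance_index(risk, outcomes_frame)
        c2 = concordance_index(np.exp(3 * risk), outcomes_frame)
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_no_events_undefined(self):
        out = pd.DataFrame({"time_days": [1.0, 2.0], "event": [0, 0]})
        with pytest.raises(UndefinedMetricError):
            concordance_index([1.0, 2.0], out)


class TestTimeDependentAuc:
    def test_perfect_separation_gives_one(self):
        out = pd.DataFrame(
            {"time_days": [50.0, 80, 120, 400, 500, 600], "event": [1, 1, 1, 0, 0, 0]}
        )
        risk = np.array([3.0, 2.5, 2.0, 0.5, 0.2, 0.1])
        assert time_dependent_auc(risk, out, 200.0) == pytest.approx(1.0)

    def test_uncensored_reduces_to_mann_whitney(self, rng):
        n = 60
        time = rng.exponential(300, size=n) + 1
        out = pd.DataFrame({"time_days": time, "event": np.ones(n, dtype=int)})
        risk = rng.normal(size=n)
        h = float(np.median(time))
        got = time_dependent_auc(risk, out, h)
        cases = time <= h
        from scipy.stats import mannwhitneyu

        u = mannwhitneyu(risk[cases], risk[~cases]).statistic
        expect = u / (cases.sum() * (~cases).sum())
        assert got == pytest.approx(expect, abs=1e-12)

    def test_matches_ipcw_reference_implementation(self, rng):
        """Censored case cross-checked against scikit-survival's
        cumulative/dynamic AUC estimator."""
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        n = 120
        time = rng.exponential(300, size=n) + 1
        cens = rng.exponential(500, size=n)
        out = pd.DataFrame(
            {"time_days": np.minimum(time, cens), "event": (time <= cens).astype(int)}
        )
        risk = -time + rng.normal(scale=100, size=n)
        y = Surv.from_arrays(out["event"].astype(bool), out["time_days"])
        h = float(np.quantile(out["time_days"], 0.5))
        expect, _ = cumulative_dynamic_auc(y, y, risk, [h])
        got = time_dependent_auc(risk, out, h)
        assert got == pytest.approx(float(expect[0]), abs=0.02)

    def test_random_risk_near_half(self):
        vals = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            time = r.exponential(300, size=500) + 1
            out = pd.DataFrame({"time_days": time, "event": np.ones(500, int)})
            vals.append(time_dependent_auc(r.normal(size=500), out, 300.0))
        assert 0.45 <= np.mean(vals) <= 0.55

    def test_no_cases_undefined(self):
        out = pd.DataFrame({"time_days": [400.0, 500.0], "event": [1, 0]})
        with pytest.raises(UndefinedMetricError):
            time_dependent_auc([1.0, 2.0], out, 100.0)


class TestBootstrapCompare:
    def _toy(self, rng, n=80):
        time = rng.exponential(300, size=n) + 1
        out = pd.DataFrame({"time_days": time, "event": np.ones(n, int)})
        return out

    def test_identical_models_p_near_one(self, rng):
        out = self._toy(rng)
        risk = rng.normal(size=len(out))
        res = bootstrap_compare(
            {"a": risk, "b": risk.copy()}, out, [300.0], B=50, seed=0, reference="a"
        )
        assert res["p_values"][("b", "a")][300.0] == pytest.approx(1.0)

    def test_same_seed_identical_replicates(self, rng):
        out = self._toy(rng)
        risk = {"a": rng.normal(size=len(out)), "b": rng.normal(size=len(out))}
        r1 = bootstrap_compare(risk, out, [300.0], B=20, seed=5)
        r2 = bootstrap_compare(risk, out, [300.0], B=20, seed=5)
        pd.testing.assert_frame_equal(r1["replicate_c_index"], r2["replicate_c_index"])

    def test_strong_model_beats_null_decisively(self):
        rng = np.random.default_rng(2)
        n = 300
        time = rng.exponential(300, size=n) + 1
        out = pd.DataFrame({"time_days": time, "event": np.ones(n, int)})
        strong = -time + rng.normal(scale=30, size=n)
        null = rng.normal(size=n)
        res = bootstrap_compare(
            {"strong": strong, "null": null}, out, [300.0], B=100, seed=0, reference="strong"
        )
        assert res["p_values"][("null", "strong")][300.0] < 0.001


class TestYouden:
    def test_perfect_separation(self):
        out = pd.DataFrame(
            {"time_days": [50.0, 80, 400, 500], "event": [1, 1, 0, 0]}
        )
        risk = np.array([2.0, 1.8, 0.3, 0.1])
        thr = youden_threshold(risk, out, 200.0)
        assert 0.3 < thr <= 1.8

    def test_matches_exhaustive_scan_oracle(self, rng):
        n = 10
        time = rng.exponential(300, size=n) + 1
        out = pd.DataFrame({"time_days": time, "event": np.ones(n, int)})
        risk = rng.normal(size=n)
        thr = youden_threshold(risk, out, float(np.median(time)))
        # oracle: exhaustive scan, no censoring so weights are flat
        cases = time <= np.median(time)
        best_j, best_t = -np.inf, None
        for t in sorted(risk):
            sens = np.mean(risk[cases] >= t)
            spec = np.mean(risk[~cases] < t)
            j = sens + spec - 1
            if j > best_j + 1e-12:
                best_j, best_t = j, t
        assert thr == pytest.approx(best_t)

    def test_null_risk_low_j(self, rng):
        n = 400
        time = rng.exponential(300, size=n) + 1
        out = pd.DataFrame({"time_days": time, "event": np.ones(n, int)})
        risk = rng.normal(size=n)
        thr = youden_threshold(risk, out, float(np.median(time)))
        cases = time <= np.median(time)
        j = np.mean(risk[cases] >= thr) + np.mean(risk[~cases] < thr) - 1
        assert j < 0.25  # optimised J is biased upward; stays small under the null


class TestKmLogrank:
    def test_no_events_flagged(self):
        out = pd.DataFrame({"time_days": [100.0, 200, 300, 400], "event": [0, 0, 0, 0]})
        group = pd.Series(["high", "high", "low", "low"])
        res = km_logrank(group, out)
        assert np.isnan(res["logrank_p"])
        for df in res["km_curves"].values():
            assert (df["survival"] == 1.0).all()

    def test_identical_groups_statistic_zero(self):
        base = pd.DataFrame({"time_days": [50.0, 150, 250], "event": [1, 0, 1]})
        out = pd.concat([base, base], ignore_index=True)
        group = pd.Series(["high"] * 3 + ["low"] * 3)
        res = km_logrank(group, out)
        assert res["logrank_stat"] == pytest.approx(0.0, abs=1e-12)

    def test_km_steps_match_hand_computed_product_limit(self):
        # 6 subjects, one group: times 1,2,2,3 events + censoring at 2, 3
        out = pd.DataFrame(
            {"time_days": [1.0, 2.0, 2.0, 2.0, 3.0, 3.0], "event": [1, 1, 1, 0, 1, 0]}
        )
        group = pd.Series(["a"] * 6)
        from lifelines import KaplanMeierFitter

        km = KaplanMeierFitter()
        km.fit(out["time_days"], out["event"])
        s = km.survival_function_["KM_estimate"]
        # hand product-limit: S(1)=5/6; S(2)=5/6*(1-2/5)=1/2; S(3)=1/2*(1-1/2)=1/4
        assert s.loc[1.0] == pytest.approx(5 / 6)
        assert s.loc[2.0] == pytest.approx(0.5)
        assert s.loc[3.0] == pytest.approx(0.25)

    def test_logrank_matches_observed_minus_expected_oracle(self):
        out = pd.DataFrame(
            {"time_days": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0], "event": [1, 1, 1, 1, 1, 1]}
        )
        group = pd.Series(["high", "low", "high", "low", "high", "low"])
        res = km_logrank(group, out)
        # oracle: chi-square = (O-E)^2/V with hypergeometric terms per event time
        o_minus_e = 0.0
        var = 0.0
        times = out["time_days"].to_numpy()
        gh = (group == "high").to_numpy()
        for t in times:
            at_risk = times >= t
            n = at_risk.sum()
            n1 = (at_risk & gh).sum()
            d = 1
            e1 = d * n1 / n
            o1 = 1 if gh[times == t][0] else 0
            o_minus_e += o1 - e1
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expect = o_minus_e**2 / var
        assert res["logrank_stat"] == pytest.approx(expect, abs=1e-9)

    def test_km_without_censoring_is_empirical_survival(self, rng):
        t = rng.exponential(100, size=30).round(2) + 1
        out = pd.DataFrame({"time_days": t, "event": np.ones(30, int)})
        from lifelines import KaplanMeierFitter

        km = KaplanMeierFitter()
        km.fit(out["time_days"], out["event"])
        for tt in np.quantile(t, [0.2, 0.5, 0.8]):
            emp = np.mean(t > tt)
            assert float(km.predict(tt)) == pytest.approx(emp, abs=1e-9)


class TestSchoenfeldPower:
    def test_null_hr_power_equals_alpha(self):
        assert schoenfeld_power(1.0, 100) == pytest.approx(0.05, abs=1e-12)

    def test_monotone_in_effect_and_events(self):
        powers_hr = [schoenfeld_power(hr, 100) for hr in (1.2, 1.5, 2.0, 3.0)]
        assert powers_hr == sorted(powers_hr)
        powers_n = [schoenfeld_power(1.5, d) for d in (20, 50, 100, 200)]
        assert powers_n == sorted(powers_n)

    def test_symmetric_in_log_hr(self):
        assert schoenfeld_power(2.0, 80) == pytest.approx(schoenfeld_power(0.5, 80))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            schoenfeld_power(-1.0, 100)


class TestEvaluateModel:
    def test_report_fields_and_ci_ordering(self, rng):
        n = 100
        time = rng.exponential(300, size=n) + 1
        out = pd.DataFrame({"time_days": time, "event": np.ones(n, int)})
        rep = evaluate_model(-time, out, horizons_days=[200.0], n_bootstrap=30, seed=0)
        assert rep.c_index == pytest.approx(1.0)
        point, lo, hi = rep.auc_by_horizon[200.0]
        assert lo <= point <= hi
        assert 0 <= rep.c_index_ci[0] <= rep.c_index <= rep.c_index_ci[1] <= 1
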