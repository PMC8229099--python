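import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylclass.simulate import (
    OutcomeConfig,
    SimulationConfig,
    simulate_cohort,
)
from methylclass.survival import (
    assign_methylation_groups,
    cox_ph_fit,
    km_curve,
    logrank_test,
    rank_outcome_cpgs,
    run_survival_stage,
)
from methylclass.types import SampleSheet

from conftest import make_beta


def logrank_oracle(times, events, groups):
    """Brute-force: accumulate O-E and V at every distinct event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    label = np.unique(groups)[0]
    num = 0.0
    var = 0.0
    for ti in sorted(set(times[events == 1])):
        risk = [i for i in range(len(times)) if times[i] >= ti]
        n = len(risk)
        n1 = sum(1 for i in risk if groups[i] == label)
        dead = [i for i in risk if times[i] == ti and events[i] == 1]
        d = len(dead)
        d1 = sum(1 for i in dead if groups[i] == label)
        num += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return float("nan")  # degenerate: no between-group information
    return num ** 2 / var


class TestRankOutcomeCpgs:
    @staticmethod
    def _beta_with_signal(n_signal, n_total, n_per=15, seed=0):
        rng = np.random.default_rng(seed)
        values = np.full((n_total, 2 * n_per), 0.4)
        values[:n_signal, :n_per] += 0.35
        values += rng.normal(0, 0.05, values.shape)
        beta = make_beta(np.clip(values, 0, 1))
        flag = [1] * n_per + [0] * n_per
        return beta, flag

    def test_cap_is_a_maximum(self):
        beta, flag = self._beta_with_signal(20, 200, seed=1)
        ranked = rank_outcome_cpgs(beta, flag, top_k=50)
        # only the planted CpGs separate the groups strongly; a few false
        # positives can pass raw alpha but far fewer than top_k
        assert len(ranked) < 50
        assert set(beta.cpg_ids[:20]) <= set(ranked["cpg_id"])

    def test_exactly_top_k_when_many_pass(self):
        beta, flag = self._beta_with_signal(100, 100, seed=2)
        ranked = rank_outcome_cpgs(beta, flag, top_k=50)
        assert len(ranked) == 50
        assert ranked["p"].is_monotonic_increasing

    def test_null_pass_rate_near_alpha(self):
        # [DERIVED] shuffled flag -> ~5% of CpGs pass raw alpha
        rng = np.random.default_rng(3)
        rates = []
        for rep in range(20):
            beta = make_beta(rng.uniform(0, 1, (100, 30)))
            flag = rng.permutation([1] * 15 + [0] * 15)
            ranked = rank_outcome_cpgs(beta, flag, top_k=1000)
            rates.append(len(ranked) / 100)
        assert np.mean(rates) == pytest.approx(0.05, abs=0.03)

    def test_empty_class_errors(self, small_beta):
        with pytest.raises(ValueError, match="non-empty"):
            rank_outcome_cpgs(small_beta, [1] * small_beta.n_samples)


class TestAssignMethylationGroups:
    def test_high_low_by_mean(self):
        rng = np.random.default_rng(4)
        values = np.clip(np.hstack([
            np.full((30, 8), 0.7), np.full((30, 8), 0.3)])
            + rng.normal(0, 0.03, (30, 16)), 0, 1)
        beta = make_beta(values)
        groups = assign_methylation_groups(beta)
        assert all(groups[s] == "high" for s in beta.sample_ids[:8])
        assert all(groups[s] == "low" for s in beta.sample_ids[8:])

    def test_partition_recovery(self):
        from sklearn.metrics import adjusted_rand_score
        rng = np.random.default_rng(5)
        values = np.full((40, 20), 0.3)
        values[:, 10:] += 0.4
        values += rng.normal(0, 0.05, values.shape)
        beta = make_beta(np.clip(values, 0, 1))
        groups = assign_methylation_groups(beta)
        got = [groups[s] for s in beta.sample_ids]
        assert adjusted_rand_score(got, [0] * 10 + [1] * 10) == 1.0

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            assign_methylation_groups(make_beta(np.full((5, 1), 0.5)))

    def test_identical_samples_deterministic_tiebreak(self):
        beta = make_beta(np.full((10, 6), 0.5))
        groups = assign_methylation_groups(beta)
        assert set(groups.values()) == {"high", "low"}
        again = assign_methylation_groups(beta)
        assert groups == again


class TestKmCurve:
    def test_no_events_flat(self):
        km = km_curve([1, 2, 3], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_two_events_by_hand(self):
        # [DERIVED] S: 1 -> 0.5 -> 0
        km = km_curve([1, 2], [1, 1])
        np.testing.assert_allclose(km["survival"], [1.0, 0.5, 0.0])

    def test_censoring_shrinks_risk_set(self):
        # [DERIVED] event@1, censor@1.5, event@2:
        # S(2) = (1 - 1/3) * (1 - 1/1) = 0
        km = km_curve([1, 1.5, 2], [1, 0, 1])
        np.testing.assert_allclose(km["survival"], [1.0, 2 / 3, 0.0])
        assert km["n_at_risk"].tolist() == [3, 3, 1]

    def test_starts_at_one_nonincreasing(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(1, 50)
        e = rng.integers(0, 2, 50)
        km = km_curve(t, e)
        assert km.loc[0, "survival"] == 1.0
        assert (np.diff(km["survival"]) <= 1e-12).all()

    def test_equals_empirical_without_censoring(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(1, 40)
        km = km_curve(t, np.ones(40))
        for _, row in km.iloc[1:].iterrows():
            empirical = (t > row["time"]).mean()
            assert row["survival"] == pytest.approx(empirical, abs=1e-12)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(8)
        t = np.round(rng.exponential(10, 60), 1)  # induces ties
        e = rng.integers(0, 2, 60)
        if e.sum() == 0:
            e[0] = 1
        km = km_curve(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for _, row in km.iterrows():
            expected = float(kmf.survival_function_at_times(
                row["time"]).iloc[0])
            assert row["survival"] == pytest.approx(expected, abs=1e-10)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            km_curve([], [])


class TestLogrank:
    def test_identical_groups(self):
        t = [1, 2, 3, 4] * 2
        e = [1, 1, 0, 1] * 2
        g = [0] * 4 + [1] * 4
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = rng.integers(6, 20)
            t = np.round(rng.exponential(5, n), 0) + 1
            e = rng.integers(0, 2, n)
            g = rng.integers(0, 2, n)
            if e.sum() == 0 or len(set(g)) < 2:
                continue
            expected = logrank_oracle(t, e, g)
            if np.isnan(expected):
                continue
            chi2, _ = logrank_test(t, e, g)
            assert chi2 == pytest.approx(expected, rel=1e-9)

    def test_power_under_hazard_ratio_4(self):
        # [DERIVED] HR=4, n=100/group -> p < 0.01 in >= 95% of replicates
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            g = np.array([0] * 100 + [1] * 100)
            t = rng.exponential(1 / (0.05 * 4.0 ** g))
            _, p = logrank_test(t, np.ones_like(g), g)
            hits += p < 0.01
        assert hits >= 95

    def test_group_label_symmetry(self):
        rng = np.random.default_rng(10)
        t = rng.exponential(1, 30)
        e = rng.integers(0, 2, 30)
        g = rng.integers(0, 2, 30)
        if e.sum() == 0:
            e[0] = 1
        assert logrank_test(t, e, g)[0] == \
            pytest.approx(logrank_test(t, e, 1 - g)[0])

    def test_no_events_warns(self):
        with pytest.warns(UserWarning, match="no events"):
            _, p = logrank_test([1, 2], [0, 0], [0, 1])
        assert p == 1.0


class TestCoxPhFit:
    def test_identical_event_times_null_coefficient(self):
        t = np.array([1, 2, 3, 4, 5, 1, 2, 3, 4, 5], float)
        e = np.ones(10, int)
        x = np.array([0] * 5 + [1] * 5, float)
        fit = cox_ph_fit(t, e, x)
        assert abs(fit.coefficients[0]) < 1e-6
        assert fit.hazard_ratios[0] == pytest.approx(1.0, abs=1e-5)

    def test_matches_lifelines_without_ties(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(14)
        n = 150
        x = np.column_stack([rng.integers(0, 2, n).astype(float),
                             rng.normal(size=n)])
        t = rng.exponential(1 / (0.05 * np.exp(0.8 * x[:, 0] - 0.3 * x[:, 1])))
        e = (rng.random(n) > 0.2).astype(int)
        fit = cox_ph_fit(t, e, x, ["g", "z"])
        df = pd.DataFrame({"t": t, "e": e, "g": x[:, 0], "z": x[:, 1]})
        cph = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(fit.coefficients,
                                   cph.summary["coef"].to_numpy(), atol=1e-5)
        np.testing.assert_allclose(fit.standard_errors,
                                   cph.summary["se(coef)"].to_numpy(),
                                   atol=1e-5)

    def test_matches_statsmodels_breslow_with_ties(self):
        from statsmodels.duration.hazard_regression import PHReg
        rng = np.random.default_rng(11)
        n = 150
        x = np.column_stack([rng.integers(0, 2, n).astype(float),
                             rng.normal(size=n)])
        t = rng.exponential(1 / (0.05 * np.exp(0.8 * x[:, 0] - 0.3 * x[:, 1])))
        t = np.round(t, 1) + 0.1  # ties -> Breslow handling
        e = (rng.random(n) > 0.2).astype(int)
        fit = cox_ph_fit(t, e, x, ["g", "z"])
        res = PHReg(t, x, status=e, ties="breslow").fit()
        np.testing.assert_allclose(fit.coefficients, res.params, atol=1e-6)
        np.testing.assert_allclose(fit.standard_errors, res.bse, atol=1e-6)

    def test_score_test_matches_logrank(self):
        # score statistic at beta=0 for a binary covariate equals the
        # log-rank chi-square when there are no tied event times
        from methylclass.survival import _cox_loglik
        rng = np.random.default_rng(12)
        n = 40
        t = rng.exponential(1, n)  # continuous -> no ties
        e = rng.integers(0, 2, n)
        g = rng.integers(0, 2, n).astype(float)
        if e.sum() == 0:
            e[0] = 1
        _, grad, info = _cox_loglik(np.zeros(1), t, e, g[:, None])
        score_stat = grad[0] ** 2 / info[0, 0]
        chi2, _ = logrank_test(t, e, g)
        assert score_stat == pytest.approx(chi2, abs=1e-6)

    def test_hr_and_hr_equals_exp_coef(self):
        rng = np.random.default_rng(13)
        n = 300
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / (0.05 * 3.0 ** x))
        fit = cox_ph_fit(t, np.ones(n, int), x)
        np.testing.assert_allclose(fit.hazard_ratios,
                                   np.exp(fit.coefficients))
        assert fit.hazard_ratios[0] == pytest.approx(3.0, rel=0.35)
        assert (fit.hazard_ratios > 0).all()

    def test_constant_covariate_errors(self):
        with pytest.raises(ValueError, match="constant"):
            cox_ph_fit([1, 2, 3], [1, 1, 1], np.ones(3))

    def test_no_events_errors(self):
        with pytest.raises(ValueError, match="no events"):
            cox_ph_fit([1, 2], [0, 0], np.array([0.0, 1.0]))

    def test_separation_flagged(self):
        # group 0 all events early, group 1 censored late: monotone
        t = np.array([1, 1.5, 2, 9, 10, 11], float)
        e = np.array([1, 1, 1, 0, 0, 0])
        x = np.array([0, 0, 0, 1, 1, 1], float)
        with pytest.warns(UserWarning, match="separation"):
            fit = cox_ph_fit(t, e, x)
        assert fit.separation


class TestRunSurvivalStage:
    @staticmethod
    def _cohort(hazard_ratio=4.0, seed=0, n=30):
        config = SimulationConfig(
            n_cpgs=400, subtype_sizes={"X": n, "Y": 10},
            n_signature_cpgs=20, n_undefined=8, n_outcome_cpgs=40,
            outcome=OutcomeConfig(baseline_hazard=0.02,
                                  hazard_ratio=hazard_ratio,
                                  censor_rate=0.5),
            seed=seed)
        return simulate_cohort(config)

    def test_planted_hazard_detected(self):
        # [DERIVED] methylation-linked HR=4 -> log-rank p < 0.01 for RFS
        beta, sheet, _ = self._cohort(hazard_ratio=4.0, seed=1, n=60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grouping, cox = run_survival_stage(beta, sheet, "X")
        assert grouping.logrank["rfs"][1] < 0.01
        assert "rfs" in cox
        assert (grouping.selected["p"] < 0.05).all()
        assert len(grouping.selected) <= 50

    def test_include_predicted_grows_groups(self):
        beta, sheet, _ = self._cohort(hazard_ratio=4.0, seed=2, n=60)
        undefined = sheet.data.loc[
            sheet.data["reported_subtype"] == "undefined", "sample_id"]
        predicted = {s: "X" for s in undefined}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            without, _ = run_survival_stage(beta, sheet, "X")
            with_pred, _ = run_survival_stage(
                beta, sheet, "X", include_predicted=True,
                predicted=predicted)
        assert len(with_pred.groups) > len(without.groups)
        assert set(without.groups) <= set(with_pred.groups)

    def test_exclusions_removed(self):
        beta, sheet, _ = self._cohort(hazard_ratio=4.0, seed=3, n=60)
        drop = sheet.data.loc[sheet.data["reported_subtype"] == "X",
                              "sample_id"].iloc[:2].tolist()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grouping, _ = run_survival_stage(beta, sheet, "X",
                                             exclusions=drop)
        assert not (set(drop) & set(grouping.groups))

    def test_km_curves_valid(self):
        beta, sheet, _ = self._cohort(hazard_ratio=4.0, seed=4, n=60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grouping, _ = run_survival_stage(beta, sheet, "X")
        for ep in ("rfs", "os"):
            for curve in grouping.km[ep].values():
                assert curve.loc[0, "survival"] == 1.0
                assert (np.diff(curve["survival"]) <= 1e-12).all()
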