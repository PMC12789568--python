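"""Triple-marker stratification, native KM/log-rank, relapse, Cox contract."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sttme.survival import (cox_multivariate, km_curve, km_logrank, logrank,
                            relapse_test, stratify)
from sttme.synthetic import simulate_cohort


def _cohort(times_a, times_b, events_a=None, events_b=None):
    na, nb = len(times_a), len(times_b)
    return pd.DataFrame({
        "efs_days": list(times_a) + list(times_b),
        "efs_event": (events_a or [1] * na) + (events_b or [1] * nb),
        "os_days": list(times_a) + list(times_b),
        "os_event": (events_a or [1] * na) + (events_b or [1] * nb),
        "relapse": [0] * (na + nb),
    }, index=[f"p{i}" for i in range(na + nb)])


class TestStratify:
    def test_identical_markers_put_everyone_in_other(self):
        co = pd.DataFrame({"CD68": 1.0, "CD163": 1.0, "CD40LG": 1.0},
                          index=[f"p{i}" for i in range(10)])
        res = stratify(co)
        assert (res.groups == "other").all()  # strict ">" fails at the median

    def test_explicit_cuts(self):
        co = pd.DataFrame({"CD68": [5.0, 1.0], "CD163": [5.0, 1.0],
                           "CD40LG": [0.5, 5.0]}, index=["hi", "lo"])
        res = stratify(co, cutpoints={"CD68": 2, "CD163": 2, "CD40LG": 1})
        assert res.groups["hi"] == "uncommon_TME"
        assert res.groups["lo"] == "other"
        assert res.cutpoints == {"CD68": 2, "CD163": 2, "CD40LG": 1}

    def test_recovers_planted_groups_across_seeds(self):
        accs = []
        for seed in range(20):
            co = simulate_cohort(120, group_fraction=0.5, seed=300 + seed)
            res = stratify(co.set_index("patient_id"),
                           cutpoints={"CD68": 0.0, "CD163": 0.0, "CD40LG": 0.0})
            accs.append((res.groups == co.set_index("patient_id")["group_true"]).mean())
        assert np.mean(accs) >= 0.99

    def test_missing_marker_excluded_with_warning(self):
        co = pd.DataFrame({"CD68": [1.0, np.nan], "CD163": [1.0, 1.0],
                           "CD40LG": [1.0, 1.0]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="missing a marker"):
            res = stratify(co)
        assert list(res.groups.index) == ["a"]


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, 50)
        curve = km_curve(times, np.ones(50, dtype=int))
        for _, row in curve.iterrows():
            empirical = (times > row["time"]).mean()
            assert row["survival"] == pytest.approx(empirical, abs=1e-12)

    def test_hand_computed_toy(self):
        curve = km_curve([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(curve["survival"], [2 / 3, 1 / 3, 0.0], atol=1e-12)
        np.testing.assert_allclose(curve["n_risk"], [3, 2, 1])

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(1)
        times = rng.exponential(10, 80)
        events = rng.random(80) < 0.7
        curve = km_curve(times, events.astype(int))
        kmf = KaplanMeierFitter().fit(times, events)
        for _, row in curve.iterrows():
            ref = float(kmf.survival_function_at_times(row["time"]).iloc[0])
            assert row["survival"] == pytest.approx(ref, abs=1e-9)


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        co = _cohort([1, 2, 3], [1, 2, 3])
        chi2, p = logrank(co["efs_days"], co["efs_event"], ["A"] * 3 + ["B"] * 3)
        assert chi2 == 0.0 and p == 1.0

    def test_separated_toy_matches_hand_calculation(self):
        # A={1,2,3}, B={4,5,6}, all events: O_A=3, E_A=sum(3/6,2/5,1/4)
        co = _cohort([1, 2, 3], [4, 5, 6])
        chi2, p = logrank(co["efs_days"], co["efs_event"], ["A"] * 3 + ["B"] * 3)
        e = 3 / 6 + 2 / 5 + 1 / 4
        v = (3 * 3 * (6 - 3) * (6 - 1) / (6 ** 2 * 5) / 3  # unrolled per time
             )
        # variance per event time: d*(n1/n)*(1-n1/n)*(n-d)/(n-1), d=1
        v = sum((n1 / n) * (1 - n1 / n) for n1, n in [(3, 6), (2, 5), (1, 4)])
        ref = (3 - e) ** 2 / v
        assert chi2 == pytest.approx(ref, rel=1e-12)
        assert p == pytest.approx(sps.chi2.sf(ref, 1), rel=1e-12)

    def test_matches_lifelines_with_ties_and_censoring(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(2)
        times = np.round(rng.exponential(5, 120)) + 1
        events = (rng.random(120) < 0.8).astype(int)
        groups = np.array(["A"] * 60 + ["B"] * 60)
        chi2, p = logrank(times, events, groups)
        ref = logrank_test(times[:60], times[60:], events[:60], events[60:])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_time_scaling_leaves_p_unchanged(self):
        co = _cohort([1, 3, 7, 9], [2, 4, 8, 16])
        g = ["A"] * 4 + ["B"] * 4
        _, p1 = logrank(co["efs_days"], co["efs_event"], g)
        _, p2 = logrank(co["efs_days"] * 2, co["efs_event"], g)
        assert p1 == p2


class TestKmLogrankApi:
    def test_group_curves_and_test(self):
        co = _cohort([1, 2, 3], [4, 5, 6])
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=co.index)
        curves, chi2, p = km_logrank(co, groups, "efs")
        assert set(curves) == {"A", "B"}
        assert chi2 > 0

    def test_bad_endpoint_rejected(self):
        co = _cohort([1], [2])
        with pytest.raises(ValueError, match="endpoint"):
            km_logrank(co, pd.Series(["A", "B"], index=co.index), "pfs")


class TestRelapse:
    def _co(self, relapse):
        co = _cohort(range(1, len(relapse) + 1), [])
        co["relapse"] = relapse
        return co

    def test_equal_rates_give_p_one(self):
        co = self._co([1, 0, 1, 0])
        groups = pd.Series(["A", "A", "B", "B"], index=co.index)
        _, p = relapse_test(co, groups)
        assert p == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        co = self._co([1] + [0] * 9 + [1] * 8 + [0] * 2)
        groups = pd.Series(["A"] * 10 + ["B"] * 10, index=co.index)
        table, p = relapse_test(co, groups)
        assert table.loc["A"].tolist() == [1, 9]
        assert table.loc["B"].tolist() == [8, 2]
        pmf = sps.hypergeom(20, 9, 10).pmf(np.arange(10))
        ref = pmf[pmf <= pmf[1] * (1 + 1e-9)].sum()
        assert p == pytest.approx(ref, abs=1e-12)

    def test_label_transposition_invariance(self):
        co = self._co([1, 1, 0, 0, 1, 0])
        g1 = pd.Series(["A", "A", "A", "B", "B", "B"], index=co.index)
        g2 = g1.map({"A": "B", "B": "A"})
        assert relapse_test(co, g1)[1] == pytest.approx(relapse_test(co, g2)[1])

    def test_zero_margin_warns_p_one(self):
        co = self._co([0, 0, 0, 0])
        groups = pd.Series(["A", "A", "B", "B"], index=co.index)
        with pytest.warns(UserWarning, match="degenerate"):
            _, p = relapse_test(co, groups)
        assert p == 1.0


class TestCox:
    def test_duplicating_patients_preserves_estimates(self):
        co = simulate_cohort(80, seed=5).set_index("patient_id")
        groups = pd.Series(np.where(co["group_true"] == "uncommon_TME",
                                    "uncommon_TME", "other"), index=co.index)
        fit1 = cox_multivariate(co, groups)
        doubled = pd.concat([co, co.set_axis([f"{i}_b" for i in co.index])])
        groups2 = pd.concat([groups, groups.set_axis([f"{i}_b" for i in groups.index])])
        fit2 = cox_multivariate(doubled, groups2)
        # duplication creates exact ties, so Efron tie handling perturbs the
        # partial likelihood slightly; the point estimate stays put
        assert fit1.loc[0, "hr"] == pytest.approx(fit2.loc[0, "hr"], rel=0.05)

    def test_recovers_generator_hazard_ratio(self):
        hits, estimates = 0, []
        for seed in range(15):
            co = simulate_cohort(500, hazard_ratio=0.5, group_fraction=0.5,
                                 seed=600 + seed).set_index("patient_id")
            groups = pd.Series(co["group_true"], index=co.index)
            hr = cox_multivariate(co, groups).set_index("term").loc["group_uncommon", "hr"]
            estimates.append(hr)
            hits += 0.4 <= hr <= 0.62
        assert hits >= 12
        assert 0.4 <= np.median(estimates) <= 0.62

    def test_null_covariate_ci_covers_one(self):
        covered = 0
        for seed in range(30):
            co = simulate_cohort(150, hazard_ratio=1.0, seed=900 + seed).set_index("patient_id")
            groups = pd.Series(co["group_true"], index=co.index)
            fit = cox_multivariate(co, groups).set_index("term")
            lo, hi = fit.loc["group_uncommon", ["hr_ci_low", "hr_ci_high"]]
            covered += lo <= 1.0 <= hi
        assert covered >= 24  # ~95% nominal coverage

    def test_constant_covariate_rejected(self):
        co = simulate_cohort(40, seed=6).set_index("patient_id")
        co["flat"] = 1.0
        groups = pd.Series(co["group_true"], index=co.index)
        with pytest.raises(ValueError, match="constant"):
            cox_multivariate(co, groups, covariates=["flat"])
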