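import itertools

import numpy as np
import pandas as pd
import pytest

from spatialtme.cohort_stats import (
    StatsError,
    administrative_censor,
    dichotomize_at_median,
    expression_ratio_survival,
    group_compare,
    km_curve,
    km_hazard,
    pearson_r2,
    sample_ratios,
)
from spatialtme.synthetic_data import simulate_expression_cohort


def exact_mw_p(x, y):
    """Full-enumeration two-sided Mann-Whitney oracle (no ties)."""
    combined = np.concatenate([x, y])
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    observed = u_stat(x, y)
    n = len(combined)
    us = []
    for idx in itertools.combinations(range(n), n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        us.append(u_stat(combined[mask], combined[~mask]))
    us = np.array(us)
    mu = len(x) * len(y) / 2
    return float((np.abs(us - mu) >= abs(observed - mu) - 1e-12).mean())


class TestGroupCompare:
    def test_exact_p_three_vs_three(self):
        stat, p = group_compare([1, 2, 3], [4, 5, 6])
        assert stat == 0.0
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 6, 2)
        pool = rng.permutation(20)[: n1 + n2].astype(float)  # distinct values
        x, y = pool[:n1], pool[n1:]
        _, p = group_compare(x, y)
        assert p == pytest.approx(exact_mw_p(x, y))

    def test_identical_groups_p_near_one(self):
        # ties force the asymptotic path; identical groups give p ~ 1
        _, p = group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.99

    def test_welch_contract(self):
        stat, p = group_compare([1.0, 2, 3], [1.0, 2, 3], method="welch_t")
        assert p == pytest.approx(1.0)
        with pytest.raises(StatsError):
            group_compare([1.0], [2.0, 3.0], method="welch_t")
        with pytest.raises(StatsError):
            group_compare([], [1.0])


class TestPearson:
    def test_perfect_linear(self):
        r, r2, p = pearson_r2(np.arange(10.0), 2 * np.arange(10.0))
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)
        assert p < 1e-6

    def test_hand_computed_half(self):
        r, r2, _ = pearson_r2([1.0, 2, 3], [1.0, 3, 2])
        assert r == pytest.approx(0.5)
        assert r2 == pytest.approx(0.25)

    def test_zero_variance_fatal(self):
        with pytest.raises(StatsError):
            pearson_r2([1.0, 1, 1], [1.0, 2, 3])

    def test_null_p_values_roughly_uniform(self, rng):
        # vectorized nulls: n=50 pairs, many reps; p should be U(0,1)
        from scipy import stats as ss

        reps, n = 1500, 50
        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        xc = x - x.mean(1, keepdims=True)
        yc = y - y.mean(1, keepdims=True)
        r = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * ss.t.sf(np.abs(t), df=n - 2)
        ks = ss.kstest(p, "uniform")
        assert ks.pvalue > 0.01


class TestDichotomize:
    def test_even_split(self):
        high = dichotomize_at_median(np.array([1.0, 2, 3, 4]))
        assert list(high) == [False, False, True, True]

    def test_ties_go_low(self):
        high = dichotomize_at_median(np.array([1.0, 2, 2, 3]))
        assert list(high) == [False, False, False, True]

    def test_all_equal_all_low(self):
        assert not dichotomize_at_median(np.array([2.0, 2, 2])).any()


class TestSampleRatios:
    def _pos(self, n_nos2, n_cd8, n=100):
        return pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(n)],
                "sample_id": "S1",
                "NOS2": [i < n_nos2 for i in range(n)],
                "CD8": [i < n_cd8 for i in range(n)],
            }
        )

    def test_simple_ratio(self):
        out = sample_ratios(self._pos(30, 10), ratios=(("NOS2", "CD8"),))
        assert out["ratio_NOS2_CD8"].iloc[0] == pytest.approx(3.0)
        assert out["ratio_NOS2_CD8_flag"].iloc[0] == "ok"

    def test_zero_denominator_flagged(self):
        out = sample_ratios(self._pos(30, 0), ratios=(("NOS2", "CD8"),))
        assert np.isinf(out["ratio_NOS2_CD8"].iloc[0])
        assert out["ratio_NOS2_CD8_flag"].iloc[0] == "zero_denominator"

    def test_counts_match_brute_force(self, rng):
        n = 1000
        pos = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(n)],
                "sample_id": rng.choice(["A", "B"], n),
                "NOS2": rng.random(n) < 0.2,
                "CD8": rng.random(n) < 0.3,
            }
        )
        out = sample_ratios(pos, ratios=(("NOS2", "CD8"),)).set_index("sample_id")
        for sid in ("A", "B"):
            sub = pos[pos["sample_id"] == sid]
            assert out.loc[sid, "n_NOS2"] == sub["NOS2"].sum()
            assert out.loc[sid, "ratio_NOS2_CD8"] == pytest.approx(
                sub["NOS2"].sum() / sub["CD8"].sum()
            )


class TestKaplanMeier:
    def test_km_equals_empirical_without_censoring(self, rng):
        t = rng.exponential(10, 200)
        curve = km_curve(t, np.ones(200, dtype=bool))
        for _, row in curve.iloc[1:].iterrows():
            emp = (t > row["time"]).mean()
            assert row["survival"] == pytest.approx(emp, abs=1e-12)

    def test_hand_built_oe_oracle(self):
        # A deaths {1,2,3}; B deaths {4,5,6}; no censoring.
        times = np.array([1.0, 2, 3, 4, 5, 6])
        events = np.ones(6, dtype=bool)
        groups = np.array(["A", "A", "A", "B", "B", "B"])
        res = km_hazard(times, events, groups, group_order=("A", "B"))
        # independent risk-set table, built by hand
        O1, E1, V = 0.0, 0.0, 0.0
        at_risk = [("A", 1.0), ("A", 2.0), ("A", 3.0), ("B", 4.0), ("B", 5.0), ("B", 6.0)]
        for t in (1.0, 2, 3, 4, 5, 6):
            risk = [(g, tt) for g, tt in at_risk if tt >= t]
            n = len(risk)
            n1 = sum(1 for g, _ in risk if g == "A")
            d1 = sum(1 for g, tt in risk if tt == t and g == "A")
            O1 += d1
            E1 += n1 / n
            V += (n1 / n) * (1 - n1 / n) * (n - 1) / max(n - 1, 1)
        O2, E2 = 3.0 - O1 + 3.0 - 0.0 - (3.0 - O1), 6.0 - E1  # O2 = 3
        expected_hr = (O1 / E1) / (3.0 / E2)
        assert res.hr == pytest.approx(expected_hr, abs=1e-10)
        assert res.hr == pytest.approx(4.217391304347826, abs=1e-9)
        assert res.o_e["E1"] == pytest.approx(E1, abs=1e-10)

    def test_cross_check_against_lifelines(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(0)
        t1 = rng.exponential(20, 60)
        t2 = rng.exponential(10, 50)
        e1 = rng.random(60) < 0.8
        e2 = rng.random(50) < 0.8
        res = km_hazard(
            np.concatenate([t1, t2]),
            np.concatenate([e1, e2]),
            np.array(["A"] * 60 + ["B"] * 50),
            group_order=("A", "B"),
        )
        lr = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
        assert res.p_logrank == pytest.approx(lr.p_value, rel=1e-6)
        gbw = logrank_test(
            t1, t2, event_observed_A=e1, event_observed_B=e2, weightings="wilcoxon"
        )
        assert res.p_gbw == pytest.approx(gbw.p_value, rel=1e-6)

    def test_km_curve_cross_check_against_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(10, 100)
        e = rng.random(100) < 0.7
        curve = km_curve(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for _, row in curve.iterrows():
            assert row["survival"] == pytest.approx(
                float(kmf.predict(row["time"])), abs=1e-9
            )

    def test_identical_groups_hr_one(self):
        t = np.array([1.0, 2, 3, 1.0, 2, 3])
        e = np.ones(6, dtype=bool)
        g = np.array(["A"] * 3 + ["B"] * 3)
        res = km_hazard(t, e, g, group_order=("A", "B"))
        assert res.hr == pytest.approx(1.0)
        assert res.p_logrank == pytest.approx(1.0)

    def test_group_swap_inverts_hr(self, rng):
        t = rng.exponential(10, 80)
        e = rng.random(80) < 0.8
        g = np.where(rng.random(80) < 0.5, "A", "B")
        r1 = km_hazard(t, e, g, group_order=("A", "B"))
        r2 = km_hazard(t, e, g, group_order=("B", "A"))
        assert r1.hr == pytest.approx(1.0 / r2.hr, rel=1e-12)

    def test_time_rescaling_invariance(self, rng):
        t = rng.exponential(10, 80)
        e = rng.random(80) < 0.7
        g = np.where(rng.random(80) < 0.5, "A", "B")
        r1 = km_hazard(t, e, g, group_order=("A", "B"))
        r2 = km_hazard(t * 12.0, e, g, group_order=("A", "B"))
        assert r1.hr == pytest.approx(r2.hr, rel=1e-12)
        assert r1.p_logrank == pytest.approx(r2.p_logrank, rel=1e-12)

    def test_contract_errors(self):
        with pytest.raises(StatsError):
            km_hazard(np.array([1.0]), np.array([True]), np.array(["A"]))
        res = km_hazard(
            np.array([1.0, 2.0]),
            np.array([False, False]),
            np.array(["A", "B"]),
            group_order=("A", "B"),
        )
        assert res.flag == "no_events" and np.isnan(res.hr)

    def test_administrative_censoring(self):
        t, e = administrative_censor(
            np.array([10.0, 70.0]), np.array([True, True]), 60.0
        )
        assert list(t) == [10.0, 60.0]
        assert list(e) == [True, False]


class TestExpressionRatioSurvival:
    def test_planted_hr_recovered(self):
        expr, clin = simulate_expression_cohort(n=400, true_hr=4.0, seed=11)
        res = expression_ratio_survival(expr, clin, "NOS2", "CD8A", horizon_months=60.0)
        assert res.groups == ("high", "low")
        assert 2.5 < res.hr < 6.5
        assert res.ci[0] <= 4.0 <= res.ci[1]

    def test_null_ratio_hr_near_one(self):
        covered = 0
        for seed in range(5):
            expr, clin = simulate_expression_cohort(n=300, true_hr=1.0, seed=seed)
            res = expression_ratio_survival(expr, clin, "NOS2", "CD8A")
            covered += res.ci[0] <= 1.0 <= res.ci[1]
        assert covered >= 4

    def test_degenerate_ratios_raise(self):
        expr, clin = simulate_expression_cohort(n=30, true_hr=2.0, seed=0)
        expr.loc["NOS2"] = expr.loc["CD8A"]
        with pytest.raises(StatsError, match="degenerate"):
            expression_ratio_survival(expr, clin, "NOS2", "CD8A")

    def test_nonpositive_denominator_dropped(self):
        expr, clin = simulate_expression_cohort(n=30, true_hr=2.0, seed=1)
        expr.iloc[1, 0] = 0.0
        with pytest.warns(UserWarning, match="non-positive"):
            expression_ratio_survival(expr, clin, "NOS2", "CD8A")
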