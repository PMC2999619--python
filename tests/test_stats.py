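import math

import numpy as np
import pandas as pd
import pytest

from ihcscore.stats import (
    build_table1,
    contingency_test,
    cox_fit,
    format_p,
    km_estimate,
    logrank_test,
    spearman_rho,
)
from ihcscore.synthetic.cohort import COVARIATE_LEVELS, CohortSimConfig, generate_cohort

# Published 2x2 association tables (rows = ratio-group low/high) and the
# p-values they print at 3-decimal rounding.
PRINTED_TABLES = {
    "er_by_cnr": ([[53, 143], [28, 130]], 0.038),
    "grade_by_cnr": ([[119, 79], [118, 42]], 0.007),
    "grade_by_snas": ([[145, 55], [92, 66]], 0.005),
    "her2_by_cnr": ([[149, 47], [136, 22]], 0.018),
    "ki67_by_snas": ([[82, 105], [46, 106]], 0.010),
}


class TestContingencyTest:
    @pytest.mark.parametrize("name", sorted(PRINTED_TABLES))
    def test_printed_p_values_reproduced(self, name):
        table, expected_p = PRINTED_TABLES[name]
        res = contingency_test(table)
        assert round(res.p, 3) == expected_p

    def test_ki67_by_cnr_below_point_001(self):
        res = contingency_test([[55, 133], [73, 78]])
        assert res.p < 0.001
        assert format_p(res.p) == "<0.001"

    def test_independent_table_gives_zero_statistic(self):
        res = contingency_test([[10, 20], [30, 60]])
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_df_is_one(self):
        assert contingency_test([[5, 10], [12, 7]]).df == 1

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            contingency_test([[0, 0], [5, 10]])

    def test_negative_count_raises(self):
        with pytest.raises(ValueError):
            contingency_test([[-1, 5], [5, 10]])

    def test_matches_hand_formula(self):
        """Pearson statistic recomputed from the definitional sum."""
        table = np.array([[53.0, 143.0], [28.0, 130.0]])
        n = table.sum()
        expected = np.outer(table.sum(1), table.sum(0)) / n
        chi2 = ((table - expected) ** 2 / expected).sum()
        assert contingency_test(table).chi_square == pytest.approx(chi2)


class TestBuildTable1:
    @pytest.fixture(scope="class")
    @staticmethod
    def cohort():
        cfg = CohortSimConfig(n_patients=400, assoc_logodds={"er": 0.9}, seed=21)
        patients, _ = generate_cohort(cfg)
        patients["cnr_group"] = np.where(patients.cnr > 5.0, "high", "low")
        return patients

    def test_planted_dependence_recovered(self, cohort):
        t1 = build_table1(cohort, "cnr_group", dict(COVARIATE_LEVELS))
        p = t1.loc[t1.covariate == "er", "p"].iloc[0]
        assert p < 0.05

    def test_counts_account_for_cohort(self, cohort):
        t1 = build_table1(cohort, "cnr_group", dict(COVARIATE_LEVELS))
        for cov in COVARIATE_LEVELS:
            block = t1[(t1.covariate == cov) & (t1.level != "Unknown")]
            total = block[["n_high", "n_low"]].to_numpy().sum()
            unknowns = int(cohort[cov].isna().sum())
            assert total == len(cohort) - unknowns

    def test_percentages_recompute_from_counts(self, cohort):
        t1 = build_table1(cohort, "cnr_group", dict(COVARIATE_LEVELS))
        block = t1[(t1.covariate == "grade") & (t1.level != "Unknown")]
        col_total = block["n_low"].sum()
        for _, row in block.iterrows():
            assert row["pct_low"] == pytest.approx(
                round(100.0 * row["n_low"] / col_total, 1))

    def test_printed_percentage_convention(self):
        # 53 of 196 -> 27.0 at one decimal
        assert round(100.0 * 53 / 196, 1) == 27.0

    def test_single_level_stratifier_raises(self, cohort):
        bad = cohort.assign(cnr_group="low")
        with pytest.raises(ValueError, match="2 levels"):
            build_table1(bad, "cnr_group", dict(COVARIATE_LEVELS))


class TestKmEstimate:
    def test_toy_hand_computation(self):
        """times (1,2,3,4), events (1,1,0,1): S = 3/4, 1/2 then 0 at t=4."""
        curves = km_estimate([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 1], ["a"] * 4)
        s = curves["a"]
        surv = dict(zip(s.times, s.survival))
        assert surv[1.0] == pytest.approx(3 / 4)
        assert surv[2.0] == pytest.approx(3 / 4 * 2 / 3)
        assert surv[4.0] == pytest.approx(0.0)

    def test_no_censoring_reduces_to_empirical_fraction(self, rng):
        times = rng.exponential(10, 40).round(2)
        curves = km_estimate(times, np.ones(40), ["g"] * 40)
        c = curves["g"]
        for t, s in zip(c.times, c.survival):
            if t > 0:
                assert s == pytest.approx((times > t).mean())

    def test_curve_starts_at_one_and_non_increasing(self, rng):
        times = rng.exponential(10, 50)
        events = rng.random(50) < 0.6
        c = km_estimate(times, events, ["g"] * 50)["g"]
        assert c.survival[0] <= 1.0 + 1e-12
        assert (np.diff(c.survival) <= 1e-12).all()

    def test_negative_times_raise(self):
        with pytest.raises(ValueError, match="negative"):
            km_estimate([-1.0, 2.0], [1, 1], ["a", "a"])


class TestLogrankTest:
    def test_identical_groups(self):
        t = [1.0, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 0, 1, 1, 1, 0, 1]
        g = ["a"] * 4 + ["b"] * 4
        stat, p = logrank_test(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_toy_eight_subjects_hand_computation(self):
        """O-E and variance sums accumulated by hand over pooled event times."""
        times = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        events = np.array([1, 1, 1, 1, 1, 0, 1, 0], dtype=bool)
        groups = np.array(["a", "b", "a", "b", "a", "b", "a", "b"])
        o_minus_e = 0.0
        var = 0.0
        for t in np.unique(times[events]):
            at_risk = times >= t
            n, n_a = at_risk.sum(), (at_risk & (groups == "a")).sum()
            d = (events & (times == t)).sum()
            d_a = (events & (times == t) & (groups == "a")).sum()
            o_minus_e += d_a - d * n_a / n
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / max(n - 1, 1)
        expected = o_minus_e**2 / var
        stat, _ = logrank_test(times, events, groups)
        assert stat == pytest.approx(expected, rel=1e-9)

    def test_group_label_swap_invariance(self, rng):
        t = rng.exponential(5, 30)
        e = rng.random(30) < 0.7
        g = np.where(rng.random(30) < 0.5, "x", "y")
        stat1, _ = logrank_test(t, e, g)
        stat2, _ = logrank_test(t, e, np.where(g == "x", "y", "x"))
        assert stat1 == pytest.approx(stat2)

    def test_single_group_raises(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test([1.0, 2.0], [1, 1], ["a", "a"])


def brute_force_cox_beta(times, events, x, grid):
    """Grid maximisation of the written Cox partial likelihood (no ties)."""
    order = np.argsort(times)
    t, e, xv = times[order], events[order], x[order]

    def log_pl(beta):
        ll = 0.0
        for i in range(len(t)):
            if e[i]:
                risk_set = xv[i:]
                ll += beta * xv[i] - math.log(np.exp(beta * risk_set).sum())
        return ll

    vals = [log_pl(b) for b in grid]
    return grid[int(np.argmax(vals))]


class TestCoxFit:
    def test_matches_partial_likelihood_grid_search(self, rng):
        n = 40
        x = (rng.random(n) < 0.5).astype(float)
        times = rng.exponential(10 * np.exp(-0.8 * x))
        times = np.round(times, 6)  # distinct to machine precision: no ties
        events = np.ones(n, dtype=bool)
        df = pd.DataFrame({"grp": x, "bcss_time": times, "bcss_event": events})
        res = cox_fit(df, ["grp"], outcome="bcss")["grp"]
        grid = np.linspace(-3, 3, 1201)
        beta_hat = brute_force_cox_beta(times, events, x, grid)
        assert res.estimates.iloc[0].coef == pytest.approx(beta_hat, abs=0.01)

    def test_hr_recovery_and_ci_coverage(self):
        """Scaled-down HR-0.47 recovery (30 replicates; the 200-replicate
        version lives in the acceptance suite)."""
        hrs, covered = [], 0
        for seed in range(30):
            cfg = CohortSimConfig(n_patients=359,
                                  log_hr={"cnr_high": math.log(0.47)}, seed=seed)
            patients, _ = generate_cohort(cfg)
            est = cox_fit(patients, ["cnr_high"], outcome="bcss")["cnr_high"].estimates.iloc[0]
            hrs.append(est.hazard_ratio)
            covered += est.ci_low <= 0.47 <= est.ci_high
        assert 0.40 <= np.mean(hrs) <= 0.54
        assert covered / 30 >= 0.8

    def test_sign_agrees_with_km_ordering(self):
        cfg = CohortSimConfig(n_patients=400, log_hr={"cnr_high": math.log(0.3)}, seed=8)
        patients, _ = generate_cohort(cfg)
        est = cox_fit(patients, ["cnr_high"], outcome="bcss")["cnr_high"].estimates.iloc[0]
        assert est.coef < 0
        curves = km_estimate(patients.bcss_time, patients.bcss_event,
                             np.where(patients.cnr_high, "high", "low"))
        # protective group keeps higher survival at its last observed time
        assert curves["high"].survival[-1] > curves["low"].survival[-1]

    def test_multivariate_joint_model(self):
        cfg = CohortSimConfig(n_patients=400, log_hr={"cnr_high": math.log(0.4)}, seed=8)
        patients, _ = generate_cohort(cfg)
        patients["cnr_high"] = patients.cnr_high.astype(bool)
        res = cox_fit(patients, ["cnr_high", "grade", "nodal", "er"],
                      outcome="bcss", multivariate=True)
        assert len(res.estimates) == 4
        assert res.converged
        res.validate()

    def test_constant_covariate_error_names_it(self):
        cfg = CohortSimConfig(n_patients=100, seed=1)
        patients, _ = generate_cohort(cfg)
        patients["flat"] = 1.0
        with pytest.raises(ValueError, match="flat"):
            cox_fit(patients, ["flat"], outcome="bcss")

    def test_too_few_events_raises(self):
        cfg = CohortSimConfig(n_patients=60, baseline_hazard=0.00001,
                              other_cause_rate=0.0, seed=1)
        patients, _ = generate_cohort(cfg)
        with pytest.raises(ValueError, match="events"):
            cox_fit(patients, ["cnr_high"], outcome="bcss")

    def test_subgroup_filter(self):
        cfg = CohortSimConfig(n_patients=500, log_hr={"cnr_high": math.log(0.4)}, seed=2)
        patients, _ = generate_cohort(cfg)
        sub = patients.er == ">=10%"
        res = cox_fit(patients, ["cnr_high"], outcome="bcss", subgroup=sub)["cnr_high"]
        assert res.n == int(sub.sum())


class TestSpearman:
    def test_perfect_monotone(self):
        res = spearman_rho([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert res.rho == pytest.approx(1.0)

    def test_constant_input_flagged(self):
        res = spearman_rho([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])
        assert not res.defined
        assert math.isnan(res.rho)

    def test_too_few_pairs_raise(self):
        with pytest.raises(ValueError, match="complete pairs"):
            spearman_rho([1, 2, 3], [1, 2, 3])

    def test_seven_point_toy_matches_rank_formula(self, rng):
        from test_scoring import brute_force_spearman

        x = rng.uniform(0, 1, 7)
        y = x + rng.normal(0, 0.3, 7)
        res = spearman_rho(x, y)
        assert res.rho == pytest.approx(brute_force_spearman(x, y), rel=1e-9)

    def test_nan_pairs_dropped(self):
        x = [1, 2, 3, 4, 5, np.nan]
        y = [2, 4, 6, 8, 10, 1]
        res = spearman_rho(x, y)
        assert res.n == 5
        assert res.rho == pytest.approx(1.0)


class TestFormatP:
    @pytest.mark.parametrize("p,text", [
        (0.038, "0.038"), (0.0004, "<0.001"), (0.4999, "0.500"), (float("nan"), "NA"),
    ])
    def test_formatting(self, p, text):
        assert format_p(p) == text
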