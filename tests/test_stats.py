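"""Tests of the diagnostic statistics: comparisons, regressions, ROC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from lungdens import stats as ld


def _table(control_vals, bo_vals, var="x"):
    rows = [{"subject_id": f"c{i}", "group": "control", var: v} for i, v in enumerate(control_vals)]
    rows += [{"subject_id": f"b{i}", "group": "BO", var: v} for i, v in enumerate(bo_vals)]
    return pd.DataFrame(rows)


def _cohort_frame(rng, n, beta_x=0.0, logistic=False, log_or=0.0):
    age = rng.uniform(4, 18, n)
    sex = rng.choice(["male", "female"], n)
    x = rng.normal(0, 10, n)
    male = (sex == "male").astype(float)
    if logistic:
        eta = log_or * x + 0.02 * (age - 11) + 0.1 * (male - 0.5)
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        group = np.where(y, "BO", "control")
        return pd.DataFrame(
            {"subject_id": np.arange(n).astype(str), "group": group,
             "age_years": age, "sex": sex, "x": x}
        )
    y = beta_x * x + 2.0 * age + 3.0 * male + rng.normal(0, 5, n)
    return pd.DataFrame(
        {"subject_id": np.arange(n).astype(str), "group": "control",
         "age_years": age, "sex": sex, "x": x, "y": y}
    )


class TestCompareGroups:
    def test_exact_mann_whitney_small_sample(self):
        """{1,2,3} vs {4,5,6}: two-sided exact p = 2/20 = 0.1."""
        cmp = ld.compare_groups(_table([1, 2, 3], [4, 5, 6]), "x")
        assert cmp.test == "mann-whitney"
        assert cmp.p_value == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        cmp = ld.compare_groups(_table([1, 2, 3, 4], [1, 2, 3, 4]), "x")
        assert cmp.p_value == pytest.approx(1.0, abs=1e-6)

    def test_chi_square_with_continuity_correction(self):
        """18/12 vs 32/19 male/female split: p = 0.993 with Yates correction."""
        sex = ["male"] * 18 + ["female"] * 12 + ["male"] * 32 + ["female"] * 19
        group = ["control"] * 30 + ["BO"] * 51
        df = pd.DataFrame({"group": group, "x": sex})
        cmp = ld.compare_groups(df, "x")
        assert cmp.test == "chi-square"
        assert cmp.p_value == pytest.approx(0.993, abs=5e-4)

    def test_all_missing_variable_errors(self):
        df = _table([1, 2, 3], [4, 5, 6])
        df["x"] = np.nan
        with pytest.raises(ValueError):
            ld.compare_groups(df, "x")


class TestSpearman:
    def test_monotone_and_reversed(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4], "b": [10, 20, 25, 70], "c": [5, 4, 3, 1]})
        assert ld.spearman_rho(df, "a", "b")[0] == pytest.approx(1.0)
        assert ld.spearman_rho(df, "a", "c")[0] == pytest.approx(-1.0)

    def test_matches_brute_force_with_ties(self):
        xs = [3.0, 1.0, 4.0, 1.0, 5.0]
        ys = [2.0, 7.0, 1.0, 8.0, 1.0]
        df = pd.DataFrame({"a": xs, "b": ys})
        rho, _, n = ld.spearman_rho(df, "a", "b")
        assert n == 5
        assert rho == pytest.approx(oracles.brute_spearman(xs, ys))

    def test_too_few_pairs_errors(self):
        df = pd.DataFrame({"a": [1, 2, np.nan], "b": [1, np.nan, 3]})
        with pytest.raises(ValueError, match="pairs"):
            ld.spearman_rho(df, "a", "b")


class TestLinearFit:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(0)
        df = _cohort_frame(rng, 60, beta_x=0.5)
        male = (df["sex"] == "male").astype(float)
        df["y"] = 0.5 * df["x"] + 2.0 * df["age_years"] + 3.0 * male  # no noise
        (res,) = ld.adjusted_linear_fit(df, "y", ["x"], "univariate")
        assert res.estimate == pytest.approx(0.5, abs=1e-8)
        assert res.ci_low == res.ci_high == pytest.approx(res.estimate)

    def test_planted_coefficient_recovered(self):
        rng = np.random.default_rng(1)
        df = _cohort_frame(rng, 500, beta_x=0.5)
        (res,) = ld.adjusted_linear_fit(df, "y", ["x"], "univariate")
        se = (res.ci_high - res.ci_low) / (2 * 1.96)
        assert res.estimate == pytest.approx(0.5, abs=3 * se)
        assert res.covariates == ("age_years", "sex")

    def test_backward_elimination_controls_type_i(self):
        """Pure-noise predictors are almost never retained at stay p<0.05.

        With two independent noise predictors the familywise retention
        probability is about 1-(0.95)^2 ~ 0.10; assert the empirical rate
        stays within 3 binomial SEs of that bound.
        """
        rng = np.random.default_rng(2)
        retained = 0
        n_rep = 150
        for _ in range(n_rep):
            df = _cohort_frame(rng, 120)
            df["z1"] = rng.normal(size=120)
            df["z2"] = rng.normal(size=120)
            res = ld.adjusted_linear_fit(df, "y", ["z1", "z2"], "backward")
            retained += bool(res)
        bound = 0.0975 + 3 * np.sqrt(0.0975 * 0.9025 / n_rep)
        assert retained / n_rep <= bound

    def test_all_subset_finds_true_model(self):
        rng = np.random.default_rng(3)
        df = _cohort_frame(rng, 300, beta_x=2.0)
        df["noise1"] = rng.normal(size=300)
        res = ld.adjusted_linear_fit(df, "y", ["x", "noise1"], "all_subset")
        assert any(r.predictor == "x" for r in res)

    def test_collinear_design_names_offenders(self):
        rng = np.random.default_rng(4)
        df = _cohort_frame(rng, 50, beta_x=1.0)
        df["x_twin"] = 2.0 * df["x"]
        with pytest.raises(ld.RankDeficiencyError, match="x_twin"):
            ld.adjusted_linear_fit(df, "y", ["x", "x_twin"], "backward")


class TestLogisticOr:
    def test_null_predictor_or_near_one(self):
        rng = np.random.default_rng(5)
        df = _cohort_frame(rng, 2000, logistic=True, log_or=0.0)
        res = ld.adjusted_logistic_or(df, "x")
        assert res.ci_low <= 1.0 <= res.ci_high
        assert res.scale == "odds_ratio"

    def test_planted_log_odds_recovered(self):
        rng = np.random.default_rng(6)
        df = _cohort_frame(rng, 1000, logistic=True, log_or=0.05)
        res = ld.adjusted_logistic_or(df, "x")
        log_or = np.log(res.estimate)
        se = (np.log(res.ci_high) - np.log(res.ci_low)) / (2 * 1.959964)
        assert log_or == pytest.approx(0.05, abs=3 * se)

    def test_perfect_separation_diagnosed(self):
        df = pd.DataFrame(
            {
                "subject_id": [str(i) for i in range(24)],
                "group": ["control"] * 12 + ["BO"] * 12,
                "age_years": np.tile(np.arange(12), 2),
                "sex": ["male", "female"] * 12,
                "x": np.r_[np.arange(12), np.arange(12) + 100.0],
            }
        )
        with pytest.raises(ld.SeparationError):
            ld.adjusted_logistic_or(df, "x")


class TestRoc:
    def test_perfect_separation_auc_one(self):
        df = _table([1, 2, 3, 4], [10, 11, 12, 13])
        r = ld.roc_analysis(df, "x")
        assert r.auc == 1.0
        assert r.sensitivity == 100.0 and r.specificity == 100.0
        assert r.orientation == ld.Orientation.HIGHER_INDICATES_BO

    def test_orientation_flips_for_protective_marker(self):
        df = _table([10, 11, 12, 13], [1, 2, 3, 4])
        r = ld.roc_analysis(df, "x")
        assert r.orientation == ld.Orientation.LOWER_INDICATES_BO
        assert r.auc == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_auc_equals_pair_counting_and_trapezoid(self, seed):
        rng = np.random.default_rng(seed)
        n1, n0 = rng.integers(3, 12, 2)
        pos = rng.choice(np.arange(20), n1).astype(float)
        neg = rng.choice(np.arange(20), n0).astype(float)
        auc = ld.auc_mann_whitney(pos, neg)
        assert auc == pytest.approx(oracles.brute_auc(pos.tolist(), neg.tolist()))
        from sklearn.metrics import roc_auc_score

        y = np.r_[np.ones(n1), np.zeros(n0)]
        assert auc == pytest.approx(roc_auc_score(y, np.r_[pos, neg]))

    @pytest.mark.parametrize("seed", range(10))
    def test_youden_cutoff_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(100 + seed)
        pos = rng.normal(2, 1.5, rng.integers(5, 25)).round(1)
        neg = rng.normal(0, 1.5, rng.integers(5, 25)).round(1)
        df = _table(neg.tolist(), pos.tolist())
        r = ld.roc_analysis(df, "x")
        higher = r.orientation == ld.Orientation.HIGHER_INDICATES_BO
        cut, tp, fp, fn, tn = oracles.brute_youden(pos.tolist(), neg.tolist(), higher)
        assert r.cutoff == pytest.approx(cut)
        assert (r.tp, r.fp, r.fn, r.tn) == (tp, fp, fn, tn)
        assert r.tp + r.fp + r.fn + r.tn == r.n_used

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        pos = rng.normal(1, 1, 30)
        neg = rng.normal(0, 1, 20)
        df1 = _table(neg.tolist(), pos.tolist())
        df2 = _table(np.exp(neg).tolist(), np.exp(pos).tolist())
        r1, r2 = ld.roc_analysis(df1, "x"), ld.roc_analysis(df2, "x")
        assert r1.auc == pytest.approx(r2.auc)
        assert (r1.tp, r1.fp, r1.fn, r1.tn) == (r2.tp, r2.fp, r2.fn, r2.tn)
        assert r2.cutoff == pytest.approx(np.exp(r1.cutoff))

    def test_delong_ci_brackets_auc_and_covers_truth(self):
        rng = np.random.default_rng(8)
        pos = rng.normal(1.0, 1.0, 200)
        neg = rng.normal(0.0, 1.0, 200)
        auc, lo, hi = ld.delong_auc_ci(pos, neg)
        assert lo <= auc <= hi
        from scipy.stats import norm

        truth = norm.cdf(1.0 / np.sqrt(2.0))
        assert lo - 0.02 <= truth <= hi + 0.02
        assert hi - lo < 0.2

    def test_bootstrap_ci_is_seeded_and_close_to_delong(self):
        df = _table(list(range(20)), [v + 3.0 for v in range(20)])
        r1 = ld.roc_analysis(df, "x", ci_method="bootstrap", n_bootstrap=400, seed=3)
        r2 = ld.roc_analysis(df, "x", ci_method="bootstrap", n_bootstrap=400, seed=3)
        assert r1.auc_ci == r2.auc_ci
        rd = ld.roc_analysis(df, "x")
        assert r1.auc == pytest.approx(rd.auc)

    def test_single_class_errors(self):
        df = _table([1, 2, 3], [])
        with pytest.raises(ValueError):
            ld.roc_analysis(df, "x")

    def test_constant_score_errors(self):
        df = _table([1, 1], [1, 1])
        with pytest.raises(ValueError, match="distinct"):
            ld.roc_analysis(df, "x")


class TestDiagnosticMetrics:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((28, 3, 1, 16), (96.6, 84.2, 90.3, 94.1)),
            ((23, 0, 6, 19), (79.3, 100.0, 100.0, 76.0)),
            ((25, 4, 4, 15), (86.2, 78.9, 86.2, 78.9)),
        ],
    )
    def test_division_examples(self, counts, expected):
        m = ld.diagnostic_metrics(*counts)
        assert (
            round(m.sensitivity, 1),
            round(m.specificity, 1),
            round(m.ppv, 1),
            round(m.npv, 1),
        ) == expected

    def test_zero_margins_flagged_not_numeric(self):
        m = ld.diagnostic_metrics(0, 0, 0, 10)
        assert m.sensitivity is None and "sensitivity" in m.undefined
        assert m.ppv is None and "ppv" in m.undefined
        assert m.specificity == 100.0 and m.npv == 100.0

    @settings(derandomize=True, max_examples=50)
    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        fn=st.integers(0, 50), tn=st.integers(0, 50),
        k=st.integers(1, 7),
    )
    def test_scale_invariance(self, tp, fp, fn, tn, k):
        a = ld.diagnostic_metrics(tp, fp, fn, tn)
        b = ld.diagnostic_metrics(k * tp, k * fp, k * fn, k * tn)
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            va, vb = getattr(a, name), getattr(b, name)
            assert (va is None) == (vb is None)
            if va is not None:
                assert va == pytest.approx(vb)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ld.diagnostic_metrics(-1, 0, 0, 0)
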