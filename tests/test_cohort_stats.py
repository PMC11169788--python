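"""Inference layer: tertiles, trends, correlations, stepwise, mediation,
mixed models, Holm, logistic fit, power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmrquant import cohort_stats as cs
from cmrquant import synthetic
from cmrquant.exceptions import (
    DegenerateDesignError,
    InvalidParameterError,
    SeparationError,
)


class TestTertiles:
    def test_hand_quantiles_one_to_nine(self):
        strat = cs.tertile_stratify(np.arange(1.0, 10.0))
        assert strat.boundaries == pytest.approx((11 / 3, 19 / 3))
        counts = strat.counts()
        assert counts == {"lower": 3, "middle": 3, "upper": 3}
        assert list(strat.labels[:3]) == ["lower"] * 3

    def test_all_equal_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            cs.tertile_stratify(np.full(30, 5.0))

    def test_balanced_groups_on_continuous_sample(self, rng):
        strat = cs.tertile_stratify(rng.normal(46, 10, 89))
        counts = strat.counts()
        assert max(counts.values()) - min(counts.values()) <= 2

    def test_missing_values_excluded(self):
        vals = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, np.nan])
        strat = cs.tertile_stratify(vals)
        assert strat.n_missing == 1
        assert strat.labels.isna().sum() == 1


class TestTrendTest:
    def test_flat_outcome_null(self):
        labels = ["lower"] * 10 + ["middle"] * 10 + ["upper"] * 10
        res = cs.linear_trend_test(np.ones(30), labels)
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.99

    def test_perfect_trend(self):
        labels = ["lower"] * 30 + ["middle"] * 30 + ["upper"] * 30
        outcome = np.repeat([1.0, 2.0, 3.0], 30)
        res = cs.linear_trend_test(outcome, labels)
        assert res.slope == pytest.approx(1.0)
        assert res.p_value < 1e-12

    def test_declining_mbf_power_at_cohort_scale(self, rng):
        # group means 0.97/0.85/0.81, sd 0.2, n = 27/32/30: the trend is
        # detected in the majority of replicates
        labels = ["lower"] * 27 + ["middle"] * 32 + ["upper"] * 30
        means = np.concatenate([np.full(27, 0.97), np.full(32, 0.85), np.full(30, 0.81)])
        pvals = [
            cs.linear_trend_test(means + rng.normal(0, 0.2, 89), labels).p_value
            for _ in range(200)
        ]
        assert np.median(pvals) < 0.05


class TestPearson:
    def test_self_and_anticorrelation(self):
        x = np.linspace(0, 1, 20)
        df = pd.DataFrame({"x": x, "y": -x, "z": x**2})
        r, p, n = cs.pearson_matrix(df, ["x", "y", "z"])
        assert r.loc["x", "x"] == 1.0
        assert r.loc["x", "y"] == pytest.approx(-1.0)
        assert p.loc["x", "y"] < 1e-12

    def test_known_correlation_recovered_in_mean(self, rng):
        target, n_rep = 0.42, 300
        rhat = []
        for _ in range(n_rep):
            x = rng.standard_normal(92)
            y = target * x + np.sqrt(1 - target**2) * rng.standard_normal(92)
            df = pd.DataFrame({"x": x, "y": y})
            r, _, _ = cs.pearson_matrix(df, ["x", "y"])
            rhat.append(r.loc["x", "y"])
        assert np.mean(rhat) == pytest.approx(target, abs=0.03)

    def test_insufficient_pairs_marked_missing(self):
        df = pd.DataFrame({"x": [1.0, 2.0, np.nan, np.nan], "y": [np.nan, np.nan, 1.0, 2.0]})
        r, _, n = cs.pearson_matrix(df, ["x", "y"])
        assert np.isnan(r.loc["x", "y"])
        assert n.loc["x", "y"] == 0


class TestStepwiseAic:
    def test_empty_candidates_returns_forced_model(self, rng):
        df = pd.DataFrame(
            {"y": rng.standard_normal(50), "age": rng.standard_normal(50)}
        )
        res = cs.stepwise_aic(df, "y", candidates=[], forced=["age"])
        assert res.selected == []
        assert "age" in res.params.index

    def test_strong_predictor_selected(self, rng):
        hits = 0
        for _ in range(100):
            x = rng.standard_normal((200, 6))
            y = 1.0 * x[:, 0] + rng.standard_normal(200)
            df = pd.DataFrame(x, columns=[f"v{i}" for i in range(6)])
            df["y"] = y
            res = cs.stepwise_aic(df, "y", candidates=[f"v{i}" for i in range(6)])
            hits += "v0" in res.selected
        assert hits >= 95

    def test_noise_candidates_rarely_selected(self, rng):
        # AIC's known liberality: per-candidate false-inclusion stays modest
        n_rep, n_cand, included = 100, 5, 0
        for _ in range(n_rep):
            x = rng.standard_normal((500, n_cand))
            df = pd.DataFrame(x, columns=[f"v{i}" for i in range(n_cand)])
            df["y"] = rng.standard_normal(500)
            res = cs.stepwise_aic(df, "y", candidates=list(df.columns[:-1]))
            included += len(res.selected)
        assert included / (n_rep * n_cand) <= 0.20


class TestMediation:
    def test_noiseless_linear_system_exact(self, rng):
        # a=-0.5, b=0.3, c'=-0.4; mediator residual constructed orthogonal
        # to x so every OLS path is exact, not just consistent
        x = rng.standard_normal(40)
        e = rng.standard_normal(40)
        e -= e.mean()
        xc = x - x.mean()
        e -= (e @ xc) / (xc @ xc) * xc
        m = -0.5 * x + e
        y = -0.4 * x + 0.3 * m
        med = cs.fit_mediation(x, m, y, n_boot=50, seed=0)
        assert med.a == pytest.approx(-0.5, abs=1e-6)
        assert med.b == pytest.approx(0.3, abs=1e-6)
        assert med.c_prime == pytest.approx(-0.4, abs=1e-6)
        assert med.indirect == pytest.approx(-0.15, abs=1e-6)
        assert med.total == pytest.approx(-0.55, abs=1e-6)

    def test_null_mediator_ci_covers_zero(self, rng):
        x = rng.standard_normal(200)
        m = 0.5 * x + rng.standard_normal(200)
        y = -0.4 * x + rng.standard_normal(200)  # y independent of m given x
        med = cs.fit_mediation(x, m, y, n_boot=500, seed=1)
        lo, hi = med.ci["indirect"]
        assert lo < 0 < hi

    def test_printed_effect_shares(self):
        # per-5%-ECV effects: direct -0.366, indirect -0.068 -> 84% / 16%
        share_direct, share_indirect = cs.effect_shares(-0.366, -0.068)
        assert round(100 * share_indirect) == 16
        assert round(100 * share_direct) == 84

    def test_identity_and_shares_on_fit(self, rng):
        df = synthetic.gen_mediation_dataset(-0.25, 0.35, -0.48, n=92, seed=5)
        med = cs.fit_mediation(df.x, df.m, df.y, n_boot=200, seed=5)
        assert med.total == med.c_prime + med.a * med.b
        assert med.share_direct + med.share_indirect == pytest.approx(1.0)
        assert med.per_scale["direct"] == pytest.approx(5 * med.c_prime)

    def test_bootstrap_ci_shrinks_with_n(self):
        widths = {100: [], 400: []}
        for rep in range(20):
            for n in (100, 400):
                df = synthetic.gen_mediation_dataset(-0.25, 0.35, -0.48, n=n, seed=rep)
                med = cs.fit_mediation(df.x, df.m, df.y, n_boot=200, seed=rep)
                lo, hi = med.ci["indirect"]
                widths[n].append(hi - lo)
        assert np.mean(widths[400]) < np.mean(widths[100])

    def test_rmsea_saturated_is_zero(self):
        df = synthetic.gen_mediation_dataset(-0.25, 0.35, -0.48, n=92, seed=2)
        med = cs.fit_mediation(df.x, df.m, df.y, n_boot=50, seed=2)
        assert med.df == 0
        assert med.rmsea == 0.0

    def test_rmsea_good_fit_when_direct_path_truly_absent(self):
        # dropping the direct path on data generated with c' = 0 leaves one
        # df of misfit whose chi-square is central: RMSEA < 0.05 nearly always
        good = 0
        for seed in range(100):
            df = synthetic.gen_mediation_dataset(-0.4, 0.5, 0.0, n=2000, seed=seed)
            res = cs.fit_mediation_no_direct(df.x, df.m, df.y)
            good += res["rmsea"] < 0.05
        assert good >= 95


class TestLmm:
    def test_zero_between_variance_reduces_to_ols(self, rng):
        # residuals centered within each group: the realized between-group
        # variance is exactly zero, so the REML estimate sits on the
        # boundary and GLS coincides with OLS
        n_groups, per = 20, 10
        g = np.repeat(np.arange(n_groups), per)
        x = rng.standard_normal(n_groups * per)
        e = rng.standard_normal(n_groups * per)
        e -= pd.Series(e).groupby(g).transform("mean").to_numpy()
        y = 1.5 + 0.8 * x + e
        df = pd.DataFrame({"y": y, "x": x, "g": g})
        res = cs.fit_lmm_random_intercept(df, "y", ["x"], group="g")
        import statsmodels.api as sm

        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.fe_params["x"] == pytest.approx(ols.params[1], abs=1e-6)
        assert res.var_group < 0.05

    def test_balanced_design_matches_anova_moments(self, rng):
        n_groups, per = 20, 10
        g = np.repeat(np.arange(n_groups), per)
        y = rng.normal(0, 1.0, n_groups * per) + np.repeat(rng.normal(0, 1.0, n_groups), per)
        df = pd.DataFrame({"y": y, "g": g})
        res = cs.fit_lmm_random_intercept(df, "y", [], group="g")
        gm = df.groupby("g")["y"].mean()
        msw = float(((df.y - gm[g].to_numpy()) ** 2).sum() / (n_groups * (per - 1)))
        msb = float(per * ((gm - df.y.mean()) ** 2).sum() / (n_groups - 1))
        assert res.var_resid == pytest.approx(msw, rel=0.02)
        assert res.var_group == pytest.approx((msb - msw) / per, rel=0.05)

    def test_single_group_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "g": ["a", "a", "a"]})
        with pytest.raises(DegenerateDesignError):
            cs.fit_lmm_random_intercept(df, "y", [], group="g")

    def test_segmental_ecv_effect_recovered(self):
        subj, seg, _ = synthetic.gen_cohort(seed=42)
        res = cs.fit_lmm_random_intercept(
            seg, "mbf", ["ecv_seg_pct", "rpp"], group="subject_id"
        )
        est, se = res.fe_params["ecv_seg_pct"], res.fe_bse["ecv_seg_pct"]
        assert est < 0
        assert abs(est - (-0.003)) <= 2 * se

    def test_nested_grouping_fits(self):
        subj, seg, _ = synthetic.gen_cohort(seed=3)
        res = cs.fit_lmm_random_intercept(
            seg, "mbf", ["ecv_seg_pct"], group="subject_id", nested="slice"
        )
        assert res.grouping == "subject_id/slice"
        assert res.var_group >= 0


class TestBaseToApex:
    def test_identical_slices_null(self):
        rows = []
        for s in range(10):
            for sl in ("basal", "mid", "apical"):
                rows.append({"subject_id": s, "slice": sl, "mbf": 0.9})
        res = cs.base_to_apex_analysis(pd.DataFrame(rows))
        assert all(abs(v) < 1e-9 for v in res.contrasts.values())
        assert (res.pairwise.p_holm > 0.99).all()

    def test_gradient_recovered(self, rng):
        rows = []
        for s in range(60):
            base = 0.85 + rng.normal(0, 0.15)
            for sl, inc in (("basal", 0.0), ("mid", 0.05), ("apical", 0.10)):
                rows.append(
                    {"subject_id": s, "slice": sl, "mbf": base + inc + rng.normal(0, 0.1)}
                )
        res = cs.base_to_apex_analysis(pd.DataFrame(rows))
        assert res.contrasts["mid"] > 0
        assert res.contrasts["apical"] > res.contrasts["mid"]

    def test_single_subject_rejected(self):
        df = pd.DataFrame(
            {"subject_id": [1, 1, 1], "slice": ["basal", "mid", "apical"], "mbf": [1, 1, 1]}
        )
        with pytest.raises(DegenerateDesignError):
            cs.base_to_apex_analysis(df)


class TestHolm:
    def test_single_p_unchanged(self):
        assert cs.holm_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_down(self):
        assert cs.holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])
        assert cs.holm_adjust([0.05, 0.05]) == pytest.approx([0.10, 0.10])

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            cs.holm_adjust([0.5, 1.2])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10))
    def test_adjusted_dominate_raw_and_monotone(self, pvals):
        adj = cs.holm_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestLogistic:
    def test_known_or_recovered(self, rng):
        true_or, hits = 1.55, []
        for seed in range(200):
            r = np.random.default_rng(seed)
            ecv = np.clip(r.normal(46, 10, 89), 20, 70)
            p = 1 / (1 + np.exp(-(np.log(true_or) * (ecv - 41.5))))
            lge = r.random(89) < p
            if lge.all() or (~lge).all():
                continue
            try:
                fit = cs.logistic_lge(ecv, lge.astype(int))
            except SeparationError:
                continue
            hits.append(fit.odds_ratio)
        assert abs(np.median(hits) - true_or) / true_or < 0.10

    def test_null_coverage(self, rng):
        covered, total = 0, 100
        for _ in range(total):
            ecv = rng.normal(46, 10, 500)
            lge = rng.random(500) < 0.5
            fit = cs.logistic_lge(ecv, lge.astype(int))
            covered += fit.ci[0] <= 1.0 <= fit.ci[1]
        assert 0.88 <= covered / total <= 0.99

    def test_one_class_rejected(self):
        with pytest.raises(SeparationError):
            cs.logistic_lge(np.linspace(30, 60, 20), np.ones(20))

    def test_complete_separation_detected(self):
        ecv = np.linspace(30, 60, 20)
        lge = (ecv > 45).astype(int)
        with pytest.raises(SeparationError):
            cs.logistic_lge(ecv, lge)


class TestPower:
    def test_null_effect_gives_alpha(self):
        assert cs.power_two_sample_t(30, 0.0, 0.2, 0.05) == pytest.approx(0.05, abs=1e-6)

    def test_design_claim_exceeds_090(self):
        # 0.2 ml/min/g difference, sd 0.2, 30 per group
        assert cs.power_two_sample_t(30, 0.2, 0.2, 0.05) > 0.9

    def test_monotone_in_n_delta_alpha(self):
        p_n = [cs.power_two_sample_t(n, 0.2, 0.2) for n in (10, 20, 40, 80)]
        assert np.all(np.diff(p_n) > 0)
        p_d = [cs.power_two_sample_t(30, d, 0.2) for d in (0.05, 0.1, 0.2, 0.4)]
        assert np.all(np.diff(p_d) > 0)
        p_a = [cs.power_two_sample_t(30, 0.1, 0.2, a) for a in (0.01, 0.05, 0.1)]
        assert np.all(np.diff(p_a) > 0)
        assert cs.power_two_sample_t(5000, 0.2, 0.2) > 0.9999
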