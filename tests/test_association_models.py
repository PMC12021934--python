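import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from actiscan.association_models import (
    SurveyDesign,
    fit_weighted_linear,
    fit_weighted_logistic,
    run_window_scan,
    trend_test,
)
from actiscan.synthetic_data import SimConfig, simulate_feature_cohort, _model_frame


def weighted_2x2(w_ec=30.0, w_en=10.0, w_uc=10.0, w_un=30.0, reps=20):
    """Saturated binary-exposure table with the given weight totals."""
    rows = []
    for y, x, wtot in [(1, 2, w_ec), (0, 2, w_en), (1, 1, w_uc), (0, 1, w_un)]:
        rows += [(y, x, wtot / reps)] * reps
    df = pd.DataFrame(rows, columns=["y", "q", "w"])
    df.index = [f"P{i}" for i in range(len(df))]
    return df


def no_covariates(index):
    return pd.DataFrame(index=index)


class TestWeightedLogistic:
    def test_saturated_toy_or_equals_weighted_cross_product(self):
        """Weighted-MLE OR on a 30/10/10/30 weight table is exactly 9."""
        df = weighted_2x2()
        res = fit_weighted_logistic(df["y"], df["q"], no_covariates(df.index), SurveyDesign(weights=df["w"]))
        est = res.loc[res["quintile"] == 2, "estimate"].iloc[0]
        assert np.exp(est) == pytest.approx(9.0, abs=1e-6)

    def test_reference_quintile_is_exactly_zero(self):
        df = weighted_2x2()
        res = fit_weighted_logistic(df["y"], df["q"], no_covariates(df.index), SurveyDesign(weights=df["w"]))
        assert res.loc[res["quintile"] == 1, "estimate"].iloc[0] == 0.0

    def test_equal_weights_match_unweighted_mle(self):
        rng = np.random.default_rng(0)
        n = 400
        q = pd.Series(rng.integers(1, 6, n), index=range(n))
        x = pd.get_dummies(q, prefix="q", drop_first=True, dtype=float)
        lin = -1.2 + 0.3 * q
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-lin))).astype(float), index=q.index)
        res = fit_weighted_logistic(y, q, no_covariates(q.index), SurveyDesign(weights=pd.Series(1.0, index=q.index)))
        X = sm.add_constant(x)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        for k in range(2, 6):
            ours = res.loc[res["quintile"] == k, "estimate"].iloc[0]
            assert ours == pytest.approx(ref.params[f"q_{k}"], abs=1e-8)

    def test_halved_weight_duplicates_leave_estimates_unchanged(self):
        df = weighted_2x2()
        dup = pd.concat([df.assign(w=df["w"] / 2)] * 2)
        dup.index = [f"D{i}" for i in range(len(dup))]
        a = fit_weighted_logistic(df["y"], df["q"], no_covariates(df.index), SurveyDesign(weights=df["w"]))
        b = fit_weighted_logistic(dup["y"], dup["q"], no_covariates(dup.index), SurveyDesign(weights=dup["w"]))
        assert a.loc[a["quintile"] == 2, "estimate"].iloc[0] == pytest.approx(
            b.loc[b["quintile"] == 2, "estimate"].iloc[0], abs=1e-8
        )

    def test_weight_scale_invariance_of_estimates_and_robust_cis(self):
        df = weighted_2x2(w_ec=33, w_en=12, w_uc=9, w_un=28)
        a = fit_weighted_logistic(df["y"], df["q"], no_covariates(df.index), SurveyDesign(weights=df["w"]))
        b = fit_weighted_logistic(
            df["y"], df["q"], no_covariates(df.index), SurveyDesign(weights=df["w"] * 7.3)
        )
        row_a = a.loc[a["quintile"] == 2].iloc[0]
        row_b = b.loc[b["quintile"] == 2].iloc[0]
        assert row_a["estimate"] == pytest.approx(row_b["estimate"], abs=1e-9)
        assert row_a["ci_low"] == pytest.approx(row_b["ci_low"], abs=1e-8)
        assert row_a["ci_high"] == pytest.approx(row_b["ci_high"], abs=1e-8)

    def test_degenerate_exposure_is_skipped_with_warning(self):
        n = 100
        idx = range(n)
        y = pd.Series(np.tile([0.0, 1.0], n // 2), index=idx)
        q = pd.Series(1, index=idx)
        with pytest.warns(UserWarning, match="degenerate"):
            res = fit_weighted_logistic(y, q, no_covariates(y.index), SurveyDesign(weights=pd.Series(1.0, index=idx)))
        assert (res["status"] == "degenerate").all()


class TestWeightedLinear:
    def test_zero_noise_recovers_slope_exactly(self):
        q = pd.Series(np.tile(np.arange(1, 6), 20), index=range(100))
        y = 0.1 * q.astype(float) + 0.7
        res = fit_weighted_linear(y, q, no_covariates(q.index), SurveyDesign(weights=pd.Series(1.0, index=q.index)))
        for k in range(2, 6):
            est = res.loc[res["quintile"] == k, "estimate"].iloc[0]
            assert est == pytest.approx(0.1 * (k - 1), abs=1e-8)
        assert res["trend_estimate"].iloc[0] == pytest.approx(0.1, abs=1e-8)

    def test_null_outcome_cis_cover_zero_mostly(self):
        rng = np.random.default_rng(1)
        hits = 0
        reps = 60
        for _ in range(reps):
            q = pd.Series(rng.permutation(np.tile(np.arange(1, 6), 40)), index=range(200))
            y = pd.Series(rng.normal(0, 1, 200), index=q.index)
            res = fit_weighted_linear(y, q, no_covariates(q.index), SurveyDesign(weights=pd.Series(1.0, index=q.index)))
            sub = res[res["quintile"] > 1]
            hits += int(((sub["ci_low"] <= 0) & (sub["ci_high"] >= 0)).all())
        assert hits / reps >= 0.7  # joint coverage of four 95% CIs


class TestTrend:
    def test_affine_recode_leaves_p_unchanged(self):
        rng = np.random.default_rng(2)
        q = pd.Series(rng.integers(1, 6, 300), index=range(300))
        y = pd.Series((rng.random(300) < 0.2 + 0.05 * q).astype(float), index=q.index)
        w = SurveyDesign(weights=pd.Series(1.0, index=q.index))
        a = trend_test(y, q, no_covariates(q.index), w)
        b = trend_test(y, q - 1, no_covariates(q.index), w)
        assert a["p"] == pytest.approx(b["p"], abs=1e-10)
        assert a["estimate"] == pytest.approx(b["estimate"], abs=1e-10)

    def test_strong_monotone_effect_is_detected(self):
        cfg = SimConfig(n_participants=4000, seed=21, effect_window=13, effect_log_or_per_quintile=-0.3)
        sim = simulate_feature_cohort(cfg)
        from actiscan.hourly_features import assign_quintiles

        design = SurveyDesign(
            weights=sim["covariates"]["weight"], stratum=sim["covariates"]["stratum"], psu=sim["covariates"]["psu"]
        )
        q = assign_quintiles(sim["features"]["rel_h13"])
        tr = trend_test(sim["panel"]["diabetes_true"].astype(float), q, _model_frame(sim), design, variance="taylor")
        assert tr["p"] < 0.001 and tr["estimate"] < 0


class TestScanAndCoverage:
    def test_null_scan_rarely_excludes_the_null(self):
        sim = simulate_feature_cohort(SimConfig(n_participants=2000, seed=31))
        design = SurveyDesign(
            weights=sim["covariates"]["weight"], stratum=sim["covariates"]["stratum"], psu=sim["covariates"]["psu"]
        )
        grid = run_window_scan(
            sim["features"], sim["panel"]["diabetes_true"].astype(float), _model_frame(sim), design, variance="taylor"
        )
        cells = grid[(grid["quintile"] > 1) & (grid["status"] == "ok")]
        exclude = ((cells["ci_low"] > 0) | (cells["ci_high"] < 0)).mean()
        assert exclude <= 0.15  # ~5% expected at the 95% level

    def test_trend_ci_coverage_under_known_effect(self):
        """95% trend CI covers the injected per-step log-OR in 92-98% of cohorts."""
        from actiscan.hourly_features import assign_quintiles

        covered = []
        for rep in range(200):
            cfg = SimConfig(
                n_participants=2000, seed=40_000 + rep, effect_window=13, effect_log_or_per_quintile=-0.2
            )
            sim = simulate_feature_cohort(cfg)
            design = SurveyDesign(
                weights=sim["covariates"]["weight"], stratum=sim["covariates"]["stratum"], psu=sim["covariates"]["psu"]
            )
            q = assign_quintiles(sim["features"]["rel_h13"])
            tr = trend_test(
                sim["panel"]["diabetes_true"].astype(float), q, _model_frame(sim), design, variance="robust"
            )
            covered.append(tr["ci_low"] <= -0.2 <= tr["ci_high"])
        rate = np.mean(covered)
        assert 0.92 <= rate <= 0.98
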