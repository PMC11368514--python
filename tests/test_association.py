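"""Cross-sectional models: COPD derivation, linear/logistic oracles,
weighting and spline-sensitivity contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from airwayhet import (
    CopdDefinition,
    compare_spline_fit,
    derive_copd_status,
    fit_linear_association,
    fit_logistic_association,
    make_synthetic_lln_rule,
)
from airwayhet.errors import (
    CollinearityError,
    DegenerateExposureError,
    SchemaError,
    SeparationError,
)


def spiro(fev1, fvc, **kw):
    d = {"fev1": [fev1], "fvc": [fvc], "bronchodilator": ["post"]}
    d.update({k: [v] for k, v in kw.items()})
    return pd.DataFrame(d)


class TestCopdStatus:
    def test_strict_threshold(self):
        assert derive_copd_status(spiro(690.0, 1000.0)).iloc[0] == True  # noqa: E712
        # exactly 0.70 is NOT COPD: the definition is a strict inequality
        assert derive_copd_status(spiro(700.0, 1000.0)).iloc[0] == False  # noqa: E712

    def test_symptom_definition_cat_boundary(self):
        defn = CopdDefinition(kind="ratio_plus_symptoms")
        row = spiro(650.0, 1000.0, cat_score=10, mmrc=0, chronic_bronchitis=0)
        assert derive_copd_status(row, defn).iloc[0] == True  # noqa: E712
        row = spiro(650.0, 1000.0, cat_score=9, mmrc=0, chronic_bronchitis=0)
        assert derive_copd_status(row, defn).iloc[0] == False  # noqa: E712

    def test_lln_definition(self, small_cfg):
        defn = CopdDefinition(kind="below_lln", lln_rule=make_synthetic_lln_rule(small_cfg))
        df = spiro(700.0, 1000.0, age=60.0)
        lln = small_cfg.ratio_norm_intercept - 1.6449 * small_cfg.ratio_resid_sd
        assert (0.7 < lln) == bool(derive_copd_status(df, defn).iloc[0])

    def test_missing_spirometry_marked_not_false(self):
        df = spiro(np.nan, 1000.0)
        assert derive_copd_status(df).isna().iloc[0]

    def test_prebronchodilator_requires_optin(self):
        df = spiro(600.0, 1000.0)
        df["bronchodilator"] = "pre"
        with pytest.raises(SchemaError):
            derive_copd_status(df)
        with pytest.warns(UserWarning, match="pre-bronchodilator"):
            assert derive_copd_status(df, allow_prebronchodilator=True).iloc[0]


class TestLinear:
    def test_exact_linear_recovery(self):
        x = np.linspace(0, 10, 40)
        df = pd.DataFrame({"heterogeneity_sd": x, "fev1": 2.0 * x + 3.0})
        res = fit_linear_association(
            df, exposure_coding="raw", covariate_set="unadjusted"
        )
        c = res.contrasts[0]
        assert c.estimate == pytest.approx(2.0, abs=1e-10)

    def test_constant_weights_match_unweighted(self, analysis_table):
        df = analysis_table.assign(weight=3.7)
        a = fit_linear_association(df, exposure_coding="per_sd")
        b = fit_linear_association(df, exposure_coding="per_sd", weighted=True)
        assert b.contrasts[0].estimate == pytest.approx(
            a.contrasts[0].estimate, abs=1e-10
        )

    def test_per_sd_equals_raw_times_sd(self, analysis_table):
        raw = fit_linear_association(
            analysis_table, exposure_coding="raw", covariate_set="model1"
        )
        per = fit_linear_association(
            analysis_table, exposure_coding="per_sd", covariate_set="model1"
        )
        sd = analysis_table["heterogeneity_sd"].std(ddof=1)
        assert per.contrasts[0].estimate == pytest.approx(
            raw.contrasts[0].estimate * sd, rel=1e-10
        )
        assert per.exposure_sd == pytest.approx(sd)

    def test_cov_coding_shares_per_sd_path(self, analysis_table):
        direct = fit_linear_association(
            analysis_table.assign(heterogeneity_sd=analysis_table["cov"]),
            exposure_coding="per_sd",
        )
        cov = fit_linear_association(analysis_table, exposure_coding="cov")
        assert cov.contrasts[0].estimate == pytest.approx(
            direct.contrasts[0].estimate, rel=1e-12
        )

    def test_quartile_contrasts_ordered_under_linear_truth(self, analysis_table):
        """With a negative linear exposure effect, Q4-vs-Q1 is more negative
        than Q2-vs-Q1 (checked on the default-effect synthetic cohort)."""
        res = fit_linear_association(analysis_table, exposure_coding="quartiles")
        by = {c.name: c.estimate for c in res.contrasts}
        assert by["Q4 vs Q1"] < by["Q2 vs Q1"] < 0

    def test_collinear_design_rejected(self, analysis_table):
        df = analysis_table.assign(mean_caliber=analysis_table["age"])
        # age and mean_caliber identical -> aliased with age column
        with pytest.raises(CollinearityError):
            fit_linear_association(df, exposure_coding="per_sd")

    def test_zero_variance_exposure_rejected(self, analysis_table):
        df = analysis_table.assign(heterogeneity_sd=5.0)
        with pytest.raises(DegenerateExposureError):
            fit_linear_association(df, exposure_coding="per_sd")

    def test_latent_columns_refused(self, cohort, models):
        from airwayhet.pipeline import _summaries_with_covariates

        with_latent = _summaries_with_covariates(cohort.subjects, models)
        with pytest.raises(SchemaError, match="latent"):
            fit_linear_association(with_latent, exposure_coding="per_sd")

    def test_missing_indicator_method(self, analysis_table):
        df = analysis_table.copy()
        df.loc[df.index[:40], "pack_years"] = np.nan
        res = fit_linear_association(
            df, exposure_coding="per_sd", covariate_set="model2",
            missing_indicators=True,
        )
        assert res.n == len(df)
        assert "pack_years_missing" in res.diagnostics["missing_indicator_columns"]
        cc = fit_linear_association(
            df, exposure_coding="per_sd", covariate_set="model2",
            missing_indicators=False,
        )
        assert cc.n == len(df) - 40


def bernoulli_nll(params, X, y):
    eta = X @ params
    return float(np.sum(np.log1p(np.exp(eta)) - y * eta))


class TestLogistic:
    def toy_2x2(self):
        # exposed: 10 cases / 40 non-cases; unexposed: 20 cases / 30 non-cases
        rows = (
            [(1, 1)] * 10 + [(1, 0)] * 40 + [(0, 1)] * 20 + [(0, 0)] * 30
        )
        return pd.DataFrame(rows, columns=["heterogeneity_sd", "y"]).astype(float)

    def test_2x2_matches_cross_product_odds_ratio(self):
        df = self.toy_2x2()
        res = fit_logistic_association(
            df, outcome="y", exposure_coding="raw", covariate_set="unadjusted"
        )
        assert res.contrasts[0].estimate == pytest.approx(0.375, abs=1e-6)

    def test_mle_matches_naive_optimizer_oracle(self):
        """Brute-force likelihood maximisation on a <=200-row instance."""
        df = self.toy_2x2()
        X = np.column_stack([np.ones(len(df)), df["heterogeneity_sd"]])
        y = df["y"].to_numpy()
        opt = optimize.minimize(
            bernoulli_nll, np.zeros(2), args=(X, y), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        res = fit_logistic_association(
            df, outcome="y", exposure_coding="raw", covariate_set="unadjusted"
        )
        assert np.log(res.contrasts[0].estimate) == pytest.approx(opt.x[1], abs=1e-6)

    def test_constant_weights_match_unweighted(self, analysis_table):
        df = analysis_table.assign(weight=2.0)
        a = fit_logistic_association(df, exposure_coding="per_sd")
        b = fit_logistic_association(df, exposure_coding="per_sd", weighted=True)
        assert b.contrasts[0].estimate == pytest.approx(
            a.contrasts[0].estimate, rel=1e-8
        )

    def test_separation_reported(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        df = pd.DataFrame({"heterogeneity_sd": x, "y": x})
        with pytest.raises(SeparationError):
            fit_logistic_association(
                df, outcome="y", exposure_coding="raw", covariate_set="unadjusted"
            )

    def test_single_class_rejected(self):
        df = pd.DataFrame({"heterogeneity_sd": [1.0, 2, 3, 4], "y": [0.0, 0, 0, 0]})
        with pytest.raises(SeparationError):
            fit_logistic_association(
                df, outcome="y", exposure_coding="raw", covariate_set="unadjusted"
            )


class TestSplineComparison:
    def test_nesting_identity(self, analysis_table):
        """The spline model with nonlinear coefficients at 0 is the linear
        model: the F statistic is computed from nested fits on identical
        designs, so a truly linear fit gives a small F."""
        cmp_ = compare_spline_fit(analysis_table)
        assert cmp_.df_num == 1  # 3 knots -> one nonlinear column
        assert cmp_.f_statistic >= 0

    def test_quadratic_alternative_detected(self, rng):
        n = 2000
        x = rng.normal(14, 5, n)
        y = 100.0 - 2.0 * x + 0.8 * (x - 14) ** 2 + rng.normal(0, 5, n)
        df = pd.DataFrame({"heterogeneity_sd": x, "fev1": y})
        cmp_ = compare_spline_fit(df, covariate_set="unadjusted")
        assert cmp_.verdict == "improvement"
        assert cmp_.p_value < 1e-3

    def test_verdict_consistent_with_test_and_aic(self, rng):
        n = 1500
        x = rng.normal(14, 5, n)
        y = 100.0 - 2.0 * x + rng.normal(0, 5, n)
        df = pd.DataFrame({"heterogeneity_sd": x, "fev1": y})
        cmp_ = compare_spline_fit(df, covariate_set="unadjusted")
        expected = "improvement" if (
            cmp_.p_value < 0.05 and cmp_.aic_difference >= 2
        ) else "no improvement"
        assert cmp_.verdict == expected
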