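"""Synthetic-cohort generator: determinism, configured moments, weights."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from airwayhet import (
    SimulationConfig,
    assign_selection_weights,
    generate_cohort,
    generate_normative_sample,
    generate_visits,
)
from airwayhet.errors import ConfigError
from airwayhet.pipeline import _summaries_with_covariates, analysis_view
from airwayhet.simulate import (
    c4_constant,
    default_strata,
    normative_conditional_means,
)
from airwayhet.sites import AIRWAY_SITES


class TestConfig:
    def test_invalid_fields_listed(self):
        with pytest.raises(ConfigError, match="ar1_rho"):
            SimulationConfig(ar1_rho=1.5).validate()
        with pytest.raises(ConfigError, match="het_sd"):
            SimulationConfig(het_sd=-1.0).validate()
        with pytest.raises(ConfigError, match="visit_times"):
            SimulationConfig(visit_times=(1.0, 0.5)).validate()

    def test_unknown_field_rejected(self):
        with pytest.raises(ConfigError, match="not_a_field"):
            SimulationConfig.from_dict({"not_a_field": 1})

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = SimulationConfig(n_subjects=42, het_mean=12.0)
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert SimulationConfig.from_yaml(path) == cfg


class TestNormative:
    def test_same_seed_identical(self, small_cfg):
        a = generate_normative_sample(small_cfg, rng=4)
        b = generate_normative_sample(small_cfg, rng=4)
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv() == b.to_csv()

    def test_zero_noise_is_deterministic_function_of_covariates(self):
        cfg = SimulationConfig(n_normative=50, diam_noise_sd=0.0)
        df = generate_normative_sample(cfg, rng=1)
        cond = normative_conditional_means(cfg, df)
        for site in ("TRACHEA", "sRB10"):
            np.testing.assert_allclose(df[site], cond[site], rtol=1e-12)

    def test_empirical_means_match_generating_law(self):
        cfg = SimulationConfig(n_normative=10000)
        df = generate_normative_sample(cfg, rng=2)
        cond = normative_conditional_means(cfg, df)
        for site in AIRWAY_SITES:
            resid = df[site] - cond[site]
            mc_se = resid.std(ddof=1) / np.sqrt(len(df))
            assert abs(resid.mean()) < 2.5 * mc_se

    def test_risk_factor_free(self, normative_sample):
        assert (normative_sample["smoking_status"] == "never").all()
        assert (normative_sample[["secondhand", "occupational", "asthma"]] == 0).all().all()


class TestCohort:
    def test_seed_determinism(self, small_cfg, models):
        a = generate_cohort(small_cfg, models, rng=7).subjects
        b = generate_cohort(small_cfg, models, rng=7).subjects
        pd.testing.assert_frame_equal(a, b)

    def test_moments_of_recomputed_summaries(self, models):
        """Recomputed per-subject summaries reproduce the configured cohort
        moments (mean caliber 99 +/- 10, heterogeneity 14 +/- 5) at n = 5000."""
        cfg = SimulationConfig(n_subjects=5000)
        cohort = generate_cohort(cfg, models, rng=11)
        ana = _summaries_with_covariates(analysis_view(cohort.subjects), models)
        n = len(ana)
        het = ana["heterogeneity_sd"]
        mean = ana["mean_caliber"]
        # MC tolerances: 3 standard errors of a mean / SD at n = 5000
        assert het.mean() == pytest.approx(14.0, abs=3 * 5.0 / np.sqrt(n))
        assert het.std(ddof=1) == pytest.approx(5.0, abs=3 * 5.0 / np.sqrt(2 * n) + 0.15)
        assert mean.mean() == pytest.approx(99.0, abs=3 * 10.0 / np.sqrt(n))
        assert mean.std(ddof=1) == pytest.approx(10.0, abs=3 * 10.0 / np.sqrt(2 * n) + 0.15)

    def test_latent_truth_equals_recomputed_summary(self, cohort, models, analysis_table):
        """Full-path recovery: normalising the generated diameters with the
        same reference models recovers the carried ground truth exactly."""
        np.testing.assert_allclose(
            analysis_table["heterogeneity_sd"],
            cohort.subjects["latent_sd"],
            rtol=1e-10,
        )
        r = np.corrcoef(analysis_table["heterogeneity_sd"], cohort.subjects["latent_sd"])
        assert r[0, 1] > 0.95

    def test_null_effects_and_zero_noise_give_demographic_norm(self, models):
        cfg = SimulationConfig(
            n_subjects=100,
            beta_het_fev1=0.0,
            beta_mean_fev1=0.0,
            fev1_resid_sd=0.0,
            smoking_probs=(1.0, 0.0, 0.0),
            asthma_p=0.0,
        )
        cohort = generate_cohort(cfg, models, rng=3)
        df = cohort.subjects
        male = (df["sex"] == "male").to_numpy()
        norm = (
            cfg.fev1_norm_intercept
            + cfg.fev1_age_slope * (df["age"] - 60.0)
            + cfg.fev1_male_shift * male
            + cfg.fev1_height_slope * (df["height"] - 170.0)
        )
        np.testing.assert_allclose(df["fev1"], norm, rtol=1e-12)

    def test_degenerate_zero_heterogeneity(self, models):
        cfg = SimulationConfig(n_subjects=50, het_mean=0.0, het_sd=0.0)
        cohort = generate_cohort(cfg, models, rng=6)
        ana = _summaries_with_covariates(analysis_view(cohort.subjects), models)
        np.testing.assert_allclose(ana["heterogeneity_sd"], 0.0, atol=1e-9)

    def test_spirometry_positive_and_ratio_in_unit_interval(self, cohort):
        df = cohort.subjects
        assert (df["fev1"] > 0).all()
        assert (df["fvc"] > 0).all()
        ratio = df["fev1"] / df["fvc"]
        assert ((ratio > 0) & (ratio < 1)).all()

    def test_c4_calibration_constant(self):
        # frozen oracle: sqrt(2/18) * Gamma(9.5) / Gamma(9) via math.gamma
        assert c4_constant(19) == pytest.approx(0.9862141368601937, abs=1e-12)


class TestVisits:
    def test_deterministic_slope_when_noise_free(self, models):
        cfg = SimulationConfig(
            n_subjects=40,
            random_intercept_sd=0.0,
            ar1_sd=0.0,
            interaction_gamma=0.0,
            visit_times=(0.0, 2.0),
            smoking_transition_rate=0.0,
        )
        cohort = generate_cohort(cfg, models, rng=5)
        visits = generate_visits(cfg, cohort, rng=6)
        for _, g in visits.groupby("subject_id"):
            slope = np.diff(g["fev1"]) / np.diff(g["time"])
            assert slope[0] == pytest.approx(cfg.fev1_decline, rel=1e-12)

    def test_rho_zero_gives_uncorrelated_residuals(self, models):
        cfg = SimulationConfig(
            n_subjects=2000, ar1_rho=0.0, random_intercept_sd=0.0,
            visit_times=(0.0, 1.0, 2.0),
        )
        cohort = generate_cohort(cfg, models, rng=8)
        visits = generate_visits(cfg, cohort, rng=9)
        wide = visits.pivot(index="subject_id", columns="time", values="fev1")
        base = cohort.subjects.set_index("subject_id")
        resid = wide.sub(base["fev1"], axis=0) - np.outer(
            np.ones(len(wide)), [0.0, 1.0, 2.0]
        ) * cfg.fev1_decline
        r01 = np.corrcoef(resid[0.0], resid[1.0])[0, 1]
        r12 = np.corrcoef(resid[1.0], resid[2.0])[0, 1]
        for r in (r01, r12):
            assert abs(r) < 3.0 / np.sqrt(len(wide))

    def test_seed_determinism(self, small_cfg, cohort):
        a = generate_visits(small_cfg, cohort, rng=10)
        b = generate_visits(small_cfg, cohort, rng=10)
        pd.testing.assert_frame_equal(a, b)

    def test_negative_visit_times_rejected(self, small_cfg, cohort):
        cfg = dataclasses.replace(small_cfg, visit_times=(-1.0, 1.0))
        with pytest.raises(ConfigError):
            generate_visits(cfg, cohort, rng=1)

    def test_every_visit_subject_exists(self, small_cfg, cohort):
        visits = generate_visits(small_cfg, cohort, rng=2)
        assert set(visits["subject_id"]) <= set(cohort.subjects["subject_id"])


class TestSelectionWeights:
    def test_census_case(self, cohort):
        strata = default_strata(cohort.subjects)
        probs = {h: 1.0 for h in strata.unique()}
        out = assign_selection_weights(cohort.subjects, probs, strata, rng=1)
        assert len(out) == len(cohort.subjects)
        assert (out["weight"] == 1.0).all()

    def test_horvitz_thompson_totals(self, rng):
        n = 1000
        df = pd.DataFrame({"subject_id": [f"s{i}" for i in range(2 * n)]})
        strata = pd.Series(["a"] * n + ["b"] * n, index=df.index)
        out = assign_selection_weights(
            df, {"a": 1.0, "b": 0.25}, strata, rng=rng
        )
        wt = out.groupby("stratum")["weight"].sum()
        assert wt["a"] == n
        # binomial MC tolerance around the Horvitz-Thompson expectation
        se = np.sqrt(n * 0.25 * 0.75) / 0.25
        assert abs(wt["b"] - n) < 3 * se

    def test_weight_constant_within_stratum(self, cohort, rng):
        strata = default_strata(cohort.subjects)
        probs = {h: 0.5 for h in strata.unique()}
        out = assign_selection_weights(cohort.subjects, probs, strata, rng=rng)
        assert (out.groupby("stratum")["weight"].nunique() == 1).all()

    def test_invalid_probability_rejected(self, cohort):
        strata = default_strata(cohort.subjects)
        probs = {h: 0.0 for h in strata.unique()}
        with pytest.raises(ConfigError):
            assign_selection_weights(cohort.subjects, probs, strata, rng=1)
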