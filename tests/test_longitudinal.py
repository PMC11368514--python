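"""Mixed decline model: exact contracts, OLS equivalence, independent
full-likelihood oracle, centering invariance, annualised change."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import optimize

from airwayhet import (
    MixedModelSpec,
    annualized_change,
    fit_mixed_decline,
)
from airwayhet.errors import SchemaError


def toy_visits(n=30, times=(0.0, 2.0), slope=-50.0, seed=0, noise=0.0,
               ri_sd=0.0, base=2500.0):
    rng = np.random.default_rng(seed)
    rows = []
    b = rng.normal(0, ri_sd, n)
    for i in range(n):
        y0 = base + rng.normal(0, 100)
        for t in times:
            rows.append(
                {
                    "subject_id": f"s{i:03d}",
                    "time": t,
                    "fev1": y0 + slope * t + b[i] + rng.normal(0, noise),
                }
            )
    visits = pd.DataFrame(rows)
    baseline = pd.DataFrame(
        {
            "subject_id": [f"s{i:03d}" for i in range(n)],
            "heterogeneity_sd": rng.normal(14, 5, n),
        }
    )
    return visits, baseline


UNADJ = MixedModelSpec(exposure_coding="raw", covariate_set="unadjusted")


class TestContracts:
    def test_deterministic_two_visit_slope_exact(self):
        visits, baseline = toy_visits(slope=-50.0)
        res = fit_mixed_decline(visits, baseline, UNADJ)
        assert res.effect("time")["estimate"] == pytest.approx(-50.0, abs=1e-8)
        assert res.effect("time_x_exposure")["estimate"] == pytest.approx(0.0, abs=1e-8)
        # two visits per subject cannot separate rho from the intercept
        assert res.rho == 0.0
        assert any("degenerate" in n for n in res.notes)

    def test_variances_forced_zero_equals_pooled_ols(self):
        visits, baseline = toy_visits(noise=80.0, ri_sd=100.0, seed=3,
                                      times=(0.0, 1.5, 3.0))
        spec = MixedModelSpec(
            exposure_coding="raw", covariate_set="unadjusted",
            random_intercept=False, ar1=False,
        )
        res = fit_mixed_decline(visits, baseline, spec)
        merged = visits.merge(baseline, on="subject_id")
        X = np.column_stack(
            [
                np.ones(len(merged)),
                merged["heterogeneity_sd"],
                merged["time"],
                merged["time"] * merged["heterogeneity_sd"],
            ]
        )
        ols = sm.OLS(merged["fev1"].to_numpy(), X).fit()
        got = res.fixed_effects.set_index("term")["estimate"]
        np.testing.assert_allclose(
            got[["const", "exposure", "time", "time_x_exposure"]],
            ols.params, rtol=1e-8,
        )

    def test_single_visit_subjects_rejected(self):
        visits, baseline = toy_visits(times=(0.0,))
        with pytest.raises(SchemaError):
            fit_mixed_decline(visits, baseline, UNADJ)

    def test_centering_invariance_of_product_term(self):
        visits, baseline = toy_visits(noise=60.0, ri_sd=80.0, seed=9,
                                      times=(0.0, 1.0, 2.0, 3.0))
        res = fit_mixed_decline(visits, baseline, UNADJ)
        shifted = baseline.assign(
            heterogeneity_sd=baseline["heterogeneity_sd"] - 14.0
        )
        res2 = fit_mixed_decline(visits, shifted, UNADJ)
        assert res2.effect("time_x_exposure")["estimate"] == pytest.approx(
            res.effect("time_x_exposure")["estimate"], rel=1e-6
        )
        # the time main effect changes by 14 * interaction
        assert res2.effect("time")["estimate"] == pytest.approx(
            res.effect("time")["estimate"]
            + 14.0 * res.effect("time_x_exposure")["estimate"],
            rel=1e-5,
        )


def naive_full_ml(visits, baseline, rho_free: bool):
    """Independent oracle: unprofiled ML over (beta via GLS, tau2, sigma2,
    rho) with explicit per-subject covariance matrices."""
    merged = visits.merge(baseline, on="subject_id").sort_values(
        ["subject_id", "time"], kind="stable"
    )
    X = np.column_stack(
        [
            np.ones(len(merged)),
            merged["heterogeneity_sd"],
            merged["time"],
            merged["time"] * merged["heterogeneity_sd"],
        ]
    )
    y = merged["fev1"].to_numpy()
    groups = merged["subject_id"].to_numpy()
    ids = np.unique(groups)

    def nll(theta):
        tau2, sig2 = np.exp(theta[0]), np.exp(theta[1])
        rho = 0.99 * np.tanh(theta[2]) if rho_free else 0.0
        XtVX = np.zeros((X.shape[1], X.shape[1]))
        XtVy = np.zeros(X.shape[1])
        logdet = 0.0
        Vinvs = []
        for g in ids:
            idx = groups == g
            ni = idx.sum()
            lag = np.abs(np.subtract.outer(np.arange(ni), np.arange(ni)))
            V = tau2 + sig2 * rho**lag
            Vinv = np.linalg.inv(V)
            logdet += np.linalg.slogdet(V)[1]
            Vinvs.append((idx, Vinv))
            XtVX += X[idx].T @ Vinv @ X[idx]
            XtVy += X[idx].T @ Vinv @ y[idx]
        beta = np.linalg.solve(XtVX, XtVy)
        quad = 0.0
        for idx, Vinv in Vinvs:
            r = y[idx] - X[idx] @ beta
            quad += r @ Vinv @ r
        return 0.5 * (len(y) * np.log(2 * np.pi) + logdet + quad), beta

    def obj(theta):
        return nll(theta)[0]

    res = optimize.minimize(
        obj, np.array([8.0, 8.0, 0.2]) if rho_free else np.array([8.0, 8.0, 0.0]),
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 8000},
    )
    val, beta = nll(res.x)
    tau2, sig2 = np.exp(res.x[0]), np.exp(res.x[1])
    rho = 0.99 * np.tanh(res.x[2]) if rho_free else 0.0
    return {"beta": beta, "tau2": tau2, "sigma2": sig2, "rho": rho, "nll": val}


class TestOracle:
    def test_compound_symmetry_oracle_small_instance(self):
        """Balanced data, rho = 0 truth: fixed effects and variance
        components agree with an independently coded full-ML optimiser."""
        visits, baseline = toy_visits(
            n=40, times=(0.0, 1.0, 2.0), noise=60.0, ri_sd=120.0, seed=21
        )
        spec = MixedModelSpec(
            exposure_coding="raw", covariate_set="unadjusted", fix_rho=0.0
        )
        res = fit_mixed_decline(visits, baseline, spec)
        oracle = naive_full_ml(visits, baseline, rho_free=False)
        got = res.fixed_effects["estimate"].to_numpy()
        np.testing.assert_allclose(got, oracle["beta"], rtol=1e-6)
        assert res.random_intercept_var == pytest.approx(oracle["tau2"], rel=1e-3)
        assert res.sigma2 == pytest.approx(oracle["sigma2"], rel=1e-3)
        assert res.loglik == pytest.approx(-oracle["nll"], abs=1e-4)

    def test_ar1_oracle_small_instance(self):
        visits, baseline = toy_visits(
            n=35, times=(0.0, 1.0, 2.0, 3.0), noise=70.0, ri_sd=90.0, seed=33
        )
        res = fit_mixed_decline(visits, baseline, UNADJ)
        oracle = naive_full_ml(visits, baseline, rho_free=True)
        # atol covers the near-zero interaction coefficient
        np.testing.assert_allclose(
            res.fixed_effects["estimate"].to_numpy(), oracle["beta"],
            rtol=1e-5, atol=1e-6,
        )
        assert res.rho == pytest.approx(oracle["rho"], abs=1e-3)
        assert res.loglik == pytest.approx(-oracle["nll"], abs=1e-3)


class TestAnnualizedChange:
    def test_two_point_slope(self):
        visits = pd.DataFrame(
            {
                "subject_id": ["a", "a"],
                "time": [0.0, 2.0],
                "fev1": [2500.0, 2400.0],
            }
        )
        slopes, summary = annualized_change(visits)
        assert slopes["slope"].iloc[0] == pytest.approx(-50.0)
        assert summary["n"] == 1

    def test_collinear_three_visits(self):
        visits = pd.DataFrame(
            {
                "subject_id": ["a"] * 3,
                "time": [0.0, 1.0, 2.0],
                "fev1": [3000.0, 2930.0, 2860.0],
            }
        )
        slopes, _ = annualized_change(visits)
        assert slopes["slope"].iloc[0] == pytest.approx(-70.0, abs=1e-10)

    def test_single_visit_subjects_excluded_with_count(self):
        visits = pd.DataFrame(
            {
                "subject_id": ["a", "a", "b"],
                "time": [0.0, 1.0, 0.0],
                "fev1": [2000.0, 1950.0, 2200.0],
            }
        )
        slopes, summary = annualized_change(visits)
        assert summary["n_excluded"] == 1
        assert set(slopes["subject_id"]) == {"a"}

    def test_recovers_configured_decline(self, small_cfg, cohort, models):
        from airwayhet import generate_visits

        visits = generate_visits(small_cfg, cohort, rng=44)
        _, summary = annualized_change(visits)
        mc_se = summary["sd"] / np.sqrt(summary["n"])
        assert summary["mean"] == pytest.approx(small_cfg.fev1_decline, abs=4 * mc_se)
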