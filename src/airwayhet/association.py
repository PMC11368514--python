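"""Cross-sectional associations of caliber heterogeneity with lung function.

Linear models for baseline FEV1 (mL) and FEV1/FVC, logistic models for
COPD, with the heterogeneity exposure coded by quartile (Q1 reference),
per 1-SD, as the CoV, or with a restricted cubic spline, under the
model 1 / model 2 covariate sets. Optional inverse-probability selection
weights (point estimates by weighted least squares / weighted scoring,
inference by robust sandwich standard errors) and the missing-covariate
indicator method.

COPD status is derived from post-bronchodilator spirometry by one of
three definitions: ratio < 0.7 (strict inequality), ratio below a lower
limit of normal, or the ratio criterion combined with respiratory
symptoms (CAT >= 10, chronic bronchitis, or mMRC > 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import build_design
from .errors import SchemaError, SeparationError

Z95 = 1.959963984540054  # Phi^{-1}(0.975)


@dataclass(frozen=True)
class CopdDefinition:
    """Which spirometric COPD definition is active.

    ``kind``: ``ratio_lt_0p7`` (post-BD FEV1/FVC < 0.7, strict),
    ``below_lln`` (ratio below a lower limit of normal computed by
    ``lln_rule`` from the covariate row), or ``ratio_plus_symptoms``
    (the 0.7 criterion AND the symptom rule: CAT >= 10, chronic
    bronchitis, or mMRC > 0).
    """

    kind: str = "ratio_lt_0p7"
    lln_rule: Callable[[pd.DataFrame], np.ndarray] | None = None

    def __post_init__(self):
        if self.kind not in ("ratio_lt_0p7", "below_lln", "ratio_plus_symptoms"):
            raise ValueError(f"unknown COPD definition kind {self.kind!r}")
        if self.kind == "below_lln" and self.lln_rule is None:
            raise ValueError("below_lln definition requires an lln_rule")


def make_synthetic_lln_rule(cfg) -> Callable[[pd.DataFrame], np.ndarray]:
    """LLN as the 5th percentile of the generator's healthy ratio law.

    Healthy ratio | age ~ Normal(ratio_norm(age), ratio_resid_sd), so the
    LLN is the age-specific mean minus 1.645 residual SDs. Injectable:
    real-data use supplies its own rule.
    """

    def rule(df: pd.DataFrame) -> np.ndarray:
        mu = cfg.ratio_norm_intercept + cfg.ratio_age_slope * (
            df["age"].to_numpy(dtype=float) - 60.0
        )
        return mu - 1.6448536269514722 * cfg.ratio_resid_sd

    return rule


def derive_copd_status(
    data: pd.DataFrame,
    defn: CopdDefinition | None = None,
    allow_prebronchodilator: bool = False,
) -> pd.Series:
    """Boolean COPD status per row; missing spirometry yields <NA>.

    Requires post-bronchodilator records unless ``allow_prebronchodilator``
    (then pre- rows are used with a logged caveat).
    """
    defn = defn or CopdDefinition()
    for col in ("fev1", "fvc"):
        if col not in data.columns:
            raise SchemaError(f"spirometry table lacks column {col!r}")
    if "bronchodilator" in data.columns:
        pre = data["bronchodilator"] == "pre"
        if pre.any():
            if not allow_prebronchodilator:
                raise SchemaError(
                    f"{int(pre.sum())} rows are pre-bronchodilator; pass "
                    "allow_prebronchodilator=True to use them (logged caveat)"
                )
            warnings.warn(
                f"using {int(pre.sum())} pre-bronchodilator spirometry rows "
                "in a post-bronchodilator COPD definition",
                stacklevel=2,
            )
    ratio = data["fev1"].astype(float) / data["fvc"].astype(float)
    missing = ratio.isna()
    if defn.kind == "ratio_lt_0p7":
        status = ratio < 0.7
    elif defn.kind == "below_lln":
        lln = np.asarray(defn.lln_rule(data), dtype=float)
        status = ratio < lln
    else:  # ratio_plus_symptoms
        for col in ("cat_score", "mmrc", "chronic_bronchitis"):
            if col not in data.columns:
                raise SchemaError(
                    f"symptom-based COPD definition needs column {col!r}"
                )
        symptoms = (
            (data["cat_score"].astype(float) >= 10)
            | (data["chronic_bronchitis"].astype(float) == 1)
            | (data["mmrc"].astype(float) > 0)
        )
        status = (ratio < 0.7) & symptoms
    out = status.astype("boolean")
    out[missing] = pd.NA  # missing-outcome marker, never silently False
    return out


@dataclass(frozen=True)
class Contrast:
    """One reported exposure contrast (e.g. Q4 vs Q1, or per 1-SD)."""

    name: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class AssociationResult:
    """Contrast estimates with Wald 95% CIs for one fitted model."""

    outcome: str
    scale: str  # mean_difference | odds_ratio
    exposure_coding: str
    covariate_set: str
    weighted: bool
    n: int
    contrasts: list[Contrast]
    exposure_sd: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "outcome": self.outcome,
                    "scale": self.scale,
                    "contrast": c.name,
                    "estimate": c.estimate,
                    "se": c.se,
                    "ci_low": c.ci_low,
                    "ci_high": c.ci_high,
                    "p_value": c.p_value,
                    "covariate_set": self.covariate_set,
                    "weighted": self.weighted,
                    "n": self.n,
                }
                for c in self.contrasts
            ]
        )


def _contrast_names(info) -> list[tuple[str, str]]:
    mapping = {
        "exposure_Q2": "Q2 vs Q1",
        "exposure_Q3": "Q3 vs Q1",
        "exposure_Q4": "Q4 vs Q1",
        "exposure_per_sd": "per 1-SD",
        "exposure": "per unit",
        "exposure_linear": "linear term",
    }
    out = []
    for col in info.exposure_columns:
        out.append((col, mapping.get(col, col)))
    return out


def _weights_vector(data: pd.DataFrame, index, weighted: bool) -> np.ndarray:
    if not weighted:
        return np.ones(len(index))
    if "weight" not in data.columns:
        raise SchemaError("weighted fit requested but no 'weight' column present")
    w = data.loc[index, "weight"].to_numpy(dtype=float)
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise SchemaError("weights must be positive and finite")
    return w


def fit_linear_association(
    data: pd.DataFrame,
    outcome: str = "fev1",
    exposure_coding: str = "quartiles",
    covariate_set: str = "model1",
    exposure: str = "heterogeneity_sd",
    weighted: bool = False,
    missing_indicators: bool = False,
) -> AssociationResult:
    """(Weighted) least-squares association fit; Wald 95% CIs.

    With weights on, point estimates are the WLS solution and standard
    errors are robust (HC0 sandwich), appropriate for inverse-probability
    selection weights.
    """
    ycol = "ratio" if outcome == "ratio" else outcome
    if ycol == "ratio" and "ratio" not in data.columns:
        data = data.assign(ratio=data["fev1"] / data["fvc"])
    if ycol not in data.columns:
        raise SchemaError(f"analysis table lacks outcome column {ycol!r}")
    X, info = build_design(
        data, exposure_coding, covariate_set, exposure, missing_indicators
    )
    y = data.loc[X.index, ycol].to_numpy(dtype=float)
    w = _weights_vector(data, X.index, weighted)
    model = sm.WLS(y, X.to_numpy(dtype=float), weights=w)
    res = model.fit(cov_type="HC0" if weighted else "nonrobust")
    names = list(X.columns)
    contrasts = []
    for col, label in _contrast_names(info):
        j = names.index(col)
        est, se = float(res.params[j]), float(res.bse[j])
        contrasts.append(
            Contrast(
                name=label,
                estimate=est,
                se=se,
                ci_low=est - Z95 * se,
                ci_high=est + Z95 * se,
                p_value=float(2 * stats.norm.sf(abs(est / se))),
            )
        )
    return AssociationResult(
        outcome=outcome,
        scale="mean_difference",
        exposure_coding=exposure_coding,
        covariate_set=covariate_set,
        weighted=weighted,
        n=len(X),
        contrasts=contrasts,
        exposure_sd=info.exposure_sd,
        diagnostics={
            "n_dropped_missing": info.n_dropped_missing,
            "missing_indicator_columns": info.missing_indicator_columns,
            "r_squared": float(res.rsquared),
        },
    )


def fit_logistic_association(
    data: pd.DataFrame,
    outcome: str = "copd",
    exposure_coding: str = "quartiles",
    covariate_set: str = "model1",
    exposure: str = "heterogeneity_sd",
    weighted: bool = False,
    missing_indicators: bool = False,
    copd_definition: CopdDefinition | None = None,
) -> AssociationResult:
    """Maximum-likelihood logistic fit; odds ratios with Wald 95% CIs.

    The binary outcome is either an existing column or COPD derived on the
    fly via :func:`derive_copd_status`. Weighted fits use weighted scoring
    (GLM with frequency weights) and HC0 sandwich standard errors.
    Separation and non-convergence raise, never return silently.
    """
    if outcome == "copd" and "copd" not in data.columns:
        status = derive_copd_status(data, copd_definition)
        data = data.assign(copd=status)
    if outcome not in data.columns:
        raise SchemaError(f"analysis table lacks outcome column {outcome!r}")
    valid = data[outcome].notna()
    data = data.loc[valid]
    X, info = build_design(
        data, exposure_coding, covariate_set, exposure, missing_indicators
    )
    y = data.loc[X.index, outcome].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise SeparationError("outcome has a single class; logistic fit undefined")
    w = _weights_vector(data, X.index, weighted)
    Xa = X.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            model = sm.GLM(y, Xa, family=sm.families.Binomial(), freq_weights=w)
            res = model.fit(maxiter=200, tol=1e-10)
        except (
            sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning,
        ) as exc:
            raise SeparationError(f"separation detected in logistic fit: {exc}") from exc
    if not res.converged:
        raise SeparationError("logistic fit did not converge")
    mu = res.fittedvalues
    if np.all(mu[y == 1] > 1 - 1e-8) and np.all(mu[y == 0] < 1e-8):
        raise SeparationError(
            "complete separation: the model classifies every outcome perfectly"
        )
    if weighted:
        res = res.model.fit(maxiter=200, tol=1e-10, cov_type="HC0")
    names = list(X.columns)
    contrasts = []
    for col, label in _contrast_names(info):
        j = names.index(col)
        b, se = float(res.params[j]), float(res.bse[j])
        contrasts.append(
            Contrast(
                name=label,
                estimate=float(np.exp(b)),
                se=se,
                ci_low=float(np.exp(b - Z95 * se)),
                ci_high=float(np.exp(b + Z95 * se)),
                p_value=float(2 * stats.norm.sf(abs(b / se))),
            )
        )
    return AssociationResult(
        outcome=outcome,
        scale="odds_ratio",
        exposure_coding=exposure_coding,
        covariate_set=covariate_set,
        weighted=weighted,
        n=len(X),
        contrasts=contrasts,
        exposure_sd=info.exposure_sd,
        diagnostics={
            "n_dropped_missing": info.n_dropped_missing,
            "missing_indicator_columns": info.missing_indicator_columns,
            "converged": bool(res.converged),
            "n_cases": int(y.sum()),
        },
    )


@dataclass(frozen=True)
class SplineComparison:
    """Linear vs restricted-cubic-spline exposure: is there nonlinearity?"""

    aic_linear: float
    aic_spline: float
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    verdict: str  # "no improvement" | "improvement"

    @property
    def aic_difference(self) -> float:
        return self.aic_linear - self.aic_spline


def compare_spline_fit(
    data: pd.DataFrame,
    outcome: str = "fev1",
    covariate_set: str = "model1",
    exposure: str = "heterogeneity_sd",
    missing_indicators: bool = False,
) -> SplineComparison:
    """F-test of the nonlinear spline terms against the linear-exposure fit.

    Fits the model with the exposure entered linearly and with a 3-knot
    restricted cubic spline, and reports the extra-sum-of-squares F test of
    the nonlinear terms plus the AIC difference. Verdict "no improvement"
    when p >= 0.05 and the AIC improvement is < 2.
    """
    ycol = "ratio" if outcome == "ratio" else outcome
    if ycol not in data.columns:
        raise SchemaError(f"analysis table lacks outcome column {ycol!r}")
    X0, _ = build_design(data, "raw", covariate_set, exposure, missing_indicators)
    X1, _ = build_design(
        data, "rcs_spline", covariate_set, exposure, missing_indicators
    )
    y = data.loc[X0.index, ycol].to_numpy(dtype=float)
    fit0 = sm.OLS(y, X0.to_numpy(dtype=float)).fit()
    fit1 = sm.OLS(y, X1.to_numpy(dtype=float)).fit()
    q = X1.shape[1] - X0.shape[1]
    df_den = len(y) - X1.shape[1]
    f = ((fit0.ssr - fit1.ssr) / q) / (fit1.ssr / df_den)
    p = float(stats.f.sf(f, q, df_den))
    improvement = p < 0.05 and (fit0.aic - fit1.aic) >= 2
    return SplineComparison(
        aic_linear=float(fit0.aic),
        aic_spline=float(fit1.aic),
        f_statistic=float(f),
        df_num=q,
        df_den=df_den,
        p_value=p,
        verdict="improvement" if improvement else "no improvement",
    )
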