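"""Longitudinal decline models: random intercept + AR(1) residuals, ML.

The outcome at visit t of subject i is modelled as

    y_it = x_it' beta + b_i + e_it,
    b_i ~ N(0, tau^2),      e_i ~ N(0, sigma^2 R_i(rho)),

where R_i is a first-order autoregressive correlation matrix indexed by
visit order, and the fixed effects include baseline covariates, time, and
the time x heterogeneity product term (the variable of interest). Smoking
status may enter as a time-varying covariate.

Estimation is by maximum likelihood (so likelihood-ratio comparisons of
fixed-effect specifications are valid): for each variance configuration
(lambda = tau^2/sigma^2, rho), beta is the GLS solution and sigma^2 has a
closed form, leaving a 2-parameter profiled deviance optimised
numerically. The per-subject marginal covariance lambda*J + R(rho)
depends only on the visit count, so its inverse and log-determinant are
shared across subjects with equal numbers of visits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .association import Z95
from .design import apply_missing_policy, check_full_rank, covariate_frame, encode_exposure
from .errors import SchemaError


@dataclass(frozen=True)
class MixedModelSpec:
    """Specification of a longitudinal decline model.

    ``exposure_coding`` is ``per_sd``, ``raw`` or ``quartiles``;
    ``covariate_set`` is ``model1``, ``model2`` (adds baseline tobacco
    covariates and time-varying smoking status) or ``unadjusted``.
    ``ar1`` turns the AR(1) residual correlation on; ``random_intercept``
    the subject intercept. ``fix_rho`` pins rho (e.g. 0.0) instead of
    estimating it.
    """

    outcome: str = "fev1"
    exposure_coding: str = "per_sd"
    covariate_set: str = "model1"
    exposure: str = "heterogeneity_sd"
    ar1: bool = True
    random_intercept: bool = True
    fix_rho: float | None = None
    missing_indicators: bool = False


@dataclass
class MixedDeclineResult:
    """ML fit of the decline model."""

    fixed_effects: pd.DataFrame  # term, estimate, se, ci_low, ci_high, p_value
    interaction_terms: list[str]
    sigma2: float
    random_intercept_var: float
    rho: float
    loglik: float
    converged: bool
    n_subjects: int
    n_obs: int
    notes: list[str] = field(default_factory=list)

    def effect(self, term: str) -> pd.Series:
        return self.fixed_effects.set_index("term").loc[term]


def _ar1_corr(n: int, rho: float) -> np.ndarray:
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


class _GroupedData:
    """Visits grouped by per-subject visit count for shared covariance."""

    def __init__(self, X: np.ndarray, y: np.ndarray, subject: np.ndarray):
        order = np.argsort(subject, kind="stable")
        X, y, subject = X[order], y[order], subject[order]
        self.p = X.shape[1]
        self.n_obs = len(y)
        ids, starts, counts = np.unique(
            subject, return_index=True, return_counts=True
        )
        self.n_subjects = len(ids)
        self.blocks: list[tuple[int, np.ndarray, np.ndarray]] = []
        for c in np.unique(counts):
            rows = []
            for s, k in zip(starts, counts):
                if k == c:
                    rows.append((s, s + k))
            Xg = np.stack([X[a:b] for a, b in rows])  # (g, c, p)
            yg = np.stack([y[a:b] for a, b in rows])  # (g, c)
            self.blocks.append((int(c), Xg, yg))
        self.max_visits = max(c for c, _, _ in self.blocks)

    def profiled_deviance(self, lam: float, rho: float):
        """Profile out beta and sigma^2; return (-2logL, beta, XtWX, sigma2)."""
        XtWX = np.zeros((self.p, self.p))
        XtWy = np.zeros(self.p)
        yWy = 0.0
        logdet = 0.0
        for c, Xg, yg in self.blocks:
            W = lam * np.ones((c, c)) + _ar1_corr(c, rho)
            sign, ld = np.linalg.slogdet(W)
            if sign <= 0:
                return np.inf, None, None, None
            Winv = np.linalg.inv(W)
            logdet += ld * Xg.shape[0]
            WX = np.matmul(Winv, Xg)  # (g, c, p)
            XtWX += np.tensordot(Xg, WX, axes=([0, 1], [0, 1]))
            Wy = yg @ Winv  # (g, c): rows times symmetric Winv
            XtWy += np.tensordot(Xg, Wy, axes=([0, 1], [0, 1]))
            yWy += float(np.sum(Wy * yg))
        try:
            beta = np.linalg.solve(XtWX, XtWy)
        except np.linalg.LinAlgError:
            return np.inf, None, None, None
        rss = yWy - float(XtWy @ beta)
        if rss <= 0:
            rss = max(rss, 1e-300)
        sigma2 = rss / self.n_obs
        dev = self.n_obs * (math.log(2 * math.pi * sigma2) + 1.0) + logdet
        return dev, beta, XtWX, sigma2


def fit_mixed_decline(
    visits: pd.DataFrame,
    baseline: pd.DataFrame,
    spec: MixedModelSpec | None = None,
) -> MixedDeclineResult:
    """Fit the decline model and test the time x heterogeneity product term.

    ``visits`` has one row per (subject, visit): ``subject_id, time`` and
    the outcome columns (``fev1`` or ``ratio``; ratio is derived from
    fev1/fvc if absent), plus optionally ``smoking_status`` at the visit.
    ``baseline`` has one row per subject with the exposure summary
    (heterogeneity SD, mean caliber) and the adjustment covariates.

    Falls back to rho = 0 (logged in ``notes``) when AR(1) estimation is
    degenerate, e.g. when no subject has more than one visit.
    """
    spec = spec or MixedModelSpec()
    for col in ("subject_id", "time"):
        if col not in visits.columns:
            raise SchemaError(f"visit table lacks column {col!r}")
    if (visits["time"] < 0).any():
        raise SchemaError("visit times must be non-negative")
    if "subject_id" not in baseline.columns:
        raise SchemaError("baseline table lacks subject_id")
    unknown = set(visits["subject_id"]) - set(baseline["subject_id"])
    if unknown:
        raise SchemaError(
            f"{len(unknown)} visit subjects missing from the baseline table"
        )

    ycol = spec.outcome
    v = visits.copy()
    if ycol == "ratio" and "ratio" not in v.columns:
        v["ratio"] = v["fev1"] / v["fvc"]
    if ycol not in v.columns:
        raise SchemaError(f"visit table lacks outcome column {ycol!r}")
    v = v.sort_values(["subject_id", "time"], kind="stable").reset_index(drop=True)

    counts = v.groupby("subject_id").size()
    if (counts < 2).all():
        raise SchemaError(
            "all subjects have a single visit; a decline model is not identified"
        )

    base = baseline.set_index("subject_id")
    covars = covariate_frame(base, spec.covariate_set)
    covars, keep, indicator_cols = apply_missing_policy(
        covars, spec.missing_indicators
    )
    kept_ids = base.index[keep.to_numpy()]
    v = v[v["subject_id"].isin(kept_ids)].reset_index(drop=True)
    x_exposure = base.loc[
        kept_ids, "cov" if spec.exposure_coding == "cov" else spec.exposure
    ]
    exp_cols, _, exp_sd = encode_exposure(x_exposure, spec.exposure_coding)

    # expand baseline terms to visit rows
    Xb = (
        pd.concat([exp_cols, covars.loc[kept_ids]], axis=1)
        .loc[v["subject_id"]]
        .reset_index(drop=True)
    )
    X = pd.concat([pd.DataFrame({"const": 1.0}, index=v.index), Xb], axis=1)
    # time-varying smoking status (model 2)
    if spec.covariate_set == "model2" and "smoking_status" in v.columns:
        X["visit_smoking_former"] = (v["smoking_status"] == "former").astype(float)
        X["visit_smoking_current"] = (v["smoking_status"] == "current").astype(float)
        X = X.drop(columns=[c for c in ("smoking_former", "smoking_current") if c in X])
    X["time"] = v["time"].astype(float)
    interaction_terms = []
    for col in exp_cols.columns:
        suffix = col.removeprefix("exposure").lstrip("_") or "exposure"
        name = f"time_x_{suffix}"
        X[name] = X["time"] * X[col]
        interaction_terms.append(name)
    check_full_rank(X)

    data = _GroupedData(
        X.to_numpy(dtype=float),
        v[ycol].to_numpy(dtype=float),
        v["subject_id"].to_numpy(),
    )

    notes = list(indicator_cols and [f"missing indicators: {indicator_cols}"] or [])
    rho_estimable = spec.ar1 and spec.fix_rho is None and data.max_visits >= 3
    if spec.ar1 and spec.fix_rho is None and not rho_estimable:
        notes.append(
            "AR(1) degenerate (fewer than 3 visits per subject leaves rho "
            "confounded with the random intercept); rho fixed at 0"
        )
    fixed_rho = (
        spec.fix_rho
        if spec.fix_rho is not None
        else (None if rho_estimable else 0.0)
    )
    if not spec.ar1:
        fixed_rho = 0.0

    RHO_CAP = 0.995

    def unpack(u):
        j = 0
        if spec.random_intercept:
            lam = math.exp(min(u[j], 30.0))
            j += 1
        else:
            lam = 0.0
        rho = fixed_rho if fixed_rho is not None else RHO_CAP * math.tanh(u[j])
        return lam, rho

    def objective(u):
        lam, rho = unpack(u)
        dev, *_ = data.profiled_deviance(lam, rho)
        return dev

    n_free = int(spec.random_intercept) + int(fixed_rho is None)
    converged = True
    if n_free == 0:
        u_opt = np.zeros(0)
    else:
        x0 = []
        if spec.random_intercept:
            x0.append(math.log(0.5))
        if fixed_rho is None:
            x0.append(math.atanh(0.3 / RHO_CAP))
        res = optimize.minimize(
            objective, np.asarray(x0), method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 1000},
        )
        converged = bool(res.success)
        u_opt = res.x

    lam, rho = unpack(u_opt)
    dev, beta, XtWX, sigma2 = data.profiled_deviance(lam, rho)
    if beta is None:
        raise SchemaError("mixed-model likelihood is degenerate at the optimum")
    cov_beta = sigma2 * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov_beta))
    est = beta
    terms = list(X.columns)
    fe = pd.DataFrame(
        {
            "term": terms,
            "estimate": est,
            "se": se,
            "ci_low": est - Z95 * se,
            "ci_high": est + Z95 * se,
            "p_value": 2 * stats.norm.sf(np.abs(est / se)),
        }
    )
    return MixedDeclineResult(
        fixed_effects=fe,
        interaction_terms=interaction_terms,
        sigma2=float(sigma2),
        random_intercept_var=float(lam * sigma2),
        rho=float(rho),
        loglik=float(-0.5 * dev),
        converged=converged,
        n_subjects=data.n_subjects,
        n_obs=data.n_obs,
        notes=notes,
    )


def annualized_change(
    visits: pd.DataFrame, outcome: str = "fev1"
) -> tuple[pd.DataFrame, dict]:
    """Per-subject least-squares slopes and their cohort mean +/- SD.

    Subjects with fewer than 2 visits are excluded; the count is reported
    in the summary dict.
    """
    v = visits.copy()
    if outcome == "ratio" and "ratio" not in v.columns:
        v["ratio"] = v["fev1"] / v["fvc"]
    if outcome not in v.columns:
        raise SchemaError(f"visit table lacks outcome column {outcome!r}")
    counts = v.groupby("subject_id")["time"].count()
    ok = counts[counts >= 2].index
    n_excluded = int((counts < 2).sum())
    sub = v[v["subject_id"].isin(ok)]

    def slope(g: pd.DataFrame) -> float:
        t = g["time"].to_numpy(dtype=float)
        y = g[outcome].to_numpy(dtype=float)
        tc = t - t.mean()
        denom = float(tc @ tc)
        if denom == 0:
            return np.nan
        return float(tc @ (y - y.mean()) / denom)

    slopes = (
        sub.groupby("subject_id")[["time", outcome]]
        .apply(slope)
        .rename("slope")
        .reset_index()
    )
    vals = slopes["slope"].dropna()
    summary = {
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
        "n": int(len(vals)),
        "n_excluded": n_excluded,
    }
    return slopes, summary
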