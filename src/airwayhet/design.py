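"""Regression design construction shared by the association and
longitudinal models.

Covariate sets follow the study's two adjustment models:

* **model 1** (main model): age, age^2, sex, height, height^2,
  race-ethnicity, mean airway tree caliber;
* **model 2**: model 1 + cigarette smoking status, pack-years, pipe
  status/years, cigar status/years, secondhand smoke, occupational
  exposure, asthma.

Exposure codings: quartiles (Q1 = lowest heterogeneity, reference),
per-1-SD (exposure divided by its SD in the analysis sample), CoV (the
SD/mean ratio run through the same per-SD machinery), a 3-knot restricted
cubic spline, or the raw scale.

Missing covariates are handled by the indicator method when enabled
(mean-fill plus a missingness indicator column); otherwise complete-case.
Columns prefixed ``latent_`` (simulation ground truth) are never read.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CollinearityError, DegenerateExposureError, SchemaError
from .metrics import assign_quartiles
from .splines import rcs_basis

MODEL1_NUMERIC = ("age", "height", "mean_caliber")
MODEL2_EXTRA_NUMERIC = ("pack_years", "pipe_years", "cigar_years")
MODEL2_EXTRA_BINARY = ("pipe", "cigar", "secondhand", "occupational", "asthma")

EXPOSURE_CODINGS = ("quartiles", "per_sd", "cov", "rcs_spline", "raw")
COVARIATE_SETS = ("model1", "model2", "unadjusted")


@dataclass
class DesignInfo:
    """Bookkeeping from a built design."""

    exposure_columns: list[str]
    exposure_sd: float | None
    n_dropped_missing: int
    missing_indicator_columns: list[str]


def _check_no_latent(columns) -> None:
    latent = [c for c in columns if str(c).startswith("latent_")]
    if latent:
        raise SchemaError(
            f"analysis must not read simulation ground-truth columns: {latent}"
        )


def exposure_series(data: pd.DataFrame, exposure_coding: str, exposure: str) -> pd.Series:
    """The raw exposure variable for a coding (CoV coding reads ``cov``)."""
    col = "cov" if exposure_coding == "cov" else exposure
    if col not in data.columns:
        raise SchemaError(f"analysis table lacks exposure column {col!r}")
    return data[col]


def encode_exposure(
    x: pd.Series, exposure_coding: str
) -> tuple[pd.DataFrame, list[str], float | None]:
    """Encode the exposure; returns (columns, contrast names, sample SD)."""
    if exposure_coding not in EXPOSURE_CODINGS:
        raise ValueError(f"unknown exposure coding {exposure_coding!r}")
    v = x.to_numpy(dtype=float)
    if np.all(v == v[0]):
        raise DegenerateExposureError("exposure has zero variance")
    if exposure_coding == "quartiles":
        q = assign_quartiles(v)
        cols = pd.DataFrame(
            {f"exposure_{lab}": (q == lab).astype(float) for lab in ("Q2", "Q3", "Q4")},
            index=x.index,
        )
        return cols, ["Q2", "Q3", "Q4"], None
    if exposure_coding in ("per_sd", "cov"):
        sd = float(np.std(v, ddof=1))
        cols = pd.DataFrame({"exposure_per_sd": v / sd}, index=x.index)
        return cols, ["per_sd"], sd
    if exposure_coding == "rcs_spline":
        knots = np.quantile(v, [0.10, 0.50, 0.90])
        basis = rcs_basis(v, knots)
        names = ["exposure_linear"] + [
            f"exposure_rcs{j}" for j in range(1, basis.shape[1])
        ]
        return pd.DataFrame(basis, columns=names, index=x.index), names, None
    return pd.DataFrame({"exposure": v}, index=x.index), ["exposure"], None


def covariate_frame(data: pd.DataFrame, covariate_set: str) -> pd.DataFrame:
    """Adjustment covariates (without intercept or exposure)."""
    if covariate_set not in COVARIATE_SETS:
        raise ValueError(f"unknown covariate set {covariate_set!r}")
    if covariate_set == "unadjusted":
        return pd.DataFrame(index=data.index)
    for col in ("age", "sex", "height", "mean_caliber"):
        if col not in data.columns:
            raise SchemaError(f"analysis table lacks model-1 covariate {col!r}")
    out = pd.DataFrame(index=data.index)
    out["age"] = data["age"].astype(float)
    out["age_sq"] = out["age"] ** 2
    out["sex_male"] = (data["sex"] == "male").astype(float)
    out["height"] = data["height"].astype(float)
    out["height_sq"] = out["height"] ** 2
    if "race_ethnicity" in data.columns:
        race = pd.get_dummies(
            data["race_ethnicity"], prefix="race", dtype=float
        ).sort_index(axis=1)
        out = pd.concat([out, race.iloc[:, 1:]], axis=1)  # first category reference
    out["mean_caliber"] = data["mean_caliber"].astype(float)
    if covariate_set == "model2":
        if "smoking_status" in data.columns:
            out["smoking_former"] = (data["smoking_status"] == "former").astype(float)
            out["smoking_current"] = (data["smoking_status"] == "current").astype(float)
        for col in MODEL2_EXTRA_NUMERIC:
            if col in data.columns:
                out[col] = data[col].astype(float)
        for col in MODEL2_EXTRA_BINARY:
            if col in data.columns:
                out[col] = data[col].astype(float)
    return out


def apply_missing_policy(
    X: pd.DataFrame, use_indicators: bool
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Indicator method (mean-fill + indicator) or complete-case.

    Returns (X, keep-row mask, indicator column names).
    """
    miss_cols = [c for c in X.columns if X[c].isna().any()]
    if not miss_cols:
        return X, pd.Series(True, index=X.index), []
    if use_indicators:
        X = X.copy()
        indicators = []
        for c in miss_cols:
            ind = f"{c}_missing"
            X[ind] = X[c].isna().astype(float)
            X[c] = X[c].fillna(X[c].mean())
            indicators.append(ind)
        return X, pd.Series(True, index=X.index), indicators
    keep = X.notna().all(axis=1)
    return X, keep, []


def check_full_rank(X: pd.DataFrame) -> None:
    """Raise naming aliased columns if the design is rank-deficient."""
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # pivoted-QR style identification of dependent columns
        _, R = np.linalg.qr(A)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(A.shape) * np.finfo(float).eps
        aliased = [X.columns[j] for j in range(A.shape[1]) if diag[j] < tol]
        raise CollinearityError(
            f"design is rank deficient (rank {rank} < {A.shape[1]}); "
            f"aliased terms: {aliased or 'unidentified (near-collinear set)'}"
        )


def build_design(
    data: pd.DataFrame,
    exposure_coding: str,
    covariate_set: str,
    exposure: str = "heterogeneity_sd",
    missing_indicators: bool = False,
) -> tuple[pd.DataFrame, DesignInfo]:
    """Full design matrix: intercept + exposure coding + covariates."""
    _check_no_latent(data.columns)
    x = exposure_series(data, exposure_coding, exposure)
    if x.isna().any():
        raise SchemaError(f"exposure {x.name!r} has missing values")
    covars = covariate_frame(data, covariate_set)
    covars, keep, indicator_cols = apply_missing_policy(covars, missing_indicators)
    # per-1-SD scaling uses the SD within the analysis set actually fitted
    exp_cols, _, exp_sd = encode_exposure(x.loc[keep], exposure_coding)
    X = pd.concat(
        [
            pd.DataFrame({"const": 1.0}, index=exp_cols.index),
            exp_cols,
            covars.loc[keep],
        ],
        axis=1,
    )
    check_full_rank(X)
    info = DesignInfo(
        exposure_columns=list(exp_cols.columns),
        exposure_sd=exp_sd,
        n_dropped_missing=int((~keep).sum()),
        missing_indicator_columns=indicator_cols,
    )
    return X, info
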