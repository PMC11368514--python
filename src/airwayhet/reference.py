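"""Sex-stratified, airway-specific normative lumen-diameter models.

For each (sex, site) cell a normative regression of lumen diameter (mm) on
restricted-cubic-spline expansions of total lung volume (L), age (yr) and
height (cm) is fitted by least squares on a risk-factor-free sample
(never-smokers without secondhand/occupational exposure or asthma). An
observed diameter is then expressed as a percent of its predicted value:

    percent_predicted = 100 * observed / predicted(sex, site, tlv, age, height)

The model set holds exactly 38 models (2 sexes x 19 sites) and serialises
to a versioned, byte-stable JSON document.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import (
    CellSizeError,
    ExtrapolationWarning,
    MissingCovariateError,
    ProfileError,
    RankDeficiencyError,
    SchemaError,
)
from .metrics import CaliberProfile
from .sites import AIRWAY_SITES, SEXES, validate_site
from .splines import n_basis_columns, rcs_basis, validate_knots

SCHEMA_VERSION = "airwayhet-reference-1"

#: Predictors of the normative design, in design-matrix order.
PREDICTORS: tuple[str, ...] = ("tlv", "age", "height")

#: Exposure flags that must be clean in a normative (risk-factor-free) sample.
RISK_FACTOR_COLUMNS: dict[str, object] = {
    "smoking_status": "never",
    "secondhand": 0,
    "occupational": 0,
    "asthma": 0,
}


@dataclass(frozen=True)
class SubjectCovariates:
    """Covariates needed to predict a subject's expected diameters.

    Units: age in years, height in cm, tlv (CT total lung volume) in litres.
    """

    subject_id: str
    age: float
    sex: str
    height: float
    tlv: float
    race_ethnicity: str | None = None

    def __post_init__(self):
        if self.sex not in SEXES:
            raise MissingCovariateError(
                f"sex must be one of {SEXES}, got {self.sex!r}"
            )
        for name in ("age", "height", "tlv"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise MissingCovariateError(
                    f"subject {self.subject_id!r}: required covariate "
                    f"{name!r} is missing or non-finite"
                )
            if v <= 0:
                raise MissingCovariateError(
                    f"subject {self.subject_id!r}: {name} must be > 0, got {v}"
                )


@dataclass(frozen=True)
class KnotRule:
    """How knots are placed within each normative cell.

    Default: 3 knots at the 10th/50th/90th within-cell percentiles of each
    predictor, the conventional compromise between flexibility and
    stability at modest cell sizes.
    """

    quantiles: tuple[float, ...] = (0.10, 0.50, 0.90)

    def place(self, x: np.ndarray) -> np.ndarray:
        k = np.quantile(np.asarray(x, dtype=float), self.quantiles)
        return validate_knots(k)


@dataclass(frozen=True)
class ReferenceModel:
    """One fitted normative model for a (sex, site) cell."""

    sex: str
    site: str
    knots: dict[str, list[float]]
    coefficients: list[float]
    residual_sd: float
    n_fit: int

    def design_row(self, covars: SubjectCovariates) -> np.ndarray:
        return _design_matrix(
            {p: np.array([getattr(covars, p)]) for p in PREDICTORS}, self.knots
        )[0]

    def predict(self, covars: SubjectCovariates) -> float:
        return float(self.design_row(covars) @ np.asarray(self.coefficients))


def _design_matrix(values: dict[str, np.ndarray], knots: dict[str, list[float]]) -> np.ndarray:
    n = len(next(iter(values.values())))
    blocks = [np.ones((n, 1))]
    for p in PREDICTORS:
        blocks.append(rcs_basis(values[p], knots[p]))
    return np.hstack(blocks)


@dataclass
class ReferenceModelSet:
    """The complete 2-sex x 19-site family of normative models."""

    models: dict[tuple[str, str], ReferenceModel]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        expected = {(sex, site) for sex in SEXES for site in AIRWAY_SITES}
        got = set(self.models)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise SchemaError(
                f"reference model set incomplete: missing {missing[:4]}..., "
                f"unexpected {extra[:4]}"
            )

    def __getitem__(self, key: tuple[str, str]) -> ReferenceModel:
        sex, site = key
        validate_site(site)
        return self.models[(sex, site)]

    def to_json(self) -> str:
        doc = {
            "schema": SCHEMA_VERSION,
            "metadata": self.metadata,
            "models": [
                asdict(self.models[(sex, site)])
                for sex in SEXES
                for site in AIRWAY_SITES
            ],
        }
        return json.dumps(doc, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ReferenceModelSet":
        doc = json.loads(text)
        if doc.get("schema") != SCHEMA_VERSION:
            raise SchemaError(
                f"unsupported reference schema {doc.get('schema')!r}"
            )
        models = {}
        for m in doc["models"]:
            rm = ReferenceModel(
                sex=m["sex"],
                site=m["site"],
                knots={p: list(map(float, m["knots"][p])) for p in PREDICTORS},
                coefficients=list(map(float, m["coefficients"])),
                residual_sd=float(m["residual_sd"]),
                n_fit=int(m["n_fit"]),
            )
            models[(rm.sex, rm.site)] = rm
        return cls(models=models, metadata=doc.get("metadata", {}))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "ReferenceModelSet":
        with open(path) as fh:
            return cls.from_json(fh.read())


def validate_normative_sample(df: pd.DataFrame) -> None:
    """Check the risk-factor-free criterion on whichever flags are present."""
    for col, clean in RISK_FACTOR_COLUMNS.items():
        if col in df.columns:
            bad = df[col] != clean
            if bad.any():
                raise SchemaError(
                    f"normative sample violates the risk-factor-free "
                    f"criterion: {int(bad.sum())} rows have {col} != {clean!r}"
                )


def fit_reference_models(
    normative: pd.DataFrame,
    knot_rule: KnotRule | None = None,
    min_cell_n: int = 25,
    check_risk_factors: bool = True,
    metadata: dict | None = None,
) -> ReferenceModelSet:
    """Fit all 38 normative models on a risk-factor-free sample.

    ``normative`` is wide: one row per subject with columns ``subject_id,
    sex, age, height, tlv`` plus one diameter column (mm) per airway site;
    missing diameters are NaN. Each cell is fitted by ordinary least
    squares of diameter on [1, rcs(tlv), rcs(age), rcs(height)];
    ``residual_sd`` is the root mean squared residual with denominator
    n - p.
    """
    knot_rule = knot_rule or KnotRule()
    for col in ("sex", "age", "height", "tlv"):
        if col not in normative.columns:
            raise SchemaError(f"normative sample lacks required column {col!r}")
    if "subject_id" in normative.columns and normative["subject_id"].duplicated().any():
        raise SchemaError("normative sample has duplicated subject_id rows")
    if check_risk_factors:
        validate_normative_sample(normative)

    models: dict[tuple[str, str], ReferenceModel] = {}
    for sex in SEXES:
        cell_all = normative[normative["sex"] == sex]
        for site in AIRWAY_SITES:
            if site not in normative.columns:
                raise SchemaError(f"normative sample lacks diameter column {site!r}")
            cell = cell_all.dropna(subset=[site, "age", "height", "tlv"])
            n = len(cell)
            if n < min_cell_n:
                raise CellSizeError(
                    f"normative cell (sex={sex}, site={site}) has n={n} < "
                    f"minimum {min_cell_n}"
                )
            y = cell[site].to_numpy(dtype=float)
            if np.any(y <= 0):
                raise SchemaError(
                    f"non-positive diameter in cell (sex={sex}, site={site})"
                )
            knots = {
                p: knot_rule.place(cell[p].to_numpy(dtype=float)).tolist()
                for p in PREDICTORS
            }
            X = _design_matrix(
                {p: cell[p].to_numpy(dtype=float) for p in PREDICTORS}, knots
            )
            p_cols = X.shape[1]
            rank = np.linalg.matrix_rank(X)
            if rank < p_cols:
                raise RankDeficiencyError(
                    f"rank-deficient normative design in cell (sex={sex}, "
                    f"site={site}): rank {rank} < {p_cols} columns; "
                    f"consider fewer knots"
                )
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            dof = n - p_cols
            residual_sd = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
            models[(sex, site)] = ReferenceModel(
                sex=sex,
                site=site,
                knots=knots,
                coefficients=beta.tolist(),
                residual_sd=residual_sd,
                n_fit=n,
            )
    meta = {
        "knot_quantiles": list(knot_rule.quantiles),
        "normative_n": int(normative["subject_id"].nunique())
        if "subject_id" in normative.columns
        else int(len(normative)),
        "min_cell_n": min_cell_n,
    }
    if metadata:
        meta.update(metadata)
    return ReferenceModelSet(models=models, metadata=meta)


def _check_envelope(model: ReferenceModel, covars: SubjectCovariates) -> None:
    for p in PREDICTORS:
        v = getattr(covars, p)
        k = model.knots[p]
        if v < k[0] or v > k[-1]:
            warnings.warn(
                f"subject {covars.subject_id!r}: {p}={v} lies outside the "
                f"boundary knots [{k[0]}, {k[-1]}] of the (sex={model.sex}, "
                f"site={model.site}) normative model; prediction is a linear "
                f"extrapolation",
                ExtrapolationWarning,
                stacklevel=3,
            )


def predict_expected_diameter(
    models: ReferenceModelSet, covars: SubjectCovariates, site: str
) -> float:
    """Expected (predicted) lumen diameter in mm for one subject and site.

    Deterministic; warns (does not fail) when a covariate lies beyond the
    model's boundary knots, where the prediction is a linear extrapolation.
    """
    validate_site(site)
    model = models[(covars.sex, site)]
    _check_envelope(model, covars)
    return model.predict(covars)


def predict_expected_diameters(
    models: ReferenceModelSet, covars: pd.DataFrame, warn_extrapolation: bool = False
) -> pd.DataFrame:
    """Vectorised expected diameters: one row per subject, one column per site."""
    for col in ("sex", "age", "height", "tlv"):
        if col not in covars.columns:
            raise MissingCovariateError(f"covariate table lacks column {col!r}")
        if col != "sex" and covars[col].isna().any():
            raise MissingCovariateError(f"covariate column {col!r} has missing values")
    out = pd.DataFrame(
        np.nan, index=covars.index, columns=list(AIRWAY_SITES), dtype=float
    )
    for sex in SEXES:
        mask = (covars["sex"] == sex).to_numpy()
        if not mask.any():
            continue
        sub = covars.loc[mask]
        vals = {p: sub[p].to_numpy(dtype=float) for p in PREDICTORS}
        for site in AIRWAY_SITES:
            model = models[(sex, site)]
            X = _design_matrix(vals, model.knots)
            out.loc[mask, site] = X @ np.asarray(model.coefficients)
            if warn_extrapolation:
                for p in PREDICTORS:
                    k = model.knots[p]
                    n_out = int(((vals[p] < k[0]) | (vals[p] > k[-1])).sum())
                    if n_out:
                        warnings.warn(
                            f"{n_out} subjects extrapolate beyond the {p} "
                            f"boundary knots of (sex={sex}, site={site})",
                            ExtrapolationWarning,
                            stacklevel=2,
                        )
    return out


def percent_predicted_profile(
    models: ReferenceModelSet,
    covars: SubjectCovariates,
    observed: dict[str, float],
) -> CaliberProfile:
    """Percent-predicted profile: 100 * observed / predicted per site.

    Sites absent from ``observed`` are simply missing from the profile.
    """
    if not observed:
        raise ProfileError(
            f"subject {covars.subject_id!r}: no observed diameters supplied"
        )
    values: dict[str, float] = {}
    for site, d in observed.items():
        validate_site(site)
        if d is None or not np.isfinite(d) or d <= 0:
            raise ProfileError(
                f"subject {covars.subject_id!r}: observed diameter at site "
                f"{site!r} must be positive, got {d!r}"
            )
        pred = predict_expected_diameter(models, covars, site)
        values[site] = 100.0 * d / pred
    return CaliberProfile(subject_id=covars.subject_id, values=values)


def percent_predicted_table(
    models: ReferenceModelSet, subjects: pd.DataFrame
) -> pd.DataFrame:
    """Vectorised percent-predicted values for a cohort table.

    ``subjects`` carries the covariate columns plus the 19 diameter columns
    (mm, NaN where unmeasured). Returns a frame of percent-predicted values
    with the same index and one column per site.
    """
    pred = predict_expected_diameters(models, subjects)
    site_cols = [c for c in AIRWAY_SITES if c in subjects.columns]
    if not site_cols:
        raise SchemaError("subject table has no airway-site diameter columns")
    obs = subjects[site_cols].to_numpy(dtype=float)
    if np.any(obs[np.isfinite(obs)] <= 0):
        raise ProfileError("observed diameters must be strictly positive")
    out = 100.0 * obs / pred[site_cols].to_numpy()
    return pd.DataFrame(out, index=subjects.index, columns=site_cols)
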