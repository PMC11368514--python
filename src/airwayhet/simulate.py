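"""Synthetic cohorts with known ground truth.

No individual-level study data are deposited for this problem, so every
analysis stage is validated on generated cohorts that emulate the study's
statistical structure:

* a **normative sample** of risk-factor-free never-smokers for fitting the
  sex-stratified reference equations;
* a **study cohort** whose 19 percent-predicted diameters are Gaussian
  within subject (site values ~ N(m_i, sigma_i^2)), with cohort-level
  moments matching the reported summaries (mean caliber 99 +/- 10 %,
  heterogeneity 14 +/- 5 %), and spirometry linearly linked to mean
  caliber and heterogeneity with configurable effect sizes;
* **longitudinal visits** with annual decline, a subject random intercept
  and AR(1) within-subject noise, plus a time-varying smoking status;
* **stratified selection** with known inclusion probabilities for
  inverse-probability-weighted analysis.

Ground-truth semantics: a subject's true heterogeneity is the *realised*
19-site profile SD (the measurand itself is that statistic), and likewise
the true mean caliber is the realised profile mean. The latent Gaussian
mean and Gamma scale that generate the site values are internal mixing
parameters, calibrated in closed form (via the normal-theory c4 constant
and the variance decomposition of the 19-site mean/SD) so that the
realised per-subject summaries have exactly the configured cohort moments.
Outcomes are generated from the realised summaries, so downstream
regression recovery is unbiased by construction.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import gammaln

from .errors import ConfigError
from .reference import ReferenceModelSet, predict_expected_diameters
from .sites import AIRWAY_SITES, N_SITES

#: Structural per-site lumen-diameter scales (mm) at the reference
#: covariate point (tlv 4.5 L, height 170 cm, age 60 yr); trachea largest,
#: subsegmental path averages smallest.
SITE_SCALES_MM: dict[str, float] = {
    "TRACHEA": 16.9,
    "RMB": 14.0,
    "LMB": 11.8,
    "BRONINT": 10.5,
    "RUL": 8.4,
    "RML": 6.0,
    "RLL": 9.0,
    "LUL": 8.8,
    "LLL": 8.2,
    "RB1": 4.7,
    "RB4": 4.0,
    "RB10": 4.5,
    "LB1": 4.6,
    "LB10": 4.4,
    "sRB1": 3.4,
    "sRB4": 3.0,
    "sRB10": 3.2,
    "sLB1": 3.3,
    "sLB10": 3.1,
}

RACE_CATEGORIES = ("white", "black", "hispanic", "chinese")


def c4_constant(n: int) -> float:
    """Normal-theory unbiasing constant c4: E[sample SD] = c4(n) * sigma."""
    return math.sqrt(2.0 / (n - 1)) * math.exp(gammaln(n / 2) - gammaln((n - 1) / 2))


@dataclass
class SimulationConfig:
    """All generator knobs, with defaults set to the study conditions.

    Percent-predicted structure defaults reproduce the reported cohort
    summaries (mean caliber 99 +/- 10 % predicted, heterogeneity
    14 +/- 5 %); the cross-sectional effect default (-12 mL FEV1 per 1% of
    heterogeneity, i.e. -60 mL per 1-SD of 5%) and the annual decline
    (-33 mL/yr) are on the magnitude scale of the reported estimates.
    """

    # cohort sizes
    n_subjects: int = 2500
    n_normative: int = 800

    # covariate distributions
    age_range: tuple[float, float] = (45.0, 85.0)
    female_fraction: float = 0.5
    height_mean_female: float = 162.0
    height_sd_female: float = 6.0
    height_mean_male: float = 176.0
    height_sd_male: float = 7.0
    tlv_intercept: float = 4.3
    tlv_height_slope: float = 0.045  # L per cm from 170
    tlv_male_shift: float = 0.7
    tlv_sd: float = 0.55
    tlv_floor: float = 1.5

    # normative diameter law: scale * (tlv/4.5)^a * (height/170)^b * (1 + c*(age-60))
    diam_tlv_exp: float = 0.35
    diam_height_exp: float = 0.30
    diam_age_slope: float = -0.0015
    diam_noise_sd: float = 0.08  # log-scale sd of multiplicative noise
    measurement_noise_sd: float = 0.0  # within-site scan noise, log scale

    # percent-predicted structure (cohort moments of realised summaries)
    pop_mean_caliber: float = 99.0
    between_subject_mean_sd: float = 10.0
    het_mean: float = 14.0
    het_sd: float = 5.0
    het_floor: float = 0.5

    # cross-sectional spirometry
    beta_mean_fev1: float = 15.0  # mL per 1% of mean caliber
    beta_het_fev1: float = -12.0  # mL per 1% of heterogeneity
    fev1_resid_sd: float = 400.0
    beta_mean_ratio: float = 0.0015
    beta_het_ratio: float = -0.001
    ratio_resid_sd: float = 0.05
    fev1_norm_intercept: float = 3200.0  # mL at age 60, female, height 170
    fev1_age_slope: float = -28.0
    fev1_male_shift: float = 650.0
    fev1_height_slope: float = 22.0
    ratio_norm_intercept: float = 0.76
    ratio_age_slope: float = -0.0012

    # exposures and their outcome effects
    smoking_probs: tuple[float, float, float] = (0.45, 0.35, 0.20)  # never/former/current
    pack_years_mean: float = 25.0
    pack_years_sd: float = 18.0
    secondhand_p: float = 0.30
    occupational_p: float = 0.25
    asthma_p: float = 0.10
    fev1_current_effect: float = -150.0
    fev1_former_effect: float = -60.0
    fev1_packyear_effect: float = -3.0
    ratio_current_effect: float = -0.02
    ratio_packyear_effect: float = -0.0008
    fev1_asthma_effect: float = -100.0
    ratio_asthma_effect: float = -0.01
    missing_covariate_rate: float = 0.0

    # longitudinal structure
    visit_times: tuple[float, ...] = (0.0, 3.0, 6.0)
    fev1_decline: float = -33.0  # mL/yr
    interaction_gamma: float = 0.0  # mL/yr per 1% heterogeneity
    ratio_decline: float = -0.002
    random_intercept_sd: float = 150.0
    ar1_rho: float = 0.4
    ar1_sd: float = 120.0
    ratio_random_intercept_sd: float = 0.02
    ratio_ar1_sd: float = 0.015
    smoking_transition_rate: float = 0.05

    # stratified selection (stratum label -> inclusion probability)
    selection_probs: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        bad: list[str] = []
        for name in (
            "diam_noise_sd", "measurement_noise_sd", "between_subject_mean_sd",
            "het_sd", "fev1_resid_sd", "ratio_resid_sd", "random_intercept_sd",
            "ar1_sd", "ratio_random_intercept_sd", "ratio_ar1_sd",
            "pack_years_sd", "tlv_sd",
        ):
            if getattr(self, name) < 0:
                bad.append(f"{name} must be >= 0")
        if not (-1.0 < self.ar1_rho < 1.0):
            bad.append("ar1_rho must satisfy |rho| < 1")
        if self.het_mean < 0 or self.het_floor <= 0:
            bad.append("het_mean must be >= 0 and het_floor > 0")
        if self.het_mean == 0 and self.het_sd > 0:
            bad.append("het_sd must be 0 when het_mean is 0")
        if self.n_subjects < 1 or self.n_normative < 1:
            bad.append("n_subjects and n_normative must be >= 1")
        if not (0.0 <= self.female_fraction <= 1.0):
            bad.append("female_fraction must lie in [0, 1]")
        if abs(sum(self.smoking_probs) - 1.0) > 1e-9 or min(self.smoking_probs) < 0:
            bad.append("smoking_probs must be a probability vector")
        if any(t < 0 for t in self.visit_times) or list(self.visit_times) != sorted(
            self.visit_times
        ):
            bad.append("visit_times must be non-negative and non-decreasing")
        for h, p in self.selection_probs.items():
            if not (0.0 < p <= 1.0):
                bad.append(f"selection_probs[{h!r}] must lie in (0, 1]")
        if self.het_sd > 0:
            c4 = c4_constant(N_SITES)
            mu_sigma = self.het_mean / c4
            if self.het_sd**2 - (1 - c4**2) * mu_sigma**2 <= 0:
                bad.append(
                    "het_sd too small for the site-sampling variability of a "
                    f"{N_SITES}-site SD at het_mean={self.het_mean}"
                )
            if (
                self.between_subject_mean_sd > 0
                and self.between_subject_mean_sd**2
                <= (self.het_mean / c4) ** 2 / N_SITES
            ):
                bad.append(
                    "between_subject_mean_sd too small for the site-sampling "
                    "variability of the profile mean"
                )
        if bad:
            raise ConfigError("invalid simulation config: " + "; ".join(bad))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation config fields: {sorted(unknown)}")
        kwargs = dict(d)
        for name in ("age_range", "smoking_probs", "visit_times"):
            if name in kwargs and isinstance(kwargs[name], list):
                kwargs[name] = tuple(kwargs[name])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SyntheticCohort:
    """Generated subjects (wide table), optional visits, and a generation log.

    Subject columns prefixed ``latent_`` carry the ground truth used to
    generate outcomes; analysis code never reads them (the model-design
    builder rejects them).
    """

    subjects: pd.DataFrame
    visits: pd.DataFrame | None
    config: SimulationConfig
    log: dict = field(default_factory=dict)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _draw_covariates(cfg: SimulationConfig, n: int, rng, prefix: str) -> pd.DataFrame:
    female = rng.random(n) < cfg.female_fraction
    sex = np.where(female, "female", "male")
    age = rng.uniform(*cfg.age_range, size=n)
    height = np.where(
        female,
        rng.normal(cfg.height_mean_female, cfg.height_sd_female, n),
        rng.normal(cfg.height_mean_male, cfg.height_sd_male, n),
    )
    tlv = (
        cfg.tlv_intercept
        + cfg.tlv_height_slope * (height - 170.0)
        + cfg.tlv_male_shift * (~female)
        + rng.normal(0.0, cfg.tlv_sd, n)
    )
    tlv = np.maximum(tlv, cfg.tlv_floor)
    race = rng.choice(RACE_CATEGORIES, size=n, p=(0.4, 0.25, 0.2, 0.15))
    return pd.DataFrame(
        {
            "subject_id": [f"{prefix}{i:05d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "height": height,
            "tlv": tlv,
            "race_ethnicity": race,
        }
    )


def normative_conditional_means(cfg: SimulationConfig, covars: pd.DataFrame) -> pd.DataFrame:
    """Analytic E[diameter | covariates] per site under the generating law."""
    g = (
        (covars["tlv"].to_numpy() / 4.5) ** cfg.diam_tlv_exp
        * (covars["height"].to_numpy() / 170.0) ** cfg.diam_height_exp
        * (1.0 + cfg.diam_age_slope * (covars["age"].to_numpy() - 60.0))
    )
    lognorm_mean = math.exp(0.5 * cfg.diam_noise_sd**2)
    out = {
        site: SITE_SCALES_MM[site] * g * lognorm_mean for site in AIRWAY_SITES
    }
    return pd.DataFrame(out, index=covars.index)


def generate_normative_sample(cfg: SimulationConfig, rng=0) -> pd.DataFrame:
    """Risk-factor-free normative sample, wide (one row per subject).

    Diameters follow ``scale_site * g(tlv, height, age) * exp(eps)`` with
    iid Gaussian log-scale noise; all exposure flags are clean so the
    sample satisfies the never-smoker / no-secondhand / no-occupational /
    no-asthma criterion.
    """
    cfg.validate()
    rng = _as_rng(rng)
    df = _draw_covariates(cfg, cfg.n_normative, rng, prefix="N")
    cond = normative_conditional_means(cfg, df)
    noise = rng.normal(0.0, cfg.diam_noise_sd, size=(cfg.n_normative, N_SITES))
    lognorm_mean = math.exp(0.5 * cfg.diam_noise_sd**2)
    for j, site in enumerate(AIRWAY_SITES):
        df[site] = cond[site].to_numpy() / lognorm_mean * np.exp(noise[:, j])
    df["smoking_status"] = "never"
    df["pack_years"] = 0.0
    for col in ("pipe", "cigar", "secondhand", "occupational", "asthma"):
        df[col] = 0
    return df


def _heterogeneity_mixing_params(cfg: SimulationConfig) -> tuple[float, float, float]:
    """(mu_sigma, var_sigma, var_m): c4-calibrated latent mixing moments."""
    c4 = c4_constant(N_SITES)
    mu_sigma = cfg.het_mean / c4
    var_sigma = max(cfg.het_sd**2 - (1 - c4**2) * mu_sigma**2, 0.0)
    e_sigma2 = var_sigma + mu_sigma**2
    var_m = max(cfg.between_subject_mean_sd**2 - e_sigma2 / N_SITES, 0.0)
    return mu_sigma, var_sigma, var_m


def generate_cohort(
    cfg: SimulationConfig, models: ReferenceModelSet, rng=0
) -> SyntheticCohort:
    """Study cohort with diameters, baseline spirometry, exposures, symptoms.

    Site percent-predicted values are N(m_i, sigma_i^2) truncated positive;
    observed diameters are the reference-model predictions scaled by the
    percent-predicted values (times optional measurement noise). Baseline
    FEV1 and FEV1/FVC are linear in the realised profile mean and SD plus
    exposure effects and Gaussian error; FVC = FEV1 / ratio, so the ratio
    lies in (0, 1) and FEV1 <= FVC by construction.
    """
    cfg.validate()
    rng = _as_rng(rng)
    n = cfg.n_subjects
    df = _draw_covariates(cfg, n, rng, prefix="S")

    # exposures
    status = rng.choice(["never", "former", "current"], size=n, p=cfg.smoking_probs)
    ever = status != "never"
    shape = (cfg.pack_years_mean / cfg.pack_years_sd) ** 2 if cfg.pack_years_sd > 0 else 1.0
    scale = cfg.pack_years_mean / shape
    pack = np.where(ever, rng.gamma(shape, scale, size=n), 0.0)
    df["smoking_status"] = status
    df["pack_years"] = pack
    df["pipe"] = (rng.random(n) < 0.05).astype(int)
    df["pipe_years"] = np.where(df["pipe"] == 1, rng.uniform(1, 20, n), 0.0)
    df["cigar"] = (rng.random(n) < 0.06).astype(int)
    df["cigar_years"] = np.where(df["cigar"] == 1, rng.uniform(1, 20, n), 0.0)
    df["secondhand"] = (rng.random(n) < cfg.secondhand_p).astype(int)
    df["occupational"] = (rng.random(n) < cfg.occupational_p).astype(int)
    df["asthma"] = (rng.random(n) < cfg.asthma_p).astype(int)

    # latent mixing draws, c4-calibrated (see module docstring)
    mu_sigma, var_sigma, var_m = _heterogeneity_mixing_params(cfg)
    m_lat = rng.normal(cfg.pop_mean_caliber, math.sqrt(var_m), n)
    if cfg.het_mean == 0:
        sigma = np.zeros(n)
    elif var_sigma > 0:
        k = mu_sigma**2 / var_sigma
        sigma = np.maximum(rng.gamma(k, var_sigma / mu_sigma, n), cfg.het_floor)
    else:
        sigma = np.full(n, mu_sigma)

    p = rng.normal(m_lat[:, None], sigma[:, None], size=(n, N_SITES))
    n_trunc = 0
    bad = p <= 0
    while bad.any():  # truncation at > 0; negligible mass at defaults
        n_trunc += int(bad.sum())
        p[bad] = rng.normal(
            np.broadcast_to(m_lat[:, None], p.shape)[bad],
            np.broadcast_to(sigma[:, None], p.shape)[bad],
        )
        bad = p <= 0

    m_real = p.mean(axis=1)
    s_real = p.std(axis=1, ddof=1)

    pred = predict_expected_diameters(models, df)
    diam = pred[list(AIRWAY_SITES)].to_numpy() * p / 100.0
    if cfg.measurement_noise_sd > 0:
        diam = diam * np.exp(
            rng.normal(0.0, cfg.measurement_noise_sd, size=diam.shape)
        )
    for j, site in enumerate(AIRWAY_SITES):
        df[site] = diam[:, j]

    male = (df["sex"] == "male").to_numpy()
    fev1_norm = (
        cfg.fev1_norm_intercept
        + cfg.fev1_age_slope * (df["age"].to_numpy() - 60.0)
        + cfg.fev1_male_shift * male
        + cfg.fev1_height_slope * (df["height"].to_numpy() - 170.0)
    )
    smoke_fev1 = (
        cfg.fev1_current_effect * (status == "current")
        + cfg.fev1_former_effect * (status == "former")
        + cfg.fev1_packyear_effect * pack
        + cfg.fev1_asthma_effect * df["asthma"].to_numpy()
    )
    fev1 = (
        fev1_norm
        + cfg.beta_mean_fev1 * (m_real - 100.0)
        + cfg.beta_het_fev1 * (s_real - cfg.het_mean)
        + smoke_fev1
        + rng.normal(0.0, cfg.fev1_resid_sd, n)
    )
    n_fev1_clip = int((fev1 < 200.0).sum())
    fev1 = np.maximum(fev1, 200.0)

    ratio = (
        cfg.ratio_norm_intercept
        + cfg.ratio_age_slope * (df["age"].to_numpy() - 60.0)
        + cfg.beta_mean_ratio * (m_real - 100.0)
        + cfg.beta_het_ratio * (s_real - cfg.het_mean)
        + cfg.ratio_current_effect * (status == "current")
        + cfg.ratio_packyear_effect * pack
        + cfg.ratio_asthma_effect * df["asthma"].to_numpy()
        + rng.normal(0.0, cfg.ratio_resid_sd, n)
    )
    n_ratio_clip = int(((ratio < 0.30) | (ratio > 0.95)).sum())
    ratio = np.clip(ratio, 0.30, 0.95)

    df["fev1"] = fev1
    df["fvc"] = fev1 / ratio
    df["bronchodilator"] = "post"

    # symptom scores, loosely coupled to obstruction severity
    sev = np.clip(0.75 - ratio, 0.0, None)
    cat = np.clip(np.rint(rng.normal(6.0 + 60.0 * sev, 4.0)), 0, 40).astype(int)
    mmrc = np.clip(np.rint(rng.normal(0.4 + 8.0 * sev, 0.8)), 0, 4).astype(int)
    bronchitis = (
        rng.random(n) < 1.0 / (1.0 + np.exp(-(-2.2 + 8.0 * sev + 0.8 * (status == "current"))))
    ).astype(int)
    df["cat_score"] = cat
    df["mmrc"] = mmrc
    df["chronic_bronchitis"] = bronchitis

    if cfg.missing_covariate_rate > 0:
        for col in ("pack_years", "secondhand", "occupational"):
            miss = rng.random(n) < cfg.missing_covariate_rate
            df.loc[miss, col] = np.nan

    df["latent_mean"] = m_real
    df["latent_sd"] = s_real
    df["latent_sigma"] = sigma
    df["weight"] = 1.0

    log = {
        "n_truncated_percent_predicted": n_trunc,
        "n_fev1_floored": n_fev1_clip,
        "n_ratio_clipped": n_ratio_clip,
    }
    return SyntheticCohort(subjects=df, visits=None, config=cfg, log=log)


def generate_visits(cfg: SimulationConfig, cohort: SyntheticCohort, rng=0) -> pd.DataFrame:
    """Longitudinal visit table under the decline model.

    FEV1_it = FEV1_i0 + (decline + gamma * (s_i - het_mean)) * t + b_i + e_it
    with b_i ~ N(0, tau^2) and e_it a stationary AR(1) sequence in visit
    order with marginal sd ``ar1_sd`` and parameter rho. The FEV1/FVC
    ratio follows the same structure with its own (smaller) components;
    FVC_it = FEV1_it / ratio_it. Smoking status evolves by a two-state
    current<->former Markov step per visit.
    """
    cfg.validate()
    if len(cohort.subjects) == 0:
        raise ConfigError("cohort is empty; cannot generate visits")
    rng = _as_rng(rng)
    sub = cohort.subjects
    n = len(sub)
    times = np.asarray(cfg.visit_times, dtype=float)
    T = times.size
    s_real = sub["latent_sd"].to_numpy()
    slope = cfg.fev1_decline + cfg.interaction_gamma * (s_real - cfg.het_mean)

    def ar1_noise(sd: float) -> np.ndarray:
        if sd == 0:
            return np.zeros((n, T))
        e = np.empty((n, T))
        e[:, 0] = rng.normal(0.0, sd, n)
        innov_sd = sd * math.sqrt(1.0 - cfg.ar1_rho**2)
        for t in range(1, T):
            e[:, t] = cfg.ar1_rho * e[:, t - 1] + rng.normal(0.0, innov_sd, n)
        return e

    b = rng.normal(0.0, cfg.random_intercept_sd, n) if cfg.random_intercept_sd > 0 else np.zeros(n)
    e = ar1_noise(cfg.ar1_sd)
    fev1 = sub["fev1"].to_numpy()[:, None] + slope[:, None] * times[None, :] + b[:, None] + e
    fev1 = np.maximum(fev1, 200.0)

    b_r = (
        rng.normal(0.0, cfg.ratio_random_intercept_sd, n)
        if cfg.ratio_random_intercept_sd > 0
        else np.zeros(n)
    )
    e_r = ar1_noise(cfg.ratio_ar1_sd)
    ratio0 = (sub["fev1"] / sub["fvc"]).to_numpy()
    ratio = ratio0[:, None] + cfg.ratio_decline * times[None, :] + b_r[:, None] + e_r
    ratio = np.clip(ratio, 0.2, 0.98)

    # two-state smoking transitions (never stays never)
    status = np.tile(sub["smoking_status"].to_numpy(dtype=object)[:, None], (1, T))
    rate = cfg.smoking_transition_rate
    for t in range(1, T):
        prev = status[:, t - 1]
        u = rng.random(n)
        nxt = prev.copy()
        nxt[(prev == "current") & (u < rate)] = "former"
        nxt[(prev == "former") & (u < rate / 2.0)] = "current"
        status[:, t] = nxt

    visits = pd.DataFrame(
        {
            "subject_id": np.repeat(sub["subject_id"].to_numpy(), T),
            "time": np.tile(times, n),
            "fev1": fev1.ravel(),
            "fvc": (fev1 / ratio).ravel(),
            "ratio": ratio.ravel(),
            "smoking_status": status.ravel(),
        }
    )
    return visits


def default_strata(subjects: pd.DataFrame) -> pd.Series:
    """COLD-style strata: smoking history x spirometric obstruction."""
    ever = np.where(subjects["smoking_status"] == "never", "never", "ever")
    obstructed = np.where(
        subjects["fev1"] / subjects["fvc"] < 0.7, "obstructed", "normal"
    )
    return pd.Series(
        [f"{e}_{o}" for e, o in zip(ever, obstructed)], index=subjects.index
    )


def assign_selection_weights(
    subjects: pd.DataFrame,
    probabilities: dict[str, float],
    strata: pd.Series | None = None,
    rng=0,
) -> pd.DataFrame:
    """Stratified Bernoulli selection with inverse-probability weights.

    Each stratum ``h`` is subsampled with its inclusion probability
    ``pi_h``; retained subjects receive weight ``1 / pi_h``, so weighted
    totals are Horvitz-Thompson estimates of the pre-selection stratum
    sizes. Returns the retained rows with ``stratum`` and ``weight``
    columns.
    """
    rng = _as_rng(rng)
    strata = default_strata(subjects) if strata is None else strata
    labels = pd.unique(strata)
    missing = [h for h in labels if h not in probabilities]
    if missing:
        raise ConfigError(f"no inclusion probability for strata {sorted(missing)}")
    for h, pi in probabilities.items():
        if not (0.0 < pi <= 1.0):
            raise ConfigError(f"inclusion probability for {h!r} must be in (0, 1], got {pi}")
    pi = strata.map(probabilities).to_numpy(dtype=float)
    keep = rng.random(len(subjects)) < pi
    out = subjects.loc[keep].copy()
    out["stratum"] = strata.loc[keep].to_numpy()
    out["weight"] = 1.0 / pi[keep]
    return out
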