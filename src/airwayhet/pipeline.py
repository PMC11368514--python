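"""End-to-end orchestration and simulation-based validation.

``run_pipeline`` drives the whole workflow under a single seed: generate
(or ingest) data, fit the sex-stratified reference models, compute
per-subject caliber summaries, run the cross-sectional and longitudinal
association battery, and write every table as CSV plus a plain-text
rendering, together with a manifest (seed, config hash, output hashes)
that makes any run exactly reproducible.

``run_validation_study`` runs replicate simulations per scenario (null
and non-null cross-sectional effects, null and non-null decline
interactions) and reports estimate bias, empirical SE, 95% CI coverage
and rejection rates with Monte-Carlo standard errors.

One master seed governs a run; per-stage generators are spawned from a
``numpy`` SeedSequence so stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    derive_copd_status,
    fit_linear_association,
    fit_logistic_association,
)
from .errors import ConfigError, SchemaError
from .longitudinal import MixedModelSpec, annualized_change, fit_mixed_decline
from .metrics import density_curve, distribution_report, spearman_with_ci, summarize_cohort
from .reference import ReferenceModelSet, fit_reference_models, percent_predicted_table
from .simulate import (
    SimulationConfig,
    assign_selection_weights,
    generate_cohort,
    generate_normative_sample,
    generate_visits,
)
from .sites import AIRWAY_SITES

logger = logging.getLogger("airwayhet")

LATENT_COLUMNS = ("latent_mean", "latent_sd", "latent_sigma")

SUBJECT_REQUIRED = ("subject_id", "sex", "age", "height", "tlv")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "simulate"  # simulate | analyze | validate
    out_dir: str = "airwayhet_out"
    seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    subjects_csv: str | None = None
    visits_csv: str | None = None
    reference_json: str | None = None
    normative_csv: str | None = None
    validation_replicates: int = 200
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown run-config fields: {sorted(unknown)}")
        cfg = cls(**d, sim=SimulationConfig.from_dict(sim) if isinstance(sim, dict) else sim)
        if cfg.mode not in ("simulate", "analyze", "validate"):
            raise ConfigError(f"mode must be simulate|analyze|validate, got {cfg.mode!r}")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent per-stage generators derived from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _config_hash(config: RunConfig) -> str:
    d = config.to_dict()
    d.pop("out_dir", None)  # where outputs land does not change what they are
    d.pop("log_level", None)
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_subjects_schema(df: pd.DataFrame) -> None:
    """Row/column-addressed validation of the subjects CSV contract."""
    for col in SUBJECT_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"subjects table lacks required column {col!r}")
    sites = [c for c in AIRWAY_SITES if c in df.columns]
    if not sites:
        raise SchemaError("subjects table has none of the 19 airway-site columns")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise SchemaError(f"duplicated subject_id {dup!r}")
    for col in ("age", "height", "tlv"):
        bad = df.index[(df[col] <= 0) | df[col].isna()]
        if len(bad):
            raise SchemaError(f"column {col!r}: non-positive/missing at row {bad[0]}")
    for col in sites:
        bad = df.index[df[col].notna() & (df[col] <= 0)]
        if len(bad):
            raise SchemaError(f"diameter column {col!r}: non-positive at row {bad[0]}")


def analysis_view(subjects: pd.DataFrame) -> pd.DataFrame:
    """The subjects table with simulation ground-truth columns removed."""
    return subjects.drop(columns=[c for c in LATENT_COLUMNS if c in subjects.columns])


def _summaries_with_covariates(
    subjects: pd.DataFrame, models: ReferenceModelSet
) -> pd.DataFrame:
    pp = percent_predicted_table(models, subjects)
    summaries = summarize_cohort(pp)
    return pd.concat([subjects.reset_index(drop=True), summaries.reset_index(drop=True)], axis=1)


def _render_table2(results: list, outcome_label: str) -> str:
    """Plain-text rendering in the quartile + per-1-SD row layout."""
    lines = [f"== {outcome_label} =="]
    for res in results:
        lines.append(f"-- covariates: {res.covariate_set}, weighted: {res.weighted} --")
        if res.exposure_coding == "quartiles":
            lines.append("Q1: Reference")
        for c in res.contrasts:
            if res.scale == "odds_ratio":
                lines.append(
                    f"{c.name}: OR {c.estimate:.2f} "
                    f"({c.ci_low:.2f}, {c.ci_high:.2f}) P = {c.p_value:.3g}"
                )
            else:
                lines.append(
                    f"{c.name}: {c.estimate:.1f} "
                    f"({c.ci_low:.1f}, {c.ci_high:.1f}) P = {c.p_value:.3g}"
                )
    return "\n".join(lines) + "\n"


def run_association_battery(
    analysis: pd.DataFrame, weighted: bool = False
) -> tuple[pd.DataFrame, str]:
    """The standard cross-sectional battery: FEV1, ratio, COPD; quartile +
    per-1-SD codings; model 1 and model 2."""
    frames, text = [], []
    for outcome, fitter in (
        ("fev1", fit_linear_association),
        ("ratio", fit_linear_association),
        ("copd", fit_logistic_association),
    ):
        block = []
        for covset in ("model1", "model2"):
            for coding in ("quartiles", "per_sd"):
                res = fitter(
                    analysis,
                    outcome=outcome,
                    exposure_coding=coding,
                    covariate_set=covset,
                    weighted=weighted,
                )
                frames.append(res.to_frame())
                block.append(res)
        text.append(_render_table2(block, outcome))
    return pd.concat(frames, ignore_index=True), "\n".join(text)


def run_longitudinal_battery(
    visits: pd.DataFrame, baseline: pd.DataFrame
) -> tuple[pd.DataFrame, str]:
    """Mixed decline models for FEV1 and ratio, quartile + per-1-SD."""
    rows, text = [], []
    for outcome in ("fev1", "ratio"):
        for coding in ("quartiles", "per_sd"):
            spec = MixedModelSpec(outcome=outcome, exposure_coding=coding)
            res = fit_mixed_decline(visits, baseline, spec)
            fe = res.fixed_effects.set_index("term")
            for term in res.interaction_terms:
                r = fe.loc[term]
                rows.append(
                    {
                        "outcome": outcome,
                        "coding": coding,
                        "term": term,
                        "estimate": r["estimate"],
                        "se": r["se"],
                        "ci_low": r["ci_low"],
                        "ci_high": r["ci_high"],
                        "p_value": r["p_value"],
                        "rho": res.rho,
                        "random_intercept_var": res.random_intercept_var,
                        "converged": res.converged,
                    }
                )
                text.append(
                    f"{outcome} ({coding}) {term}: "
                    f"{r['estimate']:.3g} ({r['ci_low']:.3g}, {r['ci_high']:.3g}) "
                    f"P = {r['p_value']:.3g}"
                )
        slopes, summary = annualized_change(visits, outcome)
        text.append(
            f"{outcome} annualized change: mean {summary['mean']:.3g} "
            f"+/- {summary['sd']:.3g} (n = {summary['n']})"
        )
    return pd.DataFrame(rows), "\n".join(text) + "\n"


def run_pipeline(config: RunConfig) -> dict:
    """Execute one run; returns the manifest dict (also written to disk)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    if config.mode == "validate":
        table = run_validation_study(
            config.sim, n_replicates=config.validation_replicates, seed=config.seed
        )
        path = out / "validation_metrics.csv"
        _write(table, path)
        outputs[path.name] = _hash_file(path)
        return _finish_manifest(config, out, outputs)

    if config.mode == "simulate":
        rng_norm, rng_cohort, rng_visits, rng_weights = spawn_rngs(config.seed, 4)
        normative = generate_normative_sample(config.sim, rng_norm)
        models = fit_reference_models(normative)
        cohort = generate_cohort(config.sim, models, rng_cohort)
        visits = generate_visits(config.sim, cohort, rng_visits)
        subjects = cohort.subjects
        if config.sim.selection_probs:
            subjects = assign_selection_weights(
                subjects, config.sim.selection_probs, rng=rng_weights
            )
            # only enrolled (selected) subjects are followed up
            visits = visits[visits["subject_id"].isin(subjects["subject_id"])]
        latent = subjects[["subject_id", *LATENT_COLUMNS]]
        public = analysis_view(subjects)
        _write(normative, out / "normative.csv")
        (out / "reference_models.json").write_text(models.to_json())
        _write(public, out / "subjects.csv")
        _write(latent, out / "latent_truth.csv")
        _write(visits, out / "visits.csv")
        (out / "generation_log.json").write_text(json.dumps(cohort.log, sort_keys=True))
    else:  # analyze
        if not config.subjects_csv:
            raise ConfigError("analyze mode requires subjects_csv")
        public = pd.read_csv(config.subjects_csv)
        validate_subjects_schema(public)
        public = analysis_view(public)
        if config.reference_json:
            models = ReferenceModelSet.load(config.reference_json)
        elif config.normative_csv:
            normative = pd.read_csv(config.normative_csv)
            models = fit_reference_models(normative)
        else:
            raise ConfigError("analyze mode requires reference_json or normative_csv")
        visits = pd.read_csv(config.visits_csv) if config.visits_csv else None

    # shared analysis path
    analysis = _summaries_with_covariates(public, models)
    if "copd" not in analysis.columns and {"fev1", "fvc"} <= set(analysis.columns):
        analysis["copd"] = derive_copd_status(analysis)
    summary_cols = [
        "subject_id", "mean_caliber", "heterogeneity_sd", "cov", "n_sites",
    ]
    summaries_out = analysis[summary_cols].copy()
    from .metrics import assign_quartiles

    summaries_out["quartile"] = assign_quartiles(analysis["heterogeneity_sd"])
    _write(summaries_out, out / "summaries.csv")

    pp = percent_predicted_table(models, public)
    pooled = pp.to_numpy().ravel()
    pooled = pooled[np.isfinite(pooled)]
    curve = density_curve(pooled)
    _write(
        pd.DataFrame({"percent_predicted": curve.grid, "density": curve.density}),
        out / "density_curve.csv",
    )
    rho = spearman_with_ci(analysis["heterogeneity_sd"], analysis["mean_caliber"])
    report = {
        "spearman_rho": rho.rho,
        "spearman_ci": [rho.ci_low, rho.ci_high],
        "spearman_p": rho.p_value,
        "distribution": distribution_report(pooled),
    }
    (out / "distribution_report.json").write_text(json.dumps(report, sort_keys=True))

    assoc, assoc_text = run_association_battery(
        analysis, weighted="weight" in analysis.columns and analysis["weight"].nunique() > 1
    )
    _write(assoc, out / "association_results.csv")
    (out / "association_table.txt").write_text(assoc_text)

    if visits is not None:
        longit, longit_text = run_longitudinal_battery(visits, analysis)
        _write(longit, out / "longitudinal_results.csv")
        (out / "longitudinal_table.txt").write_text(longit_text)

    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            outputs[p.name] = _hash_file(p)
    return _finish_manifest(config, out, outputs)


def _finish_manifest(config: RunConfig, out: Path, outputs: dict) -> dict:
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "config_sha256": _config_hash(config),
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# replicate simulation helpers (validation + acceptance)
# ---------------------------------------------------------------------------


def fit_shared_reference(cfg: SimulationConfig, seed: int) -> ReferenceModelSet:
    """One normative draw + reference fit, shared across replicates."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 911]))
    return fit_reference_models(generate_normative_sample(cfg, rng))


def replicate_cross_sectional(
    cfg: SimulationConfig,
    models: ReferenceModelSet,
    n_replicates: int,
    seed: int,
    outcome: str = "fev1",
    exposure_coding: str = "per_sd",
    covariate_set: str = "model1",
) -> pd.DataFrame:
    """Replicate cohort draws + association fits; one row per replicate."""
    rows = []
    for child in np.random.SeedSequence(seed).spawn(n_replicates):
        rng = np.random.default_rng(child)
        cohort = generate_cohort(cfg, models, rng)
        analysis = _summaries_with_covariates(analysis_view(cohort.subjects), models)
        if outcome == "copd":
            analysis["copd"] = derive_copd_status(analysis)
            res = fit_logistic_association(
                analysis, exposure_coding=exposure_coding, covariate_set=covariate_set
            )
        else:
            res = fit_linear_association(
                analysis,
                outcome=outcome,
                exposure_coding=exposure_coding,
                covariate_set=covariate_set,
            )
        c = res.contrasts[-1]
        rows.append(
            {
                "estimate": c.estimate,
                "se": c.se,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
                "p_value": c.p_value,
            }
        )
    return pd.DataFrame(rows)


def replicate_longitudinal(
    cfg: SimulationConfig,
    models: ReferenceModelSet,
    n_replicates: int,
    seed: int,
    outcome: str = "fev1",
    exposure_coding: str = "raw",
    covariate_set: str = "model1",
) -> pd.DataFrame:
    """Replicate visit generation + mixed-model fits of the product term."""
    spec = MixedModelSpec(
        outcome=outcome, exposure_coding=exposure_coding, covariate_set=covariate_set
    )
    rows = []
    for child in np.random.SeedSequence(seed).spawn(n_replicates):
        rng = np.random.default_rng(child)
        cohort = generate_cohort(cfg, models, rng)
        visits = generate_visits(cfg, cohort, rng)
        baseline = _summaries_with_covariates(analysis_view(cohort.subjects), models)
        res = fit_mixed_decline(visits, baseline, spec)
        r = res.fixed_effects.set_index("term").loc[res.interaction_terms[-1]]
        rows.append(
            {
                "estimate": float(r["estimate"]),
                "se": float(r["se"]),
                "ci_low": float(r["ci_low"]),
                "ci_high": float(r["ci_high"]),
                "p_value": float(r["p_value"]),
                "rho": res.rho,
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows)


def _summ(scenario, metric, value, mc_se, usable=True):
    return {
        "scenario": scenario,
        "metric": metric,
        "value": value,
        "mc_se": mc_se,
        "mc_se_usable": usable,
    }


def run_validation_study(
    cfg: SimulationConfig | None = None,
    n_replicates: int = 200,
    seed: int = 0,
    n_subjects: int = 1000,
) -> pd.DataFrame:
    """Parameter-recovery / calibration study over the standard scenarios.

    Scenarios: cross-sectional null (no heterogeneity effect) and effect
    (the configured -12 mL/% truth), and longitudinal null / effect
    (interaction 0 and -3 mL/yr per %). Reports bias, empirical SE, 95%
    CI coverage and Wald rejection rates with binomial Monte-Carlo SEs.
    """
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    cfg = cfg or SimulationConfig()
    cfg = dataclasses.replace(cfg, n_subjects=n_subjects)
    usable = n_replicates >= 2
    models = fit_shared_reference(cfg, seed)
    rows = []

    def bin_se(p):
        return float(np.sqrt(p * (1 - p) / n_replicates)) if usable else float("nan")

    # cross-sectional
    for label, beta in (("cross_sectional_null", 0.0), ("cross_sectional_effect", None)):
        c = dataclasses.replace(cfg, beta_het_fev1=beta if beta is not None else cfg.beta_het_fev1)
        reps = replicate_cross_sectional(c, models, n_replicates, seed + 1)
        truth = c.beta_het_fev1 * c.het_sd
        rej = float((reps["p_value"] < 0.05).mean())
        cover = float(((reps["ci_low"] <= truth) & (truth <= reps["ci_high"])).mean())
        est_se = float(reps["estimate"].std(ddof=1)) if usable else float("nan")
        rows += [
            _summ(label, "rejection_rate", rej, bin_se(rej), usable),
            _summ(label, "bias", float(reps["estimate"].mean() - truth),
                  est_se / np.sqrt(n_replicates) if usable else float("nan"), usable),
            _summ(label, "empirical_se", est_se, float("nan"), usable),
            _summ(label, "ci_coverage", cover, bin_se(cover), usable),
        ]

    # longitudinal
    for label, gamma in (("longitudinal_null", 0.0), ("longitudinal_effect", -3.0)):
        c = dataclasses.replace(cfg, interaction_gamma=gamma)
        reps = replicate_longitudinal(c, models, n_replicates, seed + 2)
        truth = gamma
        rej = float((reps["p_value"] < 0.05).mean())
        cover = float(((reps["ci_low"] <= truth) & (truth <= reps["ci_high"])).mean())
        est_se = float(reps["estimate"].std(ddof=1)) if usable else float("nan")
        rows += [
            _summ(label, "rejection_rate", rej, bin_se(rej), usable),
            _summ(label, "bias", float(reps["estimate"].mean() - truth),
                  est_se / np.sqrt(n_replicates) if usable else float("nan"), usable),
            _summ(label, "empirical_se", est_se, float("nan"), usable),
            _summ(label, "ci_coverage", cover, bin_se(cover), usable),
        ]
    return pd.DataFrame(rows)
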