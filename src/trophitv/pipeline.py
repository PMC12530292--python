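"""End-to-end orchestration: tables in, per-stage artifacts out.

Stages run in method order: MNI diet matrices -> individual traits ->
ecological-opportunity summaries -> electivity null models -> path
analysis (BIC and INW separately) -> seasonal contrasts of the variables
the path models retained.  Every intermediate table is written as TSV, the
model reports as JSON, and a manifest records the configuration, seed and
library versions so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import diet as diet_mod
from . import electivity as elect_mod
from . import opportunity as opp_mod
from . import paths as paths_mod
from . import seasonal as seas_mod
from . import traits as traits_mod

logger = logging.getLogger(__name__)

DENSITY_VARS = ["MeanBae", "MeanBae5sup", "MeanHep", "MeanHep5sup", "MeanOrt"]


@dataclass
class RunConfig:
    """Inputs, thresholds and convention switches of one pipeline run."""

    detections: str
    biometry: str
    survey_counts: str
    survey_habitat: str
    outdir: str
    seed: int = 0
    r_max: float = 0.70
    vif_threshold: float = 5.0
    alpha: float = 0.05
    min_occurrence: float = 0.05
    n_sub: int = 45
    iters: int = 1000
    n_sims: int = 1000
    population_diet: str = "sum"         # or "average"
    bray_transform: str = "raw"          # or "ln1p"
    electivity_statistic: str = "total"  # or "mean"

    def validate(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.min_occurrence <= 1):
            raise ValueError("alpha and min_occurrence must lie in (0, 1)")
        if min(self.n_sub, self.iters, self.n_sims) <= 0:
            raise ValueError("n_sub, iters and n_sims must be positive integers")


def load_inputs(config: RunConfig):
    detections = pd.read_csv(config.detections, sep="\t", dtype=str)
    biometry = pd.read_csv(config.biometry, sep="\t")
    counts = pd.read_csv(
        config.survey_counts, sep="\t", dtype={"size_class": str}, keep_default_na=False
    )
    counts["count"] = counts["count"].astype(int)
    habitat = pd.read_csv(config.survey_habitat, sep="\t")
    survey = opp_mod.SurveyTable(counts=counts, habitat=habitat)
    return detections, biometry, survey


def validate_inputs(
    detections: pd.DataFrame, biometry: pd.DataFrame, survey: opp_mod.SurveyTable
) -> list[str]:
    """Schema, referential-integrity and ordinal-range report (no raising)."""
    problems: list[str] = []
    for col in diet_mod.DETECTION_COLUMNS:
        if col not in detections.columns:
            problems.append(f"detections: missing column {col}")
    for col in ["individual_id", "campaign_id", "site", "year", "fork_length", "weight"]:
        if col not in biometry.columns:
            problems.append(f"biometry: missing column {col}")
    problems.extend(opp_mod.validate_survey(survey))
    if "campaign_id" in detections.columns and "campaign_id" in biometry.columns:
        survey_camps = set(survey.habitat["campaign_id"])
        for name, camps in [
            ("detections", set(detections["campaign_id"].dropna())),
            ("biometry", set(biometry["campaign_id"].dropna())),
        ]:
            orphan = camps - survey_camps
            if orphan:
                problems.append(
                    f"{name}: campaigns without surveys: {sorted(orphan)[:5]}"
                    + ("..." if len(orphan) > 5 else "")
                )
        det_inds = set(detections["individual_id"].dropna())
        bio_inds = set(biometry["individual_id"])
        orphan = det_inds - bio_inds
        if orphan:
            problems.append(f"detections: {len(orphan)} individuals missing from biometry")
    return problems


def build_campaign_table(
    summary: pd.DataFrame,
    size_structure: pd.DataFrame,
    opportunity: pd.DataFrame,
    biometry: pd.DataFrame,
) -> pd.DataFrame:
    """Campaign-level table: traits, size variability, ln+1 opportunity."""
    meta_cols = ["campaign_id", "site", "year"] + (
        ["season"] if "season" in biometry.columns else []
    )
    meta = biometry[meta_cols].drop_duplicates(subset="campaign_id")
    table = meta.merge(summary, on="campaign_id", how="inner")
    if "size_variability" not in table.columns:
        table = table.merge(size_structure, on="campaign_id", how="left")
    table = table.merge(opportunity, on="campaign_id", how="inner")
    for var in DENSITY_VARS:
        if var in table.columns:
            table[var] = opp_mod.ln1p_transform(table[var])
    return table


def _path_stage(
    campaign_table: pd.DataFrame,
    records: pd.DataFrame,
    biometry: pd.DataFrame,
    config: RunConfig,
    trait: str,
):
    """Prune variables and run the selection procedure for one trait."""
    prey_vars = [
        v
        for v in [*opp_mod.PREY_MEAN_VARS, *(f"cv-{v}" for v in opp_mod.PREY_MEAN_VARS), "BrayCurtis"]
        if v in campaign_table.columns
    ]
    hab_vars = [
        v
        for v in [*opp_mod.HABITAT_VARS.values(), *(f"cv-{c}" for c in opp_mod.HABITAT_VARS.values())]
        if v in campaign_table.columns
    ]
    if trait == "bic":
        size_vars = ["size_variability"]
        data = records.reset_index().merge(campaign_table, on="campaign_id", how="inner")
    else:
        size_vars = ["fork_length", "weight"]
        data = (
            records.reset_index()
            .merge(biometry[["individual_id", "fork_length", "weight"]], on="individual_id")
            .merge(campaign_table, on="campaign_id", how="inner")
        )
    data = data.dropna(subset=[trait])
    camp_level = data.drop_duplicates(subset="campaign_id")
    retained = paths_mod.prune_correlated(camp_level, prey_vars + hab_vars, r_max=config.r_max)
    retained = paths_mod.vif_prune(camp_level, retained, threshold=config.vif_threshold)
    prey_kept = [v for v in retained if v in prey_vars]
    hab_kept = [v for v in retained if v in hab_vars]
    spec = paths_mod.initial_path_spec(hab_kept, prey_kept, size_vars, trait)
    model = paths_mod.select_model(data, spec, alpha=config.alpha)
    effects = paths_mod.effect_decomposition(model)
    return model, effects


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    detections, biometry, survey = load_inputs(config)
    problems = validate_inputs(detections, biometry, survey)
    (outdir / "validation.json").write_text(json.dumps(problems, indent=2))
    if problems:
        logger.warning("input validation reported %d issues", len(problems))

    # diet stage
    biometry_kept = diet_mod.filter_age_class(biometry)
    detections_kept = detections[
        detections["individual_id"].isin(biometry_kept["individual_id"])
    ]
    matrix = diet_mod.compute_mni(detections_kept, deduplicate=True)
    diet_mod.write_diet_tables(matrix, outdir / "diet_wide.tsv", outdir / "diet_long.tsv")
    logger.info(
        "diet stage: %d individuals, %d taxa (dropped %d young-of-the-year)",
        len(matrix.individuals),
        len(matrix.taxa),
        len(biometry) - len(biometry_kept),
    )

    # traits stage
    records, summary = traits_mod.campaign_traits(
        matrix, convention=config.population_diet
    )
    size_structure = traits_mod.campaign_size_structure(biometry_kept)
    summary = summary.merge(size_structure, on="campaign_id", how="left")
    records.to_csv(outdir / "traits.tsv", sep="\t")
    summary.to_csv(outdir / "trait_summary.tsv", sep="\t", index=False)

    # opportunity stage
    min_points = min(len(survey.points(c)) for c in survey.campaigns)
    n_sub = min(config.n_sub, min_points)
    if n_sub < config.n_sub:
        logger.warning("n_sub reduced to %d (minimum campaign effort)", n_sub)
    opportunity = opp_mod.campaign_opportunity(
        survey,
        n_sub=n_sub,
        iters=config.iters,
        seed=np.random.default_rng(config.seed),
        bray_transform=config.bray_transform,
    )
    opportunity.to_csv(outdir / "opportunity.tsv", sep="\t", index=False)

    # electivity stage
    elect = elect_mod.run_electivity(
        matrix,
        survey.counts,
        min_occurrence=config.min_occurrence,
        n_sims=config.n_sims,
        n_sub=n_sub,
        iters=config.iters,
        alpha=config.alpha,
        statistic=config.electivity_statistic,
        seed=config.seed + 1,
    )
    elect.to_csv(outdir / "electivity.tsv", sep="\t", index=False)
    elect_mod.selection_summary(elect).to_csv(
        outdir / "electivity_summary.tsv", sep="\t", index=False
    )

    # path analysis stage (BIC and INW separately)
    campaign_table = build_campaign_table(summary, size_structure, opportunity, biometry_kept)
    retained_vars: set[str] = set()
    for trait in ("bic", "inw"):
        model, effects = _path_stage(campaign_table, records, biometry_kept, config, trait)
        report = model.to_report()
        report["effects"] = effects.to_dict(orient="records")
        (outdir / f"paths_{trait}.json").write_text(json.dumps(report, indent=2))
        model.edges.to_csv(outdir / f"paths_{trait}_edges.tsv", sep="\t", index=False)
        (outdir / f"paths_{trait}.txt").write_text(paths_mod.path_diagram(model))
        retained_vars.update(model.spec.habitat)
        retained_vars.update(model.spec.prey)

    # seasonal stage (variables retained by the path models)
    season_vars = sorted(v for v in retained_vars if v in campaign_table.columns)
    if "season" in campaign_table.columns and season_vars:
        contrasts = seas_mod.seasonal_contrast_table(campaign_table, season_vars)
    else:
        contrasts = pd.DataFrame(
            columns=["variable", "season_a", "season_b", "estimate", "se", "p_raw", "p_adj", "code"]
        )
        logger.warning("seasonal stage skipped: no season labels or no retained variables")
    contrasts.to_csv(outdir / "seasonal.tsv", sep="\t", index=False)

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "versions": _versions(),
        "n_individuals": len(matrix.individuals),
        "n_taxa": len(matrix.taxa),
        "n_campaigns": int(summary.shape[0]),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %s", outdir)
    return outdir


def _versions() -> dict[str, str]:
    import scipy
    import statsmodels

    from . import __version__

    return {
        "trophitv": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
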