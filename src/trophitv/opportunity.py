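"""Ecological-opportunity estimators per sampling campaign.

Each campaign (one site x date) is described by point samples: Surber
benthic samples (0.05 m^2) giving per-taxon macroinvertebrate counts, and
six habitat measurements at the same points (substrate size-class richness,
maximum substrate size class on a 0-10 ordinal scale, water velocity at
3 cm above the bed, water depth, substrate clogging 1-5, vegetal
development 1-5).

The biotic dimension is summarised by per-point prey richness, Shannon
diversity and densities of the focal prey (Baetis and Heptageniidae, split
into total and large >= 5 mm cohorts, plus Orthocladiinae), each reduced to
a campaign mean and a coefficient of variation (CV = 100 * SD / mean, the
spatial-heterogeneity estimator), together with the mean pairwise
Bray-Curtis dissimilarity between points.  The abiotic dimension is the
mean and CV of each habitat variable.

Because campaigns differ in sampling effort (45-90 points), prey-community
estimators are standardised to the minimum effort by a permutation scheme:
the estimator is averaged over random without-replacement subsamples of
n_sub points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["campaign_id", "point_id", "taxon_id", "size_class", "count"]
HABITAT_VARS: dict[str, str] = {
    "substrate_richness": "SbV",
    "substrate_max": "SbG",
    "velocity": "vs3",
    "depth": "Dep",
    "clogging": "Clg",
    "vegetal": "VgD",
}
ORDINAL_RANGES = {"substrate_max": (0, 10), "clogging": (1, 5), "vegetal": (1, 5)}
FOCAL_TAXA = {"Baetis": "Bae", "Heptageniidae": "Hep"}
LARGE_CLASS = "large"  # body length >= 5 mm


@dataclass
class SurveyTable:
    """Point-sample survey: long count table + per-point habitat table."""

    counts: pd.DataFrame  # campaign_id point_id taxon_id size_class count
    habitat: pd.DataFrame  # campaign_id point_id + HABITAT_VARS keys

    def __post_init__(self) -> None:
        missing = [c for c in COUNT_COLUMNS if c not in self.counts.columns]
        if missing:
            raise ValueError(f"survey count table missing columns: {missing}")
        hmissing = [
            c for c in ["campaign_id", "point_id", *HABITAT_VARS] if c not in self.habitat.columns
        ]
        if hmissing:
            raise ValueError(f"habitat table missing columns: {hmissing}")
        if (self.counts["count"] < 0).any():
            raise ValueError("negative counts in survey table")

    @property
    def campaigns(self) -> list[str]:
        return sorted(self.habitat["campaign_id"].unique())

    def points(self, campaign_id: str) -> pd.Index:
        return pd.Index(
            sorted(self.habitat.loc[self.habitat["campaign_id"] == campaign_id, "point_id"])
        )


def point_taxon_matrix(counts: pd.DataFrame, points: pd.Index) -> pd.DataFrame:
    """Point x taxon count matrix (size classes pooled), zero-filled."""
    mat = (
        counts.groupby(["point_id", "taxon_id"])["count"].sum().unstack(fill_value=0)
    )
    return mat.reindex(points, fill_value=0).fillna(0)


def shannon_counts(counts: np.ndarray) -> float:
    """Shannon diversity (natural log) of a count vector; 0 for empty samples."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def sample_metrics(counts: np.ndarray) -> tuple[int, float]:
    """Per-point (richness, Shannon diversity) from a taxon count vector."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    richness = int((counts > 0).sum())
    return richness, shannon_counts(counts)


def cv(values: np.ndarray) -> float:
    """Coefficient of variation, 100 * sample SD / mean.

    NaN (with a warning) when the mean is zero; error on a single value.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) < 2:
        raise ValueError("CV requires at least two values")
    mu = values.mean()
    if mu == 0:
        logger.warning("CV undefined: zero mean")
        return float("nan")
    return float(values.std(ddof=1) / mu * 100.0)


def mean_bray_curtis(matrix: np.ndarray | pd.DataFrame) -> float:
    """Mean pairwise Bray-Curtis dissimilarity between point samples.

    BC(x, y) = sum|x−y| / sum(x+y); pairs where both samples are empty are
    skipped (their dissimilarity is undefined).
    """
    x = np.asarray(matrix, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("mean Bray-Curtis requires >= 2 samples")
    with np.errstate(invalid="ignore"):
        d = pdist(x, metric="braycurtis")
    bad = np.isnan(d)
    if bad.any():
        logger.warning("skipping %d empty-vs-empty sample pairs in Bray-Curtis", int(bad.sum()))
        d = d[~bad]
    if len(d) == 0:
        raise ValueError("all sample pairs are empty")
    return float(d.mean())


def cohort_split(
    counts: pd.DataFrame, focal_taxa: Mapping[str, str] = FOCAL_TAXA
) -> pd.DataFrame:
    """Per-point total and large (>= 5 mm) densities of the focal taxa.

    Rows of focal taxa without a recorded size class are counted in the
    total only, with a logged flag.
    """
    points = counts["point_id"].unique()
    out = pd.DataFrame(index=pd.Index(sorted(points), name="point_id"))
    for taxon, code in focal_taxa.items():
        sub = counts[counts["taxon_id"] == taxon]
        missing = sub["size_class"].isna() | (sub["size_class"] == "")
        if missing.any():
            logger.warning(
                "%s: %d rows lack a size class; counted in total only",
                taxon,
                int(missing.sum()),
            )
        total = sub.groupby("point_id")["count"].sum()
        large = sub[sub["size_class"] == LARGE_CLASS].groupby("point_id")["count"].sum()
        out[f"Mean{code}"] = total.reindex(out.index, fill_value=0)
        out[f"Mean{code}5sup"] = large.reindex(out.index, fill_value=0)
    return out.fillna(0)


def ln1p_transform(values: np.ndarray | pd.DataFrame | pd.Series):
    """ln(x + 1) for density variables entering models; rejects negatives."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("ln+1 transform requires non-negative input")
    if isinstance(values, (pd.DataFrame, pd.Series)):
        return np.log1p(values)
    return np.log1p(arr)


def standardise_by_permutation(
    points: pd.DataFrame,
    estimator: Callable[[pd.DataFrame], float],
    n_sub: int = 45,
    iters: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Mean of ``estimator`` over without-replacement subsamples of points.

    With n_sub equal to the number of points the subsample is always the
    full set and the plain estimator is returned.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = len(points)
    if n < n_sub:
        raise ValueError(f"campaign has {n} points, fewer than n_sub={n_sub}")
    if n == n_sub:
        return float(estimator(points))
    vals = np.empty(iters)
    for i in range(iters):
        idx = rng.choice(n, size=n_sub, replace=False)
        vals[i] = estimator(points.iloc[idx])
    return float(vals.mean())


def _point_table(survey: SurveyTable, campaign_id: str, focal_taxa: Mapping[str, str]):
    """Per-point prey metric table and point x taxon matrix for one campaign."""
    pts = survey.points(campaign_id)
    counts = survey.counts[survey.counts["campaign_id"] == campaign_id]
    mat = point_taxon_matrix(counts, pts)
    metrics = pd.DataFrame(index=pts)
    arr = mat.to_numpy(dtype=float)
    metrics["Richness"] = (arr > 0).sum(axis=1)
    totals = arr.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals[:, None] > 0, arr / np.where(totals[:, None] == 0, 1, totals[:, None]), 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    metrics["Diversity"] = -plogp.sum(axis=1)
    focal = cohort_split(counts, focal_taxa).reindex(pts, fill_value=0)
    for col in focal.columns:
        metrics[col] = focal[col]
    ort = counts[counts["taxon_id"] == "Orthocladiinae"].groupby("point_id")["count"].sum()
    metrics["MeanOrt"] = ort.reindex(pts, fill_value=0.0).fillna(0.0)
    return metrics, mat


PREY_MEAN_VARS = ["Richness", "Diversity", "MeanBae", "MeanBae5sup", "MeanHep", "MeanHep5sup", "MeanOrt"]


def campaign_opportunity(
    survey: SurveyTable,
    n_sub: int = 45,
    iters: int = 1000,
    seed: int | np.random.Generator = 0,
    standardise: bool = True,
    bray_transform: str = "raw",
    focal_taxa: Mapping[str, str] = FOCAL_TAXA,
) -> pd.DataFrame:
    """Campaign x estimator table: prey means, CVs, Bray-Curtis, habitat.

    Prey estimators are permutation-standardised to ``n_sub`` points
    (``iters`` subsamples, seeded); habitat estimators use all points.
    ``bray_transform`` chooses raw or ln+1 counts for Bray-Curtis
    (default raw).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if bray_transform not in {"raw", "ln1p"}:
        raise ValueError("bray_transform must be 'raw' or 'ln1p'")
    rows = []
    for camp in survey.campaigns:
        metrics, mat = _point_table(survey, camp, focal_taxa)
        n = len(metrics)
        if n < n_sub:
            raise ValueError(f"campaign {camp} has {n} points, fewer than n_sub={n_sub}")
        bc_mat = mat.to_numpy(dtype=float)
        if bray_transform == "ln1p":
            bc_mat = np.log1p(bc_mat)
        with np.errstate(invalid="ignore"):
            bc_full = squareform(pdist(bc_mat, metric="braycurtis"))

        vals = metrics.to_numpy(dtype=float)  # n x 7
        row: dict[str, float] = {"campaign_id": camp, "n_points": n}
        if standardise and n > n_sub:
            idx = np.stack([rng.choice(n, size=n_sub, replace=False) for _ in range(iters)])
            sub = vals[idx]  # iters x n_sub x 7
            means = sub.mean(axis=1)
            sds = sub.std(axis=1, ddof=1)
            mu = means.mean(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                cvs = np.where(means != 0, sds / means * 100.0, np.nan)
            cv_est = np.nanmean(cvs, axis=0)
            bc_vals = np.empty(iters)
            for i in range(iters):
                sq = bc_full[np.ix_(idx[i], idx[i])]
                tri = sq[np.triu_indices(n_sub, 1)]
                bc_vals[i] = np.nanmean(tri)
            bc = float(bc_vals.mean())
        else:
            mu = vals.mean(axis=0)
            sds = vals.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                cv_est = np.where(mu != 0, sds / mu * 100.0, np.nan)
            tri = bc_full[np.triu_indices(n, 1)]
            bc = float(np.nanmean(tri))
        for j, name in enumerate(PREY_MEAN_VARS):
            row[name] = float(mu[j])
            row[f"cv-{name}"] = float(cv_est[j])
        row["BrayCurtis"] = bc
        rows.append(row)
    prey = pd.DataFrame(rows).set_index("campaign_id")
    hab = habitat_summary(survey.habitat).set_index("campaign_id")
    return prey.join(hab).reset_index()


def habitat_summary(habitat: pd.DataFrame) -> pd.DataFrame:
    """Six habitat means + six CVs per campaign (pairwise-complete on NaN)."""
    rows = []
    for camp, grp in habitat.groupby("campaign_id"):
        row: dict[str, float] = {"campaign_id": camp}
        for var, code in HABITAT_VARS.items():
            x = grp[var].to_numpy(dtype=float)
            n_missing = int(np.isnan(x).sum())
            if n_missing:
                logger.info("campaign %s: %d missing %s values", camp, n_missing, var)
            x = x[~np.isnan(x)]
            row[code] = float(x.mean()) if len(x) else float("nan")
            row[f"cv-{code}"] = cv(x) if len(x) >= 2 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def validate_survey(survey: SurveyTable) -> list[str]:
    """Ordinal-range and referential checks; returns violation messages."""
    problems: list[str] = []
    for var, (lo, hi) in ORDINAL_RANGES.items():
        x = survey.habitat[var].dropna()
        bad = x[(x < lo) | (x > hi)]
        if len(bad):
            problems.append(
                f"{var}: {len(bad)} values outside ordinal range [{lo}, {hi}]"
            )
    count_points = set(zip(survey.counts["campaign_id"], survey.counts["point_id"]))
    hab_points = set(zip(survey.habitat["campaign_id"], survey.habitat["point_id"]))
    orphan = count_points - hab_points
    if orphan:
        problems.append(f"{len(orphan)} count points lack a habitat row")
    return problems
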