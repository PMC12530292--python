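"""Null-model tests of prey selection (electivity) per campaign.

Observed consumption of each prey taxon is compared against a null model in
which every individual's total consumption (its summed MNI) is
redistributed across the available taxa in proportion to local prey
availability — i.e., diet breadth is conserved but selectivity is removed.
Each of ``n_sims`` simulations draws, per individual, a multinomial diet
with probabilities proportional to availability; the per-taxon statistic
(default: total MNI across individuals) is aggregated, and the observed
value is classified against the empirical 95% envelope of the simulated
values:

* positive electivity: observed above the upper quantile (consumed more
  than availability predicts),
* negative electivity: observed below the lower quantile,
* neutral: inside the envelope (ties at a boundary count as inside).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diet import DietMatrix, occurrence_filter

logger = logging.getLogger(__name__)


def null_consumption(
    diet_counts: pd.DataFrame,
    availability: pd.Series,
    n_sims: int = 1000,
    seed: int | np.random.Generator = 0,
    statistic: str = "total",
) -> pd.DataFrame:
    """Simulate the null distribution of per-taxon consumption.

    Parameters
    ----------
    diet_counts
        Individual x taxon MNI counts for one campaign (columns already
        restricted to the tested taxa).
    availability
        Per-taxon relative abundance, indexed like ``diet_counts.columns``;
        only relative magnitudes matter.
    statistic
        "total" (summed MNI across individuals, default) or "mean"
        (mean per-individual consumption).

    Returns an ``n_sims x taxa`` DataFrame of simulated statistics.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if statistic not in {"total", "mean"}:
        raise ValueError("statistic must be 'total' or 'mean'")
    avail = availability.reindex(diet_counts.columns).to_numpy(dtype=float)
    if np.isnan(avail).any() or (avail < 0).any():
        raise ValueError("availability must be non-negative and cover all tested taxa")
    if avail.sum() <= 0:
        raise ValueError("availability has no positive entry")
    totals = diet_counts.sum(axis=1).to_numpy(dtype=int)
    if (totals <= 0).any():
        raise ValueError("every individual must have positive total MNI over tested taxa")
    # simulate in canonical taxon order so results are invariant to the
    # caller's column ordering (multinomial draws are order-dependent)
    order = sorted(diet_counts.columns)
    probs = (availability.reindex(order) / avail.sum()).to_numpy(dtype=float)
    sims = np.zeros((n_sims, len(probs)))
    for total in totals:
        sims += rng.multinomial(total, probs, size=n_sims)
    if statistic == "mean":
        sims /= len(totals)
    return pd.DataFrame(sims, columns=order)[diet_counts.columns]


def classify_electivity(
    observed: pd.Series,
    null_matrix: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify observed consumption against the empirical null envelope.

    Quantiles are empirical (linear-interpolation, type 7); observations
    equal to a boundary are inside the envelope, so a degenerate null
    (all simulations identical) yields neutral unless the observation
    actually differs.
    """
    lo = null_matrix.quantile(alpha / 2)
    hi = null_matrix.quantile(1 - alpha / 2)
    rows = []
    for taxon in null_matrix.columns:
        obs = float(observed[taxon])
        degenerate = null_matrix[taxon].nunique() == 1
        if degenerate:
            logger.warning("degenerate null distribution for taxon %s", taxon)
        if obs > hi[taxon]:
            cls = "positive"
        elif obs < lo[taxon]:
            cls = "negative"
        else:
            cls = "neutral"
        rows.append(
            {
                "taxon_id": taxon,
                "observed": obs,
                "null_mean": float(null_matrix[taxon].mean()),
                "null_lo": float(lo[taxon]),
                "null_hi": float(hi[taxon]),
                "classification": cls,
            }
        )
    return pd.DataFrame(rows)


def campaign_availability(
    survey_counts: pd.DataFrame,
    points: pd.Index,
    n_sub: int = 45,
    iters: int = 1000,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Relative prey availability: permutation-standardised mean density.

    Mean per-taxon density over points, averaged over without-replacement
    subsamples of ``n_sub`` points, then normalised to proportions.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mat = (
        survey_counts.groupby(["point_id", "taxon_id"])["count"].sum().unstack(fill_value=0)
    ).reindex(points, fill_value=0).fillna(0)
    arr = mat.to_numpy(dtype=float)
    n = len(mat)
    if n > n_sub:
        idx = np.stack([rng.choice(n, size=n_sub, replace=False) for _ in range(iters)])
        means = arr[idx].mean(axis=1).mean(axis=0)
    else:
        means = arr.mean(axis=0)
    avail = pd.Series(means, index=mat.columns)
    total = avail.sum()
    if total <= 0:
        raise ValueError("no prey recorded in surveys for this campaign")
    return avail / total


def run_electivity(
    matrix: DietMatrix,
    survey_counts: pd.DataFrame,
    min_occurrence: float = 0.05,
    n_sims: int = 1000,
    n_sub: int = 45,
    iters: int = 1000,
    alpha: float = 0.05,
    statistic: str = "total",
    seed: int = 0,
) -> pd.DataFrame:
    """Electivity tests for every campaign shared by diets and surveys.

    The >= ``min_occurrence`` occurrence filter is applied on diet samples
    pooled across campaigns; tests then run per campaign.  Tested taxa
    consumed but absent from a campaign's surveys receive pseudo-availability
    equal to half the smallest nonzero availability (flagged) — dropping
    them would bias tests toward neutrality.
    """
    taxa = occurrence_filter(matrix, min_occurrence)
    if not taxa:
        return pd.DataFrame(
            columns=["campaign_id", "taxon_id", "observed", "null_mean", "null_lo", "null_hi", "classification"]
        )
    rng = np.random.default_rng(seed)
    results = []
    campaigns = sorted(matrix.meta["campaign_id"].unique())
    survey_campaigns = set(survey_counts["campaign_id"].unique())
    for camp in campaigns:
        if camp not in survey_campaigns:
            logger.warning("campaign %s has no surveys: electivity skipped", camp)
            continue
        inds = matrix.meta.index[matrix.meta["campaign_id"] == camp]
        counts = matrix.counts.loc[inds, taxa]
        counts = counts[counts.sum(axis=1) > 0]
        if counts.empty:
            logger.warning("campaign %s: no consumption of tested taxa", camp)
            continue
        camp_counts = survey_counts[survey_counts["campaign_id"] == camp]
        points = pd.Index(sorted(camp_counts["point_id"].unique()))
        avail = campaign_availability(
            camp_counts, points, n_sub=min(n_sub, len(points)), iters=iters, seed=rng
        )
        avail = avail.reindex(taxa, fill_value=0.0)
        zero = avail == 0
        if zero.any():
            floor = avail[avail > 0].min() / 2.0
            logger.warning(
                "campaign %s: pseudo-availability %.3g for unsurveyed taxa %s",
                camp,
                floor,
                list(avail.index[zero]),
            )
            avail[zero] = floor
        null = null_consumption(counts, avail, n_sims=n_sims, seed=rng, statistic=statistic)
        observed = counts.sum(axis=0) if statistic == "total" else counts.mean(axis=0)
        res = classify_electivity(observed, null, alpha=alpha)
        res.insert(0, "campaign_id", camp)
        results.append(res)
    if not results:
        return pd.DataFrame(
            columns=["campaign_id", "taxon_id", "observed", "null_mean", "null_lo", "null_hi", "classification"]
        )
    return pd.concat(results, ignore_index=True)


def selection_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon counts of positive/neutral/negative campaigns."""
    if results.empty:
        return pd.DataFrame(columns=["taxon_id", "positive", "neutral", "negative", "n_campaigns"])
    tab = (
        results.groupby(["taxon_id", "classification"]).size().unstack(fill_value=0)
    )
    for col in ["positive", "neutral", "negative"]:
        if col not in tab:
            tab[col] = 0
    tab["n_campaigns"] = tab[["positive", "neutral", "negative"]].sum(axis=1)
    return tab[["positive", "neutral", "negative", "n_campaigns"]].reset_index()
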