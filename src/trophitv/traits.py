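"""Individual trophic traits and population size structure.

Two per-individual traits summarise trophic niche variation:

* INW (individual niche width): Shannon diversity of the individual's diet
  proportions, natural log, so an individual eating a single taxon has
  INW = 0 and one eating k taxa evenly has INW = ln k.
* BIC (between-individual component): the individual specialisation index
  V = 1 − PS_i, where PS_i = sum_j min(p_ij, q_j) is the proportional
  similarity between the individual's diet p_i and its population's diet q.
  V is 0 when the individual matches the population exactly and approaches
  1 when its diet is fully divergent.  Equivalently V is the total-variation
  distance 0.5 * sum_j |p_ij − q_j|.

Population size structure per sampling campaign is the mean pairwise
Euclidean distance between individuals in z-scored (fork length, weight)
space; z-scoring makes the statistic unit-free, and because Euclidean
distance is rotation-invariant the value equals the distance computed on
all PCA scores of the same two variables.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .diet import DietMatrix, diet_proportions, pooled_diet

logger = logging.getLogger(__name__)


def shannon_inw(p: np.ndarray, tol: float = 1e-6) -> float:
    """Shannon diversity H = −sum_{p>0} p ln p of a proportion vector."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    total = p.sum()
    if total == 0:
        raise ValueError("all-zero proportion vector")
    if abs(total - 1.0) > tol:
        raise ValueError(f"proportions sum to {total:.6g}, not 1")
    if abs(total - 1.0) > 1e-12:
        logger.warning("normalising proportions off by %.2g", abs(total - 1.0))
        p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def bic_v(p_i: np.ndarray, q: np.ndarray) -> float:
    """Individual specialisation V = 1 − sum_j min(p_ij, q_j)."""
    p_i = np.asarray(p_i, dtype=float)
    q = np.asarray(q, dtype=float)
    if p_i.shape != q.shape:
        raise ValueError("individual and population diets are on different taxon sets")
    return float(1.0 - np.minimum(p_i, q).sum())


def campaign_traits(
    matrix: DietMatrix,
    grouping: pd.Series | None = None,
    convention: str = "sum",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual INW and BIC plus per-campaign summaries.

    BIC is computed against the individual's own campaign population diet q
    (pooled-sum convention by default).  Returns ``(records, summary)``
    where summary holds n, mean and sample SD of each trait per campaign.
    Campaigns with a single individual have BIC flagged as NaN (a
    one-individual "population" makes V degenerate at 0).
    """
    if grouping is None:
        grouping = matrix.meta["campaign_id"]
    props = diet_proportions(matrix)
    grouping = grouping.reindex(props.index)
    q = pooled_diet(matrix.subset(props.index), grouping, convention=convention)

    rows = []
    for ind in props.index:
        g = grouping.loc[ind]
        p = props.loc[ind].to_numpy()
        n_in_group = int((grouping == g).sum())
        v = bic_v(p, q.loc[g].to_numpy()) if n_in_group >= 2 else np.nan
        if n_in_group < 2:
            logger.warning("campaign %s has <2 individuals: BIC undefined", g)
        rows.append(
            {
                "individual_id": ind,
                "campaign_id": g,
                "inw": shannon_inw(p),
                "bic": v,
            }
        )
    records = pd.DataFrame(rows).set_index("individual_id")

    summary = (
        records.groupby("campaign_id")
        .agg(
            n=("inw", "size"),
            bic_mean=("bic", "mean"),
            bic_sd=("bic", lambda s: s.std(ddof=1)),
            inw_mean=("inw", "mean"),
            inw_sd=("inw", lambda s: s.std(ddof=1)),
        )
        .reset_index()
    )
    return records, summary


def size_variability(lengths: np.ndarray, weights: np.ndarray) -> float:
    """Mean pairwise Euclidean distance on z-scored biometry.

    Both variables are standardised within the campaign using the 1/n
    (population) SD — the scaling convention of PCA implementations in the
    ade4 tradition, so two individuals sit at z = ±1 on each axis.  A
    variable with zero variance contributes a zero coordinate.  Requires at
    least two individuals with both measurements.
    """
    lengths = np.asarray(lengths, dtype=float)
    weights = np.asarray(weights, dtype=float)
    ok = ~(np.isnan(lengths) | np.isnan(weights))
    x = np.column_stack([lengths[ok], weights[ok]])
    if len(x) < 2:
        raise ValueError("size variability needs >= 2 individuals with both measurements")
    sd = x.std(axis=0, ddof=0)
    mu = x.mean(axis=0)
    z = np.zeros_like(x)
    nz = sd > 0
    z[:, nz] = (x[:, nz] - mu[nz]) / sd[nz]
    return float(pdist(z).mean())


def campaign_size_structure(biometry: pd.DataFrame) -> pd.DataFrame:
    """Size variability per campaign from a biometry table.

    Expects columns ``campaign_id``, ``fork_length``, ``weight``.  Campaigns
    with fewer than two measured individuals get NaN with a warning.
    """
    out = []
    for camp, grp in biometry.groupby("campaign_id"):
        try:
            sv = size_variability(grp["fork_length"].to_numpy(), grp["weight"].to_numpy())
        except ValueError:
            logger.warning("campaign %s: size variability undefined (<2 individuals)", camp)
            sv = np.nan
        out.append({"campaign_id": camp, "size_variability": sv})
    return pd.DataFrame(out)
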