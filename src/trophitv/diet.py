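"""Individual diet matrices from validated metabarcoding detections.

Faecal metabarcoding yields, per faecal sample, a set of validated sequence
variants (ASVs, or contigs merged across overlapping COI markers), each
assigned to a harmonised prey taxon.  Prey abundance in a sample is
estimated with the Minimal Number of Individuals (MNI) rule: the MNI of a
taxon is the number of *distinct* variants of that taxon detected in the
sample — a conservative count, since two prey individuals sharing a
genotype collapse to one variant.

The module turns a long detection table into a wide individual x taxon MNI
matrix, derives per-individual diet proportions ``p_ij`` and per-group
(population) diets ``q_j``, and applies the pooled occurrence filter used
to decide which taxa enter electivity tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DETECTION_COLUMNS = ["sample_id", "individual_id", "campaign_id", "variant_id", "taxon_id"]


class TaxonomyError(ValueError):
    """A detection references a taxon absent from the taxonomy map."""


class DuplicateDetectionError(ValueError):
    """Duplicate (sample_id, variant_id) rows without the deduplication flag."""


@dataclass
class DietMatrix:
    """Individual x prey-taxon MNI counts plus sample metadata.

    Attributes
    ----------
    counts
        DataFrame indexed by ``individual_id`` with one integer column per
        prey taxon; cell (i, t) is the MNI of taxon t in individual i's
        faecal sample.
    meta
        DataFrame indexed by ``individual_id`` with at least ``sample_id``
        and ``campaign_id`` columns.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.meta.index):
            raise ValueError("counts and meta must be indexed by the same individuals")

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def individuals(self) -> list[str]:
        return list(self.counts.index)

    def subset(self, individuals: pd.Index | list[str]) -> "DietMatrix":
        return DietMatrix(self.counts.loc[individuals], self.meta.loc[individuals])

    def to_long(self) -> pd.DataFrame:
        """Long-format table (individual, taxon, mni, proportion)."""
        props = diet_proportions(self)
        long = (
            self.counts.stack()
            .rename("mni")
            .reset_index()
            .rename(columns={"level_0": "individual_id", "level_1": "taxon_id"})
        )
        long.columns = ["individual_id", "taxon_id", "mni"]
        plong = props.stack().rename("proportion").reset_index()
        plong.columns = ["individual_id", "taxon_id", "proportion"]
        out = long.merge(plong, on=["individual_id", "taxon_id"], how="left")
        return out[out["mni"] > 0].reset_index(drop=True)


def validate_detections(
    detections: pd.DataFrame,
    taxonomy: set[str] | None = None,
    deduplicate: bool = False,
) -> pd.DataFrame:
    """Check schema, taxonomy membership and (sample, variant) uniqueness.

    Returns the validated (possibly deduplicated) table.
    """
    missing = [c for c in DETECTION_COLUMNS if c not in detections.columns]
    if missing:
        raise ValueError(f"detection table missing columns: {missing}")
    det = detections[DETECTION_COLUMNS].copy()
    if det[DETECTION_COLUMNS].isna().any().any():
        raise ValueError("detection table contains missing values")
    if taxonomy is not None:
        unknown = set(det["taxon_id"]) - set(taxonomy)
        if unknown:
            raise TaxonomyError(f"taxa absent from taxonomy map: {sorted(unknown)}")
    dup = det.duplicated(subset=["sample_id", "variant_id"])
    if dup.any():
        if not deduplicate:
            raise DuplicateDetectionError(
                f"{int(dup.sum())} duplicate (sample_id, variant_id) rows; "
                "pass deduplicate=True to collapse them"
            )
        det = det[~dup]
        logger.warning("dropped %d duplicate (sample, variant) detection rows", int(dup.sum()))
    # one faecal sample per individual per campaign
    per_ind = det.groupby(["campaign_id", "individual_id"])["sample_id"].nunique()
    if (per_ind > 1).any():
        bad = per_ind[per_ind > 1].index.tolist()
        raise ValueError(f"individuals with >1 sample within a campaign: {bad}")
    return det


def compute_mni(
    detections: pd.DataFrame,
    taxonomy: set[str] | None = None,
    deduplicate: bool = False,
) -> DietMatrix:
    """Build the MNI diet matrix: distinct variants per (sample, taxon).

    Samples with zero validated variants cannot appear in the long table and
    are therefore absent from the result; individuals listed in the table
    always have at least one detection.
    """
    det = validate_detections(detections, taxonomy=taxonomy, deduplicate=deduplicate)
    if det.empty:
        raise ValueError("no validated detections")
    mni = (
        det.groupby(["individual_id", "taxon_id"])["variant_id"]
        .nunique()
        .unstack(fill_value=0)
        .sort_index()
    )
    mni = mni[sorted(mni.columns)].astype(int)
    mni.columns.name = None
    mni.index.name = "individual_id"
    meta = (
        det[["individual_id", "sample_id", "campaign_id"]]
        .drop_duplicates()
        .set_index("individual_id")
        .sort_index()
    )
    return DietMatrix(mni, meta)


def diet_proportions(matrix: DietMatrix) -> pd.DataFrame:
    """Per-individual proportions p_ij = MNI_ij / sum_j MNI_ij.

    Zero-total rows are excluded with a warning (they carry no diet
    information).
    """
    totals = matrix.counts.sum(axis=1)
    empty = totals == 0
    if empty.any():
        logger.warning("excluding %d zero-total diet rows", int(empty.sum()))
    counts = matrix.counts.loc[~empty]
    return counts.div(counts.sum(axis=1), axis=0)


def pooled_diet(
    matrix: DietMatrix,
    grouping: pd.Series | None = None,
    convention: str = "sum",
) -> pd.DataFrame:
    """Population diet q_j per group (default grouping: campaign).

    convention="sum"   : q_j = sum_i MNI_ij / sum_ij MNI_ij (pooled counts);
    convention="average": q_j = mean over individuals of p_ij.
    Returns a group x taxon DataFrame whose rows sum to 1.
    """
    if convention not in {"sum", "average"}:
        raise ValueError(f"unknown population-diet convention: {convention!r}")
    if grouping is None:
        grouping = matrix.meta["campaign_id"]
    grouping = grouping.reindex(matrix.counts.index)
    if grouping.isna().any():
        raise ValueError("every individual must be assigned to exactly one group")
    if convention == "sum":
        sums = matrix.counts.groupby(grouping).sum()
        totals = sums.sum(axis=1)
        if (totals == 0).any():
            raise ValueError("group with zero total MNI")
        return sums.div(totals, axis=0)
    props = diet_proportions(matrix)
    return props.groupby(grouping.reindex(props.index)).mean()


def occurrence_filter(matrix: DietMatrix, min_occurrence: float = 0.05) -> list[str]:
    """Taxa present (MNI > 0) in at least ``min_occurrence`` of all samples.

    Occurrence is pooled across campaigns; the threshold is inclusive.
    """
    if not 0 < min_occurrence <= 1:
        raise ValueError("min_occurrence must lie in (0, 1]")
    n = len(matrix.counts)
    occ = (matrix.counts > 0).sum(axis=0) / n
    return [t for t in matrix.taxa if occ[t] >= min_occurrence]


def filter_age_class(
    biometry: pd.DataFrame, exclude: tuple[str, ...] = ("yoy",)
) -> pd.DataFrame:
    """Drop young-of-the-year (or other excluded age classes) before trait work."""
    if "age_class" not in biometry.columns:
        return biometry
    keep = ~biometry["age_class"].isin(exclude)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("age-class filter removed %d individuals (%s)", n_drop, exclude)
    return biometry[keep]


def write_diet_tables(matrix: DietMatrix, wide_path, long_path) -> None:
    wide = matrix.counts.copy()
    wide.insert(0, "campaign_id", matrix.meta["campaign_id"])
    wide.to_csv(wide_path, sep="\t")
    matrix.to_long().to_csv(long_path, sep="\t", index=False)


def read_detections(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)
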