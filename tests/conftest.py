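import logging

import numpy as np
import pandas as pd
import pytest

import trophitv as tv

logging.getLogger("trophitv").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_study():
    """One small mechanistic study shared by integration-style tests."""
    cfg = tv.GeneratorConfig(seed=101, n_sites=2, n_years=1, fish_per_campaign=15)
    return tv.simulate_study(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_study):
    return tv.compute_mni(small_study.detections)


def random_detections(rng, n_samples=6, n_taxa=4, n_variants=12):
    """Random detection table (deduplicated) for oracle comparisons."""
    rows = []
    taxa = [f"tax{j}" for j in range(n_taxa)]
    variant_taxon = {f"v{k}": taxa[rng.integers(n_taxa)] for k in range(n_variants)}
    for i in range(n_samples):
        variants = rng.choice(n_variants, size=rng.integers(1, n_variants), replace=False)
        for k in variants:
            rows.append(
                {
                    "sample_id": f"s{i}",
                    "individual_id": f"ind{i}",
                    "campaign_id": f"c{i % 2}",
                    "variant_id": f"v{k}",
                    "taxon_id": variant_taxon[f"v{k}"],
                }
            )
    return pd.DataFrame(rows)


def brute_force_mni(det):
    """Independent recount: distinct variants per (individual, taxon)."""
    out = {}
    for _, row in det.iterrows():
        key = (row["individual_id"], row["taxon_id"])
        out.setdefault(key, set()).add(row["variant_id"])
    return {k: len(v) for k, v in out.items()}
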