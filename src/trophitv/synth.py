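"""Synthetic study generator with known ground truth.

Generates complete studies — habitat point samples, prey communities, fish
biometry and faecal metabarcoding detections — so every pipeline stage can
be exercised against planted parameters.  The generative chain mirrors the
structure the analysis assumes:

1. *Habitat*: each campaign (site x year x season) draws campaign-level
   habitat means (site baseline + seasonal shift); point-level values add a
   smooth spatial gradient along the transect plus noise, and ordinal
   variables are discretised onto their field scales.
2. *Prey*: each point's expected density per taxon is log-linear in the
   point's (z-scored) habitat values; counts are negative-binomial so
   spatial CVs vary realistically.  The focal mayflies (Baetis,
   Heptageniidae) get a seasonal large/small length mixture so the >= 5 mm
   cohort exists.
3. *Fish*: sizes come from a site-specific distribution; each fish sits at
   a position on the transect and forages over the points within a patch
   radius, so its prey availability is the local prey mix.
4. *Diet*: the number of items per faeces is a count draw; items are
   multinomial over taxa with probability proportional to
   (preference weight) x (local availability) x (per-individual jitter),
   where the jitter SD is the individual-heterogeneity parameter —
   optionally modulated by campaign habitat, a direct (non-prey-mediated)
   habitat channel into trait variation.
5. *Detections*: every consumed item is assigned a genotype uniformly from
   its taxon's pool, and a sample's variants are the distinct genotypes —
   so the MNI recovered downstream is a conservative lower bound on the
   items actually consumed.

A separate linear-Gaussian layer (:func:`simulate_path_data`) plants exact
standardized path coefficients at campaign level for calibrating and
validating the path-analysis machinery.

All randomness flows from one root seed through named child seeds
(`numpy` SeedSequence spawning), so stage-level reruns reproduce exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .opportunity import HABITAT_VARS, SurveyTable

logger = logging.getLogger(__name__)

DEFAULT_TAXA = [
    # name, preference weight, genotype pool, base ln density, p(large) by season
    ("Baetis", 4.0, 30, 2.0),
    ("Heptageniidae", 3.0, 20, 1.4),
    ("Orthocladiinae", 0.5, 25, 2.6),
    ("Gammarus", 1.2, 15, 1.0),
    ("Hydropsyche", 1.5, 12, 1.0),
    ("Simuliidae", 1.0, 10, 1.2),
    ("Chironomini", 0.8, 18, 1.6),
    ("Psychomyiidae", 1.0, 8, 0.4),
    ("Leuctra", 1.0, 10, 0.8),
    ("Limnephilidae", 0.7, 6, 0.2),
]

HVARS = list(HABITAT_VARS)  # continuous latents behind the six field variables

# log-linear habitat -> prey coefficients (rows: taxa, cols: HVARS order:
# substrate_richness, substrate_max, velocity, depth, clogging, vegetal)
DEFAULT_HABITAT_PREY = {
    "Baetis": [0.1, 0.1, 0.45, 0.0, -0.35, 0.15],
    "Heptageniidae": [0.15, 0.4, 0.25, 0.0, -0.45, 0.0],
    "Orthocladiinae": [0.0, -0.1, 0.0, 0.0, 0.35, 0.4],
    "Gammarus": [0.1, 0.0, -0.2, 0.1, 0.0, 0.3],
    "Hydropsyche": [0.0, 0.2, 0.35, 0.0, -0.1, 0.0],
    "Simuliidae": [0.0, 0.0, 0.5, -0.1, -0.2, 0.0],
    "Chironomini": [0.0, -0.2, -0.25, 0.2, 0.3, 0.1],
    "Psychomyiidae": [0.1, 0.2, 0.0, 0.1, -0.2, 0.0],
    "Leuctra": [0.2, 0.2, 0.15, 0.0, -0.3, 0.0],
    "Limnephilidae": [0.1, 0.0, -0.2, 0.1, 0.0, 0.2],
}

# seasonal multipliers on expected densities (preferred mayflies crash in autumn)
DEFAULT_SEASONAL = {
    "spring": {"Baetis": 1.3, "Heptageniidae": 1.2},
    "summer": {},
    "autumn": {"Baetis": 0.35, "Heptageniidae": 0.35, "Orthocladiinae": 1.3, "Gammarus": 1.3},
}

# probability that a focal-taxon individual is >= 5 mm, per season
P_LARGE = {"spring": 0.5, "summer": 0.4, "autumn": 0.15}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic study; defaults echo the study's scale.

    23-odd campaigns (sites x years x seasons), 45-90 Surber points and
    ~30 faeces per campaign, ~10 harmonised prey taxa with genotype pools
    driving MNI saturation.
    """

    seed: int
    n_sites: int = 4
    n_years: int = 2
    seasons: tuple[str, ...] = ("spring", "summer", "autumn")
    points_cycle: tuple[int, ...] = (90, 60, 45)
    fish_per_campaign: int = 30
    taxa: list[str] = field(default_factory=lambda: [t[0] for t in DEFAULT_TAXA])
    preference: dict[str, float] = field(
        default_factory=lambda: {t[0]: t[1] for t in DEFAULT_TAXA}
    )
    genotype_pool: dict[str, int] = field(
        default_factory=lambda: {t[0]: t[2] for t in DEFAULT_TAXA}
    )
    base_log_density: dict[str, float] = field(
        default_factory=lambda: {t[0]: t[3] for t in DEFAULT_TAXA}
    )
    habitat_prey_coefs: dict[str, list[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_HABITAT_PREY.items()}
    )
    trait_habitat_coefs: dict[str, float] = field(default_factory=dict)
    seasonal_multipliers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(m) for s, m in DEFAULT_SEASONAL.items()}
    )
    heterogeneity: float = 1.0
    patch_radius: float = 0.3
    items_rate: float = 30.0
    nb_dispersion: float = 2.0
    spatial_amplitude: float = 0.8
    yoy_fraction: float = 0.05

    def validate(self) -> None:
        for name, mapping in [
            ("preference", self.preference),
            ("genotype_pool", self.genotype_pool),
            ("base_log_density", self.base_log_density),
            ("habitat_prey_coefs", self.habitat_prey_coefs),
        ]:
            missing = set(self.taxa) - set(mapping)
            if missing:
                raise ValueError(f"{name} missing taxa: {sorted(missing)}")
        for t, row in self.habitat_prey_coefs.items():
            if len(row) != len(HVARS):
                raise ValueError(
                    f"habitat_prey_coefs[{t}] has {len(row)} entries, expected {len(HVARS)}"
                )
        if any(w < 0 for w in self.preference.values()):
            raise ValueError("preference weights must be non-negative")
        if self.heterogeneity < 0 or self.items_rate <= 0 or self.patch_radius <= 0:
            raise ValueError("rates and scales must be positive")


@dataclass
class GroundTruth:
    """Planted generator parameters (what recovery tests compare against)."""

    preference: dict[str, float]
    heterogeneity: float
    patch_radius: float
    habitat_prey_coefs: dict[str, list[float]]
    trait_habitat_coefs: dict[str, float]
    seasonal_multipliers: dict[str, dict[str, float]]
    seed: int


@dataclass
class SyntheticStudy:
    """Generated study: tables plus the campaign design and ground truth."""

    survey: SurveyTable
    biometry: pd.DataFrame
    detections: pd.DataFrame
    campaigns: pd.DataFrame  # campaign_id site year season n_points
    config: GeneratorConfig

    def ground_truth(self) -> GroundTruth:
        c = self.config
        return GroundTruth(
            preference=dict(c.preference),
            heterogeneity=c.heterogeneity,
            patch_radius=c.patch_radius,
            habitat_prey_coefs={k: list(v) for k, v in c.habitat_prey_coefs.items()},
            trait_habitat_coefs=dict(c.trait_habitat_coefs),
            seasonal_multipliers={s: dict(m) for s, m in c.seasonal_multipliers.items()},
            seed=c.seed,
        )


def _rngs(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    """Named child generators spawned from one root seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


_SEASON_SHIFT = {
    # additive shifts on the latent habitat means, per season
    "spring": {"velocity": 0.4, "clogging": -0.4, "vegetal": 0.2},
    "summer": {"velocity": 0.0, "clogging": 0.0, "vegetal": 0.4},
    "autumn": {"velocity": -0.4, "clogging": 0.8, "vegetal": -0.6},
}


def simulate_study(config: GeneratorConfig) -> SyntheticStudy:
    """Generate one complete synthetic study (see module docstring)."""
    config.validate()
    rngs = _rngs(config.seed, ["habitat", "prey", "fish", "diet", "detect"])
    taxa = config.taxa
    B = np.array([config.habitat_prey_coefs[t] for t in taxa])  # taxa x hvars
    alpha = np.array([config.base_log_density[t] for t in taxa])

    rng_h = rngs["habitat"]
    campaigns = []
    idx = 0
    site_base = {
        s: rng_h.normal(0.0, 0.5, size=len(HVARS)) for s in range(config.n_sites)
    }
    hab_rows = []
    count_rows = []
    latent_by_campaign: dict[str, np.ndarray] = {}
    pos_by_campaign: dict[str, np.ndarray] = {}
    for site in range(config.n_sites):
        for year in range(config.n_years):
            for season in config.seasons:
                camp_id = f"s{site + 1}y{year + 1}{season[:3]}"
                n_points = config.points_cycle[idx % len(config.points_cycle)]
                idx += 1
                campaigns.append(
                    {
                        "campaign_id": camp_id,
                        "site": f"site{site + 1}",
                        "year": f"y{year + 1}",
                        "season": season,
                        "n_points": n_points,
                    }
                )
                shift = np.array([_SEASON_SHIFT[season].get(v, 0.0) for v in HVARS]) if season in _SEASON_SHIFT else np.zeros(len(HVARS))
                camp_mean = site_base[site] + shift + rng_h.normal(0.0, 0.25, len(HVARS))
                pos = (np.arange(n_points) + 0.5) / n_points
                phase = rng_h.uniform(0, 2 * np.pi, len(HVARS))
                freq = rng_h.integers(1, 4, len(HVARS))
                grad = config.spatial_amplitude * np.sin(
                    2 * np.pi * freq[None, :] * pos[:, None] + phase[None, :]
                )
                latent = camp_mean[None, :] + grad + rng_h.normal(0.0, 0.5, (n_points, len(HVARS)))
                latent_by_campaign[camp_id] = latent
                pos_by_campaign[camp_id] = pos
                hab = _discretise_habitat(latent)
                for i in range(n_points):
                    row = {"campaign_id": camp_id, "point_id": f"p{i + 1:03d}"}
                    row.update({v: hab[v][i] for v in HVARS})
                    hab_rows.append(row)
    campaigns_df = pd.DataFrame(campaigns)

    # prey counts (negative binomial around log-linear expectation)
    rng_p = rngs["prey"]
    counts_by_campaign: dict[str, np.ndarray] = {}
    for camp in campaigns_df.itertuples():
        latent = latent_by_campaign[camp.campaign_id]
        mult = np.array(
            [config.seasonal_multipliers.get(camp.season, {}).get(t, 1.0) for t in taxa]
        )
        log_mu = alpha[None, :] + latent @ B.T + np.log(mult)[None, :]
        mu = np.exp(np.clip(log_mu, -10, 8))
        k = config.nb_dispersion
        counts = rng_p.negative_binomial(k, k / (k + mu))
        counts_by_campaign[camp.campaign_id] = counts
        p_large = P_LARGE.get(camp.season, 0.4)
        for j, taxon in enumerate(taxa):
            focal = taxon in ("Baetis", "Heptageniidae")
            for i in np.nonzero(counts[:, j])[0]:
                c = int(counts[i, j])
                if focal:
                    n_large = int(rng_p.binomial(c, p_large))
                    if n_large:
                        count_rows.append(
                            (camp.campaign_id, f"p{i + 1:03d}", taxon, "large", n_large)
                        )
                    if c - n_large:
                        count_rows.append(
                            (camp.campaign_id, f"p{i + 1:03d}", taxon, "small", c - n_large)
                        )
                else:
                    count_rows.append((camp.campaign_id, f"p{i + 1:03d}", taxon, "", c))
    survey = SurveyTable(
        counts=pd.DataFrame(
            count_rows, columns=["campaign_id", "point_id", "taxon_id", "size_class", "count"]
        ),
        habitat=pd.DataFrame(hab_rows),
    )

    # fish biometry and positions
    rng_f = rngs["fish"]
    site_len = {
        f"site{s + 1}": rng_f.uniform(120, 180) for s in range(config.n_sites)
    }
    bio_rows = []
    fish_pos: dict[str, float] = {}
    for camp in campaigns_df.itertuples():
        for i in range(config.fish_per_campaign):
            ind = f"{camp.campaign_id}_f{i + 1:03d}"
            yoy = rng_f.random() < config.yoy_fraction
            length = float(
                np.clip(rng_f.normal(60 if yoy else site_len[camp.site], 8 if yoy else 20), 40, 230)
            )
            weight = float(2.4e-5 * length**2.9 * np.exp(rng_f.normal(0, 0.08)))
            bio_rows.append(
                {
                    "individual_id": ind,
                    "campaign_id": camp.campaign_id,
                    "site": camp.site,
                    "year": camp.year,
                    "season": camp.season,
                    "fork_length": round(length),
                    "weight": round(weight, 1),
                    "age_class": "yoy" if yoy else "adult",
                }
            )
            fish_pos[ind] = float(rng_f.random())
    biometry = pd.DataFrame(bio_rows)

    # diets and detections
    rng_d = rngs["diet"]
    rng_v = rngs["detect"]
    omega = np.array([config.preference[t] for t in taxa])
    pools = np.array([config.genotype_pool[t] for t in taxa])
    det_rows = []
    camp_latent_mean = {c: latent_by_campaign[c].mean(axis=0) for c in latent_by_campaign}
    hv_index = {v: i for i, v in enumerate(HVARS)}
    for fish in biometry.itertuples():
        camp_id = fish.campaign_id
        counts = counts_by_campaign[camp_id]
        pos = pos_by_campaign[camp_id]
        local = np.abs(pos - fish_pos[fish.individual_id]) <= config.patch_radius
        if not local.any():
            local[np.argmin(np.abs(pos - fish_pos[fish.individual_id]))] = True
        avail = counts[local].mean(axis=0)
        if avail.sum() == 0:
            avail = np.ones(len(taxa))
        eta = config.heterogeneity
        if config.trait_habitat_coefs:
            mod = sum(
                coef * camp_latent_mean[camp_id][hv_index[v]]
                for v, coef in config.trait_habitat_coefs.items()
            )
            eta = eta * float(np.exp(mod))
        jitter = np.exp(eta * rng_d.standard_normal(len(taxa)))
        w = omega * jitter * avail
        if w.sum() == 0:
            w = np.ones(len(taxa))
        n_items = 1 + rng_d.poisson(max(config.items_rate - 1, 0.0))
        items = rng_d.multinomial(n_items, w / w.sum())
        sample_id = f"S_{fish.individual_id}"
        for j, m in enumerate(items):
            if m == 0:
                continue
            genotypes = np.unique(rng_v.integers(0, pools[j], size=m))
            for g in genotypes:
                det_rows.append(
                    {
                        "sample_id": sample_id,
                        "individual_id": fish.individual_id,
                        "campaign_id": camp_id,
                        "variant_id": f"{taxa[j]}_v{g:03d}",
                        "taxon_id": taxa[j],
                    }
                )
    detections = pd.DataFrame(det_rows)
    return SyntheticStudy(
        survey=survey,
        biometry=biometry,
        detections=detections,
        campaigns=campaigns_df,
        config=config,
    )


def _discretise_habitat(latent: np.ndarray) -> dict[str, np.ndarray]:
    """Map continuous latent habitat onto the field measurement scales."""
    out: dict[str, np.ndarray] = {}
    z = {v: latent[:, i] for i, v in enumerate(HVARS)}
    out["substrate_richness"] = np.clip(np.round(3.0 + 1.2 * z["substrate_richness"]), 1, 8).astype(int)
    out["substrate_max"] = np.clip(np.round(5.0 + 1.8 * z["substrate_max"]), 0, 10).astype(int)
    out["velocity"] = np.round(np.clip(40.0 + 18.0 * z["velocity"], 0, None), 1)
    out["depth"] = np.round(np.clip(30.0 + 10.0 * z["depth"], 3, None), 1)
    out["clogging"] = np.clip(np.round(2.5 + 1.0 * z["clogging"]), 1, 5).astype(int)
    out["vegetal"] = np.clip(np.round(2.5 + 1.0 * z["vegetal"]), 1, 5).astype(int)
    return out


# --------------------------------------------------------------------------
# linear-Gaussian path layer (exact planted standardized effects)
# --------------------------------------------------------------------------

def simulate_path_data(
    seed: int,
    n_campaigns: int = 40,
    n_individuals: int = 30,
    direct: float = 0.3,
    b: float = 0.5,
    c: float = 0.4,
    size_effect: float = 0.3,
    var_site: float = 0.05,
    var_year: float = 0.05,
    n_sites: int = 8,
    n_years: int = 2,
    n_noise_habitat: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Campaign-level linear-Gaussian data with planted standardized paths.

    Structure: H1 -> P1 (coef b), P1 -> T (c), H1 -> T (direct), S1 -> T
    (size_effect); S1 independent of H1 and P1.  H1, P1, S1 are standard
    normal at campaign level (P1's residual variance is 1 − b²) and the
    trait T has total variance 1 (residual variance absorbs the remainder
    after fixed, site and year components), so the planted raw coefficients
    *are* the planted standardized effects.  Optional pure-noise habitat
    variables (H2, ...) are independent of everything.

    Returns the individual-level frame and the ground-truth effect dict.
    """
    rng = np.random.default_rng(seed)
    var_fixed = direct**2 + c**2 + 2 * direct * c * b + size_effect**2
    var_resid = 1.0 - var_fixed - var_site - var_year
    if var_resid <= 0:
        raise ValueError("planted coefficients leave no residual variance")
    H = rng.standard_normal(n_campaigns)
    P = b * H + np.sqrt(1 - b**2) * rng.standard_normal(n_campaigns)
    S = rng.standard_normal(n_campaigns)
    noise_H = rng.standard_normal((n_campaigns, n_noise_habitat))
    site = np.arange(n_campaigns) % n_sites
    year = np.arange(n_campaigns) // (n_campaigns // n_years) % n_years
    u_site = rng.normal(0, np.sqrt(var_site), n_sites)
    u_year = rng.normal(0, np.sqrt(var_year), n_years)
    rows = []
    for k in range(n_campaigns):
        t_mean = direct * H[k] + c * P[k] + size_effect * S[k] + u_site[site[k]] + u_year[year[k]]
        resid = rng.normal(0, np.sqrt(var_resid), n_individuals)
        for i in range(n_individuals):
            row = {
                "campaign_id": f"c{k + 1:03d}",
                "site": f"site{site[k] + 1}",
                "year": f"y{year[k] + 1}",
                "H1": H[k],
                "P1": P[k],
                "S1": S[k],
                "T": t_mean + resid[i],
            }
            for m in range(n_noise_habitat):
                row[f"H{m + 2}"] = noise_H[k, m]
            rows.append(row)
    truth = {
        "direct": direct,
        "indirect": b * c,
        "total": direct + b * c,
        "b": b,
        "c": c,
        "size_effect": size_effect,
    }
    return pd.DataFrame(rows), truth


def write_study(study: SyntheticStudy, outdir) -> dict[str, str]:
    """Write the study tables as TSV plus the ground truth as JSON."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "detections": outdir / "detections.tsv",
        "biometry": outdir / "biometry.tsv",
        "survey_counts": outdir / "survey_counts.tsv",
        "survey_habitat": outdir / "survey_habitat.tsv",
        "campaigns": outdir / "campaigns.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    study.detections.to_csv(paths["detections"], sep="\t", index=False)
    study.biometry.to_csv(paths["biometry"], sep="\t", index=False)
    study.survey.counts.to_csv(paths["survey_counts"], sep="\t", index=False)
    study.survey.habitat.to_csv(paths["survey_habitat"], sep="\t", index=False)
    study.campaigns.to_csv(paths["campaigns"], sep="\t", index=False)
    gt = study.ground_truth()
    with open(paths["ground_truth"], "w") as fh:
        json.dump(
            {
                "preference": gt.preference,
                "heterogeneity": gt.heterogeneity,
                "patch_radius": gt.patch_radius,
                "habitat_prey_coefs": gt.habitat_prey_coefs,
                "trait_habitat_coefs": gt.trait_habitat_coefs,
                "seasonal_multipliers": gt.seasonal_multipliers,
                "seed": gt.seed,
            },
            fh,
            indent=2,
        )
    return {k: str(v) for k, v in paths.items()}
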