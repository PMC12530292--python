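# trophitv

Individual trophic trait variation from diet metabarcoding: MNI diet
matrices, specialisation indices, prey-electivity null models, and
piecewise path analysis separating direct from prey-mediated habitat
effects.

## The problem

Within-species individual trait variation (ITV) in diet is shaped by
*ecological opportunity* — the prey community and the habitat an individual
can exploit at a given moment.  Quantifying that link requires a chain of
analyses: faecal metabarcoding detections must be turned into per-individual
diet estimates; individual trophic traits must be computed against the right
population baseline; prey availability and habitat structure must be
summarised per sampling campaign at matched effort; prey selection must be
tested against availability-conditional null models; and finally the direct
habitat effect on traits must be separated from the indirect, prey-mediated
one.  `trophitv` implements that full chain for riverine, benthic systems
(a low-mobility fish feeding on macroinvertebrates sampled by Surber
quadrats), plus a synthetic-study generator with known ground truth so
every stage can be validated end to end.

## The quantities at the core

* **MNI** (Minimal Number of Individuals): the abundance of a prey taxon in
  one faecal sample is the number of *distinct* sequence variants
  (ASVs/contigs) of that taxon detected — a conservative lower bound on the
  number of prey individuals consumed.
* **INW** (individual niche width): Shannon diversity of the individual's
  diet proportions, `H_i = −Σ_j p_ij ln p_ij`.
* **BIC** (between-individual component): the individual specialisation
  index `V = 1 − PS_i`, with `PS_i = Σ_j min(p_ij, q_j)` the proportional
  similarity between individual diet `p_i` and the population diet `q` of
  its sampling campaign.  `V = 0` means the individual eats like its
  population; `V → 1` means full divergence.
* **Ecological opportunity estimators** per campaign: mean prey richness,
  Shannon diversity, densities of key taxa (Baetis and Heptageniidae, total
  and ≥ 5 mm cohorts, Orthocladiinae), mean pairwise Bray–Curtis
  dissimilarity between points, six habitat variables — each paired with a
  spatial-heterogeneity estimator `CV = 100·σ/μ` over sampling points, and
  standardised to equal sampling effort by permutation subsampling.
* **Electivity**: observed per-taxon consumption versus a null model that
  redistributes each individual's total MNI by a multinomial draw
  proportional to local availability; classification against the empirical
  95% envelope (positive / neutral / negative selection).
* **Path analysis**: piecewise SEM over linear mixed models with crossed
  site and year random intercepts.  Missing edges imply d-separation
  claims, combined with Fisher's `C = −2 Σ ln p` (df = 2k); the direct
  habitat effect on a trait is the standardized path estimate, the indirect
  effect is `Σ_j β_std(H→P_j)·β_std(P_j→trait)`.

## Worked example

Simulate a small two-site study and push it through the diet, trait and
electivity stages:

```python
import trophitv as tv

cfg = tv.GeneratorConfig(seed=42, n_sites=2, n_years=1, fish_per_campaign=15)
study = tv.simulate_study(cfg)

adults = study.biometry.loc[study.biometry.age_class != "yoy", "individual_id"]
matrix = tv.compute_mni(study.detections[study.detections.individual_id.isin(adults)])

records, summary = tv.campaign_traits(matrix)
print(summary.round(2).to_string(index=False))
```

```
campaign_id  n  bic_mean  bic_sd  inw_mean  inw_sd
    s1y1aut 15      0.36    0.13      1.56    0.36
    s1y1spr 15      0.27    0.11      1.47    0.22
    s1y1sum 14      0.29    0.10      1.39    0.38
    s2y1aut 15      0.33    0.09      1.73    0.23
    s2y1spr 15      0.28    0.10      0.98    0.49
    s2y1sum 13      0.35    0.10      1.49    0.28
```

Each row is one sampling campaign (site × season): `bic_mean` is the mean
diet divergence of individuals from their campaign's pooled diet, and
`inw_mean` the mean individual Shannon niche width in nats.  Electivity
tests recover the planted preference structure — the generator gives
Baetis the strongest preference weight and makes Orthocladiinae avoided
despite its high availability:

```python
from trophitv.electivity import selection_summary
res = tv.run_electivity(matrix, study.survey.counts, n_sims=1000, iters=200, seed=1)
print(selection_summary(res).to_string(index=False))
```

```
      taxon_id  positive  neutral  negative  n_campaigns
        Baetis         6        0         0            6
 Heptageniidae         5        1         0            6
Orthocladiinae         0        0         6            6
...
```

The full pipeline (traits → opportunity → electivity → path analysis →
seasonal contrasts) runs from the shell:

```sh
trophitv simulate --out study/ --seed 7
trophitv all --detections study/detections.tsv --biometry study/biometry.tsv \
  --survey-counts study/survey_counts.tsv --survey-habitat study/survey_habitat.tsv \
  --out run/ --seed 7
```

`run/` then holds the diet matrices, trait tables, the campaign
ecological-opportunity table, electivity classifications, the BIC and INW
path-model reports (JSON with edges, standardized estimates, Fisher's C
and R² values), seasonal Tukey contrasts, and a manifest that makes the
run bit-for-bit reproducible.

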