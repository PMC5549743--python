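# divgrad

Hierarchical diversity analysis of plant communities sampled along combined
gradients of **elevation** and **forest-use intensity**.

The package is written for community ecologists working with nested
presence/absence surveys: several elevational locations, each holding stands
of different forest-use intensity (old-growth `OG`, degraded `DE`, secondary
`SE`), each stand sampled with a fixed number of equal-area plots.  From a
plots × species 0/1 matrix and a plot metadata table it computes:

* **α-diversity** — per-plot species richness — and **γ-diversity** — the
  pooled richness of all plots of a location;
* **β-diversity** as pairwise Sørensen dissimilarity, `β = 1 − S` with
  `S = 2C/(A+B)` (A, B species counts of the two plots, C the shared count),
  aggregated by *habitat transition* (the six unordered pairs of habitat
  codes) with bootstrap standard errors that resample plots within cells;
* **multiplicative diversity partitioning** per location,
  `γ = ᾱ · β_w · β_b`, where `β_w = ᾱ₂/ᾱ` is the effective number of
  compositionally distinct plots per habitat and `β_b = γ/ᾱ₂` the effective
  number of distinct habitats (`ᾱ₂` = mean pooled habitat richness);
* **Hill-number diversity profiles** `⁰D…³D` per location from incidence
  frequency counts, both empirical and asymptotic — the asymptotic estimator
  reduces to the bias-corrected Chao2 richness at `q = 0` and to the
  classical unbiased incidence Simpson estimator at `q = 2`;
* **GLM model selection**: 31 candidate models per response (negative
  binomial for richness, beta for the per-plot endemic proportion,
  log-normal for pairwise β), ranked by AICc with deviance pseudo-R².

A synthetic-landscape generator reproduces the statistical structure such
surveys exhibit — hump-shaped richness along elevation, elevational species
turnover, habitat-driven compositional differentiation, and an endemic
fraction that varies with elevation — so every stage of the pipeline runs
and is tested without any external data.

## Worked example

```python
from divgrad import (LandscapeConfig, generate_landscape,
                     transition_means, partition_all)

ls = generate_landscape(LandscapeConfig(seed=42))   # 120 plots, 264-species pool
tm = transition_means(ls.matrix, ls.meta,
                      exclude_locations=["L50"], reps=1000, seed=0)
print(tm[["transition", "mean_beta", "se", "n_pairs"]].round(3))
```

```
transition  mean_beta    se  n_pairs
     OG-OG      0.570 0.040       70
     DE-DE      0.567 0.035       70
     SE-SE      0.659 0.049       70
     OG-DE      0.662 0.023      175
     OG-SE      0.692 0.025      175
     DE-SE      0.700 0.024      175
```

Each row is the mean Sørensen dissimilarity over every plot pair of one
habitat transition, pooled across the seven upper locations (the lowest,
nearly species-free belt is excluded), with a bootstrap SE from 1000
plot-resampling replicates.  Between-habitat transitions (bottom three rows)
are more dissimilar than within-habitat ones — forest-use change drives
compositional turnover beyond the baseline heterogeneity of a stand.

```python
print(partition_all(ls.matrix, ls.meta)
      [["location", "alpha_bar", "beta_w", "beta_b", "gamma"]].round(2))
```

```
location  alpha_bar  beta_w  beta_b  gamma
     L50       1.47    2.05    1.00      3
    L650       4.73    2.25    1.22     13
   L1000       5.00    2.60    1.38     18
   L1500       8.67    2.35    1.48     30
   L2100      10.73    2.55    1.35     37
   L2500      13.33    2.43    1.36     44
   L3100      13.60    2.23    1.32     40
   L3500       2.40    2.92    1.71     12
```

Per location, mean plot richness times the two multiplicative β components
reconstructs the pooled richness exactly (`ᾱ · β_w · β_b = γ`): e.g. at
2500 m, 13.33 × 2.43 × 1.36 = 44.  Richness is hump-shaped with elevation
while the between-habitat component `β_b` shows which belts owe their
species pool to habitat differentiation.

The same stages are scriptable from a shell:

```bash
divgrad simulate --seed 42 --out sim/
divgrad validate --matrix sim/matrix.csv --meta sim/meta.csv
divgrad beta --matrix sim/matrix.csv --meta sim/meta.csv \
        --exclude-location L50 --reps 1000 --seed 0 --out beta.csv
divgrad glm --matrix sim/matrix.csv --meta sim/meta.csv \
        --response alpha --out models.csv
divgrad run --config run.yaml        # whole pipeline from one config
```

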