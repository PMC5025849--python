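# shortstop

Analysis toolkit for **winter shortstopping** in migratory birds — the
shortening of a migration route by shifting the wintering grounds toward
the breeding grounds. It was built around the reintroduced eastern
migratory population of whooping cranes (*Grus americana*), whose
individually identifiable, lifetime-tracked birds established dozens of
new overwintering sites between Florida and Indiana within little more
than a decade, and is aimed at movement ecologists who have per-individual
relocation records and want to ask *who innovates new wintering sites,
and why there*.

## What it computes

Starting from timestamped relocations (`bird_id, date, lat, lon`) and
hatch years, the pipeline:

1. **Detects overwintering events** per bird and winter
   (November–April): single-linkage clusters of observations within
   10 km whose temporal span is ≥ 15 days. When a bird uses several
   sites in one winter, the southernmost is kept (a conservative
   estimate of shortstopping).
2. **Clusters events into population-level sites** — two events belong
   to the same site if any of their observations are within 10 km
   (alternates: event centroids within 20 km or 10 km) — and records
   each site's first year of use and its **founding group**.
3. **Builds the site-level regression table** with the distance of each
   site from the breeding centroid (azimuthal equidistant projection
   centred at 36° N, −86° E) as the response $y_j$, and as predictors:
   the founding group's **maximum age**, the site's **winter temperature
   anomaly** (mean Jan–Feb, 1990–2010 minus 1900–1920, °C), **percent
   grain cover** within 10 km, and a **spatial autocovariate**

   $$\mathrm{ac}_i=\sum_{j\in N(i)} \frac{y_j}{d_{ij}},$$

   over neighbours within 100 km (nearest neighbour as fallback),
   z-scaled; a weighted-mean variant is available behind a switch.
4. **Fits three mixed-effects models**:
   * `distance ~ max_age + temp_anomaly + grain_cover + autocov + (1 | first_use_year)` (REML),
   * `log(min prior distance to site) ~ age + (1|bird) + (1|year) + (1|site)` (REML) — the
     individual-experience model, with prior distances floored at 10 km,
   * `shortstopped ~ age + year + (1|bird)` (binomial GLMM, logit link,
     Gauss–Hermite maximum likelihood), where a bird-winter is a
     shortstop if its migration distance is < 1,200 km; with a
     1,000-replicate parametric-bootstrap band for the predicted
     probabilities.
5. **Guards the age effect** with two year-stratified randomization
   tests (founding groups, or founder individuals, reshuffled among the
   same year's new sites) and checks model residuals with a **Moran's I
   correlogram** at 50/200/1,650 km with permutation p-values.

A synthetic-population generator (`shortstop.synthetic_data`) emulates
the study system — 175 birds in annual cohorts over winters 2002–2015,
68 latent overwintering sites, a −40 km/yr group-age effect,
latitude-correlated covariates, age-dependent prior ranging, and social
adoption of northern sites — with complete ground truth, so every stage
of the pipeline is testable as a parameter-recovery exercise.

## Worked example

```python
from shortstop import (GeneratorConfig, generate, TrueSiteCovariateProvider,
                       PipelineConfig, run_pipeline)

dataset = generate(GeneratorConfig(seed=0))
config = PipelineConfig(seed=0, n_randomization_reps=200, n_bootstrap_reps=0)
result = run_pipeline(config,
                      relocations=dataset.relocations,
                      metadata=dataset.metadata,
                      provider=TrueSiteCovariateProvider(dataset.covariates))

print(f"sites detected: {result.summary['n_sites']}")
print(result.distance_fit.fe_table.round(2).to_string(index=False))
r = result.randomization_group
print(f"randomization (group): observed {r.observed_age_coef:.1f} km/yr, "
      f"null mean {r.randomized_age_coefs.mean():.1f}, p = {r.p_value:.3f}")
```

prints

```
sites detected: 68
        term  estimate    se     z    p
   intercept   1691.17 72.06 23.47 0.00
     max_age    -31.30  7.73 -4.05 0.00
temp_anomaly   -129.07 63.40 -2.04 0.04
 grain_cover     -9.75  2.02 -4.83 0.00
     autocov     40.29 23.62  1.71 0.09
randomization (group): observed -31.3 km/yr, null mean -9.3, p = 0.010
```

Read: all 68 generated sites were recovered from the raw relocations;
each extra year of age of the oldest bird in a founding group moves new
sites 31 km (±8 SE) closer to the breeding grounds (the generating value
is −40 km/yr, well within the confidence interval); warmer-anomaly and
grain-richer sites sit closer to the breeding grounds; and the
year-stratified randomization puts the observed age coefficient far in
the tail of its null (p = 0.010), so the effect is not an artefact of
the population ageing over the study.

The same steps are available from the shell:

```bash
shortstop generate --seed 0 --out data/
shortstop detect-sites --relocations data/relocations.csv --meta data/metadata.csv --out out/
shortstop run-all --relocations data/relocations.csv --meta data/metadata.csv \
          --covariates data/covariates.csv --seed 0 --out out/
```

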