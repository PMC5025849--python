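# Methods

This note records the models implemented in `shortstop`, the numerical
and design choices behind them, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## Geography

All coordinates are decimal-degree WGS84-style lat/lon. The Earth model
is a sphere of radius 6,371.0088 km for both the haversine distance and
the azimuthal equidistant (AEQD) projection; within the study region
(roughly 28–45° N, 95–80° W) the spherical/ellipsoidal discrepancy and
the AEQD pairwise distortion are each below 0.5% (property-tested),
which is immaterial against the 10-km-scale thresholds used everywhere.
Every *threshold* comparison (10 km residence and linkage, 100 km
neighbourhood, 1,200 km shortstop) is made on great-circle distances
from raw coordinates; the projection (centred 36° N, −86° E, the
midpoint of the historical training route) is used only for the
distance-from-breeding response, matching how that metric is defined.
The breeding reference point is the arithmetic centroid of the three
summer pen locations (43.87° N, −89.23° E); plain averaging is valid
because the pens span under two degrees.

## Overwintering events and sites

The residence rule — "observed in the same place (<10 km) for at least
15 days within November–April" — is operationalised as single-linkage
clustering of each bird-winter's observations at 10 km, keeping clusters
with ≥ 2 observations spanning ≥ 15 days. Single linkage is the natural
closure of the stated two-point rule under sparse VHF-style sampling:
any qualifying pair is contained in such a cluster. Threshold
comparisons are strict `<` as printed. A winter running November of
year Y through April of Y+1 is labelled Y; age in winter Y is
Y − hatch year, and birds younger than 1 are excluded before detection.
Exact duplicate records are dropped and same-bird same-day observations
within 1 km are collapsed to their centroid (both logged with counts).

When a bird has several events in one winter (the generator produces
these for ~19% of observed bird-winters, mirroring the study system),
the southernmost is retained — conservative with respect to detecting
shortstopping; latitude ties break by earliest arrival (logged).

Sites are connected components of events under one of three
interchangeable linkage rules: any-observation pairwise < 10 km
(default), or event centroids < 20 km / < 10 km. Candidate pairs are
pruned with a KD-tree on AEQD-projected coordinates at a 2%-inflated
radius (the projection's tangential stretch is ≤ 1.1% in the study
area) and confirmed with exact great-circle distances, so the result is
identical to the brute-force O(n²) computation (oracle-tested) at a
fraction of the cost. Site labels are assigned by (first-use year,
descending latitude), making the output invariant to input order. On
data whose latent sites are > 50 km apart all three rules give identical
partitions — the package's analogue of the robustness of the site
definition to these alternates.

## Covariates

**Spatial autocovariate.** For site *i* with neighbours N(i) (all sites
within 100 km, else the single nearest neighbour), the default raw
autocovariate is the inverse-distance-weighted **sum**
Σ_{j∈N(i)} y_j/d_ij, z-scaled to mean 0 / sd 1 (sample sd, n−1). The
weighted-**mean** form (weights normalised to 1) is available behind
`normalised=True`. The sum is the default for a structural reason: the
response is itself a distance, and the neighbourhood is defined by the
same metric, so the weighted mean of neighbours' responses reproduces
the response almost exactly (R² ≈ 0.97 on default synthetic data) and
absorbs every substantive effect in the regression — a degeneracy, not
an optimiser artefact (an independent mixed-model implementation gives
the identical fit). The weighted sum is dominated by local site density
instead, absorbs spatial clustering without cannibalising the response,
and leaves the age effect identifiable.

**Individual experience.** For each founding-group member, the minimum
great-circle distance from any of its relocations strictly before
November 1 of the site's first winter to the site centroid, floored at
10 km (anything closer would count as presence at the site) and
natural-log transformed. Founders with no prior relocations are
excluded and counted.

**Environmental covariates** enter through a provider interface
returning (temperature anomaly °C, grain cover %) per site. Shipped
providers: a site-id-keyed table join and a synthetic latitude-gradient
provider. Extraction from real temperature or cropland rasters is out
of scope, but the contract a raster provider must satisfy is: anomaly =
mean(Jan, Feb; 1990–2010) − mean(Jan, Feb; 1900–1920); grain = percent
cover of corn, wheat, sorghum, millet, oats, sunflower and peanuts
within a 10 km radius of the site centroid.

A collinearity screen (pairwise Pearson |r| ≤ 0.70 among the four fixed
effects) runs before the main model; on default synthetic data the
maximum |r| is ≈ 0.27.

## Mixed models

**Site-distance LMM** (`distance ~ max_age + temp_anomaly + grain_cover
+ autocov + (1 | first_use_year)`, REML). Fit by a profiled-REML
routine specialised to the single-random-intercept structure: V = I +
θZZ′ is inverted in closed form per group (Woodbury) and the REML
criterion is minimised over log θ by 1-D bounded search (xatol 1e−10),
giving an exact fit in ~1 ms. It matches an independent general-purpose
mixed-model implementation to ~1e−6 (asserted in tests) and never
fails on boundary variance. Rows are canonically re-ordered and the
design internally centred before solving, so estimates are exactly
invariant to input permutation and response shifts. Fixed-effect
p-values are Wald-z; with 68 sites the normal and t-based intervals are
practically indistinguishable (measured coverage of the nominal 95% CI
for the age effect across 100 full-pipeline replicates: 0.90–0.93,
slightly below nominal because the generator's placement rule induces
mild residual spatial correlation — see below). A near-zero year
variance issues a singular-fit warning rather than an error.

**Experience LMM** (`log_min_prev ~ age` with crossed random intercepts
for bird, year and site, REML) uses the general mixed-model machinery
via variance components. Fixed-effect covariance is computed by GLS at
the estimated variance components (the Hessian-based covariance can
lose positive definiteness at a variance boundary); this is the same
conditional covariance the standard mixed-model packages report. The
fit carries mean predictions by age with a 95% band for the mean,
random effects conditioned at zero, plus the back-transform exp(·).

**Shortstop GLMM** (`shortstopped ~ age + year + (1 | bird)`, binomial
with logit link). The marginal likelihood integrates the individual
intercept with 21-node Gauss–Hermite quadrature — more accurate than a
one-point Laplace approximation — and is maximised by BFGS over
(β, log σ) with optimiser tolerances gtol 1e−6 / 10,000 iterations.
Year enters centred on its midpoint for conditioning; the slope is
unchanged by centring and is reported per calendar year. Standard
errors come from the numerical Hessian at the optimum. In the σ → 0
limit the fitter agrees with plain logistic regression within 2%
(tested), and its Wald p-values are calibrated under the null (KS
uniformity test over 200 simulations). Complete separation is detected
via a pooled logistic pre-fit and raised as an error. Predicted
probabilities (random effect at zero) are reported only for age × year
combinations present in the data, with a parametric-bootstrap 95%
percentile band (default 1,000 replicates, seed-controlled; an error is
raised if over 5% of replicate refits fail).

## Randomization tests

Two year-stratified permutation schemes, both leaving the response, the
other covariates and the year structure untouched: **group mode**
permutes founding groups (their max age) among the same year's new
sites; **individual mode** pools that year's founder individuals,
reassigns them uniformly among the year's new sites with every site
kept non-empty (rejection sampling; redraw counts logged), and
recomputes group max age. A single-site year is the identity. Each of
the n_reps replicates refits the distance LMM (via the fast REML
backend) from a deterministic per-replicate substream of the master
seed, so results are independent of execution order.

The primary p-value is the two-sided empirical permutation p,
2·min(rank-based tails) with the +1 correction — calibrated by
construction (measured: KS uniformity across 100 null populations,
≈3% false positives at α = 0.05). The one-sample Student's t-test of
the randomized coefficients against the observed one is also reported
(`t_statistic`, `t_p_value`) because it is the comparison the original
analysis describes; note that it contrasts the observed draw with the
null *mean*, so its p-value shrinks as n_reps grows and should be read
as descriptive, not as a calibrated test.

## Moran's I diagnostics

Binary weights in successive half-open distance bins ending at each
listed class (default 50, 200, 1,650 km; the last bin closed above),
row-standardised by default (switchable to raw binary). Significance by
residual permutation (999 draws, seeded, two-sided with +1 correction);
E[I] = −1/(n−1). A class with no pairs is reported flagged
(`n_pairs = 0`, NaN p) rather than raised: with the generator's ≥ 55 km
site separation the 50 km class is empty by construction, so the
correlogram's calibration and sensitivity are verified on directly
simulated point sets instead (i.i.d. residuals stay inside the null
band; a latitude-gradient positive control is detected).

## Synthetic-data generator

The generator is the package's stand-in for the tracking database. Its
defaults are the study conditions: 175 birds in 14 annual cohorts,
winters 2002–2015, 68 sites, founding groups of 1–6 (plus the founding
first winter), winter groups up to ~20, a −40 km/yr max-age effect,
site noise sd 150 km, year-intercept sd 100 km, ~19% of observed
bird-winters given a second (more northern) early-winter site, 6 winter
observations per observed bird-winter with 2 km noise, and a 0.55
per-winter observation probability (founders always observed, as new
sites are discovered through the birds using them) — yielding ~800
retained overwintering events, the scale of the study dataset.

Site distances are drawn from exactly the linear model the analysis
fits: y = 1750 − 40·max_age − 120·temp − 12·grain + u_year + ε, with
temperature anomaly (N(0.6, 0.35²) °C) and grain cover (N(15, 12²)%,
clipped at 0) drawn **exogenously** per site and the site then placed
at exactly distance y from the breeding centroid along a
bearing-jittered corridor toward the Gulf Coast (minimum separation
55 km, enforced by rejection). Because warm/grain-rich sites *cause*
closer placement, the northward covariate gradients of the study region
emerge rather than being painted on, and the fitted model is correctly
specified — the full pipeline is an honest parameter-recovery exercise.
Two side effects of placing sites at their generated distance are
documented rather than removed: sites that end up neighbours share
part of their realised distance, so residuals carry mild positive
spatial correlation at intermediate lags (visible in the pipeline's own
correlogram) and CI coverage of the age effect sits at the lower edge
of nominal (0.90–0.93 measured).

Migration stopovers (1–3 per leg, October and May) are offset laterally
from the bird's path by a lognormal distance whose log-mean falls by
0.38 per year of age from 5.61 at age 0 — so a 1–2 year old has
typically been ~150 km from areas where sites appear and a 7-year-old
~20 km, giving the experience metric its age gradient. Social dynamics:
birds keep their previous site with probability 0.6, otherwise adopt an
existing northern (< 1,200 km) site with probability
logistic(−4 + 0.25·age + 0.35·(year−2002)), producing rising shortstop
probability in both age and year for the GLMM. Ground truth (site
assignments, founding groups, coefficients, shortstop indicators) is
emitted alongside the data; one master seed drives all randomness
through documented stream-splitting, and outputs are byte-identical
across runs.

What the generator does **not** emulate: observation-effort
seasonality, transmitter failure, mortality and permanent emigration,
within-winter southward site switching, habitat geography (synthetic
sites can fall on water), or individual cognition — site innovation is
modelled at the group level, which is the unit of analysis. Passing
tests on these data show the pipeline recovers the statistical
structure the analysis assumes; they do not show that real field data
satisfy those assumptions.

## Problem sizes used in the shipped checks

The end-to-end checks run the full chain at study scale (175 birds, 68
sites) for single-fit assertions, 100 seeded replicates for CI
coverage, 100 null populations × 200 permutation replicates for
randomization calibration (null populations use a reduced 70-bird /
36-site configuration so the null ensemble remains cheap), and
`scripts/acceptance.py` reports the same quantities at the same sizes
with 200-replicate randomization and bootstrap runs.

## Known limitations

* Fixed-effect inference is Wald-type (z); no Satterthwaite/Kenward-
  Roger small-sample df correction is implemented.
* The experience model's SEs condition on the estimated variance
  components, as is standard, and near-boundary variance estimates can
  differ between optimisers (the slope is stable).
* The t-test reported alongside the randomization test is descriptive
  (see above).
* No ellipsoidal geodesy; no handling of satellite-telemetry error
  ellipses — inputs are assumed visually confirmed, pre-screened
  records.
* Whether site membership should be assigned by re-clustering all years
  jointly (implemented) or incrementally year by year is an open design
  point; joint clustering is deterministic and order-invariant, which
  we prioritised.
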