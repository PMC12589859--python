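# Methods

## Scope and shape

The package reconstructs, as a reusable pipeline, the analysis chain that
takes a continent-scale bipartite plant–microherbivore association table to
statements about trophic integration of non-native plants: per-plant
richness construction, covariate engineering, host-specialisation metrics,
hierarchical modelling with variance partitioning, and derived integration
thresholds. Models are exposed statsmodels-style: `RichnessMixedLM` is
built from an analysis frame, `fit()` returns a `RichnessMixedLMResults`
with estimates, uncertainties, diagnostics and `summary()`; simulation
(parametric bootstrap) hangs off the results object.

## Richness construction

Interaction edge lists are de-duplicated after optional synonym mapping
(a plain two-column table standing in for full taxonomic harmonisation,
which is out of scope). Records identified only to plant genus carry no
species-level information and are dropped, inferred from a one-token name
unless an explicit rank column exists. Richness is the count of distinct
herbivore names per plant; by construction it sums to the number of
distinct pairs, and every retained plant has richness ≥ 1 — observational
association data contain no zero-interaction plants.

## Covariates

* **Woodiness gap-fill.** Missing growth-form states are imputed with the
  modal observed state within the genus; a genus with no observed state or
  a tie stays unknown (a mode is undefined at a tie; an alphabetical
  tie-break would bias toward one state). Observed states are never
  overwritten.
* **Area of occupancy.** Grid cells are abstract integer indices on an
  equal-area grid (default cell area 2,500 km²; no map projection is
  performed). AOO = |occupied cells ∩ region cells| × cell area; a cell
  counts fully or not at all.
* **Introduction year.** Earliest record per species across regional
  entries; species whose earliest record is ≤ 1492 are excluded — the
  operational definition covers the era of large-scale species exchange
  only, and isolated ancient records would add leverage far outside the
  observed distribution.
* **Native-range proximity.** A species' native-range centroid is the
  unweighted lat/lon mean of its region centroids; distance to the fixed
  continental reference point (59.56° N, 28.21° E) is the haversine
  great-circle distance on a sphere of mean Earth radius 6,371.0088 km.
  Species closer than 2,500 km are excluded (strictly `<`; equality is
  retained) to avoid artificial proximity from averaging disjunct ranges.
  Longitudes are not wrapped, so ranges straddling ±180° average poorly —
  a documented limitation of centroid averaging, not handled specially.
* **Relatedness.** Congeneric if the genus occurs in the native flora,
  else confamilial if the family does, else unrelated; the three labels
  partition the non-native set.

## Host specialisation

Host breadth is the number of distinct host-plant species a herbivore uses
in the **full** dataset, computed before any integration filtering. The
categorical index checks, narrow to broad: monophagous (one host species);
oligophagous (> 1 species across ≤ 4 genera within one family); mesophagous
(> 1 species across > 1 genus within ≤ 3 families); polyphagous
(remaining). The precedence resolves the overlap where a multi-genus
single-family host set satisfies both the oligophagous and mesophagous
conditions; an exhaustive enumeration test verifies every consistent
(species, genera, families) triple up to 50 receives exactly one class.
The "well-integrated" subset keeps natives plus non-natives whose AOO
strictly exceeds a growth-form-specific threshold (default 1.1 × 10⁶ km²
non-woody, 2.7 × 10⁵ km² woody — the woody threshold is lower because the
richness–range slope is steeper in woody species). Residence-time
compositions use 50-year bins by default.

## Mixed models

Estimation is REML via statsmodels `MixedLM` with a plant-family random
intercept. The drivers model parameterises each continuous predictor as
woodiness-specific slopes (`C(woodiness):x`), so woody and non-woody slopes
and their standard errors are read directly off the coefficient vector.
Wald normal-approximation z-tests are reported; denominator-degrees-of-
freedom machinery (Satterthwaite/Kenward-Roger) is deliberately not
implemented — p-values are not load-bearing for any derived quantity here.
Incomplete rows are removed listwise with a logged count.

Numerical choices:

* A response that an OLS fit reproduces exactly (mean squared residual
  < 1e-12, as in noiseless simulations) makes the mixed likelihood
  degenerate; such fits short-circuit to the exact OLS coefficients with
  zero variance components.
* A family variance estimated at ~0 triggers a singular-fit warning, not a
  failure, and the best linear predictor of every family effect is taken
  as 0 for residual diagnostics.
* Marginal R² = var(Xβ̂)/(var(Xβ̂) + σ̂²_family + σ̂²_resid); conditional
  adds σ̂²_family to the numerator. Semi-partial R² for a predictor group
  is the drop in marginal R² when the group and its woodiness interactions
  are removed and the model refitted by REML on identical rows (a
  variance-based, not likelihood-ratio, comparison); small negative drops
  are truncated to 0 with a log line. CIs are percentile intervals over
  parametric-bootstrap refits (response resimulated from the fitted
  model), 500 draws by default, seeded; fewer than 2 draws omits the CI.
* Crossover thresholds solve `predicted log10 richness = log10(target)`
  exactly, holding other covariates at the sample means (continuous) or
  modal level (categorical) of the fitted frame — the conditioning point
  is a package choice; a zero slope raises a no-crossover error. For log10
  predictors the threshold is returned on the natural (km²) scale.
* Residual diagnostics report skewness, excess kurtosis and the
  Kolmogorov–Smirnov distance of conditional residuals to a fitted
  normal; constant residuals warn rather than fail.

Back-transformations: `10^β` per decade of log10 range; `(10^(−β·100) −
1)·100` percent per century earlier; the distance contrast uses
`(exp(β·Δ) − 1)·100`, kept verbatim in the natural-exponential form in
which such contrasts are conventionally reported even though the response
is log10.

## Synthetic data

The generator emulates a European-style association dataset: 5,751/1,061
native and 2,074/1,379 non-native non-woody/woody species in 157 families
(≈ 10 genera each); occupied-cell counts log-uniform on [1, 4,000] cells of
2,500 km²; introduction years uniform on 1493–2000; native-range centroid
distances uniform on 2,654–17,523 km, realised by placing region centroids
at great-circle destination points so the pipeline's recomputed distance
equals the generating one exactly. Latent log10 richness is
`intercept(origin, woodiness) + β_range·log10(AOO) + β_year·year +
β_dist·dist + u_family + ε` for non-natives (intercept + noise for
natives), with defaults β_range = 0.218/0.308 (non-woody/woody), β_year =
−0.00097/−0.0014, β_dist = −2.31 × 10⁻⁵, σ_family = 0.12, σ_resid = 0.35.
Intercepts are calibrated with the lognormal mean correction
`log10(m) − (σ²_family + σ²_resid)·ln10/2` so raw-scale group means land
near 6.2/4.1 (native woody/non-woody) and 2.2/1.8 (non-native); the σ
values were chosen so the fixed effects explain roughly a third of the
latent variance with a modest family share. Realised richness is
`max(1, round(10^latent))`.

Herbivore identities realise the per-plant richness exactly. Host-set
sizes for non-specialists are 1 + geometric (mean 5) and are planned
adaptively until the share of single-host herbivores equals the configured
specialist fraction (default 0.4); each non-specialist samples distinct
hosts, weighted by unfilled richness slots, within a scope drawn as
one-family (≤ 4 hosts, yielding oligophages), two-to-three families
(mesophages) or the whole flora (polyphages), so all four phagy classes
arise. Specialists pick native hosts with probability 0.9, reproducing the
nestedness of specialist richness on natives. Everything is driven by
deterministically derived sub-streams of one seed; identical config + seed
gives byte-identical CSVs.

**What the generator does not emulate:** sampling effort and literature
coverage, guild composition, spatial autocorrelation of occurrences,
phylogenetic signal beyond a family intercept, and any relatedness effect
(relatedness is null by construction, which is what the variance
partitioning tests exploit). Passing tests therefore demonstrate that the
estimators recover known generating structure, not that real data satisfy
the model.

**Discretisation attenuation.** At baseline mean richness near 2, the
integer rounding and floor at 1 censor the log response (more than half
the plants sit at richness 1–2) and attenuate fitted slopes by roughly
30%. This is a property of modelling log-transformed small counts, not an
estimator defect; consequently parameter-recovery studies are run with
intercepts one log10 unit higher (baseline ≈ 20 herbivores per plant),
where the latent model is identifiable, while the default configuration
keeps the realistic low baseline. Recovery conditions: 1,000 non-native
plants, 30 families, 20 seeds; each generating slope is required to fall
in its fitted 95% CI in ≥ 90% of seeds.

## Problem sizes

The test suite uses datasets of ~200–1,500 plants per fit plus one
default-scale (~10,000 plants) realisation shared across tests;
`scripts/acceptance.py` runs one default-scale pipeline (bootstrap CIs
off, point semi-partials only) and an 8-seed recovery study, about one
minute on one CPU. These sizes were chosen so the statistical checks
(coverage, null semi-partials) have adequate power while the suite stays
fast.

## Known limitations

* No Satterthwaite/Kenward-Roger degrees of freedom; F-statistics are not
  reported.
* Antimeridian-straddling native ranges average to misleading centroids.
* AOO counts whole cells; partially occupied border cells are not clipped.
* The generator's heavy tail is calibrated qualitatively (modal richness
  1); the true richness-distribution shape of association databases is not
  publicly parameterised.
* Robust (heavy-tail-resistant) mixed-model estimation is out of scope;
  the residual-normality summary flags, but does not correct, skew.
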