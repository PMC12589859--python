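# microherbivory

Tools for asking how non-native plants become **trophically integrated**
into networks of microherbivores — small plant-feeding organisms that live
in or on living tissue (leaf miners, gall formers, borers, eriophyid mites,
plant-pathogenic fungi). The package is aimed at macroecologists working
with bipartite plant–herbivore association tables: it builds per-plant
interaction richness from an edge list, engineers the macroecological
covariates that predict it, quantifies host specialisation of the
herbivores, and fits the hierarchical models that partition the variance
between contemporary processes (range expansion, residence time) and
evolutionary legacy (native-range proximity, relatedness to the resident
flora).

## The model

For plant species *i* in family *f*, microherbivory richness
*S<sub>i</sub>* (number of distinct associated microherbivore species) is
modelled on the log scale with a family random intercept:

```
log10(S_i) = β0 + β1·log10(AOO_i) + β2·year_i + β3·dist_i
             + relatedness_i + woodiness_i + woodiness × (each predictor)
             + u_f + ε_i,        u_f ~ N(0, σ²_family),  ε_i ~ N(0, σ²_resid)
```

where `AOO` is the area of occupancy in the introduced range (occupied
equal-area grid cells × cell area, km²), `year` the earliest recorded
introduction year (post-1492 only), `dist` the great-circle distance (km)
from the native-range centroid to the continental reference point, and
`relatedness` ∈ {congeneric, confamilial, unrelated}. Estimation is REML
(via statsmodels `MixedLM`). Explained variance is decomposed as

* marginal R² = σ²_fixed / (σ²_fixed + σ²_family + σ²_resid),
* conditional R² = (σ²_fixed + σ²_family) / (σ²_fixed + σ²_family + σ²_resid),
* semi-partial R² per predictor group = marginal R²(full) − marginal
  R²(without the group and its woodiness interactions), with a parametric
  bootstrap CI.

Fitted slopes back-transform to the reporting scale: `10^β1` is the fold
change in richness per tenfold range increase; `(10^(−β2·100) − 1)·100` is
the percent change per century of earlier introduction. Crossover
thresholds (the range size or introduction year at which a non-native's
predicted richness equals the average native's) come from the exact linear
inversion of the fitted predictor.

A companion host-specialisation module classifies each herbivore from its
counts of host species/genera/families as monophagous, oligophagous,
mesophagous or polyphagous, and summarises per-plant partner composition by
plant group.

Because the underlying association databases are proprietary, the package
ships a synthetic-data generator (`microherbivory.synthetic`) that emulates
their statistical structure with known ground truth — every downstream
stage is tested against the generating parameters.

## Worked example

Run the whole pipeline on a default-scale synthetic dataset (~10,000
plants) from the shell:

```sh
microherb -v all --output-dir demo --seed 1
```

or from Python:

```python
from microherbivory import PipelineConfig, SyntheticConfig, run_pipeline

cfg = PipelineConfig(output_dir="demo", simulate=SyntheticConfig(seed=1), seed=1)
result = run_pipeline(cfg)
print(f"marginal R2 = {result.drivers_fit.marginal_r2:.4f}")
print(f"conditional R2 = {result.drivers_fit.conditional_r2:.4f}")
print({k: round(v, 4) for k, v in result.r2.semipartial.items()})
```

which prints

```
marginal R2 = 0.3678
conditional R2 = 0.4108
{'range_size': 0.2186, 'intro_year': 0.0998, 'proximity': 0.033, 'relatedness': 0.0001}
```

Reading: of the variance in log-richness across the 3,436 complete-case
non-native plants, 36.8% is explained by the four predictors jointly
(41.1% once family membership is added); range size uniquely accounts for
21.9 points of it, residence time 10.0, native-range proximity 3.3, and
relatedness — which the generator leaves null by construction —
essentially nothing. The run directory also contains the origin × woodiness
group means and fold contrasts, herbivore phagy profiles, the host-breadth
model on the well-integrated subset, coefficient tables
(`fit_*.txt`), and a manifest with the filter ledger (genus-only records
dropped, woodiness states imputed, pre-1492 and proximity exclusions).

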