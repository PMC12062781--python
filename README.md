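# nichesize

Tools for asking how bird and mammal body size varies with a species'
position inside its climatic niche, in the presence of land-use change —
from raw specimen records to a fitted phylogenetic mixed model with a full
diagnostics battery.

## The problem

Museum and field databases hold millions of body mass / body length records
with dates and coordinates. Whether individuals measured near the warm (or
dry) edge of their species' climatic tolerance are systematically smaller is
a comparative question that needs four ingredients this package provides:

1. **Record cleaning** — coordinate/date validity filters, life-stage and
   sex vocabulary reclassification, synonym-table name harmonization, site
   grouping, a 5-MAD (median absolute deviation) filter around each species'
   adult median to drop likely juveniles and digitization outliers, and a
   minimum of 100 unique measurements per species; log10 sizes and the
   volume-to-surface proxy mass^(1/3)/length are derived at the end.

2. **Niche limits** — for each species and calendar month, the range-wide
   extremes of monthly maximum temperature and of the aridity index
   AI = PPT/PET, taken within each baseline year (1961–1975) and averaged
   across years, giving monthly N_min and N_max. Extreme AI cells (from very
   low PET) are clamped to Tukey fences Q1 − 1.5·IQR / Q3 + 1.5·IQR before
   taking extremes.

3. **Position indices** — each observation gets a Thermal Position Index

       TPI = (N_m − N_min) / (N_max − N_min)

   where N_m is the monthly maximum temperature at its place and date: 0 at
   the species' lower derived limit, 1 at the upper, with values outside
   [0, 1] kept (conditions beyond the baseline tolerance). API is the same
   statistic on AI. Land-use covariates ALU (cropland + pasture fraction)
   and ULU (urban fraction) come from gridded quadrats.

4. **The PGLMM** — a Gaussian phylogenetic mixed model on the z-scored size
   metric:

       y = β₀ + β·[TPI, API, ALU, ULU, Year, TPI×API, TPI×ALU, TPI×ULU]
           + realm + site + species_iid + species_phylo
           + (slope_iid + slope_phylo)·TPI + ε

   with four random intercepts and two uncorrelated random slopes; the
   `*_phylo` terms carry a Brownian-motion correlation matrix built from a
   time-calibrated tree (shared root-to-tip path length, unit diagonal).
   Estimation is penalized REML (a weak gamma prior keeps variance
   components off the zero boundary); fixed effects get 95% t-intervals and
   a probability of direction (pd).

Diagnostics: VIF, spline correlograms of residuals vs great-circle distance,
Durbin–Watson tests on one-residual-per-year resamples (globally and per
species), standardized-residual influence screening, posterior predictive
checks.

Because the original multi-source global compilation is not shipped, the
package includes a first-class **synthetic world**: seeded climate with a
warming trend, contiguous ranges, an ultrametric pure-birth phylogeny,
land-use and realm layers, and trait records drawn from the exact model
above with known effects and planted contamination — so every stage can be
scored against ground truth.

## Worked example

```python
from nichesize import exposure_covariates as cov, phylo_mixed_model as pm
from nichesize import trait_cleaning as tc
from nichesize.synthetic_world import WorldConfig, generate_world

world = generate_world(WorldConfig(seed=1, juvenile_frac=0, outlier_frac=0))
table = tc.assign_sites(tc.derive_size_metrics(world.observations))
zed, _, _ = cov.zscore_columns(table, ["log10_mass", "tpi", "api",
                                       "alu", "ulu", "year"])
zed = cov.add_interactions(zed, [("tpi", "api"), ("tpi", "alu"),
                                 ("tpi", "ulu")])
C = pm.phylo_correlation(world.tree, sorted(zed["species_id"].unique()))
fit = pm.fit(pm.assemble(zed, pm.ModelSpec(), C))
print(fit.fixed.round(4))
```

prints (seed 1; truth: TPI −0.3, API +0.3, TPI×API +0.15 on the z scale):

```
     term  estimate     se  ci_low  ci_high     pd
intercept   -0.0360 0.3387 -0.7287   0.6566 0.5420
      tpi   -0.2561 0.0715 -0.4024  -0.1098 0.9994
      api    0.2877 0.0094  0.2686   0.3069 1.0000
      alu   -0.0113 0.0166 -0.0453   0.0226 0.7503
      ulu    0.0114 0.0170 -0.0233   0.0461 0.7458
     year    0.0039 0.0094 -0.0153   0.0231 0.6614
tpi_x_api    0.1451 0.0093  0.1261   0.1641 1.0000
tpi_x_alu    0.0167 0.0136 -0.0111   0.0444 0.8851
tpi_x_ulu    0.0105 0.0144 -0.0190   0.0400 0.7639
```

The negative TPI coefficient says individuals observed nearer the warm edge
of their species' thermal niche are smaller; the positive TPI×API term says
that effect weakens in wetter conditions. All three planted effects are
recovered with intervals covering the truth; the null effects are not
declared significant. `examples/` holds one short script per capability, and
the `nichesize` CLI (`synth`, `clean`, `limits`, `covariates`, `fit`,
`diagnose`, `run`) drives the same stages from a YAML config with a
manifest that makes re-runs bit-identical.

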