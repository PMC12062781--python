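# Methods

This note records the model, the numerical choices, and what the synthetic
validation does and does not establish.

## Cleaning

The cleaner runs in a fixed order: provider `exclude` flag → validity
filters (|lat| ≤ 90, |lon| ≤ 180, lat ≠ lon exactly, year+month present,
coordinates present, at least one size field, species id present) →
life-stage/sex reclassification onto {adult, juvenile, unknown} /
{male, female, unknown} (unmapped strings → unknown) → synonym-table name
harmonization (unresolvable names are excluded and counted; no fuzzy
matching) → covariate attachment → drop labelled juveniles → MAD filter →
minimum-count filter → derived metrics. Every removal is counted per rule
and the report must reconcile exactly with the row delta.

MAD filter: per species, the median M and MAD = median(|x − M|) are
computed on **adult** records of the **raw** metric (no 1.4826 consistency
constant — the constant is configurable but the retention rule is stated in
plain MAD units); adult and unknown-stage records are kept iff
M − k·MAD ≤ x ≤ M + k·MAD, inclusive, with k = 5. Below-band removals are
counted as likely juveniles, above-band as outliers. A species whose adult
MAD is 0 is retained in full with a warning; unknown-stage records of a
species with no adult reference are removed. One pass is applied (re-running
the cleaner can remove a handful more boundary records because the band
recomputed on filtered adults shrinks slightly; exact idempotence would
require iterating the filter to a fixed point, which changes the stated
rule).

"Unique" measurements for the ≥100 rule are distinct
(value, date, lat, lon) tuples, guarding against exact duplicate ingestion.
Sites group records whose coordinates coincide after rounding to 4 decimals
(~11 m); exact float equality is too brittle across data sources.

## Niche limits and indices

For each species × month, the limit derivation takes the range-wide min and
max within each baseline year (1961–1975 by default) and then averages
across years ("mean of yearly extremes"); pooling all years before taking
extremes is available behind `pooled_extremes=True`. For the aridity index
the per-month-year range-wide cell values are first clamped to Tukey fences
(type-7 quantiles, factor 1.5); replacement counts are kept per
species × month, and the fraction of upper limits touched is reported — on
synthetic aridity fields with lognormal-ish tails this fraction is high and
is data-dependent, not a constant of the method. Temperature limits are
never fenced. With a single temperature cube both limits come from it; a
separate monthly-minimum cube can supply N_min when available.

The position index (N_m − N_min)/(N_max − N_min) requires N_max > N_min and
is deliberately not truncated to [0, 1]; degenerate limits raise. Indices
are invariant to affine rescaling of the climate variable. Missing
cell-months (e.g. AI over snow, where PET is undefined) yield missing
indices; rows are only dropped, with counts, at model assembly.

## The mixed model

Response and predictors are z-scored over the modelled dataset (one dataset
per metric), and interactions are products of z-scored main effects, so a
coefficient reads as the effect of a 1-SD change. Year enters as a z-scored
linear covariate; `include_year=False` gives the sensitivity variant with 7
fixed terms. The default random-slope predictor set is {TPI} — two terms,
one iid across species and one with the Brownian correlation matrix C —
matching a literal reading of "two uncorrelated random slopes"; a config
flag extends slopes to every level-1 effect for the alternative reading.

C is built from shared root-to-tip path lengths normalized to unit diagonal
(so the phylogenetic variance is on the same scale as the iid species
variance). Matrices with minimum eigenvalue in (−1e−8, 1e−10) are
ridge-repaired and renormalized; more negative eigenvalues are an error.

Estimation: REML profiled over β and σ², optimizing log variance ratios
(L-BFGS-B with a Nelder–Mead fallback) through the q×q capacitance matrix
S = I + U′U — cost O(q³) per evaluation, never O(n³). By default the
criterion carries a nondegeneracy penalty, +log σ_k per random-effect
standard deviation (a weak gamma(2, rate→0) prior in the sense of Chung et
al.). This is the deterministic counterpart of the weakly-informative
variance priors a Bayesian fit would use: without it, weakly-identified
components — especially the phylogenetic slope variance, which behaves like
a handful of effective observations — collapse to the zero boundary and the
fixed-effect standard errors lose the uncertainty contributed by the common
slope draw, which measurably degrades interval coverage in simulation.
`sd_penalty=0` recovers plain REML (used when cross-checking against a
generic mixed-model implementation).

Intervals and pd for fixed effects use a Student-t with df = n_species − 1,
a conservative between-cluster containment choice for clustered data; pd is
the one-sided t mass on the side of the point estimate, labelled as an
asymptotic approximation (no posterior is available from this backend).
Variance-component intervals come from a numerical Hessian of the penalized
criterion on the log scale (delta method, σ² treated fixed); they are
approximate and unavailable at hard boundaries.

Partial R² is the squared Pearson correlation between the observed response
and fitted values including random effects ("conditional"); it is not
invariant to affine transforms of the fitted values and is labelled
accordingly.

## Diagnostics

Durbin–Watson significance uses a permutation null (199 shuffles, one-sided
toward positive autocorrelation by default; two-sided available) rather than
tabulated bounds, because the resampled one-per-year series are short. The
global resampler draws one residual per year, 1000 times; the per-species
variant 100 times per species. The spline correlogram is a distance-binned
Moran-type correlation against great-circle (haversine) distance in km,
spline-smoothed, with a bootstrap envelope from resampling observations
(self-pairs excluded — duplicated points would otherwise bias short
distances upward). Influence screening flags |standardized conditional
residual| > 4 (configurable; the threshold choice is a package decision
since no specific detector is prescribed). Posterior predictive checks
simulate from the fitted generative model (fitted β, estimated variance
components incl. the phylogenetic blocks) and compare observed mean, sd and
deciles against 95% simulation envelopes.

## Synthetic world

The generator's defaults are the package's standard study conditions:
30 species × 200 records over 1961–2018 on a 24×36-cell 2° grid; maximum
temperature = 32 °C at the equatorward edge − 0.6 °C per degree latitude +
8 °C seasonal cosine (July peak) + 0.3 °C/decade trend + N(0, 1) noise; PET
tracks temperature and is missing where the deterministic temperature is
below freezing ("snow" cell-months); precipitation is lognormal with mild
seasonality. Ranges are contiguous rectangles of varied size and latitude;
the tree is a pure-birth tree rescaled to unit depth; realms are 3
longitudinal blocks; land-use layers are smooth static random fields.
Records sit on 12 reused sites per species (5–50 is the plausible band;
12 keeps the site intercept identifiable without exploding the
random-effect dimension), uniform over months and years, re-drawn in time
when they land on a missing-AI cell-month so every generated record carries
complete covariates.

True effects default to β_TPI = −0.3, β_API = +0.3, β_TPI×API = +0.15 on
the z scale (others 0) with variance components
(realm, site, species, phylo, slope_iid, slope_phylo, resid) =
(0.05, 0.05, 0.15, 0.15, 0.02, 0.02, 0.5) — totalling ≈1 so the latent
response is already near unit scale. The latent z response maps to
log10 mass as 1.5 + 0.04·y; the 0.04 within-species scale keeps raw masses
strictly positive under the deepest (10-MAD) contaminant displacement and
puts the 5-MAD band's false-removal rate for clean lognormal records near
0.2%. Contaminants (2.5% pseudo-juveniles with stage 'unknown', 2.5%
outliers) are displaced 6–10 raw-scale MADs from the species **adult
median** — measured from the median, not the source record, so they are
strictly outside the median-centred retention band and always positive.

Because the fitted model standardizes the response, the estimand for a
replicate is β/sd(latent response); recovery studies score intervals
against that quantity using the stored latent column. The generator does
not rescale the latent response to unit variance — its sample variance must
equal the configured variance total (that identity is itself tested).

What the synthetic world does not emulate: real spatial sampling bias,
taxonomic error structure, season-dependent detectability, correlated
climate noise, or polygon-shaped ranges. Passing recovery tests therefore
shows the estimator and filters behave as designed under the stated model,
not that any real-data estimate is unbiased.

## Validation sizes and numerics

Parameter recovery: 25 replicate worlds at the standard conditions
(coverage of each true effect by the 95% intervals, and sign agreement for
TPI). Null calibration: 120 replicate worlds with all effects zero
(per-term fraction of intervals excluding zero); 120 was chosen to keep the
binomial Monte-Carlo error on a ~5% rate well below the 10% decision bound.
Replicate worlds for these studies carry no planted contamination — the
cleaning filters are scored by their own dedicated study. The
dense-likelihood oracle runs at n = 50, 5 species, 20 parameter draws,
agreement to 1e−6; fence and index identities to 1e−12.

Degenerate inputs: empty post-filter tables warn rather than raise;
constant fields give N_min = N_max, which the index layer rejects
downstream; all-zero residual series and single-location correlograms
raise. Optimizer bounds on log variance ratios are [−12, 8]; starting value
log 0.1.

## Known limitations

- No Bayesian sampler backend; pd is an asymptotic approximation.
- The MAD filter is single-pass (see above).
- Variance-component intervals are delta-method approximations.
- GeoTIFF climate stacks are not read (NetCDF and CSV cell lists are);
  range polygons are supported via shapely geometries in memory.
- The spline correlogram implements the contract (smooth correlation vs
  distance with a bootstrap envelope), not any specific reference
  algorithm.
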