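"""Generate a seeded synthetic study and look at what it contains.

The world bundles monthly climate cubes, species ranges, an ultrametric
phylogeny, land-use/realm layers, baseline niche limits, and body-size
records drawn from a known mixed model with planted contamination.
"""

from nichesize.synthetic_world import WorldConfig, generate_world

config = WorldConfig(seed=42, n_species=10, obs_per_species=120,
                     years=(1961, 2000))
world = generate_world(config)

obs = world.observations
print(f"species: {config.n_species}, records: {len(obs)}")
print("truth flags:", obs["truth_flag"].value_counts().to_dict())
print("tmax cube:", world.cubes["tmax"].values.shape, "(months, lat, lon)")
print("tree tips:", len(world.tree.tip_labels))

lim = world.limits
jan = lim[(lim.variable == "tmax") & (lim.month == 1)].head(3)
print("\nJanuary thermal niche limits (first 3 species):")
print(jan[["species_id", "n_min", "n_max"]].to_string(index=False))
# n_min/n_max are the coldest/warmest range-wide monthly temperatures,
# averaged over the 1961-1975 baseline years; TPI positions an observed
# temperature between them (0 = lower limit, 1 = upper limit).
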