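"""Derive baseline niche limits and position indices for observations.

TPI = (N_m - N_min) / (N_max - N_min): 0 at the species' range-derived lower
thermal limit, 1 at the upper limit, outside [0, 1] when conditions exceed
the derived tolerance. API is the same statistic on the aridity index
(precipitation / potential evapotranspiration), where fencing at
Q1/Q3 +/- 1.5 IQR tames extreme low-PET cells.
"""

from nichesize import exposure_covariates as cov
from nichesize import niche_limits as nl
from nichesize.synthetic_world import (WorldConfig, derive_world_limits,
                                       gen_climate, gen_landuse_and_realm,
                                       gen_ranges_and_tree)

config = WorldConfig(seed=3, n_species=6, obs_per_species=50,
                     years=(1961, 1990))
cubes = gen_climate(config)
masks, tree = gen_ranges_and_tree(config)
limits, ai = derive_world_limits(config, {**cubes, "masks": masks})

sp = masks[0].species_id
row = limits[(limits.species_id == sp) & (limits.variable == "tmax")
             & (limits.month == 7)].iloc[0]
print(f"{sp}, July thermal limits: N_min={row.n_min:.2f} C, "
      f"N_max={row.n_max:.2f} C")

for temp in (row.n_min, (row.n_min + row.n_max) / 2, row.n_max + 1.0):
    tpi = cov.position_index(temp, row.n_min, row.n_max)
    print(f"  observed {temp:6.2f} C -> TPI {tpi:5.2f}")
# TPI 0.5 is the middle of the realized niche; TPI > 1 means the observation
# sits beyond the warmest baseline condition the range experienced.

frac = nl.adjusted_upper_fraction(limits)
print(f"fraction of species-month upper AI limits touched by fencing: "
      f"{frac:.1%}")
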