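"""Seeded synthetic world: climate, ranges, land use, tree, trait records.

The generator emulates the study design end to end so every downstream stage
can be tested against known ground truth:

* monthly maximum temperature with a meridional gradient, sinusoidal
  seasonality, a linear warming trend and Gaussian noise; precipitation and
  potential evapotranspiration (PET) positive, with PET missing in "snow"
  cells (cell-months whose deterministic temperature is below freezing);
* contiguous rectangular species ranges at varied sizes and latitudes, an
  ultrametric pure-birth phylogeny over the same species;
* static cropland/pasture/urban fraction layers and a longitudinal-block
  realm partition;
* body-size records drawn from the exact mixed model the estimation stage
  fits (fixed effects at configured true values, random intercepts and
  slopes from their stated covariances including the tree-derived matrix,
  Gaussian residual), placed uniformly in space-time within each species'
  range on a reused set of sampling sites;
* planted contamination: pseudo-juveniles (species adult median minus 6-10
  raw-scale MADs, life stage left 'unknown') and outliers (median +/- 6-10
  MADs), both strictly outside the 5-MAD retention band, flagged in a
  ground-truth column.

Everything is a pure function of :class:`WorldConfig`; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .formats_io import ClimateCube, PhyloTree, RangeMask, SynonymTable
from . import exposure_covariates as cov
from . import niche_limits as nl
from .phylo_mixed_model import phylo_correlation

BETA_TERMS = ["tpi", "api", "alu", "ulu", "year",
              "tpi_x_api", "tpi_x_alu", "tpi_x_ulu"]


def _default_betas():
    return {"tpi": -0.3, "api": 0.3, "alu": 0.0, "ulu": 0.0, "year": 0.0,
            "tpi_x_api": 0.15, "tpi_x_alu": 0.0, "tpi_x_ulu": 0.0}


def _default_variances():
    return {"realm": 0.05, "site": 0.05, "species": 0.15, "phylo": 0.15,
            "slope_sp": 0.02, "slope_phylo": 0.02, "resid": 0.5}


@dataclass
class WorldConfig:
    """All knobs of the synthetic world; defaults are the study conditions."""

    seed: int = 0
    # grid
    n_lat: int = 24
    n_lon: int = 36
    resolution: float = 2.0
    lat_start: float = 2.0
    lon_start: float = -35.0
    # time
    years: tuple[int, int] = (1961, 2018)
    baseline_years: tuple[int, int] = (1961, 1975)
    # sampling
    n_species: int = 30
    obs_per_species: int = 200
    sites_per_species: int = 12
    # true effects on the z scale
    betas: dict = field(default_factory=_default_betas)
    # variance components (z scale)
    variances: dict = field(default_factory=_default_variances)
    # contamination
    juvenile_frac: float = 0.025
    outlier_frac: float = 0.025
    displacement_mads: tuple[float, float] = (6.0, 10.0)
    # climate
    seasonal_amplitude: float = 8.0
    meridional_lapse: float = 0.6     # degC per degree latitude
    base_tmax: float = 32.0           # degC at the equatorward grid edge
    warming_trend: float = 0.3        # degC per decade
    noise_sd: float = 1.0
    # realms
    n_realms: int = 3
    # size back-transform (log10 grams / mm per latent z unit)
    mass_mu: float = 1.5
    mass_scale: float = 0.04
    length_mu: float = 2.0
    length_scale: float = 0.02
    length_noise: float = 0.01

    def __post_init__(self):
        if any(v < 0 for v in self.variances.values()):
            raise ConfigurationError("variance components must be >= 0")
        for f in (self.juvenile_frac, self.outlier_frac):
            if not 0 <= f <= 1:
                raise ConfigurationError("contamination fractions in [0,1]")
        if self.years[1] < self.years[0]:
            raise ConfigurationError("end year must be >= start year")
        if set(self.betas) != set(BETA_TERMS):
            raise ConfigurationError(f"betas must cover {BETA_TERMS}")

    @property
    def species_ids(self) -> list[str]:
        return [f"Species_{i:03d}" for i in range(1, self.n_species + 1)]

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,)))


def _grid(config):
    lats = config.lat_start + config.resolution * np.arange(config.n_lat)
    lons = config.lon_start + config.resolution * np.arange(config.n_lon)
    return lats, lons


def _months(config):
    y0, y1 = config.years
    return [(y, m) for y in range(y0, y1 + 1) for m in range(1, 13)]


def _tmax_deterministic(config, lats, times):
    """Noise-free tmax per (time, lat): gradient + season + trend."""
    y0 = config.years[0]
    out = np.empty((len(times), len(lats)))
    for t, (y, m) in enumerate(times):
        season = config.seasonal_amplitude * np.cos(2 * np.pi * (m - 7) / 12)
        trend = config.warming_trend * (y - y0) / 10.0
        out[t] = (config.base_tmax
                  - config.meridional_lapse * (lats - lats.min())
                  + season + trend)
    return out


def gen_climate(config: WorldConfig) -> dict[str, ClimateCube]:
    """Monthly tmax, ppt, pet cubes (pet missing in snow cell-months)."""
    rng = config._rng(0)
    lats, lons = _grid(config)
    times = _months(config)
    det = _tmax_deterministic(config, lats, times)  # (T, n_lat)
    shape = (len(times), len(lats), len(lons))
    tmax = det[:, :, None] + config.noise_sd * rng.standard_normal(shape)

    # precipitation: positive, wetter toward low latitudes, seasonal
    month_idx = np.array([m for _, m in times])
    season_p = 0.4 * np.sin(2 * np.pi * (month_idx - 1) / 12)
    logppt = (np.log(60.0) + season_p[:, None, None]
              - 0.01 * (lats - lats.min())[None, :, None]
              + 0.3 * rng.standard_normal(shape))
    ppt = np.exp(logppt)

    # PET tracks temperature; undefined where snow covers the ground
    pet = np.maximum(5.0, 20.0 + 3.0 * det[:, :, None]
                     + 2.0 * rng.standard_normal(shape))
    snow = det[:, :, None] < 0.0
    pet = np.where(np.broadcast_to(snow, shape), np.nan, pet)

    mk = lambda name, vals, units: ClimateCube(name, vals, lats, lons,
                                               list(times), units)
    return {"tmax": mk("tmax", tmax, "degC"),
            "ppt": mk("ppt", ppt, "mm/month"),
            "pet": mk("pet", pet, "mm/month")}


def gen_ranges_and_tree(config: WorldConfig
                        ) -> tuple[list[RangeMask], PhyloTree]:
    """Contiguous rectangular ranges + an ultrametric pure-birth tree."""
    rng = config._rng(1)
    shape = (config.n_lat, config.n_lon)
    masks = []
    for sp in config.species_ids:
        hi = int(rng.integers(2, 6))
        hj = int(rng.integers(3, 9))
        ci = int(rng.integers(0, config.n_lat))
        cj = int(rng.integers(0, config.n_lon))
        i0, i1 = max(0, ci - hi), min(config.n_lat, ci + hi + 1)
        j0, j1 = max(0, cj - hj), min(config.n_lon, cj + hj + 1)
        cells = [(i, j) for i in range(i0, i1) for j in range(j0, j1)]
        masks.append(RangeMask(sp, np.array(cells), shape))

    import dendropy
    from dendropy.model import birthdeath

    pyrng = _random.Random(int(rng.integers(2**31)))
    tree = birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=config.n_species,
        rng=pyrng)
    # rename tips and rescale to unit depth
    leaves = list(tree.leaf_node_iter())
    for leaf, sp in zip(leaves, config.species_ids):
        leaf.taxon.label = sp
    depth = max(lf.distance_from_root() for lf in leaves)
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length /= depth
    return masks, PhyloTree(tree)


def gen_landuse_and_realm(config: WorldConfig) -> dict[str, ClimateCube]:
    """Static cropland/pasture/urban fraction layers + realm blocks."""
    rng = config._rng(3)
    lats, lons = _grid(config)
    shape = (config.n_lat, config.n_lon)

    def smooth_field(scale, bias):
        f = rng.standard_normal(shape)
        # crude smoothing by neighbour averaging, twice
        for _ in range(2):
            f = (f + np.roll(f, 1, 0) + np.roll(f, -1, 0)
                 + np.roll(f, 1, 1) + np.roll(f, -1, 1)) / 5.0
        return np.clip(scale / (1 + np.exp(-(f * 2 + bias))), 0.0, 1.0)

    crop = smooth_field(0.8, -0.5)
    past = smooth_field(0.6, -1.0)
    urb = smooth_field(0.3, -2.5)
    # keep fraction sums sane in most quadrats
    tot = crop + past + urb
    over = tot > 1.0
    for f in (crop, past, urb):
        f[over] /= tot[over]

    edges = np.linspace(0, config.n_lon, config.n_realms + 1).astype(int)
    realm = np.zeros(shape)
    for r in range(config.n_realms):
        realm[:, edges[r]:edges[r + 1]] = r
    cats = {r: f"realm_{chr(65 + r)}" for r in range(config.n_realms)}

    mk = lambda name, vals: ClimateCube(name, vals, lats, lons, None, "fraction")
    out = {"cropland": mk("cropland", crop), "pasture": mk("pasture", past),
           "urban": mk("urban", urb)}
    out["realm"] = ClimateCube("realm", realm, lats, lons, None, "",
                               categories=cats)
    return out


def derive_world_limits(config, cubes) -> pd.DataFrame:
    """Baseline niche-limit table for tmax and ai over all species."""
    ai = nl.compute_ai(cubes["ppt"], cubes["pet"])
    lim_t = nl.derive_limits_table(cubes["tmax"], cubes["masks"],
                                   config.baseline_years)
    lim_a = nl.derive_limits_table(ai, cubes["masks"], config.baseline_years)
    return pd.concat([lim_t, lim_a], ignore_index=True), ai


def gen_observations(config: WorldConfig, cubes: dict, masks: list[RangeMask],
                     tree: PhyloTree) -> pd.DataFrame:
    """Trait records drawn from the generative mixed model, plus planted
    contamination. Ground truth lives in 'true_y' and 'truth_flag'."""
    rng = config._rng(2)
    missing = set(m.species_id for m in masks) - set(tree.tip_labels)
    if missing:
        raise ConfigurationError(
            f"species present in ranges but absent from tree: {sorted(missing)}")

    lats, lons = _grid(config)
    res = config.resolution
    limits, ai_cube = derive_world_limits(
        config, {**cubes, "masks": masks})
    y0, y1 = config.years

    # sampling sites: reused points inside each range
    site_lut = {}
    for m in masks:
        k = min(config.sites_per_species, len(m.cells))
        pick = m.cells[rng.choice(len(m.cells), size=k, replace=False)]
        jit = rng.uniform(-res / 4, res / 4, size=(k, 2))
        pts = np.column_stack([lats[pick[:, 0]] + jit[:, 0],
                               lons[pick[:, 1]] + jit[:, 1]]).round(4)
        site_lut[m.species_id] = pts

    frames = []
    for m in masks:
        pts = site_lut[m.species_id]
        n = config.obs_per_species
        sel = rng.integers(0, len(pts), n)
        frames.append(pd.DataFrame({
            "species_id": m.species_id,
            "year": rng.integers(y0, y1 + 1, n),
            "month": rng.integers(1, 13, n),
            "day": rng.integers(1, 29, n),
            "lat": pts[sel, 0], "lon": pts[sel, 1],
        }))
    obs = pd.concat(frames, ignore_index=True)

    # attach covariates; re-draw the date for records landing on missing AI
    obs = cov.attach_climate_indices(obs, cubes["tmax"], ai_cube, limits)
    for _ in range(40):
        bad = obs["tpi"].isna() | obs["api"].isna()
        if not bad.any():
            break
        nb = int(bad.sum())
        redraw = obs.loc[bad, ["species_id", "lat", "lon"]].copy()
        redraw["year"] = rng.integers(y0, y1 + 1, nb)
        redraw["month"] = rng.integers(1, 13, nb)
        redraw["day"] = rng.integers(1, 29, nb)
        redraw = cov.attach_climate_indices(redraw, cubes["tmax"], ai_cube,
                                            limits)
        for c in redraw.columns:
            obs.loc[bad, c] = redraw[c].to_numpy()
    obs = obs[obs["tpi"].notna() & obs["api"].notna()].reset_index(drop=True)

    obs = cov.attach_landuse(obs, cubes["cropland"], cubes["pasture"],
                             cubes["urban"])
    obs = cov.attach_realm(obs, cubes["realm"])

    # z-scored design exactly as the estimation stage builds it
    zed, _, _ = cov.zscore_columns(obs, ["tpi", "api", "alu", "ulu", "year"])
    zed = cov.add_interactions(zed, [("tpi", "api"), ("tpi", "alu"),
                                     ("tpi", "ulu")])
    X = np.column_stack([zed[t].to_numpy(dtype=float) for t in BETA_TERMS])
    beta = np.array([config.betas[t] for t in BETA_TERMS])

    v = config.variances
    species = sorted(obs["species_id"].unique())
    sp_code = obs["species_id"].map({s: i for i, s in enumerate(species)}).to_numpy()
    realm_lab, realm_code = np.unique(zed["realm"].astype(str), return_inverse=True)
    site_key = list(zip(obs["lat"].round(4), obs["lon"].round(4)))
    site_code, _ = pd.factorize(pd.Series(site_key), sort=True)

    C = phylo_correlation(tree, species).matrix
    L = np.linalg.cholesky(C + 1e-10 * np.eye(len(C)))
    s = len(species)
    b_realm = np.sqrt(v["realm"]) * rng.standard_normal(len(realm_lab))
    b_site = np.sqrt(v["site"]) * rng.standard_normal(site_code.max() + 1)
    b_sp = np.sqrt(v["species"]) * rng.standard_normal(s)
    b_ph = np.sqrt(v["phylo"]) * (L @ rng.standard_normal(s))
    b_slope_sp = np.sqrt(v["slope_sp"]) * rng.standard_normal(s)
    b_slope_ph = np.sqrt(v["slope_phylo"]) * (L @ rng.standard_normal(s))
    eps = np.sqrt(v["resid"]) * rng.standard_normal(len(obs))

    ztpi = zed["tpi"].to_numpy(dtype=float)
    y = (X @ beta + b_realm[realm_code] + b_site[site_code]
         + b_sp[sp_code] + b_ph[sp_code]
         + (b_slope_sp[sp_code] + b_slope_ph[sp_code]) * ztpi + eps)

    obs["true_y"] = y
    for t in BETA_TERMS:
        obs[f"true_z_{t}"] = zed[t].to_numpy(dtype=float)
    obs["log10_mass_true"] = config.mass_mu + config.mass_scale * y
    obs["mass"] = 10.0 ** obs["log10_mass_true"]
    llen = (config.length_mu + config.length_scale * y
            + config.length_noise * rng.standard_normal(len(obs)))
    obs["length"] = 10.0 ** llen
    obs["life_stage"] = np.where(rng.random(len(obs)) < 0.8, "adult", "unknown")
    obs["sex"] = rng.choice(["male", "female", "unknown"], len(obs))
    obs["source"] = "synthetic_world"
    obs["truth_flag"] = "clean"

    # planted contamination, displaced from the species adult median in
    # raw-mass MAD units so it sits strictly outside the 5-MAD band
    contam = []
    d0, d1 = config.displacement_mads
    for sp, g in obs.groupby("species_id", sort=True):
        adult_mass = g.loc[g["life_stage"] == "adult", "mass"]
        med = float(adult_mass.median())
        mad = float((adult_mass - med).abs().median())
        if mad <= 0:
            continue
        n_j = int(round(config.juvenile_frac * len(g)))
        n_o = int(round(config.outlier_frac * len(g)))
        base = g.sample(n=n_j + n_o, random_state=int(rng.integers(2**31)),
                        replace=True).copy()
        d = rng.uniform(d0, d1, n_j + n_o)
        sign = np.concatenate([-np.ones(n_j),
                               rng.choice([-1.0, 1.0], n_o)])
        vals = med + sign * d * mad
        assert np.all(vals > 0), "contaminant masses must stay positive"
        base["mass"] = vals
        base["length"] = np.nan
        base["life_stage"] = np.where(np.arange(n_j + n_o) < n_j,
                                      "unknown", "adult")
        base["truth_flag"] = np.where(np.arange(n_j + n_o) < n_j,
                                      "juvenile_contaminant",
                                      "outlier_contaminant")
        contam.append(base)
    if contam:
        obs = pd.concat([obs] + contam, ignore_index=True)
    return obs


@dataclass
class World:
    """Everything one seeded synthetic study needs."""

    config: WorldConfig
    cubes: dict
    masks: list[RangeMask]
    tree: PhyloTree
    limits: pd.DataFrame
    ai: ClimateCube
    observations: pd.DataFrame
    synonyms: SynonymTable


def generate_world(config: WorldConfig) -> World:
    """Run every generator stage and bundle the results."""
    cubes = gen_climate(config)
    cubes.update(gen_landuse_and_realm(config))
    masks, tree = gen_ranges_and_tree(config)
    limits, ai = derive_world_limits(config, {**cubes, "masks": masks})
    obs = gen_observations(config, cubes, masks, tree)
    synonyms = SynonymTable({s: s for s in config.species_ids})
    return World(config, cubes, masks, tree, limits, ai, obs, synonyms)
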