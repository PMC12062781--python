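"""Domain types and file I/O.

The package works on five kinds of objects:

* :class:`ClimateCube` — a regular lat/lon grid of a monthly (or static)
  variable: maximum temperature, precipitation, potential evapotranspiration,
  aridity index, land-use fractions, or a categorical realm layer.
* :class:`RangeMask` — the set of grid cells a species occupies.
* observation tables — plain :class:`pandas.DataFrame` objects with the
  canonical column set in :data:`OBS_COLUMNS`.
* :class:`PhyloTree` — a thin wrapper over a dendropy tree read from Newick.
* :class:`SynonymTable` — raw name -> canonical binomial lookup.

Grid convention: coordinates are cell centers; a point maps to the cell whose
half-open interval ``[center - res/2, center + res/2)`` contains it.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .errors import ConfigurationError, FormatError

logger = logging.getLogger(__name__)

#: Variables whose values are fractions and must lie in [0, 1].
FRACTION_VARIABLES = {"cropland", "pasture", "urban"}

#: Canonical observation columns produced by :func:`read_observations`.
OBS_COLUMNS = [
    "species_id", "year", "month", "day", "lat", "lon",
    "mass", "length", "life_stage", "sex", "source",
]

LIFE_STAGES = {"adult", "juvenile", "unknown"}
SEXES = {"male", "female", "unknown"}


# ---------------------------------------------------------------------------
# ClimateCube
# ---------------------------------------------------------------------------

@dataclass
class ClimateCube:
    """A gridded variable, monthly over years or static.

    ``values`` has shape ``(n_time, n_lat, n_lon)`` for monthly cubes and
    ``(n_lat, n_lon)`` for static layers. ``times`` is a list of
    ``(year, month)`` pairs, strictly ordered, or ``None`` for static layers.
    Missing cells are NaN.
    """

    variable: str
    values: np.ndarray
    lats: np.ndarray
    lons: np.ndarray
    times: list[tuple[int, int]] | None = None
    units: str = ""
    categories: dict[int, str] | None = None

    def __post_init__(self):
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.lats.ndim != 1 or self.lons.ndim != 1:
            raise FormatError("lats/lons must be 1-D cell-center vectors")
        if np.any(np.abs(self.lats) > 90) or np.any(np.abs(self.lons) > 180):
            raise FormatError("grid centers outside [-90,90] x [-180,180]")
        for v in (self.lats, self.lons):
            if len(v) > 1:
                steps = np.diff(v)
                if not np.allclose(steps, steps[0]) or steps[0] <= 0:
                    raise FormatError("grid must be regular and increasing")
        if self.times is not None:
            expected = (len(self.times), len(self.lats), len(self.lons))
            keys = [y * 12 + (m - 1) for y, m in self.times]
            if any(b <= a for a, b in zip(keys, keys[1:])):
                raise FormatError("time index must be strictly ordered")
        else:
            expected = (len(self.lats), len(self.lons))
        if self.values.shape != expected:
            raise FormatError(
                f"values shape {self.values.shape} != expected {expected}")
        if self.variable in FRACTION_VARIABLES:
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise FormatError(
                    f"{self.variable} is fraction-valued but has values "
                    "outside [0, 1]")

    # -- geometry -----------------------------------------------------------
    @property
    def resolution(self) -> float:
        if len(self.lats) > 1:
            return float(self.lats[1] - self.lats[0])
        if len(self.lons) > 1:
            return float(self.lons[1] - self.lons[0])
        raise FormatError("cannot infer resolution from a 1-cell grid")

    @property
    def is_static(self) -> bool:
        return self.times is None

    def cell_index(self, lat, lon):
        """Map points to (i, j) cell indices; -1 where off-grid.

        Half-open convention: a point on the lower edge belongs to the cell,
        a point on the upper edge belongs to the next one.
        """
        res = self.resolution
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        i = np.floor((lat - (self.lats[0] - res / 2)) / res).astype(int)
        j = np.floor((lon - (self.lons[0] - res / 2)) / res).astype(int)
        i = np.where((i < 0) | (i >= len(self.lats)), -1, i)
        j = np.where((j < 0) | (j >= len(self.lons)), -1, j)
        return i, j

    @property
    def _time_lut(self) -> dict:
        lut = getattr(self, "_time_lut_cache", None)
        if lut is None and self.times is not None:
            lut = {ym: k for k, ym in enumerate(self.times)}
            object.__setattr__(self, "_time_lut_cache", lut)
        return lut

    def time_index(self, year, month):
        """Index into the time axis; -1 for (year, month) not covered."""
        if self.times is None:
            raise FormatError(f"{self.variable} is a static layer")
        lut = self._time_lut
        year = np.atleast_1d(np.asarray(year, dtype=int))
        month = np.atleast_1d(np.asarray(month, dtype=int))
        return np.array([lut.get((y, m), -1) for y, m in zip(year, month)])

    def same_grid(self, other: "ClimateCube") -> bool:
        return (self.lats.shape == other.lats.shape
                and self.lons.shape == other.lons.shape
                and np.allclose(self.lats, other.lats)
                and np.allclose(self.lons, other.lons))

    @staticmethod
    def from_layers(variable: str, layers, lats, lons, times, units: str = ""):
        """Stack per-time 2-D layers; all must share one grid shape."""
        shapes = {np.asarray(l).shape for l in layers}
        if len(shapes) != 1:
            raise FormatError(
                f"inconsistent grids across time steps: {sorted(shapes)}")
        return ClimateCube(variable, np.stack([np.asarray(l) for l in layers]),
                           lats, lons, list(times), units)


def write_climate_cube(cube: ClimateCube, path) -> None:
    """Write a cube as NetCDF3 (xarray, scipy engine)."""
    coords = {"lat": cube.lats, "lon": cube.lons}
    if cube.is_static:
        da = xr.DataArray(cube.values, coords=coords, dims=("lat", "lon"))
    else:
        tcode = np.array([y * 100 + m for y, m in cube.times], dtype=np.int32)
        da = xr.DataArray(cube.values, coords={"time": tcode, **coords},
                          dims=("time", "lat", "lon"))
    da.name = cube.variable
    da.attrs["units"] = cube.units
    if cube.categories:
        da.attrs["category_codes"] = ",".join(
            f"{k}:{v}" for k, v in sorted(cube.categories.items()))
    da.to_dataset().to_netcdf(path, engine="scipy")


def read_climate_cube(path) -> ClimateCube:
    """Read a cube written by :func:`write_climate_cube`.

    Round-trips bit-exactly on finite values; missing cells stay NaN.
    Only NetCDF is supported; raster directories (e.g. GeoTIFF stacks) must
    be converted upstream.
    """
    import os

    if os.path.isdir(path):
        raise FormatError(
            f"{path} is a directory; climate cubes are read from a single "
            "NetCDF file (GeoTIFF stacks are not supported)")
    with xr.open_dataset(path, engine="scipy") as ds:
        names = list(ds.data_vars)
        if len(names) != 1:
            raise FormatError(f"expected one variable, found {names}")
        da = ds[names[0]].load()
    times = None
    if "time" in da.dims:
        tcode = da["time"].values.astype(int)
        times = [(int(t) // 100, int(t) % 100) for t in tcode]
    cats = None
    if "category_codes" in da.attrs:
        cats = {int(p.split(":")[0]): p.split(":")[1]
                for p in str(da.attrs["category_codes"]).split(",")}
    return ClimateCube(names[0], da.values, da["lat"].values, da["lon"].values,
                       times, units=str(da.attrs.get("units", "")),
                       categories=cats)


# ---------------------------------------------------------------------------
# RangeMask
# ---------------------------------------------------------------------------

@dataclass
class RangeMask:
    """Cells of a companion grid occupied by one species."""

    species_id: str
    cells: np.ndarray  # (n, 2) int array of (lat_index, lon_index)
    grid_shape: tuple[int, int]

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=int).reshape(-1, 2)
        if self.cells.shape[0] == 0:
            raise FormatError(f"empty range mask for {self.species_id}")
        ni, nj = self.grid_shape
        if (self.cells[:, 0].min() < 0 or self.cells[:, 0].max() >= ni
                or self.cells[:, 1].min() < 0 or self.cells[:, 1].max() >= nj):
            raise FormatError(
                f"range cells outside the companion grid for {self.species_id}")

    @property
    def flat(self) -> np.ndarray:
        return self.cells[:, 0] * self.grid_shape[1] + self.cells[:, 1]

    @staticmethod
    def from_polygon(species_id: str, polygon, cube: ClimateCube) -> "RangeMask":
        """Cells whose centers fall inside a shapely polygon (lon, lat)."""
        from shapely.geometry import Point

        cells = [(i, j)
                 for i, la in enumerate(cube.lats)
                 for j, lo in enumerate(cube.lons)
                 if polygon.contains(Point(lo, la))]
        return RangeMask(species_id, np.array(cells).reshape(-1, 2),
                         (len(cube.lats), len(cube.lons)))


def write_range_masks(masks: list[RangeMask], cube: ClimateCube, path) -> None:
    """CSV cell list: species_id, lat, lon of occupied cell centers."""
    rows = [(m.species_id, cube.lats[i], cube.lons[j])
            for m in masks for i, j in m.cells]
    pd.DataFrame(rows, columns=["species_id", "lat", "lon"]).to_csv(
        path, index=False)


def read_range_masks(path, cube: ClimateCube) -> list[RangeMask]:
    df = pd.read_csv(path)
    i, j = cube.cell_index(df["lat"].values, df["lon"].values)
    if np.any(i < 0) or np.any(j < 0):
        raise FormatError("range cell centers off the companion grid")
    shape = (len(cube.lats), len(cube.lons))
    out = []
    for sp, g in df.assign(i=i, j=j).groupby("species_id", sort=True):
        out.append(RangeMask(str(sp), g[["i", "j"]].values, shape))
    return out


# ---------------------------------------------------------------------------
# Observations
# ---------------------------------------------------------------------------

def read_observations(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a delimited observation file into the canonical schema.

    ``column_map`` maps canonical names (see :data:`OBS_COLUMNS`, plus
    ``date`` for a single ISO date column) to the file's headers. Unparseable
    size or date fields become missing; rows are never dropped here.
    """
    df = pd.read_csv(path, dtype=str)
    colmap = dict(column_map or {})
    rename = {v: k for k, v in colmap.items() if v in df.columns}
    df = df.rename(columns=rename)

    missing = [c for c in ("species_id", "lat", "lon") if c not in df.columns]
    if "date" not in df.columns and "year" not in df.columns:
        missing.append("date")
    if "mass" not in df.columns and "length" not in df.columns:
        missing.append("mass|length")
    if missing:
        raise ConfigurationError(
            f"missing mandatory column(s): {', '.join(missing)}")

    n_in = len(df)
    out = pd.DataFrame(index=df.index)
    out["species_id"] = df["species_id"].astype("string")
    if "date" in df.columns:
        dt = pd.to_datetime(df["date"], errors="coerce")
        out["year"], out["month"], out["day"] = dt.dt.year, dt.dt.month, dt.dt.day
    else:
        for part in ("year", "month", "day"):
            out[part] = (pd.to_numeric(df.get(part), errors="coerce")
                         if part in df.columns else np.nan)
    for c in ("lat", "lon", "mass", "length"):
        out[c] = pd.to_numeric(df.get(c), errors="coerce") if c in df.columns else np.nan
    for c in ("life_stage", "sex"):
        out[c] = (df[c].astype("string") if c in df.columns
                  else pd.Series("unknown", index=df.index, dtype="string"))
    out["source"] = (df["source"].astype("string").fillna("")
                     if "source" in df.columns
                     else pd.Series("", index=df.index, dtype="string"))
    if "exclude" in df.columns:
        out["exclude"] = df["exclude"].astype("string").str.lower().isin(
            {"1", "true", "yes"})
    assert len(out) == n_in, "reader must preserve row count"
    return out


def write_observations(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Phylogenetic trees
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """A rooted tree with branch lengths, tip labels = species ids."""

    tree: "object"  # dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def check_species(self, species: set[str]) -> list[str]:
        """Tips absent from ``species``; logged as a warning if non-empty."""
        extra = sorted(set(self.tip_labels) - set(species))
        if extra:
            logger.warning("tree tips without a matching species: %s", extra)
        return extra

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip label."""
        out = {}
        for lf in self.tree.leaf_node_iter():
            out[lf.taxon.label] = lf.distance_from_root()
        return out


def parse_tree(newick: str) -> PhyloTree:
    import dendropy

    try:
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"malformed Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise FormatError("duplicate tip labels in tree")
    for e in tree.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            raise FormatError("negative branch length in tree")
    return PhyloTree(tree)


def read_tree(path) -> PhyloTree:
    with open(path) as fh:
        return parse_tree(fh.read())


def write_tree(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.tree.as_string(schema="newick"))


# ---------------------------------------------------------------------------
# Synonym table
# ---------------------------------------------------------------------------

@dataclass
class SynonymTable:
    """raw name -> canonical binomial; canonical names are fixed points."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for canonical in set(self.mapping.values()):
            if self.mapping.get(canonical, canonical) != canonical:
                raise FormatError(
                    f"canonical name '{canonical}' is not a fixed point")

    def resolve(self, name: str) -> str | None:
        """Canonical form, or None when the name is unresolvable."""
        if name in self.mapping:
            return self.mapping[name]
        if name in set(self.mapping.values()):
            return name
        return None


def read_synonyms(path) -> SynonymTable:
    df = pd.read_csv(path, dtype=str)
    if not {"raw", "canonical"} <= set(df.columns):
        raise ConfigurationError("synonym table needs columns raw, canonical")
    return SynonymTable(dict(zip(df["raw"], df["canonical"])))


def write_synonyms(table: SynonymTable, path) -> None:
    pd.DataFrame(sorted(table.mapping.items()),
                 columns=["raw", "canonical"]).to_csv(path, index=False)
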