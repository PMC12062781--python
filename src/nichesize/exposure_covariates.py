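"""Per-observation exposure covariates.

The thermal position index (TPI) locates an observed temperature within a
species' realized thermal niche::

    P = (1/t) * sum_i (N_m - N_min) / (N_max - N_min)

with N_min/N_max the species' monthly niche limits. 0 and 1 mark the derived
lower and upper tolerance limits; values outside [0, 1] are meaningful (they
mark conditions beyond the derived limits) and are never truncated. The
aridity position index (API) is the same statistic on the aridity index.

Land-use covariates: ALU = cropland + pasture fraction, ULU = urban fraction,
at the observation's grid quadrat and year.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateLimitsError
from .formats_io import ClimateCube

logger = logging.getLogger(__name__)


def position_index(n_m, n_min, n_max):
    """(N_m - N_min) / (N_max - N_min); may fall outside [0, 1]."""
    n_m = np.asarray(n_m, dtype=float)
    n_min = np.asarray(n_min, dtype=float)
    n_max = np.asarray(n_max, dtype=float)
    if np.any(~(n_max > n_min)):
        raise DegenerateLimitsError("position index needs n_max > n_min")
    out = (n_m - n_min) / (n_max - n_min)
    return float(out) if out.ndim == 0 else out


def position_index_mean(values, limits) -> float:
    """Mean of unit-wise position indices over t time units.

    ``limits`` is a sequence of (n_min, n_max) pairs matching ``values``.
    """
    values = np.asarray(values, dtype=float)
    lim = np.asarray(limits, dtype=float).reshape(-1, 2)
    if len(values) != len(lim) or len(values) < 1:
        raise ConfigurationError("values and limits must match, t >= 1")
    return float(np.mean(position_index(values, lim[:, 0], lim[:, 1])))


def _limit_lookup(limits: pd.DataFrame, variable: str):
    sub = limits[limits["variable"] == variable]
    return {(r.species_id, int(r.month)): (r.n_min, r.n_max)
            for r in sub.itertuples()}


def _extract_cell_values(table: pd.DataFrame, cube: ClimateCube) -> np.ndarray:
    i, j = cube.cell_index(table["lat"].values, table["lon"].values)
    t = cube.time_index(table["year"].values.astype(int),
                        table["month"].values.astype(int))
    ok = (i >= 0) & (j >= 0) & (t >= 0)
    out = np.full(len(table), np.nan)
    out[ok] = cube.values[t[ok], i[ok], j[ok]]
    return out


def _attach_index(table, cube, limits, variable, colname):
    lut = _limit_lookup(limits, variable)
    n_m = _extract_cell_values(table, cube)
    n_min = np.full(len(table), np.nan)
    n_max = np.full(len(table), np.nan)
    for k, (sp, mo) in enumerate(zip(table["species_id"].values,
                                     table["month"].values)):
        key = (sp, int(mo))
        if key not in lut:
            raise ConfigurationError(
                f"no {variable} limit row for species {sp}, month {int(mo)}")
        n_min[k], n_max[k] = lut[key]
    valid = np.isfinite(n_m) & np.isfinite(n_min) & (n_max > n_min)
    idx = np.full(len(table), np.nan)
    idx[valid] = (n_m[valid] - n_min[valid]) / (n_max[valid] - n_min[valid])
    n_missing = int((~valid).sum())
    if n_missing:
        logger.info("%s: %d records with missing value or degenerate limits",
                    colname, n_missing)
    table[colname] = idx
    table[f"{colname}_nm"] = n_m
    table[f"{colname}_nmin"] = n_min
    table[f"{colname}_nmax"] = n_max
    return table


def attach_climate_indices(table: pd.DataFrame, tmax_cube: ClimateCube,
                           ai_cube: ClimateCube,
                           limits: pd.DataFrame) -> pd.DataFrame:
    """Add tpi and api columns (plus N_m/N_min/N_max audit columns).

    Rows are never dropped or reordered; records whose cell-month value is
    missing get a missing index (excluded later, at model assembly).
    """
    table = table.copy()
    table = _attach_index(table, tmax_cube, limits, "tmax", "tpi")
    table = _attach_index(table, ai_cube, limits, "ai", "api")
    return table


def attach_landuse(table: pd.DataFrame, cropland: ClimateCube,
                   pasture: ClimateCube, urban: ClimateCube) -> pd.DataFrame:
    """Add alu (= cropland + pasture, clamped to [0,1]) and ulu columns.

    Static layers apply to every year; for yearly stacks the observation year
    is matched to the nearest covered year (warned when outside coverage).
    """
    table = table.copy()
    parts = {}
    for name, cube in (("cropland", cropland), ("pasture", pasture),
                       ("urban", urban)):
        if cube.is_static:
            i, j = cube.cell_index(table["lat"].values, table["lon"].values)
            ok = (i >= 0) & (j >= 0)
            v = np.full(len(table), np.nan)
            v[ok] = cube.values[i[ok], j[ok]]
        else:
            years = np.array(sorted({y for y, _ in cube.times}))
            obs_years = table["year"].values.astype(int)
            snapped = years[np.argmin(
                np.abs(obs_years[:, None] - years[None, :]), axis=1)]
            if np.any(snapped != obs_years):
                warnings.warn(f"{name}: some observation years outside "
                              "coverage; nearest covered year used")
            tbl = table.copy()
            tbl["year"] = snapped
            tbl["month"] = cube.times[0][1]
            v = _extract_cell_values(tbl, cube)
        parts[name] = v
    alu_raw = parts["cropland"] + parts["pasture"]
    if np.any(alu_raw[np.isfinite(alu_raw)] > 1):
        warnings.warn("cropland + pasture exceeds 1 in some quadrats; "
                      "ALU clamped to 1")
    table["alu"] = np.clip(alu_raw, 0.0, 1.0)
    table["ulu"] = parts["urban"]
    return table


def attach_realm(table: pd.DataFrame, realm_cube: ClimateCube) -> pd.DataFrame:
    """Add a categorical realm label per record; missing cells flagged NaN."""
    table = table.copy()
    i, j = realm_cube.cell_index(table["lat"].values, table["lon"].values)
    ok = (i >= 0) & (j >= 0)
    code = np.full(len(table), np.nan)
    code[ok] = realm_cube.values[i[ok], j[ok]]
    cats = realm_cube.categories or {}
    table["realm"] = pd.Series(
        [cats.get(int(c), str(int(c))) if np.isfinite(c) else None
         for c in code], index=table.index, dtype="string")
    n_missing = int((~np.isfinite(code)).sum())
    if n_missing:
        logger.info("realm: %d records with no realm cell", n_missing)
    return table


def zscore_columns(table: pd.DataFrame, columns: list[str]
                   ) -> tuple[pd.DataFrame, dict[str, float], dict[str, float]]:
    """z-score columns in place (copy); returns (table, means, sds).

    Interactions must be formed AFTER z-scoring the main effects so that a
    coefficient reads as the effect of a 1-SD change.
    """
    table = table.copy()
    means, sds = {}, {}
    for c in columns:
        x = table[c].astype(float)
        mu = float(x.mean(skipna=True))
        sd = float(x.std(skipna=True, ddof=1))
        if not np.isfinite(sd) or sd == 0:
            raise ConfigurationError(f"zero or undefined sd in column '{c}'")
        table[c] = (x - mu) / sd
        means[c], sds[c] = mu, sd
    return table, means, sds


def add_interactions(table: pd.DataFrame,
                     pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Products of (already z-scored) main effects, named 'a_x_b'."""
    table = table.copy()
    for a, b in pairs:
        table[f"{a}_x_{b}"] = table[a].astype(float) * table[b].astype(float)
    return table
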