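"""Per-species monthly niche limits from range geometry and gridded climate.

For each species and calendar month, the lower and upper limits N_min / N_max
of a climate variable are the range-wide extremes taken within each baseline
year (default 1961-1975) and then averaged across years. For the aridity
index, range-wide cell values are first passed through Tukey fences
(Q1 - 1.5 IQR, Q3 + 1.5 IQR, type-7 quantiles); values beyond a fence are
replaced by the fence itself and the replacements are counted.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .errors import FormatError
from .formats_io import ClimateCube, RangeMask

logger = logging.getLogger(__name__)

DEFAULT_BASELINE = (1961, 1975)

LIMIT_COLUMNS = ["species_id", "variable", "month", "n_min", "n_max",
                 "n_adjusted_upper", "n_adjusted_lower"]


def compute_ai(ppt_cube: ClimateCube, pet_cube: ClimateCube) -> ClimateCube:
    """Aridity index AI = PPT / PET per cell-month.

    Cells with missing or non-positive PET (e.g. snow-covered areas, where
    evapotranspiration is undefined) yield missing AI.
    """
    if not ppt_cube.same_grid(pet_cube) or ppt_cube.times != pet_cube.times:
        raise FormatError("ppt and pet cubes must share grid and time index")
    pet = pet_cube.values
    with np.errstate(divide="ignore", invalid="ignore"):
        ai = np.where(np.isfinite(pet) & (pet > 0),
                      ppt_cube.values / pet, np.nan)
    return ClimateCube("ai", ai, ppt_cube.lats, ppt_cube.lons,
                       None if ppt_cube.times is None else list(ppt_cube.times),
                       units="")


def iqr_fences(values) -> tuple[float, float]:
    """Tukey fences (Q1 - 1.5 IQR, Q3 + 1.5 IQR), linear-interpolation quantiles."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("iqr_fences needs at least 2 finite values")
    q1, q3 = np.quantile(x, [0.25, 0.75], method="linear")
    iqr = q3 - q1
    return float(q1 - 1.5 * iqr), float(q3 + 1.5 * iqr)


def clamp_to_fences(values, fences) -> tuple[np.ndarray, int, int]:
    """Replace values beyond the fences by the fence values; count replacements."""
    lo, hi = fences
    x = np.asarray(values, dtype=float).copy()
    finite = np.isfinite(x)
    above = finite & (x > hi)
    below = finite & (x < lo)
    x[above] = hi
    x[below] = lo
    return x, int(above.sum()), int(below.sum())


def derive_limits(cube: ClimateCube, mask: RangeMask,
                  baseline_years: tuple[int, int] = DEFAULT_BASELINE,
                  fence: bool | None = None,
                  pooled_extremes: bool = False) -> pd.DataFrame:
    """Monthly N_min/N_max for one species over the baseline period.

    Parameters
    ----------
    fence
        Apply IQR fencing to range-wide cell values per month-year before
        taking extremes. Defaults to True for the aridity index and False
        otherwise (temperature limits are not fenced).
    pooled_extremes
        If True, take extremes over all baseline years pooled rather than the
        default mean-of-yearly-extremes.
    """
    if cube.is_static:
        raise FormatError("limits need a monthly cube")
    if fence is None:
        fence = cube.variable == "ai"
    y0, y1 = baseline_years
    flat = mask.flat
    n_cells = len(cube.lats) * len(cube.lons)
    if flat.max() >= n_cells:
        raise FormatError(f"range of {mask.species_id} off the cube grid")

    vals2d = cube.values.reshape(cube.values.shape[0], -1)
    rows = []
    for month in range(1, 13):
        tidx = [cube.time_index(y, month)[0] for y in range(y0, y1 + 1)]
        tidx = [t for t in tidx if t >= 0]
        yearvals = vals2d[np.asarray(tidx, dtype=int)][:, flat] if tidx \
            else np.empty((0, len(flat)))
        n_valid = np.isfinite(yearvals).sum(axis=1)
        yearvals = yearvals[n_valid > 0]
        n_up = n_lo = 0
        if fence and yearvals.size:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                q1, q3 = np.nanquantile(yearvals, [0.25, 0.75], axis=1,
                                        method="linear")
            lo = q1 - 1.5 * (q3 - q1)
            hi = q3 + 1.5 * (q3 - q1)
            above = yearvals > hi[:, None]
            below = yearvals < lo[:, None]
            n_up = int(above.sum())
            n_lo = int(below.sum())
            yearvals = np.where(above, hi[:, None], yearvals)
            yearvals = np.where(below, lo[:, None], yearvals)
        if yearvals.size:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                ymin = np.nanmin(yearvals, axis=1)
                ymax = np.nanmax(yearvals, axis=1)
            if pooled_extremes:
                n_min, n_max = float(ymin.min()), float(ymax.max())
            else:
                n_min, n_max = float(ymin.mean()), float(ymax.mean())
        else:
            logger.warning("%s/%s month %d: no valid cells in any baseline year",
                           mask.species_id, cube.variable, month)
            n_min = n_max = np.nan
        rows.append((mask.species_id, cube.variable, month,
                     n_min, n_max, n_up, n_lo))
    return pd.DataFrame(rows, columns=LIMIT_COLUMNS)


def derive_limits_table(cube: ClimateCube, masks: list[RangeMask],
                        baseline_years: tuple[int, int] = DEFAULT_BASELINE,
                        **kwargs) -> pd.DataFrame:
    """Stack :func:`derive_limits` over many species."""
    parts = [derive_limits(cube, m, baseline_years, **kwargs) for m in masks]
    return pd.concat(parts, ignore_index=True)


def adjusted_upper_fraction(limits: pd.DataFrame) -> float:
    """Fraction of species-month upper limits altered by fencing (ai rows)."""
    ai = limits[limits["variable"] == "ai"]
    if len(ai) == 0:
        return 0.0
    return float((ai["n_adjusted_upper"] > 0).mean())


def write_limits(limits: pd.DataFrame, path) -> None:
    limits.to_csv(path, index=False)


def read_limits(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(LIMIT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"limit table missing columns: {sorted(missing)}")
    return df
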