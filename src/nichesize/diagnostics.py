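"""Model-validation battery.

All diagnostics are pure functions of (fit, data, seed): repeated calls with
the same seed return identical results.

* VIF per fixed-effect term, 1/(1 - R^2_j).
* Durbin-Watson statistic with a permutation p-value, plus the resampling
  scheme that draws one residual per year and repeats (globally, and per
  species).
* A spline correlogram: distance-binned Moran-type correlation of residuals
  against great-circle distance (km), smoothed, with a bootstrap envelope.
* Influence screening by standardized conditional residuals.
* Posterior predictive checks simulating response vectors from the fitted
  generative model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.interpolate import UnivariateSpline

from .errors import ConfigurationError
from .phylo_mixed_model import Design, ModelFit, _block_sqrt

EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# Collinearity
# ---------------------------------------------------------------------------

def vif(X: np.ndarray, names: list[str] | None = None) -> pd.Series:
    """Variance inflation factor per column: 1 / (1 - R^2_j).

    The intercept column (if constant) is excluded from the report; exact
    collinearity yields inf.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    names = names or [f"x{j}" for j in range(p)]
    out = {}
    const = [j for j in range(p) if np.ptp(X[:, j]) == 0]
    for j in range(p):
        if j in const:
            continue
        others = [c for c in range(p) if c != j]
        A = X[:, others]
        if not const:  # regress on the others plus an intercept
            A = np.column_stack([np.ones(n), A])
        coef, _, _, _ = np.linalg.lstsq(A, X[:, j], rcond=None)
        resid = X[:, j] - A @ coef
        tss = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        rss = float(resid @ resid)
        if tss <= 0:
            continue
        r2 = 1.0 - rss / tss
        out[names[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


# ---------------------------------------------------------------------------
# Durbin-Watson
# ---------------------------------------------------------------------------

def durbin_watson(series) -> float:
    """DW = sum (e_t - e_{t-1})^2 / sum e_t^2; ~2 under independence."""
    e = np.asarray(series, dtype=float)
    if len(e) < 2:
        raise ValueError("Durbin-Watson needs at least 2 values")
    denom = float(e @ e)
    if denom == 0:
        raise ValueError("all-zero residual series")
    return float(np.sum(np.diff(e) ** 2) / denom)


def dw_pvalue(series, n_perm: int = 199, seed=None,
              alternative: str = "positive") -> float:
    """Permutation p-value for the DW statistic.

    'positive' (default) tests for positive autocorrelation (small DW);
    'two-sided' uses |DW - 2|.
    """
    rng = np.random.default_rng(seed)
    e = np.asarray(series, dtype=float)
    obs = durbin_watson(e)
    denom = float(e @ e)
    perms = np.array([rng.permutation(e) for _ in range(n_perm)])
    dws = np.sum(np.diff(perms, axis=1) ** 2, axis=1) / denom
    if alternative == "positive":
        count = int(np.sum(dws <= obs))
    elif alternative == "two-sided":
        count = int(np.sum(np.abs(dws - 2) >= abs(obs - 2)))
    else:
        raise ConfigurationError(f"unknown alternative '{alternative}'")
    return (1 + count) / (1 + n_perm)


def dw_resample(residuals, years, n_iter: int = 1000, alpha: float = 0.05,
                seed=None, n_perm: int = 199,
                alternative: str = "positive") -> dict:
    """Fraction of resampled one-per-year residual series that show no
    significant autocorrelation.

    Each iteration draws one residual per year uniformly, orders by year, and
    computes DW with a permutation p-value; returns the fraction of
    iterations with p >= alpha.
    """
    rng = np.random.default_rng(seed)
    residuals = np.asarray(residuals, dtype=float)
    years = np.asarray(years)
    uyears = np.unique(years)
    groups = []
    for yv in uyears:
        idx = np.flatnonzero(years == yv)
        if len(idx) == 0:
            warnings.warn(f"year {yv} has no residuals; skipped")
            continue
        groups.append(idx)
    if len(groups) < 2:
        raise ConfigurationError("need residuals from at least 2 years")
    nonsig = 0
    dws = np.empty(n_iter)
    for it in range(n_iter):
        picks = np.array([g[rng.integers(len(g))] for g in groups])
        series = residuals[picks]
        dws[it] = durbin_watson(series)
        p = dw_pvalue(series, n_perm=n_perm, seed=rng.integers(2**31),
                      alternative=alternative)
        if p >= alpha:
            nonsig += 1
    return {"n_iter": n_iter, "fraction_nonsignificant": nonsig / n_iter,
            "mean_dw": float(dws.mean())}


def dw_resample_per_species(residuals, years, species, n_iter: int = 100,
                            alpha: float = 0.05, seed=None,
                            n_perm: int = 199) -> pd.DataFrame:
    """Per-species mean DW and mean permutation p over n_iter resamples."""
    rng = np.random.default_rng(seed)
    residuals = np.asarray(residuals, dtype=float)
    years = np.asarray(years)
    species = np.asarray(species)
    rows = []
    for sp in np.unique(species):
        m = species == sp
        if len(np.unique(years[m])) < 2:
            continue
        dws, ps = [], []
        for _ in range(n_iter):
            picks = []
            for yv in np.unique(years[m]):
                idx = np.flatnonzero(m & (years == yv))
                picks.append(idx[rng.integers(len(idx))])
            series = residuals[np.array(picks)]
            dws.append(durbin_watson(series))
            ps.append(dw_pvalue(series, n_perm=n_perm,
                                seed=rng.integers(2**31)))
        rows.append((sp, float(np.mean(dws)), float(np.mean(ps)),
                     float(np.mean(ps)) < alpha))
    return pd.DataFrame(rows, columns=["species_id", "mean_dw", "mean_p",
                                       "flagged"])


# ---------------------------------------------------------------------------
# Spatial autocorrelation
# ---------------------------------------------------------------------------

def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in kilometres."""
    la1, lo1, la2, lo2 = (np.radians(np.asarray(a, dtype=float))
                          for a in (lat1, lon1, lat2, lon2))
    dlat = la2 - la1
    dlon = lo2 - lo1
    h = np.sin(dlat / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def _binned_correlogram(z, lat, lon, bins, orig=None):
    """Moran-type correlation of standardized residuals per distance bin.

    ``orig`` carries original point ids under bootstrap resampling; pairs of
    the same original point are self-pairs and are excluded.
    """
    n = len(z)
    ii, jj = np.triu_indices(n, k=1)
    if orig is not None:
        keep = orig[ii] != orig[jj]
        ii, jj = ii[keep], jj[keep]
    d = haversine_km(lat[ii], lon[ii], lat[jj], lon[jj])
    prod = z[ii] * z[jj]
    which = np.digitize(d, bins) - 1
    est = np.full(len(bins) - 1, np.nan)
    for b in range(len(bins) - 1):
        m = which == b
        if m.sum() >= 2:
            est[b] = prod[m].mean()
    return est


def spline_correlogram(residuals, lat, lon, n_boot: int = 99,
                       max_dist: float | None = None, seed=None,
                       n_bins: int = 12) -> dict:
    """Residual correlation as a smooth function of distance, with a
    bootstrap envelope from resampling observations."""
    rng = np.random.default_rng(seed)
    e = np.asarray(residuals, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if len(e) < 20:
        raise ConfigurationError("spline correlogram needs >= 20 points")
    if len(np.unique(np.column_stack([lat, lon]), axis=0)) < 2:
        raise ConfigurationError("all points at a single location")
    z = (e - e.mean()) / e.std()
    ii, jj = np.triu_indices(len(e), k=1)
    dall = haversine_km(lat[ii], lon[ii], lat[jj], lon[jj])
    if max_dist is None:
        max_dist = float(np.quantile(dall, 0.9))
    bins = np.linspace(0, max_dist, n_bins + 1)
    mids = 0.5 * (bins[:-1] + bins[1:])

    def smooth(est):
        ok = np.isfinite(est)
        if ok.sum() < 4:
            return est
        spl = UnivariateSpline(mids[ok], est[ok], k=3,
                               s=len(mids[ok]) * np.nanvar(est[ok]))
        return spl(mids)

    est = smooth(_binned_correlogram(z, lat, lon, bins))
    boots = np.full((n_boot, len(mids)), np.nan)
    for b in range(n_boot):
        pick = rng.integers(0, len(e), len(e))
        zb = z[pick]
        zb = (zb - zb.mean()) / (zb.std() if zb.std() > 0 else 1.0)
        boots[b] = smooth(_binned_correlogram(zb, lat[pick], lon[pick], bins,
                                              orig=pick))
    lo = np.nanpercentile(boots, 2.5, axis=0)
    hi = np.nanpercentile(boots, 97.5, axis=0)
    return {"distance_km": mids, "correlation": est,
            "envelope_low": lo, "envelope_high": hi}


# ---------------------------------------------------------------------------
# Influence and posterior predictive checks
# ---------------------------------------------------------------------------

def influence_screen(fit_result: ModelFit, threshold: float = 4.0) -> dict:
    """Flag records with |standardized conditional residual| > threshold."""
    e = fit_result.residuals
    sd = np.std(e, ddof=1)
    if sd == 0:
        return {"flagged": np.array([], dtype=int), "fraction": 0.0}
    z = np.abs(e / sd)
    flagged = np.flatnonzero(z > threshold)
    return {"flagged": flagged, "fraction": len(flagged) / len(e)}


def refit_without_flagged(table: pd.DataFrame, fit_result: ModelFit,
                          spec, C, flagged: np.ndarray,
                          fit_kwargs: dict | None = None):
    """Convenience: refit after dropping flagged rows, return beta shifts."""
    from . import phylo_mixed_model as pm

    keep_labels = np.delete(fit_result.index, flagged)
    design = pm.assemble(table.loc[keep_labels], spec, C)
    refit = pm.fit(design, **(fit_kwargs or {}))
    shift = refit.fixed["estimate"].to_numpy() - fit_result.fixed["estimate"].to_numpy()
    return refit, pd.Series(shift, index=fit_result.fixed["term"].tolist())


def posterior_predictive_check(fit_result: ModelFit, design: Design,
                               n_sim: int = 1000, seed=None) -> dict:
    """Simulate response vectors from the fitted generative model and compare
    observed summary statistics against the simulated envelopes."""
    rng = np.random.default_rng(seed)
    if n_sim < 2:
        warnings.warn("n_sim < 2: the predictive envelope is degenerate")
    beta = fit_result.fixed["estimate"].to_numpy()
    mu = design.X @ beta
    T = _block_sqrt(design, fit_result.gammas)  # T T' = blockdiag(gamma G)
    sigma = np.sqrt(fit_result.sigma2_resid)
    n, q = design.n, design.q
    y_obs = design.y
    qs = np.arange(0.1, 1.0, 0.1)
    sims_mean = np.empty(n_sim)
    sims_sd = np.empty(n_sim)
    sims_dec = np.empty((n_sim, len(qs)))
    for s in range(n_sim):
        b = sigma * (T @ rng.standard_normal(q))
        y = mu + design.Z @ b + sigma * rng.standard_normal(n)
        sims_mean[s] = y.mean()
        sims_sd[s] = y.std(ddof=1)
        sims_dec[s] = np.quantile(y, qs)
    out = {
        "observed_mean": float(y_obs.mean()),
        "observed_sd": float(y_obs.std(ddof=1)),
        "mean_envelope": [float(np.quantile(sims_mean, 0.025)),
                          float(np.quantile(sims_mean, 0.975))],
        "sd_envelope": [float(np.quantile(sims_sd, 0.025)),
                        float(np.quantile(sims_sd, 0.975))],
        "decile_coverage": float(np.mean(
            (np.quantile(y_obs, qs) >= np.quantile(sims_dec, 0.025, axis=0))
            & (np.quantile(y_obs, qs) <= np.quantile(sims_dec, 0.975, axis=0)))),
    }
    out["mean_in_envelope"] = bool(
        out["mean_envelope"][0] <= out["observed_mean"] <= out["mean_envelope"][1])
    return out


# ---------------------------------------------------------------------------
# Aggregate report
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticsReport:
    vif: dict = field(default_factory=dict)
    dw_global: dict = field(default_factory=dict)
    dw_species: list = field(default_factory=list)
    correlogram: dict = field(default_factory=dict)
    influence: dict = field(default_factory=dict)
    ppc: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        def conv(o):
            if isinstance(o, np.ndarray):
                return [None if not np.isfinite(v) else float(v) for v in o]
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))
        text = json.dumps(self.__dict__, default=conv, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def run_all(fit_result: ModelFit, design: Design, table: pd.DataFrame,
            seed=None, n_iter_dw: int = 1000, n_boot: int = 99,
            n_sim_ppc: int = 500) -> DiagnosticsReport:
    """The full battery on a fitted model. ``table`` must hold the rows the
    design was assembled from (matched by ``design.index``)."""
    rng = np.random.default_rng(seed)
    rows = table.loc[design.index]
    rep = DiagnosticsReport()
    rep.vif = vif(design.X, design.fixed_names).to_dict()
    rep.dw_global = dw_resample(fit_result.residuals,
                                rows["year"].to_numpy(),
                                n_iter=n_iter_dw, seed=rng.integers(2**31))
    rep.dw_species = dw_resample_per_species(
        fit_result.residuals, rows["year"].to_numpy(),
        rows["species_id"].to_numpy(), seed=rng.integers(2**31)
    ).to_dict(orient="records")
    rep.correlogram = spline_correlogram(
        fit_result.residuals, rows["lat"].to_numpy(), rows["lon"].to_numpy(),
        n_boot=n_boot, seed=rng.integers(2**31))
    inf = influence_screen(fit_result)
    rep.influence = {"n_flagged": int(len(inf["flagged"])),
                     "fraction": inf["fraction"]}
    rep.ppc = posterior_predictive_check(fit_result, design, n_sim=n_sim_ppc,
                                         seed=rng.integers(2**31))
    return rep
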