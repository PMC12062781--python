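import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nichesize import diagnostics as dg
from nichesize import phylo_mixed_model as pm
from nichesize.errors import ConfigurationError


# ---------------------------------------------------------------------------
# VIF
# ---------------------------------------------------------------------------

def test_vif_orthogonal_predictors_are_one():
    X = np.column_stack([np.ones(8),
                         np.tile([1, -1], 4),
                         np.tile([1, 1, -1, -1], 2)])
    v = dg.vif(X, ["const", "a", "b"])
    assert v["a"] == pytest.approx(1.0, abs=1e-12)
    assert v["b"] == pytest.approx(1.0, abs=1e-12)


def test_vif_duplicated_column_infinite():
    rng = np.random.default_rng(0)
    x = rng.normal(size=50)
    X = np.column_stack([np.ones(50), x, x])
    v = dg.vif(X, ["const", "a", "a_copy"])
    assert np.isinf(v["a"])


def test_vif_matches_inverse_correlation_oracle():
    """VIF equals the diagonal of the inverted correlation matrix."""
    rng = np.random.default_rng(1)
    x1, x2 = rng.normal(size=200), rng.normal(size=200)
    x3 = x1 + x2 + 0.5 * rng.normal(size=200)
    X = np.column_stack([np.ones(200), x1, x2, x3])
    v = dg.vif(X, ["const", "x1", "x2", "x3"])
    R = np.corrcoef(X[:, 1:], rowvar=False)
    oracle = np.diag(np.linalg.inv(R))
    for j, name in enumerate(["x1", "x2", "x3"]):
        assert v[name] == pytest.approx(oracle[j], abs=1e-8)


# ---------------------------------------------------------------------------
# Durbin-Watson
# ---------------------------------------------------------------------------

def test_dw_exact_arithmetic():
    assert dg.durbin_watson([1, -1, 1, -1]) == pytest.approx(3.0)  # 12/4
    assert dg.durbin_watson([1, 2, 3, 4]) == pytest.approx(0.1)    # 3/30
    with pytest.raises(ValueError):
        dg.durbin_watson([0.0, 0.0])


def test_dw_concentrates_near_two_for_iid():
    rng = np.random.default_rng(2)
    dws = [dg.durbin_watson(rng.standard_normal(500)) for _ in range(20)]
    assert abs(np.mean(dws) - 2.0) < 0.05


def test_dw_permutation_p_uniform_under_null():
    """Kolmogorov-Smirnov check of p-value uniformity on exchangeable data."""
    rng = np.random.default_rng(3)
    ps = [dg.dw_pvalue(rng.standard_normal(30), n_perm=99,
                       seed=rng.integers(2**31)) for _ in range(500)]
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_dw_resample_deterministic_and_skips_empty_years():
    rng = np.random.default_rng(4)
    resid = rng.standard_normal(300)
    years = rng.integers(1990, 2010, 300)
    a = dg.dw_resample(resid, years, n_iter=50, seed=99)
    b = dg.dw_resample(resid, years, n_iter=50, seed=99)
    assert a == b
    with pytest.raises(ConfigurationError):
        dg.dw_resample(resid, np.full(300, 2000), n_iter=10, seed=0)


def test_dw_resample_detects_strong_autocorrelation():
    rng = np.random.default_rng(5)
    years = np.repeat(np.arange(1961, 2011), 6)
    ar = np.zeros(50)
    for t in range(1, 50):                      # AR(1), rho = 0.9
        ar[t] = 0.9 * ar[t - 1] + rng.standard_normal()
    resid = ar[years - 1961] + 0.05 * rng.standard_normal(len(years))
    out = dg.dw_resample(resid, years, n_iter=200, seed=6)
    assert out["fraction_nonsignificant"] < 0.5
    assert out["mean_dw"] < 1.5


def test_dw_per_species_table():
    rng = np.random.default_rng(7)
    n = 400
    years = rng.integers(1990, 2010, n)
    species = rng.choice(["A", "B"], n)
    out = dg.dw_resample_per_species(rng.standard_normal(n), years, species,
                                     n_iter=20, seed=8)
    assert set(out["species_id"]) == {"A", "B"}
    assert out["mean_p"].between(0, 1).all()


# ---------------------------------------------------------------------------
# spatial correlogram
# ---------------------------------------------------------------------------

def test_haversine_symmetric_and_scaled():
    d1 = dg.haversine_km(0, 0, 0, 1)
    d2 = dg.haversine_km(0, 1, 0, 0)
    assert d1 == pytest.approx(d2)
    assert d1 == pytest.approx(111.19, abs=0.5)  # one equatorial degree


def test_correlogram_null_covers_zero():
    rng = np.random.default_rng(9)
    n = 150
    lat, lon = rng.uniform(0, 20, n), rng.uniform(0, 20, n)
    out = dg.spline_correlogram(rng.standard_normal(n), lat, lon,
                                n_boot=99, seed=10)
    covered = ((out["envelope_low"] <= 0) & (out["envelope_high"] >= 0))
    assert covered.mean() >= 0.7


def test_correlogram_detects_planted_spatial_signal():
    rng = np.random.default_rng(11)
    n = 200
    lat, lon = rng.uniform(0, 20, n), rng.uniform(0, 20, n)
    centers = rng.uniform(0, 20, (5, 2))
    field = np.zeros(n)
    for cy, cx in centers:                      # smooth distance-decaying field
        d2 = (lat - cy) ** 2 + (lon - cx) ** 2
        field += np.exp(-d2 / 20.0)
    resid = field + 0.1 * rng.standard_normal(n)
    out = dg.spline_correlogram(resid, lat, lon, n_boot=49, seed=12)
    assert out["correlation"][0] > 0            # positive at shortest distances


def test_correlogram_degenerate_inputs():
    with pytest.raises(ConfigurationError):
        dg.spline_correlogram(np.random.default_rng(0).standard_normal(30),
                              np.full(30, 5.0), np.full(30, 5.0), seed=1)
    with pytest.raises(ConfigurationError):
        dg.spline_correlogram(np.zeros(5), np.arange(5.), np.arange(5.))


# ---------------------------------------------------------------------------
# influence and posterior predictive
# ---------------------------------------------------------------------------

def test_influence_screen_flags_planted_outlier(clean_fit):
    _, _, fit = clean_fit
    doctored = pm.ModelFit(fit.fixed, fit.variance_components,
                           fit.sigma2_resid, fit.gammas,
                           fit.residuals.copy(), fit.fitted, fit.ranef,
                           fit.loglik, fit.df, fit.n, 0, fit.species_order)
    doctored.residuals[17] = 10 * np.std(fit.residuals)
    out = dg.influence_screen(doctored, threshold=4.0)
    assert 17 in out["flagged"]
    assert dg.influence_screen(doctored, threshold=np.inf)["fraction"] == 0.0


def test_influence_low_rate_on_well_specified_model(clean_fit):
    _, _, fit = clean_fit
    assert dg.influence_screen(fit, threshold=4.0)["fraction"] < 0.01


def test_ppc_self_consistency_and_determinism(clean_fit):
    _, design, fit = clean_fit
    a = dg.posterior_predictive_check(fit, design, n_sim=150, seed=20)
    b = dg.posterior_predictive_check(fit, design, n_sim=150, seed=20)
    assert a == b
    assert a["mean_in_envelope"]
    assert a["decile_coverage"] >= 0.8
    with pytest.warns(UserWarning, match="degenerate"):
        dg.posterior_predictive_check(fit, design, n_sim=1, seed=21)


def test_refit_without_flagged_reports_beta_shifts(clean_fit):
    table, design, fit = clean_fit
    flagged = np.array([0, 5])         # drop two arbitrary rows
    from nichesize.phylo_mixed_model import ModelSpec, PhyloCovariance
    C = PhyloCovariance(design.species_order,
                        np.eye(len(design.species_order)))
    refit, shifts = dg.refit_without_flagged(
        table, fit, ModelSpec(), C, flagged,
        fit_kwargs={"vc_intervals": False})
    assert refit.n == fit.n - 2
    assert list(shifts.index) == fit.fixed["term"].tolist()
    # removing 2 of ~900 well-behaved rows barely moves the slope terms
    # (the intercept legitimately shifts here because the refit uses an
    # identity species covariance instead of the original tree)
    assert np.abs(shifts.drop("intercept").to_numpy()).max() < 0.05


def test_run_all_report_is_serializable(clean_fit):
    table, design, fit = clean_fit
    rep = dg.run_all(fit, design, table, seed=22, n_iter_dw=30, n_boot=19,
                     n_sim_ppc=40)
    text = rep.to_json()
    assert "dw_global" in text and "vif" in text
    assert 0 <= rep.dw_global["fraction_nonsignificant"] <= 1
    assert all(v >= 1 for v in rep.vif.values())
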