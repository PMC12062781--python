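import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nichesize import formats_io as fio
from nichesize import phylo_mixed_model as pm
from nichesize.errors import ConfigurationError


# ---------------------------------------------------------------------------
# phylogenetic correlation
# ---------------------------------------------------------------------------

def test_star_tree_gives_identity():
    tree = fio.parse_tree("(A:1,B:1,C:1,D:1);")
    C = pm.phylo_correlation(tree, ["A", "B", "C", "D"]).matrix
    np.testing.assert_allclose(C, np.eye(4), atol=1e-12)


def test_worked_three_taxon_tree():
    tree = fio.parse_tree("((A:1,B:1):1,C:2);")
    C = pm.phylo_correlation(tree, ["A", "B", "C"]).matrix
    assert C[0, 1] == pytest.approx(0.5)   # shared path 1 of depth 2
    assert C[0, 2] == pytest.approx(0.0)
    assert np.all(np.diag(C) == 1.0)


def test_unit_diagonal_on_random_trees():
    import random
    from dendropy.model import birthdeath

    for seed in range(10):
        t = birthdeath.birth_death_tree(1.0, 0.0, num_extant_tips=8,
                                        rng=random.Random(seed))
        tree = fio.PhyloTree(t)
        C = pm.phylo_correlation(tree, tree.tip_labels).matrix
        np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-12)
        assert np.linalg.eigvalsh(C).min() > -1e-8


def test_missing_tip_listed():
    tree = fio.parse_tree("((A:1,B:1):1,C:2);")
    with pytest.raises(ConfigurationError, match="Zz"):
        pm.phylo_correlation(tree, ["A", "Zz"])


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _toy_table(n=200, s=4, seed=0, missing_api_rows=0):
    rng = np.random.default_rng(seed)
    t = pd.DataFrame({
        "species_id": rng.choice([f"S{i}" for i in range(s)], n),
        "realm": rng.choice(["R1", "R2"], n),
        "site": rng.integers(0, 10, n),
        "tpi": rng.normal(size=n), "api": rng.normal(size=n),
        "alu": rng.normal(size=n), "ulu": rng.normal(size=n),
        "year": rng.normal(size=n),
    })
    for a, b in [("tpi", "api"), ("tpi", "alu"), ("tpi", "ulu")]:
        t[f"{a}_x_{b}"] = t[a] * t[b]
    t["log10_mass"] = rng.normal(size=n)
    if missing_api_rows:
        t.loc[t.index[:missing_api_rows], "api"] = np.nan
    return t


def _toy_C(s=4, seed=1):
    import random
    from dendropy.model import birthdeath

    t = birthdeath.birth_death_tree(1.0, 0.0, num_extant_tips=s,
                                    rng=random.Random(seed))
    tree = fio.PhyloTree(t)
    for leaf, name in zip(t.leaf_node_iter(), [f"S{i}" for i in range(s)]):
        leaf.taxon.label = name
    return pm.phylo_correlation(tree, sorted(tree.tip_labels))


def test_assemble_shapes_and_counts():
    t = _toy_table()
    design = pm.assemble(t, pm.ModelSpec(), _toy_C())
    assert design.X.shape == (200, 9)          # intercept + 8 terms
    species_block = [b for b in design.blocks if b.name == "species_iid"][0]
    assert species_block.size == 4
    assert {b.name for b in design.blocks} == {
        "realm", "site", "species_iid", "species_phylo",
        "slope_iid_tpi", "slope_phylo_tpi"}


def test_year_removed_sensitivity_design():
    t = _toy_table()
    design = pm.assemble(t, pm.ModelSpec(include_year=False), _toy_C())
    assert design.X.shape[1] == 8              # intercept + 7 terms
    assert "year" not in design.fixed_names


def test_missing_rows_dropped_with_count():
    t = _toy_table(missing_api_rows=7)
    design = pm.assemble(t, pm.ModelSpec(), _toy_C())
    assert design.n == 193 and design.n_dropped == 7


def test_collinear_design_reported():
    t = _toy_table()
    t["api"] = 2.0 * t["tpi"]
    t["tpi_x_api"] = t["tpi"] * t["api"]
    with pytest.raises(ConfigurationError, match="collinear"):
        pm.assemble(t, pm.ModelSpec(), _toy_C())


# ---------------------------------------------------------------------------
# likelihood and fitting
# ---------------------------------------------------------------------------

def _dense_sigma(design, sigma2, gammas):
    """Brute-force marginal covariance sigma2 (I + sum gamma Z G Z')."""
    n = design.n
    V = np.eye(n)
    Z = design.Z.toarray()
    for k, b in enumerate(design.blocks):
        Zk = Z[:, b.start:b.start + b.size]
        G = b.chol @ b.chol.T if b.kind == "phylo" else np.eye(b.size)
        V += gammas[k] * Zk @ G @ Zk.T
    return sigma2 * V


def test_loglik_matches_dense_multivariate_normal():
    t = _toy_table(n=45, s=4, seed=5)
    design = pm.assemble(t, pm.ModelSpec(), _toy_C())
    rng = np.random.default_rng(6)
    for _ in range(5):
        beta = rng.normal(size=design.X.shape[1])
        sigma2 = float(rng.uniform(0.3, 2.0))
        gammas = rng.uniform(0.05, 1.5, size=len(design.blocks))
        ll = pm.marginal_loglik(design, beta, sigma2, gammas)
        V = _dense_sigma(design, sigma2, gammas)
        oracle = stats.multivariate_normal.logpdf(
            design.y, mean=design.X @ beta, cov=V)
        assert ll == pytest.approx(oracle, abs=1e-6)


def test_zero_noise_interpolation_limit():
    t = _toy_table(n=300, s=4, seed=7)
    beta_true = np.array([0.5, -0.3, 0.2, 0.0, 0.1, 0.05, 0.0, 0.0, -0.1])
    design = pm.assemble(t, pm.ModelSpec(), _toy_C())
    design.y[:] = design.X @ beta_true          # exact linear response
    fit = pm.fit(design, vc_intervals=False)
    np.testing.assert_allclose(fit.fixed["estimate"].to_numpy(), beta_true,
                               atol=1e-6)


def test_iid_reduction_matches_generic_lmm_oracle():
    """With only a species intercept and C = I data, the fit reduces to a
    standard random-intercept LMM."""
    import statsmodels.api as sm

    rng = np.random.default_rng(8)
    n, s = 400, 8
    sp = rng.integers(0, s, n)
    x = rng.normal(size=(n, 2))
    b = 0.7 * rng.standard_normal(s)
    y = 1.0 + x @ [0.5, -0.25] + b[sp] + 0.6 * rng.standard_normal(n)
    t = _toy_table(n=n, s=s, seed=8)
    t["tpi"], t["api"] = x[:, 0], x[:, 1]
    t["species_id"] = [f"S{i}" for i in sp]
    t["log10_mass"] = y
    spec = pm.ModelSpec(random_intercepts=("species_iid",),
                        slope_predictors=())
    # restrict fixed effects to the two informative terms
    for c in ("alu", "ulu", "year", "tpi_x_api", "tpi_x_alu", "tpi_x_ulu"):
        t[c] = rng.normal(size=n) * 0  # drop from model below
    t = t.drop(columns=["alu", "ulu", "year", "tpi_x_api", "tpi_x_alu",
                        "tpi_x_ulu"])

    class TwoTermSpec(pm.ModelSpec):
        def fixed_effects(self):
            return ["tpi", "api"]

    design = pm.assemble(t, TwoTermSpec(random_intercepts=("species_iid",),
                                        slope_predictors=()), None)
    # plain REML (no nondegeneracy penalty) to match the oracle's criterion
    ours = pm.fit(design, vc_intervals=False, sd_penalty=0.0)
    oracle = sm.MixedLM(y, np.column_stack([np.ones(n), x]),
                        groups=sp).fit(reml=True)
    np.testing.assert_allclose(ours.fixed["estimate"].to_numpy(),
                               oracle.params[:3], atol=1e-4)


def test_fit_invariants_and_pd_range(clean_fit):
    _, _, fit = clean_fit
    f = fit.fixed
    assert (f["ci_low"] <= f["estimate"]).all()
    assert (f["estimate"] <= f["ci_high"]).all()
    assert ((f["pd"] >= 0.5) & (f["pd"] <= 1.0)).all()
    vc = fit.variance_components
    assert (vc["sigma2"] >= 0).all()
    assert fit.converged


def test_fit_recovers_strong_effects(clean_fit):
    """Effects without a random slope are recovered tightly on the tiny
    world; TPI itself is confounded with the common phylogenetic slope draw
    at 6 species, so only its interval behaviour is checked elsewhere."""
    table, design, fit = clean_fit
    f = fit.fixed.set_index("term")
    assert f.loc["api", "estimate"] > 0
    assert f.loc["api", "pd"] > 0.99
    assert f.loc["tpi_x_api", "estimate"] > 0
    # the TPI interval is honestly wide with 6 species and random slopes
    assert f.loc["tpi", "se"] > f.loc["api", "se"]


# ---------------------------------------------------------------------------
# partial R^2
# ---------------------------------------------------------------------------

def test_partial_r2_worked_and_degenerate(clean_fit):
    _, _, fit = clean_fit
    r2 = pm.partial_r2(fit)
    # independent correlation oracle on the same vectors
    obs = fit.fitted + fit.residuals
    oracle = np.corrcoef(obs, fit.fitted)[0, 1] ** 2
    assert r2 == pytest.approx(oracle, abs=1e-12)
    assert 0 < r2 <= 1

    perfect = _fake_fit(np.zeros(5), np.arange(5.0))
    assert pm.partial_r2(perfect) == pytest.approx(1.0)
    flat = _fake_fit(np.array([1., -1, 2, -2, 0]), np.ones(5))
    with pytest.warns(UserWarning, match="degenerate"):
        assert pm.partial_r2(flat) == 0.0


def _fake_fit(residuals, fitted):
    return pm.ModelFit(fixed=None, variance_components=None, sigma2_resid=1.0,
                       gammas=np.array([]), residuals=residuals,
                       fitted=fitted, ranef=np.array([]), loglik=0.0,
                       df=4.0, n=len(fitted), n_dropped=0, species_order=[])


def test_partial_r2_five_point_worked_set():
    obs = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    fitted = np.array([1.1, 1.9, 3.2, 3.8, 5.0])
    fake = _fake_fit(obs - fitted, fitted)
    r = np.corrcoef(obs, fitted)[0, 1] ** 2
    assert pm.partial_r2(fake) == pytest.approx(r, abs=1e-12)
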