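"""Gaussian phylogenetic mixed model (PGLMM).

The model for the z-scored body-size response y is

    y = X beta + sum_k Z_k b_k + e,      e ~ N(0, sigma^2 I)
    b_k ~ N(0, sigma_k^2 G_k)

with fixed effects X = [1, TPI, API, ALU, ULU, Year, TPI*API, TPI*ALU,
TPI*ULU], random intercepts for biogeographic realm, site, species (iid,
G = I) and species with phylogenetic structure (G = C, the Brownian-motion
correlation matrix from the tree), and a pair of uncorrelated random slopes
(iid species and phylogenetically correlated species) on a configurable
predictor set (default {TPI}).

Estimation is by restricted maximum likelihood (REML) profiled over the
residual variance and the fixed effects, optimizing the variance ratios
gamma_k = sigma_k^2 / sigma^2 on the log scale. The marginal covariance
V = sigma^2 (I + U U') with U = Z T (T the block square root of
blockdiag(gamma_k G_k)) is handled through the q x q capacitance matrix
S = I + U'U, so the cost per likelihood evaluation is O(q^3) with q the
total number of random-effect levels, never O(n^3).

Intervals and the probability of direction (pd) for fixed effects use a
Student-t approximation with a conservative between-cluster df
(n_species - 1) by default.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy import optimize, stats

from .errors import ConfigurationError, FormatError, NicheSizeError
from .formats_io import PhyloTree

logger = logging.getLogger(__name__)

DEFAULT_FIXED = ["tpi", "api", "alu", "ulu", "year",
                 "tpi_x_api", "tpi_x_alu", "tpi_x_ulu"]


class ConvergenceError(NicheSizeError):
    """The variance-component optimizer failed to converge."""


# ---------------------------------------------------------------------------
# Phylogenetic covariance
# ---------------------------------------------------------------------------

@dataclass
class PhyloCovariance:
    """Brownian-motion correlation among species.

    C[i, j] is the shared root-to-tip path length of species i and j divided
    by sqrt(depth_i * depth_j); the diagonal is exactly 1.
    """

    species: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        C = np.asarray(self.matrix, dtype=float)
        if not np.allclose(C, C.T, atol=1e-12):
            raise FormatError("phylo covariance must be symmetric")
        eigmin = float(np.linalg.eigvalsh(C).min())
        if eigmin < -1e-8:
            raise FormatError(
                f"phylo covariance not positive semidefinite (min eig {eigmin:.3g})")
        if eigmin < 1e-10:  # repair a numerically semidefinite matrix
            C = C + (1e-10 - eigmin) * np.eye(len(C))
            d = np.sqrt(np.diag(C))
            C = C / np.outer(d, d)
        np.fill_diagonal(C, 1.0)
        self.matrix = C

    def subset(self, species: list[str]) -> "PhyloCovariance":
        idx = {s: i for i, s in enumerate(self.species)}
        missing = [s for s in species if s not in idx]
        if missing:
            raise ConfigurationError(f"species not in tree: {missing}")
        sel = [idx[s] for s in species]
        return PhyloCovariance(list(species), self.matrix[np.ix_(sel, sel)])

    def cholesky(self) -> np.ndarray:
        return np.linalg.cholesky(self.matrix + 1e-10 * np.eye(len(self.matrix)))


def phylo_correlation(tree: PhyloTree, species: list[str]) -> PhyloCovariance:
    """Brownian correlation matrix for ``species``, pruned from the tree."""
    tips = set(tree.tip_labels)
    missing = [s for s in species if s not in tips]
    if missing:
        raise ConfigurationError(f"species missing from tree: {missing}")
    depths = tree.depths()
    import dendropy

    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.tree.taxon_namespace}
    s = len(species)
    C = np.eye(s)
    for i in range(s):
        for j in range(i + 1, s):
            d = pdm.patristic_distance(taxa[species[i]], taxa[species[j]])
            shared = 0.5 * (depths[species[i]] + depths[species[j]] - d)
            denom = np.sqrt(depths[species[i]] * depths[species[j]])
            C[i, j] = C[j, i] = shared / denom if denom > 0 else 0.0
    return PhyloCovariance(list(species), C)


# ---------------------------------------------------------------------------
# Model specification and assembly
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Which response, fixed effects, and random structure to fit."""

    response: str = "log10_mass"
    include_year: bool = True
    random_intercepts: tuple = ("realm", "site", "species_iid", "species_phylo")
    slope_predictors: tuple = ("tpi",)  # each gets an iid + a phylo term

    def fixed_effects(self) -> list[str]:
        fx = [t for t in DEFAULT_FIXED if self.include_year or t != "year"]
        return fx

    def validate(self):
        bad = set(self.slope_predictors) - set(self.fixed_effects())
        if bad:
            raise ConfigurationError(
                f"slope predictors not among fixed effects: {sorted(bad)}")


@dataclass
class RandomBlock:
    name: str
    kind: str            # 'iid' or 'phylo'
    start: int           # first column in Z
    size: int
    chol: np.ndarray | None = None   # lower Cholesky of G for phylo blocks
    labels: list | None = None


@dataclass
class Design:
    y: np.ndarray
    X: np.ndarray
    fixed_names: list[str]
    Z: sp.csr_matrix
    blocks: list[RandomBlock]
    species_order: list[str]
    n_dropped: int
    index: np.ndarray  # row labels of retained rows in the source table

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def q(self) -> int:
        return self.Z.shape[1]


def assemble(table: pd.DataFrame, spec: ModelSpec,
             C: PhyloCovariance | None = None) -> Design:
    """Build fixed/random design structures from a covariate-complete table.

    Rows with a missing value in any modelled column are dropped (counted).
    """
    spec.validate()
    fixed = spec.fixed_effects()
    needs_phylo = ("species_phylo" in spec.random_intercepts
                   or len(spec.slope_predictors) > 0)
    if needs_phylo and C is None:
        raise ConfigurationError("a phylogenetic covariance is required")

    cols = [spec.response] + fixed
    cat_cols = [c for c in ("realm", "site", "species_id") if c in table.columns]
    sub = table[cols + cat_cols].copy()
    ok = sub[cols].notna().all(axis=1)
    for c in cat_cols:
        ok &= sub[c].notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("assemble: dropped %d rows with missing modelled values",
                    n_dropped)
    sub = sub[ok]
    n = len(sub)
    if n == 0:
        raise ConfigurationError("no complete rows to model")

    y = sub[spec.response].to_numpy(dtype=float)
    X = np.column_stack([np.ones(n)] +
                        [sub[c].to_numpy(dtype=float) for c in fixed])
    names = ["intercept"] + fixed
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, R, piv = sla.qr(X, mode="economic", pivoting=True)
        tol = abs(R[0, 0]) * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(X.shape[1]) if abs(R[i, i]) < tol]
        raise ConfigurationError(f"rank-deficient fixed design; collinear "
                                 f"terms include {bad}")

    species = sorted(sub["species_id"].unique())
    Csub = C.subset(species) if C is not None else None
    Lc = Csub.cholesky() if Csub is not None else None
    sp_code = sub["species_id"].map({s: i for i, s in enumerate(species)}).to_numpy()

    blocks: list[RandomBlock] = []
    zcols, zrows, zvals = [], [], []
    start = 0

    def add_block(name, kind, codes, size, values=None, labels=None):
        nonlocal start
        zrows.append(np.arange(n))
        zcols.append(codes + start)
        zvals.append(np.ones(n) if values is None else values)
        blocks.append(RandomBlock(name, kind, start, size,
                                  Lc if kind == "phylo" else None, labels))
        start += size

    for term in spec.random_intercepts:
        col = {"realm": "realm", "site": "site"}.get(term)
        if col is not None and col not in sub.columns:
            raise ConfigurationError(f"random intercept '{term}' needs a "
                                     f"'{col}' column")
        if term == "realm":
            labels, codes = np.unique(sub["realm"].astype(str), return_inverse=True)
            add_block("realm", "iid", codes, len(labels), labels=list(labels))
        elif term == "site":
            labels, codes = np.unique(sub["site"].to_numpy(), return_inverse=True)
            add_block("site", "iid", codes, len(labels), labels=list(labels))
        elif term == "species_iid":
            add_block("species_iid", "iid", sp_code, len(species), labels=species)
        elif term == "species_phylo":
            add_block("species_phylo", "phylo", sp_code, len(species),
                      labels=species)
        else:
            raise ConfigurationError(f"unknown random intercept '{term}'")
    for pred in spec.slope_predictors:
        v = sub[pred].to_numpy(dtype=float)
        add_block(f"slope_iid_{pred}", "iid", sp_code, len(species),
                  values=v, labels=species)
        add_block(f"slope_phylo_{pred}", "phylo", sp_code, len(species),
                  values=v, labels=species)

    Z = sp.csr_matrix(
        (np.concatenate(zvals), (np.concatenate(zrows), np.concatenate(zcols))),
        shape=(n, start))
    return Design(y, X, names, Z, blocks, species, n_dropped,
                  sub.index.to_numpy())


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------

def _block_sqrt(design: Design, gammas: np.ndarray) -> np.ndarray:
    """Dense T with T T' = blockdiag(gamma_k G_k)."""
    q = design.q
    T = np.zeros((q, q))
    for k, b in enumerate(design.blocks):
        s = slice(b.start, b.start + b.size)
        g = np.sqrt(max(gammas[k], 0.0))
        if b.kind == "phylo":
            T[s, s] = g * b.chol
        else:
            T[s, s] = g * np.eye(b.size)
    return T


class _Profiler:
    """Caches cross-products and evaluates the profiled REML criterion."""

    def __init__(self, design: Design):
        self.d = design
        Z, X, y = design.Z, design.X, design.y
        self.ZtZ = (Z.T @ Z).toarray()
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.n, self.p = X.shape

    def core(self, gammas: np.ndarray):
        T = _block_sqrt(self.d, gammas)
        S = T.T @ self.ZtZ @ T
        S[np.diag_indices_from(S)] += 1.0
        cho = sla.cho_factor(S, lower=True)
        logdetS = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        TZX = T.T @ self.ZtX
        Tzy = T.T @ self.Zty
        SiTZX = sla.cho_solve(cho, TZX)
        SiTzy = sla.cho_solve(cho, Tzy)
        XQX = self.XtX - TZX.T @ SiTZX
        XQy = self.Xty - TZX.T @ SiTzy
        yQy = self.yty - float(Tzy @ SiTzy)
        beta = sla.solve(XQX, XQy, assume_a="pos")
        quad = max(yQy - float(beta @ XQy), 1e-300)
        return T, cho, logdetS, XQX, beta, quad

    def reml(self, theta: np.ndarray, penalty: float = 0.0) -> float:
        """-2 restricted log-likelihood, profiled over beta and sigma^2.

        ``penalty`` > 0 adds a weakly-informative gamma(2, ~0) prior on each
        random-effect standard deviation (a ``- 2 penalty log sigma_k``
        term). This keeps weakly-identified variance components off the zero
        boundary so fixed-effect standard errors retain the corresponding
        uncertainty — the deterministic analogue of the weak variance priors
        a Bayesian fit would use.
        """
        try:
            _, _, logdetS, XQX, _, quad = self.core(np.exp(theta))
        except (np.linalg.LinAlgError, ValueError):
            return 1e12
        nm = self.n - self.p
        sign, logdetXQX = np.linalg.slogdet(XQX)
        if sign <= 0:
            return 1e12
        out = nm * np.log(quad / nm) + logdetS + logdetXQX + nm
        if penalty:
            sigma2 = quad / nm
            # log sigma_k = (theta_k + log sigma^2) / 2
            out -= penalty * (np.sum(theta) + len(theta) * np.log(sigma2))
        return out


def marginal_loglik(design: Design, beta: np.ndarray, sigma2: float,
                    gammas: np.ndarray) -> float:
    """Exact marginal Gaussian log-likelihood at given parameters.

    Evaluates N(y | X beta, sigma2 (I + Z G Z')) through the capacitance
    matrix; agrees with a dense multivariate-normal evaluation.
    """
    T = _block_sqrt(design, np.asarray(gammas, dtype=float))
    Z = design.Z
    S = T.T @ (Z.T @ Z).toarray() @ T
    S[np.diag_indices_from(S)] += 1.0
    cho = sla.cho_factor(S, lower=True)
    logdetS = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    r = design.y - design.X @ beta
    u = T.T @ (Z.T @ r)
    quad = (float(r @ r) - float(u @ sla.cho_solve(cho, u))) / sigma2
    n = design.n
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdetS + quad)


# ---------------------------------------------------------------------------
# Fit result
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """REML estimates with t-approximation intervals and pd."""

    fixed: pd.DataFrame          # term, estimate, se, ci_low, ci_high, pd
    variance_components: pd.DataFrame  # name, sigma2, ci_low, ci_high
    sigma2_resid: float
    gammas: np.ndarray
    residuals: np.ndarray        # conditional (random effects included)
    fitted: np.ndarray
    ranef: np.ndarray
    loglik: float
    df: float
    n: int
    n_dropped: int
    species_order: list[str]
    method: str = "reml"
    pd_method: str = "t-approximation"
    converged: bool = True
    index: np.ndarray | None = None

    def to_json(self, path=None) -> str:
        obj = {
            "method": self.method,
            "pd_method": self.pd_method,
            "n": int(self.n),
            "n_dropped": int(self.n_dropped),
            "df": float(self.df),
            "loglik": float(self.loglik),
            "sigma2_resid": float(self.sigma2_resid),
            "fixed": self.fixed.to_dict(orient="records"),
            "variance_components":
                self.variance_components.to_dict(orient="records"),
        }
        text = json.dumps(obj, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def fit(design: Design, theta0: float = np.log(0.1),
        df: float | None = None, vc_intervals: bool = True,
        sd_penalty: float = 1.0, maxiter: int = 400) -> ModelFit:
    """REML fit of the assembled model.

    ``df`` is the Student-t degrees of freedom for fixed-effect intervals and
    pd; default n_species - 1 (between-cluster containment), falling back to
    n - p when no species block exists. ``sd_penalty`` is the weight of the
    weak gamma prior on random-effect standard deviations (1 = the standard
    ``+ log sigma_k`` nondegeneracy penalty; 0 = plain REML).
    """
    prof = _Profiler(design)
    k = len(design.blocks)
    x0 = np.full(k, theta0)
    obj = lambda th: prof.reml(th, penalty=sd_penalty)
    res = optimize.minimize(obj, x0, method="L-BFGS-B",
                            bounds=[(-12.0, 8.0)] * k,
                            options={"maxiter": maxiter, "ftol": 1e-10})
    if not res.success:
        res2 = optimize.minimize(obj, res.x, method="Nelder-Mead",
                                 options={"maxiter": 4000, "fatol": 1e-8,
                                          "xatol": 1e-6})
        if res2.fun <= res.fun:
            res = res2
        if not res.success and not np.isfinite(res.fun):
            raise ConvergenceError(
                f"REML optimizer failed: {res.message}; theta={res.x}")
    theta = res.x
    gammas = np.exp(theta)

    T, cho, logdetS, XQX, beta, quad = prof.core(gammas)
    n, p = prof.n, prof.p
    sigma2 = quad / (n - p)
    cov_beta = sigma2 * np.linalg.inv(XQX)
    se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))

    if df is None:
        n_sp = len(design.species_order)
        df = float(n_sp - 1) if n_sp > 1 else float(n - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, np.abs(beta) / se, np.inf)
    tcrit = stats.t.ppf(0.975, df)
    pd_val = stats.t.cdf(tstat, df)
    fixed = pd.DataFrame({
        "term": design.fixed_names,
        "estimate": beta,
        "se": se,
        "ci_low": beta - tcrit * se,
        "ci_high": beta + tcrit * se,
        "pd": pd_val,
    })

    # variance components with delta-method intervals on the log scale
    names = [b.name for b in design.blocks]
    vc = gammas * sigma2
    lo = np.full(k, np.nan)
    hi = np.full(k, np.nan)
    if vc_intervals:
        try:
            H = _numerical_hessian(obj, theta)
            cov_theta = 2.0 * np.linalg.pinv(H)
            sd_theta = np.sqrt(np.maximum(np.diag(cov_theta), 0.0))
            lo = vc * np.exp(-1.96 * sd_theta)
            hi = vc * np.exp(1.96 * sd_theta)
        except Exception as exc:  # singular Hessian at a boundary
            warnings.warn(f"variance-component intervals unavailable: {exc}")
    vcomp = pd.DataFrame({"name": names, "sigma2": vc,
                          "ci_low": lo, "ci_high": hi})
    vcomp.loc[len(vcomp)] = ["residual", sigma2, np.nan, np.nan]

    # BLUPs, fitted values, conditional residuals
    r = design.y - design.X @ beta
    u = T.T @ (design.Z.T @ r)
    b = T @ sla.cho_solve(cho, u)
    fitted = design.X @ beta + design.Z @ b
    resid = design.y - fitted

    ll = marginal_loglik(design, beta, quad / n, gammas)
    return ModelFit(fixed, vcomp, float(sigma2), gammas, resid, fitted, b,
                    float(ll), float(df), n, design.n_dropped,
                    design.species_order, converged=bool(res.success),
                    index=design.index)


def _numerical_hessian(f, x, h: float = 1e-4) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (f(x + ei + ej) - f(x + ei - ej)
                                     - f(x - ei + ej) + f(x - ei - ej)) / (4 * h**2)
    return H


def partial_r2(fit_result: ModelFit, y: np.ndarray | None = None,
               definition: str = "conditional") -> float:
    """Squared Pearson correlation of observed response and fitted values.

    'Conditional': fitted values include the random effects. Not invariant to
    affine transforms of the fitted values (plain correlation definition).
    """
    if definition != "conditional":
        raise ConfigurationError(f"unknown partial R2 definition '{definition}'")
    obs = fit_result.fitted + fit_result.residuals if y is None else np.asarray(y)
    fitted = fit_result.fitted
    if np.std(fitted) == 0 or np.std(obs) == 0:
        warnings.warn("degenerate fitted values; partial R2 reported as 0")
        return 0.0
    return float(np.corrcoef(obs, fitted)[0, 1] ** 2)
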