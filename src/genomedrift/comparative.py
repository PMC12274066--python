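"""Phylogenetically controlled association tests.

Under Brownian motion on a tree, tip trait vectors are multivariate normal
with covariance C (shared root-to-MRCA path lengths) times a trait
covariance R.  Two equivalent routes to phylogenetically corrected
association are implemented:

* Felsenstein independent contrasts, regressed through the origin — the
  classic comparative test, whose slope equals the GLS slope under C; and
* a direct multivariate-Brownian fit — REML-style estimates
  mu_hat = (1'C^-1 1)^-1 1'C^-1 Y and
  R_hat = (Y - 1 mu_hat)' C^-1 (Y - 1 mu_hat) / (n - 1),
  with pairwise significance read off a seeded parametric bootstrap under
  the no-correlation null (support > 0.9 or < 0.1 flags a pair, mirroring
  the posterior-probability reading convention of Bayesian coevolution
  models).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import Phylogeny, PipelineConfig, SpeciesTraitTable, logger


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    """Slope/intercept with adjusted R^2 and two-sided p-value."""

    slope: float
    intercept: float | None
    adj_r2: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need n >= 3")
        if self.adj_r2 > 1 + 1e-12:
            raise ValueError("adjusted R^2 cannot exceed 1")


@dataclass
class ContrastSet:
    """Standardized independent contrasts for one trait."""

    trait: str
    node_labels: list[str]
    contrasts: np.ndarray
    variances: np.ndarray

    @property
    def n_contrasts(self) -> int:
        return len(self.contrasts)


@dataclass
class BrownianFit:
    """Estimated Brownian trait covariance on a tree."""

    trait_names: list[str]
    R: np.ndarray
    mu: np.ndarray
    log_likelihood: float
    n: int
    support: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def correlation(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.R))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = self.R / np.outer(d, d)
        return np.clip(corr, -1.0, 1.0)


# ---------------------------------------------------------------------------
# Tree covariance and contrasts
# ---------------------------------------------------------------------------


def phylo_covariance(tree: Phylogeny) -> pd.DataFrame:
    """Brownian tip covariance: C[i, j] = root-to-MRCA(i, j) path length."""
    tips = tree.tip_names
    index = {t: k for k, t in enumerate(tips)}
    n = len(tips)
    C = np.zeros((n, n))

    def walk(node, depth: float) -> list[int]:
        depth += node.length
        if node.is_tip:
            k = index[node.name]
            C[k, k] = depth
            return [k]
        below = [walk(child, depth) for child in node.children]
        # tips split at this node share exactly the node's own depth
        for a in range(len(below)):
            for b in range(a + 1, len(below)):
                for i in below[a]:
                    for j in below[b]:
                        C[i, j] = C[j, i] = depth
        return [i for grp in below for i in grp]

    walk(tree.root, -tree.root.length)
    return pd.DataFrame(C, index=tips, columns=tips)


def compute_contrasts(tree: Phylogeny, values: pd.Series,
                      trait: str | None = None) -> ContrastSet:
    """Felsenstein's standardized contrasts.

    Species with missing values are pruned first; polytomies are resolved
    with zero-length branches (warned).  At each internal node with
    children (i, j): c = (x_i - x_j) / sqrt(v_i + v_j), the ancestral value
    is the precision-weighted average, and the node's effective branch
    length is extended by v_i v_j / (v_i + v_j).
    """
    values = values.dropna()
    name = trait or (values.name if values.name else "trait")
    keep = [t for t in tree.tip_names if t in values.index]
    if len(keep) < 2:
        raise ValueError("need at least 2 tips with trait values")
    work = tree.prune_to(keep) if len(keep) < tree.n_tips else tree
    work = work.resolve_polytomies()

    contrasts, variances, labels = [], [], []
    state: dict[int, tuple[float, float]] = {}  # node id -> (value, edge var)
    counter = 0
    for node in work.postorder():
        if node.is_tip:
            state[id(node)] = (float(values[node.name]), node.length)
            continue
        (xi, vi), (xj, vj) = (state[id(c)] for c in node.children)
        total = vi + vj
        if total <= 0:
            if abs(xi - xj) > 1e-12:
                raise ZeroDivisionError(
                    "zero total branch variance with differing tip values")
            contrast = 0.0
            total = np.inf
        else:
            contrast = (xi - xj) / np.sqrt(total)
        counter += 1
        contrasts.append(contrast)
        variances.append(vi + vj if np.isfinite(total) else 0.0)
        labels.append(node.name or f"node{counter}")
        if np.isfinite(total):
            anc = (xi / vi + xj / vj) / (1 / vi + 1 / vj) \
                if vi > 0 and vj > 0 else (xi if vj > 0 else xj)
            extra = vi * vj / total
        else:
            anc, extra = xi, 0.0
        state[id(node)] = (anc, node.length + extra)
    return ContrastSet(trait=name, node_labels=labels,
                       contrasts=np.array(contrasts),
                       variances=np.array(variances))


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------


def pic_regression(contrasts_x: ContrastSet | np.ndarray,
                   contrasts_y: ContrastSet | np.ndarray) -> RegressionResult:
    """Through-origin regression of y-contrasts on x-contrasts.

    slope = sum(cx*cy)/sum(cx^2); the p-value is two-sided from the t
    statistic with n - 1 degrees of freedom (no intercept).
    """
    cx = np.asarray(contrasts_x.contrasts
                    if isinstance(contrasts_x, ContrastSet) else contrasts_x,
                    dtype=float)
    cy = np.asarray(contrasts_y.contrasts
                    if isinstance(contrasts_y, ContrastSet) else contrasts_y,
                    dtype=float)
    if len(cx) != len(cy):
        raise ValueError("contrast sets differ in length")
    n = len(cx)
    if n < 3:
        raise ValueError("need at least 3 contrasts")
    sxx = float(cx @ cx)
    if sxx == 0:
        raise ZeroDivisionError("all x contrasts are zero")
    res = sm.OLS(cy, cx[:, None]).fit()
    return RegressionResult(slope=float(res.params[0]), intercept=None,
                            adj_r2=float(res.rsquared_adj),
                            p_value=float(res.pvalues[0]), n=n)


def ols_regression(x: np.ndarray, y: np.ndarray, log_x: bool = False,
                   log_y: bool = False) -> RegressionResult:
    """Ordinary least squares with optional natural-log transforms."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("need at least 3 complete observations")
    if log_x:
        if np.any(x <= 0):
            raise ValueError("non-positive x under log transform")
        x = np.log(x)
    if log_y:
        if np.any(y <= 0):
            raise ValueError("non-positive y under log transform")
        y = np.log(y)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(slope=float(res.params[1]),
                            intercept=float(res.params[0]),
                            adj_r2=float(res.rsquared_adj),
                            p_value=float(res.pvalues[1]), n=len(x))


def gls_slope(tree: Phylogeny, x: pd.Series, y: pd.Series) -> float:
    """Generalized-least-squares slope of y on x under the Brownian tip
    covariance; the independent-oracle counterpart of pic_regression."""
    common = [t for t in tree.tip_names
              if t in x.index and t in y.index
              and np.isfinite(x[t]) and np.isfinite(y[t])]
    C = phylo_covariance(tree.prune_to(common)
                         if len(common) < tree.n_tips else tree)
    Ci = np.linalg.inv(C.loc[common, common].to_numpy())
    one = np.ones(len(common))
    X = np.column_stack([one, x[common].to_numpy(dtype=float)])
    Y = y[common].to_numpy(dtype=float)
    beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ Y)
    return float(beta[1])


# ---------------------------------------------------------------------------
# Multivariate Brownian fit and bootstrap support
# ---------------------------------------------------------------------------


def fit_brownian_multivariate(tree: Phylogeny, traits: pd.DataFrame,
                              ) -> BrownianFit:
    """REML-style multivariate Brownian fit on complete cases.

    Estimates the root state mu and the per-unit-branch-length trait
    covariance R from the tip data, with the tree covariance C fixed by the
    phylogeny.
    """
    traits = traits.dropna()
    names = list(traits.columns)
    common = [t for t in tree.tip_names if t in traits.index]
    n, p = len(common), len(names)
    if n < p + 1:
        raise ValueError("need n >= p + 1 complete species")
    if n < p + 2:
        logger.warning("fit_brownian_multivariate: n=%d barely exceeds "
                       "p=%d; estimates will be unstable", n, p)
    sub = tree.prune_to(common) if len(common) < tree.n_tips else tree
    C = phylo_covariance(sub).loc[common, common].to_numpy()
    Y = traits.loc[common, names].to_numpy(dtype=float)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular tree covariance (duplicate zero-length tips?)") from exc
    one = np.ones(n)
    Ci_one = np.linalg.solve(C, one)
    denom = float(one @ Ci_one)
    mu = (Ci_one @ Y) / denom
    Z = np.linalg.solve(L, Y - mu)
    R = (Z.T @ Z) / (n - 1)
    # Gaussian log-likelihood at (mu, R) with ML normalization n
    sign, logdet_C = np.linalg.slogdet(C)
    Rml = (Z.T @ Z) / n
    sign_r, logdet_R = np.linalg.slogdet(np.atleast_2d(Rml))
    if sign_r <= 0:
        loglik = -np.inf
    else:
        loglik = -0.5 * (n * p * np.log(2 * np.pi) + p * logdet_C
                         + n * logdet_R + n * p)
    return BrownianFit(trait_names=names, R=R, mu=mu,
                       log_likelihood=float(loglik), n=n)


def bootstrap_support(tree: Phylogeny, traits: pd.DataFrame,
                      n_reps: int = 1000, seed: int = 0,
                      fit: BrownianFit | None = None,
                      ) -> BrownianFit:
    """Parametric-bootstrap support for each trait-pair correlation.

    For a pair (a, b), data are re-simulated under the fitted R with the
    (a, b) covariance zeroed; support is the fraction of null bootstrap
    correlations lying below the observed one.  Support > 0.9 flags a
    positive association, < 0.1 a negative one (same reading convention as
    posterior probabilities in Bayesian coevolution models).
    """
    if n_reps < 100:
        logger.warning("bootstrap_support: n_reps=%d is small", n_reps)
    fit = fit or fit_brownian_multivariate(tree, traits)
    traits = traits.dropna()
    common = [t for t in tree.tip_names if t in traits.index]
    sub = tree.prune_to(common) if len(common) < tree.n_tips else tree
    C = phylo_covariance(sub).loc[common, common].to_numpy()
    Lc = np.linalg.cholesky(C)
    one = np.ones(len(common))
    Ci_one = np.linalg.solve(C, one)
    denom = float(one @ Ci_one)
    rng = np.random.default_rng(seed)
    names = fit.trait_names
    obs_corr = fit.correlation
    n, p = len(common), len(names)
    support = {}
    for a in range(p):
        for b in range(a + 1, p):
            R0 = fit.R.copy()
            R0[a, b] = R0[b, a] = 0.0
            w, v = np.linalg.eigh(R0)
            half = v * np.sqrt(np.clip(w, 0.0, None))
            count_below = 0
            for _ in range(n_reps):
                E = rng.standard_normal((n, p))
                Ysim = fit.mu + Lc @ E @ half.T
                mu_sim = (Ci_one @ Ysim) / denom
                Z = np.linalg.solve(Lc, Ysim - mu_sim)
                Rb = (Z.T @ Z) / (n - 1)
                db = np.sqrt(Rb[a, a] * Rb[b, b])
                corr_b = Rb[a, b] / db if db > 0 else 0.0
                if corr_b < obs_corr[a, b]:
                    count_below += 1
            support[(names[a], names[b])] = count_below / n_reps
    fit.support = support
    return fit


# ---------------------------------------------------------------------------
# Duplication screen
# ---------------------------------------------------------------------------


def duplication_screen(table: SpeciesTraitTable,
                       cfg: PipelineConfig | None = None,
                       ) -> tuple[SpeciesTraitTable, SpeciesTraitTable]:
    """(full, reduced) species sets; the reduced set drops species with
    BUSCO duplication strictly above ``duplication_max`` percent, so
    analyses can be run with and without likely whole-genome duplicates."""
    cfg = cfg or PipelineConfig()
    df = table.df
    if "busco_duplicated" not in df.columns:
        raise KeyError("duplication_screen requires 'busco_duplicated'")
    reduced = df[~(df["busco_duplicated"] > cfg.duplication_max)].copy()
    return table, SpeciesTraitTable(reduced)
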