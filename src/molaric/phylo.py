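"""Phylogenetic comparative methods under Brownian motion.

Provides the Brownian-motion (BM) trait covariance implied by a rooted
tree with branch lengths, phylogenetic generalized least squares (PGLS)
regression against that covariance, ordinary least squares for the
non-phylogenetic baseline, Blomberg's K statistic of phylogenetic signal
with a tip-permutation test, maximum-likelihood ancestral state
estimates for a continuous character, and BM trait simulation.

Under BM with rate sigma^2, tip traits are jointly Gaussian with
covariance sigma^2 * C where C[i, j] is the shared root-to-MRCA path
length of tips i and j.  PGLS fits y = Xb + e with Cov(e) = sigma^2 C,
i.e. generalized least squares after whitening both sides by the
Cholesky factor of C; with C = I it reduces exactly to OLS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .io_tables import PhyloTree, ValidationError


@dataclass(frozen=True)
class BMCovariance:
    """Brownian-motion tip covariance structure (rate factored out).

    ``C[i][j]`` is the root-to-MRCA path length of tips ``labels[i]``
    and ``labels[j]``; the diagonal holds root-to-tip distances.
    """

    labels: tuple[str, ...]
    C: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1] or C.shape[0] != len(self.labels):
            raise ValidationError("covariance matrix shape does not match labels")
        if not np.allclose(C, C.T, atol=1e-12):
            raise ValidationError("covariance matrix must be symmetric")
        object.__setattr__(self, "C", C)

    @property
    def n(self) -> int:
        return len(self.labels)

    def reordered(self, labels) -> "BMCovariance":
        idx = [list(self.labels).index(l) for l in labels]
        return BMCovariance(tuple(labels), self.C[np.ix_(idx, idx)])


@dataclass(frozen=True)
class RegressionResult:
    """Simple linear regression result (one predictor plus intercept)."""

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    ci95_slope: tuple[float, float]
    ci95_intercept: tuple[float, float]
    r2: float
    sigma2: float
    method: str
    n: int
    df: int

    def __post_init__(self) -> None:
        if self.ci95_slope[0] > self.ci95_slope[1]:
            raise ValidationError("slope CI endpoints out of order")
        if self.ci95_intercept[0] > self.ci95_intercept[1]:
            raise ValidationError("intercept CI endpoints out of order")


def bm_covariance(tree: PhyloTree, labels=None) -> BMCovariance:
    """Brownian-motion covariance structure of the tip traits of ``tree``."""
    labs, C = tree.mrca_depth_matrix(labels)
    return BMCovariance(tuple(labs), C)


def _align(x, y, cov: BMCovariance | np.ndarray | None):
    """Align trait vectors (arrays or label-indexed Series) with C."""
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        if isinstance(cov, BMCovariance):
            labels = list(cov.labels)
            x = x.reindex(labels)
            y = y.reindex(labels)
            if x.isna().any() or y.isna().any():
                missing = sorted(set(labels) - set(x.dropna().index) | set(labels) - set(y.dropna().index))
                raise ValidationError(f"trait missing for tips: {missing}")
        x = x.to_numpy(dtype=float)
        y = y.to_numpy(dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and of equal length")
    C = cov.C if isinstance(cov, BMCovariance) else cov
    if C is not None:
        C = np.asarray(C, dtype=float)
        if C.shape != (x.size, x.size):
            raise ValidationError("covariance matrix does not match data length")
    return x, y, C


def _summarize_gls(x, y, beta, cov_beta, rss_w, tss_w, n, method) -> RegressionResult:
    df = n - 2
    sigma2 = rss_w / df if df > 0 else np.nan
    se = np.sqrt(np.diag(cov_beta))
    tcrit = stats.t.ppf(0.975, df)
    r2 = 1.0 - rss_w / tss_w if tss_w > 0 else 1.0
    r2 = float(min(max(r2, 0.0), 1.0))
    return RegressionResult(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        se_slope=float(se[1]),
        se_intercept=float(se[0]),
        ci95_slope=(float(beta[1] - tcrit * se[1]), float(beta[1] + tcrit * se[1])),
        ci95_intercept=(float(beta[0] - tcrit * se[0]), float(beta[0] + tcrit * se[0])),
        r2=r2,
        sigma2=float(sigma2),
        method=method,
        n=int(n),
        df=int(df),
    )


def pgls_fit(x, y, cov: BMCovariance | np.ndarray) -> RegressionResult:
    """Phylogenetic generalized least squares of ``y`` on ``x``.

    Residual covariance is proportional to the BM matrix ``C`` (Pagel's
    lambda fixed at 1).  Coefficients are (X'C^-1X)^-1 X'C^-1 y with
    X = [1, x]; the residual variance uses n-2 degrees of freedom; 95%
    confidence intervals use Student's t.  R^2 is computed on the
    whitened (C^-1/2-transformed) model, against the whitened
    intercept-only fit, so it stays in [0, 1].

    Estimates are invariant to rescaling C by a positive constant.
    Solves use a Cholesky factorization of C, never an explicit inverse.
    """
    x, y, C = _align(x, y, cov)
    n = x.size
    if n < 3:
        raise ValidationError(f"PGLS needs >= 3 observations, got {n}")
    if np.ptp(x) == 0:
        raise ValidationError("collinear design: predictor is constant")
    try:
        L = linalg.cholesky(C, lower=True)
    except linalg.LinAlgError as exc:
        raise ValidationError("covariance matrix is not positive definite") from exc
    X = np.column_stack([np.ones(n), x])
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid_w = yw - Xw @ beta
    rss_w = float(resid_w @ resid_w)
    # whitened intercept-only (phylogenetic-mean) model for the R^2 baseline
    ones_w = Xw[:, 0]
    mu = float(ones_w @ yw) / float(ones_w @ ones_w)
    tss_w = float(np.sum((yw - mu * ones_w) ** 2))
    df = n - 2
    sigma2 = rss_w / df
    XtX = Xw.T @ Xw
    cov_beta = sigma2 * np.linalg.inv(XtX)
    return _summarize_gls(x, y, beta, cov_beta, rss_w, tss_w, n, "PGLS")


def ols_fit(x, y) -> RegressionResult:
    """Ordinary least squares of ``y`` on ``x`` via the normal equations.

    Implemented independently of :func:`pgls_fit` (no whitening path) so
    the PGLS(identity) == OLS equivalence is a genuine cross-check.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValidationError(f"OLS needs >= 3 observations, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValidationError("collinear design: predictor is constant")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - intercept - slope * x
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    df = n - 2
    sigma2 = rss / df
    se_slope = np.sqrt(sigma2 / sxx)
    se_intercept = np.sqrt(sigma2 * (1.0 / n + x.mean() ** 2 / sxx))
    beta = np.array([intercept, slope])
    cov_beta = np.diag([se_intercept**2, se_slope**2])
    return _summarize_gls(x, y, beta, cov_beta, rss, tss, n, "OLS")


# ---------------------------------------------------------------------------
# Phylogenetic signal


def _phylo_mean_and_resid(y: np.ndarray, C: np.ndarray):
    """GLS grand mean a_hat = (1'C^-1 1)^-1 1'C^-1 y and the
    phylogenetically corrected residual sum (y-a)'C^-1(y-a)."""
    L = linalg.cholesky(C, lower=True)
    ones_w = linalg.solve_triangular(L, np.ones(y.size), lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    denom = float(ones_w @ ones_w)
    a_hat = float(ones_w @ yw) / denom
    mse_num = float(np.sum((yw - a_hat * ones_w) ** 2))
    return a_hat, mse_num, denom


def blomberg_k(tree: PhyloTree, trait) -> float:
    """Blomberg's K statistic of phylogenetic signal.

    K compares the observed ratio of the tip variance around the
    phylogenetic (GLS) mean to the phylogenetically corrected residual
    variance, against the ratio expected under Brownian motion on the
    supplied tree:

        K = [sum_i (y_i - a)^2 / (y - a)'C^-1(y - a)]
            / [(tr C - n / (1'C^-1 1)) / (n - 1)]

    K = 1 is the BM expectation; K > 1 indicates stronger clustering of
    trait values among relatives than BM predicts; on a star phylogeny
    K equals 1 for any non-constant trait.
    """
    if isinstance(trait, pd.Series):
        labels = tree.tip_labels
        trait = trait.reindex(labels)
        if trait.isna().any():
            raise ValidationError(
                f"trait missing for tips: {sorted(trait.index[trait.isna()])}"
            )
        y = trait.to_numpy(dtype=float)
        cov = bm_covariance(tree, labels)
    else:
        y = np.asarray(trait, dtype=float)
        cov = bm_covariance(tree)
    n = y.size
    if n < 4:
        raise ValidationError(f"Blomberg's K needs >= 4 tips, got {n}")
    if np.ptp(y) == 0:
        raise ValidationError("degenerate trait: zero variance")
    C = cov.C
    a_hat, mse_num, denom = _phylo_mean_and_resid(y, C)
    observed = float(np.sum((y - a_hat) ** 2)) / mse_num
    expected = (float(np.trace(C)) - n / denom) / (n - 1)
    return observed / expected


def phylosignal_test(
    tree: PhyloTree, trait, n_perm: int = 999, seed: int | None = None
):
    """Permutation test for phylogenetic signal.

    Tip values are shuffled across the tips of the tree; the test
    statistic is the phylogenetically corrected residual sum
    (y-a)'C^-1(y-a), which is small when trait values cluster on the
    tree.  The p-value uses the add-one correction
    p = (1 + #{perm <= observed}) / (n_perm + 1).

    Returns ``(K, p)``.
    """
    if n_perm < 99:
        raise ValidationError("use at least 99 permutations")
    if seed is None:
        raise ValidationError("seed is required for reproducibility")
    if isinstance(trait, pd.Series):
        trait = trait.reindex(tree.tip_labels)
        y = trait.to_numpy(dtype=float)
    else:
        y = np.asarray(trait, dtype=float)
    k = blomberg_k(tree, y)
    C = bm_covariance(tree).C
    _, observed, _ = _phylo_mean_and_resid(y, C)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        _, stat, _ = _phylo_mean_and_resid(rng.permutation(y), C)
        if stat <= observed + 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return k, p


# ---------------------------------------------------------------------------
# Ancestral states and BM simulation


def ancestral_states(tree: PhyloTree, trait) -> pd.Series:
    """Maximum-likelihood Brownian-motion estimates at internal nodes.

    For internal node k, the estimate is the conditional expectation of
    the node state given the tips under the joint BM Gaussian:
    a_hat + c_k' C^-1 (y - a_hat 1), where c_k[i] is the shared
    root-to-MRCA path length between node k and tip i.  The root
    estimate equals the phylogenetic mean a_hat.

    Returns a Series indexed by node id (``nodeK`` preorder labels for
    unlabeled internal nodes).
    """
    labels = tree.tip_labels
    if isinstance(trait, pd.Series):
        trait = trait.reindex(labels)
        if trait.isna().any():
            raise ValidationError("trait missing for some tips")
        y = trait.to_numpy(dtype=float)
    else:
        y = np.asarray(trait, dtype=float)
    cov = bm_covariance(tree, labels)
    C = cov.C
    depth = tree.depths()
    dtree = tree.dendropy_tree
    nodes = list(dtree.preorder_node_iter())
    node_ids = tree.node_ids()
    leaves = {leaf.taxon.label: leaf for leaf in dtree.leaf_node_iter()}

    # ancestor chain (ids) per tip for MRCA lookup
    chains = {}
    for lab in labels:
        chain = []
        node = leaves[lab]
        while node is not None:
            chain.append(id(node))
            node = node.parent_node
        chains[lab] = chain

    a_hat, _, _ = _phylo_mean_and_resid(y, C)
    L = linalg.cholesky(C, lower=True)
    # C^-1 (y - a 1) via two triangular solves
    w = linalg.solve_triangular(L, y - a_hat, lower=True)
    v = linalg.solve_triangular(L.T, w, lower=False)

    estimates = {}
    for node, node_id in zip(nodes, node_ids):
        if node.is_leaf():
            continue
        anc = []
        nd = node
        while nd is not None:
            anc.append(id(nd))
            nd = nd.parent_node
        anc_set = set(anc)
        ck = np.empty(len(labels))
        for i, lab in enumerate(labels):
            shared = next(a for a in chains[lab] if a in anc_set)
            ck[i] = depth[shared]
        estimates[node_id] = a_hat + float(ck @ v)
    return pd.Series(estimates, name="estimate")


def simulate_bm(
    tree: PhyloTree,
    sigma2: float,
    root_value: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Simulate a continuous trait by Brownian motion along the tree.

    Each edge receives an independent Gaussian increment with variance
    ``sigma2 * branch_length``; a tip's value is the root value plus the
    sum of increments on its root path.  Tip values are returned as a
    Series indexed by tip label; their exact covariance is
    ``sigma2 * bm_covariance(tree).C``.
    """
    if sigma2 < 0:
        raise ValidationError("sigma2 must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    dtree = tree.dendropy_tree
    value = {id(dtree.seed_node): root_value}
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        bl = node.edge.length or 0.0
        incr = rng.normal(0.0, np.sqrt(sigma2 * bl)) if sigma2 * bl > 0 else 0.0
        value[id(node)] = value[id(node.parent_node)] + incr
    return pd.Series(
        {leaf.taxon.label: value[id(leaf)] for leaf in dtree.leaf_node_iter()},
        name="trait",
    )
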