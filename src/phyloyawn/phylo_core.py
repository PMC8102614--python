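"""Deterministic phylogenetic numerics.

Covariance construction from a rooted tree, Pagel's lambda transform and
its maximum-likelihood estimation, phylogenetic generalized least squares
(PGLS), evolutionary (phylogenetic) correlation, and variance inflation
factors.

Conventions
-----------
The phylogenetic covariance matrix ``C`` has entries equal to the shared
root-to-MRCA path length of each tip pair — the trait covariance implied
by Brownian motion on the tree.  Pagel's lambda multiplies the
off-diagonal entries of ``C``; lambda = 0 is a star phylogeny, lambda = 1
the untransformed Brownian structure.  All generalized least squares
solves go through a Cholesky factorization of ``C_lambda`` (never an
explicit inverse), with a 1e-10 jitter added to the diagonal if the
factorization fails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.optimize import minimize_scalar

from .exceptions import (
    CollinearityError,
    DegenerateDataError,
    DomainError,
    InputError,
    InsufficientDataError,
)

__all__ = [
    "PhyloCovariance",
    "PglsFit",
    "phylo_cov",
    "lambda_transform",
    "estimate_lambda",
    "pgls_fit",
    "phylo_correlation",
    "vif",
    "chol_with_jitter",
]

_JITTER = 1e-10


@dataclass
class PhyloCovariance:
    """Species-by-species shared-path-length matrix for a rooted tree."""

    matrix: np.ndarray
    tip_order: list[str]
    height: float

    @property
    def n(self) -> int:
        return len(self.tip_order)


@dataclass
class PglsFit:
    """Result of a phylogenetic generalized least squares fit."""

    coefficients: np.ndarray
    residuals: np.ndarray
    sigma2: float  # ML residual variance rate (RSS_gls / n)
    lambda_used: float
    loglik: float
    se: np.ndarray = field(default=None)
    df_resid: int = 0
    tvalues: np.ndarray = field(default=None)
    pvalues: np.ndarray = field(default=None)
    names: list[str] = field(default_factory=list)


def chol_with_jitter(C: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor of ``C``, retrying with diagonal jitter.

    Jitter of 1e-10 (relative to mean diagonal) is added once on failure;
    a second failure propagates.
    """
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        bump = _JITTER * float(np.mean(np.diag(C)) or 1.0)
        return np.linalg.cholesky(C + bump * np.eye(C.shape[0]))


def _check_rooted(tree: dendropy.Tree) -> None:
    # trees explicitly flagged unrooted ([&U] in Newick) are rejected;
    # basal polytomies (including star trees) are treated as hard
    # polytomies rooted at the seed node, the comparative-methods
    # convention
    if tree.is_rooted is False:
        raise InputError("tree is explicitly unrooted; root it first")


def phylo_cov(tree: dendropy.Tree, scale_to_unit_height: bool = False) -> PhyloCovariance:
    """Phylogenetic covariance matrix of a rooted tree.

    Entry (i, j) is the sum of branch lengths from the root to the most
    recent common ancestor of tips i and j; the diagonal holds each tip's
    root-to-tip distance.  With ``scale_to_unit_height`` the matrix is
    divided by the tree height (maximum root-to-tip distance), so an
    ultrametric tree yields a correlation matrix with unit diagonal.
    """
    _check_rooted(tree)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise InputError("tree has a negative branch length")

    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = list(tree.leaf_node_iter())
    n = len(leaves)
    labels = [lf.taxon.label for lf in leaves]
    depths = np.array([lf.root_distance for lf in leaves], dtype=float)
    index = {id(lf): i for i, lf in enumerate(leaves)}

    # entry (i, j) = depth of mrca(i, j): walk the tree once, setting each
    # internal node's depth for every tip pair split across its children
    C = np.zeros((n, n), dtype=float)
    np.fill_diagonal(C, depths)
    tip_sets: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tip_sets[id(node)] = np.array([index[id(node)]], dtype=int)
            continue
        child_tips = [tip_sets.pop(id(c)) for c in node.child_nodes()]
        depth = node.root_distance or 0.0
        for a in range(len(child_tips)):
            for b in range(a + 1, len(child_tips)):
                C[np.ix_(child_tips[a], child_tips[b])] = depth
                C[np.ix_(child_tips[b], child_tips[a])] = depth
        tip_sets[id(node)] = np.concatenate(child_tips)

    height = float(depths.max())
    if scale_to_unit_height:
        if height <= 0:
            raise InputError("tree height is zero; cannot scale")
        C = C / height
    return PhyloCovariance(matrix=C, tip_order=labels, height=height)


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda transform: off-diagonal entries scaled by ``lam``."""
    if not 0.0 <= lam <= 1.0:
        raise DomainError(f"lambda must lie in [0, 1]; got {lam}")
    C = np.asarray(C, dtype=float)
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


def _gls_profile(y: np.ndarray, X: np.ndarray, C: np.ndarray):
    """Profile-ML pieces for y ~ N(X b, sigma^2 C): (beta, rss, logdet, Lw)."""
    L = chol_with_jitter(C)
    yw = sla.solve_triangular(L, y, lower=True)
    Xw = sla.solve_triangular(L, X, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    rss = float(np.sum((yw - Xw @ beta) ** 2))
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return beta, rss, logdet, Xw, rank


def _profile_loglik(y: np.ndarray, X: np.ndarray, C: np.ndarray, lam: float) -> float:
    n = len(y)
    Cl = lambda_transform(C, lam)
    _, rss, logdet, _, _ = _gls_profile(y, X, Cl)
    if rss <= 0:
        rss = np.finfo(float).tiny
    s2 = rss / n
    return -0.5 * n * (math.log(2 * math.pi) + 1.0 + math.log(s2)) - 0.5 * logdet


@dataclass
class LambdaEstimate:
    lambda_hat: float
    max_loglik: float
    loglik: Callable[[float], float]


def estimate_lambda(y: Sequence[float], tree: dendropy.Tree) -> LambdaEstimate:
    """Maximum-likelihood Pagel's lambda for a single trait.

    The trait is modeled as multivariate normal with a common mean and
    covariance sigma^2 * C_lambda; the mean and rate are profiled out
    analytically and lambda is optimized on [0, 1] by bounded scalar
    search (tolerance 1e-6).  ``y`` must be aligned to the tree's tip
    order.
    """
    y = np.asarray(y, dtype=float)
    cov = phylo_cov(tree, scale_to_unit_height=True)
    n = cov.n
    if len(y) != n:
        raise InputError(f"trait length {len(y)} != number of tips {n}")
    if n < 4:
        raise InsufficientDataError("at least 4 species required to estimate lambda")
    if np.ptp(y) == 0:
        raise DegenerateDataError("trait is constant; lambda is undefined")

    X = np.ones((n, 1))
    C = cov.matrix

    def ll(lam: float) -> float:
        return _profile_loglik(y, X, C, lam)

    res = minimize_scalar(
        lambda lam: -ll(lam), bounds=(0.0, 1.0), method="bounded",
        options={"xatol": 1e-6},
    )
    candidates = [(float(res.x), ll(float(res.x))), (0.0, ll(0.0)), (1.0, ll(1.0))]
    lam_hat, best = max(candidates, key=lambda t: t[1])
    return LambdaEstimate(lambda_hat=lam_hat, max_loglik=best, loglik=ll)


def _column_names(X) -> list[str]:
    if isinstance(X, pd.DataFrame):
        return [str(c) for c in X.columns]
    X = np.asarray(X)
    return [f"x{j}" for j in range(X.shape[1])]


def pgls_fit(y, X, tree: dendropy.Tree, lambda_mode="ml") -> PglsFit:
    """Phylogenetic generalized least squares.

    ``lambda_mode`` is either the string ``"ml"`` (profile-ML lambda on
    [0, 1], the same profile used by :func:`estimate_lambda`) or a fixed
    value in [0, 1].  ``X`` must include an intercept column and rows must
    be aligned to the tree's tip order.  The GLS solve is done through a
    Cholesky whitening, never an explicit matrix inverse.
    """
    names = _column_names(X)
    y = np.asarray(y, dtype=float)
    Xa = np.asarray(X, dtype=float)
    cov = phylo_cov(tree, scale_to_unit_height=True)
    n, p = Xa.shape
    if len(y) != n or cov.n != n:
        raise InputError("y, X and tree tip counts disagree")

    C = cov.matrix
    if lambda_mode == "ml":
        res = minimize_scalar(
            lambda lam: -_profile_loglik(y, Xa, C, lam),
            bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-6},
        )
        cands = [float(res.x), 0.0, 1.0]
        lam = max(cands, key=lambda l: _profile_loglik(y, Xa, C, l))
    else:
        lam = float(lambda_mode)
        if not 0.0 <= lam <= 1.0:
            raise DomainError(f"lambda must lie in [0, 1]; got {lam}")

    Cl = lambda_transform(C, lam)
    beta, rss, logdet, Xw, rank = _gls_profile(y, Xa, Cl)
    if rank < p:
        # identify offending columns via pivoted QR on the whitened design
        _, _, piv = sla.qr(Xw, pivoting=True)
        bad = [names[j] for j in piv[rank:]]
        raise CollinearityError(
            f"design matrix is rank deficient; collinear columns: {bad}", columns=bad
        )

    sigma2_ml = rss / n
    loglik = -0.5 * n * (math.log(2 * math.pi) + 1.0 + math.log(max(sigma2_ml, np.finfo(float).tiny))) - 0.5 * logdet
    residuals = y - Xa @ beta

    df = n - p
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    s2_unbiased = rss / df if df > 0 else np.nan
    se = np.sqrt(s2_unbiased * np.diag(XtX_inv)) if df > 0 else np.full(p, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    from scipy import stats as sstats

    pvals = 2.0 * sstats.t.sf(np.abs(tvals), df) if df > 0 else np.full(p, np.nan)

    return PglsFit(
        coefficients=beta,
        residuals=residuals,
        sigma2=sigma2_ml,
        lambda_used=lam,
        loglik=loglik,
        se=se,
        df_resid=df,
        tvalues=tvals,
        pvalues=pvals,
        names=names,
    )


def phylo_correlation(x, y, tree: dendropy.Tree) -> float:
    """Evolutionary correlation of two traits under bivariate Brownian motion.

    Maximum-likelihood correlation of the bivariate Brownian rate matrix:
    each trait's GLS mean is removed and the evolutionary cross-products
    are taken in the C-metric.  Equivalent to the correlation of
    phylogenetically independent contrasts through the origin.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = phylo_cov(tree, scale_to_unit_height=True)
    n = cov.n
    if len(x) != n or len(y) != n:
        raise InputError("trait vectors must align with the tree tips")
    if n < 4:
        raise InsufficientDataError("at least 4 species required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero-variance trait; correlation undefined")

    L = chol_with_jitter(cov.matrix)
    ones = np.ones(n)
    ow = sla.solve_triangular(L, ones, lower=True)
    xw = sla.solve_triangular(L, x, lower=True)
    yw = sla.solve_triangular(L, y, lower=True)
    mu_x = float(ow @ xw) / float(ow @ ow)
    mu_y = float(ow @ yw) / float(ow @ ow)
    rx = xw - mu_x * ow
    ry = yw - mu_y * ow
    sxx = float(rx @ rx)
    syy = float(ry @ ry)
    if sxx <= 0 or syy <= 0:
        raise DegenerateDataError("zero evolutionary variance")
    r = float(rx @ ry) / math.sqrt(sxx * syy)
    return float(np.clip(r, -1.0, 1.0))


def vif(X) -> np.ndarray:
    """Variance inflation factor per predictor column.

    ``X`` holds the non-intercept predictors (DataFrame or 2-D array).
    VIF_j = 1 / (1 - R^2_j) from the ordinary least-squares regression of
    column j on the remaining columns plus an intercept.  Perfect
    collinearity is reported as ``inf``, not raised.
    """
    Xa = np.asarray(X, dtype=float)
    if Xa.ndim != 2 or Xa.shape[1] < 2:
        raise InputError("vif requires at least two non-intercept columns")
    n, p = Xa.shape
    if n <= p:
        raise InputError("vif requires more rows than columns")
    out = np.empty(p)
    for j in range(p):
        yj = Xa[:, j]
        others = np.column_stack([np.ones(n), np.delete(Xa, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        if ss_tot == 0:
            out[j] = np.inf
            continue
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out
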