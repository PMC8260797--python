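"""Pagel's λ phylogenetic signal under λ-transformed Brownian motion.

The model: a continuous trait y across n species is multivariate normal,

    y ~ N(μ·1, σ² C(λ)),

where C is the Brownian-motion covariance from the tree (shared root-to-MRCA
path lengths) and C(λ) multiplies the off-diagonals by λ ∈ [0, 1].  λ = 1
means trait covariance matches the phylogeny; λ = 0 phylogenetic
independence.  For a fixed λ, μ and σ² have closed-form GLS/ML estimates,

    μ̂ = (1ᵀC(λ)⁻¹1)⁻¹ 1ᵀC(λ)⁻¹y,
    σ̂² = (y − μ̂1)ᵀ C(λ)⁻¹ (y − μ̂1) / n     (ML divisor n),

so λ is estimated by maximizing the profile log-likelihood with bounded 1-D
search started from a coarse grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator

from .trees import PhyloCovariance, Phylogeny, lambda_transform_matrix

__all__ = [
    "PagelLambda",
    "StatResult",
    "bm_loglik",
    "fit_lambda",
    "fit_lambda_table",
    "compare_lambda_distributions",
    "rank_sum_test",
]

_RIDGE_FRAC = 1e-10  # ridge added as fraction of trace when C(λ) is singular


@dataclass(frozen=True)
class StatResult:
    """A two-sample (or goodness-of-fit) test result."""

    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _chol_loglik_terms(V: np.ndarray):
    """Cholesky factor of V with a ridge fallback for near-singular input.

    Returns (cho_factor result, log-determinant)."""
    try:
        c, low = linalg.cho_factor(V, check_finite=False)
    except linalg.LinAlgError:
        ridge = _RIDGE_FRAC * np.trace(V)
        c, low = linalg.cho_factor(
            V + ridge * np.eye(V.shape[0]), check_finite=False
        )
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    return (c, low), logdet


def bm_loglik(
    y,
    cov: PhyloCovariance,
    lam: float,
    sigma2: float,
    mu: float,
) -> float:
    """Log-likelihood of a trait vector under the λ-Brownian model.

    `y` may be a label-keyed Series/dict (aligned to ``cov.labels``) or an
    array already in label order.  ``sigma2 > 0`` and ``0 <= lam <= 1``.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    yv = cov.align(y)
    n = cov.n
    V = sigma2 * lambda_transform_matrix(cov.matrix, lam)
    cfac, logdet = _chol_loglik_terms(V)
    r = yv - mu
    quad = float(r @ linalg.cho_solve(cfac, r, check_finite=False))
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)


def _profile_loglik(lam: float, C: np.ndarray, y: np.ndarray):
    """Profile log-likelihood over (μ, σ²) at a given λ.

    Returns (loglik, mu_hat, sigma2_hat)."""
    n = y.shape[0]
    V = lambda_transform_matrix(C, lam)
    cfac, logdet = _chol_loglik_terms(V)
    ones = np.ones(n)
    Vi_1 = linalg.cho_solve(cfac, ones, check_finite=False)
    Vi_y = linalg.cho_solve(cfac, y, check_finite=False)
    mu = float(ones @ Vi_y) / float(ones @ Vi_1)
    r = y - mu
    sigma2 = float(r @ (Vi_y - mu * Vi_1)) / n
    if sigma2 <= 0:  # numerically degenerate trait
        return -np.inf, mu, sigma2
    ll = -0.5 * (
        n * np.log(2.0 * np.pi) + n * np.log(sigma2) + logdet + n
    )
    return ll, mu, sigma2


class PagelLambda(BaseEstimator):
    """Maximum-likelihood Pagel's λ estimator for one continuous trait.

    Parameters
    ----------
    tree : Phylogeny or PhyloCovariance
        Phylogeny relating the species (the covariance is computed once and
        reused across fits).
    n_grid : int
        Number of equally spaced λ starting points on [0, 1] screened
        before the bounded scalar refinement.
    tol : float
        Absolute tolerance on λ for the bounded optimizer.

    Attributes (after :meth:`fit`)
    ------------------------------
    lambda_ : float in [0, 1]
    sigma2_ : float > 0      — BM rate, trait-units² per branch-length unit
    mu_ : float              — root (GLS) mean
    loglik_ : float          — profile log-likelihood at ``lambda_``
    converged_ : bool
    n_species_ : int
    """

    def __init__(self, tree=None, n_grid: int = 11, tol: float = 1e-6):
        self.tree = tree
        self.n_grid = n_grid
        self.tol = tol

    def _cov(self) -> PhyloCovariance:
        if isinstance(self.tree, PhyloCovariance):
            return self.tree
        if isinstance(self.tree, Phylogeny):
            return self.tree.covariance()
        raise TypeError("tree must be a Phylogeny or PhyloCovariance")

    def fit(self, y, X=None):
        """Fit λ, σ², μ to trait vector `y` (label-keyed or in tip order)."""
        cov = self._cov()
        yv = cov.align(y)
        if yv.shape[0] < 3:
            raise ValueError("need >= 3 species to estimate lambda")
        if not np.all(np.isfinite(yv)):
            raise ValueError("trait vector contains non-finite values")
        if np.ptp(yv) == 0:
            raise ValueError("trait is constant across species; "
                             "lambda is unidentifiable")
        C = cov.matrix

        grid = np.linspace(0.0, 1.0, self.n_grid)
        grid_ll = np.array([_profile_loglik(g, C, yv)[0] for g in grid])
        best = int(np.argmax(grid_ll))
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, self.n_grid - 1)]

        converged = True
        if lo == hi:
            lam_hat = grid[best]
        else:
            res = optimize.minimize_scalar(
                lambda g: -_profile_loglik(g, C, yv)[0],
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": self.tol},
            )
            lam_hat = float(res.x)
            converged = bool(res.success)
        ll_hat = _profile_loglik(lam_hat, C, yv)[0]
        # ties resolve to the boundary (λ̂ exactly 0 or 1)
        for boundary, ll_b in ((0.0, grid_ll[0]), (1.0, grid_ll[-1])):
            if ll_b >= ll_hat - 1e-9:
                lam_hat, ll_hat = boundary, ll_b
        ll, mu, sigma2 = _profile_loglik(lam_hat, C, yv)

        self.lambda_ = float(np.clip(lam_hat, 0.0, 1.0))
        self.mu_ = mu
        self.sigma2_ = sigma2
        self.loglik_ = ll
        self.converged_ = converged
        self.n_species_ = yv.shape[0]
        self.labels_ = cov.labels
        return self


def fit_lambda(y, tree) -> PagelLambda:
    """Functional wrapper: fit Pagel's λ for one trait; returns the fitted
    :class:`PagelLambda` (attributes ``lambda_``, ``sigma2_``, ``mu_``,
    ``loglik_``, ``converged_``, ``n_species_``)."""
    return PagelLambda(tree=tree).fit(y)


def fit_lambda_table(tm: pd.DataFrame, tree, on_error: str = "drop") -> pd.DataFrame:
    """Fit λ independently for every feature column of a trait matrix.

    Rows of `tm` are species (index must match tip labels); columns are
    features.  Unfittable traits (constant across species) are dropped with
    a count recorded in ``result.attrs["n_dropped"]`` (``on_error="drop"``)
    or re-raised (``on_error="raise"``).
    """
    cov = tree.covariance() if isinstance(tree, Phylogeny) else tree
    est = PagelLambda(tree=cov)
    rows, dropped = [], 0
    for feature in tm.columns:
        try:
            est.fit(tm[feature])
        except ValueError:
            if on_error == "raise":
                raise
            dropped += 1
            continue
        rows.append(
            (feature, est.lambda_, est.sigma2_, est.mu_, est.loglik_,
             est.n_species_)
        )
    out = pd.DataFrame(
        rows, columns=["feature", "lambda_hat", "sigma2_hat", "mu_hat",
                       "loglik", "n"]
    )
    out.attrs["n_dropped"] = dropped
    return out


def rank_sum_test(a, b) -> StatResult:
    """Two-sided Mann-Whitney / Wilcoxon rank-sum test.

    Exact null distribution when both samples have <= 8 observations and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    exact = no_ties and a.size <= 8 and b.size <= 8
    res = stats.mannwhitneyu(
        a, b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return StatResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="mannwhitney_exact" if exact else "mannwhitney_normal",
        n1=a.size,
        n2=b.size,
    )


def compare_lambda_distributions(lams_a, lams_b) -> StatResult:
    """Compare two sets of per-trait λ estimates (e.g. male vs female
    chemical features) by the unpaired two-sided Wilcoxon rank-sum test."""
    return rank_sum_test(lams_a, lams_b)
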