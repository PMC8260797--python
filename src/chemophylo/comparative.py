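"""Phylogenetic regressions linking chemical production to neuronal response.

Two encodings of the chemical response variable are supported, mirroring
how chemical levels are analyzed against neuronal predictors:

* continuous — phylogenetic generalized least squares (PGLS) with the error
  covariance set to the identity (star phylogeny / OLS), the full Brownian
  covariance (λ = 1), or a λ estimated by ML; the branch-length
  transformation is chosen by BIC;
* binary (presence/absence) — a phylogenetic logistic regression with a
  single dependence parameter, with coefficient significance from a
  parametric bootstrap under the fitted null.

Both are sklearn-style estimators; `pgls_fit` / `phyloglm_fit` are thin
functional wrappers returning fitted instances.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special, stats
from sklearn.base import BaseEstimator

from .phylosignal import StatResult, _chol_loglik_terms
from .trees import PhyloCovariance, Phylogeny, lambda_transform_matrix

__all__ = [
    "PhylogeneticRegression",
    "PhylogeneticLogisticRegression",
    "pgls_fit",
    "select_model_bic",
    "phyloglm_fit",
    "chisq_choice_test",
]

PGLS_MODELS = ("OLS_star", "BM", "lambda_ML")


def _as_cov(tree) -> PhyloCovariance:
    if isinstance(tree, PhyloCovariance):
        return tree
    if isinstance(tree, Phylogeny):
        return tree.covariance()
    raise TypeError("tree must be a Phylogeny or PhyloCovariance")


def _design(X, cov: PhyloCovariance, add_intercept: bool):
    """Label-align predictors and prepend an intercept column."""
    if isinstance(X, pd.DataFrame):
        missing = [l for l in cov.labels if l not in X.index]
        if missing:
            raise KeyError(f"predictors missing species: {missing}")
        M = np.asarray(X.reindex(list(cov.labels)), dtype=float)
        names = list(X.columns)
    elif isinstance(X, pd.Series):
        M = cov.align(X, "predictor")[:, None]
        names = [X.name or "x1"]
    else:
        M = np.asarray(X, dtype=float)
        if M.ndim == 1:
            M = M[:, None]
        if M.shape[0] != cov.n:
            raise ValueError(
                f"predictors have {M.shape[0]} rows, expected {cov.n}"
            )
        names = [f"x{j + 1}" for j in range(M.shape[1])]
    if add_intercept:
        M = np.column_stack([np.ones(cov.n), M])
        names = ["intercept"] + names
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise ValueError("collinear predictors (design matrix rank-deficient)")
    return M, names


class PhylogeneticRegression(BaseEstimator):
    """PGLS: generalized least squares with phylogenetic error covariance.

    Parameters
    ----------
    tree : Phylogeny or PhyloCovariance
    model : {"OLS_star", "BM", "lambda_ML"}
        Error structure V: identity (phylogenetically independent
        residuals), the full Brownian covariance C, or C(λ) with λ
        estimated by ML jointly with the coefficients.
    add_intercept : bool

    Attributes (after :meth:`fit`)
    ------------------------------
    coef_ : ndarray            — GLS coefficients β̂ (intercept first)
    coef_names_ : list of str
    lambda_ : float or None    — λ̂ when ``model="lambda_ML"``, else the
                                 implied value (0 for OLS_star, 1 for BM)
    sigma2_ : float            — ML residual rate (divisor n)
    loglik_ : float            — full ML log-likelihood
    bic_ : float               — k·ln(n) − 2·loglik with k counting β, σ²,
                                 and λ when estimated
    pvalues_ : ndarray         — per-coefficient two-sided t tests,
                                 n − k_beta degrees of freedom
    """

    def __init__(self, tree=None, model: str = "lambda_ML",
                 add_intercept: bool = True):
        self.tree = tree
        self.model = model
        self.add_intercept = add_intercept

    def fit(self, X, y):
        if self.model not in PGLS_MODELS:
            raise ValueError(f"unknown model {self.model!r}; "
                             f"choose from {PGLS_MODELS}")
        cov = _as_cov(self.tree)
        yv = cov.align(y, "response")
        M, names = _design(X, cov, self.add_intercept)
        n, p = M.shape
        if n <= p:
            raise ValueError(f"need n > number of coefficients ({n} <= {p})")

        if self.model == "OLS_star":
            lam = 0.0
            V = np.eye(n)
        elif self.model == "BM":
            lam = 1.0
            V = cov.matrix
        else:
            lam = self._optimize_lambda(cov.matrix, M, yv)
            V = lambda_transform_matrix(cov.matrix, lam)

        beta, sigma2, ll, se, tvals, pvals = _gls(M, yv, V)
        k = p + 1 + (1 if self.model == "lambda_ML" else 0)

        self.coef_ = beta
        self.coef_names_ = names
        self.lambda_ = lam
        self.sigma2_ = sigma2
        self.loglik_ = ll
        self.n_params_ = k
        self.bic_ = k * np.log(n) - 2.0 * ll
        self.se_ = se
        self.tvalues_ = tvals
        self.pvalues_ = pvals
        self.n_species_ = n
        self.labels_ = cov.labels
        return self

    @staticmethod
    def _optimize_lambda(C, M, y):
        def nll(lam):
            V = lambda_transform_matrix(C, lam)
            return -_gls(M, y, V)[2]

        grid = np.linspace(0.0, 1.0, 11)
        vals = [nll(g) for g in grid]
        best = int(np.argmin(vals))
        lo, hi = grid[max(best - 1, 0)], grid[min(best + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-6}
        )
        lam = float(res.x)
        for boundary, v in ((0.0, vals[0]), (1.0, vals[-1])):
            if v <= res.fun + 1e-9:
                lam = boundary
        return lam

    def predict(self, X):
        cov = _as_cov(self.tree)
        M, _ = _design(X, cov, self.add_intercept)
        return M @ self.coef_


def _gls(M, y, V):
    """GLS fit with ML σ² and coefficient t-tests (n − p df)."""
    n, p = M.shape
    cfac, logdet = _chol_loglik_terms(V)
    Vi_M = linalg.cho_solve(cfac, M, check_finite=False)
    Vi_y = linalg.cho_solve(cfac, y, check_finite=False)
    XtViX = M.T @ Vi_M
    beta = np.linalg.solve(XtViX, M.T @ Vi_y)
    r = y - M @ beta
    quad = float(r @ linalg.cho_solve(cfac, r, check_finite=False))
    sigma2_ml = quad / n
    ll = -0.5 * (n * np.log(2.0 * np.pi) + n * np.log(sigma2_ml) + logdet + n)
    s2 = quad / (n - p)  # unbiased scale for the t statistics
    se = np.sqrt(s2 * np.diag(np.linalg.inv(XtViX)))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p)
    return beta, sigma2_ml, ll, se, tvals, pvals


def pgls_fit(y, X, tree, model: str = "lambda_ML") -> PhylogeneticRegression:
    """Fit a PGLS model; returns the fitted estimator."""
    return PhylogeneticRegression(tree=tree, model=model).fit(X, y)


def select_model_bic(fits) -> PhylogeneticRegression:
    """Pick the fit with minimal BIC; ties broken toward fewer parameters."""
    fits = list(fits)
    if not fits:
        raise ValueError("empty fit list")
    return min(fits, key=lambda f: (round(f.bic_, 12), f.n_params_))


# ---------------------------------------------------------------------
# phylogenetic logistic regression


class PhylogeneticLogisticRegression(BaseEstimator):
    """Logistic regression for a binary species trait with phylogenetic
    dependence governed by a single strength parameter.

    Model: P(y_i = 1) = logistic(x_iᵀβ); residual dependence between
    species i and j decays with their patristic distance d_ij through a
    working correlation exp(−α·d_ij) (α large → independence).  β is
    estimated by quasi-Fisher scoring (GEE); α by a profiled Gaussian
    pseudo-likelihood of the standardized residuals over a fixed grid that
    includes exact independence.  Significance of a coefficient comes from
    a parametric bootstrap: the model is refit with that coefficient
    removed, `n_boot` datasets are simulated from the fitted null via a
    latent-threshold (Gaussian copula) draw matching the null marginal
    means and correlation, and the two-sided p-value is the fraction of
    bootstrap |β̂*| at least as large as the observed |β̂|.

    Parameters
    ----------
    tree : Phylogeny or PhyloCovariance (patristic distances derived)
    n_boot : int — bootstrap replicates (paper-scale default 2000)
    alpha : float or None — fix the dependence parameter (``np.inf`` for
        independence) instead of estimating it
    alpha_grid_corr : tuple — candidate mean-distance correlations
        exp(−α·d̄) defining the α grid
    test_coef : int — index of the tested coefficient (1 = first slope)
    beta_cap : float — absolute cap on coefficients (perfect separation)
    random_state : int or numpy Generator

    Attributes (after :meth:`fit`)
    ------------------------------
    coef_ : ndarray; alpha_ : float; boot_pvalues_ : dict {index: p};
    separation_ : bool; n_boot_ : int
    """

    def __init__(self, tree=None, n_boot: int = 2000, alpha=None,
                 alpha_grid_corr=(0.95, 0.85, 0.7, 0.5, 0.3, 0.15, 0.05, 0.01),
                 test_coef: int = 1, beta_cap: float = 15.0,
                 random_state=None):
        self.tree = tree
        self.n_boot = n_boot
        self.alpha = alpha
        self.alpha_grid_corr = alpha_grid_corr
        self.test_coef = test_coef
        self.beta_cap = beta_cap
        self.random_state = random_state

    # -- correlation-structure cache (per distance matrix) -------------

    def _structures(self):
        if getattr(self, "_struct_cache", None) is None:
            cov = _as_cov(self.tree)
            if isinstance(self.tree, Phylogeny):
                D = self.tree.distance_matrix().matrix
            else:
                depths = np.diag(cov.matrix)
                D = depths[:, None] + depths[None, :] - 2.0 * cov.matrix
                np.fill_diagonal(D, 0.0)
            dbar = float(D[np.triu_indices_from(D, k=1)].mean())
            alphas = [-np.log(r) / dbar for r in self.alpha_grid_corr]
            alphas.append(np.inf)
            structs = []
            n = D.shape[0]
            for a in alphas:
                R = np.eye(n) if np.isinf(a) else np.exp(-a * D)
                R = R + 1e-8 * np.eye(n)
                try:
                    L = linalg.cholesky(R, lower=True)
                except linalg.LinAlgError:
                    R = R + 1e-4 * np.eye(n)
                    L = linalg.cholesky(R, lower=True)
                logdet = 2.0 * np.sum(np.log(np.diag(L)))
                structs.append((a, L, logdet, R))
            self._struct_cache = (cov, structs)
            self._distance_cache = D
        return self._struct_cache

    def _structure_for(self, a: float):
        """Correlation factor for one fixed α not on the grid."""
        self._structures()
        D = self._distance_cache
        n = D.shape[0]
        R = np.eye(n) if np.isinf(a) else np.exp(-a * D)
        R = R + 1e-8 * np.eye(n)
        L = linalg.cholesky(R, lower=True)
        return a, L, 2.0 * np.sum(np.log(np.diag(L))), R

    # -- core scoring --------------------------------------------------

    def _gee_beta(self, M, y, L, beta0=None, max_iter=60, tol=1e-10):
        """Quasi-Fisher scoring for β at fixed correlation factor L.

        Steps are damped to length 2 on the logit scale; coefficients are
        capped at ``beta_cap`` (quasi-separation)."""
        n, p = M.shape
        beta = np.zeros(p) if beta0 is None else beta0.copy()
        separated = False
        for _ in range(max_iter):
            eta = np.clip(M @ beta, -30, 30)
            mu = special.expit(eta)
            w = np.sqrt(mu * (1.0 - mu))
            w = np.maximum(w, 1e-8)
            # working residual in standardized space: R^{-1/2} applied via L
            Z = linalg.solve_triangular(L, M * w[:, None], lower=True,
                                        check_finite=False)
            z = linalg.solve_triangular(L, (y - mu) / w, lower=True,
                                        check_finite=False)
            score = Z.T @ z
            info = Z.T @ Z + 1e-8 * np.eye(p)
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(info, score, rcond=None)[0]
            biggest = np.max(np.abs(step))
            if biggest > 2.0:
                step *= 2.0 / biggest
            beta_new = beta + step
            over = np.abs(beta_new) > self.beta_cap
            if over.any():
                separated = True
                beta_new = np.clip(beta_new, -self.beta_cap, self.beta_cap)
            if np.max(np.abs(beta_new - beta)) < tol:
                beta = beta_new
                break
            beta = beta_new
        return beta, separated

    @staticmethod
    def _composite_loglik(y, p, R):
        """Pairwise composite log-likelihood of binary data whose pairwise
        joint law has marginals p and correlation R (Fréchet-clipped)."""
        w = np.sqrt(p * (1.0 - p))
        p11 = np.outer(p, p) + R * np.outer(w, w)
        # Fréchet bounds keep every 2x2 table valid
        upper = np.minimum.outer(p, p)
        lower = np.maximum(np.add.outer(p, p) - 1.0, 0.0)
        p11 = np.clip(p11, lower + 1e-12, upper - 1e-12)
        pi_ = p[:, None]
        pj_ = p[None, :]
        tab = {
            (1, 1): p11,
            (1, 0): pi_ - p11,
            (0, 1): pj_ - p11,
            (0, 0): 1.0 - pi_ - pj_ + p11,
        }
        yi = y[:, None]
        yj = y[None, :]
        probs = np.select(
            [
                (yi == 1) & (yj == 1),
                (yi == 1) & (yj == 0),
                (yi == 0) & (yj == 1),
            ],
            [tab[(1, 1)], tab[(1, 0)], tab[(0, 1)]],
            default=tab[(0, 0)],
        )
        iu = np.triu_indices_from(probs, k=1)
        return float(np.sum(np.log(np.maximum(probs[iu], 1e-300))))

    def _fit_beta_alpha(self, M, y, beta0=None):
        """Estimate (β, α).

        β is first fit under independence; α then maximizes the pairwise
        composite likelihood over the grid (given the fitted means), and β
        is refit by GEE at the selected α.  Returns (α̂, β̂, separated, L)."""
        _, structs = self._structures()
        if self.alpha is not None:
            target = [s for s in structs
                      if (np.isinf(s[0]) and np.isinf(self.alpha))
                      or np.isclose(s[0], self.alpha)]
            a, L, _, _ = (target if target
                          else [self._structure_for(self.alpha)])[0]
            beta, sep = self._gee_beta(M, y, L, beta0=beta0)
            return a, beta, sep, L

        # independence fit for the mean model (last struct is α=∞)
        a_ind, L_ind, _, _ = structs[-1]
        beta_ind, sep_ind = self._gee_beta(M, y, L_ind, beta0=beta0)
        p_ind = special.expit(np.clip(M @ beta_ind, -30, 30))

        best = None
        for a, L, _, R in structs:
            cl = self._composite_loglik(y, p_ind, R)
            if best is None or cl > best[0]:
                best = (cl, a, L)
        _, a_hat, L_hat = best
        if np.isinf(a_hat):
            return a_hat, beta_ind, sep_ind, L_hat
        beta, sep = self._gee_beta(M, y, L_hat, beta0=beta_ind)
        return a_hat, beta, sep, L_hat

    # -- public API ----------------------------------------------------

    def fit(self, X, y):
        cov, _ = self._structures()
        yv = cov.align(y, "response")
        if not np.isin(yv, (0.0, 1.0)).all():
            raise ValueError("response must be binary 0/1")
        if yv.min() == yv.max():
            raise ValueError("response has a single class; "
                             "logistic model unidentifiable")
        M, names = _design(X, cov, add_intercept=True)
        if self.n_boot < 0:
            raise ValueError("n_boot must be >= 0 (0 skips the bootstrap)")

        alpha_hat, beta_hat, separated, _ = self._fit_beta_alpha(M, yv)
        if separated:
            warnings.warn("possible perfect separation; coefficients capped",
                          stacklevel=2)

        self.coef_ = beta_hat
        self.coef_names_ = names
        self.alpha_ = alpha_hat
        self.separation_ = separated
        self.labels_ = cov.labels
        self.n_boot_ = self.n_boot
        if self.n_boot > 0:
            self.boot_pvalues_ = {
                self.test_coef: self._bootstrap_p(M, yv, self.test_coef)
            }
        else:
            self.boot_pvalues_ = {}
        return self

    def _mk_edges(self):
        """Preorder edge arrays (parent slot, length, tip row) for the
        evolving-binary-trait simulator; requires a Phylogeny tree."""
        if getattr(self, "_mk_edge_cache", None) is None:
            if not isinstance(self.tree, Phylogeny):
                raise TypeError("null simulation by trait evolution needs a "
                                "Phylogeny, not a bare covariance")
            cov, _ = self._structures()
            tip_row = {lab: i for i, lab in enumerate(cov.labels)}
            dtree = self.tree._tree
            slot = {id(dtree.seed_node): 0}
            parents, lengths, tips = [], [], []
            k = 1
            from .trees import _leaf_label
            for node in dtree.preorder_node_iter():
                if node.parent_node is None:
                    continue
                slot[id(node)] = k
                parents.append(slot[id(node.parent_node)])
                lengths.append(node.edge.length or 0.0)
                tips.append(tip_row[_leaf_label(node)] if node.is_leaf()
                            else -1)
                k += 1
            self._mk_edge_cache = (
                np.asarray(parents), np.asarray(lengths, dtype=float),
                np.asarray(tips), k,
            )
        return self._mk_edge_cache

    def _simulate_null_mk(self, pi: float, alpha: float, n_rep: int, rng):
        """Simulate `n_rep` binary tip vectors from the stationary two-state
        chain on the tree with stationary presence `pi` and total switching
        rate `alpha` (tip correlation exp(−α·d_ij); α=∞ gives iid draws).

        Vectorized across replicates; returns (n_tips, n_rep)."""
        parents, lengths, tips, n_slots = self._mk_edges()
        n_tips = sum(tips >= 0)
        decay = np.zeros_like(lengths) if np.isinf(alpha) else \
            np.exp(-alpha * lengths)
        states = np.empty((n_slots, n_rep), dtype=bool)
        states[0] = rng.random(n_rep) < pi
        Y = np.empty((n_tips, n_rep))
        for e in range(len(parents)):
            parent = states[parents[e]]
            p1 = np.where(parent, pi + (1 - pi) * decay[e],
                          pi * (1 - decay[e]))
            s = rng.random(n_rep) < p1
            states[e + 1] = s
            if tips[e] >= 0:
                Y[tips[e]] = s
        return Y

    def _bootstrap_p(self, M, y, j):
        """Parametric bootstrap p-value for coefficient j (two-sided).

        The null model (coefficient j removed) is refit; `n_boot` datasets
        are simulated from it and the full model refit on each.  With an
        intercept-only null the simulator is the stationary two-state
        chain on the tree (the model's own generative form); with
        covariates left in the null, a latent-threshold draw matching the
        null marginal means and working correlation is used instead.
        """
        rng = np.random.default_rng(self.random_state)
        keep = [k for k in range(M.shape[1]) if k != j]
        M0 = M[:, keep]
        alpha0, beta0, _, L0 = self._fit_beta_alpha(M0, y)
        p0 = special.expit(np.clip(M0 @ beta0, -30, 30))

        n = y.shape[0]
        if M0.shape[1] == 1 and np.allclose(M0, M0[0, 0]) and \
                isinstance(self.tree, Phylogeny):
            Yb = self._simulate_null_mk(float(p0[0]), alpha0, self.n_boot,
                                        rng)
        else:
            thresh = stats.norm.ppf(np.clip(p0, 1e-12, 1 - 1e-12))
            Z = L0 @ rng.standard_normal((n, self.n_boot))
            Yb = (Z < thresh[:, None]).astype(float)

        observed = abs(self.coef_[j])
        exceed = 0
        warm = None
        for b in range(self.n_boot):
            yb = Yb[:, b].astype(float)
            if yb.min() == yb.max():  # degenerate draw: conservative
                exceed += 1
                continue
            _, bb, _, _ = self._fit_beta_alpha(M, yb, beta0=warm)
            warm = bb
            if abs(bb[j]) >= observed:
                exceed += 1
        return (1.0 + exceed) / (1.0 + self.n_boot)


def phyloglm_fit(y, X, tree, n_boot: int = 2000,
                 random_state=None, **kwargs) -> PhylogeneticLogisticRegression:
    """Fit the phylogenetic logistic regression; returns the fitted
    estimator (``coef_``, ``alpha_``, ``boot_pvalues_``)."""
    est = PhylogeneticLogisticRegression(
        tree=tree, n_boot=n_boot, random_state=random_state, **kwargs
    )
    return est.fit(X, y)


# ---------------------------------------------------------------------
# behavioral two-choice test


def chisq_choice_test(n_option_a: int, n_option_b: int) -> StatResult:
    """Pearson goodness-of-fit χ² of two-choice counts against 50:50.

    One degree of freedom, no continuity correction.  Used for e.g.
    copulation counts with a perfumed versus a solvent-treated male.
    """
    if n_option_a < 0 or n_option_b < 0:
        raise ValueError("counts must be non-negative")
    total = n_option_a + n_option_b
    if total == 0:
        raise ValueError("total count must be positive")
    res = stats.chisquare([n_option_a, n_option_b])
    return StatResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="chisq_gof_1df",
        n1=int(n_option_a),
        n2=int(n_option_b),
    )
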