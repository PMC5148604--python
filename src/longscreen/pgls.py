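"""Phylogenetic generalized least squares with maximum-likelihood model choice.

A feature value ``y`` (log10 expression or metabolite level, species means)
is regressed on a log10 life-history trait ``x`` under

    y = X beta + e,   e ~ MVN(0, sigma2 * V0(theta)),

where ``V0`` is one of four correlation structures derived from the phylogeny
(``null``, ``brownian``, ``lambda``, ``ou``; see :mod:`longscreen.covariance`).
``beta`` and ``sigma2`` are profiled analytically; ``lambda`` / ``alpha`` are
optimized by a coarse grid followed by nested vectorized grid refinement
(lambda to 1e-6, alpha to 1% on the log scale), and the best structure is
the one with the highest maximized log-likelihood.

The reported log-likelihood is the profile value

    ll = -n/2 (log 2 pi + log sigma2_hat + 1) - 1/2 log|V0|,
    sigma2_hat = r' V0^-1 r / n,

so likelihoods are comparable across structures.  Slope inference uses the
unbiased variance (``rss / (n - p)``) and a t distribution with ``n - p``
degrees of freedom.

Because the leave-one-out screen refits the same covariance structures for
thousands of features, solve operators are cached per exclusion subset: the
lambda profile is diagonalized once per subset (making each candidate lambda
O(n)), and the OU grid is stored as stacked inverses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import stdtr

from .covariance import MODELS, CovMatrix
from .trees import PhyloTree

_LOG2PI = math.log(2.0 * math.pi)
_DEFAULT_ALPHA_RANGE = (1e-4, 50.0)  # per unit tree depth
_TINY_RSS = 1e-300


@dataclass
class GLSFit:
    """One generalized-least-squares fit of intercept and slope."""

    beta: np.ndarray
    se: np.ndarray
    t: float
    p: float
    sigma2: float
    loglik: float
    df_resid: int
    n: int
    model: str = ""
    params: dict = field(default_factory=dict)


@dataclass
class ModelSelection:
    """All fitted evolution models plus the maximum-likelihood winner."""

    fits: dict[str, GLSFit]
    best: str

    @property
    def best_fit(self) -> GLSFit:
        return self.fits[self.best]

    @property
    def best_params(self) -> dict:
        return self.fits[self.best].params


def _slope_stats(beta, rss, XtViX_inv, n, p):
    df = n - p
    s2 = rss / df if df > 0 else np.nan
    cov_beta = s2 * XtViX_inv
    se = np.sqrt(np.diag(cov_beta))
    i = 1 if p > 1 else 0
    tval = beta[i] / se[i] if se[i] > 0 else math.inf
    pval = 2.0 * stdtr(df, -abs(tval)) if df > 0 else np.nan
    return se, float(tval), max(float(pval), 5e-324), df


def gls_fit(y, X, V, model: str = "", params: dict | None = None) -> GLSFit:
    """GLS under a known covariance ``V`` (matrix or :class:`CovMatrix`).

    ``beta = (X'V^-1 X)^-1 X'V^-1 y``; the overall residual scale is profiled
    as ``sigma2 = r'V^-1 r / n`` for the likelihood and re-estimated with an
    ``n - p`` denominator for standard errors.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(V, CovMatrix):
        V = V.V
    V = np.asarray(V, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive definite") from exc
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    ViX = cho_solve(cf, X)
    Viy = cho_solve(cf, y)
    XtViX = X.T @ ViX
    XtViy = X.T @ Viy
    try:
        XtViX_inv = np.linalg.inv(XtViX)
    except np.linalg.LinAlgError as exc:
        raise ValueError("design matrix is rank deficient under V") from exc
    beta = XtViX_inv @ XtViy
    rss = max(float(y @ Viy - beta @ XtViy), _TINY_RSS)
    sigma2_ml = rss / n
    loglik = -0.5 * n * (_LOG2PI + math.log(sigma2_ml) + 1.0) - 0.5 * logdet
    se, tval, pval, df = _slope_stats(beta, rss, XtViX_inv, n, p)
    return GLSFit(beta=beta, se=se, t=tval, p=pval, sigma2=sigma2_ml,
                  loglik=float(loglik), df_resid=df, n=n, model=model,
                  params=dict(params or {}))


class _Pack:
    """Cached solve operators for one (subset, fixed-covariance) pair."""

    __slots__ = ("Vinv", "logdet", "ViX", "XtViX_inv", "X", "n")

    def __init__(self, V0: np.ndarray, X: np.ndarray):
        n = V0.shape[0]
        jitter = 1e-12 * float(np.mean(np.diag(V0)))
        cf = cho_factor(V0 + jitter * np.eye(n), lower=True)
        self.logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        self.Vinv = cho_solve(cf, np.eye(n))
        self.ViX = self.Vinv @ X
        self.XtViX_inv = np.linalg.inv(X.T @ self.ViX)
        self.X = X
        self.n = n

    def fit(self, y: np.ndarray, model: str, params: dict) -> GLSFit:
        n = self.n
        Viy = self.Vinv @ y
        XtViy = self.ViX.T @ y
        beta = self.XtViX_inv @ XtViy
        rss = max(float(y @ Viy - beta @ XtViy), _TINY_RSS)
        ll = (-0.5 * n * (_LOG2PI + math.log(rss / n) + 1.0)
              - 0.5 * self.logdet)
        se, tval, pval, df = _slope_stats(beta, rss, self.XtViX_inv, n, 2)
        return GLSFit(beta=beta, se=se, t=tval, p=pval, sigma2=rss / n,
                      loglik=ll, df_resid=df, n=n, model=model,
                      params=dict(params))


def _solve2_batch(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve stacked symmetric 2x2 systems by the closed form."""
    a11, a12, a22 = A[:, 0, 0], A[:, 0, 1], A[:, 1, 1]
    det = a11 * a22 - a12 * a12
    x0 = (a22 * b[:, 0] - a12 * b[:, 1]) / det
    x1 = (a11 * b[:, 1] - a12 * b[:, 0]) / det
    return np.column_stack([x0, x1])


class _SubsetCache:
    """Per-exclusion-subset geometry plus parameter-grid solve operators."""

    def __init__(self, tmat, dmat, T, x, lambda_grid, alpha_grid):
        self.n = n = len(T)
        self.tmat, self.dmat, self.T = tmat, dmat, T
        xc = x - x.mean()
        self.X = X = np.column_stack([np.ones(n), xc])
        self.packs = {"null": _Pack(np.eye(n), X),
                      "brownian": _Pack(tmat, X)}
        # --- lambda: simultaneous diagonalization w.r.t. diag(T) ----------
        s = 1.0 / np.sqrt(T)
        A = tmat * np.outer(s, s)
        mu, Q = np.linalg.eigh(A)           # A = Q diag(mu) Q'
        self.mu = mu
        self.P = Q.T * s[None, :]           # V(lam)^-1 = P' W(lam) P
        self.logdetD = float(np.sum(np.log(T)))
        self.Xt_l = self.P @ X
        self.lambda_grid = np.asarray(lambda_grid, dtype=float)
        W = 1.0 / (self.lambda_grid[:, None] * mu[None, :]
                   + (1.0 - self.lambda_grid[:, None]))
        self.lam_W = W
        self.lam_logdet = (-np.sum(np.log(W), axis=1)) + self.logdetD
        AXX = np.einsum("gn,ni,nj->gij", W, self.Xt_l, self.Xt_l)
        self.lam_AXX_inv = np.linalg.inv(AXX)
        # --- OU: stacked grid operators -----------------------------------
        self.alpha_grid = np.asarray(alpha_grid, dtype=float)
        G = self.alpha_grid.size
        self.ou_Vinv = np.empty((G, n, n))
        self.ou_ViX = np.empty((G, n, 2))
        self.ou_XtViX_inv = np.empty((G, 2, 2))
        self.ou_logdet = np.empty(G)
        eye = np.eye(n)
        for g, a in enumerate(self.alpha_grid):
            V0 = self.v_ou(a)
            jitter = 1e-12 * float(np.mean(np.diag(V0)))
            cf = cho_factor(V0 + jitter * eye, lower=True)
            self.ou_logdet[g] = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            Vinv = cho_solve(cf, eye)
            self.ou_Vinv[g] = Vinv
            self.ou_ViX[g] = Vinv @ X
            self.ou_XtViX_inv[g] = np.linalg.inv(X.T @ self.ou_ViX[g])

    def v_lambda(self, lam: float) -> np.ndarray:
        V = lam * self.tmat.copy()
        np.fill_diagonal(V, self.T)
        return V

    def v_ou(self, alpha: float) -> np.ndarray:
        return (np.exp(-alpha * self.dmat)
                * (1.0 - np.exp(-2.0 * alpha * self.tmat)) / (2.0 * alpha))

    # -- lambda profile ----------------------------------------------------
    def lambda_grid_loglik(self, yt: np.ndarray) -> np.ndarray:
        n = self.n
        Wy = self.lam_W * yt[None, :]
        bvec = Wy @ self.Xt_l                     # (G, 2)
        yy = Wy @ yt                              # (G,)
        beta = np.einsum("gij,gj->gi", self.lam_AXX_inv, bvec)
        rss = np.maximum(yy - np.einsum("gi,gi->g", beta, bvec), _TINY_RSS)
        return (-0.5 * n * (_LOG2PI + np.log(rss / n) + 1.0)
                - 0.5 * self.lam_logdet)

    def lambda_loglik_vec(self, yt: np.ndarray, lams: np.ndarray) -> np.ndarray:
        """Profile log-likelihood at many lambda values, O(G n) total."""
        n = self.n
        W = 1.0 / (lams[:, None] * self.mu[None, :] + (1.0 - lams)[:, None])
        logdet = -np.sum(np.log(W), axis=1) + self.logdetD
        Wy = W * yt[None, :]
        bvec = Wy @ self.Xt_l                     # (G, 2)
        yy = Wy @ yt
        AXX = np.einsum("gn,ni,nj->gij", W, self.Xt_l, self.Xt_l)
        beta = _solve2_batch(AXX, bvec)
        rss = np.maximum(yy - np.einsum("gi,gi->g", beta, bvec), _TINY_RSS)
        return (-0.5 * n * (_LOG2PI + np.log(rss / n) + 1.0) - 0.5 * logdet)

    # -- OU profile --------------------------------------------------------
    def ou_grid_loglik(self, y: np.ndarray) -> np.ndarray:
        n = self.n
        Viy = self.ou_Vinv @ y                    # (G, n)
        XtViy = np.einsum("gni,n->gi", self.ou_ViX, y)
        beta = np.einsum("gij,gj->gi", self.ou_XtViX_inv, XtViy)
        rss = np.maximum(Viy @ y - np.einsum("gi,gi->g", beta, XtViy),
                         _TINY_RSS)
        return (-0.5 * n * (_LOG2PI + np.log(rss / n) + 1.0)
                - 0.5 * self.ou_logdet)

    def ou_loglik_vec(self, y: np.ndarray, alphas: np.ndarray) -> np.ndarray:
        """Profile log-likelihood at many alpha values via batched solves."""
        n = self.n
        a = alphas[:, None, None]
        V0 = (np.exp(-a * self.dmat[None])
              * (1.0 - np.exp(-2.0 * a * self.tmat[None])) / (2.0 * a))
        jit = 1e-12 * V0.reshape(alphas.size, -1)[:, :: n + 1].mean(axis=1)
        V0 = V0 + jit[:, None, None] * np.eye(n)[None]
        _, logdet = np.linalg.slogdet(V0)
        rhs = np.concatenate([y[:, None], self.X], axis=1)   # (n, 3)
        sol = np.linalg.solve(V0, np.broadcast_to(rhs, (alphas.size, n, 3)))
        Viy, ViX = sol[:, :, 0], sol[:, :, 1:]
        XtViy = np.einsum("ni,gn->gi", self.X, Viy)
        XtViX = np.einsum("ni,gnj->gij", self.X, ViX)
        beta = _solve2_batch(XtViX, XtViy)
        rss = np.maximum(Viy @ y - np.einsum("gi,gi->g", beta, XtViy),
                         _TINY_RSS)
        return (-0.5 * n * (_LOG2PI + np.log(rss / n) + 1.0) - 0.5 * logdet)


class PGLSWorkspace:
    """Reusable fitter for one (tree, trait) pair across many features."""

    def __init__(self, tree: PhyloTree, x: pd.Series, species=None,
                 n_lambda_grid: int = 21, n_alpha_grid: int = 20,
                 alpha_range: tuple[float, float] = _DEFAULT_ALPHA_RANGE,
                 lambda_tol: float = 1e-6, alpha_log_tol: float = 1e-2):
        x = pd.Series(x)
        if species is None:
            species = [s for s in tree.tip_labels if s in x.index]
        labels, tmat, dmat, T = tree.path_matrices(list(species))
        if len(labels) < 4:
            raise ValueError("need at least 4 species for model fitting")
        self.species = labels
        self.tmat, self.dmat, self.T = tmat, dmat, T
        self.x = x.reindex(labels).to_numpy(dtype=float)
        if np.isnan(self.x).any():
            raise ValueError("trait undefined for some species")
        depth = float(np.mean(T))
        self.lambda_grid = np.linspace(0.0, 1.0, n_lambda_grid)
        self.alpha_grid = np.geomspace(alpha_range[0] / depth,
                                       alpha_range[1] / depth, n_alpha_grid)
        self.lambda_tol = lambda_tol
        self.alpha_log_tol = alpha_log_tol
        self._caches: dict[frozenset, _SubsetCache] = {}

    def _cache(self, exclude: frozenset) -> _SubsetCache:
        cache = self._caches.get(exclude)
        if cache is None:
            keep = [i for i, s in enumerate(self.species) if s not in exclude]
            if len(keep) < 4:
                raise ValueError("fewer than 4 species left after exclusion")
            ix = np.ix_(keep, keep)
            cache = _SubsetCache(self.tmat[ix], self.dmat[ix], self.T[keep],
                                 self.x[keep], self.lambda_grid,
                                 self.alpha_grid)
            self._caches[exclude] = cache
        return cache

    def fit(self, y, exclude=frozenset(), models=MODELS) -> ModelSelection:
        """Fit the requested evolution models; ``y`` aligned to ``species``."""
        exclude = frozenset(exclude)
        cache = self._cache(exclude)
        if isinstance(y, pd.Series):
            y = y.reindex(self.species).to_numpy(dtype=float)
        else:
            y = np.asarray(y, dtype=float)
        keep = [i for i, s in enumerate(self.species) if s not in exclude]
        ysub = y[keep]
        ysub = ysub - ysub.mean()
        fits: dict[str, GLSFit] = {}
        if "null" in models:
            fits["null"] = cache.packs["null"].fit(ysub, "null", {})
        if "brownian" in models:
            fits["brownian"] = cache.packs["brownian"].fit(ysub, "brownian", {})
        if "lambda" in models:
            fits["lambda"] = self._fit_lambda(cache, ysub)
        if "ou" in models:
            fits["ou"] = self._fit_ou(cache, ysub)
        best = None
        for m in MODELS:
            if m in fits and (best is None
                              or fits[m].loglik > fits[best].loglik):
                best = m
        return ModelSelection(fits=fits, best=best)

    def _fit_lambda(self, cache: _SubsetCache, y: np.ndarray) -> GLSFit:
        yt = cache.P @ y
        lls = cache.lambda_grid_loglik(yt)
        i = int(np.argmax(lls))
        grid = cache.lambda_grid
        best_lam, best_ll = float(grid[i]), float(lls[i])
        lo = float(grid[max(i - 1, 0)])
        hi = float(grid[min(i + 1, grid.size - 1)])
        # nested vectorized grids until the bracket is below lambda_tol
        while hi - lo > self.lambda_tol:
            g = np.linspace(lo, hi, 41)
            lls2 = cache.lambda_loglik_vec(yt, g)
            j = int(np.argmax(lls2))
            if lls2[j] > best_ll:
                best_lam, best_ll = float(g[j]), float(lls2[j])
            lo = float(g[max(j - 1, 0)])
            hi = float(g[min(j + 1, 40)])
        best_lam = min(max(best_lam, 0.0), 1.0)
        return gls_fit(y, cache.X, cache.v_lambda(best_lam),
                       model="lambda", params={"lambda": best_lam})

    def _fit_ou(self, cache: _SubsetCache, y: np.ndarray) -> GLSFit:
        lls = cache.ou_grid_loglik(y)
        i = int(np.argmax(lls))
        grid = cache.alpha_grid
        best_a, best_ll = float(grid[i]), float(lls[i])
        lo = math.log10(grid[max(i - 1, 0)])
        hi = math.log10(grid[min(i + 1, grid.size - 1)])
        while hi - lo > self.alpha_log_tol:
            g = np.linspace(lo, hi, 21)
            lls2 = cache.ou_loglik_vec(y, 10.0 ** g)
            j = int(np.argmax(lls2))
            if lls2[j] > best_ll:
                best_a, best_ll = float(10.0 ** g[j]), float(lls2[j])
            lo = float(g[max(j - 1, 0)])
            hi = float(g[min(j + 1, 20)])
        return gls_fit(y, cache.X, cache.v_ou(best_a),
                       model="ou", params={"alpha": best_a})


def fit_trait_models(y, x, tree: PhyloTree, species=None,
                     models=MODELS) -> ModelSelection:
    """Fit the four evolution models for one feature and pick the ML winner.

    ``y`` is the per-species feature value (log10 scale), ``x`` the
    per-species log10 trait; both are centered internally.  Needs at least
    four species shared between ``y``, ``x`` and the tree.
    """
    if isinstance(x, pd.Series) and isinstance(y, pd.Series) and species is None:
        species = [s for s in tree.tip_labels
                   if s in x.index and s in y.index]
    elif species is None:
        species = list(tree.tip_labels)
    if not isinstance(x, pd.Series):
        x = pd.Series(np.asarray(x, dtype=float), index=species)
    if not isinstance(y, pd.Series):
        y = pd.Series(np.asarray(y, dtype=float), index=species)
    ws = PGLSWorkspace(tree, x, species=species)
    return ws.fit(y.reindex(ws.species), models=models)
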