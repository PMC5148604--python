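"""Lifespan-metabolite regression with group-specific slopes.

For fibroblast panels spanning two taxonomic groups (birds and primates),
log lifespan is regressed on a metabolite level with separate intercepts and
slopes per group:

    full model:    log(ML) ~ group intercepts + group-specific slopes
    reduced model: log(ML) ~ group intercepts only
    F = [(RSS_red - RSS_full) / 2] / [RSS_full / (n - 4)]

Because species are phylogenetically related, parametric F quantiles are not
trusted; significance comes from an empirical null built by permuting the
metabolite values within each group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GroupRegressionResult:
    F: float
    slopes: dict
    intercepts: dict
    rss_full: float
    rss_reduced: float
    n: int
    overflow: bool = False  # exact fit: RSS_full ~ 0, F unbounded


@dataclass
class PermutationResult:
    p_perm: float
    F_obs: float
    B: int
    seed: int
    fit: GroupRegressionResult


def _design(metabolite: np.ndarray, gmask: np.ndarray):
    g0 = (~gmask).astype(float)
    g1 = gmask.astype(float)
    return np.column_stack([g0, g1, metabolite * g0, metabolite * g1])


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r), beta


def group_slope_ftest(lifespan, metabolite, group,
                      min_per_group: int = 3) -> GroupRegressionResult:
    """F-statistic for metabolite association allowing unequal group slopes."""
    lifespan = np.asarray(lifespan, dtype=float)
    metabolite = np.asarray(metabolite, dtype=float)
    group = np.asarray(group)
    levels = sorted(pd.unique(group).tolist())
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    counts = {lv: int((group == lv).sum()) for lv in levels}
    small = [lv for lv, c in counts.items() if c < min_per_group]
    if small:
        raise ValueError(
            f"group(s) with fewer than {min_per_group} species: {small}")
    if (lifespan <= 0).any():
        raise ValueError("lifespan must be positive")
    y = np.log(lifespan)
    gmask = group == levels[1]
    n = y.size
    rss_full, beta = _rss(_design(metabolite, gmask), y)
    rss_red, _ = _rss(np.column_stack([(~gmask).astype(float),
                                       gmask.astype(float)]), y)
    df_resid = n - 4
    if df_resid <= 0:
        raise ValueError("too few species for the full model")
    overflow = rss_full <= 1e-12 * max(rss_red, 1.0)
    if overflow:
        F = np.inf
    else:
        F = ((rss_red - rss_full) / 2.0) / (rss_full / df_resid)
    return GroupRegressionResult(
        F=float(F),
        slopes={levels[0]: float(beta[2]), levels[1]: float(beta[3])},
        intercepts={levels[0]: float(beta[0]), levels[1]: float(beta[1])},
        rss_full=rss_full, rss_reduced=rss_red, n=n, overflow=overflow)


def permutation_pvalue(lifespan, metabolite, group, B: int = 10000,
                       seed: int = 0,
                       min_per_group: int = 3) -> PermutationResult:
    """Add-one permutation p-value for the group-slope F statistic.

    Metabolite values are shuffled independently within each group (lifespans
    and group labels stay fixed), preserving the group structure of the null.
    ``p = (1 + #{F_b >= F_obs}) / (B + 1)``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    obs = group_slope_ftest(lifespan, metabolite, group, min_per_group)
    lifespan = np.asarray(lifespan, dtype=float)
    metabolite = np.asarray(metabolite, dtype=float)
    group = np.asarray(group)
    levels = sorted(pd.unique(group).tolist())
    gmask = group == levels[1]
    y = np.log(lifespan)
    n = y.size
    rng = np.random.default_rng(seed)
    # permuted metabolite matrix, within-group shuffles
    perm = np.tile(metabolite, (B, 1))
    for lv in levels:
        idx = np.where(group == lv)[0]
        block = perm[:, idx]
        perm[:, idx] = rng.permuted(block, axis=1)
    # batched least squares via normal equations (4 regressors)
    g0 = (~gmask).astype(float)
    g1 = gmask.astype(float)
    X = np.empty((B, n, 4))
    X[:, :, 0] = g0
    X[:, :, 1] = g1
    X[:, :, 2] = perm * g0
    X[:, :, 3] = perm * g1
    XtX = np.einsum("bni,bnj->bij", X, X)
    Xty = np.einsum("bni,n->bi", X, y)
    beta = np.linalg.solve(XtX, Xty[:, :, None])[:, :, 0]
    rss_full = y @ y - np.einsum("bi,bi->b", beta, Xty)
    rss_red = obs.rss_reduced
    df_resid = n - 4
    with np.errstate(divide="ignore", invalid="ignore"):
        F_b = ((rss_red - rss_full) / 2.0) / (rss_full / df_resid)
    F_b = np.where(rss_full <= 1e-12 * max(rss_red, 1.0), np.inf, F_b)
    hits = int(np.sum(F_b >= obs.F))
    p = (1.0 + hits) / (B + 1.0)
    return PermutationResult(p_perm=p, F_obs=obs.F, B=B, seed=seed, fit=obs)


def strongest_feature(lifespan, features: pd.DataFrame) -> str:
    """Among features annotated to the same metabolite, the one whose level
    correlates most strongly (|Pearson r|) with log lifespan."""
    y = np.log(np.asarray(lifespan, dtype=float))
    best, best_r = None, -1.0
    for col in features.columns:
        v = features[col].to_numpy(dtype=float)
        r = abs(np.corrcoef(v, y)[0, 1])
        if r > best_r:
            best, best_r = col, r
    return best
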