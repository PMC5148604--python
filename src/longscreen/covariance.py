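"""Phylogenetic variance-covariance matrices for the four trait-evolution models.

The screen's regressions assume residuals are multivariate normal with a
covariance determined by shared evolutionary history.  Four structures are
supported, nested so that likelihoods are directly comparable:

* ``null``      — independent residuals (identity), no phylogenetic signal;
* ``brownian``  — Brownian motion: ``V_ij = sigma2 * t_ij`` where ``t_ij`` is
  the shared root-to-MRCA path length;
* ``lambda``    — Pagel's lambda: Brownian off-diagonals multiplied by
  ``lam`` in [0, 1], diagonal unchanged;
* ``ou``        — Ornstein-Uhlenbeck (non-stationary Hansen form, process
  started at the optimum with zero root variance):
  ``V_ij = sigma2/(2 alpha) * exp(-alpha d_ij) * (1 - exp(-2 alpha t_ij))``.

The OU form reduces to Brownian motion as ``alpha -> 0``, which keeps the
maximum-likelihood model comparison well behaved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trees import PhyloTree

MODELS = ("null", "brownian", "lambda", "ou")


@dataclass
class CovMatrix:
    """A species-labeled covariance matrix tied to an evolution model."""

    labels: list[str]
    V: np.ndarray
    model: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        V = np.asarray(self.V, dtype=float)
        if V.shape != (len(self.labels), len(self.labels)):
            raise ValueError("V shape does not match labels")
        if not np.allclose(V, V.T, atol=1e-10):
            raise ValueError("V is not symmetric")
        self.V = V


def _paths(tree: PhyloTree, labels=None):
    if not tree.rooted:
        raise ValueError("covariance construction requires a rooted tree")
    return tree.path_matrices(labels)


def bm_covariance(tree: PhyloTree, sigma2: float = 1.0,
                  labels=None) -> CovMatrix:
    """Brownian-motion covariance ``V_ij = sigma2 * t_ij``."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    labels, tmat, _, _ = _paths(tree, labels)
    return CovMatrix(labels, sigma2 * tmat, "brownian", {"sigma2": sigma2})


def lambda_covariance(tree: PhyloTree, lam: float, sigma2: float = 1.0,
                      labels=None) -> CovMatrix:
    """Pagel's-lambda covariance: BM off-diagonals scaled by ``lam``."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    labels, tmat, _, T = _paths(tree, labels)
    V = lam * tmat * sigma2
    np.fill_diagonal(V, sigma2 * T)
    return CovMatrix(labels, V, "lambda", {"lambda": lam, "sigma2": sigma2})


def ou_covariance(tree: PhyloTree, alpha: float, sigma2: float = 1.0,
                  labels=None) -> CovMatrix:
    """Ornstein-Uhlenbeck covariance (non-stationary, root at the optimum)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    labels, tmat, dmat, _ = _paths(tree, labels)
    V = sigma2 / (2.0 * alpha) * np.exp(-alpha * dmat) * (
        1.0 - np.exp(-2.0 * alpha * tmat))
    return CovMatrix(labels, V, "ou",
                     {"alpha": alpha, "sigma2": sigma2})


def null_covariance(tree: PhyloTree, sigma2: float = 1.0,
                    labels=None) -> CovMatrix:
    """Independence (identity) covariance — the 'null' evolution model."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    labels, _, _, _ = _paths(tree, labels)
    return CovMatrix(labels, sigma2 * np.eye(len(labels)), "null",
                     {"sigma2": sigma2})


def covariance(tree: PhyloTree, model: str, labels=None, **params) -> CovMatrix:
    """Dispatch on model name; ``params`` are model-specific."""
    if model == "null":
        return null_covariance(tree, params.get("sigma2", 1.0), labels)
    if model == "brownian":
        return bm_covariance(tree, params.get("sigma2", 1.0), labels)
    if model == "lambda":
        if "lam" not in params and "lambda" not in params:
            raise ValueError("lambda model requires 'lam'")
        lam = params.get("lam", params.get("lambda"))
        return lambda_covariance(tree, lam, params.get("sigma2", 1.0), labels)
    if model == "ou":
        if "alpha" not in params:
            raise ValueError("ou model requires 'alpha'")
        return ou_covariance(tree, params["alpha"],
                             params.get("sigma2", 1.0), labels)
    raise ValueError(f"unknown evolution model {model!r}; choose from {MODELS}")
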