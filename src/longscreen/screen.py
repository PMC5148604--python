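"""The two-step robustness screen and multi-trait top-hit calling.

For every feature x trait pair:

1. full fit on all species (``coef.all``, ``p.value.all``);
2. *robust step* — refit leaving out each single species; the exclusion that
   most improves the slope p-value marks the potential outlier, which is
   removed unconditionally, and the minimal p-value is ``p.value.robust``;
3. *max step* — from the outlier-free set, leave out each remaining species
   one at a time and refit; the largest (least significant) p-value is
   ``p.value.max``, guarding against associations carried by one species.

The evolution model is re-selected (all four structures refit) inside every
exclusion refit.  Benjamini-Hochberg q-values are computed per trait across
features for each p column.  A *top hit* satisfies ``p.value.robust < 0.01``
and ``p.value.max < 0.05``; for enrichment input a feature must additionally
be a top hit in two or more longevity traits (AW does not count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .omics import OmicsMatrix
from .pgls import ModelSelection, PGLSWorkspace
from .trees import PhyloTree

logger = logging.getLogger(__name__)

LONGEVITY_TRAITS = ("ML", "FTM", "MLres", "FTMres")
ALL_TRAITS = ("AW",) + LONGEVITY_TRAITS

RECORD_COLUMNS = ["feature", "trait", "coef.all", "p.value.all", "q.value.all",
                  "outlier", "p.value.robust", "q.value.robust",
                  "p.value.max", "q.value.max", "best.model"]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, clipped to [0, 1])."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class RobustResult:
    outlier: str
    p_robust: float
    fit: ModelSelection


def robust_step(y, x=None, tree: PhyloTree | None = None,
                workspace: PGLSWorkspace | None = None) -> RobustResult:
    """Leave-one-out outlier identification (step 1 of the verification).

    Refits the model selection with each single species excluded; the
    exclusion minimizing the slope p-value names the potential outlier
    (ties broken by species-label order) and that minimal p is
    ``p.value.robust``.  The outlier is removed even if no exclusion beats
    the all-species fit.
    """
    ws = _ensure_workspace(workspace, tree, x)
    if len(ws.species) < 5:
        raise ValueError("robust step needs at least 5 species")
    yv = _align_y(ws, y)
    best = None
    for sp in sorted(ws.species):
        sel = ws.fit(yv, exclude={sp})
        p = sel.best_fit.p
        if best is None or p < best[1]:
            best = (sp, p, sel)
    return RobustResult(outlier=best[0], p_robust=best[1], fit=best[2])


def max_step(y, x=None, tree: PhyloTree | None = None,
             outlier: str | None = None,
             workspace: PGLSWorkspace | None = None) -> float:
    """Worst-case p-value over further single-species exclusions (step 2)."""
    ws = _ensure_workspace(workspace, tree, x)
    if outlier is None or outlier not in ws.species:
        raise ValueError("outlier species must be one of the fitted species")
    remaining = [s for s in ws.species if s != outlier]
    if len(remaining) - 1 < 4:
        raise ValueError("fewer than 4 species would remain in the max step")
    yv = _align_y(ws, y)
    p_max = 0.0
    for sp in remaining:
        sel = ws.fit(yv, exclude={outlier, sp})
        p_max = max(p_max, sel.best_fit.p)
    return p_max


def _ensure_workspace(workspace, tree, x) -> PGLSWorkspace:
    if workspace is not None:
        return workspace
    if tree is None or x is None:
        raise ValueError("provide either a workspace or (x, tree)")
    return PGLSWorkspace(tree, pd.Series(x))


def _align_y(ws: PGLSWorkspace, y) -> pd.Series:
    if isinstance(y, pd.Series):
        return y.reindex(ws.species)
    return pd.Series(np.asarray(y, dtype=float), index=ws.species)


def screen_features(matrix: OmicsMatrix, traits: pd.DataFrame,
                    tree: PhyloTree,
                    trait_cols=ALL_TRAITS) -> pd.DataFrame:
    """Run the full two-step screen for every feature against every trait.

    ``matrix`` must be species-level (columns = species).  Species present in
    the matrix, the trait table and the tree are intersected (tree tip
    order); features failing to fit are logged and skipped.  Returns a long
    table with the source-data column layout (``coef.all`` ... ``best.model``).
    """
    species = [s for s in tree.tip_labels
               if s in matrix.sample_ids and s in traits.index]
    if len(species) < 5:
        raise ValueError("need at least 5 species shared by matrix, traits, tree")
    dropped = (set(matrix.sample_ids) | set(traits.index)) - set(species)
    if dropped:
        logger.info("species outside the common set ignored: %s",
                    sorted(dropped))
    rows = []
    for trait in trait_cols:
        if trait not in traits.columns:
            raise ValueError(f"trait column {trait!r} missing from trait table")
        x = np.log10(traits.loc[species, trait].astype(float))
        ws = PGLSWorkspace(tree, x, species=species)
        for feat in matrix.feature_ids:
            y = matrix.values_frame.loc[feat, species].astype(float)
            try:
                full = ws.fit(y)
                rb = robust_step(y, workspace=ws)
                pm = max_step(y, outlier=rb.outlier, workspace=ws)
            except Exception:
                logger.exception("fit failed for feature %s, trait %s",
                                 feat, trait)
                continue
            rows.append({
                "feature": feat, "trait": trait,
                "coef.all": full.best_fit.beta[1],
                "p.value.all": full.best_fit.p,
                "outlier": rb.outlier,
                "p.value.robust": rb.p_robust,
                "p.value.max": pm,
                "best.model": full.best,
            })
    records = pd.DataFrame(rows)
    if records.empty:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    for col in ("all", "robust", "max"):
        records[f"q.value.{col}"] = np.nan
        for trait in records["trait"].unique():
            sel = records["trait"] == trait
            records.loc[sel, f"q.value.{col}"] = bh_adjust(
                records.loc[sel, f"p.value.{col}"].to_numpy())
    return records[RECORD_COLUMNS].reset_index(drop=True)


def call_top_hits(records: pd.DataFrame, p_robust_cut: float = 0.01,
                  p_max_cut: float = 0.05, min_traits: int = 2,
                  longevity_traits=LONGEVITY_TRAITS) -> pd.DataFrame:
    """Features passing both cuts in at least ``min_traits`` longevity traits.

    Adult weight is never counted as a supporting trait.  Returns one row per
    called feature with the supporting traits and per-trait slope signs.
    """
    need = set(longevity_traits) - set(records["trait"].unique())
    if need:
        raise ValueError(f"records missing longevity trait(s): {sorted(need)}")
    out = []
    for feat, grp in records.groupby("feature", sort=True):
        grp = grp.set_index("trait")
        support = [t for t in longevity_traits
                   if t in grp.index
                   and grp.loc[t, "p.value.robust"] < p_robust_cut
                   and grp.loc[t, "p.value.max"] < p_max_cut]
        if len(support) < min_traits:
            continue
        signs = ["+" if grp.loc[t, "coef.all"] > 0 else "-" for t in support]
        out.append({"feature": feat, "n_traits": len(support),
                    "traits": ",".join(support),
                    "directions": ",".join(signs)})
    return pd.DataFrame(out, columns=["feature", "n_traits", "traits",
                                      "directions"])
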