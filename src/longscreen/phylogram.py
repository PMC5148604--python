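"""Data-driven phylograms and nucleotide distances.

Samples are clustered by ``1 - Pearson correlation`` of their (standardized)
expression or metabolite profiles, a neighbor-joining tree is built on that
distance, and branching reliability is assessed by bootstrap over features.
Kimura two-parameter distances quantify sequence divergence within ortholog
sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .trees import PhyloTree

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """K2P distance undefined: substitutions have saturated."""


@dataclass
class DistanceMatrix:
    labels: list[str]
    D: np.ndarray

    def __post_init__(self):
        D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if D.shape != (n, n):
            raise ValueError("D shape does not match labels")
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(D), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        self.D = D

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.labels, columns=self.labels)


@dataclass
class K2PResult:
    P: float
    Q: float
    d: float
    n_sites: int


def correlation_distance(values) -> DistanceMatrix:
    """``D_ij = 1 - Pearson(sample_i, sample_j)`` over feature profiles.

    ``values`` is a features x samples DataFrame (or an object with a
    ``.values`` DataFrame attribute, e.g. an OmicsMatrix).
    """
    df = getattr(values, "values_frame", None)
    if df is None:
        df = values if isinstance(values, pd.DataFrame) else pd.DataFrame(values)
    if df.shape[0] < 2:
        raise ValueError("need at least 2 features to correlate samples")
    sds = df.std(axis=0, ddof=0)
    dead = sds[sds == 0].index.tolist()
    if dead:
        raise ValueError(f"zero-variance sample column(s): {dead}")
    corr = np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
    D = 1.0 - corr
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)
    return DistanceMatrix(list(df.columns), D)


def neighbor_joining(dist: DistanceMatrix) -> PhyloTree:
    """Neighbor joining (Studier-Keppler Q-criterion).

    On an additive distance matrix the returned tree's patristic distances
    reproduce the input exactly.  Negative branch-length estimates are clamped
    to zero with the deficit moved to the sibling branch.  Ties in Q are
    broken by the smallest (row, column) index pair, so the result is
    deterministic.  The tree is returned unrooted (trifurcating seed node).
    """
    n = len(dist.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dist.D.copy()
    taxa = dendropy.TaxonNamespace(list(dist.labels))
    nodes = []
    for lab in dist.labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(nd)
    active = list(range(n))

    def clamp(li, lj):
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        return li, lj

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (m - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major: first minimum = smallest (i, j)
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (R[ai] - R[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        # distances from the new node to the remaining taxa
        new_row = np.zeros(D.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (D[i, ak] + D[j, ak] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = dendropy.Node()
    for node, length in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        root.add_child(node)
        node.edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    return PhyloTree(tree, rooted=False)


def _bipartitions(tree: PhyloTree) -> set[frozenset]:
    """Non-trivial splits of the tip set, canonicalized to the smaller side."""
    tips = set(tree.tip_labels)
    splits = set()
    dtree = tree._tree
    for node in dtree.postorder_node_iter():
        if node is dtree.seed_node:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(below) < 2 or len(below) > len(tips) - 2:
            continue
        other = frozenset(tips - below)
        splits.add(min(below, other, key=lambda s: (len(s), tuple(sorted(s)))))
    return splits


def bootstrap_support(values, n_boot: int = 1000, seed: int = 0):
    """NJ phylogram with per-edge bootstrap support.

    Features (rows) are resampled with replacement ``n_boot`` times; the
    correlation-distance NJ tree is rebuilt each time and support for each
    internal edge of the point-estimate tree is the fraction of replicates
    containing that bipartition.  Returns ``(tree, supports)`` where
    ``supports`` maps the canonical bipartition (frozenset of tip labels) to
    a fraction in [0, 1]; the tree's internal nodes carry the supports as
    labels.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    df = getattr(values, "values_frame", None)
    if df is None:
        df = values if isinstance(values, pd.DataFrame) else pd.DataFrame(values)
    if df.shape[0] < 2:
        raise ValueError("need at least 2 features to bootstrap")
    rng = np.random.default_rng(seed)
    point = neighbor_joining(correlation_distance(df))
    target = _bipartitions(point)
    counts = {s: 0 for s in target}
    nrow = df.shape[0]
    for _ in range(n_boot):
        rows = rng.integers(0, nrow, size=nrow)
        boot = df.iloc[rows]
        try:
            reps = _bipartitions(neighbor_joining(correlation_distance(boot)))
        except ValueError:
            continue  # degenerate resample (zero-variance column)
        for s in target:
            if s in reps:
                counts[s] += 1
    supports = {s: c / n_boot for s, c in counts.items()}
    # annotate internal nodes of the point tree
    tips = set(point.tip_labels)
    dtree = point._tree
    for node in dtree.postorder_internal_node_iter():
        if node is dtree.seed_node:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        key = min(below, frozenset(tips - below),
                  key=lambda s: (len(s), tuple(sorted(s))))
        if key in supports:
            node.label = f"{supports[key]:.4g}"
    return point, supports


def kimura_2p(seq_a: str, seq_b: str) -> K2PResult:
    """Kimura two-parameter distance between aligned nucleotide sequences.

    Sites where either sequence has a non-ACGT symbol are excluded pairwise.
    ``d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)`` with P the transition and Q
    the transversion proportion; raises :class:`SaturationError` where the
    logarithms are undefined.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    a = seq_a.upper()
    b = seq_b.upper()
    n_sites = transitions = transversions = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n_sites += 1
        if x == y:
            continue
        same_class = ({x, y} <= PURINES) or ({x, y} <= PYRIMIDINES)
        if same_class:
            transitions += 1
        else:
            transversions += 1
    if n_sites == 0:
        raise ValueError("no comparable ACGT sites")
    P = transitions / n_sites
    Q = transversions / n_sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"distance undefined at P={P:.4g}, Q={Q:.4g} (saturated)")
    d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    return K2PResult(P=P, Q=Q, d=float(d), n_sites=n_sites)
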