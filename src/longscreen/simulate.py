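"""Synthetic data with the statistical structure the screen assumes.

Every downstream stage — normalization, phylogenetic regression, the two-step
robustness screen, enrichment, the auxiliary analyses — can be exercised and
calibrated on data from this module, with truth tables recording what was
planted.  All generators are driven by numpy's PCG64 (``default_rng``) so a
fixed seed is bit-reproducible and portable.

Default conditions emulate the fibroblast study design: ~15 species spanning
adult weights of 10 g to 20 kg and maximum lifespans of a few to tens of
years, thousands of gene features with a ~10% associated fraction, replicate
samples, three metabolite acquisition modes with internal standards, and
phylogenetically correlated residual noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import norm

from .covariance import MODELS as EVO_MODELS, covariance as build_covariance
from .omics import OmicsMatrix
from .traits import FTM_ALLOMETRY, ML_ALLOMETRY, build_trait_table
from .trees import PhyloTree

DEFAULT_MODES = ("HILIC-pos", "HILIC-neg", "C8-pos")


@dataclass
class SimulationConfig:
    """Conditions for an expression-screen simulation."""

    n_species: int = 15
    n_genes: int = 9389
    frac_associated: float = 0.10
    slope_mean: float = 1.0
    slope_sd: float = 0.2
    evo_model: str = "brownian"
    evo_params: dict = field(default_factory=lambda: {"sigma2": 0.04})
    replicate_noise_sd: float = 0.1
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2 or self.n_genes < 1:
            raise ValueError("n_species >= 2 and n_genes >= 1 required")
        if not 0.0 <= self.frac_associated <= 1.0:
            raise ValueError("frac_associated must be in [0, 1]")
        if self.replicate_noise_sd < 0:
            raise ValueError("replicate_noise_sd must be nonnegative")
        if self.evo_model not in EVO_MODELS:
            raise ValueError(f"evo_model must be one of {EVO_MODELS}")
        p = self.evo_params
        if p.get("sigma2", 0.0) <= 0:
            raise ValueError("evo_params must include sigma2 > 0")
        if self.evo_model == "lambda":
            lam = p.get("lambda", p.get("lam"))
            if lam is None or not 0.0 <= lam <= 1.0:
                raise ValueError("lambda model needs 'lambda' in [0, 1]")
        if self.evo_model == "ou" and p.get("alpha", 0.0) <= 0:
            raise ValueError("ou model needs alpha > 0")

    @property
    def n_associated(self) -> int:
        return int(round(self.frac_associated * self.n_genes))


def gen_tree(n_tips: int, seed: int) -> PhyloTree:
    """Ultrametric pure-birth (Yule) tree, scaled to unit root-to-tip depth.

    Tip labels are ``sp01, sp02, ...`` in tree traversal order.
    """
    if n_tips < 2:
        raise ValueError("a tree needs at least 2 tips")
    rng = np.random.default_rng(seed)
    root = dendropy.Node()
    birth = {id(root): 0.0}
    active = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        birth[id(child)] = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        node = active.pop(rng.integers(k))
        node.edge.length = t - birth[id(node)]
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            birth[id(child)] = t
            active.append(child)
    total = t + rng.exponential(1.0 / n_tips)
    for node in active:
        node.edge.length = total - birth[id(node)]
    width = max(2, len(str(n_tips)))
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    i = 0
    for leaf in tree.leaf_node_iter():
        i += 1
        leaf.taxon = taxa.new_taxon(f"sp{i:0{width}d}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= total
    return PhyloTree(tree, rooted=True)


def gen_traits(tree: PhyloTree, seed: int,
               aw_range: tuple[float, float] = (10.0, 20000.0),
               bm_sd: float = 0.4) -> pd.DataFrame:
    """Life-history table for the tree's tips.

    Adult weight is log-uniform over ``aw_range`` (grams); ML and FTM follow
    the allometric laws ``4.88 AW^0.153`` (years) and ``78.1 AW^0.217`` (days)
    times a lognormal deviate whose log evolves by Brownian motion on the
    tree (sd ``bm_sd`` at the tips; 0 gives exact allometry, MLres = 1).
    """
    rng = np.random.default_rng(seed)
    labels, tmat, _, _ = tree.path_matrices()
    n = len(labels)
    aw = np.exp(rng.uniform(np.log(aw_range[0]), np.log(aw_range[1]), size=n))
    L = np.linalg.cholesky(tmat + 1e-12 * np.eye(n))
    eps_ml = bm_sd * (L @ rng.standard_normal(n)) if bm_sd > 0 else np.zeros(n)
    eps_ftm = bm_sd * (L @ rng.standard_normal(n)) if bm_sd > 0 else np.zeros(n)
    ml = ML_ALLOMETRY.predict(aw) * np.exp(eps_ml)
    ftm = FTM_ALLOMETRY.predict(aw) * np.exp(eps_ftm)
    df = pd.DataFrame({"AW": aw, "ML": ml, "FTM": ftm}, index=labels)
    df.index.name = "species"
    return build_trait_table(df)


def gen_expression(tree: PhyloTree, trait: pd.Series,
                   config: SimulationConfig):
    """Expression matrix with a planted trait-associated fraction.

    For associated features ``y = a + b * log10(trait) + eta`` with ``eta``
    multivariate normal under ``config.evo_model``; non-associated features
    have ``b = 0``.  With ``n_replicates > 1`` each species contributes that
    many columns with i.i.d. within-species noise (``replicate_noise_sd``)
    added on the log10 scale.  Returns ``(OmicsMatrix, truth)`` where
    ``truth`` records each feature's true slope.
    """
    labels = list(tree.tip_labels)
    trait = pd.Series(trait).reindex(labels)
    if trait.isna().any() or (trait <= 0).any():
        raise ValueError("trait must be positive and defined for every tip")
    rng = np.random.default_rng(config.seed)
    x = np.log10(trait.to_numpy(dtype=float))
    n_sp, n_genes = len(labels), config.n_genes
    V = build_covariance(tree, config.evo_model, labels=labels,
                         **config.evo_params).V
    jitter = 1e-12 * float(np.mean(np.diag(V)))
    L = np.linalg.cholesky(V + jitter * np.eye(n_sp))
    b = np.zeros(n_genes)
    n_assoc = config.n_associated
    if n_assoc:
        signs = rng.choice([-1.0, 1.0], size=n_assoc)
        b[:n_assoc] = signs * rng.normal(config.slope_mean, config.slope_sd,
                                         size=n_assoc)
    a = rng.normal(3.0, 0.5, size=n_genes)
    eta = rng.standard_normal((n_genes, n_sp)) @ L.T
    species_vals = a[:, None] + np.outer(b, x) + eta
    width = max(2, len(str(n_genes)))
    genes = [f"g{i + 1:0{width}d}" for i in range(n_genes)]
    cols, species_of = [], {}
    blocks = []
    for r in range(config.n_replicates):
        noise = (rng.standard_normal((n_genes, n_sp)) * config.replicate_noise_sd
                 if config.replicate_noise_sd > 0 else 0.0)
        blocks.append(species_vals + noise)
    data = np.empty((n_genes, n_sp * config.n_replicates))
    for si, sp in enumerate(labels):
        for r in range(config.n_replicates):
            col = f"{sp}_r{r + 1}"
            cols.append(col)
            species_of[col] = sp
            data[:, len(cols) - 1] = blocks[r][:, si]
    vf = pd.DataFrame(data, index=genes, columns=cols)
    om = OmicsMatrix(vf, pd.Series(species_of), ["gen_expression"])
    truth = pd.DataFrame({"b": b, "associated": b != 0.0}, index=genes)
    truth.index.name = "feature"
    return om, truth


def gen_counts(n_genes: int, n_samples: int, lib_sizes, seed: int,
               dispersion: float = 0.1, n_low: int = 0, n_high: int = 0):
    """Negative-binomial count matrix with optional planted pathologies.

    ``n_high`` features are forced to hold 10% of each sample's total
    (violating the >5% rule); ``n_low`` features get Poisson(2) counts
    (violating the <10-counts-in->=4-samples rule).  Returns
    ``(OmicsMatrix, planted)`` with the planted feature IDs per rule.
    """
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if lib_sizes.size != n_samples:
        raise ValueError("lib_sizes must have length n_samples")
    rng = np.random.default_rng(seed)
    rel = rng.lognormal(0.0, 1.0, size=n_genes)
    rel /= rel.sum()
    mean = np.outer(rel, lib_sizes)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    counts = rng.poisson(lam).astype(np.int64)
    width = max(2, len(str(n_genes)))
    genes = [f"g{i + 1:0{width}d}" for i in range(n_genes)]
    frames = [pd.DataFrame(
        counts, index=genes,
        columns=[f"s{j + 1:02d}" for j in range(n_samples)])]
    planted = {"high": [], "low": []}
    for i in range(n_low):
        name = f"lowcount{i + 1:02d}"
        planted["low"].append(name)
        frames.append(pd.DataFrame(
            rng.poisson(2.0, size=(1, n_samples)).astype(np.int64),
            index=[name], columns=frames[0].columns))
    vf = pd.concat(frames)
    for i in range(n_high):
        name = f"highcount{i + 1:02d}"
        planted["high"].append(name)
        rest = vf.sum(axis=0).to_numpy()
        row = np.ceil(0.10 * rest / 0.90).astype(np.int64)
        vf.loc[name] = row
    om = OmicsMatrix(vf, None, ["gen_counts"])
    return om, planted


@dataclass
class MetaboliteSim:
    raw: pd.DataFrame            # metabolites x samples, NaN = missing
    mode_map: pd.Series          # metabolite -> acquisition mode
    standards: pd.DataFrame      # modes x samples internal-standard readings
    clean: pd.DataFrame          # batch-free raw intensities
    batch: pd.DataFrame          # modes x samples multiplicative factors
    planted_missing: list[str]


def gen_metabolites(n_metabolites: int, n_samples: int,
                    modes=DEFAULT_MODES, missing_rate: float = 0.0,
                    seed: int = 0, n_planted_missing: int = 0,
                    batch_sd: float = 0.25) -> MetaboliteSim:
    """Raw intensity table in three acquisition modes with internal standards.

    Intensities are log-normal; each (mode, sample) carries a multiplicative
    batch factor that also multiplies that mode's internal standard, so the
    factor cancels exactly under internal-standard division.  Missing cells
    are injected completely at random at ``missing_rate``; additionally
    ``n_planted_missing`` metabolites get >= 10% missingness planted.
    """
    if len(modes) != 3:
        raise ValueError("exactly three acquisition modes expected")
    rng = np.random.default_rng(seed)
    samples = [f"s{j + 1:02d}" for j in range(n_samples)]
    width = max(2, len(str(n_metabolites)))
    mets = [f"m{i + 1:0{width}d}" for i in range(n_metabolites)]
    mode_map = pd.Series([modes[i % 3] for i in range(n_metabolites)],
                         index=mets)
    base = rng.lognormal(12.0, 1.0, size=n_metabolites)
    noise = rng.lognormal(0.0, 0.2, size=(n_metabolites, n_samples))
    clean = pd.DataFrame(base[:, None] * noise, index=mets, columns=samples)
    batch = pd.DataFrame(
        rng.lognormal(0.0, batch_sd, size=(3, n_samples)),
        index=list(modes), columns=samples)
    raw = clean.mul(batch.loc[mode_map].set_axis(mets), axis=0)
    standards = batch * 1e6  # IS base reading of 1e6 per mode
    if missing_rate > 0:
        holes = rng.random(raw.shape) < missing_rate
        raw = raw.mask(holes)
    planted = []
    n_miss = int(np.ceil(0.10 * n_samples))
    for i in range(n_planted_missing):
        m = mets[i]
        planted.append(m)
        cols = rng.choice(n_samples, size=n_miss, replace=False)
        raw.iloc[raw.index.get_loc(m), cols] = np.nan
    return MetaboliteSim(raw=raw, mode_map=mode_map, standards=standards,
                         clean=clean, batch=batch, planted_missing=planted)


def gen_dose_response(ld50: float, slope: float, doses, n_per_dose: int,
                      seed: int) -> pd.DataFrame:
    """Binomial survival counts with ``P(survive) = Phi(slope * (ld50 - dose))``."""
    if slope == 0:
        raise ValueError("slope must be nonzero")
    if ld50 <= 0:
        raise ValueError("ld50 must be positive")
    doses = np.asarray(doses, dtype=float)
    rng = np.random.default_rng(seed)
    p = norm.cdf(slope * (ld50 - doses))
    surv = rng.binomial(n_per_dose, p)
    return pd.DataFrame({"dose": doses, "n_survived": surv,
                         "n_total": np.full(doses.size, n_per_dose)})
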