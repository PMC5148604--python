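"""End-to-end orchestration: normalize -> traits -> screen -> top hits -> enrichment.

A run is configured by a single YAML file, validated up front, and produces a
run directory containing the association records, top-hit calls, enrichment
table, phylogram, PCA coordinates, a log, and a manifest (config hash,
package version, per-stage row counts) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import normalize as nz
from . import screen as sc
from .omics import OmicsMatrix
from .phylogram import bootstrap_support
from .simulate import SimulationConfig, gen_expression, gen_traits, gen_tree
from .enrichment import hypergeom_enrich, read_gmt
from .traits import read_traits_csv
from .trees import read_newick, write_newick_file

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    matrix: str
    traits: str
    tree: str
    out_dir: str
    species_map: str | None = None
    annotations: str | None = None
    trait_cols: list[str] = field(
        default_factory=lambda: list(sc.ALL_TRAITS))
    p_robust_cut: float = 0.01
    p_max_cut: float = 0.05
    min_traits: int = 2
    normalization: str = "none"      # none | counts
    trim_m: float = 0.30
    trim_a: float = 0.05
    pseudo_offset: float = 0.5
    n_boot: int = 200
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for key in ("matrix", "traits", "tree"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"{key} file not found: {p}")
        for key in ("species_map", "annotations"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key} file not found: {p}")
        for cut in (self.p_robust_cut, self.p_max_cut):
            if not 0.0 < cut <= 1.0:
                raise ValueError("thresholds must lie in (0, 1]")
        if self.normalization not in ("none", "counts"):
            raise ValueError("normalization must be 'none' or 'counts'")


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage; returns the run directory."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("longscreen")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    counts: dict[str, int] = {}
    try:
        stage = "load"
        tree = read_newick(cfg.tree)
        traits = read_traits_csv(cfg.traits)
        matrix = OmicsMatrix.from_tsv(cfg.matrix, cfg.species_map)
        counts["features_in"] = matrix.shape[0]
        counts["samples_in"] = matrix.shape[1]

        if cfg.normalization == "counts":
            stage = "normalize"
            rep = nz.filter_counts(matrix)
            logger.info("filtered %d high-count, %d low-count features",
                        len(rep.removed_high), len(rep.removed_low))
            matrix = rep.matrix
            factors = nz.tmm_factors(matrix, cfg.trim_m, cfg.trim_a)
            totals = matrix.values_frame.sum(axis=0)
            eff = factors * totals
            eff = eff / np.exp(np.log(eff).mean())
            matrix = nz.log_quantile_normalize(matrix, eff,
                                               pseudo_offset=cfg.pseudo_offset)
        counts["features_normalized"] = matrix.shape[0]

        stage = "phylogram"
        std = nz.standardize_features(matrix)
        ptree, _ = bootstrap_support(std.values_frame, n_boot=cfg.n_boot,
                                     seed=cfg.seed)
        write_newick_file(ptree, out / "phylogram.nwk")
        coords, varfrac = nz.pca_project(std, n_components=3)
        coords.to_csv(out / "pca.tsv", sep="\t", index_label="sample")
        (out / "pca_variance.json").write_text(
            json.dumps({"variance_fraction": varfrac.tolist()}) + "\n")

        stage = "average_replicates"
        if matrix.sample_species is not None:
            species_matrix, _ = nz.average_replicates(matrix)
        else:
            species_matrix = matrix
        counts["species"] = species_matrix.shape[1]

        stage = "screen"
        records = sc.screen_features(species_matrix, traits, tree,
                                     trait_cols=cfg.trait_cols)
        records.to_csv(out / "records.tsv", sep="\t", index=False)
        counts["records"] = len(records)

        stage = "top_hits"
        longevity = [t for t in cfg.trait_cols if t != "AW"]
        hits = sc.call_top_hits(records, cfg.p_robust_cut, cfg.p_max_cut,
                                cfg.min_traits, longevity_traits=longevity)
        hits.to_csv(out / "tophits.tsv", sep="\t", index=False)
        counts["top_hits"] = len(hits)

        if cfg.annotations:
            stage = "enrichment"
            annot = read_gmt(cfg.annotations)
            universe = set(species_matrix.feature_ids)
            hit_set = set(hits["feature"]) & universe
            enr = hypergeom_enrich(hit_set, annot, universe)
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            counts["enrichment_sets"] = len(enr)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()

    manifest = {"version": __version__, "config": asdict(cfg),
                "config_hash": _config_hash(cfg), "stage_rows": counts}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return out


def make_demo(out_dir, seed: int = 1, n_species: int = 15,
              n_genes: int = 120, frac_associated: float = 0.10) -> Path:
    """Write a self-contained synthetic demo (inputs + config) and return the
    config path.  The demo emulates the fibroblast screen at reduced width."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = gen_tree(n_species, seed)
    write_newick_file(tree, out / "tree.nwk")
    traits = gen_traits(tree, seed + 1)
    tdf = traits[["AW", "ML", "FTM"]].rename(
        columns={"AW": "AW_g", "ML": "ML_yr", "FTM": "FTM_d"})
    tdf.to_csv(out / "traits.csv", index_label="species")
    simcfg = SimulationConfig(n_species=n_species, n_genes=n_genes,
                              frac_associated=frac_associated, seed=seed + 2)
    om, truth = gen_expression(tree, traits["ML"], simcfg)
    om.to_tsv(out / "expression.tsv", out / "samples.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t")
    cfg = RunConfig(matrix=str(out / "expression.tsv"),
                    species_map=str(out / "samples.tsv"),
                    traits=str(out / "traits.csv"),
                    tree=str(out / "tree.nwk"),
                    out_dir=str(out / "run"),
                    normalization="none", n_boot=50, seed=seed)
    (out / "config.yaml").write_text(yaml.safe_dump(asdict(cfg)))
    return out / "config.yaml"
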