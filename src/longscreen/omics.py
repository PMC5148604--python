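"""The features x samples container shared by all normalization stages."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class OmicsMatrix:
    """A numeric features x samples matrix with species mapping and provenance.

    ``values_frame`` holds the data (rows = features, columns = samples).
    ``sample_species`` maps sample IDs to species labels (optional until
    replicate averaging).  ``mask`` marks missing cells (metabolites only);
    masked cells hold NaN in ``values_frame``.  ``provenance`` is the
    append-only list of transforms applied so far.
    """

    values_frame: pd.DataFrame
    sample_species: pd.Series | None = None
    provenance: list[str] = field(default_factory=list)
    mask: pd.DataFrame | None = None

    def __post_init__(self):
        vf = self.values_frame
        if vf.index.duplicated().any():
            raise ValueError("duplicate feature IDs")
        if vf.columns.duplicated().any():
            raise ValueError("duplicate sample IDs")
        if self.sample_species is not None:
            self.sample_species = pd.Series(self.sample_species)
            missing = set(vf.columns) - set(self.sample_species.index)
            if missing:
                raise ValueError(
                    f"samples without species mapping: {sorted(missing)}")
        if self.mask is not None and self.mask.shape != vf.shape:
            raise ValueError("mask shape does not match values")

    # convenience -----------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values_frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values_frame.columns)

    @property
    def shape(self):
        return self.values_frame.shape

    def species_of(self, sample: str) -> str:
        if self.sample_species is None:
            raise ValueError("no sample->species map attached")
        return self.sample_species[sample]

    def evolve(self, values: pd.DataFrame, step: str,
               mask: pd.DataFrame | None = None) -> "OmicsMatrix":
        """New matrix with an extra provenance entry; mapping is carried over."""
        species = None
        if self.sample_species is not None:
            species = self.sample_species.reindex(values.columns)
        return OmicsMatrix(values, species,
                           self.provenance + [step], mask)

    # I/O --------------------------------------------------------------------
    def to_tsv(self, path, species_path=None, provenance_path=None) -> None:
        self.values_frame.to_csv(path, sep="\t", index_label="feature")
        if species_path is not None and self.sample_species is not None:
            self.sample_species.rename("species").to_csv(
                species_path, sep="\t", index_label="sample")
        if provenance_path is not None:
            Path(provenance_path).write_text(
                json.dumps({"provenance": self.provenance}, indent=2) + "\n")

    @classmethod
    def from_tsv(cls, path, species_path=None) -> "OmicsMatrix":
        vf = pd.read_csv(path, sep="\t", index_col=0)
        species = None
        if species_path is not None:
            sdf = pd.read_csv(species_path, sep="\t", index_col=0)
            species = sdf.iloc[:, 0]
        mask = vf.isna() if vf.isna().any().any() else None
        return cls(vf, species, [f"loaded:{Path(path).name}"], mask)
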