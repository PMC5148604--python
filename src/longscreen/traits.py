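"""Life-history traits and body-mass-adjusted longevity residuals.

Both maximum lifespan (ML, years) and female time to maturity (FTM, days)
scale allometrically with adult weight (AW, grams).  The residuals

    MLres  = ML  / (4.88 * AW**0.153)
    FTMres = FTM / (78.1 * AW**0.217)

are the ratio of observed to mass-expected longevity and serve as
mass-adjusted longevity traits in the screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

# plausible ranges for unit sanity checks (grams, years, days)
_PLAUSIBLE = {"AW": (0.5, 5e6), "ML": (0.1, 250.0), "FTM": (5.0, 2e4)}


@dataclass(frozen=True)
class AllometricModel:
    """Power law ``trait = c * AW**k`` used to form residual ratios."""

    c: float
    k: float

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("scale constant c must be positive")

    def predict(self, aw):
        return self.c * np.asarray(aw, dtype=float) ** self.k

    def residual(self, trait, aw):
        trait = np.asarray(trait, dtype=float)
        aw = np.asarray(aw, dtype=float)
        if (trait <= 0).any() or (aw <= 0).any():
            raise ValueError("trait and AW must be strictly positive")
        return trait / self.predict(aw)


ML_ALLOMETRY = AllometricModel(c=4.88, k=0.153)
FTM_ALLOMETRY = AllometricModel(c=78.1, k=0.217)


def compute_residual(trait, aw, model: AllometricModel):
    """``trait / (c * AW**k)`` — observed over mass-expected longevity."""
    return model.residual(trait, aw)


def compute_mlres(ml, aw):
    """Maximum-lifespan residual; ML in years, AW in grams."""
    return compute_residual(ml, aw, ML_ALLOMETRY)


def compute_ftmres(ftm, aw):
    """Female-time-to-maturity residual; FTM in days, AW in grams."""
    return compute_residual(ftm, aw, FTM_ALLOMETRY)


def fit_allometry(aw, trait) -> AllometricModel:
    """OLS of log10(trait) on log10(AW); returns ``c = 10**intercept, k = slope``."""
    aw = np.asarray(aw, dtype=float)
    trait = np.asarray(trait, dtype=float)
    if aw.size < 3:
        raise ValueError("need at least 3 species to fit an allometry")
    if (aw <= 0).any() or (trait <= 0).any():
        raise ValueError("AW and trait must be strictly positive")
    X = np.column_stack([np.ones_like(aw), np.log10(aw)])
    coef, *_ = np.linalg.lstsq(X, np.log10(trait), rcond=None)
    return AllometricModel(c=float(10.0 ** coef[0]), k=float(coef[1]))


def build_trait_table(df: pd.DataFrame) -> pd.DataFrame:
    """Attach MLres/FTMres to a table with AW/ML/FTM columns (index = species)."""
    required = {"AW", "ML", "FTM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    for col in ("AW", "ML", "FTM"):
        vals = df[col]
        if (vals <= 0).any():
            bad = list(df.index[vals <= 0])
            raise ValueError(f"nonpositive {col} for species {bad}")
        lo, hi = _PLAUSIBLE[col]
        odd = df.index[(vals < lo) | (vals > hi)]
        if len(odd):
            warnings.warn(
                f"{col} outside plausible range [{lo}, {hi}] for "
                f"{list(odd)} — check units (AW g, ML yr, FTM d)")
    out = df.copy()
    out["MLres"] = compute_mlres(df["ML"].to_numpy(), df["AW"].to_numpy())
    out["FTMres"] = compute_ftmres(df["FTM"].to_numpy(), df["AW"].to_numpy())
    return out


def read_traits_csv(path) -> pd.DataFrame:
    """Read an AnAge-style CSV (species, AW_g, ML_yr, FTM_d) and add residuals."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    renames = {}
    for want, aliases in (("species", ("species",)),
                          ("AW", ("aw_g", "aw")),
                          ("ML", ("ml_yr", "ml")),
                          ("FTM", ("ftm_d", "ftm"))):
        for a in aliases:
            if a in cols:
                renames[cols[a]] = want
                break
        else:
            raise ValueError(f"traits CSV lacks a column for {want}")
    df = df.rename(columns=renames).set_index("species")
    if df.index.duplicated().any():
        raise ValueError("duplicate species in traits CSV")
    return build_trait_table(df[["AW", "ML", "FTM"]])
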