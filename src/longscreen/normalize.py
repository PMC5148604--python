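"""Count filtering, TMM scaling, quantile normalization, metabolite processing.

This is the processing stage between a raw count/intensity matrix and the
species-level matrix the phylogenetic screen consumes:

counts:       filter -> TMM scale -> log10 -> quantile normalize
metabolites:  internal-standard / total-signal scaling per acquisition mode
              -> <10% missingness filter -> log10 -> quantile normalize
then:         replicate averaging, per-feature standardization, PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .omics import OmicsMatrix

HIGH_COUNT_FRACTION = 0.05   # remove features holding >5% of a sample's total
LOW_COUNT_THRESHOLD = 10     # ...or with <10 counts
LOW_COUNT_MIN_SAMPLES = 4    # ...in at least this many samples
MAX_MISSING_FRACTION = 0.10  # metabolites with >=10% missing cells are dropped


@dataclass
class FilterReport:
    matrix: OmicsMatrix
    removed_high: list[str]
    removed_low: list[str]


def filter_counts(counts: OmicsMatrix) -> FilterReport:
    """Drop features with extreme counts.

    A feature is removed if it contributes more than 5% of the total counts of
    any one sample, or if it has fewer than 10 counts in four or more samples.
    Totals are those of the input matrix (single pass).
    """
    vf = counts.values_frame
    arr = vf.to_numpy()
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integers")
    totals = arr.sum(axis=0)
    high = (arr > HIGH_COUNT_FRACTION * totals[None, :]).any(axis=1)
    low = (arr < LOW_COUNT_THRESHOLD).sum(axis=1) >= LOW_COUNT_MIN_SAMPLES
    keep = ~(high | low)
    out = counts.evolve(vf.loc[keep], "filter_counts")
    return FilterReport(out,
                        removed_high=list(vf.index[high]),
                        removed_low=list(vf.index[low]))


def tmm_factors(counts: OmicsMatrix, trim_m: float = 0.30,
                trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors, rescaled so their product is 1.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of those fractions.  Per non-reference sample, gene
    log-ratios M and average log-abundances A versus the reference are doubly
    trimmed (``trim_m`` from each M tail, ``trim_a`` from each A tail) and the
    factor is 2 to the precision-weighted mean of the retained M values.
    """
    vf = counts.values_frame
    arr = vf.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    totals = arr.sum(axis=0)
    if (totals == 0).any():
        bad = [vf.columns[i] for i in np.where(totals == 0)[0]]
        raise ValueError(f"all-zero sample column(s): {bad}")
    f75 = np.array([np.quantile(arr[:, s] / totals[s], 0.75)
                    for s in range(arr.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    log_factors = np.zeros(arr.shape[1])
    for s in range(arr.shape[1]):
        if s == ref:
            continue
        log_factors[s] = _tmm_pair(arr[:, s], totals[s],
                                   arr[:, ref], totals[ref], trim_m, trim_a)
    factors = 2.0 ** (log_factors - log_factors.mean())  # product == 1
    return pd.Series(factors, index=vf.columns, name="tmm_factor")


def _tmm_pair(obs, n_obs, ref, n_ref, trim_m, trim_a) -> float:
    """Weighted trimmed mean of M values of one sample against the reference."""
    pos = (obs > 0) & (ref > 0)
    obs, ref = obs[pos], ref[pos]
    if obs.size == 0:
        return 0.0
    p_obs = obs / n_obs
    p_ref = ref / n_ref
    M = np.log2(p_obs / p_ref)
    A = 0.5 * np.log2(p_obs * p_ref)
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(M) & np.isfinite(A)
    M, A, w = M[fin], A[fin], w[fin]
    n = M.size
    if n == 0:
        return 0.0
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = _rank(M)
    rank_a = _rank(A)
    keep = ((rank_m >= lo_m) & (rank_m <= hi_m)
            & (rank_a >= lo_a) & (rank_a <= hi_a))
    if not keep.any() or w[keep].sum() == 0:
        return 0.0
    prec = 1.0 / w[keep]
    return float(np.sum(prec * M[keep]) / prec.sum())


def _rank(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata
    return rankdata(x, method="average")


def quantile_normalize(values: pd.DataFrame,
                       mask: pd.DataFrame | None = None) -> pd.DataFrame:
    """Force every column onto the mean-of-sorted-columns distribution.

    Without missing cells the result is exact: each column's sorted values
    equal the mean of the sorted input columns, and ties within a column
    receive the mean of the reference quantiles they span.  With a missing
    mask, each column's observed values are mapped through the average
    empirical quantile function (linear interpolation); masked cells stay NaN.
    """
    arr = values.to_numpy(dtype=float)
    nrow, ncol = arr.shape
    if mask is None or not mask.to_numpy().any():
        sorted_cols = np.sort(arr, axis=0)
        ref = sorted_cols.mean(axis=1)
        out = np.empty_like(arr)
        for c in range(ncol):
            order = np.argsort(arr[:, c], kind="stable")
            assigned = np.empty(nrow)
            assigned[order] = ref
            # average reference values over tied input values
            col = arr[:, c]
            uniq, inv = np.unique(col, return_inverse=True)
            sums = np.bincount(inv, weights=assigned)
            cnts = np.bincount(inv)
            out[:, c] = (sums / cnts)[inv]
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    m = mask.to_numpy(dtype=bool)
    grid = (np.arange(nrow) + 0.5) / nrow
    ref_curves = []
    for c in range(ncol):
        obs = np.sort(arr[~m[:, c], c])
        if obs.size == 0:
            raise ValueError(f"sample {values.columns[c]} is entirely missing")
        q = (np.arange(obs.size) + 0.5) / obs.size
        ref_curves.append(np.interp(grid, q, obs))
    ref = np.mean(ref_curves, axis=0)
    out = np.full_like(arr, np.nan)
    from scipy.stats import rankdata
    for c in range(ncol):
        good = ~m[:, c]
        vals = arr[good, c]
        q = (rankdata(vals, method="average") - 0.5) / vals.size
        out[good, c] = np.interp(q, grid, ref)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def log_quantile_normalize(matrix: OmicsMatrix,
                           factors: pd.Series | None = None,
                           pseudo_offset: float = 0.0) -> OmicsMatrix:
    """Scale by per-sample factors, log10-transform, quantile-normalize.

    ``pseudo_offset`` (e.g. 0.5 for counts) is added before scaling so zeros
    survive the log; with the offset disabled a nonpositive value raises an
    error naming the offending feature and sample.
    """
    vf = matrix.values_frame.astype(float)
    if pseudo_offset:
        vf = vf + pseudo_offset
    if factors is not None:
        factors = pd.Series(factors).reindex(vf.columns)
        if factors.isna().any() or (factors <= 0).any():
            raise ValueError("factors must be positive for every sample")
        vf = vf.div(factors, axis=1)
    bad = np.argwhere((vf.to_numpy() <= 0)
                      & ~(matrix.mask.to_numpy() if matrix.mask is not None
                          else np.zeros(vf.shape, bool)))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"nonpositive value at feature {vf.index[i]!r}, sample "
            f"{vf.columns[j]!r}; enable pseudo_offset for zero counts")
    logged = np.log10(vf)
    qn = quantile_normalize(logged, matrix.mask)
    return matrix.evolve(qn, "log10+quantile", mask=matrix.mask)


def normalize_metabolites(raw: pd.DataFrame, mode_map: pd.Series,
                          standards: pd.DataFrame,
                          max_missing: float = MAX_MISSING_FRACTION
                          ) -> OmicsMatrix:
    """Internal-standard and total-signal normalization per acquisition mode.

    Within each mode, each sample's intensities are divided first by that
    sample's internal-standard reading and then by the sample's total signal
    within the mode.  Metabolites missing in >= ``max_missing`` of samples are
    dropped; the survivors are log10-transformed and quantile-normalized
    across samples, with missing cells masked out of the quantile pools.
    """
    mode_map = pd.Series(mode_map)
    unknown = set(raw.index) - set(mode_map.index)
    if unknown:
        raise ValueError(f"metabolites without a mode: {sorted(unknown)}")
    pieces = []
    for mode in standards.index:
        rows = [m for m in raw.index if mode_map[m] == mode]
        if not rows:
            continue
        sub = raw.loc[rows].astype(float)
        std = standards.loc[mode].reindex(sub.columns)
        if std.isna().any() or (std <= 0).any():
            bad = list(std.index[std.isna() | (std <= 0)])
            raise ValueError(
                f"missing/invalid internal standard for sample(s) {bad} "
                f"in mode {mode!r}")
        sub = sub.div(std, axis=1)
        totals = sub.sum(axis=0, skipna=True)
        sub = sub.div(totals, axis=1)
        pieces.append(sub)
    merged = pd.concat(pieces)
    merged = merged.loc[raw.index.intersection(merged.index)]
    missing_frac = merged.isna().mean(axis=1)
    keep = missing_frac < max_missing
    merged = merged.loc[keep]
    mask = merged.isna()
    om = OmicsMatrix(merged, None,
                     ["internal_standard+total_signal",
                      f"missing_filter(<{max_missing:.0%})"],
                     mask)
    return log_quantile_normalize(om)


def average_replicates(matrix: OmicsMatrix):
    """Collapse replicate samples to per-species means.

    Returns ``(species_matrix, standard_errors)``; species order follows the
    first appearance of each species among the samples.
    """
    if matrix.sample_species is None:
        raise ValueError("sample->species map required to average replicates")
    species_of = matrix.sample_species
    seen: list[str] = []
    for s in matrix.sample_ids:
        sp = species_of[s]
        if sp not in seen:
            seen.append(sp)
    means = {}
    ses = {}
    for sp in seen:
        cols = [s for s in matrix.sample_ids if species_of[s] == sp]
        block = matrix.values_frame[cols]
        if block.isna().all(axis=None):
            warnings.warn(f"species {sp!r} has no usable samples; skipped")
            continue
        means[sp] = block.mean(axis=1)
        n = block.notna().sum(axis=1)
        sd = block.std(axis=1, ddof=1)
        ses[sp] = (sd / np.sqrt(n)).fillna(0.0)
    mdf = pd.DataFrame(means)
    sdf = pd.DataFrame(ses)
    out = OmicsMatrix(mdf, pd.Series(mdf.columns, index=mdf.columns),
                      matrix.provenance + ["average_replicates"],
                      mdf.isna() if mdf.isna().any().any() else None)
    return out, sdf


def standardize_features(matrix: OmicsMatrix, ddof: int = 1) -> OmicsMatrix:
    """Center and scale each feature to mean 0, sd 1 (sample sd by default).

    Zero-variance features are dropped with a warning.
    """
    vf = matrix.values_frame
    mu = vf.mean(axis=1)
    sd = vf.std(axis=1, ddof=ddof)
    dead = sd[(sd == 0) | sd.isna()].index
    if len(dead):
        warnings.warn(f"dropping {len(dead)} zero-variance feature(s)")
        vf = vf.drop(index=dead)
        mu = mu.drop(index=dead)
        sd = sd.drop(index=dead)
    z = vf.sub(mu, axis=0).div(sd, axis=0)
    mask = matrix.mask.loc[z.index] if matrix.mask is not None else None
    return matrix.evolve(z, "standardize", mask=mask)


def pca_project(matrix: OmicsMatrix, n_components: int = 3):
    """Project samples onto principal axes of the feature space.

    Returns ``(coordinates, variance_fractions)``; the sign convention makes
    the largest-magnitude loading of each component positive.
    """
    X = matrix.values_frame.to_numpy(dtype=float).T  # samples x features
    if matrix.mask is not None and matrix.mask.to_numpy().any():
        raise ValueError("PCA requires a complete matrix; impute or drop NAs")
    max_rank = min(X.shape)
    if n_components > max_rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank bound {max_rank}; "
            "truncating")
        n_components = max_rank
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    for k in range(n_components):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, k] *= -1
    cols = [f"PC{k + 1}" for k in range(n_components)]
    cdf = pd.DataFrame(coords, index=matrix.sample_ids, columns=cols)
    return cdf, pca.explained_variance_ratio_.copy()
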