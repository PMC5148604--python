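import math
import warnings

import numpy as np
import pandas as pd
import pytest

import longscreen as ls
from longscreen.omics import OmicsMatrix


def _om(arr, features=None, samples=None, species=None):
    arr = np.asarray(arr)
    features = features or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return OmicsMatrix(pd.DataFrame(arr, index=features, columns=samples),
                       pd.Series(species) if species else None)


def tmm_oracle(arr, trim_m=0.30, trim_a=0.05):
    """Naive loop/sort reimplementation of the doubly trimmed weighted mean."""
    arr = np.asarray(arr, dtype=float)
    n_genes, n_samples = arr.shape
    totals = arr.sum(axis=0)
    f75 = [np.quantile(arr[:, s] / totals[s], 0.75) for s in range(n_samples)]
    ref = min(range(n_samples), key=lambda s: abs(f75[s] - np.mean(f75)))
    logf = []
    for s in range(n_samples):
        if s == ref:
            logf.append(0.0)
            continue
        M, A, w = [], [], []
        for g in range(n_genes):
            o, r = arr[g, s], arr[g, ref]
            if o > 0 and r > 0:
                po, pr = o / totals[s], r / totals[ref]
                M.append(math.log2(po / pr))
                A.append(0.5 * math.log2(po * pr))
                w.append((totals[s] - o) / (totals[s] * o)
                         + (totals[ref] - r) / (totals[ref] * r))
        n = len(M)
        if n == 0:
            logf.append(0.0)
            continue

        def rank(vals):
            out = []
            for v in vals:
                below = sum(1 for u in vals if u < v)
                ties = sum(1 for u in vals if u == v)
                out.append(below + (ties + 1) / 2.0)
            return out

        rM, rA = rank(M), rank(A)
        loM = math.floor(n * trim_m) + 1
        hiM = n + 1 - loM
        loA = math.floor(n * trim_a) + 1
        hiA = n + 1 - loA
        num = den = 0.0
        for i in range(n):
            if loM <= rM[i] <= hiM and loA <= rA[i] <= hiA:
                num += M[i] / w[i]
                den += 1.0 / w[i]
        logf.append(num / den if den > 0 else 0.0)
    logf = np.array(logf)
    return 2.0 ** (logf - logf.mean())


class TestFilterCounts:
    def test_low_count_rule(self):
        arr = np.array([[9, 9, 9, 9, 50],
                        [20, 20, 20, 20, 20],
                        [100, 100, 100, 100, 100],
                        [11, 12, 13, 14, 15],
                        [500, 480, 510, 490, 505]])
        rep = ls.filter_counts(_om(arr))
        assert rep.removed_low == ["g0"]
        assert "g0" not in rep.matrix.feature_ids

    def test_high_count_rule(self):
        arr = np.full((20, 4), 50)
        arr[0, 2] = 2000   # ~68% of that column
        rep = ls.filter_counts(_om(arr))
        assert rep.removed_high == ["g0"]

    def test_clean_matrix_unchanged(self):
        rng = np.random.default_rng(0)
        arr = rng.integers(40, 80, size=(30, 6))   # each <5%, all >=10
        rep = ls.filter_counts(_om(arr))
        assert rep.matrix.shape == (30, 6)
        assert rep.removed_high == [] and rep.removed_low == []

    def test_idempotent_on_generated_counts(self):
        om, _ = ls.gen_counts(300, 8, [2e5] * 8, seed=3, n_low=4, n_high=1)
        once = ls.filter_counts(om).matrix
        twice = ls.filter_counts(once)
        assert twice.matrix.feature_ids == once.feature_ids

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ls.filter_counts(_om(np.array([[-1, 2], [3, 4]])))


class TestTMM:
    def test_identical_columns_unit_factors(self):
        arr = np.tile(np.arange(10, 60), (4, 1)).T
        f = ls.tmm_factors(_om(arr))
        assert np.allclose(f, 1.0)

    def test_pure_depth_scaling_unit_factors(self):
        rng = np.random.default_rng(1)
        col = rng.integers(20, 500, size=60)
        arr = np.column_stack([col, 2 * col, 5 * col])
        f = ls.tmm_factors(_om(arr))
        assert np.allclose(f, 1.0, atol=1e-12)

    def test_matches_bruteforce_oracle_on_inflated_sample(self):
        rng = np.random.default_rng(2)
        arr = rng.integers(10, 400, size=(20, 5)).astype(float)
        arr[:4, 1] *= 8.0   # composition shift in one sample
        f = ls.tmm_factors(_om(arr))
        assert np.abs(f.to_numpy() - tmm_oracle(arr)).max() < 1e-10

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.integers(1, 500, size=(50, 6)).astype(float)
        f = ls.tmm_factors(_om(arr))
        oracle = tmm_oracle(arr)
        assert np.abs(f.to_numpy() - oracle).max() < 1e-10
        assert np.prod(f.to_numpy()) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_column_rejected(self):
        arr = np.array([[1, 0], [2, 0]])
        with pytest.raises(ValueError):
            ls.tmm_factors(_om(arr))


class TestQuantileNormalize:
    def test_hand_case(self):
        df = pd.DataFrame({"a": [2.0, 4.0, 6.0], "b": [1.0, 3.0, 8.0]})
        out = ls.quantile_normalize(df)
        assert out["a"].tolist() == [1.5, 3.5, 7.0]
        assert out["b"].tolist() == [1.5, 3.5, 7.0]

    def test_identical_columns_fixed_point(self):
        df = pd.DataFrame({"a": [5.0, 1.0, 3.0], "b": [5.0, 1.0, 3.0]})
        out = ls.quantile_normalize(df)
        assert np.array_equal(out.to_numpy(), df.to_numpy())

    def test_sorted_columns_exactly_equal(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(200, 7)))
        out = ls.quantile_normalize(df).to_numpy()
        s = np.sort(out, axis=0)
        assert (s == s[:, [0]]).all()

    def test_ties_get_mean_of_spanned_quantiles(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [10.0, 20.0, 30.0]})
        out = ls.quantile_normalize(df)
        ref = np.sort(df.to_numpy(), axis=0).mean(axis=1)
        assert out["a"].tolist() == [(ref[0] + ref[1]) / 2,
                                     (ref[0] + ref[1]) / 2, ref[2]]

    def test_nonpositive_error_names_offender(self):
        om = _om(np.array([[1.0, 2.0], [0.0, 3.0]]))
        with pytest.raises(ValueError, match="g1.*s0"):
            ls.log_quantile_normalize(om)

    def test_pseudo_offset_admits_zeros(self):
        om = _om(np.array([[0, 10], [5, 3]]))
        out = ls.log_quantile_normalize(om, pseudo_offset=0.5)
        assert np.isfinite(out.values_frame.to_numpy()).all()


class TestMetaboliteNormalization:
    def test_global_sample_scaling_cancels(self):
        sim = ls.gen_metabolites(18, 6, seed=4, batch_sd=0.0)
        raw2 = sim.raw.copy()
        raw2.iloc[:, 0] *= 2.0          # one sample doubled everywhere
        std2 = sim.standards.copy()
        std2.iloc[:, 0] *= 2.0          # internal standards double too
        a = ls.normalize_metabolites(sim.raw, sim.mode_map, sim.standards)
        b = ls.normalize_metabolites(raw2, sim.mode_map, std2)
        assert np.allclose(a.values_frame, b.values_frame)

    def test_missingness_filter_at_ten_percent(self):
        sim = ls.gen_metabolites(20, 22, seed=5)
        raw = sim.raw.copy()
        raw.iloc[0, :3] = np.nan        # 3/22 = 13.6% missing
        out = ls.normalize_metabolites(raw, sim.mode_map, sim.standards)
        assert raw.index[0] not in out.feature_ids

    def test_batch_factor_roundtrip(self):
        sim = ls.gen_metabolites(30, 10, seed=6, batch_sd=0.5)
        with_batch = ls.normalize_metabolites(sim.raw, sim.mode_map,
                                              sim.standards)
        clean = ls.normalize_metabolites(sim.clean, sim.mode_map,
                                         sim.standards / sim.batch)
        diff = (with_batch.values_frame - clean.values_frame).abs()
        assert np.nanmax(diff.to_numpy()) < 1e-10

    def test_missing_internal_standard_rejected(self):
        sim = ls.gen_metabolites(9, 4, seed=7)
        std = sim.standards.copy()
        std.iloc[0, 1] = np.nan
        with pytest.raises(ValueError, match="standard"):
            ls.normalize_metabolites(sim.raw, sim.mode_map, std)


class TestReplicatesAndStandardize:
    def test_replicate_averaging_arithmetic(self):
        om = _om(np.array([[1.0, 3.0, 7.0]]), samples=["a_r1", "a_r2", "b_r1"],
                 species={"a_r1": "a", "a_r2": "a", "b_r1": "b"})
        mat, se = ls.average_replicates(om)
        assert mat.values_frame.loc["g0", "a"] == 2.0   # mean of 1, 3
        assert se.loc["g0", "a"] == 1.0                 # SE of n=2
        assert mat.values_frame.loc["g0", "b"] == 7.0   # single sample
        assert se.loc["g0", "b"] == 0.0

    def test_identical_replicates_zero_se(self):
        om = _om(np.array([[4.0, 4.0]]), samples=["a_r1", "a_r2"],
                 species={"a_r1": "a", "a_r2": "a"})
        mat, se = ls.average_replicates(om)
        assert mat.values_frame.loc["g0", "a"] == 4.0
        assert se.loc["g0", "a"] == 0.0

    def test_standardize_hand_case(self):
        om = _om(np.array([[1.0, 2.0, 3.0]]))
        out = ls.standardize_features(om)
        assert np.allclose(out.values_frame.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_standardize_is_idempotent(self):
        rng = np.random.default_rng(8)
        om = _om(rng.normal(size=(12, 6)))
        once = ls.standardize_features(om)
        twice = ls.standardize_features(once)
        assert np.abs(once.values_frame.to_numpy()
                      - twice.values_frame.to_numpy()).max() < 1e-12

    def test_constant_feature_dropped_with_warning(self):
        om = _om(np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 4.0]]))
        with pytest.warns(UserWarning, match="zero-variance"):
            out = ls.standardize_features(om)
        assert out.feature_ids == ["g1"]


class TestPCA:
    def test_rank_one_matrix(self):
        u = np.array([[1.0], [2.0], [-1.0]])
        v = np.array([[1.0, -2.0, 0.5, 3.0]])
        om = _om(u @ v)
        coords, frac = ls.pca_project(om, n_components=2)
        assert frac[0] == pytest.approx(1.0)

    def test_rotation_invariant_variance_fractions(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 6))
        Q, _ = np.linalg.qr(rng.normal(size=(10, 10)))
        _, f1 = ls.pca_project(_om(X), n_components=3)
        _, f2 = ls.pca_project(_om(Q @ X), n_components=3)
        assert np.allclose(f1, f2, atol=1e-10)

    def test_two_cluster_separation_on_pc1(self):
        rng = np.random.default_rng(10)
        left = rng.normal(0, 0.1, size=(20, 4))
        right = rng.normal(3, 0.1, size=(20, 4))
        om = _om(np.hstack([left, right]))
        coords, _ = ls.pca_project(om, n_components=2)
        a, b = coords["PC1"][:4], coords["PC1"][4:]
        assert max(a.max(), b.max()) > min(a.min(), b.min())  # sanity
        assert (a.mean() - b.mean()) ** 2 > 4 * (a.var() + b.var())

    def test_overlarge_n_components_truncated(self):
        om = _om(np.random.default_rng(11).normal(size=(3, 5)))
        with pytest.warns(UserWarning, match="truncating"):
            coords, frac = ls.pca_project(om, n_components=5)
        assert coords.shape[1] == 3
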