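import numpy as np
import pandas as pd
import pytest

import longscreen as ls
from tests.conftest import simulate_bm_feature


def bh_oracle(p):
    """Naive Benjamini-Hochberg step-up."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


class TestBHAdjust:
    def test_hand_case(self):
        q = ls.bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert ls.bh_adjust([0.2])[0] == pytest.approx(0.2)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_stepup_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(int(rng.integers(1, 200)))
        assert np.allclose(ls.bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ls.bh_adjust([0.5, 1.2])


@pytest.fixture(scope="module")
def screen_setup():
    tree = ls.gen_tree(15, 40)
    labels, tmat, _, _ = tree.path_matrices()
    L = np.linalg.cholesky(tmat + 1e-12 * np.eye(15))
    rng = np.random.default_rng(41)
    x = pd.Series(rng.normal(size=15), index=labels)
    ws = ls.PGLSWorkspace(tree, x)
    return tree, labels, L, x, ws


class TestTwoStep:
    def test_p_robust_is_min_over_loo(self, screen_setup):
        tree, labels, L, x, ws = screen_setup
        rng = np.random.default_rng(1)
        for _ in range(5):
            y = simulate_bm_feature(labels, L, rng, slope=0.4, x=x)
            rb = ls.robust_step(y, workspace=ws)
            loo = {sp: ws.fit(y, exclude={sp}).best_fit.p for sp in labels}
            assert rb.p_robust == min(loo.values())
            assert loo[rb.outlier] == rb.p_robust

    def test_oracle_equivalence_with_fresh_fits(self, screen_setup):
        """Brute-force loops re-using fit_trait_models directly."""
        tree, labels, L, x, ws = screen_setup
        rng = np.random.default_rng(2)
        y = simulate_bm_feature(labels, L, rng, slope=0.6, x=x)
        rb = ls.robust_step(y, workspace=ws)
        pm = ls.max_step(y, outlier=rb.outlier, workspace=ws)
        loo = {}
        for sp in sorted(labels):
            keep = [s for s in labels if s != sp]
            loo[sp] = ls.fit_trait_models(y[keep], x[keep], tree,
                                          species=keep).best_fit.p
        outlier = min(sorted(loo), key=lambda s: loo[s])
        assert rb.outlier == outlier
        assert rb.p_robust == loo[outlier]
        p2 = []
        for sp in labels:
            if sp == outlier:
                continue
            keep = [s for s in labels if s not in (outlier, sp)]
            p2.append(ls.fit_trait_models(y[keep], x[keep], tree,
                                          species=keep).best_fit.p)
        assert pm == max(p2)

    def test_planted_gross_outlier_found(self, screen_setup):
        tree, labels, L, x, ws = screen_setup
        rng = np.random.default_rng(3)
        for _ in range(20):
            y = pd.Series(1.0 * x.to_numpy()
                          + 0.01 * rng.standard_normal(15), index=labels)
            culprit = labels[int(rng.integers(15))]
            y[culprit] += rng.choice([-1, 1]) * 5.0
            rb = ls.robust_step(y, workspace=ws)
            assert rb.outlier == culprit

    def test_single_species_signal_fails_max_step(self, screen_setup):
        tree, labels, L, x, ws = screen_setup
        rng = np.random.default_rng(4)
        # flat response except one extreme species aligned with extreme x
        y = pd.Series(0.05 * rng.standard_normal(15), index=labels)
        driver = x.idxmax()
        y[driver] += 3.0
        rb = ls.robust_step(y, workspace=ws)
        if rb.outlier == driver:
            # outlier step itself removes the driver: association gone
            assert rb.p_robust > 0.05 or ls.max_step(
                y, outlier=rb.outlier, workspace=ws) > 0.05
        else:
            assert ls.max_step(y, outlier=rb.outlier, workspace=ws) > 0.05

    def test_preconditions(self, screen_setup):
        tree, labels, L, x, ws = screen_setup
        small_tree = ls.gen_tree(4, 0)
        xs = pd.Series([1.0, 2, 3, 4], index=small_tree.tip_labels)
        ys = pd.Series([1.0, 2, 1, 2], index=small_tree.tip_labels)
        with pytest.raises(ValueError):
            ls.robust_step(ys, xs, small_tree)
        rng = np.random.default_rng(5)
        y = simulate_bm_feature(labels, L, rng)
        with pytest.raises(ValueError):
            ls.max_step(y, workspace=ws, outlier="not-a-species")


class TestScreenFeatures:
    @pytest.fixture(scope="class")
    def screen_inputs(self):
        tree = ls.gen_tree(15, 50)
        traits = ls.gen_traits(tree, 51)
        cfg = ls.SimulationConfig(n_species=15, n_genes=3,
                                  frac_associated=0.5, seed=52,
                                  n_replicates=1, replicate_noise_sd=0.0)
        om, truth = ls.gen_expression(tree, traits["ML"], cfg)
        mat, _ = ls.average_replicates(om)
        return tree, traits, mat

    def test_record_columns_and_q_monotone(self, screen_inputs):
        tree, traits, mat = screen_inputs
        rec = ls.screen_features(mat, traits, tree, trait_cols=("ML", "AW"))
        assert list(rec.columns) == ls.screen.RECORD_COLUMNS
        for trait in ("ML", "AW"):
            sub = rec[rec.trait == trait].sort_values("p.value.robust")
            assert sub["q.value.robust"].is_monotonic_increasing

    def test_compositionality_with_single_feature_path(self, screen_inputs):
        tree, traits, mat = screen_inputs
        rec = ls.screen_features(mat, traits, tree, trait_cols=("ML",))
        x = np.log10(traits["ML"])
        ws = ls.PGLSWorkspace(tree, x, species=list(mat.sample_ids))
        for _, row in rec.iterrows():
            y = mat.values_frame.loc[row["feature"]]
            full = ws.fit(y)
            rb = ls.robust_step(y, workspace=ws)
            pm = ls.max_step(y, outlier=rb.outlier, workspace=ws)
            assert row["coef.all"] == pytest.approx(full.best_fit.beta[1])
            assert row["p.value.all"] == pytest.approx(full.best_fit.p)
            assert row["outlier"] == rb.outlier
            assert row["p.value.robust"] == pytest.approx(rb.p_robust)
            assert row["p.value.max"] == pytest.approx(pm)

    def test_feature_and_species_order_invariance(self, screen_inputs):
        tree, traits, mat = screen_inputs
        rec1 = ls.screen_features(mat, traits, tree, trait_cols=("ML",))
        shuffled = ls.OmicsMatrix(
            mat.values_frame.iloc[::-1, ::-1],
            mat.sample_species[mat.values_frame.columns[::-1]])
        rec2 = ls.screen_features(shuffled, traits, tree, trait_cols=("ML",))
        merged = rec1.merge(rec2, on=["feature", "trait"],
                            suffixes=("_a", "_b"))
        assert len(merged) == len(rec1)
        assert np.allclose(merged["p.value.robust_a"],
                           merged["p.value.robust_b"])

    def test_too_few_shared_species(self, screen_inputs):
        tree, traits, mat = screen_inputs
        tiny = ls.OmicsMatrix(mat.values_frame.iloc[:, :3],
                              mat.sample_species[mat.values_frame.columns[:3]])
        with pytest.raises(ValueError, match="5 species"):
            ls.screen_features(tiny, traits, tree)


class TestTopHits:
    @staticmethod
    def _records(rows):
        base = {"coef.all": 1.0, "p.value.all": 0.5, "q.value.all": 0.5,
                "outlier": "sp01", "p.value.robust": 0.5,
                "q.value.robust": 0.5, "p.value.max": 0.5,
                "q.value.max": 0.5, "best.model": "brownian"}
        recs = []
        for feature, trait, p_rob, p_max, coef in rows:
            r = dict(base)
            r.update({"feature": feature, "trait": trait,
                      "p.value.robust": p_rob, "p.value.max": p_max,
                      "coef.all": coef})
            recs.append(r)
        traits = {r[1] for r in rows}
        for t in {"ML", "FTM", "MLres", "FTMres"} - traits:
            for feature in {r[0] for r in rows}:
                r = dict(base)
                r.update({"feature": feature, "trait": t})
                recs.append(r)
        return pd.DataFrame(recs)

    def test_two_trait_support(self):
        rec = self._records([("g1", "ML", 0.001, 0.01, 2.0),
                             ("g1", "FTM", 0.005, 0.04, -1.0)])
        hits = ls.call_top_hits(rec)
        assert len(hits) == 1
        assert hits.iloc[0]["traits"] == "ML,FTM"
        assert hits.iloc[0]["directions"] == "+,-"

    def test_adult_weight_does_not_count(self):
        rec = self._records([("g1", "AW", 0.0001, 0.001, 1.0),
                             ("g1", "ML", 0.001, 0.01, 1.0)])
        hits = ls.call_top_hits(rec)
        assert hits.empty

    def test_vacuous_cuts_call_everything(self):
        rec = self._records([("g1", "ML", 0.9, 0.9, 1.0),
                             ("g2", "ML", 0.9, 0.9, 1.0)])
        hits = ls.call_top_hits(rec, p_robust_cut=1.1, p_max_cut=1.1,
                                min_traits=1)
        assert set(hits["feature"]) == {"g1", "g2"}

    def test_missing_trait_rejected(self):
        rec = pd.DataFrame([{"feature": "g1", "trait": "ML",
                             "p.value.robust": 0.001, "p.value.max": 0.01,
                             "coef.all": 1.0}])
        with pytest.raises(ValueError, match="missing longevity"):
            ls.call_top_hits(rec)
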