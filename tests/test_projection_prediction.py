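import numpy as np
import pandas as pd
import pytest

import projwire as pw

from conftest import distinct_config


@pytest.fixture(scope="module")
def trained(distinct_sim, distinct_profiles):
    ds, truth = distinct_sim
    feats = pw.build_features(ds.expr.values, ds.expr.gene_ids, ds.meta.table,
                              ds.expr.cell_ids, n_pcs=20)
    res = pw.train_predictors(feats, distinct_profiles.binary, distinct_profiles.target_ids, seed=4)
    res = pw.evaluate_roc(res, feats, distinct_profiles.binary, distinct_profiles.target_ids, seed=4)
    return feats, res


class TestBuildFeatures:
    def _expr(self, n=200, g=30, seed=0):
        rng = np.random.default_rng(seed)
        return rng.lognormal(0, 0.5, (n, g)), [f"g{i}" for i in range(g)]

    def _coords(self, n, seed=1):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"ap_mm": rng.normal(1.5, 0.3, n),
                             "dv_mm": rng.normal(1.5, 0.3, n),
                             "ml_mm": rng.uniform(0, 1.5, n)})

    def test_feature_counts(self):
        expr, genes = self._expr()
        cells = [f"c{i}" for i in range(len(expr))]
        f1 = pw.build_features(expr, genes, None, cells, n_pcs=7, use_spatial=False)
        assert f1.features.shape[1] == 7
        f2 = pw.build_features(expr, genes, self._coords(len(expr)), cells, n_pcs=7)
        assert f2.features.shape[1] == 10
        assert f2.feature_names[-3:] == ["ap_mm", "dv_mm", "ml_mm"]

    def test_columns_standardized(self):
        expr, genes = self._expr()
        f = pw.build_features(expr, genes, self._coords(len(expr)),
                              [f"c{i}" for i in range(len(expr))], n_pcs=5)
        assert np.allclose(f.features.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(f.features.std(axis=0), 1, atol=1e-9)

    def test_stored_pc_model_round_trip(self):
        """Re-projecting the training matrix through the stored parameters
        reproduces the PC features to 1e-8."""
        expr, genes = self._expr()
        f = pw.build_features(expr, genes, None, [f"c{i}" for i in range(len(expr))],
                              n_pcs=6, use_spatial=False)
        again = f.pc_model.transform_expression(expr, genes)
        assert np.allclose(again, f.features, atol=1e-8)

    def test_constant_gene_dropped(self):
        expr, genes = self._expr()
        expr[:, 0] = 4.2
        f = pw.build_features(expr, genes, None, [f"c{i}" for i in range(len(expr))],
                              n_pcs=5, use_spatial=False)
        assert "g0" not in f.pc_model.gene_ids


class TestTrainAndEvaluate:
    def test_separable_labels_perfect_auc(self):
        rng = np.random.default_rng(2)
        expr = rng.lognormal(0, 0.5, (600, 20))
        cells = [f"c{i}" for i in range(600)]
        feats = pw.build_features(expr, [f"g{i}" for i in range(20)], None, cells,
                                  n_pcs=5, use_spatial=False)
        labels = (feats.features[:, 0] > 0).astype(int)[:, None]
        res = pw.train_predictors(feats, labels, ["A-I"], seed=0)
        res = pw.evaluate_roc(res, feats, labels, ["A-I"], seed=0, controls=False)
        rec = res.per_target["A-I"]
        assert rec["auc"] == pytest.approx(1.0, abs=1e-6)
        assert (np.diff(rec["roc"]["tpr"]) >= 0).all()

    def test_uninformative_features_near_chance(self):
        rng = np.random.default_rng(3)
        expr = rng.lognormal(0, 0.5, (800, 20))
        cells = [f"c{i}" for i in range(800)]
        feats = pw.build_features(expr, [f"g{i}" for i in range(20)], None, cells,
                                  n_pcs=5, use_spatial=False)
        aucs = []
        for seed in range(5):
            labels = np.random.default_rng(50 + seed).permutation(
                np.repeat([0, 1], 400))[:, None]
            res = pw.train_predictors(feats, labels, ["A-I"], seed=seed)
            res = pw.evaluate_roc(res, feats, labels, ["A-I"], seed=seed, controls=False)
            aucs.append(res.per_target["A-I"]["auc"])
        assert sum(0.4 <= a <= 0.6 for a in aucs) >= 4

    def test_skips_rare_targets_with_report(self):
        rng = np.random.default_rng(4)
        expr = rng.lognormal(0, 0.5, (200, 15))
        cells = [f"c{i}" for i in range(200)]
        feats = pw.build_features(expr, [f"g{i}" for i in range(15)], None, cells,
                                  n_pcs=4, use_spatial=False)
        labels = np.zeros((200, 2), dtype=int)
        labels[:5, 0] = 1  # too few positives
        labels[:100, 1] = 1
        res = pw.train_predictors(feats, labels, ["rare-I", "ok-I"], seed=0)
        assert "rare-I" in res.skipped
        assert "ok-I" in res.per_target

    def test_planted_signal_recovered(self, trained):
        _, res = trained
        tab = res.auc_table()
        assert (tab["auc"] >= 0.9).all()
        assert ((tab["auc_shuffle"] > 0.4) & (tab["auc_shuffle"] < 0.6)).all()

    def test_deterministic_given_seed(self, distinct_sim, distinct_profiles):
        ds, _ = distinct_sim
        aucs = []
        for _ in range(2):
            feats = pw.build_features(ds.expr.values, ds.expr.gene_ids, ds.meta.table,
                                      ds.expr.cell_ids, n_pcs=10)
            res = pw.train_predictors(feats, distinct_profiles.binary,
                                      distinct_profiles.target_ids, seed=7)
            res = pw.evaluate_roc(res, feats, distinct_profiles.binary,
                                  distinct_profiles.target_ids, seed=7, controls=False)
            aucs.append(res.auc_table()["auc"].to_numpy())
        assert np.allclose(aucs[0], aucs[1], atol=1e-10)


class TestTransfer:
    def test_identity_transfer_reproduces_in_sample_scores(self, distinct_sim, trained):
        ds, _ = distinct_sim
        feats, res = trained
        pred = pw.transfer_predict(ds.expr.values, ds.expr.gene_ids, ds.meta.table, res, feats)
        t = next(iter(res.per_target))
        direct = res.per_target[t]["model"].predict_proba(feats.features)[:, 1]
        assert np.allclose(pred[f"{t}:proba"].to_numpy(), direct, atol=1e-8)

    def test_same_distribution_transfer_auc(self, trained):
        """Held-out replicate of the same simulation: transfer AUC within
        0.05 of the in-sample test AUC per target."""
        from sklearn.metrics import roc_auc_score
        feats, res = trained
        ds2, truth2 = pw.simulate_dataset(distinct_config(), seed=11)
        prof2 = pw.filter_background(ds2.barcode)
        pred = pw.transfer_predict(ds2.expr.values, ds2.expr.gene_ids, ds2.meta.table, res, feats)
        for j, t in enumerate(prof2.target_ids):
            if t not in res.per_target:
                continue
            auc_ext = roc_auc_score(prof2.binary[:, j], pred[f"{t}:proba"])
            assert abs(auc_ext - res.per_target[t]["auc"]) < 0.05

    def test_missing_genes_degrade_but_beat_chance(self, trained):
        from sklearn.metrics import roc_auc_score
        feats, res = trained
        ds2, _ = pw.simulate_dataset(distinct_config(), seed=12)
        prof2 = pw.filter_background(ds2.barcode)
        rng = np.random.default_rng(0)
        keep = rng.permutation(len(ds2.expr.gene_ids))[: int(0.6 * len(ds2.expr.gene_ids))]
        keep.sort()
        pred = pw.transfer_predict(ds2.expr.values[:, keep],
                                   [ds2.expr.gene_ids[i] for i in keep],
                                   ds2.meta.table, res, feats)
        aucs = [
            roc_auc_score(prof2.binary[:, j], pred[f"{t}:proba"])
            for j, t in enumerate(prof2.target_ids) if t in res.per_target
        ]
        assert np.mean(aucs) > 0.6

    def test_too_few_shared_genes(self, trained):
        feats, res = trained
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="shared genes"):
            pw.transfer_predict(rng.random((10, 3)), ["x", "y", "z"], None, res, feats)


class TestMapsAndGroupTests:
    def test_reference_against_itself_r_one(self):
        rng = np.random.default_rng(5)
        calls = pd.DataFrame((rng.random((300, 3)) < 0.4).astype(int),
                             columns=["A-I", "B-I", "C-I"])
        regions = rng.choice(["ACC", "PL", "ILA"], 300)
        out = pw.compare_projection_maps(calls, regions, calls, regions)
        assert out["r"] == pytest.approx(1.0)
        assert ((out["predicted"].to_numpy() >= 0) & (out["predicted"].to_numpy() <= 100)).all()

    def test_unshared_region_excluded(self):
        rng = np.random.default_rng(6)
        calls = pd.DataFrame((rng.random((100, 2)) < 0.5).astype(int), columns=["A-I", "B-I"])
        r1 = np.array(["ACC"] * 50 + ["PL"] * 50)
        r2 = np.array(["ACC"] * 50 + ["MOs"] * 50)
        out = pw.compare_projection_maps(calls, r1, calls, r2)
        assert out["excluded_regions"] == ["MOs", "PL"]

    def test_group_proportions_identical_gives_p_one(self):
        calls = pd.DataFrame({"A-I:call": np.ones(80, dtype=int)})
        flags = np.tile([True, False], 40)  # exactly half flagged everywhere
        groups = np.repeat(["FR", "NF"], 40)
        reps = np.tile(np.repeat([0, 1], 20), 2)
        out = pw.group_proportion_test(calls, flags, groups, reps)
        assert out.loc["A-I", "p_value"] == 1.0

    def test_planted_enrichment_detected_in_one_target(self):
        rng = np.random.default_rng(7)
        n = 1600
        calls = pd.DataFrame({
            "A-I:call": np.ones(n, dtype=int),
            "B-I:call": np.ones(n, dtype=int),
        })
        groups = np.repeat(["FR", "NF"], n // 2)
        reps = np.tile(np.repeat([0, 1, 2, 3], n // 8), 2)
        p_flag = np.where(groups == "FR", 0.6, 0.3)
        flags_a = rng.random(n) < p_flag  # A-I pool enriched in FR
        out_a = pw.group_proportion_test(calls[["A-I:call"]], flags_a, groups, reps)
        assert out_a.loc["A-I", "p_value"] < 0.05
        flags_b = rng.random(n) < 0.4  # B-I pool unenriched
        out_b = pw.group_proportion_test(calls[["B-I:call"]], flags_b, groups, reps)
        assert out_b.loc["B-I", "p_value"] > 0.05
        assert out_a[["mean_FR", "mean_NF"]].to_numpy().min() >= 0
        assert out_a[["mean_FR", "mean_NF"]].to_numpy().max() <= 1
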