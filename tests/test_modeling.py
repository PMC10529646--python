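"""Splits, grid search, forest training, jackknife errors, control model."""

import numpy as np
import pandas as pd
import pytest

import bkgating as bk
from bkgating.modeling import _jackknife_variance


@pytest.fixture(scope="module")
def xy(small_feature_matrix):
    pruned, _ = bk.prune_features(small_feature_matrix)
    scaled = bk.standardize(pruned)
    return scaled.X, scaled.y


class TestSplits:
    def test_sizes_match_80_20_convention(self):
        ids = [f"m{i}" for i in range(473)]
        plans = bk.make_splits(ids, n_splits=1, seeds=[0])
        assert len(plans[0].train_ids) == 378
        assert len(plans[0].test_ids) == 95

    def test_same_seed_identical(self):
        ids = [f"m{i}" for i in range(50)]
        a = bk.make_splits(ids, n_splits=2, seeds=[4, 9])
        b = bk.make_splits(ids, n_splits=2, seeds=[4, 9])
        assert a == b

    def test_distinct_seeds_distinct_tests(self):
        ids = [f"m{i}" for i in range(100)]
        plans = bk.make_splits(ids, n_splits=5, seeds=list(range(5)))
        tests = {plan.test_ids for plan in plans}
        assert len(tests) == 5

    def test_union_covers_disjoint(self):
        ids = [f"m{i}" for i in range(40)]
        plan = bk.make_splits(ids, n_splits=1, seeds=[1])[0]
        assert set(plan.train_ids) | set(plan.test_ids) == set(ids)
        assert not set(plan.train_ids) & set(plan.test_ids)

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            bk.make_splits([f"m{i}" for i in range(20)], fraction=1.2)


class TestGridSearch:
    def test_single_cell_returned(self, xy):
        X, y = xy
        best, res = bk.grid_search(X, y, "ridge", {"alpha": [1.0]}, k=3)
        assert best == {"alpha": 1.0}
        assert len(res) == 1

    def test_forest_beats_ridge_on_planted_signal(self, study):
        # the planted signal saturates and carries an interaction, so at study
        # scale the tree ensemble outruns the linear baseline on validation R
        _, _, _, fm = study
        pruned, _ = bk.prune_features(fm)
        scaled = bk.standardize(pruned)
        _, res_f = bk.grid_search(scaled.X, scaled.y, "random_forest",
                                  {"max_depth": [10]}, k=5, seed=0)
        _, res_r = bk.grid_search(scaled.X, scaled.y, "ridge",
                                  {"alpha": [1.0]}, k=5, seed=0)
        assert res_f["mean_test_r"].max() > res_r["mean_test_r"].max()

    def test_leave_one_out_boundary(self, xy):
        X, y = xy
        Xs, ys = X.iloc[:12], y.iloc[:12]
        best, res = bk.grid_search(Xs, ys, "ridge", {"alpha": [0.1, 1.0]},
                                   k=len(Xs))
        assert set(best) == {"alpha"}


class TestTrainForest:
    def test_training_fit_is_tight_on_planted_data(self, small_model):
        model, scaled = small_model
        r = bk.pearson_r(model.predict(scaled.X), scaled.y)
        assert r >= 0.95

    def test_one_row_rejected(self, xy):
        X, y = xy
        with pytest.raises(ValueError):
            bk.train_forest(X.iloc[:1], y.iloc[:1])

    def test_nonfinite_rejected(self, xy):
        X, y = xy
        bad = X.iloc[:20].copy()
        bad.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            bk.train_forest(bad, y.iloc[:20])

    def test_fixed_seed_reproducible(self, xy):
        X, y = xy
        a = bk.train_forest(X, y, seed=11).predict(X)
        b = bk.train_forest(X, y, seed=11).predict(X)
        pd.testing.assert_series_equal(a, b)

    def test_oob_score_exposed(self, small_model):
        model, _ = small_model
        assert model.oob_score is not None

    def test_feature_list_enforced_at_predict(self, small_model):
        model, scaled = small_model
        with pytest.raises(ValueError, match="feature"):
            model.predict(scaled.X.iloc[:, ::-1])


class TestPredictionError:
    def test_identical_trees_zero_error(self, xy):
        X, y = xy
        const = pd.Series(np.zeros(len(y)), index=y.index)
        model = bk.train_forest(X, const, seed=0,
                                hyperparameters={"n_estimators": 25, "bootstrap": True})
        ps = bk.predict_with_error(model, X)
        assert np.allclose(ps.errors, 0.0)

    def test_error_correlates_with_true_error(self, study):
        # at full study scale the bagged error estimate tracks the true error;
        # per-point jackknife stability needs B well above n, so the check
        # runs with a larger ensemble than the production forest
        _, _, _, fm = study
        plan = bk.make_splits(list(fm.X.index), n_splits=1, seeds=[3])[0]
        pruned, _ = bk.prune_features(fm.subset_rows(list(plan.train_ids)))
        scaled = bk.standardize(pruned)
        hp = dict(bk.FOREST_HYPERPARAMETERS, n_estimators=2000)
        model = bk.train_forest(scaled.X, fm.y.loc[list(plan.train_ids)], hp, seed=0)
        test_X = (fm.X.loc[list(plan.test_ids), pruned.feature_names]
                  - scaled.scaler_mean) / scaled.scaler_sd
        ps = bk.predict_with_error(model, test_X)
        truth = fm.y.loc[list(plan.test_ids)]
        true_err = (ps.predictions - truth).abs()
        assert bk.pearson_r(ps.errors, true_err) > 0.2

    def test_more_trees_do_not_inflate_error(self, xy):
        X, y = xy
        m1 = bk.train_forest(X, y, seed=0, hyperparameters={"n_estimators": 200})
        m2 = bk.train_forest(X, y, seed=0, hyperparameters={"n_estimators": 400})
        e1 = bk.predict_with_error(m1, X).errors.mean()
        e2 = bk.predict_with_error(m2, X).errors.mean()
        assert e2 <= e1 * 1.15  # allow Monte-Carlo wiggle

    def test_jackknife_matches_bruteforce_loops(self):
        rng = np.random.default_rng(0)
        n, B, m = 15, 40, 6
        inbag = rng.integers(0, 3, size=(n, B))
        preds = rng.normal(size=(B, m))
        fast = _jackknife_variance(preds, inbag)
        for q in range(m):
            t = preds[:, q]
            v_ij = 0.0
            for i in range(n):
                cov = np.mean((inbag[i] - inbag[i].mean()) * (t - t.mean()))
                v_ij += cov**2
            corr = n * np.mean((t - t.mean()) ** 2) / B
            assert fast[q] == pytest.approx(max(v_ij - corr, 0.0), abs=1e-12)

    def test_non_forest_rejected(self, xy):
        X, y = xy
        model = bk.GatingModel("ridge", {}, None, list(X.columns))
        with pytest.raises(ValueError, match="forest"):
            bk.predict_with_error(model, X)

    def test_tree_spread_fallback_nonnegative(self, small_model):
        model, scaled = small_model
        ps = bk.predict_with_error(model, scaled.X, method="tree_spread")
        assert (ps.errors >= 0).all()


class TestImportanceAndControl:
    def test_importances_sum_to_one_descending(self, small_model):
        model, _ = small_model
        imp = bk.feature_importance(model)
        vals = [v for _, v in imp]
        assert sum(vals) == pytest.approx(1.0, abs=1e-9)
        assert vals == sorted(vals, reverse=True)

    def test_signal_terms_rank_in_top_quartile(self, small_model, small_cfg):
        model, _ = small_model
        ranked = [name for name, _ in bk.feature_importance(model)]
        cutoff = max(1, len(ranked) // 4)
        top = set(ranked[:cutoff])
        hits = sum(1 for t in small_cfg.signal_features if t in top)
        assert hits >= len(small_cfg.signal_features) - 1

    def test_pure_noise_column_ranks_below_signal(self, xy, small_cfg):
        X, y = xy
        wins = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            X2 = X.copy()
            X2["pure_noise"] = rng.normal(size=len(X2))
            model = bk.train_forest(X2, y, seed=s,
                                    hyperparameters={"n_estimators": 150, "ccp_alpha": 0.01})
            rank = {n: i for i, (n, _) in enumerate(bk.feature_importance(model))}
            if all(rank[t] < rank["pure_noise"] for t in small_cfg.signal_features):
                wins += 1
        assert wins >= 9

    def test_control_self_mutation_deltas_zero(self, small_feature_matrix, small_curated):
        ds = small_curated.copy()
        ds["mut_aa"] = ds["wt_aa"]  # force self-mutations
        cfm = bk.control_features(ds, small_feature_matrix)
        delta_cols = [c for c in cfm.X.columns if cfm.provenance[c] == "aaindex-control"]
        assert np.allclose(cfm.X[delta_cols].to_numpy(), 0.0)

    def test_control_drops_physics_columns(self, small_feature_matrix, small_curated):
        cfm = bk.control_features(small_curated, small_feature_matrix)
        assert not set(cfm.columns_from("energetics", "dynamics"))
        assert len([c for c in cfm.X.columns if c.startswith("d_")]) \
            >= len(bk.AA_PROPERTY_TABLE.columns)

    def test_property_matrix_coverage_enforced(self, small_feature_matrix, small_curated):
        partial = bk.AA_PROPERTY_TABLE.drop(index="W")
        with pytest.raises(ValueError, match="missing residues"):
            bk.control_features(small_curated, small_feature_matrix, partial)


class TestRFE:
    def test_single_feature_returned_unchanged(self, xy):
        X, y = xy
        retained, _ = bk.recursive_feature_elimination(X.iloc[:, :1], y)
        assert retained == [X.columns[0]]

    def test_step_bound(self, xy):
        X, y = xy
        with pytest.raises(ValueError, match="step"):
            bk.recursive_feature_elimination(X, y, step=X.shape[1])

    def test_signal_features_retained(self, xy, small_cfg):
        X, y = xy
        retained, trace = bk.recursive_feature_elimination(X, y, k=3, seed=0)
        hits = sum(1 for t in small_cfg.signal_features if t in retained)
        assert hits >= len(small_cfg.signal_features) - 1
        assert trace["n_features"].max() == X.shape[1]
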