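import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import paintcluster as pc
from paintcluster.discriminate import feature_names


def make_matrix(X, y, channels=("A", "B", "C", "D", "E")):
    X = np.asarray(X, float)
    return pc.FeatureMatrix(
        X,
        np.asarray(y, int),
        feature_names(channels),
        np.array(["cell0"] * len(X), object),
        tuple(channels),
    )


def synthetic_matrix(n0, n1, seed=0, informative=None, shift=1.0, p=20):
    """Gaussian noise features; optionally one mean-shifted informative column."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n0 + n1, p))
    y = np.array([0] * n0 + [1] * n1)
    if informative is not None:
        X[y == 1, informative] += shift
    X = np.abs(X)  # densities are non-negative
    if informative is not None:
        X[y == 1, informative] = np.abs(
            rng.normal(shift + 2.0, 0.5, n1)
        )  # keep the planted signal after abs
    return make_matrix(X, y)


class TestFeatureNames:
    def test_five_channels_give_twenty_features(self):
        names = feature_names(("A", "B", "C", "D", "E"))
        assert len(names) == 20
        assert len(set(names)) == 20
        assert sum("*" in n for n in names) == 15

    def test_products_include_squares(self):
        names = feature_names(("A", "B"))
        assert names == ("d_A", "d_B", "d_A*d_A", "d_A*d_B", "d_B*d_B")


class TestBuildFeatures:
    def _cluster_table(self, dens_rows, condition, channels=("A", "B", "C", "D", "E")):
        import pandas as pd

        rows = []
        for i, dens in enumerate(dens_rows):
            row = {
                "cluster_id": i,
                "n_total": 50,
                "area_nm2": 1000.0,
                "mode_x_nm": 0.0,
                "mode_y_nm": 0.0,
                "boundary_dist_nm": 500.0,
            }
            for ch, d in zip(channels, dens):
                row[f"n_{ch}"] = int(d * 1000)
                row[f"d_{ch}"] = d
            rows.append(row)
        df = pd.DataFrame(rows)
        df["retained"] = True
        df["discard_reason"] = ""
        return pc.ClusterTable(df, {}, tuple(channels), cell_id="c", condition=condition)

    def test_product_columns_are_products(self):
        dens = [(1e-3, 2e-3, 3e-3, 4e-3, 5e-3)]
        fm = pc.build_features([self._cluster_table(dens, 0), self._cluster_table(dens, 1)])
        assert fm.X.shape == (2, 20)
        d = dict(zip(fm.feature_names, fm.X[0]))
        for i, j in itertools.combinations_with_replacement(range(5), 2):
            a, b = "ABCDE"[i], "ABCDE"[j]
            assert d[f"d_{a}*d_{b}"] == pytest.approx(d[f"d_{a}"] * d[f"d_{b}"])

    def test_all_zero_densities_give_zero_features(self):
        fm = pc.build_features(
            [
                self._cluster_table([(0, 0, 0, 0, 0)], 0),
                self._cluster_table([(0, 0, 0, 0, 0)], 1),
            ]
        )
        assert (fm.X == 0).all()

    def test_channel_relabelling_permutes_columns(self):
        dens = [(1e-3, 2e-3, 3e-3, 4e-3, 5e-3), (5e-3, 4e-3, 3e-3, 2e-3, 1e-3)]
        fm1 = pc.build_features([self._cluster_table(dens, 0), self._cluster_table(dens, 1)])
        # swap channels A and B everywhere (labels and density values)
        swapped = [(d[1], d[0], d[2], d[3], d[4]) for d in dens]
        fm2 = pc.build_features(
            [self._cluster_table(swapped, 0), self._cluster_table(swapped, 1)]
        )
        for name in fm1.feature_names:
            # translate a feature name under the A<->B swap
            trans = name.replace("d_A", "d_#").replace("d_B", "d_A").replace("d_#", "d_B")
            parts = sorted(trans.split("*"))
            trans = "*".join(parts)
            assert name in fm2.feature_names or trans in fm2.feature_names
            col1 = fm1.X[:, fm1.feature_names.index(name)]
            col2 = fm2.X[:, fm2.feature_names.index(trans if trans in fm2.feature_names else name)]
            np.testing.assert_allclose(col1, col2)

    def test_condition_labels_required(self):
        with pytest.raises(ValueError):
            pc.build_features([self._cluster_table([(0, 0, 0, 0, 0)], None)])


class TestSubsampleBalanced:
    def test_counts_follow_unstimulated_fraction(self):
        fm = synthetic_matrix(1000, 5000, seed=1)
        sub = pc.subsample_balanced(fm, 0.66, seed=0)
        assert (sub.y == 0).sum() == 660
        assert (sub.y == 1).sum() == 660

    def test_full_fraction_equal_classes(self):
        fm = synthetic_matrix(300, 300, seed=2)
        sub = pc.subsample_balanced(fm, 1.0, seed=0)
        assert (sub.y == 0).sum() == 300
        assert (sub.y == 1).sum() == 300

    def test_same_seed_identical_selection(self):
        fm = synthetic_matrix(500, 800, seed=3)
        a = pc.subsample_balanced(fm, 0.66, seed=42)
        b = pc.subsample_balanced(fm, 0.66, seed=42)
        np.testing.assert_array_equal(a.X, b.X)

    def test_insufficient_stimulated_rows_error(self):
        fm = synthetic_matrix(1000, 100, seed=4)
        with pytest.raises(ValueError, match="insufficient"):
            pc.subsample_balanced(fm, 0.66, seed=0)

    @given(st.integers(0, 1000))
    def test_balance_exact_property(self, seed):
        fm = synthetic_matrix(400, 700, seed=5)
        sub = pc.subsample_balanced(fm, 0.5, seed=seed)
        assert (sub.y == 0).sum() == (sub.y == 1).sum() == 200


class TestTrainForest:
    def test_separable_fixture_high_oob_accuracy(self):
        fm = synthetic_matrix(800, 800, seed=6, informative=3, shift=3.0)
        cfg = pc.ForestConfig(n_trees=25, min_leaf=50, n_forests=1)
        forest = pc.train_forest(fm, cfg, seed=0)
        assert forest.oob_accuracy > 0.95

    def test_permuted_labels_chance_level(self):
        rng = np.random.default_rng(7)
        fm = synthetic_matrix(800, 800, seed=7)
        cfg = pc.ForestConfig(n_trees=25, min_leaf=50, n_forests=1)
        forest = pc.train_forest(fm, cfg, seed=0)
        # pure noise: accuracy within Monte-Carlo range of 0.5
        assert abs(forest.oob_accuracy - 0.5) < 0.05

    def test_duplicated_rows_stable_accuracy(self):
        fm = synthetic_matrix(400, 400, seed=8, informative=0, shift=2.0)
        doubled = pc.FeatureMatrix(
            np.vstack([fm.X, fm.X]),
            np.concatenate([fm.y, fm.y]),
            fm.feature_names,
            np.concatenate([fm.cell_ids, fm.cell_ids]),
            fm.channels,
        )
        cfg = pc.ForestConfig(n_trees=25, min_leaf=50, n_forests=1)
        acc1 = pc.train_forest(fm, cfg, seed=1).oob_accuracy
        acc2 = pc.train_forest(doubled, cfg, seed=1).oob_accuracy
        assert abs(acc1 - acc2) < 0.05

    def test_single_class_rejected(self):
        fm = synthetic_matrix(500, 500, seed=9)
        only0 = pc.FeatureMatrix(
            fm.X[fm.y == 0], fm.y[fm.y == 0], fm.feature_names, fm.cell_ids[fm.y == 0], fm.channels
        )
        with pytest.raises(ValueError):
            pc.train_forest(only0, pc.ForestConfig(n_trees=5, min_leaf=10), seed=0)

    def test_too_few_rows_for_leaf_size_rejected(self):
        fm = synthetic_matrix(100, 100, seed=10)
        with pytest.raises(ValueError):
            pc.train_forest(fm, pc.ForestConfig(min_leaf=300), seed=0)


class TestPermutationImportance:
    def test_informative_feature_has_largest_delta(self):
        fm = synthetic_matrix(800, 800, seed=11, informative=5, shift=3.0)
        cfg = pc.ForestConfig(n_trees=25, min_leaf=50, n_forests=1)
        forest = pc.train_forest(fm, cfg, seed=0)
        delta = pc.permutation_importance(forest, fm, seed=0)
        assert np.argmax(delta) == 5
        assert delta[5] > 0.2

    def test_noise_features_near_zero(self):
        fm = synthetic_matrix(800, 800, seed=12, informative=5, shift=3.0)
        cfg = pc.ForestConfig(n_trees=25, min_leaf=50, n_forests=1)
        forest = pc.train_forest(fm, cfg, seed=0)
        delta = pc.permutation_importance(forest, fm, seed=0)
        noise = np.delete(delta, 5)
        assert np.abs(noise).max() < 0.05

    def test_fixed_seed_bit_reproducible(self):
        fm = synthetic_matrix(600, 600, seed=13, informative=2, shift=2.0)
        cfg = pc.ForestConfig(n_trees=10, min_leaf=50, n_forests=1)
        forest = pc.train_forest(fm, cfg, seed=3)
        d1 = pc.permutation_importance(forest, fm, seed=99)
        d2 = pc.permutation_importance(forest, fm, seed=99)
        np.testing.assert_array_equal(d1, d2)


class TestImportanceEnsemble:
    def test_two_forest_ensemble_equals_manual_composition(self):
        fm = synthetic_matrix(600, 900, seed=14, informative=4, shift=2.0)
        cfg = pc.ForestConfig(n_trees=10, min_leaf=50, n_forests=2, seed=123)
        report = pc.importance_ensemble(fm, cfg)
        deltas, accs = [], []
        for f in range(2):
            ss = pc.forest_seed(123, f)
            s_sub, s_train, s_perm = ss.spawn(3)
            sub = pc.subsample_balanced(fm, cfg.subsample_fraction, s_sub)
            forest = pc.train_forest(sub, cfg, s_train)
            accs.append(forest.oob_accuracy)
            deltas.append(pc.permutation_importance(forest, sub, s_perm))
        np.testing.assert_allclose(report.mean_delta_error, np.mean(deltas, axis=0))
        assert report.oob_accuracy_mean == pytest.approx(np.mean(accs))

    def test_identical_distributions_chance_and_flat(self):
        fm = synthetic_matrix(700, 700, seed=15)
        cfg = pc.ForestConfig(n_trees=20, min_leaf=50, n_forests=10, seed=0)
        report = pc.importance_ensemble(fm, cfg)
        assert abs(report.oob_accuracy_mean - 0.5) < 0.04
        assert np.abs(report.mean_delta_error).max() < 0.02

    def test_ranks_are_a_permutation(self):
        fm = synthetic_matrix(500, 500, seed=16, informative=1, shift=2.0)
        cfg = pc.ForestConfig(n_trees=10, min_leaf=50, n_forests=3, seed=5)
        report = pc.importance_ensemble(fm, cfg)
        assert sorted(report.ranks) == list(range(1, 21))
        assert report.top_feature() == report.feature_names[1]

    def test_monotone_transform_leaves_ranks(self):
        fm = synthetic_matrix(600, 600, seed=17, informative=7, shift=2.5)
        cfg = pc.ForestConfig(n_trees=15, min_leaf=50, n_forests=4, seed=9)
        r1 = pc.importance_ensemble(fm, cfg)
        X2 = fm.X.copy()
        X2[:, 7] = np.log1p(X2[:, 7]) * 3.0  # strictly monotone transform
        fm2 = pc.FeatureMatrix(X2, fm.y, fm.feature_names, fm.cell_ids, fm.channels)
        r2 = pc.importance_ensemble(fm2, cfg)
        assert r1.top_feature() == r2.top_feature() == fm.feature_names[7]
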