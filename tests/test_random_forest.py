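"""The from-scratch regression random forest."""

import numpy as np
import pytest

from rfmqa.errors import ParameterError
from rfmqa.random_forest import (Forest, fit_forest, oob_importance,
                                 predict)

_TIE_EPS = 1e-12


# ---------------------------------------------------------------------------
# exhaustive CART oracle (independent re-implementation for comparison)
# ---------------------------------------------------------------------------

def _oracle_cart_predict(x, y, node_cutoff, query):
    """Grow a full CART by exhaustive split search; predict one query row.

    Mirrors the documented contract: variance-reduction gain, midpoint
    thresholds, ties to lowest feature index then lowest threshold, stop
    below node_cutoff rows or when no split strictly improves.
    """
    if len(y) < node_cutoff or np.ptp(y) == 0:
        return y.mean()
    parent_sse = ((y - y.mean()) ** 2).sum()
    best = None  # (gain, feature, threshold)
    for f in range(x.shape[1]):
        vals = np.unique(x[:, f])
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = (lo + hi) / 2.0
            left, right = y[x[:, f] <= thr], y[x[:, f] > thr]
            sse = ((left - left.mean()) ** 2).sum() + \
                ((right - right.mean()) ** 2).sum()
            gain = parent_sse - sse
            if best is None or gain > best[0] + _TIE_EPS:
                best = (gain, f, thr)
    if best is None or best[0] <= _TIE_EPS:
        return y.mean()
    _, f, thr = best
    mask = x[:, f] <= thr
    if query[f] <= thr:
        return _oracle_cart_predict(x[mask], y[mask], node_cutoff, query)
    return _oracle_cart_predict(x[~mask], y[~mask], node_cutoff, query)


class TestTreeGrowth:
    def test_single_tree_with_all_features_matches_exhaustive_cart(self):
        """m_try = p removes feature subsampling, so the grown tree must
        equal the exhaustively searched CART on the bootstrap sample."""
        rng = np.random.default_rng(11)
        x = rng.random((12, 2))
        y = np.sin(3 * x[:, 0]) + 0.5 * x[:, 1] + 0.1 * rng.normal(size=12)
        forest = fit_forest(x, y, n_tree=1, m_try=2, node_cutoff=5, seed=3)
        tree = forest.trees[0]
        xb, yb = x[tree.bootstrap_indices], y[tree.bootstrap_indices]
        queries = rng.random((200, 2))
        mine = tree.predict(queries)
        oracle = np.array([
            _oracle_cart_predict(xb, yb, 5, q) for q in queries])
        np.testing.assert_allclose(mine, oracle, atol=1e-12)

    def test_matches_sklearn_tree_partition(self):
        """Cross-check against an independent CART implementation.

        Small nodes admit several splits that separate the sample
        identically, and the two implementations break such ties
        differently, so the comparable invariants are the fitted values
        on the training rows and the shape of the induced partition —
        not off-sample predictions.
        """
        sktree = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(21)
        x = rng.random((40, 3))
        y = 2 * x[:, 0] - x[:, 1] ** 2 + 0.05 * rng.normal(size=40)
        forest = fit_forest(x, y, n_tree=1, m_try=3, node_cutoff=5, seed=8)
        tree = forest.trees[0]
        xb, yb = x[tree.bootstrap_indices], y[tree.bootstrap_indices]
        ref = sktree.DecisionTreeRegressor(min_samples_split=5,
                                           random_state=0).fit(xb, yb)
        np.testing.assert_allclose(tree.predict(xb), ref.predict(xb),
                                   atol=1e-10)
        assert tree.n_nodes == ref.tree_.node_count
        skl_leaves = ref.tree_.n_node_samples[ref.tree_.children_left == -1]
        assert sorted(tree.count[tree.feature == -1].tolist()) == \
            sorted(skl_leaves.tolist())

    def test_constant_response_yields_single_leaf(self):
        x = np.random.default_rng(1).random((20, 4))
        y = np.full(20, 0.7)
        forest = fit_forest(x, y, n_tree=3, m_try=2, seed=0)
        for tree in forest.trees:
            assert tree.n_nodes == 1
        assert forest.predict(x[0]) == pytest.approx(0.7)

    def test_node_cutoff_bounds_leaf_sizes(self):
        rng = np.random.default_rng(2)
        x, y = rng.random((60, 3)), rng.random(60)
        forest = fit_forest(x, y, n_tree=5, m_try=2, node_cutoff=5, seed=4)
        for tree in forest.trees:
            internal = tree.feature >= 0
            # every split node held at least node_cutoff rows
            assert tree.count[internal].min() >= 5

    def test_bootstrap_and_oob_partition_the_rows(self):
        forest = fit_forest(np.random.default_rng(3).random((30, 2)),
                            np.arange(30.0), n_tree=10, m_try=1, seed=5)
        for tree in forest.trees:
            assert len(tree.bootstrap_indices) == 30
            boot = set(tree.bootstrap_indices.tolist())
            oob = set(tree.oob_indices.tolist())
            assert boot.isdisjoint(oob)
            assert boot | oob == set(range(30))


@pytest.fixture(scope="module")
def smooth_data():
    rng = np.random.default_rng(6)
    x = rng.random((150, 4))
    y = np.sin(4 * x[:, 0]) + x[:, 1] + 0.05 * rng.normal(size=150)
    return x, y


class TestForest:
    def test_prediction_is_mean_of_tree_predictions(self, smooth_data):
        x, y = smooth_data
        forest = fit_forest(x, y, n_tree=7, m_try=2, seed=9)
        q = x[:5]
        stacked = np.mean([t.predict(q) for t in forest.trees], axis=0)
        np.testing.assert_allclose(forest.predict(q), stacked, atol=1e-12)
        # scalar form for a single row
        assert forest.predict(x[0]) == pytest.approx(stacked[0])

    def test_learns_a_smooth_function(self, smooth_data):
        x, y = smooth_data
        forest = fit_forest(x, y, n_tree=100, m_try=2, seed=10)
        rng = np.random.default_rng(7)
        xt = rng.random((200, 4))
        yt = np.sin(4 * xt[:, 0]) + xt[:, 1]
        pred = forest.predict(xt)
        ss_res = ((pred - yt) ** 2).sum()
        ss_tot = ((yt - yt.mean()) ** 2).sum()
        assert 1 - ss_res / ss_tot > 0.7

    def test_oob_error_below_response_variance(self, smooth_data):
        x, y = smooth_data
        forest = fit_forest(x, y, n_tree=60, m_try=2, seed=11)
        assert 0 < forest.oob_error < y.var()

    def test_same_seed_reproduces_forest_exactly(self, smooth_data):
        x, y = smooth_data
        a = fit_forest(x, y, n_tree=10, m_try=2, seed=12)
        b = fit_forest(x, y, n_tree=10, m_try=2, seed=12)
        assert a.to_json() == b.to_json()

    def test_different_seed_changes_forest(self, smooth_data):
        x, y = smooth_data
        a = fit_forest(x, y, n_tree=10, m_try=2, seed=12)
        b = fit_forest(x, y, n_tree=10, m_try=2, seed=13)
        assert a.to_json() != b.to_json()

    def test_growing_the_ensemble_preserves_existing_trees(self, smooth_data):
        """Per-tree random streams: tree t is the same for any n_tree > t."""
        x, y = smooth_data
        small = fit_forest(x, y, n_tree=3, m_try=2, seed=14)
        large = fit_forest(x, y, n_tree=8, m_try=2, seed=14)
        for ts, tl in zip(small.trees, large.trees):
            np.testing.assert_array_equal(ts.feature, tl.feature)
            np.testing.assert_allclose(ts.threshold, tl.threshold)
            np.testing.assert_array_equal(ts.bootstrap_indices,
                                          tl.bootstrap_indices)

    def test_serialization_round_trip_preserves_predictions(self, smooth_data,
                                                            tmp_path):
        x, y = smooth_data
        forest = fit_forest(x, y, n_tree=5, m_try=2, seed=15,
                            feature_names=("a", "b", "c", "d"),
                            feature_hash="deadbeef")
        path = tmp_path / "forest.json"
        forest.to_json(path)
        back = Forest.from_json(path)
        np.testing.assert_array_equal(back.predict(x), forest.predict(x))
        assert back.feature_names == ("a", "b", "c", "d")
        assert back.feature_hash == "deadbeef"
        assert back.oob_error == forest.oob_error

    def test_bad_format_tag_rejected(self):
        with pytest.raises(ParameterError, match="format"):
            Forest.from_json('{"format": "something-else"}')

    def test_parameter_validation(self, smooth_data):
        x, y = smooth_data
        with pytest.raises(ParameterError, match="m_try"):
            fit_forest(x, y, n_tree=2, m_try=5)
        with pytest.raises(ParameterError, match="n_tree"):
            fit_forest(x, y, n_tree=0, m_try=1)
        with pytest.raises(ParameterError, match="finite"):
            fit_forest(x, np.where(y > 0, y, np.nan), n_tree=1, m_try=1)
        forest = fit_forest(x, y, n_tree=2, m_try=2, seed=0)
        with pytest.raises(ParameterError, match="features"):
            forest.predict(np.zeros((3, 7)))

    def test_module_level_predict_alias(self, smooth_data):
        x, y = smooth_data
        forest = fit_forest(x, y, n_tree=3, m_try=2, seed=16)
        np.testing.assert_array_equal(predict(forest, x[:4]),
                                      forest.predict(x[:4]))


class TestImportance:
    def test_informative_feature_dominates(self):
        rng = np.random.default_rng(17)
        x = rng.random((200, 5))
        y = 3 * x[:, 2] + 0.1 * rng.normal(size=200)
        forest = fit_forest(x, y, n_tree=60, m_try=2, seed=18)
        imp = oob_importance(forest, x, y)
        assert imp.argmax() == 2
        assert imp[2] > 3 * np.delete(imp, 2).max()

    def test_pure_noise_importances_near_zero(self):
        rng = np.random.default_rng(19)
        x, y = rng.random((150, 4)), rng.normal(size=150)
        forest = fit_forest(x, y, n_tree=60, m_try=2, seed=20)
        imp = oob_importance(forest, x, y)
        # permuting an uninformative feature cannot systematically raise
        # the OOB error by a meaningful fraction of the response variance
        assert np.abs(imp).max() < 0.5 * y.var()

    def test_importance_is_deterministic_and_stored(self):
        rng = np.random.default_rng(22)
        x = rng.random((80, 3))
        y = x[:, 0] + rng.normal(size=80) * 0.1
        forest = fit_forest(x, y, n_tree=20, m_try=1, seed=23)
        imp1 = oob_importance(forest, x, y)
        imp2 = oob_importance(
            fit_forest(x, y, n_tree=20, m_try=1, seed=23), x, y)
        np.testing.assert_array_equal(imp1, imp2)
        np.testing.assert_array_equal(forest.importance, imp1)
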