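"""Fisher-split correctness (vs brute-force and LDA oracles), tree/forest
behaviour, OOB error and permutation importance."""

import numpy as np
import pytest

import rfecs
from rfecs.forest import (
    _tree_predict,
    fit_fisher_split,
    fit_forest,
    grow_tree,
    oob_error,
    oob_variable_importance,
    predict_votes,
)
from rfecs.training import ENHANCER, NON_ENHANCER, FeatureBlockMatrix


def brute_force_split(X, y):
    """Independent oracle: closed-form discriminant via pseudo-inverse (same
    trace-scaled ridge convention, computed from scratch), then an O(n^2)
    scan of *all* projection midpoints scoring Gini from first principles.
    Shares no code with the implementation's prefix-sum search."""
    pos = y == 1
    mu1, mu0 = X[pos].mean(0), X[~pos].mean(0)
    d1, d0 = X[pos] - mu1, X[~pos] - mu0
    sw = d1.T @ d1 + d0.T @ d0
    ridge = max(1e-6 * np.trace(sw) / X.shape[1], 1e-12)
    w = np.linalg.pinv(sw + ridge * np.eye(X.shape[1])) @ (mu1 - mu0)
    proj = X @ w
    ps = np.sort(np.unique(proj))
    best = (np.inf, None)
    for a, b in zip(ps[:-1], ps[1:]):
        thr = (a + b) / 2
        left = proj <= thr
        impurity = 0.0
        for side in (left, ~left):
            n = side.sum()
            if n:
                p1 = (y[side] == 1).mean()
                impurity += n / len(y) * 2 * p1 * (1 - p1)
        if impurity < best[0] - 1e-12:
            best = (impurity, thr)
    return w, best[1], best[0]


def random_instance(rng, n, dim=20, sep=2.0):
    n1 = rng.integers(3, n - 2)
    y = np.zeros(n, dtype=np.int64)
    y[:n1] = 1
    shift = rng.normal(scale=sep, size=dim)
    X = rng.normal(size=(n, dim))
    X[y == 1] += shift
    return X, y


class TestFisherSplit:
    def test_identity_scatter_weights_proportional_to_mean_difference(self):
        # classes with means e0 and e1 and *exactly* isotropic within-class
        # scatter (symmetric ±delta displacements): w must align with mu1-mu0
        mu1 = np.zeros(20); mu1[0] = 1.0
        mu0 = np.zeros(20); mu0[1] = 1.0
        delta = 0.05 * np.eye(20)
        X = np.vstack([mu1 + delta, mu1 - delta, mu0 + delta, mu0 - delta])
        y = np.array([1] * 40 + [0] * 40)
        w, thr, dec = fit_fisher_split(X, y)
        expect = (mu1 - mu0) / np.linalg.norm(mu1 - mu0)
        cos = abs(w @ expect)
        assert cos > 1 - 1e-9

    def test_separable_projections_reach_zero_impurity(self):
        rng = np.random.default_rng(1)
        X, y = random_instance(rng, 30, sep=50.0)
        w, thr, dec = fit_fisher_split(X, y)
        proj = X @ w
        left, right = y[proj <= thr], y[proj > thr]
        assert len(np.unique(left)) == 1 and len(np.unique(right)) == 1
        p1 = (y == 1).mean()
        assert dec == pytest.approx(2 * p1 * (1 - p1))

    def test_matches_brute_force_oracle_on_random_instances(self):
        """Node classification must agree with the independent exhaustive
        midpoint search on >= 50 random 12-40 sample instances."""
        rng = np.random.default_rng(2)
        for _ in range(60):
            X, y = random_instance(rng, int(rng.integers(12, 41)), sep=1.5)
            got = fit_fisher_split(X, y)
            assert got is not None
            w, thr, _ = got
            wo, thro, _ = brute_force_split(X, y)
            # directions agree up to sign/scale, decisions agree exactly
            assert abs(w @ wo) / np.linalg.norm(wo) > 1 - 1e-8
            np.testing.assert_array_equal(X @ w <= thr, np.sign(w @ wo) * (X @ wo) <= np.sign(w @ wo) * thro)

    def test_direction_agrees_with_sklearn_lda(self):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(3)
        X, y = random_instance(rng, 200, dim=5, sep=1.0)
        w, _, _ = fit_fisher_split(X, y)
        lda = sklearn.LinearDiscriminantAnalysis(solver="eigen").fit(X, y)
        ref = lda.coef_[0] / np.linalg.norm(lda.coef_[0])
        assert abs(w @ ref) > 0.999

    def test_one_class_node_is_a_precondition_violation(self):
        X = np.ones((5, 20))
        with pytest.raises(ValueError):
            fit_fisher_split(X, np.ones(5, dtype=int))

    def test_singular_scatter_handled_by_ridge(self):
        # zero within-class variance: scatter is singular, ridge must cope
        X = np.zeros((10, 20))
        X[:5, 0] = 1.0
        y = np.array([1] * 5 + [0] * 5)
        got = fit_fisher_split(X, y)
        assert got is not None
        w, thr, dec = got
        assert dec > 0


def toy_matrix(rng, n=60, m=3, informative=0, sep=4.0):
    y = (np.arange(n) < n // 3).astype(np.int64)
    X = rng.normal(size=(n, m, 20))
    X[y == 1, informative, :] += sep
    return FeatureBlockMatrix(np.abs(X), tuple(f"mk{i}" for i in range(m)), y)


class TestGrowTree:
    def test_single_class_gives_single_leaf(self):
        rng = np.random.default_rng(0)
        X = rng.random((10, 2, 20))
        tree = grow_tree(X, np.ones(10, dtype=np.int64), mtry=2, min_node=2, rng=rng)
        assert tree.is_leaf and tree.leaf_class == ENHANCER

    def test_min_node_equal_n_gives_majority_leaf(self):
        rng = np.random.default_rng(0)
        X = rng.random((10, 2, 20))
        y = np.array([1] * 3 + [0] * 7)
        tree = grow_tree(X, y, mtry=2, min_node=10, rng=rng)
        assert tree.is_leaf and tree.leaf_class == NON_ENHANCER

    def test_separable_data_zero_training_error(self):
        rng = np.random.default_rng(4)
        ts = toy_matrix(rng, sep=8.0)
        tree = grow_tree(ts.values, ts.labels, mtry=3, min_node=2, rng=rng)
        pred = _tree_predict(tree, ts.values)
        assert (pred == ts.labels).all()

    def test_leaf_tie_breaks_to_non_enhancer(self):
        rng = np.random.default_rng(0)
        X = np.ones((4, 1, 20))
        y = np.array([1, 1, 0, 0])
        tree = grow_tree(X, y, mtry=1, min_node=2, rng=rng)
        assert tree.is_leaf and tree.leaf_class == NON_ENHANCER


class TestForest:
    def test_same_seed_identical_forests(self):
        rng = np.random.default_rng(5)
        ts = toy_matrix(rng)
        a = fit_forest(ts, n_trees=8, seed=42)
        b = fit_forest(ts, n_trees=8, seed=42)

        def same(n1, n2):
            if n1.is_leaf or n2.is_leaf:
                return n1.is_leaf and n2.is_leaf and n1.leaf_class == n2.leaf_class
            return (
                n1.mark_index == n2.mark_index
                and n1.threshold == n2.threshold
                and np.array_equal(n1.weights, n2.weights)
                and same(n1.left, n2.left)
                and same(n1.right, n2.right)
            )

        assert all(same(t1, t2) for t1, t2 in zip(a.trees, b.trees))
        assert all(np.array_equal(x, y) for x, y in zip(a.bootstrap_indices, b.bootstrap_indices))

    def test_one_tree_votes_are_binary_and_match_tree(self):
        rng = np.random.default_rng(6)
        ts = toy_matrix(rng)
        f = fit_forest(ts, n_trees=1, seed=0)
        votes = predict_votes(f, ts)
        assert set(np.unique(votes)) <= {0.0, 1.0}
        np.testing.assert_array_equal(votes, (_tree_predict(f.trees[0], ts.values) == ENHANCER).astype(float))

    def test_votes_sum_to_one_and_bounded(self):
        rng = np.random.default_rng(7)
        ts = toy_matrix(rng)
        f = fit_forest(ts, n_trees=9, seed=1)
        votes = predict_votes(f, ts)
        assert ((votes >= 0) & (votes <= 1)).all()
        non_votes = 1 - votes  # two-class: enhancer + non-enhancer votes = 1
        np.testing.assert_allclose(votes + non_votes, 1.0)

    def test_mark_mismatch_fatal_and_lists_marks(self):
        rng = np.random.default_rng(8)
        ts = toy_matrix(rng)
        f = fit_forest(ts, n_trees=3, seed=0)
        other = FeatureBlockMatrix(ts.values, ("a", "b", "c"), ts.labels)
        with pytest.raises(ValueError, match="mark mismatch"):
            predict_votes(f, other)

    def test_depth_one_single_tree_reproduces_standalone_split(self):
        """A 1-tree, mtry-1, depth-1 forest on one mark must equal the
        standalone Fisher split's decisions (oracle equivalence)."""
        rng = np.random.default_rng(9)
        n = 40
        y = (np.arange(n) < 15).astype(np.int64)
        X = rng.normal(size=(n, 1, 20))
        X[y == 1] += 6.0  # separable: the root split leaves pure children
        ts = FeatureBlockMatrix(X, ("only",), y)
        f = fit_forest(ts, n_trees=1, mtry=1, seed=3)
        tree = f.trees[0]
        assert not tree.is_leaf and tree.left.is_leaf and tree.right.is_leaf
        boot = f.bootstrap_indices[0]
        w, thr, _ = fit_fisher_split(X[boot, 0, :], y[boot])
        np.testing.assert_allclose(tree.weights, w)
        assert tree.threshold == pytest.approx(thr)
        proj = X[:, 0, :] @ w
        side = proj <= thr
        expect = np.where(side, tree.left.leaf_class, tree.right.leaf_class)
        np.testing.assert_array_equal(_tree_predict(tree, X), expect)

    def test_vote_variance_shrinks_with_more_trees(self):
        rng = np.random.default_rng(10)
        ts = toy_matrix(rng, n=90, sep=1.0)
        probe = ts.values[::3]

        def spread(n_trees):
            votes = np.stack([
                predict_votes(fit_forest(ts, n_trees=n_trees, seed=s), probe)
                for s in range(8)
            ])
            return votes.var(axis=0).mean()

        assert spread(65) < spread(5)

    def test_tiny_training_set_fatal(self):
        rng = np.random.default_rng(11)
        ts = toy_matrix(rng, n=6)
        with pytest.raises(ValueError, match="too small"):
            fit_forest(ts, n_trees=2, min_node=5)

    def test_serialization_round_trip_preserves_votes(self, tmp_path):
        rng = np.random.default_rng(12)
        ts = toy_matrix(rng)
        f = fit_forest(ts, n_trees=5, seed=2)
        path = str(tmp_path / "model.rfecs.json")
        rfecs.save_forest(f, path)
        back = rfecs.load_forest(path)
        assert back.mark_names == f.mark_names
        assert back.params == f.params
        np.testing.assert_allclose(predict_votes(back, ts), predict_votes(f, ts))
        for a, b in zip(back.oob_indices, f.oob_indices):
            np.testing.assert_array_equal(a, b)


class TestOob:
    def test_oob_error_near_zero_on_separable_data(self):
        rng = np.random.default_rng(13)
        ts = toy_matrix(rng, n=120, sep=8.0)
        f = fit_forest(ts, n_trees=25, seed=0)
        err, excluded = oob_error(f, ts)
        assert 0 <= err <= 0.05
        assert excluded < ts.n_samples

    def test_permuted_labels_give_chance_level_error(self):
        """With labels shuffled, OOB error approaches the minority share
        (the enhancer class fraction), averaged over seeds."""
        rng = np.random.default_rng(14)
        errs = []
        for s in range(10):
            ts = toy_matrix(rng, n=120, sep=6.0)
            labels = np.random.default_rng(s).permutation(ts.labels)
            shuffled = FeatureBlockMatrix(ts.values, ts.mark_names, labels)
            f = fit_forest(shuffled, n_trees=15, seed=s)
            errs.append(oob_error(f, shuffled)[0])
        base = (ts.labels == ENHANCER).mean()
        assert abs(np.mean(errs) - base) < 0.15

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(15)
        ts = toy_matrix(rng)
        e1 = oob_error(fit_forest(ts, n_trees=10, seed=9), ts)
        e2 = oob_error(fit_forest(ts, n_trees=10, seed=9), ts)
        assert e1 == e2


class TestImportance:
    def test_constant_mark_has_zero_importance(self):
        rng = np.random.default_rng(16)
        ts = toy_matrix(rng, m=3, sep=6.0)
        ts.values[:, 2, :] = 1.0  # constant block: permutation changes nothing
        f = fit_forest(ts, n_trees=10, seed=0)
        rep = oob_variable_importance(f, ts, n_permutations=2, seed=0)
        assert rep.importance[2] == 0.0

    def test_all_zero_mark_importance_negligible_across_seeds(self):
        vals = []
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            ts = toy_matrix(rng, m=3, sep=6.0)
            ts.values[:, 1, :] = 0.0
            f = fit_forest(ts, n_trees=10, seed=s)
            rep = oob_variable_importance(f, ts, n_permutations=2, seed=s)
            vals.append(rep.importance[1])
        assert all(abs(v) < 0.01 for v in vals)

    def test_planted_informative_mark_ranked_first(self):
        wins = 0
        for s in range(10):
            rng = np.random.default_rng(200 + s)
            ts = toy_matrix(rng, m=4, informative=1, sep=3.0)
            f = fit_forest(ts, n_trees=15, seed=s)
            rep = oob_variable_importance(f, ts, n_permutations=3, seed=s)
            wins += rep.ranks[1] == 1
        assert wins >= 9

    def test_ranks_are_a_permutation(self):
        rng = np.random.default_rng(17)
        ts = toy_matrix(rng, m=5)
        f = fit_forest(ts, n_trees=5, seed=0)
        rep = oob_variable_importance(f, ts, n_permutations=1, seed=0)
        assert sorted(rep.ranks) == [1, 2, 3, 4, 5]
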