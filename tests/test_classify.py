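import numpy as np
import pytest
from scipy import stats

from fidgetkit import (
    FidgetyNetClassifier,
    FoldResults,
    NetworkSpec,
    TrainConfig,
    ablation_grid,
    build_network,
    compare_conditions,
    cross_validate,
)

TINY = dict(n_filters=8, filter_len=5, fc_sizes=(16,), max_epochs=15,
            patience=4, restarts=1, val_fraction=0.25)


def separable_toy(n_per_class=24, frames=40, channels=4, noise=0.0, seed=0):
    """Class 0 hovers near 0.2, class 1 near 0.8 in every channel."""
    rng = np.random.default_rng(seed)
    X0 = 0.2 + noise * rng.standard_normal((n_per_class, frames, channels))
    X1 = 0.8 + noise * rng.standard_normal((n_per_class, frames, channels))
    X = np.concatenate([X0, X1])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return X, y


class TestBuildNetwork:
    def test_shapes_and_output(self):
        rng = np.random.default_rng(0)
        net = build_network(NetworkSpec(), (250, 42), rng)
        out = net.predict_proba(np.zeros((3, 250, 42), dtype=np.float32))
        assert out.shape == (3,)
        assert np.all((out >= 0) & (out <= 1))

    def test_single_fc_spec_has_one_hidden_dense(self):
        from fidgetkit._net import Dense

        rng = np.random.default_rng(0)
        net = build_network(NetworkSpec(fc_sizes=(100,)), (250, 42), rng)
        denses = [l for l in net.layers if isinstance(l, Dense)]
        assert len(denses) == 2  # one hidden block + output head

    def test_same_seed_identical_init(self):
        a = build_network(NetworkSpec(), (100, 10), np.random.default_rng(7))
        b = build_network(NetworkSpec(), (100, 10), np.random.default_rng(7))
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa, pb)

    def test_input_shorter_than_filter_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            build_network(NetworkSpec(filter_len=7), (5, 4),
                          np.random.default_rng(0))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            NetworkSpec(fc_sizes=(10, 10, 10))
        with pytest.raises(ValueError):
            NetworkSpec(filter_len=6)
        with pytest.raises(ValueError):
            NetworkSpec(dropout=1.0)


class TestTraining:
    def test_separable_toy_reaches_perfect_validation(self):
        X, y = separable_toy()
        clf = FidgetyNetClassifier(random_state=0, **TINY).fit(X, y)
        assert clf.validation_accuracy_ == 1.0
        assert clf.score(X, y) == 1.0

    def test_shuffled_labels_stay_in_chance_band(self):
        X, _ = separable_toy(n_per_class=100, noise=0.05, seed=1)
        rng = np.random.default_rng(2)
        y_perm = rng.permutation([0] * 100 + [1] * 100)
        clf = FidgetyNetClassifier(random_state=0, **TINY).fit(X, y_perm)
        assert 0.35 <= clf.validation_accuracy_ <= 0.72

    def test_more_restarts_never_hurt_validation(self):
        X, y = separable_toy(noise=0.4, seed=3)
        accs = {}
        for r in (1, 4):
            clf = FidgetyNetClassifier(random_state=5,
                                       **{**TINY, "restarts": r}).fit(X, y)
            accs[r] = clf.validation_accuracy_
        assert accs[4] >= accs[1] - 1e-12

    def test_channel_permutation_invariance_on_retrain(self):
        X, y = separable_toy()
        perm = np.random.default_rng(1).permutation(X.shape[2])
        a = FidgetyNetClassifier(random_state=0, **TINY).fit(X, y)
        b = FidgetyNetClassifier(random_state=0, **TINY).fit(X[:, :, perm], y)
        assert a.score(X, y) == b.score(X[:, :, perm], y) == 1.0

    def test_single_class_raises(self):
        X, _ = separable_toy()
        with pytest.raises(ValueError, match="2 classes"):
            FidgetyNetClassifier(random_state=0, **TINY).fit(
                X, np.zeros(len(X))
            )

    def test_deterministic_refit(self):
        X, y = separable_toy(noise=0.3)
        p1 = FidgetyNetClassifier(random_state=9, **TINY).fit(X, y).predict_proba(X)
        p2 = FidgetyNetClassifier(random_state=9, **TINY).fit(X, y).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_sklearn_estimator_contract(self):
        clf = FidgetyNetClassifier(random_state=0)
        params = clf.get_params()
        assert params["n_filters"] == 64 and params["batch_size"] == 32
        clf.set_params(n_filters=16)
        assert clf.n_filters == 16

    def test_predicts_original_label_values(self):
        X, y = separable_toy()
        clf = FidgetyNetClassifier(random_state=0, **TINY).fit(X, y + 5)
        assert set(clf.predict(X)) <= {5, 6}


class TestCrossValidation:
    def test_separable_toy_zero_variance_folds(self):
        X, y = separable_toy(n_per_class=30)
        spec = NetworkSpec(n_filters=8, filter_len=5, fc_sizes=(16,))
        cfg = TrainConfig(restarts=3, max_epochs=15, patience=4,
                          val_fraction=0.25)
        res = cross_validate(X, y, spec, cfg, k=5, seed=0)
        assert res.mean == pytest.approx(100.0)
        assert res.ci95 == pytest.approx(0.0)

    def test_fold_membership_deterministic(self):
        from sklearn.model_selection import StratifiedKFold

        X = np.zeros((40, 5, 2))
        y = np.array([0, 1] * 20)
        m = np.random.default_rng(4)
        s1 = list(StratifiedKFold(5, shuffle=True,
                                  random_state=int(m.integers(2**31))).split(X, y))
        m = np.random.default_rng(4)
        s2 = list(StratifiedKFold(5, shuffle=True,
                                  random_state=int(m.integers(2**31))).split(X, y))
        for (a, _), (b, _) in zip(s1, s2):
            np.testing.assert_array_equal(a, b)

    def test_mean_equals_fold_mean(self):
        res = FoldResults(np.array([0.8, 0.9, 0.85, 0.95, 0.9]), True,
                          NetworkSpec())
        assert res.mean == pytest.approx(np.mean([0.8, 0.9, 0.85, 0.95, 0.9]) * 100,
                                         abs=1e-12)

    def test_k_below_two_rejected(self):
        X, y = separable_toy()
        with pytest.raises(ValueError):
            cross_validate(X, y, k=1)


class TestAblationAndComparison:
    def test_grid_cardinality_and_best_flag(self):
        X, y = separable_toy(n_per_class=20)
        grid = [NetworkSpec(n_filters=4, filter_len=3, fc_sizes=(8,)),
                NetworkSpec(n_filters=8, filter_len=3, fc_sizes=(8,))]
        cfg = TrainConfig(restarts=1, max_epochs=8, patience=3,
                          val_fraction=0.25)
        rows = ablation_grid({True: (X, y), False: (X, y)}, grid, cfg,
                             k=2, seed=0)
        assert len(rows) == 4
        for cond in (True, False):
            group = [r for r in rows if r["with_head"] == cond]
            best = [r for r in group if r["best_in_group"]]
            assert len(best) == 1
            assert best[0]["mean_percent"] == max(r["mean_percent"] for r in group)

    def test_identical_folds_give_p_one(self):
        r = FoldResults(np.array([0.9] * 5), True, NetworkSpec())
        assert compare_conditions(r, r)["p"] == 1.0

    def test_textbook_t_test(self):
        a = FoldResults(np.array([0.90, 0.91, 0.89, 0.90, 0.90]), True,
                        NetworkSpec())
        b = FoldResults(np.array([0.60, 0.61, 0.59, 0.60, 0.60]), False,
                        NetworkSpec())
        out = compare_conditions(a, b)
        t_ref, p_ref = stats.ttest_ind(a.fold_accuracies, b.fold_accuracies)
        assert out["t"] == pytest.approx(t_ref)
        assert out["p"] == pytest.approx(p_ref) and out["p"] < 0.001

    def test_swap_symmetry(self):
        a = FoldResults(np.array([0.8, 0.85, 0.8, 0.9, 0.82]), True,
                        NetworkSpec())
        b = FoldResults(np.array([0.7, 0.75, 0.72, 0.71, 0.74]), False,
                        NetworkSpec())
        ab, ba = compare_conditions(a, b), compare_conditions(b, a)
        assert ab["p"] == pytest.approx(ba["p"])
        assert ab["t"] == pytest.approx(-ba["t"])

    def test_unequal_fold_counts_rejected(self):
        a = FoldResults(np.array([0.8, 0.9]), True, NetworkSpec())
        b = FoldResults(np.array([0.8, 0.9, 0.85]), False, NetworkSpec())
        with pytest.raises(ValueError):
            compare_conditions(a, b)
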