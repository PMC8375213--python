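import numpy as np
import pytest

from prfbio import (
    FeatureMatrix,
    LabelConfig,
    SyntheticSpec,
    generate,
    label_dataset,
)
from prfbio.prf_core import (
    ProbabilisticRandomForestClassifier,
    Tree,
    fit,
    fit_hard_rf,
    load_model,
    modified_gini,
    predict_proba,
    save_model,
    split_cost,
    weighted_class_probs,
)


# --- brute-force split oracle (independent of the learner's code path) ----

def brute_gini(labels):
    if not labels:
        return 0.0
    pa = sum(labels) / len(labels)
    return 1.0 - (pa**2 + (1.0 - pa) ** 2)


def brute_best_split(X, y, idx):
    """Exhaustive search over every feature; plain loops, unit weights.

    Returns (best_feature, best_cost, parent_impurity); degenerate splits
    cost the parent impurity, ties go to the lowest feature id.
    """
    parent = brute_gini([y[i] for i in idx])
    best_f, best_cost = None, np.inf
    for f in range(X.shape[1]):
        left = [y[i] for i in idx if X[i, f] <= 0.5]
        right = [y[i] for i in idx if X[i, f] > 0.5]
        if not left or not right:
            cost = parent
        else:
            n = len(idx)
            cost = (
                brute_gini(left) * len(left) / n
                + brute_gini(right) * len(right) / n
            )
        if cost < best_cost - 1e-15:
            best_f, best_cost = f, cost
    return best_f, best_cost, parent


def assert_tree_matches_oracle(tree: Tree, X, y, idx, node=0):
    f = tree.feature[node]
    best_f, best_cost, parent = brute_best_split(X, y, idx)
    if f < 0:
        # Terminal: no strictly improving split may exist (the learner has
        # no depth/min-samples limit in these runs).
        assert best_cost >= parent - 1e-9
        return
    assert best_cost < parent
    assert f == best_f
    left_idx = np.array([i for i in idx if X[i, f] <= 0.5])
    right_idx = np.array([i for i in idx if X[i, f] > 0.5])
    assert_tree_matches_oracle(tree, X, y, left_idx, tree.left[node])
    assert_tree_matches_oracle(tree, X, y, right_idx, tree.right[node])


# --- node-level statistics -----------------------------------------------

class TestNodeStatistics:
    @pytest.mark.parametrize(
        "p_a, pi, expected",
        [
            ([1, 1, 0, 0], None, 0.5),
            ([0.63, 0.37], None, 0.5),
            ([0.63], None, 0.63),
            ([1.0, 0.0], [3.0, 1.0], 0.75),
        ],
    )
    def test_weighted_class_probs(self, p_a, pi, expected):
        pa, pb = weighted_class_probs(p_a, pi)
        assert pa == pytest.approx(expected, abs=1e-12)
        assert pa + pb == pytest.approx(1.0, abs=1e-12)

    def test_zero_mass_node_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            weighted_class_probs([0.5, 0.5], [0.0, 0.0])

    @pytest.mark.parametrize(
        "pa, pb, expected",
        [(1.0, 0.0, 0.0), (0.5, 0.5, 0.5), (0.63, 0.37, 0.4662)],
    )
    def test_modified_gini_values(self, pa, pb, expected):
        assert modified_gini(pa, pb) == pytest.approx(expected, abs=1e-12)

    def test_modified_gini_bounds(self):
        assert modified_gini(1.0, 0.0) == 0.0
        assert modified_gini(0.0, 1.0) == 0.0
        grid = np.linspace(0, 1, 51)
        values = [modified_gini(p, 1 - p) for p in grid]
        assert min(values) >= 0.0 and max(values) <= 0.5 + 1e-12

    def test_split_cost_perfect_separation_is_zero(self):
        assert split_cost([1, 1], None, [0, 0], None) == pytest.approx(0.0)

    def test_split_cost_identical_mix_equals_parent(self):
        parent = modified_gini(0.5, 0.5)
        assert split_cost([1, 0], None, [1, 0], None) == pytest.approx(parent)

    def test_split_cost_isolating_one_active(self):
        # 4 hard labels [1,1,0,0]; isolate one active: 0.75 * G(2/3, 1/3).
        cost = split_cost([1.0], None, [1.0, 0.0, 0.0], None)
        assert cost == pytest.approx(0.75 * modified_gini(1 / 3, 2 / 3), abs=1e-12)
        assert cost == pytest.approx(1 / 3, abs=1e-12)

    def test_split_cost_zero_mass_side_returns_parent_impurity(self):
        parent = modified_gini(0.5, 0.5)
        cost = split_cost([1.0, 0.0], [1.0, 1.0], [0.5], [0.0])
        assert cost == pytest.approx(parent)


# --- fitting --------------------------------------------------------------

def _toy_labelled(n=60, seed=0, sigma=0.3):
    ds = generate(
        SyntheticSpec(
            n_active=n // 2, n_measured_inactive=n // 2, n_putative_inactive=0,
            n_features=16, n_informative=8, seed=seed,
        )
    )
    return ds, label_dataset(
        ds.to_activity_records(), ds.features, LabelConfig(5.0, sigma)
    )


class TestFit:
    def test_memorises_separable_hard_labels(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(40, 6))
        y = X[:, 2].astype(float)  # perfectly separable on feature 2
        model = ProbabilisticRandomForestClassifier(
            n_estimators=10, random_state=1, bootstrap=False, max_features=None
        ).fit(X, y)
        assert (model.predict(X) == y).all()

    def test_uninformative_half_labels_give_depth_zero_trees(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, size=(30, 5))
        y = np.full(30, 0.5)
        model = ProbabilisticRandomForestClassifier(
            n_estimators=5, random_state=0
        ).fit(X, y)
        for tree in model.trees_:
            assert tree.n_nodes == 1 and tree.feature[0] == -1
        assert np.allclose(model.predict_proba(X)[:, 1], 0.5)

    def test_single_tree_split_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, size=(6, 3))
        y = rng.random(6)
        model = ProbabilisticRandomForestClassifier(
            n_estimators=1, max_depth=1, bootstrap=False, max_features=None,
            random_state=0,
        ).fit(X, y)
        tree = model.trees_[0]
        best_f, best_cost, parent = brute_best_split(X, y, np.arange(6))
        if best_cost < parent:
            assert tree.feature[0] == best_f
        else:
            assert tree.feature[0] == -1

    def test_identical_rows_give_prior_forest(self, caplog):
        X = np.ones((10, 4), dtype=int)
        y = np.array([1.0] * 6 + [0.0] * 4)
        import logging

        with caplog.at_level(logging.WARNING):
            model = ProbabilisticRandomForestClassifier(
                n_estimators=3, bootstrap=False, random_state=0
            ).fit(X, y)
        assert all(t.n_nodes == 1 for t in model.trees_)
        assert np.allclose(model.predict_proba(X)[:, 1], 0.6)

    def test_soft_and_hard_modes_detected(self):
        _, lab = _toy_labelled()
        soft = fit(lab, n_estimators=2, random_state=0)
        hard = fit_hard_rf(lab, n_estimators=2, random_state=0)
        assert soft.mode_ == "soft"
        assert hard.mode_ == "hard"

    def test_invalid_inputs_rejected(self):
        X = np.array([[0, 1], [1, 0]])
        model = ProbabilisticRandomForestClassifier()
        with pytest.raises(ValueError, match="binary"):
            model.fit(np.array([[0.3, 1], [1, 0]]), [0, 1])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            model.fit(X, [0.5, 1.2])
        with pytest.raises(ValueError, match="keep_proba"):
            ProbabilisticRandomForestClassifier(keep_proba=1.0).fit(X, [0, 1])


class TestDegeneracyAndDeterminism:
    def test_binary_soft_labels_reproduce_hard_mode_forest(self):
        _, lab0 = _toy_labelled(sigma=0.0)
        soft = fit(lab0, n_estimators=8, random_state=4)
        hard = fit_hard_rf(lab0, n_estimators=8, random_state=4)
        for a, b in zip(soft.trees_, hard.trees_):
            assert (a.feature == b.feature).all()
            assert (a.left == b.left).all() and (a.right == b.right).all()
            assert np.allclose(a.prob_active, b.prob_active)

    def test_fixed_seed_is_bit_reproducible(self):
        ds, lab = _toy_labelled()
        m1 = fit(lab, n_estimators=5, random_state=9)
        m2 = fit(lab, n_estimators=5, random_state=9)
        X = ds.features.values
        assert (m1.predict_proba(X) == m2.predict_proba(X)).all()
        for a, b in zip(m1.trees_, m2.trees_):
            assert (a.feature == b.feature).all()
            assert (a.prob_active == b.prob_active).all()

    def test_sample_order_permutation_invariance_without_bootstrap(self):
        ds, lab = _toy_labelled()
        X, y = ds.features.values, lab.delta_y
        perm = np.random.default_rng(0).permutation(len(y))
        kwargs = dict(n_estimators=5, bootstrap=False, random_state=2)
        m1 = ProbabilisticRandomForestClassifier(**kwargs).fit(X, y)
        m2 = ProbabilisticRandomForestClassifier(**kwargs).fit(X[perm], y[perm])
        assert np.allclose(m1.predict_proba(X), m2.predict_proba(X))


class TestPrediction:
    def test_depth_zero_tree_predicts_its_leaf_everywhere(self):
        X = np.zeros((5, 3), dtype=int)
        y = np.full(5, 0.63)
        model = ProbabilisticRandomForestClassifier(
            n_estimators=4, random_state=0
        ).fit(X, y)
        proba = model.predict_proba(np.array([[1, 0, 1], [0, 0, 0]]))
        assert np.allclose(proba[:, 1], 0.63)

    def test_probabilities_sum_to_one(self, default_dataset, default_soft_labels):
        model = fit(default_soft_labels, n_estimators=10, random_state=0)
        proba = model.predict_proba(default_dataset.features.values)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        detail = model.predict_detail(default_dataset.features.values[:20])
        assert np.allclose(detail.prob_active + detail.prob_inactive, 1.0)
        assert detail.per_tree.shape == (20, 10)
        assert ((detail.vote_dispersion >= 0)).all()

    def test_feature_count_mismatch_rejected(self):
        X = np.array([[0, 1], [1, 0]])
        model = ProbabilisticRandomForestClassifier(n_estimators=1).fit(X, [0, 1])
        with pytest.raises(ValueError, match="features"):
            model.predict_proba(np.array([[0, 1, 1]]))

    def test_keep_proba_prunes_light_branch_exactly(self):
        # Hand-built one-split tree: leaves (P̄_A) 0.9 left, 0.1 right.
        tree = Tree(
            feature=np.array([0, -1, -1], dtype=np.int32),
            threshold=np.array([0.5, 0.5, 0.5]),
            left=np.array([1, -1, -1], dtype=np.int32),
            right=np.array([2, -1, -1], dtype=np.int32),
            prob_active=np.array([0.5, 0.9, 0.1]),
        )
        model = ProbabilisticRandomForestClassifier(n_estimators=1, keep_proba=0.05)
        model.trees_ = [tree]
        model.n_features_in_ = 1
        model.classes_ = np.array([0, 1])
        model.mode_ = "soft"
        # Feature sd chosen so the sample splits ~0.96 left / ~0.04 right:
        # x = 0, sd such that P(x + eps > 0.5) ~ 0.04  =>  sd = 0.5/1.75.
        from scipy.stats import norm

        sd = 0.5 / norm.ppf(0.96)
        p_right = 1 - norm.cdf(0.5 / sd)
        assert p_right == pytest.approx(0.04, abs=1e-9)
        out = model.predict_proba(np.array([[0]]), X_sd=np.array([sd]))
        # The 0.04 branch is pruned and the surviving mass renormalised: the
        # output is the left leaf exactly.
        assert out[0, 1] == pytest.approx(0.9, abs=1e-12)

        # With a keep_proba below the light branch's mass, both leaves count.
        model.keep_proba = 0.01
        out = model.predict_proba(np.array([[0]]), X_sd=np.array([sd]))
        assert out[0, 1] == pytest.approx(0.96 * 0.9 + 0.04 * 0.1, abs=1e-9)

    def test_pure_class_dataset_predicts_that_class_certainly(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 2, size=(20, 4))
        model = ProbabilisticRandomForestClassifier(
            n_estimators=5, random_state=0
        ).fit(X, np.ones(20))
        assert np.allclose(model.predict_proba(X)[:, 1], 1.0)


class TestExternalReferenceConcordance:
    def test_hard_mode_agrees_with_reference_rf_on_separable_data(self):
        from sklearn.ensemble import RandomForestClassifier

        ds = generate(
            SyntheticSpec(
                n_active=120, n_measured_inactive=180, n_putative_inactive=0,
                sigma_experimental=0.0, near_threshold_weight=0.0, seed=13,
            )
        )
        X = ds.features.values
        y = (ds.observed_p_activity >= 5.0).astype(int)
        ours = ProbabilisticRandomForestClassifier(
            n_estimators=60, random_state=1
        ).fit(X, y.astype(float))
        ref = RandomForestClassifier(
            n_estimators=60, max_features="sqrt", random_state=1
        ).fit(X, y)
        agree = (ours.predict(X) == ref.predict(X)).mean()
        assert agree >= 0.95


class TestSerialization:
    def test_round_trip_reproduces_predictions_bit_exactly(self, tmp_path,
                                                           default_dataset,
                                                           default_soft_labels):
        model = fit(default_soft_labels, n_estimators=5, random_state=0)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        X = default_dataset.features.values
        assert (model.predict_proba(X) == back.predict_proba(X)).all()
        assert back.label_config_ == model.label_config_
        assert back.get_params() == model.get_params()

    def test_unknown_format_version_rejected(self, tmp_path, default_soft_labels):
        model = fit(default_soft_labels, n_estimators=1, random_state=0)
        d = model.to_dict()
        d["format_version"] = 99
        with pytest.raises(ValueError, match="version"):
            ProbabilisticRandomForestClassifier.from_dict(d)


class TestModuleWrappers:
    def test_predict_proba_wrapper_accepts_feature_matrix(self, default_dataset,
                                                          default_soft_labels):
        model = fit(default_soft_labels, n_estimators=3, random_state=0)
        out = predict_proba(model, default_dataset.features)
        assert out.shape == (default_dataset.features.n_samples,)
        assert ((out >= 0) & (out <= 1)).all()
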