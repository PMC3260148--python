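"""Random-forest classifier: votes, OOB, MDA, CV, representative tree."""

import numpy as np
import pandas as pd
import pytest

from mitomorph.classify import (
    CLASS_ORDER,
    aggregate_condition,
    cross_validate,
    major_class,
    mda_importance,
    model_from_json,
    model_to_json,
    predict_scores,
    representative_tree,
    train_rf,
)
from mitomorph.features import FEATURE_COLUMNS


def _toy_dataset(n_per_class=30, n_features=2, sep=4.0, seed=0, noise_features=0):
    """Well-separated 3-class Gaussian blobs."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for i, cls in enumerate(CLASS_ORDER):
        mu = np.zeros(n_features)
        mu[i % n_features] = sep * (1 + i // n_features)
        X.append(rng.normal(mu, 1.0, size=(n_per_class, n_features)))
        y += [cls] * n_per_class
    X = np.vstack(X)
    if noise_features:
        X = np.hstack([X, rng.normal(0, 1, size=(len(X), noise_features))])
    cols = [f"f{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=cols), np.array(y), cols


def test_scores_sum_to_one_and_match_vote_enumeration():
    """Vote fractions from a 3-tree forest equal brute-force enumeration."""
    feats, labels, cols = _toy_dataset(10)
    model = train_rf(feats, labels, n_trees=3, seed=1, feature_names=cols)
    scores = predict_scores(model, feats)
    assert np.allclose(scores[list(CLASS_ORDER)].sum(axis=1), 1.0, atol=1e-12)
    X = feats[cols].to_numpy()
    expected = np.zeros((len(X), 3))
    for tree in model.trees:
        pred = tree.predict(X)
        for i, c in enumerate(pred):
            expected[i, list(CLASS_ORDER).index(c)] += 1
    assert np.allclose(scores[list(CLASS_ORDER)].to_numpy(), expected / 3)


def test_oob_error_well_separated_and_seed_stable():
    feats, labels, cols = _toy_dataset(60)
    m1 = train_rf(feats, labels, n_trees=100, seed=7, feature_names=cols)
    m2 = train_rf(feats, labels, n_trees=100, seed=7, feature_names=cols)
    assert m1.oob_error <= 0.08
    assert m1.oob_error == m2.oob_error


def test_oob_error_at_chance_for_permuted_labels(rng):
    feats, labels, cols = _toy_dataset(60)
    permuted = rng.permutation(labels)
    model = train_rf(feats, permuted, n_trees=200, seed=3, feature_names=cols)
    assert abs(model.oob_error - 2.0 / 3.0) < 0.07


def test_missing_feature_column_named():
    feats, labels, cols = _toy_dataset(10)
    model = train_rf(feats, labels, n_trees=5, seed=0, feature_names=cols)
    with pytest.raises(ValueError, match="f1"):
        predict_scores(model, feats.drop(columns=["f1"]))


def test_class_batch_stratified_bootstrap_preserves_counts():
    feats, labels, cols = _toy_dataset(20)
    batches = np.tile([0, 1], len(labels) // 2)
    model = train_rf(feats, labels, batches, n_trees=10, seed=2, feature_names=cols)
    key = pd.DataFrame({"label": labels, "batch": batches})
    expected = key.value_counts().sort_index()
    for boot in model.bootstrap_indices:
        got = key.iloc[boot].value_counts().sort_index()
        assert got.equals(expected)


def test_empty_stratum_falls_back_to_class_only():
    feats, labels, cols = _toy_dataset(10)
    batches = np.zeros(len(labels), dtype=int)
    batches[labels == "networked"] = 1  # batch 0 has no networked cells
    with pytest.warns(UserWarning, match="strata"):
        train_rf(feats, labels, batches, n_trees=5, seed=0, feature_names=cols)


class TestMajorClass:
    @pytest.mark.parametrize(
        "scores, expected",
        [
            ((0.7, 0.2, 0.1), "networked"),
            ((0.2, 0.5, 0.3), "fragmented"),
            ((0.1, 0.2, 0.7), "swollen"),
            ((0.4, 0.4, 0.2), "networked"),  # tie broken N > F > S
            ((0.0, 0.5, 0.5), "fragmented"),
        ],
    )
    def test_argmax_with_declared_tie_order(self, scores, expected):
        assert major_class(scores) == expected


class TestMDA:
    def test_pure_noise_feature_near_zero(self):
        feats, labels, cols = _toy_dataset(40, noise_features=1, seed=2)
        model = train_rf(feats, labels, n_trees=100, seed=2, feature_names=cols)
        report = mda_importance(model, feats, labels, seed=0)
        noise_mda = report.loc[report.feature == cols[-1], "mda"].iloc[0]
        assert abs(noise_mda) < 0.5

    def test_informative_feature_ranks_first(self):
        rng = np.random.default_rng(8)
        n = 120
        labels = np.repeat(list(CLASS_ORDER), n // 3)
        signal = np.array([list(CLASS_ORDER).index(c) * 3.0 for c in labels]) + rng.normal(0, 0.3, n)
        feats = pd.DataFrame(
            {"signal": signal, **{f"noise{i}": rng.normal(0, 1, n) for i in range(5)}}
        )
        model = train_rf(feats, labels, n_trees=100, seed=8, feature_names=list(feats.columns))
        report = mda_importance(model, feats, labels, seed=8)
        assert report.iloc[0]["feature"] == "signal"

    def test_invalid_repeats_rejected(self, small_model, small_training_features):
        with pytest.raises(ValueError):
            mda_importance(
                small_model, small_training_features,
                small_training_features["label"].to_numpy(), n_repeats=0,
            )


class TestCrossValidate:
    def test_chance_level_for_permuted_labels(self, rng):
        feats, labels, cols = _toy_dataset(40)
        permuted = rng.permutation(labels)
        cv = cross_validate(feats, permuted, folds=5, repeats=2, n_trees=50, seed=0, feature_names=cols)
        assert abs(cv["overall_accuracy"] - 1.0 / 3.0) < 0.07

    def test_small_class_rejected(self):
        feats, labels, cols = _toy_dataset(5)
        with pytest.raises(ValueError, match="class"):
            cross_validate(feats, labels, folds=10, feature_names=cols)

    def test_oob_and_cv_agree(self, small_training_features):
        feats = small_training_features
        labels = feats["label"].to_numpy()
        model = train_rf(feats, labels, n_trees=100, seed=5, feature_names=list(FEATURE_COLUMNS))
        cv = cross_validate(feats, labels, folds=6, repeats=2, n_trees=100, seed=5,
                            feature_names=list(FEATURE_COLUMNS))
        assert abs((1 - model.oob_error) - cv["overall_accuracy"]) <= 0.05


class TestRepresentativeTree:
    def test_high_mda_feature_wins_equal_gain_tie(self):
        # two identical columns -> equal Gini gain; weighting must pick f_hi
        x = np.array([0.0, 0.0, 1.0, 1.0] * 6)
        labels = np.array((["networked"] * 2 + ["fragmented"] * 2) * 6)
        feats = pd.DataFrame({"f_lo": x, "f_hi": x.copy()})
        importance = pd.DataFrame({"feature": ["f_lo", "f_hi"], "mda": [0.0, 5.0]})
        tree = representative_tree(feats, labels, importance, max_depth=2)
        assert tree.feature == 1  # f_hi

    def test_first_split_isolates_most_distinct_class(
        self, small_training_features, small_model
    ):
        """On calibrated synthetic cells the root split peels off one pure
        morphology class, and depth 2 suffices to separate all three."""
        feats = small_training_features
        labels = feats["label"].to_numpy()
        imp = mda_importance(small_model, feats, labels, seed=0)
        tree = representative_tree(feats, labels, imp, feature_names=list(FEATURE_COLUMNS))
        assert not tree.is_leaf()
        left = tree.left.class_fractions
        right = tree.right.class_fractions
        # one side of the root is (nearly) pure in a single class
        assert max(max(left.values()), max(right.values())) >= 0.9

        def leaves(node):
            if node.is_leaf():
                return [node]
            return leaves(node.left) + leaves(node.right)

        purities = [max(leaf.class_fractions.values()) for leaf in leaves(tree)]
        assert min(purities) >= 0.9

    def test_all_nonpositive_mda_falls_back_unweighted(self):
        feats, labels, cols = _toy_dataset(10)
        importance = pd.DataFrame({"feature": cols, "mda": [0.0] * len(cols)})
        with pytest.warns(UserWarning, match="MDA"):
            tree = representative_tree(feats, labels, importance)
        assert not tree.is_leaf()


class TestAggregation:
    def test_single_cell_summary(self):
        scores = pd.DataFrame(
            {"networked": [0.5], "fragmented": [0.3], "swollen": [0.2], "condition": ["FM"]}
        )
        out = aggregate_condition(scores)
        assert out.iloc[0]["networked_mean_pct"] == pytest.approx(50.0)
        assert out.iloc[0]["fragmented_mean_pct"] == pytest.approx(30.0)
        assert out.iloc[0]["swollen_mean_pct"] == pytest.approx(20.0)

    def test_two_cell_intercellular_sd(self):
        scores = pd.DataFrame(
            {
                "networked": [1.0, 0.0],
                "fragmented": [0.0, 1.0],
                "swollen": [0.0, 0.0],
                "condition": ["c", "c"],
            }
        )
        out = aggregate_condition(scores)
        assert out.iloc[0]["networked_mean_pct"] == pytest.approx(50.0)
        # population StDev of {0, 1} = 0.5 -> 50 percentage points
        assert out.iloc[0]["networked_intercell_sd_pct"] == pytest.approx(50.0)
        assert out.iloc[0]["swollen_intercell_sd_pct"] == pytest.approx(0.0)

    def test_mean_percentages_sum_to_100(self, small_model, small_training_features):
        scores = predict_scores(small_model, small_training_features)
        scores["condition"] = small_training_features["label"].to_numpy()
        out = aggregate_condition(scores)
        sums = out[[f"{c}_mean_pct" for c in CLASS_ORDER]].sum(axis=1)
        assert np.allclose(sums, 100.0, atol=1e-9)


def test_json_roundtrip_preserves_votes(small_model, small_training_features, tmp_path):
    path = tmp_path / "model.json"
    model_to_json(small_model, path)
    loaded = model_from_json(path)
    a = predict_scores(small_model, small_training_features)
    b = predict_scores(loaded, small_training_features)
    assert np.allclose(
        a[list(CLASS_ORDER)].to_numpy(), b[list(CLASS_ORDER)].to_numpy()
    )
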