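"""Classification protocol: splits, CV, tuning, metric formulas, importances."""

import numpy as np
import pandas as pd
import pytest

from pfmus import classify as cl


LABELS4 = list(cl.LABEL_ORDER)


def make_table(n_per_class=20, n_features=5, seed=0, class_shift=None,
               classes=LABELS4, participants=None):
    """Synthetic labelled feature frame; ``class_shift`` maps class -> mean
    offset of feature f0 (making f0 the informative feature)."""
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for c, cls in enumerate(classes):
        for _ in range(n_per_class):
            feats = rng.normal(0, 1, n_features)
            if class_shift is not None:
                feats[0] += class_shift[cls]
            rows.append({
                "clip_id": f"clip{idx}",
                "recording_id": f"rec{idx // 4}",
                "participant_id": (participants[idx] if participants
                                   else f"part{idx // 8}"),
                "label": cls,
                **{f"f{j}": feats[j] for j in range(n_features)},
            })
            idx += 1
    return pd.DataFrame(rows)


class TestSplitTrainTest:
    def test_rounding_rule(self):
        df = make_table(n_per_class=5, classes=["correct", "none"])  # n=10
        train, test = cl.split_train_test(df, cl.SplitSpec(test_fraction=0.3))
        assert len(test) == 3 and len(train) == 7

    def test_stratified_balanced_classes(self):
        df = make_table(n_per_class=10)  # 40 clips over 4 classes
        train, test = cl.split_train_test(df, cl.SplitSpec(test_fraction=0.3))
        assert test["label"].value_counts().eq(3).all()

    def test_grouped_split_keeps_participants_on_one_side(self):
        # one participant holds 40% of the clips
        participants = ["big"] * 16 + [f"p{i}" for i in range(24)]
        df = make_table(n_per_class=10, participants=participants)
        spec = cl.SplitSpec(test_fraction=0.3, group_by_participant=True)
        train, test = cl.split_train_test(df, spec)
        overlap = set(train["participant_id"]) & set(test["participant_id"])
        assert overlap == set()
        assert len(train) + len(test) == len(df)

    def test_identical_spec_gives_identical_partition(self):
        df = make_table(n_per_class=10)
        a = cl.split_train_test(df, cl.SplitSpec(seed=5))
        b = cl.split_train_test(df, cl.SplitSpec(seed=5))
        assert list(a[0]["clip_id"]) == list(b[0]["clip_id"])
        assert list(a[1]["clip_id"]) == list(b[1]["clip_id"])

    def test_class_missing_from_train_raises_with_hint(self):
        df = make_table(n_per_class=1)  # 4 clips, one per class
        with pytest.raises(ValueError, match="more data|smaller test_fraction"):
            cl.split_train_test(df, cl.SplitSpec(test_fraction=0.5))


class TestMetricsFromConfusion:
    def test_identity_matrix_perfect_scores(self):
        m = cl.metrics_from_confusion(np.diag([10, 10, 10, 10]))
        assert m["accuracy"] == 1.0
        assert m["macro_precision"] == 1.0
        assert m["macro_recall"] == 1.0
        assert m["macro_f1"] == 1.0
        assert m["undefined_flags"] == []

    def test_all_one_class_predictor_on_balanced_truth(self):
        c = np.zeros((4, 4), dtype=int)
        c[:, 0] = 10  # everything predicted as class 0
        m = cl.metrics_from_confusion(c)
        assert m["accuracy"] == 0.25
        assert m["macro_recall"] == 0.25
        # classes 1-3 have no predictions: precision 0/0 -> 0, flagged
        assert m["per_class"][1]["precision"] == 0.0
        assert any("precision" in f for f in m["undefined_flags"])

    def test_padded_binary_matrix_footnote_formulas(self):
        c = np.zeros((4, 4), dtype=int)
        c[:2, :2] = [[8, 2], [3, 7]]
        m = cl.metrics_from_confusion(c)
        assert m["accuracy"] == pytest.approx(15 / 20)
        assert m["per_class"][0]["precision"] == pytest.approx(8 / 11)
        assert m["per_class"][0]["recall"] == pytest.approx(8 / 10)

    def test_per_class_counts_sum_to_total(self):
        rng = np.random.default_rng(1)
        c = rng.integers(0, 20, (4, 4))
        m = cl.metrics_from_confusion(c)
        for stats in m["per_class"].values():
            assert stats["tp"] + stats["fp"] + stats["fn"] + stats["tn"] == c.sum()

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            cl.metrics_from_confusion(np.zeros((3, 4)))
        with pytest.raises(ValueError):
            cl.metrics_from_confusion(np.array([[1, -1], [0, 1]]))
        with pytest.raises(ValueError):
            cl.metrics_from_confusion(np.zeros((4, 4)))


def pair_counting_auc(scores_pos, scores_neg):
    """Mann-Whitney oracle: fraction of (pos, neg) pairs correctly ordered."""
    wins = ties = 0
    for p in scores_pos:
        for q in scores_neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(scores_pos) * len(scores_neg))


class TestEvaluateModel:
    class _FixedScoreModel:
        """Binary scorer with predetermined probabilities."""

        def __init__(self, scores, labels, classes):
            self._scores = np.asarray(scores, dtype=float)
            self._labels = labels
            self.classes_ = np.array(classes)

        def predict(self, X):
            return np.where(self._scores >= 0.5, self.classes_[1], self.classes_[0])

        def predict_proba(self, X):
            return np.column_stack([1 - self._scores, self._scores])

    def test_auc_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(6, 21))
            y = np.array(["correct"] * (n // 2) + ["none"] * (n - n // 2))
            scores = np.round(rng.uniform(0, 1, n), 1)  # coarse -> ties occur
            df = pd.DataFrame({
                "clip_id": [f"c{i}" for i in range(n)],
                "recording_id": "r", "participant_id": "p",
                "label": y, "f0": 0.0,
            })
            model = self._FixedScoreModel(scores, y, ["correct", "none"])
            out = cl.evaluate_model(model, df)
            oracle = pair_counting_auc(scores[y == "none"], scores[y == "correct"])
            assert out["per_class_auc"]["none"] == pytest.approx(oracle)

    def test_one_inversion_six_item_score_set(self):
        y = np.array(["none", "none", "none", "correct", "correct", "correct"])
        scores = np.array([0.9, 0.8, 0.4, 0.5, 0.3, 0.2])  # one swapped pair
        df = pd.DataFrame({
            "clip_id": list("abcdef"), "recording_id": "r",
            "participant_id": "p", "label": y, "f0": 0.0,
        })
        model = self._FixedScoreModel(scores, y, ["correct", "none"])
        out = cl.evaluate_model(model, df)
        assert out["per_class_auc"]["none"] == pytest.approx(
            pair_counting_auc(scores[y == "none"], scores[y == "correct"]))

    def test_perfect_classifier_scores_one(self):
        df = make_table(n_per_class=30)
        # one indicator feature per class -> linearly separable simplex
        for j, cls in enumerate(LABELS4):
            df.loc[df["label"] == cls, f"f{j}"] += 20
        train, test = cl.split_train_test(df, cl.SplitSpec(seed=0))
        model = cl.build_estimator("multinomial_logistic", {}, seed=0)
        X = train[[c for c in train.columns if c.startswith("f")]]
        model.fit(X, train["label"])
        out = cl.evaluate_model(model, test)
        assert out["metrics"]["accuracy"] == 1.0
        assert out["macro_auc"] == pytest.approx(1.0)

    def test_label_independent_scores_give_chance_auc(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 60
            y = np.array((["correct"] * (n // 2)) + (["none"] * (n // 2)))
            scores = rng.uniform(0, 1, n)
            df = pd.DataFrame({
                "clip_id": [f"c{i}" for i in range(n)],
                "recording_id": "r", "participant_id": "p",
                "label": y, "f0": 0.0,
            })
            model = self._FixedScoreModel(scores, y, ["correct", "none"])
            aucs.append(cl.evaluate_model(model, df)["macro_auc"])
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)

    def test_model_without_probabilities_reports_auc_missing(self):
        class Hard:
            classes_ = np.array(["correct", "none"])

            def predict(self, X):
                return np.array(["correct"] * len(X))

        df = make_table(n_per_class=3, classes=["correct", "none"])
        out = cl.evaluate_model(Hard(), df)
        assert out["macro_auc"] is None
        assert out["metrics"]["accuracy"] == 0.5


class TestCrossValidateAndTune:
    def test_separable_fixture_high_cv_accuracy(self):
        df = make_table(n_per_class=15, class_shift={
            "undeterminable": 0, "correct": 15, "failure": 30, "none": 45})
        table = cl.cross_validate_models(
            df, [cl.ModelSpec("random_forest_ensemble",
                              base_params={"n_estimators": 50})], k=5)
        rf = table[table["model"] == "random_forest_ensemble"]
        assert rf["accuracy"].iloc[0] >= 0.95

    def test_logistic_reference_always_reported(self):
        df = make_table(n_per_class=10)
        table = cl.cross_validate_models(
            df, [cl.ModelSpec("random_forest_ensemble",
                              base_params={"n_estimators": 20})], k=2)
        assert "multinomial_logistic" in set(table["model"])

    def test_duplicate_spec_gives_identical_rows(self):
        df = make_table(n_per_class=10)
        spec = cl.ModelSpec("random_forest_ensemble",
                            base_params={"n_estimators": 20})
        table = cl.cross_validate_models(df, [spec, spec], k=2)
        rows = table[table["model"] == "random_forest_ensemble"]
        assert len(rows) == 2
        assert np.allclose(rows["accuracy"].iloc[0], rows["accuracy"].iloc[1])

    def test_class_smaller_than_k_rejected(self):
        df = make_table(n_per_class=3)
        with pytest.raises(ValueError, match="smaller k"):
            cl.cross_validate_models(df, [cl.ModelSpec("multinomial_logistic")], k=5)

    def test_singleton_grid_returns_that_combination(self):
        df = make_table(n_per_class=10, classes=["correct", "none"])
        spec = cl.ModelSpec("random_forest_ensemble",
                            base_params={"n_estimators": 20},
                            grid={"max_depth": [3]})
        model, params, _ = cl.grid_search_tune(df, spec, k=2)
        assert params["max_depth"] == 3

    def test_interaction_fixture_selects_deep_trees(self):
        """XOR-style labels need feature interactions: stumps cannot fit."""
        rng = np.random.default_rng(0)
        n = 200
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        y = np.where(a ^ b, "correct", "none")
        df = pd.DataFrame({
            "clip_id": [f"c{i}" for i in range(n)],
            "recording_id": "r", "participant_id": "p", "label": y,
            "f0": a + rng.normal(0, 0.05, n),
            "f1": b + rng.normal(0, 0.05, n),
        })
        spec = cl.ModelSpec("random_forest_ensemble",
                            base_params={"n_estimators": 50},
                            grid={"max_depth": [1, 6]})
        _, params, _ = cl.grid_search_tune(df, spec, k=5)
        assert params["max_depth"] == 6

    def test_tie_broken_to_first_listed_combination(self):
        df = make_table(n_per_class=10, classes=["correct", "none"],
                        class_shift={"correct": 50, "none": 0})
        # both depths solve this trivially -> identical CV accuracy -> tie
        spec = cl.ModelSpec("random_forest_ensemble",
                            base_params={"n_estimators": 20},
                            grid={"max_depth": [4, 8]})
        _, params, acc = cl.grid_search_tune(df, spec, k=2)
        assert acc == 1.0
        assert params["max_depth"] == 4

    def test_empty_grid_rejected(self):
        df = make_table(n_per_class=5)
        with pytest.raises(ValueError, match="grid"):
            cl.grid_search_tune(df, cl.ModelSpec("random_forest_ensemble"), k=2)


class TestFeatureImportances:
    def test_single_informative_feature_ranked_first(self):
        rng = np.random.default_rng(4)
        n = 200
        y = np.array(["correct"] * (n // 2) + ["none"] * (n // 2))
        df = pd.DataFrame({
            "base_elevation": np.where(y == "correct", 10, 1)
            + rng.normal(0, 0.5, n),
            **{f"noise{j}": rng.normal(0, 1, n) for j in range(5)},
        })
        model = cl.build_estimator(
            "gradient_boosting_ensemble",
            {"n_estimators": 50, "min_child_samples": 10}, seed=0)
        model.fit(df, y)
        top = cl.top_feature_importances(model, 3)
        assert top[0][0] == "base_elevation"

    def test_n_larger_than_feature_count_returns_full_list(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({f"f{j}": rng.normal(0, 1, 60) for j in range(4)})
        y = np.array(["correct", "none"] * 30)
        model = cl.build_estimator("random_forest_ensemble",
                                   {"n_estimators": 10}, seed=0)
        model.fit(df, y)
        assert len(cl.top_feature_importances(model, 100)) == 4

    def test_scores_sorted_descending_ties_alphabetical(self):
        class Stub:
            feature_importances_ = np.array([1.0, 3.0, 1.0, 3.0])
            feature_name_ = ["d", "c", "a", "b"]

        top = cl.top_feature_importances(Stub(), 4)
        assert [t[0] for t in top] == ["b", "c", "a", "d"]

    def test_model_without_importances_rejected(self):
        with pytest.raises(ValueError, match="importances"):
            cl.top_feature_importances(object(), 10)
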