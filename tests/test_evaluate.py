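import numpy as np
import pandas as pd
import pytest

from leadii.evaluate import (
    EvalReport,
    ModelSpec,
    SplitSpec,
    balanced_holdout,
    evaluate,
    report_from_predictions,
    resolve_subset,
    run_experiment,
    train_classifier,
)
from leadii.simulate import generate_feature_table


@pytest.fixture(scope="module")
def planted_table():
    shifts = [3.0, 0.0, -3.0, 1.5]
    effect = {f"sig{i}": dict(zip("ABCD", np.roll(shifts, i)))
              for i in range(4)}
    return generate_feature_table(120, effect, seed=2, n_features=10)


class TestBalancedHoldout:
    def test_exact_counts_and_disjoint(self):
        labels = np.array(["A"] * 1000 + ["B"] * 1000 + ["C"] * 1000
                          + ["D"] * 1000)
        train, test = balanced_holdout(labels, 500, seed=0)
        assert test.size == 2000
        for cls in "ABCD":
            assert (labels[test] == cls).sum() == 500
        assert np.intersect1d(train, test).size == 0
        assert train.size + test.size == labels.size

    def test_class_too_small_named(self):
        labels = np.array(["A"] * 30 + ["B"] * 10)
        with pytest.raises(ValueError, match="'B'"):
            balanced_holdout(labels, 10, seed=0)

    def test_seed_reproducible(self):
        labels = np.array(["A", "B"] * 50)
        t1 = balanced_holdout(labels, 10, seed=5)
        t2 = balanced_holdout(labels, 10, seed=5)
        np.testing.assert_array_equal(t1[0], t2[0])
        np.testing.assert_array_equal(t1[1], t2[1])

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SplitSpec(mode="bogus")
        with pytest.raises(ValueError):
            SplitSpec(mode="fraction_split", test_fraction=1.5)


class TestReports:
    def test_perfect_predictions(self):
        y = np.array(["A", "B", "A", "B"] * 10)
        scores = np.column_stack([(y == "A") * 1.0, (y == "B") * 1.0])
        rep = report_from_predictions(y, y, ("A", "B"), scores)
        assert rep.accuracy == 1.0
        assert rep.macro_f1 == 1.0
        assert all(v == 1.0 for v in rep.auc_per_class.values())

    def test_hand_confusion_macro_f1(self):
        """Confusion [[40,10],[10,40]] gives accuracy 0.8 and macro F1 0.8."""
        y_true = np.array(["A"] * 50 + ["B"] * 50)
        y_pred = np.array(["A"] * 40 + ["B"] * 10 + ["A"] * 10 + ["B"] * 40)
        rep = report_from_predictions(y_true, y_pred, ("A", "B"))
        np.testing.assert_array_equal(rep.confusion, [[40, 10], [10, 40]])
        assert rep.accuracy == pytest.approx(0.8)
        assert rep.macro_f1 == pytest.approx(0.8)
        assert rep.macro_precision == pytest.approx(0.8)
        assert rep.macro_recall == pytest.approx(0.8)

    def test_accuracy_equals_trace_over_sum(self, planted_table):
        spec = ModelSpec("knn")
        labels = planted_table["label"].to_numpy()
        train, test = balanced_holdout(labels, 20, seed=1)
        model = train_classifier(planted_table, train, spec, seed=1)
        rep = evaluate(model, planted_table, test)
        assert rep.accuracy == pytest.approx(
            np.trace(rep.confusion) / rep.confusion.sum())
        assert rep.confusion.sum() == test.size

    def test_random_scores_auc_half(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.array(["A", "B"] * 500)
            scores = rng.random((1000, 2))
            pred = np.where(scores[:, 0] > scores[:, 1], "A", "B")
            rep = report_from_predictions(y, pred, ("A", "B"), scores)
            aucs.append(rep.auc_per_class["A"])
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_zero_predicted_positives_warns(self):
        y_true = np.array(["A", "A", "B", "B"])
        y_pred = np.array(["A", "A", "A", "A"])
        with pytest.warns(UserWarning, match="precision"):
            rep = report_from_predictions(y_true, y_pred, ("A", "B"))
        assert rep.macro_precision == pytest.approx(0.25)


class TestTraining:
    def test_separable_toy_perfect_train_accuracy(self):
        tab = pd.DataFrame({
            "f": np.r_[np.zeros(20), np.ones(20) * 10],
            "label": ["A"] * 20 + ["B"] * 20,
        })
        model = train_classifier(tab, np.arange(40), ModelSpec("bagged_trees"))
        assert (model.predict(tab[["f"]]) == tab["label"]).all()

    def test_single_class_training_rejected(self):
        tab = pd.DataFrame({"f": np.arange(10.0), "label": ["A"] * 10})
        with pytest.raises(ValueError, match="single class"):
            train_classifier(tab, np.arange(10), ModelSpec("knn"))

    def test_refit_same_seed_identical_predictions(self, planted_table):
        labels = planted_table["label"].to_numpy()
        train, test = balanced_holdout(labels, 20, seed=3)
        spec = ModelSpec("bagged_trees")
        m1 = train_classifier(planted_table, train, spec, seed=3)
        m2 = train_classifier(planted_table, train, spec, seed=3)
        X = planted_table.drop(columns=["label"]).iloc[test]
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("deep_transformer")

    def test_no_leakage_of_test_statistics(self, planted_table):
        """Imputer/scaler statistics come from training rows only: poisoning a
        test row with an extreme outlier leaves them unchanged."""
        labels = planted_table["label"].to_numpy()
        train, test = balanced_holdout(labels, 20, seed=0)
        spec = ModelSpec("knn")
        clean = train_classifier(planted_table, train, spec, seed=0)
        poisoned = planted_table.copy()
        poisoned.iloc[test[0], 0] = 1e9
        dirty = train_classifier(poisoned, train, spec, seed=0)
        np.testing.assert_array_equal(clean["impute"].statistics_,
                                      dirty["impute"].statistics_)
        # memory-layout differences after the copy permit ulp-level noise;
        # a leaked 1e9 outlier would shift the mean by ~2e6
        np.testing.assert_allclose(clean["scale"].mean_, dirty["scale"].mean_,
                                   rtol=1e-9)


class TestRunExperiment:
    def test_strong_signal_high_accuracy(self, planted_table):
        split = SplitSpec(n_test_per_class=30, seed=0, repetitions=5)
        res = run_experiment(planted_table, list(planted_table.columns[:-1]),
                             split, [ModelSpec("bagged_trees")])
        assert res["bagged_trees"].mean_accuracy > 0.9
        assert len(res["bagged_trees"].reports) == 5

    def test_shuffled_labels_chance_level(self, planted_table):
        """Balanced protocol pins chance accuracy at 1/k even when the
        original class sizes are imbalanced."""
        rng = np.random.default_rng(0)
        # build an imbalanced table, then shuffle its labels
        tab = pd.concat([
            planted_table[planted_table["label"] == "A"].iloc[:30],
            planted_table[planted_table["label"] == "B"],
            planted_table[planted_table["label"] == "C"].iloc[:60],
            planted_table[planted_table["label"] == "D"],
        ]).reset_index(drop=True)
        tab["label"] = rng.permutation(tab["label"].to_numpy())
        split = SplitSpec(n_test_per_class=20, seed=0, repetitions=10)
        res = run_experiment(tab, list(tab.columns[:-1]), split,
                             [ModelSpec("knn")])
        assert abs(res["knn"].mean_accuracy - 0.25) < 0.08

    def test_subset_restricts_columns(self, small_table):
        split = SplitSpec(n_test_per_class=1, seed=0, repetitions=2)
        res = run_experiment(small_table, "ours29", split, [ModelSpec("knn")])
        rep = res["knn"].reports[0]
        assert rep.confusion.sum() == 4
        # the fitted imputer saw exactly 29 columns
        labels = small_table["label"].to_numpy()
        train, _ = balanced_holdout(labels, 1, seed=0)
        model = train_classifier(small_table[list(
            resolve_subset("ours29", small_table.columns)) + ["label"]],
            train, ModelSpec("knn"))
        assert model["impute"].statistics_.size == 29

    def test_unknown_subset_rejected(self, small_table):
        split = SplitSpec(n_test_per_class=1, repetitions=1)
        with pytest.raises(KeyError, match="unknown feature subset"):
            run_experiment(small_table, "nope", split, [ModelSpec("knn")])

    def test_fraction_split_mode(self, planted_table):
        split = SplitSpec(mode="fraction_split", n_test_per_class=None,
                          test_fraction=0.2, seed=0, repetitions=2)
        res = run_experiment(planted_table, list(planted_table.columns[:-1]),
                             split, [ModelSpec("knn")])
        assert res["knn"].reports[0].confusion.sum() == 96
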