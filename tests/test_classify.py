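"""Stacking ensemble contracts and the cross-validation engine."""

import numpy as np
import pandas as pd
import pytest

from eegmdd import (
    FeatureTable,
    StackedEEGClassifier,
    baseline_learners,
    cross_validate,
)


def _separable_table(n_per=30, n_feat=8, gap=6.0, seed=0, epochs_per=1):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2 * n_per * epochs_per, n_feat))
    y_subj = [1] * n_per + [0] * n_per
    labels, subjects = [], []
    for s, lab in enumerate(y_subj):
        for _ in range(epochs_per):
            labels.append("MDD" if lab else "HC")
            subjects.append(f"s{s}")
    X[np.array(labels) == "MDD", 0] += gap
    values = pd.DataFrame(X, columns=[f"R__f{i}" for i in range(n_feat)])
    return FeatureTable(values, labels, subjects)


class TestBaselineLearners:
    def test_eight_models_with_study_parameters(self):
        models = baseline_learners(seed=0)
        assert sorted(models) == ["dt", "gb", "knn", "lgbm", "nn", "rf",
                                  "svm", "xgboost"]
        assert models["dt"].max_depth == 20
        assert models["dt"].min_samples_split == 10
        assert models["knn"].n_neighbors == 5
        assert models["knn"].weights == "distance"
        assert models["rf"].max_depth == 10
        assert models["rf"].n_estimators == 200
        assert models["svm"].C == 1 and models["svm"].kernel == "rbf"
        assert models["lgbm"].learning_rate == 0.1
        assert models["lgbm"].n_estimators == 500
        assert models["xgboost"].learning_rate == 0.05
        assert models["xgboost"].n_estimators == 1000
        assert models["gb"].learning_rate == 0.1
        assert models["gb"].n_estimators == 200
        assert models["nn"].hidden_layer_sizes == (50, 50)
        assert models["nn"].max_iter == 1000


class TestStackingFit:
    def test_meta_feature_width_is_bases_plus_passthrough(self):
        table = _separable_table(n_per=30, n_feat=56)
        model = StackedEEGClassifier(random_state=0)
        model.fit(table.X(), table.y())
        assert model.meta_feature_width_ == 3 + 56  # = 59

    def test_passthrough_off_width_is_base_count(self):
        table = _separable_table(n_per=30, n_feat=10)
        model = StackedEEGClassifier(passthrough=False, random_state=0)
        model.fit(table.X(), table.y())
        assert model.meta_feature_width_ == 3

    def test_separable_training_accuracy_perfect(self):
        table = _separable_table(n_per=30)
        model = StackedEEGClassifier(random_state=0)
        model.fit(table.X(), table.y())
        assert (model.predict(table.X()) == table.y()).mean() == 1.0

    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="single class"):
            StackedEEGClassifier().fit(rng.standard_normal((20, 3)),
                                       np.ones(20))

    def test_prediction_deterministic_per_row(self):
        table = _separable_table(n_per=20)
        model = StackedEEGClassifier(random_state=0).fit(table.X(), table.y())
        X = table.X()
        dup = np.vstack([X[:1], X])
        scores = model.predict_proba(dup)[:, 1]
        assert scores[0] == scores[1]

    def test_same_seed_identical_predictions(self):
        table = _separable_table(n_per=25, gap=1.0)
        X, y = table.X(), table.y()
        p1 = StackedEEGClassifier(random_state=3).fit(X, y).predict_proba(X)
        p2 = StackedEEGClassifier(random_state=3).fit(X, y).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_column_mismatch_named(self):
        table = _separable_table(n_per=20, n_feat=5)
        model = StackedEEGClassifier(random_state=0).fit(table.X(), table.y())
        with pytest.raises(ValueError, match="5"):
            model.predict(table.X()[:, :4])

    def test_perfect_base_with_deep_meta_reaches_training_accuracy_one(self):
        # one base sees a perfectly separating feature; meta depth >= bases
        from sklearn.tree import DecisionTreeClassifier

        table = _separable_table(n_per=20, n_feat=4, gap=10.0)
        model = StackedEEGClassifier(
            passthrough=False,
            meta_estimator=DecisionTreeClassifier(max_depth=3,
                                                  random_state=0),
            random_state=0,
        )
        model.fit(table.X(), table.y())
        assert (model.predict(table.X()) == table.y()).mean() == 1.0

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        m = StackedEEGClassifier(passthrough=False, oof_folds=4,
                                 random_state=9)
        c = clone(m)
        assert c.get_params()["oof_folds"] == 4
        assert c.get_params()["passthrough"] is False


class TestCrossValidate:
    def test_subject_grouping_keeps_subjects_together(self):
        table = _separable_table(n_per=15, epochs_per=4, gap=1.0)
        from sklearn.model_selection import StratifiedGroupKFold

        X, y, groups = table.X(), table.y(), table.groups()
        splitter = StratifiedGroupKFold(n_splits=5, shuffle=True,
                                        random_state=0)
        for tr, te in splitter.split(X, y, groups):
            assert set(groups[tr]) & set(groups[te]) == set()

    def test_epoch_grouping_balanced_folds(self):
        table = _separable_table(n_per=32, epochs_per=4)
        report = cross_validate(table, learners={}, k=5, grouping="epoch",
                                seed=0)
        sizes = [sum(f["tp"] + f["fp"] + f["tn"] + f["fn"]
                     for f in [m]) for m in
                 [report.models["stacking"]["confusion"]]]
        assert sizes[0] == table.n_rows  # every row scored exactly once

    def test_report_carries_all_requested_models(self):
        table = _separable_table(n_per=15, epochs_per=2)
        from sklearn.tree import DecisionTreeClassifier

        report = cross_validate(
            table,
            learners={"dt": DecisionTreeClassifier(random_state=0)},
            k=3, grouping="subject", seed=0)
        assert set(report.models) == {"dt", "stacking"}
        for m in report.models.values():
            assert 0 <= m["accuracy"] <= 1
            assert 0 <= m["auc"] <= 1
            assert len(m["fold_aucs"]) == 3

    def test_k_below_two_rejected(self):
        table = _separable_table(n_per=10)
        with pytest.raises(ValueError, match="k must be"):
            cross_validate(table, k=1)

    def test_determinism_same_seed(self):
        table = _separable_table(n_per=15, gap=1.0, epochs_per=2)
        r1 = cross_validate(table, learners={}, k=3, seed=4)
        r2 = cross_validate(table, learners={}, k=3, seed=4)
        assert r1.models["stacking"] == r2.models["stacking"]

    def test_permuted_labels_give_chance_accuracy(self):
        """Label permutation destroys the signal: CV accuracy ≈ 0.5."""
        rng = np.random.default_rng(8)
        accs = []
        for rep in range(10):
            table = _separable_table(n_per=15, gap=4.0, epochs_per=2,
                                     seed=rep)
            perm = rng.permutation(table.n_rows)
            shuffled = FeatureTable(
                table.values,
                table.labels.to_numpy()[perm].tolist(),
                table.subject_ids.to_numpy()[perm].tolist(),
            )
            report = cross_validate(shuffled, learners={}, k=5,
                                    grouping="epoch", seed=rep)
            accs.append(report.models["stacking"]["accuracy"])
        assert 0.35 <= np.mean(accs) <= 0.65
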