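"""Baseline classifiers and the passthrough stacking ensemble.

Eight standard learners (decision tree, KNN, random forest, RBF SVM,
LightGBM, XGBoost, gradient boosting, MLP) with the study's fixed
hyperparameters, plus ``StackedEEGClassifier``: KNN, a shallow decision
tree and a small XGBoost as base learners whose out-of-fold positive-class
probabilities are concatenated with the original features ("passthrough")
to train a decision-tree meta-learner.  The stacking logic and the
grouped/stratified cross-validation engine are implemented here; base
learner internals are delegated to their established libraries.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import (
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .core import ConfusionCounts, FeatureTable
from .evaluate import EvalReport, roc_auc

__all__ = [
    "baseline_learners",
    "StackedEEGClassifier",
    "cross_validate",
]


def baseline_learners(seed: int = 0) -> dict[str, BaseEstimator]:
    """The eight baseline classifiers with the study's fixed parameters."""
    from lightgbm import LGBMClassifier
    from xgboost import XGBClassifier

    return {
        "dt": DecisionTreeClassifier(
            max_depth=20, min_samples_split=10, random_state=seed
        ),
        "knn": KNeighborsClassifier(n_neighbors=5, weights="distance"),
        "rf": RandomForestClassifier(
            max_depth=10, n_estimators=200, random_state=seed
        ),
        "svm": SVC(C=1, gamma="auto", kernel="rbf", probability=True,
                   random_state=seed),
        "lgbm": LGBMClassifier(
            learning_rate=0.1, n_estimators=500, random_state=seed,
            verbosity=-1,
        ),
        "xgboost": XGBClassifier(
            learning_rate=0.05, n_estimators=1000, random_state=seed,
            eval_metric="logloss", verbosity=0,
        ),
        "gb": GradientBoostingClassifier(
            learning_rate=0.1, n_estimators=200, random_state=seed
        ),
        "nn": MLPClassifier(
            hidden_layer_sizes=(50, 50), max_iter=1000, solver="adam",
            random_state=seed,
        ),
    }


def _default_bases(seed: int) -> list[tuple[str, BaseEstimator]]:
    from xgboost import XGBClassifier

    return [
        ("knn", KNeighborsClassifier(n_neighbors=5)),
        ("dt", DecisionTreeClassifier(max_depth=5, random_state=seed)),
        ("xgboost", XGBClassifier(
            learning_rate=0.01, max_depth=3, n_estimators=100,
            random_state=seed, eval_metric="logloss", verbosity=0,
        )),
    ]


class StackedEEGClassifier(BaseEstimator, ClassifierMixin):
    """Stacking ensemble with original-feature passthrough.

    Base learners produce out-of-fold positive-class probabilities on the
    training rows (stratified ``oof_folds``-fold internal split, so the
    meta-learner never sees in-fold base predictions).  The meta-feature
    matrix is ``[base scores | original features]`` when
    ``passthrough=True``; the meta decision tree is fit on it and the base
    learners are refit on the full training data for inference.

    Parameters
    ----------
    base_estimators : list of (name, estimator) or None
        Defaults to KNN(5), DecisionTree(depth 5) and
        XGBoost(lr 0.01, depth 3, 100 trees).
    meta_estimator : estimator or None
        Defaults to a decision tree.
    passthrough : bool
        Concatenate the original features to the base scores.
    oof_folds : int
        Internal folds for out-of-fold score generation.
    random_state : int
        Seeds the internal split, the meta learner and any seeded bases.
    """

    def __init__(self, base_estimators=None, meta_estimator=None,
                 passthrough: bool = True, oof_folds: int = 5,
                 random_state: int = 0):
        self.base_estimators = base_estimators
        self.meta_estimator = meta_estimator
        self.passthrough = passthrough
        self.oof_folds = oof_folds
        self.random_state = random_state

    def _resolve(self):
        bases = (self.base_estimators if self.base_estimators is not None
                 else _default_bases(self.random_state))
        meta = (self.meta_estimator if self.meta_estimator is not None
                else DecisionTreeClassifier(random_state=self.random_state))
        return [(n, clone(e)) for n, e in bases], clone(meta)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("training data contains a single class")
        if len(y) < 2 * self.oof_folds:
            raise ValueError(
                f"need at least {2 * self.oof_folds} rows for "
                f"{self.oof_folds}-fold out-of-fold stacking"
            )
        bases, meta = self._resolve()

        y_bin = (y == self.classes_[-1]).astype(int)
        oof = np.zeros((len(y), len(bases)))
        skf = StratifiedKFold(n_splits=self.oof_folds, shuffle=True,
                              random_state=self.random_state)
        for tr, te in skf.split(X, y_bin):
            for j, (_, est) in enumerate(bases):
                m = clone(est)
                m.fit(X[tr], y_bin[tr])
                oof[te, j] = m.predict_proba(X[te])[:, 1]

        meta_X = np.hstack([oof, X]) if self.passthrough else oof
        meta.fit(meta_X, y_bin)

        self.base_estimators_ = []
        for name, est in bases:
            m = clone(est)
            m.fit(X, y_bin)
            self.base_estimators_.append((name, m))
        self.meta_estimator_ = meta
        self.n_features_in_ = X.shape[1]
        self.meta_feature_width_ = meta_X.shape[1]
        return self

    def _meta_features(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was fit with "
                f"{self.n_features_in_}"
            )
        scores = np.column_stack(
            [m.predict_proba(X)[:, 1] for _, m in self.base_estimators_]
        )
        return np.hstack([scores, X]) if self.passthrough else scores

    def predict_proba(self, X):
        check_is_fitted(self, "meta_estimator_")
        proba1 = self.meta_estimator_.predict_proba(self._meta_features(X))
        # meta was trained on 0/1; map back to classes_ order
        out = np.zeros((proba1.shape[0], 2))
        cls = list(self.meta_estimator_.classes_)
        out[:, 1] = proba1[:, cls.index(1)] if 1 in cls else 0.0
        out[:, 0] = 1.0 - out[:, 1]
        return out

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        score = self.predict_proba(X)[:, 1]
        return np.where(score >= 0.5, self.classes_[-1], self.classes_[0])


def cross_validate(
    table: FeatureTable,
    learners: dict[str, BaseEstimator] | None = None,
    k: int = 5,
    grouping: str = "subject",
    seed: int = 0,
    include_stacking: bool = True,
) -> EvalReport:
    """Stratified k-fold cross-validation over the feature table.

    ``grouping='subject'`` keeps every subject's epochs in a single fold
    (no identity leakage); ``grouping='epoch'`` splits rows freely.  For
    each model the per-fold confusion counts, fold metrics, pooled-score
    AUC and mean-of-fold AUC are collected into an :class:`EvalReport`.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if grouping not in ("subject", "epoch"):
        raise ValueError("grouping must be 'subject' or 'epoch'")
    X = table.X()
    y = table.y()
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation needs both classes present")

    models: dict[str, BaseEstimator] = dict(learners or {})
    if include_stacking:
        models.setdefault("stacking", StackedEEGClassifier(random_state=seed))

    if grouping == "subject":
        groups = table.groups()
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                        random_state=seed)
        splits = list(splitter.split(X, y, groups=groups))
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(splitter.split(X, y))

    for tr, te in splits:
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            raise ValueError(
                "a fold contains a single class; stratification failed "
                "(too few subjects per class for the requested k?)"
            )

    report = EvalReport()
    for name, proto in models.items():
        fold_counts: list[ConfusionCounts] = []
        fold_aucs: list[float] = []
        pooled_scores: list[np.ndarray] = []
        pooled_labels: list[np.ndarray] = []
        for tr, te in splits:
            model = clone(proto)
            model.fit(X[tr], y[tr])
            if hasattr(model, "predict_proba"):
                score = model.predict_proba(X[te])[:, -1]
            else:  # pragma: no cover - all shipped models expose proba
                score = model.decision_function(X[te])
            pred = (score >= 0.5).astype(int) if hasattr(
                model, "predict_proba") else model.predict(X[te])
            c = ConfusionCounts(
                tp=int(((pred == 1) & (y[te] == 1)).sum()),
                fp=int(((pred == 1) & (y[te] == 0)).sum()),
                tn=int(((pred == 0) & (y[te] == 0)).sum()),
                fn=int(((pred == 0) & (y[te] == 1)).sum()),
            )
            fold_counts.append(c)
            fold_aucs.append(roc_auc(score, y[te]))
            pooled_scores.append(score)
            pooled_labels.append(y[te])
        report.add_model(
            name,
            fold_counts=fold_counts,
            fold_aucs=fold_aucs,
            pooled_auc=roc_auc(np.concatenate(pooled_scores),
                               np.concatenate(pooled_labels)),
        )
    report.meta.update({"k": k, "grouping": grouping, "seed": seed,
                        "n_rows": len(y)})
    return report
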