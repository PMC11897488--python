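"""Stacked ensemble classification on top-k lifespan features.

Pipeline: stratified train/test split (80/20 by default); recursive feature
elimination with a random forest down to five of the ten lifespan features;
ten base classifiers ranked by stratified 5-fold cross-validation accuracy on
the training set; the five best are stacked under a random-forest meta-model;
held-out accuracy is reported on the untouched test split.

CatBoost is not among the supported backends, so the roster's tenth member is
sklearn's histogram gradient boosting, an equivalent gradient-boosting
implementation; the substitution is recorded in every report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
    StackingClassifier,
)
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import (
    StratifiedKFold,
    cross_val_score,
    train_test_split,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

DEFAULT_ROSTER = (
    "svc",
    "random_forest",
    "gradient_boosting",
    "xgboost",
    "adaboost",
    "extra_trees",
    "logistic_regression",
    "knn",
    "lightgbm",
    "hist_gradient_boosting",  # gradient-boosting stand-in for CatBoost
)

SUBSTITUTIONS = {"catboost": "hist_gradient_boosting"}


@dataclass
class EnsembleConfig:
    base_model_roster: tuple = DEFAULT_ROSTER
    n_selected_features: int = 5
    n_stack_members: int = 5
    meta_model: str = "random_forest"
    cv_folds: int = 5
    test_fraction: float = 0.2
    seed: int = 0

    def validate(self, n_features: int) -> None:
        if self.n_selected_features > n_features:
            raise ValueError("n_selected_features exceeds feature count")
        if self.n_stack_members > len(self.base_model_roster):
            raise ValueError("n_stack_members exceeds roster size")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


def default_roster(seed: int = 0) -> dict:
    """The ten base classifiers, seeded; small-sample-friendly settings."""
    return {
        "svc": SVC(kernel="rbf", random_state=seed),
        "random_forest": RandomForestClassifier(
            n_estimators=100, random_state=seed),
        "gradient_boosting": GradientBoostingClassifier(random_state=seed),
        "xgboost": XGBClassifier(
            n_estimators=100, max_depth=3, learning_rate=0.1,
            eval_metric="logloss", verbosity=0, random_state=seed),
        "adaboost": AdaBoostClassifier(random_state=seed),
        "extra_trees": ExtraTreesClassifier(
            n_estimators=100, random_state=seed),
        "logistic_regression": LogisticRegression(max_iter=2000),
        "knn": KNeighborsClassifier(n_neighbors=5),
        "lightgbm": LGBMClassifier(
            n_estimators=100, min_child_samples=5, verbose=-1,
            random_state=seed),
        "hist_gradient_boosting": HistGradientBoostingClassifier(
            min_samples_leaf=5, random_state=seed),
    }


def rfe_select(features, labels, n_selected: int = 5,
               seed: int = 0) -> np.ndarray:
    """Recursive feature elimination with a random forest ranker.

    Returns the indices of the ``n_selected`` surviving features (ascending).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes for feature selection")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if n_selected >= X.shape[1]:
        return np.arange(X.shape[1])
    rfe = RFE(RandomForestClassifier(n_estimators=100, random_state=seed),
              n_features_to_select=n_selected, step=1)
    rfe.fit(X, y)
    return np.flatnonzero(rfe.support_)


def fit_stacked_ensemble(features, labels, config: EnsembleConfig | None = None):
    """Rank-select-stack ensemble; returns (fitted model, report dict).

    The report carries the CV ranking of all roster members, the selected
    feature indices, and the held-out accuracy on the stratified test split.
    """
    config = config or EnsembleConfig()
    X = np.asarray(features, dtype=float)
    y_raw = np.asarray(labels)
    config.validate(X.shape[1])
    classes, counts = np.unique(y_raw, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    y = np.searchsorted(classes, y_raw)  # integer-encode for all backends
    if counts.min() < config.cv_folds:
        raise ValueError(
            f"smallest class has {counts.min()} subjects; "
            f"need >= cv_folds = {config.cv_folds} for stratification"
        )
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=config.test_fraction, stratify=y,
        random_state=config.seed,
    )
    selected = rfe_select(X_tr, y_tr, config.n_selected_features, config.seed)
    X_tr_s, X_te_s = X_tr[:, selected], X_te[:, selected]

    roster = default_roster(config.seed)
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                         random_state=config.seed)
    with warnings.catch_warnings():
        # lightgbm's sklearn wrapper warns about feature names on plain arrays
        warnings.filterwarnings(
            "ignore", message="X does not have valid feature names")
        ranking = {}
        for name in config.base_model_roster:
            scores = cross_val_score(roster[name], X_tr_s, y_tr, cv=cv,
                                     scoring="accuracy")
            ranking[name] = float(scores.mean())
        ordered = sorted(config.base_model_roster,
                         key=lambda n: -ranking[n])  # roster order on ties
        top = ordered[:config.n_stack_members]

        meta = RandomForestClassifier(n_estimators=100,
                                      random_state=config.seed)
        model = StackingClassifier(
            estimators=[(n, roster[n]) for n in top],
            final_estimator=meta,
            cv=StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                               random_state=config.seed),
        )
        model.fit(X_tr_s, y_tr)
        acc = float(np.mean(model.predict(X_te_s) == y_te))
    report = {
        "classes": [str(c) for c in classes],
        "config": {
            "roster": list(config.base_model_roster),
            "n_selected_features": config.n_selected_features,
            "n_stack_members": config.n_stack_members,
            "meta_model": config.meta_model,
            "cv_folds": config.cv_folds,
            "test_fraction": config.test_fraction,
            "seed": config.seed,
        },
        "substitutions": dict(SUBSTITUTIONS),
        "selected_features": [int(i) for i in selected],
        "cv_ranking": ranking,
        "stack_members": top,
        "held_out_accuracy": acc,
        "n_train": int(len(y_tr)),
        "n_test": int(len(y_te)),
    }
    return model, report
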