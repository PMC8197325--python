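"""Classifier adapters with a uniform fit / positive-class-probability contract.

Every adapter exposes scikit-learn's ``fit`` / ``predict_proba``; predicted
labels are always derived by thresholding the positive-class probability at
0.5, so the (label, proba) pair emitted for stacking is internally consistent
for every learner.  All stochastic learners are seeded and restricted to a
single thread so that identical seeds give identical models.
"""

from __future__ import annotations

from typing import Any

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, GradientBoostingClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

LEARNER_TAGS = ("knn", "adaboost", "gbdt", "xgboost", "lightgbm", "catboost")
DEFAULT_ROSTER = ("knn", "adaboost", "gbdt", "xgboost", "lightgbm")

__all__ = ["LEARNER_TAGS", "DEFAULT_ROSTER", "make_classifier", "make_meta_classifier",
           "predict_label_proba"]


def make_classifier(tag: str, seed: int = 0, params: dict[str, Any] | None = None):
    """Instantiate a base classifier by tag.

    ``params`` overrides the library defaults (e.g. smaller tree counts for
    quick runs).  The ``catboost`` tag requires the catboost library and
    raises ``ImportError`` when it is not installed.
    """
    params = dict(params or {})
    if tag == "knn":
        return KNeighborsClassifier(**params)
    if tag == "adaboost":
        return AdaBoostClassifier(random_state=seed, **params)
    if tag == "gbdt":
        return GradientBoostingClassifier(random_state=seed, **params)
    if tag == "xgboost":
        from xgboost import XGBClassifier

        defaults = dict(
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
            verbosity=0,
        )
        defaults.update(params)
        return XGBClassifier(**defaults)
    if tag == "lightgbm":
        from lightgbm import LGBMClassifier

        defaults = dict(random_state=seed, n_jobs=1, deterministic=True,
                        force_row_wise=True, verbose=-1)
        defaults.update(params)
        return LGBMClassifier(**defaults)
    if tag == "catboost":
        try:
            from catboost import CatBoostClassifier
        except ImportError as exc:  # pragma: no cover - depends on install
            raise ImportError(
                "the 'catboost' learner tag requires the catboost package"
            ) from exc
        defaults = dict(random_seed=seed, verbose=False, thread_count=1)
        defaults.update(params)
        return CatBoostClassifier(**defaults)
    raise KeyError(f"unknown classifier tag {tag!r}; choose from {LEARNER_TAGS}")


def make_meta_classifier(tag: str = "svm", seed: int = 0, params: dict[str, Any] | None = None):
    """Meta-classifier for stacking; default is a linear-kernel SVM (C=1)."""
    params = dict(params or {})
    if tag == "svm":
        defaults = dict(kernel="linear", C=1.0, random_state=seed)
        defaults.update(params)
        return SVC(**defaults)
    return make_classifier(tag, seed=seed, params=params)


def predict_label_proba(model, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Positive-class probability and its 0.5-threshold label for each row."""
    proba = np.asarray(model.predict_proba(X))
    classes = list(getattr(model, "classes_", [0, 1]))
    pos = classes.index(1) if 1 in classes else proba.shape[1] - 1
    p1 = proba[:, pos]
    return (p1 >= 0.5).astype(int), p1
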