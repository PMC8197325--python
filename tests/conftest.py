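"""Shared fixtures: tiny datasets, stub learners, scripted evaluators."""

from __future__ import annotations

import numpy as np
import pytest

from xgbstack import Dataset, SyntheticSpec, generate_synthetic


class MajorityStub:
    """Predicts the majority training label; positive-class probability is the
    training frequency of class 1, so the 0.5-threshold label equals the
    majority class."""

    def __init__(self) -> None:
        self.p1 = None
        self.classes_ = [0, 1]

    def fit(self, X, y):
        self.p1 = float(np.mean(np.asarray(y) == 1))
        return self

    def predict_proba(self, X):
        n = np.asarray(X).shape[0]
        return np.column_stack([np.full(n, 1 - self.p1), np.full(n, self.p1)])


class RowFeatureStub:
    """Ignores training data; the positive-class probability of a row is its
    own first feature clipped to [0,1].  Isolates OOF plumbing: a row's
    meta-features depend only on that row."""

    classes_ = [0, 1]

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        p1 = np.clip(np.asarray(X)[:, 0], 0.0, 1.0)
        return np.column_stack([1 - p1, p1])


class SpyStub:
    """Records the row ids (first feature) it was trained on; predicts 0.5."""

    classes_ = [0, 1]

    def __init__(self, log: list) -> None:
        self.log = log

    def fit(self, X, y):
        self.train_ids = frozenset(np.asarray(X)[:, 0].astype(int).tolist())
        return self

    def predict_proba(self, X):
        ids = np.asarray(X)[:, 0].astype(int)
        for i in ids:
            self.log.append((i, self.train_ids))
        n = len(ids)
        return np.column_stack([np.full(n, 0.5), np.full(n, 0.5)])


class LookupEvaluator:
    """Scripted subset evaluator: a lookup table with a default value.

    Counts every call, mirroring the real evaluator's accounting.
    """

    def __init__(self, table: dict, default: float = 0.6) -> None:
        self.table = {frozenset(k): v for k, v in table.items()}
        self.default = default
        self.n_calls = 0
        self.seen: list[tuple[frozenset, float]] = []

    def __call__(self, subset) -> float:
        self.n_calls += 1
        key = frozenset(subset)
        acc = self.table.get(key, self.default)
        self.seen.append((key, acc))
        return acc


@pytest.fixture
def majority_stub_factory():
    return lambda spec=None: MajorityStub()


@pytest.fixture
def tiny_dataset() -> Dataset:
    rng = np.random.default_rng(0)
    X = rng.standard_normal((20, 3))
    y = (X[:, 0] > 0).astype(int)
    return Dataset(["a", "b", "c"], X, y)


@pytest.fixture(scope="session")
def small_synth() -> Dataset:
    """A small planted-structure dataset for wrapper/fusion tests."""
    spec = SyntheticSpec(
        n_samples=300, n_informative=4, n_redundant=3, n_noise=8,
        n_qualitative=5, effect_size=1.5, seed=11,
    )
    return generate_synthetic(spec)


FAST_PARAMS = {
    "knn": None,
    "adaboost": {"n_estimators": 30},
    "gbdt": {"n_estimators": 30},
    "xgboost": {"n_estimators": 30, "max_depth": 3},
    "lightgbm": {"n_estimators": 30, "min_child_samples": 5},
}
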