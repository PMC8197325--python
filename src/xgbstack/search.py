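"""Buffered floating backward feature-subset search (BFGSBS) and its wrapper.

The search works on two orderings of the nonzero-importance features: I1,
ascending by one importance metric (so the least important feature is deleted
first), and I2, descending by another (so the most important absent feature is
offered back first).  A buffer subset O starts at the full nonzero set and the
algorithm alternates

* Stage 1 — unconditional backward deletion: remove the N-th feature of I1
  from O (if still present), evaluate, advance N;
* Stage 2 — floating forward re-addition: walk I2 once from the front; each
  feature absent from O is tentatively added and kept only if the evaluation
  strictly improves on the current buffer's evaluation.

The best subset/accuracy ever evaluated is tracked separately and returned
once N has walked off the end of I1.  Strict (>) improvement tests prevent
cycling between equal-accuracy subsets and bias the result toward smaller
subsets.  The wrapper (`xgbibs_select`) fits an XGBoost booster to obtain the
importance ranking, wraps the chosen classifier as the subset evaluator
(train on the training partition, accuracy on the evaluation partition) and
runs the search.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd

from .data import Dataset
from .importance import METRICS, RankingQueues, booster_importance, build_ranking_queues
from .learners import make_classifier, predict_label_proba
from .metrics import dimension_reduction

__all__ = [
    "SubsetEvaluator",
    "SearchState",
    "SearchResult",
    "stage1_delete",
    "stage2_float_add",
    "run_bfgsbs",
    "xgbibs_select",
    "enumerate_metric_pairs",
]


class SubsetEvaluator:
    """Wrapped evaluation function: accuracy of a classifier trained on a
    feature subset.

    Trains ``make_classifier(tag)`` on the training partition restricted to
    the subset and returns classification accuracy on the evaluation
    partition.  Results are cached per subset, so repeated queries within a
    run are consistent and cheap; ``n_calls`` counts every query (cached or
    not) for complexity accounting.
    """

    def __init__(
        self,
        train: Dataset,
        eval: Dataset,
        classifier: str = "xgboost",
        seed: int = 0,
        params: dict[str, Any] | None = None,
    ) -> None:
        self.train = train
        self.eval = eval
        self.classifier = classifier
        self.seed = seed
        self.params = params
        self.n_calls = 0
        self._cache: dict[frozenset, float] = {}

    def __call__(self, subset) -> float:
        self.n_calls += 1
        key = frozenset(subset)
        if not key:
            raise ValueError("cannot evaluate an empty feature subset")
        if key in self._cache:
            return self._cache[key]
        cols = sorted(key)
        model = make_classifier(self.classifier, seed=self.seed, params=self.params)
        try:
            model.fit(self.train.frame(cols), self.train.y)
            label, _ = predict_label_proba(model, self.eval.frame(cols))
        except Exception as exc:
            raise RuntimeError(
                f"evaluator failed on subset {cols}: {exc}"
            ) from exc
        acc = float(np.mean(label == self.eval.y))
        self._cache[key] = acc
        return acc


@dataclass
class SearchState:
    """Mutable state of the search: buffer O, best-so-far, and the two cursors."""

    O: set
    best_subset: frozenset
    best_acc: float
    current_acc: float
    n: int = 1  # 1-based cursor into I1
    trace: list[tuple] = field(default_factory=list)

    def log(self, kind: str, feature, acc: float) -> None:
        self.trace.append((kind, feature, len(self.O), acc))

    def consider_best(self, acc: float) -> None:
        if acc > self.best_acc:
            self.best_acc = acc
            self.best_subset = frozenset(self.O)


@dataclass
class SearchResult:
    """Outcome of a subset search."""

    best_subset: frozenset
    best_acc: float
    trace: list[tuple]
    n_evaluations: int = 0
    dr: float | None = None          # dimension reduction vs the full feature count
    full_acc: float | None = None    # evaluation of the initial full subset
    queues: RankingQueues | None = None

    def to_dict(self) -> dict:
        return {
            "best_subset": sorted(self.best_subset),
            "best_acc": self.best_acc,
            "n_evaluations": self.n_evaluations,
            "dr": self.dr,
            "full_acc": self.full_acc,
            "trace": [list(t) for t in self.trace],
        }


def stage1_delete(state: SearchState, I1: list, ev: Callable) -> SearchState:
    """One backward-deletion step: drop the N-th feature of I1 from the buffer.

    The deletion is unconditional (the buffer keeps the smaller subset even if
    accuracy drops); the best-so-far is updated only on strict improvement.
    If the cursor's feature already left the buffer, or removing it would
    empty the buffer, the step only advances the cursor.
    """
    if state.n > len(I1):
        raise IndexError("deletion cursor ran past the end of I1")
    feat = I1[state.n - 1]
    state.n += 1
    if feat not in state.O or len(state.O) == 1:
        state.log("delete_skip", feat, state.current_acc)
        return state
    state.O.discard(feat)
    acc = ev(state.O)
    state.current_acc = acc
    state.consider_best(acc)
    state.log("delete", feat, acc)
    return state


def stage2_float_add(state: SearchState, I2: list, ev: Callable) -> SearchState:
    """One full traversal of I2: tentatively re-add each absent feature.

    An addition is kept only if it strictly improves on the current buffer's
    evaluation; otherwise it is rolled back.  Kept additions that also beat
    the best-so-far update it.
    """
    for feat in I2:
        if feat in state.O:
            continue
        state.O.add(feat)
        acc = ev(state.O)
        if acc > state.current_acc:
            state.current_acc = acc
            state.consider_best(acc)
            state.log("add_keep", feat, acc)
        else:
            state.O.discard(feat)
            state.log("add_reject", feat, acc)
    return state


def run_bfgsbs(
    queues: RankingQueues,
    ev: Callable,
    full_set: set | None = None,
    sweeps: int = 1,
) -> SearchResult:
    """Run the full backward/floating search over the ranking queues.

    Starts from the full set of queue features, alternates Stage 1 (one
    deletion) with Stage 2 (one I2 traversal) until the deletion cursor has
    visited every I1 position, optionally repeating for extra ``sweeps``.
    Deterministic whenever the evaluator is.
    """
    if not queues.I1:
        raise ValueError("empty ranking queues")
    O = set(full_set) if full_set is not None else set(queues.I1)
    init_acc = ev(O)
    state = SearchState(
        O=O,
        best_subset=frozenset(O),
        best_acc=init_acc,
        current_acc=init_acc,
    )
    state.log("init", None, init_acc)
    n_calls_before = getattr(ev, "n_calls", None)
    for _ in range(max(1, sweeps)):
        state.n = 1
        while state.n <= len(queues.I1):
            stage1_delete(state, queues.I1, ev)
            stage2_float_add(state, queues.I2, ev)
    n_eval = (
        ev.n_calls if n_calls_before is not None else sum(1 for t in state.trace if t[0] != "delete_skip")
    )
    return SearchResult(
        best_subset=state.best_subset,
        best_acc=state.best_acc,
        trace=state.trace,
        n_evaluations=n_eval,
        full_acc=init_acc,
        queues=queues,
    )


def xgbibs_select(
    train: Dataset,
    eval: Dataset,
    classifier: str = "xgboost",
    i1: str = "total_gain",
    i2: str = "cover",
    seed: int = 0,
    learner_params: dict[str, Any] | None = None,
    booster_params: dict[str, Any] | None = None,
) -> SearchResult:
    """Wrapped feature selection: XGBoost importance queues + BFGSBS search.

    Fits an XGBoost booster on the training partition to rank features,
    filters out zero-importance features, builds the (i1, i2) queues and runs
    the search with the named classifier as evaluation function.  The result
    additionally reports the dimension reduction achieved against the full
    feature count of the dataset.
    """
    if set(train.feature_names) != set(eval.feature_names):
        raise ValueError("train and eval partitions must share the feature universe")
    booster = make_classifier("xgboost", seed=seed, params=booster_params)
    # fit on a named frame so the booster's importance report uses real names
    booster.fit(train.frame(), train.y)
    table = booster_importance(booster, train.feature_names)
    if not table.nonzero_features():
        raise ValueError(
            "all feature importances are zero; the booster never split — "
            "cannot build a search space"
        )
    queues = build_ranking_queues(table, i1, i2)
    ev = SubsetEvaluator(train, eval, classifier=classifier, seed=seed, params=learner_params)
    result = run_bfgsbs(queues, ev)
    result.dr = dimension_reduction(len(result.best_subset), train.n_features)
    return result


def enumerate_metric_pairs(
    train: Dataset,
    eval: Dataset,
    classifier: str = "xgboost",
    seed: int = 0,
    learner_params: dict[str, Any] | None = None,
    booster_params: dict[str, Any] | None = None,
) -> tuple[tuple[str, str], SearchResult, dict[tuple[str, str], SearchResult]]:
    """Exhaustively try all 20 ordered (i1, i2) metric pairs with i1 != i2.

    Returns the best pair (highest best_acc, ties broken by higher dimension
    reduction then lexicographic pair name), its result, and the full table.
    """
    results: dict[tuple[str, str], SearchResult] = {}
    for i1, i2 in itertools.permutations(METRICS, 2):
        results[(i1, i2)] = xgbibs_select(
            train, eval, classifier, i1=i1, i2=i2, seed=seed,
            learner_params=learner_params, booster_params=booster_params,
        )
    best_pair = min(
        results, key=lambda p: (-results[p].best_acc, -(results[p].dr or 0.0), p)
    )
    return best_pair, results[best_pair], results
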