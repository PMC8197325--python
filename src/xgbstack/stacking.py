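"""Sel-Stacking model fusion.

Base classifiers (each optionally restricted to its own selected feature
subset) are stacked under a meta-classifier.  Two departures from plain
stacking:

* the meta-input is the *Label-Proba* matrix — for every sample each base
  classifier contributes both its predicted label (the 0.5 threshold of its
  positive-class probability) and the probability itself, so M samples and N
  base classifiers give an M x 2N matrix;
* the set of base classifiers is not fixed: every non-empty subset of the
  candidate roster is scored (meta-classifier trained on the subset's
  out-of-fold columns, accuracy measured on the validation partition) and the
  argmax is kept — a global search over 2^N - 1 combinations.

Out-of-fold (OOF) construction keeps the meta-training honest: each training
row's meta-features come from base models fit on the K-1 folds that exclude
that row.  Holdout (validation/test) meta-features come from base models
refit on the full training partition.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .data import Dataset
from .learners import make_classifier, make_meta_classifier, predict_label_proba

logger = logging.getLogger(__name__)

INPUT_MODES = ("label", "proba", "label_proba")
MAX_EXHAUSTIVE = 12

__all__ = [
    "BaseLearnerSpec",
    "LabelProbaMatrix",
    "FusionConfig",
    "FusionResult",
    "oof_label_proba",
    "holdout_label_proba",
    "enumerate_and_select",
    "sel_stacking_fit_predict",
]


@dataclass(frozen=True)
class BaseLearnerSpec:
    """One candidate base classifier with its selected feature subset."""

    tag: str
    feature_subset: frozenset
    seed: int = 0
    params: dict | None = None

    def __post_init__(self) -> None:
        if not self.feature_subset:
            raise ValueError(f"base learner {self.tag!r} has an empty feature subset")


@dataclass
class LabelProbaMatrix:
    """Per-sample (label, proba) meta-feature block, M rows x 2N columns.

    Column order is (label_1, proba_1, ..., label_N, proba_N) following the
    order of ``tags``.
    """

    values: np.ndarray
    tags: tuple

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 2 * len(self.tags):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with {len(self.tags)} classifiers"
            )
        labels = self.values[:, 0::2]
        probas = self.values[:, 1::2]
        if not np.isin(labels, (0.0, 1.0)).all():
            raise ValueError("label columns must be 0/1")
        if probas.size and (probas.min() < 0 or probas.max() > 1):
            raise ValueError("probability columns must lie in [0,1]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def select(self, subset: Sequence[str], input_mode: str = "label_proba") -> np.ndarray:
        """Columns for a subset of classifiers under an input convention.

        ``label`` keeps only the predicted labels (width |subset|), ``proba``
        only the probabilities (width |subset|), ``label_proba`` both (width
        2 |subset|).
        """
        if input_mode not in INPUT_MODES:
            raise KeyError(f"input_mode must be one of {INPUT_MODES}")
        cols = []
        for tag in subset:
            k = self.tags.index(tag)
            if input_mode in ("label", "label_proba"):
                cols.append(2 * k)
            if input_mode in ("proba", "label_proba"):
                cols.append(2 * k + 1)
        return self.values[:, cols]

    def to_csv(self, path) -> None:
        import pandas as pd

        names = []
        for t in self.tags:
            names += [f"{t}_label", f"{t}_proba"]
        pd.DataFrame(self.values, columns=names).to_csv(path, index=False)


@dataclass
class FusionConfig:
    """Configuration of the fusion stage."""

    candidates: list[BaseLearnerSpec]
    K: int = 6
    meta: str = "svm"
    input_mode: str = "label_proba"
    seed: int = 0
    meta_params: dict | None = None
    allow_large_roster: bool = False

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("need at least 2 folds")
        if not self.candidates:
            raise ValueError("candidate roster is empty")
        tags = [c.tag for c in self.candidates]
        if len(set(tags)) != len(tags):
            raise ValueError("candidate tags must be unique")


@dataclass
class FusionResult:
    """Outcome of the combination search."""

    chosen_combination: tuple
    val_accuracy: float
    test_accuracy: float | None = None
    per_combination_scores: dict = field(default_factory=dict)
    failed_combinations: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "chosen_combination": list(self.chosen_combination),
            "val_accuracy": self.val_accuracy,
            "test_accuracy": self.test_accuracy,
            "per_combination_scores": {
                "+".join(k): v for k, v in sorted(self.per_combination_scores.items())
            },
            "failed_combinations": ["+".join(k) for k in self.failed_combinations],
        }


def _default_factory(spec: BaseLearnerSpec):
    return make_classifier(spec.tag, seed=spec.seed, params=spec.params)


def _check_fold_classes(y_part: np.ndarray, fold: int) -> None:
    if len(np.unique(y_part)) < 2:
        raise ValueError(f"fold {fold} has a single class in its training part")


def oof_label_proba(
    train: Dataset,
    specs: list[BaseLearnerSpec],
    K: int = 6,
    seed: int = 0,
    learner_factory: Callable[[BaseLearnerSpec], Any] | None = None,
) -> LabelProbaMatrix:
    """Out-of-fold meta-features for the training partition.

    For every stratified fold, each base classifier is trained on the other
    K-1 folds (restricted to its feature subset) and predicts label + proba
    for the held-out fold, so no row's meta-features were produced by a model
    that saw that row.
    """
    if K > train.n_samples:
        raise ValueError("more folds than training samples")
    factory = learner_factory or _default_factory
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    values = np.empty((train.n_samples, 2 * len(specs)))
    folds = list(skf.split(train.X, train.y))
    for fold, (fit_idx, oof_idx) in enumerate(folds):
        _check_fold_classes(train.y[fit_idx], fold)
        for k, spec in enumerate(specs):
            cols = sorted(spec.feature_subset)
            Xall = train.frame(cols)
            Xfit = Xall.iloc[fit_idx]
            Xoof = Xall.iloc[oof_idx]
            model = factory(spec)
            model.fit(Xfit, train.y[fit_idx])
            label, proba = predict_label_proba(model, Xoof)
            values[oof_idx, 2 * k] = label
            values[oof_idx, 2 * k + 1] = proba
    return LabelProbaMatrix(values, tuple(s.tag for s in specs))


def holdout_label_proba(
    train: Dataset,
    holdout: Dataset,
    specs: list[BaseLearnerSpec],
    learner_factory: Callable[[BaseLearnerSpec], Any] | None = None,
) -> LabelProbaMatrix:
    """Meta-features for a holdout partition from base models refit on the
    full training partition; column order matches :func:`oof_label_proba`."""
    factory = learner_factory or _default_factory
    values = np.empty((holdout.n_samples, 2 * len(specs)))
    for k, spec in enumerate(specs):
        cols = sorted(spec.feature_subset)
        model = factory(spec)
        model.fit(train.frame(cols), train.y)
        label, proba = predict_label_proba(model, holdout.frame(cols))
        values[:, 2 * k] = label
        values[:, 2 * k + 1] = proba
    return LabelProbaMatrix(values, tuple(s.tag for s in specs))


def enumerate_and_select(
    oof: LabelProbaMatrix,
    val: LabelProbaMatrix,
    y_train: np.ndarray,
    y_val: np.ndarray,
    meta: str = "svm",
    candidates: Sequence[str] | None = None,
    input_mode: str = "label_proba",
    seed: int = 0,
    meta_params: dict | None = None,
    score_fn: Callable[[tuple], float] | None = None,
    allow_large_roster: bool = False,
) -> FusionResult:
    """Global search over every non-empty base-classifier combination.

    For each of the 2^N - 1 subsets the meta-classifier is trained on the
    subset's OOF columns against ``y_train`` and scored by accuracy on the
    subset's validation columns against ``y_val``.  Ties break toward fewer
    members, then lexicographic tag order.  ``score_fn`` replaces the default
    train-and-score step with a custom combination scorer (advanced hook).
    """
    tags = tuple(candidates) if candidates is not None else oof.tags
    if len(tags) > MAX_EXHAUSTIVE and not allow_large_roster:
        raise ValueError(
            f"{len(tags)} candidates means {2**len(tags)-1} combinations; "
            "pass allow_large_roster=True to force the exhaustive search"
        )
    scores: dict[tuple, float] = {}
    failed: list[tuple] = []
    for r in range(1, len(tags) + 1):
        for combo in itertools.combinations(tags, r):
            try:
                if score_fn is not None:
                    acc = float(score_fn(combo))
                else:
                    model = make_meta_classifier(meta, seed=seed, params=meta_params)
                    model.fit(oof.select(combo, input_mode), y_train)
                    pred = model.predict(val.select(combo, input_mode))
                    acc = float(np.mean(pred == y_val))
            except Exception as exc:
                warnings.warn(f"meta training failed on {combo}: {exc}", stacklevel=2)
                logger.warning("meta training failed on %s: %s", combo, exc)
                failed.append(combo)
                continue
            scores[combo] = acc
    if not scores:
        raise RuntimeError("every combination failed meta training")
    chosen = min(scores, key=lambda c: (-scores[c], len(c), c))
    return FusionResult(
        chosen_combination=chosen,
        val_accuracy=scores[chosen],
        per_combination_scores=scores,
        failed_combinations=failed,
    )


def sel_stacking_fit_predict(
    train: Dataset,
    val: Dataset,
    test: Dataset,
    cfg: FusionConfig,
    learner_factory: Callable[[BaseLearnerSpec], Any] | None = None,
) -> FusionResult:
    """End-to-end fusion: OOF matrix on train, holdout matrices on val/test,
    combination search on validation accuracy, final refit and test scoring.

    The test partition enters only the very last step: scoring the already
    chosen combination's meta-classifier.
    """
    for part in (val, test):
        if set(part.feature_names) != set(train.feature_names):
            raise ValueError("partitions must share the feature universe")
    oof = oof_label_proba(train, cfg.candidates, K=cfg.K, seed=cfg.seed,
                          learner_factory=learner_factory)
    val_m = holdout_label_proba(train, val, cfg.candidates, learner_factory=learner_factory)
    result = enumerate_and_select(
        oof, val_m, train.y, val.y,
        meta=cfg.meta, input_mode=cfg.input_mode, seed=cfg.seed,
        meta_params=cfg.meta_params, allow_large_roster=cfg.allow_large_roster,
    )
    chosen_specs = [c for c in cfg.candidates if c.tag in result.chosen_combination]
    model = make_meta_classifier(cfg.meta, seed=cfg.seed, params=cfg.meta_params)
    model.fit(oof.select(result.chosen_combination, cfg.input_mode), train.y)
    test_m = holdout_label_proba(train, test, chosen_specs, learner_factory=learner_factory)
    test_m = LabelProbaMatrix(test_m.values, tuple(s.tag for s in chosen_specs))
    pred = model.predict(test_m.select(result.chosen_combination, cfg.input_mode))
    result.test_accuracy = float(np.mean(pred == test.y))
    return result
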