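"""Gradient-boosted-tree feature-importance metrics and ranking queues.

Five importance metrics are defined over the set X of tree splits that use a
feature:

* ``weight``      — |X|, the number of splits using the feature,
* ``gain``        — mean split gain over X,
* ``cover``       — mean split cover (instance weight reaching the split),
* ``total_gain``  — summed split gain,
* ``total_cover`` — summed split cover,

so ``total_gain = gain * weight`` and ``total_cover = cover * weight`` hold
identically.  The split gain of a candidate split with left/right gradient
sums (G_L, H_L), (G_R, H_R), L2 penalty lambda and split penalty gamma is

    gain = 1/2 [ G_L^2/(H_L+l) + G_R^2/(H_R+l) - (G_L+G_R)^2/(H_L+H_R+l) ] - g

Two sources are supported: a minimal in-package tree-ensemble representation
(so the formulas are independently testable) and a fitted XGBoost booster's
own importance report (the production path).  Both feed the same queue
construction: features with zero importance are excluded from the search
space, the I1 queue orders the survivors ascending by metric i1 (deletion
order) and the I2 queue descending by metric i2 (re-addition order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METRICS = ("weight", "gain", "cover", "total_gain", "total_cover")

__all__ = [
    "METRICS",
    "TreeSplit",
    "TreeEnsemble",
    "ImportanceTable",
    "RankingQueues",
    "split_gain",
    "feature_importance",
    "booster_importance",
    "build_ranking_queues",
]


@dataclass(frozen=True)
class TreeSplit:
    """One internal node of a boosted tree: gradient sums and split penalties."""

    feature: str
    G_L: float
    G_R: float
    H_L: float
    H_R: float
    cover: float = 0.0
    lam: float = 0.0
    gamma: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.G_L, self.G_R, self.H_L, self.H_R, self.cover, self.lam, self.gamma)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("TreeSplit fields must be finite")
        if self.cover < 0 or self.lam < 0 or self.gamma < 0:
            raise ValueError("cover, lam and gamma must be non-negative")
        if self.H_L + self.lam <= 0 or self.H_R + self.lam <= 0:
            raise ValueError("H + lambda must be positive in each child")


@dataclass
class TreeEnsemble:
    """A forest as a list of trees, each tree a list of :class:`TreeSplit`."""

    trees: list[list[TreeSplit]]
    max_depth: int = 0
    n_trees: int = 0

    def __post_init__(self) -> None:
        if not self.n_trees:
            self.n_trees = len(self.trees)

    def all_splits(self):
        for tree in self.trees:
            yield from tree


@dataclass
class ImportanceTable:
    """Per-feature importance metrics, indexed by feature name."""

    table: pd.DataFrame  # columns: weight, gain, cover, total_gain, total_cover

    def __post_init__(self) -> None:
        missing = set(METRICS) - set(self.table.columns)
        if missing:
            raise ValueError(f"importance table missing columns {sorted(missing)}")

    def metric(self, name: str) -> pd.Series:
        if name not in METRICS:
            raise KeyError(f"unknown importance metric {name!r}; choose from {METRICS}")
        return self.table[name]

    @property
    def features(self) -> list[str]:
        return list(self.table.index)

    def nonzero_features(self) -> list[str]:
        """Features that appear in at least one split (weight > 0)."""
        return list(self.table.index[self.table["weight"] > 0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="feature")


@dataclass
class RankingQueues:
    """The two feature orderings that drive the backward/floating search."""

    i1: str
    i2: str
    I1: list[str] = field(default_factory=list)  # ascending by i1
    I2: list[str] = field(default_factory=list)  # descending by i2

    @property
    def features(self) -> set[str]:
        return set(self.I1)


def split_gain(s: TreeSplit) -> float:
    """Gain of a single split from its child gradient statistics."""
    l, g = s.lam, s.gamma
    return 0.5 * (
        s.G_L**2 / (s.H_L + l)
        + s.G_R**2 / (s.H_R + l)
        - (s.G_L + s.G_R) ** 2 / (s.H_L + s.H_R + l)
    ) - g


def feature_importance(
    e: TreeEnsemble, feature_universe: list[str] | None = None
) -> ImportanceTable:
    """Aggregate the five importance metrics over an ensemble's splits.

    Features in ``feature_universe`` that never split get all-zero rows.
    """
    if not e.trees:
        raise ValueError("ensemble has no trees")
    gains: dict[str, list[float]] = {}
    covers: dict[str, list[float]] = {}
    for s in e.all_splits():
        gains.setdefault(s.feature, []).append(split_gain(s))
        covers.setdefault(s.feature, []).append(s.cover)
    universe = list(feature_universe) if feature_universe is not None else sorted(gains)
    for f in gains:
        if f not in universe:
            raise ValueError(f"split feature {f!r} outside the feature universe")
    rows = {}
    for f in universe:
        g = gains.get(f, [])
        c = covers.get(f, [])
        w = len(g)
        rows[f] = {
            "weight": float(w),
            "gain": float(np.mean(g)) if w else 0.0,
            "cover": float(np.mean(c)) if w else 0.0,
            "total_gain": float(np.sum(g)) if w else 0.0,
            "total_cover": float(np.sum(c)) if w else 0.0,
        }
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=list(METRICS))
    return ImportanceTable(df.loc[universe])


def booster_importance(model, feature_names: list[str]) -> ImportanceTable:
    """Importance table from a fitted XGBoost sklearn-API classifier.

    Reads the booster's own importance report for each of the five metric
    names; features the booster never used are filled with zeros.
    """
    booster = model.get_booster()
    cols = {}
    for metric in METRICS:
        score = booster.get_score(importance_type=metric)
        cols[metric] = [float(score.get(f, 0.0)) for f in feature_names]
    df = pd.DataFrame(cols, index=list(feature_names)).reindex(columns=list(METRICS))
    return ImportanceTable(df)


def build_ranking_queues(t: ImportanceTable, i1: str, i2: str) -> RankingQueues:
    """Build the deletion (I1, ascending by i1) and re-addition (I2,
    descending by i2) queues over the nonzero-importance features.

    Ties break lexicographically by feature name, so queue order is
    deterministic across runs and platforms.
    """
    if i1 not in METRICS or i2 not in METRICS:
        raise KeyError(f"metrics must be among {METRICS}, got ({i1!r}, {i2!r})")
    feats = t.nonzero_features()
    if not feats:
        raise ValueError("no feature has nonzero importance; nothing to search")
    v1 = t.metric(i1)
    v2 = t.metric(i2)
    I1 = sorted(feats, key=lambda f: (v1[f], f))
    I2 = sorted(feats, key=lambda f: (-v2[f], f))
    return RankingQueues(i1=i1, i2=i2, I1=I1, I2=I2)
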