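"""Tabular dataset container, CSV I/O, preprocessing, partitioning and a synthetic generator.

The datasets this package targets are small, high-dimensional clinical tables:
a few thousand rows, tens of features mixing qualitative indicators (disease
flags, demographic codes, stored as integers) with quantitative biochemical
measurements, and a binary outcome label.  The synthetic generator emulates
that structure with a known ground truth (which features actually drive the
label) so that feature-selection behaviour can be tested.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

QUALITATIVE = "qualitative"
QUANTITATIVE = "quantitative"

__all__ = [
    "Dataset",
    "SplitSpec",
    "SyntheticSpec",
    "PreprocessReport",
    "load_dataset",
    "save_dataset",
    "preprocess",
    "split_dataset",
    "split_sizes",
    "generate_synthetic",
]


@dataclass
class Dataset:
    """A feature matrix with a binary label vector.

    Attributes
    ----------
    feature_names : list of str
        Unique column identifiers, in matrix column order.
    X : ndarray of shape (n_samples, n_features)
        Feature values as floats.  Missing values are NaN.
    y : ndarray of shape (n_samples,)
        Binary labels in {0, 1}.
    feature_kinds : list of str
        Per-feature tag, ``"qualitative"`` or ``"quantitative"``.
    provenance : dict
        Optional generator metadata (feature roles, generating probabilities).
        Not used by any algorithm; carried for testing and reporting.
    """

    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray
    feature_kinds: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]} entries"
            )
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"X has {self.X.shape[1]} columns but {len(self.feature_names)} names given"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        labels = set(np.unique(self.y[~pd.isna(self.y)]).tolist())
        if not labels <= {0, 1}:
            raise ValueError(f"labels must be binary 0/1, found {sorted(labels)}")
        self.y = self.y.astype(int)
        if not self.feature_kinds:
            self.feature_kinds = [QUANTITATIVE] * len(self.feature_names)
        if len(self.feature_kinds) != len(self.feature_names):
            raise ValueError("feature_kinds must align with feature_names")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset_rows(self, idx: np.ndarray) -> "Dataset":
        return Dataset(
            feature_names=list(self.feature_names),
            X=self.X[idx],
            y=self.y[idx],
            feature_kinds=list(self.feature_kinds),
            provenance=dict(self.provenance),
        )

    def columns(self, names: list[str] | set[str] | frozenset) -> np.ndarray:
        """Return the sub-matrix of the named features, in dataset column order."""
        wanted = set(names)
        idx = [i for i, n in enumerate(self.feature_names) if n in wanted]
        missing = wanted - {self.feature_names[i] for i in idx}
        if missing:
            raise KeyError(f"unknown features: {sorted(missing)}")
        return self.X[:, idx]

    def frame(self, names: list[str] | set[str] | frozenset | None = None) -> pd.DataFrame:
        """Like :meth:`columns` but as a named DataFrame, so estimators see
        consistent feature names at fit and predict time."""
        if names is None:
            return pd.DataFrame(self.X, columns=self.feature_names)
        wanted = set(names)
        cols = [n for n in self.feature_names if n in wanted]
        missing = wanted - set(cols)
        if missing:
            raise KeyError(f"unknown features: {sorted(missing)}")
        return pd.DataFrame(self.columns(cols), columns=cols)

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df[label_column] = self.y
        return df


@dataclass(frozen=True)
class SplitSpec:
    """Three-way partition specification (train : validation : test)."""

    ratio_train: float = 6.0
    ratio_val: float = 2.0
    ratio_test: float = 2.0
    seed: int = 42
    stratified: bool = True

    def __post_init__(self) -> None:
        for r in (self.ratio_train, self.ratio_val, self.ratio_test):
            if not (np.isfinite(r) and r > 0):
                raise ValueError("split ratios must be positive and finite")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic clinical-table generator.

    Defaults emulate the scale of the study dataset: 2990 samples and 68
    features of which a small informative core drives the outcome, a band of
    redundant features echoes it, and the bulk is pure noise.
    """

    n_samples: int = 2990
    n_informative: int = 8
    n_redundant: int = 10
    n_noise: int = 50
    n_qualitative: int = 32
    effect_size: float = 1.0
    label_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative < 1:
            raise ValueError("need at least one informative feature")
        if not (0.0 < self.label_balance < 1.0):
            raise ValueError("label_balance must be in (0,1)")
        if min(self.n_redundant, self.n_noise, self.n_qualitative) < 0:
            raise ValueError("feature counts must be non-negative")
        if self.n_qualitative > self.n_features:
            raise ValueError("n_qualitative exceeds total feature count")

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise


@dataclass
class PreprocessReport:
    rows_removed_missing: int = 0
    rows_removed_outlier: int = 0
    cells_imputed: int = 0


def load_dataset(path: str | Path, label_column: str = "label") -> Dataset:
    """Read a header-ed CSV into a :class:`Dataset`.

    The label column is removed from the feature matrix; remaining column
    order is preserved.  Integer-valued columns are tagged qualitative,
    others quantitative.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise KeyError(f"label column {label_column!r} not in {list(df.columns)}")
    y = df[label_column].to_numpy()
    bad = set(pd.unique(y[~pd.isna(y)])) - {0, 1}
    if bad or pd.isna(y).any():
        raise ValueError(f"label column must contain only 0/1, found {sorted(map(str, bad))}")
    feats = df.drop(columns=[label_column])
    try:
        X = feats.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric feature cells: {exc}") from exc
    kinds = [
        QUALITATIVE if _is_integer_column(feats[c]) else QUANTITATIVE
        for c in feats.columns
    ]
    return Dataset(list(feats.columns), X, y, kinds)


def _is_integer_column(col: pd.Series) -> bool:
    vals = col.dropna().to_numpy(dtype=float)
    return vals.size > 0 and np.all(vals == np.round(vals))


def save_dataset(d: Dataset, path: str | Path, label_column: str = "label") -> None:
    d.to_frame(label_column).to_csv(path, index=False)


def preprocess(
    d: Dataset,
    max_missing_frac: float = 0.5,
    impute: Literal["median_mode"] = "median_mode",
    outlier_sd: float = 5.0,
) -> tuple[Dataset, PreprocessReport]:
    """Row filtering, imputation and outlier removal for raw clinical tables.

    Three passes, in order: (1) drop rows whose fraction of missing cells
    exceeds ``max_missing_frac``; (2) impute remaining missing cells with the
    column median (quantitative) or mode (qualitative); (3) drop rows holding
    any quantitative cell more than ``outlier_sd`` column standard deviations
    from the column mean.  Outlier removal is iterated to a fixed point so
    the operation is idempotent on its own output.
    """
    if not (0.0 <= max_missing_frac <= 1.0):
        raise ValueError("max_missing_frac must be in [0,1]")
    if not outlier_sd > 0:
        raise ValueError("outlier_sd must be positive")
    if impute != "median_mode":
        raise ValueError(f"unknown imputation strategy {impute!r}")

    report = PreprocessReport()
    X = d.X.copy()
    y = d.y.copy()

    miss_frac = np.isnan(X).mean(axis=1) if X.size else np.zeros(len(y))
    keep = miss_frac <= max_missing_frac
    report.rows_removed_missing = int((~keep).sum())
    X, y = X[keep], y[keep]
    if X.shape[0] == 0:
        raise ValueError("preprocessing removed every row (missing-fraction filter)")

    for j, kind in enumerate(d.feature_kinds):
        col = X[:, j]
        nan = np.isnan(col)
        if not nan.any():
            continue
        if nan.all():
            fill = 0.0
        elif kind == QUANTITATIVE:
            fill = float(np.nanmedian(col))
        else:
            vals, counts = np.unique(col[~nan], return_counts=True)
            fill = float(vals[np.argmax(counts)])
        col[nan] = fill
        report.cells_imputed += int(nan.sum())

    quant = [j for j, k in enumerate(d.feature_kinds) if k == QUANTITATIVE]
    while quant and X.shape[0] > 1:
        sub = X[:, quant]
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0)
        sd[sd == 0] = 1.0
        z = np.abs((sub - mu) / sd)
        bad = (z > outlier_sd).any(axis=1)
        if not bad.any():
            break
        report.rows_removed_outlier += int(bad.sum())
        X, y = X[~bad], y[~bad]
        if X.shape[0] == 0:
            raise ValueError("preprocessing removed every row (outlier filter)")

    out = Dataset(list(d.feature_names), X, y, list(d.feature_kinds), dict(d.provenance))
    return out, report


def split_sizes(n: int, spec: SplitSpec) -> tuple[int, int, int]:
    """Partition sizes: floor for train and validation, remainder to test."""
    total = spec.ratio_train + spec.ratio_val + spec.ratio_test
    n_train = int(np.floor(n * spec.ratio_train / total))
    n_val = int(np.floor(n * spec.ratio_val / total))
    return n_train, n_val, n - n_train - n_val


def _apportion(class_counts: np.ndarray, avail: np.ndarray, total: int, n: int) -> np.ndarray:
    """Largest-remainder allocation of `total` slots across classes.

    Targets proportionality to `class_counts` (so each class lands within one
    sample of its ideal share) while never exceeding `avail`.
    """
    ideal = class_counts * total / n
    alloc = np.minimum(np.floor(ideal).astype(int), avail)
    frac = ideal - np.floor(ideal)
    order = np.lexsort((np.arange(len(frac)), -frac))
    k = 0
    while alloc.sum() < total:
        c = order[k % len(order)]
        if alloc[c] < avail[c]:
            alloc[c] += 1
        k += 1
    return alloc


def split_dataset(d: Dataset, spec: SplitSpec) -> tuple[Dataset, Dataset, Dataset]:
    """Seeded three-way partition of a dataset.

    Sizes follow :func:`split_sizes` exactly.  With ``stratified=True`` each
    partition's class counts stay within one sample of the proportional
    share.  Identical seed gives an identical partition.
    """
    n = d.n_samples
    if n < 3:
        raise ValueError("need at least 3 rows to form 3 partitions")
    n_train, n_val, n_test = split_sizes(n, spec)
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("partition sizes must be non-negative")
    rng = np.random.default_rng(spec.seed)

    if spec.stratified:
        classes, y_idx = np.unique(d.y, return_inverse=True)
        counts = np.bincount(y_idx, minlength=len(classes))
        train_c = _apportion(counts, counts, n_train, n)
        val_c = _apportion(counts, counts - train_c, n_val, n)
        tr, va, te = [], [], []
        for c in range(len(classes)):
            members = np.flatnonzero(y_idx == c)
            members = members[rng.permutation(len(members))]
            a, b = train_c[c], train_c[c] + val_c[c]
            tr.append(members[:a])
            va.append(members[a:b])
            te.append(members[b:])
        idx_tr = np.sort(np.concatenate(tr))
        idx_va = np.sort(np.concatenate(va))
        idx_te = np.sort(np.concatenate(te))
    else:
        perm = rng.permutation(n)
        idx_tr = np.sort(perm[:n_train])
        idx_va = np.sort(perm[n_train : n_train + n_val])
        idx_te = np.sort(perm[n_train + n_val :])

    return d.subset_rows(idx_tr), d.subset_rows(idx_va), d.subset_rows(idx_te)


def save_split_indices(path: str | Path, train: np.ndarray, val: np.ndarray, test: np.ndarray) -> None:
    Path(path).write_text(
        json.dumps(
            {"train": train.tolist(), "val": val.tolist(), "test": test.tolist()},
            sort_keys=True,
        )
    )


def generate_synthetic(spec: SyntheticSpec) -> Dataset:
    """Generate a synthetic clinical-style binary classification table.

    The label is drawn from a logistic model over the informative features'
    latent (continuous, standard normal) values with coefficients of
    magnitude ``effect_size`` and alternating sign; the intercept is
    calibrated on the realized scores so the expected positive fraction
    equals ``label_balance``.  Redundant features are noisy linear copies of
    informative ones; noise features are independent of the label.  A seeded
    subset of columns is discretized (median-thresholded to 0/1) and tagged
    qualitative, mimicking disease-flag indicators.  ``provenance`` records
    each feature's role and the generating probabilities.
    """
    rng = np.random.default_rng(spec.seed)
    n, p_inf, p_red, p_noise = (
        spec.n_samples,
        spec.n_informative,
        spec.n_redundant,
        spec.n_noise,
    )
    p = spec.n_features

    Z_inf = rng.standard_normal((n, p_inf))
    beta = spec.effect_size * np.array([(-1.0) ** k for k in range(p_inf)])
    scores = Z_inf @ beta
    intercept = _calibrate_intercept(scores, spec.label_balance)
    probs = 1.0 / (1.0 + np.exp(-(scores + intercept)))
    y = (rng.random(n) < probs).astype(int)

    X = np.empty((n, p))
    roles = []
    X[:, :p_inf] = Z_inf
    roles += ["informative"] * p_inf
    if p_red:
        src = rng.integers(0, p_inf, size=p_red)
        X[:, p_inf : p_inf + p_red] = Z_inf[:, src] + 0.5 * rng.standard_normal((n, p_red))
        roles += ["redundant"] * p_red
    if p_noise:
        X[:, p_inf + p_red :] = rng.standard_normal((n, p_noise))
        roles += ["noise"] * p_noise

    names = [f"f{j:03d}" for j in range(p)]
    kinds = [QUANTITATIVE] * p
    qual_cols = rng.choice(p, size=spec.n_qualitative, replace=False)
    for j in qual_cols:
        X[:, j] = (X[:, j] > np.median(X[:, j])).astype(float)
        kinds[j] = QUALITATIVE

    provenance = {
        "roles": dict(zip(names, roles)),
        "probs": probs,
        "informative_latents": Z_inf,
        "coefficients": dict(zip(names[:p_inf], beta.tolist())),
        "intercept": float(intercept),
        "spec": dataclasses.asdict(spec),
    }
    return Dataset(names, X, y, kinds, provenance)


def _calibrate_intercept(scores: np.ndarray, balance: float) -> float:
    """Bisect for the intercept b with mean sigmoid(scores + b) == balance."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.mean(1.0 / (1.0 + np.exp(-(scores + mid)))) < balance:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
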