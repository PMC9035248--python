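"""Classifier benchmarking and the full metric set.

The three benchmark algorithms (random forest, 1-nearest-neighbour with
Euclidean distance, AdaBoost) are thin adapters over scikit-learn; the
module's own contract is the split discipline (seeded, stratified k-fold
or hold-out), the leakage rules (balancing and min-max normalization are
fitted on the training part of each fold only) and the metrics.

Metrics follow the standard closed forms:

    ACC = (TP + TN) / (TP + TN + FP + FN)
    SN  = TP / (TP + FN)
    SP  = TN / (TN + FP)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

ROC-AUC is computed as the pairwise-concordance probability (ties count
1/2), which equals the trapezoidal area under the ROC curve; AUPRC is
the area under the precision-recall step curve.  Undefined metrics (zero
denominators, single-class folds) are reported as NaN, never silently
dropped: means are over defined folds with the defined count disclosed.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.neighbors import KNeighborsClassifier

from .feature_extraction import FeatureMatrix
from .sampling_balance import SamplingSpec, balance_indices

__all__ = [
    "ConfusionCounts",
    "confusion",
    "accuracy",
    "sensitivity",
    "specificity",
    "mcc",
    "roc_auc",
    "pr_auc",
    "SplitPlan",
    "make_split_plan",
    "KFOLD_PRESETS",
    "HOLDOUT_PRESETS",
    "ClassifierSpec",
    "MetricsReport",
    "run_benchmark",
    "run_grid",
]

METRIC_NAMES = ("acc", "sn", "sp", "mcc", "auc", "auprc")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN counts with the SNARE class as positive."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


def confusion(labels: Sequence, predictions: Sequence, positive) -> ConfusionCounts:
    """Tally a confusion matrix; ``positive`` names the SNARE class."""
    if len(labels) != len(predictions):
        raise ValueError("labels and predictions must have equal length")
    classes = set(labels) | set(predictions)
    if positive not in classes and labels:
        # a fold may legitimately contain only negatives; still require
        # predictions to use known labels
        classes.add(positive)
    if len(classes) > 2:
        raise ValueError(f"more than two distinct labels: {sorted(map(str, classes))}")
    tp = tn = fp = fn = 0
    for truth, pred in zip(labels, predictions):
        if truth == positive:
            if pred == positive:
                tp += 1
            else:
                fn += 1
        else:
            if pred == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def accuracy(c: ConfusionCounts) -> float:
    """Fraction of correct predictions; NaN on an empty fold."""
    return (c.tp + c.tn) / c.total if c.total else math.nan


def sensitivity(c: ConfusionCounts) -> float:
    """True-positive rate TP/(TP+FN); NaN when no positives were validated."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else math.nan


def specificity(c: ConfusionCounts) -> float:
    """True-negative rate TN/(TN+FP); NaN when no negatives were validated."""
    denom = c.tn + c.fp
    return c.tn / denom if denom else math.nan


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1].

    By convention the value is 0 when any marginal sum is zero (the
    correlation is undefined there; 0 matches the no-information reading).
    """
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def _check_scores(labels, scores, positive):
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape[0] != scores.shape[0]:
        raise ValueError("labels and scores must have equal length")
    pos_mask = labels == positive
    return scores[pos_mask], scores[~pos_mask]


def roc_auc(labels: Sequence, scores: Sequence, positive) -> float:
    """Probability a random positive outscores a random negative (ties 1/2).

    Computed by the rank (Mann-Whitney) formulation; equals the
    trapezoidal area under the ROC curve.  NaN on single-class input.
    """
    pos, neg = _check_scores(labels, scores, positive)
    if len(pos) == 0 or len(neg) == 0:
        return math.nan
    # midranks over the pooled scores
    pooled = np.concatenate([pos, neg])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_scores = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    rank_sum_pos = ranks[: len(pos)].sum()
    u = rank_sum_pos - len(pos) * (len(pos) + 1) / 2
    return u / (len(pos) * len(neg))


def pr_auc(labels: Sequence, scores: Sequence, positive) -> float:
    """Area under the precision-recall step curve across score thresholds.

    Equivalent to average precision: sum over threshold steps of
    (recall increase) x (precision at that threshold).  NaN when no
    positives are present.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape[0] != scores.shape[0]:
        raise ValueError("labels and scores must have equal length")
    n_pos = int((labels == positive).sum())
    if n_pos == 0 or n_pos == len(labels):
        return math.nan
    order = np.argsort(-scores, kind="mergesort")
    y = (labels[order] == positive).astype(float)
    s = scores[order]
    tp = np.cumsum(y)
    predicted = np.arange(1, len(y) + 1)
    # evaluate only at the last index of each tied-score block
    block_end = np.flatnonzero(np.r_[s[1:] != s[:-1], True])
    precision = tp[block_end] / predicted[block_end]
    recall = tp[block_end] / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


@dataclass(frozen=True)
class SplitPlan:
    """A deterministic assignment of record indices to train/validation roles.

    ``folds`` holds (train_indices, validation_indices) pairs: k of them
    for k-fold, one for hold-out.
    """

    kind: str  # kfold | holdout
    param: float  # k, or the validation fraction
    seed: int
    folds: tuple[tuple[np.ndarray, np.ndarray], ...]

    @property
    def n_folds(self) -> int:
        return len(self.folds)


#: The benchmark grid presets: k-fold k in 10..100 step 10, hold-out
#: validation fractions 20%..80% step 10.
KFOLD_PRESETS = tuple(range(10, 101, 10))
HOLDOUT_PRESETS = tuple(f / 100 for f in range(20, 81, 10))


def make_split_plan(labels: Sequence, kind: str, param: float, seed: int = 0) -> SplitPlan:
    """Build a seeded, class-stratified split plan.

    ``kind="kfold"`` uses ``param`` as the fold count k (2 <= k <= n);
    ``kind="holdout"`` uses ``param`` as the validation fraction in
    (0, 1).  Stratification keeps each fold's class ratio near the
    overall ratio, which matters at k close to the record count.
    """
    y = np.asarray(labels)
    n = len(y)
    if kind == "kfold":
        k = int(param)
        if not 2 <= k <= n:
            raise ValueError(f"k must be in [2, {n}], got {param}")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = tuple((tr.copy(), va.copy()) for tr, va in splitter.split(np.zeros(n), y))
        return SplitPlan(kind="kfold", param=k, seed=seed, folds=folds)
    if kind == "holdout":
        frac = float(param)
        if not 0 < frac < 1:
            raise ValueError(f"hold-out fraction must be in (0, 1), got {param}")
        splitter = StratifiedShuffleSplit(n_splits=1, test_size=frac, random_state=seed)
        tr, va = next(splitter.split(np.zeros(n), y))
        return SplitPlan(kind="holdout", param=frac, seed=seed, folds=((tr.copy(), va.copy()),))
    raise ValueError(f"unknown split kind {kind!r}")


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the three benchmark algorithms plus its parameters.

    Defaults mirror the benchmark configuration: random forest with 100
    trees; KNN with k=1 and Euclidean distance; AdaBoost with 10
    iterations (the Weka-style weight threshold of 100 is recorded for
    fidelity but has no scikit-learn counterpart and is unused).
    """

    algorithm: str  # random_forest | knn | adaboost
    parameters: Mapping[str, float] = field(default_factory=dict)

    _DEFAULTS = {
        "random_forest": {"n_trees": 100},
        "knn": {"n_neighbors": 1},
        "adaboost": {"n_iterations": 10, "weight_threshold": 100},
    }
    _ALIASES = {"rf": "random_forest", "ada": "adaboost", "knn": "knn"}

    def __post_init__(self) -> None:
        algo = self._ALIASES.get(self.algorithm, self.algorithm)
        object.__setattr__(self, "algorithm", algo)
        if algo not in self._DEFAULTS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        params = {**self._DEFAULTS[algo], **dict(self.parameters)}
        unknown = set(params) - set(self._DEFAULTS[algo])
        if unknown:
            raise ValueError(f"unknown parameters for {algo}: {sorted(unknown)}")
        object.__setattr__(self, "parameters", params)

    @property
    def normalizes_by_default(self) -> bool:
        # distance-based learners get within-fold min-max normalization
        return self.algorithm == "knn"

    def build(self, seed: int):
        p = self.parameters
        if self.algorithm == "random_forest":
            return RandomForestClassifier(n_estimators=int(p["n_trees"]), random_state=seed)
        if self.algorithm == "knn":
            return KNeighborsClassifier(n_neighbors=int(p["n_neighbors"]), metric="euclidean")
        if self.algorithm == "adaboost":
            return AdaBoostClassifier(n_estimators=int(p["n_iterations"]), random_state=seed)
        raise AssertionError(self.algorithm)


def _min_max_fit(train: np.ndarray):
    lo = train.min(axis=0)
    hi = train.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return lo, span


@dataclass(frozen=True)
class MetricsReport:
    """Per-fold metrics, their means, and the pooled-confusion variant."""

    fold_metrics: pd.DataFrame  # one row per evaluated fold
    means: Mapping[str, float]
    n_defined: Mapping[str, int]
    pooled: Mapping[str, float]
    spec: ClassifierSpec
    plan_kind: str
    plan_param: float
    sampling_mode: str
    seed: int
    skipped_folds: tuple[int, ...] = ()

    def summary(self) -> dict:
        out = {f"mean_{k}": v for k, v in self.means.items()}
        out.update({f"pooled_{k}": v for k, v in self.pooled.items()})
        return out


def _score_positive(model, X: np.ndarray, positive) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        pos_col = list(model.classes_).index(positive)
        return proba[:, pos_col]
    scores = model.decision_function(X)
    # decision_function is oriented toward classes_[1]
    return scores if model.classes_[1] == positive else -scores


def run_benchmark(
    matrix: FeatureMatrix,
    spec: ClassifierSpec,
    plan: SplitPlan,
    sampling: SamplingSpec | None = None,
    normalize: bool | None = None,
    seed: int | None = None,
) -> MetricsReport:
    """Train and validate one classifier under one split plan.

    Per fold: the training part is optionally balanced (``sampling``),
    optionally min-max normalized (fitted on train, applied to
    validation; defaults on for KNN, off for tree learners), the model is
    fitted and the validation part scored.  Folds whose training part
    contains a single class are skipped with a record of the skip.
    Reported metrics are per-fold values, their arithmetic means over the
    defined folds, and the pooled-confusion alternative.
    """
    matrix.validate_binary()
    sampling = sampling or SamplingSpec()
    if normalize is None:
        normalize = spec.normalizes_by_default
    if seed is None:
        seed = plan.seed
    X = matrix.X.to_numpy(dtype=float)
    y = matrix.y.to_numpy()
    positive = matrix.positive_label
    rows = []
    skipped = []
    pooled_counts = ConfusionCounts(0, 0, 0, 0)
    pooled_labels: list = []
    pooled_scores: list[float] = []
    for fold_i, (train_idx, val_idx) in enumerate(plan.folds):
        fold_seed = (seed * 100_003 + fold_i * 7919 + 1) % (2**31 - 1)
        y_train = y[train_idx]
        if len(np.unique(y_train)) < 2:
            skipped.append(fold_i)
            continue
        rng = np.random.default_rng(fold_seed)
        sel = balance_indices(y_train, sampling.mode, rng)
        X_train = X[train_idx][sel]
        y_train = y_train[sel]
        X_val = X[val_idx]
        y_val = y[val_idx]
        if normalize:
            lo, span = _min_max_fit(X_train)
            X_train = (X_train - lo) / span
            X_val = (X_val - lo) / span
        model = spec.build(fold_seed)
        model.fit(X_train, y_train)
        preds = model.predict(X_val)
        scores = _score_positive(model, X_val, positive)
        counts = confusion(y_val, preds, positive)
        pooled_counts = pooled_counts + counts
        pooled_labels.extend(y_val)
        pooled_scores.extend(scores)
        rows.append(
            {
                "fold": fold_i,
                "n_train": len(y_train),
                "n_val": len(y_val),
                "tp": counts.tp,
                "tn": counts.tn,
                "fp": counts.fp,
                "fn": counts.fn,
                "acc": accuracy(counts),
                "sn": sensitivity(counts),
                "sp": specificity(counts),
                "mcc": mcc(counts),
                "auc": roc_auc(y_val, scores, positive),
                "auprc": pr_auc(y_val, scores, positive),
            }
        )
    if not rows:
        raise ValueError("every fold was skipped (single-class training parts)")
    fold_metrics = pd.DataFrame(rows)
    means = {}
    n_defined = {}
    for name in METRIC_NAMES:
        values = fold_metrics[name].to_numpy(dtype=float)
        defined = values[~np.isnan(values)]
        n_defined[name] = int(defined.size)
        means[name] = float(defined.mean()) if defined.size else math.nan
    pooled = {
        "acc": accuracy(pooled_counts),
        "sn": sensitivity(pooled_counts),
        "sp": specificity(pooled_counts),
        "mcc": mcc(pooled_counts),
        "auc": roc_auc(np.array(pooled_labels), np.array(pooled_scores), positive),
        "auprc": pr_auc(np.array(pooled_labels), np.array(pooled_scores), positive),
    }
    return MetricsReport(
        fold_metrics=fold_metrics,
        means=means,
        n_defined=n_defined,
        pooled=pooled,
        spec=spec,
        plan_kind=plan.kind,
        plan_param=plan.param,
        sampling_mode=sampling.mode,
        seed=seed,
        skipped_folds=tuple(skipped),
    )


def run_grid(
    matrices: Mapping[str, FeatureMatrix],
    specs: Sequence[ClassifierSpec],
    plans: Sequence[tuple[str, float]],
    samplings: Sequence[SamplingSpec] = (SamplingSpec(),),
    seed: int = 0,
    checkpoint_path=None,
) -> pd.DataFrame:
    """Evaluate the Cartesian product feature-class x classifier x plan x sampling.

    Returns a long-format table with one row per cell per fold per
    metric.  With ``checkpoint_path`` set, finished cells are appended to
    that CSV as they complete and already-present cells are skipped on
    rerun, making interrupted grids resumable.
    """
    if not matrices or not specs or not plans:
        raise ValueError("grid requires at least one matrix, spec and plan")
    if len(set(matrices)) != len(matrices):
        raise ValueError("duplicate matrix names")
    done_cells: set[str] = set()
    previous: pd.DataFrame | None = None
    if checkpoint_path is not None:
        if os.path.exists(checkpoint_path):
            previous = pd.read_csv(checkpoint_path)
            done_cells = set(previous["cell"].unique())
    frames: list[pd.DataFrame] = [] if previous is None else [previous]
    for feat_name, matrix in matrices.items():
        for spec in specs:
            for kind, param in plans:
                plan = make_split_plan(matrix.y.to_numpy(), kind, param, seed=seed)
                for sampling in samplings:
                    cell = f"{feat_name}|{spec.algorithm}|{kind}:{param}|{sampling.mode}"
                    if cell in done_cells:
                        continue
                    report = run_benchmark(matrix, spec, plan, sampling=sampling, seed=seed)
                    long = report.fold_metrics.melt(
                        id_vars=["fold"],
                        value_vars=list(METRIC_NAMES),
                        var_name="metric",
                        value_name="value",
                    )
                    long.insert(0, "cell", cell)
                    long.insert(1, "feature_class", feat_name)
                    long.insert(2, "algorithm", spec.algorithm)
                    long.insert(3, "plan", f"{kind}:{param}")
                    long.insert(4, "sampling", sampling.mode)
                    frames.append(long)
                    if checkpoint_path is not None:
                        write_header = not os.path.exists(checkpoint_path)
                        long.to_csv(checkpoint_path, mode="a", header=write_header, index=False)
                    done_cells.add(cell)
    return pd.concat(frames, ignore_index=True)
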