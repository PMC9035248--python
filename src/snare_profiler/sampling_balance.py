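"""Class balancing by random oversampling or subsampling.

Plain random duplication (oversample) and random deletion (subsample)
with a fixed seed; no synthetic-minority interpolation.  The same
primitives are reused inside cross-validation folds, where balancing is
applied to the training part only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .feature_extraction import FeatureMatrix

__all__ = ["SamplingSpec", "oversample", "subsample", "balance_indices", "apply_sampling"]


@dataclass(frozen=True)
class SamplingSpec:
    """How (and whether) to balance class sizes before training."""

    mode: str = "none"  # none | oversample | subsample
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "oversample", "subsample"):
            raise ValueError(f"unknown sampling mode {self.mode!r}")


def balance_indices(y: np.ndarray, mode: str, rng: np.random.Generator) -> np.ndarray:
    """Row indices implementing the requested balancing of label array ``y``.

    ``oversample`` keeps every row and appends minority rows drawn with
    replacement until the classes match; ``subsample`` keeps the minority
    intact and draws a majority subset without replacement.  Already
    balanced input returns the identity selection.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"balancing requires exactly two classes, found {len(classes)}")
    if mode == "none" or counts[0] == counts[1]:
        return np.arange(len(y))
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    min_idx = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y == majority)
    if mode == "oversample":
        extra = rng.choice(min_idx, size=len(maj_idx) - len(min_idx), replace=True)
        return np.concatenate([np.arange(len(y)), extra])
    if mode == "subsample":
        kept_maj = rng.choice(maj_idx, size=len(min_idx), replace=False)
        kept = np.concatenate([min_idx, np.sort(kept_maj)])
        return np.sort(kept)
    raise ValueError(f"unknown sampling mode {mode!r}")


def _resample(matrix: FeatureMatrix, mode: str, seed: int) -> FeatureMatrix:
    matrix.validate_binary()
    rng = np.random.default_rng(seed)
    idx = balance_indices(matrix.y.to_numpy(), mode, rng)
    if len(idx) == len(matrix.y) and (idx == np.arange(len(matrix.y))).all():
        return matrix
    X = matrix.X.iloc[idx].copy()
    y = matrix.y.iloc[idx].copy()
    # duplicated rows keep provenance via a #dupN suffix on the id
    ids = list(X.index)
    seen: dict = {}
    new_ids = []
    for rid in ids:
        n = seen.get(rid, 0)
        new_ids.append(rid if n == 0 else f"{rid}#dup{n}")
        seen[rid] = n + 1
    X.index = pd.Index(new_ids, name=X.index.name)
    y.index = X.index
    return FeatureMatrix(X=X, y=y, positive_label=matrix.positive_label)


def oversample(matrix: FeatureMatrix, seed: int = 0) -> FeatureMatrix:
    """Duplicate minority rows (with replacement) until classes match."""
    return _resample(matrix, "oversample", seed)


def subsample(matrix: FeatureMatrix, seed: int = 0) -> FeatureMatrix:
    """Drop a random majority subset until classes match."""
    return _resample(matrix, "subsample", seed)


def apply_sampling(matrix: FeatureMatrix, spec: SamplingSpec) -> FeatureMatrix:
    """Apply a SamplingSpec to a whole matrix (global balancing, pre-split)."""
    if spec.mode == "none":
        return matrix
    return _resample(matrix, spec.mode, spec.seed)
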