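"""Sequence -> feature-vector encoders.

Implements the five feature classes used by the SNARE classification
benchmark — grouped amino-acid composition (GAAC), CTD transition
features (CTDT), k-spaced amino-acid pair composition (CKSAAP), the
classic 188-dimensional composition/transition/distribution vector
(188D), and the 24-descriptor SNARER panel means — plus the ``.ext``
concatenations of each base class with the SNARER features.

All encoders operate on sanitized sequences over the 20-letter canonical
alphabet and are pure functions: the same sequence always yields the
same vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .descriptor_tables import (
    ALPHABET,
    ALPHABET_SET,
    CTD_SCHEMES,
    GAAC5,
    DescriptorPanel,
    GroupingScheme,
    get_grouping,
    load_snarer_panel,
)

__all__ = [
    "ProteinRecord",
    "SanitizedSequence",
    "FeatureVector",
    "FeatureMatrix",
    "InvalidSequenceError",
    "sanitize",
    "extract_gaac",
    "extract_cksaap",
    "extract_ctdt",
    "extract_188d",
    "extract_snarer",
    "extend_features",
    "build_matrix",
    "FEATURE_METHODS",
]


class InvalidSequenceError(ValueError):
    """Raised when a sequence is empty or unusable after sanitization."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified protein sequence."""

    id: str
    sequence: str
    description: str = ""


class SanitizedSequence(NamedTuple):
    sequence: str
    n_removed: int


def sanitize(seq: str, policy: str = "drop") -> SanitizedSequence:
    """Uppercase a raw sequence and handle non-canonical symbols.

    Parameters
    ----------
    seq
        Raw sequence, possibly lowercase and containing ambiguity codes
        (X, B, Z, U, O) or formatting characters.
    policy
        ``"drop"`` removes non-canonical symbols; ``"reject"`` raises on
        the first one.

    Returns
    -------
    SanitizedSequence
        The cleaned sequence and the number of removed symbols.
    """
    if policy not in ("drop", "reject"):
        raise ValueError(f"unknown sanitize policy {policy!r}")
    if not seq:
        raise InvalidSequenceError("empty sequence")
    upper = seq.upper()
    kept = [c for c in upper if c in ALPHABET_SET]
    removed = len(upper) - len(kept)
    if policy == "reject" and removed:
        bad = sorted({c for c in upper if c not in ALPHABET_SET})
        raise InvalidSequenceError(f"non-canonical symbols {bad} (policy=reject)")
    if not kept:
        raise InvalidSequenceError("sequence empty after removing non-canonical symbols")
    return SanitizedSequence("".join(kept), removed)


@dataclass(frozen=True)
class FeatureVector:
    """Named, ordered real-valued features for one sequence."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if len(self.names) != values.shape[0]:
            raise ValueError("names and values must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature values must be finite")

    def __len__(self) -> int:
        return len(self.names)


_RES_INDEX = {r: i for i, r in enumerate(ALPHABET)}


def extract_gaac(seq: str) -> FeatureVector:
    """Grouped amino-acid composition: frequencies of the 5 GAAC groups.

    Feature order is fixed (positive, negative, aromatic, aliphatic,
    uncharged) and the five frequencies sum to 1.
    """
    if not seq:
        raise InvalidSequenceError("empty sequence")
    idx = GAAC5.class_index()
    counts = np.zeros(len(GAAC5.labels))
    for c in seq:
        counts[idx[c]] += 1
    return FeatureVector(
        names=tuple(f"gaac.{label}" for label in GAAC5.labels),
        values=counts / len(seq),
    )


def _pair_names(k: int) -> list[str]:
    return [f"cksaap.k{k}.{a}{b}" for a in ALPHABET for b in ALPHABET]


def extract_cksaap(seq: str, kmax: int = 5, normalize: bool = True) -> FeatureVector:
    """Composition of k-spaced amino-acid pairs for k = 0..kmax.

    For each spacing k the 400 ordered residue pairs are counted over all
    positions i with ``seq[i] = a`` and ``seq[i + k + 1] = b``; with
    ``normalize=True`` (default) each count is divided by the number of
    k-spaced windows, ``L - k - 1``.  Blocks are concatenated in
    increasing k, pairs in row-major alphabet order, giving
    ``400 * (kmax + 1)`` features (2400 at the default kmax=5).
    Sequences too short for a spacing get an all-zero block.
    """
    if not seq:
        raise InvalidSequenceError("empty sequence")
    if kmax < 0:
        raise ValueError("kmax must be >= 0")
    L = len(seq)
    codes = np.fromiter((_RES_INDEX[c] for c in seq), dtype=np.intp, count=L)
    names: list[str] = []
    blocks: list[np.ndarray] = []
    for k in range(kmax + 1):
        counts = np.zeros(400)
        windows = L - k - 1
        if windows > 0:
            pair_ids = codes[: L - k - 1] * 20 + codes[k + 1 :]
            np.add.at(counts, pair_ids, 1.0)
            if normalize:
                counts /= windows
        names.extend(_pair_names(k))
        blocks.append(counts)
    return FeatureVector(names=tuple(names), values=np.concatenate(blocks))


_TRANSITION_PAIRS = ((0, 1), (0, 2), (1, 2))


def _transition_frequencies(class_codes: Sequence[int], L: int) -> np.ndarray:
    freqs = np.zeros(3)
    for i in range(L - 1):
        a, b = class_codes[i], class_codes[i + 1]
        if a == b:
            continue
        pair = (min(a, b), max(a, b))
        freqs[_TRANSITION_PAIRS.index(pair)] += 1
    return freqs / (L - 1)


def extract_ctdt(
    seq: str, partitions: Sequence[GroupingScheme] | None = None
) -> FeatureVector:
    """CTD transition features under three-class property partitions.

    For each partition the sequence is mapped to its class string and the
    frequency of adjacent unordered class changes {1,2}, {1,3}, {2,3} is
    computed over the ``L - 1`` adjacent pairs.  The default partition
    list is the seven classic CTD properties, giving 21 features.
    """
    if partitions is None:
        partitions = [s for s in CTD_SCHEMES if s.name != "ctd_surface_tension"]
    if len(seq) < 2:
        raise InvalidSequenceError("CTDT needs sequence length >= 2")
    names: list[str] = []
    out: list[np.ndarray] = []
    for scheme in partitions:
        if len(scheme.labels) != 3:
            raise ValueError(
                f"CTDT partition {scheme.name!r} must have exactly 3 classes, "
                f"found {len(scheme.labels)}"
            )
        idx = scheme.class_index()
        codes = [idx[c] for c in seq]
        out.append(_transition_frequencies(codes, len(seq)))
        labels = scheme.labels
        names.extend(
            f"ctdt.{scheme.name}.{labels[a]}-{labels[b]}" for a, b in _TRANSITION_PAIRS
        )
    return FeatureVector(names=tuple(names), values=np.concatenate(out))


# The 8 properties of the 188D encoding, in fixed order.  The first four
# are the ones conventionally named for this feature class; the list is
# completed with the remaining classic CTD properties.
D188_PROPERTIES = (
    "ctd_hydrophobicity",
    "ctd_vdw_volume",
    "ctd_polarity",
    "ctd_polarizability",
    "ctd_charge",
    "ctd_surface_tension",
    "ctd_secondary_structure",
    "ctd_solvent_accessibility",
)


def _distribution_positions(positions: Sequence[int], L: int) -> list[float]:
    """First / 25% / 50% / 75% / 100% occurrence positions divided by L.

    ``positions`` are the 1-based indices where a class occurs; the p-th
    percentile is taken as the ceil(p * n)-th occurrence.  Absent classes
    yield five zeros.
    """
    if not positions:
        return [0.0] * 5
    n = len(positions)
    out = [positions[0] / L]
    for p in (0.25, 0.50, 0.75, 1.00):
        out.append(positions[math.ceil(p * n) - 1] / L)
    return out


def extract_188d(seq: str) -> FeatureVector:
    """The classic 188-dimensional composition/transition/distribution vector.

    Features 1-20 are the residue frequencies in alphabet order.  For each
    of 8 three-class physicochemical properties, 21 further features are
    extracted: 3 class compositions, 3 transition frequencies and 15
    distribution features (per class, the relative sequence positions of
    its first, 25%, 50%, 75% and 100% occurrence).
    """
    if len(seq) < 2:
        raise InvalidSequenceError("188D needs sequence length >= 2")
    L = len(seq)
    counts = np.zeros(20)
    for c in seq:
        counts[_RES_INDEX[c]] += 1
    names = [f"188d.freq.{r}" for r in ALPHABET]
    values: list[float] = list(counts / L)
    for prop in D188_PROPERTIES:
        scheme = get_grouping(prop)
        idx = scheme.class_index()
        codes = [idx[c] for c in seq]
        class_positions: list[list[int]] = [[], [], []]
        for pos, code in enumerate(codes, start=1):
            class_positions[code].append(pos)
        labels = scheme.labels
        # composition
        for ci, label in enumerate(labels):
            names.append(f"188d.{prop}.comp.{label}")
            values.append(len(class_positions[ci]) / L)
        # transition
        trans = _transition_frequencies(codes, L)
        names.extend(
            f"188d.{prop}.trans.{labels[a]}-{labels[b]}" for a, b in _TRANSITION_PAIRS
        )
        values.extend(trans)
        # distribution
        for ci, label in enumerate(labels):
            dist = _distribution_positions(class_positions[ci], L)
            names.extend(
                f"188d.{prop}.dist.{label}.p{tag}" for tag in ("first", "25", "50", "75", "100")
            )
            values.extend(dist)
    return FeatureVector(names=tuple(names), values=np.array(values))


def extract_snarer(seq: str, panel: DescriptorPanel | None = None) -> FeatureVector:
    """SNARER descriptor means: one feature per panel entry.

    Each feature is the arithmetic mean over the residues of the entry's
    per-residue scale, so the encoding is length-invariant and
    order-invariant.  Feature order follows the panel.
    """
    if panel is None:
        panel = load_snarer_panel()
    if not seq:
        raise InvalidSequenceError("empty sequence")
    counts = np.zeros(20)
    for c in seq:
        counts[_RES_INDEX[c]] += 1
    freqs = counts / len(seq)
    table = np.array([entry.as_array() for entry in panel.entries])
    return FeatureVector(
        names=tuple(f"snarer.{e.code}" for e in panel.entries),
        values=table @ freqs,
    )


def extend_features(base: FeatureVector, extra: FeatureVector) -> FeatureVector:
    """Concatenate two feature vectors, preserving order.

    Name collisions are resolved by prefixing the colliding names of the
    second vector with ``ext.``.
    """
    if len(extra) == 0:
        return base
    taken = set(base.names)
    extra_names = tuple(
        f"ext.{n}" if n in taken else n for n in extra.names
    )
    return FeatureVector(
        names=base.names + extra_names,
        values=np.concatenate([base.values, extra.values]),
    )


def _method_registry() -> dict:
    base = {
        "gaac": lambda seq, panel: extract_gaac(seq),
        "ctdt": lambda seq, panel: extract_ctdt(seq),
        "cksaap": lambda seq, panel: extract_cksaap(seq),
        "188d": lambda seq, panel: extract_188d(seq),
        "snarer": lambda seq, panel: extract_snarer(seq, panel),
    }
    methods = dict(base)
    for name, fn in base.items():
        if name == "snarer":
            continue
        methods[f"{name}.ext"] = (
            lambda seq, panel, _fn=fn: extend_features(
                _fn(seq, panel), extract_snarer(seq, panel)
            )
        )
    return methods


#: method name -> extractor(seq, panel) for every supported feature class.
FEATURE_METHODS = _method_registry()


@dataclass
class FeatureMatrix:
    """A records × features table with binary labels."""

    X: pd.DataFrame
    y: pd.Series
    positive_label: str = "SNARE"

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise ValueError("feature table and labels must share the same index")
        if self.X.index.has_duplicates:
            raise ValueError("duplicate record ids in feature matrix")

    @property
    def record_ids(self) -> list:
        return list(self.X.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def class_counts(self) -> dict:
        return self.y.value_counts().to_dict()

    def validate_binary(self) -> None:
        labels = set(self.y.unique())
        if len(labels) != 2:
            raise ValueError(f"expected exactly two classes, found {sorted(map(str, labels))}")
        if self.positive_label not in labels:
            raise ValueError(
                f"positive label {self.positive_label!r} absent from labels {sorted(map(str, labels))}"
            )

    def to_csv(self, path, sep: str = ",") -> None:
        frame = self.X.copy()
        frame.insert(0, "label", self.y)
        frame.to_csv(path, sep=sep, index_label="id")

    @classmethod
    def from_csv(cls, path, sep: str = ",", positive_label: str = "SNARE") -> "FeatureMatrix":
        frame = pd.read_csv(path, sep=sep, index_col="id")
        if "label" not in frame.columns:
            raise ValueError("feature CSV must contain a 'label' column")
        y = frame["label"]
        X = frame.drop(columns=["label"])
        return cls(X=X, y=y, positive_label=positive_label)


def build_matrix(
    records: Sequence[ProteinRecord],
    labels: Sequence,
    method: str,
    panel: DescriptorPanel | None = None,
    positive_label: str = "SNARE",
    sanitize_policy: str = "drop",
) -> FeatureMatrix:
    """Encode labeled records into a feature matrix.

    ``method`` is one of the registered feature classes (``gaac``,
    ``ctdt``, ``cksaap``, ``188d``, ``snarer``) or a ``.ext`` variant.
    Row order equals input order; record ids must be unique and each
    class must be non-empty.
    """
    if method not in FEATURE_METHODS:
        raise ValueError(
            f"unknown feature method {method!r}; available: {sorted(FEATURE_METHODS)}"
        )
    if len(records) != len(labels):
        raise ValueError("records and labels must have equal length")
    if not records:
        raise ValueError("no records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate record ids: {dupes}")
    label_set = set(labels)
    if len(label_set) != 2:
        raise ValueError(
            f"need records from exactly two classes, found {sorted(map(str, label_set))}"
        )
    if panel is None and (method == "snarer" or method.endswith(".ext")):
        panel = load_snarer_panel()
    extractor = FEATURE_METHODS[method]
    rows = []
    names: tuple[str, ...] | None = None
    for record in records:
        clean, _ = sanitize(record.sequence, policy=sanitize_policy)
        vec = extractor(clean, panel)
        if names is None:
            names = vec.names
        elif vec.names != names:
            raise ValueError(f"inconsistent feature names for record {record.id!r}")
        rows.append(vec.values)
    X = pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="id"), columns=list(names))
    y = pd.Series(list(labels), index=X.index, name="label")
    matrix = FeatureMatrix(X=X, y=y, positive_label=positive_label)
    matrix.validate_binary()
    return matrix
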