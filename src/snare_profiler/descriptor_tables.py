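"""Static descriptor panels and amino-acid grouping schemes.

This module vendors the SNARER panel — 24 per-residue physicochemical
scales (17 AAindex accessions plus the seven Fauchère amino-acid
parameter sets) — and the named partitions of the 20-residue alphabet
used by the grouped-composition (GAAC) and composition/transition/
distribution (CTD) encoders.  Everything here is validated static data:
panels must carry one finite value per canonical residue, and grouping
schemes must partition the alphabet exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

#: The 20 canonical residues in fixed lexicographic order.  This order is
#: load-bearing: it fixes CKSAAP pair enumeration and panel column order.
ALPHABET: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

ALPHABET_SET = frozenset(ALPHABET)

#: Symbols that may appear in real-world FASTA but are not canonical
#: residues (ambiguity codes and the rare translated selenocysteine /
#: pyrrolysine).
NONSTANDARD_SYMBOLS = frozenset("XBZUO")


class PanelError(ValueError):
    """Raised when vendored or user-supplied descriptor data is invalid."""


@dataclass(frozen=True)
class DescriptorEntry:
    """One named per-residue property scale.

    Parameters
    ----------
    code
        Short identifier, e.g. an AAindex accession (``EISD860101``) or a
        Fauchère parameter name.
    description
        Human-readable property name.
    source
        Either ``"AAindex"`` or ``"Fauchere"``.
    values
        Mapping residue -> value with exactly one finite entry per
        canonical residue.
    """

    code: str
    description: str
    source: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = ALPHABET_SET - set(self.values)
        extra = set(self.values) - ALPHABET_SET
        if missing or extra:
            raise PanelError(
                f"descriptor {self.code!r}: values must cover the 20 canonical "
                f"residues exactly (missing={sorted(missing)}, extra={sorted(extra)})"
            )
        for residue, value in self.values.items():
            if not math.isfinite(value):
                raise PanelError(
                    f"descriptor {self.code!r}: non-finite value for residue {residue!r}"
                )
        if self.source not in ("AAindex", "Fauchere"):
            raise PanelError(
                f"descriptor {self.code!r}: unknown source {self.source!r}"
            )

    def as_array(self) -> tuple[float, ...]:
        """Values in fixed alphabet order."""
        return tuple(self.values[r] for r in ALPHABET)


@dataclass(frozen=True)
class DescriptorPanel:
    """An ordered, validated collection of descriptor entries."""

    name: str
    entries: tuple[DescriptorEntry, ...]

    def __post_init__(self) -> None:
        codes = [e.code for e in self.entries]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise PanelError(f"panel {self.name!r}: duplicate codes {dupes}")
        if not self.entries:
            raise PanelError(f"panel {self.name!r}: empty panel")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(e.code for e in self.entries)

    def to_tsv(self, path) -> None:
        """Re-export the panel in the documented tabular format."""
        with open(path, "w") as handle:
            handle.write("code\tsource\tdescription\t" + "\t".join(ALPHABET) + "\n")
            for entry in self.entries:
                row = [entry.code, entry.source, entry.description]
                row += [repr(v) for v in entry.as_array()]
                handle.write("\t".join(row) + "\n")


@dataclass(frozen=True)
class GroupingScheme:
    """A named partition of the residue alphabet into labelled classes.

    ``classes`` preserves insertion order; that order defines the class
    indices used by transition features.
    """

    name: str
    classes: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        union: set[str] = set()
        total = 0
        for label, members in self.classes.items():
            members = frozenset(members)
            if not members <= ALPHABET_SET:
                raise PanelError(
                    f"grouping {self.name!r}: class {label!r} contains "
                    f"non-canonical symbols {sorted(members - ALPHABET_SET)}"
                )
            if union & members:
                raise PanelError(
                    f"grouping {self.name!r}: class {label!r} overlaps a previous class"
                )
            union |= members
            total += len(members)
        if union != ALPHABET_SET or total != len(ALPHABET):
            raise PanelError(
                f"grouping {self.name!r}: classes do not partition the alphabet "
                f"(covered {total} residues)"
            )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.classes)

    def class_index(self) -> dict[str, int]:
        """Residue -> 0-based class index, in class declaration order."""
        index: dict[str, int] = {}
        for i, members in enumerate(self.classes.values()):
            for residue in members:
                index[residue] = i
        return index


def _scheme(name: str, *pairs: tuple[str, str]) -> GroupingScheme:
    return GroupingScheme(
        name=name,
        classes={label: frozenset(members) for label, members in pairs},
    )


#: GAAC's five physicochemical groups, in fixed feature order.
GAAC5 = _scheme(
    "gaac5",
    ("positive", "KRH"),
    ("negative", "DE"),
    ("aromatic", "FYW"),
    ("aliphatic", "AGILMV"),
    ("uncharged", "CNPQST"),
)

# Classic three-class CTD property partitions (Dubchak-style, as used by
# the common CTD feature extractors).
CTD_SCHEMES = (
    _scheme(
        "ctd_hydrophobicity",
        ("polar", "RKEDQN"),
        ("neutral", "GASTPHY"),
        ("hydrophobic", "CLVIMFW"),
    ),
    _scheme(
        "ctd_vdw_volume",
        ("small", "GASTPDC"),
        ("medium", "NVEQIL"),
        ("large", "MHKFRYW"),
    ),
    _scheme(
        "ctd_polarity",
        ("low", "LIFWCMVY"),
        ("medium", "PATGS"),
        ("high", "HQRKNED"),
    ),
    _scheme(
        "ctd_polarizability",
        ("low", "GASDT"),
        ("medium", "CPNVEQIL"),
        ("high", "KMHFRYW"),
    ),
    _scheme(
        "ctd_charge",
        ("positive", "KR"),
        ("neutral", "ANCQGHILMFPSTWYV"),
        ("negative", "DE"),
    ),
    _scheme(
        "ctd_secondary_structure",
        ("helix", "EALMQKRH"),
        ("strand", "VIYCWFT"),
        ("coil", "GNPSD"),
    ),
    _scheme(
        "ctd_solvent_accessibility",
        ("buried", "ALFCGIVW"),
        ("exposed", "RKQEND"),
        ("intermediate", "MPSTHY"),
    ),
    _scheme(
        "ctd_surface_tension",
        ("high", "GQDNAHR"),
        ("medium", "KTSEC"),
        ("low", "ILMFPWYV"),
    ),
)

_GROUPINGS: dict[str, GroupingScheme] = {GAAC5.name: GAAC5}
_GROUPINGS.update({s.name: s for s in CTD_SCHEMES})


def registered_groupings() -> tuple[str, ...]:
    """Names of all built-in grouping schemes."""
    return tuple(_GROUPINGS)


def get_grouping(name: str) -> GroupingScheme:
    """Look up a registered grouping scheme by name.

    Raises
    ------
    KeyError
        If ``name`` is not registered; the message lists valid names.
    """
    try:
        return _GROUPINGS[name]
    except KeyError:
        raise KeyError(
            f"unknown grouping scheme {name!r}; registered: {sorted(_GROUPINGS)}"
        ) from None


def _parse_panel_tsv(lines: Iterable[str], name: str) -> DescriptorPanel:
    entries: list[DescriptorEntry] = []
    header: list[str] | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            expected = ["code", "source", "description", *ALPHABET]
            if header != expected:
                raise PanelError(
                    f"panel {name!r}: bad header at line {lineno}; expected {expected}"
                )
            continue
        if len(fields) != 3 + len(ALPHABET):
            raise PanelError(
                f"panel {name!r}: line {lineno} has {len(fields)} fields, "
                f"expected {3 + len(ALPHABET)}"
            )
        code, source, description = fields[:3]
        try:
            values = {r: float(v) for r, v in zip(ALPHABET, fields[3:])}
        except ValueError as exc:
            raise PanelError(
                f"panel {name!r}: non-numeric value for entry {code!r} "
                f"(line {lineno}): {exc}"
            ) from None
        entries.append(
            DescriptorEntry(code=code, description=description, source=source, values=values)
        )
    if header is None:
        raise PanelError(f"panel {name!r}: empty panel file")
    return DescriptorPanel(name=name, entries=tuple(entries))


def load_panel(path, name: str | None = None) -> DescriptorPanel:
    """Load a descriptor panel from a TSV file in the documented format.

    The format is one header row (``code  source  description`` followed by
    the 20 residue columns in alphabet order) and one row per descriptor;
    ``#`` lines are comments.
    """
    with open(path) as handle:
        return _parse_panel_tsv(handle, name or str(path))


def load_snarer_panel() -> DescriptorPanel:
    """Load the vendored 24-entry SNARER descriptor panel.

    The panel combines 17 AAindex scales chosen for helix propensity,
    solvent accessibility, charge and energetic properties with the seven
    Fauchère amino-acid parameter sets.  Loading validates every entry
    (20 finite values each) and the fixed panel size.
    """
    ref = resources.files("snare_profiler.data").joinpath("snarer_panel.tsv")
    with ref.open() as handle:
        panel = _parse_panel_tsv(handle, name="snarer")
    if len(panel) != 24:
        raise PanelError(
            f"vendored SNARER panel must have 24 entries, found {len(panel)}"
        )
    return panel
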