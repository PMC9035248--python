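"""Synthetic protein corpora with an injectable two-class signal.

The generator draws i.i.d. sequences over the 20-letter alphabet.  The
positive class can be enriched for a chosen residue set: a total
probability mass ``delta`` is added to the enriched residues (split
equally among them) and the remaining residues are scaled down so the
composition renormalizes.  The default enriched set is {Q, R} — an echo
of the conserved glutamine/arginine zero-layer of SNARE bundles — so the
signal is visible to composition-derived feature classes.  A motif mode
instead plants a fixed substring in positive sequences, which k-spaced
pair features can detect even when composition differences are small.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .descriptor_tables import ALPHABET
from .feature_extraction import ProteinRecord

__all__ = ["CorpusSpec", "enriched_composition", "random_corpus", "imbalanced_corpus"]


def _uniform_composition() -> dict[str, float]:
    return {r: 1.0 / len(ALPHABET) for r in ALPHABET}


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of a synthetic two-class corpus.

    Defaults emulate a small balanced SNARE-vs-background design: 64
    sequences per class, lengths uniform on [60, 200] (the scale of
    SNARE-motif-bearing proteins), uniform background composition, and a
    Q/R enrichment of total mass ``delta`` in the positive class.
    ``delta=0`` gives a null corpus (both classes identically
    distributed).  ``motif`` optionally plants a substring at a random
    position in every positive sequence instead of shifting composition.
    """

    n_pos: int = 64
    n_neg: int = 64
    length: tuple[int, int] = (60, 200)
    composition: dict[str, float] | None = None
    enriched: tuple[str, ...] = ("Q", "R")
    delta: float = 0.15
    motif: str | None = None
    seed: int = 0

    def base_composition(self) -> dict[str, float]:
        comp = self.composition or _uniform_composition()
        if set(comp) != set(ALPHABET):
            raise ValueError("composition must assign a probability to each of the 20 residues")
        total = sum(comp.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition probabilities must sum to 1 (got {total})")
        if any(p < 0 for p in comp.values()):
            raise ValueError("composition probabilities must be non-negative")
        return dict(comp)

    def positive_composition(self) -> dict[str, float]:
        if self.motif is not None:
            return self.base_composition()
        return enriched_composition(self.base_composition(), self.enriched, self.delta)


def enriched_composition(
    base: dict[str, float], enriched: tuple[str, ...], delta: float
) -> dict[str, float]:
    """Shift total mass ``delta`` onto ``enriched`` residues, renormalized.

    Each enriched residue gains ``delta / len(enriched)``; the remaining
    residues are scaled by a common factor so probabilities sum to 1.
    ``delta`` must leave every probability inside [0, 1].
    """
    if delta == 0:
        return dict(base)
    if not enriched:
        raise ValueError("enriched residue set is empty")
    if not set(enriched) <= set(ALPHABET):
        raise ValueError(f"enriched residues must be canonical: {sorted(set(enriched) - set(ALPHABET))}")
    if not 0 < delta < 1:
        raise ValueError(f"delta must be in (0, 1), got {delta}")
    other_mass = sum(p for r, p in base.items() if r not in enriched)
    if other_mass <= delta:
        raise ValueError("delta too large: non-enriched residues cannot absorb it")
    scale = (other_mass - delta) / other_mass
    share = delta / len(enriched)
    comp = {}
    for r, p in base.items():
        comp[r] = p + share if r in enriched else p * scale
    if any(not 0 <= p <= 1 for p in comp.values()):
        raise ValueError("delta pushes a probability outside [0, 1]")
    return comp


def _draw_sequences(
    rng: np.random.Generator,
    n: int,
    length: tuple[int, int],
    composition: dict[str, float],
) -> list[str]:
    lo, hi = length
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid length range {length}")
    residues = np.array(list(ALPHABET))
    probs = np.array([composition[r] for r in ALPHABET])
    probs = probs / probs.sum()
    out = []
    for _ in range(n):
        L = int(rng.integers(lo, hi + 1))
        out.append("".join(rng.choice(residues, size=L, p=probs)))
    return out


def random_corpus(spec: CorpusSpec):
    """Draw a labeled two-class corpus.

    Returns ``(records, labels)`` with positives first; deterministic
    under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    pos_seqs = _draw_sequences(rng, spec.n_pos, spec.length, spec.positive_composition())
    if spec.motif is not None:
        pos_seqs = [_plant_motif(rng, s, spec.motif) for s in pos_seqs]
    neg_seqs = _draw_sequences(rng, spec.n_neg, spec.length, spec.base_composition())
    records = [
        ProteinRecord(id=f"pos{i:04d}", sequence=s, description=f"pos{i:04d} synthetic positive")
        for i, s in enumerate(pos_seqs)
    ] + [
        ProteinRecord(id=f"neg{i:04d}", sequence=s, description=f"neg{i:04d} synthetic negative")
        for i, s in enumerate(neg_seqs)
    ]
    labels = ["SNARE"] * spec.n_pos + ["NON_SNARE"] * spec.n_neg
    return records, labels


def _plant_motif(rng: np.random.Generator, seq: str, motif: str) -> str:
    if len(motif) >= len(seq):
        return motif[: len(seq)]
    start = int(rng.integers(0, len(seq) - len(motif) + 1))
    return seq[:start] + motif + seq[start + len(motif) :]


def imbalanced_corpus(spec: CorpusSpec, ratio: float):
    """A corpus with ``ratio`` times more negatives than positives.

    Useful for exercising the balancing filters at the ~2.9:1 imbalance
    of a realistic unbalanced design.
    """
    if ratio <= 1:
        raise ValueError(f"ratio must exceed 1, got {ratio}")
    n_neg = int(round(spec.n_pos * ratio))
    return random_corpus(replace(spec, n_neg=n_neg))
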