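"""Base composition, AT/GC content, and strand skews.

AT skew = (A - T) / (A + T) and GC skew = (G - C) / (G + C), computed on the
majority strand for whole genomes and on the coding strand for gene
partitions. Skews are scale-invariant: counts and percentages give the same
value. Reported percentages use 1 decimal place and skews 3, rounding half
away from zero, matching the usual presentation of these statistics; full
precision is kept internally.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

from .model import CircularGenome, extract_region

__all__ = [
    "CompositionProfile",
    "at_skew",
    "gc_skew",
    "composition_profile",
    "partition_profiles",
    "round_half_away",
    "UndefinedSkewError",
]


class UndefinedSkewError(ZeroDivisionError):
    """Skew requested for a base pair with zero total."""


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (Python's round() rounds half-to-even)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def at_skew(a: float, t: float) -> float:
    """(A - T) / (A + T); accepts counts, proportions or percentages."""
    if a + t <= 0:
        raise UndefinedSkewError("A + T is zero; AT skew undefined")
    return (a - t) / (a + t)


def gc_skew(g: float, c: float) -> float:
    """(G - C) / (G + C); accepts counts, proportions or percentages."""
    if g + c <= 0:
        raise UndefinedSkewError("G + C is zero; GC skew undefined")
    return (g - c) / (g + c)


@dataclass
class CompositionProfile:
    """Base counts and derived composition statistics for one sequence
    partition. Ambiguity codes are tallied in ``other`` and excluded from
    percentages and skews."""

    counts: dict[str, int]
    other: int = 0

    @classmethod
    def from_sequence(cls, seq: str) -> "CompositionProfile":
        if not seq:
            raise ValueError("empty sequence")
        tally = Counter(seq.upper())
        counts = {b: tally.pop(b, 0) for b in "ACGT"}
        return cls(counts=counts, other=sum(tally.values()))

    def __add__(self, o: "CompositionProfile") -> "CompositionProfile":
        return CompositionProfile(
            counts={b: self.counts[b] + o.counts[b] for b in "ACGT"},
            other=self.other + o.other,
        )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def pct(self, base: str) -> float:
        return 100.0 * self.counts[base] / self.total

    @property
    def at_content(self) -> float:
        return self.pct("A") + self.pct("T")

    @property
    def gc_content(self) -> float:
        return self.pct("G") + self.pct("C")

    @property
    def at_skew(self) -> float:
        return at_skew(self.counts["A"], self.counts["T"])

    @property
    def gc_skew(self) -> float:
        return gc_skew(self.counts["G"], self.counts["C"])

    def as_row(self) -> dict[str, float]:
        """Rounded presentation row (percentages 1 dp, skews 3 dp)."""
        return {
            "n": self.total,
            "pct_a": round_half_away(self.pct("A"), 1),
            "pct_g": round_half_away(self.pct("G"), 1),
            "pct_t": round_half_away(self.pct("T"), 1),
            "pct_c": round_half_away(self.pct("C"), 1),
            "pct_at": round_half_away(self.at_content, 1),
            "at_skew": round_half_away(self.at_skew, 3),
            "gc_skew": round_half_away(self.gc_skew, 3),
        }


def composition_profile(seq: str) -> CompositionProfile:
    """Exact base counts and composition statistics of a nucleotide string."""
    return CompositionProfile.from_sequence(seq)


def partition_profiles(
    genome: CircularGenome, include_whole: bool = True
) -> dict[str, CompositionProfile]:
    """Composition per feature category (PCG, tRNA, rRNA, CR) computed over
    the concatenated coding-strand sequences, plus the whole majority strand.

    Bases inside overlapping features are counted once per feature (each
    gene is profiled over its own full extent), not once per genome.
    """
    out: dict[str, CompositionProfile] = {}
    if genome.sequence is None:
        raise ValueError(f"{genome.identifier}: no sequence attached")
    for feat in genome.features:
        if feat.category is None:
            continue
        prof = CompositionProfile.from_sequence(extract_region(genome, feat))
        out[feat.category] = out[feat.category] + prof if feat.category in out else prof
    if include_whole:
        out["genome"] = CompositionProfile.from_sequence(genome.sequence)
    return out
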