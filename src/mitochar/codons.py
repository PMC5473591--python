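"""Codon usage under the invertebrate mitochondrial genetic code.

CDS extraction with incomplete-stop handling, start/stop classification,
codon counting, relative synonymous codon usage (RSCU) and amino-acid
composition. Under translation table 5 (invertebrate mitochondrial),
AGA/AGG encode Ser (an 8-codon serine family UCN+AGN), AUA encodes Met and
UGA encodes Trp; UAA/UAG form the stop family.

RSCU of codon c in a synonymous family of size k with counts n_i is
``rscu(c) = n_c * k / sum(n_i)`` — 1 for unbiased usage. Inputs are DNA;
reports use the RNA alphabet.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from Bio.Data import CodonTable

from .model import CircularGenome, GeneFeature, extract_region

__all__ = [
    "GeneticCode",
    "Cds",
    "CodonCountTable",
    "IncompleteCdsError",
    "extract_cds",
    "classify_start_stop",
    "count_codons",
    "rscu",
    "translate",
    "Protein",
    "aa_composition",
]

_BASES = "TCAG"
_ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


class IncompleteCdsError(ValueError):
    """CDS length is not reducible to whole codons by stop completion."""


@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry codon -> amino acid map with a start-codon set.

    Stop codons map to ``'*'``. Codons are DNA triplets internally.
    """

    name: str
    table: Mapping[str, str]
    starts: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"genetic code needs 64 codons, got {len(self.table)}")

    @classmethod
    def from_ncbi_id(cls, table_id: int) -> "GeneticCode":
        ncbi = CodonTable.unambiguous_dna_by_id[table_id]
        table = dict(ncbi.forward_table)
        for stop in ncbi.stop_codons:
            table[stop] = "*"
        return cls(name=ncbi.names[0], table=table,
                   starts=frozenset(ncbi.start_codons))

    @classmethod
    def invertebrate_mito(cls) -> "GeneticCode":
        return cls.from_ncbi_id(5)

    def amino_acid(self, codon: str) -> str:
        return self.table[codon.upper().replace("U", "T")]

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.table.items() if aa == "*")

    def families(self) -> dict[str, tuple[str, ...]]:
        """Synonymous families: amino acid (or '*') -> codons, in TCAG order."""
        fams: dict[str, list[str]] = {}
        for codon in _ALL_CODONS:
            fams.setdefault(self.table[codon], []).append(codon)
        return {aa: tuple(cs) for aa, cs in fams.items()}


@dataclass
class Cds:
    """A codon-ready coding sequence. ``padded`` counts inferred A's appended
    to complete a truncated stop codon (polyadenylation convention)."""

    seq: str
    padded: int = 0
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.seq) % 3:
            raise IncompleteCdsError(
                f"{self.gene or 'CDS'}: length {len(self.seq)} not divisible by 3"
            )

    def codons(self, include_padded_stop: bool = True) -> list[str]:
        cods = [self.seq[i:i + 3] for i in range(0, len(self.seq), 3)]
        if self.padded and not include_padded_stop:
            cods = cods[:-1]
        return cods


def extract_cds(genome: CircularGenome, feat: GeneFeature) -> Cds:
    """Strand-oriented CDS of a protein-coding feature, padded to whole
    codons when it ends in the truncated stop ``T``/``TA`` (completed to UAA
    by post-transcriptional polyadenylation)."""
    if feat.category != "PCG":
        raise ValueError(f"{feat.name} is not a protein-coding gene")
    seq = extract_region(genome, feat)
    rem = len(seq) % 3
    if rem == 0:
        return Cds(seq, 0, feat.name)
    if rem == 2 and seq.endswith("TA"):
        return Cds(seq + "A", 1, feat.name)
    if rem == 1 and seq.endswith("T"):
        return Cds(seq + "AA", 2, feat.name)
    raise IncompleteCdsError(
        f"{feat.name}: length {len(seq)} mod 3 = {rem} with suffix "
        f"{seq[-2:]!r}; not a truncated stop"
    )


def classify_start_stop(
    cds: Union[Cds, str], code: Optional[GeneticCode] = None
) -> tuple[str, str, bool]:
    """(start codon, stop codon, complete) of a codon-ready CDS.

    For a padded CDS the stop is reported as the observed partial (``TA`` or
    ``T``) with ``complete=False``. A start codon outside the code's start
    set triggers a warning but is still reported.
    """
    code = code or GeneticCode.invertebrate_mito()
    if isinstance(cds, str):
        cds = Cds(cds)
    if len(cds.seq) < 6:
        raise ValueError("CDS shorter than two codons")
    start = cds.seq[:3]
    if cds.padded:
        stop = cds.seq[-3: len(cds.seq) - cds.padded]
        complete = False
    else:
        stop = cds.seq[-3:]
        complete = stop in code.stop_codons
    if start not in code.starts:
        warnings.warn(f"{cds.gene or 'CDS'}: unusual start codon {start}")
    return start, stop, complete


@dataclass
class CodonCountTable:
    """Per-codon counts (DNA internally, RNA in reports)."""

    counts: dict[str, int] = field(default_factory=dict)
    skipped: int = 0  # codons with non-ACGT characters

    def __post_init__(self) -> None:
        normalized = {}
        for codon, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {codon}")
            normalized[codon.upper().replace("U", "T")] = n
        self.counts = normalized

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "CodonCountTable":
        return cls(counts=dict(counts))

    def count(self, codon: str) -> int:
        return self.counts.get(codon.upper().replace("U", "T"), 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def rna_counts(self) -> dict[str, int]:
        return {c.replace("T", "U"): n for c, n in self.counts.items()}

    def family_total(self, code: GeneticCode, amino_acid: str) -> int:
        return sum(self.count(c) for c in code.families()[amino_acid])

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        merged = Counter(self.counts)
        merged.update(other.counts)
        return CodonCountTable(counts=dict(merged),
                               skipped=self.skipped + other.skipped)


def count_codons(cds_list: Iterable[Union[Cds, str]]) -> CodonCountTable:
    """Count codons over a collection of codon-ready CDSs.

    Complete stop codons are counted; codons completed by padding are
    excluded (their bases are inferred, not observed). Codons containing
    non-ACGT characters are skipped and tallied in ``skipped``.
    """
    counts: Counter[str] = Counter()
    skipped = 0
    for cds in cds_list:
        if isinstance(cds, str):
            cds = Cds(cds)
        for codon in cds.codons(include_padded_stop=False):
            if set(codon) <= set("ACGT"):
                counts[codon] += 1
            else:
                skipped += 1
    return CodonCountTable(counts=dict(counts), skipped=skipped)


def rscu(table: CodonCountTable, code: Optional[GeneticCode] = None) -> dict[str, float]:
    """RSCU per codon, keyed by RNA triplet. Families with zero total are
    omitted (0/0 is undefined, not zero)."""
    code = code or GeneticCode.invertebrate_mito()
    out: dict[str, float] = {}
    for aa, codons in code.families().items():
        fam_total = sum(table.count(c) for c in codons)
        if fam_total == 0:
            continue
        k = len(codons)
        for c in codons:
            out[c.replace("T", "U")] = table.count(c) * k / fam_total
    return out


class Protein(str):
    """A translated peptide; ``internal_stops`` lists 0-based residue
    positions of stop codons before the final one."""

    internal_stops: tuple[int, ...] = ()

    def __new__(cls, seq: str, internal_stops: tuple[int, ...] = ()):
        obj = super().__new__(cls, seq)
        obj.internal_stops = internal_stops
        return obj


def translate(cds: Union[Cds, str], code: Optional[GeneticCode] = None) -> Protein:
    """Codon-by-codon translation; the terminal stop is rendered ``'*'`` and
    internal stops are flagged on the result rather than raised."""
    code = code or GeneticCode.invertebrate_mito()
    if isinstance(cds, str):
        cds = Cds(cds)
    residues = [code.amino_acid(c) for c in cds.codons()]
    internal = tuple(i for i, aa in enumerate(residues[:-1]) if aa == "*")
    return Protein("".join(residues), internal)


def aa_composition(
    table: CodonCountTable,
    code: Optional[GeneticCode] = None,
    split_leucine: bool = True,
) -> dict[str, float]:
    """Relative amino-acid frequencies implied by a codon count table.

    Frequencies sum to 1 over non-stop residues. With ``split_leucine`` the
    two leucine codon classes are reported separately as ``L(UUR)`` (UUA,
    UUG) and ``L(CUN)`` (CUN), the usual mitochondrial presentation.
    """
    code = code or GeneticCode.invertebrate_mito()
    if table.total == 0:
        raise ValueError("empty codon count table")
    sums: dict[str, int] = {}
    for codon, n in table.counts.items():
        aa = code.amino_acid(codon)
        if aa == "*":
            continue
        if split_leucine and aa == "L":
            aa = "L(UUR)" if codon in ("TTA", "TTG") else "L(CUN)"
        sums[aa] = sums.get(aa, 0) + n
    grand = sum(sums.values())
    return {aa: n / grand for aa, n in sums.items()}
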