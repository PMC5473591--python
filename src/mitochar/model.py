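"""Core data model and I/O for circular annotated mitogenomes.

Single source of coordinate and strand conventions for the whole package:
coordinates are 1-based inclusive on the majority strand, features that span
the replication origin are encoded with ``end < start``, ``F``/``R`` denote
the majority/minority strand, and the control region (CR) carries no strand.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneFeature",
    "CircularGenome",
    "AnnotationReport",
    "ValidationError",
    "FeatureTableParseError",
    "normalize_gene_name",
    "gene_category",
    "read_feature_table",
    "write_feature_table",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "intergenic_report",
    "extract_region",
    "feature_size",
]

PCG_NAMES = frozenset(
    {"atp6", "atp8", "cox1", "cox2", "cox3", "cob",
     "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6"}
)
TRNA_NAMES = frozenset(
    "trn" + x for x in ("A", "R", "N", "D", "C", "Q", "E", "G", "H", "I",
                        "K", "M", "F", "P", "T", "W", "Y", "V",
                        "S1", "S2", "L1", "L2")
)
RRNA_NAMES = frozenset({"rrnL", "rrnS"})

#: 13 protein-coding genes in the order they occur around the genome
#: (used as the canonical concatenation order downstream).
PCG_ORDER = ("cox1", "cox2", "atp8", "atp6", "cox3", "nad3", "nad5",
             "nad4", "nad4L", "nad6", "cob", "nad1", "nad2")

# One-letter amino acid -> tRNA symbol, for GenBank "tRNA-Xxx" products.
_AA3_TO_TRNA = {
    "Ala": "trnA", "Arg": "trnR", "Asn": "trnN", "Asp": "trnD",
    "Cys": "trnC", "Gln": "trnQ", "Glu": "trnE", "Gly": "trnG",
    "His": "trnH", "Ile": "trnI", "Lys": "trnK", "Met": "trnM",
    "Phe": "trnF", "Pro": "trnP", "Thr": "trnT", "Trp": "trnW",
    "Tyr": "trnY", "Val": "trnV",
}

# GenBank dialects vary; normalize on ingest.
_NAME_ALIASES = {
    "COI": "cox1", "COII": "cox2", "COIII": "cox3",
    "CO1": "cox1", "CO2": "cox2", "CO3": "cox3",
    "COX1": "cox1", "COX2": "cox2", "COX3": "cox3",
    "ATP6": "atp6", "ATP8": "atp8", "ATPASE6": "atp6", "ATPASE8": "atp8",
    "ND1": "nad1", "ND2": "nad2", "ND3": "nad3", "ND4": "nad4",
    "ND4L": "nad4L", "ND5": "nad5", "ND6": "nad6",
    "NAD1": "nad1", "NAD2": "nad2", "NAD3": "nad3", "NAD4": "nad4",
    "NAD4L": "nad4L", "NAD5": "nad5", "NAD6": "nad6",
    "CYTB": "cob", "COB": "cob", "CYB": "cob",
    "12S": "rrnS", "16S": "rrnL", "SRRNA": "rrnS", "LRRNA": "rrnL",
    "RRNS": "rrnS", "RRNL": "rrnL",
    "12S RRNA": "rrnS", "16S RRNA": "rrnL",
    "D-LOOP": "CR", "DLOOP": "CR", "CONTROL REGION": "CR", "CR": "CR",
    "A+T RICH REGION": "CR",
}


class ValidationError(ValueError):
    """An annotation violates a model invariant."""


class FeatureTableParseError(ValueError):
    """A feature table line could not be parsed."""


def normalize_gene_name(raw: str, anticodon: Optional[str] = None) -> str:
    """Map a gene name from an arbitrary annotation dialect onto the
    controlled vocabulary (cox1..3, atp6/8, nad1..6/4L, cob, trnX, rrnL/S, CR).

    ``anticodon`` disambiguates serine/leucine tRNAs when the name itself
    does not (S1=AGN/anticodon TCT, S2=UCN/TGA, L1=CUN/TAG, L2=UUR/TAA).
    """
    name = raw.strip()
    if name in PCG_NAMES or name in TRNA_NAMES or name in RRNA_NAMES or name == "CR":
        return name
    upper = name.upper().replace("_", "-")
    if upper in _NAME_ALIASES:
        return _NAME_ALIASES[upper]
    m = re.match(r"^TRNA[-_ ]?([A-Z][A-Za-z]{2})[-_ ]?([12])?$", name, re.IGNORECASE)
    if m:
        aa3 = m.group(1).capitalize()
        num = m.group(2) or ""
        if aa3 in _AA3_TO_TRNA:
            return _AA3_TO_TRNA[aa3]
        if aa3 in ("Ser", "Leu"):
            base = "trnS" if aa3 == "Ser" else "trnL"
            if num:
                return base + num
            if anticodon:
                ac = anticodon.upper().replace("U", "T")
                return {"TCT": "trnS1", "TGA": "trnS2",
                        "TAG": "trnL1", "TAA": "trnL2"}.get(ac, base)
            return base
    m = re.match(r"^trn([A-Z])([12])?$", name)
    if m:
        return name
    return name


def gene_category(name: str) -> Optional[str]:
    """Return PCG | tRNA | rRNA | CR, or None for names outside the vocabulary."""
    if name in PCG_NAMES:
        return "PCG"
    if name in RRNA_NAMES:
        return "rRNA"
    if name == "CR":
        return "CR"
    if name.startswith("trn"):
        return "tRNA"
    return None


def feature_size(start: int, end: int, genome_length: Optional[int] = None) -> int:
    """Size in nucleotides of a 1-based inclusive span, allowing the span to
    cross the origin (``end < start``) when ``genome_length`` is known."""
    if end >= start:
        return end - start + 1
    if genome_length is None:
        raise ValidationError(
            f"origin-spanning span {start}-{end} needs the genome length"
        )
    return (genome_length - start + 1) + end


@dataclass
class GeneFeature:
    """One annotated gene or region on a circular mitogenome.

    ``start``/``end`` are 1-based inclusive positions on the majority strand;
    ``end < start`` marks an origin-spanning feature. ``strand`` is ``'F'``
    (majority), ``'R'`` (minority) or ``None`` (control region only).
    """

    name: str
    strand: Optional[str]
    start: int
    end: int
    size: Optional[int] = None
    anticodon: Optional[str] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category is None:
            self.category = gene_category(self.name)
        if self.strand not in ("F", "R", None):
            raise ValidationError(f"{self.name}: strand must be F, R or None")
        if self.start < 1:
            raise ValidationError(f"{self.name}: start must be >= 1")
        if self.category == "CR" and self.strand is not None:
            raise ValidationError("CR must have no strand")
        if self.category not in ("CR", None) and self.strand is None:
            raise ValidationError(f"{self.name}: non-CR feature needs a strand")

    @property
    def spans_origin(self) -> bool:
        return self.end < self.start


@dataclass
class CircularGenome:
    """A circular annotated mitogenome (sequence optional, majority strand)."""

    identifier: str
    length: int
    sequence: Optional[str] = None
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.length:
                raise ValidationError(
                    f"{self.identifier}: sequence length {len(self.sequence)} "
                    f"!= declared length {self.length}"
                )
        self.features = sorted(self.features, key=lambda f: f.start)
        bad: list[str] = []
        for f in self.features:
            if f.start > self.length or f.end > self.length:
                raise ValidationError(
                    f"{self.identifier}: {f.name} coordinates exceed length "
                    f"{self.length}"
                )
            implied = feature_size(f.start, f.end, self.length)
            if f.size is None:
                f.size = implied
            elif f.size != implied:
                bad.append(f"{f.name} (declared {f.size}, coordinates imply {implied})")
        if bad:
            raise ValidationError(
                f"{self.identifier}: size/coordinate mismatch: " + "; ".join(bad)
            )

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def features_by_category(self, category: str) -> list[GeneFeature]:
        return [f for f in self.features if f.category == category]


@dataclass
class AnnotationReport:
    """Intergenic spacing and strand/category tallies for one genome.

    ``gaps`` holds one ``(gene, next_gene, gap)`` triple per feature in
    genome order, wrapping around the circle; negative gaps are overlaps.
    Strand tallies exclude the strandless CR.
    """

    identifier: str
    gaps: list[tuple[str, str, int]]
    strand_counts: dict[str, int]
    category_counts: dict[str, int]

    def gap_after(self, gene: str) -> int:
        for name, _nxt, gap in self.gaps:
            if name == gene:
                return gap
        raise KeyError(gene)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.gaps, columns=["gene", "next_gene", "intergenic_nt"])


def intergenic_report(genome: CircularGenome) -> AnnotationReport:
    """Signed gap (negative = overlap) between each feature and the next one
    around the circle, plus strand and category tallies."""
    feats = genome.features
    if len(feats) < 2:
        raise ValidationError("intergenic report needs at least two features")
    gaps = []
    for cur, nxt in zip(feats, feats[1:] + feats[:1]):
        nxt_start = nxt.start if nxt is not feats[0] else nxt.start + genome.length
        gaps.append((cur.name, nxt.name, nxt_start - cur.end - 1))
    strand_counts = {"F": 0, "R": 0}
    for f in feats:
        if f.strand in strand_counts:
            strand_counts[f.strand] += 1
    category_counts: dict[str, int] = {}
    for f in feats:
        key = f.category or "other"
        category_counts[key] = category_counts.get(key, 0) + 1
    return AnnotationReport(genome.identifier, gaps, strand_counts, category_counts)


def extract_region(genome: CircularGenome, feat: GeneFeature) -> str:
    """Feature sequence 5'->3' on its own strand (reverse complement for R);
    origin-spanning features concatenate tail+head before orienting."""
    if genome.sequence is None:
        raise ValidationError(f"{genome.identifier}: no sequence attached")
    if feat.start > genome.length or feat.end > genome.length:
        raise ValidationError(f"{feat.name}: coordinates exceed genome length")
    if feat.spans_origin:
        raw = genome.sequence[feat.start - 1:] + genome.sequence[: feat.end]
    else:
        raw = genome.sequence[feat.start - 1: feat.end]
    if feat.strand == "R":
        return str(Seq(raw).reverse_complement())
    return raw


# ---------------------------------------------------------------------------
# feature table I/O (Table-2 style TSV dialect)
# ---------------------------------------------------------------------------

_LOCATION_RE = re.compile(r"^(\d+)\s*[-–—−]\s*(\d+)$")
_MISSING = {"", "-", "–", "—", "none", "NA", "na", "."}


def _parse_location(text: str, lineno: int) -> tuple[int, int]:
    cleaned = text.replace(",", "").replace(" ", "")
    m = _LOCATION_RE.match(cleaned)
    if not m:
        raise FeatureTableParseError(
            f"line {lineno}: malformed location {text!r} (expected start-end)"
        )
    return int(m.group(1)), int(m.group(2))


def _clean(value: str) -> Optional[str]:
    value = value.strip()
    return None if value in _MISSING else value


def read_feature_table(
    path: str | Path,
    length: Optional[int] = None,
    identifier: Optional[str] = None,
    sequence: Optional[str] = None,
) -> CircularGenome:
    """Read a tab-separated annotation table into a :class:`CircularGenome`.

    Expected columns (header row, case-insensitive): gene, direction,
    location, size, and optionally anticodon, start_codon, stop_codon.
    Locations accept hyphen/en-dash separators and thousands separators.
    The genome length defaults to the maximum end coordinate.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise FeatureTableParseError(f"{path}: empty file")
    header = [h.strip().lower().replace(" ", "_") for h in rows[0]]
    required = {"gene", "direction", "location"}
    missing = required - set(header)
    if missing:
        raise FeatureTableParseError(f"{path}: missing columns {sorted(missing)}")
    idx = {name: header.index(name) for name in header}

    feats: list[GeneFeature] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue

        def cell(col: str) -> Optional[str]:
            i = idx.get(col)
            return _clean(row[i]) if i is not None and i < len(row) else None

        raw_name = cell("gene")
        if raw_name is None:
            raise FeatureTableParseError(f"line {lineno}: missing gene name")
        anticodon = cell("anticodon")
        name = normalize_gene_name(raw_name, anticodon)
        direction = cell("direction")
        if direction is not None and direction not in ("F", "R"):
            raise FeatureTableParseError(
                f"line {lineno}: direction must be F, R or missing, got {direction!r}"
            )
        start, end = _parse_location(cell("location") or "", lineno)
        size_text = cell("size")
        size = int(size_text.replace(",", "")) if size_text else None
        feats.append(
            GeneFeature(
                name=name, strand=direction, start=start, end=end, size=size,
                anticodon=anticodon, start_codon=cell("start_codon"),
                stop_codon=cell("stop_codon"),
            )
        )
    if length is None:
        length = len(sequence) if sequence else max(
            max(f.start, f.end) for f in feats
        )
    return CircularGenome(
        identifier=identifier or path.stem, length=length,
        sequence=sequence, features=feats,
    )


def write_feature_table(genome: CircularGenome, path: str | Path) -> None:
    """Write the Table-2 style TSV dialect read by :func:`read_feature_table`."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["gene", "direction", "location", "size", "anticodon",
             "start_codon", "stop_codon"]
        )
        for f in genome.features:
            writer.writerow(
                [f.name, f.strand or "-", f"{f.start}-{f.end}", f.size,
                 f.anticodon or "-", f.start_codon or "-", f.stop_codon or "-"]
            )


# ---------------------------------------------------------------------------
# GenBank and FASTA I/O
# ---------------------------------------------------------------------------

_GENBANK_KEY_CATEGORY = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                         "D-loop": "CR", "misc_feature": "CR"}


def _genbank_feature_name(feat: SeqFeature) -> Optional[str]:
    for key in ("gene", "product", "note", "standard_name"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    if feat.type == "D-loop":
        return "CR"
    return None


def _genbank_anticodon(feat: SeqFeature) -> Optional[str]:
    if "anticodon" not in feat.qualifiers:
        return None
    m = re.search(r"seq\s*:\s*([a-zA-Z]{3})", str(feat.qualifiers["anticodon"][0]))
    return m.group(1).upper().replace("U", "T") if m else None


def read_genbank(path: str | Path) -> CircularGenome:
    """Read a GenBank flat file; complement locations become strand R and
    join locations spanning the origin are folded into ``end < start``."""
    record = SeqIO.read(str(path), "genbank")
    if record.annotations.get("topology", "circular") != "circular":
        warnings.warn(
            f"{record.id}: topology is not circular; treating as circular"
        )
    length = len(record.seq)
    feats: list[GeneFeature] = []
    for feat in record.features:
        if feat.type not in _GENBANK_KEY_CATEGORY:
            continue
        raw_name = _genbank_feature_name(feat)
        if raw_name is None:
            continue
        anticodon = _genbank_anticodon(feat)
        name = normalize_gene_name(raw_name, anticodon)
        category = gene_category(name) or _GENBANK_KEY_CATEGORY[feat.type]
        loc = feat.location
        if isinstance(loc, CompoundLocation):
            parts = sorted(loc.parts, key=lambda p: int(p.start))
            if int(parts[-1].end) == length and int(parts[0].start) == 0:
                # join(x..length, 1..y) encodes an origin-spanning feature
                start, end = int(parts[-1].start) + 1, int(parts[0].end)
            else:
                start, end = int(loc.start) + 1, int(loc.end)
        else:
            start, end = int(loc.start) + 1, int(loc.end)
        strand = None if category == "CR" else ("R" if loc.strand == -1 else "F")
        feats.append(
            GeneFeature(name=name, strand=strand, start=start, end=end,
                        anticodon=anticodon, category=category)
        )
    return CircularGenome(
        identifier=record.id or Path(path).stem, length=length,
        sequence=str(record.seq), features=feats,
    )


def write_genbank(genome: CircularGenome, path: str | Path) -> None:
    """Write a minimal GenBank flat file for a genome with sequence."""
    if genome.sequence is None:
        raise ValidationError("write_genbank requires a sequence")
    record = SeqRecord(
        Seq(genome.sequence), id=genome.identifier, name=genome.identifier[:16],
        description="circular mitogenome",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    key_for = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "D-loop"}
    for f in genome.features:
        strand = -1 if f.strand == "R" else 1
        if f.spans_origin:
            loc = CompoundLocation(
                [SimpleLocation(f.start - 1, genome.length, strand),
                 SimpleLocation(0, f.end, strand)]
            )
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand)
        qualifiers: dict[str, list[str]] = {"gene": [f.name]}
        if f.anticodon:
            qualifiers["anticodon"] = [f"(seq:{f.anticodon.lower()})"]
        record.features.append(
            SeqFeature(loc, type=key_for.get(f.category or "PCG", "misc_feature"),
                       qualifiers=qualifiers)
        )
    SeqIO.write(record, str(path), "genbank")


def read_fasta(path: str | Path) -> tuple[str, str]:
    """Return (identifier, sequence) of the first record in a FASTA file."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return record.id, str(record.seq).upper()


def write_fasta(identifier: str, sequence: str, path: str | Path) -> None:
    SeqIO.write(SeqRecord(Seq(sequence), id=identifier, description=""),
                str(path), "fasta")
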