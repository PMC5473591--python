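"""PCG supermatrix preparation and a distance-based sanity tree.

Builds concatenated nucleotide or amino-acid matrices over the 13
mitochondrial protein-coding genes (canonical genome order), applies a
simple column-occupancy filter, computes uncorrected p-distances, and runs
neighbor joining as a quick topology check. No multiple sequence alignment
is performed: unequal partition lengths are right-padded with the missing
symbol, which is adequate for the indel-free synthetic families this stage
is validated on; real-data alignment remains an external step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from io import StringIO
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .codons import GeneticCode, extract_cds, translate
from .model import PCG_ORDER, CircularGenome

__all__ = [
    "Supermatrix",
    "MISSING",
    "build_supermatrix",
    "occupancy_filter",
    "p_distance",
    "distance_matrix",
    "neighbor_joining",
    "sister_check",
    "UndefinedDistanceError",
]

MISSING = "-"


class UndefinedDistanceError(ValueError):
    """p-distance requested for rows with no comparable sites."""


@dataclass(frozen=True)
class Supermatrix:
    """Concatenated per-taxon sequences with partition boundaries.

    ``partitions`` holds (gene, start, end) with 1-based inclusive columns
    tiling each row; all rows have equal length.
    """

    taxa: tuple[str, ...]
    rows: dict[str, str]
    partitions: tuple[tuple[str, int, int], ...]
    mode: str = "nt"

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")
        width = lengths.pop() if lengths else 0
        expected = 1
        for _gene, start, end in self.partitions:
            if start != expected or end < start - 1:
                raise ValueError("partition boundaries do not tile the matrix")
            expected = end + 1
        if self.partitions and expected != width + 1:
            raise ValueError("partitions do not cover the matrix width")

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for taxon in self.taxa:
                fh.write(f">{taxon}\n{self.rows[taxon]}\n")

    def write_partitions(self, path: str | Path) -> None:
        """RAxML-style partition lines, e.g. ``DNA, cox1 = 1-1559``."""
        kind = "DNA" if self.mode == "nt" else "AA"
        with open(path, "w") as fh:
            for gene, start, end in self.partitions:
                fh.write(f"{kind}, {gene} = {start}-{end}\n")


def build_supermatrix(
    genomes: Mapping[str, CircularGenome],
    mode: str = "nt",
    code: Optional[GeneticCode] = None,
) -> Supermatrix:
    """Concatenate the 13 PCGs of each genome in canonical order.

    ``mode='aa'`` translates each CDS with the invertebrate mitochondrial
    code first (terminal stop dropped). Within each partition, shorter
    sequences are right-padded with ``-``; a genome missing a PCG gets an
    all-missing partition and a warning.
    """
    if mode not in ("nt", "aa"):
        raise ValueError("mode must be 'nt' or 'aa'")
    code = code or GeneticCode.invertebrate_mito()
    taxa = tuple(genomes)
    per_gene: dict[str, dict[str, str]] = {g: {} for g in PCG_ORDER}
    for taxon, genome in genomes.items():
        have = {f.name for f in genome.features_by_category("PCG")}
        for gene in PCG_ORDER:
            if gene not in have:
                warnings.warn(f"{taxon}: missing {gene}; filling with gaps")
                per_gene[gene][taxon] = ""
                continue
            cds = extract_cds(genome, genome.feature(gene))
            if mode == "nt":
                per_gene[gene][taxon] = cds.seq
            else:
                per_gene[gene][taxon] = str(translate(cds, code)).rstrip("*")

    rows = {taxon: [] for taxon in taxa}
    partitions = []
    position = 1
    for gene in PCG_ORDER:
        width = max((len(s) for s in per_gene[gene].values()), default=0)
        for taxon in taxa:
            s = per_gene[gene][taxon]
            rows[taxon].append(s + MISSING * (width - len(s)))
        partitions.append((gene, position, position + width - 1))
        position += width
    return Supermatrix(
        taxa=taxa, rows={t: "".join(parts) for t, parts in rows.items()},
        partitions=tuple(partitions), mode=mode,
    )


def occupancy_filter(matrix: Supermatrix, min_fraction: float) -> Supermatrix:
    """Drop columns whose non-missing fraction is below ``min_fraction``
    (a coarse stand-in for alignment-quality filtering), updating the
    partition boundaries."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    arr = np.array([list(matrix.rows[t]) for t in matrix.taxa])
    occupancy = (arr != MISSING).mean(axis=0)
    keep = occupancy >= min_fraction
    if not keep.any():
        raise ValueError("occupancy filter removed every column")
    partitions = []
    position = 1
    for gene, start, end in matrix.partitions:
        width = int(keep[start - 1: end].sum())
        partitions.append((gene, position, position + width - 1))
        position += width
    rows = {
        t: "".join(np.array(list(matrix.rows[t]))[keep]) for t in matrix.taxa
    }
    return replace(matrix, rows=rows, partitions=tuple(partitions))


def p_distance(a: str, b: str) -> float:
    """Uncorrected mismatch proportion over sites non-missing in both rows."""
    if len(a) != len(b):
        raise ValueError("rows have unequal length")
    compared = mismatches = 0
    for x, y in zip(a, b):
        if x == MISSING or y == MISSING:
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        raise UndefinedDistanceError("no comparable sites")
    return mismatches / compared


def distance_matrix(matrix: Supermatrix) -> DistanceMatrix:
    """Pairwise p-distances over the supermatrix, taxa sorted
    lexicographically so downstream tie-breaking is deterministic."""
    taxa = sorted(matrix.taxa)
    n = len(taxa)
    data = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = p_distance(matrix.rows[taxa[i]], matrix.rows[taxa[j]])
            data[i, j] = data[j, i] = d
    return DistanceMatrix(data, ids=taxa)


def neighbor_joining(
    dm: Union[DistanceMatrix, tuple[Sequence[str], np.ndarray]]
) -> TreeNode:
    """Standard neighbor joining (exact on additive matrices). Negative
    branch lengths are clamped to zero; ids are sorted lexicographically
    before agglomeration so ties resolve deterministically."""
    if not isinstance(dm, DistanceMatrix):
        ids, data = dm
        data = np.asarray(data, dtype=float)
        if not np.allclose(data, data.T):
            raise ValueError("distance matrix is not symmetric")
        dm = DistanceMatrix(data, ids=list(ids))
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    order = sorted(dm.ids)
    dm = dm.filter(order)
    return nj(dm, neg_as_zero=True)


def sister_check(tree: Union[TreeNode, str], pair: Sequence[str]) -> bool:
    """True iff the two named taxa form a cherry: tips attached to the same
    node whose only tip neighbors are exactly these two (so no pair of an
    unresolved star counts as sisters)."""
    if isinstance(tree, str):
        tree = TreeNode.read(StringIO(tree))
    x, y = pair
    tips = {t.name: t for t in tree.tips()}
    for name in (x, y):
        if name not in tips:
            raise KeyError(f"taxon {name!r} not in tree")
    tx, ty = tips[x], tips[y]
    if tx.parent is not ty.parent or tx.parent is None:
        return False
    tip_children = {c.name for c in tx.parent.children if c.is_tip()}
    return tip_children == {x, y}
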