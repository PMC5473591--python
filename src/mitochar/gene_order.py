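"""Signed circular gene-order algebra for mitogenome rearrangement analysis.

Gene orders are circular sequences of signed gene symbols (+ = majority
strand, - = minority strand); the control region participates as an
unsigned marker. Comparison is signed, rotation-invariant and without
reflection (the two strands of a mitogenome are distinguishable), with
canonical forms anchored at cox1. Includes breakpoint distance, a
neighborhood diff against a reference order, and the single
tandem-duplication-random-loss (TDRL) derivability test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .model import CircularGenome

__all__ = [
    "SignedGene",
    "SignedGeneOrder",
    "RearrangementDiff",
    "TdrlResult",
    "SymbolSetError",
    "linearize",
    "orders_identical",
    "breakpoint_distance",
    "diff_orders",
    "tdrl_derivable",
    "read_orders",
    "write_orders",
]

SignedGene = tuple[str, int]  # (symbol, +1 | -1 | 0); 0 = unsigned (CR)


class SymbolSetError(ValueError):
    """Two orders do not carry the same gene symbols."""


def _parse_token(token: str) -> SignedGene:
    if token.startswith("+"):
        return token[1:], +1
    if token.startswith("-") or token.startswith("−"):
        return token[1:], -1
    return token, 0


def _format_gene(g: SignedGene) -> str:
    name, sign = g
    return {1: "+", -1: "-", 0: ""}[sign] + name


@dataclass(frozen=True)
class SignedGeneOrder:
    """A circular signed permutation of gene symbols for one taxon."""

    taxon: str
    genes: tuple[SignedGene, ...]
    circular: bool = True

    def __post_init__(self) -> None:
        names = [g[0] for g in self.genes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"{self.taxon}: duplicate gene symbols {dupes}")

    @classmethod
    def from_string(cls, taxon: str, text: str) -> "SignedGeneOrder":
        return cls(taxon, tuple(_parse_token(t) for t in text.split()))

    def to_string(self) -> str:
        return " ".join(_format_gene(g) for g in self.genes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(g[0] for g in self.genes)

    def sign_of(self, name: str) -> int:
        for n, s in self.genes:
            if n == name:
                return s
        raise KeyError(name)

    def rotated(self, k: int) -> "SignedGeneOrder":
        k %= len(self.genes)
        return replace(self, genes=self.genes[k:] + self.genes[:k])

    def canonical(self, anchor: str = "cox1") -> "SignedGeneOrder":
        """Rotate so the anchor gene (cox1 by Fig-4 convention) comes first;
        if absent, the first protein-coding gene is used with a warning."""
        names = self.names
        if anchor in names:
            return self.rotated(names.index(anchor))
        from .model import PCG_NAMES

        for i, n in enumerate(names):
            if n in PCG_NAMES:
                warnings.warn(
                    f"{self.taxon}: {anchor} absent; anchoring at {n}"
                )
                return self.rotated(i)
        return self

    def without(self, drop: Iterable[str]) -> "SignedGeneOrder":
        dropset = set(drop)
        return replace(
            self, genes=tuple(g for g in self.genes if g[0] not in dropset)
        )

    def adjacencies(self) -> tuple[tuple[SignedGene, SignedGene], ...]:
        g = self.genes
        if self.circular:
            return tuple((g[i], g[(i + 1) % len(g)]) for i in range(len(g)))
        return tuple((g[i], g[i + 1]) for i in range(len(g) - 1))


def linearize(source: Union[CircularGenome, SignedGeneOrder]) -> SignedGeneOrder:
    """Canonical signed gene order of an annotated genome (or re-anchor an
    existing order): rotation starts at cox1, orientation from strand."""
    if isinstance(source, SignedGeneOrder):
        return source.canonical()
    genes = tuple(
        (f.name, 0 if f.strand is None else (+1 if f.strand == "F" else -1))
        for f in source.features
    )
    return SignedGeneOrder(source.identifier, genes).canonical()


def _require_same_symbols(a: SignedGeneOrder, b: SignedGeneOrder) -> None:
    sa, sb = set(a.names), set(b.names)
    if sa != sb:
        raise SymbolSetError(
            f"symbol sets differ: only in {a.taxon}: {sorted(sa - sb)}; "
            f"only in {b.taxon}: {sorted(sb - sa)}"
        )


def orders_identical(a: SignedGeneOrder, b: SignedGeneOrder) -> bool:
    """True iff the two circular signed orders are equal up to rotation."""
    _require_same_symbols(a, b)
    return a.canonical().genes == b.canonical().genes


def _flip(g: SignedGene) -> SignedGene:
    return (g[0], -g[1])


def _adjacency_key(adj: tuple[SignedGene, SignedGene]):
    """Orientation-free key: (x, y) and (-y, -x) are the same adjacency."""
    x, y = adj
    forward = (x, y)
    backward = (_flip(y), _flip(x))
    return min(forward, backward)


def breakpoint_distance(a: SignedGeneOrder, b: SignedGeneOrder) -> int:
    """Number of signed adjacencies of one circular order absent from the
    other (a symmetric metric on canonical orders)."""
    _require_same_symbols(a, b)
    keys_b = {_adjacency_key(adj) for adj in b.adjacencies()}
    return sum(1 for adj in a.adjacencies() if _adjacency_key(adj) not in keys_b)


@dataclass(frozen=True)
class RearrangementDiff:
    """Differences of order ``b`` relative to reference ``a``: displaced
    genes with their (unsigned) flanking neighbors before and after,
    genes inverted in place, and maximal conserved blocks of ``a``."""

    displaced: dict[str, tuple[tuple[str, str], tuple[str, str]]]
    inverted: tuple[str, ...]
    conserved_blocks: tuple[tuple[str, ...], ...]

    @property
    def is_empty(self) -> bool:
        return not self.displaced and not self.inverted


def _neighbors(order: SignedGeneOrder, name: str) -> tuple[str, str]:
    names = order.names
    i = names.index(name)
    return names[i - 1], names[(i + 1) % len(names)]


def _orders_equal_anchored(a: SignedGeneOrder, b: SignedGeneOrder) -> bool:
    """Equality of two circular signed orders up to rotation (any anchor)."""
    if len(a.genes) != len(b.genes):
        return False
    if not a.genes:
        return True
    anchor = a.genes[0][0]
    names_b = b.names
    if anchor not in names_b:
        return False
    return a.genes == b.rotated(names_b.index(anchor)).genes


def diff_orders(
    a: SignedGeneOrder, b: SignedGeneOrder, max_displaced: int = 6
) -> RearrangementDiff:
    """Describe how order ``b`` differs from reference ``a``.

    Displaced genes are a minimal set whose removal from both orders makes
    them identical (ties broken deterministically by position in ``a``);
    each is reported with its flanking neighbors in ``a`` and in ``b``.
    Genes with unchanged neighbors but opposite orientation are reported as
    inverted instead.
    """
    _require_same_symbols(a, b)
    ca, cb = a.canonical(), b.canonical()

    inverted = []
    for name in ca.names:
        if ca.sign_of(name) != cb.sign_of(name) and (
            set(_neighbors(ca, name)) == set(_neighbors(cb, name))
        ):
            inverted.append(name)
    # normalize in-place inversions away before looking for displacements
    cb_norm = replace(
        cb,
        genes=tuple(
            (n, ca.sign_of(n)) if n in inverted else (n, s) for n, s in cb.genes
        ),
    )

    keys_b = {_adjacency_key(adj) for adj in cb_norm.adjacencies()}
    candidates = []
    for i, g in enumerate(ca.genes):
        left = ca.genes[i - 1]
        right = ca.genes[(i + 1) % len(ca.genes)]
        if (_adjacency_key((left, g)) not in keys_b
                or _adjacency_key((g, right)) not in keys_b):
            candidates.append(g[0])

    displaced_set: Optional[tuple[str, ...]] = None
    for k in range(0, min(max_displaced, len(candidates)) + 1):
        for combo in itertools.combinations(candidates, k):
            if _orders_equal_anchored(ca.without(combo), cb_norm.without(combo)):
                displaced_set = combo
                break
        if displaced_set is not None:
            break
    if displaced_set is None:  # too rearranged; report every changed context
        displaced_set = tuple(candidates)

    displaced = {
        name: (_neighbors(ca, name), _neighbors(cb, name))
        for name in displaced_set
    }

    # maximal runs of a with every adjacency conserved in b
    blocks: list[tuple[str, ...]] = []
    n = len(ca.genes)
    conserved = [
        _adjacency_key((ca.genes[i], ca.genes[(i + 1) % n])) in keys_b
        for i in range(n)
    ]
    if all(conserved):
        blocks.append(ca.names)
    else:
        start = next(i for i in range(n) if not conserved[i])
        run: list[str] = []
        for off in range(1, n + 1):
            i = (start + off) % n
            run.append(ca.genes[i][0])
            if not conserved[i]:
                if len(run) >= 2:
                    blocks.append(tuple(run))
                run = []
    return RearrangementDiff(
        displaced=displaced, inverted=tuple(inverted),
        conserved_blocks=tuple(blocks),
    )


@dataclass(frozen=True)
class TdrlResult:
    derivable: bool
    reason: str = ""
    copy1: tuple[str, ...] = ()
    copy2: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.derivable


def tdrl_derivable(
    a: SignedGeneOrder,
    b: SignedGeneOrder,
    window: Optional[Sequence[str]] = None,
) -> TdrlResult:
    """Can ``b`` arise from ``a`` by one tandem duplication-random loss of
    ``window`` (a contiguous segment of ``a``)?

    A single TDRL duplicates the window in tandem and keeps each gene in
    exactly one copy, so the rearranged window must be a concatenation of
    two subsequences of the original window order; equivalently its index
    sequence has at most one descent. TDRL never inverts, so any
    orientation change inside the window refutes it. The witness reports
    which genes each tandem copy retained.
    """
    _require_same_symbols(a, b)
    ca, cb = a.canonical(), b.canonical()

    if window is None:
        diffs = [i for i, (ga, gb) in enumerate(zip(ca.genes, cb.genes))
                 if ga != gb]
        if not diffs:
            return TdrlResult(True, "orders identical (second copy fully lost)",
                              copy1=ca.names, copy2=())
        window = [ca.genes[i][0] for i in range(min(diffs), max(diffs) + 1)]

    window = list(window)
    positions = [ca.names.index(g) for g in window]
    lo, hi = min(positions), max(positions)
    if sorted(positions) != list(range(lo, hi + 1)):
        raise ValueError("window is not a contiguous segment of the reference")
    window_in_a = [ca.genes[i] for i in range(lo, hi + 1)]

    outside_a = [g for g in ca.genes if g[0] not in set(window)]
    outside_b = [g for g in cb.genes if g[0] not in set(window)]
    if outside_a != outside_b:
        raise ValueError("orders differ outside the window")
    window_in_b = [g for g in cb.genes if g[0] in set(window)]

    sign_a = {n: s for n, s in window_in_a}
    for n, s in window_in_b:
        if sign_a[n] != s:
            return TdrlResult(False, "inversion present")

    index_of = {g[0]: i for i, g in enumerate(window_in_a)}
    idx = [index_of[g[0]] for g in window_in_b]
    descents = [i for i in range(len(idx) - 1) if idx[i + 1] < idx[i]]
    if len(descents) > 1:
        return TdrlResult(
            False, f"{len(descents)} descents; one TDRL allows a single split"
        )
    split = descents[0] + 1 if descents else len(idx)
    names_b = [g[0] for g in window_in_b]
    return TdrlResult(True, "window is a concatenation of two subsequences",
                      copy1=tuple(names_b[:split]), copy2=tuple(names_b[split:]))


def read_orders(path: str | Path) -> list[SignedGeneOrder]:
    """Order file: one taxon per line, first token the taxon name, then
    whitespace-separated signed gene symbols (CR unsigned)."""
    orders = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        taxon, _, rest = line.partition("\t")
        if not rest:
            parts = line.split()
            taxon, rest = parts[0], " ".join(parts[1:])
        orders.append(SignedGeneOrder.from_string(taxon.strip(), rest))
    return orders


def write_orders(orders: Iterable[SignedGeneOrder], path: str | Path) -> None:
    with open(path, "w") as fh:
        for order in orders:
            fh.write(f"{order.taxon}\t{order.to_string()}\n")
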