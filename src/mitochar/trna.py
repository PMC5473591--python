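"""Simplified cloverleaf folding of annotated mitochondrial tRNA genes.

A constrained combinatorial search over arm placements rather than a
covariance-model or thermodynamic search: acceptor stem 6-7 bp, D stem
0-4 bp (0 models the D-armless trnS1 type), anticodon stem 4-5 bp with a
7-nt loop, T stem 4-5 bp, variable loop 3-9 nt, Watson-Crick and G·U pairs
allowed with equal weight. The placement maximizing the number of base
pairs wins; ties prefer a longer acceptor stem, then a longer anticodon
stem, then loop sizes closest to (8, 7, 7) for the D/anticodon/T loops.

The primary pass requires every stem position to pair; when no such
placement exists a mismatch-tolerant pass supplies the best partial, and
anything below 12 pairs is reported as a fold failure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import pandas as pd

from .model import CircularGenome, extract_region

__all__ = ["Arm", "Cloverleaf", "FoldFailure", "fold_cloverleaf",
           "locate_anticodon", "batch_fold", "MIN_FOLD_PAIRS"]

_PAIRABLE = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
             ("G", "T"), ("T", "G")}

MIN_FOLD_PAIRS = 12

Span = tuple[int, int]  # 1-based inclusive


@dataclass(frozen=True)
class Arm:
    """One cloverleaf arm: 5' stem span, loop span (None for the acceptor),
    3' stem span, and the number of paired stem positions."""

    stem5: Optional[Span]
    loop: Optional[Span]
    stem3: Optional[Span]
    length: int


@dataclass(frozen=True)
class Cloverleaf:
    acceptor_stem: Arm
    d_arm: Arm
    anticodon_arm: Arm
    t_arm: Arm
    variable_loop: Span
    anticodon: str
    dhu_present: bool
    pair_count: int

    @property
    def ok(self) -> bool:
        return True


@dataclass(frozen=True)
class FoldFailure:
    reason: str
    best: Optional[Cloverleaf] = None

    @property
    def ok(self) -> bool:
        return False


def _pairs(seq: str, s5: int, s3: int, length: int) -> int:
    """Paired positions when seq[s5:s5+length] stems against
    seq[s3:s3+length] (antiparallel)."""
    n = 0
    for i in range(length):
        if (seq[s5 + i], seq[s3 + length - 1 - i]) in _PAIRABLE:
            n += 1
    return n


def _search(seq: str, strict: bool, hint: Optional[str]):
    """Enumerate arm placements; return (key, placement) of the best one.

    ``strict`` demands fully paired stems (fast, prunes hard); otherwise
    stems may contain mismatches and the pair count is what it is.
    """
    n = len(seq)
    best_key = None
    best = None
    for acc in (7, 6):
        for tail in range(0, 4):
            a3 = n - tail - acc
            if a3 <= acc:
                continue
            acc_pairs = _pairs(seq, 0, a3, acc)
            if strict and acc_pairs < acc:
                continue
            # D-arm branch: (d, sp1, dloop, sp2); d == 0 is the armless
            # connector, a single unpaired stretch.
            for d in (4, 3, 2, 0):
                if d == 0:
                    d_geoms = [(0, conn, 0, 0) for conn in range(4, 15)]
                else:
                    d_geoms = [(sp1, dl, sp2, d)
                               for sp1 in (1, 2, 3)
                               for dl in range(3, 12)
                               for sp2 in (1, 2)]
                for sp1, dl, sp2, _d in d_geoms:
                    if d == 0:
                        p2 = acc + dl
                        d_pairs = 0
                        d5s = d3s = None
                    else:
                        d5s = acc + sp1
                        d3s = d5s + d + dl
                        p2 = d3s + d + sp2
                        d_pairs = _pairs(seq, d5s, d3s, d)
                        if strict and d_pairs < d:
                            continue
                    for ac in (5, 4):
                        ac3s = p2 + ac + 7
                        if ac3s + ac >= a3:
                            continue
                        ac_pairs = _pairs(seq, p2, ac3s, ac)
                        if strict and ac_pairs < ac:
                            continue
                        v0 = p2 + 2 * ac + 7
                        for tst in (5, 4):
                            for var in range(3, 10):
                                t5s = v0 + var
                                tl = a3 - (t5s + 2 * tst)
                                if not 3 <= tl <= 9:
                                    continue
                                t3s = t5s + tst + tl
                                t_pairs = _pairs(seq, t5s, t3s, tst)
                                if strict and t_pairs < tst:
                                    continue
                                total = acc_pairs + d_pairs + ac_pairs + t_pairs
                                anticodon = seq[p2 + ac + 2: p2 + ac + 5]
                                dev = abs(dl - 8) + abs(tl - 7)
                                key = (total, acc, ac, -dev,
                                       1 if hint and anticodon == hint else 0)
                                if best_key is None or key > best_key:
                                    best_key = key
                                    best = (acc, tail, d, sp1, dl, sp2, ac,
                                            var, tst, tl, total, anticodon,
                                            d5s, d3s, p2, t5s, a3)
    return best_key, best


def _build_leaf(seq: str, placement) -> Cloverleaf:
    (acc, tail, d, sp1, dl, sp2, ac, var, tst, tl, total, anticodon,
     d5s, d3s, p2, t5s, a3) = placement

    def span(start0: int, length: int) -> Span:
        return (start0 + 1, start0 + length)

    acceptor = Arm(span(0, acc), None, span(a3, acc), acc)
    if d == 0:
        d_arm = Arm(None, span(acc, dl), None, 0)
    else:
        d_arm = Arm(span(d5s, d), span(d5s + d, dl), span(d3s, d), d)
    ac_arm = Arm(span(p2, ac), span(p2 + ac, 7), span(p2 + ac + 7, ac), ac)
    t_arm = Arm(span(t5s, tst), span(t5s + tst, tl), span(t5s + tst + tl, tst), tst)
    v0 = p2 + 2 * ac + 7
    return Cloverleaf(
        acceptor_stem=acceptor, d_arm=d_arm, anticodon_arm=ac_arm, t_arm=t_arm,
        variable_loop=span(v0, var), anticodon=anticodon,
        dhu_present=d >= 2, pair_count=total,
    )


def fold_cloverleaf(
    seq: str, anticodon_hint: Optional[str] = None
) -> Union[Cloverleaf, FoldFailure]:
    """Best cloverleaf placement of a tRNA gene sequence (55-95 nt, DNA,
    5'->3' on the gene's own strand). Deterministic: identical input gives
    an identical structure. Returns a :class:`FoldFailure` (never raises)
    when no placement reaches ``MIN_FOLD_PAIRS`` pairs."""
    seq = seq.upper().replace("U", "T")
    if not 55 <= len(seq) <= 95:
        return FoldFailure(f"length {len(seq)} outside the 55-95 nt window")
    hint = anticodon_hint.upper().replace("U", "T") if anticodon_hint else None
    key, placement = _search(seq, strict=True, hint=hint)
    if placement is None:
        key, placement = _search(seq, strict=False, hint=hint)
    if placement is None:
        return FoldFailure("no arm placement fits the length constraints")
    leaf = _build_leaf(seq, placement)
    if leaf.pair_count < MIN_FOLD_PAIRS:
        return FoldFailure(
            f"best placement pairs only {leaf.pair_count} positions", best=leaf
        )
    return leaf


def locate_anticodon(leaf: Cloverleaf, seq: str) -> tuple[str, bool]:
    """Central triplet of the anticodon loop, in the DNA alphabet.

    Returns ``(triplet, low_confidence)``: the flag is set when the loop is
    not the canonical 7 nt, where "central" is only nominal.
    """
    seq = seq.upper().replace("U", "T")
    loop = leaf.anticodon_arm.loop
    if loop is None:
        raise ValueError("cloverleaf has no anticodon loop")
    s, e = loop
    size = e - s + 1
    mid = s - 1 + (size - 3) // 2
    return seq[mid: mid + 3], size != 7


def batch_fold(genome: CircularGenome) -> pd.DataFrame:
    """Fold every annotated tRNA of a genome; failures become rows, not
    errors. Columns: gene, length, status, dhu_present, anticodon,
    annotated_anticodon, anticodon_match, pair_count."""
    rows = []
    for feat in genome.features_by_category("tRNA"):
        seq = extract_region(genome, feat)
        result = fold_cloverleaf(seq, anticodon_hint=feat.anticodon)
        if result.ok:
            anticodon, _low = locate_anticodon(result, seq)
            rows.append({
                "gene": feat.name, "length": len(seq), "status": "folded",
                "dhu_present": result.dhu_present, "anticodon": anticodon,
                "annotated_anticodon": feat.anticodon,
                "anticodon_match": (feat.anticodon is None
                                    or anticodon == feat.anticodon),
                "pair_count": result.pair_count,
            })
        else:
            rows.append({
                "gene": feat.name, "length": len(seq), "status": "fold-failure",
                "dhu_present": None, "anticodon": None,
                "annotated_anticodon": feat.anticodon,
                "anticodon_match": False, "pair_count":
                    result.best.pair_count if result.best else 0,
            })
    columns = ["gene", "length", "status", "dhu_present", "anticodon",
               "annotated_anticodon", "anticodon_match", "pair_count"]
    return pd.DataFrame(rows, columns=columns)
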