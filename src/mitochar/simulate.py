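"""Synthetic circular mitogenomes with planted, recoverable ground truth.

Every pipeline stage is testable without downloads: protein-coding genes
are built codon-by-codon from a biased synonymous-codon distribution with
proper start codons and (optionally truncated) stops, tRNA genes
instantiate cloverleaf templates with fully paired stems and a planted
anticodon (optionally D-armless, the metazoan trnS1 condition), rRNA and
control-region tracts are composition-matched noise, and whole genomes can
be evolved along a tree by synonymous third-position substitutions to make
families with a known topology.

Every stochastic call takes a single mandatory integer seed and uses one
numpy Generator stream; identical seeds give identical genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from skbio import TreeNode

from .codons import GeneticCode, translate
from .gene_order import SignedGene, SignedGeneOrder
from .model import CircularGenome, GeneFeature, feature_size, gene_category
from .trna import Cloverleaf

__all__ = ["GenomeSpec", "generate_mitogenome", "apply_event",
           "evolve_family", "table2_spec"]

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
_PYRIMIDINES = ("C", "T")


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _base_probs(at: float, at_skew: float, gc_skew: float) -> np.ndarray:
    """Probabilities over (A, C, G, T) matching target AT content and skews."""
    p_a = at * (1 + at_skew) / 2
    p_t = at * (1 - at_skew) / 2
    p_g = (1 - at) * (1 + gc_skew) / 2
    p_c = (1 - at) * (1 - gc_skew) / 2
    return np.array([p_a, p_c, p_g, p_t])


def _noise(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


@dataclass
class GenomeSpec:
    """Recipe for one synthetic mitogenome.

    Defaults emulate the bundled reference architecture: the S. sinensis
    gene order and sizes, 75.7% AT with AT skew -0.012 and GC skew -0.228,
    an AT-enriched control region (83.2%), and a D-armless trnS1. The
    synonymous-codon concentration ``codon_alpha`` scales the Dirichlet
    prior on per-family codon weights around the composition-implied bias
    (smaller = wilder genome-specific RSCU deviation).
    """

    seed: int
    identifier: str = "synthetic"
    order: Optional[SignedGeneOrder] = None
    gene_lengths: Optional[dict[str, int]] = None
    explicit_features: Optional[Sequence[tuple[str, Optional[str], int, int]]] = None
    length: Optional[int] = None
    spacer: int = 2
    at: float = 0.757
    at_skew: float = -0.012
    gc_skew: float = -0.228
    codon_alpha: float = 50.0
    cr_at: float = 0.832
    cr_at_skew: float = 0.107
    cr_gc_skew: float = -0.111
    anticodons: Optional[dict[str, str]] = None
    d_armless: frozenset = frozenset({"trnS1"})

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("seed is mandatory and must be an integer")
        if not 0 < self.at < 1:
            raise ValueError("AT fraction must lie in (0, 1)")
        if self.order is None:
            from .datasets import sinensis_gene_order

            self.order = sinensis_gene_order()
        lengths = dict(self.gene_lengths or {})
        if self.explicit_features is None:
            from .datasets import sinensis_gene_sizes

            defaults = sinensis_gene_sizes()
            for name, _sign in self.order.genes:
                lengths.setdefault(name, defaults.get(name, 100))
        if any(v <= 0 for v in lengths.values()):
            raise ValueError("gene lengths must be positive")
        self.gene_lengths = lengths
        if self.anticodons is None:
            from .datasets import load_annotation

            self.anticodons = {
                f.name: f.anticodon
                for f in load_annotation().features
                if f.anticodon
            }


# ---------------------------------------------------------------------------
# gene-content builders
# ---------------------------------------------------------------------------

def _codon_model(rng: np.random.Generator, code: GeneticCode, alpha: float,
                 probs: np.ndarray) -> dict:
    """Per-genome codon sampler targeting the genome base composition.

    The codon base measure is the product of the target base probabilities
    (so AT-rich genomes get AT-rich, Leu/Ile/Phe-heavy coding sequence, as
    in real mitogenomes); amino acids are drawn with their family mass and
    within-family codon weights get a Dirichlet perturbation with mean
    equal to the base measure and concentration ``alpha`` (smaller = wilder
    RSCU deviation).
    """
    fams = code.families()
    aas = sorted(aa for aa in fams if aa != "*")
    coding = [c for aa in aas for c in fams[aa]]
    at_of = np.array([sum(b in "AT" for b in c) / 3 for c in coding])

    # Conditioning on non-stop codons shifts AT below the genome target
    # (both stops are AT-rich); solve for the effective AT that restores it.
    target_at = probs[0] + probs[3]
    at_skew = (probs[0] - probs[3]) / target_at
    gc_skew = (probs[2] - probs[1]) / (probs[1] + probs[2])
    eff_at = target_at
    for _ in range(25):
        p = dict(zip("ACGT", _base_probs(eff_at, at_skew, gc_skew)))
        mass = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in coding])
        achieved = float((mass / mass.sum()) @ at_of)
        eff_at = float(np.clip(eff_at + (target_at - achieved), 0.05, 0.95))
    base = dict(zip("ACGT", _base_probs(eff_at, at_skew, gc_skew)))

    aa_mass = []
    weights = {}
    for aa in aas:
        codons = fams[aa]
        m = np.array([base[c[0]] * base[c[1]] * base[c[2]] for c in codons])
        aa_mass.append(m.sum())
        mean = m / m.sum()
        weights[aa] = rng.dirichlet(alpha * len(codons) * mean + 0.05)
    aa_p = np.array(aa_mass) / sum(aa_mass)
    return {"aas": aas, "aa_p": aa_p, "weights": weights, "families": fams}


def _pcg_sequence(rng: np.random.Generator, length: int, code: GeneticCode,
                  model: Mapping) -> tuple[str, dict]:
    rem = length % 3
    if rem == 0:
        n_inner = length // 3 - 2
        stop = "TAA" if rng.random() < 11 / 12 else "TAG"
    elif rem == 2:
        n_inner = (length - 2) // 3 - 1
        stop = "TA"
    else:
        n_inner = (length - 1) // 3 - 1
        stop = "T"
    if n_inner < 1:
        raise ValueError(f"PCG length {length} too short")
    start = rng.choice(["ATG", "ATT", "ATA"], p=[10 / 13, 2 / 13, 1 / 13])
    fams = model["families"]
    inner = []
    for aa in rng.choice(model["aas"], size=n_inner, p=model["aa_p"]):
        codons = fams[aa]
        inner.append(codons[rng.choice(len(codons), p=model["weights"][aa])])
    coding = str(start) + "".join(inner)
    truth = {
        "peptide": str(translate(coding, code)),
        "start_codon": str(start),
        "stop_codon": stop,
    }
    return coding + stop, truth


def _stem(rng: np.random.Generator, length: int,
          probs: np.ndarray) -> tuple[str, str]:
    """A fully Watson-Crick-paired stem: (5' half, 3' half). Complementary
    pairing preserves AT content, so stems follow the genome composition."""
    five = "".join(rng.choice(list("ACGT"), size=length, p=probs))
    return five, _revcomp(five)


def _loop(rng: np.random.Generator, length: int, probs: np.ndarray,
          anticodon: Optional[str] = None) -> str:
    """Loop/spacer bases from pyrimidines only, so planted stems stay the
    unique fully paired placement; T carries the target AT fraction since
    A and G are excluded. A planted anticodon replaces the loop center."""
    p_t = probs[0] + probs[3]
    bases = list(rng.choice(_PYRIMIDINES, size=length, p=[1 - p_t, p_t]))
    if anticodon is not None:
        mid = (length - 3) // 2
        bases[mid: mid + 3] = list(anticodon)
    return "".join(bases)


def _trna_geometry(length: int, d_armless: bool) -> dict[str, int]:
    if d_armless:
        rem = length - 40
        for conn in (8, 9, 7, 10, 6, 11, 5, 12, 4, 13, 14):
            for tloop in (7, 6, 8, 5, 9, 4, 3):
                var = rem - conn - tloop
                if 3 <= var <= 9:
                    return {"acc": 7, "conn": conn, "d": 0, "dloop": 0,
                            "ac": 5, "var": var, "t": 4, "tloop": tloop,
                            "tail": 1}
    else:
        rem = length - 54
        for extra in range(0, 6):
            for tloop in (7, 6, 8, 5, 9, 4, 3):
                var = rem - tloop - extra
                if 3 <= var <= 9:
                    return {"acc": 7, "sp1": 1, "d": 3, "dloop": 6 + extra,
                            "sp2": 1, "ac": 5, "var": var, "t": 4,
                            "tloop": tloop, "tail": 1}
    raise ValueError(f"no cloverleaf geometry for a {length}-nt tRNA")


def _trna_sequence(rng: np.random.Generator, length: int, anticodon: str,
                   d_armless: bool, probs: np.ndarray) -> tuple[str, dict]:
    g = _trna_geometry(length, d_armless)
    acc5, acc3 = _stem(rng, g["acc"], probs)
    ac5, ac3 = _stem(rng, g["ac"], probs)
    t5, t3 = _stem(rng, g["t"], probs)
    ac_loop = _loop(rng, 7, probs, anticodon)
    parts = [acc5]
    if d_armless:
        parts.append(_loop(rng, g["conn"], probs))
    else:
        d5, d3 = _stem(rng, g["d"], probs)
        parts += [_loop(rng, g["sp1"], probs), d5, _loop(rng, g["dloop"], probs),
                  d3, _loop(rng, g["sp2"], probs)]
    parts += [ac5, ac_loop, ac3, _loop(rng, g["var"], probs), t5,
              _loop(rng, g["tloop"], probs), t3, acc3, _loop(rng, g["tail"], probs)]
    seq = "".join(parts)
    assert len(seq) == length
    pair_count = g["acc"] + g["d"] + g["ac"] + g["t"]
    truth = {"anticodon": anticodon, "d_armless": d_armless,
             "pair_count": pair_count, "geometry": g}
    return seq, truth


def generate_mitogenome(spec: GenomeSpec) -> tuple[CircularGenome, dict]:
    """Build a genome from a spec; returns (genome, truth) where ``truth``
    records every planted parameter (order, peptides, anticodons, arm
    geometries, composition targets) for tests to check recovery against.
    """
    rng = np.random.default_rng(spec.seed)
    code = GeneticCode.invertebrate_mito()
    # Discount the AT-enriched control region so the genome-wide AT lands
    # on the spec target rather than above it.
    if spec.explicit_features is not None:
        total = spec.length or max(max(s, e) for _, _, s, e in spec.explicit_features)
        cr_len = sum(
            feature_size(s, e, total)
            for name, _, s, e in spec.explicit_features
            if gene_category(name) == "CR"
        )
    else:
        total = sum(spec.gene_lengths[n] for n, _ in spec.order.genes)
        total += spec.spacer * len(spec.order.genes)
        cr_len = sum(
            spec.gene_lengths[n] for n, _ in spec.order.genes
            if gene_category(n) == "CR"
        )
    cr_frac = cr_len / total if total else 0.0
    at_rest = float(np.clip(
        (spec.at - cr_frac * spec.cr_at) / (1 - cr_frac), 0.05, 0.95
    ))
    probs = _base_probs(at_rest, spec.at_skew, spec.gc_skew)
    cr_probs = _base_probs(spec.cr_at, spec.cr_at_skew, spec.cr_gc_skew)
    model = _codon_model(rng, code, spec.codon_alpha, probs)

    truth: dict = {"identifier": spec.identifier, "seed": spec.seed,
                   "order": spec.order, "at": spec.at,
                   "peptides": {}, "trna": {}}

    def content(name: str, length: int) -> tuple[str, dict]:
        cat = gene_category(name)
        meta: dict = {}
        if cat == "PCG":
            seq, info = _pcg_sequence(rng, length, code, model)
            truth["peptides"][name] = info["peptide"]
            meta = {"start_codon": info["start_codon"],
                    "stop_codon": info["stop_codon"]}
        elif cat == "tRNA":
            anticodon = spec.anticodons.get(name) or "".join(
                rng.choice(list("ACGT"), size=3)
            )
            seq, info = _trna_sequence(
                rng, length, anticodon, name in spec.d_armless, probs
            )
            truth["trna"][name] = info
            meta = {"anticodon": anticodon}
        elif cat == "CR":
            seq = _noise(rng, length, cr_probs)
        else:  # rRNA or unclassified filler
            seq = _noise(rng, length, probs)
        return seq, meta

    feats: list[GeneFeature] = []
    if spec.explicit_features is not None:
        length = spec.length or max(max(s, e) for _, _, s, e in spec.explicit_features)
        buffer = list(_noise(rng, length, probs))
        for name, strand, start, end in spec.explicit_features:
            gene_len = feature_size(start, end, length)
            oriented, meta = content(name, gene_len)
            placed = _revcomp(oriented) if strand == "R" else oriented
            if end >= start:
                buffer[start - 1: end] = placed
            else:
                head = length - start + 1
                buffer[start - 1:] = placed[:head]
                buffer[: end] = placed[head:]
            feats.append(GeneFeature(name, strand, start, end, **meta))
        sequence = "".join(buffer)
    else:
        parts: list[str] = []
        pos = 1
        for name, sign in spec.order.genes:
            gene_len = spec.gene_lengths[name]
            strand = None if sign == 0 else ("F" if sign > 0 else "R")
            oriented, meta = content(name, gene_len)
            parts.append(_revcomp(oriented) if strand == "R" else oriented)
            feats.append(
                GeneFeature(name, strand, pos, pos + gene_len - 1, **meta)
            )
            pos += gene_len
            if spec.spacer:
                parts.append(_noise(rng, spec.spacer, probs))
                pos += spec.spacer
        sequence = "".join(parts)
        length = len(sequence)

    genome = CircularGenome(
        identifier=spec.identifier, length=length,
        sequence=sequence, features=feats,
    )
    truth["length"] = length
    return genome, truth


def table2_spec(seed: int) -> GenomeSpec:
    """A spec that reproduces the reference architecture at its exact
    coordinates (including overlaps), yielding a 15,905 bp genome."""
    from .datasets import load_annotation

    annotation = load_annotation()
    return GenomeSpec(
        seed=seed,
        identifier="synthetic_sinensis",
        explicit_features=[
            (f.name, f.strand, f.start, f.end) for f in annotation.features
        ],
        length=annotation.length,
    )


# ---------------------------------------------------------------------------
# rearrangement events
# ---------------------------------------------------------------------------

def apply_event(order: SignedGeneOrder, event: tuple) -> SignedGeneOrder:
    """Apply a rearrangement event and return the modified order.

    Events: ``("swap", g1, g2)`` exchange two genes in place;
    ``("invert", [genes])`` reverse and re-strand a contiguous segment;
    ``("translocate", gene, after)`` move a gene behind another;
    ``("tdrl", [window genes], {gene: 1|2})`` tandem-duplicate the window
    and keep each gene in the stated copy — by construction the result
    satisfies the single-TDRL test with this loss mask as witness.
    """
    genes = list(order.genes)
    names = [g[0] for g in genes]
    kind = event[0]
    if kind == "swap":
        _, g1, g2 = event
        i, j = names.index(g1), names.index(g2)
        genes[i], genes[j] = genes[j], genes[i]
    elif kind == "invert":
        _, segment = event
        idx = [names.index(g) for g in segment]
        if idx != list(range(min(idx), max(idx) + 1)):
            raise ValueError("inversion segment must be contiguous")
        lo, hi = min(idx), max(idx)
        genes[lo: hi + 1] = [
            (n, -s) for n, s in reversed(genes[lo: hi + 1])
        ]
    elif kind == "translocate":
        _, gene, after = event
        moved = genes.pop(names.index(gene))
        names = [g[0] for g in genes]
        genes.insert(names.index(after) + 1, moved)
    elif kind == "tdrl":
        _, window, mask = event
        idx = [names.index(g) for g in window]
        if idx != list(range(min(idx), max(idx) + 1)):
            raise ValueError("TDRL window must be contiguous")
        counts = {g: 0 for g in window}
        for g, copy in mask.items():
            if g not in counts or copy not in (1, 2):
                raise ValueError(f"bad loss-mask entry {g!r}: {copy!r}")
            counts[g] += 1
        if any(c != 1 for c in counts.values()):
            bad = sorted(g for g, c in counts.items() if c != 1)
            raise ValueError(
                f"loss mask must retain each window gene exactly once: {bad}"
            )
        lo, hi = min(idx), max(idx)
        segment = genes[lo: hi + 1]
        rebuilt = [g for g in segment if mask[g[0]] == 1] + [
            g for g in segment if mask[g[0]] == 2
        ]
        genes[lo: hi + 1] = rebuilt
    else:
        raise ValueError(f"unknown event kind {kind!r}")
    return SignedGeneOrder(order.taxon, tuple(genes), order.circular)


# ---------------------------------------------------------------------------
# family evolution
# ---------------------------------------------------------------------------

def _third_position_sites(genome: CircularGenome) -> list[tuple[GeneFeature, int]]:
    """(feature, oriented offset of a codon third base) for all full codons
    of every PCG (truncated-stop bases excluded)."""
    sites = []
    for feat in genome.features_by_category("PCG"):
        usable = feat.size - feat.size % 3
        for j in range(2, usable, 3):
            sites.append((feat, j))
    return sites


def _oriented_to_genome(feat: GeneFeature, j: int, length: int) -> int:
    """0-based genome index of oriented position j of a feature."""
    if feat.strand == "R":
        pos = feat.end - 1 - j
    else:
        pos = feat.start - 1 + j
    return pos % length


def _mutate(genome: CircularGenome, k: int, rng: np.random.Generator,
            code: GeneticCode, synonymous_only: bool) -> CircularGenome:
    seq = list(genome.sequence)
    length = genome.length
    sites = _third_position_sites(genome)
    fams = code.families()
    for _ in range(k):
        feat, j = sites[rng.integers(len(sites))]
        if synonymous_only:
            idx = [_oriented_to_genome(feat, p, length) for p in (j - 2, j - 1, j)]
            codon = "".join(
                seq[i] if feat.strand != "R" else _COMPLEMENT[seq[i]]
                for i in idx
            )
            aa = code.amino_acid(codon)
            options = [
                c[2] for c in fams[aa]
                if c[:2] == codon[:2] and c[2] != codon[2]
            ]
            if not options:
                continue
            new_base = options[rng.integers(len(options))]
            gi = idx[2]
            seq[gi] = new_base if feat.strand != "R" else _COMPLEMENT[new_base]
        else:
            gi = _oriented_to_genome(feat, j, length)
            current = seq[gi]
            seq[gi] = "ACGT".replace(current, "")[rng.integers(3)]
    return CircularGenome(
        identifier=genome.identifier, length=length,
        sequence="".join(seq), features=[f for f in genome.features],
    )


def evolve_family(
    root_genome: CircularGenome,
    tree: Union[TreeNode, str],
    seed: int,
    synonymous_only: bool = True,
) -> dict[str, CircularGenome]:
    """Evolve a genome along a tree whose branch lengths are substitution
    counts; returns leaf-name -> genome. Substitutions hit third codon
    positions of PCGs and are synonymous by default, keeping translations
    stable (set ``synonymous_only=False`` to test amino-acid matrices)."""
    if isinstance(tree, str):
        tree = TreeNode.read(StringIO(tree))
    rng = np.random.default_rng(seed)
    code = GeneticCode.invertebrate_mito()
    leaves: dict[str, CircularGenome] = {}

    def descend(node: TreeNode, genome: CircularGenome) -> None:
        for child in node.children:
            k = int(child.length or 0)
            evolved = _mutate(genome, k, rng, code, synonymous_only)
            if child.is_tip():
                leaves[child.name] = CircularGenome(
                    identifier=child.name, length=evolved.length,
                    sequence=evolved.sequence,
                    features=[f for f in evolved.features],
                )
            else:
                descend(child, evolved)

    descend(tree, root_genome)
    return leaves
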