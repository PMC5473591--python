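"""Bundled reference fixtures: the Sesarmops sinensis mitogenome annotation
summary, the 40-species Brachyura composition table, the S. sinensis codon
count / RSCU table, and the Pancrustacean ground-pattern gene order.

These are the published summary tables of the study genome (GenBank
KR336554) and its comparison set, shipped as reviewable plain-text data so
the statistics pipeline can be exercised without any downloads.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .codons import CodonCountTable
from .gene_order import SignedGeneOrder, linearize, read_orders
from .model import CircularGenome, read_feature_table

__all__ = [
    "load_annotation",
    "load_composition_table",
    "load_codon_table",
    "load_codon_counts",
    "load_ground_pattern",
    "sinensis_gene_order",
    "sinensis_gene_sizes",
]

_DATA = resources.files("mitochar.data")


def load_annotation() -> CircularGenome:
    """The 38-feature S. sinensis annotation (37 genes + control region)."""
    with resources.as_file(_DATA / "table2_features.tsv") as path:
        return read_feature_table(path, identifier="S_sinensis")


def load_composition_table() -> pd.DataFrame:
    """Printed whole-genome composition percentages and skews for 40
    Brachyura mitogenomes (percentages at 1 dp, skews as printed)."""
    with resources.as_file(_DATA / "table3_composition.tsv") as path:
        return pd.read_csv(path, sep="\t")


def load_codon_table() -> pd.DataFrame:
    """Published S. sinensis codon counts with amino-acid assignments under
    the invertebrate mitochondrial code and the printed RSCU values (as
    strings, preserving printed precision)."""
    with resources.as_file(_DATA / "table4_codons.tsv") as path:
        return pd.read_csv(path, sep="\t", dtype={"rscu": str})


def load_codon_counts() -> CodonCountTable:
    df = load_codon_table()
    return CodonCountTable.from_counts(dict(zip(df["codon"], df["count"])))


def load_ground_pattern() -> SignedGeneOrder:
    """The Pancrustacean ancestral (ground pattern) gene order."""
    with resources.as_file(_DATA / "ground_pattern.txt") as path:
        return read_orders(path)[0]


def sinensis_gene_order() -> SignedGeneOrder:
    return linearize(load_annotation())


def sinensis_gene_sizes() -> dict[str, int]:
    """Gene symbol -> size (nt) from the bundled annotation; the default
    gene-length table of the synthetic genome generator."""
    return {f.name: f.size for f in load_annotation().features}
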