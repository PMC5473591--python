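# Methods

## Coordinate and strand conventions

All coordinates are 1-based inclusive on the majority strand; a feature
with `end < start` spans the replication origin of the circular molecule
(tail and head are concatenated before orientation). Strands are `F`
(majority) and `R` (minority); the control region (CR) carries no strand
and participates in gene-order analysis as an unsigned marker. Feature
tables cross-check the declared size column against the coordinates and
refuse mismatches; locations tolerate hyphen/en-dash separators and
thousands separators, and gene names from common GenBank dialects (ND5,
COI, 12S, D-loop, tRNA-Ser + anticodon, ...) are normalized onto a
controlled vocabulary on ingest. The intergenic value after feature *i* is
`start(i+1) − end(i) − 1` with circular wrap-around, so negative values are
overlaps and the feature sizes plus signed gaps telescope to the genome
length — an invariant the tests assert.

## Composition and skews

`AT skew = (A − T)/(A + T)`, `GC skew = (G − C)/(G + C)`; both are
scale-invariant, so counts and percentages give identical values. Whole-
genome composition is reported for the majority strand; per-category
partitions (PCG, tRNA, rRNA, CR) orient every feature to its own coding
strand first, and bases inside overlapping features are counted once per
feature, not once per genome. Reports round percentages to 1 decimal and
skews to 3, half away from zero; full precision is kept internally.
Recomputing the bundled 40-species composition table confirms printed AT
contents to 0.1 but shows two printed skews that do not follow from their
own printed percentages (the reference genome's GC skew recomputes to
−0.226 against a printed −0.228, presumably from unrounded counts; one
taxon's 4-decimal AT skew is likewise inconsistent). The package reports
recomputed full-precision values and does not chase printed values it
cannot derive.

## Codon usage

The genetic code is NCBI translation table 5 (invertebrate mitochondrial),
taken from Biopython and wrapped in a pluggable 64-entry `GeneticCode`.
Synonymous families group all codons of one amino acid: leucine is one
6-codon family, serine the 8-codon UCN+AGN family, UAA/UAG the stop
family, and UGA is tryptophan. CDS extraction orients the gene, then
completes a truncated terminal stop (`TA` → +A, `T` → +AA), the
post-transcriptional polyadenylation convention; any other non-multiple-
of-3 length is an error. Codon counts include start codons and complete
stops but exclude padded stops, whose bases are inferred rather than
observed — the printed-count replication path (counts → RSCU) is
independent of this choice. `RSCU(c) = n_c · k / Σ n_i`; families with
zero total are omitted (0/0 is undefined, not zero). Amino-acid
composition splits leucine into L(UUR) and L(CUN), the usual mitochondrial
presentation. Note the bundled published counts give an exact tie between
isoleucine and phenylalanine (356 each), so only the set of the second and
third most common residues is well-defined.

## tRNA cloverleaf assessment

The folder is a deliberately simplified constrained search, not a
covariance model or free-energy minimization: acceptor stem 6–7 bp with an
unpaired 3' tail of 0–3 nt, D stem 0–4 bp (0 = D-armless) with a 3–11 nt
loop and 1–3/1–2 nt spacers, anticodon stem 4–5 bp with a fixed 7-nt loop,
variable loop 3–9 nt, T stem 4–5 bp with a 3–9 nt loop. Watson–Crick and
G·U pairs count equally. The primary pass requires fully paired stems and
maximizes the pair count; ties prefer a longer acceptor stem, then a
longer anticodon stem, then loop sizes closest to (8, 7, 7) for D/
anticodon/T, making folding deterministic. If no fully paired placement
exists, a mismatch-tolerant pass supplies the best partial; below 12 pairs
the result is a fold failure (a value, not an exception). `dhu_present` is
false when the best placement's D stem is under 2 bp. The anticodon is the
central triplet of the anticodon loop, reported in DNA letters; a
non-7-nt loop flags the call low-confidence. Accuracy is assessed against
generator-planted structures (≥ 95% anticodon recovery on 200 planted
canonical tRNAs, ≥ 95% D-armless detection), not against published
structure figures.

## Gene-order analysis

Orders are signed circular permutations, canonically rotated to start at
*cox1*; comparison is signed and rotation-invariant without reflection,
since the two strands of a mitogenome are distinguishable. The breakpoint
distance counts adjacencies `(x, y)` of one order with neither `(x, y)`
nor `(−y, −x)` adjacent in the other. `diff_orders` reports the minimal
set of genes whose removal from both orders makes them identical (found by
exhaustive subset search over changed-context genes, deterministic
tie-break by position; in-place orientation flips are reported separately
as inversions). Minimal sets need not be unique: for the bundled reference
vs the ancestral pattern, {trnH, trnI} and {trnH, trnQ} are both minimal
and the search reports the first, either of which expresses the I/Q swap.
The single-TDRL test uses the outcome characterization of tandem
duplication followed by random loss: the rearranged window must be a
concatenation of two subsequences of the original window order
(equivalently, its index sequence has at most one descent), gene
orientations unchanged. The brute-force enumeration of all duplication+
loss patterns is kept in the test suite as an independent oracle. General
minimum-TDRL distance is out of scope. The Pancrustacean ground pattern
ships as a reviewable order file rather than hard-coded data.

## Supermatrix preparation and sanity tree

The 13 PCGs are concatenated in their genome order (cox1, cox2, atp8,
atp6, cox3, nad3, nad5, nad4, nad4L, nad6, cob, nad1, nad2); amino-acid
mode translates with table 5 first and drops the terminal stop. No
alignment is performed in-package — synthetic families are generated
without indels, so per-partition right-padding with `-` suffices; real
data should be aligned externally. The occupancy filter removes columns
whose non-missing fraction falls below a threshold and updates partition
boundaries. Distances are uncorrected p-distances over sites non-missing
in both rows. Neighbor joining is delegated to scikit-bio (negative branch
lengths clamped to zero) with taxa sorted lexicographically beforehand so
tie-breaking is deterministic; it is exact on additive matrices, which the
tests verify against path-length oracles. `sister_check` calls two taxa
sisters only when their shared node has exactly those two tips as tip
neighbors, so no pair of an unresolved star qualifies. The tree stage is a
sanity surrogate: model-based inference on real multi-taxon datasets is
deliberately out of scope.

## Synthetic genome generator

`GenomeSpec` defaults emulate the bundled reference architecture: its gene
order and sizes, genome AT fraction 0.757 with AT skew −0.012 and GC skew
−0.228, an AT-enriched control region (0.832 with its own skews), and a
D-armless trnS1. One mandatory integer seed drives a single numpy
Generator stream per call.

- **PCGs** are built codon by codon. The codon base measure is the product
  of per-base target probabilities, which automatically yields the
  Leu/Ile/Phe-heavy, AT-biased usage of real mitogenomes; amino acids are
  drawn by family mass and within-family weights get a Dirichlet
  perturbation with that mean and concentration `codon_alpha`
  (default 50 — visible genome-specific RSCU wobble without disturbing
  composition targets). Because conditioning on non-stop codons (both
  stops are AT-rich) depresses AT, the effective base measure is solved by
  a short fixed point so expected coding AT hits the target. Start codons
  are ATG/ATT/ATA (10:2:1); stops are TAA/TAG (11:1) or planted truncated
  `TA`/`T` when the gene length is not a multiple of 3.
- **tRNAs** instantiate cloverleaf templates with fully Watson–Crick-paired
  stems (composition-matched stem bases) and pyrimidine-only loops and
  spacers, so the planted placement is the unambiguous pairing optimum;
  the planted anticodon sits at the loop center. A geometry solver spreads
  the gene length over the variable loop, T loop and D loop (supported
  lengths 60–77 nt canonical, 50–72 D-armless). Pyrimidine-only loops make
  tRNA partitions T-heavy, a known unrealism accepted for unambiguous
  structure recovery.
- **rRNA and CR** are i.i.d. noise at the genome and CR composition
  targets respectively. Since the CR is AT-enriched, the non-CR target is
  adjusted downward so the genome-wide AT expectation lands on the spec
  value; on ≥ 15 kb genomes the realized AT stays within ±1 percentage
  point of the target across seeds.
- **Coordinates**: by default genes are laid out sequentially with a fixed
  spacer (2 nt); an explicit-coordinate mode reproduces a real
  architecture exactly, including overlaps (later features overwrite the
  overlap, so planted-content guarantees apply to genes without downstream
  overlaps) and origin-spanning features.
- **Events** (`apply_event`): swap, contiguous inversion (re-strands),
  translocation, and TDRL implemented literally as duplicate-window-then-
  apply-loss-mask, so outputs are single-TDRL-derivable by construction
  with the mask as witness.
- **Families** (`evolve_family`): branch lengths are substitution counts;
  sites are third codon positions of PCGs, with replacement, substituted
  synonymously by default so translations (and amino-acid matrices) stay
  fixed; `synonymous_only=False` frees all bases for amino-acid-mode
  testing. Collisions make realized differences slightly undershoot the
  nominal count at large counts.

What passing on synthetic data does **not** show: the generator has no
indels, no within-gene rate heterogeneity, no secondary-structure-aware
rRNA, no selection, and loops drawn from a reduced alphabet — so folder
and tree-stage accuracy on real genomes will be lower than on planted
data. Values tied to published summary tables (composition, RSCU,
gene-order differences) are exact desk-scale recomputations and do not
depend on the generator.

## Problem sizes used in the checks

The bundled annotation (38 features, 15,905 bp), full Table-scale codon
counts, synthetic genomes of ~15 kb (and ~1.2 kb miniatures for round-trip
tests), 200 + 60 planted tRNAs for folder accuracy, exhaustive TDRL
enumeration on windows up to 6 genes, breakpoint oracles on signed circular
permutations up to 7 genes, additive NJ instances up to 8 taxa, and 40
four-taxon replicates for sister-pair recovery.
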