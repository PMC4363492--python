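# Methods

## Scope and data model

The toolkit covers the computation *between* the heavy external tools
of a strain-resequencing project: it consumes genome assemblies
(FASTA), candidate ORF annotations from two predictors (GFF3),
pairwise alignment hits (BLAST-style 12-column tabular) and SAM flag
integers, and produces refined annotations, homology labels,
non-reference ORF catalogues, presence/absence matrices and
neighbor-joining dendrograms.  Read mapping, assembly, and gene
prediction themselves are out of scope by design — they are
well-served by dedicated tools whose standard outputs this package
ingests.

Coordinates are 0-based half-open everywhere inside the package;
`formats_io.to_internal` / `to_gff3` are the only conversion points,
so off-by-one drift cannot accumulate.  An `OrfModel` stores exons in
coding order (descending genomic order on the minus strand), which
makes spliced-CDS extraction and intron enumeration strand-uniform.

## Refinement rules

Merging keeps the union of both predictor outputs; two models are the
*same* annotation only when contig, strand and the full exon list
match, so same-stop/alternative-start pairs survive as separate
records.  The structural filters are:

* start codon ATG only, stop ∈ {TAA, TAG, TGA} (standard nuclear
  code; yeast initiates at ATG essentially without exception), length
  divisible by 3, no in-frame internal stop;
* every intron of a spliced model must contain one of the seven
  branch-point heptamers — UACUAAC (consensus) or CACUAAC, GACUAAC,
  UGCUAAC, AACUAAC, UAUUAAC, AAUUAAC — searched as a case-insensitive
  DNA substring (U→T) over the whole intron on the coding strand.
  Introns shorter than 7 bp fail outright.

Unlabeled ("undefined") models are consolidated per contig and strand:
within a transitively-overlapping cluster only the longest spliced
model survives (ties: leftmost start), and survivors shorter than
300 bp are dropped.  The cutoff is inclusive (≥ 300 bp) by default
with a flag for the strict reading (> 300), since both phrasings occur
in practice; labeled models are never touched by consolidation.
Every filter returns its discards with a single machine-readable
reason, so `|input| = |kept| + |discarded|` holds at each stage and is
logged.

## Homology tiers and e-values

Pairwise protein comparison is Smith–Waterman with affine gaps
(BLOSUM62, gap open 11, extend 1, BLASTP's convention that a gap of
length L costs 11 + L), executed by Biopython's C `PairwiseAligner`.
Identity is exact matches over alignment columns (gap columns
included); similarity is BLAST-style positives (substitution score
> 0) over the same columns.  E-values use the Karlin–Altschul formula
E = K·m·n·exp(−λS) with the fixed gapped-BLOSUM62 constants λ = 0.267,
K = 0.041 and the full sequence lengths as the search space.  These
approximate BLAST e-values but are not bit-identical (no edge
correction, no composition adjustment); when BLAST-exact behaviour is
needed, precomputed tabular hits can be supplied instead and flow
through the identical classification pathway.  The 12-column dialect
carries no positives count or subject length, so in ingest mode
percent identity stands in for similarity (a conservative lower
bound) and sequence lengths come from optional length maps, falling
back to aligned span lengths.

Classification tiers: *strict* requires E < 1e-6, length difference
≤ 5% of the subject length, similarity > 90%; *relaxed* keeps the
e-value cutoff, drops the length test and requires similarity > 80%
— only the similarity stringency is reduced.  The best passing
subject (lowest E, then highest raw score, then lexicographic name)
becomes the label.  The strict tier's length-difference test depends
only on the sequence lengths, so pairs that cannot pass it are
skipped without aligning; this changes no label.  Homologue-grouping
edges use the much looser E < 0.1, identity > 75%, length similarity
(min/max of full lengths) > 0.75, all strict inequalities.

Multiple HSPs per subject are not tiled; each pair is scored by its
single best local alignment.

## Novelty detection

The unmapped-read triage is pure bit logic: a flag is extracted iff it
matches any of (require 4, exclude 264), (require 8, exclude 260),
(require 12, exclude 256) — i.e. either end unmapped, secondary
alignments always excluded.  Contigs assembled from those reads are
kept when ≥ 300 bp (the same cutoff as for ORFs) and when at most
half of the contig aligns to the reference at ≥ 90% identity; the
0.5 coverage and 90% identity knobs are configurable defaults, since
"absent from the reference" admits no single canonical criterion, and
are recorded in output metadata.  Surviving contigs are placed on the
strain's own assembly by best hit (highest bit score, then longest
alignment, then lexicographic target), and any annotated ORF whose
genomic span overlaps a placed interval by ≥ 1 bp, on either strand,
is collected as non-reference.

## Presence/absence and the dendrogram

Groups are connected components of the undirected similarity graph
(single linkage; an edge exists if the criterion passes in either
direction).  The presence matrix has one row per strain and one
column per group; strains with no non-reference ORF are dropped with
a warning, since an all-zero row is indistinguishable from the
reference and contributes no signal.  Gene distance is the Hamming
count of differing columns (a proportion variant divides by the
number of groups).  Neighbor joining follows Saitou–Nei with the
Studier–Keppler criterion Q(i,j) = (n−2)d(i,j) − r_i − r_j; ties in Q
break on the lexicographically smallest label pair, and negative
branch lengths are retained by default (clamping to zero is an
option) — both choices are documented because library
implementations differ silently on them.  The result is an unrooted
tree serialized as a trifurcating root in Newick with six-decimal
branch lengths.

Tree quality against an external catalogue is summarized by shared /
exclusive counts and the shared percentage; topology comparisons in
the tests use Robinson–Foulds-style bipartition sets, which is a
coarser statistic than branch-length-aware tree distances.

## Synthetic fixtures: what they emulate and what they prove

`SimConfig` defaults describe a reduced-scale strain panel: 6 strains,
a 60 kb single-contig reference with 30 core genes (100–250 codons,
~30% spliced), 12 novel gene families, 2% within-family protein
divergence, plus planted defects (2 candidates lacking stops, 3
spurious intergenic ORFs, optional Dubious overlaps and motif-free
introns).  Two construction guarantees make end-to-end recovery exact
rather than probabilistic:

* family protein lengths grow geometrically with ratio > 4/3
  (101, 136, 182, … aa), so any cross-family pair already fails the
  length-similarity grouping cutoff — no alignment score can create a
  spurious inter-family edge.  The shortest family (303 bp) clears
  the 300 bp retention cutoff;
* family sharing is derived from a planted random binary tree over
  the strains: every family's strain set is a clade, and every
  non-trivial split is covered by at least one family.  Hamming
  distances over clade-indicator columns are then exactly additive on
  the planted tree, so NJ provably recovers every planted
  bipartition.

Cassettes are inserted only at intergenic points, keeping core
annotations valid; each strain also receives a too-short decoy contig
and a reference-derived decoy to exercise the novelty filters.  All
randomness flows through one numpy generator seeded from
`SimConfig.seed`; identical seeds give byte-identical files.

What passing these tests does *not* show: the fixtures contain no
sequencing error, no heterozygosity or ploidy structure, no
repeat-induced misassembly, no fragmented gene models and no
borderline homology (families are either nearly identical or
unalignable).  On real data the grouping outcome depends on the
cutoffs in ways the planted structure deliberately avoids, and
annotation accuracy is bounded by assembly quality; the validation
and recovery numbers here certify the correctness of the decision
logic, not expected field performance.

## Problem sizes and numerical choices

The test-suite oracles run at sizes where exhaustive enumeration is
exact: all 4096 SAM flags; 100 random peptide pairs of length ≤ 8
against enumeration of every monotone alignment; random additive
matrices of 4–6 taxa against all 3–105 unrooted topologies with
least-squares fit; 200 random graphs against union-find; 1000 random
introns (a third with planted motifs, a third with near-miss 6-mers)
against a per-offset scan.  The end-to-end run uses the default
6-strain/12-family configuration.  Floating-point comparisons in NJ
use a 1e-12 slack when comparing Q values so tie-breaking is stable
under summation order; validation percentages are kept unrounded
internally and rounded only at presentation (1 decimal for the
identical fraction, 2 for the FDR, matching how such figures are
conventionally reported).

## Known limitations

GFF3 support is limited to the feature types the workflow emits
(gene/mRNA/CDS with ID/Parent/Name); GTF is not read.  The internal
aligner reports one best local alignment, so identity percentages on
highly repetitive proteins may differ from HSP-tiled BLAST output.
`build_true_set` applies its overlap-exclusion rules to a fixed
point, which is idempotent but can, for long exclusion chains, remove
more Dubious models than a single-pass reading would.  Branch-point
search accepts a motif anywhere in the intron, not only near the 3'
end where biological branch points reside.
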