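"""Annotation merging and refinement for predicted ORFs.

The refinement stage combines ORF calls from a homology-based source and
an ab initio source, then applies the structural filters a yeast
annotator would: every kept ORF must start with ATG, end with a stop
codon, be in frame with no premature stop, and every predicted intron
must contain a spliceosomal branch-point heptamer (consensus UACUAAC or
one of the six rarer variants).  ORFs that no protein-database tier
could name ("undefined") are consolidated so a single, longest model
survives per overlapping cluster, and only models of at least 300 bp
spliced length are retained.

A validation mode compares a predicted set against a curated truth set
built with the reference-annotation overlap rules (Dubious ORFs yield
to overlapping non-Dubious ones; of two overlapping Dubious ORFs the
shorter is dropped) and reports the fraction of exactly reproduced
models and the corresponding false discovery rate.

All coordinates in this module are internal 0-based half-open;
:mod:`panorf.formats_io` converts at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .formats_io import FeatureRecord, GenomeSequence, to_gff3, to_internal

__all__ = [
    "OrfModel",
    "BranchPointCatalog",
    "ValidationReport",
    "BRANCH_POINTS",
    "STOP_CODONS",
    "START_CODON",
    "extract_spliced_cds",
    "extract_introns",
    "check_terminal_codons",
    "check_branch_points",
    "merge_sources",
    "consolidate_undefined",
    "build_true_set",
    "validation_metrics",
    "comparison_metrics",
    "reverse_complement",
    "translate_orf",
    "orf_to_features",
    "features_to_orfs",
]

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BranchPointCatalog:
    """The seven yeast intron branch-point heptamers.

    The spliceosome forms the lariat at a conserved heptamer, consensus
    5'-UACUAAC-3'; six rarer variants are accepted.  Searching is done
    in DNA space (U transliterated to T) on the coding strand.
    """

    motifs: tuple[str, ...] = (
        "UACUAAC",
        "CACUAAC",
        "GACUAAC",
        "UGCUAAC",
        "AACUAAC",
        "UAUUAAC",
        "AAUUAAC",
    )

    def __post_init__(self) -> None:
        if len(self.motifs) != 7 or any(len(m) != 7 for m in self.motifs):
            raise ValueError("branch-point catalog must hold 7 heptamers")

    @property
    def dna_motifs(self) -> tuple[str, ...]:
        return tuple(m.replace("U", "T") for m in self.motifs)


BRANCH_POINTS = BranchPointCatalog()


@dataclass(frozen=True)
class OrfModel:
    """A predicted protein-coding feature with exon structure.

    ``exons`` are 0-based half-open genomic intervals listed in coding
    order: ascending for the plus strand, descending for the minus
    strand (the first exon always carries the start codon).
    """

    orf_id: str
    seq_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    source: str = "merged"  # homology | abinitio | merged
    classification: str = "unknown"  # Verified | Dubious | Uncharacterized | unknown
    label: str = "undefined"
    status: str = "raw"  # raw | validated | discarded
    discard_reason: str | None = None
    non_reference: bool = False
    strain_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.orf_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.orf_id}: at least one exon required")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 > s2:
                raise ValueError(f"{self.orf_id}: overlapping exons")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if tuple(expected) != tuple(self.exons):
            raise ValueError(f"{self.orf_id}: exons not in coding order")

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic extent (0-based half-open) from first to last base."""
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    @property
    def structure_key(self) -> tuple:
        """Identity key: two ORFs with equal keys are the same model."""
        return (self.seq_id, self.strand, self.exons)

    def shifted(self, offset: int) -> "OrfModel":
        return replace(
            self, exons=tuple((s + offset, e + offset) for s, e in self.exons)
        )


@dataclass(frozen=True)
class ValidationReport:
    """Accuracy of a predicted ORF set against a curated truth set."""

    n_true: int
    n_predicted: int
    n_identical: int

    def __post_init__(self) -> None:
        if self.n_predicted < 1:
            raise ValueError("FDR undefined for an empty prediction set")
        if self.n_identical > min(self.n_true, self.n_predicted):
            raise ValueError("n_identical exceeds set sizes")

    @property
    def identical_pct(self) -> float:
        return 100.0 * self.n_identical / self.n_predicted

    @property
    def fdr_pct(self) -> float:
        return 100.0 * (self.n_predicted - self.n_identical) / self.n_predicted

    def as_dict(self) -> dict:
        return {
            "n_true": self.n_true,
            "n_predicted": self.n_predicted,
            "n_identical": self.n_identical,
            "identical_pct": self.identical_pct,
            "fdr_pct": self.fdr_pct,
        }


# ---------------------------------------------------------------------------
# sequence extraction
# ---------------------------------------------------------------------------

def extract_spliced_cds(orf: OrfModel, genome: GenomeSequence) -> str:
    """Concatenate exon sequences in coding order (revcomp on minus)."""
    parts = []
    for s, e in orf.exons:
        if not 0 <= s < e <= len(genome):
            raise ValueError(
                f"{orf.orf_id}: exon {s}..{e} outside {genome.record_id} "
                f"(length {len(genome)})"
            )
        chunk = genome.sequence[s:e]
        parts.append(reverse_complement(chunk) if orf.strand == "-" else chunk)
    return "".join(parts)


def extract_introns(orf: OrfModel, genome: GenomeSequence) -> list[str]:
    """Coding-strand sequences of the gaps between consecutive exons."""
    introns = []
    for (s1, e1), (s2, e2) in zip(orf.exons, orf.exons[1:]):
        if orf.strand == "+":
            lo, hi = e1, s2
        else:
            lo, hi = e2, s1
        chunk = genome.sequence[lo:hi]
        introns.append(reverse_complement(chunk) if orf.strand == "-" else chunk)
    return introns


_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_orf(orf: OrfModel, genome: GenomeSequence) -> str:
    """Protein sequence of the spliced CDS, without the terminal stop."""
    cds = extract_spliced_cds(orf, genome)
    if len(cds) % 3:
        raise ValueError(f"{orf.orf_id}: CDS length not divisible by 3")
    protein = []
    for i in range(0, len(cds) - 3, 3):
        protein.append(_CODON_TABLE.get(cds[i : i + 3], "X"))
    return "".join(protein)


# ---------------------------------------------------------------------------
# structural filters
# ---------------------------------------------------------------------------

def check_terminal_codons(orf: OrfModel, genome: GenomeSequence) -> OrfModel:
    """ATG start, in-frame stop at the end, no premature stop.

    Returns the ORF with ``status`` set to ``validated`` or ``discarded``
    with a machine-readable reason (``no_start``, ``no_stop``,
    ``not_in_frame``, ``internal_stop``).
    """
    cds = extract_spliced_cds(orf, genome).upper()

    def discard(reason: str) -> OrfModel:
        return replace(orf, status="discarded", discard_reason=reason)

    if not cds.startswith(START_CODON):
        return discard("no_start")
    if len(cds) % 3 != 0:
        return discard("not_in_frame")
    if cds[-3:] not in STOP_CODONS:
        return discard("no_stop")
    for i in range(0, len(cds) - 3, 3):
        if cds[i : i + 3] in STOP_CODONS:
            return discard("internal_stop")
    return replace(orf, status="validated", discard_reason=None)


def check_branch_points(
    orf: OrfModel,
    genome: GenomeSequence,
    catalog: BranchPointCatalog = BRANCH_POINTS,
) -> OrfModel:
    """Every intron must contain a branch-point heptamer.

    Single-exon ORFs pass vacuously.  The search is a case-insensitive
    substring scan over the full intron on the coding strand; introns
    shorter than 7 bp cannot contain a heptamer and fail outright.
    """
    motifs = catalog.dna_motifs
    for intron in extract_introns(orf, genome):
        seq = intron.upper()
        if len(seq) < 7 or not any(m in seq for m in motifs):
            return replace(orf, status="discarded", discard_reason="no_branch_point")
    return replace(orf, status="validated", discard_reason=None)


# ---------------------------------------------------------------------------
# merging and consolidation
# ---------------------------------------------------------------------------

def _sort_key(orf: OrfModel) -> tuple:
    (lo, hi) = orf.span
    return (orf.seq_id, lo, hi, orf.strand)


def merge_sources(
    homology_set: Sequence[OrfModel], abinitio_set: Sequence[OrfModel]
) -> list[OrfModel]:
    """Union of both prediction sets.

    Exact structural duplicates (same contig, strand and exon list)
    collapse to one record tagged ``source='merged'``.  ORFs sharing a
    stop coordinate but differing in start (alternative start sites)
    are distinct structures and are both kept.
    """
    by_key: dict[tuple, OrfModel] = {}
    for orf in list(homology_set) + list(abinitio_set):
        key = orf.structure_key
        if key in by_key:
            kept = by_key[key]
            if kept.source != orf.source:
                by_key[key] = replace(kept, source="merged")
        else:
            by_key[key] = orf
    return sorted(by_key.values(), key=_sort_key)


def _overlap_clusters(orfs: list[OrfModel]) -> list[list[OrfModel]]:
    """Transitive ≥1 bp span-overlap clusters (input pre-grouped by contig)."""
    ordered = sorted(orfs, key=_sort_key)
    clusters: list[list[OrfModel]] = []
    current: list[OrfModel] = []
    current_end = -1
    for orf in ordered:
        lo, hi = orf.span
        if current and lo < current_end:
            current.append(orf)
            current_end = max(current_end, hi)
        else:
            if current:
                clusters.append(current)
            current = [orf]
            current_end = hi
    if current:
        clusters.append(current)
    return clusters


def consolidate_undefined(
    orfs: Sequence[OrfModel],
    min_len: int = 300,
    strict_greater: bool = False,
    return_discarded: bool = False,
):
    """Resolve clusters of overlapping 'undefined' ORFs and apply the
    length cutoff.

    Within each same-strand, same-contig cluster of overlapping
    undefined ORFs only the longest spliced model survives (ties:
    leftmost start).  Surviving undefined ORFs shorter than ``min_len``
    spliced bp are dropped (``strict_greater`` switches the cutoff from
    ``>= min_len`` to ``> min_len``).  Labeled ORFs pass through
    untouched.  With ``return_discarded`` the dropped models are
    returned too, each carrying its discard reason, so
    ``|in| = |kept| + |discarded|``.
    """
    labeled = [o for o in orfs if o.label != "undefined"]
    undefined = [o for o in orfs if o.label == "undefined"]

    survivors: list[OrfModel] = []
    discarded: list[OrfModel] = []
    groups: dict[tuple[str, str], list[OrfModel]] = {}
    for o in undefined:
        groups.setdefault((o.seq_id, o.strand), []).append(o)
    for group in groups.values():
        for cluster in _overlap_clusters(group):
            best = max(cluster, key=lambda o: (o.spliced_length, -o.span[0]))
            survivors.append(best)
            discarded.extend(
                replace(o, status="discarded", discard_reason="consolidated")
                for o in cluster
                if o is not best
            )

    def long_enough(o: OrfModel) -> bool:
        return o.spliced_length > min_len if strict_greater else o.spliced_length >= min_len

    kept = labeled + [o for o in survivors if long_enough(o)]
    discarded.extend(
        replace(o, status="discarded", discard_reason="too_short")
        for o in survivors
        if not long_enough(o)
    )
    kept = sorted(kept, key=_sort_key)
    if return_discarded:
        return kept, sorted(discarded, key=_sort_key)
    return kept


# ---------------------------------------------------------------------------
# validation mode
# ---------------------------------------------------------------------------

def build_true_set(
    reference_orfs: Sequence[OrfModel], min_len: int = 300
) -> list[OrfModel]:
    """Curate a reference truth set with the Dubious-overlap rules.

    ORFs shorter than ``min_len`` are removed first.  Then, per contig
    and regardless of strand: if an overlapping pair has exactly one
    Dubious member, the Dubious one is excluded; of two overlapping
    Dubious ORFs the shorter (ties: the one starting later) is excluded;
    overlapping Verified pairs are both kept.  Applied to a fixed point,
    so the operation is idempotent.
    """
    pool = [o for o in reference_orfs if o.spliced_length >= min_len]

    changed = True
    while changed:
        changed = False
        removed: set[str] = set()
        by_contig: dict[str, list[OrfModel]] = {}
        for o in pool:
            by_contig.setdefault(o.seq_id, []).append(o)
        for contig_orfs in by_contig.values():
            ordered = sorted(contig_orfs, key=_sort_key)
            for i, a in enumerate(ordered):
                for b in ordered[i + 1 :]:
                    if b.span[0] >= a.span[1]:
                        break
                    if a.orf_id in removed or b.orf_id in removed:
                        continue
                    a_dub = a.classification == "Dubious"
                    b_dub = b.classification == "Dubious"
                    if a_dub and b_dub:
                        loser = min(
                            (a, b),
                            key=lambda o: (o.spliced_length, -o.span[0]),
                        )
                        removed.add(loser.orf_id)
                    elif a_dub:
                        removed.add(a.orf_id)
                    elif b_dub:
                        removed.add(b.orf_id)
        if removed:
            pool = [o for o in pool if o.orf_id not in removed]
            changed = True
    return sorted(pool, key=_sort_key)


def validation_metrics(
    predicted: Sequence[OrfModel], true_set: Sequence[OrfModel]
) -> ValidationReport:
    """Exact-structure agreement between predictions and the truth set.

    An ORF counts as identical when contig, strand and the full exon
    list match exactly.  ``identical_pct`` and ``fdr_pct`` are exact
    complements; rounding happens only at presentation.
    """
    true_keys = {o.structure_key for o in true_set}
    pred_keys = {o.structure_key for o in predicted}
    if not pred_keys:
        raise ValueError("FDR undefined for an empty prediction set")
    n_identical = len(pred_keys & true_keys)
    return ValidationReport(
        n_true=len(true_keys), n_predicted=len(pred_keys), n_identical=n_identical
    )


def comparison_metrics(
    mine: set, theirs: set
) -> tuple[int, int, int, float]:
    """Overlap of two catalogues of (group) labels.

    Returns ``(shared, mine_only, theirs_only, shared_pct_of_theirs)``
    where the percentage is 100·|shared|/|theirs|, unrounded.
    """
    if not theirs:
        raise ValueError("comparison undefined for an empty external catalogue")
    shared = len(mine & theirs)
    return (
        shared,
        len(mine - theirs),
        len(theirs - mine),
        100.0 * shared / len(theirs),
    )


# ---------------------------------------------------------------------------
# GFF3 conversion
# ---------------------------------------------------------------------------

def orf_to_features(orf: OrfModel, source: str | None = None) -> list[FeatureRecord]:
    """One mRNA line plus one CDS line per exon, 1-based inclusive."""
    lo, hi = orf.span
    g_start, g_end = to_gff3(lo, hi)
    attrs = {"ID": orf.orf_id, "Name": orf.label}
    if orf.classification != "unknown":
        attrs["classification"] = orf.classification
    if orf.non_reference:
        attrs["non_reference"] = "true"
    src = source or orf.source
    feats = [
        FeatureRecord(orf.seq_id, src, "mRNA", g_start, g_end, orf.strand, ".", ".", attrs)
    ]
    phase = 0
    for i, (s, e) in enumerate(orf.exons):
        cs, ce = to_gff3(s, e)
        feats.append(
            FeatureRecord(
                orf.seq_id, src, "CDS", cs, ce, orf.strand, str(phase), ".",
                {"ID": f"{orf.orf_id}.cds", "Parent": orf.orf_id},
            )
        )
        phase = (3 - ((e - s) - phase) % 3) % 3
    return feats


def features_to_orfs(features: Iterable[FeatureRecord]) -> list[OrfModel]:
    """Assemble CDS segments sharing a Parent into :class:`OrfModel`s."""
    parents: dict[str, FeatureRecord] = {}
    cds: dict[str, list[FeatureRecord]] = {}
    for f in features:
        if f.feature_type == "mRNA" and "ID" in f.attributes:
            parents[f.attributes["ID"]] = f
        elif f.feature_type == "CDS":
            parent = f.attributes.get("Parent") or f.attributes.get("ID")
            if parent is None:
                raise ValueError("CDS feature without Parent or ID attribute")
            cds.setdefault(parent, []).append(f)
    orfs = []
    for parent_id, segs in cds.items():
        strand = segs[0].strand
        if any(s.strand != strand for s in segs):
            raise ValueError(f"{parent_id}: CDS segments on mixed strands")
        intervals = sorted(to_internal(s.start, s.end) for s in segs)
        if strand == "-":
            intervals = intervals[::-1]
        meta = parents.get(parent_id)
        attrs = meta.attributes if meta else segs[0].attributes
        orfs.append(
            OrfModel(
                orf_id=parent_id,
                seq_id=segs[0].seq_id,
                strand=strand,
                exons=tuple(intervals),
                source=(meta.source if meta else segs[0].source),
                classification=attrs.get("classification", "unknown"),
                label=attrs.get("Name", "undefined"),
                non_reference=attrs.get("non_reference") == "true",
            )
        )
    return sorted(orfs, key=_sort_key)
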