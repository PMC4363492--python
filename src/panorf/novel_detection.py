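"""Discovery of strain sequences absent from the reference genome.

The upstream workflow maps each strain's reads to the reference,
extracts the unmapped fraction with three samtools flag filters
(``-f 4 -F 264``, ``-f 8 -F 260``, ``-f 12 -F 256``), assembles those
reads into contigs, and discards contigs that are short or that align
back to the reference.  The surviving "novel" contigs are located on
the strain's own whole-genome assembly, and ORFs annotated over those
assembly regions become the strain's non-reference ORF set.

This module implements the decision logic of that chain — the flag
triage as bit arithmetic, the contig filters, best-hit placement, and
interval-overlap ORF collection — and consumes the standard outputs
(SAM flags, FASTA contigs, tabular alignments) of the external mapping
and assembly tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

from .formats_io import TabularHit
from .orf_refinement import OrfModel

__all__ = [
    "FlagFilter",
    "NovelContig",
    "UNMAPPED_FILTERS",
    "unmapped_triage",
    "filter_novel_contigs",
    "map_to_own_assembly",
    "collect_nonreference_orfs",
]


@dataclass(frozen=True)
class FlagFilter:
    """A samtools-style require (-f) / exclude (-F) SAM flag mask pair."""

    require_mask: int
    exclude_mask: int

    def __post_init__(self) -> None:
        if self.require_mask & self.exclude_mask:
            raise ValueError("require and exclude masks share bits")

    def matches(self, flag: int) -> bool:
        return (flag & self.require_mask) == self.require_mask and (
            flag & self.exclude_mask
        ) == 0


# read unmapped, not secondary/mate-unmapped-dup combination per filter:
#   -f 4  -F 264 : read unmapped,          exclude mate-unmapped | secondary
#   -f 8  -F 260 : mate unmapped,          exclude read-unmapped | secondary
#   -f 12 -F 256 : both ends unmapped,     exclude secondary
UNMAPPED_FILTERS: tuple[FlagFilter, ...] = (
    FlagFilter(4, 264),
    FlagFilter(8, 260),
    FlagFilter(12, 256),
)


def unmapped_triage(flag: int) -> bool:
    """True if a SAM flag belongs to the unmapped-read extraction.

    The union of the three filters: reads where either end (or both)
    is unmapped, excluding secondary alignments.
    """
    if not 0 <= flag < 4096:
        raise ValueError(f"SAM flag {flag} out of range [0, 4096)")
    return any(f.matches(flag) for f in UNMAPPED_FILTERS)


@dataclass(frozen=True)
class NovelContig:
    """A contig assembled from unmapped reads, candidate novel sequence."""

    contig_id: str
    sequence: str
    reference_aligned_fraction: float = 0.0
    assembly_interval: tuple[str, int, int, str] | None = None  # seq_id, start, end, strand
    unplaced: bool = False
    discard_reason: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.reference_aligned_fraction <= 1.0:
            raise ValueError("reference_aligned_fraction must be in [0, 1]")

    @property
    def length(self) -> int:
        return len(self.sequence)


def reference_aligned_fractions(
    contigs: Sequence[NovelContig],
    ref_hits: Sequence[TabularHit],
    min_identity: float = 90.0,
) -> list[NovelContig]:
    """Populate each contig's aligned-to-reference fraction.

    The fraction is the union of the contig (query) intervals of all
    reference hits at >= ``min_identity`` percent identity, divided by
    the contig length.
    """
    by_query: dict[str, list[tuple[int, int]]] = {}
    for h in ref_hits:
        if h.percent_identity < min_identity:
            continue
        s, e = sorted((h.q_start, h.q_end))
        by_query.setdefault(h.query_id, []).append((s - 1, e))

    out = []
    for c in contigs:
        ivals = sorted(by_query.get(c.contig_id, ()))
        covered = 0
        cur_s = cur_e = None
        for s, e in ivals:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            covered += cur_e - cur_s
        out.append(replace(c, reference_aligned_fraction=min(covered / c.length, 1.0)))
    return out


def filter_novel_contigs(
    contigs: Sequence[NovelContig],
    min_len: int = 300,
    max_ref_fraction: float = 0.5,
) -> tuple[list[NovelContig], list[NovelContig]]:
    """Keep contigs that are long enough and absent from the reference.

    A contig survives iff its length is at least ``min_len`` (the same
    cutoff applied to predicted ORFs) and at most ``max_ref_fraction``
    of it aligns to the reference genome.  Returns ``(kept, discarded)``
    with each discard carrying a reason (``too_short`` /
    ``in_reference``), so ``|kept| + |discarded| = |input|``.
    """
    kept: list[NovelContig] = []
    discarded: list[NovelContig] = []
    for c in contigs:
        if c.length < min_len:
            discarded.append(replace(c, discard_reason="too_short"))
        elif c.reference_aligned_fraction > max_ref_fraction:
            discarded.append(replace(c, discard_reason="in_reference"))
        else:
            kept.append(c)
    return kept, discarded


def map_to_own_assembly(
    novel: Sequence[NovelContig], contig_hits: Sequence[TabularHit]
) -> list[NovelContig]:
    """Annotate each novel contig with its best assembly placement.

    Best hit = highest bit score; ties broken by longest alignment,
    then lexicographically smallest assembly sequence name.  Contigs
    with no hit are flagged unplaced and retained with a warning.
    """
    by_query: dict[str, list[TabularHit]] = {}
    for h in contig_hits:
        by_query.setdefault(h.query_id, []).append(h)

    placed: list[NovelContig] = []
    for c in novel:
        hits = by_query.get(c.contig_id)
        if not hits:
            warnings.warn(f"novel contig {c.contig_id} has no assembly hit", stacklevel=2)
            placed.append(replace(c, unplaced=True, assembly_interval=None))
            continue
        best = max(hits, key=lambda h: (h.bit_score, h.alignment_length, _neg_lex(h.subject_id)))
        s, e = sorted((best.s_start, best.s_end))
        strand = "+" if best.s_start <= best.s_end else "-"
        # tabular coordinates are 1-based inclusive; store internal half-open
        placed.append(
            replace(c, unplaced=False, assembly_interval=(best.subject_id, s - 1, e, strand))
        )
    return placed


class _neg_lex(str):
    """Inverts lexicographic order so max() picks the smallest name."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def collect_nonreference_orfs(
    annotated_orfs: Sequence[OrfModel], novel: Sequence[NovelContig]
) -> list[OrfModel]:
    """ORFs whose coding span overlaps any placed novel interval.

    Overlap is >= 1 bp of the genomic span, strand-agnostic.  Returned
    ORFs are deduplicated by structure and tagged ``non_reference``.
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    for c in novel:
        if c.assembly_interval is not None:
            seq_id, s, e, _ = c.assembly_interval
            intervals.setdefault(seq_id, []).append((s, e))

    collected: dict[tuple, OrfModel] = {}
    for orf in annotated_orfs:
        lo, hi = orf.span
        for s, e in intervals.get(orf.seq_id, ()):
            if lo < e and s < hi:
                collected.setdefault(orf.structure_key, replace(orf, non_reference=True))
                break
    return sorted(collected.values(), key=lambda o: (o.seq_id, o.span, o.strand))
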