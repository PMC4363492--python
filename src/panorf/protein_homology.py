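"""Pairwise protein comparison and tiered homology labeling.

Predicted ORF proteins are compared against a reference protein set
either with the built-in Smith–Waterman aligner (BLOSUM62, affine gaps,
Karlin–Altschul e-values) or by ingesting externally computed
BLAST-style tabular hits.  Two labeling tiers mirror the annotation
workflow: a *strict* tier (e-value < 1e-6, length difference <= 5%,
similarity > 90%) names an ORF after its best bona fide match, and a
*relaxed* second pass (similarity > 80%, length test dropped) is used
against broader databases.  Anything that passes neither tier stays
"undefined".  A third, much looser criterion (e-value < 0.1, identity
> 75%, length similarity > 75%) defines edges for homologue grouping.

The internal e-values use fixed gapped-BLOSUM62 Karlin–Altschul
constants; they approximate BLAST's but are not bit-for-bit equal —
users needing BLAST-exact behaviour supply tabular hits instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .formats_io import TabularHit

__all__ = [
    "AlignerParams",
    "SimilarityRecord",
    "align_proteins",
    "classify_orf",
    "grouping_edge",
    "hit_to_similarity",
    "DEFAULT_PARAMS",
    "STRICT_EVALUE",
    "STRICT_LENGTH_DIFF",
    "STRICT_SIMILARITY",
    "RELAXED_SIMILARITY",
    "GROUP_EVALUE",
    "GROUP_IDENTITY",
    "GROUP_LENGTH_SIM",
]

# labeling-tier cutoffs
STRICT_EVALUE = 1e-6
STRICT_LENGTH_DIFF = 0.05
STRICT_SIMILARITY = 90.0
RELAXED_SIMILARITY = 80.0

# homologue-grouping cutoffs
GROUP_EVALUE = 0.1
GROUP_IDENTITY = 75.0
GROUP_LENGTH_SIM = 0.75


@dataclass(frozen=True)
class AlignerParams:
    """Scoring scheme and e-value statistics for the internal aligner.

    A gap of length L costs ``gap_open + gap_extend * L`` (the BLASTP
    convention for its default 11/1 penalties).  ``karlin_lambda`` and
    ``karlin_k`` are the gapped BLOSUM62 constants; the e-value of a
    raw score S over a search space of m*n residues is K*m*n*exp(-λS).
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin constants must be positive")

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.karlin_k * m * n * math.exp(-self.karlin_lambda * score)


DEFAULT_PARAMS = AlignerParams()


@dataclass(frozen=True)
class SimilarityRecord:
    """Metrics of one pairwise protein comparison.

    ``identity_pct`` and ``similarity_pct`` are percentages over
    alignment columns (gap columns included); ``similarity`` counts
    BLAST-style positives, i.e. columns with a positive substitution
    score.  ``length_sim`` = min/max of the two full sequence lengths;
    ``length_diff`` is relative to the subject length.
    """

    query_id: str
    subject_id: str
    identity_pct: float
    similarity_pct: float
    length_sim: float
    length_diff: float
    evalue: float
    raw_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_pct <= self.similarity_pct <= 100.0 + 1e-9:
            raise ValueError("need 0 <= identity <= similarity <= 100")
        if not 0.0 < self.length_sim <= 1.0:
            raise ValueError("length_sim must be in (0, 1]")


@lru_cache(maxsize=8)
def _matrix(name: str):
    return substitution_matrices.load(name)


@lru_cache(maxsize=8)
def _aligner(name: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _matrix(name)
    # Biopython charges open on the first gapped column and extend after;
    # -(open+extend)/-extend reproduces the open + extend*L total.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_proteins(
    a: str,
    b: str,
    params: AlignerParams = DEFAULT_PARAMS,
    query_id: str = "query",
    subject_id: str = "subject",
) -> SimilarityRecord:
    """Best local alignment of two protein sequences.

    Smith–Waterman with affine gaps under ``params``; identity and
    positives are counted over the alignment columns of the single best
    local alignment (ties resolved by Biopython's deterministic
    traceback).
    """
    if not a or not b:
        raise ValueError("cannot align an empty protein sequence")
    a, b = a.upper(), b.upper()
    aligner = _aligner(params.substitution_matrix, params.gap_open, params.gap_extend)
    matrix = _matrix(params.substitution_matrix)
    alignments = aligner.align(a, b)
    la, lb = len(a), len(b)
    if len(alignments) == 0:
        # no residue pair scores positive: the best local alignment is empty
        return SimilarityRecord(
            query_id=query_id, subject_id=subject_id,
            identity_pct=0.0, similarity_pct=0.0,
            length_sim=min(la, lb) / max(la, lb),
            length_diff=abs(la - lb) / lb,
            evalue=params.evalue(0.0, la, lb),
            raw_score=0.0,
        )
    alignment = alignments[0]
    score = alignment.score

    blocks_a, blocks_b = alignment.aligned
    identical = 0
    positive = 0
    matched_cols = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        for x, y in zip(a[a0:a1], b[b0:b1]):
            matched_cols += 1
            if x == y:
                identical += 1
            if matrix[x, y] > 0:
                positive += 1
    gap_cols = 0
    for i in range(1, len(blocks_a)):
        gap_cols += blocks_a[i][0] - blocks_a[i - 1][1]
        gap_cols += blocks_b[i][0] - blocks_b[i - 1][1]
    n_cols = matched_cols + gap_cols

    return SimilarityRecord(
        query_id=query_id,
        subject_id=subject_id,
        identity_pct=100.0 * identical / n_cols if n_cols else 0.0,
        similarity_pct=100.0 * positive / n_cols if n_cols else 0.0,
        length_sim=min(la, lb) / max(la, lb),
        length_diff=abs(la - lb) / lb,
        evalue=params.evalue(score, la, lb),
        raw_score=score,
    )


def hit_to_similarity(
    hit: TabularHit,
    query_lengths: Mapping[str, int] | None = None,
    subject_lengths: Mapping[str, int] | None = None,
) -> SimilarityRecord:
    """Map a 12-column tabular hit onto the similarity metrics.

    The tabular dialect carries no positives count, so percent identity
    stands in for similarity (a conservative lower bound).  Full
    sequence lengths come from the optional length maps; without them
    the aligned span lengths are used.
    """
    lq = (query_lengths or {}).get(hit.query_id, abs(hit.q_end - hit.q_start) + 1)
    ls = (subject_lengths or {}).get(hit.subject_id, abs(hit.s_end - hit.s_start) + 1)
    return SimilarityRecord(
        query_id=hit.query_id,
        subject_id=hit.subject_id,
        identity_pct=hit.percent_identity,
        similarity_pct=hit.percent_identity,
        length_sim=min(lq, ls) / max(lq, ls),
        length_diff=abs(lq - ls) / ls,
        evalue=hit.evalue,
        raw_score=hit.bit_score,
    )


def _passes_tier(
    rec: SimilarityRecord,
    tier: str,
    evalue_cutoff: float = STRICT_EVALUE,
    length_diff_cutoff: float = STRICT_LENGTH_DIFF,
    strict_similarity: float = STRICT_SIMILARITY,
    relaxed_similarity: float = RELAXED_SIMILARITY,
) -> bool:
    if rec.evalue >= evalue_cutoff:
        return False
    if tier == "strict":
        return (
            rec.length_diff <= length_diff_cutoff
            and rec.similarity_pct > strict_similarity
        )
    if tier == "relaxed":
        # second pass drops the length test and loosens only similarity
        return rec.similarity_pct > relaxed_similarity
    raise ValueError(f"unknown tier {tier!r}")


def classify_orf(
    orf_protein: str | None,
    db: Mapping[str, str] | None = None,
    tier: str = "strict",
    hits: Sequence[TabularHit] | None = None,
    params: AlignerParams = DEFAULT_PARAMS,
    query_id: str = "query",
    query_lengths: Mapping[str, int] | None = None,
    subject_lengths: Mapping[str, int] | None = None,
) -> str:
    """Label an ORF after its best passing database match, else "undefined".

    ``db`` mode aligns the ORF protein against every database protein
    with the internal aligner; ``hits`` mode ingests precomputed
    tabular records.  The best passing subject is the one with the
    lowest e-value (ties: highest raw score, then lexicographically
    smallest subject name).
    """
    records: list[SimilarityRecord]
    if hits is not None:
        records = [hit_to_similarity(h, query_lengths, subject_lengths) for h in hits]
    elif db:
        if orf_protein is None:
            raise ValueError("db mode requires the ORF protein sequence")
        records = []
        for name, seq in db.items():
            if tier == "strict":
                # strict tier rejects length_diff > 5% regardless of the
                # alignment, so skip those pairs without aligning
                if abs(len(orf_protein) - len(seq)) / len(seq) > STRICT_LENGTH_DIFF:
                    continue
            records.append(
                align_proteins(orf_protein, seq, params, query_id=query_id, subject_id=name)
            )
    else:
        raise ValueError("either a protein database or tabular hits are required")

    passing = [r for r in records if _passes_tier(r, tier)]
    if not passing:
        return "undefined"
    best = min(passing, key=lambda r: (r.evalue, -r.raw_score, r.subject_id))
    return best.subject_id


def grouping_edge(rec: SimilarityRecord) -> bool:
    """Homologue-grouping criterion for a pair of non-reference ORFs."""
    return (
        rec.evalue < GROUP_EVALUE
        and rec.identity_pct > GROUP_IDENTITY
        and rec.length_sim > GROUP_LENGTH_SIM
    )


def pairwise_similarity(
    proteins: Mapping, params: AlignerParams = DEFAULT_PARAMS
) -> list[tuple]:
    """All-vs-all ``(key_a, key_b, SimilarityRecord)`` triples.

    Pairs whose full-length ratio already fails the grouping
    length-similarity cutoff are skipped: ``length_sim`` depends only
    on the sequence lengths, so no alignment can turn such a pair into
    a grouping edge.
    """
    keys = sorted(proteins)
    triples = []
    for i, ka in enumerate(keys):
        for kb in keys[i + 1 :]:
            la, lb = len(proteins[ka]), len(proteins[kb])
            if min(la, lb) / max(la, lb) <= GROUP_LENGTH_SIM:
                continue
            rec = align_proteins(
                proteins[ka], proteins[kb], params,
                query_id=str(ka), subject_id=str(kb),
            )
            triples.append((ka, kb, rec))
    return triples


def audit_table(records: Iterable[SimilarityRecord], tier: str) -> str:
    """TSV audit of classification metrics (query, subject, tier, metrics)."""
    lines = [
        "query\tsubject\ttier\tidentity_pct\tsimilarity_pct\tlength_sim\tlength_diff\tevalue\traw_score\tpasses"
    ]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.query_id,
                    r.subject_id,
                    tier,
                    f"{r.identity_pct:.2f}",
                    f"{r.similarity_pct:.2f}",
                    f"{r.length_sim:.4f}",
                    f"{r.length_diff:.4f}",
                    f"{r.evalue:.3g}",
                    f"{r.raw_score:.1f}",
                    str(_passes_tier(r, tier)),
                ]
            )
        )
    return "\n".join(lines) + "\n"
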