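"""Readers and writers for the standard formats the toolkit touches.

Coordinate conventions
----------------------
GFF3 files use 1-based inclusive coordinates; everything inside the
toolkit uses 0-based half-open intervals.  The two converters
:func:`to_internal` and :func:`to_gff3` are the *only* place the
conversion happens — every other module consumes internal coordinates.

Formats handled here: FASTA (via Biopython), GFF3 feature lines,
BLAST-style 12-column tabular hits, and Newick trees (branch lengths
written to six decimals; parsing delegated to scikit-bio).
"""

from __future__ import annotations

import io
import urllib.parse
import warnings
from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

__all__ = [
    "GenomeSequence",
    "FeatureRecord",
    "TabularHit",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_tabular_hits",
    "write_tabular_hits",
    "write_newick",
    "read_newick",
    "to_internal",
    "to_gff3",
]

FASTA_WRAP = 60


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSequence:
    """One FASTA record: an assembly contig, scaffold or chromosome."""

    record_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.record_id!r}")
        if any(c.isspace() for c in self.sequence):
            raise ValueError(f"whitespace in sequence {self.record_id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FeatureRecord:
    """One GFF3 feature line, coordinates kept 1-based inclusive."""

    seq_id: str
    source: str
    feature_type: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    phase: str = "."
    score: str = "."
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"invalid interval {self.start}..{self.end} on {self.seq_id}"
            )


@dataclass(frozen=True)
class TabularHit:
    """One row of BLAST-style 12-column tabular output (outfmt 6)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity must be in [0, 100]")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")


# ---------------------------------------------------------------------------
# coordinate converters (the single conversion point)
# ---------------------------------------------------------------------------

def to_internal(start: int, end: int) -> tuple[int, int]:
    """GFF3 1-based inclusive -> internal 0-based half-open."""
    return start - 1, end


def to_gff3(start: int, end: int) -> tuple[int, int]:
    """Internal 0-based half-open -> GFF3 1-based inclusive."""
    return start + 1, end


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[GenomeSequence]:
    """Read a FASTA file into :class:`GenomeSequence` records.

    Sequences are uppercased; record order is preserved.  Duplicate
    record IDs raise ``ValueError``; an empty file returns an empty
    list with a warning.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA record ID {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GenomeSequence(rec.id, str(rec.seq).upper()))
    if not records:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[GenomeSequence], path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.record_id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_STRANDS = {"+", "-", ".", "?"}


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        attrs[urllib.parse.unquote(key.strip())] = urllib.parse.unquote(value)
    return attrs


def _format_attributes(attrs: dict[str, str]) -> str:
    if not attrs:
        return "."
    quoted = urllib.parse.quote
    safe = ":/ ()"  # GFF3 reserves tab, newline, ;=%&, and comma
    return ";".join(f"{quoted(k, safe=safe)}={quoted(v, safe=safe)}" for k, v in attrs.items())


def read_gff3(path) -> list[FeatureRecord]:
    """Read GFF3 feature lines, tolerating ``##`` directives and comments.

    Coordinates are kept 1-based inclusive exactly as in the file;
    attribute keys and values are percent-decoded.  Malformed intervals
    or strand symbols raise ``ValueError`` naming the line number.
    """
    features: list[FeatureRecord] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##FASTA"):
                    break
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seq_id, source, ftype, start_s, end_s, score, strand, phase, attr_s = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start > end:
                raise ValueError(f"{path}:{lineno}: start {start} > end {end}")
            if strand not in _STRANDS:
                raise ValueError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
            attrs = _parse_attributes(attr_s) if attr_s != "." else {}
            fid = attrs.get("ID")
            if fid is not None:
                # CDS segments of one feature legitimately share an ID
                if fid in seen_ids and ftype not in ("CDS", "exon"):
                    raise ValueError(f"{path}:{lineno}: duplicate feature ID {fid!r}")
                seen_ids.add(fid)
            features.append(
                FeatureRecord(seq_id, source, ftype, start, end, strand, phase, score, attrs)
            )
    return features


def write_gff3(features: Iterable[FeatureRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    [
                        f.seq_id,
                        f.source,
                        f.feature_type,
                        str(f.start),
                        str(f.end),
                        f.score,
                        f.strand,
                        f.phase,
                        _format_attributes(f.attributes),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BLAST-style tabular
# ---------------------------------------------------------------------------

def read_tabular_hits(path) -> list[TabularHit]:
    """Read 12-column tab-separated alignment hits, preserving row order."""
    hits: list[TabularHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
            try:
                hits.append(
                    TabularHit(
                        query_id=cols[0],
                        subject_id=cols[1],
                        percent_identity=float(cols[2]),
                        alignment_length=int(cols[3]),
                        mismatches=int(cols[4]),
                        gap_opens=int(cols[5]),
                        q_start=int(cols[6]),
                        q_end=int(cols[7]),
                        s_start=int(cols[8]),
                        s_end=int(cols[9]),
                        evalue=float(cols[10]),
                        bit_score=float(cols[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_tabular_hits(hits: Iterable[TabularHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id,
                        h.subject_id,
                        h.percent_identity,
                        h.alignment_length,
                        h.mismatches,
                        h.gap_opens,
                        h.q_start,
                        h.q_end,
                        h.s_start,
                        h.s_end,
                        h.evalue,
                        h.bit_score,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def _newick_node(node: TreeNode) -> str:
    if node.is_tip():
        label = node.name or ""
        if any(ch in label for ch in "(),:;\t\n "):
            label = "'" + label.replace("'", "''") + "'"
    else:
        label = "(" + ",".join(_newick_node(c) for c in node.children) + ")"
    if node.length is not None:
        label += f":{node.length:.6f}"
    return label


def write_newick(tree: TreeNode, path) -> None:
    """Serialize a tree to Newick with branch lengths to six decimals.

    Raises ``ValueError`` on duplicate leaf labels.  An unrooted tree is
    represented the standard way, as a trifurcation at the root node.
    """
    tips = [t.name for t in tree.tips()]
    if len(tips) < 2:
        raise ValueError("tree must have at least 2 leaves")
    dupes = {name for name in tips if tips.count(name) > 1}
    if dupes:
        raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
    with open(path, "w") as fh:
        fh.write(_newick_node(tree) + ";\n")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def newick_string(tree: TreeNode) -> str:
    """In-memory Newick serialization (same format as :func:`write_newick`)."""
    buf = io.StringIO()
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValueError("duplicate leaf labels")
    buf.write(_newick_node(tree) + ";")
    return buf.getvalue()
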