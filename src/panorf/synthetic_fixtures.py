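"""Deterministic synthetic genomes with planted pan-genome structure.

The generator builds a toy reference genome with planted protein-coding
genes (optionally spliced, with or without valid branch-point motifs),
then derives per-strain assemblies by inserting novel gene cassettes at
intergenic positions.  Which strains carry which novel family is
derived from a planted random binary tree over the strains: every
family's strain set is a clade of that tree, and each non-trivial
split of the tree is covered by at least one family.  Presence/absence
Hamming distances over such clade-indicator columns are exactly
additive on the planted tree, so neighbor joining provably recovers
the planted bipartitions — end-to-end recovery is a construction
guarantee, not a statistical hope.

Two further guarantees keep the planted homologue groups exactly
recoverable:

* family protein lengths grow geometrically with ratio > 4/3, so any
  two proteins from *different* families fail the length-similarity
  grouping cutoff (min/max <= 0.75) no matter how their alignment
  scores;
* within a family, members differ only by point substitutions at the
  configured per-residue rate, far inside the grouping thresholds.

Everything is drawn from a single numpy Generator seeded from
``SimConfig.seed``; the same seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .formats_io import GenomeSequence, TabularHit, write_fasta, write_gff3, write_tabular_hits
from .novel_detection import NovelContig
from .orf_refinement import (
    BRANCH_POINTS,
    OrfModel,
    orf_to_features,
    reverse_complement,
)

__all__ = [
    "SimConfig",
    "ReferenceSim",
    "StrainData",
    "simulate_reference",
    "simulate_reference_detail",
    "simulate_candidates",
    "simulate_strains",
    "write_fixture_tree",
]

_BASES = np.array(list("ACGT"))
_AA = "ACDEFGHIKLMNPQRSTVWY"
_STOPS = ("TAA", "TAG", "TGA")

# codons per residue for back-translation (standard nuclear code)
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic pan-genome.

    Defaults describe a reduced-scale analogue of a multi-strain yeast
    resequencing panel: 6 strains, 12 novel gene families shared along
    a planted strain tree, 2% protein divergence within a family, and
    30 single-copy core genes of which roughly a third are spliced.
    """

    seed: int = 7
    n_strains: int = 6
    genome_len: int = 60_000
    n_core_genes: int = 30
    n_novel_families: int = 12
    family_sharing: dict[int, tuple[str, ...]] | None = None
    intron_rate: float = 0.3
    branch_point_violation_rate: float = 0.0
    protein_mutation_rate: float = 0.02
    n_dubious_pairs: int = 0
    n_spurious: int = 3
    n_missing_stop: int = 2
    n_strains_without_families: int = 0
    min_family_protein_len: int = 101  # 303 bp, clears the 300 bp ORF cutoff
    n_decoy_short: int = 1
    n_decoy_ref: int = 1

    def __post_init__(self) -> None:
        for p in (self.intron_rate, self.branch_point_violation_rate, self.protein_mutation_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must be probabilities in [0, 1]")
        if self.n_strains < 2:
            raise ValueError("need at least 2 strains")

    @property
    def strains(self) -> tuple[str, ...]:
        return tuple(f"S{i:02d}" for i in range(1, self.n_strains + 1))

    @property
    def carrier_strains(self) -> tuple[str, ...]:
        n = self.n_strains - self.n_strains_without_families
        return self.strains[:n]


@dataclass
class ReferenceSim:
    genome: GenomeSequence
    core_orfs: list[OrfModel]
    dubious_orfs: list[OrfModel]
    spurious_orfs: list[OrfModel]
    intergenic_points: list[int]  # safe cassette insertion positions

    @property
    def annotations(self) -> list[OrfModel]:
        return self.core_orfs + self.dubious_orfs


@dataclass
class StrainData:
    strain_id: str
    assembly: GenomeSequence
    orfs: list[OrfModel]  # shifted core + novel annotations
    novel_contigs: list[NovelContig]
    contig_hits: list[TabularHit]
    novel_orf_ids: dict[int, str]  # family -> orf_id


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _random_coding(rng: np.random.Generator, n_codons: int) -> str:
    """Random in-frame codons avoiding stop codons."""
    out = []
    for _ in range(n_codons):
        codon = _random_dna(rng, 3)
        while codon in _STOPS:
            codon = _random_dna(rng, 3)
        out.append(codon)
    return "".join(out)


def _random_intron(rng: np.random.Generator, with_motif: bool) -> str:
    """A GT...AG intron, with or without any branch-point heptamer."""
    motifs = BRANCH_POINTS.dna_motifs
    if with_motif:
        motif = motifs[rng.integers(len(motifs))]
        left = _random_dna(rng, int(rng.integers(20, 40)))
        right = _random_dna(rng, int(rng.integers(8, 20)))
        return "GT" + left + motif + right + "AG"
    while True:
        body = _random_dna(rng, int(rng.integers(40, 70)))
        seq = "GT" + body + "AG"
        if not any(m in seq for m in motifs):
            return seq


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(_CODONS[a][rng.integers(len(_CODONS[a]))] for a in protein)


def _mutate_protein(rng: np.random.Generator, protein: str, rate: float) -> str:
    # position 0 stays M so the ORF keeps its start codon
    out = [protein[0]]
    for a in protein[1:]:
        if rng.random() < rate:
            choices = _AA.replace(a, "")
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(a)
    return "".join(out)


# ---------------------------------------------------------------------------
# reference simulation
# ---------------------------------------------------------------------------

def simulate_reference_detail(cfg: SimConfig) -> ReferenceSim:
    """Reference genome with planted core genes, decoys and defects.

    Core genes are valid ORFs (ATG start, in-frame stop, no internal
    stop); a fraction ``intron_rate`` of them carries one intron, and
    of those a fraction ``branch_point_violation_rate`` gets a
    motif-free intron to exercise the branch-point discard.  Optional
    overlapping Dubious models and intergenic "spurious" valid ORFs
    support the validation workflow.
    """
    rng = np.random.default_rng(cfg.seed)
    slot = cfg.genome_len // max(cfg.n_core_genes, 1)
    if cfg.n_core_genes and slot < 1200:
        raise ValueError(
            f"genome_len {cfg.genome_len} too short for {cfg.n_core_genes} genes"
        )

    genome = list(_random_dna(rng, cfg.genome_len))
    core: list[OrfModel] = []
    spans: list[tuple[int, int]] = []

    for i in range(cfg.n_core_genes):
        # >= 100 codons so every core gene clears the 300 bp length cutoff
        n_codons = int(rng.integers(100, 250))
        cds = "ATG" + _random_coding(rng, n_codons) + _STOPS[rng.integers(3)]
        has_intron = rng.random() < cfg.intron_rate
        strand = "+" if rng.random() < 0.5 else "-"
        pos = i * slot + 100

        if has_intron:
            violates = rng.random() < cfg.branch_point_violation_rate
            intron = _random_intron(rng, with_motif=not violates)
            cut = int(rng.integers(10, len(cds) - 10))
            placed = cds[:cut] + intron + cds[cut:]
            total = len(placed)
            if strand == "+":
                exons = ((pos, pos + cut), (pos + cut + len(intron), pos + total))
            else:
                placed = reverse_complement(placed)
                exons = (
                    (pos + total - cut, pos + total),
                    (pos, pos + total - cut - len(intron)),
                )
        else:
            placed = cds if strand == "+" else reverse_complement(cds)
            total = len(placed)
            exons = ((pos, pos + total),)

        genome[pos : pos + total] = list(placed)
        spans.append((pos, pos + total))
        core.append(
            OrfModel(
                orf_id=f"ref.ORF{i + 1:04d}",
                seq_id="chrI",
                strand=strand,
                exons=exons,
                source="reference",
                classification="Verified",
                label=f"GENE{i + 1:04d}",
            )
        )

    dubious: list[OrfModel] = []
    for i in range(min(cfg.n_dubious_pairs, len(core))):
        lo, hi = core[i].span
        start = lo + 30
        dubious.append(
            OrfModel(
                orf_id=f"ref.DUB{i + 1:04d}",
                seq_id="chrI",
                strand="+",
                exons=((start, start + 402),),
                source="reference",
                classification="Dubious",
                label=f"DUB{i + 1:04d}",
            )
        )

    # intergenic spurious ORFs: real ATG..stop sequences present in the
    # genome but absent from the curated annotation (over-predictions)
    spurious: list[OrfModel] = []
    gaps = _intergenic_points(spans, cfg.genome_len)
    for i in range(cfg.n_spurious):
        if not gaps:
            break
        p = gaps[i * 2 % len(gaps)]
        cds = "ATG" + _random_coding(rng, 120) + _STOPS[rng.integers(3)]
        genome[p : p + len(cds)] = list(cds)
        spans.append((p, p + len(cds)))
        spurious.append(
            OrfModel(
                orf_id=f"ref.SPUR{i + 1:02d}",
                seq_id="chrI",
                strand="+",
                exons=((p, p + len(cds)),),
                source="abinitio",
            )
        )

    points = _intergenic_points(sorted(spans), cfg.genome_len)
    return ReferenceSim(
        genome=GenomeSequence("chrI", "".join(genome)),
        core_orfs=core,
        dubious_orfs=dubious,
        spurious_orfs=spurious,
        intergenic_points=points,
    )


def _intergenic_points(spans: list[tuple[int, int]], genome_len: int) -> list[int]:
    """Midpoints of gaps between planted features, margin 50 bp."""
    points = []
    prev_end = 0
    for s, e in sorted(spans):
        if s - prev_end > 120:
            points.append((prev_end + s) // 2)
        prev_end = max(prev_end, e)
    if genome_len - prev_end > 120:
        points.append((prev_end + genome_len) // 2)
    return points


def simulate_reference(cfg: SimConfig) -> tuple[GenomeSequence, list[OrfModel]]:
    """Reference genome and its annotated ORFs (core + Dubious)."""
    sim = simulate_reference_detail(cfg)
    return sim.genome, sim.annotations


def simulate_candidates(
    cfg: SimConfig, sim: ReferenceSim
) -> tuple[list[OrfModel], list[OrfModel]]:
    """Candidate annotation sets for the validation workflow.

    The homology-based set is the core annotation with
    ``n_missing_stop`` models truncated by one codon (they fail the
    terminal-codon check); the ab initio set is the core annotation
    plus the planted spurious ORFs.  Classification metadata is
    stripped — candidates arrive unlabeled, as real predictions would.
    """
    from dataclasses import replace

    homology = []
    for i, orf in enumerate(sim.core_orfs):
        o = replace(
            orf, orf_id=f"hom.{orf.orf_id}", source="homology",
            classification="unknown", label="undefined",
        )
        if i < cfg.n_missing_stop:
            exons = list(o.exons)
            s, e = exons[-1]
            # trim the final codon from the 3'-most coding exon
            exons[-1] = (s, e - 3) if o.strand == "+" else (s + 3, e)
            o = replace(o, exons=tuple(exons))
        homology.append(o)

    abinitio = [
        replace(
            orf, orf_id=f"abi.{orf.orf_id}", source="abinitio",
            classification="unknown", label="undefined",
        )
        for orf in sim.core_orfs
    ] + [
        replace(o, classification="unknown", label="undefined")
        for o in sim.spurious_orfs
    ]
    return homology, abinitio


# ---------------------------------------------------------------------------
# strain simulation
# ---------------------------------------------------------------------------

def _planted_tree_clades(
    rng: np.random.Generator, leaves: tuple[str, ...]
) -> list[frozenset[str]]:
    """Clades of a random rooted binary tree built by sequential joins."""
    nodes: list[frozenset[str]] = [frozenset([s]) for s in leaves]
    clades: list[frozenset[str]] = []
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = nodes[i] | nodes[j]
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
        clades.append(merged)
    return clades


def _family_lengths(cfg: SimConfig) -> list[int]:
    lengths = [cfg.min_family_protein_len]
    while len(lengths) < cfg.n_novel_families:
        lengths.append(math.ceil(lengths[-1] * 4 / 3) + 1)
    return lengths


def _auto_sharing(
    rng: np.random.Generator, cfg: SimConfig
) -> tuple[dict[int, tuple[str, ...]], list[frozenset[str]]]:
    """Assign each family a clade of a planted strain tree.

    Every non-trivial split gets at least one covering family, every
    carrier strain ends up in at least one family, and leftover
    families go to random non-root clades or leaves.  Returns the
    sharing map and the planted non-trivial splits (smaller side).
    """
    carriers = cfg.carrier_strains
    all_set = frozenset(carriers)
    clades = _planted_tree_clades(rng, carriers)
    splits: list[frozenset[str]] = []
    split_reps: list[frozenset[str]] = []
    seen: set[frozenset[str]] = set()
    for clade in clades:
        if 2 <= len(clade) <= len(carriers) - 2:
            smaller = min((clade, all_set - clade), key=lambda s: (len(s), sorted(s)))
            if smaller not in seen:
                seen.add(smaller)
                splits.append(smaller)
                split_reps.append(clade)

    assignments: list[frozenset[str]] = list(split_reps)
    covered = set().union(*assignments) if assignments else set()
    for s in carriers:
        if s not in covered:
            assignments.append(frozenset([s]))
            covered.add(s)
    if len(assignments) > cfg.n_novel_families:
        raise ValueError(
            f"need at least {len(assignments)} families to cover the planted tree; "
            f"got n_novel_families={cfg.n_novel_families}"
        )
    pool = [c for c in clades if len(c) < len(carriers)] + [
        frozenset([s]) for s in carriers
    ]
    while len(assignments) < cfg.n_novel_families:
        assignments.append(pool[int(rng.integers(len(pool)))])

    sharing = {
        fid: tuple(sorted(clade)) for fid, clade in enumerate(assignments, start=1)
    }
    return sharing, splits


def simulate_strains(
    cfg: SimConfig, sim: ReferenceSim
) -> tuple[dict[str, StrainData], dict]:
    """Per-strain assemblies with planted novel cassettes plus ground truth.

    Each strain's assembly is the reference with one cassette inserted
    per novel family assigned to it (at intergenic positions), the
    cassette being a valid single-exon ORF back-translated from the
    family protein after per-strain mutation.  Emits a manifest with
    the true groups, presence matrix and planted strain bipartitions.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    if cfg.family_sharing is not None:
        sharing = {f: tuple(sorted(s)) for f, s in cfg.family_sharing.items()}
        splits: list[frozenset[str]] = []
        for s in {st for subset in sharing.values() for st in subset}:
            if s not in cfg.strains:
                raise ValueError(f"family assigned to unknown strain {s!r}")
    else:
        sharing, splits = _auto_sharing(rng, cfg)

    lengths = _family_lengths(cfg)
    base_proteins = {
        fid: "M" + "".join(rng.choice(list(_AA), size=lengths[fid - 1] - 1))
        for fid in sharing
    }
    points = sim.intergenic_points
    if len(points) == 0:
        raise ValueError("reference has no intergenic room for cassettes")

    strains: dict[str, StrainData] = {}
    membership: dict[int, list[tuple[str, str]]] = {fid: [] for fid in sharing}

    for strain in cfg.strains:
        fids = sorted(f for f, subset in sharing.items() if strain in subset)
        # one insertion point per family, fixed by family id so that all
        # strains carrying a family use the same reference locus
        inserts = []
        for fid in fids:
            protein = _mutate_protein(
                rng, base_proteins[fid], cfg.protein_mutation_rate
            )
            cds = _back_translate(rng, protein) + _STOPS[rng.integers(3)]
            cassette = _random_dna(rng, 20) + cds + _random_dna(rng, 20)
            inserts.append((points[(fid - 1) % len(points)], fid, cassette, len(cds)))
        inserts.sort()

        parts = []
        prev = 0
        offset = 0
        novel_orfs: list[OrfModel] = []
        contigs: list[NovelContig] = []
        hits: list[TabularHit] = []
        novel_ids: dict[int, str] = {}
        seq_id = f"{strain}_chrI"
        for p, fid, cassette, cds_len in inserts:
            parts.append(sim.genome.sequence[prev:p])
            ins_at = p + offset
            cds_start = ins_at + 20
            orf_id = f"{strain}.ORF{fid}"
            novel_orfs.append(
                OrfModel(
                    orf_id=orf_id,
                    seq_id=seq_id,
                    strand="+",
                    exons=((cds_start, cds_start + cds_len),),
                    source="abinitio",
                    strain_id=strain,
                )
            )
            novel_ids[fid] = orf_id
            membership[fid].append((strain, orf_id))
            contig_id = f"{strain}.contig{fid}"
            contigs.append(NovelContig(contig_id, cassette, 0.0))
            hits.append(
                TabularHit(
                    query_id=contig_id,
                    subject_id=seq_id,
                    percent_identity=100.0,
                    alignment_length=len(cassette),
                    mismatches=0,
                    gap_opens=0,
                    q_start=1,
                    q_end=len(cassette),
                    s_start=ins_at + 1,
                    s_end=ins_at + len(cassette),
                    evalue=0.0,
                    bit_score=2.0 * len(cassette),
                )
            )
            parts.append(cassette)
            offset += len(cassette)
            prev = p
        parts.append(sim.genome.sequence[prev:])
        assembly = GenomeSequence(seq_id, "".join(parts))

        # decoy contigs exercising the novelty filters
        for i in range(cfg.n_decoy_short):
            contigs.append(
                NovelContig(f"{strain}.short{i + 1}", _random_dna(rng, 150), 0.0)
            )
        for i in range(cfg.n_decoy_ref):
            start = int(rng.integers(0, cfg.genome_len - 500))
            contigs.append(
                NovelContig(
                    f"{strain}.refdup{i + 1}",
                    sim.genome.sequence[start : start + 500],
                    1.0,
                )
            )

        ins_positions = [p for p, *_ in inserts]
        ins_cum = np.cumsum([len(c) for _, _, c, _ in inserts])

        def shift_of(coord: int) -> int:
            k = int(np.searchsorted(ins_positions, coord, side="right"))
            return int(ins_cum[k - 1]) if k else 0

        shifted_core = []
        for orf in sim.core_orfs:
            exons = tuple((s + shift_of(s), e + shift_of(s)) for s, e in orf.exons)
            shifted_core.append(
                OrfModel(
                    orf_id=f"{strain}.{orf.orf_id}",
                    seq_id=seq_id,
                    strand=orf.strand,
                    exons=exons,
                    source=orf.source,
                    classification=orf.classification,
                    label=orf.label,
                    strain_id=strain,
                )
            )

        strains[strain] = StrainData(
            strain_id=strain,
            assembly=assembly,
            orfs=shifted_core + novel_orfs,
            novel_contigs=contigs,
            contig_hits=hits,
            novel_orf_ids=novel_ids,
        )

    carrier_order = [s for s in cfg.strains if any(s in subset for subset in sharing.values())]
    fids = sorted(sharing)
    presence = [
        [1 if s in sharing[f] else 0 for f in fids] for s in carrier_order
    ]
    manifest = {
        "strains": list(cfg.strains),
        "carrier_strains": carrier_order,
        "families": {
            str(f): {
                "strains": list(sharing[f]),
                "protein_len": lengths[f - 1],
                "members": sorted(membership[f]),
            }
            for f in fids
        },
        "n_groups": len(fids),
        "n_unique_groups": sum(1 for f in fids if len(sharing[f]) == 1),
        "presence_matrix": {
            "strains": carrier_order,
            "families": fids,
            "cells": presence,
        },
        "planted_splits": sorted(sorted(s) for s in splits),
    }
    return strains, manifest


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_fixture_tree(cfg: SimConfig, outdir) -> Path:
    """Write the full fixture set (FASTA/GFF3/tabular/JSON) to a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_reference_detail(cfg)
    write_fasta([sim.genome], out / "reference.fasta")
    feats = [f for o in sim.annotations for f in orf_to_features(o)]
    write_gff3(feats, out / "reference.gff3")

    strains, manifest = simulate_strains(cfg, sim)
    for strain, data in strains.items():
        sdir = out / strain
        sdir.mkdir(exist_ok=True)
        write_fasta([data.assembly], sdir / "assembly.fasta")
        write_gff3(
            [f for o in data.orfs for f in orf_to_features(o)], sdir / "annotations.gff3"
        )
        write_fasta(
            [GenomeSequence(c.contig_id, c.sequence) for c in data.novel_contigs],
            sdir / "novel_contigs.fasta",
        )
        write_tabular_hits(data.contig_hits, sdir / "contig_hits.tsv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
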