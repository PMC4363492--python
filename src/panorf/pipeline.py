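"""Stage orchestration: refinement, novelty, grouping, tree, validation.

These functions wire the per-module operations into the runnable
workflows the CLI exposes.  Every filtering stage returns (or logs)
both the kept and the discarded records so the conservation invariant
``|in| = |kept| + |discarded|`` is auditable throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import pandas as pd
from skbio import TreeNode

from .formats_io import GenomeSequence
from .novel_detection import (
    NovelContig,
    collect_nonreference_orfs,
    filter_novel_contigs,
    map_to_own_assembly,
)
from .orf_refinement import (
    BRANCH_POINTS,
    OrfModel,
    ValidationReport,
    build_true_set,
    check_branch_points,
    check_terminal_codons,
    consolidate_undefined,
    merge_sources,
    translate_orf,
    validation_metrics,
)
from .pangenome import (
    HomologueGroup,
    PresenceMatrix,
    build_presence_matrix,
    gene_distance,
    group_homologues,
    neighbor_joining,
)
from .protein_homology import (
    AlignerParams,
    DEFAULT_PARAMS,
    classify_orf,
    grouping_edge,
    pairwise_similarity,
)
from .synthetic_fixtures import (
    SimConfig,
    simulate_candidates,
    simulate_reference_detail,
    simulate_strains,
)

logger = logging.getLogger("panorf")

__all__ = [
    "RunConfig",
    "RefinementResult",
    "PangenomeResult",
    "refine",
    "classify_all",
    "novel_orfs_for_strain",
    "pangenome_analysis",
    "validation_run",
    "end_to_end",
]


@dataclass(frozen=True)
class RunConfig:
    """All tunable thresholds, at their published defaults."""

    min_orf_len: int = 300
    strict_length_cutoff: bool = False  # True: > min_orf_len instead of >=
    min_contig_len: int = 300
    max_ref_fraction: float = 0.5
    min_ref_identity: float = 90.0
    aligner: AlignerParams = field(default_factory=AlignerParams)
    clamp_negative_branches: bool = False

    def __post_init__(self) -> None:
        if self.min_orf_len < 0 or self.min_contig_len < 0:
            raise ValueError("length cutoffs must be non-negative")
        if not 0.0 <= self.max_ref_fraction <= 1.0:
            raise ValueError("max_ref_fraction must be in [0, 1]")


@dataclass
class RefinementResult:
    kept: list[OrfModel]
    discarded: list[OrfModel]

    @property
    def discard_log(self) -> list[tuple[str, str]]:
        return [(o.orf_id, o.discard_reason or "unknown") for o in self.discarded]


def _log_filter(stage: str, n_in: int, n_kept: int) -> None:
    logger.info("%s: %d in, %d kept, %d discarded", stage, n_in, n_kept, n_in - n_kept)


def refine(
    homology_set: Sequence[OrfModel],
    abinitio_set: Sequence[OrfModel],
    genomes: Mapping[str, GenomeSequence],
    ref_db: Mapping[str, str] | None = None,
    relaxed_db: Mapping[str, str] | None = None,
    config: RunConfig = RunConfig(),
) -> RefinementResult:
    """The full annotation-combination and refinement chain.

    Union of the two sources; terminal-codon check; branch-point check
    on spliced models; strict-tier labeling against ``ref_db``; relaxed
    second pass of the still-undefined against ``relaxed_db``;
    consolidation of remaining undefined models with the length cutoff.
    """
    merged = merge_sources(homology_set, abinitio_set)
    _log_filter("merge_sources", len(homology_set) + len(abinitio_set), len(merged))

    kept: list[OrfModel] = []
    discarded: list[OrfModel] = []
    for orf in merged:
        checked = check_terminal_codons(orf, genomes[orf.seq_id])
        if checked.status == "discarded":
            discarded.append(checked)
            continue
        checked = check_branch_points(checked, genomes[orf.seq_id], BRANCH_POINTS)
        (discarded if checked.status == "discarded" else kept).append(checked)
    _log_filter("structural_checks", len(merged), len(kept))

    if ref_db or relaxed_db:
        labeled = []
        for orf in kept:
            protein = translate_orf(orf, genomes[orf.seq_id])
            label = "undefined"
            if ref_db:
                label = classify_orf(
                    protein, ref_db, tier="strict", params=config.aligner,
                    query_id=orf.orf_id,
                )
            if label == "undefined" and relaxed_db:
                label = classify_orf(
                    protein, relaxed_db, tier="relaxed", params=config.aligner,
                    query_id=orf.orf_id,
                )
            labeled.append(replace(orf, label=label))
        kept = labeled

    consolidated, dropped = consolidate_undefined(
        kept,
        min_len=config.min_orf_len,
        strict_greater=config.strict_length_cutoff,
        return_discarded=True,
    )
    discarded.extend(dropped)
    _log_filter("consolidate_undefined", len(kept), len(consolidated))
    return RefinementResult(kept=consolidated, discarded=discarded)


def classify_all(
    proteins: Mapping[str, str],
    db: Mapping[str, str],
    tier: str = "strict",
    params: AlignerParams = DEFAULT_PARAMS,
) -> dict[str, str]:
    """Label every query protein against the database at the given tier."""
    return {
        qid: classify_orf(seq, db, tier=tier, params=params, query_id=qid)
        for qid, seq in proteins.items()
    }


def novel_orfs_for_strain(
    contigs: Sequence[NovelContig],
    contig_hits,
    annotations: Sequence[OrfModel],
    config: RunConfig = RunConfig(),
) -> tuple[list[OrfModel], list[NovelContig]]:
    """Novel-contig filtering, assembly placement and ORF collection."""
    kept, dropped = filter_novel_contigs(
        contigs, min_len=config.min_contig_len, max_ref_fraction=config.max_ref_fraction
    )
    _log_filter("filter_novel_contigs", len(contigs), len(kept))
    placed = map_to_own_assembly(kept, contig_hits)
    orfs = collect_nonreference_orfs(annotations, placed)
    logger.info("collect_nonreference_orfs: %d ORFs over %d novel regions", len(orfs), len(placed))
    return orfs, dropped


@dataclass
class PangenomeResult:
    groups: list[HomologueGroup]
    matrix: PresenceMatrix
    distances: pd.DataFrame
    tree: TreeNode | None

    @property
    def n_unique_groups(self) -> int:
        return sum(1 for g in self.groups if g.is_unique)


def pangenome_analysis(
    proteins: Mapping[tuple[str, str], str],
    strains: Sequence[str],
    params: AlignerParams = DEFAULT_PARAMS,
    config: RunConfig = RunConfig(),
) -> PangenomeResult:
    """Group non-reference ORF proteins, build the presence matrix and NJ tree.

    ``proteins`` maps (strain_id, orf_id) to the protein sequence.  The
    tree is omitted (None) when fewer than 3 strains carry groups.
    """
    triples = pairwise_similarity(proteins, params)
    edges = [(a, b) for a, b, rec in triples if grouping_edge(rec)]
    groups = group_homologues(sorted(proteins), edges)
    logger.info(
        "group_homologues: %d ORFs -> %d groups (%d unique)",
        len(proteins), len(groups), sum(g.is_unique for g in groups),
    )
    matrix = build_presence_matrix(groups, strains)
    distances = gene_distance(matrix)
    tree = (
        neighbor_joining(distances, clamp_negative=config.clamp_negative_branches)
        if len(matrix.strains) >= 3
        else None
    )
    return PangenomeResult(groups=groups, matrix=matrix, distances=distances, tree=tree)


# ---------------------------------------------------------------------------
# end-to-end workflows on synthetic fixtures
# ---------------------------------------------------------------------------

def validation_run(
    cfg: SimConfig, config: RunConfig = RunConfig()
) -> tuple[ValidationReport, RefinementResult]:
    """Run refinement on the simulated reference and score it.

    Mirrors the reference-assembly validation workflow: candidate
    annotations (with planted defects) are refined, the curated truth
    set is built with the Dubious-overlap rules, and the exact-match
    accuracy and FDR are reported.
    """
    sim = simulate_reference_detail(cfg)
    homology, abinitio = simulate_candidates(cfg, sim)
    genomes = {sim.genome.record_id: sim.genome}
    ref_db = {o.label: translate_orf(o, sim.genome) for o in sim.core_orfs}
    result = refine(homology, abinitio, genomes, ref_db=ref_db, config=config)
    true_set = build_true_set(sim.annotations, min_len=config.min_orf_len)
    report = validation_metrics(result.kept, true_set)
    return report, result


@dataclass
class EndToEndResult:
    pangenome: PangenomeResult
    manifest: dict
    nonref_orfs: dict[str, list[OrfModel]]
    contig_discards: dict[str, list[NovelContig]]


def end_to_end(cfg: SimConfig, config: RunConfig = RunConfig()) -> EndToEndResult:
    """Simulate strains, recover novel ORFs, group them, build the tree."""
    sim = simulate_reference_detail(cfg)
    strains, manifest = simulate_strains(cfg, sim)

    proteins: dict[tuple[str, str], str] = {}
    nonref: dict[str, list[OrfModel]] = {}
    discards: dict[str, list[NovelContig]] = {}
    for strain, data in strains.items():
        orfs, dropped = novel_orfs_for_strain(
            data.novel_contigs, data.contig_hits, data.orfs, config
        )
        nonref[strain] = orfs
        discards[strain] = dropped
        for orf in orfs:
            proteins[(strain, orf.orf_id)] = translate_orf(orf, data.assembly)

    result = pangenome_analysis(proteins, list(cfg.strains), config.aligner, config)
    return EndToEndResult(
        pangenome=result, manifest=manifest, nonref_orfs=nonref, contig_discards=discards
    )
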