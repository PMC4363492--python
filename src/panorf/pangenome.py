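"""Homologue grouping, presence/absence matrix, and the NJ dendrogram.

Non-reference ORFs from all strains are clustered into homologue groups
as the connected components of the pairwise-similarity graph (an
undirected edge exists when the grouping criterion passes in either
direction).  Group presence per strain yields a binary strains x groups
matrix; strains that carry no non-reference ORF are excluded.  Pairwise
gene distance is the count of presence columns in which two strains
differ (the classic gene-content distance; a proportion variant is
available), and the strain dendrogram is built with Saitou–Nei
neighbor joining using the Studier–Keppler Q criterion.

Tie-breaking in NJ is deterministic (lexicographically smallest taxon
pair); negative branch lengths are retained by default with an option
to clamp them to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from skbio import TreeNode

from .protein_homology import SimilarityRecord, grouping_edge

__all__ = [
    "HomologueGroup",
    "PresenceMatrix",
    "group_homologues",
    "edges_from_records",
    "build_presence_matrix",
    "gene_distance",
    "neighbor_joining",
    "bipartitions",
]

Member = tuple[str, str]  # (strain_id, orf_id)


@dataclass(frozen=True)
class HomologueGroup:
    """A connected set of non-reference ORFs under the grouping cutoffs."""

    group_id: int
    members: tuple[Member, ...]
    strains_present: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a homologue group cannot be empty")

    @property
    def is_unique(self) -> bool:
        """True when the group occurs in exactly one strain."""
        return len(self.strains_present) == 1


def edges_from_records(
    triples: Iterable[tuple[Member, Member, SimilarityRecord]],
) -> list[tuple[Member, Member]]:
    """Undirected edges from keyed pairwise records.

    An edge exists when the grouping criterion passes for the pair in
    either direction; duplicates and reversed duplicates collapse in
    the graph.
    """
    return [(a, b) for a, b, rec in triples if grouping_edge(rec)]


def group_homologues(
    members: Sequence[Member],
    edges: Iterable[tuple[Member, Member]],
) -> list[HomologueGroup]:
    """Connected components of the similarity graph as homologue groups.

    ``members`` lists every (strain_id, orf_id) node, so ORFs without a
    single passing edge form singleton groups.  Group IDs are assigned
    in order of each component's smallest member, starting at 1.
    """
    graph = nx.Graph()
    graph.add_nodes_from(members)
    member_set = set(members)
    for a, b in edges:
        if a not in member_set or b not in member_set:
            raise ValueError(f"edge endpoint not in member list: {(a, b)}")
        graph.add_edge(a, b)

    components = sorted(nx.connected_components(graph), key=min)
    groups = []
    for i, comp in enumerate(components, start=1):
        ordered = tuple(sorted(comp))
        groups.append(
            HomologueGroup(
                group_id=i,
                members=ordered,
                strains_present=frozenset(s for s, _ in ordered),
            )
        )
    return groups


@dataclass(frozen=True)
class PresenceMatrix:
    """Binary strains x homologue-groups table."""

    strains: tuple[str, ...]
    groups: tuple[int, ...]
    cells: np.ndarray  # shape (n_strains, n_groups), dtype int8

    def __post_init__(self) -> None:
        if self.cells.shape != (len(self.strains), len(self.groups)):
            raise ValueError("cell matrix shape mismatch")
        if self.groups and not self.cells.any(axis=0).all():
            raise ValueError("presence matrix contains an all-zero group column")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cells, index=list(self.strains), columns=list(self.groups)
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="strain")


def build_presence_matrix(
    groups: Sequence[HomologueGroup], strains: Sequence[str]
) -> PresenceMatrix:
    """Presence/absence of each homologue group in each strain.

    Strains with no non-reference ORF at all (all-zero rows) are
    dropped with a warning — they are indistinguishable from the
    reference in gene content and carry no signal for the distance.
    """
    strain_list = list(strains)
    strain_index = {s: i for i, s in enumerate(strain_list)}
    cells = np.zeros((len(strain_list), len(groups)), dtype=np.int8)
    for j, g in enumerate(groups):
        for s in g.strains_present:
            if s not in strain_index:
                raise ValueError(f"group {g.group_id} names unknown strain {s!r}")
            cells[strain_index[s], j] = 1

    present = cells.any(axis=1)
    if not present.all():
        dropped = [s for s, keep in zip(strain_list, present) if not keep]
        warnings.warn(
            f"strains without non-reference ORFs dropped from matrix: {dropped}",
            stacklevel=2,
        )
    kept = [s for s, keep in zip(strain_list, present) if keep]
    return PresenceMatrix(
        strains=tuple(kept),
        groups=tuple(g.group_id for g in groups),
        cells=cells[present],
    )


def gene_distance(m: PresenceMatrix, proportion: bool = False) -> pd.DataFrame:
    """Pairwise gene-content distance between strains.

    d(i, j) counts the group columns where the two presence rows
    differ (Hamming count); ``proportion=True`` divides by the number
    of columns.
    """
    x = m.cells.astype(np.int16)
    diff = (x[:, None, :] != x[None, :, :]).sum(axis=2).astype(float)
    if proportion:
        diff /= max(x.shape[1], 1)
    return pd.DataFrame(diff, index=list(m.strains), columns=list(m.strains))


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(
    d: pd.DataFrame, clamp_negative: bool = False
) -> TreeNode:
    """Saitou–Nei neighbor joining on a symmetric distance matrix.

    Uses the Studier–Keppler criterion
    ``Q(i,j) = (n-2) d(i,j) - r_i - r_j`` with ``r_i = sum_k d(i,k)``,
    joining the pair with minimal Q at each step (ties broken by the
    lexicographically smallest label pair).  Branch lengths follow the
    standard formulas; negative lengths are kept unless
    ``clamp_negative`` is set.  Returns an unrooted tree as a
    trifurcation at the root (for >= 4 taxa).
    """
    labels = list(d.index)
    if list(d.columns) != labels:
        raise ValueError("distance matrix must have matching row/column labels")
    mat = d.to_numpy(dtype=float)
    if mat.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(mat), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")

    def brlen(value: float) -> float:
        return max(value, 0.0) if clamp_negative else value

    # active nodes: label -> TreeNode; distances in a dict-of-dict
    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in labels}
    dist: dict[str, dict[str, float]] = {
        a: {b: mat[i, j] for j, b in enumerate(labels) if j != i}
        for i, a in enumerate(labels)
    }

    counter = 0
    while len(nodes) > 3:
        active = sorted(nodes)
        n = len(active)
        r = {a: sum(dist[a].values()) for a in active}
        best_q = None
        best_pair = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (n - 2) * dist[a][b] - r[a] - r[b]
                if best_q is None or q < best_q - 1e-12:
                    best_q, best_pair = q, (a, b)
        a, b = best_pair
        la = 0.5 * dist[a][b] + (r[a] - r[b]) / (2 * (n - 2))
        lb = dist[a][b] - la
        child_a, child_b = nodes.pop(a), nodes.pop(b)
        child_a.length = brlen(la)
        child_b.length = brlen(lb)
        counter += 1
        new_label = f"\x00internal{counter}"  # sorts before taxon labels deterministically
        parent = TreeNode(children=[child_a, child_b])
        new_d = {}
        for c in nodes:
            dc = 0.5 * (dist[a][c] + dist[b][c] - dist[a][b])
            new_d[c] = dc
            dist[c].pop(a, None)
            dist[c].pop(b, None)
            dist[c][new_label] = dc
        dist.pop(a)
        dist.pop(b)
        dist[new_label] = new_d
        nodes[new_label] = parent

    remaining = sorted(nodes)
    if len(remaining) == 3:
        a, b, c = remaining
        la = 0.5 * (dist[a][b] + dist[a][c] - dist[b][c])
        lb = 0.5 * (dist[a][b] + dist[b][c] - dist[a][c])
        lc = 0.5 * (dist[a][c] + dist[b][c] - dist[a][b])
        for lab, length in ((a, la), (b, lb), (c, lc)):
            nodes[lab].length = brlen(length)
        root = TreeNode(children=[nodes[lab] for lab in remaining])
    else:  # exactly 3 taxa never leaves the loop with 2; defensive
        root = TreeNode(children=[nodes[lab] for lab in remaining])
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions of an unrooted tree.

    Each internal edge splits the leaves in two; the split is reported
    as the smaller side (ties: lexicographically smaller frozenset
    content), excluding trivial single-leaf splits.
    """
    all_tips = frozenset(t.name for t in tree.tips())
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_tips - side
        if len(side) < 2 or len(other) < 2:
            continue
        smaller = min((side, other), key=lambda s: (len(s), sorted(s)))
        splits.add(smaller)
    return splits
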