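"""Shared fixtures and the independent oracles the test suite checks against.

The oracle implementations here deliberately avoid the code paths they
verify: alignment scores come from exhaustive enumeration of monotone
matchings, tree recovery from exhaustive topology enumeration with a
least-squares fit, connected components from a hand-rolled union-find,
and the SAM-flag triage from a literal transcription of the three
require/exclude mask pairs.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from panorf.formats_io import GenomeSequence
from panorf.synthetic_fixtures import SimConfig, simulate_reference_detail


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def reference_sim(sim_config):
    return simulate_reference_detail(sim_config)


@pytest.fixture()
def toy_genome() -> GenomeSequence:
    #            0         1         2         3
    #            0123456789012345678901234567890123456789
    return GenomeSequence("chrT", "ATGAAATAACCCGGGTTTACTAACGGATCCATGTTTTGACC")


# ---------------------------------------------------------------------------
# oracle: exhaustive local alignment enumeration
# ---------------------------------------------------------------------------

def brute_force_local_score(a, b, matrix, gap_open, gap_extend):
    """Best local alignment score by enumerating every monotone matching.

    An alignment is a non-empty order-preserving pairing of positions;
    each maximal unmatched run strictly between consecutive pairs is an
    affine gap of cost ``gap_open + gap_extend * length`` (runs in the
    two sequences count as separate gaps).  The empty alignment scores
    zero.  Only valid at tiny lengths.
    """
    best = 0.0
    la, lb = len(a), len(b)
    for k in range(1, min(la, lb) + 1):
        for pa in itertools.combinations(range(la), k):
            for pb in itertools.combinations(range(lb), k):
                score = 0.0
                for i, j in zip(pa, pb):
                    score += matrix[a[i], b[j]]
                for t in range(1, k):
                    da = pa[t] - pa[t - 1] - 1
                    db = pb[t] - pb[t - 1] - 1
                    if da:
                        score -= gap_open + gap_extend * da
                    if db:
                        score -= gap_open + gap_extend * db
                if score > best:
                    best = score
    return best


# ---------------------------------------------------------------------------
# oracle: exhaustive unrooted topology enumeration + least-squares fit
# ---------------------------------------------------------------------------

def enumerate_unrooted_topologies(labels):
    """All unrooted binary topologies over the labels.

    Each topology is a list of edges ``(u, v)`` over nodes that are
    either leaf labels or integer internal IDs.  Built by the standard
    leaf-insertion recursion: 3 leaves have one topology; each further
    leaf subdivides every existing edge in turn.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")
    base = [(labels[0], 0), (labels[1], 0), (labels[2], 0)]
    trees = [(base, 1)]
    for leaf in labels[3:]:
        nxt = []
        for edges, n_internal in trees:
            for i, (u, v) in enumerate(edges):
                mid = n_internal
                new_edges = edges[:i] + edges[i + 1 :]
                new_edges += [(u, mid), (mid, v), (leaf, mid)]
                nxt.append((new_edges, n_internal + 1))
        trees = nxt
    return [edges for edges, _ in trees]


def _paths(edges, labels):
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def path_edges(src, dst):
        stack = [(src, None, [])]
        while stack:
            node, prev, used = stack.pop()
            if node == dst:
                return used
            for nb in adj[node]:
                if nb != prev:
                    stack.append((nb, node, used + [frozenset((node, nb))]))
        raise RuntimeError("disconnected tree")

    edge_index = {frozenset(e): i for i, e in enumerate(edges)}
    rows = []
    for a, b in itertools.combinations(labels, 2):
        row = np.zeros(len(edges))
        for e in path_edges(a, b):
            row[edge_index[e]] = 1.0
        rows.append(row)
    return np.array(rows)


def topology_splits(edges, labels):
    """Non-trivial bipartitions of a topology given as an edge list."""
    label_set = frozenset(labels)
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def side(u, v):
        seen = {v, u}
        stack = [u]
        tips = set()
        while stack:
            node = stack.pop()
            if node in label_set:
                tips.add(node)
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return frozenset(tips)

    splits = set()
    for u, v in edges:
        s = side(u, v)
        other = label_set - s
        if len(s) >= 2 and len(other) >= 2:
            splits.add(min((s, other), key=lambda x: (len(x), sorted(x))))
    return splits


def best_fit_topology(dist, labels):
    """Least-squares best unrooted topology for a distance matrix."""
    labels = list(labels)
    pair_d = np.array(
        [dist.loc[a, b] for a, b in itertools.combinations(labels, 2)]
    )
    best = None
    for edges in enumerate_unrooted_topologies(labels):
        design = _paths(edges, labels)
        lengths, *_ = np.linalg.lstsq(design, pair_d, rcond=None)
        residual = float(np.sum((design @ lengths - pair_d) ** 2))
        if best is None or residual < best[0] - 1e-12:
            best = (residual, edges)
    return best[1], best[0]


def random_additive_tree(rng, labels):
    """A random unrooted topology with positive lengths and its distances."""
    import pandas as pd

    topos = enumerate_unrooted_topologies(list(labels))
    edges = topos[int(rng.integers(len(topos)))]
    lengths = {frozenset(e): float(rng.uniform(0.1, 1.0)) for e in edges}
    design = _paths(edges, list(labels))
    pair_d = design @ np.array([lengths[frozenset(e)] for e in edges])
    n = len(labels)
    mat = np.zeros((n, n))
    for idx, (i, j) in enumerate(itertools.combinations(range(n), 2)):
        mat[i, j] = mat[j, i] = pair_d[idx]
    return edges, pd.DataFrame(mat, index=list(labels), columns=list(labels))


# ---------------------------------------------------------------------------
# oracle: union-find connected components
# ---------------------------------------------------------------------------

def union_find_components(nodes, edges):
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps = {}
    for n in nodes:
        comps.setdefault(find(n), set()).add(n)
    return sorted(comps.values(), key=min)


# ---------------------------------------------------------------------------
# oracle: literal samtools filter transcription
# ---------------------------------------------------------------------------

def literal_unmapped_filters(flag: int) -> bool:
    f1 = (flag & 4) == 4 and (flag & 264) == 0
    f2 = (flag & 8) == 8 and (flag & 260) == 0
    f3 = (flag & 12) == 12 and (flag & 256) == 0
    return f1 or f2 or f3


# ---------------------------------------------------------------------------
# oracle: brute-force branch-point scan
# ---------------------------------------------------------------------------

_MOTIFS = ("TACTAAC", "CACTAAC", "GACTAAC", "TGCTAAC", "AACTAAC", "TATTAAC", "AATTAAC")


def brute_force_branch_scan(intron: str) -> bool:
    seq = intron.upper()
    for offset in range(len(seq) - 6):
        window = seq[offset : offset + 7]
        for motif in _MOTIFS:
            if window == motif:
                return True
    return False
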