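"""Homologue grouping, presence matrix, gene distance, neighbor joining."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from conftest import (
    best_fit_topology,
    random_additive_tree,
    topology_splits,
    union_find_components,
)
from panorf.pangenome import (
    HomologueGroup,
    PresenceMatrix,
    bipartitions,
    build_presence_matrix,
    gene_distance,
    group_homologues,
    neighbor_joining,
)


def member(strain, orf):
    return (strain, orf)


class TestGroupHomologues:
    def test_transitive_chain_forms_one_group(self):
        m = [member("s1", "a"), member("s2", "b"), member("s3", "c")]
        groups = group_homologues(m, [(m[0], m[1]), (m[1], m[2])])
        assert len(groups) == 1
        assert groups[0].members == tuple(sorted(m))
        assert not groups[0].is_unique

    def test_no_edges_gives_singletons_all_unique(self):
        m = [member(f"s{i}", f"o{i}") for i in range(4)]
        groups = group_homologues(m, [])
        assert len(groups) == 4
        assert all(g.is_unique for g in groups)

    def test_same_strain_singletons_is_unique(self):
        m = [member("s1", "a"), member("s1", "b")]
        groups = group_homologues(m, [(m[0], m[1])])
        assert len(groups) == 1 and groups[0].is_unique

    def test_group_ids_deterministic_by_smallest_member(self):
        m = [member("s2", "z"), member("s1", "a"), member("s3", "k")]
        groups = group_homologues(m, [])
        assert [g.members[0] for g in groups] == sorted(m)
        assert [g.group_id for g in groups] == [1, 2, 3]

    def test_edge_with_unknown_member_rejected(self):
        m = [member("s1", "a")]
        with pytest.raises(ValueError):
            group_homologues(m, [(m[0], member("s9", "x"))])

    def test_union_find_oracle_on_random_graphs(self):
        """Connected components equal a union-find oracle on 200 random
        graphs with varying density."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(2, 25))
            nodes = [member(f"s{i % 5}", f"o{i}") for i in range(n)]
            n_edges = int(rng.integers(0, 2 * n))
            edges = [
                (nodes[int(rng.integers(n))], nodes[int(rng.integers(n))])
                for _ in range(n_edges)
            ]
            edges = [(a, b) for a, b in edges if a != b]
            got = [set(g.members) for g in group_homologues(nodes, edges)]
            expected = union_find_components(nodes, edges)
            assert got == expected


class TestPresenceMatrix:
    def group(self, gid, strains):
        return HomologueGroup(gid, tuple((s, f"o{gid}.{s}") for s in sorted(strains)), frozenset(strains))

    def test_shared_and_private_columns(self):
        groups = [self.group(1, {"A", "B"}), self.group(2, {"A"})]
        m = build_presence_matrix(groups, ["A", "B"])
        frame = m.to_frame()
        assert list(frame.loc["A"]) == [1, 1]
        assert list(frame.loc["B"]) == [1, 0]

    def test_strain_without_groups_dropped_with_warning(self):
        groups = [self.group(1, {"A"})]
        with pytest.warns(UserWarning, match="B"):
            m = build_presence_matrix(groups, ["A", "B"])
        assert m.strains == ("A",)

    def test_unknown_strain_in_group_errors(self):
        with pytest.raises(ValueError, match="C"):
            build_presence_matrix([self.group(1, {"C"})], ["A", "B"])

    def test_cells_match_membership_invariant(self):
        groups = [self.group(1, {"A", "C"}), self.group(2, {"B"}), self.group(3, {"A", "B", "C"})]
        m = build_presence_matrix(groups, ["A", "B", "C"])
        for i, s in enumerate(m.strains):
            for j, g in enumerate(groups):
                assert m.cells[i, j] == (1 if s in g.strains_present else 0)

    def test_all_zero_column_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            PresenceMatrix(("A",), (1, 2), np.array([[1, 0]], dtype=np.int8))


class TestGeneDistance:
    def matrix(self, rows, strains=None):
        arr = np.array(rows, dtype=np.int8)
        strains = strains or [f"S{i}" for i in range(arr.shape[0])]
        return PresenceMatrix(tuple(strains), tuple(range(1, arr.shape[1] + 1)), arr)

    def test_hamming_count(self):
        m = self.matrix([[1, 0, 1], [1, 1, 0]])
        assert gene_distance(m).iloc[0, 1] == 2

    def test_identical_rows_zero(self):
        m = self.matrix([[1, 1, 1], [1, 1, 1]])
        assert gene_distance(m).iloc[0, 1] == 0

    def test_complementary_rows_full_length(self):
        m = self.matrix([[1, 1, 0, 1], [0, 0, 1, 0]])
        assert gene_distance(m).iloc[0, 1] == 4

    def test_proportion_option(self):
        m = self.matrix([[1, 0, 1, 1], [1, 1, 0, 1]])
        assert gene_distance(m, proportion=True).iloc[0, 1] == pytest.approx(0.5)

    def test_triangle_inequality_on_random_binary_rows(self):
        rng = np.random.default_rng(8)
        rows = rng.integers(0, 2, size=(6, 20))
        rows[:, 0] = 1  # avoid all-zero columns
        m = self.matrix(rows.tolist())
        d = gene_distance(m).to_numpy()
        n = d.shape[0]
        for i, j, k in itertools.permutations(range(n), 3):
            assert d[i, j] <= d[i, k] + d[k, j]


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = pd.DataFrame(
            [[0, 5, 9], [5, 0, 10], [9, 10, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree = neighbor_joining(d)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["B"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["C"] == pytest.approx((9 + 10 - 5) / 2)
        assert len(tree.children) == 3

    def test_four_taxon_additive_exact_recovery(self):
        # tree ((A,B),(C,D)) with internal edge 4
        d = pd.DataFrame(
            [
                [0, 3, 9, 10],
                [3, 0, 10, 11],
                [9, 10, 0, 5],
                [10, 11, 5, 0],
            ],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        tree = neighbor_joining(d)
        assert bipartitions(tree) == {frozenset({"A", "B"})}
        # branch lengths reproduce the additive distances
        tip = {t.name: t for t in tree.tips()}
        for a, b in itertools.combinations("ABCD", 2):
            assert tip[a].distance(tip[b]) == pytest.approx(d.loc[a, b])

    def test_recovery_matches_exhaustive_least_squares_oracle(self):
        """On random additive matrices of 4-6 taxa, NJ returns the same
        topology as exhaustive enumeration with a least-squares fit."""
        rng = np.random.default_rng(17)
        for n_taxa in (4, 5, 6):
            labels = [f"T{i}" for i in range(n_taxa)]
            for _ in range(5):
                true_edges, d = random_additive_tree(rng, labels)
                fit_edges, residual = best_fit_topology(d, labels)
                assert residual < 1e-18
                expected = topology_splits(fit_edges, labels)
                assert expected == topology_splits(true_edges, labels)
                tree = neighbor_joining(d)
                assert bipartitions(tree) == expected

    def test_ultrametric_topology_matches_single_linkage(self):
        # nested ultrametric heights: (((A,B),C),(D,E))
        labels = list("ABCDE")
        heights = {
            frozenset("AB"): 1.0, frozenset("ABC"): 2.0,
            frozenset("DE"): 1.5, frozenset("ABCDE"): 4.0,
        }

        def h(a, b):
            for clade in sorted(heights, key=len):
                if a in clade and b in clade:
                    return heights[clade]
            return heights[frozenset("ABCDE")]

        mat = np.zeros((5, 5))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    mat[i, j] = 2 * h(a, b)
        d = pd.DataFrame(mat, index=labels, columns=labels)
        tree = neighbor_joining(d)
        assert bipartitions(tree) == {
            frozenset("AB"), frozenset("DE"),
        }

    def test_agrees_with_skbio_on_random_additive_input(self):
        """Independent cross-check: same topology as scikit-bio's NJ."""
        rng = np.random.default_rng(29)
        labels = [f"T{i}" for i in range(6)]
        _, d = random_additive_tree(rng, labels)
        mine = neighbor_joining(d)
        other = skbio_nj(DistanceMatrix(d.to_numpy(), ids=labels))
        other_splits = set()
        all_tips = frozenset(labels)
        for node in other.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= len(labels) - 2:
                other_splits.add(min((side, all_tips - side), key=lambda s: (len(s), sorted(s))))
        assert bipartitions(mine) == other_splits

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0, 1, 2], [9, 0, 3], [2, 3, 0]], index=list("ABC"), columns=list("ABC"), dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(d)

    def test_negative_lengths_retained_unless_clamped(self):
        # non-additive distances that force a negative branch
        d = pd.DataFrame(
            [
                [0, 0.673, 0.343, 0.137],
                [0.673, 0, 0.115, 0.832],
                [0.343, 0.115, 0, 0.921],
                [0.137, 0.832, 0.921, 0],
            ],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        lengths = [t.length for t in neighbor_joining(d).traverse() if t.length is not None]
        clamped = [
            t.length for t in neighbor_joining(d, clamp_negative=True).traverse()
            if t.length is not None
        ]
        assert min(lengths) < 0
        assert min(clamped) >= 0


class TestLabelInvariance:
    def test_strain_input_order_does_not_change_results(self):
        groups = [
            HomologueGroup(1, (("A", "o1"), ("C", "o2")), frozenset({"A", "C"})),
            HomologueGroup(2, (("B", "o3"),), frozenset({"B"})),
            HomologueGroup(3, (("A", "o4"), ("B", "o5"), ("C", "o6")), frozenset({"A", "B", "C"})),
        ]
        m1 = build_presence_matrix(groups, ["A", "B", "C"])
        m2 = build_presence_matrix(groups, ["C", "A", "B"])
        d1, d2 = gene_distance(m1), gene_distance(m2)
        for a in "ABC":
            for b in "ABC":
                assert d1.loc[a, b] == d2.loc[a, b]
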