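"""Annotation merging, structural filters, and validation metrics."""

import numpy as np
import pytest

from conftest import brute_force_branch_scan
from panorf.formats_io import GenomeSequence
from panorf.orf_refinement import (
    BRANCH_POINTS,
    OrfModel,
    build_true_set,
    check_branch_points,
    check_terminal_codons,
    comparison_metrics,
    consolidate_undefined,
    extract_introns,
    extract_spliced_cds,
    merge_sources,
    reverse_complement,
    translate_orf,
    validation_metrics,
)


def orf(orf_id="o1", seq_id="chrT", strand="+", exons=((0, 9),), **kw):
    return OrfModel(orf_id=orf_id, seq_id=seq_id, strand=strand, exons=tuple(exons), **kw)


class TestSplicedCds:
    def test_single_exon_plus_strand(self, toy_genome):
        assert extract_spliced_cds(orf(exons=[(0, 6)]), toy_genome) == "ATGAAA"

    def test_minus_strand_is_reverse_complement(self, toy_genome):
        plus = toy_genome.sequence[0:6]
        got = extract_spliced_cds(orf(strand="-", exons=[(0, 6)]), toy_genome)
        assert got == reverse_complement(plus) == "TTTCAT"

    def test_two_exons_concatenate_in_coding_order(self, toy_genome):
        o = orf(exons=[(0, 6), (9, 15)])
        assert extract_spliced_cds(o, toy_genome) == toy_genome.sequence[0:6] + toy_genome.sequence[9:15]
        assert len(extract_spliced_cds(o, toy_genome)) == o.spliced_length

    def test_out_of_bounds_exon_names_orf(self, toy_genome):
        with pytest.raises(ValueError, match="o1"):
            extract_spliced_cds(orf(exons=[(0, 10_000)]), toy_genome)

    def test_minus_strand_intron_is_coding_strand(self):
        # genomic: revcomp(exon2) revcomp(intron) revcomp(exon1)
        exon1, intron, exon2 = "ATGAAA", "GTTTACTAACAG", "TTTTAA"
        genomic = reverse_complement(exon2) + reverse_complement(intron) + reverse_complement(exon1)
        g = GenomeSequence("c", genomic)
        o = orf(strand="-", exons=[(len(genomic) - 6, len(genomic)), (0, 6)])
        assert extract_spliced_cds(o, g) == exon1 + exon2
        assert extract_introns(o, g) == [intron]


class TestTerminalCodons:
    @pytest.mark.parametrize(
        "cds, expected_status, reason",
        [
            ("ATGAAATAA", "validated", None),
            ("ATGAAA", "discarded", "no_stop"),
            ("TTGAAATAA", "discarded", "no_start"),
            ("ATGAAAA", "discarded", "not_in_frame"),
            ("ATGTAAATGTAA", "discarded", "internal_stop"),
            ("ATGAAATAG", "validated", None),
            ("ATGAAATGA", "validated", None),
        ],
    )
    def test_start_stop_frame_rules(self, cds, expected_status, reason):
        g = GenomeSequence("c", cds)
        checked = check_terminal_codons(orf(exons=[(0, len(cds))]), g)
        assert checked.status == expected_status
        assert checked.discard_reason == reason

    def test_every_discard_has_exactly_one_reason(self):
        g = GenomeSequence("c", "TTGAAA")
        checked = check_terminal_codons(orf(exons=[(0, 6)]), g)
        assert checked.status == "discarded" and checked.discard_reason == "no_start"


class TestBranchPoints:
    def make_spliced(self, intron):
        genomic = "ATGAAA" + intron + "TTTTAA"
        g = GenomeSequence("c", genomic)
        o = orf(exons=[(0, 6), (6 + len(intron), len(genomic))])
        return o, g

    def test_consensus_motif_passes(self):
        o, g = self.make_spliced("GCGTACTAACGC")
        assert check_branch_points(o, g).status == "validated"

    def test_motif_free_intron_discards(self):
        o, g = self.make_spliced("GCGCGCGCGCGC")
        checked = check_branch_points(o, g)
        assert checked.status == "discarded"
        assert checked.discard_reason == "no_branch_point"

    def test_single_exon_passes_vacuously(self, toy_genome):
        assert check_branch_points(orf(exons=[(0, 9)]), toy_genome).status == "validated"

    def test_two_introns_require_motif_in_each(self):
        good, bad = "GGAATTAACGG", "GGGGGGGGGGG"
        genomic = "ATG" + good + "AAA" + bad + "TAA"
        g = GenomeSequence("c", genomic)
        o = orf(exons=[(0, 3), (3 + len(good), 6 + len(good)), (6 + len(good) + len(bad), len(genomic))])
        assert check_branch_points(o, g).status == "discarded"

    def test_short_intron_fails(self):
        o, g = self.make_spliced("ACT")
        assert check_branch_points(o, g).status == "discarded"

    def test_catalog_is_the_seven_heptamers(self):
        assert set(BRANCH_POINTS.motifs) == {
            "UACUAAC", "CACUAAC", "GACUAAC", "UGCUAAC", "AACUAAC", "UAUUAAC", "AAUUAAC",
        }
        assert all(len(m) == 7 for m in BRANCH_POINTS.dna_motifs)

    def test_agrees_with_brute_force_scan_on_random_introns(self):
        """Substring search equals per-offset motif comparison, including
        planted motifs and near-miss 6-mers, over 1000 random introns."""
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        motifs = BRANCH_POINTS.dna_motifs
        for i in range(1000):
            n = int(rng.integers(7, 60))
            intron = "".join(rng.choice(bases, size=n))
            if i % 3 == 0:  # plant a full motif
                m = motifs[rng.integers(7)]
                p = int(rng.integers(0, n - 6))
                intron = intron[:p] + m + intron[p + 7 :]
            elif i % 3 == 1:  # plant a near-miss 6-mer
                m = motifs[rng.integers(7)][:6]
                p = int(rng.integers(0, n - 5))
                intron = intron[:p] + m + intron[p + 6 :]
            genomic = "ATG" + intron + "TAA"
            g = GenomeSequence("c", genomic)
            o = orf(exons=[(0, 3), (3 + len(intron), len(genomic))])
            got = check_branch_points(o, g).status == "validated"
            assert got == brute_force_branch_scan(intron)


class TestMergeSources:
    def test_identical_orf_collapses_to_merged(self):
        a = orf("h1", source="homology")
        b = orf("a1", source="abinitio")
        merged = merge_sources([a], [b])
        assert len(merged) == 1
        assert merged[0].source == "merged"

    def test_alternative_starts_same_stop_kept_separate(self):
        a = orf("h1", exons=[(100, 400)], source="homology")
        b = orf("a1", exons=[(130, 400)], source="abinitio")
        merged = merge_sources([a], [b])
        assert len(merged) == 2

    def test_disjoint_sets_union(self):
        hom = [orf(f"h{i}", exons=[(i * 100, i * 100 + 30)]) for i in range(3)]
        abi = [orf(f"a{i}", exons=[(i * 100 + 50, i * 100 + 80)]) for i in range(2)]
        assert len(merge_sources(hom, abi)) == 5

    def test_set_union_oracle_on_exon_keys(self):
        rng = np.random.default_rng(3)
        def rand_orf(tag, i):
            s = int(rng.integers(0, 50)) * 10
            return orf(f"{tag}{i}", exons=[(s, s + 30)], source="homology" if tag == "h" else "abinitio")
        hom = [rand_orf("h", i) for i in range(20)]
        abi = [rand_orf("a", i) for i in range(20)]
        merged = merge_sources(hom, abi)
        expected = {o.structure_key for o in hom} | {o.structure_key for o in abi}
        assert {o.structure_key for o in merged} == expected


class TestConsolidateUndefined:
    def test_longest_survives_per_overlap_cluster(self):
        a = orf("u1", exons=[(0, 450)])
        b = orf("u2", exons=[(100, 460)])
        kept = consolidate_undefined([a, b])
        assert [o.orf_id for o in kept] == ["u1"]

    def test_short_survivor_removed(self):
        kept = consolidate_undefined([orf("u1", exons=[(0, 240)])])
        assert kept == []

    def test_exactly_300_kept_by_default_removed_when_strict(self):
        o = orf("u1", exons=[(0, 300)])
        assert consolidate_undefined([o]) == [o]
        assert consolidate_undefined([o], strict_greater=True) == []

    def test_labeled_orfs_untouched(self):
        labeled = orf("g1", exons=[(0, 150)], label="GENE1")
        kept = consolidate_undefined([labeled, orf("u1", exons=[(10, 160)])])
        assert kept == [labeled]

    def test_different_strands_not_clustered(self):
        a = orf("u1", exons=[(0, 400)])
        b = orf("u2", strand="-", exons=[(100, 500)])
        assert len(consolidate_undefined([a, b])) == 2

    def test_conservation_kept_plus_discarded(self):
        orfs = [
            orf("u1", exons=[(0, 450)]),
            orf("u2", exons=[(100, 460)]),
            orf("u3", exons=[(1000, 1100)]),
            orf("g1", exons=[(2000, 2300)], label="G"),
        ]
        kept, discarded = consolidate_undefined(orfs, return_discarded=True)
        assert len(kept) + len(discarded) == len(orfs)
        assert all(o.discard_reason in ("consolidated", "too_short") for o in discarded)


class TestBuildTrueSet:
    def v(self, oid, s, e, cls="Verified"):
        return orf(oid, exons=[(s, e)], classification=cls)

    def test_dubious_overlapping_verified_removed(self):
        kept = build_true_set([self.v("v", 0, 500), self.v("d", 100, 500, "Dubious")])
        assert [o.orf_id for o in kept] == ["v"]

    def test_shorter_of_two_dubious_removed(self):
        kept = build_true_set([self.v("d1", 0, 400, "Dubious"), self.v("d2", 50, 400, "Dubious")])
        assert [o.orf_id for o in kept] == ["d1"]

    def test_two_verified_overlapping_both_kept(self):
        kept = build_true_set([self.v("v1", 0, 500), self.v("v2", 100, 600)])
        assert len(kept) == 2

    def test_short_orfs_removed_first(self):
        kept = build_true_set([self.v("s", 0, 200), self.v("v", 1000, 1400)])
        assert [o.orf_id for o in kept] == ["v"]

    def test_overlap_is_strand_agnostic(self):
        d = orf("d", strand="-", exons=[(100, 500)], classification="Dubious")
        kept = build_true_set([self.v("v", 0, 500), d])
        assert [o.orf_id for o in kept] == ["v"]

    def test_idempotent(self):
        orfs = [
            self.v("v1", 0, 500),
            self.v("d1", 100, 500, "Dubious"),
            self.v("d2", 600, 1000, "Dubious"),
            self.v("d3", 700, 1100, "Dubious"),
            self.v("v2", 2000, 2400),
        ]
        once = build_true_set(orfs)
        assert build_true_set(once) == once


class TestValidationMetrics:
    def n_orfs(self, n, offset=0):
        return [orf(f"o{offset + i}", exons=[(1000 * (offset + i), 1000 * (offset + i) + 300)]) for i in range(n)]

    def test_published_scale_arithmetic(self):
        true_set = self.n_orfs(5684)
        predicted = true_set[:5532] + self.n_orfs(5638 - 5532, offset=9000)
        report = validation_metrics(predicted, true_set)
        assert report.n_predicted == 5638 and report.n_identical == 5532
        assert round(report.fdr_pct, 2) == 1.88
        assert round(report.identical_pct, 1) == 98.1

    def test_perfect_prediction(self):
        s = self.n_orfs(10)
        report = validation_metrics(s, s)
        assert report.fdr_pct == 0.0 and report.identical_pct == 100.0

    def test_plain_arithmetic(self):
        true_set = self.n_orfs(90)
        predicted = true_set + self.n_orfs(10, offset=500)
        assert validation_metrics(predicted, true_set).fdr_pct == pytest.approx(10.0)

    def test_percentages_are_exact_complements(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n_t, n_p = int(rng.integers(5, 50)), int(rng.integers(5, 50))
            n_shared = int(rng.integers(1, min(n_t, n_p)))
            true_set = self.n_orfs(n_t)
            predicted = true_set[:n_shared] + self.n_orfs(n_p - n_shared, offset=800)
            r = validation_metrics(predicted, true_set)
            assert r.fdr_pct + r.identical_pct == pytest.approx(100.0, abs=1e-12)

    def test_empty_prediction_errors(self):
        with pytest.raises(ValueError):
            validation_metrics([], self.n_orfs(3))


class TestComparisonMetrics:
    def test_published_scale_catalogue_overlap(self):
        theirs = {f"t{i}" for i in range(319)}
        mine = {f"t{i}" for i in range(319 - 72)} | {f"m{i}" for i in range(40)}
        shared, mine_only, theirs_only, pct = comparison_metrics(mine, theirs)
        assert shared == 247 and theirs_only == 72 and mine_only == 40
        assert round(pct) == 77

    def test_identical_and_disjoint_sets(self):
        s = {"a", "b"}
        assert comparison_metrics(s, s)[3] == 100.0
        assert comparison_metrics({"x"}, s)[3] == 0.0

    def test_empty_external_catalogue_errors(self):
        with pytest.raises(ValueError):
            comparison_metrics({"a"}, set())


class TestTranslation:
    def test_translate_drops_terminal_stop(self):
        g = GenomeSequence("c", "ATGAAATGGTAA")
        assert translate_orf(orf(exons=[(0, 12)]), g) == "MKW"
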