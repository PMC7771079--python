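import numpy as np
import pytest

from lrfuse.annotation import GeneAnnotation
from lrfuse.fusion_core import (
    DetectionParams,
    FusionSupport,
    GeneHit,
    assign_genes,
    bin_window_pairs,
    candidate_supports,
    detect_candidates,
    gap_ok,
    junction_coordinate,
    rank_candidates,
    select_breakpoints,
)

from . import oracle
from .util import make_gene, make_group, make_segment, random_annotation, random_group


@pytest.fixture
def two_gene_annotation():
    """Two distant single-transcript genes on chr1, plus one on chr2."""
    return GeneAnnotation(
        [
            make_gene("GA", "chr1", [[(1000, 1400), (1800, 2200)]]),
            make_gene("GB", "chr1", [[(9000, 9400), (9800, 10200)]]),
            make_gene("GC", "chr2", [[(500, 1500)]]),
        ]
    )


DEFAULTS = DetectionParams()


class TestAssignGenes:
    def test_sufficient_overlap(self, two_gene_annotation):
        seg = make_segment("r", "chr1", [(1100, 1250)], 0, 400)
        hits = assign_genes(seg, two_gene_annotation, DEFAULTS)
        assert [h.gene_id for h in hits] == ["GA"]
        assert hits[0].overlap_bp == 150

    def test_below_threshold(self, two_gene_annotation):
        seg = make_segment("r", "chr1", [(1100, 1199)], 0, 400)
        # 99 bp aligned: fails both min_map_len and min_exon_overlap
        assert assign_genes(seg, two_gene_annotation, DEFAULTS) == []
        seg2 = make_segment("r", "chr1", [(1301, 1400), (1800, 1801)], 0, 400)
        # 100 aligned but only 99+1 in exons? actually both in exons: 100
        hits = assign_genes(seg2, two_gene_annotation, DEFAULTS)
        assert [h.gene_id for h in hits] == ["GA"]

    def test_boundary_99_vs_100(self, two_gene_annotation):
        params = DetectionParams(min_map_len=50)
        seg99 = make_segment("r", "chr1", [(1100, 1199)], 0, 400)
        seg100 = make_segment("r", "chr1", [(1100, 1200)], 0, 400)
        assert assign_genes(seg99, two_gene_annotation, params) == []
        assert len(assign_genes(seg100, two_gene_annotation, params)) == 1

    def test_intergenic_segment(self, two_gene_annotation):
        seg = make_segment("r", "chr1", [(4000, 4500)], 0, 600)
        assert assign_genes(seg, two_gene_annotation, DEFAULTS) == []

    def test_min_map_len_gate(self, two_gene_annotation):
        seg = make_segment("r", "chr1", [(1000, 1090)], 0, 400)
        params = DetectionParams(min_exon_overlap=50)
        assert assign_genes(seg, two_gene_annotation, params) == []

    def test_pseudogene_gate(self):
        ann = GeneAnnotation(
            [
                make_gene(
                    "PS", "chr1", [[(1000, 1500)]], biotype="unprocessed_pseudogene"
                )
            ]
        )
        seg = make_segment("r", "chr1", [(1000, 1400)], 0, 500)
        assert assign_genes(seg, ann, DEFAULTS) == []
        params = DetectionParams(include_pseudogenes=True)
        assert [h.gene_id for h in assign_genes(seg, ann, params)] == ["PS"]


class TestGapRule:
    @pytest.mark.parametrize(
        "delta,expected",
        [(-21, False), (-20, True), (0, True), (20, True), (21, False)],
    )
    def test_boundaries(self, delta, expected):
        assert gap_ok(500, 500 + delta, 20) is expected


class TestJunctionCoordinate:
    def test_forward_read_end(self):
        seg = make_segment("r", "chr1", [(1000, 1200)], 0, 300)
        assert junction_coordinate(seg, "read_end") == 1200

    def test_reverse_read_end(self):
        seg = make_segment("r", "chr1", [(1000, 1200)], 0, 300, strand="-")
        assert junction_coordinate(seg, "read_end") == 1001

    def test_forward_read_start(self):
        seg = make_segment("r", "chr1", [(1000, 1200)], 0, 300)
        assert junction_coordinate(seg, "read_start") == 1001

    def test_reverse_read_start(self):
        seg = make_segment("r", "chr1", [(1000, 1200)], 0, 300, strand="-")
        assert junction_coordinate(seg, "read_start") == 1200


def _clean_pair_group(name="r1"):
    """Two segments, clean gap, hitting GA then GB."""
    seg1 = make_segment(name, "chr1", [(1200, 1400), (1800, 2200)], 0)
    seg2 = make_segment(
        name, "chr1", [(9000, 9400)], 600, record_class="supplementary"
    )
    return make_group([seg1, seg2])


class TestCandidateSupports:
    def test_clean_two_segment_read(self, two_gene_annotation):
        sups = candidate_supports(
            _clean_pair_group(), two_gene_annotation, DEFAULTS
        )
        assert len(sups) == 1
        sup = sups[0]
        assert sup.upstream_hit.gene_id == "GA"
        assert sup.downstream_hit.gene_id == "GB"
        assert sup.junction_up == 2200
        assert sup.junction_down == 9001

    def test_overlapping_gene_pair_rejected(self):
        ann = GeneAnnotation(
            [
                make_gene("GX", "chr1", [[(1000, 2000)]]),
                make_gene("GY", "chr1", [[(1900, 3000)]]),
            ]
        )
        seg1 = make_segment("r", "chr1", [(1000, 1500)], 0)
        seg2 = make_segment(
            "r", "chr1", [(2200, 2700)], 500, record_class="supplementary"
        )
        stats = {}
        assert candidate_supports(make_group([seg1, seg2]), ann, DEFAULTS, stats) == []
        assert stats["rejected_overlapping_genes"] == 1

    def test_bad_gap_rejected(self, two_gene_annotation):
        seg1 = make_segment("r", "chr1", [(1800, 2200)], 0)
        seg2 = make_segment(
            "r", "chr1", [(9000, 9400)], 425, record_class="supplementary"
        )  # gap = 425 - 400 = 25 > 20
        stats = {}
        assert (
            candidate_supports(
                make_group([seg1, seg2]), two_gene_annotation, DEFAULTS, stats
            )
            == []
        )
        assert stats["rejected_gap"] == 1

    def test_three_segments_two_supports(self, two_gene_annotation):
        seg1 = make_segment("r", "chr1", [(1800, 2200)], 0)
        seg2 = make_segment(
            "r", "chr1", [(9000, 9400)], 400, record_class="supplementary"
        )
        seg3 = make_segment(
            "r", "chr2", [(500, 900)], 800, record_class="supplementary"
        )
        sups = candidate_supports(
            make_group([seg1, seg2, seg3]), two_gene_annotation, DEFAULTS
        )
        assert [(s.upstream_hit.gene_id, s.downstream_hit.gene_id) for s in sups] == [
            ("GA", "GB"),
            ("GB", "GC"),
        ]

    def test_same_gene_both_segments_rejected(self, two_gene_annotation):
        seg1 = make_segment("r", "chr1", [(1000, 1400)], 0)
        seg2 = make_segment(
            "r", "chr1", [(1800, 2200)], 400, record_class="supplementary"
        )
        assert (
            candidate_supports(
                make_group([seg1, seg2]), two_gene_annotation, DEFAULTS
            )
            == []
        )

    def test_per_read_pair_deduplication(self, two_gene_annotation):
        # four alternating segments GA-GB-GA-GB: pair counted once
        segs = [
            make_segment("r", "chr1", [(1800, 2200)], 0),
            make_segment("r", "chr1", [(9000, 9400)], 400, record_class="supplementary"),
            make_segment("r", "chr1", [(1000, 1400)], 800, record_class="supplementary"),
            make_segment("r", "chr1", [(9800, 10200)], 1200, record_class="supplementary"),
        ]
        sups = candidate_supports(
            make_group(segs), two_gene_annotation, DEFAULTS
        )
        assert len(sups) == 1


def _support(pair_junctions, read_name="r"):
    """FusionSupport over genes WA/WB with given (junction_a, junction_b)."""
    ja, jb = pair_junctions
    seg_a = make_segment(read_name, "chr1", [(max(0, ja - 100), ja)], 0)
    seg_b = make_segment(
        read_name, "chr1", [(jb - 1, jb + 99)], 100, record_class="supplementary"
    )
    return FusionSupport(
        read_name,
        GeneHit(seg_a, "WA", 100),
        GeneHit(seg_b, "WB", 100),
        ja,
        jb,
    )


@pytest.fixture
def window_annotation():
    return GeneAnnotation(
        [
            make_gene("WA", "chr1", [[(0, 1000)]]),
            make_gene("WB", "chr1", [[(5000, 6000)]]),
        ]
    )


class TestWindows:
    def test_single_support_four_window_pairs(self, window_annotation):
        # offsets 30 into each gene span, w=50 -> windows {0,1} x {0,1}
        sup = _support((31, 5031))
        wps = bin_window_pairs([sup], window_annotation, 50)
        assert {(w.window_index_a, w.window_index_b) for w in wps} == {
            (0, 0), (0, 1), (1, 0), (1, 1),
        }
        assert all(w.count == 1 for w in wps)

    def test_offset_zero_single_window(self, window_annotation):
        sup = _support((1, 5001))
        wps = bin_window_pairs([sup], window_annotation, 50)
        assert {(w.window_index_a, w.window_index_b) for w in wps} == {(0, 0)}

    def test_tight_cluster_shares_a_window(self, window_annotation):
        sups = [
            _support((201, 5301), "r1"),
            _support((206, 5306), "r2"),
            _support((210, 5310), "r3"),
        ]
        wps = bin_window_pairs(sups, window_annotation, 50)
        assert max(w.count for w in wps) == 3
        # verified against exhaustive window enumeration
        junctions = [{"WA": s.junction_up, "WB": s.junction_down} for s in sups]
        brute = oracle.brute_window_pairs(
            ("WA", "WB"), junctions, window_annotation, 50
        )
        assert {
            (w.window_index_a, w.window_index_b): w.count for w in wps
        } == {k: len(v) for k, v in brute.items()}

    def test_junction_outside_span_clamped(self, window_annotation, caplog):
        with caplog.at_level("WARNING"):
            wps = bin_window_pairs([_support((1200, 5500))], window_annotation, 50)
        k_max = (1000 - 1) // 25
        assert all(w.window_index_a == k_max for w in wps)
        assert "clamped" in caplog.text


class TestSelectBreakpoints:
    def test_mean_of_one(self, window_annotation):
        wps = bin_window_pairs([_support((1000, 5000))], window_annotation, 50)
        picks = select_breakpoints(wps, 1)
        assert picks[0][1] == {"WA": 1000, "WB": 5000}

    def test_arithmetic_mean(self, window_annotation):
        sups = [
            _support((1000, 5100), "r1"),
            _support((1002, 5102), "r2"),
            _support((1004, 5104), "r3"),
        ]
        wps = bin_window_pairs(sups, window_annotation, 5000)
        best, bp = select_breakpoints(wps, 1)[0]
        assert best.count == 3
        assert bp["WA"] == 1002

    def test_top_window_pair_only(self, window_annotation):
        sups_big = [_support((100 + 2 * i, 5100), f"b{i}") for i in range(5)]
        sups_small = [_support((800, 5800), f"s{i}") for i in range(3)]
        wps = bin_window_pairs(sups_big + sups_small, window_annotation, 50)
        picks = select_breakpoints(wps, 1)
        assert len(picks) == 1
        assert picks[0][0].count == 5
        picks2 = select_breakpoints(wps, 2)
        assert len(picks2) == 2

    def test_no_window_pairs_raises(self):
        with pytest.raises(ValueError):
            select_breakpoints([], 1)


class TestRanking:
    def _candidate(self, pair, support_count):
        from lrfuse.fusion_core import FusionCandidate, WindowPairCount

        wp = WindowPairCount(0, 0, [])
        return FusionCandidate(
            pair[0], pair[1], "chr1", "chr1", 100, 200,
            support_count, [], wp, [],
        )

    def test_min_support_and_order(self):
        counts = {"A:B": 8, "C:D": 7, "E:F": 2, "G:H": 2, "I:J": 1}
        cands = [
            self._candidate(tuple(k.split(":")), v) for k, v in counts.items()
        ]
        ranked = rank_candidates(cands, 2)
        assert [c.support_count for c in ranked] == [8, 7, 2, 2]
        # equal support -> deterministic lexicographic order
        assert [c.gene_a for c in ranked[2:]] == ["E", "G"]

    def test_all_below_threshold(self):
        cands = [self._candidate(("A", "B"), 1)]
        assert rank_candidates(cands, 2) == []


class TestOracleEquivalence:
    def test_randomized_micro_instances(self):
        from .util import assert_oracle_equivalent

        rng = np.random.default_rng(20240917)
        pairs_seen = 0
        for _ in range(60):
            pairs_seen += assert_oracle_equivalent(rng)
        assert pairs_seen > 10  # the instances actually exercise the path


class TestProperties:
    def test_monotonicity_in_thresholds(self, two_gene_annotation):
        group = _clean_pair_group()
        loose = DetectionParams(min_map_len=50, min_exon_overlap=50)
        tight = DetectionParams(min_map_len=500, min_exon_overlap=500)
        n_loose = len(candidate_supports(group, two_gene_annotation, loose))
        n_tight = len(candidate_supports(group, two_gene_annotation, tight))
        assert n_tight <= n_loose

    def test_min_support_monotonicity(self, two_gene_annotation):
        groups = [_clean_pair_group(f"r{i}") for i in range(3)]
        lo = detect_candidates(
            iter(groups), two_gene_annotation, DetectionParams(min_support=2)
        )
        hi = detect_candidates(
            iter(groups), two_gene_annotation, DetectionParams(min_support=4)
        )
        assert {c.gene_pair for c in hi} <= {c.gene_pair for c in lo}

    def test_gene_relabel_invariance(self):
        """Swapping the two partners' gene_ids changes nothing but labels."""

        def build(id1, id2):
            ann = GeneAnnotation(
                [
                    make_gene(id1, "chr1", [[(1000, 2000)]]),
                    make_gene(id2, "chr1", [[(9000, 10000)]]),
                ]
            )
            groups = []
            for i in range(3):
                s1 = make_segment(f"r{i}", "chr1", [(1500, 2000)], 0)
                s2 = make_segment(
                    f"r{i}", "chr1", [(9000, 9500)], 500,
                    record_class="supplementary",
                )
                groups.append(make_group([s1, s2]))
            return detect_candidates(iter(groups), ann, DEFAULTS)

        c1 = build("P", "Q")[0]
        c2 = build("Q", "P")[0]
        assert c1.support_count == c2.support_count
        assert {c1.gene_a: c1.breakpoint_a, c1.gene_b: c1.breakpoint_b} == {
            "P": c1.breakpoint_a if c1.gene_a == "P" else c1.breakpoint_b,
            "Q": c1.breakpoint_b if c1.gene_a == "P" else c1.breakpoint_a,
        }
        # same physical breakpoints regardless of labelling
        bp1 = {c1.chrom_a: c1.breakpoint_a, c1.chrom_b: c1.breakpoint_b}
        bp2 = {c2.chrom_a: c2.breakpoint_a, c2.chrom_b: c2.breakpoint_b}
        assert sorted([c1.breakpoint_a, c1.breakpoint_b]) == sorted(
            [c2.breakpoint_a, c2.breakpoint_b]
        )

    def test_support_count_bounded_by_reads(self, two_gene_annotation):
        groups = [_clean_pair_group(f"r{i}") for i in range(4)]
        cands = detect_candidates(iter(groups), two_gene_annotation, DEFAULTS)
        assert len(cands) == 1
        c = cands[0]
        assert c.support_count <= len({s.read_name for s in c.supports})
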