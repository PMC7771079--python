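"""The fusion detection algorithm proper.

Per-segment gene assignment, candidate gene-pair formation with the
read-gap rule, overlapping-window breakpoint voting, breakpoint
averaging, and support-ranked output.

Junction coordinates are carried as 1-based genomic positions of the
terminal aligned base; everything else stays 0-based half-open.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .alignment_io import AlignmentSegment, ReadAlignmentGroup, group_by_read
from .annotation import GeneAnnotation, GeneModel, exon_overlap_bp, genes_overlap

log = logging.getLogger(__name__)


@dataclass
class DetectionParams:
    """Tunable thresholds; defaults match the recommended settings."""

    min_map_len: int = 100
    min_exon_overlap: int = 100
    bin_size: int = 50  # w; adjacent windows overlap by w/2
    gap_max: int = 20
    min_support: int = 2
    include_pseudogenes: bool = False
    breakpoints_out: int = 1

    def __post_init__(self) -> None:
        if self.bin_size < 2 or self.bin_size % 2 != 0:
            raise ValueError("bin_size must be even and >= 2")
        if self.gap_max < 0:
            raise ValueError("gap_max must be >= 0")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.breakpoints_out < 1:
            raise ValueError("breakpoints_out must be >= 1")


@dataclass
class GeneHit:
    """A segment's assignment to one gene, with the exonic overlap size."""

    segment: AlignmentSegment
    gene_id: str
    overlap_bp: int


@dataclass
class FusionSupport:
    """One read's evidence for a gene pair: two consecutive segments, the
    genes they hit, and the junction-side genomic coordinates."""

    read_name: str
    upstream_hit: GeneHit  # smaller read-space start
    downstream_hit: GeneHit
    junction_up: int  # 1-based; gene of upstream_hit, at read coord M2
    junction_down: int  # 1-based; gene of downstream_hit, at read coord M3

    @property
    def gene_pair(self) -> tuple[str, str]:
        return tuple(sorted((self.upstream_hit.gene_id, self.downstream_hit.gene_id)))

    def junction_for(self, gene_id: str) -> int:
        if gene_id == self.upstream_hit.gene_id:
            return self.junction_up
        if gene_id == self.downstream_hit.gene_id:
            return self.junction_down
        raise KeyError(gene_id)


@dataclass
class WindowPairCount:
    """One (window in gene a, window in gene b) combination with the
    supports whose junctions fall in both windows."""

    window_index_a: int
    window_index_b: int
    supports: list[FusionSupport]

    @property
    def count(self) -> int:
        return len(self.supports)


@dataclass
class FusionCandidate:
    """A ranked candidate: gene pair in read 5'->3' majority orientation,
    winning window pair and averaged breakpoints."""

    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    breakpoint_a: int  # 1-based
    breakpoint_b: int
    support_count: int
    supports: list[FusionSupport]
    best_window: WindowPairCount
    breakpoints: list[tuple[WindowPairCount, int, int]]

    @property
    def gene_pair(self) -> tuple[str, str]:
        return tuple(sorted((self.gene_a, self.gene_b)))

    @property
    def read_names(self) -> list[str]:
        return sorted({s.read_name for s in self.best_window.supports})


def _bump(stats: dict | None, key: str) -> None:
    if stats is not None:
        stats[key] = stats.get(key, 0) + 1


def assign_genes(
    segment: AlignmentSegment,
    annotation: GeneAnnotation,
    params: DetectionParams,
) -> list[GeneHit]:
    """All genes whose exons (of some transcript) overlap the segment's
    mapped blocks by at least ``min_exon_overlap`` bp.

    Returns an empty list for segments with fewer than ``min_map_len``
    aligned bases.  Hits are sorted by overlap descending, ties by
    gene_id.
    """
    if segment.aligned_read_len < params.min_map_len:
        return []
    hits: list[GeneHit] = []
    for gene in annotation.genes_in_region(
        segment.chrom, segment.ref_start, segment.ref_end
    ):
        if gene.is_pseudogene and not params.include_pseudogenes:
            continue
        overlap = exon_overlap_bp(gene, segment.ref_blocks)
        if overlap >= params.min_exon_overlap:
            hits.append(GeneHit(segment, gene.gene_id, overlap))
    hits.sort(key=lambda h: (-h.overlap_bp, h.gene_id))
    return hits


def gap_ok(m2: int, m3: int, gap_max: int) -> bool:
    """Read-gap rule: the two segments' read coordinates must neither
    overlap nor be separated by more than ``gap_max`` bases."""
    return -gap_max <= m3 - m2 <= gap_max


def junction_coordinate(segment: AlignmentSegment, side: str) -> int:
    """Genomic position (1-based, terminal aligned base) of the
    junction-side end of a segment.

    ``side`` is ``"read_end"`` for the upstream segment (junction at M2)
    and ``"read_start"`` for the downstream segment (junction at M3); the
    segment strand decides which reference end that is.
    """
    if side == "read_end":
        return segment.ref_end if segment.seg_strand == "+" else segment.ref_start + 1
    if side == "read_start":
        return segment.ref_start + 1 if segment.seg_strand == "+" else segment.ref_end
    raise ValueError(f"unknown side {side!r}")


def candidate_supports(
    group: ReadAlignmentGroup,
    annotation: GeneAnnotation,
    params: DetectionParams,
    stats: dict | None = None,
) -> list[FusionSupport]:
    """Form fusion supports from one read group.

    Segments are sorted by read-space start; only consecutive segment
    pairs are considered (non-adjacent pairs would imply a third
    intervening locus).  Each passing pair must hit two distinct,
    non-overlapping genes with an acceptable read gap.  A read
    contributes at most one support per gene pair.
    """
    segs = sorted(group.segments, key=lambda s: s.read_span)
    hits = [assign_genes(s, annotation, params) for s in segs]
    if len(segs) > 2:
        log.debug(
            "read %s has %d segments; may indicate a complex event",
            group.read_name,
            len(segs),
        )
    out: list[FusionSupport] = []
    seen_pairs: set[tuple[str, str]] = set()
    for i in range(len(segs) - 1):
        up, down = segs[i], segs[i + 1]
        hits_up, hits_down = hits[i], hits[i + 1]
        if not hits_up or not hits_down:
            _bump(stats, "rejected_no_gene")
            continue
        top_up, top_down = hits_up[0], hits_down[0]
        if len(hits_up) > 1 or len(hits_down) > 1:
            log.debug(
                "read %s: segment hits multiple genes (%s / %s); using top overlap",
                group.read_name,
                [h.gene_id for h in hits_up],
                [h.gene_id for h in hits_down],
            )
        if top_up.gene_id == top_down.gene_id:
            _bump(stats, "rejected_same_gene")
            continue
        gene_up = annotation.genes[top_up.gene_id]
        gene_down = annotation.genes[top_down.gene_id]
        if genes_overlap(gene_up, gene_down):
            _bump(stats, "rejected_overlapping_genes")
            log.warning(
                "read %s: gene pair %s / %s rejected (overlapping spans); "
                "locus needs manual review",
                group.read_name,
                top_up.gene_id,
                top_down.gene_id,
            )
            continue
        if not gap_ok(up.m_end, down.m_start, params.gap_max):
            _bump(stats, "rejected_gap")
            continue
        pair = tuple(sorted((top_up.gene_id, top_down.gene_id)))
        if pair in seen_pairs:
            _bump(stats, "deduplicated_within_read")
            continue
        seen_pairs.add(pair)
        out.append(
            FusionSupport(
                read_name=group.read_name,
                upstream_hit=top_up,
                downstream_hit=top_down,
                junction_up=junction_coordinate(up, "read_end"),
                junction_down=junction_coordinate(down, "read_start"),
            )
        )
    return out


def _windows_for(pos_1based: int, gene: GeneModel, w: int) -> tuple[int, ...]:
    """Indices of the (up to two) overlapping windows containing a
    junction.  Windows are anchored at the gene span start:
    W_k = [S + k*w/2, S + k*w/2 + w).  Junctions outside the span are
    clamped to the terminal window with a warning."""
    half = w // 2
    span_len = gene.span_end - gene.span_start
    k_max = max(0, (span_len - 1) // half)
    offset = (pos_1based - 1) - gene.span_start
    if offset < 0:
        log.warning(
            "junction %d left of gene %s span; clamped to window 0",
            pos_1based,
            gene.gene_id,
        )
        return (0,)
    if offset >= span_len:
        log.warning(
            "junction %d right of gene %s span; clamped to window %d",
            pos_1based,
            gene.gene_id,
            k_max,
        )
        return (k_max,)
    k_hi = offset // half
    if k_hi >= 1:
        return (k_hi - 1, k_hi)
    return (k_hi,)


def bin_window_pairs(
    supports: Sequence[FusionSupport],
    annotation: GeneAnnotation,
    w: int,
) -> list[WindowPairCount]:
    """Discretize junction coordinates of one gene pair's supports into
    overlapping windows and count every populated window pair.

    Each junction falls into up to two windows, so a single support can
    populate up to four window pairs; counts are per window pair, not
    partitioned.
    """
    if not supports:
        return []
    pair = supports[0].gene_pair
    gene_a = annotation.genes[pair[0]]
    gene_b = annotation.genes[pair[1]]
    acc: dict[tuple[int, int], list[FusionSupport]] = {}
    for sup in supports:
        if sup.gene_pair != pair:
            raise ValueError("supports from mixed gene pairs")
        for ka in _windows_for(sup.junction_for(pair[0]), gene_a, w):
            for kb in _windows_for(sup.junction_for(pair[1]), gene_b, w):
                acc.setdefault((ka, kb), []).append(sup)
    return [
        WindowPairCount(ka, kb, sups) for (ka, kb), sups in sorted(acc.items())
    ]


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def select_breakpoints(
    window_pairs: Sequence[WindowPairCount],
    breakpoints_out: int = 1,
) -> list[tuple[WindowPairCount, dict[str, int]]]:
    """Rank window pairs by support count and average the junction
    coordinates of the winners.

    Ties between equally supported window pairs break on the lexicographic
    window-index order.  Breakpoints are arithmetic means rounded half-up.
    Returns the top ``breakpoints_out`` entries as
    (window_pair, {gene_id: breakpoint}).
    """
    if not window_pairs:
        raise ValueError("no window pairs to select from")
    ranked = sorted(
        window_pairs,
        key=lambda wp: (-wp.count, wp.window_index_a, wp.window_index_b),
    )
    picks = []
    for wp in ranked[:breakpoints_out]:
        pair = wp.supports[0].gene_pair
        bp = {
            g: _round_half_up(
                sum(s.junction_for(g) for s in wp.supports) / wp.count
            )
            for g in pair
        }
        picks.append((wp, bp))
    return picks


def _build_candidate(
    pair: tuple[str, str],
    supports: list[FusionSupport],
    annotation: GeneAnnotation,
    params: DetectionParams,
) -> FusionCandidate:
    window_pairs = bin_window_pairs(supports, annotation, params.bin_size)
    picks = select_breakpoints(window_pairs, params.breakpoints_out)
    best, best_bp = picks[0]
    # Display orientation: gene that is upstream (read 5'->3') in the
    # majority of supports goes first; ties keep canonical order.
    upstream_votes = sum(
        1 for s in supports if s.upstream_hit.gene_id == pair[0]
    )
    if upstream_votes * 2 >= len(supports):
        first, second = pair
    else:
        first, second = pair[1], pair[0]
    return FusionCandidate(
        gene_a=first,
        gene_b=second,
        chrom_a=annotation.genes[first].chrom,
        chrom_b=annotation.genes[second].chrom,
        breakpoint_a=best_bp[first],
        breakpoint_b=best_bp[second],
        support_count=best.count,
        supports=supports,
        best_window=best,
        breakpoints=[(wp, bp[first], bp[second]) for wp, bp in picks],
    )


def rank_candidates(
    candidates: Iterable[FusionCandidate], min_support: int
) -> list[FusionCandidate]:
    """Drop candidates below ``min_support`` and sort by support count
    descending, ties by canonical gene pair."""
    kept = [c for c in candidates if c.support_count >= min_support]
    kept.sort(key=lambda c: (-c.support_count, c.gene_pair))
    return kept


def detect_candidates(
    groups: Iterable[ReadAlignmentGroup],
    annotation: GeneAnnotation,
    params: DetectionParams,
    stats: dict | None = None,
) -> list[FusionCandidate]:
    """Run the full detection pipeline over pre-grouped reads."""
    by_pair: dict[tuple[str, str], list[FusionSupport]] = {}
    n_groups = 0
    for group in groups:
        n_groups += 1
        for sup in candidate_supports(group, annotation, params, stats):
            by_pair.setdefault(sup.gene_pair, []).append(sup)
    if stats is not None:
        stats["multi_segment_groups"] = n_groups
        stats["gene_pairs_with_support"] = len(by_pair)
        stats["supports"] = sum(len(v) for v in by_pair.values())
    candidates = [
        _build_candidate(pair, sups, annotation, params)
        for pair, sups in sorted(by_pair.items())
    ]
    return rank_candidates(candidates, params.min_support)


def run_detection(
    alignments_path,
    annotation: GeneAnnotation,
    params: DetectionParams | None = None,
    two_pass: bool = False,
    min_mapq: int = 0,
    stats: dict | None = None,
) -> list[FusionCandidate]:
    """Convenience wrapper: SAM/BAM path -> ranked candidates."""
    if params is None:
        params = DetectionParams()
    groups = group_by_read(
        alignments_path, two_pass=two_pass, min_mapq=min_mapq, stats=stats
    )
    return detect_candidates(groups, annotation, params, stats=stats)
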