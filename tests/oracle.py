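"""Independent brute-force reference implementation.

Everything here is computed the slow, obvious way: per-base set
intersections for overlaps, a linear scan instead of an interval index,
and direct membership tests over every window index.  It shares no logic
with the optimized pipeline and exists only to cross-check it.
"""

from __future__ import annotations

import math


def brute_overlap_bp(gene, blocks) -> int:
    block_pos = set()
    for s, e in blocks:
        block_pos.update(range(s, e))
    best = 0
    for t in gene.transcripts:
        exon_pos = set()
        for ex in t.exons:
            exon_pos.update(range(ex.start, ex.end))
        best = max(best, len(exon_pos & block_pos))
    return best


def brute_genes_overlap(a, b) -> bool:
    if a.chrom != b.chrom:
        return False
    # count shared 1-based positions directly; >= 2 is significant
    shared = len(
        set(range(a.span_start + 1, a.span_end + 1))
        & set(range(b.span_start + 1, b.span_end + 1))
    )
    return shared > 1


def brute_assign(segment, annotation, params) -> list[tuple[int, str]]:
    if segment.aligned_read_len < params.min_map_len:
        return []
    hits = []
    for gene in annotation:  # linear scan on purpose
        if gene.chrom != segment.chrom:
            continue
        if gene.is_pseudogene and not params.include_pseudogenes:
            continue
        overlap = brute_overlap_bp(gene, segment.ref_blocks)
        if overlap >= params.min_exon_overlap:
            hits.append((overlap, gene.gene_id))
    hits.sort(key=lambda t: (-t[0], t[1]))
    return hits


def brute_junction(segment, side) -> int:
    if side == "read_end":
        if segment.seg_strand == "+":
            return segment.ref_end
        return segment.ref_start + 1
    if segment.seg_strand == "+":
        return segment.ref_start + 1
    return segment.ref_end


def brute_supports(group, annotation, params):
    """List of (canonical_pair, upstream_gene, downstream_gene,
    junction_up, junction_down) for one group."""
    segs = sorted(group.segments, key=lambda s: s.read_span)
    out = []
    seen = set()
    for up, down in zip(segs, segs[1:]):
        hits_up = brute_assign(up, annotation, params)
        hits_down = brute_assign(down, annotation, params)
        if not hits_up or not hits_down:
            continue
        g_up, g_down = hits_up[0][1], hits_down[0][1]
        if g_up == g_down:
            continue
        if brute_genes_overlap(annotation.genes[g_up], annotation.genes[g_down]):
            continue
        gap = down.read_span[0] - up.read_span[1]
        if not (-params.gap_max <= gap <= params.gap_max):
            continue
        pair = tuple(sorted((g_up, g_down)))
        if pair in seen:
            continue
        seen.add(pair)
        out.append(
            (
                pair,
                g_up,
                g_down,
                brute_junction(up, "read_end"),
                brute_junction(down, "read_start"),
            )
        )
    return out


def brute_windows(pos_1based, gene, w) -> list[int]:
    half = w // 2
    span_len = gene.span_end - gene.span_start
    k_max = max(0, (span_len - 1) // half)
    offset = (pos_1based - 1) - gene.span_start
    if offset < 0:
        return [0]
    if offset >= span_len:
        return [k_max]
    return [k for k in range(k_max + 1) if k * half <= offset < k * half + w]


def brute_window_pairs(pair, junction_lists, annotation, w):
    """junction_lists: list of {gene_id: junction} dicts, one per support.
    Returns {(ka, kb): [support_index, ...]}."""
    gene_a = annotation.genes[pair[0]]
    gene_b = annotation.genes[pair[1]]
    counts: dict[tuple[int, int], list[int]] = {}
    for idx, j in enumerate(junction_lists):
        for ka in brute_windows(j[pair[0]], gene_a, w):
            for kb in brute_windows(j[pair[1]], gene_b, w):
                counts.setdefault((ka, kb), []).append(idx)
    return counts


def brute_best_breakpoints(pair, junction_lists, annotation, w):
    """(best window pair, count, {gene: breakpoint}) via exhaustive
    enumeration."""
    counts = brute_window_pairs(pair, junction_lists, annotation, w)
    best_key = min(counts, key=lambda k: (-len(counts[k]), k))
    members = counts[best_key]
    bp = {}
    for g in pair:
        vals = [junction_lists[i][g] for i in members]
        bp[g] = math.floor(sum(vals) / len(vals) + 0.5)
    return best_key, len(members), bp
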