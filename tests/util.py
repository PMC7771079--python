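"""Builders for hand-constructed detection inputs used across tests."""

from __future__ import annotations

import numpy as np

from lrfuse.alignment_io import AlignmentSegment, ReadAlignmentGroup
from lrfuse.annotation import (
    ExonInterval,
    GeneAnnotation,
    GeneModel,
    TranscriptModel,
)
from lrfuse.simulate import project_tx_interval


def make_gene(
    gene_id: str,
    chrom: str,
    transcripts: list[list[tuple[int, int]]],
    strand: str = "+",
    biotype: str = "protein_coding",
) -> GeneModel:
    """Gene from lists of (start, end) exon tuples (0-based half-open),
    one list per transcript."""
    tx_models = [
        TranscriptModel(
            f"{gene_id}.t{i + 1}",
            [ExonInterval(chrom, s, e) for s, e in exons],
        )
        for i, exons in enumerate(transcripts)
    ]
    return GeneModel(gene_id, gene_id, chrom, strand, biotype, tx_models)


def make_segment(
    read_name: str,
    chrom: str,
    blocks: list[tuple[int, int]],
    m_start: int,
    read_length: int = 0,
    strand: str = "+",
    record_class: str = "primary",
    mapq: int = 60,
) -> AlignmentSegment:
    """Segment with internally consistent span/blocks/aligned length."""
    aligned = sum(e - s for s, e in blocks)
    if read_length <= 0:
        read_length = m_start + aligned
    return AlignmentSegment(
        read_name=read_name,
        record_class=record_class,
        chrom=chrom,
        ref_start=blocks[0][0],
        ref_end=blocks[-1][1],
        seg_strand=strand,
        read_span=(m_start, m_start + aligned),
        ref_blocks=list(blocks),
        aligned_read_len=aligned,
        read_length=read_length,
        mapq=mapq,
    )


def make_group(segments: list[AlignmentSegment]) -> ReadAlignmentGroup:
    read_length = max(s.m_end for s in segments)
    for s in segments:
        s.read_length = read_length
    return ReadAlignmentGroup(
        segments[0].read_name,
        sorted(segments, key=lambda s: s.read_span),
        read_length,
    )


# ---------------------------------------------------------------------------
# randomized micro-instances for oracle-equivalence testing


def assert_oracle_equivalent(rng: np.random.Generator) -> int:
    """Build one random micro-instance, run both the optimized pipeline
    and the brute-force oracle, and assert exact agreement on supports,
    window-pair counts and breakpoints.  Returns the number of gene pairs
    with at least one support (so callers can check coverage)."""
    from lrfuse.fusion_core import (
        DetectionParams,
        bin_window_pairs,
        candidate_supports,
        select_breakpoints,
    )

    from . import oracle

    annotation = random_annotation(rng)
    params = DetectionParams(
        min_map_len=int(rng.choice([30, 60, 100])),
        min_exon_overlap=int(rng.choice([30, 60, 100])),
        bin_size=int(rng.choice([8, 20, 50])),
        min_support=1,
    )
    groups = [random_group(rng, annotation, f"r{i}") for i in range(5)]

    brute_by_pair: dict = {}
    for g in groups:
        for pair, g_up, g_down, j_up, j_down in oracle.brute_supports(
            g, annotation, params
        ):
            brute_by_pair.setdefault(pair, []).append({g_up: j_up, g_down: j_down})

    pipeline_by_pair: dict = {}
    pipeline_supports: dict = {}
    for g in groups:
        for sup in candidate_supports(g, annotation, params):
            pipeline_by_pair.setdefault(sup.gene_pair, []).append(
                {
                    sup.upstream_hit.gene_id: sup.junction_up,
                    sup.downstream_hit.gene_id: sup.junction_down,
                }
            )
            pipeline_supports.setdefault(sup.gene_pair, []).append(sup)
    assert pipeline_by_pair == brute_by_pair

    for pair, junctions in brute_by_pair.items():
        wps = bin_window_pairs(
            pipeline_supports[pair], annotation, params.bin_size
        )
        got_counts = {(w.window_index_a, w.window_index_b): w.count for w in wps}
        brute_counts = oracle.brute_window_pairs(
            pair, junctions, annotation, params.bin_size
        )
        assert got_counts == {k: len(v) for k, v in brute_counts.items()}
        best, bp = select_breakpoints(wps, 1)[0]
        brute_key, brute_count, brute_bp = oracle.brute_best_breakpoints(
            pair, junctions, annotation, params.bin_size
        )
        assert (best.window_index_a, best.window_index_b) == brute_key
        assert best.count == brute_count
        assert bp == brute_bp
    return len(brute_by_pair)


def random_annotation(rng: np.random.Generator, max_genes: int = 10) -> GeneAnnotation:
    genes = []
    n = int(rng.integers(2, max_genes + 1))
    for i in range(n):
        chrom = f"chr{int(rng.integers(1, 3))}"
        start = int(rng.integers(0, 5000))
        transcripts = []
        for t in range(int(rng.integers(1, 4))):
            pos = start + int(rng.integers(0, 50))
            exons = []
            for _ in range(int(rng.integers(1, 5))):
                length = int(rng.integers(50, 300))
                exons.append(ExonInterval(chrom, pos, pos + length))
                pos += length + int(rng.integers(20, 200))
            transcripts.append(TranscriptModel(f"G{i}.t{t}", exons))
        biotype = (
            "processed_pseudogene" if rng.random() < 0.15 else "protein_coding"
        )
        genes.append(GeneModel(f"G{i}", f"G{i}", chrom, "+", biotype, transcripts))
    return GeneAnnotation(genes)


def random_group(
    rng: np.random.Generator, annotation: GeneAnnotation, name: str = "r"
) -> ReadAlignmentGroup:
    genes = list(annotation)
    n_seg = int(rng.integers(2, 5))
    m = 0
    segments = []
    for k in range(n_seg):
        gene = genes[int(rng.integers(len(genes)))]
        tx = gene.transcripts[int(rng.integers(len(gene.transcripts)))]
        length = tx.exonic_length
        a = int(rng.integers(0, max(1, length - 60)))
        b = min(length, a + int(rng.integers(60, 400)))
        blocks = project_tx_interval(tx, a, b)
        aligned = sum(e - s for s, e in blocks)
        gap = int(rng.integers(-30, 31))
        m_start = max(0, m + gap)
        strand = "+" if rng.random() < 0.5 else "-"
        record_class = "primary" if k == 0 else "supplementary"
        segments.append(
            make_segment(
                name, gene.chrom, blocks, m_start,
                strand=strand, record_class=record_class,
            )
        )
        m = m_start + aligned
    return make_group(segments)
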