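"""Synthetic fusion benchmark generator.

Builds a toy genome and multi-exon gene annotation, fuses transcript
pairs at known exonic breakpoints, assigns tiered expression, and emits
long reads together with the split SAM alignments an aligner would
produce.  Alignments are computed analytically by projecting transcript
coordinates through the exon structure onto the genome (splices become N
operations), so the ground truth is exact and no external aligner or
read simulator is needed.

Error model: substitutions perturb only the sequence; insertions and
deletions are injected into segment interiors as I/D CIGAR ops with a
consistent read sequence; junction "jitter" moves a few aligned bases at
the fusion junction into the soft clip, emulating aligner uncertainty at
split points.  With ``error_free=True`` all of these are disabled and
junction coordinates are exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation import (
    ExonInterval,
    GeneAnnotation,
    GeneModel,
    TranscriptModel,
    genes_overlap,
    write_gtf,
)

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class SimConfig:
    """Knobs for one synthetic dataset.  A fixed seed gives byte-identical
    output files."""

    seed: int = 0
    # genome / annotation
    n_chroms: int = 2
    n_genes: int = 30
    exons_per_gene: tuple[int, int] = (3, 7)
    exon_len: tuple[int, int] = (150, 400)
    intron_len: tuple[int, int] = (200, 800)
    intergenic_len: tuple[int, int] = (500, 2000)
    two_transcript_prob: float = 0.5
    overlapping_pair: bool = False  # add one deliberately overlapping gene pair
    with_pseudogene: bool = False  # add one pseudogene
    # fusions
    n_fusions: int = 5
    tpm_high_count: int | None = None  # default: half of n_fusions
    tpm_high_range: tuple[float, float] = (1000.0, 3000.0)
    tpm_low_range: tuple[float, float] = (10.0, 1000.0)
    breakpoint_margin: int = 150  # min transcript bases on each side of a cut
    # expression / reads
    background_tpm_range: tuple[float, float] = (100.0, 900.0)
    total_reads: int = 5000
    p_full: float = 0.5
    min_read_len: int = 150
    # error model
    error_free: bool = False
    sub_rate: float = 0.02
    ins_rate: float = 0.002
    del_rate: float = 0.002
    junction_jitter_prob: float = 0.5
    junction_jitter_max: int = 6
    secondary_frac: float = 0.01
    # outputs
    write_fastq: bool = True

    def __post_init__(self) -> None:
        if self.n_fusions * 2 > self.n_genes:
            raise ValueError("need n_fusions <= n_genes / 2")
        if self.tpm_high_count is not None and not (
            0 <= self.tpm_high_count <= self.n_fusions
        ):
            raise ValueError("tpm_high_count out of range")

    @property
    def high_count(self) -> int:
        if self.tpm_high_count is not None:
            return self.tpm_high_count
        return self.n_fusions // 2


@dataclass
class FusionTruth:
    """Ground truth for one simulated fusion."""

    fusion_id: str
    gene_a: str
    gene_b: str
    transcript_a: str
    transcript_b: str
    chrom_a: str
    breakpoint_a: int  # 1-based genomic, last base of the 5' part
    chrom_b: str
    breakpoint_b: int  # 1-based genomic, first base of the 3' part
    cut_a: int  # transcript coordinate: 5' part is tx_a[:cut_a]
    cut_b: int  # 3' part is tx_b[cut_b:]
    tpm: float
    tier: str  # "high" | "low"


@dataclass
class ReadProvenance:
    read_name: str
    source: str  # fusion_id or gene_id
    spanning: bool
    junction_read_pos: int  # clean-read coordinate of the junction, -1 if none
    strand: str
    read_len: int = 0  # clean (error-free) read length


@dataclass
class SimTruth:
    fusions: list[FusionTruth]
    reads: list[ReadProvenance] = field(default_factory=list)


@dataclass
class SimOutput:
    config: SimConfig
    annotation: GeneAnnotation
    truth: SimTruth
    fasta: Path
    gtf: Path
    sam: Path
    fastq: Path | None
    truth_tsv: Path
    reads_tsv: Path


# ---------------------------------------------------------------------------
# genome + annotation


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _make_gene(
    rng: np.random.Generator, config: SimConfig, chrom: str, cursor: int, gene_id: str,
    biotype: str = "protein_coding",
) -> tuple[GeneModel, int]:
    lo, hi = config.exons_per_gene
    n_exons = int(rng.integers(lo, hi + 1))
    exon_lens = rng.integers(config.exon_len[0], config.exon_len[1] + 1, n_exons)
    intron_lens = rng.integers(
        config.intron_len[0], config.intron_len[1] + 1, max(0, n_exons - 1)
    )
    pos = cursor
    exons = []
    for i in range(n_exons):
        exons.append(ExonInterval(chrom, pos, pos + int(exon_lens[i])))
        pos += int(exon_lens[i])
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    transcripts = [TranscriptModel(f"{gene_id}.t1", list(exons))]
    if n_exons >= 4 and rng.random() < config.two_transcript_prob:
        drop = int(rng.integers(1, n_exons - 1))
        transcripts.append(
            TranscriptModel(
                f"{gene_id}.t2", [e for j, e in enumerate(exons) if j != drop]
            )
        )
    strand = "+" if rng.random() < 0.5 else "-"
    return GeneModel(gene_id, gene_id, chrom, strand, biotype, transcripts), pos


def make_genome_and_annotation(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], GeneAnnotation]:
    """Random multi-chromosome genome with non-overlapping gene placement
    (plus, optionally, one deliberately overlapping pair and one
    pseudogene for negative tests)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    cursors = {c: 0 for c in chroms}
    genes: list[GeneModel] = []

    def _advance(chrom: str) -> int:
        gap = int(
            rng.integers(config.intergenic_len[0], config.intergenic_len[1] + 1)
        )
        cursors[chrom] += gap
        return cursors[chrom]

    for i in range(config.n_genes):
        chrom = chroms[i % len(chroms)]
        start = _advance(chrom)
        gene, end = _make_gene(rng, config, chrom, start, f"GENE{i + 1:04d}")
        cursors[chrom] = end
        genes.append(gene)

    if config.with_pseudogene:
        chrom = chroms[0]
        start = _advance(chrom)
        gene, end = _make_gene(
            rng, config, chrom, start, "GENEPSEUDO", biotype="processed_pseudogene"
        )
        cursors[chrom] = end
        genes.append(gene)

    if config.overlapping_pair:
        chrom = chroms[-1]
        c = _advance(chrom)
        exons_x = [ExonInterval(chrom, c, c + 400), ExonInterval(chrom, c + 700, c + 1100)]
        exons_y = [
            ExonInterval(chrom, c + 900, c + 1300),
            ExonInterval(chrom, c + 1600, c + 2000),
        ]
        genes.append(
            GeneModel("GENEOVLA", "GENEOVLA", chrom, "+", "protein_coding",
                      [TranscriptModel("GENEOVLA.t1", exons_x)])
        )
        genes.append(
            GeneModel("GENEOVLB", "GENEOVLB", chrom, "+", "protein_coding",
                      [TranscriptModel("GENEOVLB.t1", exons_y)])
        )
        cursors[chrom] = c + 2000

    genome = {c: _random_seq(rng, cursors[c] + 200) for c in chroms}
    return genome, GeneAnnotation(genes)


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as out:
        for chrom, seq in genome.items():
            out.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# transcript coordinate arithmetic


def transcript_sequence(genome: dict[str, str], tx: TranscriptModel) -> str:
    return "".join(genome[e.chrom][e.start : e.end] for e in tx.exons)


def tx_to_genomic(tx: TranscriptModel, offset: int) -> int:
    """0-based genomic position of transcript base ``offset`` (transcripts
    read in genomic order)."""
    for e in tx.exons:
        if offset < e.length:
            return e.start + offset
        offset -= e.length
    raise IndexError(f"offset {offset} beyond transcript {tx.transcript_id}")


def project_tx_interval(
    tx: TranscriptModel, u: int, v: int
) -> list[tuple[int, int]]:
    """Project transcript interval [u, v) onto genomic blocks."""
    blocks: list[tuple[int, int]] = []
    t = 0
    for e in tx.exons:
        a, b = max(u, t), min(v, t + e.length)
        if a < b:
            blocks.append((e.start + (a - t), e.start + (b - t)))
        t += e.length
        if t >= v:
            break
    return blocks


# ---------------------------------------------------------------------------
# fusions


def _eligible_fusion_genes(
    annotation: GeneAnnotation, config: SimConfig
) -> list[GeneModel]:
    min_len = 2 * config.breakpoint_margin + 50
    out = []
    for g in annotation:
        if g.is_pseudogene:
            continue
        if any(
            other.gene_id != g.gene_id and genes_overlap(g, other)
            for other in annotation.genes_in_region(g.chrom, g.span_start, g.span_end)
        ):
            continue
        if any(t.exonic_length >= min_len for t in g.transcripts):
            out.append(g)
    return out


def make_fusions(
    annotation: GeneAnnotation,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> SimTruth:
    """Pick distinct gene pairs, cut one transcript of each at a random
    exonic point, and assign tier-sampled TPM expression (half high, half
    low by default)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    truth = SimTruth(fusions=[])
    if config.n_fusions == 0:
        return truth
    eligible = _eligible_fusion_genes(annotation, config)
    if len(eligible) < 2 * config.n_fusions:
        raise ValueError(
            f"only {len(eligible)} eligible genes for {config.n_fusions} fusions; "
            "increase n_genes or exon sizes"
        )
    chosen = rng.choice(len(eligible), size=2 * config.n_fusions, replace=False)
    tiers = ["high"] * config.high_count + ["low"] * (
        config.n_fusions - config.high_count
    )
    tiers = [tiers[i] for i in rng.permutation(len(tiers))]
    margin = config.breakpoint_margin
    min_len = 2 * margin + 50
    for i in range(config.n_fusions):
        gene_a = eligible[int(chosen[2 * i])]
        gene_b = eligible[int(chosen[2 * i + 1])]
        txs_a = [t for t in gene_a.transcripts if t.exonic_length >= min_len]
        txs_b = [t for t in gene_b.transcripts if t.exonic_length >= min_len]
        tx_a = txs_a[int(rng.integers(len(txs_a)))]
        tx_b = txs_b[int(rng.integers(len(txs_b)))]
        cut_a = int(rng.integers(margin, tx_a.exonic_length - margin + 1))
        cut_b = int(rng.integers(margin, tx_b.exonic_length - margin + 1))
        tier = tiers[i]
        tpm_range = (
            config.tpm_high_range if tier == "high" else config.tpm_low_range
        )
        truth.fusions.append(
            FusionTruth(
                fusion_id=f"FUS{i + 1:03d}",
                gene_a=gene_a.gene_id,
                gene_b=gene_b.gene_id,
                transcript_a=tx_a.transcript_id,
                transcript_b=tx_b.transcript_id,
                chrom_a=gene_a.chrom,
                breakpoint_a=tx_to_genomic(tx_a, cut_a - 1) + 1,
                chrom_b=gene_b.chrom,
                breakpoint_b=tx_to_genomic(tx_b, cut_b) + 1,
                cut_a=cut_a,
                cut_b=cut_b,
                tpm=float(rng.uniform(*tpm_range)),
                tier=tier,
            )
        )
    return truth


# ---------------------------------------------------------------------------
# read + alignment emission


def _cigar_string(ops: list[list]) -> str:
    merged: list[list] = []
    for n, op in ops:
        if n <= 0:
            continue
        if merged and merged[-1][1] == op:
            merged[-1][0] += n
        else:
            merged.append([n, op])
    return "".join(f"{n}{op}" for n, op in merged)


def _segment_cigar(
    blocks: Sequence[tuple[int, int]],
    events: list[tuple[int, str]],
    lead_clip: int,
    trail_clip: int,
) -> str:
    """CIGAR for one segment: M runs over genomic blocks with N gaps,
    I/D events injected at their reference-local offsets, soft clips at
    the ends.  ``events`` offsets are in segment-local reference
    coordinates."""
    ops: list[list] = []
    if lead_clip:
        ops.append([lead_clip, "S"])
    queue = sorted(events)
    qi = 0
    loc = 0
    prev_end = None
    for g0, g1 in blocks:
        if prev_end is not None and g0 > prev_end:
            ops.append([g0 - prev_end, "N"])
        length = g1 - g0
        cur = 0
        while qi < len(queue) and queue[qi][0] < loc + length:
            d, kind = queue[qi]
            qi += 1
            d -= loc
            if d > cur:
                ops.append([d - cur, "M"])
                cur = d
            if kind == "I":
                ops.append([1, "I"])
            else:  # deletion: reference base with no read base
                ops.append([1, "D"])
                cur = d + 1
        if length > cur:
            ops.append([length - cur, "M"])
        loc += length
        prev_end = g1
    if trail_clip:
        ops.append([trail_clip, "S"])
    return _cigar_string(ops)


def _apply_errors(clean: str, events: list[tuple[int, str, str]]) -> str:
    """Apply (pos, kind, base) edits to a clean read.  Insertions insert
    ``base`` before ``pos``; deletions drop the base at ``pos``;
    substitutions replace it."""
    if not events:
        return clean
    pieces = []
    prev = 0
    for pos, kind, base in sorted(events):
        pieces.append(clean[prev:pos])
        if kind == "S":
            pieces.append(base)
            prev = pos + 1
        elif kind == "I":
            pieces.append(base)
            prev = pos
        else:  # D
            prev = pos + 1
    pieces.append(clean[prev:])
    return "".join(pieces)


class _SamWriter:
    def __init__(self, path, genome: dict[str, str]):
        self.fh = open(path, "w")
        self.fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom, seq in genome.items():
            self.fh.write(f"@SQ\tSN:{chrom}\tLN:{len(seq)}\n")

    def write_record(
        self, name, flag, chrom, pos0, cigar, seq
    ) -> None:
        self.fh.write(
            f"{name}\t{flag}\t{chrom}\t{pos0 + 1}\t60\t{cigar}\t*\t0\t0\t{seq}\t*\n"
        )

    def close(self):
        self.fh.close()


def emit_reads_and_alignments(
    truth: SimTruth,
    annotation: GeneAnnotation,
    genome: dict[str, str],
    config: SimConfig,
    rng: np.random.Generator,
    out_dir: Path,
    prefix: str = "sim",
) -> tuple[Path | None, Path]:
    """Draw reads per transcript proportional to TPM x length and write
    the SAM (and optionally FASTQ).

    Every gene gets background (wild-type) expression in addition to the
    fusion transcripts, so non-fusion reads over fusion partner genes are
    present as negative material.  Junction-spanning fusion reads are
    written as two records (primary = longer aligned part, supplementary =
    shorter, soft-clipped); a configurable fraction of reads is duplicated
    as secondary records to exercise filtering.
    """
    out_dir = Path(out_dir)
    sam_path = out_dir / f"{prefix}.sam"
    fastq_path = out_dir / f"{prefix}.fastq" if config.write_fastq else None

    # expression sources, in deterministic order
    sources: list[dict] = []
    for gene in annotation:
        tx = gene.transcripts[0]
        sources.append(
            {
                "kind": "bg",
                "id": gene.gene_id,
                "tx": tx,
                "seq": transcript_sequence(genome, tx),
                "tpm": float(rng.uniform(*config.background_tpm_range)),
                "chrom": gene.chrom,
            }
        )
    tx_by_id = {
        t.transcript_id: (g, t) for g in annotation for t in g.transcripts
    }
    for f in truth.fusions:
        gene_a, tx_a = tx_by_id[f.transcript_a]
        gene_b, tx_b = tx_by_id[f.transcript_b]
        seq = (
            transcript_sequence(genome, tx_a)[: f.cut_a]
            + transcript_sequence(genome, tx_b)[f.cut_b :]
        )
        sources.append(
            {
                "kind": "fus",
                "id": f.fusion_id,
                "fusion": f,
                "tx_a": tx_a,
                "tx_b": tx_b,
                "seq": seq,
                "tpm": f.tpm,
            }
        )

    weights = np.array(
        [s["tpm"] * len(s["seq"]) for s in sources], dtype=float
    )
    counts = rng.multinomial(config.total_reads, weights / weights.sum())

    error_free = config.error_free
    jitter_max = 0 if error_free else config.junction_jitter_max
    sam = _SamWriter(sam_path, genome)
    fq = open(fastq_path, "w") if fastq_path else None
    base_choice = "ACGT"

    try:
        for src, n_reads in zip(sources, counts):
            if n_reads == 0:
                continue
            seq_full = src["seq"]
            length = len(seq_full)
            is_fusion = src["kind"] == "fus"
            cut = src["fusion"].cut_a if is_fusion else -1

            full = rng.random(n_reads) < config.p_full
            keep_prefix = rng.random(n_reads) < 0.5
            if length > config.min_read_len:
                trunc_lens = rng.integers(
                    config.min_read_len, length + 1, n_reads
                )
            else:
                trunc_lens = np.full(n_reads, length)
            reverse = rng.random(n_reads) < 0.5
            secondary = rng.random(n_reads) < config.secondary_frac
            if error_free:
                jit_a = jit_b = np.zeros(n_reads, dtype=int)
            else:
                jit_a = np.where(
                    rng.random(n_reads) < config.junction_jitter_prob,
                    rng.integers(1, config.junction_jitter_max + 1, n_reads),
                    0,
                )
                jit_b = np.where(
                    rng.random(n_reads) < config.junction_jitter_prob,
                    rng.integers(1, config.junction_jitter_max + 1, n_reads),
                    0,
                )

            for i in range(n_reads):
                if full[i]:
                    s, e = 0, length
                elif keep_prefix[i]:
                    s, e = 0, int(trunc_lens[i])
                else:
                    s, e = length - int(trunc_lens[i]), length
                rl = e - s
                clean = seq_full[s:e]
                name = f"{prefix}_{src['id']}_r{i:06d}"
                spanning = is_fusion and s < cut < e
                junction_pos = cut - s if spanning else -1

                # --- error events in clean-read coordinates; positions are
                # kept unique across event kinds so edits commute
                events: list[tuple[int, str, str]] = []
                indels: list[tuple[int, str]] = []
                if not error_free:
                    if rl > 40:
                        n_ins = rng.binomial(rl, config.ins_rate)
                        n_del = rng.binomial(rl, config.del_rate)
                        if n_ins or n_del:
                            guard = 10 + jitter_max
                            pos = np.unique(
                                rng.integers(10, rl - 10, n_ins + n_del)
                            )
                            if spanning:
                                pos = pos[np.abs(pos - junction_pos) > guard]
                            for j, p in enumerate(pos):
                                kind = "I" if j < min(n_ins, len(pos)) else "D"
                                base = (
                                    base_choice[int(rng.integers(4))]
                                    if kind == "I"
                                    else ""
                                )
                                events.append((int(p), kind, base))
                                indels.append((int(p), kind))
                    n_sub = rng.binomial(rl, config.sub_rate)
                    if n_sub:
                        taken = {p for p, _ in indels}
                        for p in np.unique(rng.integers(0, rl, n_sub)):
                            if int(p) not in taken:
                                events.append(
                                    (int(p), "S", base_choice[int(rng.integers(4))])
                                )
                errored = _apply_errors(clean, events)
                n_ins_tot = sum(1 for _, k in indels if k == "I")
                n_del_tot = sum(1 for _, k in indels if k == "D")
                errored_len = rl + n_ins_tot - n_del_tot
                assert errored_len == len(errored)

                def _shift(x: int) -> int:
                    return (
                        x
                        + sum(1 for p, k in indels if k == "I" and p < x)
                        - sum(1 for p, k in indels if k == "D" and p < x)
                    )

                flag_base = 16 if reverse[i] else 0

                if spanning:
                    ja, jb = int(jit_a[i]), int(jit_b[i])
                    p_a = junction_pos
                    # jitter must leave a few aligned bases on each side
                    if p_a <= ja + 10:
                        ja = 0
                    if rl - p_a <= jb + 10:
                        jb = 0
                    # segment A: clean [0, p_a - ja) -> tx_a [s, s + p_a - ja)
                    seg_a_u, seg_a_v = 0, p_a - ja
                    # segment B: clean [p_a + jb, rl) -> tx_b [cut_b + jb, ...)
                    seg_b_u, seg_b_v = p_a + jb, rl
                    f = src["fusion"]
                    blocks_a = project_tx_interval(
                        src["tx_a"], s, s + (seg_a_v - seg_a_u)
                    )
                    blocks_b = project_tx_interval(
                        src["tx_b"],
                        f.cut_b + jb,
                        f.cut_b + jb + (seg_b_v - seg_b_u),
                    )
                    qlen_a = (seg_a_v - seg_a_u) + sum(
                        1 for p, k in indels if k == "I" and seg_a_u <= p < seg_a_v
                    ) - sum(
                        1 for p, k in indels if k == "D" and seg_a_u <= p < seg_a_v
                    )
                    lead_b = _shift(seg_b_u)
                    cigar_a = _segment_cigar(
                        blocks_a,
                        [(p - seg_a_u, k) for p, k in indels if seg_a_u <= p < seg_a_v],
                        0,
                        errored_len - qlen_a,
                    )
                    cigar_b = _segment_cigar(
                        blocks_b,
                        [(p - seg_b_u, k) for p, k in indels if seg_b_u <= p < seg_b_v],
                        lead_b,
                        0,
                    )
                    a_longer = qlen_a >= errored_len - lead_b
                    recs = [
                        (f.chrom_a, blocks_a, cigar_a, a_longer),
                        (f.chrom_b, blocks_b, cigar_b, not a_longer),
                    ]
                    for chrom, blocks, cigar, is_primary in recs:
                        flag = flag_base if is_primary else flag_base | 0x800
                        sam.write_record(
                            name, flag, chrom, blocks[0][0], cigar, errored
                        )
                        if is_primary and secondary[i]:
                            sam.write_record(
                                name, flag | 0x100, chrom, blocks[0][0], cigar, errored
                            )
                else:
                    if is_fusion:
                        f = src["fusion"]
                        if e <= cut:
                            tx, u = src["tx_a"], s
                            chrom = f.chrom_a
                        else:
                            tx, u = src["tx_b"], f.cut_b + (s - cut)
                            chrom = f.chrom_b
                    else:
                        tx, u = src["tx"], s
                        chrom = src["chrom"]
                    blocks = project_tx_interval(tx, u, u + rl)
                    cigar = _segment_cigar(blocks, indels, 0, 0)
                    sam.write_record(
                        name, flag_base, chrom, blocks[0][0], cigar, errored
                    )
                    if secondary[i]:
                        sam.write_record(
                            name, flag_base | 0x100, chrom, blocks[0][0], cigar, errored
                        )

                if fq is not None:
                    phys = _revcomp(errored) if reverse[i] else errored
                    fq.write(f"@{name}\n{phys}\n+\n{'I' * len(phys)}\n")
                truth.reads.append(
                    ReadProvenance(
                        read_name=name,
                        source=src["id"],
                        spanning=spanning,
                        junction_read_pos=junction_pos,
                        strand="-" if reverse[i] else "+",
                        read_len=rl,
                    )
                )
    finally:
        sam.close()
        if fq is not None:
            fq.close()
    return fastq_path, sam_path


# ---------------------------------------------------------------------------
# orchestration + truth tables


def write_truth_tsv(truth: SimTruth, path) -> None:
    cols = [
        "fusion_id", "gene_a", "gene_b", "transcript_a", "transcript_b",
        "chrom_a", "breakpoint_a", "chrom_b", "breakpoint_b",
        "cut_a", "cut_b", "tpm", "tier",
    ]
    with open(path, "w") as out:
        out.write("\t".join(cols) + "\n")
        for f in truth.fusions:
            out.write(
                "\t".join(
                    str(getattr(f, c)) for c in cols
                )
                + "\n"
            )


def write_reads_tsv(truth: SimTruth, path) -> None:
    with open(path, "w") as out:
        out.write("read_name\tsource\tspanning\tjunction_read_pos\tstrand\tread_len\n")
        for r in truth.reads:
            out.write(
                f"{r.read_name}\t{r.source}\t{int(r.spanning)}\t"
                f"{r.junction_read_pos}\t{r.strand}\t{r.read_len}\n"
            )


def simulate_dataset(
    config: SimConfig, out_dir, prefix: str = "sim"
) -> SimOutput:
    """Generate one complete dataset: FASTA genome, GTF annotation, reads
    (FASTQ), split alignments (SAM), and truth tables (TSV)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genome, annotation = make_genome_and_annotation(config, rng)
    truth = make_fusions(annotation, config, rng)

    fasta = out_dir / f"{prefix}_genome.fa"
    gtf = out_dir / f"{prefix}_genes.gtf"
    write_fasta(genome, fasta)
    write_gtf(annotation, gtf)
    fastq, sam = emit_reads_and_alignments(
        truth, annotation, genome, config, rng, out_dir, prefix
    )
    truth_tsv = out_dir / f"{prefix}_truth.tsv"
    reads_tsv = out_dir / f"{prefix}_reads.tsv"
    write_truth_tsv(truth, truth_tsv)
    write_reads_tsv(truth, reads_tsv)
    log.info(
        "simulated %d reads, %d fusions -> %s",
        config.total_reads,
        len(truth.fusions),
        out_dir,
    )
    return SimOutput(
        config=config,
        annotation=annotation,
        truth=truth,
        fasta=fasta,
        gtf=gtf,
        sam=sam,
        fastq=fastq,
        truth_tsv=truth_tsv,
        reads_tsv=reads_tsv,
    )
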