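"""GTF-backed gene/transcript/exon models and gene-level eligibility rules.

All coordinates are stored 0-based half-open internally.  Conversion from
the 1-based inclusive GTF convention happens exactly once, at parse time
(and back once, at write time).
"""

from __future__ import annotations

import gzip
import logging
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

log = logging.getLogger(__name__)

#: A generic 0-based half-open interval.
Interval = tuple[int, int]


@dataclass(frozen=True)
class ExonInterval:
    """A single exon, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty exon {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """One transcript isoform: an ordered, non-overlapping list of exons."""

    transcript_id: str
    exons: list[ExonInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        merged: list[ExonInterval] = [exons[0]]
        for ex in exons[1:]:
            last = merged[-1]
            if ex.chrom != last.chrom:
                raise ValueError(
                    f"transcript {self.transcript_id} spans chromosomes"
                )
            if ex.start < last.end:
                log.warning(
                    "merging overlapping exons in transcript %s",
                    self.transcript_id,
                )
                merged[-1] = ExonInterval(
                    last.chrom, last.start, max(last.end, ex.end)
                )
            else:
                merged.append(ex)
        self.exons = merged

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def exon_intervals(self) -> list[Interval]:
        return [(e.start, e.end) for e in self.exons]


@dataclass
class GeneModel:
    """A gene with its transcript isoforms; span covers all exons."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    biotype: str
    transcripts: list[TranscriptModel]
    span_start: int = field(init=False)
    span_end: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        if any(t.chrom != self.chrom for t in self.transcripts):
            raise ValueError(f"gene {self.gene_id}: transcript on wrong chrom")
        if self.strand not in ("+", "-"):
            self.strand = "+"
        self.span_start = min(t.exons[0].start for t in self.transcripts)
        self.span_end = max(t.exons[-1].end for t in self.transcripts)

    @property
    def is_pseudogene(self) -> bool:
        # Ensembl/GENCODE biotype vocabulary: any "...pseudogene" subtype.
        return "pseudogene" in self.biotype.lower()


class IntervalIndex:
    """Static interval index: starts sorted, with a running maximum of ends
    so queries can stop scanning early.

    Query results are exactly the payloads whose intervals intersect the
    query interval with positive width.
    """

    def __init__(self, intervals: Iterable[tuple[int, int, object]]) -> None:
        items = sorted(intervals, key=lambda t: (t[0], t[1]))
        self._items = items
        self._starts = [it[0] for it in items]
        self._maxend: list[int] = []
        running = 0
        for _, end, _ in items:
            running = max(running, end)
            self._maxend.append(running)

    def query(self, start: int, end: int) -> list:
        out = []
        i = bisect_left(self._starts, end) - 1
        while i >= 0 and self._maxend[i] > start:
            s, e, payload = self._items[i]
            if e > start:
                out.append(payload)
            i -= 1
        out.reverse()
        return out


class GeneAnnotation:
    """The gene universe: gene models plus per-chromosome interval indexes
    over gene spans and exon intervals."""

    def __init__(self, genes: Iterable[GeneModel]) -> None:
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                log.warning("duplicate gene_id %s; keeping first", g.gene_id)
                continue
            self.genes[g.gene_id] = g
        gene_items: dict[str, list] = {}
        exon_items: dict[str, list] = {}
        for g in self.genes.values():
            gene_items.setdefault(g.chrom, []).append(
                (g.span_start, g.span_end, g)
            )
            for t in g.transcripts:
                for ex in t.exons:
                    exon_items.setdefault(g.chrom, []).append(
                        (ex.start, ex.end, (ex, g.gene_id))
                    )
        self._gene_index = {c: IntervalIndex(v) for c, v in gene_items.items()}
        self._exon_index = {c: IntervalIndex(v) for c, v in exon_items.items()}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def genes_in_region(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        idx = self._gene_index.get(chrom)
        return idx.query(start, end) if idx is not None else []

    def exons_in_region(
        self, chrom: str, start: int, end: int
    ) -> list[tuple[ExonInterval, str]]:
        idx = self._exon_index.get(chrom)
        return idx.query(start, end) if idx is not None else []


def _open_text(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path)


def _parse_attributes(attr_field: str) -> dict[str, str]:
    """Parse GTF attribute column, accepting both `key "value";` and
    `key value;` dialects."""
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, sep, raw = chunk.partition(" ")
        if not sep:
            continue
        attrs[key] = raw.strip().strip('"')
    return attrs


_BIOTYPE_KEYS = ("gene_biotype", "gene_type", "transcript_biotype", "transcript_type")


def parse_gtf(path, include_pseudogenes: bool = False) -> GeneAnnotation:
    """Parse a (possibly gzipped) GTF file into a :class:`GeneAnnotation`.

    Gene and transcript records are synthesized from exon lines when
    absent, so exon-only GTFs are accepted.  Genes whose biotype contains
    "pseudogene" (case-insensitive) are excluded unless
    ``include_pseudogenes`` is set.

    Malformed lines (end < start, missing gene_id) are skipped with a
    warning; an unreadable file raises.
    """
    gene_meta: dict[str, dict] = {}
    gene_order: list[str] = []
    tx_gene: dict[str, str] = {}
    tx_exons: dict[str, list[ExonInterval]] = {}

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                log.warning("GTF line %d: fewer than 9 columns; skipped", lineno)
                continue
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields[:9]
            attrs = _parse_attributes(attr_s)
            gene_id = attrs.get("gene_id")
            if not gene_id:
                log.warning("GTF line %d: missing gene_id; skipped", lineno)
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                log.warning("GTF line %d: non-integer coordinates; skipped", lineno)
                continue
            if end < start:
                log.warning("GTF line %d: end < start; skipped", lineno)
                continue
            if gene_id not in gene_meta:
                gene_meta[gene_id] = {
                    "name": attrs.get("gene_name", gene_id),
                    "biotype": "",
                    "chrom": chrom,
                    "strand": strand,
                }
                gene_order.append(gene_id)
            meta = gene_meta[gene_id]
            if not meta["biotype"]:
                for key in _BIOTYPE_KEYS:
                    if attrs.get(key):
                        meta["biotype"] = attrs[key]
                        break
            if attrs.get("gene_name"):
                meta["name"] = attrs["gene_name"]
            if feature != "exon":
                continue
            tx_id = attrs.get("transcript_id")
            if not tx_id:
                log.warning("GTF line %d: exon without transcript_id; skipped", lineno)
                continue
            tx_gene[tx_id] = gene_id
            # 1-based inclusive -> 0-based half-open, exactly once.
            tx_exons.setdefault(tx_id, []).append(ExonInterval(chrom, start - 1, end))

    tx_by_gene: dict[str, list[TranscriptModel]] = {}
    for tx_id, exons in tx_exons.items():
        tx_by_gene.setdefault(tx_gene[tx_id], []).append(
            TranscriptModel(tx_id, exons)
        )

    genes: list[GeneModel] = []
    for gene_id in gene_order:
        transcripts = tx_by_gene.get(gene_id)
        if not transcripts:
            continue  # gene/transcript line without any exon line
        meta = gene_meta[gene_id]
        gene = GeneModel(
            gene_id,
            meta["name"],
            meta["chrom"],
            meta["strand"],
            meta["biotype"],
            transcripts,
        )
        if gene.is_pseudogene and not include_pseudogenes:
            log.info("excluding pseudogene %s (biotype %s)", gene_id, gene.biotype)
            continue
        genes.append(gene)
    return GeneAnnotation(genes)


def write_gtf(annotation: GeneAnnotation, path) -> None:
    """Write an annotation back to GTF (1-based inclusive)."""
    with open(path, "w") as out:
        for g in annotation:
            biotype = g.biotype or "protein_coding"
            gene_attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; '
                f'gene_biotype "{biotype}";'
            )
            out.write(
                f"{g.chrom}\tlrfuse\tgene\t{g.span_start + 1}\t{g.span_end}\t.\t"
                f"{g.strand}\t.\t{gene_attrs}\n"
            )
            for t in g.transcripts:
                tx_attrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'gene_name "{g.gene_name}"; gene_biotype "{biotype}";'
                )
                out.write(
                    f"{g.chrom}\tlrfuse\ttranscript\t{t.exons[0].start + 1}\t"
                    f"{t.exons[-1].end}\t.\t{g.strand}\t.\t{tx_attrs}\n"
                )
                for ex in t.exons:
                    out.write(
                        f"{g.chrom}\tlrfuse\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                        f"{g.strand}\t.\t{tx_attrs}\n"
                    )


def genes_overlap(a: GeneModel, b: GeneModel) -> bool:
    """True when two gene spans overlap "significantly".

    With the two genes relabelled so the first starts before the second,
    the test is E1 - S2 > 0 in 1-based inclusive coordinates (first
    gene's end vs. second gene's start).  The symmetric generalization
    used here — intersection of at least two bases — reduces to exactly
    that expression whenever the starts differ and neither span is
    contained in the other, and stays symmetric in the degenerate cases
    the ordered formula leaves undefined.  A single shared base is NOT
    significant (matching the abutting-gene case).  Different
    chromosomes never overlap.
    """
    if a.chrom != b.chrom:
        return False
    # half-open intersection width > 1  <=>  >= 2 shared bases
    return min(a.span_end, b.span_end) - max(a.span_start, b.span_start) > 1


def _intersect_total(a: Sequence[Interval], b: Sequence[Interval]) -> int:
    """Total intersection length of two sorted, non-overlapping interval lists."""
    i = j = 0
    total = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def exon_overlap_bp(gene: GeneModel, blocks: Sequence[Interval]) -> int:
    """Best per-transcript overlap (bp) between reference blocks and the
    gene's exons.

    The overlap is computed against each transcript's exon set separately
    and the maximum is returned (not a union across transcripts).
    """
    best = 0
    for t in gene.transcripts:
        total = _intersect_total(blocks, t.exon_intervals)
        if total > best:
            best = total
    return best
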