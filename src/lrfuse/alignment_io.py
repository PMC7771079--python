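"""SAM/BAM ingestion: record classification, CIGAR arithmetic and
grouping of alignment records by read name.

Read-coordinate spans are always expressed in the ORIGINAL read
orientation, so spans from forward and reverse segments of the same read
are directly comparable.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

import pysam

log = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=XB])")
_OP_LETTERS = "MIDNSHP=XB"  # pysam integer op codes, in order
_QUERY_OPS = frozenset("MIS=X")  # consume query (SEQ)
_ALIGN_OPS = frozenset("M=X")  # aligned to the reference
_CLIP_OPS = frozenset("SH")

CigarLike = Union[str, Sequence[tuple]]

PRIMARY = "primary"
SUPPLEMENTARY = "supplementary"
SECONDARY = "secondary"
UNMAPPED = "unmapped"


def parse_cigar(cigar: CigarLike) -> list[tuple[str, int]]:
    """Normalize a CIGAR to a list of (op_letter, length).

    Accepts a CIGAR string, a pysam ``cigartuples`` list of
    (op_code, length) ints, or an already-normalized list of
    (op_letter, length).
    """
    if isinstance(cigar, str):
        if cigar in ("", "*"):
            return []
        ops = []
        pos = 0
        for m in _CIGAR_RE.finditer(cigar):
            if m.start() != pos:
                raise ValueError(f"unparseable CIGAR {cigar!r}")
            ops.append((m.group(2), int(m.group(1))))
            pos = m.end()
        if pos != len(cigar):
            raise ValueError(f"unparseable CIGAR {cigar!r}")
        return ops
    out = []
    for a, b in cigar:
        if isinstance(a, str):
            out.append((a, int(b)))
        elif isinstance(b, str):
            out.append((b, int(a)))
        else:  # pysam order: (op_code, length)
            out.append((_OP_LETTERS[a], int(b)))
    return out


def classify_record(flag: int, mapq: int | None = None, cigar=None) -> str:
    """Classify a SAM record from its flag field."""
    if flag & 0x100:
        return SECONDARY
    if flag & 0x800:
        return SUPPLEMENTARY
    if flag & 0x4:
        return UNMAPPED
    return PRIMARY


def read_length_from_cigar(cigar: CigarLike) -> int:
    """Full read length implied by a CIGAR: query-consuming ops plus hard
    clips (hard-clipped bases count toward the original read length)."""
    return sum(
        n for op, n in parse_cigar(cigar) if op in _QUERY_OPS or op == "H"
    )


def aligned_query_length(cigar: CigarLike) -> int:
    """Query bases in alignment-match ops (M/=/X); insertions excluded."""
    return sum(n for op, n in parse_cigar(cigar) if op in _ALIGN_OPS)


def read_span_from_cigar(
    cigar: CigarLike, is_reverse: bool, read_length: int
) -> tuple[int, int]:
    """Half-open interval of original-read positions covered by this
    alignment.

    Forward segments start at the leading clip length.  Reverse segments
    are reflected through ``read_length`` so that spans from different
    segments of the same read share one coordinate system.
    """
    ops = parse_cigar(cigar)
    lead = 0
    for op, n in ops:
        if op in _CLIP_OPS:
            lead += n
        else:
            break
    consumed = sum(n for op, n in ops if op in ("M", "I", "=", "X"))
    if consumed == 0:
        raise ValueError("CIGAR consumes no query bases")
    if not is_reverse:
        return lead, lead + consumed
    return read_length - lead - consumed, read_length - lead


def ref_blocks_from_cigar(
    cigar: CigarLike, ref_start: int
) -> list[tuple[int, int]]:
    """Reference intervals consumed by alignment-match ops.

    D and N advance the reference without emitting mapped positions
    (N = intron); I/S/H advance only the query.  Adjacent blocks are
    merged when contiguous.
    """
    blocks: list[tuple[int, int]] = []
    pos = ref_start
    for op, n in parse_cigar(cigar):
        if op in _ALIGN_OPS:
            if blocks and blocks[-1][1] == pos:
                blocks[-1] = (blocks[-1][0], pos + n)
            else:
                blocks.append((pos, pos + n))
            pos += n
        elif op in ("D", "N"):
            pos += n
    return blocks


@dataclass
class AlignmentSegment:
    """One SAM record reduced to the fields detection needs."""

    read_name: str
    record_class: str
    chrom: str
    ref_start: int
    ref_end: int
    seg_strand: str  # '+' or '-'
    read_span: tuple[int, int]  # original-read coords, half-open
    ref_blocks: list[tuple[int, int]]
    aligned_read_len: int
    read_length: int
    mapq: int = 0

    @property
    def m_start(self) -> int:
        return self.read_span[0]

    @property
    def m_end(self) -> int:
        return self.read_span[1]


@dataclass
class ReadAlignmentGroup:
    """All non-secondary mapped records of one read, sorted by read-space
    start."""

    read_name: str
    segments: list[AlignmentSegment]
    read_length: int


def segment_from_record(rec: pysam.AlignedSegment) -> AlignmentSegment | None:
    """Build an AlignmentSegment from a pysam record.

    Secondary and unmapped records return None (they are never used
    downstream).
    """
    record_class = classify_record(rec.flag)
    if record_class in (SECONDARY, UNMAPPED):
        return None
    ops = parse_cigar(rec.cigartuples or [])
    if not ops:
        return None
    read_length = read_length_from_cigar(ops)
    span = read_span_from_cigar(ops, rec.is_reverse, read_length)
    blocks = ref_blocks_from_cigar(ops, rec.reference_start)
    if not blocks:
        return None
    return AlignmentSegment(
        read_name=rec.query_name,
        record_class=record_class,
        chrom=rec.reference_name,
        ref_start=blocks[0][0],
        ref_end=blocks[-1][1],
        seg_strand="-" if rec.is_reverse else "+",
        read_span=span,
        ref_blocks=blocks,
        aligned_read_len=aligned_query_length(ops),
        read_length=read_length,
        mapq=rec.mapping_quality,
    )


def build_group(
    read_name: str,
    segments: Iterable[AlignmentSegment | None],
    min_mapq: int = 0,
) -> ReadAlignmentGroup | None:
    """Assemble a read group; returns None for reads with fewer than two
    usable segments or with internally inconsistent CIGARs."""
    segs = [
        s
        for s in segments
        if s is not None
        and s.record_class in (PRIMARY, SUPPLEMENTARY)
        and s.mapq >= min_mapq
    ]
    if len(segs) < 2:
        return None
    lengths = {s.read_length for s in segs}
    if len(lengths) != 1:
        log.warning(
            "read %s: CIGAR-implied read lengths disagree (%s); group dropped",
            read_name,
            sorted(lengths),
        )
        return None
    if sum(1 for s in segs if s.record_class == PRIMARY) > 1:
        log.warning("read %s: multiple primary records; group dropped", read_name)
        return None
    segs.sort(key=lambda s: s.read_span)
    return ReadAlignmentGroup(read_name, segs, lengths.pop())


def group_by_read(
    path,
    two_pass: bool = False,
    min_mapq: int = 0,
    stats: dict | None = None,
) -> Iterator[ReadAlignmentGroup]:
    """Stream SAM/BAM records grouped by read name.

    Only groups with >= 2 non-secondary mapped segments are emitted.  The
    default streaming mode requires all records of a read to be adjacent
    (name-grouped input) and raises ``ValueError`` when a read name
    reappears after a gap; ``two_pass=True`` buffers the whole file and
    handles coordinate-sorted input at the cost of memory.
    """
    if isinstance(path, (str, Path)):
        af = pysam.AlignmentFile(str(path), check_sq=False)
    else:
        af = path

    def _count(rec):
        if stats is not None:
            stats["records"] = stats.get("records", 0) + 1
            cls = classify_record(rec.flag)
            stats[cls] = stats.get(cls, 0) + 1

    if two_pass:
        by_name: dict[str, list] = {}
        for rec in af:
            _count(rec)
            by_name.setdefault(rec.query_name, []).append(
                segment_from_record(rec)
            )
        for name, segs in by_name.items():
            group = build_group(name, segs, min_mapq)
            if group is not None:
                yield group
        return

    current: str | None = None
    buf: list = []
    finished: set[str] = set()
    for rec in af:
        _count(rec)
        name = rec.query_name
        if name != current:
            if current is not None:
                group = build_group(current, buf, min_mapq)
                if group is not None:
                    yield group
                finished.add(current)
            if name in finished:
                raise ValueError(
                    f"input is not grouped by read name (read {name!r} "
                    "reappeared after a gap); rerun with two_pass=True "
                    "(--two-pass on the command line)"
                )
            current, buf = name, []
        buf.append(segment_from_record(rec))
    if current is not None:
        group = build_group(current, buf, min_mapq)
        if group is not None:
            yield group
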