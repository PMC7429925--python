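"""Distributed SAM coordinate sorting with a two-phase Bruck shuffle.

The pipeline mirrors a message-passing external sorter.  The SAM body is
split into p contiguous, line-aligned byte blocks, one per worker.  Each
worker parses its block into routing records — the five-value vector
(c, r_i, o_i, r_d, o_d) plus the line's byte length, where

* ``c``   — genomic coordinate: (@SQ header order index, 1-based POS),
* ``r_i`` — rank that parsed the line, ``o_i`` its byte offset in that
  worker's buffer,
* ``r_d`` — rank that will write the line, ``o_d`` its byte offset in the
  sorted destination file (both known only once the sort completes).

Chromosomes are sorted successively in header order.  For each chromosome
the routing records run through the block-level bitonic sort, destination
offsets are assigned by an exclusive prefix sum over the global sorted
order (so every writer owns one contiguous byte range), and two Bruck
all-to-all phases move first the (r_d, o_d) assignments back to the origin
ranks and then the actual line bytes to the writer ranks.  Unmapped lines
(RNAME "*" or a reference absent from the header) bypass the sort and are
appended after all chromosomes in original order.

Ties on identical coordinates resolve by (origin rank, origin offset),
i.e. input file order — so for one worker the sort is plainly stable, and
for any worker count the output file is byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Optional, Sequence, Tuple, Union

from . import pengine
from .bruck import bruck_all_to_all
from .pengine import Runtime, WorkerBlock

__all__ = [
    "GenomicCoordinate",
    "SortRecord",
    "BlockRange",
    "SamHeader",
    "MalformedRecordError",
    "IntegrityError",
    "read_sam_bytes",
    "split_sam_into_blocks",
    "parse_block",
    "assign_destinations",
    "shuffle_phase1",
    "shuffle_phase2",
    "write_sorted_sam",
    "sort_sam_file",
    "required_cores",
]


class MalformedRecordError(ValueError):
    """An alignment line violates the minimal SAM contract."""


class IntegrityError(RuntimeError):
    """A shuffle phase lost, duplicated, or mis-ranged a record."""


@dataclass(frozen=True, order=True)
class GenomicCoordinate:
    """Sort key: chromosome index in @SQ header order, then 1-based POS."""

    chrom_index: int
    pos: int


@dataclass
class SortRecord:
    """Five-value routing vector plus the line's byte length.

    ``r_d``/``o_d`` stay ``None`` until the bitonic sort has completed and
    destinations are assigned.
    """

    c: GenomicCoordinate
    r_i: int
    o_i: int
    line_len: int
    r_d: Optional[int] = None
    o_d: Optional[int] = None

    def sort_key(self) -> Tuple[int, int, int, int]:
        return (self.c.chrom_index, self.c.pos, self.r_i, self.o_i)


def record_sort_key(rec: SortRecord) -> Tuple[int, int, int, int]:
    """Module-wide total order: coordinate, then origin rank, then origin offset."""
    return rec.sort_key()


@dataclass(frozen=True)
class BlockRange:
    """Half-open, line-aligned byte range [start, end) into the SAM file."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid byte range [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SamHeader:
    """Parsed @-prefixed header: raw bytes plus the @SQ reference order."""

    data: bytes
    sq_names: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.index: Dict[str, int] = {name: i for i, name in enumerate(self.sq_names)}

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def parse(cls, data: bytes) -> "SamHeader":
        names: List[str] = []
        for line in data.split(b"\n"):
            if line.startswith(b"@SQ"):
                for field_ in line.split(b"\t")[1:]:
                    if field_.startswith(b"SN:"):
                        names.append(field_[3:].decode("ascii"))
        return cls(data=data, sq_names=names)


def read_sam_bytes(data: bytes) -> Tuple[SamHeader, bytes]:
    """Split raw SAM bytes into the parsed header and the alignment body."""
    pos = 0
    while pos < len(data) and data[pos : pos + 1] == b"@":
        nl = data.find(b"\n", pos)
        pos = len(data) if nl < 0 else nl + 1
    return SamHeader.parse(data[:pos]), data[pos:]


def split_sam_into_blocks(data: Union[bytes, str], p: int) -> List[BlockRange]:
    """Partition the SAM body into p near-equal, line-aligned byte ranges.

    ``data`` is a path or the raw file bytes.  The header is excluded; the
    returned absolute ranges are non-overlapping and cover every alignment
    line exactly once.  An empty body yields p empty ranges.
    """
    if isinstance(data, str):
        with open(data, "rb") as fh:
            data = fh.read()
    if p < 1:
        raise ValueError(f"worker count must be >= 1, got {p}")
    header, body = read_sam_bytes(data)
    base = len(header)
    total = len(body)

    def snap(offset: int) -> int:
        """Advance a body offset to the next line start."""
        if offset <= 0 or offset >= total:
            return max(0, min(offset, total))
        if body[offset - 1 : offset] == b"\n":
            return offset
        nl = body.find(b"\n", offset)
        return total if nl < 0 else nl + 1

    bounds = [0]
    for i in range(1, p):
        bounds.append(max(bounds[-1], snap(i * total // p)))
    bounds.append(total)
    return [BlockRange(base + bounds[i], base + bounds[i + 1]) for i in range(p)]


def parse_block(
    block: BlockRange, buffer: bytes, header: SamHeader, rank: int = 0
) -> Tuple[List[SortRecord], List[SortRecord]]:
    """Parse one worker's buffer into routing records.

    ``buffer`` holds the block's complete lines; offsets ``o_i`` are
    relative to this buffer.  Returns ``(mapped, unmapped)`` where unmapped
    collects lines with RNAME "*" or a reference missing from the header
    (their ``c`` is a placeholder past the last chromosome).  Lines with
    fewer than 11 tab-separated fields, a non-integer POS, or carriage
    returns raise :class:`MalformedRecordError` naming the offset.
    """
    if len(buffer) != len(block):
        raise ValueError(f"buffer length {len(buffer)} does not match range length {len(block)}")
    mapped: List[SortRecord] = []
    unmapped: List[SortRecord] = []
    offset = 0
    n_chroms = len(header.sq_names)
    while offset < len(buffer):
        nl = buffer.find(b"\n", offset)
        end = len(buffer) if nl < 0 else nl + 1
        line = buffer[offset:end]
        stripped = line.rstrip(b"\n")
        if b"\r" in stripped:
            raise MalformedRecordError(f"carriage return in record at offset {offset}; LF-only SAM required")
        fields = stripped.split(b"\t")
        if len(fields) < 11:
            raise MalformedRecordError(
                f"record at offset {offset} has {len(fields)} fields, at least 11 required"
            )
        rname = fields[2].decode("ascii")
        try:
            pos = int(fields[3])
        except ValueError:
            raise MalformedRecordError(
                f"record at offset {offset} has non-integer POS {fields[3]!r}"
            ) from None
        if rname == "*" or rname not in header.index:
            rec = SortRecord(
                c=GenomicCoordinate(n_chroms, 0), r_i=rank, o_i=offset, line_len=len(line)
            )
            unmapped.append(rec)
        else:
            rec = SortRecord(
                c=GenomicCoordinate(header.index[rname], pos),
                r_i=rank,
                o_i=offset,
                line_len=len(line),
            )
            mapped.append(rec)
        offset = end
    return mapped, unmapped


def assign_destinations(sorted_blocks: List[WorkerBlock], base_offset: int) -> List[WorkerBlock]:
    """Fill ``r_d``/``o_d`` on globally sorted blocks.

    ``r_d`` is the rank holding the record after the sort; ``o_d`` is
    ``base_offset`` plus the exclusive prefix sum of line lengths over the
    global sorted order.  ``base_offset`` is the header length for a
    single-pass sort, or the running file offset when chromosomes are
    written successively.  Each rank's destinations form one contiguous
    byte range, adjacent in rank order.
    """
    offset = base_offset
    for blk in sorted_blocks:
        for rec in blk.items:
            rec.r_d = blk.rank
            rec.o_d = offset
            offset += rec.line_len
    return sorted_blocks


RoutingEntry = Tuple[int, int, int]  # (r_d, o_d, line_len) keyed by o_i


def shuffle_phase1(
    sorted_blocks: List[WorkerBlock], p: int, runtime: Optional[Runtime] = None
) -> List[Dict[int, RoutingEntry]]:
    """First Bruck phase: send each record's (r_d, o_d) back to its origin.

    Returns one routing table per rank, keyed by origin offset ``o_i``.
    Raises :class:`IntegrityError` on duplicate keys after the exchange.
    """
    outboxes = [[[] for _ in range(p)] for _ in range(p)]
    for blk in sorted_blocks:
        for rec in blk.items:
            if rec.r_d is None or rec.o_d is None:
                raise IntegrityError("destinations must be assigned before the first shuffle phase")
            outboxes[blk.rank][rec.r_i].append((rec.o_i, rec.r_d, rec.o_d, rec.line_len))
    inboxes = bruck_all_to_all(outboxes, p, runtime)
    tables: List[Dict[int, RoutingEntry]] = []
    for rank in range(p):
        table: Dict[int, RoutingEntry] = {}
        for slot in inboxes[rank]:
            for o_i, r_d, o_d, line_len in slot:
                if o_i in table:
                    raise IntegrityError(f"rank {rank}: duplicate routing entry for origin offset {o_i}")
                table[o_i] = (r_d, o_d, line_len)
        tables.append(table)
    return tables


def shuffle_phase2(
    routing_tables: Sequence[Dict[int, RoutingEntry]],
    buffers: Sequence[bytes],
    p: int,
    runtime: Optional[Runtime] = None,
) -> List[List[Tuple[int, bytes]]]:
    """Second Bruck phase: ship line bytes to their writer ranks.

    Each origin rank slices its own buffer at the routed offsets and sends
    (o_d, line bytes) to the destination rank.  Each writer's received
    pairs must tile one gap-free byte interval; a gap or overlap raises
    :class:`IntegrityError`.
    """
    outboxes = [[[] for _ in range(p)] for _ in range(p)]
    for rank in range(p):
        buf = buffers[rank]
        for o_i, (r_d, o_d, line_len) in routing_tables[rank].items():
            line = buf[o_i : o_i + line_len]
            if len(line) != line_len:
                raise IntegrityError(f"rank {rank}: origin offset {o_i} exceeds its buffer")
            outboxes[rank][r_d].append((o_d, line))
    inboxes = bruck_all_to_all(outboxes, p, runtime)
    payloads: List[List[Tuple[int, bytes]]] = []
    for rank in range(p):
        pairs = sorted(
            (pair for slot in inboxes[rank] for pair in slot), key=lambda t: t[0]
        )
        for (a, line_a), (b, _) in zip(pairs, pairs[1:]):
            if a + len(line_a) != b:
                raise IntegrityError(
                    f"writer rank {rank}: destination range has a gap or overlap at offset {b}"
                )
        payloads.append(pairs)
    return payloads


def write_sorted_sam(
    header: SamHeader, writer_payloads: Sequence[Sequence[Tuple[int, bytes]]], out_path: str
) -> str:
    """Assemble the destination file: header then every writer's block.

    The union of payload ranges must tile [header length, file size)
    exactly; any gap or overlap raises :class:`IntegrityError` before a
    single byte is written.
    """
    pairs = sorted((pair for payload in writer_payloads for pair in payload), key=lambda t: t[0])
    offset = len(header)
    for o_d, line in pairs:
        if o_d != offset:
            raise IntegrityError(
                f"destination coverage violation: expected offset {offset}, got {o_d}"
            )
        offset += len(line)
    with open(out_path, "wb") as fh:
        fh.write(header.data)
        for _, line in pairs:
            fh.write(line)
    return out_path


def sort_sam_file(
    path: str,
    p: int,
    out_path: str,
    unmapped: str = "keep-tail",
    runtime: Optional[Runtime] = None,
) -> Runtime:
    """Coordinate-sort a SAM file with p simulated workers.

    Chromosomes are processed successively in @SQ order, each through the
    full split → parse → bitonic sort → destination assignment → two Bruck
    phases → write chain.  ``unmapped`` is ``"keep-tail"`` (append after
    all chromosomes, in input order) or ``"drop"``.  Returns the runtime
    with its instrumentation counters.
    """
    if p < 1 or p & (p - 1):
        raise ValueError(f"worker count must be a power of two, got {p}")
    if unmapped not in ("keep-tail", "drop"):
        raise ValueError(f"unmapped policy must be 'keep-tail' or 'drop', got {unmapped!r}")
    if runtime is None:
        runtime = Runtime(p)

    with open(path, "rb") as fh:
        data = fh.read()
    header, _body = read_sam_bytes(data)
    ranges = split_sam_into_blocks(data, p)
    buffers = [data[r.start : r.end] for r in ranges]

    parsed: List[List[SortRecord]] = []
    unmapped_side: List[List[SortRecord]] = []
    for rank in range(p):
        mapped, unmapped_recs = parse_block(ranges[rank], buffers[rank], header, rank)
        parsed.append(mapped)
        unmapped_side.append(unmapped_recs)

    all_payloads: List[List[Tuple[int, bytes]]] = [[] for _ in range(p)]
    base = len(header)
    for chrom_index in range(len(header.sq_names)):
        blocks = [
            WorkerBlock(rank=rank, _items=[r for r in parsed[rank] if r.c.chrom_index == chrom_index])
            for rank in range(p)
        ]
        n_records = sum(blk.m for blk in blocks)
        if n_records == 0:
            continue
        pengine.pad_to_uniform(blocks)
        pengine.parallel_bitonic_sort(blocks, runtime, key=record_sort_key)
        pengine.strip_sentinels(blocks)
        assign_destinations(blocks, base)
        tables = shuffle_phase1(blocks, p, runtime)
        for rank in range(p):
            expected = sum(1 for r in parsed[rank] if r.c.chrom_index == chrom_index)
            if len(tables[rank]) != expected:
                raise IntegrityError(
                    f"rank {rank}: routing table holds {len(tables[rank])} entries, parsed {expected}"
                )
        chrom_payloads = shuffle_phase2(tables, buffers, p, runtime)
        for rank in range(p):
            all_payloads[rank].extend(chrom_payloads[rank])
        base += sum(rec.line_len for blk in blocks for rec in blk.items)

    if unmapped == "keep-tail":
        # Origin order: ranks ascend with the file split, offsets within.
        for rank in range(p):
            for rec in sorted(unmapped_side[rank], key=lambda r: r.o_i):
                rec.r_d, rec.o_d = rank, base
                base += rec.line_len
                line = buffers[rank][rec.o_i : rec.o_i + rec.line_len]
                all_payloads[rank].append((rec.o_d, line))

    write_sorted_sam(header, all_payloads, out_path)
    return runtime


def required_cores(
    sam_size_gb: float, mem_per_core_gb: float, multiplier: float = 2.5
) -> int:
    """Smallest power-of-two core count whose memory covers the sort.

    The sort holds the whole SAM in memory with working structures on top:
    total memory is about ``multiplier`` times the file size — around 2.5x
    for a single-chromosome file, around 1.5x for a whole-genome file —
    and the bitonic network needs a power-of-two core count, so the ceiling
    of ``multiplier * sam_size_gb / mem_per_core_gb`` is rounded up to the
    next power of two.
    """
    for name, value in (
        ("sam_size_gb", sam_size_gb),
        ("mem_per_core_gb", mem_per_core_gb),
        ("multiplier", multiplier),
    ):
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value}")
    # Exact decimal arithmetic so e.g. 2.5 * 110 / 4.5 cannot round past an
    # integer boundary through binary floating point.
    need = Fraction(str(multiplier)) * Fraction(str(sam_size_gb)) / Fraction(str(mem_per_core_gb))
    cores = max(1, math.ceil(need))
    return 1 << (cores - 1).bit_length()
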