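"""Offset-based FASTQ chunking and deterministic parallel SAM emission.

The alignment wrapper never copies reads around: a chunk is just a pair of
byte offsets (start, end) into the original FASTQ file — record-aligned,
non-overlapping and covering — so the chunk table is tiny no matter the
input size.  Chunks pack consecutive records greedily until the next record
(or read pair) would push the chunk past a nucleotide budget; equal
nucleotide content per chunk is what makes the chunked run reproduce a
serial aligner's behaviour, since the underlying aligner processes one
such batch at a time.  In paired mode both files advance in lock-step so
mates always share a chunk.

Each chunk is aligned independently through a pluggable aligner callable
(the real short-read aligner's seam; a deterministic mock is provided) and
the per-chunk outputs are concatenated in chunk order regardless of worker
count or completion order — the deterministic stand-in for a shared file
pointer on a parallel filesystem.  A by-chromosome variant splits the
single SAM into one file per reference plus an unmapped file.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

__all__ = [
    "ChunkSpec",
    "FastqRead",
    "ReferenceHandle",
    "MockAligner",
    "FastqFormatError",
    "PairingError",
    "AlignerError",
    "UnknownReferenceError",
    "scan_fastq",
    "compute_chunks",
    "read_chunk",
    "align_chunks",
    "split_sam_by_chromosome",
]

DEFAULT_NT_BUDGET = 10_000_000


class FastqFormatError(ValueError):
    """A FASTQ record violates the 4-line contract."""


class PairingError(ValueError):
    """Paired FASTQ files disagree on record count."""


class AlignerError(RuntimeError):
    """The aligner callable failed on a chunk."""


class UnknownReferenceError(ValueError):
    """A SAM line names a reference absent from the header."""


@dataclass(frozen=True)
class ChunkSpec:
    """Record-aligned, half-open byte range into FASTQ file 1 (and file 2
    in paired mode), with its record and nucleotide tallies."""

    start: int
    end: int
    read_count: int
    nucleotide_count: int
    start2: Optional[int] = None
    end2: Optional[int] = None

    @property
    def paired(self) -> bool:
        return self.start2 is not None


@dataclass(frozen=True)
class FastqRead:
    name: str
    sequence: str
    quality: str


@dataclass(frozen=True)
class ReferenceHandle:
    """Opaque shared reference: built once, read-only for every worker.

    Models the reference image living in shared memory on each node; only
    the chromosome table is materialised here.
    """

    name: str
    chromosomes: Tuple[Tuple[str, int], ...]

    def sam_header(self) -> str:
        lines = ["@HD\tVN:1.6\tSO:unsorted"]
        for chrom, length in self.chromosomes:
            lines.append(f"@SQ\tSN:{chrom}\tLN:{length}")
        return "\n".join(lines) + "\n"


AlignerContract = Callable[[Sequence[FastqRead], ReferenceHandle], List[str]]


def _read_bytes(source: Union[str, bytes]) -> bytes:
    if isinstance(source, bytes):
        return source
    with open(source, "rb") as fh:
        return fh.read()


def scan_fastq(data: bytes) -> List[Tuple[int, int, int]]:
    """Index a FASTQ byte buffer into (start, end, sequence length) per record.

    Validates the 4-line structure: '@' name line, '+' separator, quality
    of the same length as the sequence.  A truncated or malformed record
    raises :class:`FastqFormatError` naming the record index.
    """
    records: List[Tuple[int, int, int]] = []
    offset = 0
    index = 0
    n = len(data)
    while offset < n:
        start = offset
        lines: List[bytes] = []
        for _ in range(4):
            if offset >= n:
                raise FastqFormatError(f"record {index} is truncated")
            nl = data.find(b"\n", offset)
            end = n if nl < 0 else nl + 1
            lines.append(data[offset:end].rstrip(b"\n"))
            offset = end
        if not lines[0].startswith(b"@"):
            raise FastqFormatError(f"record {index} does not start with '@'")
        if not lines[2].startswith(b"+"):
            raise FastqFormatError(f"record {index} separator line does not start with '+'")
        if len(lines[3]) != len(lines[1]):
            raise FastqFormatError(
                f"record {index} quality length {len(lines[3])} != sequence length {len(lines[1])}"
            )
        records.append((start, offset, len(lines[1])))
        index += 1
    return records


def compute_chunks(
    fastq1: Union[str, bytes],
    fastq2: Optional[Union[str, bytes]] = None,
    nt_budget: int = DEFAULT_NT_BUDGET,
) -> List[ChunkSpec]:
    """Pack consecutive FASTQ records into chunks of ~equal nucleotide content.

    Greedy: a chunk always holds at least one record (pair) and grows while
    the next record (pair) still fits inside ``nt_budget``, so every chunk
    except possibly the last overshoots the budget by less than one record.
    In paired mode nucleotides are counted over both mates and the two
    files advance in lock-step.  Chunk byte ranges tile each input file
    exactly.
    """
    if nt_budget < 1:
        raise ValueError(f"nucleotide budget must be >= 1, got {nt_budget}")
    index1 = scan_fastq(_read_bytes(fastq1))
    index2 = scan_fastq(_read_bytes(fastq2)) if fastq2 is not None else None
    if index2 is not None and len(index2) != len(index1):
        raise PairingError(
            f"paired files hold {len(index1)} and {len(index2)} records; counts must match"
        )

    chunks: List[ChunkSpec] = []
    i = 0
    n = len(index1)
    while i < n:
        start1 = index1[i][0]
        start2 = index2[i][0] if index2 is not None else None
        count = 0
        nt = 0
        while i < n:
            record_nt = index1[i][2] + (index2[i][2] if index2 is not None else 0)
            if count and nt + record_nt > nt_budget:
                break
            nt += record_nt
            count += 1
            i += 1
        end1 = index1[i - 1][1]
        end2 = index2[i - 1][1] if index2 is not None else None
        chunks.append(
            ChunkSpec(
                start=start1,
                end=end1,
                read_count=count,
                nucleotide_count=nt,
                start2=start2,
                end2=end2,
            )
        )
    return chunks


def _parse_records(data: bytes) -> List[FastqRead]:
    reads = []
    for start, end, _ in scan_fastq(data):
        lines = data[start:end].split(b"\n")
        reads.append(
            FastqRead(
                name=lines[0][1:].decode("ascii").split()[0] if len(lines[0]) > 1 else "",
                sequence=lines[1].decode("ascii"),
                quality=lines[3].decode("ascii"),
            )
        )
    return reads


def read_chunk(
    chunk: ChunkSpec, data1: bytes, data2: Optional[bytes] = None
) -> List[FastqRead]:
    """Materialise a chunk's reads; paired mates are interleaved 1,2,1,2..."""
    reads1 = _parse_records(data1[chunk.start : chunk.end])
    if chunk.paired:
        if data2 is None:
            raise PairingError("paired chunk requires the second FASTQ buffer")
        reads2 = _parse_records(data2[chunk.start2 : chunk.end2])
        if len(reads2) != len(reads1):
            raise PairingError(
                f"chunk holds {len(reads1)} and {len(reads2)} mates; counts must match"
            )
        out: List[FastqRead] = []
        for r1, r2 in zip(reads1, reads2):
            out.extend((r1, r2))
        return out
    return reads1


class MockAligner:
    """Deterministic stand-in aligner: one minimal SAM line per read.

    Fields are pure functions of the read name and sequence, so the same
    chunk always yields the same lines — sufficient to exercise the
    single-file emission contract and to feed the sorter end to end.  A
    configurable fraction of name-space maps to unmapped lines.
    """

    def __init__(self, unmapped_every: int = 0) -> None:
        # unmapped_every = k > 0 marks every read whose name checksum is
        # divisible by k as unmapped; 0 disables.
        self.unmapped_every = unmapped_every

    def __call__(self, reads: Sequence[FastqRead], reference: ReferenceHandle) -> List[str]:
        lines = []
        chroms = reference.chromosomes
        for read in reads:
            checksum = sum(read.name.encode("ascii")) + len(read.sequence)
            if self.unmapped_every and checksum % self.unmapped_every == 0:
                lines.append(
                    f"{read.name}\t4\t*\t0\t0\t*\t*\t0\t0\t{read.sequence}\t{read.quality}"
                )
                continue
            chrom, length = chroms[checksum % len(chroms)]
            span = max(1, length - len(read.sequence) + 1)
            pos = 1 + (sum(read.sequence.encode("ascii")) * 31 + checksum) % span
            cigar = f"{len(read.sequence)}M"
            lines.append(
                f"{read.name}\t0\t{chrom}\t{pos}\t60\t{cigar}\t*\t0\t0\t{read.sequence}\t{read.quality}"
            )
        return lines


def align_chunks(
    fastq1: Union[str, bytes],
    chunks: Sequence[ChunkSpec],
    aligner: AlignerContract,
    reference: ReferenceHandle,
    workers: int = 1,
    fastq2: Optional[Union[str, bytes]] = None,
) -> str:
    """Align every chunk and emit one SAM: header once, then chunk outputs
    concatenated in chunk order.

    ``workers`` sizes the thread pool; it affects scheduling only — output
    bytes are identical for any worker count because emission order is the
    chunk order, not completion order.  An aligner exception is re-raised
    as :class:`AlignerError` naming the chunk.
    """
    if workers < 1:
        raise ValueError(f"worker count must be >= 1, got {workers}")
    data1 = _read_bytes(fastq1)
    data2 = _read_bytes(fastq2) if fastq2 is not None else None

    def run(indexed: Tuple[int, ChunkSpec]) -> List[str]:
        i, chunk = indexed
        try:
            reads = read_chunk(chunk, data1, data2)
            return aligner(reads, reference)
        except Exception as exc:  # noqa: BLE001 - reframed with chunk identity
            raise AlignerError(f"aligner failed on chunk {i}: {exc}") from exc

    if workers == 1 or len(chunks) <= 1:
        results = [run(item) for item in enumerate(chunks)]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(run, enumerate(chunks)))

    body = "".join(line + "\n" for lines in results for line in lines)
    return reference.sam_header() + body


def split_sam_by_chromosome(sam: Union[str, bytes]) -> Dict[str, str]:
    """Split one SAM into per-chromosome SAMs plus an ``unmapped`` entry.

    Every output keeps the full header; body lines are routed by RNAME
    with relative order preserved.  RNAME "*" goes to ``unmapped``; a
    reference missing from the header raises
    :class:`UnknownReferenceError`.
    """
    text = sam.decode("ascii") if isinstance(sam, bytes) else sam
    header_lines: List[str] = []
    body_lines: List[str] = []
    for line in text.splitlines():
        (header_lines if line.startswith("@") else body_lines).append(line)
    chrom_names = []
    for line in header_lines:
        if line.startswith("@SQ"):
            for f in line.split("\t")[1:]:
                if f.startswith("SN:"):
                    chrom_names.append(f[3:])
    header = "".join(line + "\n" for line in header_lines)
    outputs: Dict[str, List[str]] = {name: [] for name in chrom_names}
    outputs["unmapped"] = []
    for line in body_lines:
        rname = line.split("\t")[2]
        if rname == "*":
            outputs["unmapped"].append(line)
        elif rname in outputs:
            outputs[rname].append(line)
        else:
            raise UnknownReferenceError(f"RNAME {rname!r} is not declared in the header")
    return {name: header + "".join(l + "\n" for l in lines) for name, lines in outputs.items()}
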