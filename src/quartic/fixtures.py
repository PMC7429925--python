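"""Synthetic FASTQ/SAM generation and the single-process sort oracle.

Everything the test-bench needs is generated programmatically from a
seeded spec, so the repository carries no data files and every fixture is
byte-reproducible.  The generators emulate the *structural* properties the
engines care about — header-declared references, shuffled coordinates,
unmapped fractions, duplicate-coordinate pile-ups, paired mates in
lock-step — not sequencing realism: no error model, no quality
distributions, no reference sequence beyond chromosome names and lengths.

``oracle_sort`` is the independent single-process reference the
distributed sorter is checked against: read everything, stable-sort the
body by (chromosome header index, position) with unmapped lines keyed past
the last chromosome, write the header verbatim.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

__all__ = ["FixtureSpec", "generate_fastq", "generate_sam", "oracle_sort"]

_BASES = "ACGT"


@dataclass(frozen=True)
class FixtureSpec:
    """Seeded recipe for one synthetic dataset.

    ``duplicate_coordinate_rate`` is the probability that a mapped record
    reuses an already-emitted coordinate instead of drawing a fresh one —
    at 1.0 every record piles onto the first coordinate, the tie-break
    stress case.
    """

    seed: int = 0
    n_reads: int = 100
    read_length: int = 50
    n_chromosomes: int = 2
    chromosome_lengths: Optional[Tuple[int, ...]] = None
    paired: bool = False
    fraction_unmapped: float = 0.0
    duplicate_coordinate_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_reads < 0 or self.read_length < 0 or self.n_chromosomes < 0:
            raise ValueError("counts must be non-negative")
        for name in ("fraction_unmapped", "duplicate_coordinate_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.chromosome_lengths is not None and len(self.chromosome_lengths) != self.n_chromosomes:
            raise ValueError("chromosome_lengths must list one length per chromosome")

    @property
    def chrom_table(self) -> List[Tuple[str, int]]:
        lengths = self.chromosome_lengths or tuple(
            100_000 * (i + 1) for i in range(self.n_chromosomes)
        )
        return [(f"chr{i + 1}", lengths[i]) for i in range(self.n_chromosomes)]


def _sequence(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def generate_fastq(spec: FixtureSpec) -> Tuple[str, Optional[str]]:
    """Deterministic FASTQ text; paired mode returns matched mate files."""
    rng = random.Random(spec.seed)
    out1: List[str] = []
    out2: List[str] = []
    for i in range(spec.n_reads):
        name = f"read{i:06d}"
        seq = _sequence(rng, spec.read_length)
        qual = "".join(chr(33 + rng.randrange(40)) for _ in range(spec.read_length))
        out1.append(f"@{name}/1\n{seq}\n+\n{qual}\n" if spec.paired else f"@{name}\n{seq}\n+\n{qual}\n")
        if spec.paired:
            seq2 = _sequence(rng, spec.read_length)
            qual2 = "".join(chr(33 + rng.randrange(40)) for _ in range(spec.read_length))
            out2.append(f"@{name}/2\n{seq2}\n+\n{qual2}\n")
    return "".join(out1), ("".join(out2) if spec.paired else None)


def generate_sam(spec: FixtureSpec) -> str:
    """Deterministic SAM text with shuffled coordinates.

    Emits an @SQ line per chromosome, then ``n_reads`` valid 11-field
    alignment lines with the requested unmapped fraction and
    duplicate-coordinate rate.
    """
    rng = random.Random(spec.seed)
    chroms = spec.chrom_table
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, length in chroms:
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")

    seen_coords: List[Tuple[str, int]] = []
    for i in range(spec.n_reads):
        name = f"read{i:06d}"
        seq = _sequence(rng, spec.read_length)
        qual = "I" * spec.read_length
        unmapped = (not chroms) or rng.random() < spec.fraction_unmapped
        if unmapped:
            lines.append(f"{name}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{qual}")
            continue
        if seen_coords and rng.random() < spec.duplicate_coordinate_rate:
            chrom, pos = seen_coords[rng.randrange(len(seen_coords))]
        else:
            chrom, chrom_len = chroms[rng.randrange(len(chroms))]
            pos = rng.randrange(1, max(2, chrom_len - spec.read_length + 1))
            seen_coords.append((chrom, pos))
        lines.append(
            f"{name}\t0\t{chrom}\t{pos}\t60\t{spec.read_length}M\t*\t0\t0\t{seq}\t{qual}"
        )
    return "".join(line + "\n" for line in lines)


def oracle_sort(sam: str) -> str:
    """Single-process reference coordinate sort.

    Stable sort of the body by (chromosome index in @SQ order, POS);
    unmapped lines (RNAME "*" or undeclared) sort after every chromosome,
    keeping their input order.  The header passes through verbatim.
    """
    header_lines: List[str] = []
    body_lines: List[str] = []
    for line in sam.splitlines():
        (header_lines if line.startswith("@") else body_lines).append(line)
    order = {}
    for line in header_lines:
        if line.startswith("@SQ"):
            for f in line.split("\t")[1:]:
                if f.startswith("SN:"):
                    order[f[3:]] = len(order)
    n = len(order)

    def key(line: str) -> Tuple[int, int]:
        fields = line.split("\t")
        if len(fields) < 11:
            raise ValueError(f"alignment line has {len(fields)} fields, at least 11 required")
        rname, pos = fields[2], fields[3]
        if rname == "*" or rname not in order:
            return (n, 0)
        return (order[rname], int(pos))

    body = sorted(body_lines, key=key)
    return "".join(line + "\n" for line in header_lines + body)
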