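# Methods

## Scope and model of computation

The package re-creates two cluster-scale HTS pre-processing engines on a
simulated distributed runtime.  The simulation is the point: the
properties that matter at scale — global sortedness from purely local
operations, byte-identical output for any worker count, contiguous writer
ranges, bounded communication — are stated as invariants of explicit
small-scale machinery and verified by tests, rather than asserted about an
opaque MPI binary.

The runtime models p isolated workers stepped synchronously: a whole
network stage completes before the next begins.  A worker may read and
write only its own block; every cross-worker byte travels through a
mailbox with per-(source, destination) FIFO ordering.  When auditing is on
(the default) a direct read of a foreign block raises immediately.  The
mailbox counts messages and approximate payload bytes (`line_len` for
routing records, raw length for byte strings, `len(str(...))` otherwise);
these counters are informational instrumentation, never timing claims.  A
real message-passing backend could be slotted behind the same mailbox
contract; none is bundled, and none is needed for any correctness claim
the package makes.

## Bitonic machinery

The comparator network is materialised as an explicit staged schedule
(`build_sorting_network`), not executed recursively, so depth and
comparator counts are first-class data: for n = 2^k inputs, k(k+1)/2
parallel steps of n/2 comparators.  The construction follows the classic
iterative form — for widths 2, 4, …, n, comparators pair indices i and
i XOR stride with direction set by bit `width` of i — which reproduces the
alternating ⊕/⊖ merge structure ending in the full-width increasing
merge.  One phrasing found in the literature counts "k − 1 bitonic sorting
stages" for the build phase; with the final full-width merge the total is
k merge phases, and we expose the unambiguous quantities (parallel steps,
comparator count) instead of the phase-count phrasing.

Monotonicity is non-strict throughout.  A compare-exchange swaps only on a
strict order violation, so equal keys are never moved by a comparator —
the right behaviour when duplicate genomic coordinates are common.
`is_bitonic` implements the definition literally (some cyclic shift is
increasing-then-decreasing), at O(n²); it is a predicate for validation
and tests, not a hot path.

`bitonic_merge` instruments its recursion depth, which must equal log₂ n
exactly; `bitonic_split` validates its precondition (even length, bitonic
input) and is checked against the split theorem — both halves bitonic,
max(low) ≤ min(high), multiset conserved — on randomly generated bitonic
sequences (ascending subset + descending complement under a random cyclic
shift, duplicates allowed).

### Compare-split semantics

A compare-split merges the two sorted blocks and bisects the merged list:
the side designated "low" by the comparator direction keeps the lower m
records.  This is the only semantics under which the pair's concatenation
ends sorted; in particular two blocks with equal value content, e.g.
[1,2] and [1,2], become [1,1] and [2,2] — they do not stay unchanged,
because [1,2,1,2] is not sorted.  With the record key described below no
two records ever compare equal, so the bisection point is always
unambiguous in the SAM pipeline.

## The distributed SAM sort

Records are keyed by (chromosome index in @SQ order, POS, origin rank,
origin byte offset).  The first two components are the coordinate; the
last two are the tie-break.  Because blocks are assigned to ranks in file
order, (origin rank, origin offset) is exactly input-file order for every
worker count — so the key is a total order, ties resolve identically for
any p, and the output file is byte-identical across p.  For p = 1 the
tie-break reduces to a stable sort, matching conventional coordinate-sort
behaviour.

Design choices the underlying method leaves open, resolved here:

* **Unequal n/p remainders** are evened out by sentinel padding, not
  truncation: sentinels carry a reserved maximum key, collect at the top
  of the global order, and are stripped before destinations are assigned.
  Only the worker count must be a power of two; the per-worker block size
  m is arbitrary (including zero).
* **Unmapped reads** (RNAME "*" or a reference absent from the header)
  never enter the bitonic sort.  They are appended after all chromosomes
  in input order, or dropped, under a config switch.  Secondary and
  supplementary alignments are sorted like any other line by their own
  coordinates.
* **Successive chromosomes**: each chromosome runs the full
  sort → prefix-sum → two-shuffle chain with a running base offset, so
  destination ranges remain contiguous across the whole file.  A
  chromosome declared in the header with no reads is skipped silently.
* **Offsets** are 0-based byte offsets with half-open ranges; line
  terminator is LF, and CR-LF input is rejected as malformed rather than
  silently normalised.  The header passes through verbatim.
* **Block boundaries** snap forward to the next line start from the
  ideal equal-byte split points, so blocks are line-aligned, contiguous
  and covering; an empty body yields p empty ranges.

Integrity is checked at every hand-off: the phase-1 routing table must
hold exactly one entry per parsed line; each writer's (o_d, bytes) pairs
must tile one gap-free interval; and the final write refuses to emit a
single byte unless the union of payload ranges tiles
[header length, file size) exactly.

`required_cores` evaluates ⌈multiplier × file size / memory per core⌉ in
exact decimal arithmetic (so 2.5 × 110 / 4.5 cannot drift past an integer
boundary in binary floating point) and rounds up to the next power of
two.  The multiplier is a parameter because the constant depends on
workload shape: ~2.5 for a single-chromosome file, ~1.5 whole-genome.

## The Bruck exchange

The all-to-all is the canonical log-round scheme: local index rotation,
ceil(log₂ p) exchange rounds in which round r forwards every slot whose
index has bit r set by 2^r ranks, then inverse rotation by source.
Messages carry (slot index, payload) frames so payloads forwarded through
intermediate ranks stay unambiguous; in-memory framing is structural
rather than length-prefixed bytes, which is equivalent for the contract
being modelled.  The measured round counter is exposed and asserted to be
exactly ceil(log₂ p); a quadratic-log complexity is sometimes quoted for
this exchange in print, and we report the measured round structure rather
than any printed exponent.  Non-power-of-two p is served by the direct
(naive) exchange, which is also the correctness oracle.

## FASTQ chunking and deterministic alignment

Chunks are greedy: a chunk always holds at least one record (pair) and
grows while the next record still fits in the nucleotide budget, so every
chunk except possibly the last is within one record length of the budget,
and no chunk ever splits a read or a pair.  Nucleotides — not bytes — are
the packing unit, because batches of equal nucleotide content are what tie
a chunked run to the serial aligner's per-batch behaviour; the budget
defaults to 10,000,000 nt and is configuration.  In paired mode both
files advance in lock-step and the budget counts both mates.

Worker-count independence of the emitted SAM is achieved by contract, not
scheduling: chunk outputs are concatenated in chunk index order regardless
of completion order (the deterministic stand-in for a shared file
pointer), and the aligner callable is required to be pure.  The bundled
`MockAligner` derives RNAME/POS from checksums of the read name and
sequence — valid minimal SAM, deterministic, sufficient to drive the
sorter end-to-end; it aligns nothing.  The reference is an opaque handle
(chromosome names and lengths) constructed once and shared read-only, the
stand-in for a reference image in node-local shared memory; no on-disk
image format is implemented.

## Synthetic fixtures and oracles

`FixtureSpec` + seed fully determine every generated byte (Python's
seeded Mersenne Twister).  Generated SAM/FASTQ exercise the structural
features the engines care about: header-declared references, shuffled
coordinates, an unmapped fraction, duplicate-coordinate pile-ups
(probability of reusing an already-emitted coordinate; rate 1.0 collapses
all records onto one coordinate — the tie-break stress case), and paired
mates in matched order.  They deliberately do not emulate sequencing
realism — no error model, no quality distributions, no reference
sequence, no mate TLEN geometry — so passing tests demonstrate the
*algorithmic* contracts (sortedness, conservation, reproducibility,
coverage) on real SAM/FASTQ syntax, not robustness to the full variety of
aligner output in the wild.

Two independent oracles check the sorter: `oracle_sort`, a single-process
stable sort by (chromosome index, POS) with unmapped lines keyed past the
last chromosome, compared byte-for-byte; and samtools' coordinate sort
(via pysam) compared on the mapped coordinate sequence only, since
samtools does not promise our tie order for duplicate coordinates —
byte-level equivalence with external tools is accordingly not claimed for
tied records.

## Problem sizes

The test and acceptance workloads are sized for a laptop-class run:
exhaustive 0–1-principle sweeps up to n = 16 (65,536 binary inputs),
1,000 random bitonic splits, 200 randomized Bruck exchanges across
p ∈ {2,4,8,16}, and 50 seeded SAM fixtures of up to 512 reads and 4
chromosomes, each sorted at p ∈ {1,2,4,8}.  The whole suite completes in
seconds; the quantities it verifies (step counts, round counts, sorting
correctness, reproducibility) are size-independent claims of the
algorithms, not performance benchmarks, and no walltime or speed-up
figures are reproduced here.

## Known limitations

* No real multi-node execution, asynchronous communication, fault
  tolerance, or parallel-filesystem I/O; the mailbox runtime is a
  correctness model.
* SAM text only — no BAM/CRAM, duplicate marking, or index generation;
  FASTQ must be plain text (no gzip).
* The per-chromosome pass structure holds each chromosome's routing
  records in memory at once, mirroring the memory-bound design it models;
  it is not an external-memory sorter.
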