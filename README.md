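# quartic

Desk-scale, fully testable re-implementation of the message-passing engines
used to pre-process high-throughput sequencing data on HPC clusters:

* **a distributed SAM coordinate sorter** — block-local merge sort, a
  bitonic compare-split network over the workers, destination assignment by
  prefix sum, and a two-phase Bruck all-to-all shuffle feeding
  contiguous-block writes;
* **an alignment wrapper** — equal-nucleotide FASTQ chunking expressed as
  byte-offset pairs, pluggable per-chunk alignment (a deterministic mock is
  provided; a real aligner drops into the same seam), single-SAM emission
  that is byte-identical for any worker count, and per-chromosome output
  splitting.

The production counterparts of these engines run over MPI on hundreds of
cores, where correctness claims (sortedness, reproducibility, contiguous
writes) are painful to verify.  Here every processor is an explicit
simulated worker: workers own isolated blocks, all cross-worker traffic
goes through an audited mailbox, and instrumentation exposes the exact
step, round, message and byte counts the algorithms predict — so the whole
pipeline is testable on one machine with synthetic fixtures.  Intended
users are developers of parallel genomics tooling and anyone who wants the
algorithms behind cluster-scale SAM sorting in an inspectable form.

## The algorithms

**Bitonic sort.** A sequence ⟨a₀, …, a_{n−1}⟩ is *bitonic* if it increases
then decreases (non-strictly), or is a cyclic shift of such a sequence.
The *bitonic split* of a bitonic sequence of even length n,

    s₁ = ⟨min(a₀, a_{n/2}), …, min(a_{n/2−1}, a_{n−1})⟩
    s₂ = ⟨max(a₀, a_{n/2}), …, max(a_{n/2−1}, a_{n−1})⟩,

yields two bitonic halves with max(s₁) ≤ min(s₂), so log₂ n recursive
splits sort a bitonic input (the *bitonic merge*, BM_n⊕ increasing / BM_n⊖
decreasing).  For arbitrary input of length n = 2^k, alternating ⊕/⊖
merges of widths 2, 4, …, n/2 build a bitonic sequence and a final BM_n⊕
sorts it: a fixed comparator network with k(k+1)/2 parallel steps of n/2
comparators each (80 comparators for n = 16).

**Parallel block sort.** With p = 2^q workers holding m = n/p records
each, every comparator of the p-input network becomes a *compare-split*:
the two workers exchange blocks, merge 2m records, and keep the lower/upper
m.  After q(q+1)/2 such steps (3 steps for p = 4) the rank-order
concatenation of blocks is globally sorted.

**SAM sorting.** The SAM body is split into p line-aligned byte blocks.
Each line becomes the routing vector (c, r_i, o_i, r_d, o_d): coordinate
c = (@SQ header index, POS), origin rank/offset, and — once the bitonic
sort finishes and an exclusive prefix sum over line lengths assigns each
writer one contiguous byte range — destination rank/offset.  A first Bruck
all-to-all returns (r_d, o_d) to the origin ranks; a second ships the line
bytes to the writers.  Chromosomes are sorted successively in header
order; unmapped reads are appended afterwards in input order.  Ties on
equal coordinates resolve by (origin rank, origin offset), i.e. input file
order, which makes the output byte-identical for every worker count.

**Bruck exchange.** The all-to-all itself runs in ceil(log₂ p) rounds via
index rotation and bitwise destination grouping, instead of p−1 pairwise
rounds.

**Core sizing.** The sorter keeps the SAM in memory (~2.5× the file size
for a single-chromosome file, ~1.5× whole-genome) and needs a power-of-two
worker count, so the rule `required_cores(size, mem_per_core, multiplier)`
returns the smallest power of two ≥ ⌈multiplier · size / mem_per_core⌉ —
e.g. a 209 GB chr1 SAM at 4.5 GB/core needs 128 cores; 110 GB needs 64.

## Worked example

Generate a seeded synthetic dataset, sort it with 4 simulated workers, and
inspect the instrumentation:

```sh
$ quartic fixtures --seed 7 -o data/
$ quartic sort data/alignments.sam -o sorted.sam -p 4 --report report.json
$ cat report.json
{
  "bruck_rounds": 8,
  "bytes": 55661,
  "compare_split_steps": 6,
  "compare_splits": 12,
  "elapsed_seconds": 0.002791,
  "messages": 56,
  "p": 4
}
```

The counters are exactly what the theory predicts for p = 4 workers and a
two-chromosome file: each chromosome takes q(q+1)/2 = 3 compare-split
steps (6 total), each step compare-splits p/2 = 2 worker pairs (12
compare-splits), and each of the four Bruck phases (two per chromosome)
runs ceil(log₂ 4) = 2 rounds (8 total).  `sorted.sam` starts with the
verbatim header followed by chr1 positions in increasing order:

```
@HD     VN:1.6  SO:unsorted
@SQ     SN:chr1 LN:100000
@SQ     SN:chr2 LN:200000
read000051      0       chr1    948     60      50M     ...
read000094      0       chr1    1713    60      50M     ...
```

Chunk a FASTQ into ~500-nucleotide batches (each chunk is just two byte
offsets into the original file — 10 reads × 50 nt here):

```sh
$ quartic chunk data/reads.fastq --nt-budget 500
[
  {
    "start": 0,
    "end": 1160,
    "read_count": 10,
    "nucleotide_count": 500,
    ...
```

`quartic align` runs the chunks through the pluggable aligner into one
SAM, `quartic bychr` splits a SAM per chromosome, and `quartic selftest`
re-checks oracle equivalence and worker-count independence on fresh
fixtures:

```sh
$ quartic selftest --seed 1 --fixtures 3
case 0: oracle+p-independence ok
case 1: oracle+p-independence ok
case 2: oracle+p-independence ok
selftest passed on 3/3 cases
```

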