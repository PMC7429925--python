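"""SAM block partitioning, routing records, the two-phase shuffle, and the
end-to-end distributed coordinate sort."""

from collections import Counter

import pytest

from quartic import pengine
from quartic.fixtures import FixtureSpec, generate_sam, oracle_sort
from quartic.pengine import Runtime, WorkerBlock
from quartic.samsort import (
    GenomicCoordinate,
    IntegrityError,
    MalformedRecordError,
    SamHeader,
    SortRecord,
    assign_destinations,
    parse_block,
    read_sam_bytes,
    record_sort_key,
    required_cores,
    shuffle_phase1,
    shuffle_phase2,
    sort_sam_file,
    split_sam_into_blocks,
    write_sorted_sam,
)

HEADER = b"@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n@SQ\tSN:chr2\tLN:1000\n"


def line(name, chrom, pos, flag=0):
    rname = chrom if chrom else "*"
    mapq = 0 if rname == "*" else 60
    cigar = "*" if rname == "*" else "5M"
    return f"{name}\t{flag}\t{rname}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\tACGTA\tIIIII\n".encode()


def sam_bytes(lines):
    return HEADER + b"".join(lines)


class TestSplitIntoBlocks:
    def test_even_split_of_equal_lines(self):
        lines = [line(f"r{i}", "chr1", 100 + i) for i in range(8)]
        data = sam_bytes(lines)
        ranges = split_sam_into_blocks(data, 2)
        body_len = sum(len(l) for l in lines)
        assert len(ranges) == 2
        assert len(ranges[0]) == len(ranges[1]) == body_len // 2

    def test_boundary_snaps_to_newline(self):
        # 7 equal-length lines over 2 workers: the midpoint falls inside
        # line 4, so the boundary advances and the split is 4 lines / 3 lines.
        lines = [line(f"r{i}", "chr1", 100 + i) for i in range(7)]
        data = sam_bytes(lines)
        ranges = split_sam_into_blocks(data, 2)
        line_len = len(lines[0])
        assert len(ranges[0]) == 4 * line_len
        assert len(ranges[1]) == 3 * line_len

    def test_ranges_tile_the_body(self):
        lines = [line(f"read{i}", "chr1", i + 1) for i in range(11)]
        data = sam_bytes(lines)
        for p in (1, 2, 3, 4, 8):
            ranges = split_sam_into_blocks(data, p)
            assert ranges[0].start == len(HEADER)
            assert ranges[-1].end == len(data)
            for a, b in zip(ranges, ranges[1:]):
                assert a.end == b.start
            assert b"".join(data[r.start : r.end] for r in ranges) == b"".join(lines)

    def test_empty_body_gives_empty_ranges(self):
        ranges = split_sam_into_blocks(HEADER, 4)
        assert len(ranges) == 4
        assert all(len(r) == 0 for r in ranges)


class TestParseBlock:
    def test_coordinate_from_sq_order(self):
        data = sam_bytes([line("r1", "chr2", 100)])
        header, _ = read_sam_bytes(data)
        ranges = split_sam_into_blocks(data, 1)
        mapped, unmapped = parse_block(ranges[0], data[ranges[0].start :], header, rank=0)
        assert len(mapped) == 1 and not unmapped
        assert mapped[0].c == GenomicCoordinate(1, 100)

    def test_star_rname_routed_to_unmapped(self):
        data = sam_bytes([line("r2", None, 0, flag=4)])
        header, _ = read_sam_bytes(data)
        ranges = split_sam_into_blocks(data, 1)
        mapped, unmapped = parse_block(ranges[0], data[ranges[0].start :], header)
        assert not mapped and len(unmapped) == 1

    def test_undeclared_rname_routed_to_unmapped(self):
        data = sam_bytes([line("r3", "chrX", 5)])
        header, _ = read_sam_bytes(data)
        ranges = split_sam_into_blocks(data, 1)
        mapped, unmapped = parse_block(ranges[0], data[ranges[0].start :], header)
        assert not mapped and len(unmapped) == 1

    def test_offsets_equal_cumulative_line_lengths(self):
        lines = [line(f"r{i}", "chr1", 10**i) for i in range(1, 5)]  # varying lengths
        data = sam_bytes(lines)
        header, _ = read_sam_bytes(data)
        ranges = split_sam_into_blocks(data, 1)
        mapped, _ = parse_block(ranges[0], data[ranges[0].start :], header)
        cumulative, expected = 0, []
        for l in lines:
            expected.append(cumulative)
            cumulative += len(l)
        assert [r.o_i for r in mapped] == expected
        assert [r.line_len for r in mapped] == [len(l) for l in lines]

    @pytest.mark.parametrize(
        "bad,message",
        [
            (b"r1\t0\tchr1\t100\t60\t5M\t*\t0\t0\tACGTA\n", "fields"),
            (b"r1\t0\tchr1\tabc\t60\t5M\t*\t0\t0\tACGTA\tIIIII\n", "POS"),
            (b"r1\t0\tchr1\t100\t60\t5M\t*\t0\t0\tACGTA\tIIIII\r\n", "carriage return"),
        ],
    )
    def test_malformed_records_rejected_with_offset(self, bad, message):
        data = HEADER + bad
        header, _ = read_sam_bytes(data)
        ranges = split_sam_into_blocks(data, 1)
        with pytest.raises(MalformedRecordError, match=message):
            parse_block(ranges[0], data[ranges[0].start :], header)


def sorted_blocks_for(lines, p):
    """Parse + sort a tiny fixture through the real pipeline front half."""
    data = sam_bytes(lines)
    header, _ = read_sam_bytes(data)
    ranges = split_sam_into_blocks(data, p)
    buffers = [data[r.start : r.end] for r in ranges]
    blocks = []
    for rank in range(p):
        mapped, _ = parse_block(ranges[rank], buffers[rank], header, rank)
        blocks.append(WorkerBlock(rank, mapped))
    pengine.pad_to_uniform(blocks)
    pengine.parallel_bitonic_sort(blocks, key=record_sort_key)
    pengine.strip_sentinels(blocks)
    return header, buffers, blocks


class TestAssignDestinations:
    def test_hand_prefix_sum(self):
        blocks = [
            WorkerBlock(0, [SortRecord(GenomicCoordinate(0, i), 0, 10 * i, 10) for i in range(2)]),
            WorkerBlock(1, [SortRecord(GenomicCoordinate(0, 2 + i), 1, 10 * i, 10) for i in range(2)]),
        ]
        assign_destinations(blocks, base_offset=50)
        records = [r for blk in blocks for r in blk.items]
        assert [r.o_d for r in records] == [50, 60, 70, 80]
        assert [r.r_d for r in records] == [0, 0, 1, 1]

    def test_single_worker_strictly_increasing_by_line_len(self):
        lines = [line(f"r{i}", "chr1", 100 + i) for i in range(4)]
        _, _, blocks = sorted_blocks_for(lines, 1)
        assign_destinations(blocks, base_offset=len(HEADER))
        offsets = [r.o_d for r in blocks[0].items]
        lens = [r.line_len for r in blocks[0].items]
        assert all(b - a == l for a, b, l in zip(offsets, offsets[1:], lens))

    def test_total_bytes_conserved(self):
        lines = [line(f"r{i}", "chr1", 500 - i) for i in range(6)]
        _, _, blocks = sorted_blocks_for(lines, 2)
        assign_destinations(blocks, base_offset=len(HEADER))
        records = [r for blk in blocks for r in blk.items]
        assert max(r.o_d + r.line_len for r in records) == len(HEADER) + sum(len(l) for l in lines)


class TestShufflePhases:
    def make_fixture(self, p, n=16):
        lines = [line(f"r{i:02d}", "chr1", (7 * i) % 97 + 1) for i in range(n)]
        header, buffers, blocks = sorted_blocks_for(lines, p)
        assign_destinations(blocks, base_offset=len(header))
        return lines, header, buffers, blocks

    def test_phase1_tables_match_parsed_counts(self):
        p = 4
        lines, header, buffers, blocks = self.make_fixture(p)
        tables = shuffle_phase1(blocks, p)
        data = sam_bytes(lines)
        ranges = split_sam_into_blocks(data, p)
        for rank in range(p):
            mapped, _ = parse_block(ranges[rank], buffers[rank], header, rank)
            assert len(tables[rank]) == len(mapped)
            assert set(tables[rank]) == {r.o_i for r in mapped}

    def test_phase1_union_covers_every_record_once(self):
        p = 4
        _, _, _, blocks = self.make_fixture(p)
        tables = shuffle_phase1(blocks, p)
        total = sum(len(t) for t in tables)
        assert total == sum(blk.m for blk in blocks)

    def test_phase1_identity_for_single_worker(self):
        _, header, buffers, blocks = self.make_fixture(1)
        tables = shuffle_phase1(blocks, 1)
        assert len(tables) == 1
        for o_i, (r_d, _o_d, _len) in tables[0].items():
            assert r_d == 0

    def test_phase2_writers_tile_the_sorted_body(self):
        p = 4
        lines, header, buffers, blocks = self.make_fixture(p)
        tables = shuffle_phase1(blocks, p)
        payloads = shuffle_phase2(tables, buffers, p)
        assembled = b"".join(
            line_bytes for payload in payloads for _, line_bytes in sorted(payload)
        )
        expected = oracle_sort(sam_bytes(lines).decode()).encode()
        assert assembled == expected[len(HEADER) :]

    def test_phase2_byte_totals_conserved(self):
        p = 4
        lines, _, buffers, blocks = self.make_fixture(p)
        tables = shuffle_phase1(blocks, p)
        payloads = shuffle_phase2(tables, buffers, p)
        assert sum(len(b) for payload in payloads for _, b in payload) == sum(len(l) for l in lines)

    def test_missing_destination_detected(self):
        blocks = [WorkerBlock(0, [SortRecord(GenomicCoordinate(0, 1), 0, 0, 10)])]
        with pytest.raises(IntegrityError, match="destinations"):
            shuffle_phase1(blocks, 1)


class TestWriteSortedSam:
    def test_equals_single_process_oracle(self, tmp_path):
        p = 4
        lines = [line(f"r{i:02d}", "chr1", (13 * i) % 89 + 1) for i in range(16)]
        header, buffers, blocks = sorted_blocks_for(lines, p)
        assign_destinations(blocks, base_offset=len(header))
        payloads = shuffle_phase2(shuffle_phase1(blocks, p), buffers, p)
        out = tmp_path / "out.sam"
        write_sorted_sam(header, payloads, str(out))
        assert out.read_text() == oracle_sort(sam_bytes(lines).decode())

    def test_coverage_violation_blocks_the_write(self, tmp_path):
        header = SamHeader.parse(HEADER)
        gap = [[(len(HEADER) + 5, b"x" * 10)]]  # first payload not at header end
        out = tmp_path / "bad.sam"
        with pytest.raises(IntegrityError, match="coverage"):
            write_sorted_sam(header, gap, str(out))
        assert not out.exists()


class TestSortSamFile:
    @pytest.mark.parametrize("p", [1, 2, 4])
    def test_multichromosome_fixture_matches_oracle(self, sam_file, tmp_path, p):
        path, text = sam_file(seed=11, n_reads=60, n_chromosomes=3, duplicate_coordinate_rate=0.4)
        out = tmp_path / f"out_p{p}.sam"
        sort_sam_file(path, p, str(out))
        assert out.read_text() == oracle_sort(text)

    def test_outputs_byte_identical_across_worker_counts(self, sam_file, tmp_path):
        path, _ = sam_file(seed=12, n_reads=80, n_chromosomes=4, fraction_unmapped=0.15)
        outputs = []
        for p in (1, 2, 4, 8):
            out = tmp_path / f"p{p}.sam"
            sort_sam_file(path, p, str(out))
            outputs.append(out.read_bytes())
        assert all(o == outputs[0] for o in outputs)

    def test_line_multiset_preserved(self, sam_file, tmp_path):
        path, text = sam_file(seed=13, n_reads=50, n_chromosomes=2, fraction_unmapped=0.2)
        out = tmp_path / "out.sam"
        sort_sam_file(path, 2, str(out))
        in_body = [l for l in text.splitlines() if not l.startswith("@")]
        out_body = [l for l in out.read_text().splitlines() if not l.startswith("@")]
        assert Counter(out_body) == Counter(in_body)

    def test_already_sorted_input_unchanged(self, sam_file, tmp_path):
        path, text = sam_file(seed=14, n_reads=40, n_chromosomes=2)
        sorted_text = oracle_sort(text)
        src = tmp_path / "sorted.sam"
        src.write_text(sorted_text)
        out = tmp_path / "resorted.sam"
        sort_sam_file(str(src), 4, str(out))
        assert out.read_text() == sorted_text

    def test_empty_chromosome_in_header_is_silent(self, tmp_path):
        data = HEADER + line("r1", "chr2", 7)  # chr1 declared but empty
        src = tmp_path / "in.sam"
        src.write_bytes(data)
        out = tmp_path / "out.sam"
        sort_sam_file(str(src), 2, str(out))
        body = [l for l in out.read_text().splitlines() if not l.startswith("@")]
        assert len(body) == 1

    def test_unmapped_kept_in_origin_order_at_tail(self, sam_file, tmp_path):
        path, text = sam_file(seed=15, n_reads=30, n_chromosomes=2, fraction_unmapped=0.4)
        out = tmp_path / "out.sam"
        sort_sam_file(path, 4, str(out))
        in_unmapped = [l for l in text.splitlines() if not l.startswith("@") and l.split("\t")[2] == "*"]
        out_lines = [l for l in out.read_text().splitlines() if not l.startswith("@")]
        assert out_lines[len(out_lines) - len(in_unmapped) :] == in_unmapped

    def test_unmapped_drop_policy(self, sam_file, tmp_path):
        path, text = sam_file(seed=16, n_reads=30, n_chromosomes=1, fraction_unmapped=0.5)
        out = tmp_path / "out.sam"
        sort_sam_file(path, 2, str(out), unmapped="drop")
        body = [l for l in out.read_text().splitlines() if not l.startswith("@")]
        assert all(l.split("\t")[2] != "*" for l in body)

    def test_non_power_of_two_worker_count_rejected(self, sam_file, tmp_path):
        path, _ = sam_file(seed=17, n_reads=8)
        with pytest.raises(ValueError, match="power of two"):
            sort_sam_file(path, 3, str(tmp_path / "out.sam"))

    def test_mapped_coordinate_order_agrees_with_samtools(self, sam_file, tmp_path):
        # Independent cross-check against samtools' coordinate sort.
        pysam = pytest.importorskip("pysam")
        path, _ = sam_file(seed=18, n_reads=64, n_chromosomes=3, duplicate_coordinate_rate=0.3)
        ours = tmp_path / "ours.sam"
        theirs = tmp_path / "theirs.sam"
        sort_sam_file(path, 4, str(ours))
        pysam.sort("-O", "sam", "-o", str(theirs), path)

        def mapped_coords(sam_path):
            return [
                (l.split("\t")[2], int(l.split("\t")[3]))
                for l in open(sam_path).read().splitlines()
                if not l.startswith("@") and l.split("\t")[2] != "*"
            ]

        assert mapped_coords(str(ours)) == mapped_coords(str(theirs))


class TestRequiredCores:
    def test_single_chromosome_worked_examples(self):
        assert required_cores(209, 4.5, 2.5) == 128
        assert required_cores(110, 4.5, 2.5) == 64

    def test_small_file_fits_one_core(self):
        assert required_cores(1, 4.5, 2.5) == 1

    def test_whole_genome_multiplier(self):
        # 1.5 x 100 GB / 4.5 GB per core = 33.3 -> 34 -> next power of two.
        assert required_cores(100, 4.5, 1.5) == 64

    def test_exact_boundary_is_not_overshot(self):
        assert required_cores(64, 1, 1.0) == 64

    @pytest.mark.parametrize("args", [(0, 4.5, 2.5), (100, 0, 2.5), (100, 4.5, -1)])
    def test_non_positive_arguments_rejected(self, args):
        with pytest.raises(ValueError, match="positive"):
            required_cores(*args)
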