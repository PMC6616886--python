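import sys

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcrkit.alignment_coverage import (
    AlignmentBlock,
    filter_by_evalue,
    hcr_alignment,
    parse_alignments,
    run_external_aligner,
    union_length,
    write_coverage_results,
)
from hcrkit.errors import (
    AlignerUnavailableError,
    ConfigurationError,
    FormatError,
    InputError,
)

from .conftest import assembly


def block(ia, ib, evalue=1e-30, contig_a="A_c1", contig_b="B_c1", strand="+"):
    return AlignmentBlock("A", "B", contig_a, contig_b, ia, ib, strand, evalue)


def boolean_union_oracle(intervals, size=10_000):
    """Per-base boolean-array oracle for covered length."""
    mask = np.zeros(size, dtype=bool)
    for start, end in intervals:
        mask[start:end] = True
    return int(mask.sum())


class TestParseTabular:
    def test_coordinate_conversion(self, tmp_path):
        path = tmp_path / "aln.tsv"
        path.write_text(
            "q1\ts1\t99.0\t100\t1\t0\t1\t100\t151\t250\t1e-40\t180\n"
            "q1\ts1\t98.0\t100\t2\t0\t11\t110\t200\t101\t1e-35\t170\n"
        )
        fwd, rev = parse_alignments(path, "tabular", "A", "B")
        assert fwd.interval_a == (0, 100)
        assert fwd.interval_b == (150, 250)
        assert fwd.strand_b == "+"
        assert rev.interval_b == (100, 200)
        assert rev.strand_b == "-"
        assert rev.evalue == 1e-35

    def test_malformed_record_names_line(self, tmp_path):
        path = tmp_path / "aln.tsv"
        path.write_text("q1\ts1\tbad\n")
        with pytest.raises(FormatError, match=":1"):
            parse_alignments(path, "tabular")

    def test_unknown_dialect(self, tmp_path):
        path = tmp_path / "aln.tsv"
        path.write_text("")
        with pytest.raises(ConfigurationError):
            parse_alignments(path, "sam")


class TestParseMaf:
    MAF = (
        "##maf version=1\n"
        "a score=120 E=1e-44\n"
        "s ctgA 10 40 + 1000 " + "A" * 40 + "\n"
        "s ctgB 20 40 - 500 " + "A" * 40 + "\n"
        "\n"
        "a score=80 E=2e-09\n"
        "s ctgA 100 30 + 1000 " + "C" * 30 + "\n"
        "s ctgB 50 30 + 500 " + "C" * 30 + "\n"
    )

    def test_blocks_and_strand_normalization(self, tmp_path):
        path = tmp_path / "aln.maf"
        path.write_text(self.MAF)
        first, second = parse_alignments(path, "maf", "A", "B")
        assert first.interval_a == (10, 50)  # start + length, half-open
        # reverse strand: forward-strand coordinates are srcSize-start-size
        assert first.interval_b == (500 - 20 - 40, 500 - 20)
        assert first.strand_b == "-"
        assert first.evalue == 1e-44
        assert second.interval_b == (50, 80)
        assert second.strand_b == "+"

    def test_block_with_wrong_sequence_count(self, tmp_path):
        path = tmp_path / "aln.maf"
        path.write_text("a score=1 E=1e-20\ns ctgA 0 5 + 100 ACGTA\n")
        with pytest.raises(FormatError, match="1 sequence"):
            parse_alignments(path, "maf")

    def test_missing_evalue_rejected(self, tmp_path):
        path = tmp_path / "aln.maf"
        path.write_text(
            "a score=1\ns ctgA 0 5 + 100 ACGTA\ns ctgB 0 5 + 100 ACGTA\n"
        )
        with pytest.raises(FormatError, match="E-value|E="):
            parse_alignments(path, "maf")


class TestEvalueFilter:
    def test_strictly_below_threshold(self):
        kept = filter_by_evalue(
            [block((0, 10), (0, 10), e) for e in (1e-12, 1e-10, 2e-10, 0.0)]
        )
        assert [b.evalue for b in kept] == [1e-12, 0.0]

    def test_boundary_value_removed(self):
        assert filter_by_evalue([block((0, 10), (0, 10), 1e-10)]) == []

    def test_empty_input(self):
        assert filter_by_evalue([]) == []


class TestUnionLength:
    def test_overlap_counted_once(self):
        assert union_length([(0, 10), (5, 15)]) == 15

    def test_disjoint_sum(self):
        assert union_length([(0, 10), (20, 30)]) == 20

    def test_empty(self):
        assert union_length([]) == 0

    def test_invalid_interval(self):
        with pytest.raises(InputError):
            union_length([(10, 10)])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 9_000), st.integers(1, 1_000)).map(
                lambda t: (t[0], t[0] + t[1])
            ),
            max_size=30,
        )
    )
    def test_matches_boolean_array_oracle(self, intervals):
        assert union_length(intervals) == boolean_union_oracle(intervals)


class TestHcrAlignment:
    def test_worked_example_with_overlap(self):
        genome_a = assembly("A", "A" * 100)
        genome_b = assembly("B", "C" * 100)
        blocks = [
            block((0, 30), (0, 30)),
            block((20, 50), (100, 130)),
        ]
        # B's second interval exceeds its 100 bp contig
        with pytest.raises(InputError):
            hcr_alignment(blocks, genome_a, genome_b)
        genome_b200 = assembly("B", "C" * 200)
        blocks = [
            AlignmentBlock("A", "B", "A_c1", "B_c1", (0, 30), (0, 30), "+", 1e-30),
            AlignmentBlock("A", "B", "A_c1", "B_c1", (20, 50), (100, 130), "+", 1e-30),
        ]
        result = hcr_alignment(blocks, genome_a, genome_b200)
        assert (result.h_a, result.h_b) == (50, 60)
        assert result.hcr == pytest.approx((50 + 60) / (100 + 200))

    def test_self_alignment_full_length_is_one(self):
        genome = assembly("A", "ACGT" * 50)
        full = AlignmentBlock(
            "A", "A", "A_c1", "A_c1", (0, 200), (0, 200), "+", 0.0
        )
        result = hcr_alignment([full], genome, genome)
        assert result.hcr == 1.0

    def test_high_evalue_blocks_do_not_contribute(self):
        genome_a, genome_b = assembly("A", "A" * 100), assembly("B", "C" * 100)
        base = [block((0, 40), (0, 40), 1e-20)]
        with_noise = base + [block((50, 90), (50, 90), 1e-3)]
        r1 = hcr_alignment(base, genome_a, genome_b)
        r2 = hcr_alignment(with_noise, genome_a, genome_b)
        assert (r1.h_a, r1.h_b, r1.hcr) == (r2.h_a, r2.h_b, r2.hcr)
        assert r2.n_blocks_filtered == 1

    def test_contained_block_changes_nothing_new_block_increases(self):
        genome_a, genome_b = assembly("A", "A" * 100), assembly("B", "C" * 100)
        base = [block((10, 60), (10, 60))]
        contained = base + [block((20, 40), (20, 40))]
        extending = base + [block((70, 90), (70, 90))]
        r_base = hcr_alignment(base, genome_a, genome_b)
        assert hcr_alignment(contained, genome_a, genome_b).hcr == r_base.hcr
        assert hcr_alignment(extending, genome_a, genome_b).hcr > r_base.hcr

    def test_symmetric_under_role_swap(self):
        genome_a, genome_b = assembly("A", "A" * 120), assembly("B", "C" * 80)
        blocks = [block((5, 45), (10, 50)), block((60, 100), (30, 70))]
        swapped = [
            AlignmentBlock("B", "A", b.contig_b, b.contig_a, b.interval_b,
                           b.interval_a, b.strand_b, b.evalue)
            for b in blocks
        ]
        fwd = hcr_alignment(blocks, genome_a, genome_b)
        rev = hcr_alignment(swapped, genome_b, genome_a)
        assert fwd.hcr == rev.hcr
        assert (fwd.h_a, fwd.h_b) == (rev.h_b, rev.h_a)

    def test_unknown_contig_is_an_input_error(self):
        genome_a, genome_b = assembly("A", "A" * 100), assembly("B", "C" * 100)
        bad = [block((0, 10), (0, 10), contig_a="nope")]
        with pytest.raises(InputError, match="nope"):
            hcr_alignment(bad, genome_a, genome_b)


class TestExternalAligner:
    def test_missing_executable(self):
        genome = assembly("A", "ACGT" * 10)
        with pytest.raises(AlignerUnavailableError, match="PATH"):
            run_external_aligner(
                genome, genome, "definitely-not-an-aligner {query} {target} {output}"
            )

    def test_unfilled_placeholder(self):
        genome = assembly("A", "ACGT" * 10)
        with pytest.raises(ConfigurationError, match="output"):
            run_external_aligner(genome, genome, "lastal {query} {target}")

    def test_stub_aligner_invocation(self, tmp_path):
        # a stand-in aligner: emits one full-length tabular self-hit
        stub = tmp_path / "stub_aligner.py"
        stub.write_text(
            "import sys\n"
            "q, t, out = sys.argv[1:4]\n"
            "with open(out, 'w') as fh:\n"
            "    fh.write('A_c1\\tB_c1\\t100.0\\t40\\t0\\t0\\t1\\t40\\t1\\t40\\t1e-20\\t80\\n')\n"
        )
        genome_a, genome_b = assembly("A", "ACGT" * 10), assembly("B", "ACGT" * 10)
        out = run_external_aligner(
            genome_a, genome_b,
            f"{sys.executable} {stub} {{query}} {{target}} {{output}}",
            workdir=tmp_path / "work",
        )
        blocks = parse_alignments(out, "tabular", "A", "B")
        assert blocks[0].interval_a == (0, 40)
        result = hcr_alignment(blocks, genome_a, genome_b)
        assert result.hcr == 1.0


def test_coverage_tsv_format(tmp_path):
    genome = assembly("A", "ACGT" * 25)
    full = AlignmentBlock("A", "A", "A_c1", "A_c1", (0, 100), (0, 100), "+", 0.0)
    result = hcr_alignment([full], genome, genome)
    path = write_coverage_results([result], tmp_path / "cov.tsv")
    lines = path.read_text().splitlines()
    assert lines[0].split("\t") == [
        "accession_a", "accession_b", "S_a", "S_b", "H_a", "H_b",
        "hcr", "n_blocks_used", "n_blocks_filtered",
    ]
    assert lines[1].split("\t") == ["A", "A", "100", "100", "100", "100",
                                    "1.000000000", "1", "0"]
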