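"""Junction parsing, matrix reading, and isoform quantification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from splicestrat.errors import (
    DefinitionError,
    FormatError,
    ParseError,
    UsageError,
)
from splicestrat.junctions import (
    GenomicJunction,
    IsoformDefinition,
    JunctionMatrix,
    P55A_JUNCTION,
    P85A_JUNCTION,
    default_isoform_definitions,
    parse_junction_region,
    quantify_isoforms,
    read_expression_csv,
    read_junction_matrix,
    write_expression_csv,
)


class TestParseJunctionRegion:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("chr5:68281007-68292258:+", ("chr5", 68281007, 68292258, "+")),
            ("chr1:100-200:-", ("chr1", 100, 200, "-")),
            # en dash separator and unicode minus strand
            ("chr5:68290835–68292258:+", ("chr5", 68290835, 68292258, "+")),
            ("chr1:100-200:−", ("chr1", 100, 200, "-")),
            # digit-grouping commas
            ("5:68,290,834-68,292,259:+", ("5", 68290834, 68292259, "+")),
        ],
    )
    def test_well_formed(self, text, expected):
        j = parse_junction_region(text)
        assert (j.chrom, j.start, j.end, j.strand) == expected

    def test_reversed_interval_swaps_with_warning(self):
        # minus-strand genes are often printed 5'->3' of the transcript
        with pytest.warns(UserWarning, match="swapping"):
            j = parse_junction_region("5:68,290,834-68,281,006:+")
        assert (j.chrom, j.start, j.end, j.strand) == ("5", 68281006, 68290834, "+")

    @pytest.mark.parametrize(
        "bad",
        ["chr1:100-200", "chr1:100:200:+", ":100-200:+", "chr1:a-200:+",
         "chr1:100..200:+", "chr1:100-200:*"],
    )
    def test_malformed_raises(self, bad):
        with pytest.raises(ParseError):
            parse_junction_region(bad)

    def test_zero_length_interval_rejected(self):
        with pytest.raises(ParseError, match="start == end"):
            parse_junction_region("chr1:100-100:+")

    @given(
        chrom=st.sampled_from(["chr1", "chr5", "chrX", "5", "scaffold_12"]),
        start=st.integers(min_value=1, max_value=10**8),
        span=st.integers(min_value=1, max_value=10**6),
        strand=st.sampled_from(["+", "-"]),
    )
    def test_format_parse_round_trip(self, chrom, start, span, strand):
        j = GenomicJunction(chrom, start, start + span, strand)
        assert parse_junction_region(str(j)) == j


class TestReadJunctionMatrix:
    def make_matrix(self):
        junctions = [P85A_JUNCTION, P55A_JUNCTION]
        return JunctionMatrix(junctions, ["s1", "s2", "s3"],
                              np.array([[12, 0, 5], [0, 7, 1]]))

    def test_tsv_round_trip(self, tmp_path):
        jm = self.make_matrix()
        path = tmp_path / "j.tsv"
        jm.write_tsv(path)
        back = read_junction_matrix(path, format="tsv")
        assert back.samples == jm.samples
        assert back.junctions == sorted(
            jm.junctions, key=lambda j: (j.chrom, j.start, j.end, j.strand)
        )
        key_to_row = {j.key: i for i, j in enumerate(back.junctions)}
        for j, row in zip(jm.junctions, jm.counts):
            assert (back.counts[key_to_row[j.key]] == row).all()

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "chrom\tstart\tend\tstrand\ts1\nchr1\t10\t20\t+\t-1\n"
        )
        with pytest.raises(FormatError, match="negative"):
            read_junction_matrix(path, format="tsv")

    def test_duplicate_key_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "chrom\tstart\tend\tstrand\ts1\n"
            "chr1\t10\t20\t+\t3\nchr1\t10\t20\t+\t4\n"
        )
        with pytest.raises(FormatError, match="duplicate"):
            read_junction_matrix(path, format="tsv")

    def test_star_sj_merge_missing_is_zero(self, tmp_path):
        # STAR columns: chrom start end strandcode motif annotated unique multi overhang
        a = tmp_path / "sampleA.SJ.out.tab"
        b = tmp_path / "sampleB.SJ.out.tab"
        a.write_text("chr1\t10\t20\t1\t1\t1\t9\t2\t30\n"
                     "chr2\t5\t15\t2\t1\t0\t4\t0\t20\n")
        b.write_text("chr1\t10\t20\t1\t1\t1\t6\t1\t30\n")
        jm = read_junction_matrix([a, b], format="star_sj")
        assert jm.samples == ["sampleA.SJ.out", "sampleB.SJ.out"]
        rows = {j.key: jm.counts[i] for i, j in enumerate(jm.junctions)}
        assert (rows[("chr1", 10, 20, "+")] == [9, 6]).all()
        assert (rows[("chr2", 5, 15, "-")] == [4, 0]).all()

    def test_star_sj_total_count_column(self, tmp_path):
        a = tmp_path / "a.tab"
        a.write_text("chr1\t10\t20\t1\t1\t1\t9\t2\t30\n")
        jm = read_junction_matrix([a], format="star_sj", count_column="total")
        assert jm.counts[0, 0] == 11

    def test_star_sj_undefined_strand_skipped(self, tmp_path):
        a = tmp_path / "a.tab"
        a.write_text("chr1\t10\t20\t0\t0\t0\t5\t0\t10\n"
                     "chr1\t30\t40\t1\t1\t1\t2\t0\t10\n")
        with pytest.warns(UserWarning, match="undefined-strand"):
            jm = read_junction_matrix([a], format="star_sj")
        assert jm.shape == (1, 1)


class TestQuantifyIsoforms:
    def fixture_matrix(self):
        return JunctionMatrix(
            [P85A_JUNCTION, P55A_JUNCTION],
            ["s1", "s2"],
            np.array([[12, 0], [0, 7]]),
        )

    def test_discriminating_junction_counts(self):
        et = quantify_isoforms(self.fixture_matrix(), default_isoform_definitions())
        assert list(et.raw["p85a"]) == [12, 0]
        assert list(et.raw["p55a"]) == [0, 7]
        assert et.log.loc["s2", "p85a"] == 0.0  # log10(0 + 1)

    def test_absent_junction_is_zero(self):
        ghost = IsoformDefinition(
            "ghost", "PIK3R1", (GenomicJunction("chr9", 5, 10, "+"),)
        )
        et = quantify_isoforms(self.fixture_matrix(), [ghost])
        assert (et.raw["ghost"] == 0).all()
        assert (et.log["ghost"] == 0.0).all()

    def test_multi_junction_additivity(self):
        j1 = GenomicJunction("chr1", 10, 20, "+")
        j2 = GenomicJunction("chr1", 30, 40, "+")
        jm = JunctionMatrix([j1, j2], ["s"], np.array([[3], [4]]))
        combined = quantify_isoforms(jm, [IsoformDefinition("iso", "G", (j1, j2))])
        separate = sum(
            quantify_isoforms(jm, [IsoformDefinition("iso", "G", (j,))]).raw["iso"]["s"]
            for j in (j1, j2)
        )
        assert combined.raw["iso"]["s"] == 7 == separate

    def test_order_invariance(self, rng):
        jm = self.fixture_matrix()
        perm_j = JunctionMatrix(jm.junctions[::-1], jm.samples, jm.counts[::-1])
        col = rng.permutation(len(jm.samples))
        perm_s = JunctionMatrix(
            jm.junctions, [jm.samples[i] for i in col], jm.counts[:, col]
        )
        defs = default_isoform_definitions()
        base = quantify_isoforms(jm, defs).raw
        assert quantify_isoforms(perm_j, defs).raw.equals(base)
        assert (
            quantify_isoforms(perm_s, defs).raw.sort_index().equals(base.sort_index())
        )

    def test_strand_discipline(self):
        flipped = GenomicJunction(
            P85A_JUNCTION.chrom, P85A_JUNCTION.start, P85A_JUNCTION.end, "-"
        )
        jm = JunctionMatrix([flipped], ["s"], np.array([[99]]))
        et = quantify_isoforms(jm, default_isoform_definitions())
        assert et.raw.loc["s", "p85a"] == 0

    def test_empty_definitions_rejected(self):
        with pytest.raises(UsageError):
            quantify_isoforms(self.fixture_matrix(), [])

    def test_duplicate_junction_across_isoforms_rejected(self):
        dup = [
            IsoformDefinition("a", "G", (P85A_JUNCTION,)),
            IsoformDefinition("b", "G", (P85A_JUNCTION,)),
        ]
        with pytest.raises(DefinitionError):
            quantify_isoforms(self.fixture_matrix(), dup)


class TestExpressionCsv:
    def test_round_trip(self, tmp_path):
        jm = TestQuantifyIsoforms().fixture_matrix()
        et = quantify_isoforms(
            jm, default_isoform_definitions(),
            sample_type={"s1": "tumor", "s2": "normal"},
        )
        path = tmp_path / "expr.csv"
        write_expression_csv(et, path)
        back = read_expression_csv(path)
        assert back.raw.equals(et.raw)
        assert np.allclose(back.log, et.log, atol=1e-12)
        assert list(back.sample_type) == ["tumor", "normal"]

    def test_single_sample_writes_header_plus_row(self, tmp_path):
        jm = JunctionMatrix([P85A_JUNCTION], ["only"], np.array([[5]]))
        et = quantify_isoforms(jm, [default_isoform_definitions()[0]])
        path = tmp_path / "one.csv"
        write_expression_csv(et, path)
        assert len(path.read_text().strip().splitlines()) == 2

    def test_empty_table_rejected(self, tmp_path):
        jm = JunctionMatrix([P85A_JUNCTION], [], np.zeros((1, 0)))
        et = quantify_isoforms(jm, [default_isoform_definitions()[0]])
        with pytest.raises(UsageError):
            write_expression_csv(et, tmp_path / "empty.csv")
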