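"""Absolute/relative coordinate conversion and range phrasing."""

import pytest
from hypothesis import given, settings, strategies as st

import trackscribe as ts
from trackscribe.assemblies import HG38_CHROM_SIZES
from trackscribe.genome_coords import CoordinateError, chromosome_phrase


class TestBuildAssembly:
    def test_bundled_hg38(self, hg38):
        assert len(hg38.chromosomes) == 24
        assert hg38.offset_of("chr2") == hg38.length_of("chr1")
        # brute-force sum oracle for the cumulative total
        assert hg38.total == sum(HG38_CHROM_SIZES.values())

    def test_custom_table(self):
        t = ts.build_assembly([("A", 10), ("B", 5)])
        assert t.total == 15
        assert t.offsets == (0, 10)

    def test_chrom_sizes_file(self, tmp_path):
        p = tmp_path / "toy.chrom.sizes"
        p.write_text("chr1\t100\nchr2\t50\n")
        t = ts.build_assembly(p)
        assert t.total == 150 and t.chromosomes == ("chr1", "chr2")

    @pytest.mark.parametrize("pairs", [[("A", 10), ("A", 5)], [("A", 0)], [("A", -3)]])
    def test_invalid_tables_rejected(self, pairs):
        with pytest.raises(CoordinateError):
            ts.build_assembly(pairs)


class TestAbsToRel:
    def test_reproduces_reference_conversion(self, hg38):
        """The documented hg38 conversion: 1191936000 -> chr6:130737676."""
        rel = ts.abs_to_rel(1191936000, hg38)
        assert (rel.chromosome, rel.position, rel.mapped) == ("chr6", 130737676, True)

    def test_first_base(self, hg38):
        rel = ts.abs_to_rel(1, hg38)
        assert (rel.chromosome, rel.position) == ("chr1", 1)

    def test_chromosome_boundary_matches_linear_scan(self, hg38):
        pos = hg38.length_of("chr1") + 1
        rel = ts.abs_to_rel(pos, hg38)
        assert (rel.chromosome, rel.position) == ("chr2", 1)
        # independent linear-scan oracle over several positions
        for p in (1, 17, hg38.length_of("chr1"), pos, hg38.total):
            running = 0
            for chrom, length in zip(hg38.chromosomes, hg38.lengths):
                if p <= running + length:
                    expected = (chrom, p - running)
                    break
                running += length
            got = ts.abs_to_rel(p, hg38)
            assert (got.chromosome, got.position) == expected

    def test_unmapped_beyond_total(self, hg38):
        rel = ts.abs_to_rel(hg38.total + 1, hg38)
        assert not rel.mapped and rel.chromosome is None

    def test_position_below_one_rejected(self, hg38):
        with pytest.raises(CoordinateError):
            ts.abs_to_rel(0, hg38)


class TestRelToAbs:
    def test_inverse_of_reference_conversion(self, hg38):
        assert ts.rel_to_abs("chr6", 130737676, hg38) == 1191936000

    def test_first_base(self, hg38):
        assert ts.rel_to_abs("chr1", 1, hg38) == 1

    @pytest.mark.parametrize("chrom,pos", [("chrZ", 1), ("chr1", 0), ("chr1", 10**10)])
    def test_out_of_range_rejected(self, hg38, chrom, pos):
        with pytest.raises(CoordinateError):
            ts.rel_to_abs(chrom, pos, hg38)


@settings(derandomize=True, max_examples=300)
@given(st.integers(min_value=1, max_value=sum(HG38_CHROM_SIZES.values())))
def test_roundtrip_bijection(pos):
    """abs->rel->abs is the identity on the mapped genome."""
    table = ts.build_assembly("hg38")
    rel = ts.abs_to_rel(pos, table)
    assert rel.mapped
    assert 1 <= rel.position <= table.length_of(rel.chromosome)
    assert ts.rel_to_abs(rel.chromosome, rel.position, table) == pos


@settings(derandomize=True, max_examples=100)
@given(st.integers(min_value=1, max_value=3_088_269_831),
       st.integers(min_value=0, max_value=10_000_000))
def test_monotonicity(pos, step):
    """abs_to_rel is non-decreasing in (chromosome order, position)."""
    table = ts.build_assembly("hg38")
    a, b = ts.abs_to_rel(pos, table), ts.abs_to_rel(min(pos + step, table.total), table)
    ia = table.chromosomes.index(a.chromosome)
    ib = table.chromosomes.index(b.chromosome)
    assert (ia, a.position) <= (ib, b.position)


class TestDescribeRange:
    def test_whole_genome_with_unmapped_tail(self, hg38):
        sentence = ts.describe_range(1, hg38.total + 15_000_000, hg38)
        assert sentence == (
            "The genomic range is shown from chromosome 1 to chromosome 22 "
            "and the X and Y chromosomes, as well as an unmapped part of the "
            "genome at the end."
        )

    def test_single_chromosome_range(self, hg38):
        start = ts.rel_to_abs("chr3", 1000, hg38)
        end = ts.rel_to_abs("chr3", 2000, hg38)
        assert ts.describe_range(start, end, hg38) == (
            "The genomic range is shown on chromosome 3, position 1000 to position 2000."
        )

    def test_custom_assembly_endpoints(self):
        table = ts.build_assembly([(f"chr{i}", 100) for i in range(1, 6)])
        start, end = ts.rel_to_abs("chr3", 50, table), ts.rel_to_abs("chr5", 10, table)
        sentence = ts.describe_range(start, end, table)
        # endpoint-conversion oracle: both endpoint chromosomes are named
        assert "chromosome 3" in sentence and "chromosome 5" in sentence
        assert "unknown" not in sentence

    def test_never_names_unknown_chromosome(self, hg38):
        sentence = ts.describe_range(hg38.total - 5, hg38.total + 5, hg38)
        assert "unknown" not in sentence
        assert "unmapped part of the genome at the end" in sentence

    def test_reversed_range_rejected(self, hg38):
        with pytest.raises(CoordinateError):
            ts.describe_range(10, 5, hg38)


def test_chromosome_phrasing():
    assert chromosome_phrase("chr6") == "chromosome 6"
    assert chromosome_phrase("chrX") == "the X chromosome"
    assert chromosome_phrase("scaffold_1") == "chromosome scaffold_1"
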