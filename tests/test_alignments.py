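import numpy as np
import pytest

from mitophylo.alignments import (
    Alignment,
    AlignmentError,
    PartitionScheme,
    RegionSpec,
    build_partition_scheme,
    extract_regions,
    read_alignment,
    ry_recode,
    window_slice,
    write_alignment,
)


@pytest.fixture
def nexus_file(tmp_path):
    path = tmp_path / "toy.nxs"
    path.write_text(
        "#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=4 NCHAR=12;\n"
        "FORMAT DATATYPE=DNA MISSING=? GAP=-;\nMATRIX\n"
        "a ACGTACGTACGT\nb ACGTACGTACCT\nc ACG-ACGTAC?T\nd ACGTACRTACGT\n;\nEND;\n"
        "BEGIN SETS;\ncharset pos1 = 1-12\\3;\ncharset pos2 = 2-12\\3;\n"
        "charset rest = 3 6 9 12;\nEND;\n")
    return str(path)


class TestReadWrite:
    def test_charset_stride_semantics(self, nexus_file):
        aln, scheme = read_alignment(nexus_file, "nexus")
        assert aln.ntaxa == 4 and aln.ncols == 12
        assert scheme.partitions["pos1"] == [1, 4, 7, 10]
        assert scheme.partitions["pos2"] == [2, 5, 8, 11]
        assert scheme.partitions["rest"] == [3, 6, 9, 12]

    @pytest.mark.parametrize("fmt", ["nexus", "fasta"])
    def test_round_trip_identity(self, nexus_file, tmp_path, fmt):
        aln, scheme = read_alignment(nexus_file, "nexus")
        out = str(tmp_path / f"rt.{fmt}")
        write_alignment(aln, out, fmt, scheme if fmt == "nexus" else None)
        back, scheme2 = read_alignment(out, fmt)
        assert back.taxa == aln.taxa
        assert back.matrix == aln.matrix
        if fmt == "nexus":
            assert scheme2.partitions == scheme.partitions

    def test_ragged_rows_rejected(self):
        with pytest.raises(AlignmentError, match="ragged"):
            Alignment(["a", "b"], ["ACGT", "ACG"])

    def test_duplicate_taxon_rejected(self):
        with pytest.raises(AlignmentError, match="duplicate"):
            Alignment(["a", "a"], ["ACGT", "ACGT"])


class TestPartitionScheme:
    def test_overlap_rejected(self):
        with pytest.raises(AlignmentError, match="overlap"):
            PartitionScheme({"x": [1, 2], "y": [2, 3]})

    def test_codon_frame_arithmetic(self):
        aln = Alignment(["a", "b"], ["ACGACGACG", "ACGACGACG"])
        scheme = build_partition_scheme(aln, ["codon1", "codon2", "codon3"] * 3)
        assert scheme.partitions["codon1"] == [1, 4, 7]
        assert scheme.partitions["codon2"] == [2, 5, 8]
        assert scheme.partitions["codon3"] == [3, 6, 9]

    def test_partition_sizes_sum_to_columns(self):
        ann = ["codon1", "codon2", "codon3", "stem", "loop", "other"] * 4
        aln = Alignment(["a", "b"], ["A" * 24, "C" * 24])
        scheme = build_partition_scheme(aln, ann)
        assert sum(scheme.sizes().values()) == 24

    def test_merge_rna_partition(self):
        ann = ["stem", "loop", "codon1", "codon2", "codon3", "stem"]
        aln = Alignment(["a", "b"], ["ACGTAC", "ACGTAC"])
        scheme = build_partition_scheme(aln, ann, merge_rna=True)
        assert scheme.partitions["rna"] == [1, 2, 6]
        assert "stem" not in scheme.partitions

    def test_unlabeled_column_rejected(self):
        aln = Alignment(["a", "b"], ["ACG", "ACG"])
        with pytest.raises(AlignmentError):
            build_partition_scheme(aln, ["codon1", "codon2"])


class TestRYRecode:
    def test_purine_pyrimidine_definition(self):
        aln = Alignment(["w", "x", "y", "z"], ["A", "G", "C", "T"])
        out = ry_recode(aln, [1])
        assert [row for row in out.matrix] == ["R", "R", "Y", "Y"]

    def test_ambiguity_and_gap_to_missing(self):
        aln = Alignment(["w", "x", "y", "z"], ["R", "N", "-", "W"])
        out = ry_recode(aln, [1])
        assert [row for row in out.matrix] == ["R", "?", "?", "?"]

    def test_idempotent_and_untouched_outside(self):
        aln = Alignment(["a", "b"], ["ACGTAC", "TGCATG"])
        once = ry_recode(aln, [2, 4, 6])
        twice = ry_recode(once, [2, 4, 6])
        assert once.matrix == twice.matrix
        for row_in, row_out in zip(aln.matrix, once.matrix):
            assert all(row_in[i] == row_out[i] for i in (0, 2, 4))

    def test_preserves_taxon_order(self, small_alignment):
        out = ry_recode(small_alignment, list(range(1, 11)))
        assert out.taxa == small_alignment.taxa
        assert out.ncols == small_alignment.ncols


class TestRegions:
    def test_study_region_widths(self):
        # three regions shaped like the short-fragment dataset: 672 + 702 + 578
        aln = Alignment(["a", "b"], ["A" * 2500, "C" * 2500])
        regions = [RegionSpec("cytb", [(1, 672)]),
                   RegionSpec("coi", [(700, 1401)]),
                   RegionSpec("dloop", [(1500, 2077)])]
        out = extract_regions(aln, regions)
        assert out.ncols == 1952
        assert out.column_labels[0] == "cytb"
        assert out.column_labels[-1] == "dloop"

    def test_empty_and_identity(self, small_alignment):
        empty = extract_regions(small_alignment, [])
        assert empty.ncols == 0 and empty.taxa == small_alignment.taxa
        full = extract_regions(small_alignment,
                               [RegionSpec("all", [(1, small_alignment.ncols)])])
        assert full.matrix == small_alignment.matrix

    def test_out_of_range_rejected(self, small_alignment):
        with pytest.raises(AlignmentError):
            extract_regions(small_alignment, [RegionSpec("bad", [(1, 999)])])


class TestWindows:
    def test_genome_window_arithmetic(self):
        # 14471 = 14 * 1000 + 471
        aln = Alignment(["a", "b"], ["A" * 14471, "C" * 14471])
        wins = window_slice(aln, 1000)
        assert len(wins) == 15
        assert wins[-1].width == 471 and wins[-1].partial
        assert all(not w.partial for w in wins[:-1])

    def test_degenerate_width(self, small_alignment):
        wins = window_slice(small_alignment, 10_000)
        assert len(wins) == 1
        assert wins[0].alignment.matrix == small_alignment.matrix

    def test_concatenation_identity(self, small_alignment):
        wins = window_slice(small_alignment, 7)
        rebuilt = ["".join(w.alignment.matrix[i] for w in wins)
                   for i in range(small_alignment.ntaxa)]
        assert rebuilt == small_alignment.matrix

    def test_bad_width_rejected(self, small_alignment):
        with pytest.raises(AlignmentError):
            window_slice(small_alignment, 0)
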