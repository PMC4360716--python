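import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from viroclade.core_io import (
    GeneCall,
    ParseError,
    SequenceRecord,
    dedupe_exact,
    find_orfs,
    quality_trim,
    read_fasta,
    read_fastq,
    read_gff3,
    write_fasta,
    write_fastq,
    write_gff3,
)


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACGT\n")
        recs = read_fasta(p)
        assert [(r.id, r.seq) for r in recs] == [("a", "ACGT")]

    def test_round_trip_preserves_records(self, tmp_path):
        recs = [
            SequenceRecord("a", "ACGTN", desc="first"),
            SequenceRecord("b", "A" * 200),
        ]
        p = tmp_path / "x.fasta"
        write_fasta(recs, p)
        back = read_fasta(p)
        assert [(r.id, r.seq, r.desc) for r in back] == [
            (r.id, r.seq, r.desc) for r in recs
        ]

    def test_duplicate_id_error_names_offender(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">a\nAC\n>a\nGT\n")
        with pytest.raises(ParseError, match="'a'"):
            read_fasta(p)

    def test_empty_file_and_headerless_data(self, tmp_path):
        p = tmp_path / "e.fasta"
        p.write_text("")
        with pytest.raises(ParseError):
            read_fasta(p)
        p.write_text("ACGT\n")
        with pytest.raises(ParseError, match=":1:"):
            read_fasta(p)

    def test_sequences_uppercased(self, tmp_path):
        p = tmp_path / "lc.fasta"
        p.write_text(">a\nacgt\n")
        assert read_fasta(p)[0].seq == "ACGT"


class TestFastq:
    def test_well_formed_record_has_quals(self, tmp_path):
        p = tmp_path / "r.fastq"
        p.write_text("@r1 desc\nACGT\n+\nIIII\n")
        (rec,) = read_fastq(p)
        assert rec.quals == [40, 40, 40, 40]
        assert rec.desc == "desc"

    def test_round_trip(self, tmp_path):
        recs = [SequenceRecord("r1", "ACGT", quals=[2, 20, 30, 41])]
        p = tmp_path / "w.fastq"
        write_fastq(recs, p)
        back = read_fastq(p)
        assert back[0].quals == recs[0].quals and back[0].seq == recs[0].seq

    def test_length_mismatch_error(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r1\nACGT\n+\nIII\n")
        with pytest.raises(ParseError, match="quality length"):
            read_fastq(p)

    def test_truncated_record_error(self, tmp_path):
        p = tmp_path / "tr.fastq"
        p.write_text("@r1\nACGT\n+\n")
        with pytest.raises(ParseError, match="truncated"):
            read_fastq(p)


class TestGff3:
    def test_round_trip_with_coordinates(self, tmp_path):
        calls = [
            GeneCall("c1", 9, 18, "+", "g1", "MAA", annotation="g23"),
            GeneCall("c1", 30, 45, "-", "g2", "MAAAA"),
        ]
        p = tmp_path / "g.gff3"
        write_gff3(calls, p)
        text = p.read_text()
        assert "\t10\t18\t" in text  # 1-based inclusive on disk
        back = read_gff3(p, proteins={"g1": "MAA", "g2": "MAAAA"})
        assert [(c.contig_id, c.start, c.end, c.strand, c.gene_id, c.protein, c.annotation)
                for c in back] == [
            ("c1", 9, 18, "+", "g1", "MAA", "g23"),
            ("c1", 30, 45, "-", "g2", "MAAAA", None),
        ]


class TestQualityTrim:
    def test_high_quality_unchanged(self):
        r = SequenceRecord("r", "A" * 80, quals=[40] * 80)
        assert quality_trim(r).seq == r.seq

    def test_trimmed_below_min_len_discarded(self):
        r = SequenceRecord("r", "A" * 100, quals=[40] * 40 + [2] * 60)
        assert quality_trim(r, cutoff=30, min_len=50) is None

    def test_short_low_quality_tail_removed(self):
        r = SequenceRecord("r", "A" * 65, quals=[40] * 60 + [10] * 5)
        out = quality_trim(r, cutoff=30, min_len=50)
        assert len(out.seq) == 60

    def test_requires_qualities(self):
        with pytest.raises(ValueError):
            quality_trim(SequenceRecord("r", "ACGT"))

    @given(
        quals=st.lists(st.integers(min_value=0, max_value=41), min_size=1, max_size=80),
        cutoff=st.integers(min_value=0, max_value=41),
    )
    @settings(max_examples=100, deadline=None)
    def test_never_lengthens_and_suffix_clean(self, quals, cutoff):
        r = SequenceRecord("r", "A" * len(quals), quals=quals)
        out = quality_trim(r, cutoff=cutoff, min_len=1)
        if out is not None:
            assert len(out.seq) <= len(r.seq)
            assert not out.quals or out.quals[-1] >= cutoff


class TestDedupe:
    def test_smallest_id_kept(self):
        recs = [SequenceRecord("b", "ACGT"), SequenceRecord("a", "ACGT")]
        kept, removed = dedupe_exact(recs)
        assert [r.id for r in kept] == ["a"] and removed == {"b": "a"}

    def test_all_distinct_identity(self):
        recs = [SequenceRecord("a", "AC"), SequenceRecord("b", "GT")]
        kept, removed = dedupe_exact(recs)
        assert kept == recs and removed == {}

    def test_triplicate_plus_unique(self):
        recs = [
            SequenceRecord("c", "AAAA"),
            SequenceRecord("a", "AAAA"),
            SequenceRecord("b", "AAAA"),
            SequenceRecord("z", "TTTT"),
        ]
        kept, removed = dedupe_exact(recs)
        assert len(kept) == 2 and len(kept) + len(removed) == len(recs)
        assert set(removed.values()) == {"a"}

    @given(
        st.lists(
            st.text(alphabet="ACGT", min_size=1, max_size=6), min_size=1, max_size=20
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_counts_conserved_and_no_duplicates_remain(self, seqs):
        recs = [SequenceRecord(f"r{i}", s) for i, s in enumerate(seqs)]
        kept, removed = dedupe_exact(recs)
        assert len(kept) + len(removed) == len(recs)
        assert len({r.seq for r in kept}) == len(kept)


class TestFindOrfs:
    GENE = "ATG" + "GAA" * 61 + "TAA"

    def test_no_start_codon(self):
        assert find_orfs(SequenceRecord("c", "CCC" * 100)) == []

    def test_embedded_orf_exact_coordinates(self):
        seq = "C" * 50 + self.GENE + "C" * 40
        (call,) = find_orfs(SequenceRecord("c", seq))
        assert (call.start, call.end, call.strand) == (50, 50 + len(self.GENE), "+")
        assert call.protein == "M" + "E" * 61

    def test_reverse_strand_forward_axis_coordinates(self):
        from Bio.Seq import Seq

        rc_gene = str(Seq(self.GENE).reverse_complement())
        seq = "C" * 30 + rc_gene + "C" * 20
        (call,) = find_orfs(SequenceRecord("c", seq))
        assert (call.start, call.end, call.strand) == (30, 30 + len(self.GENE), "-")
        assert call.protein == "M" + "E" * 61

    def test_reverse_complement_mirrors_coordinates(self):
        from Bio.Seq import Seq

        seq = "C" * 17 + self.GENE + "G" * 23 + self.GENE + "C" * 5
        fwd = find_orfs(SequenceRecord("c", seq))
        rev = find_orfs(SequenceRecord("c", str(Seq(seq).reverse_complement())))
        n = len(seq)
        mirrored = {(n - c.end, n - c.start, "-" if c.strand == "+" else "+") for c in fwd}
        assert {(c.start, c.end, c.strand) for c in rev} == mirrored
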