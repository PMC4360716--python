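import math
import random

import pytest
from Bio import Align as BioAlign
from Bio.Align import substitution_matrices

from viroclade.align import (
    MSA,
    ScoringScheme,
    bit_and_evalue,
    conservation_and_consensus,
    global_align,
    local_align,
    local_score,
    progressive_msa,
    trim_msa,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="module")
def protein_scheme():
    return ScoringScheme.protein_default()


@pytest.fixture(scope="module")
def oracle_aligner():
    a = BioAlign.PairwiseAligner()
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -12  # gap of length L costs 11 + L under our convention
    a.extend_gap_score = -1
    a.mode = "local"
    return a


class TestLocalAlign:
    def test_identical_short_peptide(self, protein_scheme):
        hit = local_align("ACDE", "ACDE", protein_scheme)
        assert hit.raw_score == 24  # 4 + 9 + 6 + 5 on BLOSUM62
        assert hit.identity == 1.0
        assert (hit.q_start, hit.q_end) == (0, 4)

    def test_all_negative_comparison_is_empty(self, protein_scheme):
        hit = local_align("AAAA", "WWWW", protein_scheme)
        assert hit.raw_score == 0 and hit.aligned_query == ""

    def test_matches_independent_engine_on_random_pairs(
        self, protein_scheme, oracle_aligner
    ):
        rng = random.Random(1)
        for _ in range(200):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(5, 30)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(5, 30)))
            assert local_align(a, b, protein_scheme).raw_score == oracle_aligner.score(
                a, b
            )

    def test_score_symmetry(self, protein_scheme):
        rng = random.Random(2)
        for _ in range(50):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(5, 25)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(5, 25)))
            assert (
                local_align(a, b, protein_scheme).raw_score
                == local_align(b, a, protein_scheme).raw_score
            )

    def test_score_only_agrees_with_traceback(self, protein_scheme):
        rng = random.Random(3)
        for _ in range(100):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(4, 40)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(4, 40)))
            assert local_score(a, b, protein_scheme) == local_align(
                a, b, protein_scheme
            ).raw_score

    def test_dominates_ungapped_windows(self, protein_scheme):
        rng = random.Random(4)
        mat = protein_scheme.matrix
        for _ in range(30):
            a = "".join(rng.choice(AA) for _ in range(20))
            b = "".join(rng.choice(AA) for _ in range(20))
            best = local_align(a, b, protein_scheme).raw_score
            for off in range(-5, 6):
                run = 0
                for i in range(20):
                    j = i + off
                    if 0 <= j < 20:
                        run = max(
                            0,
                            run
                            + mat[
                                protein_scheme.encode(a[i])[0],
                                protein_scheme.encode(b[j])[0],
                            ],
                        )
                        assert best >= run


class TestBitAndEvalue:
    def test_worked_example(self, protein_scheme):
        bit, ev = bit_and_evalue(24, protein_scheme, 100, 100)
        assert bit == pytest.approx(13.85, abs=0.01)
        assert ev == pytest.approx(0.68, abs=0.01)

    def test_zero_score_closed_form(self, protein_scheme):
        bit, ev = bit_and_evalue(0, protein_scheme, 50, 70)
        assert bit == pytest.approx(-math.log(protein_scheme.K) / math.log(2))
        assert ev == pytest.approx(50 * 70 * protein_scheme.K)

    def test_evalue_linear_in_search_space(self, protein_scheme):
        _, e1 = bit_and_evalue(30, protein_scheme, 100, 100)
        _, e2 = bit_and_evalue(30, protein_scheme, 100, 200)
        assert e2 == pytest.approx(2 * e1)

    def test_strictly_monotone(self, protein_scheme):
        bits, evs = zip(
            *(bit_and_evalue(s, protein_scheme, 100, 100) for s in range(0, 80, 5))
        )
        assert all(b1 < b2 for b1, b2 in zip(bits, bits[1:]))
        assert all(e1 > e2 for e1, e2 in zip(evs, evs[1:]))


class TestProgressiveMsa:
    def test_single_sequence(self, protein_scheme):
        msa = progressive_msa([("a", "MKV")], protein_scheme)
        assert msa.rows == [("a", "MKV")]

    def test_identical_sequences_gap_free(self, protein_scheme):
        msa = progressive_msa(
            [("a", "MKVLF"), ("b", "MKVLF"), ("c", "MKVLF")], protein_scheme
        )
        assert all(seq == "MKVLF" for _, seq in msa.rows)

    def test_two_sequences_match_pairwise_global(self, protein_scheme):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        ga, gb = global_align(a, b, protein_scheme)
        msa = progressive_msa([("a", a), ("b", b)], protein_scheme)
        assert msa.rows == [("a", ga), ("b", gb)]

    def test_rows_recover_inputs(self, protein_scheme):
        rng = random.Random(5)
        seqs = [
            (f"s{i}", "".join(rng.choice(AA) for _ in range(rng.randint(5, 25))))
            for i in range(6)
        ]
        msa = progressive_msa(seqs, protein_scheme)
        assert msa.ids == [sid for sid, _ in seqs]  # input order preserved
        for sid, seq in seqs:
            assert msa.ungapped(sid) == seq


class TestTrimAndConservation:
    def test_trim_full_range_identity(self):
        msa = MSA([("a", "AC-GT"), ("b", "ACAGT")])
        assert trim_msa(msa, 0, 5).rows == msa.rows

    def test_trim_slice(self):
        msa = MSA([("a", "AC-GT"), ("b", "ACAGT")])
        assert trim_msa(msa, 2, 4).rows == [("a", "-G"), ("b", "AG")]

    def test_trim_flags_all_gap_rows(self):
        msa = MSA([("a", "A--T"), ("b", "ACGT")])
        assert trim_msa(msa, 1, 3).flagged == {"a"}

    @pytest.mark.parametrize("lo,hi", [(2, 2), (3, 2), (0, 6), (-1, 2)])
    def test_trim_bad_range_errors(self, lo, hi):
        msa = MSA([("a", "AC-GT"), ("b", "ACAGT")])
        with pytest.raises(ValueError):
            trim_msa(msa, lo, hi)

    def test_conservation_identical_rows(self):
        msa = MSA([("a", "MKV"), ("b", "MKV")])
        assert [c for c, _ in conservation_and_consensus(msa)] == [1.0, 1.0, 1.0]

    def test_conservation_mixed_column(self):
        msa = MSA([("a", "A"), ("b", "A"), ("c", "T"), ("d", "-")])
        (score, consensus), = conservation_and_consensus(msa)
        assert consensus == "A" and score == pytest.approx(2 / 3)

    def test_conservation_all_gap_column(self):
        msa = MSA([("a", "-"), ("b", "-")])
        assert conservation_and_consensus(msa) == [(0.0, "-")]

    def test_conservation_tie_breaks_alphabetically(self):
        msa = MSA([("a", "T"), ("b", "A")])
        assert conservation_and_consensus(msa)[0][1] == "A"
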