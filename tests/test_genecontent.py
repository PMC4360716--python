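import random

import numpy as np
import pytest

from viroclade.core_io import GeneCall, SequenceRecord
from viroclade.genecontent import (
    SharingMatrix,
    build_sharing_matrix,
    classify_novelty,
    cluster_contigs,
    exclude_duplicates,
    shared_gene_count,
    sharing_proportion,
    synteny_blocks,
)
from viroclade.phylo import rf_distance

AA = "ACDEFGHIKLMNPQRSTVWY"


def _genes(contig: str, proteins: list[str]) -> list[GeneCall]:
    return [
        GeneCall(contig, 100 * i, 100 * i + 3 * len(p), "+", f"{contig}_g{i}", p)
        for i, p in enumerate(proteins)
    ]


def _random_proteins(rng, n, length=80):
    return ["".join(rng.choice(AA) for _ in range(length)) for _ in range(n)]


class TestSharedGenes:
    def test_self_comparison_counts_all_genes(self):
        rng = random.Random(0)
        genes = _genes("c1", _random_proteins(rng, 5))
        assert shared_gene_count(genes, genes) == 5

    def test_disjoint_random_proteins_share_nothing(self):
        rng = random.Random(1)
        a = _genes("c1", _random_proteins(rng, 4))
        b = _genes("c2", _random_proteins(rng, 4))
        assert shared_gene_count(a, b) == 0

    def test_known_core_overlap(self):
        rng = random.Random(2)
        core = _random_proteins(rng, 6)
        a = _genes("c1", core + _random_proteins(rng, 3))
        b = _genes("c2", core + _random_proteins(rng, 2))
        assert shared_gene_count(a, b) == 6

    @pytest.mark.parametrize(
        "count,na,nb,want", [(4, 10, 8, 0.5), (0, 3, 7, 0.0), (5, 5, 9, 1.0)]
    )
    def test_sharing_proportion(self, count, na, nb, want):
        assert sharing_proportion(count, na, nb) == pytest.approx(want)

    def test_zero_genes_errors(self):
        with pytest.raises(ValueError):
            sharing_proportion(0, 0, 5)


class TestSharingMatrix:
    def test_matrix_properties_on_clean_sim(self, clean_sim):
        by_contig = {}
        for g in clean_sim.gene_calls:
            by_contig.setdefault(g.contig_id, []).append(g)
        sm = build_sharing_matrix(by_contig)
        assert np.allclose(sm.P, sm.P.T)
        assert (sm.P >= 0).all() and (sm.P <= 1).all()
        assert np.allclose(np.diag(sm.P), 1.0)  # every gene self-hits

    def test_within_exceeds_between_on_diverged_sim(self, small_sim):
        by_contig = {}
        for g in small_sim.gene_calls:
            by_contig.setdefault(g.contig_id, []).append(g)
        sm = build_sharing_matrix(by_contig)
        clade = {cid: small_sim.truth.clade_of(cid) for cid in sm.ids}
        within, between = [], []
        for i in range(len(sm.ids)):
            for j in range(i + 1, len(sm.ids)):
                (within if clade[sm.ids[i]] == clade[sm.ids[j]] else between).append(
                    sm.P[i, j]
                )
        assert np.mean(within) > np.mean(between)


class TestExcludeDuplicates:
    def test_cross_sample_duplicates_collapse(self):
        contigs = [
            SequenceRecord("sample4m_c1", "ACGT" * 10),
            SequenceRecord("sample8m_c9", "ACGT" * 10),
        ]
        kept, log = exclude_duplicates(contigs)
        assert [c.id for c in kept] == ["sample4m_c1"]
        assert log == {"sample8m_c9": "sample4m_c1"}

    def test_no_duplicates_identity(self):
        contigs = [SequenceRecord("a", "AAAA"), SequenceRecord("b", "TTTT")]
        kept, log = exclude_duplicates(contigs)
        assert kept == contigs and log == {}

    def test_triplicate_logs_two(self):
        contigs = [SequenceRecord(i, "ACGT") for i in ("c", "a", "b")]
        kept, log = exclude_duplicates(contigs)
        assert len(kept) == 1 and len(log) == 2


class TestClustering:
    def test_identity_matrix_all_singletons(self):
        ids = ["a", "b", "c"]
        P = np.eye(3)
        tree = cluster_contigs(SharingMatrix(ids, P, np.eye(3, dtype=int)))
        assert sorted(l.name for l in tree.get_terminals()) == ids

    def test_two_perfect_blocks_separate(self):
        ids = ["a1", "a2", "b1", "b2"]
        P = np.array(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]], dtype=float
        )
        tree = cluster_contigs(SharingMatrix(ids, P, P.astype(int)))
        kids = {
            frozenset(l.name for l in c.get_terminals()) for c in tree.root.clades
        }
        assert kids == {frozenset({"a1", "a2"}), frozenset({"b1", "b2"})}

    def test_input_order_invariance(self):
        rng = np.random.default_rng(5)
        ids = [f"c{i}" for i in range(6)]
        M = rng.random((6, 6))
        P = (M + M.T) / 2
        np.fill_diagonal(P, 1.0)
        t1 = cluster_contigs(SharingMatrix(ids, P, np.zeros((6, 6), dtype=int)))
        perm = list(rng.permutation(6))
        t2 = cluster_contigs(
            SharingMatrix(
                [ids[i] for i in perm],
                P[np.ix_(perm, perm)],
                np.zeros((6, 6), dtype=int),
            )
        )
        assert rf_distance(t1, t2) == 0


class TestNovelty:
    def test_classes_and_fractions(self):
        rng = random.Random(7)
        ref_prot = "".join(rng.choice(AA) for _ in range(90))
        shared = "".join(rng.choice(AA) for _ in range(90))
        unique = "".join(rng.choice(AA) for _ in range(90))
        by_contig = {
            "c1": _genes("c1", [ref_prot, shared, unique]),
            "c2": _genes("c2", [shared]),
        }
        report = classify_novelty(
            by_contig, [SequenceRecord("nr1", ref_prot)], clades={"c1": "x", "c2": "x"}
        )
        assert report.gene_class["c1_g0"] == "affiliated_reference"
        assert report.gene_class["c1_g1"] == "group_only"
        assert report.gene_class["c1_g2"] == "unique"
        assert sum(report.contig_fractions["c1"].values()) == pytest.approx(1.0)

    def test_self_contig_hits_do_not_count_as_group(self):
        rng = random.Random(8)
        p = "".join(rng.choice(AA) for _ in range(90))
        by_contig = {"c1": _genes("c1", [p, p])}
        report = classify_novelty(by_contig, [])
        assert set(report.gene_class.values()) == {"unique"}

    def test_removing_reference_degrades_not_upgrades(self):
        rng = random.Random(9)
        shared = "".join(rng.choice(AA) for _ in range(90))
        by_contig = {"c1": _genes("c1", [shared]), "c2": _genes("c2", [shared])}
        with_ref = classify_novelty(by_contig, [SequenceRecord("nr", shared)])
        without = classify_novelty(by_contig, [])
        assert with_ref.gene_class["c1_g0"] == "affiliated_reference"
        assert without.gene_class["c1_g0"] == "group_only"


class TestSynteny:
    def test_self_comparison_full_block(self):
        rng = random.Random(10)
        seq = "".join(rng.choice("ACGT") for _ in range(2_000))
        c = SequenceRecord("c", seq)
        blocks = synteny_blocks(c, SequenceRecord("c2", seq))
        assert blocks[0][:3] == ((0, 2_000), (0, 2_000), 1.0)

    def test_unrelated_sequences_no_blocks(self):
        rng = random.Random(11)
        a = SequenceRecord("a", "".join(rng.choice("ACGT") for _ in range(1_500)))
        b = SequenceRecord("b", "".join(rng.choice("ACGT") for _ in range(1_500)))
        assert synteny_blocks(a, b) == []

    def test_shared_cassette_found_at_offsets(self):
        rng = random.Random(12)
        bg1 = "".join(rng.choice("ACGT") for _ in range(3_000))
        bg2 = "".join(rng.choice("ACGT") for _ in range(3_000))
        cassette = "".join(rng.choice("ACGT") for _ in range(500))
        a = SequenceRecord("a", bg1[:1_000] + cassette + bg1[1_000:2_000])
        b = SequenceRecord("b", bg2[:1_700] + cassette + bg2[1_700:2_500])
        ((a_iv, b_iv, ident, strand),) = synteny_blocks(a, b)
        # ungapped extension may run a few chance-matching bases past the
        # cassette edges, but must contain it
        assert a_iv[0] <= 1_000 and a_iv[1] >= 1_500 and a_iv[1] - a_iv[0] < 520
        assert b_iv[0] <= 1_700 and b_iv[1] >= 2_200 and strand == "+"
        assert ident > 0.98

    def test_reverse_strand_block(self):
        from Bio.Seq import Seq

        rng = random.Random(13)
        bg = "".join(rng.choice("ACGT") for _ in range(1_000))
        cassette = "".join(rng.choice("ACGT") for _ in range(400))
        a = SequenceRecord("a", bg[:300] + cassette + bg[300:600])
        b = SequenceRecord(
            "b", bg[600:900] + str(Seq(cassette).reverse_complement()) + bg[300:500]
        )
        blocks = synteny_blocks(a, b)
        assert any(
            s == "-" and iv[0] <= 300 and iv[1] >= 700 and iv[1] - iv[0] < 420
            for iv, _b, _i, s in blocks
        )
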