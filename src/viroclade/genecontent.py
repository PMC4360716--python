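"""Gene-content comparison of contigs: shared-gene proportions, clustering,
gene novelty, and nucleotide synteny blocks.

Two genes are "shared" between contigs when their protein products align
locally with a bit score above 50 and an e-value below 0.001 (per-pair
search space). The sharing proportion between two contigs divides the
shared-gene count by the gene complement of the contig with fewer genes, so
a fragment fully contained in a larger genome scores 1. Contigs are
clustered by complete linkage on 1 - proportion, mirroring the defaults of
the usual heatmap tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio.Phylo.BaseTree import Clade, Tree
from Bio.Seq import Seq

from .align import (
    ScoringScheme,
    bit_and_evalue,
    default_scheme,
    local_score,
    shares_kmer,
)
from .core_io import GeneCall, SequenceRecord, dedupe_exact


@dataclass
class SharingMatrix:
    ids: list[str]
    P: np.ndarray  # proportions in [0, 1], symmetric
    counts: np.ndarray  # shared-gene counts (ints)


@dataclass
class NoveltyReport:
    gene_class: dict[str, str]  # gene_id -> affiliated_reference|group_only|unique
    contig_fractions: dict[str, dict[str, float]]  # contig -> class -> fraction
    clade_fractions: dict[str, dict[str, float]]  # clade -> class -> fraction


def _qualifies(
    a: str, b: str, scheme: ScoringScheme, min_bit: float, max_evalue: float
) -> bool:
    if not shares_kmer(a, b, scheme.kmer):
        return False
    raw = local_score(a, b, scheme)
    bit, ev = bit_and_evalue(raw, scheme, len(a), len(b))
    return bit > min_bit and ev < max_evalue


def shared_gene_count(
    genes_a: Sequence[GeneCall],
    genes_b: Sequence[GeneCall],
    scheme: Optional[ScoringScheme] = None,
    min_bit: float = 50.0,
    max_evalue: float = 1e-3,
) -> int:
    """Number of genes of the smaller gene set with >= 1 qualifying protein
    hit in the other contig."""
    scheme = scheme or default_scheme("protein")
    small, large = sorted((list(genes_a), list(genes_b)), key=len)
    count = 0
    for g in small:
        for h in large:
            if _qualifies(g.protein, h.protein, scheme, min_bit, max_evalue):
                count += 1
                break
    return count


def sharing_proportion(count: int, n_genes_a: int, n_genes_b: int) -> float:
    """count / min(gene counts). The denominator is the gene complement of
    the contig with fewer genes ("shortest contig" read as gene count; a
    bp denominator would not yield a proportion)."""
    if n_genes_a <= 0 or n_genes_b <= 0:
        raise ValueError("gene counts must be positive")
    return count / min(n_genes_a, n_genes_b)


def build_sharing_matrix(
    genes_by_contig: dict[str, list[GeneCall]],
    scheme: Optional[ScoringScheme] = None,
    min_bit: float = 50.0,
    max_evalue: float = 1e-3,
) -> SharingMatrix:
    scheme = scheme or default_scheme("protein")
    ids = sorted(genes_by_contig)
    n = len(ids)
    P = np.zeros((n, n))
    C = np.zeros((n, n), dtype=int)
    for i in range(n):
        gi = genes_by_contig[ids[i]]
        C[i, i] = shared_gene_count(gi, gi, scheme, min_bit, max_evalue)
        P[i, i] = sharing_proportion(C[i, i], len(gi), len(gi))
        for j in range(i + 1, n):
            gj = genes_by_contig[ids[j]]
            c = shared_gene_count(gi, gj, scheme, min_bit, max_evalue)
            C[i, j] = C[j, i] = c
            P[i, j] = P[j, i] = sharing_proportion(c, len(gi), len(gj))
    return SharingMatrix(ids, P, C)


def exclude_duplicates(
    contigs: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Drop exact-sequence duplicate contigs (identical fragments assembled
    from different samples); the log maps removed id -> kept id."""
    return dedupe_exact(contigs)


def cluster_contigs(sharing: SharingMatrix) -> Tree:
    """Complete-linkage agglomerative clustering on dissimilarity 1 - P,
    returned as a (topology-only meaningful) tree over contig ids. Contig
    ids are ordered lexicographically so linkage ties resolve to the
    smallest id pair."""
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    n = len(sharing.ids)
    if n < 2:
        raise ValueError("clustering needs at least 2 contigs")
    order = np.argsort(sharing.ids)
    ids = [sharing.ids[i] for i in order]
    D = 1.0 - sharing.P[np.ix_(order, order)]
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="complete")
    nodes: dict[int, Clade] = {
        i: Clade(name=ids[i], branch_length=1.0) for i in range(n)
    }
    for k, (za, zb, height, _cnt) in enumerate(Z):
        nodes[n + k] = Clade(
            clades=[nodes.pop(int(za)), nodes.pop(int(zb))], branch_length=1.0
        )
    root = nodes[n + len(Z) - 1]
    root.branch_length = None
    return Tree(root=root, rooted=True)


def classify_novelty(
    genes_by_contig: dict[str, list[GeneCall]],
    reference_db: Sequence[SequenceRecord],
    scheme: Optional[ScoringScheme] = None,
    min_bit: float = 50.0,
    max_evalue: float = 1e-3,
    clades: Optional[dict[str, str]] = None,
) -> NoveltyReport:
    """Classify each gene as affiliated_reference (hit in the reference
    protein database), group_only (hit only in another contig of the group;
    self-contig hits never count), or unique. Precedence in that order."""
    scheme = scheme or default_scheme("protein")
    gene_class: dict[str, str] = {}
    for cid, genes in sorted(genes_by_contig.items()):
        others = [
            g
            for ocid, ogenes in genes_by_contig.items()
            if ocid != cid
            for g in ogenes
        ]
        for g in genes:
            if any(
                _qualifies(g.protein, ref.seq, scheme, min_bit, max_evalue)
                for ref in reference_db
            ):
                gene_class[g.gene_id] = "affiliated_reference"
            elif any(
                _qualifies(g.protein, o.protein, scheme, min_bit, max_evalue)
                for o in others
            ):
                gene_class[g.gene_id] = "group_only"
            else:
                gene_class[g.gene_id] = "unique"
    classes = ("affiliated_reference", "group_only", "unique")

    def fractions(gene_ids: list[str]) -> dict[str, float]:
        total = len(gene_ids)
        return {
            c: sum(1 for g in gene_ids if gene_class[g] == c) / total
            for c in classes
        }

    contig_fractions = {
        cid: fractions([g.gene_id for g in genes])
        for cid, genes in genes_by_contig.items()
        if genes
    }
    clade_fractions: dict[str, dict[str, float]] = {}
    if clades:
        by_clade: dict[str, list[str]] = {}
        for cid, genes in genes_by_contig.items():
            cl = clades.get(cid)
            if cl is not None:
                by_clade.setdefault(cl, []).extend(g.gene_id for g in genes)
        clade_fractions = {cl: fractions(gs) for cl, gs in by_clade.items() if gs}
    return NoveltyReport(gene_class, contig_fractions, clade_fractions)


# ---------------------------------------------------------------------------
# Nucleotide synteny blocks (seed-and-extend, ungapped)
# ---------------------------------------------------------------------------

def _diagonal_segments(a: str, b: str, scheme: ScoringScheme, min_bit: float):
    """Best ungapped segment per seeded diagonal (maximum-scoring subarray of
    the match/mismatch score profile)."""
    k = scheme.kmer
    match = int(scheme.matrix[0, 0])
    mismatch = int(scheme.matrix[0, 1])
    index: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        index.setdefault(a[i : i + k], []).append(i)
    diags: set[int] = set()
    for j in range(len(b) - k + 1):
        for i in index.get(b[j : j + k], ()):
            diags.add(j - i)
    ac = np.frombuffer(a.encode(), dtype=np.uint8)
    bc = np.frombuffer(b.encode(), dtype=np.uint8)
    for d in sorted(diags):
        lo_a = max(0, -d)
        length = min(len(a) - lo_a, len(b) - (lo_a + d))
        if length < k:
            continue
        sa = ac[lo_a : lo_a + length]
        sb = bc[lo_a + d : lo_a + d + length]
        eq = sa == sb
        scores = np.where(eq, match, mismatch).astype(np.int64)
        # Kadane: maximal scoring segment
        best = run = 0
        best_end = run_start = 0
        best_start = 0
        for idx, s in enumerate(scores):
            if run <= 0:
                run = 0
                run_start = idx
            run += int(s)
            if run > best:
                best = run
                best_start, best_end = run_start, idx + 1
        if best <= 0:
            continue
        bit, _ev = bit_and_evalue(best, scheme, len(a), len(b))
        if bit <= min_bit:
            continue
        seg_eq = eq[best_start:best_end]
        yield (
            (lo_a + best_start, lo_a + best_end),
            (lo_a + d + best_start, lo_a + d + best_end),
            float(seg_eq.mean()),
            best,
        )


def synteny_blocks(
    contig_a: SequenceRecord,
    contig_b: SequenceRecord,
    scheme_nuc: Optional[ScoringScheme] = None,
    min_bit: float = 50.0,
) -> list[tuple[tuple[int, int], tuple[int, int], float, str]]:
    """Qualifying ungapped nucleotide similarity blocks between two contigs,
    both strands, as (a_interval, b_interval, identity, strand) with
    0-based half-open intervals on the forward axes, sorted by a_interval.
    Overlapping blocks (on a) are resolved best-score-first."""
    scheme = scheme_nuc or default_scheme("nucleotide")
    candidates = []
    for strand, bseq in (
        ("+", contig_b.seq),
        ("-", str(Seq(contig_b.seq).reverse_complement())),
    ):
        for (a_lo, a_hi), (b_lo, b_hi), ident, raw in _diagonal_segments(
            contig_a.seq, bseq, scheme, min_bit
        ):
            if strand == "-":
                L = len(contig_b.seq)
                b_lo, b_hi = L - b_hi, L - b_lo
            candidates.append(((a_lo, a_hi), (b_lo, b_hi), ident, strand, raw))
    candidates.sort(key=lambda c: (-c[4], c[0]))
    taken: list[tuple[int, int]] = []
    blocks = []
    for a_iv, b_iv, ident, strand, _raw in candidates:
        if any(a_iv[0] < hi and lo < a_iv[1] for lo, hi in taken):
            continue
        taken.append(a_iv)
        blocks.append((a_iv, b_iv, ident, strand))
    blocks.sort(key=lambda blk: blk[0])
    return blocks
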