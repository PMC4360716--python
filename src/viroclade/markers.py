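"""Marker-gene identification and contig selection rules.

Candidate genes are screened against reference protein sets for the major
capsid protein (g23), portal protein (g20), terminase large subunit (g17)
and the auxiliary ATPase phoH. A gene is assigned the marker of its best
qualifying hit (bit score > 50, e-value < 0.001 by default). A g23 call
"passes" contig selection only if the contig is long enough (>= 10 kb by
default) and the protein displays both the N-terminal and C-terminal
domains of the reference capsid alignment; domain presence is
operationalized as >= 80% non-gap coverage of the stated column ranges,
which are 1-based columns of the reference MSA (not residue positions of
any single sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align import (
    MSA,
    PairwiseHit,
    ScoringScheme,
    bit_and_evalue,
    conservation_and_consensus,
    default_scheme,
    global_align,
    local_align,
    local_score,
    shares_kmer,
)
from .core_io import GeneCall, SequenceRecord


@dataclass
class MarkerScreenConfig:
    refsets: dict[str, list[SequenceRecord]]  # marker label -> reference proteins
    reference_msa: Optional[MSA] = None  # g23 reference alignment (domain checks)
    min_bit: float = 50.0
    max_evalue: float = 1e-3
    min_contig_len: int = 10_000
    n_domain_cols: tuple[int, int] = (122, 162)  # 1-based inclusive MSA columns
    c_domain_cols: tuple[int, int] = (735, 766)
    min_domain_cov: float = 0.8
    scheme: ScoringScheme = field(default_factory=lambda: default_scheme("protein"))

    def __post_init__(self) -> None:
        if not self.refsets or any(not v for v in self.refsets.values()):
            raise ValueError("every marker refset must be non-empty")
        if self.reference_msa is not None:
            w = self.reference_msa.n_cols
            for lo, hi in (self.n_domain_cols, self.c_domain_cols):
                if not (1 <= lo <= hi <= w):
                    raise ValueError(
                        f"domain columns ({lo},{hi}) outside reference MSA width {w}"
                    )


@dataclass
class MarkerCall:
    gene_id: str
    contig_id: str
    marker: str
    hit: PairwiseHit
    n_present: bool
    c_present: bool
    passes: bool


def check_domains(
    candidate_protein: str, reference_msa: MSA, cfg: MarkerScreenConfig
) -> tuple[bool, bool]:
    """Does the candidate cover the N- and C-terminal domain column ranges of
    the reference alignment?

    The candidate is placed onto the reference by a free-end-gap global
    alignment against the column consensus; a domain is present iff at least
    min_domain_cov of its columns receive a candidate residue."""
    cons = "".join(
        c if c != "-" else "X" for _, c in conservation_and_consensus(reference_msa)
    )
    g_cand, g_cons = global_align(
        candidate_protein, cons, cfg.scheme, free_ends=True
    )
    covered = [False] * len(cons)
    pos = 0
    for x, y in zip(g_cand, g_cons):
        if y != "-":
            covered[pos] = x != "-"
            pos += 1

    def frac(lo: int, hi: int) -> float:
        cols = covered[lo - 1 : hi]
        return sum(cols) / len(cols)

    n_lo, n_hi = cfg.n_domain_cols
    c_lo, c_hi = cfg.c_domain_cols
    return (
        frac(n_lo, n_hi) >= cfg.min_domain_cov,
        frac(c_lo, c_hi) >= cfg.min_domain_cov,
    )


def best_marker_hit(
    protein: str, cfg: MarkerScreenConfig
) -> Optional[tuple[str, str, PairwiseHit]]:
    """Best qualifying (marker, ref_id, hit) by bit score; ties break toward
    the alphabetically first reference id."""
    best: Optional[tuple[float, str, str]] = None
    for marker, refs in cfg.refsets.items():
        for ref in refs:
            if not shares_kmer(protein, ref.seq, cfg.scheme.kmer):
                continue
            raw = local_score(protein, ref.seq, cfg.scheme)
            bit, ev = bit_and_evalue(raw, cfg.scheme, len(protein), len(ref.seq))
            if bit > cfg.min_bit and ev < cfg.max_evalue:
                key = (-bit, ref.id)
                if best is None or key < (-best[0], best[2]):
                    best = (bit, marker, ref.id)
    if best is None:
        return None
    _bit, marker, ref_id = best
    ref = next(r for r in cfg.refsets[marker] if r.id == ref_id)
    hit = local_align(protein, ref.seq, cfg.scheme, subject_id=ref.id)
    return marker, ref_id, hit


def screen_markers(
    gene_calls: Sequence[GeneCall],
    cfg: MarkerScreenConfig,
    contig_lengths: dict[str, int],
) -> list[MarkerCall]:
    """Assign at most one marker per gene and apply the contig selection
    rules (contig length; both capsid domains for g23)."""
    calls: list[MarkerCall] = []
    for gene in gene_calls:
        if not gene.protein:
            continue
        found = best_marker_hit(gene.protein, cfg)
        if found is None:
            continue
        marker, _ref_id, hit = found
        hit.query_id = gene.gene_id
        n_present = c_present = True
        if marker == "g23" and cfg.reference_msa is not None:
            n_present, c_present = check_domains(gene.protein, cfg.reference_msa, cfg)
        long_enough = contig_lengths.get(gene.contig_id, 0) >= cfg.min_contig_len
        passes = long_enough and (marker != "g23" or (n_present and c_present))
        calls.append(
            MarkerCall(
                gene_id=gene.gene_id,
                contig_id=gene.contig_id,
                marker=marker,
                hit=hit,
                n_present=n_present,
                c_present=c_present,
                passes=passes,
            )
        )
    return calls


def marker_length_ratio(
    group_a_lengths: Sequence[float], group_b_lengths: Sequence[float]
) -> float:
    """Relative mean length excess of group a over group b: mean(a)/mean(b) - 1."""
    if not group_a_lengths or not group_b_lengths:
        raise ValueError("both groups must be non-empty")
    mean_a = sum(group_a_lengths) / len(group_a_lengths)
    mean_b = sum(group_b_lengths) / len(group_b_lengths)
    return mean_a / mean_b - 1.0


def write_marker_table(calls: Sequence[MarkerCall], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tcontig_id\tmarker\tbit_score\tevalue\tidentity\t"
            "n_domain\tc_domain\tpasses\n"
        )
        for c in calls:
            fh.write(
                f"{c.gene_id}\t{c.contig_id}\t{c.marker}\t{c.hit.bit_score:.1f}\t"
                f"{c.hit.evalue:.3g}\t{c.hit.identity:.3f}\t"
                f"{int(c.n_present)}\t{int(c.c_present)}\t{int(c.passes)}\n"
            )
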