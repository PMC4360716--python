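"""Composition-based host prediction, CRISPR-spacer matching, and protein
search against microbial genomes.

Phage genomes tend to drift toward the nucleotide composition of their host
(amelioration), so the Euclidean distance between tetranucleotide frequency
vectors of a phage contig and candidate host genomes carries host signal.
The distance tiers and their stated accuracies come from a published
calibration on known virus-host pairs and are treated as fixed constants:
distance < 4e-4 predicts the host family with 95% accuracy, 4e-4..1e-3 with
84%, and larger distances are not called.

4-mers are counted on the given strand only (the cited counter's default);
a strand-symmetric canonical mode is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .align import PairwiseHit, ScoringScheme, default_scheme, local_align, shares_kmer
from .core_io import SequenceRecord

HIGH_TIER_MAX = 4e-4  # strict upper bound of the 95%-accuracy tier
MODERATE_TIER_MAX = 1e-3  # strict upper bound of the 84%-accuracy tier

_LOOKUP = np.full(256, -1, dtype=np.int64)
for _i, _c in enumerate("ACGT"):
    _LOOKUP[ord(_c)] = _i


@dataclass
class TetraProfile:
    sequence_id: str
    counts: np.ndarray  # 256 ints, lexicographic 4-mer rank
    freqs: np.ndarray  # 256 floats summing to 1 (when any valid window)


@dataclass
class HostCall:
    contig_id: str
    best_host_id: str
    distance: float
    tier: str  # high_95 | moderate_84 | none
    stated_accuracy: Optional[int]  # 95, 84, or None


@dataclass
class SpacerMatch:
    spacer_id: str
    contig_id: str
    coverage: float  # aligned spacer positions / spacer length
    identity: float  # matches / alignment columns
    strand: str
    exact: bool
    passes: bool


def tetra_profile(seq: SequenceRecord | str, canonical: bool = False) -> TetraProfile:
    """Overlapping 4-mer frequency vector; windows containing N (or any
    non-ACGT base) are excluded from the counts."""
    if isinstance(seq, str):
        seq = SequenceRecord("seq", seq)
    if len(seq.seq) < 4:
        raise ValueError(f"{seq.id}: need length >= 4 for tetranucleotides")
    codes = _LOOKUP[np.frombuffer(seq.seq.upper().encode("ascii"), dtype=np.uint8)]
    n_win = len(codes) - 3
    ranks = (
        codes[:-3] * 64 + codes[1:-2] * 16 + codes[2:-1] * 4 + codes[3:]
    )
    valid = (
        (codes[:-3] >= 0) & (codes[1:-2] >= 0) & (codes[2:-1] >= 0) & (codes[3:] >= 0)
    )
    counts = np.bincount(ranks[valid], minlength=256).astype(np.int64)
    if canonical:
        rc = np.empty(256, dtype=np.int64)
        for r in range(256):
            digits = [(r >> (2 * k)) & 3 for k in (3, 2, 1, 0)]
            comp = [3 - d for d in digits][::-1]
            rc[r] = comp[0] * 64 + comp[1] * 16 + comp[2] * 4 + comp[3]
        counts = counts + counts[rc]
    total = counts.sum()
    freqs = counts / total if total else counts.astype(float)
    return TetraProfile(seq.id, counts, freqs)


def tetra_distance(p1: TetraProfile, p2: TetraProfile) -> float:
    """Euclidean (L2) distance between the frequency vectors."""
    return float(np.linalg.norm(p1.freqs - p2.freqs))


def host_tier(distance: float) -> tuple[str, Optional[int]]:
    """Calibrated distance tier: strictly below 4e-4 -> 95%-accuracy call,
    [4e-4, 1e-3) -> 84%-accuracy call, otherwise no call."""
    if distance < 0:
        raise ValueError("distance must be >= 0")
    if distance < HIGH_TIER_MAX:
        return "high_95", 95
    if distance < MODERATE_TIER_MAX:
        return "moderate_84", 84
    return "none", None


def predict_host(
    contig: SequenceRecord | TetraProfile,
    host_profiles: Sequence[TetraProfile],
) -> HostCall:
    """Nearest host genome in tetranucleotide space; ties break toward the
    alphabetically first host id. The best host is reported even when the
    distance is too large for a calibrated call (tier 'none')."""
    if not host_profiles:
        raise ValueError("need at least one host genome")
    prof = contig if isinstance(contig, TetraProfile) else tetra_profile(contig)
    best = min(
        host_profiles, key=lambda hp: (tetra_distance(prof, hp), hp.sequence_id)
    )
    d = tetra_distance(prof, best)
    tier, acc = host_tier(d)
    return HostCall(prof.sequence_id, best.sequence_id, d, tier, acc)


def match_spacer(
    spacer: SequenceRecord,
    contig: SequenceRecord,
    scheme_nuc: Optional[ScoringScheme] = None,
) -> SpacerMatch:
    """Best local alignment of a CRISPR spacer on either strand of a contig.

    Significance follows the short-sequence rule: coverage > 80% of the
    spacer and identity > 90%. The exact flag (full-length, 100% identity)
    marks the only matches short spacers can truly be trusted on."""
    if len(spacer.seq) < 15:
        raise ValueError(f"{spacer.id}: spacer shorter than 15 nt")
    scheme = scheme_nuc or default_scheme("nucleotide")
    best_hit: Optional[PairwiseHit] = None
    best_strand = "+"
    for strand, sseq in (
        ("+", spacer.seq),
        ("-", str(Seq(spacer.seq).reverse_complement())),
    ):
        hit = local_align(sseq, contig.seq, scheme, spacer.id, contig.id)
        if best_hit is None or hit.raw_score > best_hit.raw_score:
            best_hit = hit
            best_strand = strand
    aligned = sum(1 for c in best_hit.aligned_query if c != "-")
    coverage = aligned / len(spacer.seq)
    identity = best_hit.identity
    exact = coverage == 1.0 and identity == 1.0
    return SpacerMatch(
        spacer_id=spacer.id,
        contig_id=contig.id,
        coverage=coverage,
        identity=identity,
        strand=best_strand,
        exact=exact,
        passes=coverage > 0.8 and identity > 0.9,
    )


def search_microbial_genomes(
    contig_proteins: Sequence[SequenceRecord],
    microbial_proteins: dict[str, list[SequenceRecord]],
    scheme: Optional[ScoringScheme] = None,
    min_bit: float = 50.0,
    max_evalue: float = 1e-3,
) -> tuple[list[PairwiseHit], dict[str, float]]:
    """Best qualifying hit per contig protein against per-genome microbial
    protein sets; the summary maps genome id -> maximum amino-acid identity.
    """
    scheme = scheme or default_scheme("protein")
    if not contig_proteins or not microbial_proteins:
        raise ValueError("protein sets must be non-empty")
    hits: list[PairwiseHit] = []
    summary: dict[str, float] = {}
    for prot in contig_proteins:
        best: Optional[tuple[PairwiseHit, str]] = None
        for genome_id in sorted(microbial_proteins):
            for ref in microbial_proteins[genome_id]:
                if not shares_kmer(prot.seq, ref.seq, scheme.kmer):
                    continue
                hit = local_align(prot.seq, ref.seq, scheme, prot.id, ref.id)
                if hit.bit_score > min_bit and hit.evalue < max_evalue:
                    if best is None or hit.bit_score > best[0].bit_score:
                        best = (hit, genome_id)
        if best is not None:
            hit, genome_id = best
            hits.append(hit)
            summary[genome_id] = max(summary.get(genome_id, 0.0), hit.identity)
    return hits, summary


def write_host_calls(calls: Sequence[HostCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tbest_host_id\tdistance\ttier\tstated_accuracy\n")
        for c in calls:
            acc = "NA" if c.stated_accuracy is None else str(c.stated_accuracy)
            fh.write(
                f"{c.contig_id}\t{c.best_host_id}\t{c.distance:.6g}\t{c.tier}\t{acc}\n"
            )


def write_spacer_matches(matches: Sequence[SpacerMatch], path) -> None:
    with open(path, "w") as fh:
        fh.write("spacer_id\tcontig_id\tcoverage\tidentity\tstrand\texact\tpasses\n")
        for m in matches:
            fh.write(
                f"{m.spacer_id}\t{m.contig_id}\t{m.coverage:.4f}\t{m.identity:.4f}\t"
                f"{m.strand}\t{int(m.exact)}\t{int(m.passes)}\n"
            )
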