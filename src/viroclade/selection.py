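"""Counting-method dN/dS (Nei-Gojobori 1986) on codon alignments.

For each codon, every position contributes the fraction of its three
possible nucleotide changes that are synonymous; changes creating a stop
codon count as nonsynonymous (they sit in the denominator). Observed
differences between codon pairs are averaged over all mutational pathways
with equal weight, excluding pathways that pass through a stop codon.
Proportions are Jukes-Cantor corrected, d = -3/4 ln(1 - 4p/3), and
omega = dN/dS (undefined when dS = 0).

This is a descriptive counting estimator: it deliberately does not fit
maximum-likelihood codon models (site classes, branch models, likelihood
ratio tests). The group comparison mirrors a two-ratio branch question as
within-group means of pairwise omega.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .align import MSA

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"
SENSE_CODONS = sorted(_CODON_TABLE)


@dataclass
class DnDsResult:
    label: str
    S: float  # synonymous sites
    N: float  # nonsynonymous sites
    Sd: float  # observed synonymous differences
    Nd: float  # observed nonsynonymous differences
    pS: float
    pN: float
    dS: Optional[float]  # None when the JC correction is undefined (p >= 3/4)
    dN: Optional[float]
    omega: Optional[float]  # None when dS == 0 (undefined)
    omega_flag: str  # "", "identical", or "dS_zero"


def _check_codon_seq(seq: str, label: str) -> list[str]:
    if len(seq) % 3:
        raise ValueError(f"{label}: length {len(seq)} is not a multiple of 3")
    codons = [seq[i : i + 3].upper() for i in range(0, len(seq), 3)]
    for i, c in enumerate(codons):
        if c in _STOPS:
            raise ValueError(f"{label}: internal stop codon {c} at codon {i}")
        if any(b not in _BASES for b in c):
            raise ValueError(f"{label}: non-ACGT codon {c} at codon {i}")
    return codons


def synonymous_sites(codon: str) -> float:
    """NG86 synonymous site count of one codon (0..3); changes to stop
    codons are nonsynonymous."""
    aa = _CODON_TABLE[codon]
    syn = 0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in _STOPS and _CODON_TABLE[alt] == aa:
                syn += 1
    return syn / 3.0


def _pathway_diffs(ca: str, cb: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    with equal weight over all orderings of the changed positions; pathways
    through stop codons are excluded."""
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = ca
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                ok = False
                break
            if _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:
        # all pathways blocked by stops: fall back to including them
        for order in permutations(diff_pos):
            cur = ca
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if nxt in _STOPS or _CODON_TABLE.get(cur) != _CODON_TABLE.get(nxt):
                    nd += 1
                else:
                    sd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jc(p: float) -> Optional[float]:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1 - 4 * p / 3)


def ng86_pair(
    codon_seq_a: str, codon_seq_b: str, label: str = "pair"
) -> DnDsResult:
    """Nei-Gojobori (1986) pairwise dN/dS with Jukes-Cantor correction."""
    if len(codon_seq_a) != len(codon_seq_b):
        raise ValueError(
            f"codon sequences differ in length: {len(codon_seq_a)} vs {len(codon_seq_b)}"
        )
    cod_a = _check_codon_seq(codon_seq_a, "sequence a")
    cod_b = _check_codon_seq(codon_seq_b, "sequence b")
    S = sum((synonymous_sites(a) + synonymous_sites(b)) / 2 for a, b in zip(cod_a, cod_b))
    N = 3 * len(cod_a) - S
    Sd = Nd = 0.0
    for a, b in zip(cod_a, cod_b):
        sd, nd = _pathway_diffs(a, b)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jc(pS)
    dN = _jc(pN)
    if Sd == 0 and Nd == 0:
        return DnDsResult(label, S, N, Sd, Nd, pS, pN, dS, dN, None, "identical")
    if dS is not None and dS > 0:
        omega = None if dN is None else dN / dS
        flag = "" if omega is not None else "dN_saturated"
        return DnDsResult(label, S, N, Sd, Nd, pS, pN, dS, dN, omega, flag)
    if dS is None:
        # synonymous changes saturated the JC correction; the ratio is still
        # determined (0) when no nonsynonymous change was seen at all
        if dN == 0:
            return DnDsResult(label, S, N, Sd, Nd, pS, pN, dS, dN, 0.0, "dS_saturated")
        return DnDsResult(label, S, N, Sd, Nd, pS, pN, dS, dN, None, "dS_saturated")
    return DnDsResult(label, S, N, Sd, Nd, pS, pN, dS, dN, None, "dS_zero")


def group_dnds(
    codon_msa: MSA, group_ids: Sequence[str]
) -> tuple[Optional[float], Optional[float], dict[str, int]]:
    """Mean pairwise omega within a designated group and within the rest.

    Gap-containing or undefined pairs are excluded and counted; returns
    (omega_group, omega_rest, excluded counts)."""
    ids = codon_msa.ids
    group = [i for i in ids if i in set(group_ids)]
    rest = [i for i in ids if i not in set(group_ids)]
    if len(group) < 2 or len(rest) < 2:
        raise ValueError("both partitions need at least 2 sequences")
    excluded = {"group": 0, "rest": 0}

    def mean_omega(members: list[str], key: str) -> Optional[float]:
        omegas = []
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a = codon_msa.row(members[i])
                b = codon_msa.row(members[j])
                keep = [
                    k
                    for k in range(0, len(a) - 2, 3)
                    if "-" not in a[k : k + 3] + b[k : k + 3]
                ]
                ca = "".join(a[k : k + 3] for k in keep)
                cb = "".join(b[k : k + 3] for k in keep)
                if not ca:
                    excluded[key] += 1
                    continue
                res = ng86_pair(ca, cb)
                if res.omega is None:
                    excluded[key] += 1
                else:
                    omegas.append(res.omega)
        return sum(omegas) / len(omegas) if omegas else None

    return mean_omega(group, "group"), mean_omega(rest, "rest"), excluded


def write_dnds_table(results: Sequence[DnDsResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("label\tS\tN\tSd\tNd\tpS\tpN\tdS\tdN\tomega\tflag\n")
        for r in results:
            def fmt(x):
                return "NA" if x is None else f"{x:.6g}"
            fh.write(
                f"{r.label}\t{r.S:.4f}\t{r.N:.4f}\t{r.Sd:.4f}\t{r.Nd:.4f}\t"
                f"{r.pS:.6g}\t{r.pN:.6g}\t{fmt(r.dS)}\t{fmt(r.dN)}\t{fmt(r.omega)}\t{r.omega_flag}\n"
            )
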