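"""Pairwise and multiple alignment with BLAST-like score statistics.

The workhorse is an exact affine-gap Smith-Waterman with an optional k-mer
prefilter, standing in for the heuristic seed-and-extend searches used in
large-scale annotation (blastp/blastn/tblastx). Raw scores are converted to
bit scores and e-values with the Karlin-Altschul formulas

    S' = (lambda * S - ln K) / ln 2        E = m * n * 2**(-S')

using standard gapped constants; the search space is m x n per pair (the
comparisons here are pairwise, not database-wide).

Gap convention: a gap of length L costs gap_open + L * gap_extend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

GAP = "-"
_NEG = -(1 << 40)


class AlphabetError(ValueError):
    """Sequence contains a residue outside the scoring scheme's alphabet."""


def _blosum62() -> tuple[str, np.ndarray]:
    mat = substitution_matrices.load("BLOSUM62")
    alphabet = str(mat.alphabet)
    return alphabet, np.array(mat).astype(np.int64)


def _nuc_matrix(match: int = 2, mismatch: int = -3) -> tuple[str, np.ndarray]:
    # N scores as a mismatch against everything (including N); masked or
    # ambiguous stretches therefore never contribute positive score.
    alphabet = "ACGTN"
    m = np.full((5, 5), mismatch, dtype=np.int64)
    np.fill_diagonal(m, match)
    m[4, :] = mismatch
    m[:, 4] = mismatch
    return alphabet, m


@dataclass
class ScoringScheme:
    """Substitution matrix plus gap and Karlin-Altschul parameters."""

    name: str
    alphabet: str
    matrix: np.ndarray
    gap_open: int
    gap_extend: int
    lam: float
    K: float
    kmer: int  # prefilter word size

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        self._lookup = np.full(256, -1, dtype=np.int64)
        for i, c in enumerate(self.alphabet):
            self._lookup[ord(c)] = i

    def encode(self, seq: str) -> np.ndarray:
        codes = self._lookup[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        if (codes < 0).any():
            bad = sorted({c for c in seq if self._lookup[ord(c)] < 0})
            raise AlphabetError(f"residues {bad} not in {self.name} alphabet")
        return codes

    @classmethod
    def protein_default(cls) -> "ScoringScheme":
        """BLOSUM62, gap 11/1, standard gapped constants (lambda 0.267, K 0.041)."""
        alphabet, mat = _blosum62()
        return cls("blosum62", alphabet, mat, 11, 1, 0.267, 0.041, kmer=4)

    @classmethod
    def nucleotide_default(cls) -> "ScoringScheme":
        """match +2 / mismatch -3, gap 5/2, gapped constants for that scheme."""
        alphabet, mat = _nuc_matrix()
        return cls("nuc+2/-3", alphabet, mat, 5, 2, 0.625, 0.41, kmer=11)


@lru_cache(maxsize=4)
def default_scheme(kind: str) -> ScoringScheme:
    if kind == "protein":
        return ScoringScheme.protein_default()
    if kind == "nucleotide":
        return ScoringScheme.nucleotide_default()
    raise ValueError(f"unknown scheme kind {kind!r}")


@dataclass
class PairwiseHit:
    """A local alignment between two sequences with BLAST-like statistics."""

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    identity: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    aligned_query: str
    aligned_subject: str

    @property
    def length(self) -> int:
        return len(self.aligned_query)


def bit_and_evalue(
    raw_score: int, scheme: ScoringScheme, m: int, n: int
) -> tuple[float, float]:
    """Karlin-Altschul bit score and e-value for a raw score in search space m*n."""
    if raw_score < 0:
        raise ValueError("raw_score must be >= 0")
    bit = (scheme.lam * raw_score - math.log(scheme.K)) / math.log(2)
    evalue = m * n * 2.0 ** (-bit)
    return bit, evalue


# ---------------------------------------------------------------------------
# Affine-gap Smith-Waterman (exact, with deterministic tie-breaks)
# ---------------------------------------------------------------------------

def _sw_fill(a: np.ndarray, b: np.ndarray, scheme: ScoringScheme):
    """Fill the three affine-gap DP matrices.

    M[i,j]: best local alignment ending with a[i-1] aligned to b[j-1].
    X[i,j]: ending with a gap in the subject (consuming a).
    Y[i,j]: ending with a gap in the query (consuming b).
    Gap states open only from M (adjacent opposite gaps are never optimal
    under these penalties).
    """
    m, n = len(a), len(b)
    go, ge = scheme.gap_open, scheme.gap_extend
    M = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    X = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    Y = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    jj = np.arange(n, dtype=np.int64)
    for i in range(1, m + 1):
        sub = scheme.matrix[a[i - 1], b]
        prev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        prev = np.maximum(prev, 0)
        M[i, 1:] = sub + prev[:-1]
        X[i] = np.maximum(M[i - 1] - go - ge, X[i - 1] - ge)
        # Y chains within the row: Y[i,j] = max_{k<j} M[i,k] - go - (j-k)*ge
        run = np.maximum.accumulate(M[i, :-1] + ge * jj)
        Y[i, 1:] = run - go - ge * (jj + 1)
        Y[i, 0] = _NEG
    return M, X, Y


def _sw_traceback(a_seq, b_seq, M, X, Y, scheme, i, j):
    """Trace one optimal local alignment ending at M[i,j].

    Tie preference: diagonal, then up (gap in subject), then left."""
    go, ge = scheme.gap_open, scheme.gap_extend
    qa, qb = [], []
    state = "M"
    while True:
        if state == "M":
            qa.append(a_seq[i - 1])
            qb.append(b_seq[j - 1])
            best = max(0, M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            i, j = i - 1, j - 1
            if M[i, j] == best:
                state = "M"
            elif X[i, j] == best:
                state = "X"
            elif Y[i, j] == best:
                state = "Y"
            else:
                break
        elif state == "X":
            qa.append(a_seq[i - 1])
            qb.append(GAP)
            if X[i, j] == M[i - 1, j] - go - ge:
                state = "M"
            i -= 1
        else:
            qa.append(GAP)
            qb.append(b_seq[j - 1])
            if Y[i, j] == M[i, j - 1] - go - ge:
                state = "M"
            j -= 1
    return i, j, "".join(reversed(qa)), "".join(reversed(qb))


def local_align(
    a: str,
    b: str,
    scheme: Optional[ScoringScheme] = None,
    query_id: str = "query",
    subject_id: str = "subject",
    search_m: Optional[int] = None,
    search_n: Optional[int] = None,
) -> PairwiseHit:
    """Optimal Smith-Waterman local alignment with affine gaps.

    Deterministic: the end cell is the highest-scoring cell with smallest
    (q_end, s_end) lexicographically, and the traceback prefers diagonal,
    then up, then left. An all-negative comparison yields the empty
    alignment with raw score 0.
    """
    scheme = scheme or default_scheme("protein")
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ac, bc = scheme.encode(a), scheme.encode(b)
    M, X, Y = _sw_fill(ac, bc, scheme)
    raw = int(max(M.max(), 0))
    if raw == 0:
        bit, ev = bit_and_evalue(0, scheme, search_m or len(a), search_n or len(b))
        return PairwiseHit(query_id, subject_id, 0, bit, ev, 0.0, 0, 0, 0, 0, "", "")
    end = np.unravel_index(int(np.argmax(M)), M.shape)  # row-major: smallest (i, j)
    i0, j0, qa, qb = _sw_traceback(a, b, M, X, Y, scheme, int(end[0]), int(end[1]))
    matches = sum(1 for x, y in zip(qa, qb) if x == y and x != GAP)
    bit, ev = bit_and_evalue(raw, scheme, search_m or len(a), search_n or len(b))
    return PairwiseHit(
        query_id,
        subject_id,
        raw,
        bit,
        ev,
        matches / len(qa),
        i0,
        int(end[0]),
        j0,
        int(end[1]),
        qa,
        qb,
    )


def local_score(a: str, b: str, scheme: Optional[ScoringScheme] = None) -> int:
    """Optimal local alignment raw score only (rolling rows; no traceback)."""
    scheme = scheme or default_scheme("protein")
    ac, bc = scheme.encode(a), scheme.encode(b)
    go, ge = scheme.gap_open, scheme.gap_extend
    n = len(bc)
    M = np.full(n + 1, _NEG, dtype=np.int64)
    X = np.full(n + 1, _NEG, dtype=np.int64)
    Y = np.full(n + 1, _NEG, dtype=np.int64)
    newM = np.full(n + 1, _NEG, dtype=np.int64)
    prev = np.empty(n + 1, dtype=np.int64)
    tmp = np.empty(n, dtype=np.int64)
    ramp_in = ge * np.arange(n, dtype=np.int64)
    ramp_out = go + ge * np.arange(1, n + 1, dtype=np.int64)
    sub = scheme.matrix[:, bc]
    best = 0
    for i in range(len(ac)):
        np.maximum(M, X, out=prev)
        np.maximum(prev, Y, out=prev)
        np.maximum(prev, 0, out=prev)
        np.add(sub[ac[i]], prev[:-1], out=newM[1:])
        np.subtract(M, go + ge, out=prev)  # prev reused as scratch
        np.subtract(X, ge, out=X)
        np.maximum(X, prev, out=X)
        np.add(newM[:-1], ramp_in, out=tmp)
        np.maximum.accumulate(tmp, out=tmp)
        np.subtract(tmp, ramp_out, out=Y[1:])
        M, newM = newM, M
        m = int(M.max())
        if m > best:
            best = m
    return best


# ---------------------------------------------------------------------------
# k-mer prefilter and seeded alignment for long subjects
# ---------------------------------------------------------------------------

def shares_kmer(a: str, b: str, k: int) -> bool:
    if len(a) < k or len(b) < k:
        return False
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    return any(b[j : j + k] in kmers for j in range(len(b) - k + 1))


def _seed_windows(a: str, b: str, k: int, margin: int) -> list[tuple[int, int]]:
    """Diagonal-clustered windows of b containing shared k-mers with a."""
    index: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        index.setdefault(a[i : i + k], []).append(i)
    diags: dict[int, list[int]] = {}
    for j in range(len(b) - k + 1):
        for i in index.get(b[j : j + k], ()):
            diags.setdefault(j - i, []).append(j)
    if not diags:
        return []
    # merge nearby diagonals into (lo, hi) subject windows
    spans = []
    for d, js in diags.items():
        spans.append((min(js) - margin, max(js) + k + margin))
    spans.sort()
    merged = [list(spans[0])]
    for lo, hi in spans[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(max(0, lo), min(len(b), hi)) for lo, hi in merged]


def seeded_local_align(
    a: str,
    b: str,
    scheme: Optional[ScoringScheme] = None,
    query_id: str = "query",
    subject_id: str = "subject",
    margin: Optional[int] = None,
) -> Optional[PairwiseHit]:
    """Best local alignment of a against a long b, restricted to windows of b
    around shared k-mers (word size from the scheme). Returns None when no
    seed exists. Subject coordinates refer to the full b."""
    scheme = scheme or default_scheme("protein")
    margin = margin if margin is not None else max(2 * len(a), 64)
    best: Optional[PairwiseHit] = None
    for lo, hi in _seed_windows(a, b, scheme.kmer, margin):
        hit = local_align(
            a,
            b[lo:hi],
            scheme,
            query_id,
            subject_id,
            search_m=len(a),
            search_n=len(b),
        )
        if hit.raw_score == 0:
            continue
        hit.s_start += lo
        hit.s_end += lo
        if best is None or (hit.raw_score, -hit.s_start) > (best.raw_score, -best.s_start):
            best = hit
    return best


# ---------------------------------------------------------------------------
# Multiple alignment
# ---------------------------------------------------------------------------

@dataclass
class MSA:
    """Ordered gapped rows of equal length; ungapping a row reproduces its
    input sequence."""

    rows: list[tuple[str, str]]
    flagged: set[str] = field(default_factory=set)  # e.g. rows all-gap after trimming

    def __post_init__(self) -> None:
        widths = {len(s) for _, s in self.rows}
        if len(widths) > 1:
            raise ValueError(f"ragged MSA: row lengths {sorted(widths)}")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, rid: str) -> str:
        for r, s in self.rows:
            if r == rid:
                return s
        raise KeyError(rid)

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace(GAP, "")


def read_msa(path: str | Path) -> MSA:
    from . import core_io

    return MSA([(r.id, r.seq) for r in core_io.read_fasta(path)])


def write_msa(msa: MSA, path: str | Path) -> None:
    from . import core_io

    core_io.write_fasta(
        [core_io.SequenceRecord(rid, seq) for rid, seq in msa.rows], path
    )


def _column_freqs(rows: Sequence[str], scheme: ScoringScheme) -> np.ndarray:
    """(n_cols, alphabet) frequency matrix; gap characters carry no mass."""
    A = len(scheme.alphabet)
    n_cols = len(rows[0])
    freqs = np.zeros((n_cols, A))
    for row in rows:
        codes = scheme._lookup[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]
        ok = codes >= 0
        freqs[np.nonzero(ok)[0], codes[ok]] += 1.0
    return freqs / len(rows)


def _profile_align(
    rows_a: list[str],
    rows_b: list[str],
    scheme: ScoringScheme,
    free_ends: bool = False,
) -> tuple[list[str], list[str]]:
    """Global (Needleman-Wunsch, affine) alignment of two profiles.

    Column score is the expected substitution score between residues drawn
    from the two columns. With free_ends, terminal gaps are unpenalized
    (used to place a fragment onto a reference profile)."""
    go, ge = float(scheme.gap_open), float(scheme.gap_extend)
    fa = _column_freqs(rows_a, scheme)
    fb = _column_freqs(rows_b, scheme)
    S = fa @ scheme.matrix.astype(float) @ fb.T
    m, n = S.shape
    NEG = -1e18
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)  # gap in b (consume a)
    Y = np.full((m + 1, n + 1), NEG)  # gap in a (consume b)
    M[0, 0] = 0.0
    ii = np.arange(1, m + 1)
    jj = np.arange(1, n + 1)
    if free_ends:
        X[1:, 0] = 0.0
        Y[0, 1:] = 0.0
    else:
        X[1:, 0] = -go - ge * ii
        Y[0, 1:] = -go - ge * jj
    jj0 = np.arange(n)
    for i in range(1, m + 1):
        best_prev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = S[i - 1] + best_prev[:-1]
        X[i, 1:] = np.maximum(M[i - 1, 1:] - go - ge, X[i - 1, 1:] - ge)
        # Y chains within the row from M (gap in a opens only after a match)
        run = np.maximum.accumulate(M[i, :-1] + ge * jj0)
        Y[i, 1:] = run - go - ge * (jj0 + 1)
    cols: list[tuple[bool, bool]] = []  # (consume a, consume b), built backwards
    if free_ends:
        # best end anywhere on the last row or column; the rest is free gaps
        cand = [(max(M[i_, n], X[i_, n], Y[i_, n]), i_, n) for i_ in range(m + 1)]
        cand += [(max(M[m, j_], X[m, j_], Y[m, j_]), m, j_) for j_ in range(n + 1)]
        _, ei, ej = max(cand, key=lambda t: (t[0], t[1] + t[2]))
        for _ in range(n - ej):
            cols.append((False, True))
        for _ in range(m - ei):
            cols.append((True, False))
        i, j = ei, ej
    else:
        i, j = m, n
    vals = {"M": M[i, j], "X": X[i, j], "Y": Y[i, j]}
    state = max(("M", "X", "Y"), key=lambda s: vals[s])
    eps = 1e-9
    while i > 0 or j > 0:
        if i == 0:
            cols.append((False, True))
            j -= 1
            continue
        if j == 0:
            cols.append((True, False))
            i -= 1
            continue
        if state == "M":
            cols.append((True, True))
            prev = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            if abs(M[i, j] - prev) < eps:
                state = "M"
            elif abs(X[i, j] - prev) < eps:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            cols.append((True, False))
            if abs(X[i, j] - (M[i - 1, j] - go - ge)) < eps:
                state = "M"
            i -= 1
        else:
            cols.append((False, True))
            if abs(Y[i, j] - (M[i, j - 1] - go - ge)) < eps:
                state = "M"
            j -= 1
    cols.reverse()
    out_a = []
    out_b = []
    ai = bi = 0
    pat_a, pat_b = [], []
    for ca, cb in cols:
        pat_a.append(ai if ca else None)
        pat_b.append(bi if cb else None)
        ai += ca
        bi += cb
    for row in rows_a:
        out_a.append("".join(row[p] if p is not None else GAP for p in pat_a))
    for row in rows_b:
        out_b.append("".join(row[p] if p is not None else GAP for p in pat_b))
    return out_a, out_b


def global_align(a: str, b: str, scheme: Optional[ScoringScheme] = None,
                 free_ends: bool = False) -> tuple[str, str]:
    """Global pairwise alignment (profile engine specialised to 1-row profiles)."""
    scheme = scheme or default_scheme("protein")
    (ga,), (gb,) = _profile_align([a], [b], scheme, free_ends=free_ends)
    return ga, gb


def _kmer_distance(seqs: Sequence[str], k: int) -> np.ndarray:
    """1 - fraction of shared k-mers (over the smaller k-mer set)."""
    sets = [
        {s[i : i + k] for i in range(max(0, len(s) - k + 1))} or {s} for s in seqs
    ]
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j]))
            frac = len(sets[i] & sets[j]) / denom if denom else 0.0
            D[i, j] = D[j, i] = 1.0 - frac
    return D


def progressive_msa(
    seqs: Sequence[tuple[str, str]], scheme: Optional[ScoringScheme] = None
) -> MSA:
    """Progressive multiple alignment: k-mer distance guide tree (average
    linkage) with profile-profile global merges. Row order equals input order.
    """
    scheme = scheme or default_scheme("protein")
    seqs = list(seqs)
    if not seqs:
        raise ValueError("progressive_msa requires at least one sequence")
    if len(seqs) == 1:
        return MSA([(seqs[0][0], seqs[0][1])])
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    D = _kmer_distance([s for _, s in seqs], k=3)
    Z = linkage(squareform(D, checks=False), method="average")
    profiles: dict[int, tuple[list[str], list[str]]] = {
        i: ([rid], [seq]) for i, (rid, seq) in enumerate(seqs)
    }
    nxt = len(seqs)
    for za, zb, _, _ in Z:
        ids_a, rows_a = profiles.pop(int(za))
        ids_b, rows_b = profiles.pop(int(zb))
        new_a, new_b = _profile_align(rows_a, rows_b, scheme)
        profiles[nxt] = (ids_a + ids_b, new_a + new_b)
        nxt += 1
    ids, rows = profiles.popitem()[1]
    by_id = dict(zip(ids, rows))
    return MSA([(rid, by_id[rid]) for rid, _ in seqs])


def trim_msa(msa: MSA, start_col: int, end_col: int) -> MSA:
    """Column slice [start_col, end_col); rows that become all-gap are kept
    but flagged."""
    if not (0 <= start_col < end_col <= msa.n_cols):
        raise ValueError(
            f"trim range [{start_col},{end_col}) outside 0..{msa.n_cols}"
        )
    rows = [(rid, seq[start_col:end_col]) for rid, seq in msa.rows]
    flagged = {rid for rid, seq in rows if set(seq) == {GAP}}
    return MSA(rows, flagged=flagged)


def conservation_and_consensus(msa: MSA) -> list[tuple[float, str]]:
    """Per column: (modal-count / non-gap count, modal non-gap residue).

    Ties resolve alphabetically; all-gap columns give (0.0, '-')."""
    if len(msa.rows) < 2:
        raise ValueError("conservation requires at least 2 rows")
    out = []
    for col in range(msa.n_cols):
        counts: dict[str, int] = {}
        for _, seq in msa.rows:
            c = seq[col]
            if c != GAP:
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            out.append((0.0, GAP))
            continue
        total = sum(counts.values())
        best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0])))
        out.append((best[1] / total, best[0]))
    return out


# ---------------------------------------------------------------------------
# 12-column hit table (1-based inclusive coordinates, this format only)
# ---------------------------------------------------------------------------

def write_hit_table(hits: Iterable[PairwiseHit], path: str | Path) -> None:
    cols = "query subject pident length mismatches gapopens qstart qend sstart send evalue bitscore".split()
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for h in hits:
            gaps = 0
            for row in (h.aligned_query, h.aligned_subject):
                in_gap = False
                for c in row:
                    if c == GAP and not in_gap:
                        gaps += 1
                    in_gap = c == GAP
            mism = sum(
                1
                for x, y in zip(h.aligned_query, h.aligned_subject)
                if x != GAP and y != GAP and x != y
            )
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{100 * h.identity:.2f}",
                        str(h.length),
                        str(mism),
                        str(gaps),
                        str(h.q_start + 1),
                        str(h.q_end),
                        str(h.s_start + 1),
                        str(h.s_end),
                        f"{h.evalue:.3g}",
                        f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )
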