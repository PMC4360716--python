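"""Domain types, file formats, and elementary read preprocessing.

Internal coordinates are 0-based half-open everywhere; GFF3 on disk is
1-based inclusive and is converted at the boundary. Nucleotide sequences are
uppercase over {A,C,G,T,N}; ambiguous bases are permitted and operations
that cannot handle them state their policy individually.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq

NUC_ALPHABET = set("ACGTN")


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line."""


@dataclass
class SequenceRecord:
    """A named nucleotide or protein sequence with optional phred qualities."""

    id: str
    seq: str
    desc: str = ""
    quals: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if self.quals is not None and len(self.quals) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: {len(self.quals)} qualities for "
                f"{len(self.seq)} bases"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(
            id=self.id,
            seq=str(Seq(self.seq).reverse_complement()),
            desc=self.desc,
            quals=None if self.quals is None else self.quals[::-1],
        )


@dataclass
class GeneCall:
    """A located, stranded gene on a contig with its protein translation."""

    contig_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # '+' or '-'
    gene_id: str
    protein: str
    annotation: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: bad interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")


@dataclass
class ContigTableRow:
    """One row of the published contig summary table."""

    dataset: str
    sequence_id: str
    length: int
    clade: str
    markers: set[str] = field(default_factory=set)
    phoH: bool = False
    crispr_host: Optional[str] = None
    tetra_host: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.sequence_id}: length must be positive")


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (sequences uppercased).

    Raises ParseError (naming the line) for empty files, text before the
    first header, or duplicate record ids.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    header: Optional[str] = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        fields = header.split(None, 1)
        if not fields:
            raise ParseError(f"{path}:{header_line}: empty FASTA header")
        rid = fields[0]
        if rid in seen:
            raise ParseError(
                f"{path}:{header_line}: duplicate sequence id {rid!r} "
                f"(first seen at line {seen[rid]})"
            )
        seen[rid] = header_line
        records.append(
            SequenceRecord(
                id=rid,
                seq="".join(chunks).upper(),
                desc=fields[1] if len(fields) > 1 else "",
            )
        )

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError(f"{path}:{lineno}: sequence data before first '>' header")
                chunks.append(line.strip())
    flush()
    if not records:
        raise ParseError(f"{path}:1: empty FASTA file")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id}" + (f" {rec.desc}" if rec.desc else "")
            fh.write(head + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read 4-line phred+33 FASTQ; raises ParseError on truncation or
    sequence/quality length mismatch."""
    path = Path(path)
    records: list[SequenceRecord] = []
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    while lines and not lines[-1].strip():
        lines.pop()
    if not lines:
        raise ParseError(f"{path}:1: empty FASTQ file")
    if len(lines) % 4:
        raise ParseError(f"{path}:{len(lines)}: truncated FASTQ record")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        lineno = i + 1
        if not head.startswith("@"):
            raise ParseError(f"{path}:{lineno}: FASTQ header must start with '@'")
        if not plus.startswith("+"):
            raise ParseError(f"{path}:{lineno + 2}: FASTQ separator must start with '+'")
        if len(seq) != len(qual):
            raise ParseError(
                f"{path}:{lineno + 3}: quality length {len(qual)} != sequence length {len(seq)}"
            )
        fields = head[1:].split(None, 1)
        records.append(
            SequenceRecord(
                id=fields[0],
                seq=seq.upper(),
                desc=fields[1] if len(fields) > 1 else "",
                quals=[ord(c) - 33 for c in qual],
            )
        )
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.quals is None:
                raise ValueError(f"record {rec.id!r} has no qualities; cannot write FASTQ")
            head = f"@{rec.id}" + (f" {rec.desc}" if rec.desc else "")
            qual = "".join(chr(q + 33) for q in rec.quals)
            fh.write(f"{head}\n{rec.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# GFF3 (type=CDS, attribute ID=gene_id) -- 1-based inclusive on disk
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path, proteins: Optional[dict[str, str]] = None) -> list[GeneCall]:
    """Read CDS features from GFF3. `proteins` optionally maps gene_id to its
    translation (from a companion protein FASTA)."""
    path = Path(path)
    calls: list[GeneCall] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "CDS":
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attr_map.get("ID")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: CDS without ID attribute")
            annotation = attr_map.get("annotation") or None
            calls.append(
                GeneCall(
                    contig_id=seqid,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    gene_id=gene_id,
                    protein=(proteins or {}).get(gene_id, ""),
                    annotation=annotation,
                )
            )
    return calls


def write_gff3(calls: Iterable[GeneCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gc in calls:
            attrs = f"ID={gc.gene_id}"
            if gc.annotation:
                attrs += f";annotation={gc.annotation}"
            fh.write(
                "\t".join(
                    [
                        gc.contig_id,
                        "viroclade",
                        "CDS",
                        str(gc.start + 1),
                        str(gc.end),
                        ".",
                        gc.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

CONTIG_TABLE_COLUMNS = [
    "dataset",
    "sequence_id",
    "length",
    "clade",
    "markers",
    "phoH",
    "crispr_host",
    "tetra_host",
]


def read_contig_table(path: str | Path) -> list[ContigTableRow]:
    """Read a contig summary table (TSV with the published column schema)."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != CONTIG_TABLE_COLUMNS:
            raise ParseError(
                f"{path}:1: expected columns {CONTIG_TABLE_COLUMNS}, got {reader.fieldnames}"
            )
        rows = []
        for rec in reader:
            markers = {
                m.strip().replace(" (partial)", "")
                for m in rec["markers"].split(";")
                if m.strip()
            }
            rows.append(
                ContigTableRow(
                    dataset=rec["dataset"],
                    sequence_id=rec["sequence_id"],
                    length=int(rec["length"]),
                    clade=rec["clade"],
                    markers=markers,
                    phoH=rec["phoH"].strip() == "+",
                    crispr_host=rec["crispr_host"].strip() or None,
                    tetra_host=rec["tetra_host"].strip() or None,
                )
            )
    if not rows:
        raise ParseError(f"{path}:1: contig table has no rows")
    return rows


def write_matrix_tsv(ids: Sequence[str], matrix, path: str | Path) -> None:
    """Write a square labelled matrix as TSV (header row and column of ids)."""
    with open(path, "w") as fh:
        fh.write("\t".join([""] + list(ids)) + "\n")
        for i, rid in enumerate(ids):
            fh.write("\t".join([rid] + [repr(float(v)) for v in matrix[i]]) + "\n")


def read_matrix_tsv(path: str | Path):
    """Read a labelled square matrix written by write_matrix_tsv."""
    import numpy as np

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows = []
        for line in fh:
            rows.append([float(v) for v in line.rstrip("\n").split("\t")[1:]])
    return header, np.array(rows)


# ---------------------------------------------------------------------------
# Read preprocessing
# ---------------------------------------------------------------------------

def quality_trim(
    read: SequenceRecord, cutoff: int = 30, min_len: int = 50
) -> Optional[SequenceRecord]:
    """Trim low-quality 3' tail; drop the read entirely if it ends up shorter
    than min_len. Trimming is 3'-only: trailing bases with quality < cutoff
    are removed, nothing else."""
    if read.quals is None:
        raise ValueError(f"read {read.id!r} has no quality scores")
    end = len(read.seq)
    while end > 0 and read.quals[end - 1] < cutoff:
        end -= 1
    if end < min_len:
        return None
    return SequenceRecord(read.id, read.seq[:end], read.desc, read.quals[:end])


def dedupe_exact(
    records: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Collapse byte-identical sequences; among duplicates the record with the
    lexicographically smallest id is kept. Returns (kept, removed_id -> kept_id).
    """
    by_seq: dict[str, SequenceRecord] = {}
    for rec in records:
        cur = by_seq.get(rec.seq)
        if cur is None or rec.id < cur.id:
            by_seq[rec.seq] = rec
    keep_ids = {rec.id for rec in by_seq.values()}
    kept = [rec for rec in records if rec.id in keep_ids]
    removed = {
        rec.id: by_seq[rec.seq].id for rec in records if rec.id not in keep_ids
    }
    return kept, removed


# ---------------------------------------------------------------------------
# Naive ORF finding (stand-in used when no external gene calls are supplied)
# ---------------------------------------------------------------------------

def _orfs_one_strand(seq: str, min_len_aa: int):
    """Maximal ATG..stop ORFs on the forward strand of `seq`, as (start, end)
    0-based half-open intervals including the stop codon."""
    stops = {"TAA", "TAG", "TGA"}
    n = len(seq)
    for frame in range(3):
        start = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in stops:
                aa_len = (pos - start) // 3
                if aa_len >= min_len_aa:
                    yield start, pos + 3
                start = None


def find_orfs(contig: SequenceRecord, min_len_aa: int = 60) -> list[GeneCall]:
    """All maximal ATG->stop ORFs of at least min_len_aa codons, both strands,
    standard genetic code; coordinates on the forward axis."""
    calls: list[GeneCall] = []
    seq = contig.seq.upper()
    n = len(seq)
    for start, end in _orfs_one_strand(seq, min_len_aa):
        prot = str(Seq(seq[start : end - 3]).translate())
        calls.append(
            GeneCall(contig.id, start, end, "+", f"{contig.id}_orf{len(calls) + 1}", prot)
        )
    rc = str(Seq(seq).reverse_complement())
    for start, end in _orfs_one_strand(rc, min_len_aa):
        prot = str(Seq(rc[start : end - 3]).translate())
        calls.append(
            GeneCall(
                contig.id, n - end, n - start, "-", f"{contig.id}_orf{len(calls) + 1}", prot
            )
        )
    calls.sort(key=lambda g: (g.start, g.end, g.strand))
    for i, gc in enumerate(calls, start=1):
        gc.gene_id = f"{contig.id}_orf{i}"
    return calls
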