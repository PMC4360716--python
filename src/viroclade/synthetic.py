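"""Synthetic community generator: clade-structured phage genomes with a
core-gene backbone, host-ameliorated composition, sequencing reads, and
CRISPR spacers, together with the truth tables needed to score every
pipeline stage.

The generative model:

* Hosts are sampled from distinct order-k Markov chains (one random
  transition table per host), so their tetranucleotide signatures are
  separable.
* A single root phage genome is an ordered series of gene modules: core
  genes (the first four are the labelled markers g23, g20, g17, phoH) and
  flexible gene slots, separated by intergenic spacers. Each clade derives
  an ancestor from the root at between_clade_div substitutions/site and is
  assigned a host; each genome derives from its clade ancestor at
  within_clade_div. Within a clade, genomes descend from the crown ancestor
  along a random ultrametric genealogy whose root-to-leaf paths carry
  within_clade_div substitutions/site; flexible-gene turnover (swap-in of
  new clade-specific genes) accrues along the same edges, so sequence
  divergence and gene-content differences share one genealogy, as in real
  phage clades. With zero within-clade divergence all genomes of a clade
  are identical. Gene order is preserved and there are no indels inside
  genes (coordinates stay validatable).
* Amelioration: clade-specific material (flexible genes and intergenic
  spacers) is drawn base-by-base from the host chain with probability
  amelioration_w and from a uniform background otherwise; core genes are
  host-agnostic, as befits genes conserved across clades.
* Substitutions use a uniform (Jukes-Cantor-like) kernel; inside genes they
  are applied per codon and any change creating a stop codon is discarded,
  so translations stay valid. Start and stop codons are never mutated.
* Reads are drawn from genomes proportionally to abundance x length with
  uniform starts, random strand, and a per-base substitution error rate.
* Spacers are excised at random positions and mutated at rate spacer_mut;
  ids encode the source genome and realized mutation count.

Everything derives from one global seed through labelled child seeds, so a
config reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .align import MSA
from .core_io import (
    GeneCall,
    SequenceRecord,
    write_fasta,
    write_fastq,
    write_gff3,
)

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]

# marker aa lengths: g23 long enough that the reference alignment reaches
# the C-terminal domain columns (735-766) used in contig selection
_MARKER_LENGTHS = {"g23": 790, "g20": 420, "g17": 410, "phoH": 230}
_EXTRA_CORE_AA = 250
_FLEX_AA = 150  # flexible genes are shorter and more numerous than core


@dataclass
class SimConfig:
    seed: int = 0
    n_hosts: int = 3
    host_len: int = 200_000
    host_order: int = 3
    n_clades: int = 3
    genomes_per_clade: int = 4
    genome_len: int = 20_000
    n_core_genes: int = 6
    n_flexible_genes: int = 10
    within_clade_div: float = 0.05
    between_clade_div: float = 0.5
    amelioration_w: float = 0.7
    read_len: int = 150
    n_reads: int = 2000
    read_error: float = 0.005
    spacer_len: int = 32
    spacer_mut: float = 0.03
    n_spacers: int = 2

    def __post_init__(self) -> None:
        rates = {
            "within_clade_div": self.within_clade_div,
            "between_clade_div": self.between_clade_div,
            "amelioration_w": self.amelioration_w,
            "read_error": self.read_error,
            "spacer_mut": self.spacer_mut,
        }
        for name, v in rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.within_clade_div > self.between_clade_div:
            raise ValueError("within_clade_div must be <= between_clade_div")
        for name in ("n_hosts", "host_len", "n_clades", "genomes_per_clade",
                     "genome_len", "read_len", "n_reads", "spacer_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_core_genes < 4:
            raise ValueError("need at least 4 core genes (the labelled markers)")


@dataclass
class TruthGene:
    gene_id: str
    label: str  # g23/g20/g17/phoH/core5../flex1..
    kind: str  # core | flexible_clade | flexible_private
    start: int
    end: int


@dataclass
class TruthEntry:
    genome_id: str
    clade_id: str
    host_id: str
    genes: list[TruthGene]


@dataclass
class TruthTable:
    entries: dict[str, TruthEntry]
    # reference material for marker screening / rooting, filled by the generator
    root_marker_proteins: dict[str, str] = field(default_factory=dict)
    clade_marker_proteins: dict[str, dict[str, str]] = field(default_factory=dict)
    outgroup_g23: str = ""

    def clade_of(self, genome_id: str) -> str:
        return self.entries[genome_id].clade_id

    def host_of(self, genome_id: str) -> str:
        return self.entries[genome_id].host_id

    def marker_coords(self, genome_id: str, label: str) -> tuple[int, int]:
        for g in self.entries[genome_id].genes:
            if g.label == label:
                return g.start, g.end
        raise KeyError(f"{genome_id} has no gene labelled {label}")


def child_seed(seed: int, label: str) -> int:
    """Deterministic labelled child seed (stable across platforms)."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)


def _rng(cfg_seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(cfg_seed, label))


# ---------------------------------------------------------------------------
# Hosts
# ---------------------------------------------------------------------------

def _markov_table(rng: np.random.Generator, order: int) -> np.ndarray:
    """Cumulative transition table (4^order, 4), Dirichlet(0.5) rows for
    distinctive signatures."""
    probs = rng.dirichlet([0.5] * 4, size=4**order)
    return probs.cumsum(axis=1)


def _sample_markov(
    rng: np.random.Generator, length: int, cum: np.ndarray, order: int
) -> str:
    u = rng.random(length)
    ctx = int(rng.integers(0, cum.shape[0]))
    mod = cum.shape[0] // 4
    out = np.empty(length, dtype=np.uint8)
    for i in range(length):
        row = cum[ctx]
        b = int(row[0] < u[i]) + int(row[1] < u[i]) + int(row[2] < u[i])
        out[i] = b
        ctx = (ctx % mod) * 4 + b
    return "".join(_BASES[b] for b in out)


def _sample_mixture(
    rng: np.random.Generator,
    length: int,
    cum: np.ndarray,
    order: int,
    w: float,
) -> str:
    """Host-chain base with probability w, uniform background otherwise; the
    Markov context always tracks the emitted sequence."""
    u = rng.random(length)
    pick_host = rng.random(length) < w
    bg = rng.integers(0, 4, size=length)
    ctx = int(rng.integers(0, cum.shape[0]))
    mod = cum.shape[0] // 4
    out = np.empty(length, dtype=np.uint8)
    for i in range(length):
        if pick_host[i]:
            row = cum[ctx]
            b = int(row[0] < u[i]) + int(row[1] < u[i]) + int(row[2] < u[i])
        else:
            b = int(bg[i])
        out[i] = b
        ctx = (ctx % mod) * 4 + b
    return "".join(_BASES[b] for b in out)


def make_hosts(cfg: SimConfig) -> list[SequenceRecord]:
    """n_hosts genomes from distinct order-k Markov chains."""
    hosts = []
    for h in range(cfg.n_hosts):
        rng = _rng(cfg.seed, f"host{h}")
        cum = _markov_table(rng, cfg.host_order)
        seq = _sample_markov(rng, cfg.host_len, cum, cfg.host_order)
        hosts.append(SequenceRecord(f"host_{h + 1}", seq, desc="synthetic host genome"))
    return hosts


def _host_tables(cfg: SimConfig) -> list[np.ndarray]:
    """The cumulative transition tables, regenerated deterministically (the
    host rng draws the table before the genome, so tables match genomes)."""
    tables = []
    for h in range(cfg.n_hosts):
        rng = _rng(cfg.seed, f"host{h}")
        tables.append(_markov_table(rng, cfg.host_order))
    return tables


# ---------------------------------------------------------------------------
# Genes and mutation kernels
# ---------------------------------------------------------------------------

def _random_gene(rng: np.random.Generator, aa_len: int) -> str:
    codons = rng.choice(len(_SENSE_CODONS), size=aa_len)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in codons) + "TAA"


def _mixture_gene(
    rng: np.random.Generator, aa_len: int, cum: np.ndarray, order: int, w: float
) -> str:
    body = _sample_mixture(rng, 3 * aa_len, cum, order, w)
    codons = [body[i : i + 3] for i in range(0, len(body), 3)]
    fixed = [
        c if c not in _STOPS else _SENSE_CODONS[int(rng.integers(0, len(_SENSE_CODONS)))]
        for c in codons
    ]
    return "ATG" + "".join(fixed) + "TAA"


def _p_sub(divergence: float) -> float:
    """Expected substitutions/site -> probability a site differs (JC)."""
    return 0.75 * (1.0 - np.exp(-4.0 * divergence / 3.0))


def _mutate_plain(rng: np.random.Generator, seq: str, divergence: float) -> str:
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    lut = np.zeros(256, dtype=np.int8)
    for i, c in enumerate(_BASES):
        lut[ord(c)] = i
    idx = lut[codes]
    hit = rng.random(len(seq)) < _p_sub(divergence)
    shift = rng.integers(1, 4, size=len(seq))
    new = (idx + shift) % 4
    out = np.where(hit, new, idx)
    return "".join(_BASES[b] for b in out)


def _mutate_gene(rng: np.random.Generator, gene_nt: str, divergence: float) -> str:
    """Codon-aware substitution: start/stop codons fixed; any mutated codon
    that would become a stop reverts (no stop codons are ever created)."""
    body = gene_nt[3:-3]
    mutated = _mutate_plain(rng, body, divergence)
    out = []
    for k in range(0, len(body), 3):
        cod = mutated[k : k + 3]
        out.append(cod if cod not in _STOPS else body[k : k + 3])
    return gene_nt[:3] + "".join(out) + gene_nt[-3:]


# flexible-gene turnover intensity along the within-clade genealogy:
# per flexible slot, P(swap on an edge) = 1 - exp(-rate * edge_divergence),
# so gene content differences accumulate with sequence divergence and the
# two signals share one genealogy (zero divergence -> zero turnover)
_FLEX_SWAP_RATE = 8.0


def _evolve_within_clade(crng, cfg, clade_genes, clade_spacers, plan, cum):
    """Evolve genomes_per_clade leaves down a random ultrametric genealogy
    rooted at the clade (crown) ancestor. Substitutions and flexible-gene
    swaps both accrue along the same edges; every root-to-leaf path carries
    within_clade_div substitutions/site in total. Returns, per leaf,
    (gene dict, spacer list, set of swapped flexible labels)."""
    k = cfg.genomes_per_clade
    flex_labels = [label for label, kind, _aa in plan if kind == "flexible_clade"]
    aa_by_label = {label: aa for label, _kind, aa in plan}
    results: list = [None] * k

    def descend(indices, height, genes, spacers, swapped):
        if len(indices) == 1:
            genes2, spacers2, swapped2 = _along_edge(
                genes, spacers, swapped, height
            )
            results[indices[0]] = (genes2, spacers2, swapped2)
            return
        order = [indices[i] for i in crng.permutation(len(indices))]
        cut = int(crng.integers(1, len(order)))
        child_h = height * float(crng.uniform(0.3, 0.7)) if height > 0 else 0.0
        for part in (sorted(order[:cut]), sorted(order[cut:])):
            genes2, spacers2, swapped2 = _along_edge(
                genes, spacers, swapped, height - child_h
            )
            descend(part, child_h, genes2, spacers2, swapped2)

    def _along_edge(genes, spacers, swapped, edge):
        genes2 = {
            label: _mutate_gene(crng, nt, edge) for label, nt in genes.items()
        }
        spacers2 = [_mutate_plain(crng, s, edge) for s in spacers]
        swapped2 = set(swapped)
        if edge > 0:
            p_swap = 1.0 - float(np.exp(-_FLEX_SWAP_RATE * edge))
            for label in flex_labels:
                if crng.random() < p_swap:
                    genes2[label] = _mixture_gene(
                        crng, aa_by_label[label], cum, cfg.host_order,
                        cfg.amelioration_w,
                    )
                    swapped2.add(label)
        return genes2, spacers2, swapped2

    descend(list(range(k)), cfg.within_clade_div, clade_genes, clade_spacers, set())
    return results


def _gene_plan(cfg: SimConfig) -> list[tuple[str, str, int]]:
    """(label, kind, aa_len) for each gene slot, in genome order."""
    plan: list[tuple[str, str, int]] = []
    for i, (label, aa) in enumerate(_MARKER_LENGTHS.items()):
        plan.append((label, "core", aa))
    for i in range(4, cfg.n_core_genes):
        plan.append((f"core{i + 1}", "core", _EXTRA_CORE_AA))
    for i in range(cfg.n_flexible_genes):
        plan.append((f"flex{i + 1}", "flexible_clade", _FLEX_AA))
    return plan


def _translate_gene(gene_nt: str) -> str:
    return str(Seq(gene_nt[:-3]).translate())


def make_phage_clades(
    cfg: SimConfig, hosts: Sequence[SequenceRecord]
) -> tuple[list[SequenceRecord], list[GeneCall], TruthTable]:
    """Clade-structured phage genomes, their gene calls, and the truth table."""
    if len(hosts) < 1:
        raise ValueError("need at least one host")
    plan = _gene_plan(cfg)
    gene_total = sum(3 * (aa + 2) for _, _, aa in plan)
    n_gaps = len(plan) + 1
    intergenic_total = cfg.genome_len - gene_total
    if intergenic_total < n_gaps:
        raise ValueError(
            f"genome_len {cfg.genome_len} too small for {gene_total} bp of genes"
        )
    tables = _host_tables(cfg)

    root_rng = _rng(cfg.seed, "root")
    root_genes = {label: _random_gene(root_rng, aa) for label, _, aa in plan}
    # the clade stem is split just below the crown so each clade gets a
    # sister reference sequence (emulating published members of the clade);
    # total root->crown divergence remains between_clade_div
    delta = min(0.1, cfg.between_clade_div / 2)

    genomes: list[SequenceRecord] = []
    gene_calls: list[GeneCall] = []
    entries: dict[str, TruthEntry] = {}
    clade_ref_proteins: dict[str, dict[str, str]] = {}
    for c in range(cfg.n_clades):
        clade_id = f"clade_{c + 1}"
        host_idx = c % cfg.n_hosts
        host_id = hosts[host_idx].id
        cum = tables[host_idx]
        crng = _rng(cfg.seed, f"clade{c}")
        clade_genes: dict[str, str] = {}
        clade_ref_proteins[clade_id] = {}
        for label, kind, aa in plan:
            if kind == "core":
                pre = _mutate_gene(
                    crng, root_genes[label], cfg.between_clade_div - delta
                )
                clade_genes[label] = _mutate_gene(crng, pre, delta)
                if label in _MARKER_LENGTHS:
                    clade_ref_proteins[clade_id][label] = _translate_gene(
                        _mutate_gene(crng, pre, delta)
                    )
            else:
                clade_genes[label] = _mixture_gene(
                    crng, aa, cum, cfg.host_order, cfg.amelioration_w
                )
        # intergenic spacers: equal split, remainder on the last one
        base = intergenic_total // n_gaps
        sizes = [base] * n_gaps
        sizes[-1] += intergenic_total - base * n_gaps
        clade_spacers = [
            _sample_mixture(crng, s, cum, cfg.host_order, cfg.amelioration_w)
            for s in sizes
        ]
        leaf_states = _evolve_within_clade(
            crng, cfg, clade_genes, clade_spacers, plan, cum
        )
        for g, (leaf_genes, leaf_spacers, swapped) in enumerate(leaf_states):
            genome_id = f"phage_c{c + 1}_{g + 1}"
            parts: list[str] = []
            truth_genes: list[TruthGene] = []
            pos = 0
            for slot, (label, kind, aa) in enumerate(plan):
                parts.append(leaf_spacers[slot])
                pos += len(leaf_spacers[slot])
                gene_nt = leaf_genes[label]
                kind_out = "flexible_turnover" if label in swapped else kind
                gene_id = f"{genome_id}_{label}"
                start, end = pos, pos + len(gene_nt)
                parts.append(gene_nt)
                pos = end
                truth_genes.append(TruthGene(gene_id, label, kind_out, start, end))
                gene_calls.append(
                    GeneCall(
                        contig_id=genome_id,
                        start=start,
                        end=end,
                        strand="+",
                        gene_id=gene_id,
                        protein=_translate_gene(gene_nt),
                        annotation=label if label in _MARKER_LENGTHS else None,
                    )
                )
            parts.append(leaf_spacers[-1])
            seq = "".join(parts)
            genomes.append(
                SequenceRecord(genome_id, seq, desc=f"{clade_id} {host_id}")
            )
            entries[genome_id] = TruthEntry(genome_id, clade_id, host_id, truth_genes)
    truth = TruthTable(entries)
    # stash reference material for marker screening and outgroup rooting
    truth.root_marker_proteins = {
        label: _translate_gene(root_genes[label]) for label in _MARKER_LENGTHS
    }
    ogrng = _rng(cfg.seed, "outgroup")
    truth.outgroup_g23 = _translate_gene(
        _mutate_gene(ogrng, root_genes["g23"], 1.5)
    )
    truth.clade_marker_proteins = clade_ref_proteins
    return genomes, gene_calls, truth


def marker_reference(truth: TruthTable):
    """Reference protein sets per marker plus a gap-free g23 reference MSA
    (root + per-clade reference sequences; core genes have no indels, so the
    reference alignment is trivially column-consistent)."""
    refsets: dict[str, list[SequenceRecord]] = {}
    for label, prot in truth.root_marker_proteins.items():
        refsets[label] = [SequenceRecord(f"ref_{label}_root", prot)]
        for clade, prots in truth.clade_marker_proteins.items():
            refsets[label].append(SequenceRecord(f"ref_{label}_{clade}", prots[label]))
    msa = MSA([(r.id, r.seq) for r in refsets["g23"]])
    return refsets, msa


# ---------------------------------------------------------------------------
# Reads and spacers
# ---------------------------------------------------------------------------

def make_reads(
    genomes: Sequence[SequenceRecord],
    cfg: SimConfig,
    abundances: Optional[dict[str, float]] = None,
) -> list[SequenceRecord]:
    """n_reads reads of read_len: genome chosen proportionally to
    abundance x length, uniform start, random strand, per-base error rate.
    Read ids encode the true origin: read|genome|start|strand."""
    if abundances is None:
        abundances = {g.id: 1.0 / len(genomes) for g in genomes}
    total = sum(abundances.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"abundances sum to {total}, expected 1")
    if cfg.read_len > min(len(g.seq) for g in genomes):
        raise ValueError("read_len exceeds the shortest genome")
    rng = _rng(cfg.seed, "reads")
    ids = [g.id for g in genomes]
    weights = np.array([abundances.get(g.id, 0.0) * len(g.seq) for g in genomes])
    weights = weights / weights.sum()
    picks = rng.choice(len(genomes), size=cfg.n_reads, p=weights)
    reads: list[SequenceRecord] = []
    for i, gidx in enumerate(picks):
        g = genomes[gidx]
        start = int(rng.integers(0, len(g.seq) - cfg.read_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        frag = g.seq[start : start + cfg.read_len]
        if strand == "-":
            frag = str(Seq(frag).reverse_complement())
        if cfg.read_error > 0:
            frag = _error_bases(rng, frag, cfg.read_error)
        reads.append(
            SequenceRecord(
                f"read{i:06d}|{g.id}|{start}|{strand}",
                frag,
                quals=[40] * cfg.read_len,
            )
        )
    return reads


def _error_bases(rng: np.random.Generator, seq: str, rate: float) -> str:
    lut = {c: i for i, c in enumerate(_BASES)}
    out = list(seq)
    hit = rng.random(len(seq)) < rate
    shift = rng.integers(1, 4, size=len(seq))
    for i in np.nonzero(hit)[0]:
        out[i] = _BASES[(lut.get(out[i], 0) + int(shift[i])) % 4]
    return "".join(out)


def make_spacers(
    phage_genomes: Sequence[SequenceRecord], cfg: SimConfig
) -> list[SequenceRecord]:
    """Spacers excised at random positions and mutated at rate spacer_mut;
    ids encode source genome, position, and realized mutation count."""
    rng = _rng(cfg.seed, "spacers")
    spacers: list[SequenceRecord] = []
    for g in phage_genomes:
        if cfg.spacer_len >= len(g.seq):
            raise ValueError(f"spacer_len >= genome length for {g.id}")
        for s in range(cfg.n_spacers):
            start = int(rng.integers(0, len(g.seq) - cfg.spacer_len + 1))
            frag = g.seq[start : start + cfg.spacer_len]
            hit = rng.random(cfg.spacer_len) < cfg.spacer_mut
            shift = rng.integers(1, 4, size=cfg.spacer_len)
            lut = {c: i for i, c in enumerate(_BASES)}
            out = list(frag)
            nmut = 0
            for i in np.nonzero(hit)[0]:
                out[i] = _BASES[(lut.get(out[i], 0) + int(shift[i])) % 4]
                nmut += 1
            spacers.append(
                SequenceRecord(
                    f"spacer{len(spacers):04d}|{g.id}|{start}|m{nmut}",
                    "".join(out),
                )
            )
    return spacers


# ---------------------------------------------------------------------------
# Bundled simulation + on-disk layout
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    cfg: SimConfig
    hosts: list[SequenceRecord]
    genomes: list[SequenceRecord]
    gene_calls: list[GeneCall]
    truth: TruthTable
    reads: list[SequenceRecord]
    spacers: list[SequenceRecord]
    refsets: dict[str, list[SequenceRecord]]
    reference_msa: MSA
    outgroup_g23: SequenceRecord


def simulate(cfg: SimConfig, abundances: Optional[dict[str, float]] = None) -> SimResult:
    hosts = make_hosts(cfg)
    genomes, gene_calls, truth = make_phage_clades(cfg, hosts)
    reads = make_reads(genomes, cfg, abundances)
    spacers = make_spacers(genomes, cfg)
    refsets, ref_msa = marker_reference(truth)
    return SimResult(
        cfg=cfg,
        hosts=hosts,
        genomes=genomes,
        gene_calls=gene_calls,
        truth=truth,
        reads=reads,
        spacers=spacers,
        refsets=refsets,
        reference_msa=ref_msa,
        outgroup_g23=SequenceRecord("outgroup_g23", truth.outgroup_g23),
    )


def write_simulation(result: SimResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.hosts, outdir / "hosts.fasta")
    write_fasta(result.genomes, outdir / "genomes.fasta")
    write_gff3(result.gene_calls, outdir / "genes.gff3")
    write_fasta(
        [SequenceRecord(g.gene_id, g.protein) for g in result.gene_calls],
        outdir / "proteins.fasta",
    )
    write_fastq(result.reads, outdir / "reads.fastq")
    write_fasta(result.spacers, outdir / "spacers.fasta")
    for label, refs in result.refsets.items():
        write_fasta(refs, outdir / f"ref_{label}.fasta")
    write_fasta([result.outgroup_g23], outdir / "outgroup_g23.fasta")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("genome_id\tclade_id\thost_id\tgene_id\tlabel\tkind\tstart\tend\n")
        for entry in result.truth.entries.values():
            for g in entry.genes:
                fh.write(
                    f"{entry.genome_id}\t{entry.clade_id}\t{entry.host_id}\t"
                    f"{g.gene_id}\t{g.label}\t{g.kind}\t{g.start}\t{g.end}\n"
                )
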