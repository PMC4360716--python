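"""Recovery studies: does the pipeline recover what the generator planted?

These are the package's own calibration experiments — clade recovery from
the marker tree (adjusted Rand index against the truth table), concordance
between the gene-content dendrogram and the marker tree, composition-based
host recovery, permutation-test calibration, and a neutral-evolution sanity
check of the dN/dS estimator. They are deliberately part of the library so
a user can rerun them under different generator settings.
"""

from __future__ import annotations

import random
from dataclasses import replace
from typing import Optional

import numpy as np
from scipy import stats as scipy_stats
from sklearn.metrics import adjusted_rand_score

from . import markers, phylo, selection
from .align import default_scheme, progressive_msa
from .pipeline import genecontent_stage
from .synthetic import (
    SimConfig,
    SimResult,
    child_seed,
    make_hosts,
    make_phage_clades,
    marker_reference,
)
from .core_io import SequenceRecord


def _sim_without_reads(cfg: SimConfig) -> SimResult:
    """Hosts + phage community only (reads and spacers left empty)."""
    hosts = make_hosts(cfg)
    genomes, gene_calls, truth = make_phage_clades(cfg, hosts)
    refsets, ref_msa = marker_reference(truth)
    return SimResult(
        cfg=cfg,
        hosts=hosts,
        genomes=genomes,
        gene_calls=gene_calls,
        truth=truth,
        reads=[],
        spacers=[],
        refsets=refsets,
        reference_msa=ref_msa,
        outgroup_g23=SequenceRecord("outgroup_g23", truth.outgroup_g23),
    )


def marker_clade_recovery(
    seed: int,
    cfg: Optional[SimConfig] = None,
    bootstrap_reps: int = 100,
    min_support: int = 80,
) -> dict:
    """One clade-recovery replicate: simulate, screen g23, build the marker
    tree, delineate clades, and score against the truth table.

    Screening is restricted to the g23 refset here (the other markers do not
    enter the tree); the full multi-marker screen is exercised elsewhere.
    """
    cfg = replace(cfg or SimConfig(), seed=seed)
    sim = _sim_without_reads(cfg)
    mcfg = markers.MarkerScreenConfig(
        refsets={"g23": sim.refsets["g23"]}, reference_msa=sim.reference_msa
    )
    lengths = {g.id: len(g.seq) for g in sim.genomes}
    calls = markers.screen_markers(sim.gene_calls, mcfg, lengths)
    g23 = [c for c in calls if c.marker == "g23" and c.passes]
    proteins = {g.gene_id: g.protein for g in sim.gene_calls}
    query = {c.contig_id: proteins[c.gene_id] for c in g23}
    seqs = sorted(query.items())
    seqs.append(("ref_g23_root", sim.truth.root_marker_proteins["g23"]))
    seqs.extend(
        (f"ref_g23_{clade}", prots["g23"])
        for clade, prots in sorted(sim.truth.clade_marker_proteins.items())
    )
    seqs.append(("outgroup_g23", sim.outgroup_g23.seq))
    msa = progressive_msa(seqs, default_scheme("protein"))
    tree = phylo.bootstrap_support(
        msa, n_reps=bootstrap_reps, seed=child_seed(seed, "eval-bootstrap")
    )
    tree = phylo.collapse_low_support(tree, 50)
    rooted = phylo.root_with_outgroup(tree, ["outgroup_g23"])
    clades, unassigned = phylo.delineate_clades(
        rooted, set(query), min_support=min_support
    )
    ids = sorted(query)
    assigned = {leaf: cid for cid, leaves in clades.items() for leaf in leaves}
    ari = adjusted_rand_score(
        [sim.truth.clade_of(i) for i in ids],
        [assigned.get(i, f"unassigned_{i}") for i in ids],
    )
    return {
        "ari": float(ari),
        "n_clades": len(clades),
        "n_unassigned": len(unassigned),
        "tree": rooted,
        "sim": sim,
    }


def clade_recovery_rate(
    base_seed: int, n_seeds: int = 20, cfg: Optional[SimConfig] = None
) -> dict:
    """Fraction of seeds with perfect clade recovery (ARI = 1)."""
    aris = []
    for k in range(n_seeds):
        run = marker_clade_recovery(child_seed(base_seed, f"clade-sweep-{k}"), cfg)
        aris.append(run["ari"])
    aris = np.array(aris)
    return {
        "perfect_rate": float((aris == 1.0).mean()),
        "mean_ari": float(aris.mean()),
        "n_seeds": n_seeds,
    }


def concordance_test(
    seed: int, cfg: Optional[SimConfig] = None, n_perm: int = 1000
) -> phylo.PermutationResult:
    """Gene-content dendrogram vs marker tree on one simulated community."""
    run = marker_clade_recovery(seed, cfg)
    sim = run["sim"]
    sharing, dendro, _ = genecontent_stage(sim)
    return phylo.rf_permutation_test(
        run["tree"], dendro, n_perm=n_perm, seed=child_seed(seed, "eval-concord")
    )


def host_recovery_rate(
    seed: int,
    n_hosts: int = 5,
    amelioration_w: float = 0.7,
    host_len: int = 200_000,
    genomes_per_clade: int = 2,
) -> dict:
    """Top-1 tetranucleotide host-prediction accuracy on a fresh community."""
    from .hostpred import predict_host, tetra_profile

    cfg = SimConfig(
        seed=seed,
        n_hosts=n_hosts,
        n_clades=n_hosts,
        genomes_per_clade=genomes_per_clade,
        host_len=host_len,
        amelioration_w=amelioration_w,
    )
    hosts = make_hosts(cfg)
    genomes, _calls, truth = make_phage_clades(cfg, hosts)
    profiles = [tetra_profile(h) for h in hosts]
    correct = sum(
        predict_host(g, profiles).best_host_id == truth.host_of(g.id)
        for g in genomes
    )
    return {
        "top1_rate": correct / len(genomes),
        "n_genomes": len(genomes),
        "baseline": 1.0 / n_hosts,
    }


def rf_calibration(
    seed: int, n_pairs: int = 200, n_leaves: int = 16, n_perm: int = 1000
) -> dict:
    """Kolmogorov-Smirnov uniformity of the tie-randomized permutation p
    under the null (independent random tree pairs)."""
    rng = np.random.default_rng(seed)
    names = [f"t{i}" for i in range(n_leaves)]
    ps = []
    for _ in range(n_pairs):
        t1 = phylo.random_tree(names, rng)
        t2 = phylo.random_tree(names, rng)
        res = phylo.rf_permutation_test(
            t1, t2, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        ps.append(res.p_randomized)
    ks = scipy_stats.kstest(ps, "uniform")
    return {"ks_statistic": float(ks.statistic), "ks_p": float(ks.pvalue), "n": n_pairs}


def neutral_omega(
    seed: int, n_pairs: int = 100, n_codons: int = 200, site_rate: float = 0.04
) -> dict:
    """Median NG86 omega over pairs diverged under a uniform substitution
    kernel with stop codons rejected (neutral expectation: omega near 1)."""
    rng = random.Random(seed)
    omegas = []
    for _ in range(n_pairs):
        anc = [rng.choice(selection.SENSE_CODONS) for _ in range(n_codons)]

        def derive() -> str:
            out = []
            for c in anc:
                cand = "".join(
                    rng.choice("ACGT") if rng.random() < site_rate else b for b in c
                )
                out.append(cand if cand in selection.SENSE_CODONS else c)
            return "".join(out)

        res = selection.ng86_pair(derive(), derive())
        if res.omega is not None:
            omegas.append(res.omega)
    return {"median_omega": float(np.median(omegas)), "n": len(omegas)}


def synonymous_only_omega(seed: int, n_pairs: int = 20, n_codons: int = 80) -> dict:
    """omega under purely synonymous single-base divergence (must be 0)."""
    rng = random.Random(seed)

    def syn_neighbors(c: str) -> list[str]:
        out = []
        for pos in range(3):
            for b in "ACGT":
                alt = c[:pos] + b + c[pos + 1 :]
                if alt != c and selection._CODON_TABLE.get(alt) == selection._CODON_TABLE[c]:
                    out.append(alt)
        return out

    max_abs = 0.0
    n_defined = 0
    for _ in range(n_pairs):
        a = [rng.choice(selection.SENSE_CODONS) for _ in range(n_codons)]
        b = [
            rng.choice(syn_neighbors(c))
            if syn_neighbors(c) and rng.random() < 0.5
            else c
            for c in a
        ]
        res = selection.ng86_pair("".join(a), "".join(b))
        if res.omega is not None:
            n_defined += 1
            max_abs = max(max_abs, abs(res.omega))
    return {"max_abs_omega": max_abs, "n_defined": n_defined}
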