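"""End-to-end orchestration of the analysis stages on simulated or user
data, plus validation against the packaged contig summary table.

The canonical stage order mirrors the study design: simulate (optional) ->
marker screening -> marker phylogeny and clade delineation -> gene-content
comparison -> tree/dendrogram concordance -> read recruitment -> host
prediction -> dN/dS. Every source of randomness derives from the single
config seed via labelled child seeds, so a run is reproducible
byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

from . import core_io, genecontent, hostpred, markers, phylo, recruit, selection
from .align import MSA, default_scheme, progressive_msa
from .core_io import ContigTableRow, read_contig_table
from .synthetic import SimConfig, SimResult, child_seed, simulate, write_simulation

TABLE1_RESOURCE = "table1_far_t4_contigs.tsv"


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: Optional[Path] = None
    sim: SimConfig = field(default_factory=SimConfig)
    bootstrap_reps: int = 100
    collapse_support: int = 50
    clade_min_support: int = 80
    n_perm: int = 1000
    recruit: recruit.RecruitConfig = field(default_factory=recruit.RecruitConfig)
    run_recruit: bool = True
    run_hostpred: bool = True
    run_dnds: bool = True


def packaged_table1_path() -> Path:
    return Path(str(resources.files("viroclade").joinpath("data", TABLE1_RESOURCE)))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def marker_tree_stage(
    sim: SimResult, cfg: PipelineConfig
) -> tuple[MSA, "phylo.Tree", dict[str, set[str]], set[str], list[markers.MarkerCall]]:
    """Screen markers, build the g23 tree (queries + clade references + root
    reference + outgroup), root it, and delineate clades."""
    mcfg = markers.MarkerScreenConfig(
        refsets=sim.refsets, reference_msa=sim.reference_msa
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
        msa, n_reps=cfg.bootstrap_reps, seed=child_seed(cfg.seed, "bootstrap")
    )
    tree = phylo.collapse_low_support(tree, cfg.collapse_support)
    rooted = phylo.root_with_outgroup(tree, ["outgroup_g23"])
    clades, unassigned = phylo.delineate_clades(
        rooted, set(query), min_support=cfg.clade_min_support
    )
    return msa, rooted, clades, unassigned, calls


def genecontent_stage(sim: SimResult):
    genes_by_contig: dict[str, list] = {}
    for g in sim.gene_calls:
        genes_by_contig.setdefault(g.contig_id, []).append(g)
    sharing = genecontent.build_sharing_matrix(genes_by_contig)
    dendro = genecontent.cluster_contigs(sharing)
    return sharing, dendro, genes_by_contig


def recruit_stage(sim: SimResult, cfg: PipelineConfig):
    rcfg = cfg.recruit
    reads, _flag = recruit.subsample_reads(
        sim.reads, rcfg.subsample_n, seed=child_seed(cfg.seed, "subsample")
    )
    hits = recruit.recruit_reads(reads, sim.genomes, rcfg)
    presence = {
        g.id: recruit.presence_call(hits, g.id, rcfg) for g in sim.genomes
    }
    profiles = [recruit.coverage_profile(hits, g, rcfg) for g in sim.genomes]
    return hits, presence, profiles


def hostpred_stage(sim: SimResult):
    host_profiles = [hostpred.tetra_profile(h) for h in sim.hosts]
    calls = [hostpred.predict_host(g, host_profiles) for g in sim.genomes]
    matches = []
    by_id = {g.id: g for g in sim.genomes}
    for spacer in sim.spacers:
        source = spacer.id.split("|")[1]
        matches.append(hostpred.match_spacer(spacer, by_id[source]))
    return calls, matches


def dnds_stage(sim: SimResult):
    """g23 codon alignment across genomes (core genes are indel-free, so the
    nucleotide sequences align column-for-column); omega for the first clade
    vs the rest."""
    rows = []
    for genome in sim.genomes:
        start, end = sim.truth.marker_coords(genome.id, "g23")
        rows.append((genome.id, genome.seq[start + 3 : end - 3]))  # drop start/stop
    msa = MSA(rows)
    group = [
        gid
        for gid, entry in sim.truth.entries.items()
        if entry.clade_id == "clade_1"
    ]
    omega_group, omega_rest, excluded = selection.group_dnds(msa, group)
    return msa, omega_group, omega_rest, excluded


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages on a fresh simulation; returns the report dict and, if
    cfg.outdir is set, writes the report bundle (JSON + TSVs + Newick)."""
    sim = simulate(cfg.sim)
    report: dict = {
        "seed": cfg.seed,
        "config": {
            "sim_seed": cfg.sim.seed,
            "n_clades": cfg.sim.n_clades,
            "genomes_per_clade": cfg.sim.genomes_per_clade,
            "bootstrap_reps": cfg.bootstrap_reps,
            "collapse_support": cfg.collapse_support,
            "clade_min_support": cfg.clade_min_support,
            "n_perm": cfg.n_perm,
        },
    }
    msa, rooted, clades, unassigned, calls = marker_tree_stage(sim, cfg)
    report["markers"] = {
        "n_calls": len(calls),
        "n_g23_passing": sum(1 for c in calls if c.marker == "g23" and c.passes),
    }
    report["clades"] = {k: sorted(v) for k, v in clades.items()}
    report["unassigned"] = sorted(unassigned)

    sharing, dendro, genes_by_contig = genecontent_stage(sim)
    concord = phylo.rf_permutation_test(
        rooted, dendro, n_perm=cfg.n_perm, seed=child_seed(cfg.seed, "permutation")
    )
    report["concordance"] = {
        "observed_rf": concord.observed_rf,
        "null_mean": concord.null_mean,
        "null_sd": concord.null_sd,
        "p_empirical": concord.p_empirical,
        "p_normal": concord.p_normal,
    }

    if cfg.run_recruit:
        hits, presence, profiles = recruit_stage(sim, cfg)
        report["recruitment"] = {
            "n_hits": len(hits),
            "present": sorted(k for k, v in presence.items() if v),
        }
    else:
        profiles = []
        report["recruitment"] = {"skipped": True}

    if cfg.run_hostpred:
        host_calls, spacer_matches = hostpred_stage(sim)
        correct = sum(
            1
            for c in host_calls
            if c.best_host_id == sim.truth.host_of(c.contig_id)
        )
        report["host_prediction"] = {
            "top1_correct": correct,
            "n_genomes": len(host_calls),
            "spacer_pass_rate": (
                sum(m.passes for m in spacer_matches) / len(spacer_matches)
                if spacer_matches
                else None
            ),
        }
    else:
        host_calls, spacer_matches = [], []
        report["host_prediction"] = {"skipped": True}

    if cfg.run_dnds:
        _codon_msa, omega_group, omega_rest, excluded = dnds_stage(sim)
        report["dnds"] = {
            "omega_clade1": omega_group,
            "omega_rest": omega_rest,
            "excluded_pairs": excluded,
        }
    else:
        report["dnds"] = {"skipped": True}

    if cfg.outdir is not None:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_simulation(sim, outdir / "simulation")
        markers.write_marker_table(calls, outdir / "markers.tsv")
        phylo.write_newick(rooted, outdir / "marker_tree.nwk")
        phylo.write_newick(dendro, outdir / "gene_content_dendrogram.nwk")
        core_io.write_matrix_tsv(sharing.ids, sharing.P, outdir / "sharing.tsv")
        if profiles:
            recruit.write_coverage_tsv(profiles, outdir / "coverage.tsv")
        if host_calls:
            hostpred.write_host_calls(host_calls, outdir / "host_calls.tsv")
        if spacer_matches:
            hostpred.write_spacer_matches(spacer_matches, outdir / "spacer_matches.tsv")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


# ---------------------------------------------------------------------------
# Fixture validation
# ---------------------------------------------------------------------------

def table1_summary(rows: list[ContigTableRow]) -> dict:
    """The summary counts the published contig table implies."""
    return {
        "n_contigs": len(rows),
        "n_hiseq": sum(1 for r in rows if r.dataset == "HiSeq Viromes"),
        "n_454": sum(1 for r in rows if r.dataset == "454 Viromes"),
        "n_over_25kb": sum(1 for r in rows if r.length > 25_000),
        "n_clades": len({r.clade for r in rows}),
        "n_phoH": sum(1 for r in rows if r.phoH),
        "n_crispr_hosts": sum(1 for r in rows if r.crispr_host),
        "n_tetra_hosts": sum(1 for r in rows if r.tetra_host),
        "n_all_three_markers": sum(
            1 for r in rows if {"g23", "g20", "g17"} <= r.markers
        ),
    }


# counts the published table implies (the study reports 32 contigs from the
# deeply sequenced viromes plus 8 from the 454 viromes, 12 longer than 25 kb)
EXPECTED_TABLE1_SUMMARY = {
    "n_contigs": 40,
    "n_hiseq": 32,
    "n_454": 8,
    "n_over_25kb": 12,
    "n_clades": 4,
    "n_phoH": 26,
    "n_crispr_hosts": 3,
    "n_tetra_hosts": 3,
    "n_all_three_markers": 12,
}


def validate_against_fixture(
    fixture_path: Optional[str | Path] = None,
    expected: Optional[dict] = None,
) -> dict:
    """Recompute the summary counts from the contig table, check internal
    consistency, and compare against the published values; raises ValueError
    with a diff on any mismatch."""
    path = Path(fixture_path) if fixture_path else packaged_table1_path()
    rows = read_contig_table(path)
    summary = table1_summary(rows)
    problems = []
    if summary["n_hiseq"] + summary["n_454"] != summary["n_contigs"]:
        problems.append("dataset counts do not sum to the total")
    ids = [r.sequence_id for r in rows]
    if len(set(ids)) != len(ids):
        problems.append("duplicate sequence ids")
    if any("g23" not in r.markers for r in rows):
        problems.append("contig without the g23 marker")
    expected = EXPECTED_TABLE1_SUMMARY if expected is None else expected
    for key, want in expected.items():
        got = summary.get(key)
        if got != want:
            problems.append(f"{key}: expected {want}, found {got}")
    if problems:
        raise ValueError("fixture validation failed: " + "; ".join(problems))
    return summary
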