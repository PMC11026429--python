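"""End-to-end synthetic analysis: simulate → Ks → filter → phase → date.

Mirrors the comparative-genomics workflow on generated data: an
allotetraploid dataset is simulated, homeolog/ortholog pairs are selected by
the copy-number filter, NG86 Ks is estimated for every pair, chromosomes are
phased into two subgenomes from their ortholog-Ks medians, and the homeolog
peak and per-subgenome medians are converted to ages with T = Ks/(2μ).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .dating import date_from_ks, ks_peak
from .io import PipelineConfig, derive_seed, ensure_dir, write_fasta, write_tsv
from .ks import CodonAlignmentPair, batch_ks
from .orthogroups import FilterCriterion, select_orthogroups
from .phasing import (
    homeolog_consistency,
    partition_two_clusters,
    summarize_by_chromosome,
)
from .simulate import (
    FOCAL_SPECIES,
    REFERENCE_SPECIES,
    SimScenario,
    simulate_dataset,
)


def scenario_from_config(config: PipelineConfig) -> SimScenario:
    defaults = SimScenario()
    membership = (
        defaults.subgenome_membership
        if config.n_chromosomes == defaults.n_chromosomes
        else {
            f"chr{i:02d}": ("A" if i % 2 else "B")
            for i in range(1, config.n_chromosomes + 1)
        }
    )
    return SimScenario(
        n_chromosomes=config.n_chromosomes,
        subgenome_membership=membership,
        ks_ortholog_A=config.ks_ortholog_A,
        ks_ortholog_B=config.ks_ortholog_B,
        ks_paralog=config.ks_paralog,
        genes_per_chromosome=config.genes_per_chromosome,
        codons_per_gene=config.codons_per_gene,
        seed=derive_seed(config.seed, "simulate"),
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run all stages; returns (and optionally writes) the run report.

    The report is JSON-serializable with stable key order; rerunning with
    the same config reproduces it byte-for-byte.
    """
    scenario = scenario_from_config(config)
    sim = simulate_dataset(scenario)

    criterion = FilterCriterion(
        diploid_species=(REFERENCE_SPECIES,),
        focal_species=FOCAL_SPECIES,
        reference_species=REFERENCE_SPECIES,
    )
    selected = select_orthogroups(sim.gene_map, criterion)
    if selected.triples.empty:
        raise RuntimeError("stage filter: no orthogroups passed the filter")

    # ortholog pairs (each focal copy vs the reference) and homeolog pairs
    ortho_pairs = []
    paralog_pairs = []
    for row in selected.triples.itertuples(index=False):
        ref = row.reference_gene
        for focal in (row.focal_gene_1, row.focal_gene_2):
            ortho_pairs.append(
                CodonAlignmentPair(
                    sim.sequences[ref], sim.sequences[focal], ref, focal
                )
            )
        paralog_pairs.append(
            CodonAlignmentPair(
                sim.sequences[row.focal_gene_1],
                sim.sequences[row.focal_gene_2],
                row.focal_gene_1,
                row.focal_gene_2,
            )
        )
    ortho_ks = batch_ks(ortho_pairs)
    paralog_ks = batch_ks(paralog_pairs)

    summaries, unassigned = summarize_by_chromosome(
        ortho_ks, sim.gene_map, gene_column="gene2", min_genes=config.min_genes
    )
    if not summaries:
        raise RuntimeError("stage phase: no chromosome had enough Ks records")
    partition = partition_two_clusters(summaries)
    consistency, _ = homeolog_consistency(
        partition, selected.triples, sim.gene_map
    )

    paralog_peak = ks_peak(
        paralog_ks.loc[paralog_ks["flag"] == "ok", "Ks"], config.peak_method
    )
    wgd_age = date_from_ks(paralog_peak, config.mu)
    medians_a = [
        s.median_ks for s in summaries if partition.assignments.get(s.chromosome) == "A"
    ]
    medians_b = [
        s.median_ks for s in summaries if partition.assignments.get(s.chromosome) == "B"
    ]
    subgenome_a_median = ks_peak(medians_a) if medians_a else float("nan")
    subgenome_b_median = ks_peak(medians_b) if medians_b else float("nan")

    report = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "scenario": scenario.to_dict(),
        "filter": {
            "n_orthogroups": len(selected.passing_orthogroups),
            "n_sequences": selected.n_sequences,
        },
        "phasing": {
            "n_A": partition.n_A,
            "n_B": partition.n_B,
            "assignments": dict(sorted(partition.assignments.items())),
            "unassigned": unassigned,
            "separation": partition.separation,
            "ambiguous": partition.ambiguous,
            "homeolog_split_fraction": consistency,
        },
        "ks": {
            "paralog_peak": paralog_peak,
            "subgenome_A_median": subgenome_a_median,
            "subgenome_B_median": subgenome_b_median,
        },
        "dating": {
            "wgd_mya": wgd_age.T_mya,
            "wgd_mya_rounded": wgd_age.T_mya_rounded,
            "subgenome_A_mya": date_from_ks(subgenome_a_median, config.mu).T_mya
            if medians_a
            else None,
            "subgenome_B_mya": date_from_ks(subgenome_b_median, config.mu).T_mya
            if medians_b
            else None,
            "mu": config.mu,
        },
    }

    if outdir is not None:
        out = ensure_dir(outdir)
        write_fasta(sim.sequences, out / "sequences.fasta")
        write_tsv(sim.gene_map, out / "gene_map.tsv")
        write_tsv(selected.triples, out / "triples.tsv")
        write_tsv(ortho_ks, out / "ks_orthologs.tsv")
        write_tsv(paralog_ks, out / "ks_paralogs.tsv")
        write_tsv(
            pd.DataFrame(
                [
                    {
                        "chromosome": s.chromosome,
                        "n_genes": s.n_genes,
                        "median_ks": s.median_ks,
                        "mean_ks": s.mean_ks,
                        "iqr_ks": s.iqr_ks,
                        "subgenome": partition.assignments.get(s.chromosome, "NA"),
                    }
                    for s in summaries
                ]
            ),
            out / "chromosome_summaries.tsv",
        )
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=False)
            fh.write("\n")
    return report
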