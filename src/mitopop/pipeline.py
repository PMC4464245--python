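"""End-to-end orchestration of the analysis stages.

A pipeline run either simulates a strain set (with full planted truth)
or loads real inputs (FASTA + GFF3 genomes, an aligned FASTA, population
and site tables), then runs: GC-cluster scanning and population
statistics; intron profiling with a binary-character NJ tree; diversity
statistics on the multiple alignment; the concatenated-CDS NJ tree; and
pairwise indel accounting. All tabular outputs are TSV, trees are
Newick, and a JSON manifest records versions, seed, thresholds, and
stage timings.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import (MultipleAlignment, pairwise_indels, pnps, region_pi,
                        window_polymorphism)
from .gcclusters import (ConsensusTable, anova_by_population,
                         cluster_count_table, conserved_positions,
                         default_consensus_table, m4_pairing, scan_genome,
                         write_anova_tsv, write_hits_bed, write_hits_tsv)
from .introns import (IntronSiteTable, binary_distance, build_profile_matrix,
                      format_frequency_table, intron_frequency_by_population)
from .io import (ValidationError, read_annotated_genome, write_fasta,
                 write_gff3)
from .phylo import (neighbor_joining, p_distance_matrix, population_rf,
                    write_newick)
from .simulate import (GENE_ORDER, SimConfig, default_intron_site_table,
                       simulate_population_set)

logger = logging.getLogger(__name__)

ALL_STAGES = ("gc", "introns", "diversity", "phylo", "indels")


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run.

    Exactly one of ``simulate`` (a :class:`SimConfig` or its kwargs) and
    ``inputs`` (paths to real data) must be given.
    """

    outdir: str = "mitopop_out"
    seed: int = 0
    simulate: Optional[dict] = None
    inputs: Optional[dict] = None
    stages: tuple = ALL_STAGES
    window: int = 30
    gc_threshold: float = 0.60
    pi_window: int = 100
    pi_step: int = 50
    anchor_k: int = 20

    def __post_init__(self):
        if (self.simulate is None) == (self.inputs is None):
            raise ValidationError(
                "exactly one of 'simulate' and 'inputs' must be configured"
            )
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValidationError(f"unknown stages {sorted(unknown)}")
        if not 0 < self.gc_threshold < 1 or self.window < 2:
            raise ValidationError("thresholds outside documented ranges")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _sim_config(config: PipelineConfig) -> SimConfig:
    kwargs = dict(config.simulate or {})
    kwargs.setdefault("rng_seed", config.seed)
    return SimConfig(**kwargs)


def _load_inputs(config: PipelineConfig):
    paths = config.inputs
    genomes = []
    fasta_dir = Path(paths["fasta_dir"])
    gff_dir = Path(paths["gff_dir"])
    for fasta in sorted(fasta_dir.glob("*.fasta")) + sorted(fasta_dir.glob("*.fa")):
        gff = gff_dir / (fasta.stem + ".gff3")
        genomes.append(read_annotated_genome(fasta, gff))
    alignment = None
    if paths.get("alignment"):
        alignment = MultipleAlignment.from_fasta(paths["alignment"])
    populations = None
    if paths.get("populations_tsv"):
        df = pd.read_csv(paths["populations_tsv"], sep="\t")
        populations = dict(zip(df["strain"], df["population"]))
    site_table = (IntronSiteTable.from_tsv(paths["site_table"])
                  if paths.get("site_table") else default_intron_site_table())
    consensus = (ConsensusTable.from_tsv(paths["consensus_table"])
                 if paths.get("consensus_table") else default_consensus_table())
    return genomes, alignment, populations, site_table, consensus, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the in-memory report bundle.

    The bundle maps stage names to their key results (tables, trees,
    summaries); everything is also written under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    timings: dict = {}
    t_start = time.time()

    if config.simulate is not None:
        sim = _sim_config(config)
        t0 = time.time()
        genomes, truth = simulate_population_set(sim)
        timings["simulate"] = time.time() - t0
        alignment = truth.alignment
        populations = truth.populations
        site_table = default_intron_site_table(sim.gene_templates,
                                               sim.rnl_template)
        consensus = sim.consensus_table
        bundle["truth"] = truth
        simdir = outdir / "genomes"
        simdir.mkdir(exist_ok=True)
        write_fasta(((g.strain_id, g.sequence) for g in genomes),
                    simdir / "strains.fasta")
        for g in genomes:
            write_gff3(g, simdir / f"{g.strain_id}.gff3")
        truth.intron_presence.to_csv(outdir / "truth_introns.tsv", sep="\t")
        pd.DataFrame(
            [(s, populations[s]) for s in truth.strains],
            columns=["strain", "population"],
        ).to_csv(outdir / "populations.tsv", sep="\t", index=False)
        alignment.to_fasta(outdir / "true_alignment.fasta")
    else:
        genomes, alignment, populations, site_table, consensus, truth = \
            _load_inputs(config)
        if not genomes:
            raise ValidationError("no genomes found in inputs")
    bundle["genomes"] = genomes
    bundle["populations"] = populations

    if "gc" in config.stages:
        t0 = time.time()
        scans = {g.strain_id: scan_genome(g, consensus, config.window,
                                          config.gc_threshold)
                 for g in genomes}
        counts = cluster_count_table(genomes, consensus, scans=scans)
        counts.to_csv(outdir / "gc_counts.tsv", sep="\t",
                      index_label="strain")
        write_hits_tsv(scans, outdir / "gc_hits.tsv")
        beddir = outdir / "gc_bed"
        beddir.mkdir(exist_ok=True)
        for sid, scan in scans.items():
            write_hits_bed(scan.hits, sid, beddir / f"{sid}.bed")
        pairing = {sid: m4_pairing(scan.hits, scan.arrays)
                   for sid, scan in scans.items()}
        gc_result = {"scans": scans, "counts": counts, "m4_pairing": pairing}
        if populations:
            anova = anova_by_population(counts, populations)
            write_anova_tsv(anova, outdir / "gc_anova.tsv")
            gc_result["anova"] = anova
        if alignment is not None and set(alignment.taxa) <= set(scans):
            conserved = conserved_positions(
                alignment, {t: scans[t].regions for t in alignment.taxa})
            gc_result["conserved"] = conserved
            pd.DataFrame(conserved, columns=["col_start", "col_end"]).to_csv(
                outdir / "gc_conserved.tsv", sep="\t", index=False)
        bundle["gc"] = gc_result
        timings["gc"] = time.time() - t0

    if "introns" in config.stages:
        t0 = time.time()
        matrix = build_profile_matrix(genomes, site_table)
        matrix.to_csv(outdir / "intron_matrix.tsv", sep="\t",
                      index_label="strain")
        intron_result = {"matrix": matrix}
        if populations:
            freq = intron_frequency_by_population(matrix, populations)
            format_frequency_table(freq).to_csv(
                outdir / "intron_frequencies.tsv", sep="\t",
                index_label="population")
            intron_result["frequencies"] = freq
        if len(matrix) >= 3:
            tree = neighbor_joining(binary_distance(matrix))
            write_newick(tree, outdir / "intron_tree.nwk")
            intron_result["tree"] = tree
        bundle["introns"] = intron_result
        timings["introns"] = time.time() - t0

    if "diversity" in config.stages and alignment is not None:
        t0 = time.time()
        rows = []
        regions = (sorted(set(alignment.region_labels))
                   if alignment.region_labels is not None else [None])
        for region in list(regions) + [None]:
            for mode in ("with_indels", "without_indels"):
                est = region_pi(alignment, region, mode)
                rows.append((est.region, est.mode, est.pi, est.n_sites,
                             est.n_polymorphic))
        pi_table = pd.DataFrame(
            rows, columns=["region", "mode", "pi", "n_sites", "n_polymorphic"]
        ).drop_duplicates(subset=["region", "mode"])
        pi_table.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
        windows = window_polymorphism(alignment, config.pi_window,
                                      config.pi_step)
        pd.DataFrame(
            [(w.start, w.end, w.count, w.partial) for w in windows],
            columns=["col_start", "col_end", "n_polymorphic", "partial"],
        ).to_csv(outdir / "windows.tsv", sep="\t", index=False)
        div_result = {"pi": pi_table, "windows": windows}
        if truth is not None:
            pnps_rows = []
            for gene in GENE_ORDER:
                cols = np.flatnonzero(
                    (truth.column_gene == gene)
                    & (alignment.region_labels == "exon"))
                sub = [(t, alignment.array[i, cols].tobytes().decode())
                       for i, t in enumerate(alignment.taxa)]
                res = pnps(sub, gene=gene)
                from .diversity import count_polymorphic_sites
                n_poly = count_polymorphic_sites(
                    alignment, [(c, c + 1) for c in cols], "without_indels")
                pnps_rows.append((gene, res.n_sites, res.s_sites, res.nd,
                                  res.sd, res.pn, res.ps, res.ratio, n_poly))
            pnps_table = pd.DataFrame(
                pnps_rows,
                columns=["gene", "N_sites", "S_sites", "Nd", "Sd", "pN", "pS",
                         "pN_pS", "polymorphic_sites"])
            pnps_table.to_csv(outdir / "pnps.tsv", sep="\t", index=False)
            div_result["pnps"] = pnps_table
        bundle["diversity"] = div_result
        timings["diversity"] = time.time() - t0

    if "phylo" in config.stages and alignment is not None and alignment.n_taxa >= 3:
        t0 = time.time()
        if truth is not None:
            cds_cols = np.flatnonzero(
                np.isin(truth.column_gene, list(GENE_ORDER))
                & (alignment.region_labels == "exon"))
            cds_aln = [(t, alignment.array[i, cds_cols].tobytes().decode())
                       for i, t in enumerate(alignment.taxa)]
        else:
            cds_aln = alignment
        dmat = p_distance_matrix(cds_aln)
        tree = neighbor_joining(dmat)
        write_newick(tree, outdir / "cds_tree.nwk")
        phylo_result = {"tree": tree, "distance": dmat}
        if truth is not None and populations:
            phylo_result["population_rf"] = population_rf(
                tree, populations, truth.population_tree)
            if "introns" in bundle and "tree" in bundle["introns"]:
                phylo_result["intron_population_rf"] = population_rf(
                    bundle["introns"]["tree"], populations,
                    truth.population_tree)
        bundle["phylo"] = phylo_result
        timings["phylo"] = time.time() - t0

    if "indels" in config.stages and len(genomes) >= 2:
        t0 = time.time()
        a, b = genomes[0], genomes[1]
        summary = pairwise_indels(a.sequence, b.sequence, config.anchor_k)
        pd.DataFrame(
            [(e.gap_in, e.start, e.end, e.length) for e in summary.events],
            columns=["gap_in", "start", "end", "length"],
        ).to_csv(outdir / "indels.tsv", sep="\t", index=False)
        bundle["indels"] = {"pair": (a.strain_id, b.strain_id),
                            "summary": summary}
        timings["indels"] = time.time() - t0

    manifest = {
        "mitopop_version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "thresholds": {
            "window": config.window,
            "gc_threshold": config.gc_threshold,
            "pi_window": config.pi_window,
            "pi_step": config.pi_step,
            "anchor_k": config.anchor_k,
        },
        "n_strains": len(genomes),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "total_s": round(time.time() - t_start, 3),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    bundle["manifest"] = manifest
    for stage, dt in timings.items():
        logger.debug("stage %s: %.2f s", stage, dt)
    return bundle
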