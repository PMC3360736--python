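"""End-to-end orchestration: screen -> network -> modules -> statistics -> genomics.

One configuration drives the whole analysis; every stage writes its artifact
to the output directory so any later stage can be resumed from disk, and a
JSON run report collects the headline numbers (responsive genes, selected
cutoff, network size, module count and size range, hub counts, QTL overlap
and permutation p).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import deg_screen, hub_genomics, mcl_modules, module_stats, motif_compare
from . import network_build, synthetic_data
from .deg_screen import ExpressionSet
from .hub_genomics import GenomicTrack, read_qtl_bed
from .mcl_modules import MCLParams, ModulePartition, module_agreement
from .synthetic_data import SimulationConfig

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets: stage-level reproducibility does not depend
# on whether earlier randomized stages ran
_PERM_SEED_OFFSET = 7919


@dataclass
class PipelineConfig:
    """All inputs and stage parameters of one pipeline run.

    Either ``simulation`` (a :class:`SimulationConfig`, inputs generated on
    the fly and written next to the results) or the explicit input paths
    must be provided. Stage parameter defaults follow the published
    analysis: p<0.05 with two-fold change in >=2 of 5 sets, density-minimum
    cutoff, reciprocal top-k pruning at the network's average degree, MCL
    inflation 1.2, enrichment below adjusted p 0.01, top 20% hubs, 1-Mb
    bins with score > 100 over > 0.5 Mb, 1000 permutations, motif cutoff
    0.65.
    """

    outdir: str = "drynet_out"
    seed: int = 0
    simulation: SimulationConfig | None = None
    expression: str | None = None
    design: str | None = None
    gene_bed: str | None = None
    qtl_bed: str | None = None
    go_tsv: str | None = None
    tissue_tsv: str | None = None
    motifs: str | None = None
    reference_motifs: str | None = None

    alpha: float = 0.05
    fold_cutoff: float = 2.0
    min_sets: int = 2
    cutoff: float | str = "auto"
    cutoff_grid: tuple[float, float, float] = (0.50, 0.95, 0.01)
    k_limit: int | str = "auto"
    inflation: float = 1.2
    min_module_size: int = 2
    star_alpha: float = 0.001
    enrichment_alpha: float = 0.01
    hub_fraction: float = 0.20
    bin_size: int = 1_000_000
    score_threshold: float = 100.0
    min_span: int = 500_000
    n_perm: int = 1000
    motif_cutoff: float = 0.65

    def __post_init__(self) -> None:
        if self.simulation is None and (self.expression is None or self.design is None):
            raise ValueError("provide either a simulation config or expression+design paths")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        if self.simulation is not None:
            d["simulation"]["module_sizes"] = list(self.simulation.module_sizes)
            d["simulation"]["planted_hub_regions"] = [
                list(r) for r in self.simulation.planted_hub_regions
            ]
            d["simulation"]["qtl_length_range"] = list(self.simulation.qtl_length_range)
        d["cutoff_grid"] = list(self.cutoff_grid)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig(**d["simulation"])
        if "cutoff_grid" in d:
            d["cutoff_grid"] = tuple(d["cutoff_grid"])
        return cls(**d)


def _load_expression_sets(config: PipelineConfig) -> list[ExpressionSet]:
    matrix = pd.read_csv(config.expression, sep="\t", index_col="gene")
    design = pd.read_csv(config.design, sep="\t", index_col="sample")
    esets = []
    for sid in design["set"].unique():
        d = design[design["set"] == sid]
        esets.append(ExpressionSet(matrix=matrix[list(d.index)], design=d, set_id=str(sid)))
    return esets


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full analysis; returns the run report (also saved as JSON).

    Stage order: differential screen, correlation/threshold selection,
    network build, MCL module detection, module statistics, hub genomics
    (QTL permutation only when QTLs are available), then motif comparison
    when motif inputs are given. Any stage failure propagates with its
    stage logged; artifacts of completed stages remain on disk.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": config.seed}
    planted: ModulePartition | None = None
    track: GenomicTrack | None = None
    qtls: pd.DataFrame | None = None
    go: pd.DataFrame | None = None
    sim = config.simulation

    # --- inputs ---------------------------------------------------------
    logger.info("stage inputs: %s", "synthetic" if sim else "files")
    if sim is not None:
        esets = synthetic_data.generate_expression_sets(sim)
        planted = synthetic_data.planted_partition(sim)
        go = synthetic_data.generate_go_annotation(sim, planted)
        synthetic_data.write_inputs(sim, out / "inputs", esets, go=go)
    else:
        esets = _load_expression_sets(config)
        if config.go_tsv:
            go = pd.read_csv(config.go_tsv, sep="\t")
        if config.qtl_bed:
            qtls = read_qtl_bed(config.qtl_bed)
    report["n_genes"] = int(len(esets[0].matrix.index))
    report["n_sets"] = len(esets)

    # --- differential screen -------------------------------------------
    logger.info("stage deg_screen")
    deg = deg_screen.screen(
        esets, alpha=config.alpha, fold_cutoff=config.fold_cutoff, min_sets=config.min_sets
    )
    deg.to_csv(out / "deg_table.tsv", sep="\t")
    responsive = deg.index[deg["responsive"]].tolist()
    report["n_responsive"] = len(responsive)
    if len(responsive) < 3:
        raise RuntimeError("deg_screen: fewer than 3 responsive genes; cannot build a network")

    # --- network construction ------------------------------------------
    logger.info("stage network_build")
    corr = network_build.correlation_matrix(esets, genes=responsive)
    lo, hi, step = config.cutoff_grid
    grid = np.round(np.arange(lo, hi + 1e-9, step), 6)
    curve = network_build.density_curve_and_cutoff(corr, grid=grid)
    curve.table.to_csv(out / "density_curve.tsv", sep="\t", index=False)
    cutoff = curve.selected_cutoff if config.cutoff == "auto" else float(config.cutoff)
    net = network_build.build_network(corr, cutoff=cutoff, k_limit=config.k_limit)
    net.to_edge_tsv(out / "edges.tsv")
    net.to_graphml(out / "network.graphml")
    stats = network_build.degree_stats(net) if net.n_nodes >= 10 else None
    report.update(
        selected_cutoff=cutoff,
        k_limit=net.k_limit,
        preliminary_nodes=net.summary["preliminary_nodes"],
        preliminary_edges=net.summary["preliminary_edges"],
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        mean_edge_r=net.summary["mean_edge_weight"],
        average_degree=net.summary["average_degree"],
        power_law_exponent=stats.exponent if stats else None,
    )

    # --- module detection ------------------------------------------------
    logger.info("stage mcl_modules")
    partition = mcl_modules.mcl_cluster(
        net, MCLParams(inflation=config.inflation), min_module_size=config.min_module_size
    )
    partition.to_tsv(out / "modules.tsv")
    sizes = partition.module_sizes
    report.update(
        n_modules=len(sizes),
        module_size_min=min(sizes.values()) if sizes else 0,
        module_size_max=max(sizes.values()) if sizes else 0,
        n_module_genes=len(partition.assignments),
    )
    if planted is not None and partition.assignments:
        _, ari = module_agreement(planted, partition)
        report["planted_module_ari"] = ari

    # --- module statistics ----------------------------------------------
    logger.info("stage module_stats")
    resp_tables = []
    for e in esets:
        fc = deg[f"log2fc.{e.set_id}"]
        t = module_stats.module_response_significance(
            partition, fc, star_alpha=config.star_alpha
        )
        t.insert(0, "dataset", e.set_id)
        resp_tables.append(t)
    pd.concat(resp_tables).to_csv(out / "module_response.tsv", sep="\t")
    if go is not None:
        enrich = module_stats.go_enrichment(partition, go, alpha=config.enrichment_alpha)
        enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        report["n_enriched_terms"] = int(enrich["enriched"].sum()) if len(enrich) else 0
    if config.tissue_tsv:
        tissue = pd.read_csv(config.tissue_tsv, sep="\t", index_col=0)
        module_stats.tissue_profile(partition, tissue).to_csv(
            out / "tissue_profile.tsv", sep="\t"
        )

    # --- hub genomics ----------------------------------------------------
    logger.info("stage hub_genomics")
    connectivity = hub_genomics.intramodular_connectivity(net, partition)
    connectivity.to_csv(out / "connectivity.tsv", sep="\t", header=["connectivity"])
    hubs = hub_genomics.select_hubs(partition, connectivity, fraction=config.hub_fraction)
    (out / "hub_genes.txt").write_text("\n".join(hubs) + "\n")
    report["n_hubs"] = len(hubs)

    if sim is not None:
        track = synthetic_data.generate_genome_annotation(sim, planted, connectivity)
        qtls = synthetic_data.generate_qtls(sim, track) if sim.n_qtls or sim.qtl_mode == "planted" else None
        track.to_bed(out / "inputs" / "genes.bed")
        if qtls is not None and len(qtls):
            hub_genomics.write_qtl_bed(qtls, out / "inputs" / "qtls.bed")
    elif config.gene_bed:
        track = GenomicTrack.from_bed(config.gene_bed, connectivity=connectivity)

    if track is not None:
        clusters = hub_genomics.detect_hub_clusters(
            track, bin_size=config.bin_size,
            score_threshold=config.score_threshold, min_span=config.min_span,
        )
        cl = clusters.drop(columns=["genes"]).assign(
            genes=[",".join(g) for g in clusters["genes"]]
        )
        cl.to_csv(out / "hub_clusters.tsv", sep="\t", index=False)
        report["n_hub_clusters"] = int(len(clusters))
        if qtls is not None and len(qtls):
            perm = hub_genomics.permutation_test(
                track, qtls, n_perm=config.n_perm,
                seed=(config.seed + _PERM_SEED_OFFSET) % 2**31,
                bin_size=config.bin_size, score_threshold=config.score_threshold,
                min_span=config.min_span,
            )
            pd.DataFrame(
                [dict(actual=perm.actual, null_mean=perm.null_counts.mean(),
                      null_sd=perm.null_counts.std(), p=perm.p_value,
                      n_perm=perm.n_perm)]
            ).to_csv(out / "permutation.tsv", sep="\t", index=False)
            report["n_qtl_overlaps"] = perm.actual
            report["permutation_p"] = perm.p_value
        else:
            logger.info("no QTL intervals supplied; permutation test skipped")
            report["permutation_p"] = None
    else:
        logger.info("no gene positions supplied; hub genomics limited to hub selection")

    # --- motif comparison (optional) -------------------------------------
    if config.motifs:
        logger.info("stage motif_compare")
        motifs = motif_compare.read_motifs(config.motifs)
        motifs, _ = motif_compare.filter_mononucleotide_repeats(motifs)
        cs = motif_compare.cluster_and_merge(motifs, cutoff=config.motif_cutoff)
        motif_compare.write_motifs(cs.merged, out / "merged_motifs.txt")
        report["n_motifs"] = len(motifs)
        report["n_nonredundant_motifs"] = len(cs.merged)
        if config.reference_motifs:
            refs = motif_compare.read_motifs(config.reference_motifs, width_bounds=None)
            ann = motif_compare.annotate_motifs(cs, refs, cutoff=config.motif_cutoff)
            ann.to_csv(out / "motif_annotation.tsv", sep="\t", index=False)

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    logger.info("run complete: %s", report)
    return report
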