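"""End-to-end orchestration: normalize, cluster, classify, call DIPs.

``run_pipeline`` composes the stage functions in order — optional
G-correction, power-law normalization, tag clustering with trimming and
the 5 TPM floor, consensus aggregation, promoter annotation, initiator
classification, DIP calling, ratio statistics, cohort dynamics and
optional motif enrichment — logging parameters and row counts at every
stage.  ``write_outputs`` serializes every intermediate table so each
reported number is traceable to a TSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dualinit import io as dio
from dualinit import pipeline as dpipe
from dualinit import initiator as dinit
from dualinit import dynamics as ddyn
from dualinit import motifs as dmot

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    normalized: pd.DataFrame
    clusters: list
    consensus: list
    calls: pd.DataFrame
    cluster_matrix: pd.DataFrame
    gene_matrix: pd.DataFrame | None
    dips: list[str]
    ratio_table: pd.DataFrame
    class_totals: pd.DataFrame
    cohort_stats: dict = field(default_factory=dict)
    trajectories: dict = field(default_factory=dict)
    motif_enrichment: dict = field(default_factory=dict)

    @property
    def dip_matrix(self) -> pd.DataFrame:
        matrix = self.gene_matrix if self.gene_matrix is not None else self.cluster_matrix
        return matrix.loc[self.dips]


def run_pipeline(
    genome,
    sample_tables: dict[str, pd.DataFrame],
    genes: pd.DataFrame | None = None,
    sample_sheet: pd.DataFrame | None = None,
    norm_params: dpipe.NormalizationParams | None = None,
    clust_params: dpipe.ClusteringParams | None = None,
    class_params: dinit.ClassificationParams | None = None,
    dip_params: ddyn.DipParams | None = None,
    cohort_order: list[str] | None = None,
    pfms: list | None = None,
    motif_gene_set: set[str] | None = None,
    motif_params: dmot.MotifScanParams | None = None,
    g_correction: bool = False,
) -> PipelineResult:
    """Run every stage on in-memory inputs and collect the results.

    ``sample_tables`` maps sample id to a single-sample CTSS table.
    DIP calling, ratios and trajectories run at gene level when gene
    models are provided, otherwise at consensus-cluster level.  Cohort
    dynamics require a sample sheet; trajectory selection additionally
    requires ``cohort_order`` (most-YC-enriched first).
    """
    norm_params = norm_params or dpipe.NormalizationParams()
    clust_params = clust_params or dpipe.ClusteringParams()
    class_params = class_params or dinit.ClassificationParams()
    dip_params = dip_params or ddyn.DipParams()

    merged = dio.merge_ctss_tables(sample_tables)
    logger.info("stage=merge samples=%d ctss=%d", len(sample_tables), len(merged))
    if g_correction:
        merged = dpipe.correct_extra_g(merged, genome)
        logger.info("stage=g_correction ctss=%d", len(merged))

    normalized = dpipe.power_law_normalize(merged, norm_params)
    logger.info("stage=normalize alpha_ref=%g t_ref=%g", norm_params.alpha_ref, norm_params.t_ref)

    clusters = dpipe.cluster_ctss(normalized, clust_params)
    clusters = [dpipe.trim_cluster(c, clust_params.q_low, clust_params.q_high) for c in clusters]
    clusters = dpipe.filter_clusters(clusters, clust_params.min_cluster_tpm)
    logger.info("stage=cluster max_gap=%d kept=%d", clust_params.max_gap, len(clusters))

    consensus = dpipe.aggregate_consensus(clusters, clust_params.consensus_dist)
    logger.info("stage=consensus dist=%d n=%d", clust_params.consensus_dist, len(consensus))
    if genes is not None:
        dpipe.annotate_promoters(consensus, genes, clust_params.promoter_window)
        n_assigned = sum(cc.gene_id is not None for cc in consensus)
        logger.info("stage=annotate assigned=%d/%d", n_assigned, len(consensus))

    assigned = dpipe.assign_ctss_to_consensus(normalized, consensus)
    calls = dinit.classify_all(genome, assigned, class_params)
    cluster_matrix = dinit.class_tpm_table(calls, by="cluster_id")

    gene_matrix = None
    if genes is not None:
        gene_ids = pd.Series({cc.id: cc.gene_id or "" for cc in consensus})
        gene_matrix = ddyn.merge_gene_level(cluster_matrix, gene_ids)

    matrix = gene_matrix if gene_matrix is not None else cluster_matrix
    dips = ddyn.call_dips(matrix, dip_params)
    logger.info("stage=dips n=%d of %d promoters", len(dips), len(matrix))
    ratio_table = ddyn.yc_yr_ratio(matrix.loc[dips], dip_params.ratio_pseudocount)

    samples = sorted(sample_tables)
    in_cluster = calls[calls["cluster_id"] != ""]
    class_totals = pd.DataFrame(
        {
            cls: [
                in_cluster.loc[in_cluster["major_class"] == cls, f"tpm_{s}"].sum()
                for s in samples
            ]
            for cls in ("YR", "YC", "OTHER")
        },
        index=samples,
    )

    cohort_stats: dict = {}
    trajectories: dict = {}
    if sample_sheet is not None:
        cohort_samples: dict[str, list[str]] = {}
        treated_samples: dict[str, list[str]] = {}
        for row in sample_sheet.itertuples(index=False):
            target = treated_samples if row.treatment == "irradiated" else cohort_samples
            target.setdefault(row.cohort, []).append(row.sample)
        cohort_stats["cohort_samples"] = cohort_samples
        cohort_stats["treated_samples"] = treated_samples
        if cohort_order:
            top, bottom = cohort_order[0], cohort_order[-1]
            cohort_stats["paired_test"] = ddyn.paired_ratio_test(
                ratio_table, cohort_samples[top], cohort_samples[bottom]
            )
            totals = {
                c: (
                    float(sum(class_totals.loc[s, "YC"] for s in cohort_samples[c])),
                    float(sum(class_totals.loc[s, "YR"] for s in cohort_samples[c])),
                )
                for c in (top, bottom)
            }
            cohort_stats["class_chisq"] = ddyn.class_total_chisq(
                totals[top][0], totals[top][1], totals[bottom][0], totals[bottom][1]
            )
            trajectories["ratio"] = ddyn.trajectory_select(
                ratio_table, cohort_samples, cohort_order, metric="ratio"
            )
            if all(treated_samples.get(c) for c in cohort_order):
                trajectories["delta"] = ddyn.trajectory_select(
                    ratio_table,
                    cohort_samples,
                    list(reversed(cohort_order)),
                    metric="delta",
                    treatment_samples=treated_samples,
                )

    motif_enrichment: dict = {}
    if pfms and motif_gene_set:
        motif_params = motif_params or dmot.MotifScanParams()
        pwms = [dmot.pfm_to_pwm(p, motif_params.pseudocount, motif_params.background) for p in pfms]
        annotated = [cc for cc in consensus if genes is None or cc.gene_id is not None]
        motif_enrichment = dmot.enrichment_analysis(
            genome, annotated, pwms, motif_gene_set, motif_params
        )
        logger.info("stage=motifs motifs=%d", len(motif_enrichment))

    return PipelineResult(
        normalized=normalized,
        clusters=clusters,
        consensus=consensus,
        calls=calls,
        cluster_matrix=cluster_matrix,
        gene_matrix=gene_matrix,
        dips=dips,
        ratio_table=ratio_table,
        class_totals=class_totals,
        cohort_stats=cohort_stats,
        trajectories=trajectories,
        motif_enrichment=motif_enrichment,
    )


def run_from_files(
    genome_path,
    sample_sheet_path,
    annotation_path=None,
    cohort_order: list[str] | None = None,
    jaspar_path=None,
    gene_set_path=None,
    g_correction: bool = False,
    **params,
) -> PipelineResult:
    """File-based front end of :func:`run_pipeline` (used by the CLI)."""
    genome = dio.read_fasta(genome_path)
    sheet = dio.read_sample_sheet(sample_sheet_path)
    base = Path(sample_sheet_path).parent
    tables = {}
    for row in sheet.itertuples(index=False):
        p = Path(row.path)
        tables[row.sample] = dio.read_ctss_bed(p if p.is_absolute() else base / p)
    genes = dio.read_gtf_genes(annotation_path) if annotation_path else None
    pfms = dio.read_jaspar_pfm(jaspar_path) if jaspar_path else None
    gene_set = None
    if gene_set_path:
        gene_set = {
            line.strip().upper()
            for line in Path(gene_set_path).read_text().splitlines()
            if line.strip()
        }
    return run_pipeline(
        genome,
        tables,
        genes=genes,
        sample_sheet=sheet,
        cohort_order=cohort_order,
        pfms=pfms,
        motif_gene_set=gene_set,
        g_correction=g_correction,
        **params,
    )


def write_outputs(result: PipelineResult, outdir) -> Path:
    """Serialize every stage's table; the run report references these files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cluster_rows = [
        {
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "tstart": c.tstart,
            "tend": c.tend,
            "strand": c.strand,
            "tpm": c.tpm,
            "dominant_pos": c.dominant_pos,
        }
        for c in result.clusters
    ]
    pd.DataFrame(cluster_rows).to_csv(outdir / "tag_clusters.tsv", sep="\t", index=False)

    consensus_rows = [
        {
            "id": cc.id,
            "chrom": cc.chrom,
            "start": cc.start,
            "end": cc.end,
            "strand": cc.strand,
            "gene_id": cc.gene_id or "",
            "dominant_pos": cc.dominant_pos,
        }
        for cc in result.consensus
    ]
    pd.DataFrame(consensus_rows).to_csv(outdir / "consensus_clusters.tsv", sep="\t", index=False)

    result.calls.to_csv(outdir / "ctss_calls.tsv", sep="\t", index=False)
    result.cluster_matrix.to_csv(outdir / "class_tpm_clusters.tsv", sep="\t")
    if result.gene_matrix is not None:
        result.gene_matrix.to_csv(outdir / "class_tpm_genes.tsv", sep="\t")
    (outdir / "dips.txt").write_text("\n".join(result.dips) + "\n")
    result.ratio_table.to_csv(outdir / "ratios.tsv", sep="\t")
    result.class_totals.to_csv(outdir / "class_totals.tsv", sep="\t")
    for name, genes in result.trajectories.items():
        (outdir / f"trajectory_{name}.txt").write_text("\n".join(genes) + "\n")

    report = {
        "n_ctss": int(len(result.normalized)),
        "n_tag_clusters": len(result.clusters),
        "n_consensus_clusters": len(result.consensus),
        "n_dips": len(result.dips),
        "class_totals": {
            s: {cls: float(result.class_totals.loc[s, cls]) for cls in ("YR", "YC", "OTHER")}
            for s in result.class_totals.index
        },
        "cohort_stats": {
            k: v for k, v in result.cohort_stats.items() if k not in ("cohort_samples", "treated_samples")
        },
        "trajectories": {k: len(v) for k, v in result.trajectories.items()},
        "motif_enrichment": {
            m: {k: v for k, v in res.items() if k != "clusters"}
            for m, res in result.motif_enrichment.items()
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return outdir
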