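"""End-to-end pipeline runs, mass conservation, determinism, CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from dualinit import workflow
from dualinit.cli import main as cli_main
from dualinit.simulate import SyntheticConfig, simulate_dataset, truth_compare


class TestRunPipeline:
    def test_smoke_recovers_promoter_structure(self, small_dataset, small_result):
        res = small_result
        # noise clusters exist, but every dual promoter with expression
        # should have an annotated consensus cluster
        assert res.gene_matrix is not None
        assert len(res.dips) > 0
        assert set(res.dips) <= set(res.gene_matrix.index)

    def test_class_tpm_mass_conservation(self, small_result):
        """YR + YC + OTHER TPM equals total assigned TPM per sample."""
        calls = small_result.calls
        matrix = small_result.cluster_matrix
        samples = [c[len("tpm_") :] for c in calls.columns if c.startswith("tpm_")]
        assigned = calls[calls["cluster_id"] != ""]
        for s in samples:
            total = assigned[f"tpm_{s}"].sum()
            by_class = sum(
                matrix[f"{cls}_{s}"].sum() for cls in ("yr", "yc", "other")
            )
            assert by_class == pytest.approx(total, rel=1e-6)

    def test_yc_subtypes_partition_yc(self, small_result):
        matrix = small_result.cluster_matrix
        samples = {c.split("_", 1)[1] for c in matrix.columns if c.startswith("yc_")}
        for s in samples:
            np.testing.assert_allclose(
                matrix[f"yc_{s}"],
                matrix[f"top_{s}"] + matrix[f"topdeg_{s}"] + matrix[f"ycother_{s}"],
                rtol=1e-9,
                atol=1e-9,
            )

    def test_truth_recovery_on_small_cohort(self, small_dataset, small_result):
        rep = truth_compare(
            small_dataset,
            set(small_result.dips),
            small_result.gene_matrix,
            set(small_result.trajectories["ratio"]),
        )
        assert rep["dip_sensitivity"] > 0.9
        assert rep["dip_fdr"] < 0.1
        assert rep["yc_fraction_spearman"] > 0.85

    def test_cohort_stats_present(self, small_result):
        assert "paired_test" in small_result.cohort_stats
        assert "class_chisq" in small_result.cohort_stats
        # responsive cohort is YC-enriched relative to non-responsive
        assert small_result.cohort_stats["paired_test"]["mean_log2fc"] > 0

    def test_deterministic_rerun(self, small_dataset, small_result):
        ds = small_dataset
        res2 = workflow.run_pipeline(
            ds.genome,
            ds.samples,
            genes=ds.genes,
            sample_sheet=ds.sample_sheet,
            cohort_order=["responsive", "moderate", "non_responsive"],
        )
        assert res2.dips == small_result.dips
        pd.testing.assert_frame_equal(res2.gene_matrix, small_result.gene_matrix)
        assert res2.trajectories["ratio"] == small_result.trajectories["ratio"]

    def test_write_outputs_traceable(self, small_result, tmp_path):
        out = workflow.write_outputs(small_result, tmp_path / "run")
        report = json.loads((out / "report.json").read_text())
        # every headline number traces to an intermediate file
        dips = (out / "dips.txt").read_text().split()
        assert report["n_dips"] == len(dips)
        consensus = pd.read_csv(out / "consensus_clusters.tsv", sep="\t")
        assert report["n_consensus_clusters"] == len(consensus)
        totals = pd.read_csv(out / "class_totals.tsv", sep="\t", index_col=0)
        sample = totals.index[0]
        assert report["class_totals"][sample]["YC"] == pytest.approx(
            totals.loc[sample, "YC"]
        )


class TestMotifStage:
    def test_planted_motif_enriched_in_signature(self):
        cfg = SyntheticConfig(
            seed=17,
            n_promoters=300,
            depth=300_000,
            trajectory_fraction=0.5,
            motif_rate_signature=0.6,
            motif_rate_background=0.05,
        )
        ds = simulate_dataset(cfg)
        from dualinit.io import PositionFrequencyMatrix
        from dualinit.motifs import MotifScanParams

        # PFM for the planted consensus: one-hot columns
        consensus = cfg.motif_consensus
        counts = np.zeros((4, len(consensus)))
        for i, b in enumerate(consensus):
            counts["ACGT".index(b), i] = 20
        pfm = PositionFrequencyMatrix(motif_id="planted", counts=counts)
        signature = set(ds.promoters.loc[ds.promoters["is_trajectory"], "gene_id"])
        res = workflow.run_pipeline(
            ds.genome,
            ds.samples,
            genes=ds.genes,
            sample_sheet=ds.sample_sheet,
            pfms=[pfm],
            motif_gene_set=signature,
            motif_params=MotifScanParams(rel_score_threshold=0.95),
        )
        enr = res.motif_enrichment["planted"]
        assert enr["p"] < 0.05
        assert enr["odds_ratio"] > 1


class TestCli:
    def test_simulate_then_pipeline_then_motifs(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("n_promoters: 60\ndepth: 60000\nseed: 4\n")
        r = runner.invoke(
            cli_main, ["simulate", "--config", str(cfg), "--out", str(sim_dir)]
        )
        assert r.exit_code == 0, r.output
        assert (sim_dir / "genome.fa").exists()

        out_dir = tmp_path / "run"
        r = runner.invoke(
            cli_main,
            [
                "pipeline",
                "--genome", str(sim_dir / "genome.fa"),
                "--annotation", str(sim_dir / "genes.gtf"),
                "--samples", str(sim_dir / "samples.tsv"),
                "--cohort-order", "responsive,moderate,non_responsive",
                "--out", str(out_dir),
            ],
        )
        assert r.exit_code == 0, r.output
        assert (out_dir / "report.json").exists()
        assert (out_dir / "trajectory_ratio.txt").exists()

    def test_classify_subcommand(self, tmp_path):
        runner = CliRunner()
        (tmp_path / "g.fa").write_text(">c1\nTTCGTTTT\n")
        (tmp_path / "x.bed").write_text("c1\t2\t3\t.\t5\t+\n")
        out = tmp_path / "calls.tsv"
        r = runner.invoke(
            cli_main,
            ["classify", "--genome", str(tmp_path / "g.fa"), "--ctss", str(tmp_path / "x.bed"), "--out", str(out)],
        )
        assert r.exit_code == 0, r.output
        calls = pd.read_csv(out, sep="\t")
        assert calls.loc[0, "major_class"] == "YC"

    def test_config_error_exit_code(self, tmp_path):
        runner = CliRunner()
        (tmp_path / "g.fa").write_text(">c1\nACGT\n")
        (tmp_path / "s.tsv").write_text("sample\tpath\tcohort\tpair\ttreatment\n")
        r = runner.invoke(
            cli_main,
            [
                "pipeline",
                "--genome", str(tmp_path / "g.fa"),
                "--samples", str(tmp_path / "s.tsv"),
                "--alpha", "0.9",
                "--out", str(tmp_path / "o"),
            ],
        )
        assert r.exit_code == 2

    def test_data_error_exit_code(self, tmp_path):
        runner = CliRunner()
        (tmp_path / "g.fa").write_text(">c1\nACGT\n")
        (tmp_path / "s.tsv").write_text(
            "sample\tpath\tcohort\tpair\ttreatment\na\tmissing.bed\tx\t\tc\n"
        )
        r = runner.invoke(
            cli_main,
            [
                "pipeline",
                "--genome", str(tmp_path / "g.fa"),
                "--samples", str(tmp_path / "s.tsv"),
                "--out", str(tmp_path / "o"),
            ],
        )
        assert r.exit_code == 3
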