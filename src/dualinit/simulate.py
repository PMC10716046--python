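"""Synthetic CAGE data with known ground truth.

The generator emulates the statistical structure the analysis assumes:
promoters emitting intermingled YR- and YC-initiating tags, per-promoter
YC fractions drawn per cohort, promoter expression following a discrete
power law, cohort- and irradiation-driven shifts of the YC fraction,
intergenic noise tags, and signature promoters carrying a planted
transcription-factor motif.  Sequence contexts are physically written
into the emitted genome, so classifications made by the pipeline can be
checked against truth by re-reading the FASTA.

Layout: promoters are placed at fixed spacing; each promoter has a
20-bp core of CTSS whose -1/+1 dinucleotides and (for YC starts)
first-five-base contexts are rewritten into the genome without
overlapping one another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dualinit.io import GenomeStore, revcomp, write_fasta, write_ctss_bed, write_sample_sheet

PURINES = "AG"
PYRIMIDINES_STR = "CT"

# spacing of CTSS inside a promoter core: each start owns a 6-bp context
# block [-1, +4] in transcript orientation, so blocks never overlap
CTSS_STEP = 6


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Cohort YC-fraction means (0.35 / 0.25 / 0.15) span the range of
    5'-C transcript content observed between the most and least
    radiotherapy-responsive samples in the motivating system; treatment
    effects multiply the YC fraction upon "irradiation" and shrink with
    decreasing responsiveness.  Expression follows a discrete power law
    whose reverse-cumulative slope is ``power_alpha``, scaled to
    ``depth`` tags per sample.
    """

    seed: int = 42
    n_contigs: int = 2
    n_promoters: int = 1000
    promoter_spacing: int = 400
    n_ctss_per_promoter: int = 4
    cohorts: tuple[str, ...] = ("responsive", "moderate", "non_responsive")
    cohort_yc_mean: dict = field(
        default_factory=lambda: {
            "responsive": 0.35,
            "moderate": 0.25,
            "non_responsive": 0.15,
        }
    )
    beta_concentration: float = 20.0
    samples_per_cohort: int = 2
    with_treatment: bool = False
    treatment_effect: dict = field(
        default_factory=lambda: {
            "responsive": 0.55,
            "moderate": 0.72,
            "non_responsive": 0.95,
        }
    )
    depth: int = 1_000_000
    power_alpha: float = 1.05
    noise_rate: float = 2.0  # intergenic tags per kb
    dual_fraction: float = 0.5
    trajectory_fraction: float = 0.3
    top_fraction: tuple[float, float, float] = (0.3, 0.3, 0.4)  # TOP / TOP-deg / YC-other
    internal_top_rate: float = 0.1
    motif_consensus: str = "CCGGAAGT"
    motif_rate_signature: float = 0.3
    motif_rate_background: float = 0.1

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for frac in (self.dual_fraction, self.trajectory_fraction, *self.top_fraction):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must lie in [0, 1]")
        if self.promoter_spacing < 2 * self.margin + self.core_width:
            raise ValueError(
                f"promoter_spacing must be at least {2 * self.margin + self.core_width}"
            )

    @property
    def core_width(self) -> int:
        return CTSS_STEP * (self.n_ctss_per_promoter - 1) + 1

    @property
    def margin(self) -> int:
        return 170  # room for the scanned promoter window upstream

    @property
    def sample_names(self) -> list[str]:
        names = []
        for cohort in self.cohorts:
            for i in range(1, self.samples_per_cohort + 1):
                names.append(f"{cohort}_{i}")
                if self.with_treatment:
                    names.append(f"{cohort}_{i}_irr")
        return names


# ---------------------------------------------------------------------------
# Genome and annotation
# ---------------------------------------------------------------------------


def _transcript_write(seq: list[str], pos: int, strand: str, bases: str) -> None:
    """Write ``bases`` into ``seq`` starting at ``pos`` in transcript orientation."""
    if strand == "+":
        for i, b in enumerate(bases):
            seq[pos + i] = b
    else:
        for i, b in enumerate(bases):
            seq[pos - i] = revcomp(b)


def generate_genome_and_annotation(
    config: SyntheticConfig,
) -> tuple[GenomeStore, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Build the genome, gene models and promoter/CTSS registry.

    Returns (genome, genes, promoter registry, CTSS registry).  The
    registry rows record exactly what was written into the sequence:
    per CTSS its designated class, YC subtype and internal-TOP status;
    per promoter its strand, anchor, dual/trajectory/motif labels and
    per-cohort YC fractions.
    """
    rng = np.random.default_rng(config.seed)
    per_contig = math.ceil(config.n_promoters / config.n_contigs)
    contig_len = per_contig * config.promoter_spacing + 2 * config.promoter_spacing

    seqs = {
        f"chr{c + 1}": list(rng.choice(list("ACGT"), size=contig_len))
        for c in range(config.n_contigs)
    }

    n = config.n_promoters
    is_dual = rng.random(n) < config.dual_fraction
    is_traj = is_dual & (rng.random(n) < config.trajectory_fraction)
    strands = rng.choice(["+", "-"], size=n)
    # null promoters share one YC fraction across cohorts (exchangeable);
    # trajectory promoters draw one fraction per cohort around the
    # cohort mean, redrawn until strictly ordered along the cohort ranking
    conc = config.beta_concentration
    base_mean = config.cohort_yc_mean[config.cohorts[len(config.cohorts) // 2]]
    null_frac = rng.beta(base_mean * conc, (1 - base_mean) * conc, size=n)

    promoter_rows = []
    ctss_rows = []
    gene_rows = []
    subtype_choices = np.array(["TOP", "TOP_DEG", "YC_OTHER"])

    for p in range(n):
        contig = f"chr{(p % config.n_contigs) + 1}"
        seq = seqs[contig]
        slot = p // config.n_contigs
        anchor = config.promoter_spacing + slot * config.promoter_spacing
        strand = strands[p]
        step = CTSS_STEP if strand == "+" else -CTSS_STEP
        positions = [anchor + i * step for i in range(config.n_ctss_per_promoter)]
        pid = f"P{p + 1:05d}"
        gene_id = f"G{p + 1:05d}"

        if is_dual[p]:
            classes = ["YR", "YC"] * (config.n_ctss_per_promoter // 2 + 1)
            classes = classes[: config.n_ctss_per_promoter]
        else:
            classes = ["YR"] * config.n_ctss_per_promoter

        # per-cohort YC fractions
        fracs = {}
        if is_traj[p]:
            while True:
                vals = [
                    float(
                        rng.beta(
                            config.cohort_yc_mean[c] * conc,
                            (1 - config.cohort_yc_mean[c]) * conc,
                        )
                    )
                    for c in config.cohorts
                ]
                if all(a > b for a, b in zip(vals, vals[1:])):
                    break
            fracs = dict(zip(config.cohorts, vals))
        else:
            fracs = {c: float(null_frac[p]) for c in config.cohorts}
        if not is_dual[p]:
            fracs = {c: 0.0 for c in config.cohorts}

        for i, (pos, cls) in enumerate(zip(positions, classes)):
            minus1 = rng.choice(list(PYRIMIDINES_STR))
            if cls == "YR":
                plus1 = rng.choice(list(PURINES))
                _transcript_write(seq, pos - (1 if strand == "+" else -1), strand, minus1)
                _transcript_write(seq, pos, strand, plus1)
                subtype = "NA"
            else:
                subtype = str(rng.choice(subtype_choices, p=list(config.top_fraction)))
                if subtype == "TOP":
                    tail = "".join(rng.choice(list(PYRIMIDINES_STR), size=4))
                elif subtype == "TOP_DEG":
                    tail = list(rng.choice(list(PYRIMIDINES_STR), size=4))
                    tail[rng.integers(0, 4)] = str(rng.choice(list(PURINES)))
                    tail = "".join(tail)
                else:
                    # at most two pyrimidines in the next four bases
                    n_py = int(rng.integers(0, 3))
                    tail = [str(rng.choice(list(PURINES))) for _ in range(4)]
                    for j in rng.choice(4, size=n_py, replace=False):
                        tail[j] = str(rng.choice(list(PYRIMIDINES_STR)))
                    tail = "".join(tail)
                _transcript_write(seq, pos - (1 if strand == "+" else -1), strand, minus1)
                _transcript_write(seq, pos, strand, "C" + tail)
            ctss_rows.append(
                {
                    "promoter_id": pid,
                    "chrom": contig,
                    "pos": pos,
                    "strand": strand,
                    "true_class": cls,
                    "true_subtype": subtype,
                    "internal_top": False,
                }
            )

        # optional internal-TOP leader downstream of the last CTSS
        if rng.random() < config.internal_top_rate:
            last = positions[-1]
            off = 10
            run_start = last + off if strand == "+" else last - off
            _transcript_write(seq, run_start, strand, "".join(rng.choice(list(PYRIMIDINES_STR), size=5)))
            for row in ctss_rows[-config.n_ctss_per_promoter :]:
                # the run sits within 50 nt of every member CTSS
                row["internal_top"] = True

        # motif planting upstream of the promoter core
        signature = bool(is_traj[p])
        rate = config.motif_rate_signature if signature else config.motif_rate_background
        motif_planted = bool(rng.random() < rate)
        if motif_planted:
            motif_pos = anchor - 60 if strand == "+" else anchor + 60
            _transcript_write(seq, motif_pos, strand, config.motif_consensus)

        gene_end = anchor + 300 if strand == "+" else anchor - 300
        gene_rows.append(
            {
                "gene_id": gene_id,
                "chrom": contig,
                "strand": strand,
                "tss": anchor,
                "start": min(anchor, gene_end),
                "end": max(anchor, gene_end) + 1,
            }
        )
        promoter_rows.append(
            {
                "promoter_id": pid,
                "gene_id": gene_id,
                "chrom": contig,
                "strand": strand,
                "anchor": anchor,
                "is_dual": bool(is_dual[p]),
                "is_trajectory": bool(is_traj[p]),
                "motif_planted": motif_planted,
                **{f"yc_fraction_{c}": fracs[c] for c in config.cohorts},
            }
        )

    genome = GenomeStore({name: "".join(s) for name, s in seqs.items()})
    genes = pd.DataFrame(gene_rows)
    promoters = pd.DataFrame(promoter_rows)
    ctss_registry = pd.DataFrame(ctss_rows)
    return genome, genes, promoters, ctss_registry


# ---------------------------------------------------------------------------
# Tag samples
# ---------------------------------------------------------------------------


def _power_law_expression(n: int, alpha: float, depth: float, rng) -> np.ndarray:
    """Expected per-promoter tag totals following the reference power law.

    Expression at rank r is proportional to r ** (-1/alpha) (so the
    reverse-cumulative count distribution has slope -alpha), scaled to
    sum to ``depth``; ranks are assigned to promoters in a random but
    seed-stable permutation.
    """
    ranks = np.arange(1, n + 1, dtype=float)
    weights = ranks ** (-1.0 / alpha)
    weights = weights / weights.sum() * depth
    perm = rng.permutation(n)
    out = np.empty(n)
    out[perm] = weights
    return out


def generate_ctss_samples(
    config: SyntheticConfig,
    promoters: pd.DataFrame,
    ctss_registry: pd.DataFrame,
    genome: GenomeStore,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Draw per-sample CTSS tag tables and the per-sample truth table.

    Per sample: each promoter's tag total is Poisson around its
    power-law expectation, split YC vs YR by the promoter's
    cohort-specific YC fraction (binomial), spread over the member CTSS
    of each class with fixed geometric weights; irradiated samples
    multiply the YC fraction by the cohort's treatment effect.
    Intergenic noise tags land uniformly at ``noise_rate`` per kb.
    Returns ({sample: ctss table}, per-promoter expected-TPM truth).
    """
    rng = np.random.default_rng(config.seed + 1)
    n = len(promoters)
    lam = _power_law_expression(n, config.power_alpha, config.depth, rng)

    by_promoter = {pid: grp for pid, grp in ctss_registry.groupby("promoter_id")}

    def class_weights(k: int) -> np.ndarray:
        w = 0.5 ** np.arange(k)
        return w / w.sum()

    tables: dict[str, pd.DataFrame] = {}
    truth_rows = []
    genome_kb = sum(genome.length(c) for c in genome.contigs) / 1000

    for cohort in config.cohorts:
        for i in range(1, config.samples_per_cohort + 1):
            variants = [("", 1.0)]
            if config.with_treatment:
                variants.append(("_irr", config.treatment_effect[cohort]))
            for suffix, effect in variants:
                sample = f"{cohort}_{i}{suffix}"
                counts: dict[tuple[str, int, str], int] = {}
                for p_idx, prom in enumerate(promoters.itertuples(index=False)):
                    members = by_promoter[prom.promoter_id]
                    frac = getattr(prom, f"yc_fraction_{cohort}") * effect
                    total = rng.poisson(lam[p_idx])
                    yc_total = rng.binomial(total, frac) if total > 0 else 0
                    yr_total = total - yc_total
                    for cls, cls_total in (("YR", yr_total), ("YC", yc_total)):
                        idx = members.index[members["true_class"] == cls]
                        if len(idx) == 0 or cls_total == 0:
                            continue
                        split = rng.multinomial(cls_total, class_weights(len(idx)))
                        for j, c_ix in enumerate(idx):
                            if split[j] == 0:
                                continue
                            row = members.loc[c_ix]
                            key = (row["chrom"], int(row["pos"]), row["strand"])
                            counts[key] = counts.get(key, 0) + int(split[j])
                    truth_rows.append(
                        {
                            "promoter_id": prom.promoter_id,
                            "sample": sample,
                            "cohort": cohort,
                            "treatment": "irradiated" if suffix else "control",
                            "expected_total_tpm": lam[p_idx],
                            "expected_yc_tpm": lam[p_idx] * frac,
                            "expected_yr_tpm": lam[p_idx] * (1 - frac),
                            "true_yc_fraction": frac,
                        }
                    )
                # intergenic noise
                n_noise = rng.poisson(config.noise_rate * genome_kb)
                for _ in range(n_noise):
                    contig = genome.contigs[rng.integers(0, len(genome.contigs))]
                    pos = int(rng.integers(1, genome.length(contig) - 1))
                    strand = "+" if rng.random() < 0.5 else "-"
                    key = (contig, pos, strand)
                    counts[key] = counts.get(key, 0) + 1
                df = pd.DataFrame(
                    [(c, p, s, v) for (c, p, s), v in counts.items()],
                    columns=["chrom", "pos", "strand", "count"],
                ).sort_values(["chrom", "pos", "strand"], ignore_index=True)
                tables[sample] = df

    truth = pd.DataFrame(truth_rows)
    return tables, truth


# ---------------------------------------------------------------------------
# Orchestration and truth comparison
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: GenomeStore
    genes: pd.DataFrame
    promoters: pd.DataFrame
    ctss_registry: pd.DataFrame
    samples: dict[str, pd.DataFrame]
    sample_truth: pd.DataFrame

    @property
    def sample_sheet(self) -> pd.DataFrame:
        rows = []
        for sample in self.samples:
            parts = sample.split("_")
            treated = parts[-1] == "irr"
            cohort = "_".join(parts[:-2]) if treated else "_".join(parts[:-1])
            pair = "_".join(parts[:-1]) if treated else sample
            rows.append(
                {
                    "sample": sample,
                    "path": f"{sample}.ctss.bed",
                    "cohort": cohort,
                    "pair": pair if self.config.with_treatment else "",
                    "treatment": "irradiated" if treated else "control",
                }
            )
        return pd.DataFrame(rows)

    def true_dips(self, params=None) -> set[str]:
        """Gene ids satisfying the DIP rule on expected (noise-free) TPMs.

        Control samples only, matching the calling convention.
        """
        from dualinit.dynamics import DipParams

        params = params or DipParams()
        ctrl = self.sample_truth[self.sample_truth["treatment"] == "control"]
        out = set()
        gene_of = dict(zip(self.promoters["promoter_id"], self.promoters["gene_id"]))
        for pid, grp in ctrl.groupby("promoter_id"):
            ok = (
                (grp["expected_yc_tpm"] > params.min_class_tpm)
                & (grp["expected_yr_tpm"] > params.min_class_tpm)
            ).sum()
            if ok > params.majority_fraction * len(grp):
                out.add(gene_of[pid])
        return out

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        _write_gtf(self.genes, outdir / "genes.gtf")
        for sample, df in self.samples.items():
            write_ctss_bed(df, outdir / f"{sample}.ctss.bed")
        write_sample_sheet(self.sample_sheet, outdir / "samples.tsv")
        self.promoters.to_csv(outdir / "truth_promoters.tsv", sep="\t", index=False)
        self.ctss_registry.to_csv(outdir / "truth_ctss.tsv", sep="\t", index=False)
        self.sample_truth.to_csv(outdir / "truth_samples.tsv", sep="\t", index=False)
        import yaml
        from dataclasses import asdict

        cfg = asdict(self.config)
        cfg["top_fraction"] = list(self.config.top_fraction)
        cfg["cohorts"] = list(self.config.cohorts)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)
        return outdir


def _write_gtf(genes: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        for g in genes.itertuples(index=False):
            attrs = f'gene_id "{g.gene_id}";'
            for feature in ("gene", "transcript"):
                fh.write(
                    f"{g.chrom}\tdualinit_sim\t{feature}\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


def simulate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate a complete synthetic dataset in memory."""
    config = config or SyntheticConfig()
    genome, genes, promoters, ctss_registry = generate_genome_and_annotation(config)
    samples, sample_truth = generate_ctss_samples(config, promoters, ctss_registry, genome)
    return SyntheticDataset(
        config=config,
        genome=genome,
        genes=genes,
        promoters=promoters,
        ctss_registry=ctss_registry,
        samples=samples,
        sample_truth=sample_truth,
    )


def truth_compare(
    dataset: SyntheticDataset,
    called_dips: set[str],
    gene_matrix: pd.DataFrame,
    selected_trajectory: set[str] | None = None,
) -> dict:
    """Recovery metrics of pipeline output against generator truth.

    * DIP sensitivity and FDR versus :meth:`SyntheticDataset.true_dips`;
    * Spearman correlation between the estimated per-gene YC fraction
      (YC / (YC + YR), averaged over control samples) and the true
      cohort YC fractions;
    * trajectory precision/recall when a selected gene set is supplied.
    """
    from scipy.stats import spearmanr

    truth_dips = dataset.true_dips()
    called = set(called_dips)
    tp = len(called & truth_dips)
    sensitivity = tp / len(truth_dips) if truth_dips else float("nan")
    fdr = (len(called) - tp) / len(called) if called else 0.0

    # estimated vs true YC fraction over control samples; only promoters
    # with a dual-initiation process have a drawn YC fraction to recover
    ctrl_samples = [s for s in dataset.samples if not s.endswith("_irr")]
    est, true = [], []
    dual = dataset.promoters[dataset.promoters["is_dual"]]
    gene_of = dict(zip(dual["gene_id"], dual["promoter_id"]))
    truth_ctrl = dataset.sample_truth[dataset.sample_truth["treatment"] == "control"]
    frac_truth = truth_ctrl.groupby("promoter_id")["true_yc_fraction"].mean()
    for gene_id in gene_matrix.index:
        if gene_id not in gene_of:
            continue
        yc = sum(gene_matrix.loc[gene_id, f"yc_{s}"] for s in ctrl_samples)
        yr = sum(gene_matrix.loc[gene_id, f"yr_{s}"] for s in ctrl_samples)
        if yc + yr <= 0:
            continue
        est.append(yc / (yc + yr))
        true.append(frac_truth[gene_of[gene_id]])
    rho = float(spearmanr(est, true).statistic) if len(est) > 2 else float("nan")

    out = {
        "n_true_dips": len(truth_dips),
        "n_called_dips": len(called),
        "dip_sensitivity": float(sensitivity),
        "dip_fdr": float(fdr),
        "yc_fraction_spearman": rho,
        "n_compared": len(est),
    }
    if selected_trajectory is not None:
        truth_traj = set(
            dataset.promoters.loc[dataset.promoters["is_trajectory"], "gene_id"]
        )
        eligible = truth_traj & truth_dips  # selection runs on DIPs only
        sel = set(selected_trajectory)
        tp_t = len(sel & eligible)
        out["trajectory_recall"] = tp_t / len(eligible) if eligible else float("nan")
        out["trajectory_precision"] = tp_t / len(sel) if sel else float("nan")
        out["n_true_trajectory"] = len(eligible)
        out["n_selected_trajectory"] = len(sel)
    return out
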