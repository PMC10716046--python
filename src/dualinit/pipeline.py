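"""CTSS processing: G-correction, normalization, clustering, annotation.

The stages mirror the standard CAGE promoter-calling workflow:

1. optional removal of the untemplated G added by reverse transcriptase
   at read 5' ends when it does not match the genome;
2. per-sample tag-count normalization to a reference power law
   (tags-per-million on a 10^6-tag reference library);
3. single-linkage clustering of supported CTSS into tag clusters
   (max 20 bp between neighbours), trimmed to the 10th-90th expression
   percentiles, with an expression floor of 5 TPM;
4. aggregation of tag clusters within 100 bp into consensus clusters
   (promoter units), and assignment to annotated gene TSS windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class NormalizationParams:
    """Power-law normalization settings.

    alpha_ref
        Slope of the reference power law (reverse-cumulative counts on
        log-log axes fall with this slope).  Must be > 1 so the law has
        finite total mass.
    t_ref
        Total tag count of the reference library; normalized values are
        therefore on a tags-per-million scale when ``t_ref = 10**6``.
    fit_range
        (low, high) raw-count interval over which the sample's power law
        is fitted.
    """

    alpha_ref: float = 1.05
    t_ref: float = 1e6
    fit_range: tuple[float, float] = (5.0, 1000.0)

    def __post_init__(self) -> None:
        if self.alpha_ref <= 1:
            raise ValueError("alpha_ref must be > 1")
        low, high = self.fit_range
        if low < 1 or low >= high:
            raise ValueError("fit_range must satisfy 1 <= low < high")


@dataclass
class ClusteringParams:
    ctss_support_tpm: float = 0.5
    max_gap: int = 20
    q_low: float = 0.1
    q_high: float = 0.9
    min_cluster_tpm: float = 5.0
    consensus_dist: int = 100
    promoter_window: tuple[int, int] = (500, 500)

    def __post_init__(self) -> None:
        if not (0 <= self.q_low < self.q_high <= 1):
            raise ValueError("need 0 <= q_low < q_high <= 1")
        if self.max_gap <= 0 or self.consensus_dist <= 0:
            raise ValueError("distances must be positive integers")


def _sample_names(df: pd.DataFrame, prefix: str) -> list[str]:
    return [c[len(prefix) :] for c in df.columns if c.startswith(prefix)]


# ---------------------------------------------------------------------------
# G-correction
# ---------------------------------------------------------------------------


def correct_extra_g(df: pd.DataFrame, genome, first_base_col: str = "first_base") -> pd.DataFrame:
    """Remove the CAGE protocol's untemplated 5' G.

    Rows whose observed read first base is G while the genome base at
    the CTSS position (strand-oriented) is not G are shifted one
    nucleotide in the transcript 3' direction; counts are re-aggregated
    by (chrom, pos, strand).  Rows that would shift past the contig end
    are dropped with a warning.
    """
    if first_base_col not in df.columns:
        raise ValueError(f"input table lacks the {first_base_col!r} column")
    count_cols = [c for c in df.columns if c.startswith("count_")] or ["count"]

    new_pos = df["pos"].to_numpy().copy()
    keep = np.ones(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        if getattr(row, first_base_col) != "G":
            continue
        genome_base = genome.fetch(row.chrom, row.pos, row.pos + 1, row.strand)
        if genome_base == "G":
            continue
        shifted = row.pos + 1 if row.strand == "+" else row.pos - 1
        if 0 <= shifted < genome.length(row.chrom):
            new_pos[i] = shifted
        else:
            keep[i] = False
            logger.warning(
                "G-correction shifts %s:%d:%s off-contig; row dropped",
                row.chrom,
                row.pos,
                row.strand,
            )
    out = df.loc[keep, ["chrom", "strand"] + count_cols].copy()
    out["pos"] = new_pos[keep]
    out = (
        out.groupby(["chrom", "pos", "strand"], as_index=False)[count_cols]
        .sum()
        .sort_values(["chrom", "pos", "strand"], ignore_index=True)
    )
    return out[["chrom", "pos", "strand"] + count_cols]


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def fit_power_law(counts: np.ndarray, fit_range: tuple[float, float]) -> tuple[float, float]:
    """Least-squares fit of the reverse-cumulative count distribution.

    Fits log10(#CTSS with count >= c) against log10(c) over the unique
    count values inside ``fit_range``.  Returns ``(alpha, x0)`` where
    the fitted law is rank(c) = (c / x0) ** -alpha, i.e. ``x0`` is the
    count at which the fitted law reaches rank 1.

    Raises ``ValueError`` when fewer than two distinct count values fall
    in the fit range (degenerate fit).
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    values = np.unique(counts)
    low, high = fit_range
    values = values[(values >= low) & (values <= high)]
    if len(values) < 2:
        raise ValueError(
            f"power-law fit needs >= 2 distinct count values in {fit_range}"
        )
    ranks = np.array([(counts >= v).sum() for v in values], dtype=float)
    slope, intercept = np.polyfit(np.log10(values), np.log10(ranks), 1)
    alpha = -slope
    if alpha <= 0:
        raise ValueError(f"fitted slope {slope} is not decreasing")
    x0 = 10 ** (intercept / alpha)
    return alpha, x0


def reference_rank1_count(alpha_ref: float, t_ref: float) -> float:
    """Count at rank 1 of the reference law with total tag mass t_ref.

    For the continuous law rank(c) = (c / x0) ** -alpha over c in
    [1, x0], the total tag mass is alpha * (x0**alpha - x0) / (alpha-1);
    this inverts that relation numerically.
    """

    def total(x0: float) -> float:
        return alpha_ref * (x0**alpha_ref - x0) / (alpha_ref - 1) - t_ref

    return brentq(total, 1.0 + 1e-9, max(t_ref * 10, 1e9))


def power_law_normalize(
    df: pd.DataFrame, params: NormalizationParams | None = None
) -> pd.DataFrame:
    """Map each sample's raw counts onto the reference power law.

    Per sample, the reverse-cumulative distribution is fitted over
    ``fit_range`` giving slope -a and rank-1 count x0_s; a raw count c
    then maps to ``(c / x0_s) ** (a / alpha_ref) * x0_ref``, which is a
    strictly increasing transform placing the sample on the reference
    law (slope -alpha_ref, total t_ref).  Values are stored in
    ``tpm_<sample>`` columns.  Samples whose fit is degenerate fall back
    to :func:`simple_tpm` scaling with a warning.
    """
    params = params or NormalizationParams()
    out = df.copy()
    x0_ref = reference_rank1_count(params.alpha_ref, params.t_ref)
    for sample in _sample_names(df, "count_"):
        counts = df[f"count_{sample}"].to_numpy(dtype=float)
        try:
            alpha, x0_s = fit_power_law(counts, params.fit_range)
            tpm = np.zeros_like(counts)
            nz = counts > 0
            tpm[nz] = (counts[nz] / x0_s) ** (alpha / params.alpha_ref) * x0_ref
        except ValueError as exc:
            logger.warning(
                "sample %s: %s; falling back to library-size scaling", sample, exc
            )
            total = counts.sum()
            if total <= 0:
                raise ValueError(f"sample {sample}: no tags to normalize") from exc
            tpm = counts / total * 1e6
        out[f"tpm_{sample}"] = tpm
    return out


def simple_tpm(df: pd.DataFrame) -> pd.DataFrame:
    """Plain library-size scaling: tpm = count / total * 10^6 per sample."""
    out = df.copy()
    for sample in _sample_names(df, "count_"):
        counts = df[f"count_{sample}"].to_numpy(dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError(f"sample {sample}: all-zero counts")
        out[f"tpm_{sample}"] = counts / total * 1e6
    return out


# ---------------------------------------------------------------------------
# Tag clusters
# ---------------------------------------------------------------------------


@dataclass
class TagCluster:
    """A run of CTSS on one strand with no gap larger than max_gap.

    ``positions``/``pos_tpm`` hold the member CTSS and the (pooled) TPM
    profile used for trimming; ``tstart``/``tend`` delimit the trimmed
    span (half-open).  ``tpm`` is the trimmed mass — the expression
    value the >5 TPM floor applies to.
    """

    chrom: str
    strand: str
    positions: np.ndarray
    pos_tpm: np.ndarray
    tstart: int = -1
    tend: int = -1
    tpm_by_sample: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.pos_tpm = np.asarray(self.pos_tpm, dtype=float)
        if self.tstart < 0:
            self.tstart = int(self.positions[0])
            self.tend = int(self.positions[-1]) + 1

    @property
    def start(self) -> int:
        return int(self.positions[0])

    @property
    def end(self) -> int:
        return int(self.positions[-1]) + 1

    @property
    def trimmed_mask(self) -> np.ndarray:
        return (self.positions >= self.tstart) & (self.positions < self.tend)

    @property
    def tpm(self) -> float:
        """Trimmed pooled TPM mass."""
        return float(self.pos_tpm[self.trimmed_mask].sum())

    @property
    def dominant_pos(self) -> int:
        """Member position of maximal TPM; ties break 5'-most in transcript orientation."""
        mask = self.trimmed_mask
        pos, tpm = self.positions[mask], self.pos_tpm[mask]
        best = tpm == tpm.max()
        candidates = pos[best]
        return int(candidates.min() if self.strand == "+" else candidates.max())


def cluster_ctss(df: pd.DataFrame, params: ClusteringParams | None = None) -> list[TagCluster]:
    """Single-linkage clustering of supported CTSS per (chrom, strand).

    A CTSS enters clustering when its TPM reaches ``ctss_support_tpm``
    in at least one sample; consecutive retained CTSS at most
    ``max_gap`` bp apart join the same cluster.  The cluster TPM profile
    is the pooled (summed over samples) TPM.
    """
    params = params or ClusteringParams()
    samples = _sample_names(df, "tpm_")
    if not samples:
        raise ValueError("table has no tpm_<sample> columns; normalize first")
    tpm_cols = [f"tpm_{s}" for s in samples]
    supported = df[(df[tpm_cols] >= params.ctss_support_tpm).any(axis=1)]
    clusters: list[TagCluster] = []
    for (chrom, strand), grp in supported.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy(dtype=np.int64)
        pooled = grp[tpm_cols].sum(axis=1).to_numpy(dtype=float)
        per_sample = {s: grp[f"tpm_{s}"].to_numpy(dtype=float) for s in samples}
        breaks = np.where(np.diff(pos) > params.max_gap)[0] + 1
        for idx in np.split(np.arange(len(pos)), breaks):
            clusters.append(
                TagCluster(
                    chrom=chrom,
                    strand=strand,
                    positions=pos[idx],
                    pos_tpm=pooled[idx],
                    tpm_by_sample={
                        s: float(per_sample[s][idx].sum()) for s in samples
                    },
                )
            )
    clusters.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return clusters


def trim_cluster(cluster: TagCluster, q_low: float = 0.1, q_high: float = 0.9) -> TagCluster:
    """Trim a cluster to the q_low..q_high expression percentiles.

    The trimmed start is the 5'-most (smallest) member position whose
    left-inclusive cumulative TPM reaches ``q_low`` of the total; the
    trimmed end is the smallest position whose cumulative TPM reaches
    ``q_high`` (kept inclusively).  The trimmed span therefore retains
    at least ``q_high - q_low`` of the cluster mass.
    """
    total = cluster.pos_tpm.sum()
    if total <= 0:
        raise ValueError("cannot trim a cluster with zero TPM")
    cum = np.cumsum(cluster.pos_tpm)
    i_lo = int(np.searchsorted(cum, q_low * total))
    i_hi = int(np.searchsorted(cum, q_high * total))
    return replace(
        cluster,
        tstart=int(cluster.positions[i_lo]),
        tend=int(cluster.positions[i_hi]) + 1,
    )


def filter_clusters(clusters: list[TagCluster], min_cluster_tpm: float = 5.0) -> list[TagCluster]:
    """Keep clusters whose trimmed TPM is strictly above the floor."""
    return [c for c in clusters if c.tpm > min_cluster_tpm]


# ---------------------------------------------------------------------------
# Consensus clusters
# ---------------------------------------------------------------------------


@dataclass
class ConsensusCluster:
    """Cross-sample promoter unit: the union envelope of nearby tag clusters."""

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    members: dict  # sample -> list[TagCluster]
    gene_id: str | None = None

    @property
    def member_clusters(self) -> list[TagCluster]:
        return [c for cl in self.members.values() for c in cl]

    @property
    def dominant_pos(self) -> int:
        """Highest pooled-TPM CTSS over all member clusters."""
        best_pos, best_tpm = None, -1.0
        for c in self.member_clusters:
            mask = c.trimmed_mask
            for p, t in zip(c.positions[mask], c.pos_tpm[mask]):
                if t > best_tpm or (
                    t == best_tpm
                    and best_pos is not None
                    and (p < best_pos if self.strand == "+" else p > best_pos)
                ):
                    best_pos, best_tpm = int(p), float(t)
        if best_pos is None:
            raise ValueError(f"consensus cluster {self.id} has no members")
        return best_pos


def aggregate_consensus(
    clusters_by_sample: dict[str, list[TagCluster]] | list[TagCluster],
    consensus_dist: int = 100,
) -> list[ConsensusCluster]:
    """Single-linkage aggregation of tag clusters into consensus clusters.

    Trimmed spans on the same (chrom, strand) whose gap is at most
    ``consensus_dist`` bp merge; the consensus span is the union
    envelope.  Ids are stable, assigned in (chrom, start, strand) order.
    Aggregation is strand-specific: initiator classes are defined in
    transcript orientation, so merging across strands would mix them.
    """
    if isinstance(clusters_by_sample, list):
        clusters_by_sample = {"pooled": clusters_by_sample}
    tagged = [
        (sample, c)
        for sample, clist in clusters_by_sample.items()
        for c in clist
    ]
    by_key: dict[tuple[str, str], list[tuple[str, TagCluster]]] = {}
    for sample, c in tagged:
        by_key.setdefault((c.chrom, c.strand), []).append((sample, c))

    raw: list[ConsensusCluster] = []
    for (chrom, strand), items in by_key.items():
        items.sort(key=lambda sc: (sc[1].tstart, sc[1].tend))
        group: list[tuple[str, TagCluster]] = []
        group_end = None
        for sample, c in items:
            if group and c.tstart - group_end > consensus_dist:
                raw.append(_make_consensus(chrom, strand, group))
                group = []
                group_end = None
            group.append((sample, c))
            group_end = c.tend if group_end is None else max(group_end, c.tend)
        if group:
            raw.append(_make_consensus(chrom, strand, group))

    raw.sort(key=lambda cc: (cc.chrom, cc.start, cc.strand))
    for i, cc in enumerate(raw):
        cc.id = f"CC{i + 1:05d}"
    return raw


def _make_consensus(chrom: str, strand: str, group: list[tuple[str, TagCluster]]) -> ConsensusCluster:
    members: dict[str, list[TagCluster]] = {}
    for sample, c in group:
        members.setdefault(sample, []).append(c)
    return ConsensusCluster(
        id="",
        chrom=chrom,
        strand=strand,
        start=min(c.tstart for _, c in group),
        end=max(c.tend for _, c in group),
        members=members,
    )


def annotate_promoters(
    consensus: list[ConsensusCluster],
    genes: pd.DataFrame,
    promoter_window: tuple[int, int] = (500, 500),
) -> list[ConsensusCluster]:
    """Assign consensus clusters to genes whose promoter window they overlap.

    The promoter window is [TSS - upstream, TSS + downstream] on the
    gene's strand.  When windows of several genes overlap a cluster, the
    gene with the nearest TSS wins; an exact distance tie goes to the
    lexicographically smaller gene id (logged).  Clusters overlapping no
    window keep ``gene_id = None``.
    """
    upstream, downstream = promoter_window
    gene_idx: dict[tuple[str, str], pd.DataFrame] = {
        key: grp for key, grp in genes.groupby(["chrom", "strand"])
    }
    for cc in consensus:
        cands = gene_idx.get((cc.chrom, cc.strand))
        cc.gene_id = None
        if cands is None:
            continue
        win_start = cands["tss"] - upstream
        win_end = cands["tss"] + downstream + 1  # half-open
        hit = cands[(cc.start < win_end) & (cc.end > win_start)]
        if hit.empty:
            continue
        dist = hit["tss"].apply(
            lambda t: 0 if cc.start <= t < cc.end else min(abs(cc.start - t), abs(t - (cc.end - 1)))
        )
        best = dist.min()
        winners = sorted(hit.loc[dist == best, "gene_id"])
        if len(winners) > 1:
            logger.info(
                "consensus %s equidistant from genes %s; assigning %s",
                cc.id,
                winners,
                winners[0],
            )
        cc.gene_id = winners[0]
    return consensus


def assign_ctss_to_consensus(
    df: pd.DataFrame, consensus: list[ConsensusCluster], use_trimmed: bool = True
) -> pd.DataFrame:
    """Label each CTSS row with the consensus cluster containing it.

    Adds a ``cluster_id`` column (empty string when the CTSS falls in no
    consensus span).  With ``use_trimmed`` the member tag clusters'
    trimmed spans define membership; otherwise the consensus envelope.
    """
    out = df.copy()
    out["cluster_id"] = ""
    spans: list[tuple[str, str, int, int, str]] = []
    for cc in consensus:
        if use_trimmed:
            for c in cc.member_clusters:
                spans.append((cc.chrom, cc.strand, c.tstart, c.tend, cc.id))
        else:
            spans.append((cc.chrom, cc.strand, cc.start, cc.end, cc.id))
    span_df = pd.DataFrame(spans, columns=["chrom", "strand", "start", "end", "cid"])
    for (chrom, strand), grp in out.groupby(["chrom", "strand"], sort=False):
        sub = span_df[(span_df["chrom"] == chrom) & (span_df["strand"] == strand)]
        if sub.empty:
            continue
        pos = grp["pos"].to_numpy()
        assigned = np.full(len(pos), "", dtype=object)
        for row in sub.itertuples(index=False):
            inside = (pos >= row.start) & (pos < row.end)
            assigned[inside] = row.cid
        out.loc[grp.index, "cluster_id"] = assigned
    return out
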