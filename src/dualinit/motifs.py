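"""PWM scanning of promoter windows and Fisher enrichment.

Promoter sequences are windows around the dominant CTSS of each
consensus cluster (150 bp upstream to 50 bp downstream by default).  A
JASPAR count matrix is converted to a log2 position weight matrix with
a pseudocount distributed by background frequency; a window "hits" a
motif when some subsequence scores at least 90% of the PWM's min-max
score range (on either strand by default).  Enrichment of hits in a
gene set versus all other promoters is assessed by a two-sided Fisher
exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from dualinit.io import PositionFrequencyMatrix, revcomp

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class MotifScanParams:
    upstream: int = 150
    downstream: int = 50
    rel_score_threshold: float = 0.9
    pseudocount: float = 0.8
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    scan_both_strands: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.rel_score_threshold <= 1):
            raise ValueError("rel_score_threshold must be in (0, 1]")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")


@dataclass
class PWM:
    """Log2-odds position weight matrix with precomputed score range."""

    motif_id: str
    weights: np.ndarray  # (4, width)
    min_score: float = field(init=False)
    max_score: float = field(init=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.min_score = float(self.weights.min(axis=0).sum())
        self.max_score = float(self.weights.max(axis=0).sum())
        if not np.isfinite(self.weights).all():
            raise ValueError("PWM weights must be finite (apply a pseudocount)")

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    def score(self, window: str) -> float:
        """Summed log2-odds of one window (length = width); N scores -inf."""
        if len(window) != self.width:
            raise ValueError(f"window length {len(window)} != width {self.width}")
        total = 0.0
        for i, base in enumerate(window):
            idx = _BASE_INDEX.get(base)
            if idx is None:
                return float("-inf")
            total += self.weights[idx, i]
        return total


def pfm_to_pwm(
    pfm: PositionFrequencyMatrix,
    pseudocount: float = 0.8,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> PWM:
    """Convert a count matrix to log2 odds against the background.

    weight[b, i] = log2((count[b, i] + pc * bg[b]) / (colsum_i + pc) / bg[b]).
    A degenerate matrix (all weights zero) is accepted but flagged.
    """
    counts = pfm.counts
    bg = np.asarray(background, dtype=float).reshape(4, 1)
    colsums = counts.sum(axis=0, keepdims=True)
    probs = (counts + pseudocount * bg) / (colsums + pseudocount)
    weights = np.log2(probs / bg)
    pwm = PWM(motif_id=pfm.motif_id, weights=weights)
    if pwm.max_score == pwm.min_score:
        logger.warning("PWM %s is degenerate (flat score range)", pfm.motif_id)
    return pwm


def relative_score(window: str, pwm: PWM) -> float:
    """Fraction of the PWM's score range attained by one window.

    (S - Smin) / (Smax - Smin); windows containing N score 0.  A
    degenerate (flat) PWM scores every ACGT window 1.
    """
    s = pwm.score(window)
    if s == float("-inf"):
        return 0.0
    if pwm.max_score == pwm.min_score:
        return 1.0
    return (s - pwm.min_score) / (pwm.max_score - pwm.min_score)


def scan_sequence(seq: str, pwm: PWM, params: MotifScanParams) -> tuple[bool, int | None, float]:
    """Best relative score over every window of a sequence (both strands).

    Returns (hit, best offset in ``seq``, best relative score); the
    offset always refers to the forward-strand coordinate of the
    window's left edge.
    """
    best_score, best_pos = -1.0, None
    strands = [seq]
    if params.scan_both_strands:
        strands.append(revcomp(seq))
    n = len(seq)
    for s_i, strand_seq in enumerate(strands):
        for off in range(0, n - pwm.width + 1):
            rs = relative_score(strand_seq[off : off + pwm.width], pwm)
            fwd_off = off if s_i == 0 else n - pwm.width - off
            if rs > best_score:
                best_score, best_pos = rs, fwd_off
    hit = best_score >= params.rel_score_threshold
    return hit, best_pos, best_score


def scan_promoter(
    genome,
    chrom: str,
    dominant_pos: int,
    strand: str,
    pwm: PWM,
    params: MotifScanParams | None = None,
) -> dict:
    """Scan the promoter window around a dominant CTSS for a PWM hit.

    The window runs from ``upstream`` bp before to ``downstream`` bp
    after the dominant CTSS in transcript orientation, truncated (and
    flagged) at contig edges.  Reported positions are transcript-
    oriented offsets of the window's 5' edge relative to the CTSS
    (negative = upstream).
    """
    params = params or MotifScanParams()
    if strand == "+":
        start = dominant_pos - params.upstream
        end = dominant_pos + params.downstream
    else:
        start = dominant_pos - params.downstream + 1
        end = dominant_pos + params.upstream + 1
    truncated = start < 0 or end > genome.length(chrom)
    start_c = max(start, 0)
    end_c = min(end, genome.length(chrom))
    seq = genome.fetch(chrom, start_c, end_c, strand)
    if len(seq) < pwm.width:
        return {
            "hit": False,
            "best_offset": None,
            "best_rel_score": 0.0,
            "truncated": True,
        }
    hit, pos, score = scan_sequence(seq, pwm, params)
    offset = None
    if pos is not None:
        if strand == "+":
            left_edge = start_c
            offset = left_edge + pos - dominant_pos
        else:
            # seq index 0 is the transcript-5'-most base of the window
            five_prime_of_window = end_c - 1
            offset = (five_prime_of_window - pos - dominant_pos) * -1
    return {
        "hit": bool(hit),
        "best_offset": offset,
        "best_rel_score": float(score),
        "truncated": bool(truncated),
    }


def fisher_enrichment(
    hits_in_set: int, size_set: int, hits_in_background: int, size_background: int
) -> dict:
    """Two-sided Fisher exact test of motif-hit enrichment in a gene set.

    The background must exclude the set (all other consensus clusters).
    The odds ratio uses the Haldane 0.5 correction when any cell is
    zero; the p-value is the exact two-sided hypergeometric sum.
    """
    if size_set <= 0:
        raise ValueError("empty gene set")
    if hits_in_set > size_set or hits_in_background > size_background:
        raise ValueError("more hits than promoters")
    table = np.array(
        [
            [hits_in_set, size_set - hits_in_set],
            [hits_in_background, size_background - hits_in_background],
        ],
        dtype=float,
    )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if (table == 0).any():
        table = table + 0.5
    odds_ratio = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
    return {"odds_ratio": float(odds_ratio), "p": float(p)}


def enrichment_analysis(
    genome,
    consensus,
    pwms: list[PWM],
    gene_set: set[str],
    params: MotifScanParams | None = None,
) -> dict:
    """Hit counting and Fisher enrichment for a set of promoters.

    ``consensus`` is a list of annotated consensus clusters; those whose
    assigned gene is in ``gene_set`` form the foreground, all others the
    background.  Returns per-motif hit tables and test results.
    """
    params = params or MotifScanParams()
    gene_set = {g.upper() for g in gene_set}
    results = {}
    for pwm in pwms:
        set_hits = set_n = bg_hits = bg_n = 0
        per_cluster = []
        for cc in consensus:
            res = scan_promoter(
                genome, cc.chrom, cc.dominant_pos, cc.strand, pwm, params
            )
            in_set = cc.gene_id is not None and cc.gene_id.upper() in gene_set
            if in_set:
                set_n += 1
                set_hits += res["hit"]
            else:
                bg_n += 1
                bg_hits += res["hit"]
            per_cluster.append(
                {
                    "cluster_id": cc.id,
                    "gene_id": cc.gene_id,
                    "in_set": in_set,
                    **res,
                }
            )
        test = fisher_enrichment(set_hits, set_n, bg_hits, bg_n)
        results[pwm.motif_id] = {
            "hits_in_set": set_hits,
            "size_set": set_n,
            "hits_in_background": bg_hits,
            "size_background": bg_n,
            "odds_ratio": test["odds_ratio"],
            "p": test["p"],
            "clusters": per_cluster,
        }
    return results
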