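"""Dual-initiation promoter (DIP) calling and YC:YR transcription dynamics.

A promoter is a DIP when both its YR and its YC transcription exceed
1 TPM in the majority of samples.  For DIPs the YC:YR ratio (with a
small pseudocount for finiteness) quantifies the balance between
non-canonical and canonical initiation; ratios normalized to their
per-promoter mean make shifts comparable across promoters.  Cohort
comparisons (matched cancer/healthy pairs, irradiated/control,
responsiveness groups) are run as paired two-tailed t-tests on log2
ratio changes, chi-squared tests on class totals, and strict-monotone
"trajectory" selection along an ordered cohort ranking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class DipParams:
    """DIP-calling rule parameters.

    A promoter qualifies in a sample when both class TPMs are strictly
    above ``min_class_tpm``; it is a DIP when the qualifying samples
    are strictly more than ``majority_fraction`` of all samples (or at
    least ``min_samples`` when that integer override is set).
    ``ratio_pseudocount`` is added to both terms of YC:YR ratios.
    """

    min_class_tpm: float = 1.0
    majority_fraction: float = 0.5
    ratio_pseudocount: float = 0.01
    min_samples: int | None = None

    def __post_init__(self) -> None:
        if self.min_class_tpm < 0:
            raise ValueError("min_class_tpm must be >= 0")
        if not (0 < self.majority_fraction <= 1):
            raise ValueError("majority_fraction must be in (0, 1]")
        if self.ratio_pseudocount <= 0:
            raise ValueError("ratio_pseudocount must be > 0")


def _samples_from(matrix: pd.DataFrame) -> list[str]:
    samples = [c[len("yc_") :] for c in matrix.columns if c.startswith("yc_")]
    missing = [s for s in samples if f"yr_{s}" not in matrix.columns]
    if not samples or missing:
        raise ValueError("matrix needs matching yc_<sample>/yr_<sample> columns")
    return samples


def call_dips(matrix: pd.DataFrame, params: DipParams | None = None) -> list[str]:
    """Promoters with both-class expression in a majority of samples.

    ``matrix`` is indexed by promoter id with ``yr_<sample>`` and
    ``yc_<sample>`` columns.  Returns the sorted DIP id list.
    """
    params = params or DipParams()
    samples = _samples_from(matrix)
    yr = matrix[[f"yr_{s}" for s in samples]].to_numpy()
    yc = matrix[[f"yc_{s}" for s in samples]].to_numpy()
    qualifying = ((yr > params.min_class_tpm) & (yc > params.min_class_tpm)).sum(axis=1)
    if params.min_samples is not None:
        is_dip = qualifying >= params.min_samples
    else:
        is_dip = qualifying > params.majority_fraction * len(samples)
    return sorted(matrix.index[is_dip])


def yc_yr_ratio(
    matrix: pd.DataFrame,
    pseudocount: float = 0.01,
    yc_prefix: str = "yc",
) -> pd.DataFrame:
    """Per-sample YC:YR ratios and their per-promoter normalization.

    r = (YC + eps) / (YR + eps); r_norm = r / mean_over_samples(r), so
    mean(r_norm) is exactly 1 for every promoter.  ``yc_prefix``
    selects which YC class forms the numerator (``yc``, ``top``,
    ``topdeg`` or ``ycother``).  Adds ``ratio_<s>``, ``norm_ratio_<s>``
    and ``log2_ratio_<s>`` columns.
    """
    samples = _samples_from(matrix)
    out = matrix.copy()
    ratios = np.column_stack(
        [
            (matrix[f"{yc_prefix}_{s}"] + pseudocount)
            / (matrix[f"yr_{s}"] + pseudocount)
            for s in samples
        ]
    )
    norm = ratios / ratios.mean(axis=1, keepdims=True)
    for j, s in enumerate(samples):
        out[f"ratio_{s}"] = ratios[:, j]
        out[f"norm_ratio_{s}"] = norm[:, j]
        out[f"log2_ratio_{s}"] = np.log2(ratios[:, j])
    return out


def paired_ratio_test(
    ratio_table: pd.DataFrame,
    condition_samples: list[str],
    reference_samples: list[str],
) -> dict:
    """Mean log2 fold change of YC:YR ratios and a paired two-tailed t-test.

    Per promoter, d = mean log2 ratio over condition samples minus mean
    log2 ratio over reference samples; the test is a one-sample
    two-tailed t-test of d against zero across promoters.  With fewer
    than 3 promoters the test is skipped (mean still reported); a
    zero-variance d vector is flagged degenerate with p = 0.
    """
    cond = ratio_table[[f"log2_ratio_{s}" for s in condition_samples]].mean(axis=1)
    ref = ratio_table[[f"log2_ratio_{s}" for s in reference_samples]].mean(axis=1)
    d = (cond - ref).to_numpy()
    d = d[np.isfinite(d)]
    result = {
        "n": int(len(d)),
        "mean_log2fc": float(np.mean(d)) if len(d) else float("nan"),
        "t": float("nan"),
        "p": float("nan"),
        "degenerate": False,
    }
    if len(d) < 3:
        logger.warning("paired ratio test skipped: only %d promoters", len(d))
        return result
    if np.ptp(d) == 0:
        result["degenerate"] = True
        result["p"] = 0.0 if d[0] != 0 else 1.0
        return result
    t, p = stats.ttest_1samp(d, 0.0)
    result["t"], result["p"] = float(t), float(p)
    return result


def class_total_chisq(
    yc_a: float, yr_a: float, yc_b: float, yr_b: float
) -> dict:
    """Pearson chi-squared on summed YC vs YR expression of two groups.

    TPM totals are rounded to integers to form the 2x2 table (the test
    treats them as counts — a pragmatic approximation, logged).  A zero
    cell triggers the Haldane 0.5 correction for the odds ratio.
    """
    table = np.array(
        [[round(yc_a), round(yr_a)], [round(yc_b), round(yr_b)]], dtype=float
    )
    if table.sum(axis=1).min() <= 0:
        raise ValueError("each group needs positive total expression")
    flagged = bool((table == 0).any())
    or_table = table + 0.5 if flagged else table
    odds_ratio = (or_table[0, 0] * or_table[1, 1]) / (or_table[0, 1] * or_table[1, 0])
    if (table == 0).any():
        chi2, p = stats.chi2_contingency(table + 0.5, correction=False)[:2]
    else:
        chi2, p = stats.chi2_contingency(table, correction=False)[:2]
    logger.debug("chi-squared on rounded TPM totals: %s", table.tolist())
    return {
        "chi2": float(chi2),
        "p": float(p),
        "odds_ratio": float(odds_ratio),
        "haldane": flagged,
    }


def trajectory_select(
    ratio_table: pd.DataFrame,
    cohort_samples: dict[str, list[str]],
    cohort_order: list[str],
    metric: str = "ratio",
    treatment_samples: dict[str, list[str]] | None = None,
) -> list[str]:
    """Promoters whose cohort-mean metric is strictly monotone decreasing.

    ``metric="ratio"`` orders cohorts by the mean log2 YC:YR ratio (the
    geometric mean of the ratio); ``metric="delta"`` orders them by the
    mean change in log2 ratio upon treatment, requiring
    ``treatment_samples`` (treated sample ids per cohort, compared to
    the control ids in ``cohort_samples``).  Cohorts listed first in
    ``cohort_order`` must have the strictly highest value.
    """
    if metric not in ("ratio", "delta"):
        raise ValueError(f"unknown metric {metric!r}")
    if len(cohort_order) < 2:
        raise ValueError("need at least 2 cohorts")
    for cohort in cohort_order:
        if not cohort_samples.get(cohort):
            raise ValueError(f"cohort {cohort!r} has no samples")
    means = {}
    for cohort in cohort_order:
        cols = [f"log2_ratio_{s}" for s in cohort_samples[cohort]]
        value = ratio_table[cols].mean(axis=1)
        if metric == "delta":
            if not treatment_samples or not treatment_samples.get(cohort):
                raise ValueError(f"metric 'delta' needs treated samples for {cohort!r}")
            tcols = [f"log2_ratio_{s}" for s in treatment_samples[cohort]]
            value = ratio_table[tcols].mean(axis=1) - value
        means[cohort] = value
    selected = pd.Series(True, index=ratio_table.index)
    for hi, lo in zip(cohort_order, cohort_order[1:]):
        selected &= means[hi] > means[lo]
    return sorted(ratio_table.index[selected])


def intersect_sets(named_sets: dict[str, set[str]]) -> dict:
    """All Venn regions of up to a handful of named identifier sets.

    Identifiers are case-normalized (upper).  Returns
    ``{"regions": {frozenset-key: sorted members}, "counts": {...}}``
    where each region key is a "+"-joined sorted tuple of the set names
    whose exclusive intersection it is.
    """
    norm = {name: {str(x).upper() for x in s} for name, s in named_sets.items()}
    names = sorted(norm)
    regions: dict[str, list[str]] = {}
    from itertools import combinations

    for k in range(1, len(names) + 1):
        for inside in combinations(names, k):
            members = set.intersection(*(norm[n] for n in inside))
            for outside in names:
                if outside not in inside:
                    members -= norm[outside]
            regions["+".join(inside)] = sorted(members)
    return {
        "regions": regions,
        "counts": {key: len(val) for key, val in regions.items()},
    }


def pairwise_intersection(a: set[str], b: set[str]) -> list[str]:
    """Sorted case-normalized intersection of two identifier sets."""
    return sorted({str(x).upper() for x in a} & {str(x).upper() for x in b})


def qpcr_yc_estimate(
    total_expression: float, yr_expression: float, tolerance: float = 0.05
) -> dict:
    """YC expression by subtraction from RT-qPCR measurements.

    The long (YR-initiating) transcript is measured with 5'-specific
    primers and subtracted from total expression measured with internal
    primers: yc = max(total - yr, 0).  A deficit larger than
    ``tolerance`` (fractional) is flagged as primer inconsistency.
    """
    if total_expression < 0 or yr_expression < 0:
        raise ValueError("expressions must be non-negative")
    diff = total_expression - yr_expression
    flagged = diff < -tolerance * max(yr_expression, 1e-12)
    yc = max(diff, 0.0)
    if flagged:
        logger.warning(
            "YR signal %.3g exceeds total %.3g beyond tolerance; clipping",
            yr_expression,
            total_expression,
        )
    ratio = yc / yr_expression if yr_expression > 0 else float("inf")
    return {"yc": yc, "ratio": ratio, "clipped": diff < 0, "inconsistent": bool(flagged)}


def doubling_time(elapsed_days: float, final_count: float, seed_count: float = 50_000) -> float:
    """Cell doubling time: T * ln(2) / ln(X / seed).

    ``elapsed_days`` is the growth interval, ``final_count`` the cell
    count at its end from a seed of ``seed_count`` cells.
    """
    if elapsed_days <= 0:
        raise ValueError("elapsed_days must be positive")
    if final_count <= seed_count:
        raise ValueError("no growth: final_count must exceed seed_count")
    return elapsed_days * math.log(2) / math.log(final_count / seed_count)


def relative_survival(
    treated_viability: np.ndarray, control_viability: np.ndarray
) -> dict:
    """Mean treated / mean control viability with propagated s.e.m.

    Standard error follows the ratio-of-means first-order propagation
    sqrt((se_t/mean_t)^2 + (se_c/mean_c)^2) * ratio; undefined (flagged
    NaN) with a single replicate.
    """
    treated = np.asarray(treated_viability, dtype=float)
    control = np.asarray(control_viability, dtype=float)
    if control.mean() <= 0:
        raise ValueError("control viability must be positive")
    ratio = treated.mean() / control.mean()
    if len(treated) < 2 or len(control) < 2:
        logger.warning("single replicate: s.e.m. undefined")
        return {"ratio": float(ratio), "sem": float("nan")}
    se_t = treated.std(ddof=1) / np.sqrt(len(treated))
    se_c = control.std(ddof=1) / np.sqrt(len(control))
    sem = ratio * np.sqrt((se_t / treated.mean()) ** 2 + (se_c / control.mean()) ** 2)
    return {"ratio": float(ratio), "sem": float(sem)}


def merge_gene_level(matrix: pd.DataFrame, gene_ids: pd.Series) -> pd.DataFrame:
    """Sum class-TPM rows of consensus clusters mapping to the same gene.

    ``gene_ids`` maps cluster id -> gene id (empty/NaN rows dropped).
    """
    ids = gene_ids.reindex(matrix.index)
    keep = ids.notna() & (ids != "")
    merged = matrix[keep].groupby(ids[keep]).sum()
    merged.index.name = "gene_id"
    return merged


def ratio_histogram(
    ratio_table: pd.DataFrame, sample: str, bins: int = 32, log2_range: float = 5.0
) -> pd.DataFrame:
    """Frequency distribution of normalized YC:YR ratios on log2 bins.

    Fixed log2-spaced bins over +/- ``log2_range`` for cross-run
    comparability; returns bin centers (log2) and counts.
    """
    values = np.log2(ratio_table[f"norm_ratio_{sample}"].to_numpy())
    edges = np.linspace(-log2_range, log2_range, bins + 1)
    counts, _ = np.histogram(values[np.isfinite(values)], bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    return pd.DataFrame({"log2_bin_center": centers, "count": counts})
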