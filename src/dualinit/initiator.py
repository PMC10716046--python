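"""Strand-aware classification of transcript 5' ends.

Each CTSS is classified by the genomic dinucleotide spanning its -1/+1
positions in transcript orientation:

* YR (CA, CG, TA, TG) — the canonical pyrimidine/purine initiator;
* YC (CC, TC) — the non-canonical pyrimidine/cytosine initiator that
  marks TCT/5'TOP-type transcripts;
* OTHER — everything else, including anything touching an N.

YC starts are further subtyped by the pyrimidine content of the first
five transcribed bases: 5 pyrimidines = TOP, 4 of 5 = TOP-degenerate,
otherwise YC-other.  Transcripts that are not canonical 5'TOP are also
scanned for an internal TOP: an unbroken run of five pyrimidines within
the first 50 nt of the transcript leader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PYRIMIDINES = frozenset("CT")
YR_DINUCLEOTIDES = frozenset({"CA", "CG", "TA", "TG"})
YC_DINUCLEOTIDES = frozenset({"CC", "TC"})

# major classes
YR, YC, OTHER = "YR", "YC", "OTHER"
# YC subtypes
TOP, TOP_DEG, YC_OTHER, NOT_APPLICABLE = "TOP", "TOP_DEG", "YC_OTHER", "NA"
# internal-TOP states
NOT_ASSESSED = "not_assessed"


@dataclass
class ClassificationParams:
    """TOP-calling windows.

    ``top_window`` is fixed at five bases (the transcript's first five
    nucleotides define the 5'TOP subtype).  ``internal_window`` is the
    length of the 5' leader scanned for an internal pyrimidine run of
    ``internal_run`` bases.  ``exempt_top_deg`` extends the canonical
    exemption from internal-TOP assessment (which applies to 5'TOP
    transcripts) to the degenerate TOP class as well.
    """

    top_window: int = 5
    internal_window: int = 50
    internal_run: int = 5
    exempt_top_deg: bool = False

    def __post_init__(self) -> None:
        if self.top_window != 5:
            raise ValueError("top_window is fixed at 5")
        if self.internal_run > self.internal_window:
            raise ValueError("internal_run cannot exceed internal_window")


def dinucleotide_at(genome, chrom: str, pos: int, strand: str) -> tuple[str, str]:
    """(-1, +1) bases around a CTSS, 5'->3' in transcript orientation.

    On "+" this is (genome[pos-1], genome[pos]); on "-" the two bases
    downstream in genome coordinates, reverse-complemented.  A CTSS
    whose upstream base falls off the contig yields ("N", ...) so the
    caller classifies it OTHER instead of raising.
    """
    try:
        if strand == "+":
            duo = genome.fetch(chrom, pos - 1, pos + 1, "+")
        else:
            duo = genome.fetch(chrom, pos, pos + 2, "-")
    except (IndexError, ValueError):
        try:
            plus1 = genome.fetch(chrom, pos, pos + 1, strand)
        except (IndexError, ValueError):
            plus1 = "N"
        return ("N", plus1)
    return (duo[0], duo[1])


def classify_dinucleotide(minus1: str, plus1: str) -> str:
    """YR / YC / OTHER from the -1/+1 initiator dinucleotide."""
    duo = minus1 + plus1
    if duo in YR_DINUCLEOTIDES:
        return YR
    if duo in YC_DINUCLEOTIDES:
        return YC
    return OTHER


def first_n_bases(genome, chrom: str, pos: int, strand: str, n: int) -> str:
    """First ``n`` transcribed bases starting at the CTSS.

    Runs off the contig end return the shorter available string (the
    caller treats short windows as not assessable).
    """
    if strand == "+":
        end = min(pos + n, genome.length(chrom))
        return genome.fetch(chrom, pos, end, "+")
    start = max(pos - n + 1, 0)
    return genome.fetch(chrom, start, pos + 1, "-")


def classify_yc_subtype(first5: str) -> str:
    """TOP / TOP_DEG / YC_OTHER from the transcript's first five bases.

    Requires a C start (the caller guarantees the major class is YC).
    Five pyrimidines = TOP; exactly four = TOP-degenerate (a purine at
    any one of positions 2-5); three or fewer = YC-other.  Any N in the
    window, or a short window, demotes to YC-other.
    """
    if not first5 or first5[0] != "C":
        raise ValueError(f"YC subtype called on non-C start {first5!r}")
    if len(first5) < 5 or "N" in first5:
        logger.debug("undetermined 5-mer %r -> YC_OTHER", first5)
        return YC_OTHER
    n_py = sum(b in PYRIMIDINES for b in first5)
    if n_py == 5:
        return TOP
    if n_py == 4:
        return TOP_DEG
    return YC_OTHER


def detect_internal_top(leader_seq: str, internal_run: int = 5) -> bool:
    """True when the leader contains an unbroken pyrimidine run.

    ``leader_seq`` is the transcript's first <=50 bases; N breaks a run.
    """
    run = 0
    for base in leader_seq:
        run = run + 1 if base in PYRIMIDINES else 0
        if run >= internal_run:
            return True
    return False


def classify_all(
    genome, df: pd.DataFrame, params: ClassificationParams | None = None
) -> pd.DataFrame:
    """Classify every CTSS row of a table.

    Adds columns: ``dinucleotide`` (transcript-oriented -1/+1 bases),
    ``major_class``, ``yc_subtype`` and ``internal_top`` (one of
    "true"/"false"/"not_assessed").  Per-row anomalies (contig edges,
    N bases) are flagged in-place, never abort the batch.
    """
    params = params or ClassificationParams()
    dinucs, majors, subtypes, internals = [], [], [], []
    for row in df.itertuples(index=False):
        minus1, plus1 = dinucleotide_at(genome, row.chrom, row.pos, row.strand)
        major = classify_dinucleotide(minus1, plus1)
        subtype = NOT_APPLICABLE
        if major == YC:
            first5 = first_n_bases(genome, row.chrom, row.pos, row.strand, params.top_window)
            subtype = classify_yc_subtype(first5)
        exempt = subtype == TOP or (params.exempt_top_deg and subtype == TOP_DEG)
        if major == OTHER or exempt:
            internal = NOT_ASSESSED
        else:
            leader = first_n_bases(
                genome, row.chrom, row.pos, row.strand, params.internal_window
            )
            if "N" in leader:
                internal = NOT_ASSESSED
            else:
                internal = (
                    "true" if detect_internal_top(leader, params.internal_run) else "false"
                )
        dinucs.append(minus1 + plus1)
        majors.append(major)
        subtypes.append(subtype)
        internals.append(internal)
    out = df.copy()
    out["dinucleotide"] = dinucs
    out["major_class"] = majors
    out["yc_subtype"] = subtypes
    out["internal_top"] = internals
    counts = out["major_class"].value_counts().to_dict()
    logger.info("classified %d CTSS: %s", len(out), counts)
    return out


def class_tpm_table(
    calls: pd.DataFrame,
    by: str = "cluster_id",
    classes: tuple[str, ...] = (YR, YC, OTHER, TOP, TOP_DEG, YC_OTHER),
) -> pd.DataFrame:
    """Per-promoter, per-sample, per-class TPM totals.

    ``calls`` is a classified CTSS table carrying ``tpm_<sample>``
    columns and a grouping column (consensus ``cluster_id`` or
    ``gene_id``).  Rows with an empty group label are dropped.  Output
    columns are ``yr_<s>``, ``yc_<s>``, ``other_<s>`` (partitioning each
    group's TPM) and ``top_<s>``, ``topdeg_<s>``, ``ycother_<s>``
    (partitioning the YC component).
    """
    prefix = {YR: "yr", YC: "yc", OTHER: "other", TOP: "top", TOP_DEG: "topdeg", YC_OTHER: "ycother"}
    samples = [c[len("tpm_") :] for c in calls.columns if c.startswith("tpm_")]
    if not samples:
        raise ValueError("classified table lacks tpm_<sample> columns")
    grouped = calls[calls[by] != ""]
    frames = {}
    for cls in classes:
        if cls in (YR, YC, OTHER):
            mask = grouped["major_class"] == cls
        else:
            mask = grouped["yc_subtype"] == cls
        sub = grouped[mask]
        agg = sub.groupby(by)[[f"tpm_{s}" for s in samples]].sum()
        agg.columns = [f"{prefix[cls]}_{s}" for s in samples]
        frames[cls] = agg
    out = pd.concat(frames.values(), axis=1)
    out = out.reindex(sorted(grouped[by].unique())).fillna(0.0)
    out.index.name = by
    return out
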