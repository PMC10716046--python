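"""Readers and writers for the external formats the pipeline consumes.

This module is the single home for coordinate conventions: everything is
0-based, half-open internally.  BED is native 0-based and is passed
through; GTF is 1-based, closed and is converted on read.  CTSS tag
tables are a BED6 dialect in which ``start`` is the 5' base of the
transcript, ``end = start + 1`` and the score column carries the raw tag
count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CTSS_COLUMNS = ["chrom", "pos", "strand", "count"]


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeStore:
    """In-memory genome: contig name -> uppercase A/C/G/T/N sequence.

    ``fetch`` returns strand-oriented subsequences: fetching on "-"
    equals the reverse complement of the same interval fetched on "+".
    Out-of-range requests raise rather than silently truncating.
    """

    def __init__(self, sequences: dict[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            if not seq:
                raise ValueError(f"empty sequence for contig {name!r}")
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(
                    f"contig {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )
            self._seqs[name] = seq

    @property
    def contigs(self) -> list[str]:
        return list(self._seqs)

    def length(self, contig: str) -> int:
        return len(self._seqs[contig])

    def sequence(self, contig: str) -> str:
        return self._seqs[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self._seqs

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Strand-oriented subsequence of ``contig[start:end)``."""
        if contig not in self._seqs:
            raise KeyError(f"unknown contig {contig!r}")
        seq = self._seqs[contig]
        if not (0 <= start <= end <= len(seq)):
            raise IndexError(
                f"fetch({contig!r}, {start}, {end}) out of range for "
                f"contig of length {len(seq)}"
            )
        sub = seq[start:end]
        if strand == "+":
            return sub
        if strand == "-":
            return revcomp(sub)
        raise ValueError(f"invalid strand {strand!r}")

    def reverse_complemented(self) -> "GenomeStore":
        """A new store with every contig reverse-complemented (for mirror tests)."""
        return GenomeStore({name: revcomp(seq) for name, seq in self._seqs.items()})


def read_fasta(path: str | Path) -> GenomeStore:
    """Read a FASTA file into a :class:`GenomeStore`.

    Duplicate headers are an error; sequences are uppercased and must be
    A/C/G/T/N only.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValueError(f"duplicate FASTA header {record.id!r} in {path}")
        seqs[record.id] = str(record.seq)
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    return GenomeStore(seqs)


def write_fasta(store: GenomeStore, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for contig in store.contigs:
            fh.write(f">{contig}\n")
            seq = store.sequence(contig)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_ctss_bed(path: str | Path) -> pd.DataFrame:
    """Read one sample's CTSS tag table (BED6 dialect).

    Returns a DataFrame with columns chrom, pos, strand, count; one row
    per (chrom, pos, strand).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, start, end, _name, score, strand = fields
            start, end = int(start), int(end)
            if end != start + 1:
                raise ValueError(
                    f"{path}:{lineno}: CTSS interval must have width 1 "
                    f"(start={start}, end={end})"
                )
            count = int(score)
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative tag count {count}")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: invalid strand {strand!r}")
            rows.append((chrom, start, strand, count))
    df = pd.DataFrame(rows, columns=CTSS_COLUMNS)
    if df.duplicated(["chrom", "pos", "strand"]).any():
        raise ValueError(f"{path}: duplicate (chrom, pos, strand) rows")
    return df.sort_values(["chrom", "pos", "strand"], ignore_index=True)


def write_ctss_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write a single-sample CTSS table back to the BED6 dialect.

    Deterministic line order: (chrom, pos, strand).
    """
    out = df.sort_values(["chrom", "pos", "strand"])
    with open(path, "w") as fh:
        for row in out.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t.\t{int(row.count)}\t{row.strand}\n"
            )


def merge_ctss_tables(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Outer-join per-sample CTSS tables on (chrom, pos, strand).

    Absent counts become 0.  Returns a wide table with one
    ``count_<sample>`` column per sample, sorted by (chrom, pos, strand).
    """
    if not tables:
        raise ValueError("no CTSS tables to merge")
    merged: pd.DataFrame | None = None
    for sample, df in tables.items():
        part = df.rename(columns={"count": f"count_{sample}"})
        if merged is None:
            merged = part
        else:
            merged = merged.merge(part, on=["chrom", "pos", "strand"], how="outer")
    assert merged is not None
    count_cols = [c for c in merged.columns if c.startswith("count_")]
    merged[count_cols] = merged[count_cols].fillna(0).astype(np.int64)
    return merged.sort_values(["chrom", "pos", "strand"], ignore_index=True)


def read_gtf_genes(path: str | Path) -> pd.DataFrame:
    """One gene model per gene_id from a GTF.

    TSS is the 5'-most annotated start over the gene's features: for "+"
    genes the smallest 0-based start, for "-" genes the largest end - 1.
    Which transcript's start a multi-start gene should contribute is an
    open choice in most annotation pipelines; keeping the 5'-most start
    is the conservative envelope and is what is done here.

    Returns columns: gene_id, chrom, strand, tss, start, end (0-based,
    half-open span).
    """
    import pyranges

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    gr = pyranges.read_gtf(str(path))
    df = gr.df
    if df.empty:
        raise ValueError(f"no features in {path}")
    if "gene_id" not in df.columns or df["gene_id"].isna().all():
        raise ValueError(f"{path}: GTF features lack gene_id attributes")
    feats = df[df["Feature"].isin(["gene", "transcript"])]
    if feats.empty:
        feats = df
    feats = feats.dropna(subset=["gene_id"])
    if feats["gene_id"].isna().any():
        raise ValueError(f"{path}: feature without gene_id")
    records = []
    for gene_id, grp in feats.groupby("gene_id", sort=True):
        chrom = grp["Chromosome"].iloc[0]
        strand = grp["Strand"].iloc[0]
        start = int(grp["Start"].min())
        end = int(grp["End"].max())
        tss = start if strand == "+" else end - 1
        records.append((str(gene_id), str(chrom), str(strand), tss, start, end))
    out = pd.DataFrame(
        records, columns=["gene_id", "chrom", "strand", "tss", "start", "end"]
    )
    return out.sort_values(["chrom", "start", "gene_id"], ignore_index=True)


@dataclass
class PositionFrequencyMatrix:
    """Raw motif count matrix: 4 rows (A, C, G, T) x width columns."""

    motif_id: str
    counts: np.ndarray  # shape (4, width), float
    name: str = ""
    zero_columns: list[int] = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.counts.shape[1]


def read_jaspar_pfm(path: str | Path) -> list[PositionFrequencyMatrix]:
    """Parse JASPAR-format position frequency matrices.

    Columns summing to zero are accepted but flagged (a pseudocount is
    applied downstream when converting to a PWM).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array(
            [m.counts[b] for b in "ACGT"], dtype=float
        )  # Bio.motifs enforces equal row lengths
        zero_cols = [int(i) for i in np.where(counts.sum(axis=0) == 0)[0]]
        if zero_cols:
            logger.warning(
                "PFM %s has all-zero columns %s; pseudocount will apply",
                m.matrix_id,
                zero_cols,
            )
        out.append(
            PositionFrequencyMatrix(
                motif_id=m.matrix_id or m.name,
                counts=counts,
                name=m.name or "",
                zero_columns=zero_cols,
            )
        )
    if not out:
        raise ValueError(f"no motifs parsed from {path}")
    return out


SAMPLE_SHEET_COLUMNS = ["sample", "path", "cohort", "pair", "treatment"]


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet TSV: sample, path, cohort, pair, treatment.

    Sample ids must be unique; every non-empty pair id must occur in at
    least two rows (matched cancer/healthy or control/irradiated).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {missing}")
    if df["sample"].duplicated().any():
        dupes = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    pair_counts = df.loc[df["pair"] != "", "pair"].value_counts()
    lonely = pair_counts[pair_counts < 2].index.tolist()
    if lonely:
        raise ValueError(f"{path}: pair ids with fewer than 2 members: {lonely}")
    return df[SAMPLE_SHEET_COLUMNS].copy()


def write_sample_sheet(df: pd.DataFrame, path: str | Path) -> None:
    df[SAMPLE_SHEET_COLUMNS].to_csv(path, sep="\t", index=False)


def ctss_from_bam(path: str | Path, min_mapq: int = 20) -> pd.DataFrame:
    """Optional adapter: tally aligned-read 5' ends from a BAM/SAM file.

    Reads with MAPQ <= ``min_mapq`` are discarded.  The 5' end of a
    reverse-strand alignment is its rightmost reference base.  Output
    matches :func:`read_ctss_bed`.
    """
    import pysam

    counts: dict[tuple[str, int, str], int] = {}
    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(path), mode) as bam:
        for read in bam:
            if read.is_unmapped or read.mapping_quality <= min_mapq:
                continue
            if read.is_reverse:
                key = (read.reference_name, read.reference_end - 1, "-")
            else:
                key = (read.reference_name, read.reference_start, "+")
            counts[key] = counts.get(key, 0) + 1
    rows = [(c, p, s, n) for (c, p, s), n in counts.items()]
    df = pd.DataFrame(rows, columns=CTSS_COLUMNS)
    return df.sort_values(["chrom", "pos", "strand"], ignore_index=True)
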