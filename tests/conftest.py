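"""Shared fixtures: tiny genomes and a small synthetic dataset."""

import numpy as np
import pandas as pd
import pytest

from dualinit.io import GenomeStore
from dualinit.simulate import SyntheticConfig, simulate_dataset


@pytest.fixture
def toy_genome():
    return GenomeStore({"c1": "ACGTACGTACGTACGTACGT", "c2": "TTTTCCCCGGGGAAAA"})


@pytest.fixture(scope="session")
def small_dataset():
    """Small but complete synthetic cohort (3 cohorts x 2 samples)."""
    cfg = SyntheticConfig(seed=7, n_promoters=150, depth=150_000, n_contigs=2)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_result(small_dataset):
    from dualinit import workflow

    ds = small_dataset
    return workflow.run_pipeline(
        ds.genome,
        ds.samples,
        genes=ds.genes,
        sample_sheet=ds.sample_sheet,
        cohort_order=["responsive", "moderate", "non_responsive"],
    )


def random_ctss_table(rng, n, samples=("s1",), contigs=("c1",), max_pos=1000):
    """Random wide CTSS table with tpm columns, unique (chrom,pos,strand)."""
    rows = set()
    while len(rows) < n:
        rows.add(
            (
                contigs[rng.integers(0, len(contigs))],
                int(rng.integers(0, max_pos)),
                "+" if rng.random() < 0.5 else "-",
            )
        )
    df = pd.DataFrame(sorted(rows), columns=["chrom", "pos", "strand"])
    for s in samples:
        df[f"count_{s}"] = rng.integers(1, 50, size=n)
        df[f"tpm_{s}"] = rng.uniform(0.1, 30, size=n)
    return df
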