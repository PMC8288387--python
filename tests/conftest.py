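"""Shared fixtures: small simulated populations and genome geometries.

Everything is generated programmatically at test time; dense small-genome
populations (high HE rate on short chromosomes) give well-mixed dosage
polymorphism for the association and selection-scan tests, while the
paper-scale geometry (12 x 30 Mb, 5-kb bins) is reserved for the recovery
tests that need it.
"""

import numpy as np
import pandas as pd
import pytest

from mosaiche import core_io, simtetra


@pytest.fixture(scope="session")
def small_grid():
    """Two 2.5-Mb chromosomes at 5-kb bins (1000 bins total)."""
    _, grid = simtetra.make_panel_and_grid(n_chrom=2, chrom_length=2_500_000, seed=101)
    return grid


@pytest.fixture(scope="session")
def small_panel_grid():
    return simtetra.make_panel_and_grid(n_chrom=2, chrom_length=2_500_000, seed=101)


@pytest.fixture(scope="session")
def dense_truth(small_grid):
    """200 tetraploids from 100 selfed lines with a high exchange rate:
    a well-mixed dosage mosaic for association tests."""
    ped = simtetra.PedigreeSpec(generations=4, individuals_per_line=2,
                                lines_per_cross=50, cross_directions=("NN99",))
    he = simtetra.HEModel(rate_per_pair=3.0, tract_mean_bp=300_000)
    return simtetra.simulate_population(small_grid, ped, he, seed=202)


@pytest.fixture(scope="session")
def dense_dosage(dense_truth):
    return dense_truth.dosage()


def polymorphic_bin(dosage_values: np.ndarray, rank: int = 0) -> int:
    """Global index of the rank-th most variable bin."""
    var = dosage_values.astype(float).var(axis=0)
    return int(np.argsort(var)[::-1][rank])


@pytest.fixture()
def tiny_grid():
    return core_io.GenomeGrid(
        chromosomes=[("chr1", 40_000), ("chr2", 40_000)],
        centromeres={"chr1": 20_000, "chr2": 20_000},
        bin_width=5000,
        region_bin_width=5000,
    )


def make_dosage(values, grid, individuals=None, meta=None):
    values = np.asarray(values, dtype=np.int8)
    if individuals is None:
        individuals = [f"ind{i}" for i in range(values.shape[0])]
    return core_io.DosageMatrix(values, individuals, grid, meta)
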