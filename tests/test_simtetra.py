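"""Forward-simulator properties: conservation, segregation, observation models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mosaiche import simtetra
from mosaiche.simtetra import (
    GeneticArchitecture,
    HEModel,
    PedigreeSpec,
    Qtl,
    EpistaticPair,
    SelectedSegment,
    SelectionSpec,
    TraitModel,
    genetic_values,
    make_panel_and_grid,
    sample_allele_depths,
    sample_expression,
    sample_phenotypes,
    simulate_population,
)


def test_panel_and_grid_density_and_determinism():
    panel, grid = make_panel_and_grid(n_chrom=2, chrom_length=1_000_000,
                                      snp_density=1 / 500, bin_width=5000, seed=3)
    # mean SNPs per 5-kb bin ~ 10
    assert 8 < len(panel) / grid.n_bins_total < 12
    # sorted within chromosomes
    for _, sub in panel.df.groupby("chrom"):
        assert sub["pos"].is_monotonic_increasing
    panel2, _ = make_panel_and_grid(n_chrom=2, chrom_length=1_000_000,
                                    snp_density=1 / 500, bin_width=5000, seed=3)
    pd.testing.assert_frame_equal(panel.df, panel2.df)
    with pytest.raises(ValueError):
        make_panel_and_grid(bin_width=10**9)


def test_zero_rate_population_is_invariant(small_grid):
    """Without homoeologous exchange the selfing population stays 2:2
    everywhere at any generation — HE is the only source of variation."""
    ped = PedigreeSpec(generations=3, individuals_per_line=3, lines_per_cross=3)
    truth = simulate_population(small_grid, ped, HEModel(rate_per_pair=0.0), seed=5)
    assert (truth.dosage().values == 2).all()
    assert len(truth.he_events) == 0
    assert len(truth.breakpoints()) == 0


def test_dosage_conservation(dense_truth):
    """NPB copies + 93-11 copies = 4 at every bin of every individual."""
    d = dense_truth.dosage().values
    assert d.min() >= 0 and d.max() <= 4
    npb_copies = (dense_truth.haplotypes == simtetra.NPB).sum(axis=1)
    np.testing.assert_array_equal(npb_copies, d)


def test_cumulative_he_count_matches_closed_form(small_grid):
    """Cumulative drawn breakpoints have expectation 2 * g * n_chrom * 2 * rate."""
    rate, g = 1.0, 2
    ped = PedigreeSpec(generations=g, individuals_per_line=2, lines_per_cross=40,
                       cross_directions=("NN99",))
    truth = simulate_population(small_grid, ped, HEModel(rate, tract_mean_bp=200_000), seed=6)
    counts = truth.he_events.groupby("individual").size().reindex(
        truth.individuals, fill_value=0)
    expected = 2 * g * 2 * small_grid.chromosomes.__len__() * rate  # 2 pairs/quartet
    line_means = counts.groupby(truth.meta["line"]).mean()
    se = line_means.std(ddof=1) / np.sqrt(len(line_means))
    assert abs(counts.mean() - expected) < 3 * se + 1e-9


def test_heterozygous_locus_segregates_1_2_1(small_grid):
    """A d=3 locus (one converted homolog in subgenome B) selfs to offspring
    dosages {2, 3, 4} in 1:2:1."""
    rng = np.random.default_rng(11)
    he = HEModel(rate_per_pair=0.0)
    weights = {c: he.boundary_weights(small_grid, c) for c, _ in small_grid.chromosomes}
    means = {c: 0.0 for c, _ in small_grid.chromosomes}
    parent = np.zeros((4, small_grid.n_bins_total), dtype=np.int8)
    parent[2:] = simtetra.IND
    locus = 100
    parent[2, locus] = simtetra.NPB  # d = 3 at the locus
    counts = {2: 0, 3: 0, 4: 0}
    for _ in range(2000):
        child, _ = simtetra._self(parent, small_grid, he, SelectionSpec(), "NN99",
                                  weights, means, rng)
        counts[int(4 - child[:, locus].sum())] += 1
    obs = np.array([counts[2], counts[3], counts[4]])
    p = stats.chisquare(obs, f_exp=np.array([0.25, 0.5, 0.25]) * 2000).pvalue
    assert p > 0.01


def test_selection_retention_monotone_in_s(small_grid):
    seg = SelectedSegment("chr01", 1_000_000, 1_100_000, "require_maternal",
                          ("NN99",), 1.0)
    he = HEModel(rate_per_pair=3.0, tract_mean_bp=300_000)
    ped = PedigreeSpec(generations=4, individuals_per_line=2, lines_per_cross=30,
                       cross_directions=("NN99",))
    b0 = small_grid.bin_index("chr01", 1_000_000)
    b1 = small_grid.bin_index("chr01", 1_100_000 - 1) + 1

    def retention(s):
        sel = SelectionSpec([SelectedSegment("chr01", 1_000_000, 1_100_000,
                                             "require_maternal", ("NN99",), s)])
        truth = simulate_population(small_grid, ped, he, sel, seed=17)
        d = truth.dosage().values[:, b0:b1]
        return float((d >= 1).all(axis=1).mean())

    r0, r_half, r1 = retention(0.0), retention(0.7), retention(1.0)
    assert r1 == 1.0
    assert r0 <= r_half + 0.05 <= r1 + 0.05
    assert r_half >= r0 - 0.05


def test_allele_depth_fractions(small_panel_grid):
    panel, grid = small_panel_grid
    ped = PedigreeSpec(generations=1, individuals_per_line=2, lines_per_cross=2,
                       cross_directions=("NN99",))
    truth = simulate_population(grid, ped, HEModel(0.0), seed=8)

    # d = 2 everywhere: NPB fraction 0.5 regardless of e (symmetry of f_2)
    adm = sample_allele_depths(truth, panel, coverage=10, error_rate=0.05, seed=9)
    frac = adm.npb.sum() / adm.total.sum()
    assert abs(frac - 0.5) < 0.01

    # force d = 4: all reads NPB at e = 0
    truth.haplotypes[:] = simtetra.NPB
    adm4 = sample_allele_depths(truth, panel, coverage=10, error_rate=0.0, seed=10)
    assert adm4.ind.sum() == 0

    # d = 3 at e = 0.01: pooled NPB fraction ~ f_3 = 0.75*0.98 + 0.01 = 0.745
    truth.haplotypes[:] = simtetra.NPB
    truth.haplotypes[:, 3, :] = simtetra.IND
    adm3 = sample_allele_depths(truth, panel, coverage=10, error_rate=0.01, seed=11)
    frac3 = adm3.npb.sum() / adm3.total.sum()
    assert abs(frac3 - 0.745) < 0.005
    with pytest.raises(ValueError):
        sample_allele_depths(truth, panel, coverage=0)


def test_expression_sampling(small_panel_grid):
    panel, grid = small_panel_grid
    ped = PedigreeSpec(generations=1, individuals_per_line=5, lines_per_cross=10,
                       cross_directions=("NN99",))
    truth = simulate_population(grid, ped, HEModel(0.0), seed=12)
    from mosaiche.core_io import AnnotationTable
    genes = AnnotationTable(pd.DataFrame({
        "gene_id": ["gA", "gB"], "chrom": ["chr01", "chr01"],
        "start": [10_000, 50_000], "end": [12_000, 52_000],
        "cytonuclear_flag": ["none", "none"],
    }))
    # d = 0 coupled -> zero NPB transcripts at zero overdispersion
    truth.haplotypes[:] = simtetra.IND
    ec = sample_expression(truth, genes, total_reads=400, seed=13)
    assert (ec.df["reads_npb"] == 0).all()
    # uncoupled: mean fraction 0.5 whatever the dosage
    ec_u = sample_expression(truth, genes, total_reads=400,
                             coupled={"gA": False, "gB": False}, seed=14)
    frac = ec_u.df["reads_npb"].sum() / 400 / len(ec_u.df)
    assert abs(frac - 0.5) < 0.03
    # coupled d = 1, total 400 -> mean NPB count 100
    truth.haplotypes[:] = simtetra.IND
    truth.haplotypes[:, 0, :] = simtetra.NPB
    ec1 = sample_expression(truth, genes, total_reads=400, seed=15)
    assert abs(ec1.df["reads_npb"].mean() - 100) < 6


def test_phenotype_codes_at_design_points(small_grid):
    """F-infinity coding endpoints: sigma=0, a=2 gives mu-2 at d=0 and mu+2
    at d=4; a dd=3 pair with both loci heterozygous gives mu+3."""
    model = TraitModel(qtls=[Qtl(bin=5, a=2.0, k=0.0)], mu=1.0, sigma=0.0)
    for d, expect in ((0, -1.0), (4, 3.0), (2, 1.0)):
        dosage = np.full((3, small_grid.n_bins_total), d, dtype=float)
        np.testing.assert_allclose(genetic_values(dosage, model), expect)
    pair_model = TraitModel(pairs=[EpistaticPair(2, 7, dd=3.0)], mu=1.0, sigma=0.0)
    dosage = np.full((2, small_grid.n_bins_total), 2.0)
    np.testing.assert_allclose(genetic_values(dosage, pair_model), 4.0)


def test_phenotype_variance_decomposition(dense_truth):
    """Sample trait variance ~ genetic variance + residual variance."""
    from conftest import polymorphic_bin

    qbin = polymorphic_bin(dense_truth.dosage().values)
    model = TraitModel(qtls=[Qtl(qbin, a=2.0)], mu=0.0, sigma=1.0)
    arch = GeneticArchitecture({"t": model})
    tt = sample_phenotypes(dense_truth, arch, seed=21)
    y = tt.df["t"].to_numpy(dtype=float)
    g = genetic_values(dense_truth.dosage().values.astype(float), model)
    expected_var = g.var() + 1.0
    assert abs(y.var() - expected_var) / expected_var < 0.25


def test_simulation_is_seed_deterministic(small_grid):
    ped = PedigreeSpec(generations=2, individuals_per_line=2, lines_per_cross=2)
    a = simulate_population(small_grid, ped, HEModel(1.0), seed=33)
    b = simulate_population(small_grid, ped, HEModel(1.0), seed=33)
    np.testing.assert_array_equal(a.haplotypes, b.haplotypes)
    pd.testing.assert_frame_equal(a.he_events, b.he_events)
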