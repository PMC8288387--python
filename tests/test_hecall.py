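"""Dosage caller: emission likelihoods, Viterbi smoothing vs exhaustive
enumeration, breakpoint calling, euploidy screening and rate estimation."""

import numpy as np
import pandas as pd
import pytest

from mosaiche import hecall, simtetra
from mosaiche.core_io import MISSING, AlleleDepthMatrix, GenomeGrid, SnpPanel
from mosaiche.hecall import (
    BinLikelihoods,
    bin_likelihoods,
    call_breakpoints,
    estimate_error_rate,
    he_rate,
    screen_euploidy,
    viterbi_dosage,
)

from conftest import make_dosage


def _single_chrom_grid(n_bins: int) -> GenomeGrid:
    return GenomeGrid([("c", n_bins * 5000)], {"c": n_bins * 2500},
                      bin_width=5000, region_bin_width=5000)


def _panel_one_snp_per_bin(grid: GenomeGrid) -> SnpPanel:
    bins = grid.bin_table()
    return SnpPanel(pd.DataFrame({
        "chrom": bins["chrom"],
        "pos": bins["start"] + 100,
        "npb_allele": "A",
        "ind_allele": "G",
    }))


def _bl_from_emissions(emissions: np.ndarray) -> BinLikelihoods:
    """Wrap a hand-made (n_ind, n_bins, 5) emission array (no missing bins)."""
    n_ind, n_bins, _ = emissions.shape
    grid = _single_chrom_grid(n_bins)
    n = np.full((n_ind, n_bins), 10, dtype=np.int64)
    k = np.full_like(n, 5)
    return BinLikelihoods(emissions.astype(float), k, n, np.ones(n_bins, dtype=int),
                          [f"i{j}" for j in range(n_ind)], grid, 0.01)


def _brute_force_path(emissions: np.ndarray, tau: float) -> tuple[np.ndarray, float]:
    """Exhaustive max over all 5^L state paths (independent oracle)."""
    L = emissions.shape[0]
    paths = np.stack(np.meshgrid(*([np.arange(5)] * L), indexing="ij"), axis=-1)
    paths = paths.reshape(-1, L)
    emit = emissions[np.arange(L)[None, :], paths].sum(axis=1)
    switches = (paths[:, 1:] != paths[:, :-1]).sum(axis=1)
    score = emit + switches * np.log(tau / 4) + (L - 1 - switches) * np.log(1 - tau)
    best = int(np.argmax(score))
    return paths[best], float(score[best])


def test_bin_likelihood_argmax_examples():
    grid = _single_chrom_grid(1)
    panel = _panel_one_snp_per_bin(grid)
    # K = N = 40 at e = 0 -> d = 4
    adm = AlleleDepthMatrix(["a"], np.array([[40]]), np.array([[0]]))
    bl = bin_likelihoods(adm, panel, grid, error_rate=0.0)
    assert int(bl.loglik[0, 0].argmax()) == 4
    assert np.isfinite(bl.loglik).all()  # -inf clamped, never NaN
    # K = 30 of N = 40 at e = 0.01 -> d = 3 (f_3 = 0.745 maximizes)
    adm = AlleleDepthMatrix(["a"], np.array([[30]]), np.array([[10]]))
    bl = bin_likelihoods(adm, panel, grid, error_rate=0.01)
    assert int(bl.loglik[0, 0].argmax()) == 3
    # N = 0 -> MISSING bin
    adm = AlleleDepthMatrix(["a"], np.array([[0]]), np.array([[0]]))
    bl = bin_likelihoods(adm, panel, grid, error_rate=0.01)
    assert bl.missing[0, 0]
    with pytest.raises(ValueError):
        bin_likelihoods(adm, panel, grid, error_rate=0.6)


def test_viterbi_equals_exhaustive_enumeration():
    """Smoothing matches brute-force path enumeration on random instances."""
    rng = np.random.default_rng(42)
    for _ in range(30):
        L = int(rng.integers(2, 7))
        emissions = rng.normal(0, 3, size=(1, L, 5))
        tau = float(rng.choice([1e-4, 1e-2, 0.2]))
        bl = _bl_from_emissions(emissions)
        dm = viterbi_dosage(bl, tau)
        oracle_path, oracle_score = _brute_force_path(emissions[0], tau)
        np.testing.assert_array_equal(dm.values[0], oracle_path)


def test_viterbi_smooths_isolated_state():
    """A weakly supported discordant bin inside a strong run is smoothed out;
    two strong blocks yield exactly one switch at the true boundary."""
    e = np.full((1, 8, 5), -10.0)
    e[0, :, 2] = -1.0          # strong d=2 everywhere
    e[0, 4, 2], e[0, 4, 3] = -2.0, -1.5  # weak preference for 3 at bin 4
    dm = viterbi_dosage(_bl_from_emissions(e), 1e-4)
    assert (dm.values[0] == 2).all()

    e2 = np.full((1, 8, 5), -30.0)
    e2[0, :4, 2] = -1.0
    e2[0, 4:, 3] = -1.0
    dm2 = viterbi_dosage(_bl_from_emissions(e2), 1e-4)
    assert dm2.values[0].tolist() == [2, 2, 2, 2, 3, 3, 3, 3]


def test_viterbi_all_missing_chromosome_warns():
    grid = _single_chrom_grid(4)
    bl = BinLikelihoods(np.zeros((1, 4, 5)), np.zeros((1, 4), dtype=int),
                        np.zeros((1, 4), dtype=int), np.zeros(4, dtype=int),
                        ["a"], grid, 0.01)
    with pytest.warns(UserWarning, match="all-MISSING"):
        dm = viterbi_dosage(bl, 1e-4)
    assert (dm.values[0] == MISSING).all()


def test_call_breakpoints_rules():
    grid = _single_chrom_grid(4)
    # constant states -> empty
    assert len(call_breakpoints(make_dosage([[2, 2, 2, 2]], grid))) == 0
    # [2,2,3,3] -> one event at 10000
    he = call_breakpoints(make_dosage([[2, 2, 3, 3]], grid))
    assert len(he) == 1
    row = he.iloc[0]
    assert (row["boundary"], row["left_state"], row["right_state"]) == (10000, 2, 3)
    assert not row["flagged"]
    # [2, MISSING, 3, 3] -> one flagged event at the gap midpoint boundary
    he2 = call_breakpoints(make_dosage([[2, MISSING, 3, 3]], grid))
    assert len(he2) == 1
    assert bool(he2.iloc[0]["flagged"])
    assert he2.iloc[0]["boundary"] in (5000, 10000)


def test_screen_euploidy_flags_depth_shift():
    grid = GenomeGrid([("c1", 100_000), ("c2", 100_000)],
                      {"c1": 50_000, "c2": 50_000}, bin_width=5000,
                      region_bin_width=5000)
    bins = grid.bin_table()
    panel = SnpPanel(pd.DataFrame({
        "chrom": bins["chrom"], "pos": bins["start"] + 10,
        "npb_allele": "A", "ind_allele": "G"}))
    rng = np.random.default_rng(5)
    depth = rng.poisson(50, size=(1, len(panel)))
    npb = depth // 2
    adm = AlleleDepthMatrix(["a"], npb, depth - npb)
    verdict = screen_euploidy(adm, panel, grid)
    assert verdict.loc["a", "verdict"] == "euploid"
    # scale one chromosome's depth by 0.75 (monosomic-like shift)
    scaled = depth.copy()
    c2 = (bins["chrom"] == "c2").to_numpy()
    scaled[0, c2] = (scaled[0, c2] * 0.75).astype(int)
    adm2 = AlleleDepthMatrix(["a"], scaled // 2, scaled - scaled // 2)
    assert screen_euploidy(adm2, panel, grid).loc["a", "verdict"] == "aneuploid"
    assert screen_euploidy(adm2, panel, grid, tolerance=1.0).loc["a", "verdict"] == "euploid"


def test_he_rate_arithmetic():
    def table(n_events_per_ind):
        rows = []
        for i, n in enumerate(n_events_per_ind):
            for _ in range(n):
                rows.append({"individual": f"i{i}", "chrom": "c", "boundary": 5000,
                             "left_state": 2, "right_state": 3, "flagged": False})
        return pd.DataFrame(rows)

    per_meiosis, per_pair = he_rate(table([16, 16]), generation=4)
    assert per_meiosis == pytest.approx(2.0)
    # S5-scale: mean cumulative count 190 over 10 meioses
    per_meiosis, per_pair = he_rate(table([190, 190]), generation=5)
    assert per_meiosis == pytest.approx(19.0)
    assert round(per_pair, 2) == 0.79
    assert he_rate(pd.DataFrame(), generation=1) == (0.0, 0.0)
    with pytest.raises(ValueError):
        he_rate(pd.DataFrame(), generation=0)


def test_error_rate_self_calibration(small_panel_grid):
    panel, grid = small_panel_grid
    ped = simtetra.PedigreeSpec(1, 2, 2, ("NN99",))
    truth = simtetra.simulate_population(grid, ped, simtetra.HEModel(0.0), seed=3)
    truth.haplotypes[:] = simtetra.NPB  # fully homozygous genome
    adm = simtetra.sample_allele_depths(truth, panel, coverage=20,
                                        error_rate=0.012, seed=4)
    e_hat = estimate_error_rate(adm, panel, grid)
    assert abs(e_hat - 0.012) < 0.003


def test_caller_recovers_simulated_tracts(small_panel_grid):
    """End-to-end on a dense small genome: called dosage matches truth on
    >= 99% of bins and every multi-bin tract breakpoint is recovered within
    one bin (single-bin tracts can be smoothed away by design)."""
    panel, grid = small_panel_grid
    ped = simtetra.PedigreeSpec(4, 2, 10, ("NN99",))
    he = simtetra.HEModel(rate_per_pair=1.0, tract_mean_bp=300_000)
    truth = simtetra.simulate_population(grid, ped, he, seed=31)
    adm = simtetra.sample_allele_depths(truth, panel, 10.0, 0.01, seed=32)
    bl = bin_likelihoods(adm, panel, grid, 0.01)
    dm = viterbi_dosage(bl, 1e-4)
    truth_dm = truth.dosage()
    called = dm.values != MISSING
    acc = (dm.values[called] == truth_dm.values[called]).mean()
    assert acc >= 0.99
    called_he = call_breakpoints(dm)
    true_he = call_breakpoints(truth_dm)
    bw = grid.bin_width
    n_checked = n_found = 0
    for row in true_he.itertuples(index=False):
        # skip breakpoints of tracts shorter than 3 bins: at 10x coverage the
        # Viterbi switch penalty can outweigh their pooled evidence by design
        near = true_he[(true_he["individual"] == row.individual)
                       & (true_he["chrom"] == row.chrom)
                       & (abs(true_he["boundary"] - row.boundary) <= 2 * bw)
                       & (true_he["boundary"] != row.boundary)]
        if len(near):
            continue
        n_checked += 1
        match = called_he[(called_he["individual"] == row.individual)
                          & (called_he["chrom"] == row.chrom)
                          & (abs(called_he["boundary"] - row.boundary) <= bw)]
        n_found += int(len(match) > 0)
    assert n_checked > 50
    assert n_found / n_checked >= 0.99
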