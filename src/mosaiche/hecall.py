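"""Homoeolog dosage inference and HE breakpoint calling.

Per 5-kb bin, read counts over the bin's diagnostic SNPs are pooled and
scored under the five euploid dosage states d in {0..4}: with K NPB reads of
N total and expected NPB read fraction f_d = (d/4)(1 - 2e) + e,

    loglik(d) = K log f_d + (N - K) log(1 - f_d).

A five-state Viterbi pass along each chromosome smooths the per-bin calls
(stay log(1 - tau), switch log(tau/4); bins with no reads contribute a flat
emission).  Breakpoints are the boundaries between adjacent bins with
different smoothed states; state changes across a run of MISSING bins are
placed at the gap's midpoint boundary and flagged low-resolution.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from dataclasses import dataclass

from .core_io import (
    MISSING,
    AlleleDepthMatrix,
    DosageMatrix,
    GenomeGrid,
    SnpPanel,
    empty_he_table,
)
from .simtetra import dosage_allele_fraction

log = logging.getLogger("mosaiche.hecall")

#: finite stand-in for log 0 (keeps Viterbi arithmetic NaN-free at e = 0)
LOG_ZERO = -1e12


@dataclass
class BinLikelihoods:
    """Pooled per-bin evidence: K (NPB reads), N (total reads) per individual
    per bin, SNP count per bin, and the 5-state log-likelihood array."""

    loglik: np.ndarray  # (n_individuals, n_bins, 5)
    k: np.ndarray  # (n_individuals, n_bins)
    n: np.ndarray  # (n_individuals, n_bins)
    snp_count: np.ndarray  # (n_bins,)
    individuals: list[str]
    grid: GenomeGrid
    error_rate: float

    @property
    def missing(self) -> np.ndarray:
        """Bins with no reads for an individual (no information)."""
        return self.n == 0


def bin_likelihoods(
    adm: AlleleDepthMatrix, panel: SnpPanel, grid: GenomeGrid, error_rate: float = 0.01
) -> BinLikelihoods:
    if not 0 <= error_rate < 0.5:
        raise ValueError("error rate must be in [0, 0.5)")
    snp_bins = panel.bin_indices(grid)
    n_ind = len(adm.individuals)
    nb = grid.n_bins_total
    k = np.zeros((n_ind, nb), dtype=np.int64)
    n = np.zeros((n_ind, nb), dtype=np.int64)
    for i in range(n_ind):
        k[i] = np.bincount(snp_bins, weights=adm.npb[i], minlength=nb)
        n[i] = k[i] + np.bincount(snp_bins, weights=adm.ind[i], minlength=nb)
    snp_count = np.bincount(snp_bins, minlength=nb)
    f = np.asarray(dosage_allele_fraction(np.arange(5), error_rate))
    with np.errstate(divide="ignore"):
        logf = np.where(f > 0, np.log(np.maximum(f, 1e-300)), LOG_ZERO)
        log1mf = np.where(f < 1, np.log(np.maximum(1 - f, 1e-300)), LOG_ZERO)
    kk = k[:, :, None].astype(float)
    mm = (n - k)[:, :, None].astype(float)
    # 0 * log 0 = 0: zero counts contribute nothing even at f in {0, 1}
    ll = np.where(kk > 0, kk * logf, 0.0) + np.where(mm > 0, mm * log1mf, 0.0)
    log.info(
        "bin_likelihoods: %d individuals x %d bins, %.1f SNPs/bin, e=%.4g",
        n_ind, nb, snp_count.mean(), error_rate,
    )
    return BinLikelihoods(ll, k, n, snp_count, list(adm.individuals), grid, error_rate)


def estimate_error_rate(
    adm: AlleleDepthMatrix, panel: SnpPanel, grid: GenomeGrid, extreme: float = 0.05
) -> float:
    """Self-calibrated per-read error rate: pooled minority-read fraction over
    bins whose raw NPB fraction is extreme (apparently homozygous runs); at
    d in {0, 4} the minority fraction estimates e directly."""
    bl = bin_likelihoods(adm, panel, grid, error_rate=0.0)
    n, k = bl.n, bl.k
    with np.errstate(invalid="ignore"):
        frac = np.where(n > 0, k / np.maximum(n, 1), np.nan)
    hi = frac >= 1 - extreme
    lo = frac <= extreme
    minority = np.where(hi, n - k, np.where(lo, k, 0)).sum()
    total = np.where(hi | lo, n, 0).sum()
    if total == 0:
        raise ValueError("no apparently homozygous bins; cannot estimate error rate")
    e = float(minority / total)
    log.info("estimate_error_rate: e_hat=%.4g from %d reads", e, int(total))
    return e


def viterbi_dosage(bl: BinLikelihoods, switch_prob: float = 1e-4) -> DosageMatrix:
    """Most probable 5-state dosage path per individual per chromosome.

    Transitions: stay log(1 - tau), switch log(tau / 4).  MISSING bins carry a
    flat emission (they are traversed but reported MISSING in the output).
    Ties are broken toward keeping the left neighbour's state.  All-MISSING
    chromosomes yield an all-MISSING path with a warning.
    """
    if not 0 < switch_prob < 1:
        raise ValueError("switch_prob must be in (0, 1)")
    tau = switch_prob
    stay, switch = np.log(1 - tau), np.log(tau / 4.0)
    grid = bl.grid
    n_ind = len(bl.individuals)
    out = np.full((n_ind, grid.n_bins_total), MISSING, dtype=np.int8)
    n_all_missing = 0
    for chrom, _ in grid.chromosomes:
        sl = grid.chrom_slice(chrom)
        e = bl.loglik[:, sl, :].copy()
        miss = bl.missing[:, sl]
        e[miss] = 0.0  # flat emission on uninformative bins
        L = e.shape[1]
        ptr = np.empty((n_ind, L, 5), dtype=np.int8)
        score = e[:, 0, :].copy()
        idx5 = np.arange(5, dtype=np.int8)
        for t in range(1, L):
            # switching: best previous state overall; staying: same state
            best_prev = score.argmax(axis=1)
            best_val = score[np.arange(n_ind), best_prev]
            sw = best_val[:, None] + switch
            st = score + stay
            keep = st >= sw  # tie -> keep left-neighbour state
            ptr[:, t, :] = np.where(keep, idx5[None, :], best_prev[:, None].astype(np.int8))
            score = np.where(keep, st, sw) + e[:, t, :]
        states = np.empty((n_ind, L), dtype=np.int8)
        states[:, L - 1] = score.argmax(axis=1)
        for t in range(L - 1, 0, -1):
            states[:, t - 1] = ptr[np.arange(n_ind), t, states[:, t]]
        all_missing = miss.all(axis=1)
        n_all_missing += int(all_missing.sum())
        chrom_out = np.where(miss, MISSING, states)
        chrom_out[all_missing] = MISSING
        out[:, sl] = chrom_out
    if n_all_missing:
        warnings.warn(f"{n_all_missing} individual x chromosome paths were all-MISSING")
    meta = None
    return DosageMatrix(out, list(bl.individuals), grid, meta)


def call_breakpoints(dm: DosageMatrix) -> pd.DataFrame:
    """HE breakpoints: one event per adjacent-bin state change per individual
    per chromosome.  A state change across a MISSING run is placed at the
    gap's midpoint boundary and flagged."""
    grid = dm.grid
    rows = []
    for chrom, _ in grid.chromosomes:
        vals = dm.chrom_values(chrom)
        bw = grid.bin_width
        for i, indiv in enumerate(dm.individuals):
            v = vals[i]
            obs = np.nonzero(v != MISSING)[0]
            if len(obs) < 2:
                continue
            states = v[obs]
            change = np.nonzero(states[1:] != states[:-1])[0]
            for c in change:
                left_bin, right_bin = int(obs[c]), int(obs[c + 1])
                boundary_bin = (left_bin + 1 + right_bin) // 2
                rows.append(
                    (
                        indiv,
                        chrom,
                        boundary_bin * bw,
                        int(states[c]),
                        int(states[c + 1]),
                        right_bin - left_bin > 1,
                    )
                )
    if not rows:
        return empty_he_table()
    he = pd.DataFrame(rows, columns=["individual", "chrom", "boundary", "left_state", "right_state", "flagged"])
    he["left_state"] = he["left_state"].astype(np.int8)
    he["right_state"] = he["right_state"].astype(np.int8)
    return he


def screen_euploidy(
    adm: AlleleDepthMatrix,
    panel: SnpPanel,
    grid: GenomeGrid,
    tolerance: float = 0.15,
) -> pd.DataFrame:
    """Depth-based euploidy screen.

    Per chromosome, the median per-bin total read depth is normalized by the
    individual's genome-wide median; a chromosome whose normalized depth
    deviates from 1 by more than ``tolerance`` flags the individual as a
    putative aneuploid.  Returns one row per individual with the verdict and
    the per-chromosome normalized depths.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    snp_bins = panel.bin_indices(grid)
    nb = grid.n_bins_total
    snp_count = np.bincount(snp_bins, minlength=nb)
    informative = snp_count > 0
    rows = []
    for i, indiv in enumerate(adm.individuals):
        depth = np.bincount(snp_bins, weights=adm.total[i], minlength=nb)
        genome_median = np.median(depth[informative])
        if genome_median == 0:
            raise ValueError(f"individual {indiv}: genome-wide median depth is zero")
        rec: dict = {"individual": indiv}
        aneuploid = False
        for chrom, _ in grid.chromosomes:
            sl = grid.chrom_slice(chrom)
            mask = informative[sl]
            norm = float(np.median(depth[sl][mask]) / genome_median) if mask.any() else np.nan
            rec[chrom] = norm
            if np.isfinite(norm) and abs(norm - 1.0) > tolerance:
                aneuploid = True
        rec["verdict"] = "aneuploid" if aneuploid else "euploid"
        rows.append(rec)
    return pd.DataFrame(rows).set_index("individual")


def he_rate(
    he: pd.DataFrame,
    generation: int,
    n_pairs: int = 24,
    n_individuals: int | None = None,
) -> tuple[float, float]:
    """Per-meiosis and per-chromosome-pair HE rates.

    The cumulative count per individual is divided by 2 * generation (two
    meioses per selfing generation); the per-pair rate divides further by the
    number of chromosome pairs (24 for tetraploid rice: 12 quartets = 24
    bivalents).
    """
    if generation < 1:
        raise ValueError("generation must be >= 1")
    if len(he) == 0:
        return 0.0, 0.0
    if n_individuals is None:
        n_individuals = he["individual"].nunique()
    mean_count = len(he) / n_individuals
    per_meiosis = mean_count / (2 * generation)
    return per_meiosis, per_meiosis / n_pairs
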