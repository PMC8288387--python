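"""Genome-wide HE and dosage landscape statistics.

Composition of the five homoeolog states (4:0, 3:1, 2:2, 1:3, 0:4), parental
genomic shares, exact-binomial symmetry tests, per-chromosome HE density
with permutation-based Poisson tests, and pericentromeric/subtelomeric
enrichment.  Map-style densities are expressed in cM/Mb by treating each HE
as one crossover-equivalent: cM/Mb = 100 * (events per meiosis) / Mb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MISSING, DosageMatrix, GenomeGrid

log = logging.getLogger("mosaiche.landscape")

STATE_LABELS = ["4:0", "3:1", "2:2", "1:3", "0:4"]  # NPB : 93-11, d = 4..0
REGION_LABELS = {0: "other", 1: "pericentromeric", 2: "subtelomeric"}


@dataclass
class CompositionSummary:
    """Five-state proportions (index order d = 0..4) and parental shares."""

    genome_wide: np.ndarray  # proportions for d = 0..4
    per_chromosome: pd.DataFrame
    per_cross: pd.DataFrame | None
    npb_share: float
    ind_share: float

    def as_state_labels(self) -> dict[str, float]:
        """Proportions keyed by the NPB:93-11 ratio labels (4:0 ... 0:4)."""
        return {lab: float(self.genome_wide[4 - i]) for i, lab in enumerate(STATE_LABELS)}


def _state_props(values: np.ndarray) -> np.ndarray:
    called = values[values != MISSING]
    if called.size == 0:
        raise ValueError("no called dosage cells")
    counts = np.bincount(called, minlength=5)
    return counts / counts.sum()


def composition_summary(dm: DosageMatrix) -> CompositionSummary:
    """State proportions over all individual x bin cells (MISSING excluded),
    genome-wide, per chromosome and per cross direction; parental NPB share
    = mean(d) / 4 over called cells."""
    gw = _state_props(dm.values)
    rows = []
    for chrom, _ in dm.grid.chromosomes:
        vals = dm.chrom_values(chrom)
        props = _state_props(vals) if (vals != MISSING).any() else np.full(5, np.nan)
        rows.append([chrom, *props])
    per_chrom = pd.DataFrame(rows, columns=["chrom", *[f"d{d}" for d in range(5)]])
    per_cross = None
    if dm.meta is not None and "cross" in dm.meta.columns:
        crows = []
        for cross in dict.fromkeys(dm.meta["cross"]):
            mask = (dm.meta.loc[dm.individuals, "cross"] == cross).to_numpy()
            crows.append([cross, *_state_props(dm.values[mask])])
        per_cross = pd.DataFrame(crows, columns=["cross", *[f"d{d}" for d in range(5)]])
    called = dm.values[dm.values != MISSING]
    npb_share = float(called.mean() / 4.0)
    return CompositionSummary(gw, per_chrom, per_cross, npb_share, 1.0 - npb_share)


def symmetry_test(count_a: int, count_b: int) -> float:
    """Two-sided exact binomial test of count_a vs count_b against 50%:50%
    (minimum-likelihood two-sidedness)."""
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    n = count_a + count_b
    if n < 1:
        raise ValueError("need at least one observation")
    return float(stats.binomtest(count_a, n, 0.5).pvalue)


@dataclass
class DensityResult:
    per_chromosome: pd.DataFrame
    regional: pd.DataFrame | None = None


def _empirical_two_sided(obs: float, perm: np.ndarray) -> float:
    """Two-sided empirical p with +1 pseudocount: doubled smaller tail,
    capped at 1 — never exactly zero."""
    n = len(perm)
    p_hi = (1 + int((perm >= obs).sum())) / (n + 1)
    p_lo = (1 + int((perm <= obs).sum())) / (n + 1)
    return min(1.0, 2.0 * min(p_hi, p_lo))


def chromosome_density_test(
    he: pd.DataFrame,
    grid: GenomeGrid,
    n_meioses: int,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> DensityResult:
    """Per-chromosome HE counts against a length-proportional null.

    The total event count is redistributed across chromosomes with
    probability proportional to physical length (``n_perm`` multinomial
    replicates); two-sided empirical p per chromosome.  cM/Mb =
    100 * (count / n_meioses) / length_Mb.
    """
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    rng = np.random.default_rng(seed)
    names = [c for c, _ in grid.chromosomes]
    lengths = np.array([l for _, l in grid.chromosomes], dtype=float)
    counts = he.groupby("chrom").size().reindex(names, fill_value=0).to_numpy() if len(he) else np.zeros(len(names), dtype=int)
    total = int(counts.sum())
    length_mb = lengths / 1e6
    cm_mb = 100.0 * (counts / max(n_meioses, 1)) / length_mb
    if total == 0:
        pvals = np.ones(len(names))
    else:
        perm = rng.multinomial(total, lengths / lengths.sum(), size=n_perm)
        pvals = np.array(
            [_empirical_two_sided(counts[i], perm[:, i]) for i in range(len(names))]
        )
    df = pd.DataFrame(
        {
            "chrom": names,
            "count": counts,
            "length_mb": length_mb,
            "density_per_mb": counts / length_mb,
            "cm_per_mb": cm_mb,
            "p": pvals,
        }
    )
    return DensityResult(df)


def regional_enrichment(
    he: pd.DataFrame,
    grid: GenomeGrid,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Observed/expected HE counts in pericentromeric, subtelomeric and other
    regions against uniform placement over bin boundaries.

    Returns genome-wide and per-chromosome rows with O/E ratio and two-sided
    empirical p; chromosomes with zero events report O/E as NaN.
    """
    rng = np.random.default_rng(seed)
    classes = grid.region_classes()
    rows = []
    groups = [("genome", None)] + [(c, c) for c, _ in grid.chromosomes]
    for label, chrom in groups:
        if chrom is None:
            cls = classes
            sub = he
            offsets = {c: grid.chrom_slice(c).start for c, _ in grid.chromosomes}
            if len(he):
                bins = np.array(
                    [
                        offsets[c] + b // grid.bin_width
                        for c, b in zip(sub["chrom"], sub["boundary"])
                    ]
                )
            else:
                bins = np.array([], dtype=int)
        else:
            cls = classes[grid.chrom_slice(chrom)]
            sub = he[he["chrom"] == chrom] if len(he) else he
            bins = (sub["boundary"].to_numpy() // grid.bin_width) if len(sub) else np.array([], dtype=int)
        total = len(bins)
        n_bins = len(cls)
        class_frac = {k: float((cls == k).sum()) / n_bins for k in (0, 1, 2)}
        obs = {k: int((cls[np.minimum(bins, n_bins - 1)] == k).sum()) for k in (0, 1, 2)} if total else {k: 0 for k in (0, 1, 2)}
        if total:
            perm_bins = rng.integers(0, n_bins, size=(n_perm, total))
            perm_cls = cls[perm_bins]
        for k in (0, 1, 2):
            expected = total * class_frac[k]
            if total == 0:
                oe, p = np.nan, np.nan
            else:
                oe = obs[k] / expected if expected > 0 else np.nan
                p = _empirical_two_sided(obs[k], (perm_cls == k).sum(axis=1))
            rows.append(
                {
                    "scope": label,
                    "region": REGION_LABELS[k],
                    "observed": obs[k],
                    "expected": expected,
                    "oe": oe,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)
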