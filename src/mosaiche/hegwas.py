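"""Homoeolog-dosage GWAS with additive and dominance encodings.

The genetic variable is the five-state homoeolog copy number d (NPB copies,
0..4) per bin.  Four encodings are supported — additive (0,1,2,3,4) and
three dominance codings applied to d = 0..4 in order: dom_i (0,1,1,1,0),
dom_ii (0,2,2,2,1), dom_iii (1,2,2,2,0) — reflecting heterozygote
equivalence and transgressive effects toward either parent.

Association uses an iterative fixed-effect scheme in the FarmCPU spirit:
single-marker ordinary least squares with the current pseudo-QTNs as fixed
covariates (a covariate correlated |r| > 0.7 with the tested marker is
dropped for that test), followed by greedy LD-pruned re-selection of
pseudo-QTNs among markers passing the Bonferroni threshold, iterated to a
fixed point.  The population is a single biparental selfing family with no
stratification, so no random (kinship) effect is fitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MISSING, DosageMatrix, TraitTable, AnnotationTable, GenomeGrid

log = logging.getLogger("mosaiche.hegwas")

ENCODINGS: dict[str, list[int]] = {
    "additive": [0, 1, 2, 3, 4],
    "dom_i": [0, 1, 1, 1, 0],
    "dom_ii": [0, 2, 2, 2, 1],
    "dom_iii": [1, 2, 2, 2, 0],
}


@dataclass
class EncodedGenotypes:
    """Individuals x markers numeric codes under one encoding model.

    ``codes`` is float with NaN for MISSING dosage; ``bins`` maps marker
    column -> global bin index.
    """

    codes: np.ndarray
    individuals: list[str]
    model: str
    bins: np.ndarray
    grid: GenomeGrid


@dataclass
class GwasResult:
    table: pd.DataFrame  # marker, bin, effect, se, p
    threshold: float
    model: str
    trait: str
    pseudo_qtns: list[int]
    converged: bool
    n_iter: int

    @property
    def signals(self) -> pd.DataFrame:
        return self.table[self.table["p"] < self.threshold]


def encode(dm: DosageMatrix, model: str, bins: np.ndarray | None = None) -> EncodedGenotypes:
    """Elementwise encoding of dosage states; MISSING propagates to NaN."""
    if model not in ENCODINGS:
        raise ValueError(f"unknown encoding model {model!r} (choose from {list(ENCODINGS)})")
    mapping = np.array(ENCODINGS[model], dtype=float)
    if bins is None:
        bins = np.arange(dm.grid.n_bins_total)
    vals = dm.values[:, bins]
    codes = np.where(vals == MISSING, np.nan, mapping[np.maximum(vals, 0)])
    return EncodedGenotypes(codes, list(dm.individuals), model, np.asarray(bins), dm.grid)


def bonferroni(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / M."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def _ols_marker(y: np.ndarray, covs: np.ndarray | None, g: np.ndarray) -> tuple[float, float, float]:
    """OLS of y on [1, covs, g]; returns (effect, se, p) for g's coefficient.

    Rank-deficient designs drop the offending covariate columns (the marker
    column is always kept)."""
    n = len(y)
    cols = [np.ones(n)]
    if covs is not None and covs.size:
        cols.extend(covs.T)
    cols.append(g)
    X = np.column_stack(cols)
    # drop collinear covariate columns (never the intercept or the marker)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        keep = [0]
        for j in range(1, X.shape[1] - 1):
            if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
                keep.append(j)
        X = X[:, keep + [X.shape[1] - 1]]
        if np.linalg.matrix_rank(X) < X.shape[1]:
            return 0.0, np.nan, 1.0  # marker itself collinear with covariates
    k = X.shape[1]
    dof = n - k
    if dof < 1:
        return 0.0, np.nan, 1.0
    xtx_inv = np.linalg.pinv(X.T @ X)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    s2 = float(resid @ resid) / dof
    se = float(np.sqrt(max(s2 * xtx_inv[-1, -1], 0.0)))
    eff = float(beta[-1])
    if se == 0.0:
        return eff, 0.0, (0.0 if abs(eff) > 1e-10 else 1.0)
    t = eff / se
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return eff, se, max(p, 5e-324)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def run_gwas(
    eg: EncodedGenotypes,
    tt: TraitTable,
    trait: str,
    alpha: float = 0.05,
    max_iter: int = 10,
    r_thresh: float = 0.7,
) -> GwasResult:
    """Iterative pseudo-QTN GWAS of one trait under one encoding.

    With an empty pseudo-QTN set the first iteration is plain single-marker
    OLS.  Iteration stops when the pseudo-QTN set is unchanged or
    ``max_iter`` is reached (then the last iteration is returned, flagged
    non-converged).
    """
    common = [s for s in eg.individuals if s in tt.df.index]
    if len(common) < 30:
        raise ValueError("need >= 30 individuals with both genotype and phenotype")
    row_idx = [eg.individuals.index(s) for s in common]
    G = eg.codes[row_idx]
    y = tt.df.loc[common, trait].to_numpy(dtype=float)
    keep = ~np.isnan(y)
    G, y = G[keep], y[keep]
    # mean-impute residual missing codes (rare in called data)
    n_missing = int(np.isnan(G).sum())
    if n_missing:
        col_mean = np.nanmean(G, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        G = np.where(np.isnan(G), col_mean[None, :], G)
        log.info("run_gwas: mean-imputed %d missing genotype cells", n_missing)
    M = G.shape[1]
    if M < 1:
        raise ValueError("no markers")
    threshold = bonferroni(alpha, M)
    pseudo: list[int] = []
    converged = False
    it = 0
    effects = np.zeros(M)
    ses = np.full(M, np.nan)
    pvals = np.ones(M)
    for it in range(1, max_iter + 1):
        for m in range(M):
            g = G[:, m]
            if g.std() == 0:
                effects[m], ses[m], pvals[m] = 0.0, np.nan, 1.0
                continue
            usable = [q for q in pseudo if abs(_corr(g, G[:, q])) <= r_thresh]
            covs = G[:, usable] if usable else None
            effects[m], ses[m], pvals[m] = _ols_marker(y, covs, g)
        candidates = np.argsort(pvals, kind="stable")
        new_pseudo: list[int] = []
        for m in candidates:
            if pvals[m] >= threshold:
                break
            if all(abs(_corr(G[:, m], G[:, q])) <= r_thresh for q in new_pseudo):
                new_pseudo.append(int(m))
        if set(new_pseudo) == set(pseudo):
            converged = True
            break
        pseudo = new_pseudo
    if not converged:
        log.warning("run_gwas: pseudo-QTN set did not converge in %d iterations", max_iter)
    table = pd.DataFrame(
        {
            "marker": np.arange(M),
            "bin": eg.bins,
            "effect": effects,
            "se": ses,
            "p": pvals,
        }
    )
    log.info(
        "run_gwas: trait=%s model=%s M=%d threshold=%.3g signals=%d iterations=%d",
        trait, eg.model, M, threshold, int((pvals < threshold).sum()), it,
    )
    return GwasResult(table, threshold, eg.model, trait, pseudo, converged, it)


def delineate_segment(
    dm: DosageMatrix, peak_bin: int, r_min: float = 0.9
) -> tuple[str, int, int]:
    """Extend a GWAS peak into a linked segment.

    From the peak bin, extend left and right while the Pearson correlation
    between the peak's dosage vector and each bin's dosage vector exceeds
    ``r_min``; stop at the first failure per side (or the chromosome end).
    Returns the (chrom, start, end) bp interval of the included bins.
    """
    bins = dm.grid.bin_table()
    chrom = str(bins.iloc[peak_bin]["chrom"])
    sl = dm.grid.chrom_slice(chrom)
    peak = dm.values[:, peak_bin].astype(float)
    peak[dm.values[:, peak_bin] == MISSING] = np.nan
    if np.nanstd(peak) == 0 or np.all(np.isnan(peak)):
        raise ValueError("peak bin has zero dosage variance")

    def _r(b: int) -> float:
        v = dm.values[:, b].astype(float)
        v[dm.values[:, b] == MISSING] = np.nan
        ok = ~(np.isnan(peak) | np.isnan(v))
        if ok.sum() < 3 or v[ok].std() == 0 or peak[ok].std() == 0:
            return 0.0
        return float(np.corrcoef(peak[ok], v[ok])[0, 1])

    lo = peak_bin
    while lo - 1 >= sl.start and _r(lo - 1) > r_min:
        lo -= 1
    hi = peak_bin
    while hi + 1 < sl.stop and _r(hi + 1) > r_min:
        hi += 1
    return chrom, int(bins.iloc[lo]["start"]), int(bins.iloc[hi]["end"])


def annotate_candidates(
    segments: list[tuple[str, int, int]], ann: AnnotationTable
) -> pd.DataFrame:
    """Genes whose interval intersects a segment (half-open intervals: an
    abutting gene is not reported)."""
    rows = []
    for si, (chrom, start, end) in enumerate(segments):
        hit = ann.df[
            (ann.df["chrom"] == chrom) & (ann.df["start"] < end) & (ann.df["end"] > start)
        ]
        for g in hit.itertuples(index=False):
            rows.append(
                {
                    "segment": si,
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "gene_id": g.gene_id,
                    "known_trait_link": getattr(g, "known_trait_link", ""),
                }
            )
    return pd.DataFrame(
        rows, columns=["segment", "chrom", "start", "end", "gene_id", "known_trait_link"]
    )


def plot_manhattan(result: GwasResult, grid: GenomeGrid, path: str) -> None:
    """Manhattan plot of -log10 p along the genome with the Bonferroni line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bins = grid.bin_table()
    x = result.table["bin"].to_numpy()
    y = -np.log10(np.maximum(result.table["p"].to_numpy(), 1e-300))
    colors = pd.factorize(bins.iloc[x]["chrom"])[0] % 2
    fig, ax = plt.subplots(figsize=(9, 3))
    ax.scatter(x, y, c=np.where(colors == 0, "#34618d", "#8a8fa3"), s=6)
    ax.axhline(-np.log10(result.threshold), color="green", lw=1)
    ax.set_xlabel("bin")
    ax.set_ylabel("-log10 p")
    ax.set_title(f"{result.trait} ({result.model})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_qq(result: GwasResult, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = np.sort(np.maximum(result.table["p"].to_numpy(), 1e-300))
    exp = -np.log10((np.arange(1, len(p) + 1) - 0.5) / len(p))
    obs = -np.log10(p)
    fig, ax = plt.subplots(figsize=(3.2, 3.2))
    ax.plot(exp, obs, ".", ms=4)
    lim = max(exp.max(), obs.max())
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
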