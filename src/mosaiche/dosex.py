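"""Dosage-expression concordance.

Tests, per gene and tissue, whether homoeolog transcript ratios track the
DNA homoeolog dosage of the gene's bin.  Per gene x individual the
transcript counts (K NPB, L 93-11) are scored by a Pearson goodness-of-fit
chi-square against the dosage expectation f_d = (d/4)(1-2e) + e (a small e
avoids zero expectations at d in {0, 4}); per-gene evidence is Fisher-combined
across individuals and Benjamini-Hochberg adjusted across genes.

A gene is called dosage-dependent when the dosage model is *not* rejected
(adjusted GOF p >= alpha) AND the balanced 1:1 null is rejected for at least
one individual with d != 2 — a bare non-rejection cannot distinguish
coupling from low power, and at d = 2 the two nulls coincide.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .core_io import MISSING, DosageMatrix, ExpressionCounts
from .simtetra import dosage_allele_fraction

log = logging.getLogger("mosaiche.dosex")


def homoeolog_gof(reads_npb: int, reads_ind: int, d: int, e: float = 0.0) -> tuple[float, float]:
    """Pearson GOF of (K, L) transcript counts against the dosage expectation
    (f_d, 1 - f_d); df = 1.  Returns (chi2, p)."""
    n = reads_npb + reads_ind
    f = float(dosage_allele_fraction(d, e))
    exp = np.array([n * f, n * (1 - f)])
    obs = np.array([reads_npb, reads_ind], dtype=float)
    if (exp == 0).any():
        # degenerate expectation: any observed count on the zero side rejects
        zero_side = int(np.argmin(exp))
        return (np.inf, 0.0) if obs[zero_side] > 0 else (0.0, 1.0)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _fisher_combine(pvals: np.ndarray) -> float:
    pvals = np.clip(pvals, 1e-300, 1.0)
    x2 = -2.0 * np.log(pvals).sum()
    return float(stats.chi2.sf(x2, df=2 * len(pvals)))


def concordance_test(
    ec: ExpressionCounts,
    dm: DosageMatrix,
    min_reads: int = 20,
    e: float = 1e-3,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell GOF tests and per-gene verdicts.

    Returns ``(cells, genes)``: ``cells`` has one row per tested gene x
    individual x tissue with the dosage-GOF and balanced-null p-values;
    ``genes`` has the Fisher-combined, BH-adjusted per-gene x tissue verdict
    in {dosage_dependent, dosage_independent, indeterminate}.
    """
    idx = {s: i for i, s in enumerate(dm.individuals)}
    rows = []
    n_skipped = 0
    for row in ec.df.itertuples(index=False):
        i = idx.get(str(row.individual))
        b = ec.gene_bins.get(str(row.gene_id))
        if i is None or b is None:
            n_skipped += 1
            continue
        d = int(dm.values[i, b])
        if d == MISSING:
            n_skipped += 1
            continue
        k, l = int(row.reads_npb), int(row.reads_ind)
        if k + l < min_reads:
            n_skipped += 1
            continue
        chi2_d, p_d = homoeolog_gof(k, l, d, e)
        chi2_b, p_b = homoeolog_gof(k, l, 2, 0.0)  # balanced 1:1 null
        rows.append(
            {
                "gene_id": row.gene_id,
                "individual": row.individual,
                "tissue": row.tissue,
                "dosage": d,
                "reads_npb": k,
                "reads_ind": l,
                "gof_p": p_d,
                "balanced_p": p_b,
            }
        )
    if n_skipped:
        log.info("concordance_test: %d cells skipped (missing dosage or < %d reads)",
                 n_skipped, min_reads)
    cells = pd.DataFrame(
        rows,
        columns=["gene_id", "individual", "tissue", "dosage", "reads_npb",
                 "reads_ind", "gof_p", "balanced_p"],
    )
    gene_rows = []
    for (gene, tissue), sub in cells.groupby(["gene_id", "tissue"], sort=False):
        p_gene = _fisher_combine(sub["gof_p"].to_numpy())
        informative = sub[sub["dosage"] != 2]
        balanced_rejected = bool((informative["balanced_p"] < alpha).any()) if len(informative) else False
        gene_rows.append(
            {
                "gene_id": gene,
                "tissue": tissue,
                "n_cells": len(sub),
                "gof_p": p_gene,
                "balanced_rejected": balanced_rejected,
            }
        )
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "tissue", "n_cells", "gof_p", "balanced_rejected"]
    )
    if len(genes):
        genes["gof_p_adj"] = np.nan
        for tissue, sub in genes.groupby("tissue", sort=False):
            adj = multipletests(sub["gof_p"].to_numpy(), method="fdr_bh")[1]
            genes.loc[sub.index, "gof_p_adj"] = adj
        verdict = np.where(
            genes["gof_p_adj"] < alpha,
            "dosage_independent",
            np.where(genes["balanced_rejected"], "dosage_dependent", "indeterminate"),
        )
        genes["verdict"] = verdict
    else:
        genes["gof_p_adj"] = pd.Series(dtype=float)
        genes["verdict"] = pd.Series(dtype=str)
    return cells, genes


def concordance_summary(genes: pd.DataFrame) -> pd.DataFrame:
    """Fraction of dosage-dependent genes per tissue (among genes with a
    determinate verdict) with a Wilson 95% confidence interval."""
    if len(genes) == 0:
        raise ValueError("no tested genes")
    rows = []
    for tissue, sub in genes.groupby("tissue", sort=False):
        determinate = sub[sub["verdict"] != "indeterminate"]
        n = len(determinate)
        if n == 0:
            raise ValueError(f"tissue {tissue}: no determinate genes")
        k = int((determinate["verdict"] == "dosage_dependent").sum())
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        rows.append(
            {
                "tissue": tissue,
                "n_determinate": n,
                "n_dependent": k,
                "fraction_dependent": k / n,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)
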