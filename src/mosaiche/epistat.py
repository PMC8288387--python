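"""Two-locus F-infinity epistasis decomposition.

For a pair of homoeolog-dosage loci the trait is regressed on the design

    y ~ 1 + w1 + v1 + w2 + v2 + w1*w2 + w1*v2 + v1*w2 + v1*v2

with w = (d - 2)/2 in {-1, -1/2, 0, 1/2, 1} (homozygote contrast = +/-1) and
v = [d in {1, 2, 3}] the any-heterozygote indicator — the direct five-state
generalization of the diploid F-infinity codes.  The four interaction
coefficients are the additive-by-additive (aa), additive-by-dominant (ad),
dominant-by-additive (da) and dominant-by-dominant (dd) epistatic effects;
a pair is flagged epistatic when any interaction coefficient survives the
run-level Benjamini-Hochberg adjustment (across all pairs x 4 terms).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("mosaiche.epistat")

COEF_NAMES = ["mu", "a1", "d1", "a2", "d2", "aa", "ad", "da", "dd"]
INTERACTION_TERMS = ["aa", "ad", "da", "dd"]


def f_codes(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """F-infinity design codes for a dosage vector."""
    d = np.asarray(d, dtype=float)
    w = (d - 2.0) / 2.0
    v = ((d >= 1) & (d <= 3)).astype(float)
    return w, v


@dataclass
class EpistasisFit:
    coefficients: dict[str, float]
    se: dict[str, float]
    p: dict[str, float]
    dropped: list[str]
    n: int

    def row(self) -> dict:
        out = {"n": self.n, "dropped": ",".join(self.dropped)}
        for name in COEF_NAMES:
            out[name] = self.coefficients.get(name, np.nan)
            out[f"p_{name}"] = self.p.get(name, np.nan)
        return out


def f_infinity_fit(y: np.ndarray, d1: np.ndarray, d2: np.ndarray) -> EpistasisFit:
    """OLS fit of the two-locus F-infinity model.

    Collinear design columns (e.g. a locus with only homozygous states fixes
    v) are dropped and noted.  A perfect fit (zero residual) reports p = 0
    for non-zero coefficients and p = 1 for zero ones.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 30:
        raise ValueError("need >= 30 individuals")
    w1, v1 = f_codes(d1)
    w2, v2 = f_codes(d2)
    if np.std(d1) == 0 or np.std(d2) == 0:
        raise ValueError("both loci must be polymorphic")
    columns = {
        "mu": np.ones_like(y),
        "a1": w1,
        "d1": v1,
        "a2": w2,
        "d2": v2,
        "aa": w1 * w2,
        "ad": w1 * v2,
        "da": v1 * w2,
        "dd": v1 * v2,
    }
    keep, dropped = ["mu"], []
    X = columns["mu"][:, None]
    for name in COEF_NAMES[1:]:
        cand = np.column_stack([X, columns[name]])
        if np.linalg.matrix_rank(cand) > X.shape[1]:
            keep.append(name)
            X = cand
        else:
            dropped.append(name)
    n, k = X.shape
    dof = n - k
    xtx_inv = np.linalg.pinv(X.T @ X)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    coefficients = dict(zip(keep, map(float, beta)))
    se: dict[str, float] = {}
    p: dict[str, float] = {}
    if dof > 0 and rss / dof > 1e-20:
        s2 = rss / dof
        for j, name in enumerate(keep):
            sj = float(np.sqrt(max(s2 * xtx_inv[j, j], 0.0)))
            se[name] = sj
            t = beta[j] / sj if sj > 0 else np.inf
            p[name] = max(float(2 * stats.t.sf(abs(t), dof)), 5e-324)
    else:
        for name in keep:  # sigma = 0: exact determination
            se[name] = 0.0
            p[name] = 0.0 if abs(coefficients[name]) > 1e-8 else 1.0
    return EpistasisFit(coefficients, se, p, dropped, n)


def pair_candidates(
    loci_by_trait: dict[str, list[dict]], max_pairs: int = 500
) -> dict[str, list[tuple[int, int]]]:
    """All unordered pairs of a trait's associated loci, excluding pairs on
    the same delineated segment, capped at ``max_pairs`` by descending joint
    significance.

    Each locus is a dict with keys ``bin``, ``p`` and optionally
    ``segment`` (loci sharing a segment id are never paired).
    """
    out: dict[str, list[tuple[int, int]]] = {}
    for trait, loci in loci_by_trait.items():
        if len(loci) < 2:
            out[trait] = []
            continue
        pairs = []
        for l1, l2 in itertools.combinations(loci, 2):
            if l1.get("segment") is not None and l1.get("segment") == l2.get("segment"):
                continue
            joint = np.log(max(l1.get("p", 1.0), 5e-324)) + np.log(max(l2.get("p", 1.0), 5e-324))
            pairs.append((joint, int(l1["bin"]), int(l2["bin"])))
        pairs.sort()
        out[trait] = [(b1, b2) for _, b1, b2 in pairs[:max_pairs]]
    return out


def fit_pairs(
    tt_df: pd.DataFrame,
    dosage: np.ndarray,
    pairs_by_trait: dict[str, list[tuple[int, int]]],
    individuals: list[str],
) -> pd.DataFrame:
    """F-infinity fit for every candidate pair of every trait.

    ``dosage`` is the (n_individuals, n_bins) dosage array aligned to
    ``individuals``; trait values come from ``tt_df`` (indexed by
    individual).
    """
    rows = []
    idx = [individuals.index(s) for s in tt_df.index if s in individuals]
    common = [s for s in tt_df.index if s in individuals]
    D = dosage[idx]
    for trait, pairs in pairs_by_trait.items():
        y = tt_df.loc[common, trait].to_numpy(dtype=float)
        for b1, b2 in pairs:
            try:
                fit = f_infinity_fit(y, D[:, b1], D[:, b2])
            except ValueError:
                continue
            row = {"trait": trait, "bin_i": b1, "bin_j": b2}
            row.update(fit.row())
            rows.append(row)
    return pd.DataFrame(rows)


def epistasis_summary(results: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Run-level summary with BH adjustment across all pairs x 4 terms.

    A pair can count toward multiple interaction types.  Returns per-trait
    epistatic fractions, per-type frequencies over all tested pairs, and a
    Pearson chi-square of equal type frequencies.
    """
    if len(results) == 0:
        raise ValueError("no tested pairs")
    pmat = results[[f"p_{t}" for t in INTERACTION_TERMS]].to_numpy(dtype=float)
    flat = pmat.ravel()
    ok = ~np.isnan(flat)
    adj = np.full_like(flat, np.nan)
    if ok.any():
        adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
    adj = adj.reshape(pmat.shape)
    sig = adj < alpha
    out = results.copy()
    for j, term in enumerate(INTERACTION_TERMS):
        out[f"sig_{term}"] = sig[:, j]
    out["epistatic"] = sig.any(axis=1)
    per_trait = (
        out.groupby("trait")["epistatic"].agg(["sum", "size"]).reset_index()
        .rename(columns={"sum": "n_epistatic", "size": "n_pairs"})
    )
    per_trait["fraction"] = per_trait["n_epistatic"] / per_trait["n_pairs"]
    type_counts = {t: int(sig[:, j].sum()) for j, t in enumerate(INTERACTION_TERMS)}
    n_pairs = len(out)
    type_freq = {t: c / n_pairs for t, c in type_counts.items()}
    counts = np.array(list(type_counts.values()), dtype=float)
    if counts.sum() > 0:
        chi2, chi_p = stats.chisquare(counts)[:2]
    else:
        chi2, chi_p = 0.0, 1.0
    return {
        "table": out,
        "per_trait": per_trait,
        "n_pairs": n_pairs,
        "n_epistatic": int(out["epistatic"].sum()),
        "fraction_epistatic": float(out["epistatic"].mean()),
        "type_counts": type_counts,
        "type_frequencies": type_freq,
        "type_chi2": float(chi2),
        "type_chi2_p": float(chi_p),
    }
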