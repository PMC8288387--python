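"""Descriptive variation metrics and transgressive-segregation statistics.

The tetraploid population's hallmark is variance, not mean shift: the
standard deviation (SD), range (R = max - min) and coefficient of variation
(CV = SD / mean) per trait per group quantify it, and transgression counts
tally tetraploid individuals beyond both parental extremes.  Group contrasts
use Welch's unequal-variance t-test because tetraploid and parental
variances differ grossly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import TraitTable


def variation_metrics(tt: TraitTable) -> pd.DataFrame:
    """Sample SD (n-1 denominator), range and CV per group x trait.

    CV is NaN where the group mean is zero.  Requires at least two
    non-missing values per group x trait cell.
    """
    rows = []
    for group, sub in tt.df.groupby("group", sort=False):
        for trait in tt.trait_names:
            x = sub[trait].dropna().to_numpy(dtype=float)
            if len(x) < 2:
                raise ValueError(f"group {group}, trait {trait}: need >= 2 values")
            sd = float(np.std(x, ddof=1))
            r = float(x.max() - x.min())
            mean = float(x.mean())
            cv = sd / mean if mean != 0 else np.nan
            rows.append({"group": group, "trait": trait, "n": len(x), "mean": mean,
                         "sd": sd, "range": r, "cv": cv})
    return pd.DataFrame(rows)


def transgression_counts(
    tt: TraitTable,
    parent_groups: tuple[str, str] = ("parent_NPB", "parent_911"),
    tet_groups: tuple[str, ...] = ("tet_NN99", "tet_99NN"),
) -> pd.DataFrame:
    """Per trait: tetraploids beyond both parental extremes.

    over  = individuals exceeding the maximum of both parental group maxima,
    under = individuals below the minimum of both minima; sign_p is the
    two-sided exact binomial test of (over, under) against 0.5.
    """
    parents = tt.df[tt.df["group"].isin(parent_groups)]
    tets = tt.df[tt.df["group"].isin(tet_groups)]
    for g in parent_groups:
        if (tt.df["group"] == g).sum() == 0:
            raise ValueError(f"empty parental group {g}")
    if len(tets) == 0:
        raise ValueError("empty tetraploid group")
    rows = []
    for trait in tt.trait_names:
        p = parents[trait].dropna()
        t = tets[trait].dropna()
        hi, lo = p.max(), p.min()
        n_over = int((t > hi).sum())
        n_under = int((t < lo).sum())
        n = n_over + n_under
        sign_p = float(stats.binomtest(n_over, n, 0.5).pvalue) if n > 0 else 1.0
        rows.append({"trait": trait, "n_over": n_over, "n_under": n_under, "sign_p": sign_p})
    return pd.DataFrame(rows)


def group_compare(tt: TraitTable, trait: str, group_a: str, group_b: str) -> tuple[float, float]:
    """Welch two-sided t-test of a trait between two groups -> (t, p).

    Degenerate case (zero variance in both groups, equal means) returns
    (0, 1).
    """
    a = tt.group(group_a)[trait].dropna().to_numpy(dtype=float)
    b = tt.group(group_b)[trait].dropna().to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
    res = stats.ttest_ind(a, b, equal_var=False)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(p):
        t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    return t, p


def variation_report(tt: TraitTable) -> dict:
    """Bundle of the module's outputs for the JSON report."""
    vm = variation_metrics(tt)
    tg = transgression_counts(tt)
    return {
        "variation": vm.to_dict(orient="records"),
        "transgression": tg.to_dict(orient="records"),
    }
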