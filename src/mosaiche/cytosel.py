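"""Cytonuclear biased-retention scanning.

In reciprocal crosses the two tetraploid populations differ only in their
maternal (organellar) parent, so chromosomal segments where at least one
copy of the maternal — or paternal — homoeolog is retained in nearly all
individuals mark cytonuclear selection.  Candidate bins combine a retention
fraction above a threshold (default 0.95) with a chi-square test of the
bin's five-state composition against the cross's genome-wide state
frequencies; merged segments are classified:

* Group I   — maternal homoeolog retained in both crosses (symmetric
  hetero-cytonuclear incompatibility),
* Group II  — paternal homoeolog retained in both crosses (symmetric
  hetero-cytonuclear superiority),
* Group III — paternal homoeolog retained in exactly one cross (asymmetric
  superiority).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MISSING, AnnotationTable, DosageMatrix, GenomeGrid, TraitTable

log = logging.getLogger("mosaiche.cytosel")

MATERNAL, PATERNAL = "maternal_retained", "paternal_retained"


@dataclass
class CytoSegment:
    chrom: str
    start: int
    end: int
    direction: str  # maternal_retained | paternal_retained
    crosses: tuple[str, ...]
    group: str  # I | II | III | unclassified
    retention: dict[str, float] = field(default_factory=dict)  # per cross
    min_p: float = 1.0


def _retention_masks(values: np.ndarray, cross: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell boolean arrays: has >= 1 maternal copy / >= 1 paternal copy.

    NPB is maternal in NN99 and paternal in 99NN; d counts NPB copies.
    """
    called = values != MISSING
    npb_ge1 = called & (values >= 1)
    ind_ge1 = called & (values <= 3)
    if cross == "NN99":
        return npb_ge1, ind_ge1
    return ind_ge1, npb_ge1


def _pooled_chisquare(obs: np.ndarray, exp: np.ndarray) -> float:
    """Pearson GOF p; zero-expectation categories are pooled into the next
    non-degenerate category with a warning."""
    if (exp == 0).any():
        warnings.warn("zero expected state frequency: pooling categories")
        keep_obs, keep_exp = [], []
        carry_o = carry_e = 0.0
        for o, e in zip(obs, exp):
            carry_o += o
            carry_e += e
            if carry_e > 0:
                keep_obs.append(carry_o)
                keep_exp.append(carry_e)
                carry_o = carry_e = 0.0
        if carry_o or carry_e:
            if keep_obs:
                keep_obs[-1] += carry_o
                keep_exp[-1] += carry_e
            else:
                return 1.0
        obs, exp = np.array(keep_obs), np.array(keep_exp)
        if len(obs) < 2:
            return 1.0
    exp = exp * obs.sum() / exp.sum()
    return float(stats.chisquare(obs, exp).pvalue)


def scan_retention(
    dm_by_cross: dict[str, DosageMatrix],
    grid: GenomeGrid,
    threshold: float = 0.95,
    alpha: float = 0.01,
    min_individuals: int = 20,
) -> pd.DataFrame:
    """Per-bin candidate scan for biased retention.

    A bin is a candidate in a cross and direction when the fraction of
    individuals with >= 1 copy of that parent's homoeolog exceeds
    ``threshold``, exceeds the cross's genome-wide baseline fraction for the
    same direction, and the bin's five-state counts deviate from the cross's
    genome-wide state frequencies (chi-square p < alpha).
    """
    if len(dm_by_cross) < 2:
        raise ValueError("both crosses are required")
    rows = []
    for cross, dm in dm_by_cross.items():
        n_ind = len(dm.individuals)
        if n_ind < min_individuals:
            raise ValueError(f"cross {cross}: need >= {min_individuals} individuals")
        values = dm.values
        called = values != MISSING
        n_called = called.sum(axis=0)
        mat, pat = _retention_masks(values, cross)
        with np.errstate(invalid="ignore"):
            frac_mat = np.where(n_called > 0, mat.sum(axis=0) / np.maximum(n_called, 1), np.nan)
            frac_pat = np.where(n_called > 0, pat.sum(axis=0) / np.maximum(n_called, 1), np.nan)
        state_counts = np.stack(
            [(called & (values == d)).sum(axis=0) for d in range(5)], axis=1
        )  # (n_bins, 5)
        baseline = state_counts.sum(axis=0).astype(float)
        baseline_freq = baseline / baseline.sum()
        base_mat = float(mat.sum() / called.sum())
        base_pat = float(pat.sum() / called.sum())
        for direction, frac, base in ((MATERNAL, frac_mat, base_mat), (PATERNAL, frac_pat, base_pat)):
            cand_bins = np.nonzero((frac > threshold) & (frac > base) & (n_called > 0))[0]
            for b in cand_bins:
                p = _pooled_chisquare(state_counts[b].astype(float), baseline_freq * n_called[b])
                if p < alpha:
                    rows.append(
                        {
                            "cross": cross,
                            "bin": int(b),
                            "direction": direction,
                            "fraction": float(frac[b]),
                            "p": p,
                        }
                    )
    df = pd.DataFrame(rows, columns=["cross", "bin", "direction", "fraction", "p"])
    log.info("scan_retention: %d candidate (cross, bin, direction) rows", len(df))
    return df


def merge_and_classify(
    candidates: pd.DataFrame,
    grid: GenomeGrid,
    crosses: tuple[str, str] = ("NN99", "99NN"),
    max_gap_bins: int = 1,
) -> list[CytoSegment]:
    """Merge adjacent candidate bins (gap <= ``max_gap_bins``) and classify.

    Classification is per bin first — Group I: maternal-retained in both
    crosses; Group II: paternal-retained in both; Group III: paternal-retained
    in exactly one; maternal-retained in one cross only is reported as
    unclassified — then runs of equal class are merged into segments, so a
    direction conflict splits the segment.
    """
    flags: dict[tuple[str, str], set[int]] = {
        (c, d): set() for c in crosses for d in (MATERNAL, PATERNAL)
    }
    info: dict[int, list] = {}
    for row in candidates.itertuples(index=False):
        flags[(row.cross, row.direction)].add(int(row.bin))
        info.setdefault(int(row.bin), []).append(row)
    classes: dict[int, tuple[str, str, tuple[str, ...]]] = {}
    for b in sorted(info):
        mat_in = tuple(c for c in crosses if b in flags[(c, MATERNAL)])
        pat_in = tuple(c for c in crosses if b in flags[(c, PATERNAL)])
        if len(mat_in) == 2:
            classes[b] = ("I", MATERNAL, mat_in)
        elif len(pat_in) == 2:
            classes[b] = ("II", PATERNAL, pat_in)
        elif len(pat_in) == 1:
            classes[b] = ("III", PATERNAL, pat_in)
        elif len(mat_in) == 1:
            classes[b] = ("unclassified", MATERNAL, mat_in)
    bins_table = grid.bin_table()
    segments: list[CytoSegment] = []
    run: list[int] = []

    def _flush(run: list[int]) -> None:
        if not run:
            return
        group, direction, seg_crosses = classes[run[0]]
        rows = [r for b in run for r in info[b] if r.direction == direction]
        retention = {
            c: float(np.mean([r.fraction for r in rows if r.cross == c]))
            for c in seg_crosses
        }
        first, last = bins_table.iloc[run[0]], bins_table.iloc[run[-1]]
        segments.append(
            CytoSegment(
                chrom=str(first["chrom"]),
                start=int(first["start"]),
                end=int(last["end"]),
                direction=direction,
                crosses=seg_crosses,
                group=group,
                retention=retention,
                min_p=float(min(r.p for r in rows)),
            )
        )

    chrom_of = bins_table["chrom"].to_numpy()
    for b in sorted(classes):
        if run and (
            b - run[-1] > max_gap_bins + 1
            or classes[b] != classes[run[-1]]
            or chrom_of[b] != chrom_of[run[-1]]
        ):
            _flush(run)
            run = []
        run.append(b)
    _flush(run)
    return segments


def annotation_enrichment(
    segments: list[CytoSegment], ann: AnnotationTable, by_group: bool = True
) -> pd.DataFrame:
    """Pearson chi-square (no continuity correction) of cytonuclear-flagged
    genes inside segments vs the rest of the genome, per group and overall."""
    if not segments:
        raise ValueError("no segments to test")
    df = ann.df
    flagged = (df["cytonuclear_flag"] != "none").to_numpy()

    def _in_any(segs: list[CytoSegment]) -> np.ndarray:
        inside = np.zeros(len(df), dtype=bool)
        for seg in segs:
            inside |= (
                (df["chrom"].to_numpy() == seg.chrom)
                & (df["start"].to_numpy() < seg.end)
                & (df["end"].to_numpy() > seg.start)
            )
        return inside

    scopes = [("all", segments)]
    if by_group:
        for g in ("I", "II", "III"):
            sub = [s for s in segments if s.group == g]
            if sub:
                scopes.append((g, sub))
    rows = []
    for label, segs in scopes:
        inside = _in_any(segs)
        table = np.array(
            [
                [int((flagged & inside).sum()), int((~flagged & inside).sum())],
                [int((flagged & ~inside).sum()), int((~flagged & ~inside).sum())],
            ]
        )
        if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
            chi2, p = np.nan, np.nan
        else:
            chi2, p = stats.chi2_contingency(table, correction=False)[:2]
        rows.append(
            {
                "group": label,
                "flagged_in": table[0, 0],
                "genes_in": int(inside.sum()),
                "flagged_out": table[1, 0],
                "genes_out": int((~inside).sum()),
                "chi2": float(chi2),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def fitness_contrast(
    segments: list[CytoSegment],
    dm_by_cross: dict[str, DosageMatrix],
    tt: TraitTable,
    fitness_traits: list[str],
) -> pd.DataFrame:
    """Welch t-test of fitness traits: retention-violating vs -conforming
    individuals per segment (violator = zero copies of the retained parent's
    homoeolog at some bin of the segment, in an affected cross).

    Classes with < 2 members report group means with p = NaN.
    """
    rows = []
    for si, seg in enumerate(segments):
        violators: list[str] = []
        conformers: list[str] = []
        for cross in seg.crosses:
            dm = dm_by_cross[cross]
            b0 = dm.grid.bin_index(seg.chrom, seg.start)
            b1 = dm.grid.bin_index(seg.chrom, seg.end - 1) + 1
            mat, pat = _retention_masks(dm.values[:, b0:b1], cross)
            keep = mat if seg.direction == MATERNAL else pat
            called = dm.values[:, b0:b1] != MISSING
            ok = (keep | ~called).all(axis=1)
            for i, indiv in enumerate(dm.individuals):
                (conformers if ok[i] else violators).append(indiv)
        for trait in fitness_traits:
            v = tt.df.loc[tt.df.index.intersection(violators), trait].dropna()
            c = tt.df.loc[tt.df.index.intersection(conformers), trait].dropna()
            mean_v = float(v.mean()) if len(v) else np.nan
            mean_c = float(c.mean()) if len(c) else np.nan
            if len(v) >= 2 and len(c) >= 2:
                res = stats.ttest_ind(v, c, equal_var=False)
                p = float(res.pvalue)
            else:
                p = np.nan
            rows.append(
                {
                    "segment": si,
                    "chrom": seg.chrom,
                    "start": seg.start,
                    "end": seg.end,
                    "group": seg.group,
                    "trait": trait,
                    "n_violators": len(v),
                    "n_conformers": len(c),
                    "mean_violators": mean_v,
                    "mean_conformers": mean_c,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)
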