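"""Shared domain types, file readers/writers and run plumbing.

Coordinate conventions
----------------------
Everything internal is 0-based, half-open.  VCF is the only 1-based surface
and positions are converted on read.  Genomic bins are fixed-width windows
(default 5 kb); the last bin of a chromosome may be short.  Interval outputs
use the BED dialect.

Homoeolog dosage ``d`` is the copy number of the Nipponbare (NPB) homoeolog
out of four total chromosomes, so the five euploid states 4:0, 3:1, 2:2,
1:3, 0:4 (NPB : 93-11) map to d = 4, 3, 2, 1, 0.  A missing call is encoded
by the :data:`MISSING` sentinel, never 0 (0 is the legal 0:4 state).
"""

from __future__ import annotations

import json
import logging
import platform
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("mosaiche")

#: sentinel for an uncallable dosage cell (no informative SNPs)
MISSING: int = -1

#: closed set of phenotype group labels
GROUPS = (
    "parent_NPB",
    "parent_911",
    "F1_N9",
    "F1_9N",
    "tet_NN99",
    "tet_99NN",
)

#: reciprocal cross directions (maternal parent listed first)
CROSSES = ("NN99", "99NN")

#: annotation flags for cytonuclear molecular-interaction genes
CYTO_FLAGS = ("none", "CCEC", "CEC")


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        stream=sys.stderr,
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration (empty file -> empty dict)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_manifest(out_dir: str | Path, config: dict, seed: int | None) -> Path:
    """Write a JSON run manifest capturing config, seed and versions."""
    import mosaiche

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "seed": seed,
        "versions": {
            "mosaiche": mosaiche.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


# ---------------------------------------------------------------------------
# Genome geometry
# ---------------------------------------------------------------------------


@dataclass
class GenomeGrid:
    """Chromosome lengths, centromere midpoints and the binning scheme.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    centromeres
        Centromere midpoint (bp) per chromosome name.
    bin_width
        Analysis resolution in bp (default 5000).
    region_bin_width
        Coarse window used only for regional annotation: pericentromeric =
        the three consecutive coarse windows harbouring the centromere,
        subtelomeric = the four consecutive coarse windows from the end of
        each chromosomal arm.
    """

    chromosomes: list[tuple[str, int]]
    centromeres: dict[str, int]
    bin_width: int = 5000
    region_bin_width: int = 500_000

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name}: length must be > 0")
            if self.bin_width > length:
                raise ValueError(
                    f"bin_width {self.bin_width} exceeds chromosome {name} length {length}"
                )
            cen = self.centromeres.get(name)
            if cen is None or not (0 <= cen < length):
                raise ValueError(f"chromosome {name}: centromere outside [0, length)")
        # global bin index bookkeeping
        self._n_bins = {
            name: -(-length // self.bin_width) for name, length in self.chromosomes
        }
        offsets = np.cumsum([0] + [self._n_bins[n] for n, _ in self.chromosomes])
        self._offset = {name: int(offsets[i]) for i, (name, _) in enumerate(self.chromosomes)}
        self.n_bins_total = int(offsets[-1])

    # -- bin arithmetic ----------------------------------------------------
    def n_bins(self, chrom: str) -> int:
        return self._n_bins[chrom]

    def chrom_slice(self, chrom: str) -> slice:
        off = self._offset[chrom]
        return slice(off, off + self._n_bins[chrom])

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index of a 0-based position."""
        return self._offset[chrom] + pos // self.bin_width

    def bin_table(self) -> pd.DataFrame:
        """One row per bin: chrom, start, end (0-based half-open)."""
        rows = []
        for name, length in self.chromosomes:
            starts = np.arange(0, length, self.bin_width)
            ends = np.minimum(starts + self.bin_width, length)
            rows.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    # -- regional classes --------------------------------------------------
    def region_classes(self) -> np.ndarray:
        """Per-bin regional class: 0 = other, 1 = pericentromeric, 2 = subtelomeric.

        Pericentromeric and subtelomeric windows are defined on the coarse
        ``region_bin_width`` grid; labels are broadcast down to analysis bins.
        Subtelomeric takes precedence on tiny chromosomes where windows would
        overlap is an error.
        """
        out = np.zeros(self.n_bins_total, dtype=np.int8)
        rb = self.region_bin_width
        for name, length in self.chromosomes:
            n_coarse = -(-length // rb)
            coarse = np.zeros(n_coarse, dtype=np.int8)
            cen_bin = self.centromeres[name] // rb
            peri = [b for b in (cen_bin - 1, cen_bin, cen_bin + 1) if 0 <= b < n_coarse]
            sub = list(range(min(4, n_coarse))) + list(range(max(0, n_coarse - 4), n_coarse))
            if set(peri) & set(sub):
                raise ValueError(
                    f"chromosome {name}: pericentromeric and subtelomeric windows overlap"
                )
            coarse[peri] = 1
            coarse[sub] = 2
            sl = self.chrom_slice(name)
            starts = np.arange(0, length, self.bin_width)
            out[sl] = coarse[starts // rb]
        return out

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "chrom": [c for c, _ in self.chromosomes],
                "length": [l for _, l in self.chromosomes],
                "centromere": [self.centromeres[c] for c, _ in self.chromosomes],
            }
        )
        with open(path, "w") as fh:
            fh.write(f"#bin_width={self.bin_width}\tregion_bin_width={self.region_bin_width}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeGrid":
        bin_width, region_bin_width = 5000, 500_000
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for item in first[1:].strip().split("\t"):
                    key, _, val = item.partition("=")
                    if key == "bin_width":
                        bin_width = int(val)
                    elif key == "region_bin_width":
                        region_bin_width = int(val)
                df = pd.read_csv(fh, sep="\t")
            else:
                df = pd.read_csv(path, sep="\t")
        return cls(
            chromosomes=list(zip(df["chrom"].astype(str), df["length"].astype(int))),
            centromeres=dict(zip(df["chrom"].astype(str), df["centromere"].astype(int))),
            bin_width=bin_width,
            region_bin_width=region_bin_width,
        )


# ---------------------------------------------------------------------------
# SNP panel
# ---------------------------------------------------------------------------


@dataclass
class SnpPanel:
    """Ordered parental-diagnostic biallelic SNPs.

    ``df`` columns: chrom, pos (0-based), npb_allele, ind_allele.  Sorted by
    (chromosome order of appearance, position); alleles differ at every row.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "npb_allele", "ind_allele"}
        if not required.issubset(self.df.columns):
            raise FormatError(f"SNP panel missing columns {required - set(self.df.columns)}")
        if len(self.df) == 0:
            raise FormatError("empty SNP panel: no diagnostic sites")
        if (self.df["npb_allele"] == self.df["ind_allele"]).any():
            raise FormatError("diagnostic SNP with identical parental alleles")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def bin_indices(self, grid: GenomeGrid) -> np.ndarray:
        """Global bin index of each SNP."""
        out = np.empty(len(self.df), dtype=np.int64)
        for chrom, sub in self.df.groupby("chrom", sort=False):
            off = grid.chrom_slice(str(chrom)).start
            out[sub.index] = off + sub["pos"].to_numpy() // grid.bin_width
        return out


def read_snp_panel(
    path: str | Path, parent_npb: str = "NPB", parent_ind: str = "93-11"
) -> SnpPanel:
    """Read a VCF and keep sites where the two parents are homozygous for
    different alleles (parental-diagnostic sites)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for parent in (parent_npb, parent_ind):
        if parent not in samples:
            raise FormatError(f"parental sample {parent!r} not in VCF ({samples})")
    i_npb, i_ind = samples.index(parent_npb), samples.index(parent_ind)
    rows = []
    n_seen = 0
    for var in vcf:
        n_seen += 1
        if len(var.ALT) != 1:
            continue
        gts = var.genotypes  # [[a0, a1, phased], ...]
        g_npb, g_ind = gts[i_npb], gts[i_ind]
        if -1 in g_npb[:2] or -1 in g_ind[:2]:
            continue
        if g_npb[0] != g_npb[1] or g_ind[0] != g_ind[1]:
            continue  # not homozygous
        if g_npb[0] == g_ind[0]:
            continue  # not diagnostic
        alleles = [var.REF] + var.ALT
        rows.append(
            (var.CHROM, var.POS - 1, alleles[g_npb[0]], alleles[g_ind[0]])
        )
    log.info("read_snp_panel: %d/%d sites diagnostic", len(rows), n_seen)
    if not rows:
        raise FormatError("no parental-diagnostic SNPs in VCF")
    df = pd.DataFrame(rows, columns=["chrom", "pos", "npb_allele", "ind_allele"])
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return SnpPanel(df)


def write_snp_panel_vcf(
    panel: SnpPanel,
    grid: GenomeGrid,
    path: str | Path,
    parent_npb: str = "NPB",
    parent_ind: str = "93-11",
) -> None:
    """Write a minimal VCF for a diagnostic panel, with the NPB allele as REF
    and the two parents as homozygous samples."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mosaiche\n")
        for chrom, length in grid.chromosomes:
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
            f"\t{parent_npb}\t{parent_ind}\n"
        )
        for row in panel.df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t.\t{row.npb_allele}\t{row.ind_allele}"
                "\t.\tPASS\t.\tGT\t0/0\t1/1\n"
            )


# ---------------------------------------------------------------------------
# Allele depths
# ---------------------------------------------------------------------------


@dataclass
class AlleleDepthMatrix:
    """Per-individual, per-SNP read counts supporting each parental allele.

    ``npb`` and ``ind`` are (n_individuals, n_snps) integer arrays aligned to
    the panel order.
    """

    individuals: list[str]
    npb: np.ndarray
    ind: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual IDs")
        if self.npb.shape != self.ind.shape or self.npb.shape[0] != len(self.individuals):
            raise ValueError("allele-depth array shape mismatch")
        if (self.npb < 0).any() or (self.ind < 0).any():
            raise ValueError("negative read counts")

    @property
    def total(self) -> np.ndarray:
        return self.npb + self.ind


def read_allele_depths(path: str | Path, panel: SnpPanel) -> AlleleDepthMatrix:
    """Read per-SNP parental allele depths from a VCF with AD fields or a TSV
    with columns (individual, chrom, pos, reads_npb, reads_ind; pos 1-based).

    Cells absent from the input are (0, 0).  SNPs not in the panel are
    skipped with a warning.
    """
    path = Path(path)
    if path.suffix.lower() in {".vcf", ".gz", ".bcf"}:
        return _read_allele_depths_vcf(path, panel)
    return _read_allele_depths_tsv(path, panel)


def _panel_lookup(panel: SnpPanel) -> dict[tuple[str, int], int]:
    return {
        (str(c), int(p)): i
        for i, (c, p) in enumerate(zip(panel.df["chrom"], panel.df["pos"]))
    }


def _read_allele_depths_vcf(path: Path, panel: SnpPanel) -> AlleleDepthMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    lookup = _panel_lookup(panel)
    npb = np.zeros((len(individuals), len(panel)), dtype=np.int32)
    ind = np.zeros_like(npb)
    npb_alleles = panel.df["npb_allele"].to_numpy()
    n_skipped = 0
    for var in vcf:
        key = (var.CHROM, var.POS - 1)
        j = lookup.get(key)
        if j is None:
            n_skipped += 1
            continue
        ad = var.format("AD")
        if ad is None:
            raise FormatError(f"AD field missing at {var.CHROM}:{var.POS}")
        ad = np.maximum(ad, 0)  # missing encoded negative by cyvcf2
        ref_is_npb = var.REF == npb_alleles[j]
        npb[:, j] = ad[:, 0] if ref_is_npb else ad[:, 1]
        ind[:, j] = ad[:, 1] if ref_is_npb else ad[:, 0]
    if n_skipped:
        warnings.warn(f"{n_skipped} VCF records not in panel were skipped")
    return AlleleDepthMatrix(individuals, npb, ind)


def _read_allele_depths_tsv(path: Path, panel: SnpPanel) -> AlleleDepthMatrix:
    df = pd.read_csv(path, sep="\t")
    required = {"individual", "chrom", "pos", "reads_npb", "reads_ind"}
    if not required.issubset(df.columns):
        raise FormatError(f"depth TSV missing columns {required - set(df.columns)}")
    lookup = _panel_lookup(panel)
    individuals = list(dict.fromkeys(df["individual"].astype(str)))
    idx = {s: i for i, s in enumerate(individuals)}
    npb = np.zeros((len(individuals), len(panel)), dtype=np.int32)
    ind = np.zeros_like(npb)
    n_skipped = 0
    for row in df.itertuples(index=False):
        j = lookup.get((str(row.chrom), int(row.pos) - 1))
        if j is None:
            n_skipped += 1
            continue
        i = idx[str(row.individual)]
        npb[i, j] = int(row.reads_npb)
        ind[i, j] = int(row.reads_ind)
    if n_skipped:
        warnings.warn(f"{n_skipped} depth rows not in panel were skipped")
    return AlleleDepthMatrix(individuals, npb, ind)


def write_allele_depths_tsv(
    adm: AlleleDepthMatrix, panel: SnpPanel, path: str | Path
) -> None:
    """Long-format TSV writer (1-based positions, round-trips with
    :func:`read_allele_depths`).  Zero-depth cells are omitted."""
    chroms = panel.df["chrom"].to_numpy()
    pos = panel.df["pos"].to_numpy() + 1
    with open(path, "w") as fh:
        fh.write("individual\tchrom\tpos\treads_npb\treads_ind\n")
        for i, indiv in enumerate(adm.individuals):
            nz = np.nonzero(adm.npb[i] + adm.ind[i])[0]
            for j in nz:
                fh.write(
                    f"{indiv}\t{chroms[j]}\t{pos[j]}\t{adm.npb[i, j]}\t{adm.ind[i, j]}\n"
                )


# ---------------------------------------------------------------------------
# Dosage matrix
# ---------------------------------------------------------------------------


@dataclass
class DosageMatrix:
    """Individuals x bins NPB homoeolog copy number, d in {0..4} or MISSING.

    ``values`` is (n_individuals, grid.n_bins_total) int8.  ``meta`` (optional)
    is indexed by individual with columns line, generation, cross.
    """

    values: np.ndarray
    individuals: list[str]
    grid: GenomeGrid
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.individuals), self.grid.n_bins_total):
            raise ValueError("dosage array shape does not match individuals x bins")
        bad = (self.values > 4) | ((self.values < 0) & (self.values != MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0..4} or MISSING")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual IDs")

    @property
    def called(self) -> np.ndarray:
        return self.values != MISSING

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.values[:, self.grid.chrom_slice(chrom)]

    def cross_of(self, individual: str) -> str | None:
        if self.meta is None or "cross" not in self.meta.columns:
            return None
        return str(self.meta.loc[individual, "cross"])


def write_dosage(dm: DosageMatrix, path: str | Path) -> None:
    """TSV with header (individual, chrom, bin_start, bin_end, dosage);
    0-based half-open bins; MISSING cells omitted.  Grid geometry is stored
    in comment lines so the file round-trips."""
    bins = dm.grid.bin_table()
    with open(path, "w") as fh:
        fh.write(f"#bin_width={dm.grid.bin_width}\tregion_bin_width={dm.grid.region_bin_width}\n")
        for chrom, length in dm.grid.chromosomes:
            fh.write(f"#chrom={chrom}\tlength={length}\tcentromere={dm.grid.centromeres[chrom]}\n")
        if dm.meta is not None:
            for indiv in dm.individuals:
                row = dm.meta.loc[indiv]
                fh.write(
                    f"#individual={indiv}\tline={row.get('line', '.')}"
                    f"\tgeneration={row.get('generation', '.')}\tcross={row.get('cross', '.')}\n"
                )
        fh.write("individual\tchrom\tbin_start\tbin_end\tdosage\n")
        chrom_arr = bins["chrom"].to_numpy()
        start_arr = bins["start"].to_numpy()
        end_arr = bins["end"].to_numpy()
        for i, indiv in enumerate(dm.individuals):
            called = np.nonzero(dm.values[i] != MISSING)[0]
            for b in called:
                fh.write(
                    f"{indiv}\t{chrom_arr[b]}\t{start_arr[b]}\t{end_arr[b]}\t{dm.values[i, b]}\n"
                )


def read_dosage(path: str | Path) -> DosageMatrix:
    chromosomes: list[tuple[str, int]] = []
    centromeres: dict[str, int] = {}
    meta_rows: dict[str, dict] = {}
    bin_width, region_bin_width = 5000, 500_000
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            fields = dict(item.partition("=")[::2] for item in line[1:].strip().split("\t"))
            if "bin_width" in fields:
                bin_width = int(fields["bin_width"])
                region_bin_width = int(fields.get("region_bin_width", region_bin_width))
            elif "chrom" in fields:
                chromosomes.append((fields["chrom"], int(fields["length"])))
                centromeres[fields["chrom"]] = int(fields["centromere"])
            elif "individual" in fields:
                meta_rows[fields["individual"]] = {
                    "line": fields.get("line", "."),
                    "generation": fields.get("generation", "."),
                    "cross": fields.get("cross", "."),
                }
    if not chromosomes:
        raise FormatError("dosage file lacks #chrom header lines")
    grid = GenomeGrid(chromosomes, centromeres, bin_width, region_bin_width)
    df = pd.read_csv(path, sep="\t", skiprows=header_lines)
    required = {"individual", "chrom", "bin_start", "bin_end", "dosage"}
    if not required.issubset(df.columns):
        raise FormatError(f"dosage TSV missing columns {required - set(df.columns)}")
    if ((df["dosage"] < 0) | (df["dosage"] > 4)).any():
        bad = df.index[(df["dosage"] < 0) | (df["dosage"] > 4)][0]
        raise FormatError(f"dosage out of range at data line {bad + 1}")
    individuals = list(meta_rows) if meta_rows else list(dict.fromkeys(df["individual"].astype(str)))
    idx = {s: i for i, s in enumerate(individuals)}
    values = np.full((len(individuals), grid.n_bins_total), MISSING, dtype=np.int8)
    for row in df.itertuples(index=False):
        try:
            b = grid.bin_index(str(row.chrom), int(row.bin_start))
        except KeyError as exc:
            raise FormatError(f"unknown chromosome {row.chrom}") from exc
        values[idx[str(row.individual)], b] = int(row.dosage)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index") if meta_rows else None
    return DosageMatrix(values, individuals, grid, meta)


# ---------------------------------------------------------------------------
# HE event table
# ---------------------------------------------------------------------------

HE_COLUMNS = ["individual", "chrom", "boundary", "left_state", "right_state", "flagged"]


def empty_he_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual": pd.Series(dtype=str),
            "chrom": pd.Series(dtype=str),
            "boundary": pd.Series(dtype=np.int64),
            "left_state": pd.Series(dtype=np.int8),
            "right_state": pd.Series(dtype=np.int8),
            "flagged": pd.Series(dtype=bool),
        }
    )


def write_he_bed(he: pd.DataFrame, path: str | Path, bin_width: int = 5000) -> None:
    """BED-like TSV of breakpoint uncertainty intervals.

    Columns: chrom, boundary - bin_width, boundary (0-based half-open),
    individual, left_state, right_state, flagged.  Boundaries within the
    first bin are clamped at 0 with a warning.
    """
    he = he.copy() if len(he) else empty_he_table()
    start = he["boundary"].to_numpy(dtype=np.int64, copy=True) - bin_width if len(he) else np.array([], dtype=np.int64)
    if len(he) and (start < 0).any():
        warnings.warn("breakpoint interval clamped at chromosome start")
        start = np.maximum(start, 0)
    out = pd.DataFrame(
        {
            "chrom": he["chrom"],
            "start": start,
            "end": he["boundary"],
            "individual": he["individual"],
            "left_state": he["left_state"],
            "right_state": he["right_state"],
            "flagged": he["flagged"].astype(int) if len(he) else he["flagged"],
        }
    )
    out = out.sort_values(["chrom", "start", "individual"], kind="stable")
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tindividual\tleft_state\tright_state\tflagged\n")
        out.to_csv(fh, sep="\t", index=False, header=False)


def read_he_bed(path: str | Path, bin_width: int = 5000) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        comment=None,
        skiprows=1,
        names=["chrom", "start", "end", "individual", "left_state", "right_state", "flagged"],
    )
    out = pd.DataFrame(
        {
            "individual": df["individual"].astype(str),
            "chrom": df["chrom"].astype(str),
            "boundary": df["end"].astype(np.int64),
            "left_state": df["left_state"].astype(np.int8),
            "right_state": df["right_state"].astype(np.int8),
            "flagged": df["flagged"].astype(bool),
        }
    )
    return out


# ---------------------------------------------------------------------------
# Trait table
# ---------------------------------------------------------------------------


@dataclass
class TraitTable:
    """Individuals x quantitative traits plus a closed-set group label.

    ``df`` is indexed by individual; trait columns are numeric (NaN =
    missing) and a ``group`` column holds one of :data:`GROUPS`.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if "group" not in self.df.columns:
            raise FormatError("trait table needs a 'group' column")
        bad = set(self.df["group"]) - set(GROUPS)
        if bad:
            raise FormatError(f"unknown group labels: {bad}")
        with np.errstate(invalid="ignore"):
            vals = self.df[self.trait_names].to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise FormatError("non-finite trait values")

    @property
    def trait_names(self) -> list[str]:
        return [c for c in self.df.columns if c != "group"]

    def group(self, label: str) -> pd.DataFrame:
        return self.df[self.df["group"] == label]

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index_label="individual")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TraitTable":
        return cls(pd.read_csv(path, sep="\t", index_col="individual"))


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------


@dataclass
class AnnotationTable:
    """Gene annotations: id, interval, cytonuclear flag, divergence flag.

    ``df`` columns: gene_id, chrom, start, end (0-based half-open),
    cytonuclear_flag in :data:`CYTO_FLAGS`, functional_divergence (bool),
    known_trait_link (free text, may be empty).
    """

    df: pd.DataFrame
    grid: GenomeGrid | None = None

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "start", "end", "cytonuclear_flag"}
        if not required.issubset(self.df.columns):
            raise FormatError(f"annotation missing columns {required - set(self.df.columns)}")
        bad = set(self.df["cytonuclear_flag"]) - set(CYTO_FLAGS)
        if bad:
            raise FormatError(f"unknown cytonuclear flags: {bad}")
        if (self.df["end"] <= self.df["start"]).any():
            raise FormatError("gene interval with end <= start")
        if self.grid is not None:
            lengths = self.grid.chrom_lengths()
            for row in self.df.itertuples(index=False):
                if row.end > lengths.get(str(row.chrom), -1):
                    raise FormatError(f"gene {row.gene_id} outside chromosome bounds")
        self.df = self.df.reset_index(drop=True)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, grid: GenomeGrid | None = None) -> "AnnotationTable":
        return cls(pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[]), grid)


# ---------------------------------------------------------------------------
# Homoeolog expression counts
# ---------------------------------------------------------------------------


@dataclass
class ExpressionCounts:
    """Homoeolog-resolved transcript counts.

    ``df`` columns: gene_id, individual, tissue, reads_npb, reads_ind, plus a
    gene -> bin mapping in ``gene_bins`` (gene_id -> global bin index).
    """

    df: pd.DataFrame
    gene_bins: dict[str, int]

    def __post_init__(self) -> None:
        required = {"gene_id", "individual", "tissue", "reads_npb", "reads_ind"}
        if not required.issubset(self.df.columns):
            raise FormatError(f"expression missing columns {required - set(self.df.columns)}")
        if (self.df[["reads_npb", "reads_ind"]] < 0).to_numpy().any():
            raise FormatError("negative transcript counts")

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out["bin"] = out["gene_id"].map(self.gene_bins)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionCounts":
        df = pd.read_csv(path, sep="\t")
        gene_bins = dict(
            df.drop_duplicates("gene_id")[["gene_id", "bin"]].itertuples(index=False)
        )
        return cls(df.drop(columns=["bin"]), {k: int(v) for k, v in gene_bins.items()})
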