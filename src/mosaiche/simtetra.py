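"""Forward simulator of selfing segmental-allotetraploid pedigrees.

The simulated system mirrors a nascent allotetraploid rice population: an S0
tetraploid fixed heterozygote (two Nipponbare-derived homologs in subgenome A,
two 93-11-derived homologs in subgenome B at every locus) is selfed for ``g``
generations in two reciprocal cross directions (NN99: NPB maternal, 99NN:
93-11 maternal).  Meiosis per chromosome quartet uses homologous bivalent
pairing within each subgenome with one obligate crossover per bivalent at a
uniform position, plus Poisson-distributed homoeologous exchanges (HEs) —
reciprocal crossovers between one chromatid of each subgenome at positions
drawn from a regional weight profile.  Each gamete carries one chromatid per
subgenome; cytonuclear viability selection acts at gamete union by rejection
sampling.

Haplotypes are tracked at bin resolution (ancestry label per 5-kb bin);
breakpoints snap to bin boundaries, which is sufficient because all
downstream inference is at bin scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    MISSING,
    AlleleDepthMatrix,
    AnnotationTable,
    DosageMatrix,
    ExpressionCounts,
    GenomeGrid,
    SnpPanel,
    TraitTable,
)

log = logging.getLogger("mosaiche.simtetra")

NPB, IND = 0, 1  # ancestry labels


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


@dataclass
class PedigreeSpec:
    """Reciprocal selfing pedigree: single-seed descent to generation g-1,
    then ``individuals_per_line`` sampled offspring per line at generation g."""

    generations: int = 4
    individuals_per_line: int = 6
    lines_per_cross: int = 18
    cross_directions: tuple[str, ...] = ("NN99", "99NN")

    def __post_init__(self) -> None:
        if self.generations < 1 or self.individuals_per_line < 1 or self.lines_per_cross < 1:
            raise ValueError("pedigree sizes must be >= 1")


@dataclass
class HEModel:
    """Homoeologous-exchange model.

    ``rate_per_pair`` is the expected number of transmitted HE breakpoints
    per chromosome *pair* per meiosis.  Mechanistically each exchange is a
    homoeologous pairing region that resolves as a reciprocal interstitial
    tract swap (a double crossover) between the transmitted chromatid of one
    subgenome and a homolog of the other, contributing two breakpoints — or
    one when the tract runs off the chromosome end.  A quartet comprises two
    pairs, so each quartet draws Poisson(rate_per_pair) tract events per
    meiosis (2 breakpoints each, expectation 2 * rate_per_pair breakpoints).
    Tract lengths are exponential with mean ``tract_mean_bp`` (default 1 Mb,
    the scale of observed HE segments).  The positional weight profile for
    tract starts is depleted in pericentromeric windows and elevated in
    subtelomeric windows by default, matching the regional trend of
    homologous recombination.  ``reciprocal=False`` makes exchanges
    conversion-like (the partner keeps its material).
    """

    rate_per_pair: float = 0.75
    tract_mean_bp: float = 1_000_000.0
    pericentromeric_weight: float = 0.3
    subtelomeric_weight: float = 2.0
    other_weight: float = 1.0
    reciprocal: bool = True

    def __post_init__(self) -> None:
        if self.rate_per_pair < 0:
            raise ValueError("HE rate must be >= 0")
        if self.tract_mean_bp <= 0:
            raise ValueError("tract_mean_bp must be > 0")
        if min(self.pericentromeric_weight, self.subtelomeric_weight, self.other_weight) < 0:
            raise ValueError("weights must be >= 0")

    def boundary_weights(self, grid: GenomeGrid, chrom: str) -> np.ndarray:
        """Normalized sampling weights over the interior bin boundaries
        1..n_bins-1 of a chromosome (boundary b sits before bin b)."""
        classes = grid.region_classes()[grid.chrom_slice(chrom)]
        w = np.choose(
            classes, [self.other_weight, self.pericentromeric_weight, self.subtelomeric_weight]
        ).astype(float)
        wb = w[1:]  # weight of the bin to the right of each interior boundary
        total = wb.sum()
        if total <= 0:
            raise ValueError(f"HE weight profile not normalizable on {chrom}")
        return wb / total

    def tract_event_mean(self, grid: GenomeGrid, chrom: str, weights: np.ndarray) -> float:
        """Poisson mean of tract events per quartet per meiosis on a chromosome.

        ``rate_per_pair`` is a breakpoint rate; a tract yields two breakpoints
        unless it runs off the chromosome end (then one), so the event rate is
        normalized by the expected breakpoints per tract J = 2 - P(truncate)
        to make the transmitted breakpoint rate exact by construction.
        """
        n = grid.n_bins(chrom)
        if n <= 1:
            return 2.0 * self.rate_per_pair / 2.0
        starts = np.arange(1, n)
        dist = n - starts  # bins to the chromosome end
        bw = grid.bin_width
        p_trunc = np.where(dist <= 1, 1.0, np.exp(-((dist - 0.5) * bw) / self.tract_mean_bp))
        j_per_tract = 2.0 - float((weights * p_trunc).sum())
        return 2.0 * self.rate_per_pair / j_per_tract


@dataclass
class SelectedSegment:
    chrom: str
    start: int
    end: int
    mode: str  # require_maternal | require_paternal
    crosses: tuple[str, ...] = ("NN99", "99NN")
    s: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("require_maternal", "require_paternal"):
            raise ValueError(f"unknown selection mode {self.mode}")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("selection coefficient must be in [0, 1]")


@dataclass
class SelectionSpec:
    segments: list[SelectedSegment] = field(default_factory=list)


@dataclass
class Qtl:
    bin: int  # global bin index
    a: float = 0.0  # additive effect (homozygote contrast = +/- a)
    k: float = 0.0  # dominance effect on the any-heterozygote indicator


@dataclass
class EpistaticPair:
    bin_i: int
    bin_j: int
    aa: float = 0.0
    ad: float = 0.0
    da: float = 0.0
    dd: float = 0.0


@dataclass
class TraitModel:
    qtls: list[Qtl] = field(default_factory=list)
    pairs: list[EpistaticPair] = field(default_factory=list)
    mu: float = 0.0
    sigma: float = 1.0


@dataclass
class GeneticArchitecture:
    """Simulator truth for the quantitative traits (F-infinity parameterization:
    per QTL an additive effect a on w = (d-2)/2 and a dominance effect k on the
    any-heterozygote indicator v; per pair the four interaction effects)."""

    traits: dict[str, TraitModel]


@dataclass
class TruthSet:
    """Simulation ground truth.

    haplotypes: (n_individuals, 4, n_bins) ancestry labels (0 = NPB, 1 = 93-11);
    slots 0-1 are subgenome A, slots 2-3 subgenome B.
    he_events: one row per HE drawn in any meiosis of each individual's
    pedigree (events on the shared descent chain are repeated per individual).
    """

    haplotypes: np.ndarray
    individuals: list[str]
    grid: GenomeGrid
    meta: pd.DataFrame
    he_events: pd.DataFrame

    def dosage(self) -> DosageMatrix:
        d = 4 - self.haplotypes.sum(axis=1, dtype=np.int8)
        return DosageMatrix(d.astype(np.int8), list(self.individuals), self.grid, self.meta)

    def breakpoints(self) -> pd.DataFrame:
        """Dosage-state junctions of the truth genomes (what a perfect caller
        would report), via the breakpoint caller on the truth dosage."""
        from .hecall import call_breakpoints

        return call_breakpoints(self.dosage())


# ---------------------------------------------------------------------------
# Panel and grid construction
# ---------------------------------------------------------------------------


def make_panel_and_grid(
    n_chrom: int = 12,
    chrom_length: int = 30_000_000,
    snp_density: float = 1 / 500,
    bin_width: int = 5000,
    seed: int | np.random.Generator = 0,
    centromere_frac: float = 0.4,
    region_bin_width: int | None = None,
) -> tuple[SnpPanel, GenomeGrid]:
    """Uniform diagnostic-SNP panel over an equal-length chromosome set.

    SNP counts per chromosome are Poisson(length * density) with uniform
    positions, so a bin of width w carries on average w * density SNPs.
    The regional-annotation window defaults to 500 kb, scaled down on short
    test chromosomes so the pericentromeric and subtelomeric windows fit.
    """
    if snp_density <= 0:
        raise ValueError("snp_density must be > 0")
    if bin_width > chrom_length:
        raise ValueError("bin_width exceeds chromosome length")
    if region_bin_width is None:
        region_bin_width = max(bin_width, min(500_000, chrom_length // 16))
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1:02d}" for i in range(n_chrom)]
    grid = GenomeGrid(
        chromosomes=[(n, chrom_length) for n in names],
        centromeres={n: int(chrom_length * centromere_frac) for n in names},
        bin_width=bin_width,
        region_bin_width=region_bin_width,
    )
    bases = np.array(list("ACGT"))
    rows = []
    for name in names:
        n_snp = rng.poisson(chrom_length * snp_density)
        pos = np.unique(rng.integers(0, chrom_length, size=n_snp))
        ref = rng.integers(0, 4, size=len(pos))
        alt = (ref + rng.integers(1, 4, size=len(pos))) % 4
        rows.append(
            pd.DataFrame(
                {"chrom": name, "pos": pos, "npb_allele": bases[ref], "ind_allele": bases[alt]}
            )
        )
    panel = SnpPanel(pd.concat(rows, ignore_index=True))
    log.info("make_panel_and_grid: %d SNPs over %d chromosomes", len(panel), n_chrom)
    return panel, grid


# ---------------------------------------------------------------------------
# Meiosis and pedigree
# ---------------------------------------------------------------------------


def _gamete(
    hap: np.ndarray,
    grid: GenomeGrid,
    he: HEModel,
    boundary_weights: dict[str, np.ndarray],
    event_means: dict[str, float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[str, int, bool]]]:
    """One meiosis -> one gamete (2, n_bins) plus HE events [(chrom, boundary_bin, effective)].

    ``hap`` is the parent's (4, n_bins) ancestry array; slots (0, 1) = subgenome
    A homologs, (2, 3) = subgenome B homologs.
    """
    gam = np.empty((2, grid.n_bins_total), dtype=np.int8)
    events: list[tuple[str, int, bool]] = []
    for chrom, _ in grid.chromosomes:
        sl = grid.chrom_slice(chrom)
        n = sl.stop - sl.start
        # obligate homologous crossover per bivalent: the transmitted chromatid
        # is a single-crossover recombinant of the two homologs
        for sub, (h0, h1) in enumerate(((0, 1), (2, 3))):
            start = int(rng.integers(2))
            u = int(rng.integers(1, n)) if n > 1 else 1
            chromatid = np.empty(n, dtype=np.int8)
            chromatid[:u] = hap[(h0, h1)[start], sl][:u]
            chromatid[u:] = hap[(h0, h1)[1 - start], sl][u:]
            gam[sub, sl] = chromatid
        # homoeologous exchanges: Poisson tract events per quartet (mean
        # normalized so the breakpoint rate per pair equals rate_per_pair),
        # each a reciprocal interstitial swap between the transmitted
        # chromatid of one subgenome and a designated pairing partner (a
        # random non-transmitted homolog of the other subgenome, persistent
        # for the whole meiosis so overlapping tracts stay consistent).
        n_he = rng.poisson(event_means[chrom])
        if n_he == 0:
            continue
        w = boundary_weights[chrom]
        starts = rng.choice(np.arange(1, n), size=n_he, p=w) if n > 1 else np.ones(n_he, int)
        partners = [
            hap[(2, 3)[int(rng.integers(2))], sl].copy(),  # partner of the A chromatid
            hap[(0, 1)[int(rng.integers(2))], sl].copy(),  # partner of the B chromatid
        ]
        bw = grid.bin_width
        for pos in starts:
            side = int(rng.integers(2))  # 0: subgenome-A chromatid is the recipient
            recipient = gam[side, sl]
            partner = partners[side]
            length = max(1, int(round(rng.exponential(he.tract_mean_bp) / bw)))
            end = min(int(pos) + length, n)
            eff_start = bool(recipient[pos - 1] != partner[pos])
            eff_end = bool(partner[end - 1] != recipient[end]) if end < n else False
            distal = recipient[pos:end].copy()
            recipient[pos:end] = partner[pos:end]
            if he.reciprocal:
                partner[pos:end] = distal
            events.append((chrom, int(pos), eff_start))
            if end < n:
                events.append((chrom, int(end), eff_end))
    return gam, events


def _maternal_label(cross: str) -> int:
    return NPB if cross == "NN99" else IND


def _passes_selection(
    hap: np.ndarray, grid: GenomeGrid, sel: SelectionSpec, cross: str, rng: np.random.Generator
) -> bool:
    for seg in sel.segments:
        if cross not in seg.crosses:
            continue
        mat = _maternal_label(cross)
        target = mat if seg.mode == "require_maternal" else 1 - mat
        b0 = grid.bin_index(seg.chrom, seg.start)
        b1 = grid.bin_index(seg.chrom, seg.end - 1) + 1
        copies = (hap[:, b0:b1] == target).sum(axis=0)
        if (copies == 0).any() and rng.random() < seg.s:
            return False
    return True


def _self(
    parent: np.ndarray,
    grid: GenomeGrid,
    he: HEModel,
    sel: SelectionSpec,
    cross: str,
    weights: dict[str, np.ndarray],
    event_means: dict[str, float],
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> tuple[np.ndarray, list[tuple[str, int, bool]]]:
    """One selfing: union of two independent meioses, with viability
    rejection sampling against the selection spec."""
    for _ in range(max_tries):
        g1, e1 = _gamete(parent, grid, he, weights, event_means, rng)
        g2, e2 = _gamete(parent, grid, he, weights, event_means, rng)
        child = np.stack([g1[0], g2[0], g1[1], g2[1]])  # A slots then B slots
        if _passes_selection(child, grid, sel, cross, rng):
            return child, e1 + e2
    seg = sel.segments[0] if sel.segments else None
    raise RuntimeError(
        f"selection rejection cap exceeded; unsatisfiable segment {seg}"
    )


def simulate_population(
    grid: GenomeGrid,
    pedigree: PedigreeSpec | None = None,
    he: HEModel | None = None,
    sel: SelectionSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> TruthSet:
    """Simulate the reciprocal selfing pedigree and return the truth set.

    Each line is a single-seed-descent chain from the cross's S0 individual
    through generation g-1, fanned out into ``individuals_per_line`` sampled
    S_g offspring.  HE events are recorded per meiosis with an ``effective``
    flag (the exchange changed the gamete's ancestry at the junction).
    """
    pedigree = pedigree or PedigreeSpec()
    he = he or HEModel()
    sel = sel or SelectionSpec()
    rng = np.random.default_rng(seed)
    weights = {c: he.boundary_weights(grid, c) for c, _ in grid.chromosomes}
    event_means = {c: he.tract_event_mean(grid, c, weights[c]) for c, _ in grid.chromosomes}
    g = pedigree.generations
    haps, ids, meta_rows, ev_rows = [], [], [], []
    for cross in pedigree.cross_directions:
        s0 = np.zeros((4, grid.n_bins_total), dtype=np.int8)
        s0[2:] = IND  # subgenome B carries the 93-11 homologs
        for line_i in range(pedigree.lines_per_cross):
            line = f"{cross}_L{line_i + 1:02d}"
            parent, chain_events = s0, []
            for gen in range(1, g):
                parent, ev = _self(parent, grid, he, sel, cross, weights, event_means, rng)
                chain_events.extend((gen, *e) for e in ev)
            for k in range(pedigree.individuals_per_line):
                child, ev = _self(parent, grid, he, sel, cross, weights, event_means, rng)
                indiv = f"{line}_{k + 1:02d}"
                haps.append(child)
                ids.append(indiv)
                meta_rows.append({"line": line, "generation": f"S{g}", "cross": cross})
                for gen, chrom, pos, eff in chain_events + [(g, *e) for e in ev]:
                    ev_rows.append(
                        {
                            "individual": indiv,
                            "line": line,
                            "cross": cross,
                            "generation": gen,
                            "chrom": chrom,
                            "boundary": pos * grid.bin_width,
                            "effective": eff,
                        }
                    )
    meta = pd.DataFrame(meta_rows, index=ids)
    events = pd.DataFrame(
        ev_rows,
        columns=["individual", "line", "cross", "generation", "chrom", "boundary", "effective"],
    )
    log.info(
        "simulate_population: %d individuals, %.1f HE draws/individual",
        len(ids),
        len(events) / max(len(ids), 1),
    )
    return TruthSet(np.stack(haps), ids, grid, meta, events)


# ---------------------------------------------------------------------------
# Observation models
# ---------------------------------------------------------------------------


def dosage_allele_fraction(d: np.ndarray | int, e: float) -> np.ndarray | float:
    """Expected NPB read fraction f_d = (d/4) * (1 - 2e) + e at dosage d with
    symmetric per-read error rate e."""
    return (np.asarray(d) / 4.0) * (1.0 - 2.0 * e) + e


def sample_allele_depths(
    truth: TruthSet,
    panel: SnpPanel,
    coverage: float = 10.0,
    error_rate: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> AlleleDepthMatrix:
    """Sequencing-depth sampling: per SNP, total reads ~ Poisson(coverage) and
    NPB-supporting reads ~ Binomial(total, f_d) for the bin's true dosage."""
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    snp_bins = panel.bin_indices(truth.grid)
    dosage = truth.dosage().values
    f_table = dosage_allele_fraction(np.arange(5), error_rate)
    n_ind, n_snp = len(truth.individuals), len(panel)
    npb = np.empty((n_ind, n_snp), dtype=np.int32)
    ind = np.empty_like(npb)
    for i in range(n_ind):  # chunked per individual to bound memory
        total = rng.poisson(coverage, size=n_snp)
        f = f_table[dosage[i, snp_bins]]
        k = rng.binomial(total, f)
        npb[i] = k
        ind[i] = total - k
    return AlleleDepthMatrix(list(truth.individuals), npb, ind)


def sample_expression(
    truth: TruthSet,
    genes: AnnotationTable,
    total_reads: int = 400,
    coupled: dict[str, bool] | None = None,
    overdispersion: float = 0.0,
    tissue: str = "leaf",
    seed: int | np.random.Generator = 0,
) -> ExpressionCounts:
    """Homoeolog transcript counts per gene x individual.

    Dosage-coupled genes express the NPB homoeolog in proportion to its copy
    number (Binomial(total, d/4); beta-binomial when overdispersion > 0);
    uncoupled genes keep a fixed 1:1 ratio regardless of dosage.
    """
    rng = np.random.default_rng(seed)
    dosage = truth.dosage().values
    coupled = coupled or {}
    rows, gene_bins = [], {}
    n_skipped = 0
    for grow in genes.df.itertuples(index=False):
        gene = str(grow.gene_id)
        mid = (int(grow.start) + int(grow.end)) // 2
        try:
            b = truth.grid.bin_index(str(grow.chrom), mid)
        except KeyError:
            n_skipped += 1
            continue
        gene_bins[gene] = b
        is_coupled = coupled.get(gene, True)
        for i, indiv in enumerate(truth.individuals):
            d = dosage[i, b]
            if d == MISSING:
                n_skipped += 1
                continue
            p = d / 4.0 if is_coupled else 0.5
            if overdispersion > 0 and 0.0 < p < 1.0:
                conc = 1.0 / overdispersion
                p = rng.beta(p * conc, (1 - p) * conc)
            k = rng.binomial(total_reads, p)
            rows.append((gene, indiv, tissue, int(k), int(total_reads - k)))
    if n_skipped:
        log.warning("sample_expression: %d gene x individual cells skipped", n_skipped)
    df = pd.DataFrame(rows, columns=["gene_id", "individual", "tissue", "reads_npb", "reads_ind"])
    return ExpressionCounts(df, gene_bins)


# ---------------------------------------------------------------------------
# Phenotypes (F-infinity genetic model)
# ---------------------------------------------------------------------------


def _codes(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """F-infinity design codes: w = (d-2)/2 in {-1,-1/2,0,1/2,1} and the
    any-heterozygote indicator v = [d in {1,2,3}]."""
    w = (d - 2.0) / 2.0
    v = ((d >= 1) & (d <= 3)).astype(float)
    return w, v


def genetic_values(dosage: np.ndarray, model: TraitModel) -> np.ndarray:
    """Noise-free trait values for an (n_individuals, n_bins) dosage array."""
    y = np.full(dosage.shape[0], model.mu, dtype=float)
    for q in model.qtls:
        w, v = _codes(dosage[:, q.bin].astype(float))
        y += q.a * w + q.k * v
    for p in model.pairs:
        wi, vi = _codes(dosage[:, p.bin_i].astype(float))
        wj, vj = _codes(dosage[:, p.bin_j].astype(float))
        y += p.aa * wi * wj + p.ad * wi * vj + p.da * vi * wj + p.dd * vi * vj
    return y


def sample_phenotypes(
    truth: TruthSet,
    arch: GeneticArchitecture,
    seed: int | np.random.Generator = 0,
) -> TraitTable:
    """Trait table for the tetraploid individuals under the F-infinity model
    y = mu + sum(a*w + k*v) + sum(aa*wi*wj + ad*wi*vj + da*vi*wj + dd*vi*vj) + N(0, sigma^2)."""
    rng = np.random.default_rng(seed)
    dosage = truth.dosage().values.astype(float)
    data = {}
    for trait, model in arch.traits.items():
        y = genetic_values(dosage, model)
        if model.sigma > 0:
            y = y + rng.normal(0.0, model.sigma, size=len(y))
        data[trait] = y
    df = pd.DataFrame(data, index=truth.individuals)
    df["group"] = ["tet_" + c for c in truth.meta["cross"]]
    return TraitTable(df)


def reference_phenotypes(
    arch: GeneticArchitecture,
    grid: GenomeGrid,
    n_per_group: int = 12,
    seed: int | np.random.Generator = 0,
) -> TraitTable:
    """Phenotypes of the fixed reference genotypes: the diploid-parent proxies
    (uniform d = 4 for NPB, d = 0 for 93-11) and F1 hybrids (uniform d = 2),
    with the same residual noise model as the tetraploids."""
    rng = np.random.default_rng(seed)
    profiles = {
        "parent_NPB": 4,
        "parent_911": 0,
        "F1_N9": 2,
        "F1_9N": 2,
    }
    frames = []
    for group, d in profiles.items():
        dosage = np.full((n_per_group, grid.n_bins_total), d, dtype=float)
        data = {}
        for trait, model in arch.traits.items():
            y = genetic_values(dosage, model)
            if model.sigma > 0:
                y = y + rng.normal(0.0, model.sigma, size=n_per_group)
            data[trait] = y
        df = pd.DataFrame(data, index=[f"{group}_{i + 1:02d}" for i in range(n_per_group)])
        df["group"] = group
        frames.append(df)
    return TraitTable(pd.concat(frames))


def default_architecture(
    grid: GenomeGrid,
    n_traits: int = 21,
    seed: int | np.random.Generator = 0,
    sigma: float = 1.0,
) -> GeneticArchitecture:
    """Random 21-trait architecture with additive, dominant and epistatic
    control: per trait 2-4 QTLs (additive effects ~ +/-1, one in three QTLs
    also dominant) and one epistatic pair for every other trait."""
    rng = np.random.default_rng(seed)
    traits = {}
    for t in range(n_traits):
        n_qtl = int(rng.integers(2, 5))
        bins = rng.choice(grid.n_bins_total, size=n_qtl + 2, replace=False)
        qtls = []
        for b in bins[:n_qtl]:
            a = float(rng.normal(0, 1.0))
            k = float(rng.normal(0, 0.8)) if rng.random() < 1 / 3 else 0.0
            qtls.append(Qtl(int(b), a, k))
        pairs = []
        if t % 2 == 0:
            kind = ["aa", "ad", "da", "dd"][t // 2 % 4]
            eff = float(rng.normal(0, 1.2))
            pairs.append(EpistaticPair(int(bins[-2]), int(bins[-1]), **{kind: eff}))
        traits[f"trait{t + 1:02d}"] = TraitModel(qtls, pairs, mu=10.0, sigma=sigma)
    return GeneticArchitecture(traits)
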