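# Methods

This note documents the models implemented in `mosaiche`, the reasoning
behind the open design choices, the parameter defaults, and what the
synthetic test bed does and does not establish about real data.

## Population and meiosis model (`simtetra`)

The founder (S0) is a chromosome-doubled inter-subspecific hybrid: at every
locus, subgenome A carries two Nipponbare (NPB) homologs and subgenome B two
93-11 homologs (dosage d = 2 everywhere, where d counts NPB copies of 4).
Two reciprocal founders differ only in cross direction (NN99: NPB maternal;
99NN: 93-11 maternal), hence in cytoplasm. Each line descends by
single-seed selfing to generation g−1 and fans out into the sampled S_g
sibs (defaults: g = 4, 18 lines and 6 sibs per cross — roughly the 202
euploid individuals of the study design this emulates).

Meiosis is modelled per chromosome quartet (two homologous pairs), at bin
resolution (5 kb):

* **Homologous recombination.** Each subgenome forms a bivalent with one
  obligate crossover at a uniform position; the transmitted chromatid is a
  single-crossover recombinant of the two homologs. This is the minimal
  model that produces 1:2:1 segregation at a locus made heterozygous by a
  prior HE. Homologous crossovers only matter where a subgenome is
  internally heterozygous in ancestry.
* **Homoeologous exchange.** Each quartet draws a Poisson number of
  exchange events. An event is a *reciprocal interstitial tract swap*
  between the transmitted chromatid of one subgenome and a designated
  pairing partner (a random non-transmitted homolog of the other subgenome,
  persistent for the whole meiosis so that overlapping events stay
  consistent). Tract lengths are exponential (default mean 1 Mb, the scale
  of the segmental blocks such populations display); a tract that runs off
  the chromosome end degenerates into a single terminal crossover. An event
  therefore contributes two breakpoints (one if terminal). We model tracts
  rather than lone arm-length crossovers because arm-scale swaps scramble
  the genome so fast that breakpoint accumulation saturates within two or
  three selfing generations, which is incompatible with the near-linear,
  "ratchet-like" accumulation these populations show; locally resolved
  exchanges keep accumulation linear through S4 while producing the same
  five-state mosaic.
* **Rate convention.** `HEModel.rate_per_pair` (default 0.75) is the
  expected number of *transmitted breakpoints per chromosome pair per
  meiosis*. The per-chromosome Poisson event mean is normalized by the
  expected breakpoints per tract (2 − P(truncation), computed from the
  position-weight profile and the tract-length distribution) so the
  breakpoint rate is exact by construction: with 12 quartets (24 pairs) the
  genome-wide expectation is 24 × 0.75 = 18 transmitted breakpoints per
  meiosis, and the cumulative expectation at generation g is 2·g·24·λ
  (two meioses per selfing).
* **Positional profile.** Tract starts are weighted 0.3 in pericentromeric
  windows (three 500-kb windows harbouring the centromere), 2.0 in
  subtelomeric windows (four 500-kb windows from each chromosome end), 1.0
  elsewhere — the regional trend of plant recombination. On short test
  chromosomes the regional window is scaled down (length/16) so both window
  classes fit.
* **Cytonuclear selection.** Viability selection is rejection sampling at
  gamete union: an offspring lacking every copy of the required parental
  homoeolog anywhere in a selected segment is rejected with probability s
  and redrawn (cap 1000 draws). `require_maternal` resolves per cross
  direction (NPB is maternal in NN99, 93-11 in 99NN).

**Breakpoint survival under selfing.** The truth table records every drawn
breakpoint per meiosis (`he_events`, the cumulative HE count). Not all of
them remain visible in an S4 dosage profile: a tract present on one
chromatid is a segregating polymorphism that selfing drift fixes either way,
and fixation of the unexchanged state erases the junctions. A breakpoint
drawn at generation t survives to generation g with probability
1 − (1 − 2^−(g−t))/2, i.e. on average ≈73% of cumulative breakpoints are
visible at S4 (further small losses: events landing on already-converted
ground). The per-meiosis rate estimator (`he_rate` = cumulative count /
2g) therefore recovers the generative rate when applied to the cumulative
event record, while the count of junctions *called from sequence data* sits
≈25–30% lower — an intrinsic property of selfing, not a caller defect. The
caller is validated separately: called junctions match the surviving truth
junctions (ratio ≈ 0.99 at 10× coverage).

## Observation models

* **Allele depths.** Per SNP, total reads ~ Poisson(coverage) and NPB-
  supporting reads ~ Binomial(total, f_d), f_d = (d/4)(1−2e) + e, default
  coverage 10×, e = 0.01. SNP panels are uniform with density 1/500 bp
  (≈10 SNPs per 5-kb bin).
* **Expression.** Dosage-coupled genes: NPB transcript count ~
  Binomial(total, d/4) (beta-binomial when overdispersion > 0); uncoupled
  genes stay at 1:1 regardless of dosage. Default depth 400 homoeolog-
  assigned reads per gene.
* **Traits.** F∞ model: y = μ + Σ a·w + k·v + Σ aa·w_iw_j + ad·w_iv_j +
  da·v_iw_j + dd·v_iv_j + N(0, σ²), with w = (d−2)/2 and v = 𝟙[d∈{1,2,3}].
  The default 21-trait architecture draws 2–4 QTLs per trait (a ~ N(0,1),
  one in three QTLs dominant) and one epistatic pair for every second
  trait, σ = 1.

## Dosage caller (`hecall`)

Emission: pooled-binomial log-likelihood per bin per state (see README).
`log 0` is clamped to −10¹² so e = 0 stays NaN-free, and zero counts
contribute exactly 0 (0·log 0 := 0). Smoothing: 5-state Viterbi per
individual per chromosome; transitions stay log(1−τ) / switch log(τ/4),
default τ = 10⁻⁴ per bin boundary (expected switches per chromosome ≪
bins). Ties prefer the left neighbour's state. Bins with zero reads carry a
flat emission — they are traversed, but reported MISSING in the output so
that breakpoint calls across gaps can be flagged; a state change across a
MISSING run is placed at the gap's midpoint boundary. An all-MISSING
chromosome yields an all-MISSING path with a warning.

With τ = 10⁻⁴ the switch penalty (≈21.2 log units for two switches)
exceeds the pooled evidence of a single discordant 5-kb bin at 10×
coverage (≈12.5 log units for a one-copy change), so single-bin tracts are
smoothed away *by design*; tracts of ≥2 bins are generally kept and ≥3
bins essentially always. Dosage-call accuracy at study conditions is
≥99.99% of bins.

The per-read error rate defaults to self-calibration: the pooled
minority-read fraction over bins whose raw NPB fraction is ≤0.05 or ≥0.95
(apparently homozygous runs) estimates e directly, without truth.

Euploidy screening normalizes each chromosome's median per-bin depth by
the individual's genome-wide median; deviation beyond 0.15 flags an
aneuploid (midpoint between euploid 1.0 and a one-copy gain 1.25).

## Landscape statistics (`landscape`)

Composition proportions are taken over all called individual × bin cells;
the parental NPB share is mean(d)/4. Symmetry uses the exact binomial test
with minimum-likelihood two-sidedness (scipy's convention). Chromosome
density redistributes the total event count across chromosomes with
probability ∝ physical length (multinomial permutations, default 10⁴) and
reports two-sided empirical p with a +1 pseudocount (doubled smaller tail,
capped at 1 — never zero). "cM/Mb" is operationalized as 100 × (events per
meiosis) / Mb, treating each HE as one crossover-equivalent; the number of
meioses is supplied by the caller (2g × individuals by default). Regional
enrichment places events uniformly over bins within the scope and compares
class counts (pericentromeric / subtelomeric / other); a scope with zero
events reports O/E as missing.

## Phenotype statistics (`phenostats`)

SD uses the n−1 denominator; CV is missing at zero mean. Transgression is
referenced to the *parental group extremes* (not means): over = above both
parents' maxima, under = below both minima, with a two-sided exact binomial
sign test on (over, under). Group contrasts are Welch (unequal-variance)
t-tests, because tetraploid and parental variances differ grossly; the
fully degenerate case (both groups constant and equal) reports (t, p) =
(0, 1).

## Cytonuclear scan (`cytosel`)

Per bin, cross and direction: the fraction of individuals with ≥1 copy of
the maternal (or paternal) homoeolog. A candidate needs (i) fraction >
0.95, (ii) fraction above the cross's genome-wide baseline for that
direction — this disambiguates the direction when heterozygote-rich bins
exceed the threshold both ways — and (iii) a chi-square test of the bin's
five-state counts against the cross's genome-wide state frequencies with
p < 0.01 (zero-expectation categories are pooled with a warning). The
genome-wide empirical null is used because the scan asks for *preferential*
retention relative to the rest of the genome. Candidate bins merge across
gaps of ≤1 bin (tolerating isolated MISSING bins); bin-level classification
(Group I: maternal in both crosses; II: paternal in both; III: paternal in
exactly one; maternal in one = unclassified) guarantees that direction
conflicts split segments. Enrichment of cytonuclear-flagged genes uses
Pearson's 2×2 chi-square without continuity correction; fitness contrasts
compare retention violators vs conformers by Welch's t (means only when a
class has <2 members).

The scan's false-positive behaviour depends on the number of *independent
lines*, not individuals: within-line fixation makes sibs pseudo-replicates,
so line-rich designs (≥30 lines per cross) keep neutral candidate counts
near the α × bins budget while sib-rich designs inflate them.

## Expression concordance (`dosex`)

Per gene × individual (≥20 reads): Pearson GOF of the transcript counts
against (f_d, 1−f_d) with e = 10⁻³ (avoids zero expectations at d ∈ {0,4}),
plus a balanced-1:1 GOF. Per gene: Fisher combination across individuals,
BH adjustment across genes per tissue. Verdict `dosage_dependent` requires
the dosage model *not* rejected (adjusted p ≥ 0.05) *and* the balanced null
rejected for ≥1 individual with d ≠ 2 — a bare non-rejection cannot
distinguish coupling from low power, and at d = 2 the two nulls coincide
(such genes are `indeterminate`). Both sub-statistics are emitted so either
reading of "correlated with dosage" can be reproduced. The summary fraction
is over determinate genes, with a Wilson 95% CI.

## GWAS (`hegwas`)

Encodings as in the README. The scan is an iterative fixed-effect scheme:
single-marker OLS with the current pseudo-QTNs as fixed covariates
(covariates with |r| > 0.7 to the tested marker are dropped for that test),
then greedy re-selection of pseudo-QTNs among markers below the Bonferroni
threshold (descending significance, mutual |r| ≤ 0.7), iterated to a fixed
point (max 10 iterations; non-convergence returns the last iteration,
flagged). The random-effect (kinship) component of mixed-model iterative
GWAS is deliberately omitted: a single biparental selfing family has no
population stratification, which is what that component guards against.
Bonferroni M is the number of markers actually tested in the run. Segment
delineation extends a peak while neighbouring bins' dosage vectors
correlate with the peak at r > 0.9, stopping at the first failure per side.
Plain OLS equivalence (empty pseudo-QTN set) is enforced by test against
the closed-form simple-regression t-test.

## Epistasis (`epistat`)

F∞ codes w = (d−2)/2 (homozygote contrast ±1) and v = any-heterozygote
indicator — the direct five-state generalization of the diploid F∞ codes.
Collinear design columns (e.g. a locus observed only in homozygous states)
are dropped and recorded. A perfect fit (zero residual, σ = 0 truths)
reports p = 0 for non-zero coefficients and 1 for zero ones. Pair-level
significance applies BH across all pairs × 4 interaction terms of a run; a
pair may count toward several interaction types. Candidate pairs are all
unordered pairs of a trait's associated loci, excluding pairs on one
delineated segment, capped by descending joint significance.

## Problem sizes and what the tests show

The full-scale recovery runs use the study geometry (12 × 30-Mb
chromosomes, 5-kb bins, ~10 SNPs/bin, 10× coverage, 100 S4 individuals;
the F1 control uses 20 exchange-free individuals). Association, epistasis
and selection-scan checks use a dense small-genome configuration (1–2 ×
2.5-Mb chromosomes, exchange rate 3 per pair, 300-kb tracts, 200
individuals from ≥50 lines) whose well-mixed five-state polymorphism
mirrors the real population's composition at a fraction of the compute; 20
seeded replicates back the calibration and power statements.

Passing tests establish that each estimator recovers what this generator
planted under its assumptions. Real data differ in ways the generator does
not emulate: non-exponential and position-dependent tract lengths,
non-reciprocal (conversion-like) exchanges, aneuploidy (real screens used
karyotyping; here a depth heuristic), mapping-bias and repeat-driven
artefacts in allele depths, shared environmental trait variance, and
linkage between selected segments and trait QTLs. Conclusions about those
features need real sequencing data, not this test bed.

## Other numerical conventions

All intervals are 0-based half-open; VCF is the only 1-based surface.
MISSING dosage is a sentinel (−1), never 0, since 0 is the legal 0:4
state. One seeded `numpy` Generator threads through each simulation run;
re-runs are bit-identical. p-values are floored at the smallest positive
double rather than 0 where a t statistic overflows; permutation p-values
are floored at 1/(n_perm+1) by the pseudocount.
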