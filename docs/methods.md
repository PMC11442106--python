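# Methods

## Problem setting

`polybsa` implements the statistical core of polyploid QTL-seq: bulked-
segregant QTL mapping for an autopolyploid F1 cross, developed for
autohexaploid crops such as sweetpotato where classical genotyping of six
homologous chromosomes from short reads is impractical.  Two parents and
two phenotype-extreme progeny bulks are sequenced; the analysis runs on the
per-sample allele read depths of a jointly called VCF.  All quantities are
read-fraction statistics: the *SNP-index* of a sample at a site is
alt_reads / total_reads, and the *ΔSNP-index* is
index(high bulk) − index(low bulk).

## Variant classification by plexity

The informative markers are variants carried on a known number of the donor
parent's homologs (plexity: simplex = 1, duplex = 2, triplex = 3) and
absent from the other parent (nulliplex).  With unbiased sequencing the
donor's alt-read fraction concentrates near plexity/ploidy, so dosage is
called by windowing the raw fraction:

| target plexity | donor fraction window | expectation |
|---|---|---|
| 1 (simplex) | 0.08 – 0.25 | 1/6 ≈ 0.167 |
| 2 (duplex)  | 0.22 – 0.45 | 2/6 ≈ 0.333 |
| 3 (triplex) | 0.38 – 0.62 | 3/6 = 0.5   |

The windows deliberately overlap; duplex/triplex assignment is not perfect
at ordinary depths and a run classifies at a *single* target plexity — the
three dosage classes are analysed in separate runs, and every run is
repeated with the parents swapped so QTLs from either parent are found.
"Nulliplex" in the other parent is operationalised as alt reads ≤
`max_other_alt_reads` (default 0, the strictest reading: an allele-specific
marker requires the other parent to show no alt reads at all).  Fractions
are evaluated on raw depth ratios, not on any smoothed estimate.  Sites
accepted in both donor orientations have no unambiguous segregating source
and are discarded.  At parental depth ≥ 200 the simplex window accepts
> 99% of true simplex sites and rejects > 99% of true duplex sites (exact
binomial tail computation; verified on the simulator in the test suite).

## Segregation model and null distribution

Polysomic inheritance with random bivalent pairing and no double reduction:
a parent with the allele on `d` of its `2m` homologs transmits a
hypergeometric gamete dose (choose `m` of `2m`, `d` marked).  For a
hexaploid simplex × nulliplex cross this yields the 1:1 presence/absence
ratio among progeny, expected progeny allele frequency plexity/(2·ploidy)
(1/12 ≈ 0.083 for simplex), and a ceiling of E[dose | carrier]/ploidy = 1/6
for the index of a bulk consisting entirely of carriers — hence the
ΔSNP-index moves from 0 toward ±0.167 across a fully penetrant simplex
QTL.

The no-QTL null of Δ at a site is simulated at the site's own read depths:
each bulk member's dose is drawn i.i.d. from the progeny dose distribution
(the dose *sum* is drawn in one multinomial step), the bulk allele
frequency is the dose sum over ploidy × bulk size, and the observed index
is a binomial read draw.  Unequal bulk sizes are supported (the targeted
design uses 10 low vs 21 high individuals).  Confidence thresholds are the
empirical 2.5/97.5 and 0.5/99.5 percentiles (`numpy.quantile`, linear
interpolation); per-variant P values are two-sided empirical tail
probabilities with the (r+1)/(N+1) floor so −log10 P is finite.  Default
replicates: 10,000 per depth pair (the published pipeline does not state
its replicate count or percentile convention; both are exposed in config).
Null distributions are cached per exact (depth_low, depth_high) pair with
streams derived deterministically from the global seed and the pair, so
results do not depend on evaluation order; the bulk scoring path retains
only the thresholds per pair to bound memory on dense scans.

`exact_bulk_index_pmf` provides an independent exact-enumeration oracle
(n-fold convolution of the dose pmf × binomial read outcomes, guarded to
≤ 10^7 combinations) used to validate the simulation at small n and depth.

## Genome scan and region calling

Scored variants are aggregated into 100-kb windows advanced in 20-kb
steps, anchored at position 1 on every chromosome (the method publishes
sizes, not anchoring), membership by 1-based inclusive interval.  Window
means are unweighted (depth weighting is not described by the method).
Each window tracks the directional QTL variant counts — significant
variants split by the sign of Δ — and the number of exact-zero SNP-indexes
per bulk.

A candidate region must satisfy both criteria:

1. **Sustained one-directional counts.** A run of consecutive windows whose
   directional QTL variant count exceeds 20 while the opposite direction
   stays at or below 20, spanning ≥ 2 Mb.  A window exceeding the threshold
   in both directions is bidirectional and breaks the run.  A lenient mode
   (`min_run_fraction` < 1) merges runs across sub-threshold gaps, never
   across an opposite-direction violation.  Either the 95% or the 99%
   counts can feed the criterion (`confidence`); both are plotted.
2. **One-sided zero cluster.** A run of windows (≥ 2 Mb) in which zero-index
   variants cluster in one bulk: at least `zero_min` (default 10) zeros and
   at least `dominance_ratio` (default 5) times the other bulk's.  The
   method describes "clustered … in one bulk but not in the other" without
   numbers; both knobs are exposed and recorded in run metadata.

Regions are the intersections of polarity-consistent criterion-1 and
criterion-2 intervals (a trait-increasing region depletes the donor allele
from the low bulk, so an *up* region requires the zero cluster in the *low*
bulk, and vice versa).  Bounds are exact window bounds — no sub-window
precision is claimed.  Inside a region, marker candidates are sites with
one bulk's index ≤ `zero_tol` (0.02) and the other within `simplex_tol`
(0.05) of plexity/ploidy, ranked by total bulk depth then |Δ|.

## Synthetic crosses

The simulator emulates the targeted study design: hexaploid parents, 126 F1
progeny, bulks of 10 (low) and 21 (high), per-sample depth Poisson(100)
floored at 1, parental variants placed on 1–3 homologs per donor with mix
0.6/0.25/0.15 (single-dose polymorphisms dominate in heterozygous
outcrossers, with frequency declining at higher dosage), default variant
density 1/5000 bp, and biallelic SNPs with ~10% short insertions.  Each
progeny inherits ploidy/2 homolog labels per parent per chromosome,
uniformly without replacement.  Whole homologs are transmitted intact by
default — this maximises linkage signal and makes truth evaluation exact —
with an optional Poisson-crossover mode (random bivalent pairing,
`crossover_cm_per_mb`).  Phenotype is a generic additive trait: Σ QTL dose
× effect + Gaussian noise (default sd 5 trait units against typical planted
effects of 10–20, i.e. moderate heritability); extreme-rank bulking with
deterministic index tie-breaks.  Read counts follow the same sampling
assumptions as the null model: parental alt reads binomial at
plexity/ploidy, bulk alt reads binomial at the realised bulk allele
frequency.

What the simulator does *not* model — and what passing tests therefore do
not establish for real data: preferential pairing and double reduction,
epistasis and dominance, depth heterogeneity beyond Poisson, mapping or
caller artefacts (the upstream aligner/caller options such as minMQ and
adjustMQ are recorded in config as provenance only), and the heterogeneous
variant density of real genomes.

## Problem sizes and numerical choices in the test suite

* Oracle agreement uses bulks of 1–3 members at depth ≤ 5 with 10^5
  replicates (Kolmogorov distance < 0.01).
* Type-I calibration simulates 60 chromosomes × 1.5 Mb at default density,
  scoring both orientations (~10^4 variants).  Many short chromosomes are
  used because whole-homolog transmission makes significance events highly
  correlated within a chromosome (only six homolog draws per parent per
  chromosome); averaging over many independent meioses lets the rate
  concentrate at the nominal 0.05.
* Planted-QTL recovery runs ten seeds of a 30-Mb chromosome with 126
  progeny, bulks 10/21 and depth 100 — the targeted design — at variant
  density 1/120 bp, which reproduces the per-window QTL variant counts
  (> 20) seen in real autohexaploid data.  The count criterion is evaluated
  on the 99%-confidence counts: at depth 100 with bulks of 10 and 21 the
  95% null band (≈ ±0.10) sits too close to the homolog-sampling
  anti-correlation that displaces non-QTL-homolog variants by −1/30, so
  95% down-counts scale as roughly 0.46× the up-counts and no density
  separates them at the fixed threshold of 20; at 99% the ratio falls to
  ≈ 0.15× and recovery is robust.  With no recombination the QTL signal is
  chromosome-wide, so recovery is asserted as a called up-direction region
  containing the planted position (to one window), not as sub-chromosome
  localisation.

## Known limitations

* Duplex/triplex runs share the overlapping windows of the published
  parameterisation; dosage discrimination between them is limited at
  ordinary depths.
* The null treats variants independently; no linkage-aware joint null or
  across-window multiple-testing correction is attempted (the method uses
  simulation thresholds, not FDR).
* Criterion thresholds (`zero_min`, `dominance_ratio`, strict vs lenient
  runs) quantify a qualitative published rule; alternative settings may
  call slightly different region boundaries.
* Region bounds are unions of window bounds and inherit the 20-kb grid
  resolution.
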