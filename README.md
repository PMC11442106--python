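# polybsa — polyploid QTL-seq bulked-segregant genome scans

`polybsa` maps quantitative trait loci in autopolyploid F1 crosses (the
motivating case is autohexaploid sweetpotato) by bulked-segregant analysis
of whole-genome sequencing: two parents and two phenotype-extreme progeny
bulks are sequenced, and allele-frequency skews between the bulks reveal
the trait-linked genome regions.  It is aimed at plant genetics groups who
have a jointly called multi-sample VCF and want the statistical half of a
polyploid QTL-seq pipeline — variant dosage classification, SNP-index
statistics, simulation-based significance, genome scan, region calling and
marker nomination — without the upstream read QC/alignment/calling glue.

## Method in brief

For a sample at a biallelic site, the **SNP-index** is alt reads / total
reads.  Markers are variants carried on *n* of the donor parent's 2m
homologs (plexity: simplex n=1, duplex 2, triplex 3) and absent from the
other (nulliplex) parent; they are recognised by the donor's raw read
fraction falling in a plexity window (simplex 0.08–0.25, duplex 0.22–0.45,
triplex 0.38–0.62, nulliplex = zero alt reads in the other parent).  Under
polysomic inheritance a simplex × nulliplex cross segregates 1:1, so an
unselected bulk has expected index 1/12 ≈ 0.083 while a QTL drives one
bulk toward the carrier ceiling 1/6 ≈ 0.167 and the other toward 0, moving
**ΔSNP-index** = index(high bulk) − index(low bulk) from 0 toward ±0.167.

Significance is assessed against a plexity-adapted Monte-Carlo null at each
variant's own read depths: bulk member doses are hypergeometric-gamete
draws, reads are binomial, thresholds are the empirical 95%/99% bands, and
P values are two-sided empirical tails.  Scores aggregate into 100-kb
windows at 20-kb steps; a candidate region needs (1) more than 20
null-exceeding variants per window in one direction of effect — but not
the other — sustained over ≥ 2 Mb, and (2) a ≥ 2 Mb cluster of zero-index
variants in one bulk only, with consistent polarity.  Within a region,
marker-ready sites have one bulk's index ≈ 0 and the other ≈ plexity/ploidy.

A built-in simulator generates hexaploid crosses (polysomic segregation,
planted additive QTLs, extreme-phenotype bulks, Poisson/binomial read
sampling) as VCF + truth tables, so the whole pipeline is testable without
sequencing data.  See `docs/methods.md` for model details and assumptions.

## Worked example

Simulate a 4-Mb chromosome with one fully penetrant simplex QTL from
parent P1 at 2.0 Mb (126 progeny, bulks of 10 and 21, ~100× depth), then
fit the scan:

```python
from polybsa import (CrossConfig, PolyploidQtlScan, QtlSpec, RunConfig,
                     simulate_dataset)

cfg = CrossConfig(chrom_lengths={"chrA": 4_000_000}, variant_density=1/400,
                  qtls=[QtlSpec("chrA", 2_000_000, "P1", 20.0)],
                  phenotype_noise_sd=0.0, depth_mean=100.0, seed=19)
frame, truth, cross = simulate_dataset(cfg)

rc = RunConfig(replicates=2000, seed=19, confidence=99, min_run_fraction=0.9,
               count_threshold=5, min_span_bp=1_000_000, zero_min=5)
res = PolyploidQtlScan(frame, cfg.chrom_lengths, rc).fit("P1")
print(res.summary())
```

```
Polyploid QTL-seq scan
============================================================
donor orientation : P1
ploidy / plexity  : 6 / 1
donor index range : [0.08, 0.25]
bulk sizes (low/high): 10 / 21
window / step     : 100000 / 20000 bp
null replicates   : 2000 (seed 19)
stage counts      : parsed=10000, filtered=10000, classified=2920
ΔSNP-index 95% band (median depth): [-0.0996, +0.1013]
ΔSNP-index 99% band (median depth): [-0.1199, +0.1219]
significant variants: sig95=665, sig99=469
------------------------------------------------------------
chrom              start         end   dir  zeros  windows
chrA                   1     4000000    up    low      199
```

Reading the output: of 10,000 simulated sites, 2,920 classify as
P1-derived simplex variants; the null ΔSNP-index band at the median depth
pair is about ±0.10 (95%), and 469 variants exceed the 99% band.  One
up-direction region is called — the donor allele increases the trait —
with the zero-index cluster in the low bulk, as the polarity rule requires.
(The small demonstration genome is fully linked to the QTL, hence the
region spans the chromosome; `res.markers[0]` then ranks marker-ready
sites, e.g. `chrA:2423786 A>G` with idx_low 0.000 / idx_high 0.158.)

The same pipeline runs from the shell on a VCF + chromosome-length table
driven by one YAML file (`polybsa simulate | run | plot`); `run` fits both
parent orientations and writes scored/window/region/marker TSVs, run
metadata and optional six-panel per-chromosome figures.

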