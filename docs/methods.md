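# Methods

## The statistic

`bsascan` implements bulked-segregant analysis of pooled whole-genome
sequencing (QTL-seq / BSA-seq) for an F2 population from two inbred
parents. At each SNP segregating between the parents, the **SNP index** of
a bulk is the fraction of its reads carrying the donor allele (the allele
from the non-reference parent); under no linkage to the selected trait the
expectation is 0.5. The scan statistic is

    Δ(SNP index) = index(high bulk) − index(low bulk),

which departs from 0 near a locus whose alleles were enriched by selecting
the phenotypic extremes into the bulks. Indices are polarized to the donor
allele, so a positive Δ means the donor allele raises the trait and the
region's `donor` field names the donor parent.

## Filtering

Two filters precede the scan, mirroring standard BSA-seq practice:

- **depth filter** — keep SNPs with depth ≥ `min_depth` (default 29) in
  *both* bulks. The published analyses state a single depth cutoff without
  saying whether it is per-bulk or summed; requiring it in both bulks is
  the conservative choice and keeps the two indices comparable. The rule is
  a parameter, not a constant.
- **low-index filter** — remove SNPs with index < 0.3 in *both* bulks
  (strict inequality; a SNP at exactly 0.3 is kept). A true donor allele
  segregating in the cross should reach 0.3 in at least one extreme bulk,
  so double-low SNPs are treated as sequencing/alignment artifacts.

Zero-depth records have an undefined index and are excluded (never
imputed), with the count logged. The filters commute; record counts after
each filter are logged so a chromosome-wise accounting table can be
reconstructed from the log.

## Null model and confidence bands

Significance is assessed against a Monte-Carlo null that reproduces the
two sampling layers of a bulk experiment with **no** marker–trait linkage:

1. each bulk is an independent draw of `bulk_size` (default 20) F2
   individuals whose donor dosage segregates 1:2:1, pooled into a donor
   frequency p = mean(dosage)/2;
2. reads are Binomial(depth, p) per bulk.

By the law of total variance, Var(Δ) = 2·(0.125/B + E[p(1−p)]/d) with
bulk size B and depth d; the simulation agrees with this closed form and
with its depth→∞ limit, which the tests assert. Per depth, the two-sided
band at level L is the ((1−L)/2, 1−(1−L)/2) empirical quantile pair of
100,000 replicates (default); at depth 29 and B = 20 the 95%/99% upper
bounds are ≈ 0.33–0.34 / 0.43–0.45, depending on where the quantile falls
on the 1/29 read-count lattice. Each depth's sample comes from an
independent, depth-keyed substream of one root seed, so the table does not
depend on the order depths are requested.

Per-SNP two-sided empirical p-values use the same samples with the
+1/(n+1) continuity correction, looked up at the SNP's rounded mean depth
across both bulks. **Discreteness caveat:** at low depth Δ is supported on
a lattice, so the probability of *strictly* exceeding an interpolated
quantile can sit visibly below the nominal tail rate (≈3.3% rather than 5%
at depth 29); calibration statements in the tests therefore bracket the
nominal rate between strict and inclusive exceedance.

## Windows and region calling

Windows are 1-based closed intervals `[s, s + window − 1]` with starts at
1, 1+step, … per chromosome (defaults: 2-Mb window, 10-kb step). Window
statistics are unweighted means over member SNPs, computed by slicing the
position-sorted arrays, so they agree *exactly* with a brute-force
re-scan. Windows with fewer than `min_snps` (default 3) SNPs emit no
means, which suppresses single-SNP spikes.

A window is significant when |mean Δ| exceeds the band at its rounded mean
depth **and** its mean per-SNP p-value is below 0.05 (the "mean of
per-SNP p" reading of window-average significance; the p-of-the-mean
alternative was considered and not adopted because the per-SNP p already
absorbs each SNP's own depth). Runs of same-sign significant windows merge
across gaps of up to `max_gap_windows` (default 2) non-significant
windows; a sign change always splits. Because consecutive windows overlap
by 99.5% at the default geometry, two runs a few steps apart can span the
same physical interval; a final pass merges same-sign regions whose
extents overlap, so the caller never reports two overlapping regions for
one locus. Region bounds are the outermost member windows' bounds and the
interval length is (end − start)/1e6 Mb. No genome-wide multiplicity
correction is applied beyond the per-depth band — a known limitation of
the window-scan convention this package reproduces; the false-region rate
of a null genome is exercised in the tests rather than corrected.

## The simulator

The synthetic-data generator produces the statistical structure the scan
assumes, with defaults at the scale of the rice study it emulates:

- **genome** — 12 chromosomes with the rice physical lengths (total
  373.2 Mb) or any user layout; evenly spaced SNPs; uniform recombination
  at `cm_per_mb` = 4 (rice-scale genome-wide average; configurable).
- **meiosis** — Haldane model: crossover counts in each inter-SNP interval
  are Poisson with mean equal to the interval's genetic length; the phase
  at the left end of each gamete is fair. Recombination fractions follow
  r = (1 − e^(−2m))/2, which the tests check against simulated F2 dosage
  correlations. No crossover interference is modeled.
- **trait** — per-QTL genotype values {−a, d, +a} for dosage {0, 1, 2}
  plus Gaussian noise; the noise variance is calibrated from the realized
  genetic variance so the requested heritability is exact in-sample.
  Heritability 0 returns pure unit-variance noise. Polygenic background
  beyond the declared QTLs is represented only by this noise term.
- **bulks** — the `bulk_size` = 20 largest and smallest phenotypes
  (deterministic tie-break by individual index), n = 178 individuals by
  default; pooling is idealized with exactly equal DNA per plant.
- **reads** — depth per SNP and bulk from a fixed or Poisson model
  (default Poisson, mean 22, between the two bulks' published average
  depths); symmetric per-read error (default 0.001) flips alleles before
  the binomial draw.

One root seed drives three independent substreams (meiosis, trait noise,
read sampling), so identical configurations reproduce byte-identical
outputs, which the suite asserts via SHA-256 of all artifacts.

What the simulator does **not** emulate: read-level artifacts (mapping
bias, indels, duplicated regions), variable SNP density, linkage
disequilibrium structure beyond a uniform recombination map, pooling
imbalance, and genotyping error in marker tables. Passing tests therefore
certify the statistical machinery under the stated model, not robustness
to those real-data pathologies.

## Marker–trait statistics

Single-marker analysis is OLS of phenotype on dosage coded (−1, 0, +1):
PVE = 100·R², LOD = −(n/2)·log10(1 − R²), and the additive effect is the
slope (half the homozygote difference under additivity), with the donor
parent read off the slope's sign. A 2-df genotype-class model is exposed
for dominant loci. Joint PVE is the R² of the multiple regression on all
marker dosages with listwise deletion; linearly dependent columns are
dropped greedily left-to-right and reported. The conventional LOD ≥ 3
reporting threshold is a flag, not a hard rule. The grain-elongation
ratio is mean(cooked length)/mean(milled length) per replicate (default
design 3 replicates × 10 grains), reported as mean ± s.d. across
replicates; it is scale-invariant and requires strictly positive lengths.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` work at desk scale by design:
null bands from 100,000 replicates per depth; calibration on ~3,000
effectively unlinked SNPs (adjacent genetic distance 2.5 Morgans);
parameter recovery over 100 (tests) or 50 (script) seeded replicates of a
two-chromosome genome with 50-kb SNP spacing, n = 178, bulks of 20,
~22× Poisson depth. The recovery runs use `min_depth` = 10 because their
simulated coverage is ~22×; the 29× default mirrors the original study's
selection at its own, higher coverage. Genome-scale read yields and SNP
totals from the original sequencing data are out of scope; the pipeline
logs per-filter SNP counts so equivalent accounting tables can be produced
for any input.
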