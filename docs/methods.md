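# Methods

## Scope and data model

`methylcmp` analyses per-cytosine bisulfite methylation call tables
(chrom, 0-based position, strand, context, methylated count, unmethylated
count) against a reference genome (FASTA) and feature annotation (BED6+2 or
GFF3). All intervals are 0-based half-open internally; GFF input is
converted on read, and a `one_based` flag accepts 1-based call tables.
Everything downstream of read alignment is in scope; alignment, duplicate
removal and expression quantification are upstream of the inputs.

## Context classification

A cytosine's context is the two bases 3′ of it on its own strand: CG if the
next base is G, else CHG if the base after next is G, else CHH. Minus-strand
cytosines are forward-strand Gs read on the reverse complement. Sites whose
two context bases run off the chromosome or contain an N are excluded from
all analyses — the context is unknowable, and most callers behave the same
way. Consequence: enumeration of a reverse-complemented genome is the exact
mirror of the original (a property test), and CG sites come in ±-strand
pairs at adjacent positions.

## Methylation levels

All levels are *weighted*: pooled methylated reads over pooled total reads
across the sites of interest, never a mean of per-site levels. This is what
#C/(#C+#T) gives when applied to summed counts, is robust to uneven
coverage, and makes bin/region/global levels mutually consistent (pooling
bins reproduces the global level exactly; both facts are tested). Sites with
zero coverage contribute nothing; a set with no covered site has an
undefined (NaN) level, never 0. Region averaging uses union semantics — a
site inside two overlapping regions counts once.

Bisulfite non-conversion makes the observed level p + (1−p)·ε. Where a
quantity should estimate the *true* level ratio (e.g. a mutant/WT reduction
factor), levels are first corrected by (level − ε)/(1 − ε), the standard
inversion; the random-bin regression slope needs no correction since the
observed relation is ε(1−f) + f·x, whose slope is the factor f itself.

## DMR calling

Per context, on 100-bp bins (configurable):

1. **Testability.** ≥ 4 context cytosine positions with ≥ 1 read, by default
   in *each* sample (`min_cov_mode="each"`). This is the strictest plausible
   reading of a minimum-coverage rule and prevents one-sided coverage
   artifacts; `either` and `pooled` are available because the choice is
   genuinely open.
2. **Test.** Two-sided Fisher exact test on the pooled read-level 2×2 table
   (reference meth/unmeth vs sample meth/unmeth) — read counts, not
   binarized sites. The implementation is vectorized: hypergeometric
   log-pmfs via `gammaln`, two-sided p as the sum of outcome probabilities
   no more likely than the observed one, with a 1e−7 *relative* tolerance
   for ties (the convention of the common scalar implementations; the test
   suite checks agreement with `scipy.stats.fisher_exact` and with exact
   rational enumeration). An all-zero table gets p = 1. Vectorization
   matters because a 2-Mb comparison tests ~5×10⁴ bins.
3. **Multiplicity.** Benjamini–Hochberg over exactly the tested bins of that
   context (contexts are adjusted independently — DMRs are defined per
   context). Backed by `statsmodels`, checked against the literal O(m²)
   step-up definition.
4. **Effect size and direction.** q < 0.01 and |level difference| ≥ 0.4 (CG),
   0.2 (CHG) or 0.1 (CHH); direction is hypo when the sample is below the
   reference, applied last.

Swapping reference and sample preserves p and flips direction; raising the
effect threshold or lowering the FDR never adds DMRs (both tested). Adjacent
significant bins are *not* merged — the unit of analysis stays the 100-bp
bin, which is also what makes exact-bin Venn partitions well-defined.

DMR-set comparison is by exact (chrom, start) bin identity; partition counts
sum to the union size. Bin-level matrices across samples carry NaN (not 0)
where a sample is uncovered. For clustering (complete linkage, Euclidean),
NaN entries are imputed with the row mean of defined entries and rows with
fewer than two defined entries are dropped — the sources are silent here and
this keeps all distances finite; scipy's agglomerative implementation makes
tie-breaking deterministic given input order.

## Feature profiles

Metaplots orient each feature 5′→3′ by strand, cut 2,000-bp flanks into
fixed 100-bp bins and the body into 40 length-proportional bins (a site at
body offset o of a length-L feature lands in bin ⌊o·B/L⌋). Each feature
contributes a weighted level per bin; the profile is the *mean over
features* with a defined value (per-feature averaging, so long features do
not dominate; bins a feature leaves empty reduce its support rather than
contributing zeros). For features shorter than the body bin count this
assignment simply leaves some body bins undefined for that feature — chosen
over interpolation schemes for transparency, and identical in behavior for
features of ≥ 40 bp per bin.

Chromosomal tracks are pooled-count levels in tiled (or sliding) windows,
default 100 kb. The random-bin scatter samples up to 5,000 bins without
replacement among bins with defined levels in both samples, ≥ 4 covered
sites in both, and reference level > 0.01 (excluding the unmethylated mass
from the draw), then fits ordinary least squares with intercept — the
regression convention when none is stated. Sampling is deterministic given
the seed and seed-independent when everything eligible is used. Midpoint
coverage profiles average a per-base track in 100-bp bins of signed distance
from region midpoints, with chromosome-edge truncation recorded as missing
support. TE-family enrichment is a per-family two-sided Fisher test of hits
vs non-hits, BH-adjusted across families.

## Genetics statistics

Segregation: χ² goodness of fit against a Mendelian ratio, *without* Yates
continuity correction — the uncorrected statistic on 103:368 vs 1:3 gives
p = 0.117 ≈ 0.12, the study's printed value, while the corrected one does
not. Homozygote mortality is 1 − observed/expected viable fraction (1/18
observed vs 1/4 expected ⇒ 7/9 ≈ 77.8%, i.e. "more than 75%"). MI = SAM/SAH.
Root growth rates are per-seedling OLS slopes (mm/day) summarized as
replicate mean ± sd. The BSA scan reports coverage-weighted mutant-allele
frequencies in 1-Mb windows stepped every 100 kb and calls candidate
intervals as maximal runs of windows with frequency ≥ 0.95; window, step and
threshold are this package's own defaults, exposed in the API.

## Synthetic-data generator

The generator emulates the statistical structure of plant WGBS studies, not
their sequence content:

* **Genome**: i.i.d. bases at GC 0.36, one centered pericentromere per
  chromosome (default 25% of its length).
* **Annotation**: non-overlapping TEs covering 60% of the pericentromere and
  5% of the arms; PCGs covering 40% of the arms; family labels
  (LTR/Gypsy 0.30, RC/Helitron 0.25, LTR/Copia 0.15, DNA/MuDR 0.15,
  LINE/L1 0.15).
* **True methylome**: per-site beta draws (concentration 15) around
  compartment × context means — pericentromeric TE (CG 0.85, CHG 0.65,
  CHH 0.20), arm TE (0.75, 0.45, 0.12), PCG body (0.20, 0.02, 0.01),
  intergenic (0.05, 0.02, 0.01). These are generator choices shaped like
  published plant methylome profiles (TE-concentrated non-CG methylation,
  CG-only gene bodies); with them the genome-wide weighted levels come out
  near CG 0.24, CHG 0.13, CHH 0.04, and the default uniform mutant loses
  ≈ 40% of all-context methylation — the regime the analysis targets.
* **Observed counts**: coverage ~ Poisson(30), methylated reads ~
  Binomial(coverage, p + (1−p)·ε) with ε = 0.005.
* **Mutants**: uniform proportional (defaults f_CG 0.76, f_CHG 0.38,
  f_CHH 0.50) or pathway knockout to baseline 0.01 (presets: met1 = CG
  everywhere, cmt3 = CHG everywhere, cmt2 = pericentromeric-TE CHH,
  drm = arm/RdDM CHH).
* **F2/BSA**: Mendelian causal genotypes, optional homozygote viability,
  bulk of phenotype-positive plants, marker alleles recombining from the
  causal allele with Haldane fractions at 4 cM/Mb, binomial reads at
  Poisson depth 30.

Determinism: every output is a pure function of the configuration; each
stage draws from a stream derived from the global seed with a fixed offset,
so adding a stage never perturbs earlier draws, and replicate libraries use
indexed streams.

What the generator does **not** emulate: real sequence composition
(CpG-island structure, TE consensus sequences), mapping artifacts and
coverage biases, strand- or read-position-specific conversion failure,
biological replicate variance beyond binomial sampling, linked marker-marker
correlation beyond the causal locus, and any transcriptional response.
Passing recovery tests therefore demonstrates correctness of the estimators
and calling logic under the declared sampling model, not robustness to
alignment or library artifacts.

## Problem sizes

The recovery and calibration analyses (test suite and
`scripts/acceptance.py`) run on 2-Mb single-chromosome genomes at 30×
(~7×10⁵ cytosines, ~5×10⁴ testable bins per comparison), 20 replicate pairs
for the null calibration, and 2,000-plant F2 populations — sizes at which
every target quantity's sampling error is well inside its tolerance. Unit
tests use 100–500-kb genomes.

## Known limitations

* The Fisher batch uses double-precision log-pmfs; relative error is ~1e−15,
  far inside the 1e−7 tie tolerance, but exact ties are resolved by that
  tolerance rather than by rational arithmetic.
* `metaplot` treats unstranded features as +-strand.
* `bsa_frequency_scan` windows start at 0 and extend to the last covered
  marker; a causal locus within half a window of a chromosome end may be
  reported with a truncated interval.
* The call-table reader loads entire tables into memory; at desk scale
  (≤ tens of Mb of genome) this is a few hundred MB at most.
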