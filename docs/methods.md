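# Methods

`driftld` re-implements, as a tested pipeline, an analysis of how range
expansion and a shift from outcrossing to self-fertilisation shape
linkage disequilibrium (LD) across a genome, and exercises it end to end
on a bundled forward-time simulator instead of sequencing data.  This
note documents the models, the estimators, the simulator, the numerical
choices, and what the bundled experiments do and do not show.

## The two LD estimators

**Pooled read pairs (short range).** Pooled sequencing destroys
individual identity, so two-locus haplotypes can only be observed on
single sequenced fragments covering both SNPs.  For a SNP pair with 2x2
read-pair haplotype counts (n11, n12, n21, n22), writing p11 = n11/n,
p1. = (n11+n12)/n and p.1 = (n11+n21)/n,

    D  = p11 - p1. * p.1
    r2 = D^2 / (p1. (1-p1.) p.1 (1-p.1)).

This equals the squared Pearson correlation of the two allele indicators
over the n read pairs (asserted exactly in the tests).  A pair that is
monomorphic among its read pairs has *undefined* r2 (never 0): scoring
it 0 would deflate region means.  The filtering cascade keeps pairs with
co-covering depth strictly greater than 5, population minor allele
frequency strictly above 0.15 at **both** loci (the "either locus"
phrasing common in pooled-LD protocols is ambiguous; the both-loci
reading is the default and an any-locus mode is a switch), and inter-SNP
distance 1-500 bp.  Because r2 decays with distance, population
comparisons use the residuals of an OLS regression of r2 on
log10(distance), fitted separately within genic and intergenic scope
("distance-corrected LD").  Genic/intergenic assignment requires both
loci in the same half-open interval; cross-boundary pairs are dropped.
A region enters the analysis only with >= 5 estimates in a population,
and only if fewer than 50% of populations are missing it (both bounds
strict).

**Correlation of zygosity (long range).** A single diploid genome
carries LD information in the spatial correlation of its heterozygous
sites.  Coding each callable site z = 1 if heterozygous, with
genome-wide heterozygosity theta = mean(z) and Pi(d) the co-heterozygosity
rate at distance d,

    Delta(d) = (Pi(d) - theta^2) / (theta (1 - theta)),

and Delta(d)/theta approximates r2.  This package computes Delta as a
moment estimator on called genotypes rather than re-deriving a full
maximum-likelihood fit from read pileups: the target quantity is the
same and the moment form is exactly testable.  Pair and site counts are
computed exactly by FFT autocorrelation of the callable mask and the
heterozygosity indicator within each scope interval, so no pair spans a
scope gap.  Distances follow the published stepping scheme (1 bp steps
to 5 kb, then 100 bp steps to 50 kb).  An optional ``bin_width`` pools
pairs from a window of distances around each step; toy-scale genomes
need it because exact-distance pair counts are tiny.  A genome with
fewer than ``min_het_sites`` (default 30) heterozygous sites yields an
undefined profile — there is no signal to correlate.

The **decay length** is the smallest distance at which the
rolling-median-smoothed (window 11 bins) scaled curve falls to 0.1 and
stays there for 10 further bins.  The threshold applies to the raw
scaled curve, not its logarithm: the scaled correlation approximates r2
and 0.1 is a natural "low LD" mark on that scale.  Smoothing and
persistence are robustness choices; a raw-crossing mode exists.  A curve
that never falls to 0.1 has no finite decay length (LD extends beyond
the window); with ``require_initial_above`` a curve that never *rises*
above 0.1 is reported as unmeasurable instead of "decayed at d=1".

**Callable sites.** A genotype call is callable with GQ >= 28 and depth
inside a closed window of multiples of the average depth.  The published
window (2x-5x the genome-wide average) presumes the skewed coverage
distribution of real resequencing, where the genome-wide average is
dragged down by unmappable regions.  The bundled emitter produces
uniform Poisson coverage, for which that window would be empty; the
pipeline therefore passes the equivalent guard (0.5-2.0)x.  The filter
function itself defaults to the published bounds.

## Population-genetic summaries

*Watterson's theta* per region and population is S / (a_n L) with a_n
the harmonic number of n_chrom - 1 and L the annotated region length;
n_chrom defaults to twice the pool size (50).  This replaces
depth-aware pooled estimators with the classic form on filtered SNP
calls — a declared approximation; n_chrom is configurable.

*Mutational load* is Pn fn / (Ps fs): the number of polymorphic
nonsynonymous (deleterious-class) sites times their mean derived-allele
frequency, over the same product for synonymous-class sites.  The
simulator provides derived-allele polarity directly (ancestral state is
the reference).  A site counts as polymorphic above a 0.03 minor-allele
floor, matching the usual pooled SNP-calling threshold; without the
floor, deeply sequenced pools count every singleton read and the
statistic is dominated by rare-variant loss rather than the frequency
shifts the load ratio is meant to capture.

*Gene density* is the mean gap to the up- and downstream neighbouring
genes for genic regions (terminal genes use their single gap; a lone
gene is undefined) and the region's own length for intergenic regions;
gaps run between interval boundaries, not midpoints.

## Genome segmentation

Extended runs of elevated LD are detected with a two-state hidden Markov
model on per-region mean r2, ordered along the genome: Gaussian
emissions per state, Baum-Welch (EM) estimation with log-space
recursions, Viterbi decoding with ties broken toward the low state, and
a run table of consecutive high-state regions of length >= 3 (the run
threshold is a flag; no published value exists).  Means initialise at
the 25th/75th percentiles of the sequence and half the sequence SD, with
0.9 self-transition; five seeded restarts keep the best likelihood.
Variances are floored at 1e-6; an effectively constant sequence is
flagged degenerate.  The default sequence is raw region-mean LD, with a
flag for distance-corrected means.  Exactness is asserted against
exhaustive path enumeration, and hmmlearn serves as an independent
cross-check of the recursions in the test suite.

## Expansion distance

Each population's expansion distance is the sum of great-circle legs
between consecutive node coordinates on the path from its cluster's core
node down to its leaf on a map-projected population tree; designated
rear-edge ("old") populations instead use the direct great-circle
distance to the core.  Distances use a spherical Earth of mean radius
6371.0088 km — ellipsoidal corrections are far below the model's
resolution.  Newick trees carry node labels; coordinates travel in a
separate node table because Newick has no portable coordinate slot.  The
triangle inequality (path sum >= direct distance) is asserted for every
population.

## Statistical layer

Genome-wide models are linear mixed models fitted by REML (statsmodels
MixedLM is the optimiser; the design matrices, sum-to-zero contrasts for
categorical terms, type-III Wald chi-square tests, FDR and band logic
around it are this package's).  Fixed effects: genetic cluster, log10
expansion distance, F_IS (the mating-system proxy), and log10 gene
density; random structure: a population intercept plus region variance
components, simplified stepwise (population intercept, then OLS) when a
fit is singular, with the structure recorded per fit.  The optimiser
runs lbfgs first and falls back to derivative-free Powell before any
structural simplification: boundary-variance datasets otherwise crash
lbfgs selectively and would bias which data get a mixed fit (the
calibration experiment guards this: type-I error of the Wald tests stays
in [0.03, 0.07] under the null).  Wald chi-square for a single-df term
is (beta/SE)^2; multi-column terms use the quadratic form with the
fitted covariance.

The SNP-type model codes pair classes numerically DD=0, DT=1, TT=2
(order switchable) and adds interactions with expansion distance and
F_IS.  The per-distance-bin models regress log10 of the scaled zygosity
correlation on cluster, expansion and mating system with a population
intercept, BH-FDR adjusted per term across bins.  An expansion x mating
interaction is omitted from the genome-wide model and included in the
per-gene scan, following the published model structures.

Model-predicted *relative increases* between the smallest and largest
observed predictor values hold other predictors at their means
(categorical terms averaged over levels).  Because the response is
residual-scale (distance-corrected), predictions are re-anchored by the
grand mean r2 before the percentage is formed.

The *outlier scan* fits, gene by gene, cluster + log10 expansion + F_IS
+ expansion x F_IS with a population random intercept, requires data
from at least 10 populations, BH-FDR adjusts p-values across converged
genes per coefficient (the FDR denominator excludes unfit genes, which
are reported separately), and flags a gene when it is both
FDR-significant and outside the genome-wide coefficient +/- 2 SE band
(band from the genome-wide fit's SE by default; a +/- 2 SD-of-per-gene-
coefficients mode and an OR flag rule exist for sensitivity).  Flagged
sets are compared to the background by paired per-population t-tests on
mean Watterson's theta.

## The simulator

A forward-time Wright-Fisher stepping-stone model supplies every input
the analysis consumes.  Deme 0 evolves alone for a burn-in; each
subsequent deme is founded from the previous one by K diploids that
repopulate the colony to carrying capacity in one generation (a
propagule bottleneck), every `generations_between_foundings`
generations, along a line with one map step per deme.  Offspring self
with the deme's selfing probability, otherwise outcross; parents are
drawn proportional to multiplicative fitness (1 - hs heterozygous,
1 - s homozygous derived at deleterious sites; no epistasis).  Mutation
is infinite-sites on an alternating gene/intergenic layout — genic
mutations deleterious with probability 0.4, otherwise synonymous-like
tolerated; intergenic mutations neutral.  Crossovers are a Poisson
process without interference.

Emitters: pooled sequencing samples 25 diploids and generates paired-end
fragments (insert ~ Normal, truncated at 0) whose co-covered SNP pairs
yield the 2x2 haplotype counts, with per-base errors; per-site depths
and allele counts are drawn from the equivalent per-site binomials.
Individual genomes get per-site depths ~ Poisson, binomial read-level
likelihoods, a genotype call, and a phred GQ (gap between best and
second-best genotype, capped at 40 so the GQ >= 28 filter has bite).

**Standard study conditions** (the defaults): 10 demes of 80 diploids,
K = 4 founders, one founding every 10 generations, burn-in 400
generations, genome 82.5 kb as 16 genes of 2.5 kb with 2.5 kb intergenic
blocks, mu = rho = 1e-5 per bp per generation, pool depth 300x, read
length 100, insert 150 +/- 60, sequencing error 0.002, individual
coverage 20x.  These are scaled-down analogues of the study system:
deme sizes shrink by orders of magnitude, so per-bp rates scale up
(standard forward-simulation rescaling) to preserve the composite
parameters that matter — theta = 4 N mu ~ 0.006 per bp (inside the
empirically observed range) and per-500-bp recombination strong enough
that LD decays visibly inside the read-pair window.  Two dynamics set
the calibration: founder-effect LD relaxes back toward the deme-size
equilibrium at rate ~ rho d per generation, so sampled demes must carry
*recent* foundings (short inter-founding interval) for the gradient to
be monotone; and the selection coefficient (0.05, h = 0.3) is weak
enough for edge-deme drift to accumulate expansion load yet strong
enough to differentiate the deleterious class.  The selfing-contrast
experiment raises mu to 8e-5 and compares a daughter deme that shifts to
s = 0.95 selfing at its founding, 15 generations before sampling,
against its outcrossing twin.  Its decay lengths come from the pooled
zygosity curve over 32 sampled genomes (window 12 kb): single selfed
genomes carry too few heterozygous sites for a curve of their own, so
per-genome pair counts are pooled as a ratio of sums with per-genome
centring — recently outcrossed lineages, whose long heterozygous tracts
are precisely the extended-LD signature of selfing, dominate the
estimate in proportion to their information, while the between-genome
variance in inbreeding (identity disequilibrium) cannot masquerade as
distance-dependent correlation.  The young deme age bounds how far
recombination has eroded the tracts.

**What the simulator does not emulate:** real read mapping (no
mappability variation, duplicates, or strand bias), skewed coverage, a
real gene annotation (uniform alternating layout), population structure
beyond a single linear expansion per cluster label, beneficial
mutations, 2-D landscapes, or a self-incompatibility locus.  Passing
tests therefore show that the estimators and inference recover the
processes the model contains — drift gradients, selfing effects, load
coupling — not that they would survive every artefact of real data.

## Numerical choices and degenerate inputs

- Coordinates are 1-based inclusive in VCF/GFF at the boundary and
  0-based half-open internally; converters are unit-tested both ways.
- All randomness flows from explicit seeds; identical configurations
  give byte-identical pipeline manifests (hashes of every output).
- Monomorphic r2, zero-heterozygosity profiles, lone genes, zero
  synonymous polymorphism, single-population model fits and constant
  HMM sequences all return explicit undefined/NaN-with-reason or
  flagged results rather than silent zeros.
- Replication experiment sizes (20 seeds for gradient and selfing
  batches, 500 null replicates for calibration, 40-100 genes for scan
  calibration) balance Monte-Carlo error against a desk-top compute
  budget; `scripts/acceptance.py` uses moderately smaller batches, and
  all sizes are recorded in its output.

## Known limitations

- The zygosity estimator operates on called genotypes, not read-level
  likelihoods; at very low coverage its theta is biased by miscalls in a
  way the full likelihood treatment would not be.
- Watterson's theta ignores pooled sampling noise in allele counts.
- Crossed population x scaffold random effects are approximated with a
  population grouping plus variance components; with a single simulated
  scaffold the distinction is moot, but multi-scaffold real data would
  deserve a genuinely crossed structure.
- The outlier-scan band test inherits the genome-wide SE, which shrinks
  with data volume; at very large n nearly every gene exits the band and
  the FDR step carries the control (the SD-band mode is the conservative
  alternative).
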