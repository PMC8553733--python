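# Methods

`microhap` implements the population-genetics analysis chain for a panel of
microhaplotype (MH) markers: short (< ~300 bp) genomic segments containing
two or more SNPs, whose phased SNP combinations behave as multi-allelic
alleles.  This note records the models, the parameters that matter, the
numerical choices, and what the synthetic-data generator does and does not
establish.

## Statistics

**Effective number of alleles.**  For a frequency vector `p`,
`A_e = 1 / sum(p_i^2)` — the inverse of expected homozygosity, i.e. the
number of equally frequent alleles that would give the same heterozygosity.
Bounds `1 <= A_e <= k` are property-tested; the upper bound is attained
exactly at the uniform vector.

**Rosenberg informativeness for assignment.**  Over `K` populations with
per-population frequencies `p_ij` and mean `pbar_j`:

    I_n = sum_j [ -pbar_j ln pbar_j + (1/K) sum_i p_ij ln p_ij ]

in nats (natural log; `0 ln 0 := 0`).  `0 <= I_n <= ln K`, zero iff all
populations are identical.  Natural log is the convention under which the
packaged panel's values (0.117–0.883) were published.

**Random match probability (RMP).**  Per locus, the sum of squared
Hardy-Weinberg genotype frequencies (`p_i^2` and `2 p_i p_j`); across loci,
the product.  Both RMP and the most-common-genotype frequency are computed
from HWE expectations, not observed genotype counts: per-population samples
of tens of individuals make observed genotype frequencies unstable, and the
product rule is itself an HWE argument.  (A switch to observed counts would
be easy to add; HWE is the default and the tested mode.)  Accumulation is
in log10 space — panel-wide RMPs reach the 1e-115 scale and would underflow
a double.  Loci with no data in a population are skipped in that
population's product, with a warning.

**Mixture arithmetic.**  The minimum number of contributors at a locus with
`k` observed alleles is `ceil(k / 2)`; the panel-wide minimum is the
maximum over loci.

**Allele census.**  Distinct alleles are classed by their *maximum*
per-population frequency: "common" at >= 5% (inclusive) and "> 2%"
(strict), mirroring how such censuses are usually reported; a third class
counts alleles with dataset-wide copy count <= 2.  Copy counts are
reconstructed as `frequency x 2n` per cell, so the census requires a
frequency table derived from genotype counting.

## EM haplotype frequencies and phasing

Repository-extracted genotypes often arrive as unphased per-SNP diploid
calls.  Locus allele frequencies are then estimated by the classic gametic
EM algorithm: for an individual with `h` heterozygous SNPs there are
`2^(h-1)` compatible haplotype pairs; the E-step weights each pair by its
current HWE probability (`f_a f_b`, doubled for heterozygous pairs), the
M-step re-counts haplotypes.  The log-likelihood is asserted non-decreasing
at every iteration (an `AssertionError`, not a warning — a decrease is a
bug).

Choices:

* initialization is uniform over observed-compatible haplotypes; optional
  random Dirichlet restarts (`n_restarts`, seeded) guard against the rare
  non-global fixed point;
* convergence at log-likelihood increase < 1e-8, cap 1000 iterations
  (non-convergence is reported, not raised);
* individuals with missing SNP calls at a locus are excluded from that
  locus's EM (pairwise deletion) and re-emitted as missing;
* phase assignment takes the maximum-posterior pair; ties are broken
  lexicographically by haplotype string, deterministically, with a warning.
  Both max-posterior and EM (posterior-weighted) frequencies are available;
  downstream tables use the EM frequencies.

No coalescent or read-backed prior is used: MH loci are short enough that
within-locus recombination is negligible at these sample sizes, and
assay-derived data arrive pre-phased anyway.  On tiny instances (<= 3 SNPs,
<= 8 individuals) the EM optimum is tested to coincide (within 1e-6
log-likelihood) with exhaustive maximization over haplotype assignments.

## Sequencing QC

Amplicon-panel sequencing is monitored at three levels, all strict `<`
comparisons so boundary values pass:

| level | statistic | default threshold |
|---|---|---|
| sample | total reads per sample | < 150,000 flagged |
| amplicon | count of amplicons with reads > 0.2 x the sample's mean amplicon coverage | flagged below (across-sample mean − 2 population SD) |
| base | fraction of bases at >= 100x | < 0.75 flagged |

A sample is removed only if it fails **all three** levels (configurable to
"any" for stricter pipelines); samples flagged at one or two levels are
retained and listed.  The amplicon-uniformity mean/SD are computed across
the samples of one input table (one batch); at least 3 samples are required
for the SD to be meaningful.

The **dropout screen** removes genotypes consistent with allele dropout: a
genotype homozygous for an allele whose two copies in that single
individual are the allele's only occurrences dataset-wide is set to missing
(the sample is kept).  Two different individuals homozygous for the same
rare allele are *not* removed — corroboration defeats the dropout
explanation.

## Drift distances and trees

**Tau distance.**  Per locus,

    tau_l = sum_j (p1_j - p2_j)^2 / (2 sum_j pbar_j (1 - pbar_j))

with `pbar = (p1+p2)/2`; the distance is the equal-weight mean over loci
(per-locus normalization, not pooled).  The normalization constant is
pinned by a calibration property rather than by textual convention (factor
conventions differ across the literature): under pure Wright-Fisher drift
for `t` generations at effective size `N_e` on each branch,
`E[tau] ~ t/(2 N_e)`.  Two first-order biases — the exact per-generation
variance decay `1-(1-1/2N)^t < t/2N` and the drift-reduced expected
heterozygosity in the denominator — cancel to `O((t/2N)^2)`, and the
simulation tests verify the calibration at `t/(2N_e)` in {0.02, 0.05, 0.1}
within 3 SE over 20 replicates.  Loci fixed for the same allele in both
populations are 0/0 cases carrying no information and are excluded from the
mean (not counted as zero).  Distance matrices use pairwise-complete loci
per pair and record the per-pair locus count.

**Trees.**  Neighbor joining (Saitou-Nei) with a deterministic lowest-index
tie-break seeds the topology; branch lengths for any fixed topology are
then solved *exactly* by unweighted least squares on the path-length system
(one equation per leaf pair, 0/1 branch incidence), via `numpy.linalg.lstsq`
with a rank check (a rank-deficient system raises).  Negative fitted
branches are permitted, serialized as-is in Newick, and counted separately
for internal vs external edges — internal negative segments flag violations
of the pure-drift additive model (admixture, gene flow).  Topology space is
explored by nearest-neighbor interchange (NNI) around the NJ tree to a
configurable radius, deduplicated by canonical split sets, each candidate
refit by OLS and ranked by residual sum of squares; the report counts
candidates evaluated and candidates free of negative internal segments.
NNI is a stand-in for an unspecified "similar structures" search; on 5
taxa, radius >= 3 provably covers all 15 topologies and the ranking is
tested against exhaustive enumeration.  Fitch-Margoliash weighting is not
implemented; unweighted OLS is the tested mode.

**PCA.**  Populations are rows, all haplotype alleles across loci are
columns (absent alleles = 0), column-centered via scikit-learn's PCA;
coordinates and explained-variance fractions are reported.

## Synthetic data

The generator states a world with the structure the analyses assume:

* 6 biogeographic regions holding 16/15/24/14/7/3 populations (79 total);
* 90 loci with 3–30 alleles each, allele labels being distinct SNP-state
  strings (string length grows with allele count, >= 2 SNPs);
* ancestral per-locus frequencies drawn from a symmetric Dirichlet with
  concentration 0.5 (a skewed, realistic allele-frequency spectrum);
* region drift times `t/(2N_e)` spaced linearly 0.02 → 0.20 — spanning the
  observed range of human continental differentiation — plus 0.02 of
  population-private drift; `N_e = 500` keeps multinomial resampling cheap
  while leaving drift-time calibration intact (only the ratio `t/2N`
  matters to first order);
* Hardy-Weinberg genotypes (two independent draws per individual per
  locus), 50 diploid individuals per population by default;
* a negative-binomial coverage model (mean ~705k reads/sample, dispersion
  8, Dirichlet amplicon shares) with independently injected failure modes
  at roughly the empirical rates of a 384-sample assay run (2% low-reads,
  1% poor uniformity, 1.3% low base coverage), each labelled in a truth
  table.

Wright-Fisher multinomial drift is the default so the tau calibration is
directly testable; a Balding-Nichols Dirichlet mode is available as a
cheaper alternative.  The allele universe is fixed at simulation start —
alleles lost to drift keep zero-frequency columns so cross-population
comparisons stay aligned.  One global seed expands into per-stage child
seeds via `numpy.random.SeedSequence.spawn` in documented order; identical
config + seed reproduces outputs bit-for-bit.

What the generator does **not** emulate: mutation, within-locus
recombination, admixture/LD structure, genotyping error, or related
individuals.  A green test on synthetic data therefore establishes the
*arithmetic* of the pipeline (and its statistical calibration under drift),
not robustness to those real-data features.

## Packaged tables

The panel definition (90 loci: GRCh37 coordinates as printed, 1-based, no
liftover; molecular extents stored as given without interpreting whether
they span first-to-last SNP or the amplicon), the 79-population roster with
sample sizes and data sources, the sequencing-cohort accounting, and the
region-average A_e values for the six loci that rank in every region's top
20 are shipped as TSV fixtures with provenance header lines.  The roster's
ten finer world regions collapse onto the six biogeographic regions through
an explicit mapping file; one northeast-Indian population listed under East
Asia in the roster is assigned to South Central Asia by a per-population
override so the six-region population counts (16/15/24/14/7/3) match the
regional summary table.  Panel pruning retains loci with informativeness
*strictly above* the threshold, making "exclude I_n <= t" and the retained
set exact complements.

## Known limitations

* Coverage failure modes are injected independently, so samples failing
  all three QC levels at once (the removal condition) are vanishingly rare
  in synthetic data; in real runs a failed library fails the levels
  together.  The removal logic is therefore exercised by constructed
  fixtures, the flagging logic by simulation.
* EM phasing ignores genotyping error and cannot phase across loci.
* The NNI search is local; for strongly conflicting distance matrices the
  global least-squares topology may lie outside the explored radius.
* The census's copy-count class relies on `frequency x 2n` rounding and is
  exact only for tables produced by genotype counting.
* Ancestry-clustering (admixture MCMC) is exported to, never run: the
  two-row integer format is written alongside its allele-code mapping, and
  re-import is provided for round-trip verification only.
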