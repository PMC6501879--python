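# Methods

This note records the statistical model implemented by `mutspectra`, the
defaults and their rationale, what the synthetic-data generator does and
does not emulate, and the numerical and design choices made where more than
one reasonable convention exists.

## Mutation classes and folding

A polymorphism is described by its reference sequence context of odd width
k ∈ {3, 5, 7} and the alternate allele at the central position. Because
variant calls are unoriented with respect to strand, a class and its
reverse complement are the same object; the canonical representative is the
strand on which the central reference base is A or C. This convention can
never tie (the central base is a single nucleotide), and it matches the
labels conventional in the field (TCC→T, GAT→T, ...). The folded space
contains 96·16^((k−3)/2) classes: 96, 1,536 and 24,576 at k = 3, 5, 7, and
each 3-mer class has 16^((k−3)/2) expansions at width k (256 at k = 7).

Folding is idempotent and strand-symmetric; both properties are verified
exhaustively over all 4^k·3 raw (context, alt) pairs for every supported
width in the test suite.

## Context census

θ_m needs a denominator: the number of genomic sites whose folded context
equals class m's context. The census scans every position of the reference;
a position contributes iff it lies outside the exclusion mask (BED,
0-based half-open) and its k-window contains no non-ACGT character.
Soft-masked lowercase bases are uppercased — exclusion is governed solely by
the mask, mirroring the use of precomputed accessibility masks rather than
reference soft-masking. Positions on X-named sequences (`X`, `chrX`)
accumulate in a separate partition so X and autosomal rates can be
contrasted. The census is strand-symmetric by construction (verified by
censusing reverse-complemented genomes) and 7-mer counts marginalize to
3-mer counts away from sequence edges. The census is computed once against
the single reference; no per-population reference differences are modeled.

Internal coordinates are 0-based half-open throughout; VCF positions are
converted from 1-based on ingest.

## Private variant sets

Filters applied to variant calls, in any order (they commute):

* biallelic single-nucleotide variants only (indels, multiallelic sites and
  non-ACGT alleles removed);
* `FILTER` must be PASS;
* outside the exclusion mask;
* minor allele count across **all** samples ≥ 2 (default `mac_min = 2`;
  singletons are excluded because they are dominated by ultra-recent and
  artifact-prone variation);
* optionally, a per-population missingness ceiling (fraction of expected
  alleles absent; off by default, 0.2 reproduces the stricter whole-genome
  replication setting).

A variant is **private** to a continental group when its alternate allele
count is positive in that group and zero in the other groups; variants
observed in two or more groups are discarded. "Observed" is read as
alternate-allele presence (count > 0): the minor-allele-count filter is
global, not per-group. Continent-private variants are propagated to every
subpopulation of that continent in which the alternate allele is observed,
so a variant can join several subpopulation lists and the union of a
continent's subpopulation lists reproduces its private set exactly.

Each private variant is classified at k = 3, 5, 7 by folding the window
around its site; a width is left unclassified when its window crosses a
sequence edge or contains an N, so each width's count table carries its own
row totals. X-chromosome variants are retained for tallying and
X-enrichment but excluded from DAF analysis.

## Calibrated rates

With θ_m and Θ as defined in the README, μ_m = μ_total·θ_m/Θ, where
μ_total = 1.2×10⁻⁸ per generation per site is the genome-wide de novo
calibration constant. Θ and θ_m are computed at the analysis width (their
ratio is what matters; computing Θ per width keeps each width's table
self-contained, and the width used is recorded in the outputs). The
census-weighted sum Σ w_m μ_m, with w_m the census share of m's context,
equals μ_total identically — the suite asserts this to float precision.

95% confidence intervals use the Wald binomial standard error on θ_m with
Θ⁻¹ treated as a constant (its sampling variance is negligible at realistic
variant counts, and the interval is reported on the μ scale). Classes with
zero observed count get μ_m = 0 with a rule-of-three upper bound
(3/n_context on the θ scale) and are flagged. Relative rates divide each
population's μ_m by a reference population's (Africa in the usual display),
making the reference column exactly 1.

## Heterogeneity testing and the sequential correction

Each class is tested on a 2×P contingency table: focal-class counts per
population in one row, summed counts of all **other classes in the test
universe** in the second. The second row is other *variants*, not
non-polymorphic sites: the procedure compares polymorphism proportions
among private variants, and the sequential correction's restriction step is
only coherent on a variant-count universe. The Pearson statistic is used
with no continuity correction at any table size (documented because 2×2
software defaults differ). A class is testable when all expected cells are
≥ 5 (classical floor, configurable).

Because one profoundly heterogeneous class distorts every other class's
proportions, raw p-values are not independent. The sequential correction
(*P*_ordered) ranks testable classes by raw p-value; the least significant
class keeps its raw p, and the class at rank i is re-tested with the
"other" row restricted to the i−1 classes ranked below it. Raw-p ties are
broken by class lexicographic order (recorded in the output). Untestable
classes are excluded from the ranking and from every restricted universe.
Bonferroni thresholds divide α (default 0.05) by the number of *testable*
classes at that width — 0.05/96 ≈ 5.2×10⁻⁴ at k = 3 — and
Benjamini–Hochberg q-values are provided for FDR-style reporting. Pairwise
(two-population) analyses use the same machinery with df = 1 and rank
within the pairwise analysis itself.

## X-chromosome enrichment

Fewer polymorphic sites of any class are expected on X than on autosomes at
equal mutation rates (smaller effective population size and sample-ploidy
effects). The null for class m is p₀ = ξ·p_A, with p_A the autosomal
polymorphism probability of m (count over census of m's context) and ξ the
ratio of X to autosomal polymorphism probability over all classes *other
than m*, estimated at the same context width as the focal class and per
continental group. The focal class's counts are excluded from both ξ
numerators; the census denominators are the full per-partition totals,
since one class's context is a negligible share of the censused genome.
The test is a one-sided exact binomial upper tail on the observed X count
over n_X census sites; a Poisson mode (tail at n_X·p₀) is provided for
settings where only the expected count is available, and the two agree to
two significant figures whenever n_X ≥ 10⁴ and p₀ ≤ 10⁻³. Classes with
five or fewer observations on X are reported but not tested (threshold
configurable).

## DAF spectra

The derived allele is identified from the ancestral-allele annotation;
variants with missing or low-confidence (lowercase) calls, with an
ancestral allele matching neither REF nor ALT, or on the X chromosome are
excluded. DAF is the derived-allele frequency within the variant's private
population. Variants are binned at empirical 5% quantiles with duplicate
quantile values collapsed (DAF is discrete, so low-frequency quantiles
often coincide); quantiles use the inverse-CDF (type 1) definition for
platform-stable reproducibility. Bins are left-open/right-closed with the
lowest edge inclusive, so ties at an edge fall in the lower bin — the
convention is declared in the output metadata rather than inferred.
Enrichment of class m in a bin is its share of the bin divided by its
overall share; the bin-size-weighted mean over bins is exactly 1 for every
class, which the suite asserts on every run.

## Signature clustering

The signature of a class is its vector of μ_m across populations
(typically the 20 subpopulations). Each row is normalized to log2 fold
difference over its own mean — constant rows map to zero, and rescaling a
whole class leaves its normalized form unchanged — and rows containing a
zero rate are dropped with a warning. Classes are clustered with Euclidean
distance and complete linkage (the linkage is configurable; complete is the
default of the clustering routine family the analysis descends from, and
distance ties resolve by row-index order). The number of clusters at the
cut is a parameter rather than a fixed constant, because signature
boundaries are a visual judgement in published heatmaps. Dendrograms are
serialized as Newick with branch lengths from merge-height differences.

## Synthetic data

The generator produces exactly the statistical structure the pipeline
consumes, not a demographic simulation:

* an i.i.d. random genome with named autosomes and one X chromosome
  (default 4×1 Mb + 0.5 Mb X, uniform base composition);
* four continental groups with the 1000-Genomes-like subpopulation
  structure and sample sizes (504/503/504/489 individuals in 5
  subpopulations each), with per-group overall private polymorphism
  probabilities defaulting to the observed private-set sizes over the
  accessible genome (2.4×10⁻³, 4.1×10⁻⁴, 6.8×10⁻⁴, 6.9×10⁻⁴ for the
  African, European, East Asian and South Asian groups);
* per-class polymorphism probabilities θ_m (uniform by default, so
  θ_m = Θ/3 per context site), with planted fold enrichments per
  (class set, population);
* an X baseline scaled by ξ_true (default 0.6, within the range expected
  from the reduced effective population size of X);
* derived allele counts i drawn with P(i) ∝ 1/i on [2, 2N−2] — the neutral
  constant-size SFS restricted to the minor-allele-count filter — with
  optional per-class "pulses" multiplying the weight inside a DAF band;
* a small fraction of variants where the reference allele is derived
  (2%, exercising polarity flips) and of low-confidence ancestral calls
  (2%, exercising DAF exclusions).

Privacy is structural: each eligible site becomes a private variant of at
most one population, drawn multinomially per folded context. This validates
the counting and testing machinery; it deliberately does **not** reproduce
linkage disequilibrium, shared ancestral polymorphism, population-specific
allele-frequency spectra shaped by demography, sequencing error, or
reference bias. Passing tests therefore demonstrate the correctness of the
statistics on data satisfying their assumptions, not robustness to the
artifacts of real call sets.

All randomness derives from a single seed through named SHA-256-derived
substreams per stage, so any stage is reproducible in isolation.

## Problem sizes used in the test suite

Statistical acceptance checks run at the count level, drawing class counts
multinomially (the generator's `simulate_count_table`): null calibration
uses 20 replicates of 96 classes × 4 populations × 10⁵ variants;
planted-enrichment recovery uses a 1.5× fold at 5×10⁵ variants per
population; clustering recovery uses three groups of classes at 1.3× folds
across 20 subpopulations × 5×10⁴ variants in 20 replicates. Genome-level
end-to-end runs use ~0.5–3 Mb genomes (thousands of private variants per
group), which suffices for the exact invariants (conservation,
marginalization, weighted-mean-1) and for strong planted effects; desk-size
genomes cannot support the per-class counts of a 2.9 Gb call set, which is
why effect-size recovery at published scales is exercised on count-level
draws.

## Known limitations

* ξ is estimated at the focal class's width; with sparse X counts at k = 7
  the estimate pools few events and the binomial null inherits its noise.
* The Wald interval undercovers slightly for very small counts; the
  rule-of-three bound is a convention, not an exact interval.
* The sequential correction's p-values depend on the tie-break order when
  raw p-values tie exactly; the chosen lexicographic rule is deterministic
  but arbitrary.
* CpG classes can be excluded from the testing universe via the
  `exclude_classes` option, but no CpG-specific modeling is attempted.
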