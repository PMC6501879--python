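# mutspectra

Population-level analysis of human polymorphism spectra at 3-, 5- and 7-mer
sequence-context resolution.

## The problem

The relative frequencies of different single-nucleotide polymorphism types
are not uniform across human populations: certain C→T changes in specific
trinucleotide contexts are elevated in Europe and South Asia, other classes
are enriched in Asia or Africa, and some signals only emerge when two or
three flanking bases are considered. Detecting and characterizing these
"signatures" of mutation-rate variation requires a chain of careful
bookkeeping and statistics: extracting variants private to one continental
group, tallying them by reverse-complement-folded sequence context,
calibrating per-class mutation rates against the genomic availability of
each context, testing cross-population heterogeneity with a correction for
the non-independence of class proportions, clustering classes into shared
enrichment patterns, and probing X-chromosome enrichment and
derived-allele-frequency (DAF) spectra.

`mutspectra` implements that pipeline as a tested, reusable library with a
thin command-line interface, plus a synthetic-data generator with planted,
known parameters so that every stage can be validated end to end without
any external download.

## The model

A **mutation class** is a reference context of odd width k (3, 5 or 7) with
an alternate allele at the central position, identified with its reverse
complement (TCC→T ≡ GGA→A) and represented on the strand where the central
base is A or C. There are 96 folded classes at k=3, 1,536 at k=5 and 24,576
at k=7; each 3-mer class expands into 256 7-mer classes.

For a population, let θ_m be the proportion of genomic sites carrying class
m's context that are private polymorphisms of class m, and Θ the proportion
of all censused sites that are private polymorphisms of any class. The
calibrated private mutation rate per generation per site is

```
mu_m = mu_total * theta_m / Theta        (mu_total = 1.2e-8 by default)
```

so the census-weighted sum of μ_m over classes equals μ_total exactly.
Heterogeneity of a class across P populations is tested with a Pearson
chi-square on the 2×P table of focal-class versus all-other-class counts
(df = P−1), followed by the sequential *P*_ordered correction: classes are
ranked by raw p-value, the least significant keeps its raw p, and the i-th
least significant is re-tested against only the i−1 classes ranked below
it. X-chromosome enrichment is tested one-sidedly against the null
probability p0 = ξ·p_A, where ξ is the X/autosome polymorphism-probability
ratio over all other classes. DAF spectra report, per collapsed 5%-quantile
bin, each class's share of the bin relative to its overall share.

## Worked example

Simulate a small four-population study with a 2-fold enrichment of TCC→T
planted in the European group, then run the analysis:

```python
from mutspectra import (
    SimulationConfig, PlantedEnrichment, simulate_genome,
    simulate_private_variants, census, extract_private, filter_variants,
    tally, build_signature_matrix, relative_rates, test_all_classes,
)
from mutspectra.filtering import classify_all

config = SimulationConfig(
    seed=42,
    chrom_lengths={"chr1": 1_500_000, "chr2": 1_500_000, "chrX": 300_000},
    theta_total={"AFR": 2.4e-3, "EUR": 2.4e-3, "EAS": 2.4e-3, "SAS": 2.4e-3},
    planted_enrichments=(PlantedEnrichment(("TCC>T",), "EUR", 2.0),),
)
genome = simulate_genome(config)
records, truth = simulate_private_variants(genome, config)
filtered, stats = filter_variants(records)
private = extract_private(filtered, ["AFR", "EUR", "EAS", "SAS"],
                          config.subpop_to_continent())
classify_all(private, genome)

counts = tally(private, k=3)
result = test_all_classes(counts)
print(result.sort_values("p_ordered").head(3)[
    ["p_raw", "p_ordered", "rank", "bonferroni_pass"]])

rates = build_signature_matrix(counts, census(genome, k=3))
print(relative_rates(rates, "AFR").loc["TCC>T"].round(3))
```

This prints:

```
              p_raw     p_ordered  rank  bonferroni_pass
class
TCC>T  1.639876e-12  1.639876e-12  96.0             True
ACG>T  3.859075e-02  4.140884e-02  95.0            False
AAT>T  8.514986e-02  8.230553e-02  94.0            False

AFR    1.000
EUR    2.205
EAS    0.960
SAS    1.174
```

The planted class is the only one passing the Bonferroni threshold
(0.05/96 ≈ 5.2×10⁻⁴), it ranks most significant under *P*_ordered, and its
rate relative to the African reference is estimated at 2.2 against a
planted fold of 2.0 (≈7,700 private variants per population; the remaining
95 classes sit near relative rate 1). The same analysis is available from
the shell:

```
mutspectra -c config.yaml simulate
mutspectra -c config.yaml census
mutspectra -c config.yaml private
mutspectra -c config.yaml tally
mutspectra -c config.yaml test      # heterogeneity + P_ordered
mutspectra -c config.yaml rates
mutspectra -c config.yaml cluster
mutspectra -c config.yaml xenrich
mutspectra -c config.yaml daf
```

Every output TSV carries a header recording the config hash, seed and
package version; re-running a stage with identical inputs reproduces its
output byte for byte.

## Layout

| module | role |
| --- | --- |
| `mutspectra.context` | folding, class enumeration/expansion, context census |
| `mutspectra.filtering` | VCF ingest, filters, private sets, classification |
| `mutspectra.tally` | population × class count tables, marginalization |
| `mutspectra.rates` | calibrated rates, confidence intervals, relative rates |
| `mutspectra.heterogeneity` | chi-square homogeneity, *P*_ordered, Bonferroni/FDR |
| `mutspectra.clustering` | log2 mean-fold normalization, hierarchical clustering |
| `mutspectra.xenrichment` | ξ estimation, one-sided X-enrichment tests |
| `mutspectra.daf` | DAF computation, quantile binning, enrichment spectra |
| `mutspectra.simulate` | synthetic genomes/variants with planted parameters |
| `mutspectra.cli` | YAML-configured stage runner |

See `docs/methods.md` for the statistical model, parameter defaults and the
design decisions behind each stage.
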