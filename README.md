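# exsitu

Ex situ conservation genetics toolkit: quantify how well living collections
(botanic gardens, arboreta) capture the allelic diversity of wild
populations, from diploid co-dominant genotype data — microsatellites or
SNPs.

## What it does

- **Genotype I/O** (`exsitu.genotype_io`): read/write Genepop (2/3-digit),
  STRUCTURE (one- and two-row layouts), and VCF (GT-only, via cyvcf2);
  missing-data locus filters (R0/R80-style presence thresholds),
  first-variant-per-group reduction, shared-sample subsetting, exclusion
  lists, and a sample metadata table (`sample_id`, `origin`, `population`,
  `excluded`).
- **Representation** (`exsitu.representation`): wild allele frequencies
  with per-locus missing-aware denominators; overlapping frequency
  categories (very common >10%, common >5%, low frequency 1–10%,
  rare <1%, total >0%); percent of wild alleles observed at least once in
  garden samples, per category.
- **Resampling** (`exsitu.resampling`): Monte-Carlo capture curves over
  subsample sizes 2..N (nested permutation prefixes by default), the
  minimum number of wild samples reaching a capture threshold (default
  95%) with mean ± SD over replicates, and an exact hypergeometric
  expectation (`analytic_expected_capture`) used as an independent oracle.
- **Popgen summaries** (`exsitu.popgen`): allele counts, expected
  heterozygosity, rarefied allelic richness, and pairwise Nei FST among
  wild populations (ratio of locus-averages; sample-size and
  number-of-populations corrections available as flags).
- **Synthetic data** (`exsitu.simulate`): structured metapopulations with
  tunable differentiation (Dirichlet island model), microsatellite-like
  and SNP-like marker regimes, garden collections of copied wild founders,
  heterogeneous missingness, and private singleton artifact alleles with a
  truth table.

## Command line

```sh
# make a synthetic dataset (structure format + metadata + truth table)
exsitu simulate --populations 4 --per-population 25 --loci 1000 \
    --garden-size 30 --seed 1 --format structure --out sim/

# ex situ representation at two missing-data filter levels
exsitu represent --input sim/genotypes.str --format structure \
    --meta sim/metadata.tsv --r 0 --r 0.8 --out rep/

# minimum wild sample size for 95% of total wild allelic diversity
exsitu resample --input sim/genotypes.str --format structure \
    --meta sim/metadata.tsv --replicates 5000 --seed 1 \
    --threshold 0.95 --out res/

# allele count, allelic richness, He, mean pairwise wild FST
exsitu popgen --input sim/genotypes.str --format structure \
    --meta sim/metadata.tsv --out pg/

# joined report across labelled datasets
exsitu compare --dataset msat=sim_a/genotypes.str:structure \
    --dataset snp=sim_b/genotypes.str:structure \
    --meta sim_a/metadata.tsv --replicates 1000 --seed 1 --out cmp/
```

Each command writes delimited tables plus a `provenance.json` (config
echo, package version, seeds) so outputs are regenerable bit for bit.
Logging goes to stderr.

## Notes on conventions

- Half-called genotypes are collapsed to missing: every cell is an
  all-or-nothing observation of two gene copies.
- The missing-data filter keeps loci typed in **at least** `r * N`
  individuals (strict drop below); `--r 0` disables filtering.
- Frequency-category boundaries (p = 1% and 10% inclusivity) follow the
  declared convention above, are configurable via
  `representation.FrequencyCategory`, and are echoed in report headers.
- No Hardy–Weinberg or minor-allele-frequency filters are implemented —
  deliberately, since both bias rare-allele representation measures.
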