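# pikescan

Population-genomic analysis toolkit for diploid whole-genome resequencing
cohorts: a hard-filter cascade with per-step retention reporting, diversity
statistics (genotype tallies, observed heterozygosity, private alleles,
fixed differences, windowed Tajima's D, identity-by-state distances),
chromosome-window polymorphism scanning with Tukey outlier detection, a
from-scratch DAPC stack (PCA, BIC-driven k-means, LDA, loading-based marker
selection), and three complementary sex-linked-region detectors:

1. **sexkmer** — reference-free sex-specific canonical 31-mer filtering per
   population, mapped back to the genome and summarised in 10-kb windows
   (k-mers absent from the reference are first-class output: they flag
   male-only sequence);
2. **sexscan** — a hom-alt prefilter followed by an exact all-male-het /
   all-female-het genotype-pattern scan and a DAPC loading screen with sex
   as the group;
3. **sexdepth** — presence/absence genotyping from the target/control
   read-depth ratio (hemizygous carriers sit near 0.5).

A `synth` module generates complete test beds with planted truth: a
reference genome, a multi-population cohort VCF with a configurable
per-population heterozygosity gradient, population-private alleles, a
planted XY interval, a male-only insert contig, per-sample reads, and a
machine-readable truth file.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (printed-arithmetic
checks, planted-region recovery, brute-force oracles, and the end-to-end
demo); the rest are per-module unit and property tests.

## CLI

```sh
pikescan demo --out-dir out/ --seed 1            # simulate -> filter -> ... -> sexlink
pikescan simulate --out-dir sim/ --seed 1
pikescan filter --vcf in.vcf --out filtered.vcf --report report.tsv
pikescan diversity --vcf filtered.vcf --samples samples.tsv --out-prefix div
pikescan windows --vcf filtered.vcf --fai ref.fa.fai --width 1000000 --out win.tsv
pikescan dapc --vcf filtered.vcf --samples samples.tsv --n-pc 24 --n-df 3 --out-prefix dapc
pikescan sexkmer --fastq-dir reads/ --samples samples.tsv --population CHT \
    --target-sex male --reference ref.fa --out-prefix kmers
pikescan sexscan --vcf filtered.vcf --samples samples.tsv --out scan.tsv
pikescan sexdepth --depth depth.tsv --target male_insert --control chr1 --out calls.tsv
```

`pikescan demo` runs every stage on a freshly simulated cohort and writes
`summary.json` containing the filter retention table, per-population
diversity summary, the detected sex-linked interval next to the planted
truth, the sex-specific k-mer argmax window, and coverage-ratio calls.
Sample sheets are TSV with columns `sample`, `population`, `sex`; depth
tables are TSV with `sample`, `region`, `mean_depth`.

## Notes and limitations

- Genotypes are simulated site-independently: linkage-based methods are not
  supported on synthetic cohorts.
- Window hinges use the Tukey fivenum convention (not type-7 quantiles);
  the difference matters for small window counts.
- Missing genotypes are mean-imputed before PCA.
- The k-mer sum rule reads "more than 7" strictly (sum must be >= 8).
- k-mer-to-genome anchoring supports exact matching and a one-substitution
  mode (`max_mismatches=1`); the latter is needed to anchor variant-carrying
  k-mers near their genomic origin, mimicking a short-read aligner.
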