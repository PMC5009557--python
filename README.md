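# gbspop

A population-genomics toolkit for genotype-by-sequencing (GBS) data. GBS
genotypes hundreds of individuals at thousands of markers by sequencing a
reduced, restriction-digested representation of each genome; what comes out
of the variant caller is a sparse multi-sample genotype matrix that still
needs demultiplexing upstream and merging, filtering, statistics, imputation
and quality control downstream. `gbspop` implements those stages for plant
breeding populations — biparental F1 families, and inbred lines such as
MAGIC (multiparent advanced generation intercross) populations — together
with a simulator that generates all of its own test data.

## What it does

* **Demultiplexing** — split a barcoded Illumina lane FASTQ into per-sample
  files by exact longest-prefix barcode matching, trimming 3' adapter
  read-through at the first occurrence of a short tag (default `AGATCG`).
* **VCF handling** — read/write multi-sample VCF (GT/GQ/DP), merge
  per-sample files into a population matrix with allele-index remapping,
  and export to downstream formats: allele-count tables for distance-based
  dendrograms, outbred full-sib (CP) coded loci for genetic-map
  construction, and {-1, 0, 1} numeric matrices for genomic selection.
* **Filtering** — genotype-call filters (GQ, DP), sample selection, and
  site filters: individuals genotyped, MAF, regions, marker spacing,
  observed heterozygosity, GC content of the flanking reference window,
  removal of sites monomorphic for the alternate allele.
* **Statistics** — summary counts (biallelic SNPs / indels / other, MAF and
  genotyped-count distributions, per-sample tallies); per-site diversity
  (MAF, Ho, He, Hardy-Weinberg chi-square, per-subpopulation breakdown with
  F_ST = (H_T − H̄_S)/H_T); pairwise genotype differences between files to
  find duplicates and parent-offspring pairs.
* **Imputation** — the haploid haplotype-cluster HMM for populations of
  inbred lines: k latent ancestral clusters with per-marker weights α,
  emission frequencies θ and inter-marker switch intensities ρ
  (stay probability e^(−ρ)), fitted by EM, missing genotypes filled from
  forward-backward posteriors. VCF in, VCF out; observed calls never change.
* **Segregation QC** — classify F1-family SNPs into the four Mendelian
  categories AAxAA / AAxAa / AaxAa / AAxaa from population-level
  (Ho, MAF) — expectations (0, 0), (0.5, 0.25), (0.5, 0.5), (1, 0.5) —
  count category-rule violations as errors, sweep the counts across
  genotype-quality thresholds, audit MAGIC heterozygosity against the
  selfing halving law H₀·2^(−g), and screen family integrity via
  Mendelian-impossible homozygous differences.
* **Simulation** — F1 families, MAGIC populations with founder-mosaic
  ground truth, and barcoded lanes with exact assignment/trim truth.

## Worked example

Simulate a 137-offspring F1 family at 3000 SNPs with 1 % genotyping errors
and 10 % missing calls, then run the segregation quality sweep:

```sh
gbspop simulate f1 --out-prefix fam --n-offspring 137 --n-sites 3000 --seed 7
# simulated 139 samples x 3000 sites (3798 injected errors)

gbspop f1qc fam.observed.vcf --parents P1,P2 --out sweep.tsv \
       --q-values 0,20,40,60 --min-individuals 100
```

which prints:

```
 q  n_sites  sites_c1  sites_c2  sites_c3  sites_c4  calls_c2c3  errors_c2c3  calls_c4  false_hom_c4  errors_c1
 0     3000       730       766       739       765      188389          246     95650           993        907
20     3000       730       766       739       765      187850          178     95342           685        651
40     3000       730       766       739       765      186409           23     94622            74         73
60     2646       644       676       657       669      142618            1     71440           0            0
```

Read it as the sensitivity/specificity trade-off of a genotyping pipeline:
`calls_c2c3` counts genotype calls at the SNPs useful for genetic-map
construction (categories 2 and 3), `errors_c2c3` the segregation errors
among them, `false_hom_c4` the homozygous siblings at fully segregating
AAxaa sites, and `errors_c1` the minor-allele calls at sites that should be
monomorphic. Raising the minimum genotype quality q removes the simulated
errors (which carry low GQ) much faster than it removes genuine calls —
at q = 40 the error rate in map-useful calls has dropped from 246/188k to
23/186k while keeping 99 % of the calls, and by q = 60 sites start failing
the 100-individuals filter, trading sensitivity for near-perfect
specificity.

The same matrix can be filtered and exported, e.g.:

```sh
gbspop filter fam.observed.vcf --out filtered.vcf --min-gq 40 \
       --min-individuals-genotyped 100 --min-maf 0.05
gbspop convert filtered.vcf --format gs_numeric --out genotypes.tsv
```

For inbred-line imputation: `gbspop impute magic.vcf --out imputed.vcf
--k 8 --seed 1`.

## Layout

```
src/gbspop/
  vcfio.py       data model, VCF read/write, merge, format exports
  demux.py       barcode demultiplexing and adapter trimming
  filters.py     call / sample / site filters
  popstats.py    summary, diversity and pairwise-comparison statistics
  imputation.py  haploid haplotype-cluster HMM (EM fit, impute, concordance)
  f1_qc.py       segregation categories, error counting, MAGIC het audit
  simpop.py      F1 / MAGIC / lane simulators with ground truth
  cli.py         the `gbspop` command-line interface
```

See `docs/methods.md` for the models, assumptions, defaults and known
limitations.
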