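# Methods

This note describes the models and procedures implemented in `gbspop`, the
assumptions behind them, the defaults and why they were chosen, and what the
simulation-based tests do and do not establish about real data.

## Scope and data model

`gbspop` covers the population-genotyping stages of a genotype-by-sequencing
(GBS) workflow that sit on either side of read alignment and variant
calling: lane demultiplexing before alignment, and — once a variant caller
has produced per-sample VCFs — merging, filtering, summary and diversity
statistics, format conversion, imputation and segregation-based quality
control. Alignment and the variant caller itself are external to the
package.

The central container is `PopulationVCF`: an ordered sample list plus
variant records sorted by `(chromosome, position)`, each record carrying one
`GenotypeCall` per sample. Coordinates are 1-based inclusive as VCF
mandates. Genotypes are unphased (`0/1` ≡ `0|1`); of the FORMAT fields only
GT, GQ and DP are modelled, which is what every downstream operation here
consumes. INFO tags are carried as opaque string annotations (re-declared as
`Type=String` on write); typed INFO metadata beyond that is not preserved.
Merging per-sample files keys sites on `(chromosome, position)`, requires
reference alleles to agree, unions alternate-allele lists with allele-index
remapping, and fills absent calls with missing — so the merge of N
single-sample files splits from a joint matrix reproduces the matrix
exactly, which is the invariant the tests enforce.

## Demultiplexing

Barcode assignment is exact prefix matching with a longest-match tie-break;
no mismatch tolerance is attempted, trading a small loss of reads for
reproducibility and speed. After barcode removal, the read is truncated at
the first occurrence of a short adapter tag — by default `AGATCG`, the
leading 6-mer of the common Illumina adapter, which captures 3'
read-through in short-fragment GBS libraries. Qualities are truncated in
lockstep. Reads with no matching barcode, or empty after trimming, go to a
rejects file; the lane report satisfies `assigned + unassigned + discarded =
total` identically. Zero-length post-trim reads are discarded rather than
written (logged in the report as `discarded`), since empty records break
most downstream aligners.

## Filtering

Genotype-call filters mask calls below GQ or DP thresholds to missing
without touching the site list; a call lacking the field fails a positive
threshold on it. Site filters intersect independent criteria — individuals
genotyped, MAF bounds (over non-missing called alleles; an uncalled site
fails any MAF bound), BED-style keep/drop regions (read as 0-based
half-open, converted to 1-based inclusive internally), biallelic-SNP
restriction, observed-heterozygosity bounds, removal of sites monomorphic
for an alternate allele, GC content of a centred reference window (default
100 bp total, configurable — "the region surrounding the SNP" has no
canonical size), and annotation-tag whitelists. The one order-dependent
filter is minimum inter-marker distance, implemented as a greedy
left-to-right scan that keeps the first site of a close pair; this is
documented rather than hidden because no order-free definition exists.
Multiallelic MAF is the frequency of the second-most-frequent allele.

## Population statistics

Per site: MAF; observed heterozygosity Ho (heterozygous calls / called
genotypes — any call with two distinct allele indices counts, covering
multiallelics); expected heterozygosity He = 1 − Σpᵢ² (= 2p(1−p) when
biallelic); and a Hardy-Weinberg test. The HWE test is the classical
chi-square goodness of fit of (hom-ref, het, hom-alt) counts against
(p², 2pq, q²) with 1 degree of freedom and no continuity correction;
monomorphic sites return (0, 1). An exact test would behave better at low
expected counts and is left as future work; the chi-square choice keeps the
statistic hand-checkable and matches the convention of the tools this
package interoperates with. MAF and Ho here are the single implementation
used by the filters and the segregation QC, so thresholds always agree
across modules.

With a subpopulation map, per-group MAF/Ho/He are emitted plus a Nei-style
G_ST estimator, F_ST = (H_T − mean H_S)/H_T, with H_T from allele
frequencies pooled over the grouped samples and an unweighted group mean for
H_S; no sample-size correction (Weir–Cockerham is out of scope). Small
negative sampling values are clipped to 0 so the reported value respects
F_ST ∈ [0, 1]. Per-site F_IS = 1 − Ho/He is emitted as a convenience.

Pairwise comparison of two files (or one with itself) counts, per sample
pair over shared sites, co-called sites, genotype differences, and
homozygous differences (both calls homozygous and different) — the latter is
the family-integrity statistic, since a true offspring can never be
homozygous for an allele its parent lacks homozygously. Missing never
counts as a difference.

## Haplotype-cluster HMM imputation

Inbred lines are effectively homozygous, so each line is reduced to one
haploid allele per site (heterozygous calls are masked to missing; their
count is reported because it measures information loss). The model is the
haploid haplotype-cluster HMM in the fastPHASE tradition: `k` latent
ancestral clusters, per-marker cluster weights `alpha` on the simplex,
per-cluster per-marker alternate-allele emission frequencies `theta`, and
per-interval switch intensities `rho`. Crossing interval `m` the chain stays
with probability `exp(-rho[m])`, otherwise jumps to cluster `c'` with
probability proportional to `alpha[m+1, c']`; missing observations emit
probability 1.

Fitting is EM over all lines jointly. Treating the per-interval jump
indicator as part of the complete data gives closed-form M-step updates:
`theta` from posterior-weighted allele counts; `alpha[0]` from the first
marker's posteriors; `alpha[m+1]` from expected jump destinations; and
`rho[m] = -log(1 - expected jump fraction)`. Forward variables are scaled
per marker, so likelihoods stay representable for very long marker lists.
Defaults: `k = 8` (matching the number of founders in the multiparent
populations the module targets, and a common fastPHASE choice), `theta`
floored at 1e-3 away from {0, 1}, tolerance 1e-4 on relative log-likelihood
improvement, 50 iterations maximum, and an explicit seed required — the
initialisation perturbs per-site allele frequencies per cluster. The
log-likelihood trace is retained and is non-decreasing up to the (tiny)
effect of the floor/clip steps; tests assert monotonicity with a 1e-6
relative slack for exactly that reason.

Imputation runs forward-backward with the fitted model and assigns each
missing cell the allele with maximal posterior emission probability
`P(alt) = Σ_c gamma[c] · theta[c, m]`, written as a homozygous diploid
genotype with a GQ derived from the posterior and a per-site `NIMP`
annotation counting imputed cells. Observed calls are never modified;
heterozygous input calls are preserved untouched by default (they were
observed, just uninformative to the haploid model) and re-imputed only on
request. The module's primary correctness oracle is exhaustive enumeration
over all cluster paths on instances with ≤ 4 markers and k ≤ 3, which the
scaled recursion matches to ~1e-15; the `k = 1` likelihood also reduces to
the closed-form product of per-site allele frequencies, checked exactly.

## Segregation QC for F1 families

SNPs in a biparental full-sib F1 family fall in four categories by parental
genotype combination — 1) AAxAA, 2) AAxAa, 3) AaxAa, 4) AAxaa — with
infinite-population expectations (Ho, MAF) of (0, 0), (0.5, 0.25),
(0.5, 0.5) and (1, 0.5). Because parental calls can be missing or wrong,
sites are classified from the population-level statistics with tolerant
thresholds: Ho < 0.2 → C1; Ho > 0.8 → C4; otherwise C2 if MAF ≤ 0.37 else
C3 (boundaries inclusive exactly as written). Classification statistics
include the parents by default; this is configurable since the convention is
genuinely ambiguous, and at realistic family sizes (≥ 100 offspring) the
two parental genotypes shift nothing.

Errors are the calls incompatible with each category's expected
segregation: any minor-allele carrier in C1; minor-allele homozygotes among
offspring in C2 plus deviation of the parental pair from
{homozygous-major, heterozygous}; parental deviation from {het, het} in C3;
and in C4 heterozygous parents plus homozygous siblings. A homozygous-minor
parent in C2 satisfies both the sibling rule and the parental rule; it is
counted once (as a parental deviation), with offspring-rule counting
restricted to offspring. Parental checks require both parents called (C2)
or apply to whichever parents are called (C3, C4); with parents absent the
parental checks are skipped with a notice. The quality sweep masks calls
below each GQ threshold, re-applies the site filters (repeat regions,
monomorphic-alternate removal, minimum individuals genotyped — filtering
after thresholding, in that order), reclassifies and recounts, producing
the three sensitivity/error curves: map-useful calls (C2∪C3) vs errors
there, C4 calls vs false homozygotes, and map-useful calls vs errors at
monomorphic sites.

One caveat the tests make visible: classification is a noisy estimate near
its thresholds. At small family sizes a true AaxAa site can wander below
MAF 0.37 and be scored under C2 rules; this is inherent to
population-statistic classification, not an implementation artifact, and
vanishes as family size grows.

For MAGIC populations of inbred lines, random mating of eight founders
puts per-site heterozygosity in [0.25, 0.5], and each selfing generation
halves it exactly in expectation, so F5 lines (g = 4) should sit in
[0.0156, 0.0313] — the analytic band behind the conventional "1.5–3 %"
rule of thumb. `magic_het_assessment` reports the realized heterozygous
fraction against `H0 · 2^-g`, plus the count of SNPs with Ho above a
threshold (default 0.05) as a clustering diagnostic: errors spread across
sites, while repeat-driven false heterozygosity concentrates in few sites.

## Simulators

`simulate_f1` draws site categories from a configurable mix (default
uniform), samples offspring by Mendelian gamete draws, and derives an
observed matrix by flipping calls homozygous↔heterozygous at the error rate
(the dominant discordance mode between genotyping pipelines), masking calls
at the missing rate, and assigning GQ from a high-mean discrete normal for
correct calls (mean 70, sd 10) and a low-mean one for errors (mean 25,
sd 10), clipped to [1, 99] — so quality sweeps separate errors from signal
the way real caller output does. Defaults: 137 offspring (the scale of real
GBS mapping families), 3000 sites, 1 % errors, 10 % missing. Per-call error
and missing masks are returned as ground truth, and
`inject_rule_violations` plants category-rule violations that are countable
by construction, for exact-recovery tests.

`simulate_magic` builds each line through a randomized power-of-two crossing
funnel (pairwise crosses, then crosses of the hybrids), then `g` selfing
generations of single-seed descent, tracking founder-of-origin mosaics as
imputation ground truth. Founder alleles are i.i.d. Bernoulli(0.5) by
default, which makes the expected pre-selfing per-site heterozygosity
exactly 0.5. Crossovers fall independently per adjacent-site interval
(default 0.001 per meiosis, i.e. ~2 crossovers per 2000-site chromosome —
long linkage blocks, as in real inbred populations). Defaults: 8 founders,
200 lines, 2000 sites, g = 4, the same observation model as the F1
simulator.

`simulate_lane` writes a barcoded FASTQ in which a configurable fraction of
reads (default 0.35, the adapter-contamination level reported for
single-digest GBS libraries) carries the adapter tag at a random offset.
Read bodies are generated to exclude spurious tag occurrences and
barcode-prefix ambiguities, so per-read assignment and trim-point ground
truth are exact.

What the simulators do not emulate: sequence-level base errors and quality
profiles, restriction-site fragment sampling (coverage is uniform at the
genotype level), linkage in the F1 simulator (sites are independent), allele
dropout correlated with fragment length, and population structure beyond
the single family/funnel designs. Passing tests therefore demonstrate
correctness of the statistics, the EM machinery and the bookkeeping under a
clean generative model — not robustness to the full error structure of real
GBS libraries.

## Verification sizes and statistical tolerances

Property checks are sized so the whole suite runs in about a minute on one
core while keeping sampling noise far from thresholds: the zero-error /
exact-injection check runs at 300 offspring × 10,000 sites; the HMM oracle
covers every observation pattern for k ≤ 3, ≤ 4 markers at 1e-10 (measured
~1e-15); the masking experiment at the MAGIC defaults recovers ≥ 90 % of
20 % masked calls (measured 93–94 %; ~4 % of masked cells are heterozygous
and unrecoverable under the haploid model, which bounds the ceiling near
96 %). Binomial 3-standard-error tolerances are applied where cells are
independent; the selfing-decay check therefore simulates unlinked sites
(crossover probability 0.5), because with linked defaults the realized
heterozygous fraction fluctuates with within-line block correlation an
order of magnitude beyond the binomial scale — the halving law itself does
not involve linkage. Where many per-site checks run simultaneously
(law-of-large-numbers convergence of category expectations), the per-check
threshold is Bonferroni-widened to 4 standard errors to hold the familywise
false-alarm rate at the 3-sigma level.

## Known limitations

* BCF, tabix indexing and typed INFO passthrough are unsupported.
* The HWE test is asymptotic; low-count sites deserve an exact test.
* F-statistics are the uncorrected Nei G_ST; estimator bias at small group
  sizes is not corrected.
* The imputation model is strictly haploid: residual true heterozygosity is
  invisible to it, and imputed genotypes are always homozygous.
* The distance filter is order-defined; re-sorting the input changes which
  of two close markers survives.
* Barcode matching tolerates no sequencing errors in the barcode.
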