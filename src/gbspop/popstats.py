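"""Population statistics on genotype matrices.

Three families of statistics, mirroring what a genotype-by-sequencing
pipeline needs after the population VCF is assembled:

* summary statistics — variant-type counts, MAF and genotyped-count
  distributions, per-sample call tallies (:func:`summary`);
* per-site diversity — MAF, observed/expected heterozygosity,
  Hardy-Weinberg deviation, and, given a clustering of samples into
  subpopulations, per-group statistics plus F-statistics
  (:func:`diversity_table`);
* pairwise genotype comparison between two files (or one file with
  itself) to spot duplicated material and parent-offspring pairs
  (:func:`pairwise_differences`).

MAF and observed heterozygosity computed here are the single shared
implementation used by the filtering and segregation-QC modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .vcfio import PopulationVCF, VariantRecord

__all__ = [
    "SummaryStats",
    "diversity_table",
    "pairwise_differences",
    "site_expected_het",
    "site_hwe",
    "site_maf",
    "site_observed_het",
    "summary",
]


def _allele_counts(record: VariantRecord, indices=None) -> np.ndarray:
    counts = np.zeros(record.n_alleles, dtype=np.int64)
    calls = record.calls if indices is None else (record.calls[i] for i in indices)
    for call in calls:
        if call.alleles is not None:
            counts[call.alleles[0]] += 1
            counts[call.alleles[1]] += 1
    return counts


def _maf_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return math.nan
    freqs = np.sort(counts / total)[::-1]
    return float(freqs[1]) if len(freqs) > 1 else 0.0


def site_maf(record: VariantRecord, indices=None) -> float:
    """Minor allele frequency over non-missing called alleles.

    For biallelic sites this is ``min(p, 1-p)``; for multiallelic sites the
    frequency of the second-most-frequent allele. NaN when nothing is called.
    """
    return _maf_from_counts(_allele_counts(record, indices))


def site_observed_het(record: VariantRecord, indices=None) -> float:
    """Fraction of called genotypes that are heterozygous (NaN if none called)."""
    calls = record.calls if indices is None else [record.calls[i] for i in indices]
    n_called = 0
    n_het = 0
    for call in calls:
        if call.alleles is not None:
            n_called += 1
            if call.alleles[0] != call.alleles[1]:
                n_het += 1
    if n_called == 0:
        return math.nan
    return n_het / n_called


def site_expected_het(record: VariantRecord, indices=None) -> float:
    """Expected heterozygosity 1 - sum(p_i^2) from called allele frequencies
    (= 2p(1-p) for biallelic sites)."""
    counts = _allele_counts(record, indices)
    total = counts.sum()
    if total == 0:
        return math.nan
    p = counts / total
    return float(1.0 - np.sum(p * p))


def site_hwe(record: VariantRecord, indices=None) -> tuple[float, float]:
    """Chi-square goodness-of-fit test of Hardy-Weinberg proportions.

    Observed genotype counts (hom-ref, het, hom-alt) are compared with the
    ``(p^2, 2pq, q^2)`` expectations, 1 degree of freedom, no continuity
    correction. Biallelic sites only. Monomorphic sites return ``(0.0, 1.0)``.
    """
    if record.n_alleles != 2:
        raise ValueError("HWE test defined for biallelic sites only")
    calls = record.calls if indices is None else [record.calls[i] for i in indices]
    n = np.zeros(3, dtype=np.int64)  # hom-ref, het, hom-alt
    for call in calls:
        if call.alleles is not None:
            n[call.alleles[0] + call.alleles[1]] += 1
    total = n.sum()
    if total == 0:
        raise ValueError("no called genotypes")
    p = (2 * n[0] + n[1]) / (2 * total)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 0.0, 1.0
    expected = total * np.array([p * p, 2 * p * q, q * q])
    stat = float(np.sum((n - expected) ** 2 / expected))
    return stat, float(chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# diversity table with subpopulations
# ---------------------------------------------------------------------------


def diversity_table(
    pop: PopulationVCF, subpop_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-site diversity statistics, optionally broken down by subpopulation.

    ``subpop_map`` maps sample name -> group label; samples it does not cover
    are excluded from the per-group statistics (but still count in the
    overall columns). When at least two groups are present the table gains a
    Nei-style ``fst`` column, ``(H_T - mean H_S) / H_T`` with ``H_T`` computed
    from the allele frequencies pooled over all grouped samples (absent when
    ``H_T`` is 0), plus per-group ``maf_<g>`` / ``obs_het_<g>`` /
    ``exp_het_<g>`` columns. ``f_is = 1 - Ho/He`` is emitted as a convenience.
    """
    groups: dict[str, list[int]] = {}
    if subpop_map:
        for name, grp in subpop_map.items():
            groups.setdefault(grp, []).append(pop.sample_index(name))
    grouped = sorted(i for idx in groups.values() for i in idx)

    rows = []
    for rec in pop.records:
        ho = site_observed_het(rec)
        he = site_expected_het(rec)
        row = {
            "chrom": rec.chrom,
            "pos": rec.pos,
            "n_called": sum(1 for c in rec.calls if not c.is_missing),
            "maf": site_maf(rec),
            "obs_het": ho,
            "exp_het": he,
        }
        if rec.n_alleles == 2 and row["n_called"] > 0:
            stat, pval = site_hwe(rec)
            row["hwe_stat"], row["hwe_p"] = stat, pval
        else:
            row["hwe_stat"] = row["hwe_p"] = math.nan
        row["f_is"] = 1.0 - ho / he if he and he > 0 else math.nan
        if groups:
            hs = []
            for grp, idx in sorted(groups.items()):
                row[f"maf_{grp}"] = site_maf(rec, idx)
                g_ho = site_observed_het(rec, idx)
                g_he = site_expected_het(rec, idx)
                row[f"obs_het_{grp}"] = g_ho
                row[f"exp_het_{grp}"] = g_he
                if not math.isnan(g_he):
                    hs.append(g_he)
            ht = site_expected_het(rec, grouped)
            if len(hs) >= 2 and not math.isnan(ht) and ht > 0:
                row["fst"] = max(0.0, (ht - float(np.mean(hs))) / ht)
            else:
                row["fst"] = math.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pairwise comparison
# ---------------------------------------------------------------------------


@dataclass
class PairwiseDifferences:
    """Counts per sample pair over sites shared by the two inputs.

    ``differences`` counts sites where both calls are non-missing and the
    genotypes differ; ``comparisons`` counts co-called sites;
    ``hom_differences`` counts sites where both calls are homozygous and
    differ (the quantity used for family-integrity screening).
    """

    differences: pd.DataFrame
    comparisons: pd.DataFrame
    hom_differences: pd.DataFrame


def pairwise_differences(
    pop_a: PopulationVCF, pop_b: PopulationVCF | None = None
) -> PairwiseDifferences:
    """Compare genotype calls between every pair of samples of two matrices
    (or one matrix with itself), over the sites shared by both."""
    self_cmp = pop_b is None
    if self_cmp:
        pop_b = pop_a
    keys_b = {rec.key: rec for rec in pop_b.records}
    na, nb = pop_a.n_samples, pop_b.n_samples
    diff = np.zeros((na, nb), dtype=np.int64)
    comp = np.zeros((na, nb), dtype=np.int64)
    homdiff = np.zeros((na, nb), dtype=np.int64)
    for rec_a in pop_a.records:
        rec_b = keys_b.get(rec_a.key)
        if rec_b is None:
            continue
        # encode genotypes as comparable ids; remap b's allele indices
        # onto a's allele list so identical alleles compare equal
        remap = {0: 0}
        for i, alt in enumerate(rec_b.alts, start=1):
            remap[i] = rec_a.alts.index(alt) + 1 if alt in rec_a.alts else -i
        ga = _genotype_ids(rec_a.calls)
        gb = _genotype_ids(rec_b.calls, remap)
        hom_a = np.array([c.is_hom for c in rec_a.calls])
        hom_b = np.array([c.is_hom for c in rec_b.calls])
        called = (ga[:, None] >= 0) & (gb[None, :] >= 0)
        ne = ga[:, None] != gb[None, :]
        comp += called
        diff += called & ne
        homdiff += called & ne & hom_a[:, None] & hom_b[None, :]
    idx_a, idx_b = pop_a.samples, pop_b.samples
    return PairwiseDifferences(
        pd.DataFrame(diff, index=idx_a, columns=idx_b),
        pd.DataFrame(comp, index=idx_a, columns=idx_b),
        pd.DataFrame(homdiff, index=idx_a, columns=idx_b),
    )


def _genotype_ids(calls, remap=None) -> np.ndarray:
    out = np.empty(len(calls), dtype=np.int64)
    for i, call in enumerate(calls):
        if call.alleles is None:
            out[i] = -1
        else:
            a, b = call.alleles
            if remap is not None:
                a, b = remap[a], remap[b]
                if a < 0 or b < 0:  # allele absent from the other record
                    a, b = abs(a) + 1000, abs(b) + 1000
                if a > b:
                    a, b = b, a
            out[i] = a * 2048 + b
    return out


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


@dataclass
class SummaryStats:
    n_biallelic_snps: int
    n_biallelic_indels: int
    n_other_variants: int
    maf_histogram: pd.Series
    genotyped_count_histogram: pd.Series
    per_sample: pd.DataFrame = field(repr=False)

    @property
    def n_sites(self) -> int:
        return self.n_biallelic_snps + self.n_biallelic_indels + self.n_other_variants

    def to_text(self) -> str:
        lines = [
            f"biallelic_snps\t{self.n_biallelic_snps}",
            f"biallelic_indels\t{self.n_biallelic_indels}",
            f"other_variants\t{self.n_other_variants}",
            "",
            "# MAF distribution",
        ]
        lines += [f"{b}\t{c}" for b, c in self.maf_histogram.items()]
        lines += ["", "# sites by number of individuals genotyped"]
        lines += [f"{k}\t{c}" for k, c in self.genotyped_count_histogram.items()]
        lines += ["", "# per-sample counts"]
        lines.append(self.per_sample.to_csv(sep="\t").rstrip())
        return "\n".join(lines) + "\n"


def summary(pop: PopulationVCF, maf_bin_width: float = 0.05) -> SummaryStats:
    """Summary statistics: variant-type counts, MAF histogram, distribution of
    sites by number of individuals genotyped, and per-sample tallies of
    genotyped / non-reference / heterozygous calls."""
    type_counts = {"snp": 0, "indel": 0, "other": 0}
    mafs = []
    genotyped_counts = []
    n = pop.n_samples
    genotyped = np.zeros(n, dtype=np.int64)
    nonref = np.zeros(n, dtype=np.int64)
    het = np.zeros(n, dtype=np.int64)
    for rec in pop.records:
        type_counts[rec.variant_type] += 1
        maf = site_maf(rec)
        if not math.isnan(maf):
            mafs.append(maf)
        n_called = 0
        for j, call in enumerate(rec.calls):
            if call.alleles is None:
                continue
            n_called += 1
            genotyped[j] += 1
            if call.alleles != (0, 0):
                nonref[j] += 1
            if call.alleles[0] != call.alleles[1]:
                het[j] += 1
        genotyped_counts.append(n_called)

    n_bins = int(math.ceil(0.5 / maf_bin_width))
    edges = np.linspace(0.0, n_bins * maf_bin_width, n_bins + 1)
    hist, _ = np.histogram(mafs, bins=edges)
    maf_hist = pd.Series(
        hist,
        index=[f"[{edges[i]:.2f},{edges[i + 1]:.2f})" for i in range(n_bins)],
        name="n_sites",
    )
    gc_hist = (
        pd.Series(genotyped_counts, dtype=np.int64)
        .value_counts()
        .sort_index()
        .rename("n_sites")
    )
    per_sample = pd.DataFrame(
        {"genotyped": genotyped, "non_reference": nonref, "heterozygous": het},
        index=pd.Index(pop.samples, name="sample"),
    )
    return SummaryStats(
        type_counts["snp"],
        type_counts["indel"],
        type_counts["other"],
        maf_hist,
        gc_hist,
        per_sample,
    )
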