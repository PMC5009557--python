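"""Segregation-based quality assessment for F1 families and MAGIC lines.

A biparental F1 family gives Mendelian expectations strong enough to score a
genotyping pipeline without an external gold standard. Each SNP falls in one
of four categories set by the parental genotype combination — 1) AAxAA
(monomorphic), 2) AAxAa, 3) AaxAa, 4) AAxaa — with analytic
(observed-heterozygosity, minor-allele-frequency) expectations in an
infinite, perfectly genotyped population of (0, 0), (0.5, 0.25), (0.5, 0.5)
and (1, 0.5). Because parental calls may be missing or wrong, sites are
classified from the population-level (Ho, MAF) with tolerant thresholds
(:func:`classify_site`), and genotype calls incompatible with the expected
segregation of the class are counted as errors (:func:`count_category_errors`):

* category 1 sites should be monomorphic — any genotype carrying a minor
  allele (heterozygotes included) is an error;
* category 2 — minor-allele homozygotes among the offspring are errors, and
  the parents should be one homozygous-major and one heterozygous;
* category 3 — both parents should be heterozygous;
* category 4 — every sibling should be heterozygous, so homozygous siblings
  and heterozygous parents are errors.

:func:`quality_sweep` repeats the classification and counting across a grid
of minimum genotype-quality thresholds, yielding sensitivity (genotype calls
in the map-useful categories 2 and 3) against the three error measures.

For MAGIC populations of inbred lines the expectation is instead that
residual heterozygosity halves per selfing generation, so after ``g``
generations per-site heterozygosity should sit in ``H0 * 2**-g`` for the
initial range of ``H0``; :func:`magic_het_assessment` compares the realized
heterozygous fraction against that band. :func:`family_integrity` screens
for unrelated samples via Mendelian-impossible homozygous differences
against the parents.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filters import FilterConfig, filter_genotype_calls, filter_sites
from .popstats import site_maf, site_observed_het
from .vcfio import PopulationVCF, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CategoryReport",
    "classify_site",
    "count_category_errors",
    "family_integrity",
    "magic_het_assessment",
    "quality_sweep",
]

#: Analytic (Ho, MAF) expectations per category for an infinite population.
CATEGORY_EXPECTATIONS = {1: (0.0, 0.0), 2: (0.5, 0.25), 3: (0.5, 0.5), 4: (1.0, 0.5)}


def classify_site(ho: float, maf: float) -> int:
    """Segregation category (1-4) from observed heterozygosity and MAF.

    Thresholds (boundaries inclusive as stated): 1) Ho < 0.2;
    2) 0.2 <= Ho <= 0.8 and MAF <= 0.37; 3) 0.2 <= Ho <= 0.8 and MAF > 0.37;
    4) Ho > 0.8. The four classes partition [0, 1] x [0, 0.5].
    """
    if not (0.0 <= ho <= 1.0) or not (0.0 <= maf <= 0.5):
        raise ValueError(f"(Ho, MAF) out of range: ({ho}, {maf})")
    if ho < 0.2:
        return 1
    if ho > 0.8:
        return 4
    return 2 if maf <= 0.37 else 3


@dataclass
class CategoryReport:
    """Per-category site, call and segregation-error counts for one dataset."""

    table: pd.DataFrame  # index: category 1-4; columns: n_sites, n_calls, n_errors
    site_categories: pd.DataFrame = field(repr=False)  # chrom, pos, category

    def n_sites(self, *categories: int) -> int:
        return int(self.table.loc[list(categories), "n_sites"].sum())

    def n_calls(self, *categories: int) -> int:
        return int(self.table.loc[list(categories), "n_calls"].sum())

    def n_errors(self, *categories: int) -> int:
        return int(self.table.loc[list(categories), "n_errors"].sum())


def _call_classes(rec: VariantRecord) -> np.ndarray:
    """-1 missing, 0 hom-major, 1 het, 2 hom-minor (per-site minor allele)."""
    counts: dict[int, int] = {}
    for call in rec.calls:
        if call.alleles is not None:
            for a in call.alleles:
                counts[a] = counts.get(a, 0) + 1
    if not counts:
        return np.full(len(rec.calls), -1, dtype=np.int8)
    # major = most frequent allele; ties broken toward the reference
    major = max(counts, key=lambda a: (counts[a], a == 0))
    out = np.empty(len(rec.calls), dtype=np.int8)
    for j, call in enumerate(rec.calls):
        if call.alleles is None:
            out[j] = -1
        elif call.alleles[0] != call.alleles[1]:
            out[j] = 1
        else:
            out[j] = 0 if call.alleles[0] == major else 2
    return out


def count_category_errors(
    pop: PopulationVCF,
    parents: tuple[str, str],
    include_parents_in_stats: bool = True,
) -> CategoryReport:
    """Classify every site and count segregation errors per category.

    ``parents`` are the two parental sample names; when a parent is absent
    from the sample list the parental-expectation checks are skipped with a
    logged notice. By default the classification statistics (Ho, MAF) are
    computed over all genotyped samples, parents included.
    """
    parent_idx = []
    for name in parents:
        try:
            parent_idx.append(pop.sample_index(name))
        except KeyError:
            logger.warning("parent %s absent from samples; parental checks skipped", name)
    offspring_idx = np.array(
        [j for j in range(pop.n_samples) if j not in parent_idx], dtype=np.int64
    )
    stat_idx = None if include_parents_in_stats else list(offspring_idx)

    counts = {c: {"n_sites": 0, "n_calls": 0, "n_errors": 0} for c in (1, 2, 3, 4)}
    site_rows = []
    for rec in pop.records:
        ho = site_observed_het(rec, stat_idx)
        maf = site_maf(rec, stat_idx)
        if math.isnan(ho) or math.isnan(maf):
            continue
        category = classify_site(ho, maf)
        cls = _call_classes(rec)
        called = cls >= 0
        n_calls = int(called.sum())
        off = cls[offspring_idx]
        par = cls[parent_idx] if parent_idx else np.empty(0, dtype=np.int8)
        par_called = par[par >= 0]

        if category == 1:
            n_err = int(((cls == 1) | (cls == 2)).sum())
        elif category == 2:
            n_err = int((off == 2).sum())
            if len(par_called) == 2:
                n_err += _pair_deviation(par_called, expected=(0, 1))
        elif category == 3:
            n_err = int((par_called != 1).sum())
        else:  # category 4
            n_err = int((par_called == 1).sum())
            n_err += int(((off == 0) | (off == 2)).sum())

        counts[category]["n_sites"] += 1
        counts[category]["n_calls"] += n_calls
        counts[category]["n_errors"] += n_err
        site_rows.append(
            {"chrom": rec.chrom, "pos": rec.pos, "category": category,
             "obs_het": ho, "maf": maf, "n_errors": n_err}
        )

    table = pd.DataFrame.from_dict(counts, orient="index")
    table.index.name = "category"
    return CategoryReport(table, pd.DataFrame(site_rows))


def _pair_deviation(pair: np.ndarray, expected: tuple[int, int]) -> int:
    """Minimal number of parents deviating from the expected unordered pair."""
    a, b = expected
    direct = int(pair[0] != a) + int(pair[1] != b)
    swapped = int(pair[0] != b) + int(pair[1] != a)
    return min(direct, swapped)


def quality_sweep(
    pop: PopulationVCF,
    q_values,
    parents: tuple[str, str],
    min_individuals: int = 0,
    repeats=None,
    drop_monomorphic_alt: bool = True,
    include_parents_in_stats: bool = True,
) -> pd.DataFrame:
    """Genotype-quality sweep: one classification/error report per threshold.

    For each ``q``, genotype calls below the threshold are masked, the site
    filters are re-applied (repeat regions, monomorphic-for-the-alternate
    removal, minimum individuals genotyped), sites are reclassified and
    errors recounted. The returned table carries, per ``q``, the three
    sensitivity/error pairings used to benchmark pipelines: map-useful calls
    (categories 2+3) vs errors there, category-4 calls vs false homozygotes
    there, and map-useful calls vs errors at monomorphic (category 1) sites.
    """
    cfg = FilterConfig(
        min_individuals_genotyped=min_individuals,
        drop_monomorphic_alt=drop_monomorphic_alt,
    )
    rows = []
    for q in q_values:
        filtered = filter_genotype_calls(pop, min_gq=int(q))
        filtered = filter_sites(filtered, cfg, repeats=repeats)
        report = count_category_errors(
            filtered, parents, include_parents_in_stats=include_parents_in_stats
        )
        rows.append(
            {
                "q": int(q),
                "n_sites": report.n_sites(1, 2, 3, 4),
                "sites_c1": report.n_sites(1),
                "sites_c2": report.n_sites(2),
                "sites_c3": report.n_sites(3),
                "sites_c4": report.n_sites(4),
                "calls_c2c3": report.n_calls(2, 3),
                "errors_c2c3": report.n_errors(2, 3),
                "calls_c4": report.n_calls(4),
                "false_hom_c4": report.n_errors(4),
                "errors_c1": report.n_errors(1),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MAGIC heterozygosity assessment
# ---------------------------------------------------------------------------


@dataclass
class MagicHetReport:
    """Heterozygosity audit of a genotyped population of inbred lines."""

    n_calls: int
    n_het_calls: int
    n_snps: int
    n_snps_high_het: int  # observed heterozygosity above the threshold
    het_threshold: float
    expected_band: tuple[float, float]  # analytic H0 * 2**-g range
    ho_distribution: pd.Series = field(repr=False)

    @property
    def het_fraction(self) -> float:
        return self.n_het_calls / self.n_calls if self.n_calls else math.nan

    @property
    def in_expected_band(self) -> bool:
        lo, hi = self.expected_band
        return lo <= self.het_fraction <= hi


def magic_het_assessment(
    pop: PopulationVCF,
    selfing_generations: int,
    initial_het_range: tuple[float, float] = (0.25, 0.5),
    ho_threshold: float = 0.05,
) -> MagicHetReport:
    """Compare realized heterozygosity against the selfing-decay expectation.

    With random mating of the founders the per-site heterozygous fraction
    starts in ``initial_het_range`` (25-50 % for eight founders) and halves
    each selfing generation, so after ``g`` generations it should lie in
    ``[lo, hi] * 2**-g``. Genotype calls outside that band are the prime
    suspects for genotyping errors. Also reports how many SNPs have observed
    heterozygosity above ``ho_threshold`` (clustering diagnostic).
    """
    if selfing_generations < 0:
        raise ValueError("selfing_generations must be >= 0")
    decay = 2.0 ** (-selfing_generations)
    band = (initial_het_range[0] * decay, initial_het_range[1] * decay)
    n_calls = 0
    n_het = 0
    n_high = 0
    hos = []
    for rec in pop.records:
        rec_called = 0
        rec_het = 0
        for call in rec.calls:
            if call.alleles is None:
                continue
            rec_called += 1
            if call.alleles[0] != call.alleles[1]:
                rec_het += 1
        n_calls += rec_called
        n_het += rec_het
        if rec_called:
            ho = rec_het / rec_called
            hos.append(ho)
            if ho > ho_threshold:
                n_high += 1
    return MagicHetReport(
        n_calls=n_calls,
        n_het_calls=n_het,
        n_snps=pop.n_sites,
        n_snps_high_het=n_high,
        het_threshold=ho_threshold,
        expected_band=band,
        ho_distribution=pd.Series(hos, name="obs_het"),
    )


# ---------------------------------------------------------------------------
# family integrity
# ---------------------------------------------------------------------------


def family_integrity(
    pop: PopulationVCF,
    parents: tuple[str, str],
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Flag offspring that cannot descend from the designated parents.

    For each offspring and each parent, over sites where both calls are
    homozygous, count the fraction where the genotypes differ — a true
    offspring must carry one allele of each parent at every site, so such
    homozygous differences are Mendelian-impossible and should only appear
    at the genotyping-error rate. Offspring whose worse fraction exceeds
    ``threshold`` are flagged unrelated.
    """
    idx = [pop.sample_index(p) for p in parents]
    rows = []
    fractions = {}
    for pi, pname in zip(idx, parents):
        counts = np.zeros(pop.n_samples, dtype=np.int64)
        diffs = np.zeros(pop.n_samples, dtype=np.int64)
        for rec in pop.records:
            pcall = rec.calls[pi]
            if pcall.alleles is None or pcall.alleles[0] != pcall.alleles[1]:
                continue
            pallele = pcall.alleles[0]
            for j, call in enumerate(rec.calls):
                if call.alleles is None or call.alleles[0] != call.alleles[1]:
                    continue
                counts[j] += 1
                if call.alleles[0] != pallele:
                    diffs[j] += 1
        with np.errstate(invalid="ignore"):
            fractions[pname] = np.where(counts > 0, diffs / np.maximum(counts, 1), np.nan)
        fractions[pname + "_n"] = counts
    for j, name in enumerate(pop.samples):
        if j in idx:
            continue
        f1 = fractions[parents[0]][j]
        f2 = fractions[parents[1]][j]
        finite = [v for v in (f1, f2) if not math.isnan(v)]
        worst = max(finite) if finite else math.nan
        rows.append(
            {
                "sample": name,
                f"hom_diff_{parents[0]}": f1,
                f"hom_diff_{parents[1]}": f2,
                "n_compared_p1": int(fractions[parents[0] + "_n"][j]),
                "n_compared_p2": int(fractions[parents[1] + "_n"][j]),
                "max_hom_diff": worst,
                "flagged_unrelated": bool(worst > threshold),
            }
        )
    return pd.DataFrame(rows)
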