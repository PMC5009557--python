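"""Layered filtering of population genotype matrices.

Three levels of filtering, applied in whichever order the analysis needs:

* genotype-call level — mask individual calls below a genotype-quality or
  read-depth threshold (:func:`filter_genotype_calls`);
* sample level — keep or drop named samples (:func:`select_samples`);
* site level — keep sites passing all enabled criteria: individuals
  genotyped, MAF bounds, genomic regions, biallelic-SNP restriction,
  observed-heterozygosity bounds, inter-marker distance, GC content of the
  surrounding reference window, monomorphic-for-the-alternate removal and
  annotation tags (:func:`filter_sites`).

Filters never add sites, samples or calls, and are idempotent at a fixed
configuration. All site criteria are pure set intersections except the
inter-marker distance rule, which is a greedy left-to-right scan (the first
site of a close pair is kept).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .popstats import site_maf, site_observed_het
from .vcfio import MISSING, GenotypeCall, PopulationVCF, VariantRecord

__all__ = [
    "FilterConfig",
    "filter_genotype_calls",
    "filter_sites",
    "read_bed_regions",
    "select_samples",
]


@dataclass
class FilterConfig:
    """Site-filter thresholds. Defaults are fully permissive (identity).

    ``min_maf``/``max_maf`` are applied over non-missing called alleles; a
    site with zero called alleles fails any MAF bound. ``keep_regions`` and
    ``drop_regions`` are 1-based inclusive ``(chrom, start, end)`` intervals
    (use :func:`read_bed_regions` to convert BED input). ``gc_window`` is the
    total length of the reference window centred on the site (the variant
    base included) used for the GC-content bounds.
    """

    min_individuals_genotyped: int = 0
    min_maf: float = 0.0
    max_maf: float = 0.5
    min_distance_bp: int = 0
    keep_regions: Sequence[tuple[str, int, int]] | None = None
    drop_regions: Sequence[tuple[str, int, int]] | None = None
    biallelic_snps_only: bool = False
    drop_monomorphic_alt: bool = False
    min_observed_het: float = 0.0
    max_observed_het: float = 1.0
    gc_window: int = 100
    min_gc: float | None = None
    max_gc: float | None = None
    annotation_whitelist: Sequence[str] | None = None

    def __post_init__(self):
        if not (0.0 <= self.min_maf <= self.max_maf <= 0.5):
            raise ValueError("require 0 <= min_maf <= max_maf <= 0.5")
        for bound in (self.min_gc, self.max_gc):
            if bound is not None and not (0.0 <= bound <= 1.0):
                raise ValueError("GC bounds must lie in [0, 1]")
        for regions in (self.keep_regions, self.drop_regions):
            for chrom, start, end in regions or ():
                if start > end:
                    raise ValueError(f"malformed interval {chrom}:{start}-{end}")


def read_bed_regions(path) -> list[tuple[str, int, int]]:
    """Read a 3+ column BED file (0-based half-open) into the 1-based
    inclusive intervals used internally."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            regions.append((chrom, start + 1, end))
    return regions


def _region_trees(regions: Iterable[tuple[str, int, int]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in regions:
        trees.setdefault(chrom, IntervalTree()).addi(start, end + 1)
    return trees


def _in_regions(trees: dict[str, IntervalTree], chrom: str, pos: int) -> bool:
    tree = trees.get(chrom)
    return bool(tree is not None and tree.overlaps_point(pos))


def filter_genotype_calls(
    pop: PopulationVCF, min_gq: int = 0, min_dp: int = 0
) -> PopulationVCF:
    """Mask calls with GQ < ``min_gq`` or DP < ``min_dp`` to missing.

    A call without a GQ (resp. DP) value fails a positive threshold on that
    field. Sites and samples are unchanged in number.
    """
    records = []
    for rec in pop.records:
        calls = []
        changed = False
        for call in rec.calls:
            if call.is_missing:
                calls.append(call)
                continue
            gq_fail = min_gq > 0 and (call.gq is None or call.gq < min_gq)
            dp_fail = min_dp > 0 and (call.dp is None or call.dp < min_dp)
            if gq_fail or dp_fail:
                calls.append(MISSING)
                changed = True
            else:
                calls.append(call)
        records.append(rec.copy(calls=calls) if changed else rec)
    return PopulationVCF(list(pop.samples), records)


def select_samples(
    pop: PopulationVCF,
    keep: Sequence[str] | None = None,
    drop: Sequence[str] | None = None,
) -> PopulationVCF:
    """Restrict the matrix to a subset of samples (sites are retained;
    re-apply site filters separately if thresholds should reflect the subset)."""
    if keep is not None and drop is not None:
        raise ValueError("give either keep or drop, not both")
    for name in list(keep or []) + list(drop or []):
        pop.sample_index(name)  # raises KeyError on unknown samples
    if keep is not None:
        idx = [pop.sample_index(n) for n in keep]
    else:
        dropset = set(drop or [])
        idx = [j for j, n in enumerate(pop.samples) if n not in dropset]
    samples = [pop.samples[j] for j in idx]
    records = [rec.copy(calls=[rec.calls[j] for j in idx]) for rec in pop.records]
    return PopulationVCF(samples, records)


def _gc_fraction(reference, chrom: str, pos: int, window: int) -> float:
    half = window // 2
    seq = str(reference[chrom][max(0, pos - 1 - half) : pos - 1 - half + window])
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def filter_sites(
    pop: PopulationVCF,
    cfg: FilterConfig,
    repeats: Sequence[tuple[str, int, int]] | None = None,
    reference=None,
) -> PopulationVCF:
    """Retain sites passing every enabled criterion of ``cfg``.

    ``repeats`` is an extra drop-region list (typically repeat-masked
    regions); ``reference`` is a ``pyfaidx.Fasta``-like mapping required when
    GC bounds are set.
    """
    if (cfg.min_gc is not None or cfg.max_gc is not None) and reference is None:
        raise ValueError("GC-content filtering requires a reference sequence")
    drop_trees = _region_trees(list(cfg.drop_regions or []) + list(repeats or []))
    keep_trees = _region_trees(cfg.keep_regions) if cfg.keep_regions else None
    whitelist = set(cfg.annotation_whitelist) if cfg.annotation_whitelist else None

    kept: list[VariantRecord] = []
    last_kept: dict[str, int] = {}
    for rec in pop.records:
        if cfg.biallelic_snps_only and not rec.is_biallelic_snp:
            continue
        if keep_trees is not None and not _in_regions(keep_trees, rec.chrom, rec.pos):
            continue
        if _in_regions(drop_trees, rec.chrom, rec.pos):
            continue
        if whitelist is not None and not (whitelist & rec.annotations.keys()):
            continue
        n_genotyped = sum(1 for c in rec.calls if not c.is_missing)
        if n_genotyped < cfg.min_individuals_genotyped:
            continue
        if cfg.min_maf > 0.0 or cfg.max_maf < 0.5:
            maf = site_maf(rec)
            if not (cfg.min_maf <= maf <= cfg.max_maf):  # NaN fails both
                continue
        if cfg.drop_monomorphic_alt and _monomorphic_alt(rec):
            continue
        if cfg.min_observed_het > 0.0 or cfg.max_observed_het < 1.0:
            ho = site_observed_het(rec)
            if not (cfg.min_observed_het <= ho <= cfg.max_observed_het):
                continue
        if cfg.min_gc is not None or cfg.max_gc is not None:
            gc = _gc_fraction(reference, rec.chrom, rec.pos, cfg.gc_window)
            if cfg.min_gc is not None and not gc >= cfg.min_gc:
                continue
            if cfg.max_gc is not None and not gc <= cfg.max_gc:
                continue
        if cfg.min_distance_bp > 0:
            prev = last_kept.get(rec.chrom)
            if prev is not None and rec.pos - prev < cfg.min_distance_bp:
                continue
        last_kept[rec.chrom] = rec.pos
        kept.append(rec)
    return PopulationVCF(list(pop.samples), kept)


def _monomorphic_alt(rec: VariantRecord) -> bool:
    """True when every called genotype is homozygous for one alternate allele."""
    seen = set()
    for call in rec.calls:
        if call.alleles is None:
            continue
        if call.alleles[0] != call.alleles[1]:
            return False
        seen.add(call.alleles[0])
        if len(seen) > 1:
            return False
    return bool(seen) and 0 not in seen
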