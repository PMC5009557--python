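"""Multi-sample genotype data model and VCF input/output.

The central container is :class:`PopulationVCF`: an ordered list of samples
plus variant records sorted by genomic coordinate. Per-sample VCF files
produced by a genotyper can be merged into a single population matrix with
:func:`merge_population`, and the matrix can be exported to the input formats
of common downstream tools (distance-based dendrograms, genetic-map
construction with outbred full-sib coding, numeric matrices for genomic
selection) with :func:`export_matrix`.

Coordinates are 1-based inclusive throughout, as VCF mandates. Genotypes are
unphased: ``0/1`` and ``0|1`` are the same call. Only the GT, GQ and DP
FORMAT fields are retained; INFO tags are carried as opaque annotations.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeCall",
    "MISSING",
    "PopulationVCF",
    "VariantRecord",
    "VcfFormatError",
    "export_matrix",
    "merge_population",
    "read_vcf",
    "write_vcf",
]


class VcfFormatError(ValueError):
    """Raised for malformed VCF input or an invalid in-memory model."""


# shared allele-pair tuples so large matrices mostly pay one object per call
_PAIR_CACHE = {(i, j): (i, j) for i in range(4) for j in range(4) if i <= j}


class GenotypeCall:
    """One sample's genotype at one site.

    ``alleles`` is an ordered pair of allele indices into the owning record's
    allele list (0 = reference), or ``None`` for a missing call. Phase is not
    retained; the pair is stored sorted. ``gq`` is the phred-scaled genotype
    quality and ``dp`` the read depth; either may be absent (``None``).
    """

    __slots__ = ("alleles", "gq", "dp")

    def __init__(self, alleles=None, gq=None, dp=None):
        if alleles is not None:
            a, b = alleles
            if a > b:
                a, b = b, a
            alleles = _PAIR_CACHE.get((a, b), (a, b))
        if gq is not None and gq < 0:
            raise VcfFormatError(f"negative GQ {gq}")
        self.alleles = alleles
        self.gq = gq
        self.dp = dp

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def is_het(self) -> bool:
        return self.alleles is not None and self.alleles[0] != self.alleles[1]

    @property
    def is_hom(self) -> bool:
        return self.alleles is not None and self.alleles[0] == self.alleles[1]

    def __eq__(self, other):
        return (
            isinstance(other, GenotypeCall)
            and self.alleles == other.alleles
            and self.gq == other.gq
            and self.dp == other.dp
        )

    def __hash__(self):
        return hash((self.alleles, self.gq, self.dp))

    def __repr__(self):
        gt = "./." if self.alleles is None else "/".join(map(str, self.alleles))
        return f"GenotypeCall({gt}, gq={self.gq}, dp={self.dp})"


#: Convenience missing call (no alleles, no quality, no depth).
MISSING = GenotypeCall()


@dataclass
class VariantRecord:
    """A variant site with one genotype call per sample of the owning matrix."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    calls: list[GenotypeCall]
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        self.alts = tuple(self.alts)
        for alt in self.alts:
            if not alt or alt == self.ref:
                raise VcfFormatError(
                    f"invalid alternate allele {alt!r} at {self.chrom}:{self.pos}"
                )
        n_alleles = 1 + len(self.alts)
        for call in self.calls:
            if call.alleles is not None and call.alleles[1] >= n_alleles:
                raise VcfFormatError(
                    f"allele index {call.alleles[1]} out of range at "
                    f"{self.chrom}:{self.pos}"
                )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.ref)

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)

    @property
    def variant_type(self) -> str:
        """``"snp"`` / ``"indel"`` for biallelic sites, else ``"other"``."""
        if len(self.alts) != 1:
            return "other"
        if len(self.ref) == 1 and len(self.alts[0]) == 1:
            return "snp"
        return "indel"

    @property
    def is_biallelic_snp(self) -> bool:
        return self.variant_type == "snp"

    def copy(self, calls: list[GenotypeCall] | None = None) -> "VariantRecord":
        return VariantRecord(
            self.chrom,
            self.pos,
            self.ref,
            self.alts,
            list(self.calls) if calls is None else calls,
            dict(self.annotations),
        )


def _chrom_sort_key(chrom: str):
    # natural order: "chr2" before "chr10"; tag parts so mixed numeric and
    # alphabetic names stay comparable
    return tuple(
        (0, int(part), "") if part.isdigit() else (1, 0, part)
        for part in re.split(r"(\d+)", chrom)
        if part
    )


@dataclass
class PopulationVCF:
    """Ordered samples x sorted variant records: the population genotype matrix."""

    samples: list[str]
    records: list[VariantRecord]

    def __post_init__(self):
        if len(set(self.samples)) != len(self.samples):
            raise VcfFormatError("duplicate sample identifiers")
        n = len(self.samples)
        for rec in self.records:
            if len(rec.calls) != n:
                raise VcfFormatError(
                    f"record {rec.chrom}:{rec.pos} has {len(rec.calls)} calls "
                    f"for {n} samples"
                )
        self.sort()

    def sort(self) -> None:
        self.records.sort(key=lambda r: (_chrom_sort_key(r.chrom), r.pos))

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.records)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"unknown sample {name!r}") from None

    def __eq__(self, other):
        if not isinstance(other, PopulationVCF):
            return NotImplemented
        if self.samples != other.samples or len(self.records) != len(other.records):
            return False
        for a, b in zip(self.records, other.records):
            if (a.key, a.alts, a.calls) != (b.key, b.alts, b.calls):
                return False
        return True


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------


def read_vcf(path) -> PopulationVCF:
    """Read a VCF 4.x file with GT (and optionally GQ/DP) into memory.

    Missing genotypes (``./.`` or ``.``) become :data:`MISSING`; sort order is
    established if the file is unsorted.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfFormatError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        if "GT" not in vf.header.formats:
            raise VcfFormatError(f"{path}: no GT field declared in header")
        samples = list(vf.header.samples)
        records = []
        for rec in vf:
            alts = tuple(a for a in (rec.alts or ()) if a not in (None, "."))
            calls = []
            for name in samples:
                sample = rec.samples[name]
                gt = sample.get("GT")
                if gt is None or any(a is None for a in gt) or len(gt) == 0:
                    alleles = None
                elif len(gt) == 1:  # haploid call: promote to homozygous diploid
                    alleles = (gt[0], gt[0])
                else:
                    alleles = tuple(gt)
                gq = sample.get("GQ")
                dp = sample.get("DP")
                calls.append(
                    GenotypeCall(
                        alleles,
                        int(gq) if gq is not None else None,
                        int(dp) if dp is not None else None,
                    )
                )
            annotations = {}
            for k, v in rec.info.items():
                if isinstance(v, tuple):
                    v = ",".join(str(x) for x in v)
                annotations[k] = True if v is True else str(v)
            records.append(
                VariantRecord(rec.chrom, rec.pos, rec.ref, alts, calls, annotations)
            )
    return PopulationVCF(samples, records)


def write_vcf(pop: PopulationVCF, path) -> None:
    """Write ``pop`` as an uncompressed VCF 4.2 file.

    GQ is written for every call that carries one so downstream quality
    filtering keeps working; missing calls are written as ``./.``.
    """
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(rec.chrom for rec in pop.records):
        header.contigs.add(chrom)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("GQ", 1, "Integer", "Genotype quality (phred)")
    header.formats.add("DP", 1, "Integer", "Read depth")
    info_keys = {}
    for rec in pop.records:
        for k, v in rec.annotations.items():
            info_keys.setdefault(k, v is True)
    for k, is_flag in info_keys.items():
        if is_flag:
            header.info.add(k, 0, "Flag", "annotation tag")
        else:
            header.info.add(k, 1, "String", "annotation tag")
    for name in pop.samples:
        header.add_sample(name)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in pop.records:
            vrec = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                stop=rec.pos - 1 + len(rec.ref),
                alleles=(rec.ref, *rec.alts),
            )
            for k, v in rec.annotations.items():
                vrec.info[k] = True if v is True else str(v)
            for name, call in zip(pop.samples, rec.calls):
                sample = vrec.samples[name]
                sample["GT"] = call.alleles if call.alleles is not None else (None, None)
                if call.gq is not None:
                    sample["GQ"] = call.gq
                if call.dp is not None:
                    sample["DP"] = call.dp
            out.write(vrec)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------


def merge_population(per_sample: Sequence[PopulationVCF]) -> PopulationVCF:
    """Join per-sample (or per-batch) matrices into one population matrix.

    The merged site set is the union of input sites keyed by
    ``(chromosome, position)``; reference alleles must agree at shared
    coordinates while alternate-allele lists are unioned with allele-index
    remapping. Samples are concatenated in input order; a sample without a
    call at a union site receives a missing call.
    """
    if not per_sample:
        raise ValueError("nothing to merge")
    samples: list[str] = []
    offsets = []
    for pop in per_sample:
        if not pop.samples:
            raise ValueError("input with no samples")
        offsets.append(len(samples))
        samples.extend(pop.samples)
    if len(set(samples)) != len(samples):
        raise VcfFormatError("duplicate sample names across merge inputs")
    n_total = len(samples)

    merged: dict[tuple, VariantRecord] = {}
    for pop, offset in zip(per_sample, offsets):
        for rec in pop.records:
            key = (rec.chrom, rec.pos)
            target = merged.get(key)
            if target is None:
                calls = [MISSING] * n_total
                target = VariantRecord(
                    rec.chrom, rec.pos, rec.ref, rec.alts, calls, dict(rec.annotations)
                )
                merged[key] = target
            else:
                if target.ref != rec.ref:
                    raise VcfFormatError(
                        f"conflicting reference allele at {rec.chrom}:{rec.pos} "
                        f"({target.ref!r} vs {rec.ref!r})"
                    )
                target.annotations.update(rec.annotations)
            # map this input's allele indices onto the union allele list
            remap = {0: 0}
            alts = list(target.alts)
            for i, alt in enumerate(rec.alts, start=1):
                if alt in alts:
                    remap[i] = alts.index(alt) + 1
                else:
                    alts.append(alt)
                    remap[i] = len(alts)
            target.alts = tuple(alts)
            for j, call in enumerate(rec.calls):
                if call.is_missing:
                    continue
                a, b = call.alleles
                target.calls[offset + j] = GenotypeCall(
                    (remap[a], remap[b]), call.gq, call.dp
                )
    return PopulationVCF(samples, list(merged.values()))


def split_by_sample(pop: PopulationVCF) -> list[PopulationVCF]:
    """Inverse of :func:`merge_population` for testing round trips: one
    single-sample matrix per sample, keeping every site."""
    out = []
    for j, name in enumerate(pop.samples):
        records = [rec.copy(calls=[rec.calls[j]]) for rec in pop.records]
        out.append(PopulationVCF([name], records))
    return out


# ---------------------------------------------------------------------------
# exporters
# ---------------------------------------------------------------------------


def _site_label(rec: VariantRecord) -> str:
    return f"{rec.chrom}_{rec.pos}"


def export_matrix(
    pop: PopulationVCF,
    fmt: str,
    path,
    parents: tuple[str, str] | None = None,
    missing_sentinel: str = "NA",
) -> None:
    """Export genotypes to a downstream-analysis format.

    ``fmt`` is one of:

    ``distance_dendrogram``
        Allele-count table (one row per sample, one column per site holding
        the alternate-allele dosage) for distance-based dendrogram tools.
    ``mapping_cp``
        Outbred full-sib (CP) coded loci for genetic-map construction; site
        classes (``lmxll`` / ``nnxnp`` / ``hkxhk``) are inferred from the
        designated ``parents``. Biallelic SNPs only.
    ``gs_numeric``
        Tab-separated {-1, 0, 1} matrix (hom-ref = 1, het = 0, hom-alt = -1;
        reference-major convention) for genomic-selection packages, with
        missing cells written as ``missing_sentinel``.
    """
    if fmt == "distance_dendrogram":
        _export_distance(pop, path)
    elif fmt == "mapping_cp":
        if parents is None:
            raise ValueError("mapping_cp export requires designated parent samples")
        _export_cp(pop, path, parents)
    elif fmt == "gs_numeric":
        _export_gs(pop, path, missing_sentinel)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def _require_biallelic_snps(pop: PopulationVCF, fmt: str):
    bad = [r for r in pop.records if not r.is_biallelic_snp]
    if bad:
        raise ValueError(
            f"{fmt} export requires biallelic SNPs only; filter first "
            f"(first offending site {bad[0].chrom}:{bad[0].pos})"
        )


def _export_distance(pop: PopulationVCF, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(_site_label(r) for r in pop.records) + "\n")
        for j, name in enumerate(pop.samples):
            row = [name]
            for rec in pop.records:
                call = rec.calls[j]
                if call.is_missing:
                    row.append("NA")
                else:
                    row.append(str(sum(1 for a in call.alleles if a != 0)))
            fh.write("\t".join(row) + "\n")


_CP_CODES = {
    # (class) -> {offspring genotype class: code}
    "lmxll": {"het": "lm", "hom_ref": "ll", "hom_alt": None},
    "nnxnp": {"het": "np", "hom_ref": "nn", "hom_alt": None},
    "hkxhk": {"het": "hk", "hom_ref": "hh", "hom_alt": "kk"},
}


def _call_class(call: GenotypeCall) -> str | None:
    if call.is_missing:
        return None
    if call.is_het:
        return "het"
    return "hom_ref" if call.alleles[0] == 0 else "hom_alt"


def _export_cp(pop: PopulationVCF, path, parents: tuple[str, str]) -> None:
    _require_biallelic_snps(pop, "mapping_cp")
    i1 = pop.sample_index(parents[0])
    i2 = pop.sample_index(parents[1])
    offspring = [j for j in range(pop.n_samples) if j not in (i1, i2)]
    n_skipped = 0
    with open(path, "w") as fh:
        fh.write(
            "locus\tsegregation\t"
            + "\t".join(pop.samples[j] for j in offspring)
            + "\n"
        )
        for rec in pop.records:
            c1 = _call_class(rec.calls[i1])
            c2 = _call_class(rec.calls[i2])
            if c1 is None or c2 is None:
                n_skipped += 1
                continue
            p = {c1, c2}
            if p == {"het"}:
                seg = "hkxhk"
            elif c1 == "het" and c2 != "het":
                seg = "lmxll"
            elif c2 == "het" and c1 != "het":
                seg = "nnxnp"
            else:  # both parents homozygous: uninformative for a CP map
                n_skipped += 1
                continue
            codes = _CP_CODES[seg]
            row = [_site_label(rec), f"<{seg}>"]
            for j in offspring:
                cls = _call_class(rec.calls[j])
                code = codes.get(cls) if cls is not None else None
                row.append(code if code is not None else "--")
            fh.write("\t".join(row) + "\n")
    if n_skipped:
        logger.info("mapping_cp export skipped %d uninformative sites", n_skipped)


def _export_gs(pop: PopulationVCF, path, missing_sentinel: str) -> None:
    _require_biallelic_snps(pop, "gs_numeric")
    coding = {"hom_ref": "1", "het": "0", "hom_alt": "-1"}
    with open(path, "w") as fh:
        fh.write("chrom\tpos\t" + "\t".join(pop.samples) + "\n")
        for rec in pop.records:
            row = [rec.chrom, str(rec.pos)]
            for call in rec.calls:
                cls = _call_class(call)
                row.append(coding[cls] if cls is not None else missing_sentinel)
            fh.write("\t".join(row) + "\n")
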