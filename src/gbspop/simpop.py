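"""Simulated populations and sequencing lanes with known ground truth.

Every downstream module of this package is exercised against synthetic data
produced here, so no external dataset is required:

* :func:`simulate_f1` — a biparental full-sib F1 family. Each site is drawn
  from one of the four Mendelian segregation categories of an F1 cross
  (monomorphic AAxAA, AAxAa, AaxAa, AAxaa), offspring genotypes are sampled
  by Mendelian inheritance, and an observed matrix is derived from the truth
  by injecting genotyping errors (homozygous<->heterozygous flips), missing
  calls, and genotype qualities that are stochastically lower for erroneous
  calls — so quality sweeps behave like real caller output.
* :func:`simulate_magic` — a multiparent advanced generation intercross
  (MAGIC) population: founder haplotypes are combined through a pairwise
  crossing funnel, F1 intercrosses, and single-seed-descent selfing;
  founder-of-origin mosaics are retained as imputation ground truth.
  Residual heterozygosity halves per selfing generation in expectation.
* :func:`simulate_lane` — a barcoded sequencing lane with a configurable
  fraction of reads carrying 3' adapter read-through, with exact per-read
  assignment and trim-point ground truth.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .demux import BarcodeMap, DEFAULT_ADAPTER_TAG
from .vcfio import GenotypeCall, MISSING, PopulationVCF, VariantRecord

__all__ = [
    "F1SimConfig",
    "F1Simulation",
    "MagicSimConfig",
    "MagicSimulation",
    "genotypes_to_population",
    "inject_rule_violations",
    "simulate_f1",
    "simulate_lane",
    "simulate_magic",
]

# Parental genotype (alt-allele dosage) pairs for the four F1 segregation
# categories: monomorphic, AAxAa, AaxAa, AAxaa.
CATEGORY_PARENTS = {1: (0, 0), 2: (0, 1), 3: (1, 1), 4: (0, 2)}

_SHARED_CALLS = {
    -1: MISSING,
    0: GenotypeCall((0, 0)),
    1: GenotypeCall((0, 1)),
    2: GenotypeCall((1, 1)),
}


def genotypes_to_population(
    samples: Sequence[str],
    dosages: np.ndarray,
    gq: np.ndarray | None = None,
    chrom: str = "1",
    positions: Sequence[int] | None = None,
    ref: str = "A",
    alt: str = "T",
) -> PopulationVCF:
    """Build a :class:`PopulationVCF` of biallelic SNPs from an alt-allele
    dosage matrix (``n_samples x n_sites``; -1 = missing), with optional
    per-call genotype qualities."""
    n_samples, n_sites = dosages.shape
    if positions is None:
        positions = range(1, n_sites + 1)
    records = []
    for m, pos in enumerate(positions):
        col = dosages[:, m]
        if gq is None:
            calls = [_SHARED_CALLS[int(g)] for g in col]
        else:
            gq_col = gq[:, m]
            calls = [
                MISSING
                if g < 0
                else GenotypeCall(_SHARED_CALLS[int(g)].alleles, int(gq_col[j]))
                for j, g in enumerate(col)
            ]
        records.append(VariantRecord(chrom, int(pos), ref, (alt,), calls))
    return PopulationVCF(list(samples), records)


# ---------------------------------------------------------------------------
# observation model (shared by the F1 and MAGIC simulators)
# ---------------------------------------------------------------------------


@dataclass
class _ObsModel:
    error_rate: float = 0.01
    missing_rate: float = 0.1
    gq_correct: tuple[float, float] = (70.0, 10.0)  # mean, sd
    gq_error: tuple[float, float] = (25.0, 10.0)


def _observe(truth: np.ndarray, model: _ObsModel, rng: np.random.Generator):
    """Derive an observed dosage matrix from the truth.

    Erroneous calls flip homozygous<->heterozygous (a heterozygous truth
    becomes either homozygote with equal probability), matching the dominant
    discordance mode between genotyping pipelines. GQ is drawn from a
    high-mean discrete distribution for correct calls and a low-mean one for
    errors, then clipped to [1, 99].
    """
    observed = truth.copy()
    flip = (rng.random(truth.shape) < model.error_rate) & (truth >= 0)
    hom_to = np.where(rng.random(truth.shape) < 0.5, 0, 2)
    observed[flip & (truth == 1)] = hom_to[flip & (truth == 1)]
    observed[flip & (truth != 1)] = 1
    missing = (rng.random(truth.shape) < model.missing_rate) & (observed >= 0)
    observed[missing] = -1
    error_mask = flip & ~missing

    gq = np.where(
        error_mask,
        rng.normal(*model.gq_error, size=truth.shape),
        rng.normal(*model.gq_correct, size=truth.shape),
    )
    gq = np.clip(np.rint(gq), 1, 99).astype(np.int16)
    return observed, gq, error_mask, missing


# ---------------------------------------------------------------------------
# F1 biparental family
# ---------------------------------------------------------------------------


@dataclass
class F1SimConfig:
    """Simulation settings for a biparental full-sib F1 family.

    Default family size follows the scale of real GBS mapping families (a
    hundred-odd offspring); ``category_mix`` gives the proportion of sites
    drawn from each of the four segregation categories.
    """

    n_offspring: int = 137
    n_sites: int = 3000
    category_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    error_rate: float = 0.01
    missing_rate: float = 0.1
    gq_correct: tuple[float, float] = (70.0, 10.0)
    gq_error: tuple[float, float] = (25.0, 10.0)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.category_mix) - 1.0) > 1e-9:
            raise ValueError("category_mix must sum to 1")
        for rate in (self.error_rate, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class F1Simulation:
    truth: PopulationVCF
    observed: PopulationVCF
    sites: pd.DataFrame  # chrom, pos, category
    error_mask: np.ndarray  # n_samples x n_sites, True where the observed call is wrong
    missing_mask: np.ndarray
    parents: tuple[str, str] = ("P1", "P2")

    @property
    def n_injected_errors(self) -> int:
        return int(self.error_mask.sum())


def _gametes(parent_dosage: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete allele per entry from a dosage array (0, 1 or 2)."""
    out = (parent_dosage == 2).astype(np.int8)
    het = parent_dosage == 1
    out[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return out


def simulate_f1(cfg: F1SimConfig) -> F1Simulation:
    """Simulate a full-sib F1 family with per-site category ground truth."""
    rng = np.random.default_rng(cfg.seed)
    categories = rng.choice(
        [1, 2, 3, 4], size=cfg.n_sites, p=np.asarray(cfg.category_mix)
    )
    p1 = np.array([CATEGORY_PARENTS[c][0] for c in categories], dtype=np.int8)
    p2 = np.array([CATEGORY_PARENTS[c][1] for c in categories], dtype=np.int8)

    n = cfg.n_offspring
    offspring = np.empty((n, cfg.n_sites), dtype=np.int8)
    for i in range(n):
        offspring[i] = _gametes(p1, rng) + _gametes(p2, rng)
    truth = np.vstack([p1, p2, offspring])

    model = _ObsModel(cfg.error_rate, cfg.missing_rate, cfg.gq_correct, cfg.gq_error)
    observed, gq, error_mask, missing_mask = _observe(truth, model, rng)

    samples = ["P1", "P2"] + [f"F1_{i + 1:03d}" for i in range(n)]
    positions = np.arange(1, cfg.n_sites + 1) * 100
    sites = pd.DataFrame({"chrom": "1", "pos": positions, "category": categories})
    return F1Simulation(
        truth=genotypes_to_population(samples, truth, positions=positions),
        observed=genotypes_to_population(samples, observed, gq, positions=positions),
        sites=sites,
        error_mask=error_mask,
        missing_mask=missing_mask,
    )


def inject_rule_violations(
    sim: F1Simulation,
    n_per_category: dict[int, int],
    seed: int = 0,
) -> tuple[PopulationVCF, pd.DataFrame]:
    """Inject genotypes that violate the segregation rule of their category.

    Each injection edits one call at a distinct site of the requested
    category in a copy of ``sim.observed`` (category 1: a heterozygous call;
    2: a minor-allele homozygote in an offspring; 3: a homozygous parent;
    4: a homozygous offspring) and receives a high GQ so quality filters keep
    it. Returns the edited matrix and a bookkeeping table; on an error-free
    simulation each injection adds exactly one countable segregation error.
    """
    rng = np.random.default_rng(seed)
    pop = PopulationVCF(
        list(sim.observed.samples), [r.copy() for r in sim.observed.records]
    )
    i_p1 = pop.sample_index(sim.parents[0])
    i_p2 = pop.sample_index(sim.parents[1])
    offspring_idx = [
        j for j in range(pop.n_samples) if j not in (i_p1, i_p2)
    ]
    rows = []
    for category, n_wanted in n_per_category.items():
        site_idx = np.flatnonzero(sim.sites["category"].to_numpy() == category)
        if n_wanted > len(site_idx):
            raise ValueError(f"not enough category-{category} sites to inject into")
        chosen = rng.choice(site_idx, size=n_wanted, replace=False)
        for m in chosen:
            rec = pop.records[int(m)]
            if category == 1:
                j = int(rng.choice(offspring_idx))
                alleles = (0, 1)
            elif category == 2:
                j = int(rng.choice(offspring_idx))
                alleles = (1, 1)  # minor (alternate) homozygote
            elif category == 3:
                j = int(rng.choice([i_p1, i_p2]))
                alleles = (0, 0)  # parent should be heterozygous
            else:
                j = int(rng.choice(offspring_idx))
                alleles = (0, 0) if rng.random() < 0.5 else (1, 1)
            rec.calls[j] = GenotypeCall(alleles, gq=99)
            rows.append(
                {"chrom": rec.chrom, "pos": rec.pos, "sample": pop.samples[j],
                 "category": category}
            )
    return pop, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MAGIC population
# ---------------------------------------------------------------------------


@dataclass
class MagicSimConfig:
    """Simulation settings for a MAGIC population of inbred lines.

    Eight founders combined through a per-line randomized crossing funnel,
    then ``selfing_generations`` rounds of single-seed descent (default 4,
    i.e. F5 lines). ``recombination_rate`` is the crossover probability per
    adjacent-site interval per meiosis. Founder alleles are drawn i.i.d.
    Bernoulli(``founder_alt_freq``); at the default 0.5 the expected per-site
    heterozygosity of the funnel F1 is exactly 0.5 before selfing.
    """

    n_founders: int = 8
    n_lines: int = 200
    n_sites: int = 2000
    selfing_generations: int = 4
    recombination_rate: float = 0.001
    founder_alt_freq: float = 0.5
    error_rate: float = 0.01
    missing_rate: float = 0.1
    gq_correct: tuple[float, float] = (70.0, 10.0)
    gq_error: tuple[float, float] = (25.0, 10.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_founders < 2 or self.n_founders & (self.n_founders - 1):
            raise ValueError("n_founders must be a power of two >= 2")
        if self.selfing_generations < 0:
            raise ValueError("selfing_generations must be >= 0")


@dataclass
class MagicSimulation:
    truth: PopulationVCF
    observed: PopulationVCF
    mosaics: np.ndarray  # n_lines x 2 x n_sites founder-of-origin ids
    founder_genotypes: np.ndarray  # n_founders x n_sites in {0, 1}
    error_mask: np.ndarray
    missing_mask: np.ndarray
    config: MagicSimConfig


def _recombine(
    h1: np.ndarray, h2: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """One gamete from a pair of haplotypes: crossovers fall independently in
    each interval with probability ``rate``."""
    m = h1.shape[0]
    parity = np.zeros(m, dtype=np.int64)
    parity[1:] = np.cumsum(rng.random(m - 1) < rate)
    parity = (parity + rng.integers(0, 2)) % 2
    return np.where(parity == 0, h1, h2)


def _funnel(founders: list[int], rate: float, rng, n_sites: int):
    """Recursive crossing funnel: returns the two haplotype mosaics of the
    multi-way hybrid of ``founders`` (a power-of-two list of founder ids)."""
    if len(founders) == 2:
        return (
            np.full(n_sites, founders[0], dtype=np.int16),
            np.full(n_sites, founders[1], dtype=np.int16),
        )
    half = len(founders) // 2
    left = _funnel(founders[:half], rate, rng, n_sites)
    right = _funnel(founders[half:], rate, rng, n_sites)
    return (
        _recombine(left[0], left[1], rate, rng),
        _recombine(right[0], right[1], rate, rng),
    )


def simulate_magic(cfg: MagicSimConfig) -> MagicSimulation:
    """Simulate a MAGIC population with founder-mosaic ground truth."""
    rng = np.random.default_rng(cfg.seed)
    founder_geno = (
        rng.random((cfg.n_founders, cfg.n_sites)) < cfg.founder_alt_freq
    ).astype(np.int8)

    mosaics = np.empty((cfg.n_lines, 2, cfg.n_sites), dtype=np.int16)
    for i in range(cfg.n_lines):
        order = list(rng.permutation(cfg.n_founders))
        h1, h2 = _funnel(order, cfg.recombination_rate, rng, cfg.n_sites)
        for _ in range(cfg.selfing_generations):
            h1, h2 = (
                _recombine(h1, h2, cfg.recombination_rate, rng),
                _recombine(h1, h2, cfg.recombination_rate, rng),
            )
        mosaics[i, 0] = h1
        mosaics[i, 1] = h2

    sites = np.arange(cfg.n_sites)
    truth = (
        founder_geno[mosaics[:, 0, :], sites] + founder_geno[mosaics[:, 1, :], sites]
    ).astype(np.int8)

    model = _ObsModel(cfg.error_rate, cfg.missing_rate, cfg.gq_correct, cfg.gq_error)
    observed, gq, error_mask, missing_mask = _observe(truth, model, rng)

    samples = [f"L{i + 1:03d}" for i in range(cfg.n_lines)]
    positions = np.arange(1, cfg.n_sites + 1) * 1000
    return MagicSimulation(
        truth=genotypes_to_population(samples, truth, positions=positions),
        observed=genotypes_to_population(samples, observed, gq, positions=positions),
        mosaics=mosaics,
        founder_genotypes=founder_geno,
        error_mask=error_mask,
        missing_mask=missing_mask,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# sequencing lane
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq_without(length: int, tag: str, rng: np.random.Generator) -> str:
    """Random ACGT string of the given length guaranteed not to contain tag."""
    while True:
        seq = "".join(_BASES[rng.integers(0, 4, size=length)])
        if tag not in seq:
            return seq


def simulate_lane(
    barcodes: BarcodeMap | dict[str, str],
    fastq_out,
    n_reads: int = 10000,
    read_length: int = 64,
    adapter_fraction: float = 0.35,
    tag: str = DEFAULT_ADAPTER_TAG,
    seed: int = 0,
) -> pd.DataFrame:
    """Write a simulated barcoded lane FASTQ and return its ground truth.

    A fraction ``adapter_fraction`` of reads carry the adapter tag at a
    random offset within the post-barcode sequence (the default 0.35 mirrors
    the adapter-contamination level typical of single-digest GBS libraries).
    Read bodies are generated so that no spurious tag occurrence or
    barcode-prefix ambiguity arises: ground truth assignment and trim points
    are exact. Returns a table with read_id, sample, barcode, has_adapter and
    trim_length (post-barcode length after trimming; -1 when untrimmed).
    """
    if isinstance(barcodes, dict):
        barcodes = BarcodeMap(barcodes)
    rng = np.random.default_rng(seed)
    barcode_list = sorted(barcodes.entries)
    rows = []
    with open(fastq_out, "w") as fh:
        for i in range(n_reads):
            barcode = barcode_list[rng.integers(0, len(barcode_list))]
            sample = barcodes.entries[barcode]
            body_len = read_length - len(barcode)
            has_adapter = rng.random() < adapter_fraction
            while True:
                if has_adapter:
                    offset = int(rng.integers(0, body_len - len(tag) + 1))
                    body = (
                        _random_seq_without(offset, tag, rng)
                        + tag
                        + "".join(
                            _BASES[rng.integers(0, 4, size=body_len - offset - len(tag))]
                        )
                    )
                else:
                    body = _random_seq_without(body_len, tag, rng)
                read = barcode + body
                # longest-prefix assignment must recover the generating sample
                if barcodes.match(read) == (barcode, sample):
                    break
            trim_length = body.find(tag) if has_adapter else -1
            read_id = f"r{i:06d}"
            fh.write(f"@{read_id}\n{read}\n+\n{'I' * len(read)}\n")
            rows.append(
                {
                    "read_id": read_id,
                    "sample": sample,
                    "barcode": barcode,
                    "has_adapter": has_adapter,
                    "trim_length": trim_length,
                }
            )
    return pd.DataFrame(rows)
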