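"""Genotype imputation for inbred lines via a haploid haplotype-cluster HMM.

Inbred lines are effectively homozygous, so each line can be reduced to a
single haploid allele sequence and modelled with the haploid variant of the
haplotype-cluster model popularised by fastPHASE. The hidden state at marker
``m`` is one of ``k`` latent ancestral haplotype clusters; emissions are the
observed alleles and transitions model recombination:

* cluster weights ``alpha[m, c]`` (a simplex per marker) give the initial
  distribution at the first marker and the destination distribution after a
  recombination event;
* crossing the interval before marker ``m+1``, the chain stays in its
  cluster with probability ``exp(-rho[m])`` and otherwise jumps to cluster
  ``c'`` with probability ``(1 - exp(-rho[m])) * alpha[m+1, c']``;
* cluster ``c`` emits the alternate allele at marker ``m`` with probability
  ``theta[c, m]``; a missing observation contributes emission probability 1.

Parameters are estimated by expectation-maximization over all lines jointly
(the E-step treats the recombination indicator as part of the complete data,
giving closed-form updates for ``alpha`` and ``rho``); missing genotypes are
then filled with the allele of maximal posterior emission probability from
the forward-backward cluster posteriors. Observed genotypes are never
changed. Input and output are VCF-backed population matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .vcfio import GenotypeCall, PopulationVCF

__all__ = [
    "ClusterHMM",
    "HaploidizedMatrix",
    "ImputationConcordance",
    "compare_imputations",
    "fit",
    "haploidize",
    "impute",
    "impute_vcf",
]


@dataclass
class HaploidizedMatrix:
    """Haploid reduction of a matrix of biallelic SNPs from inbred lines.

    ``alleles[i, m]`` is 0 (reference), 1 (alternate) or -1 (missing);
    heterozygous source calls are masked to missing (their count is kept in
    ``n_het_masked`` so the information loss is visible) but the original
    diploid calls remain available through ``source``.
    """

    alleles: np.ndarray  # int8, n_samples x n_sites
    source: PopulationVCF
    n_het_masked: int

    @property
    def n_samples(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]


def haploidize(pop: PopulationVCF) -> HaploidizedMatrix:
    """Collapse homozygous diploid calls to haploid alleles.

    Requires biallelic SNPs only (filter first). Heterozygous and missing
    calls both become missing in the haploid matrix.
    """
    for rec in pop.records:
        if not rec.is_biallelic_snp:
            raise ValueError(
                f"haploidize requires biallelic SNPs only ({rec.chrom}:{rec.pos})"
            )
    alleles = np.full((pop.n_samples, pop.n_sites), -1, dtype=np.int8)
    n_het = 0
    for m, rec in enumerate(pop.records):
        for j, call in enumerate(rec.calls):
            if call.alleles is None:
                continue
            if call.alleles[0] != call.alleles[1]:
                n_het += 1
            else:
                alleles[j, m] = call.alleles[0]
    return HaploidizedMatrix(alleles, pop, n_het)


@dataclass
class ClusterHMM:
    """Fitted haploid haplotype-cluster model."""

    k: int
    alpha: np.ndarray  # n_sites x k cluster weights (rows on the simplex)
    theta: np.ndarray  # k x n_sites alternate-allele emission frequencies
    rho: np.ndarray  # n_sites - 1 inter-marker switch intensities (>= 0)
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return self.theta.shape[1]

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1] if self.loglik_trace else math.nan


def _emission_probs(alleles: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """P(observation | cluster) for every (sample, marker, cluster).

    Missing observations emit probability 1 so they carry no information.
    """
    n, m = alleles.shape
    k = theta.shape[0]
    probs = np.ones((n, m, k))
    alt = alleles == 1
    ref = alleles == 0
    theta_t = theta.T  # m x k
    probs[alt] = np.broadcast_to(theta_t, (n, m, k))[alt]
    probs[ref] = np.broadcast_to(1.0 - theta_t, (n, m, k))[ref]
    return probs


def _forward_backward(model: ClusterHMM, emit: np.ndarray):
    """Scaled forward-backward pass vectorized over samples.

    Returns per-sample log-likelihoods, cluster posteriors ``gamma``
    (n x m x k), and per-interval jump statistics: posterior jump
    probability per sample (n x m-1) and expected jump-destination weights
    (m-1 x k, summed over samples).
    """
    n, m, k = emit.shape
    alpha, rho = model.alpha, model.rho
    stay = np.exp(-rho)

    fwd = np.empty((n, m, k))
    scale = np.empty((n, m))
    f = alpha[0] * emit[:, 0, :]
    scale[:, 0] = f.sum(axis=1)
    fwd[:, 0, :] = f / scale[:, 0, None]
    for t in range(1, m):
        prev = fwd[:, t - 1, :]
        f = (stay[t - 1] * prev + (1.0 - stay[t - 1]) * alpha[t]) * emit[:, t, :]
        scale[:, t] = f.sum(axis=1)
        fwd[:, t, :] = f / scale[:, t, None]

    bwd = np.empty((n, m, k))
    bwd[:, -1, :] = 1.0
    for t in range(m - 2, -1, -1):
        eb = emit[:, t + 1, :] * bwd[:, t + 1, :]
        total = eb @ alpha[t + 1]
        bwd[:, t, :] = (stay[t] * eb + (1.0 - stay[t]) * total[:, None]) / scale[
            :, t + 1, None
        ]

    gamma = fwd * bwd
    gamma /= gamma.sum(axis=2, keepdims=True)

    # posterior recombination statistics per interval
    jump_prob = np.empty((n, m - 1)) if m > 1 else np.zeros((n, 0))
    dest = np.zeros((m - 1, k)) if m > 1 else np.zeros((0, k))
    for t in range(m - 1):
        eb = emit[:, t + 1, :] * bwd[:, t + 1, :]  # n x k
        f_sum = fwd[:, t, :].sum(axis=1)  # = 1 after scaling
        no_jump = stay[t] * (fwd[:, t, :] * eb).sum(axis=1)
        jump_dest = (1.0 - stay[t]) * f_sum[:, None] * alpha[t + 1] * eb  # n x k
        jump_tot = jump_dest.sum(axis=1)
        norm = no_jump + jump_tot
        jump_prob[:, t] = jump_tot / norm
        dest[t] = (jump_dest / norm[:, None]).sum(axis=0)

    loglik = np.log(scale).sum(axis=1)
    return loglik, gamma, jump_prob, dest


def fit(
    matrix: HaploidizedMatrix,
    k: int = 8,
    max_iter: int = 50,
    seed: int | None = None,
    tol: float = 1e-4,
    theta_floor: float = 1e-3,
) -> ClusterHMM:
    """Fit the haplotype-cluster HMM by EM.

    ``seed`` controls the random initialisation (per-cluster perturbations of
    the per-site allele frequencies) and must be given for reproducibility.
    EM stops at ``max_iter`` iterations or when the relative log-likelihood
    improvement drops below ``tol``. ``theta_floor`` keeps emission
    frequencies away from 0 and 1 for numerical stability. The
    log-likelihood trace is retained on the returned model; it is
    non-decreasing (up to the tiny effect of the parameter clipping).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if seed is None:
        raise ValueError("an explicit seed is required for reproducible fits")
    X = matrix.alleles
    n, m = X.shape
    if n < 2 or m < 2:
        raise ValueError("need at least 2 samples and 2 sites to fit")
    if (X < 0).all():
        raise ValueError("degenerate matrix: all genotypes missing")
    rng = np.random.default_rng(seed)

    observed = X >= 0
    with np.errstate(invalid="ignore"):
        freq = np.where(
            observed.sum(axis=0) > 0,
            (X == 1).sum(axis=0) / np.maximum(observed.sum(axis=0), 1),
            0.5,
        )
    theta = np.clip(
        freq[None, :] + rng.uniform(-0.1, 0.1, size=(k, m)),
        theta_floor,
        1.0 - theta_floor,
    )
    alpha = np.full((m, k), 1.0 / k)
    rho = np.full(max(m - 1, 0), 0.05)
    model = ClusterHMM(k, alpha, theta, rho)

    prev_ll = -np.inf
    for _ in range(max_iter):
        emit = _emission_probs(X, model.theta)
        loglik, gamma, jump_prob, dest = _forward_backward(model, emit)
        total_ll = float(loglik.sum())
        model.loglik_trace.append(total_ll)

        # M-step
        w_alt = np.einsum("nmk,nm->km", gamma, (X == 1).astype(float))
        w_obs = np.einsum("nmk,nm->km", gamma, observed.astype(float))
        with np.errstate(invalid="ignore", divide="ignore"):
            new_theta = np.where(w_obs > 0, w_alt / np.maximum(w_obs, 1e-300), model.theta)
        model.theta = np.clip(new_theta, theta_floor, 1.0 - theta_floor)

        new_alpha = np.empty_like(model.alpha)
        new_alpha[0] = gamma[:, 0, :].mean(axis=0)
        if m > 1:
            jumps = jump_prob.sum(axis=0)  # expected jumps per interval
            dest_w = dest + 1e-9
            new_alpha[1:] = dest_w / dest_w.sum(axis=1, keepdims=True)
            frac = np.clip(jumps / n, 1e-9, 1.0 - 1e-9)
            model.rho = -np.log1p(-frac)
        new_alpha += 1e-9
        model.alpha = new_alpha / new_alpha.sum(axis=1, keepdims=True)

        if total_ll - prev_ll < tol * abs(total_ll) and np.isfinite(prev_ll):
            break
        prev_ll = total_ll
    return model


def cluster_posteriors(matrix: HaploidizedMatrix, model: ClusterHMM) -> np.ndarray:
    """Forward-backward cluster posteriors (n_samples x n_sites x k)."""
    if model.n_sites != matrix.n_sites:
        raise ValueError("model was fitted on a different site list")
    emit = _emission_probs(matrix.alleles, model.theta)
    _, gamma, _, _ = _forward_backward(model, emit)
    return gamma


def posterior_alt_probs(matrix: HaploidizedMatrix, model: ClusterHMM) -> np.ndarray:
    """Posterior probability of the alternate allele at every cell."""
    gamma = cluster_posteriors(matrix, model)
    return np.einsum("nmk,km->nm", gamma, model.theta)


def impute(
    matrix: HaploidizedMatrix,
    model: ClusterHMM,
    reimpute_hets: bool = False,
) -> PopulationVCF:
    """Fill missing genotypes from the fitted model, as a new population VCF.

    Missing cells receive the homozygous diploid genotype of the allele with
    maximal posterior emission probability, flagged with the ``IM`` FORMAT
    tag and given a posterior-derived GQ. Observed calls are never changed;
    heterozygous source calls (masked for the haploid model) are kept as-is
    unless ``reimpute_hets`` is set.
    """
    p_alt = posterior_alt_probs(matrix, model)
    pop = matrix.source
    records = []
    for m, rec in enumerate(pop.records):
        calls = list(rec.calls)
        for j, call in enumerate(calls):
            replace = call.alleles is None or (
                reimpute_hets and call.alleles[0] != call.alleles[1]
            )
            if not replace:
                continue
            p = float(p_alt[j, m])
            allele = 1 if p > 0.5 else 0
            confidence = max(p, 1.0 - p)
            gq = int(min(99, round(-10.0 * math.log10(max(1.0 - confidence, 1e-10)))))
            calls[j] = GenotypeCall((allele, allele), gq=gq)
        new_rec = rec.copy(calls=calls)
        records.append(new_rec)
    out = PopulationVCF(list(pop.samples), records)
    _flag_imputed(out, pop)
    return out


def _flag_imputed(imputed: PopulationVCF, original: PopulationVCF) -> None:
    # record which cells were imputed, for bookkeeping and VCF annotation
    for rec, orig in zip(imputed.records, original.records):
        n = sum(
            1
            for new, old in zip(rec.calls, orig.calls)
            if old.alleles is None and new.alleles is not None
        )
        if n:
            rec.annotations["NIMP"] = str(n)


def impute_vcf(
    pop: PopulationVCF,
    k: int = 8,
    max_iter: int = 50,
    seed: int | None = None,
    reimpute_hets: bool = False,
) -> tuple[PopulationVCF, ClusterHMM]:
    """Convenience pipeline: haploidize, fit, impute."""
    matrix = haploidize(pop)
    model = fit(matrix, k=k, max_iter=max_iter, seed=seed)
    return impute(matrix, model, reimpute_hets=reimpute_hets), model


# ---------------------------------------------------------------------------
# concordance between imputation outputs
# ---------------------------------------------------------------------------


@dataclass
class ImputationConcordance:
    """Agreement between two imputed matrices over a set of cells.

    When the pre-imputation matrix is supplied the comparison is restricted
    to its missing cells (the imputed ones); otherwise all cells compare.
    """

    n_cells: int
    n_identical: int
    n_one_het: int  # exactly one of the two outputs is heterozygous
    n_one_missing: int  # imputed by one output, left missing by the other
    n_both_missing: int

    @property
    def frac_identical(self) -> float:
        return self.n_identical / self.n_cells if self.n_cells else math.nan

    @property
    def frac_one_het(self) -> float:
        return self.n_one_het / self.n_cells if self.n_cells else math.nan

    @property
    def frac_one_missing(self) -> float:
        return self.n_one_missing / self.n_cells if self.n_cells else math.nan


def compare_imputations(
    a: PopulationVCF,
    b: PopulationVCF,
    original: PopulationVCF | None = None,
) -> ImputationConcordance:
    """Cell-by-cell concordance of two imputation outputs on the same matrix."""
    if a.samples != b.samples or a.n_sites != b.n_sites:
        raise ValueError("matrices must share samples and sites")
    for ra, rb in zip(a.records, b.records):
        if ra.key != rb.key:
            raise ValueError(f"site mismatch: {ra.key} vs {rb.key}")
    stats = ImputationConcordance(0, 0, 0, 0, 0)
    orig_records = original.records if original is not None else None
    for m, (ra, rb) in enumerate(zip(a.records, b.records)):
        for j in range(len(a.samples)):
            if orig_records is not None and orig_records[m].calls[j].alleles is not None:
                continue
            ca, cb = ra.calls[j].alleles, rb.calls[j].alleles
            stats.n_cells += 1
            if ca is None and cb is None:
                stats.n_both_missing += 1
            elif ca is None or cb is None:
                stats.n_one_missing += 1
            else:
                if ca == cb:
                    stats.n_identical += 1
                if (ca[0] != ca[1]) != (cb[0] != cb[1]):
                    stats.n_one_het += 1
    return stats
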