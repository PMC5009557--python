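"""Haplotype-cluster HMM: haploidization, EM fitting, posteriors, imputation."""

import itertools
import math

import numpy as np
import pytest

from gbspop import simpop
from gbspop.imputation import (
    ClusterHMM,
    HaploidizedMatrix,
    _emission_probs,
    _forward_backward,
    compare_imputations,
    fit,
    haploidize,
    impute,
    impute_vcf,
)
from gbspop.vcfio import MISSING, PopulationVCF

from conftest import make_record


def brute_force_posteriors(model: ClusterHMM, obs):
    """Exhaustive enumeration over all cluster paths (independent oracle)."""
    m = len(obs)
    k = model.k
    stay = np.exp(-model.rho)
    post = np.zeros((m, k))
    total = 0.0
    for path in itertools.product(range(k), repeat=m):
        p = model.alpha[0][path[0]]
        for t in range(1, m):
            p *= stay[t - 1] * (path[t] == path[t - 1]) + (
                1 - stay[t - 1]
            ) * model.alpha[t][path[t]]
        for t, x in enumerate(obs):
            if x == 1:
                p *= model.theta[path[t], t]
            elif x == 0:
                p *= 1 - model.theta[path[t], t]
        total += p
        for t in range(m):
            post[t, path[t]] += p
    return math.log(total), post / total


def random_model(k, m, rng):
    return ClusterHMM(
        k,
        rng.dirichlet(np.ones(k), size=m),
        rng.uniform(0.05, 0.95, (k, m)),
        rng.uniform(0.01, 1.5, max(m - 1, 0)),
    )


class TestHaploidize:
    def test_fully_homozygous_is_lossless(self):
        pop = simpop.genotypes_to_population(
            ["A", "B"], np.array([[0, 2, 0], [2, 2, 0]], dtype=np.int8)
        )
        mat = haploidize(pop)
        assert mat.n_het_masked == 0
        assert (mat.alleles == [[0, 1, 0], [1, 1, 0]]).all()

    def test_het_converted_to_missing_and_counted(self):
        pop = simpop.genotypes_to_population(
            ["A", "B"], np.array([[0, 1], [2, -1]], dtype=np.int8)
        )
        mat = haploidize(pop)
        assert mat.n_het_masked == 1
        assert mat.alleles[0, 1] == -1 and mat.alleles[1, 1] == -1

    def test_conversion_count_matches_brute_tally(self):
        sim = simpop.simulate_magic(
            simpop.MagicSimConfig(n_lines=30, n_sites=100, seed=20)
        )
        tally = sum(
            1
            for rec in sim.observed.records
            for call in rec.calls
            if call.alleles is not None and call.alleles[0] != call.alleles[1]
        )
        assert haploidize(sim.observed).n_het_masked == tally

    def test_non_snp_rejected(self):
        pop = PopulationVCF(["S"], [make_record("1", 1, [(0, 0)], alts=("AT",))])
        with pytest.raises(ValueError):
            haploidize(pop)


class TestForwardBackward:
    def test_posteriors_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(21)
        worst = 0.0
        for k in (1, 2, 3):
            for m in (2, 3, 4):
                model = random_model(k, m, rng)
                for obs in itertools.product([-1, 0, 1], repeat=m):
                    X = np.array([obs], dtype=np.int8)
                    ll, gamma, _, _ = _forward_backward(
                        model, _emission_probs(X, model.theta)
                    )
                    brute_ll, brute_post = brute_force_posteriors(model, obs)
                    worst = max(
                        worst,
                        abs(ll[0] - brute_ll),
                        float(np.abs(gamma[0] - brute_post).max()),
                    )
        assert worst < 1e-10

    def test_likelihood_vectorization_over_samples(self):
        rng = np.random.default_rng(22)
        model = random_model(3, 4, rng)
        X = rng.integers(-1, 2, size=(5, 4)).astype(np.int8)
        ll, _, _, _ = _forward_backward(model, _emission_probs(X, model.theta))
        for i in range(5):
            single_ll, _ = brute_force_posteriors(model, list(X[i]))
            assert ll[i] == pytest.approx(single_ll, abs=1e-10)


class TestFit:
    def test_loglik_monotone_on_magic_data(self):
        sim = simpop.simulate_magic(
            simpop.MagicSimConfig(n_lines=30, n_sites=80, seed=23)
        )
        model = fit(haploidize(sim.observed), k=4, max_iter=15, seed=24)
        trace = model.loglik_trace
        assert len(trace) >= 2
        for a, b in zip(trace, trace[1:]):
            assert b - a > -1e-6 * abs(a)

    def test_k1_equals_independent_site_frequencies(self):
        rng = np.random.default_rng(25)
        X = (rng.random((25, 12)) < 0.3).astype(np.int8)
        X[rng.random(X.shape) < 0.2] = -1
        mat = HaploidizedMatrix(X, None, 0)
        model = fit(mat, k=1, max_iter=50, seed=26)
        # with one cluster the model factorizes over sites: theta is the
        # per-site allele frequency and the likelihood has a closed form
        ll = 0.0
        for m in range(12):
            col = X[:, m]
            n_alt = int((col == 1).sum())
            n_obs = int((col >= 0).sum())
            freq = np.clip(n_alt / n_obs if n_obs else 0.5, 1e-3, 1 - 1e-3)
            assert model.theta[0, m] == pytest.approx(freq, abs=1e-9)
            ll += n_alt * math.log(freq) + (n_obs - n_alt) * math.log(1 - freq)
        assert model.loglik == pytest.approx(ll, abs=1e-6)

    def test_two_cluster_parameter_recovery(self):
        # two haplotype clusters with strongly contrasting allele profiles
        rng = np.random.default_rng(27)
        m = 120
        true_theta = np.vstack([
            np.where(rng.random(m) < 0.5, 0.95, 0.05),
            np.where(rng.random(m) < 0.5, 0.95, 0.05),
        ])
        labels = rng.integers(0, 2, size=60)
        X = (rng.random((60, m)) < true_theta[labels]).astype(np.int8)
        model = fit(HaploidizedMatrix(X, None, 0), k=2, max_iter=60, seed=28)
        # align cluster labels before comparing
        direct = np.abs(model.theta - true_theta).mean()
        swapped = np.abs(model.theta[::-1] - true_theta).mean()
        assert min(direct, swapped) < 0.05

    def test_degenerate_inputs_rejected(self):
        X = np.full((3, 5), -1, dtype=np.int8)
        with pytest.raises(ValueError, match="missing"):
            fit(HaploidizedMatrix(X, None, 0), k=2, seed=1)
        with pytest.raises(ValueError):
            fit(HaploidizedMatrix(np.zeros((3, 5), np.int8), None, 0), k=0, seed=1)
        with pytest.raises(ValueError, match="seed"):
            fit(HaploidizedMatrix(np.zeros((3, 5), np.int8), None, 0), k=2)


class TestImpute:
    def test_no_missing_cells_is_identity(self):
        sim = simpop.simulate_magic(
            simpop.MagicSimConfig(
                n_lines=20, n_sites=50, error_rate=0, missing_rate=0, seed=29
            )
        )
        imputed, _ = impute_vcf(sim.observed, k=2, max_iter=5, seed=30)
        assert imputed == sim.observed

    def test_observed_calls_never_changed(self):
        sim = simpop.simulate_magic(
            simpop.MagicSimConfig(n_lines=20, n_sites=50, missing_rate=0.3, seed=31)
        )
        imputed, _ = impute_vcf(sim.observed, k=3, max_iter=8, seed=32)
        for rec_in, rec_out in zip(sim.observed.records, imputed.records):
            for call_in, call_out in zip(rec_in.calls, rec_out.calls):
                if call_in.alleles is not None:
                    assert call_out.alleles == call_in.alleles

    def test_missing_cell_in_monomorphic_window_forced_to_ref(self):
        dosages = np.zeros((6, 8), dtype=np.int8)
        dosages[0, 4] = -1
        pop = simpop.genotypes_to_population([f"S{i}" for i in range(6)], dosages)
        imputed, _ = impute_vcf(pop, k=2, max_iter=10, seed=33)
        call = imputed.records[4].calls[0]
        assert call.alleles == (0, 0)
        assert call.gq is not None and call.gq > 0

    def test_imputed_cells_are_flagged(self):
        dosages = np.zeros((4, 6), dtype=np.int8)
        dosages[1, 2] = -1
        pop = simpop.genotypes_to_population([f"S{i}" for i in range(4)], dosages)
        imputed, _ = impute_vcf(pop, k=2, max_iter=5, seed=34)
        assert imputed.records[2].annotations.get("NIMP") == "1"


class TestConcordance:
    def test_self_concordance_is_one(self):
        sim = simpop.simulate_magic(
            simpop.MagicSimConfig(n_lines=15, n_sites=40, seed=35)
        )
        imputed, _ = impute_vcf(sim.observed, k=2, max_iter=5, seed=36)
        report = compare_imputations(imputed, imputed, original=sim.observed)
        assert report.frac_identical == 1.0
        assert report.n_cells == sum(
            1
            for rec in sim.observed.records
            for call in rec.calls
            if call.alleles is None
        )

    def test_one_left_missing_category(self):
        a = PopulationVCF(["S"], [make_record("1", 1, [(0, 0)])])
        b = PopulationVCF(["S"], [make_record("1", 1, [None])])
        orig = PopulationVCF(["S"], [make_record("1", 1, [None])])
        report = compare_imputations(a, b, original=orig)
        assert report.n_cells == 1 and report.n_one_missing == 1

    def test_masking_harness_matches_brute_force_score(self):
        sim = simpop.simulate_magic(
            simpop.MagicSimConfig(
                n_lines=40, n_sites=200, error_rate=0, missing_rate=0.1, seed=37
            )
        )
        rng = np.random.default_rng(38)
        records = [rec.copy() for rec in sim.observed.records]
        masked = []
        for m, rec in enumerate(records):
            for j, call in enumerate(rec.calls):
                if call.alleles is not None and rng.random() < 0.2:
                    masked.append((m, j, call.alleles))
                    rec.calls[j] = MISSING
        masked_pop = PopulationVCF(list(sim.observed.samples), records)
        imputed, _ = impute_vcf(masked_pop, k=8, max_iter=30, seed=39)
        recovered = sum(
            1 for m, j, alleles in masked if imputed.records[m].calls[j].alleles == alleles
        )
        # brute-force score over the bookkeeping list is the reference; the
        # concordance report restricted to masked-only cells must agree
        report = compare_imputations(imputed, sim.observed, original=masked_pop)
        originally_missing = sum(
            1
            for rec in sim.observed.records
            for call in rec.calls
            if call.alleles is None
        )
        assert report.n_cells == len(masked) + originally_missing
        assert report.n_identical >= recovered
        assert recovered / len(masked) > 0.85
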