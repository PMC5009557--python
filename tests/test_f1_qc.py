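"""Segregation categories, error counting, MAGIC heterozygosity, integrity."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gbspop import simpop
from gbspop.f1_qc import (
    CATEGORY_EXPECTATIONS,
    classify_site,
    count_category_errors,
    family_integrity,
    magic_het_assessment,
    quality_sweep,
)
from gbspop.popstats import site_maf, site_observed_het
from gbspop.vcfio import GenotypeCall, PopulationVCF

from conftest import make_record


def exact_offspring_record(category: int, scale: int = 4):
    """Offspring cohort realizing the exact infinite-population Mendelian
    genotype distribution of a category's parental cross."""
    proportions = {
        1: {(0, 0): 1.0},  # AA x AA
        2: {(0, 0): 0.5, (0, 1): 0.5},  # AA x Aa
        3: {(0, 0): 0.25, (0, 1): 0.5, (1, 1): 0.25},  # Aa x Aa
        4: {(0, 1): 1.0},  # AA x aa
    }[category]
    gts = []
    for gt, frac in proportions.items():
        gts.extend([gt] * int(round(frac * scale)))
    return make_record("1", 1, gts)


class TestClassification:
    @pytest.mark.parametrize("category", [1, 2, 3, 4])
    def test_analytic_expectations_land_in_their_category(self, category):
        rec = exact_offspring_record(category)
        ho = site_observed_het(rec)
        maf = site_maf(rec)
        assert (ho, maf) == CATEGORY_EXPECTATIONS[category]
        assert classify_site(ho, maf) == category

    @pytest.mark.parametrize(
        "ho,maf,expected",
        [
            (0.5, 0.25, 2),
            (1.0, 0.5, 4),
            (0.2, 0.37, 2),  # boundaries inclusive as printed
            (0.2, 0.3700001, 3),
            (0.8, 0.37, 2),
            (0.19999, 0.5, 1),
            (0.80001, 0.0, 4),
        ],
    )
    def test_threshold_boundaries(self, ho, maf, expected):
        assert classify_site(ho, maf) == expected

    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=0.5),
    )
    def test_partition_no_gaps_no_overlaps(self, ho, maf):
        assert classify_site(ho, maf) in (1, 2, 3, 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_site(1.2, 0.1)
        with pytest.raises(ValueError):
            classify_site(0.5, 0.6)


class TestErrorCounting:
    def perfect_sim(self, seed=40):
        return simpop.simulate_f1(
            simpop.F1SimConfig(
                n_offspring=60, n_sites=600, error_rate=0, missing_rate=0, seed=seed
            )
        )

    def test_perfect_segregation_zero_errors(self):
        sim = self.perfect_sim()
        report = count_category_errors(sim.observed, sim.parents)
        assert report.table["n_errors"].sum() == 0
        # classification recovers the simulated category at every site
        merged = report.site_categories.merge(sim.sites, on=["chrom", "pos"])
        assert (merged["category_x"] == merged["category_y"]).all()

    def test_c1_heterozygote_counts_one_error(self):
        rec = make_record("1", 1, [(0, 0)] * 40 + [(0, 1)])
        pop = PopulationVCF([f"S{i}" for i in range(41)], [rec])
        report = count_category_errors(pop, ("S0", "S1"))
        assert report.table.loc[1, "n_errors"] == 1

    def test_c4_homozygous_siblings_counted(self):
        sim = self.perfect_sim(seed=41)
        pop, injections = simpop.inject_rule_violations(sim, {4: 3}, seed=42)
        report = count_category_errors(pop, sim.parents)
        assert report.table.loc[4, "n_errors"] == 3

    def test_injected_violations_recovered_exactly_per_category(self):
        sim = self.perfect_sim(seed=43)
        wanted = {1: 7, 2: 5, 3: 4, 4: 6}
        pop, injections = simpop.inject_rule_violations(sim, wanted, seed=44)
        report = count_category_errors(pop, sim.parents)
        assert report.table["n_errors"].to_dict() == wanted
        assert len(injections) == sum(wanted.values())

    def test_missing_parent_skips_parental_checks(self):
        # family large enough that the offspring-only (Ho, MAF) estimates
        # stay clear of the C2/C3 boundary at every site
        sim = simpop.simulate_f1(
            simpop.F1SimConfig(
                n_offspring=300, n_sites=300, error_rate=0, missing_rate=0, seed=45
            )
        )
        from gbspop.filters import select_samples

        no_parents = select_samples(sim.observed, drop=["P1", "P2"])
        report = count_category_errors(no_parents, ("P1", "P2"))
        assert report.table["n_errors"].sum() == 0


class TestQualitySweep:
    def test_q0_reproduces_unfiltered_report(self):
        sim = simpop.simulate_f1(
            simpop.F1SimConfig(n_offspring=40, n_sites=400, seed=46)
        )
        sweep = quality_sweep(
            sim.observed, [0], sim.parents, drop_monomorphic_alt=False
        )
        report = count_category_errors(sim.observed, sim.parents)
        row = sweep.iloc[0]
        assert row["calls_c2c3"] == report.n_calls(2, 3)
        assert row["errors_c2c3"] == report.n_errors(2, 3)
        assert row["calls_c4"] == report.n_calls(4)

    def test_counts_monotone_non_increasing_in_q(self):
        sim = simpop.simulate_f1(
            simpop.F1SimConfig(n_offspring=40, n_sites=400, seed=47)
        )
        sweep = quality_sweep(sim.observed, [0, 20, 40, 60, 80], sim.parents)
        for col in ("calls_c2c3", "calls_c4", "n_sites"):
            assert (np.diff(sweep[col].to_numpy()) <= 0).all()

    def test_error_fraction_at_q0_near_injected_rate(self):
        # only category-rule-violating flips are countable, so compare the
        # counted C4 sibling errors against the simulator's bookkeeping
        eps = 0.02
        sim = simpop.simulate_f1(
            simpop.F1SimConfig(
                n_offspring=80,
                n_sites=1500,
                category_mix=(0.0, 0.0, 0.0, 1.0),
                error_rate=eps,
                missing_rate=0.0,
                seed=48,
            )
        )
        report = count_category_errors(sim.observed, sim.parents)
        c4_sites = report.site_categories[report.site_categories.category == 4]
        # every flip at a C4 site is a countable violation (hom sibling or
        # het parent); with all sites C4 the counted errors at q=0 must
        # equal the simulator's flip bookkeeping on those sites
        flips = sim.n_injected_errors
        counted = report.table.loc[4, "n_errors"]
        assert counted == pytest.approx(flips, abs=0.02 * flips)
        calls = report.table.loc[4, "n_calls"]
        se = math.sqrt(eps * (1 - eps) / calls)
        assert abs(counted / calls - eps) < 4 * se

    def test_sweep_filters_low_quality_errors_first(self):
        sim = simpop.simulate_f1(
            simpop.F1SimConfig(n_offspring=60, n_sites=800, error_rate=0.03, seed=49)
        )
        sweep = quality_sweep(sim.observed, [0, 50], sim.parents)
        err0 = sweep.iloc[0]["errors_c2c3"] / max(sweep.iloc[0]["calls_c2c3"], 1)
        err50 = sweep.iloc[1]["errors_c2c3"] / max(sweep.iloc[1]["calls_c2c3"], 1)
        assert err50 < err0


class TestMagicHet:
    def test_expected_band_analytic(self):
        pop = PopulationVCF(["S"], [])
        report = magic_het_assessment(pop, selfing_generations=4)
        assert report.expected_band == (0.015625, 0.03125)

    def test_zero_generations_band_is_initial_range(self):
        pop = PopulationVCF(["S"], [])
        report = magic_het_assessment(pop, 0, initial_het_range=(0.25, 0.5))
        assert report.expected_band == (0.25, 0.5)

    def test_simulated_magic_lands_in_band(self):
        # founder allele frequency drawn so initial per-site heterozygosity
        # spans the configured range; measured on the truth matrix
        cfg = simpop.MagicSimConfig(
            n_lines=150,
            n_sites=2000,
            recombination_rate=0.5,
            founder_alt_freq=0.25,
            error_rate=0,
            missing_rate=0,
            seed=50,
        )
        sim = simpop.simulate_magic(cfg)
        report = magic_het_assessment(sim.truth, 4)
        # founder freq 0.25 -> expected initial het 2*0.25*0.75 = 0.375
        expected = 0.375 / 16
        assert report.in_expected_band
        assert report.het_fraction == pytest.approx(expected, rel=0.15)

    def test_counts_heterozygous_calls_and_high_het_snps(self):
        pop = PopulationVCF(
            ["A", "B"],
            [
                make_record("1", 1, [(0, 1), (0, 0)]),  # Ho = 0.5
                make_record("1", 2, [(0, 0), (0, 0)]),  # Ho = 0
            ],
        )
        report = magic_het_assessment(pop, 4)
        assert report.n_calls == 4 and report.n_het_calls == 1
        assert report.n_snps == 2 and report.n_snps_high_het == 1


class TestFamilyIntegrity:
    def test_true_offspring_fraction_near_error_rate(self):
        sim = simpop.simulate_f1(
            simpop.F1SimConfig(n_offspring=60, n_sites=1500, error_rate=0.01, seed=51)
        )
        table = family_integrity(sim.observed, sim.parents, threshold=0.1)
        assert not table["flagged_unrelated"].any()
        assert table["max_hom_diff"].median() < 0.05

    def test_unrelated_sample_flagged(self):
        sim = simpop.simulate_f1(
            simpop.F1SimConfig(
                n_offspring=30,
                n_sites=800,
                category_mix=(0.0, 0.2, 0.4, 0.4),
                error_rate=0,
                missing_rate=0,
                seed=52,
            )
        )
        # replace one offspring's genotypes with random unrelated ones
        rng = np.random.default_rng(53)
        j = sim.observed.sample_index("F1_010")
        for rec in sim.observed.records:
            g = rng.integers(0, 3)
            rec.calls[j] = GenotypeCall((0, 0) if g == 0 else (0, 1) if g == 1 else (1, 1))
        table = family_integrity(sim.observed, sim.parents, threshold=0.05)
        row = table.set_index("sample").loc["F1_010"]
        assert row["flagged_unrelated"]
        others = table.set_index("sample").drop("F1_010")
        assert not others["flagged_unrelated"].any()

    def test_parent_duplicate_has_zero_fraction(self):
        sim = simpop.simulate_f1(
            simpop.F1SimConfig(n_offspring=10, n_sites=300, error_rate=0, missing_rate=0, seed=54)
        )
        pop = sim.observed
        # append a copy of P1 as a pseudo-offspring
        from gbspop.vcfio import PopulationVCF as PV

        j = pop.sample_index("P1")
        records = [rec.copy(calls=list(rec.calls) + [rec.calls[j]]) for rec in pop.records]
        dup = PV(pop.samples + ["P1_dup"], records)
        table = family_integrity(dup, ("P1", "P2"))
        row = table.set_index("sample").loc["P1_dup"]
        assert row["hom_diff_P1"] == 0.0
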