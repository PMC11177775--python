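"""Fisher exact test, chi-square transform, pattern tables and the pair scan."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from digenet import (
    CASE,
    CONTROL,
    GenotypePattern,
    SimulationConfig,
    ValidationError,
    VariantLookupError,
    fisher_two_sided,
    p_to_chisq,
    pattern_table,
    scan_pairs,
    simulate_cohort,
)
from tests.conftest import build_cohort

cells = st.tuples(*[st.integers(0, 25)] * 4)


class TestFisherTwoSided:
    def test_balanced_table_is_uninformative(self):
        assert fisher_two_sided((5, 5, 5, 5)) == 1.0

    def test_extreme_table_matches_enumeration(self):
        # frozen from exhaustive enumeration of the 11 tables with margins
        # (10,10;10,10): the two extreme tables each have probability
        # 1/C(20,10), so p = 2/184756 = 1/92378
        assert fisher_two_sided((10, 0, 0, 10)) == pytest.approx(
            1.082508822446903e-05, abs=1e-10
        )

    @pytest.mark.parametrize("table", [(0, 0, 3, 4), (3, 4, 0, 0),
                                       (0, 3, 0, 4), (3, 0, 4, 0)])
    def test_zero_margin_gives_one(self, table):
        assert fisher_two_sided(table) == 1.0

    @given(table=cells)
    def test_case_control_swap_invariance(self, table):
        a, b, c, d = table
        if a + b + c + d == 0:
            return
        assert fisher_two_sided((a, b, c, d)) == pytest.approx(
            fisher_two_sided((c, d, a, b)), rel=1e-12
        )

    @given(table=cells)
    def test_agrees_with_scipy(self, table):
        a, b, c, d = table
        if a + b + c + d == 0:
            return
        ours = fisher_two_sided(table)
        _, scipy_p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        assert ours == pytest.approx(min(scipy_p, 1.0), rel=1e-9, abs=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            fisher_two_sided((0, 0, 0, 0))


class TestPToChisq:
    def test_boundary_and_reference_quantiles(self):
        assert p_to_chisq(1.0) == 0.0
        # 1-df critical value at 0.05 and the survival value at 1.0,
        # frozen from standard chi-square tables
        assert p_to_chisq(0.05) == pytest.approx(3.841459, abs=1e-6)
        assert p_to_chisq(0.3173105) == pytest.approx(1.0, abs=1e-6)

    def test_strictly_decreasing(self):
        ps = np.linspace(0.01, 1.0, 25)
        xs = [p_to_chisq(p) for p in ps]
        assert all(a > b for a, b in zip(xs, xs[1:]))

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_domain_errors(self, p):
        with pytest.raises(ValidationError):
            p_to_chisq(p)


class TestPatternTable:
    def separation_cohort(self):
        # every case carries (1,1); no control does
        geno = np.zeros((20, 2), dtype=np.int8)
        geno[:10] = 1
        pheno = np.array([CASE] * 10 + [CONTROL] * 10)
        return build_cohort(geno, pheno, chromosomes=["1", "2"])

    def test_constructed_separation(self):
        cohort = self.separation_cohort()
        pat = GenotypePattern("rs1", 1, "rs2", 1, "1", "2")
        assert pattern_table(cohort, pat).as_tuple() == (10, 0, 0, 10)

    def test_missing_individuals_excluded(self):
        cohort = self.separation_cohort()
        cohort.genotypes[0, 0] = -1
        cohort.genotypes[1, 0] = -1
        pat = GenotypePattern("rs1", 1, "rs2", 1, "1", "2")
        assert pattern_table(cohort, pat).as_tuple() == (8, 0, 0, 10)
        assert pattern_table(cohort, pat, missing_policy="absent").as_tuple() == (
            8, 2, 0, 10,
        )

    def test_unknown_variant(self):
        with pytest.raises(VariantLookupError):
            pattern_table(self.separation_cohort(),
                          GenotypePattern("rsX", 0, "rs2", 0))

    @pytest.mark.parametrize("missing_policy", ["exclude", "absent"])
    def test_matches_naive_double_loop(self, missing_policy):
        cohort = simulate_cohort(
            SimulationConfig(n_cases=40, n_controls=40, n_variants=6,
                             missing_rate=0.1, seed=13)
        )
        for pat in [GenotypePattern("rs1", 1, "rs5", 0, "1", "3"),
                    GenotypePattern("rs2", 2, "rs6", 1, "1", "4")]:
            ja = cohort.variant_index(pat.variant_a)
            jb = cohort.variant_index(pat.variant_b)
            counts = [0, 0, 0, 0]
            for i in range(cohort.n_individuals):
                ga, gb = cohort.genotypes[i, ja], cohort.genotypes[i, jb]
                if missing_policy == "exclude" and (ga < 0 or gb < 0):
                    continue
                present = ga == pat.genotype_a and gb == pat.genotype_b
                row = 0 if cohort.phenotype[i] == CASE else 2
                counts[row + (0 if present else 1)] += 1
            assert pattern_table(cohort, pat, missing_policy).as_tuple() == tuple(
                counts
            )


class TestScanPairs:
    def small_cohort(self, seed=0, n_variants=8, chromosomes=None):
        cfg = SimulationConfig(n_cases=50, n_controls=50, n_variants=n_variants,
                               n_chromosomes=2, seed=seed)
        cohort = simulate_cohort(cfg)
        if chromosomes is not None:
            from tests.conftest import build_cohort as bc

            cohort = bc(cohort.genotypes, cohort.phenotype, chromosomes)
        return cohort

    def test_cross_chromosome_eligibility(self):
        cohort = self.small_cohort(n_variants=4, chromosomes=["1", "1", "2", "2"])
        ranked = scan_pairs(cohort, support_min=1, capacity=1000)
        pairs = {
            (sp.pattern.variant_a, sp.pattern.variant_b) for sp in ranked
        }
        assert pairs <= {("rs1", "rs3"), ("rs1", "rs4"),
                         ("rs2", "rs3"), ("rs2", "rs4")}
        assert ranked.n_tests <= 36

    def test_single_chromosome_yields_empty_scan(self):
        cohort = self.small_cohort(n_variants=4, chromosomes=["1"] * 4)
        ranked = scan_pairs(cohort, support_min=1)
        assert len(ranked) == 0 and ranked.n_tests == 0

    def test_worker_count_does_not_change_output(self):
        cohort = simulate_cohort(SimulationConfig(n_variants=20, seed=21))
        one = scan_pairs(cohort, support_min=5, capacity=200, workers=1)
        two = scan_pairs(cohort, support_min=5, capacity=200, workers=2)
        assert one == two

    def test_case_control_swap_leaves_p_unchanged(self):
        cohort = simulate_cohort(SimulationConfig(n_variants=10, seed=22))
        flipped = build_cohort(cohort.genotypes, 1 - cohort.phenotype,
                               [v.chromosome for v in cohort.variants])
        a = scan_pairs(cohort, support_min=10, capacity=50)
        b = scan_pairs(flipped, support_min=10, capacity=50)
        pa = {(sp.pattern.variant_a, sp.pattern.genotype_a,
               sp.pattern.variant_b, sp.pattern.genotype_b): sp.p_fisher
              for sp in a}
        pb = {(sp.pattern.variant_a, sp.pattern.genotype_a,
               sp.pattern.variant_b, sp.pattern.genotype_b): sp.p_fisher
              for sp in b}
        assert pa == pb

    def test_bonferroni_and_rank_invariants(self):
        cohort = simulate_cohort(SimulationConfig(n_variants=15, seed=23))
        ranked = scan_pairs(cohort, support_min=10, capacity=100)
        assert [sp.rank for sp in ranked] == list(range(1, len(ranked) + 1))
        for sp in ranked:
            assert sp.p_fisher <= sp.p_bonferroni <= 1.0
        chis = [sp.chisq for sp in ranked]
        assert all(a >= b for a, b in zip(chis, chis[1:]))

    def test_excluded_variants_absent_from_scan(self):
        cohort = simulate_cohort(SimulationConfig(n_variants=10, seed=24))
        ranked = scan_pairs(cohort, support_min=5, capacity=500,
                            excluded={"rs1", "rs7"})
        involved = {v for sp in ranked
                    for v in (sp.pattern.variant_a, sp.pattern.variant_b)}
        assert not involved & {"rs1", "rs7"}

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_digenic_pattern_ranks_first(self, seed):
        from digenet import DigenicEffect

        eff = DigenicEffect(variant_a=3, variant_b=30, genotype_a=1,
                            genotype_b=1, risk_multiplier=8.0)
        cfg = SimulationConfig(n_variants=50, n_chromosomes=4,
                               allele_freq_range=(0.3, 0.3),
                               digenic_effects=[eff], seed=seed)
        ranked = scan_pairs(simulate_cohort(cfg))
        top = ranked.patterns[0].pattern
        assert {top.variant_a, top.variant_b} == {"rs4", "rs31"}
        assert (top.genotype_a, top.genotype_b) == (1, 1)
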