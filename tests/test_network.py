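"""Connectivity extraction, the T = c/r statistic, rank permutation and S1/S2/R."""

import numpy as np
import pytest

from digenet import (
    ValidationError,
    VariantLookupError,
    DigenicNetworkTest,
    connectivity_curve,
    dnt_statistic,
    extract_unique_variants,
    network_summary,
    permutation_null,
    simulate_ranked_list,
)
from tests.conftest import make_ranked_list


class TestExtraction:
    def test_single_edge(self):
        stats = extract_unique_variants(make_ranked_list([("vA", "vB")]))
        assert len(stats) == 2
        assert all((s.c, s.r, s.T) == (1, 1, 1.0) for s in stats)

    def test_triangle_hand_enumeration(self, triangle_list):
        for mode in ("genotype_pairs", "distinct_partners"):
            by_id = {
                s.variant_id: s
                for s in extract_unique_variants(triangle_list, mode=mode)
            }
            assert (by_id["vA"].c, by_id["vA"].r, by_id["vA"].T) == (2, 1, 2.0)
            assert (by_id["vB"].c, by_id["vB"].r, by_id["vB"].T) == (2, 1, 2.0)
            assert (by_id["vC"].c, by_id["vC"].r, by_id["vC"].T) == (2, 2, 1.0)

    def test_connection_modes_differ_on_repeated_pair(self):
        # same variant pair at ranks 1 and 2 via two genotype combinations
        ranked = make_ranked_list([("vA", 0, "vB", 0), ("vA", 1, "vB", 1)])
        gp = {s.variant_id: s.c
              for s in extract_unique_variants(ranked, mode="genotype_pairs")}
        dp = {s.variant_id: s.c
              for s in extract_unique_variants(ranked, mode="distinct_partners")}
        assert gp["vA"] == 2 and dp["vA"] == 1

    def test_empty_list_rejected(self):
        ranked = make_ranked_list([("vA", "vB")])
        ranked.patterns = []
        with pytest.raises(ValidationError):
            extract_unique_variants(ranked)

    @pytest.mark.parametrize("n_patterns,n_variants", [(50, 30), (500, 100)])
    def test_connection_conservation(self, n_patterns, n_variants):
        ranked = simulate_ranked_list(n_patterns, n_variants, seed=1)
        stats = extract_unique_variants(ranked, mode="genotype_pairs")
        assert sum(s.c for s in stats) == 2 * n_patterns


class TestDntStatistic:
    def test_unit_case(self):
        assert dnt_statistic(1, 1) == 1.0

    def test_exact_quotient(self):
        assert dnt_statistic(5619, 16) == 5619 / 16

    @pytest.mark.parametrize("c,r", [(0, 1), (1, 0), (-2, 3)])
    def test_positivity_required(self, c, r):
        with pytest.raises(ValidationError):
            dnt_statistic(c, r)


class TestPermutationNull:
    def two_variant_stats(self):
        ranked = make_ranked_list([("vA", "vB")])
        stats = extract_unique_variants(ranked)
        stats[0].c, stats[0].r, stats[0].T = 10, 1, 10.0
        stats[1].c, stats[1].r, stats[1].T = 1, 2, 0.5
        return stats

    def test_two_variant_exact_enumeration(self):
        # two equally likely rank assignments: T_max in {10, 5}; the
        # proportion of T_max >= 10 converges to 1/2, and T_max >= 0.5 always
        null, stats = permutation_null(self.two_variant_stats(), n_perm=20_000,
                                       seed=3)
        assert set(np.round(null.max_values, 12)) == {10.0, 5.0}
        assert stats[0].p_empirical == pytest.approx(0.5, abs=0.02)
        assert stats[1].p_empirical == 1.0

    def test_equal_connections_give_p_one_for_top(self):
        ranked = simulate_ranked_list(10, 20, seed=2)
        stats = extract_unique_variants(ranked)
        for i, s in enumerate(stats):
            s.c, s.r = 7, i + 1
            s.T = s.c / s.r
        _, stats = permutation_null(stats, n_perm=500, seed=0)
        assert stats[0].p_empirical == 1.0

    def test_single_variant_degenerate(self):
        stats = self.two_variant_stats()[:1]
        _, stats = permutation_null(stats, n_perm=100, seed=0)
        assert stats[0].p_empirical == 1.0

    def test_deterministic_given_seed(self):
        ranked = simulate_ranked_list(200, 50, seed=9)
        s1 = extract_unique_variants(ranked)
        s2 = extract_unique_variants(ranked)
        permutation_null(s1, n_perm=500, seed=42)
        permutation_null(s2, n_perm=500, seed=42)
        assert [a.p_empirical for a in s1] == [b.p_empirical for b in s2]

    def test_p_monotone_nonincreasing_in_T(self):
        ranked = simulate_ranked_list(300, 80, seed=10)
        stats = extract_unique_variants(ranked)
        _, stats = permutation_null(stats, n_perm=1000, seed=5)
        ordered = sorted(stats, key=lambda s: s.T)
        ps = [s.p_empirical for s in ordered]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_add_one_estimator(self):
        stats = self.two_variant_stats()
        _, stats = permutation_null(stats, n_perm=1000, seed=1, add_one=True)
        assert 0 < stats[0].p_empirical < 1
        assert stats[1].p_empirical == 1.0


class TestNetworkSummary:
    def fitted_stats(self, seed=0):
        ranked = simulate_ranked_list(200, 50, seed=seed)
        stats = extract_unique_variants(ranked)
        _, stats = permutation_null(stats, n_perm=500, seed=seed)
        return stats

    def test_single_lead_distinct_partner_mode(self):
        ranked = simulate_ranked_list(30, 40, hub_spec=("v1", 10), seed=4,
                                      n_chromosomes=4)
        stats = extract_unique_variants(ranked, mode="distinct_partners")
        _, stats = permutation_null(stats, n_perm=500, seed=4)
        hub = next(s for s in stats if s.variant_id == "v1")
        for s in stats:
            s.p_empirical = 1.0
        hub.p_empirical = 0.01
        ns = network_summary(stats, alpha=0.05, scope="lead_set",
                             mode="distinct_partners")
        assert ns.lead_set == ("v1",)
        assert ns.S1 == ns.S2 == hub.c
        assert ns.R == 1.0

    def test_all_unique_scope_uses_every_variant(self):
        stats = self.fitted_stats()
        ns = network_summary(stats, scope="all_unique")
        assert ns.S1 == sum(s.c for s in stats)
        assert ns.S2 <= ns.S1 and ns.R >= 1.0

    def test_empty_lead_set_flagged(self):
        stats = self.fitted_stats()
        for s in stats:
            s.p_empirical = 1.0
        ns = network_summary(stats, scope="lead_set")
        assert ns.S1 == 0 and ns.S2 == 0
        assert not ns.defined and np.isnan(ns.R)


class TestConnectivityCurve:
    def test_below_first_occurrence_is_zero(self):
        ranked = simulate_ranked_list(20, 30, seed=6)
        stats = extract_unique_variants(ranked)
        late = max(stats, key=lambda s: s.r)
        if late.r > 1:
            curve = connectivity_curve(ranked, late.variant_id, [late.r - 1])
            assert curve.counts == (0,)

    def test_full_length_equals_c(self):
        ranked = simulate_ranked_list(50, 30, seed=7)
        for s in extract_unique_variants(ranked)[:5]:
            curve = connectivity_curve(ranked, s.variant_id, [len(ranked)])
            assert curve.counts[-1] == s.c

    def test_triangle_curve(self, triangle_list):
        curve = connectivity_curve(triangle_list, "vC", [1, 2, 3])
        assert curve.counts == (0, 1, 2)

    def test_counts_non_decreasing(self):
        ranked = simulate_ranked_list(100, 40, seed=8)
        s = extract_unique_variants(ranked)[0]
        curve = connectivity_curve(ranked, s.variant_id, [10, 25, 50, 100])
        assert all(a <= b for a, b in zip(curve.counts, curve.counts[1:]))

    def test_absent_variant_rejected(self, triangle_list):
        with pytest.raises(VariantLookupError):
            connectivity_curve(triangle_list, "vZ", [1])


def test_model_fit_summary_roundtrip():
    ranked = simulate_ranked_list(300, 60, hub_spec=("v1", 40), seed=12,
                                  n_chromosomes=4)
    res = DigenicNetworkTest(ranked, n_perm=1000, alpha=0.05).fit(seed=3)
    assert res.n_unique == len(res.stats)
    hub = next(s for s in res.stats if s.variant_id == "v1")
    assert hub.r == 1 and hub.p_empirical == min(s.p_empirical for s in res.stats)
    text = res.summary()
    assert "Digenic Network Test" in text and "S1" in text
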