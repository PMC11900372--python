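"""Monte-Carlo enrichment, ORA hypergeometrics, BH FDR, bias control."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from netprior.io_formats import PathwaySet
from netprior import enrichment_stats as es


def hypergeom_tail_oracle(k, N, K, n):
    """Exact upper-tail P(X >= k) by direct enumeration with rationals."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), math.comb(N, n))
    return float(total)


def bh_oracle(p_values):
    """Hand step-up: adjusted_i = min over j>=rank_i of p_(j) * m / j."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        adjusted[i] = running
    return adjusted


def pathway(name, members):
    return PathwaySet(name, "test", frozenset(members))


class TestMonteCarloEnrichment:
    UNIVERSE = [f"S{i:04d}" for i in range(200)]

    def test_degenerate_null_observed_equal_gives_p_one(self):
        # category == universe: every draw and the observation cover 100%
        result = es.monte_carlo_enrichment(
            self.UNIVERSE, self.UNIVERSE[:50], self.UNIVERSE, n_draws=50, rng_seed=0
        )
        assert result.observed_pct == result.null_mean == 25.0
        assert result.p_value == 1.0 and result.t_statistic == 0.0

    def test_category_fully_in_network_is_extreme(self):
        category = self.UNIVERSE[:20]
        nodes = set(category) | set(self.UNIVERSE[100:130])
        result = es.monte_carlo_enrichment(
            self.UNIVERSE, nodes, category, n_draws=100, rng_seed=1
        )
        assert result.observed_pct == 100.0
        assert result.p_value < 1e-6
        assert result.empirical_percentile == pytest.approx(1 / 101)

    def test_category_empty_is_error(self):
        with pytest.raises(ValueError):
            es.monte_carlo_enrichment(self.UNIVERSE, self.UNIVERSE[:5], [], 10, 0)

    def test_sample_larger_than_universe_is_error(self):
        with pytest.raises(ValueError):
            es.monte_carlo_enrichment(
                self.UNIVERSE[:10], self.UNIVERSE[:20], self.UNIVERSE[:5], 10, 0
            )

    def test_fixed_seed_bit_reproducible(self):
        args = (self.UNIVERSE, self.UNIVERSE[:50], self.UNIVERSE[:30], 200, 42)
        a, b = es.monte_carlo_enrichment(*args), es.monte_carlo_enrichment(*args)
        assert a == b

    def test_null_mean_stable_across_seeds(self):
        # hypergeometric analytic mean: 100 * sample_size / |universe|
        analytic = 100.0 * 50 / len(self.UNIVERSE)
        for seed in (1, 2, 3):
            r = es.monte_carlo_enrichment(
                self.UNIVERSE, self.UNIVERSE[:50], self.UNIVERSE[:40], 500, seed
            )
            assert abs(r.null_mean - analytic) <= 4 * r.null_sd / np.sqrt(r.n_draws)


class TestORA:
    REFERENCE = [f"R{i:03d}" for i in range(20)]

    def test_zero_overlap_gives_p_one_er_zero(self):
        results = es.ora(
            self.REFERENCE[:5], [pathway("PW", self.REFERENCE[10:15])], self.REFERENCE
        )
        assert results[0].p_value == 1.0
        assert results[0].enrichment_ratio == 0.0

    def test_perfect_overlap_closed_form(self):
        # query == pathway, 5 genes of 20: p = 1 / C(20,5)
        query = set(self.REFERENCE[:5])
        results = es.ora(query, [pathway("PW", query)], self.REFERENCE)
        assert results[0].p_value == pytest.approx(1 / math.comb(20, 5), rel=1e-12)
        assert results[0].enrichment_ratio == pytest.approx(4.0)  # (5/5)/(5/20)

    def test_agrees_with_tail_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            N = int(rng.integers(8, 31))
            reference = [f"R{i:03d}" for i in range(N)]
            n = int(rng.integers(2, N))
            K = int(rng.integers(1, N))
            query = set(rng.choice(reference, size=n, replace=False))
            members = set(rng.choice(reference, size=K, replace=False))
            (res,) = es.ora(query, [pathway("PW", members)], reference)
            oracle = hypergeom_tail_oracle(res.k, N, K, n)
            assert res.p_value == pytest.approx(oracle, abs=1e-12)
            assert res.enrichment_ratio == pytest.approx((res.k / n) / (K / N))

    def test_query_outside_reference_dropped(self):
        results = es.ora(
            set(self.REFERENCE[:3]) | {"OUTSIDER"},
            [pathway("PW", self.REFERENCE[:3])],
            self.REFERENCE,
        )
        assert results[0].n_list == 3

    def test_pathway_disjoint_from_reference_skipped(self):
        results = es.ora(
            self.REFERENCE[:3],
            [pathway("PW", ["X1", "X2"]), pathway("PW2", self.REFERENCE[:4])],
            self.REFERENCE,
        )
        assert [r.pathway for r in results] == ["PW2"]

    def test_empty_reference_is_error(self):
        with pytest.raises(ValueError):
            es.ora(["A"], [pathway("PW", ["A"])], [])

    def test_planted_pathway_attains_smallest_fdr(self, small_fixtures):
        fx = small_fixtures
        mapped = sorted(
            set(fx.truth["planted_candidates"]) | set(fx.truth["background_candidates"])
        )
        results = es.ora(mapped, fx.pathways, fx.universe)
        best = min(results, key=lambda r: (r.fdr, r.p_value))
        assert best.pathway == "PLANTED_PATHWAY"
        assert best.fdr <= 0.05


class TestBHFDR:
    def test_step_up_by_hand(self):
        assert es.bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert es.bh_fdr([0.2]) == [0.2]

    def test_all_ones_stay_one(self):
        assert es.bh_fdr([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            es.bh_fdr([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=30)
    )
    def test_matches_oracle_and_permutation_invariant(self, p_values):
        adjusted = es.bh_fdr(p_values)
        assert adjusted == pytest.approx(bh_oracle(p_values), abs=1e-12)
        order = np.argsort(p_values)[::-1]
        permuted = es.bh_fdr([p_values[i] for i in order])
        assert [permuted[list(order).index(i)] for i in range(len(p_values))] == pytest.approx(
            adjusted, abs=1e-12
        )


class TestRandomORAControl:
    REFERENCE = [f"R{i:03d}" for i in range(300)]
    MAPPED = [f"R{i:03d}" for i in range(60)]

    def test_pathway_covering_mapped_flagged_at_every_size(self):
        cover = pathway("COVER", self.MAPPED[:54])  # 90% of the mapped pool
        biased = es.random_ora_control(
            self.MAPPED, [40, 20, 10], [cover], self.REFERENCE, rng_seed=5
        )
        assert all("COVER" in flags for flags in biased.values())

    def test_disjoint_pathway_never_flagged(self):
        disjoint = pathway("FAR", self.REFERENCE[200:250])
        biased = es.random_ora_control(
            self.MAPPED, [40, 20], [disjoint], self.REFERENCE, rng_seed=5
        )
        assert all("FAR" not in flags for flags in biased.values())

    def test_threshold_requires_two_of_three(self):
        assert es.flag_biased({"PW": 1}, min_significant=2) == set()
        assert es.flag_biased({"PW": 2}, min_significant=2) == {"PW"}
        assert es.flag_biased({"PW": 3, "QW": 1}, min_significant=2) == {"PW"}

    def test_size_exceeding_pool_is_error(self):
        with pytest.raises(ValueError):
            es.random_ora_control(self.MAPPED, [100], [], self.REFERENCE)

    def test_bias_flags_propagate_into_results(self):
        results = es.ora(
            self.MAPPED[:10],
            [pathway("A", self.MAPPED[:10]), pathway("B", self.REFERENCE[100:110])],
            self.REFERENCE,
        )
        flagged = es.apply_bias_flags(results, {"A"})
        assert [r.bias_flag for r in flagged] == [True, False]
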