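"""Hypergeometric testing, BH adjustment, multiway overlaps, metaprofiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rosette.enrichment import (
    bh_adjust,
    hypergeometric_enrichment,
    interval_overlap_enrichment,
    multiway_overlap_counts,
    signal_profile,
)
from rosette.intervals import GenomicInterval, IntervalSet
from rosette.superenhancers import SignalLibrary

from _oracles import (
    bh_stepup,
    hypergeom_by_enumeration,
    hypergeom_upper_tail_exact,
)


class TestHypergeometricEnrichment:
    def test_zero_overlap_is_certain(self):
        assert hypergeometric_enrichment(100, 10, 10, 0).p_value == 1.0

    def test_small_case_equals_enumeration_of_draws(self):
        # N=10, K=5, n=4, k=3: 55 of the C(10,4)=210 draws have >=3 hits
        res = hypergeometric_enrichment(10, 5, 4, 3)
        exact = hypergeom_by_enumeration(10, 5, 4, 3)
        assert exact == pytest.approx(55 / 210)
        assert res.p_value == pytest.approx(float(exact), rel=1e-12)

    def test_matches_exact_rational_tail_over_small_universe(self):
        for N in range(2, 9):
            for K in range(0, N + 1):
                for n in range(0, N + 1):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        p = hypergeometric_enrichment(N, K, n, k).p_value
                        exact = float(hypergeom_upper_tail_exact(N, K, n, k))
                        assert p == pytest.approx(exact, rel=1e-9), (N, K, n, k)

    def test_matches_permutation_oracle_large_case(self, rng):
        N, K, n, k = 1000, 100, 100, 30
        p = hypergeometric_enrichment(N, K, n, k).p_value
        draws = rng.hypergeometric(K, N - K, n, size=200_000)
        mc = (draws >= k).mean()
        se = max(np.sqrt(mc * (1 - mc) / draws.size), 1e-7)
        assert abs(p - mc) <= 3 * se + 1e-9

    def test_symmetric_in_set_roles(self):
        a = hypergeometric_enrichment(500, 80, 40, 12).p_value
        b = hypergeometric_enrichment(500, 40, 80, 12).p_value
        assert a == pytest.approx(b, rel=1e-12)

    def test_p_decreases_as_overlap_grows(self):
        ps = [hypergeometric_enrichment(200, 50, 40, k).p_value for k in range(0, 30)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_log_space_stability_in_deep_tail(self):
        p = hypergeometric_enrichment(100_000, 1000, 1000, 500).p_value
        assert 0 < p < 1e-300  # survives where naive summation underflows

    def test_lower_tail_option(self):
        up = hypergeometric_enrichment(100, 30, 30, 2, tail="upper").p_value
        lo = hypergeometric_enrichment(100, 30, 30, 2, tail="lower").p_value
        assert lo < 0.05 < up  # 2 overlaps is depleted, not enriched

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(10, 5, 4, 5)
        with pytest.raises(ValueError):
            hypergeometric_enrichment(10, 12, 4, 2)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_uniformly_spaced_pvalues_all_equal_max(self):
        # step-up: adj_i = min_j>=i p_(j) m/j = 0.04 for all four
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_matches_independent_stepup_oracle(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, int(rng.integers(1, 200)))
            assert np.allclose(bh_adjust(p), bh_stepup(p.tolist()))

    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 500)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), ref)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=100, derandomize=True)
    def test_adjusted_at_least_raw_and_capped(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)  # monotone in sorted order

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])


class TestMultiwayOverlapCounts:
    def test_identical_gene_sets_all_in_both_cell(self):
        rows = multiway_overlap_counts({"A": {"g1", "g2"}, "B": {"g1", "g2"}})
        assert len(rows) == 1
        assert rows[0]["combination"] == ("A", "B") and rows[0]["total"] == 2

    def test_disjoint_sets_only_singletons(self):
        rows = multiway_overlap_counts({"A": {"g1"}, "B": {"g2"}, "C": {"g3"}})
        combos = {r["combination"] for r in rows}
        assert combos == {("A",), ("B",), ("C",)}

    def test_three_gene_sets_match_enumeration(self, rng):
        universe = [f"g{i}" for i in range(200)]
        sets = {
            name: {g for g in universe if rng.random() < 0.4}
            for name in ("A", "B", "C")
        }
        rows = {r["combination"]: r["total"] for r in multiway_overlap_counts(sets)}
        # brute force every element into its exact membership cell
        expect: dict[tuple, int] = {}
        for g in universe:
            combo = tuple(n for n in ("A", "B", "C") if g in sets[n])
            if combo:
                expect[combo] = expect.get(combo, 0) + 1
        assert rows == expect

    def test_interval_sets_counted_per_source(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 500, 600)])
        b = IntervalSet([GenomicInterval("chr1", 50, 150)])
        rows = multiway_overlap_counts({"A": a, "B": b})
        by_combo = {r["combination"]: r for r in rows}
        assert by_combo[("A",)]["counts"] == {"A": 1}
        assert by_combo[("A", "B")]["counts"] == {"A": 1, "B": 1}

    def test_set_count_limits(self):
        with pytest.raises(ValueError):
            multiway_overlap_counts({"A": set()})
        with pytest.raises(ValueError):
            multiway_overlap_counts({str(i): {i} for i in range(5)})


def _uniform_lib(n=4000, length=100_000):
    mids = np.linspace(200, length - 200, n).astype(int)
    return SignalLibrary(
        IntervalSet(GenomicInterval("chr1", int(m) - 100, int(m) + 100) for m in mids)
    )


class TestSignalProfile:
    def test_default_parameters_give_40_bins(self):
        sites = IntervalSet([GenomicInterval("chr1", 49_000, 51_000)])
        prof = signal_profile(sites, _uniform_lib())
        assert len(prof.mean_signal) == 40
        assert prof.bin_edges[0] == -2000 and prof.bin_edges[-1] == 2000

    def test_uniform_coverage_gives_flat_profile(self):
        sites = IntervalSet(
            GenomicInterval("chr1", s, s + 1000) for s in range(20_000, 80_000, 10_000)
        )
        prof = signal_profile(sites, _uniform_lib())
        assert np.allclose(prof.mean_signal, prof.mean_signal.mean(), rtol=0.2)

    def test_hand_placed_fragments_land_in_expected_bins(self):
        # site center 10_000; fragments with midpoints in two known bins
        site = IntervalSet([GenomicInterval("chr1", 9_900, 10_100)])
        mids = [10_000 - 1950] * 3 + [10_000 + 250] * 7  # bins 0 and 22
        lib = SignalLibrary(
            IntervalSet(GenomicInterval("chr1", m - 50, m + 50) for m in mids),
            library_size=1_000_000,
        )
        prof = signal_profile(site, lib)
        counts = prof.mean_signal * lib.library_size / 1e6
        assert counts[0] == pytest.approx(3)
        assert counts[22] == pytest.approx(7)
        assert counts.sum() == pytest.approx(10)

    def test_union_profile_is_count_weighted_mean(self, rng):
        lib = _uniform_lib()
        s1 = IntervalSet(
            GenomicInterval("chr1", int(s), int(s) + 500)
            for s in rng.integers(10_000, 80_000, 7)
        )
        s2 = IntervalSet(
            GenomicInterval("chr1", int(s), int(s) + 500)
            for s in rng.integers(10_000, 80_000, 13)
        )
        p1 = signal_profile(s1, lib)
        p2 = signal_profile(s2, lib)
        both = signal_profile(IntervalSet(list(s1) + list(s2)), lib)
        weighted = (7 * p1.mean_signal + 13 * p2.mean_signal) / 20
        assert np.allclose(both.mean_signal, weighted)

    def test_window_must_be_divisible_by_bin(self):
        sites = IntervalSet([GenomicInterval("chr1", 0, 10)])
        with pytest.raises(ValueError):
            signal_profile(sites, _uniform_lib(), half_window_bp=1050, bin_bp=100)

    def test_empty_sites_rejected(self):
        with pytest.raises(ValueError):
            signal_profile(IntervalSet(), _uniform_lib())


class TestIntervalOverlapEnrichment:
    def test_enrichment_detected_on_planted_overlap(self, rng):
        universe = IntervalSet(
            GenomicInterval("chr1", 1000 * i, 1000 * i + 500) for i in range(200)
        )
        members = list(universe)
        a = IntervalSet(members[:50])
        b = IntervalSet(members[:40])  # nested: maximal overlap
        res = interval_overlap_enrichment(universe, a, b)
        assert res.overlap_k == 40
        assert res.p_value < 1e-10
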