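"""Synthetic maps, planted-cluster scenarios, and detection metrics."""

import numpy as np
import pytest

from multiscan import (
    ScanConfig,
    Window,
    assign_baseline,
    evaluate_detection,
    generate_dataset,
    make_scenario,
    plant_clusters,
    power_study,
    synthetic_map,
)
from multiscan.simulate import (
    CLUSTER_EXPECTED_TOTALS,
    SCENARIO_RRS,
    TOTAL_EXPECTED,
)


class TestSyntheticMap:
    def test_lattice_324(self):
        rmap = synthetic_map(324)
        assert rmap.m == 324
        degs = [len(nb) for nb in rmap.neighbors]
        # 16*16 interior regions of an 18x18 rook grid have 4 neighbours
        assert sum(d == 4 for d in degs) == 256
        assert sum(d == 2 for d in degs) == 4  # corners

    def test_2x2_lattice(self):
        rmap = synthetic_map(4)
        assert len(rmap.edges()) == 4

    def test_random_layout_deterministic(self):
        a = synthetic_map(30, "random-planar", seed=3)
        b = synthetic_map(30, "random-planar", seed=3)
        assert np.allclose(a.centroids, b.centroids)
        assert a.edges() == b.edges()

    def test_random_layout_connected(self):
        import networkx as nx

        for seed in range(5):
            rmap = synthetic_map(40, "random-planar", seed=seed)
            g = nx.Graph(rmap.edges())
            g.add_nodes_from(range(rmap.m))
            assert nx.is_connected(g)


class TestPlantClusters:
    def test_reference_design(self):
        rmap = synthetic_map(324)
        clusters = plant_clusters(rmap, (5, 7, 8, 8, 5), seed=0)
        assert [w.size for w in clusters] == [5, 7, 8, 8, 5]
        assert sum(w.size for w in clusters) == 33
        all_members = set()
        for w in clusters:
            assert not (all_members & w.members)
            all_members |= w.members
            assert rmap.is_connected_subset(w.members)
        # min graph separation 2: no two clusters adjacent
        for a in clusters:
            for b in clusters:
                if a is b:
                    continue
                for i in a.members:
                    assert not (rmap.neighbors[i] & b.members)

    def test_singleton(self):
        rmap = synthetic_map(9)
        clusters = plant_clusters(rmap, [1], seed=1)
        assert clusters[0].size == 1

    def test_separation_waived_allows_cover(self):
        rmap = synthetic_map(9)
        clusters = plant_clusters(rmap, [9], seed=2, min_separation=1)
        assert clusters[0].size == 9

    def test_impossible_separation_raises(self):
        # three separated clusters of 3 cannot fit a 3x3 grid with buffers
        rmap = synthetic_map(9)
        with pytest.raises(ValueError, match="larger map"):
            plant_clusters(rmap, [3, 3, 3], seed=3, max_attempts=20)


class TestAssignBaseline:
    def test_equal_split(self):
        rmap = synthetic_map(324)
        clusters = plant_clusters(rmap, (5,), seed=0)
        mu0 = assign_baseline(rmap, clusters, [1941.88], 1000.0)
        inside = sorted(clusters[0].members)
        assert np.allclose(mu0[inside], 1941.88 / 5)
        assert mu0[inside][0] == pytest.approx(388.376)

    def test_background_zero(self):
        rmap = synthetic_map(9)
        clusters = plant_clusters(rmap, (3,), seed=1)
        mu0 = assign_baseline(rmap, clusters, [30.0], 0.0)
        assert mu0.sum() == pytest.approx(30.0)

    def test_single_region_cluster(self):
        rmap = synthetic_map(9)
        clusters = plant_clusters(rmap, (1,), seed=1)
        mu0 = assign_baseline(rmap, clusters, [7.5], 10.0)
        assert mu0[next(iter(clusters[0].members))] == pytest.approx(7.5)

    def test_reference_totals_preserved(self):
        sc = make_scenario("S2", seed=0)
        assert sc.baseline.sum() == pytest.approx(TOTAL_EXPECTED)
        for w, label in zip(sc.true_clusters, "ABCDE"):
            idx = sorted(w.members)
            assert sc.baseline[idx].sum() == pytest.approx(
                CLUSTER_EXPECTED_TOTALS[label])


class TestGenerateDataset:
    def test_null_scenario_means(self):
        sc = make_scenario("S1", seed=0)
        assert np.all(sc.rate_multiplier == 1.0)
        rng = np.random.default_rng(0)
        data = generate_dataset(sc, rng)
        # total within 6 sd of the expectation total
        assert abs(data.total_observed - TOTAL_EXPECTED) < 6 * np.sqrt(TOTAL_EXPECTED)

    def test_cluster_mean_elevated(self):
        sc = make_scenario("S2", seed=0)
        idx = sorted(sc.true_clusters[0].members)
        assert np.allclose(sc.rate_multiplier[idx] * sc.baseline[idx],
                           1.5 * 1941.88 / 5)

    def test_replicate_totals_match_poisson_moments(self):
        sc = make_scenario("S6", n_regions=36, sizes=(3,), seed=1)
        mean_total = float((sc.rate_multiplier * sc.baseline).sum())
        rng = np.random.default_rng(7)
        totals = [generate_dataset(sc, rng).total_observed for _ in range(200)]
        se = np.sqrt(mean_total / 200)
        assert abs(np.mean(totals) - mean_total) < 4 * se

    def test_scenario_tags(self):
        assert set(SCENARIO_RRS) == {f"S{i}" for i in range(1, 8)}
        with pytest.raises(ValueError, match="valid tags"):
            make_scenario("S9")


class TestEvaluateDetection:
    def test_perfect_detection(self):
        truth = [Window(frozenset({0, 1})), Window(frozenset({4}))]
        ev = evaluate_detection(truth, truth, 10)
        assert ev.sensitivity == 1.0
        assert ev.ppv == 1.0

    def test_superset_detection(self):
        truth = [Window(frozenset(range(33)))]
        detected = [Window(frozenset(range(35)))]
        ev = evaluate_detection(detected, truth, 40)
        assert ev.sensitivity == 1.0
        assert ev.ppv == pytest.approx(33 / 35)

    def test_disjoint_detection(self):
        truth = [Window(frozenset({0, 1}))]
        detected = [Window(frozenset({5, 6}))]
        ev = evaluate_detection(detected, truth, 10)
        assert ev.sensitivity == 0.0
        assert ev.ppv == 0.0

    def test_nothing_detected_ppv_missing(self):
        truth = [Window(frozenset({0, 1}))]
        ev = evaluate_detection([], truth, 10)
        assert ev.ppv is None
        assert ev.sensitivity == 0.0

    def test_rr1_clusters_not_counted_as_true(self):
        sc = make_scenario("S6", seed=0)  # only cluster A elevated
        assert sc.true_regions == sc.true_clusters[0].members


class TestPowerStudy:
    def test_single_dataset_power_binary(self):
        sc = make_scenario("S2", n_regions=36, sizes=(4,), seed=2)
        cfg = ScanConfig(kmax=3, replications=0)
        summary, table = power_study(sc, n_datasets=1, R=19,
                                     scan_config=cfg, seed=0)
        assert summary["power"] in (0.0, 1.0)
        assert len(table) == 1

    def test_scp_method_counts_significant_clusters(self):
        sc = make_scenario("S2", n_regions=36, sizes=(4,), seed=2)
        cfg = ScanConfig(kmax=3, replications=0)
        summary, table = power_study(sc, n_datasets=3, R=19, method="scp",
                                     scan_config=cfg, seed=0)
        assert set(table.columns) >= {"significant", "k_detected",
                                      "sensitivity", "ppv"}
        assert summary["method"] == "scp"

    def test_proposed_sensitivity_at_least_scp(self):
        """Headline comparison: under the all-RR-1.5 scenario the proposed
        procedure's mean region-level sensitivity is at least the SCP's
        (100 datasets, reference design)."""
        sc = make_scenario("S2", seed=1)
        cfg = ScanConfig(kmax=12, replications=0)
        s_prop, _ = power_study(sc, n_datasets=100, level=0.05, R=19,
                                method="proposed", scan_config=cfg, seed=9)
        s_scp, _ = power_study(sc, n_datasets=100, level=0.05, R=19,
                               method="scp", scan_config=cfg, seed=9)
        assert s_prop["mean_sensitivity"] >= s_scp["mean_sensitivity"]

    def test_reproducible(self):
        sc = make_scenario("S2", n_regions=36, sizes=(4,), seed=2)
        cfg = ScanConfig(kmax=3, replications=0)
        s1, t1 = power_study(sc, n_datasets=2, R=19, scan_config=cfg, seed=5)
        s2, t2 = power_study(sc, n_datasets=2, R=19, scan_config=cfg, seed=5)
        assert t1.equals(t2)
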