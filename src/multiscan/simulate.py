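"""Synthetic study areas, planted-cluster scenarios and the power study.

The generator emulates a disease-mapping study area of a few hundred
contiguous regions with a handful of disjoint planted clusters of known
relative risk.  The default design mirrors a national-scale admission
dataset: m = 324 regions (an 18x18 rook-adjacency lattice stands in for the
real map, which is not redistributable), five disjoint clusters A-E of
sizes (5, 7, 8, 8, 5) — 33 cluster regions — with baseline expected totals

    A 1941.88, B 772.14, C 760.88, D 437.49, E 598.06,

a study-area total of 333524.31 expected cases (the remainder spread
uniformly over background regions), and per-cluster relative risks given by
seven scenarios S1-S7 ranging from the null (all RR = 1) to mixtures of
weak elevations (RR 1.2-1.6).  Counts are independent Poisson draws with
mean RR_i * mu0_i.

Detection quality is summarized region-wise: sensitivity (fraction of true
cluster regions detected) and positive predictive value (fraction of
detected regions truly in clusters), plus the distribution of the selected
number of clusters and empirical power/size at a nominal level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .inference import overall_test
from .scan import ScanConfig, Window, scp_candidates
from .spatial import CaseData, RegionMap

__all__ = [
    "Scenario",
    "EvaluationMetrics",
    "SCENARIO_RRS",
    "CLUSTER_EXPECTED_TOTALS",
    "TOTAL_EXPECTED",
    "DEFAULT_CLUSTER_SIZES",
    "synthetic_map",
    "plant_clusters",
    "assign_baseline",
    "generate_dataset",
    "make_scenario",
    "evaluate_detection",
    "power_study",
]

# Cluster labels A-E with their baseline expected-count totals and the
# study-area total; relative risks per scenario tag.
CLUSTER_EXPECTED_TOTALS: dict[str, float] = {
    "A": 1941.88, "B": 772.14, "C": 760.88, "D": 437.49, "E": 598.06,
}
TOTAL_EXPECTED: float = 333524.31
DEFAULT_CLUSTER_SIZES: tuple[int, ...] = (5, 7, 8, 8, 5)

SCENARIO_RRS: dict[str, tuple[float, ...]] = {
    "S1": (1.0, 1.0, 1.0, 1.0, 1.0),
    "S2": (1.5, 1.5, 1.5, 1.5, 1.5),
    "S3": (1.3, 1.3, 1.3, 1.3, 1.3),
    "S4": (1.2, 1.2, 1.2, 1.2, 1.2),
    "S5": (1.6, 1.3, 1.4, 1.3, 1.2),
    "S6": (1.3, 1.0, 1.0, 1.0, 1.0),
    "S7": (1.2, 1.0, 1.0, 1.0, 1.0),
}


@dataclass
class Scenario:
    """A simulation condition: map, true clusters, relative risks, baseline."""

    region_map: RegionMap
    true_clusters: list[Window]
    rr: tuple[float, ...]
    baseline: np.ndarray
    tag: str = ""

    def __post_init__(self) -> None:
        if len(self.rr) != len(self.true_clusters):
            raise ValueError("one RR per cluster required")
        if any(r < 1.0 for r in self.rr):
            raise ValueError("relative risks must be >= 1 (1.0 encodes no cluster)")
        seen: set[int] = set()
        for w in self.true_clusters:
            if seen & w.members:
                raise ValueError("true clusters must be disjoint")
            seen |= w.members
            if not self.region_map.is_connected_subset(w.members):
                raise ValueError("true clusters must be connected")

    @property
    def true_regions(self) -> set[int]:
        """Regions in clusters with genuinely elevated risk (RR > 1)."""
        out: set[int] = set()
        for w, r in zip(self.true_clusters, self.rr):
            if r > 1.0:
                out |= w.members
        return out

    @property
    def rate_multiplier(self) -> np.ndarray:
        mult = np.ones(self.region_map.m)
        for w, r in zip(self.true_clusters, self.rr):
            idx = np.fromiter(w.members, dtype=np.intp)
            mult[idx] = r
        return mult


@dataclass
class EvaluationMetrics:
    """Region-level detection quality for one dataset."""

    sensitivity: float
    ppv: float | None  # None when nothing was detected
    detected_regions: int
    k_detected: int
    significant: bool | None = None


def synthetic_map(n_regions: int, layout: str = "lattice",
                  seed: int | None = None) -> RegionMap:
    """Generate a connected synthetic study area.

    ``lattice``: a rook-adjacency grid, as close to square as ``n_regions``
    allows (n_regions must factor into two sides >= 2).  ``random-planar``:
    uniformly jittered points with mutualized 6-nearest-neighbour adjacency,
    re-linked across components if needed so the graph is connected.
    """
    if n_regions < 4:
        raise ValueError("need at least 4 regions")
    width = len(str(n_regions - 1))
    ids = [f"R{i:0{width}d}" for i in range(n_regions)]
    if layout == "lattice":
        side = int(math.isqrt(n_regions))
        while n_regions % side:
            side -= 1
        if side < 2:
            raise ValueError("n_regions must factor into a grid with sides >= 2")
        rows, cols = side, n_regions // side
        coords = np.array([(i % cols, i // cols) for i in range(n_regions)], dtype=float)
        nbs: list[set[int]] = [set() for _ in range(n_regions)]
        for i in range(n_regions):
            r, c = divmod(i, cols)
            if c + 1 < cols:
                nbs[i].add(i + 1)
                nbs[i + 1].add(i)
            if r + 1 < rows:
                nbs[i].add(i + cols)
                nbs[i + cols].add(i)
        return RegionMap(ids, coords, nbs)
    if layout == "random-planar":
        rng = np.random.default_rng(seed)
        coords = rng.random((n_regions, 2))
        from .spatial import derive_adjacency

        rmap = derive_adjacency(RegionMap(ids, coords), min(6, n_regions - 1))
        g = nx.Graph(rmap.edges())
        g.add_nodes_from(range(n_regions))
        comps = [sorted(c) for c in nx.connected_components(g)]
        while len(comps) > 1:
            # link the two closest regions in different components
            best = None
            for a in comps[0]:
                for comp in comps[1:]:
                    for b in comp:
                        d = float(np.hypot(*(coords[a] - coords[b])))
                        if best is None or d < best[0]:
                            best = (d, a, b)
            assert best is not None
            _, a, b = best
            rmap.neighbors[a].add(b)
            rmap.neighbors[b].add(a)
            g.add_edge(a, b)
            comps = [sorted(c) for c in nx.connected_components(g)]
        return rmap
    raise ValueError(f"unknown layout: {layout!r}")


def plant_clusters(region_map: RegionMap, sizes, seed: int | None = None,
                   min_separation: int = 2, max_attempts: int = 200,
                   ) -> list[Window]:
    """Grow disjoint connected clusters by randomized breadth-first accretion.

    Each cluster starts from a random free region and accretes random
    frontier neighbours until it reaches its size.  With
    ``min_separation=2`` (default) a placed cluster blocks its members and
    their neighbours, so distinct clusters are never adjacent.
    """
    sizes = [int(s) for s in sizes]
    if any(s < 1 for s in sizes):
        raise ValueError("cluster sizes must be >= 1")
    if sum(sizes) > region_map.m:
        raise ValueError("cluster sizes exceed the number of regions")
    rng = np.random.default_rng(seed)
    for _attempt in range(max_attempts):
        blocked: set[int] = set()
        clusters: list[Window] = []
        ok = True
        for size in sizes:
            free = [i for i in range(region_map.m) if i not in blocked]
            if not free:
                ok = False
                break
            start = int(rng.choice(free))
            members = {start}
            frontier = sorted(set(region_map.neighbors[start]) - blocked)
            while len(members) < size and frontier:
                nxt = int(frontier.pop(int(rng.integers(len(frontier)))))
                members.add(nxt)
                for nb in region_map.neighbors[nxt]:
                    if nb not in members and nb not in blocked and nb not in frontier:
                        frontier.append(nb)
                frontier.sort()
            if len(members) < size:
                ok = False
                break
            clusters.append(Window(frozenset(members)))
            blocked |= members
            if min_separation >= 2:
                for i in members:
                    blocked |= region_map.neighbors[i]
        if ok:
            return clusters
    raise ValueError(
        "could not place clusters with the requested separation; "
        "try a larger map or fewer/smaller clusters"
    )


def assign_baseline(region_map: RegionMap, clusters, cluster_expected_totals,
                    background_total: float) -> np.ndarray:
    """Baseline expectations: equal split within each cluster, and the
    background total split equally over non-cluster regions."""
    mu0 = np.zeros(region_map.m)
    member_union: set[int] = set()
    for w, tot in zip(clusters, cluster_expected_totals):
        if float(tot) <= 0:
            raise ValueError("cluster expected totals must be positive")
        idx = np.fromiter(w.members, dtype=np.intp)
        mu0[idx] = float(tot) / w.size
        member_union |= w.members
    outside = np.array(sorted(set(range(region_map.m)) - member_union), dtype=np.intp)
    if background_total < 0:
        raise ValueError("background total must be >= 0")
    if outside.size:
        mu0[outside] = float(background_total) / outside.size
    return mu0


def make_scenario(tag: str = "S1", n_regions: int = 324,
                  layout: str = "lattice",
                  sizes=DEFAULT_CLUSTER_SIZES,
                  seed: int | None = 0) -> Scenario:
    """Build a built-in scenario (S1-S7) on a synthetic map.

    The five clusters receive the standard expected totals and the study
    total is preserved, so the expectation scale matches the reference
    design regardless of the map layout.
    """
    if tag not in SCENARIO_RRS:
        raise ValueError(
            f"unknown scenario {tag!r}; valid tags: {', '.join(sorted(SCENARIO_RRS))}"
        )
    rmap = synthetic_map(n_regions, layout, seed)
    clusters = plant_clusters(rmap, sizes, seed)
    totals = [CLUSTER_EXPECTED_TOTALS[c] for c in "ABCDE"][: len(clusters)]
    background = TOTAL_EXPECTED - sum(totals)
    baseline = assign_baseline(rmap, clusters, totals, background)
    return Scenario(rmap, clusters, SCENARIO_RRS[tag][: len(clusters)], baseline, tag)


def generate_dataset(scenario: Scenario,
                     rng: np.random.Generator | int | None = None) -> CaseData:
    """Draw counts y_i ~ Poisson(RR_i * mu0_i) independently per region."""
    rng = np.random.default_rng(rng)
    mean = scenario.rate_multiplier * scenario.baseline
    return CaseData(rng.poisson(mean), scenario.baseline)


def evaluate_detection(selected, truth, m: int) -> EvaluationMetrics:
    """Region-level sensitivity and PPV of a detected window set.

    ``truth`` may be a Scenario (then only RR > 1 clusters count as true) or
    a list of windows.
    """
    if isinstance(truth, Scenario):
        true_regions = truth.true_regions
    else:
        true_regions = set()
        for w in truth:
            true_regions |= w.members
    detected: set[int] = set()
    for w in selected:
        detected |= w.members
    hits = len(detected & true_regions)
    sens = hits / len(true_regions) if true_regions else 1.0
    ppv = hits / len(detected) if detected else None
    return EvaluationMetrics(
        sensitivity=sens, ppv=ppv, detected_regions=len(detected),
        k_detected=len(list(selected)),
    )


def power_study(scenario: Scenario, n_datasets: int = 100,
                level: float = 0.05, R: int = 99,
                method: str = "proposed",
                scan_config: ScanConfig | None = None,
                seed: int | None = 0,
                ) -> tuple[dict, pd.DataFrame]:
    """Empirical power/size, K distribution and Sen/PPV over replicate datasets.

    ``method="proposed"``: run candidate generation, criterion selection and
    the overall Monte Carlo test; a dataset is significant when
    ``p_M <= level`` and its detected regions are the selected windows.
    ``method="scp"``: run the secondary-cluster procedure with per-cluster
    Monte Carlo p-values; significant clusters are those with
    ``p_s <= level`` and a dataset is significant when at least one is.

    Returns a summary dict and the per-dataset table.  Sensitivity/PPV
    averages are taken over significant datasets.
    """
    if method not in {"proposed", "scp"}:
        raise ValueError("method must be 'proposed' or 'scp'")
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    scan_config = scan_config or ScanConfig(kmax=8, replications=0)
    rows = []
    base = 0 if seed is None else int(seed)
    for d in range(n_datasets):
        rng_d = np.random.default_rng(np.random.SeedSequence([base, 104729, d]))
        data = generate_dataset(scenario, rng_d)
        if method == "proposed":
            sel = overall_test(data, scenario.region_map, scan_config, R=R,
                               seed=int(rng_d.integers(0, 2**31 - 1)))
            significant = sel.p_m is not None and sel.p_m <= level
            windows = sel.selected_windows if significant else []
        else:
            from dataclasses import replace

            cfg = replace(scan_config, replications=R, ps_threshold=1.0)
            cands = scp_candidates(data, scenario.region_map, cfg,
                                   rng=int(rng_d.integers(0, 2**31 - 1)))
            windows = [c.window for c in cands
                       if c.p_s is not None and c.p_s <= level]
            significant = bool(windows)
        ev = evaluate_detection(windows, scenario, scenario.region_map.m)
        rows.append({
            "dataset": d,
            "significant": significant,
            "k_detected": len(windows),
            "detected_regions": ev.detected_regions,
            "sensitivity": ev.sensitivity if significant else np.nan,
            "ppv": ev.ppv if (significant and ev.ppv is not None) else np.nan,
        })
    table = pd.DataFrame(rows)
    sig = table[table["significant"]]
    k_counts = sig["k_detected"].value_counts().sort_index().to_dict()
    summary = {
        "method": method,
        "scenario": scenario.tag,
        "n_datasets": n_datasets,
        "level": level,
        "power": float(table["significant"].mean()),
        "k_distribution": {int(k): int(v) for k, v in k_counts.items()},
        "n_not_significant": int((~table["significant"]).sum()),
        "mean_detected_regions": float(sig["detected_regions"].mean()) if len(sig) else np.nan,
        "mean_sensitivity": float(sig["sensitivity"].mean()) if len(sig) else np.nan,
        "mean_ppv": float(sig["ppv"].mean()) if len(sig) else np.nan,
        "n_sensitivity_1": int((sig["sensitivity"] >= 1.0).sum()),
        "n_ppv_1": int((sig["ppv"] >= 1.0).sum()),
    }
    return summary, table
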