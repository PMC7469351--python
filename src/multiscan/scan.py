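"""Scanning windows, the Poisson scan likelihood ratio, and the sequential
secondary-cluster procedure (SCP).

A *window* is a candidate cluster: either the regions within a
centroid-distance ball around some region (circular scan) or an arbitrary
connected set of regions inside a bounded neighbourhood (flexibly shaped
scan, optionally restricted to individually elevated regions).  Each window
``w`` is scored with the conditional Poisson likelihood-ratio statistic

    LLR(w) = O_w log(O_w / e_w) + (O - O_w) log((O - O_w) / (O - e_w)),

where ``O_w`` is the observed count inside the window, ``O`` the study-area
total, and ``e_w = E_w * O / E`` the window expectation rescaled so the
total expectation matches the total count (the scan statistic conditions on
the observed total).  Low-rate windows score zero; only hot spots are
candidates.

The SCP repeatedly takes the most likely cluster among windows that avoid
all previously detected regions, yielding an ordered, pairwise-disjoint
candidate list: the primary cluster followed by secondary clusters, each
with an optional Monte Carlo p-value ``p_s``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from scipy import stats

from .spatial import CaseData, RegionMap

logger = logging.getLogger(__name__)

__all__ = [
    "Window",
    "ScoredWindow",
    "CandidateSequence",
    "ScanConfig",
    "poisson_llr",
    "circular_windows",
    "flexible_windows",
    "most_likely_cluster",
    "window_pvalue",
    "scp_candidates",
]


@dataclass(frozen=True)
class Window:
    """A candidate cluster: a set of region indices."""

    members: frozenset[int]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a window cannot be empty")
        object.__setattr__(self, "members", frozenset(int(i) for i in self.members))

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def sorted_members(self) -> tuple[int, ...]:
        return tuple(sorted(self.members))


@dataclass
class ScoredWindow:
    """A window with its scan score (and, once computed, its p-value)."""

    window: Window
    observed_in: int
    expected_in: float
    llr: float
    p_s: float | None = None

    @property
    def smr(self) -> float:
        """Window standardized morbidity ratio O_w / E_w."""
        return self.observed_in / self.expected_in


@dataclass
class CandidateSequence:
    """Ordered disjoint candidate clusters produced by the SCP."""

    candidates: list[ScoredWindow]
    kmax: int
    ps_threshold: float

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for c in self.candidates:
            if seen & c.window.members:
                raise ValueError("candidate windows must be pairwise disjoint")
            seen |= c.window.members
        if len(self.candidates) > self.kmax:
            raise ValueError("more candidates than kmax")

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self) -> Iterator[ScoredWindow]:
        return iter(self.candidates)

    @property
    def windows(self) -> list[Window]:
        return [c.window for c in self.candidates]


@dataclass(frozen=True)
class ScanConfig:
    """Scanning configuration.

    Parameters
    ----------
    method
        ``"circular"`` (default, fast), ``"flexible"`` (all connected subsets
        within a neighbour limit) or ``"restricted"`` (flexible over
        individually elevated regions only).
    max_fraction
        Circular windows stop growing once they hold this fraction of the
        total baseline expectation (default 0.5).
    neighbor_limit
        Flexible windows live inside each region's ``neighbor_limit``-nearest
        neighbourhood (default 20).
    alpha1
        Mid-p threshold for region eligibility in restricted mode
        (default 0.2).
    kmax
        Maximum number of SCP candidates (default 20).
    ps_threshold
        SCP stops once a candidate's p_s exceeds this (default 1.0: keep all
        candidates up to kmax).
    replications
        Monte Carlo replications for per-candidate p_s; 0 disables p_s.
    max_windows
        Emission cap for the flexible enumeration, with logged truncation.
    """

    method: str = "circular"
    max_fraction: float = 0.5
    neighbor_limit: int = 20
    alpha1: float = 0.2
    kmax: int = 20
    ps_threshold: float = 1.0
    replications: int = 999
    max_windows: int = 1_000_000

    def __post_init__(self) -> None:
        if self.method not in {"circular", "flexible", "restricted"}:
            raise ValueError(f"unknown scan method: {self.method!r}")
        if not 0 < self.max_fraction <= 0.5:
            raise ValueError("max_fraction must be in (0, 0.5]")
        if self.kmax < 1:
            raise ValueError("kmax must be >= 1")
        if not 0 < self.ps_threshold <= 1:
            raise ValueError("ps_threshold must be in (0, 1]")


# ---------------------------------------------------------------------------
# the scan statistic


def poisson_llr(observed_in: float, expected_in: float,
                total_observed: float, total_expected: float) -> float:
    """Conditional Poisson scan log likelihood ratio for one window.

    The window expectation is rescaled by ``O/E`` so that expectations sum to
    the observed total (conditioning on ``O``); when ``E = O`` this is the
    textbook form ``O_w log(O_w/E_w) + (O-O_w) log((O-O_w)/(E-E_w))``.
    Returns 0 unless the inside rate exceeds the outside rate (hot spots
    only).  Zero-count terms contribute 0.
    """
    o_w = float(observed_in)
    e_raw = float(expected_in)
    o = float(total_observed)
    e = float(total_expected)
    if e_raw <= 0 or e_raw >= e:
        raise ValueError("window expectation must satisfy 0 < E_w < E")
    if not 0 <= o_w <= o:
        raise ValueError("window count must satisfy 0 <= O_w <= O")
    # high-rate condition, cross-multiplied to avoid division
    if o_w * (e - e_raw) <= (o - o_w) * e_raw:
        return 0.0
    e_w = e_raw * o / e
    llr = 0.0
    if o_w > 0:
        llr += o_w * math.log(o_w / e_w)
    if o - o_w > 0:
        llr += (o - o_w) * math.log((o - o_w) / (o - e_w))
    return max(llr, 0.0)


# ---------------------------------------------------------------------------
# window generation


def _id_rank(region_map: RegionMap) -> np.ndarray:
    return np.argsort(np.argsort(np.asarray(region_map.region_ids, dtype=object)))


class CircularGeometry:
    """Precomputed nearest-neighbour orders for the circular scan.

    ``order[c]`` lists regions by increasing centroid distance from region
    ``c`` (ties broken by lexicographic region id, ``c`` itself first).
    Cumulative baseline expectations along each row give the expectation of
    every circular window in O(1); cumulative counts are recomputed per
    dataset.  Rows/columns beyond the expectation cap are dropped once.
    """

    def __init__(self, region_map: RegionMap, expected0: np.ndarray,
                 max_fraction: float = 0.5) -> None:
        expected0 = np.asarray(expected0, dtype=float)
        m = region_map.m
        dist = region_map.distance_matrix()
        rank = _id_rank(region_map)
        order = np.empty((m, m), dtype=np.intp)
        for i in range(m):
            d = dist[i].copy()
            d[i] = -1.0  # the center is always the innermost region
            order[i] = np.lexsort((rank, d))
        e_cum = np.cumsum(expected0[order], axis=1)
        e_total = float(expected0.sum())
        cap = max_fraction * e_total * (1 + 1e-12)
        valid = e_cum <= cap
        valid[:, 0] = True  # singletons always admissible
        ncols = int(valid.any(axis=0).sum())
        self.order = np.ascontiguousarray(order[:, :ncols])
        self.e_cum = np.ascontiguousarray(e_cum[:, :ncols])
        self.valid_cap = np.ascontiguousarray(valid[:, :ncols])
        self.e_total = e_total
        self.m = m
        self._neg_inf = float("-inf")

    def llr_matrix(self, y: np.ndarray,
                   excluded: np.ndarray | None = None) -> np.ndarray:
        """LLR of every admissible circular window; -inf where inadmissible.

        ``excluded`` marks regions already assigned to earlier SCP
        candidates: a window is admissible only while its nested growth has
        not yet swallowed an excluded region (and its center is free).
        """
        y = np.asarray(y, dtype=float)
        o = float(y.sum())
        ow = np.cumsum(y[self.order], axis=1)
        ew_raw = self.e_cum
        valid = self.valid_cap
        if excluded is not None and excluded.any():
            exc = excluded[self.order]
            valid = valid & ~np.maximum.accumulate(exc, axis=1)
        e = self.e_total
        # normalized expectation (conditional on the total count)
        ew = ew_raw * (o / e)
        rem = o - ow
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = ow * np.log(ow / ew)
            t2 = rem * np.log(rem / (o - ew))
        t1[ow == 0] = 0.0
        t2[rem == 0] = 0.0
        llr = t1 + t2
        hot = ow * (e - ew_raw) > rem * ew_raw
        llr[~hot] = 0.0
        llr[~valid] = self._neg_inf
        return llr

    def max_llr(self, y: np.ndarray) -> float:
        """Maximum window LLR (the scan statistic) for counts ``y``."""
        return float(self.llr_matrix(y).max())

    def best_window(self, y: np.ndarray,
                    excluded: np.ndarray | None = None,
                    id_rank: np.ndarray | None = None,
                    ) -> tuple[np.ndarray, float] | None:
        """Most likely cluster among admissible windows, or None.

        Ties (identical LLR to within 1e-9 relative) resolve to the smaller
        window, then to the lexicographically smallest member list.
        """
        llr = self.llr_matrix(y, excluded)
        best = llr.max()
        if not np.isfinite(best):
            return None
        tol = 1e-9 * max(1.0, abs(best))
        rows, cols = np.nonzero(llr >= best - tol)
        # (size, member ids) tie-break; exact winners only
        choice = None
        for r, c in zip(rows, cols):
            members = np.sort(self.order[r, : c + 1])
            key = (c + 1, tuple(members) if id_rank is None
                   else tuple(np.sort(id_rank[members])))
            if choice is None or key < choice[0]:
                choice = (key, members, float(llr[r, c]))
        assert choice is not None
        return choice[1], choice[2]


# The geometry depends only on (map, baseline, cap); the Monte Carlo loops
# rescan thousands of datasets on the same map, so cache a few of them.
_GEOMETRY_CACHE: dict = {}


def _get_geometry(region_map: RegionMap, expected0: np.ndarray,
                  max_fraction: float) -> CircularGeometry:
    key = (id(region_map), np.asarray(expected0).tobytes(), float(max_fraction))
    geom = _GEOMETRY_CACHE.get(key)
    if geom is None:
        geom = CircularGeometry(region_map, expected0, max_fraction)
        if len(_GEOMETRY_CACHE) >= 8:
            _GEOMETRY_CACHE.clear()
        _GEOMETRY_CACHE[key] = geom
    return geom


def circular_windows(region_map: RegionMap, data: CaseData,
                     max_fraction: float = 0.5) -> Iterator[Window]:
    """Enumerate circular windows (deduplicated nested distance balls)."""
    geom = _get_geometry(region_map, data.expected0, max_fraction)
    seen: set[frozenset[int]] = set()
    for c in range(geom.m):
        for j in range(geom.order.shape[1]):
            if not geom.valid_cap[c, j]:
                break
            members = frozenset(int(i) for i in geom.order[c, : j + 1])
            if members not in seen:
                seen.add(members)
                yield Window(members)


def _mid_p(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """One-sided Poisson mid-p: P(X > y) + 0.5 P(X = y) at mean mu."""
    y = np.asarray(y)
    mu = np.asarray(mu, dtype=float)
    return stats.poisson.sf(y, mu) + 0.5 * stats.poisson.pmf(y, mu)


def flexible_windows(region_map: RegionMap, neighbor_limit: int = 20,
                     restricted: bool = False, alpha1: float = 0.2,
                     data: CaseData | None = None,
                     max_windows: int = 1_000_000) -> Iterator[Window]:
    """Enumerate flexibly shaped windows: connected subsets within a
    bounded neighbourhood of each region.

    For each region ``i``, all connected subsets of ``{i}`` plus its
    ``neighbor_limit - 1`` nearest regions that contain ``i`` are emitted
    (deduplicated across centers).  In restricted mode only regions whose
    one-sided Poisson mid-p against their baseline expectation falls below
    ``alpha1`` are eligible members, which prunes the search drastically.
    """
    m = region_map.m
    if neighbor_limit > m:
        raise ValueError("neighbor_limit must be <= m")
    if not region_map.has_adjacency:
        raise ValueError("flexible windows require adjacency")
    eligible = np.ones(m, dtype=bool)
    if restricted:
        if data is None:
            raise ValueError("restricted mode requires case data")
        if alpha1 < 1.0:
            eligible = _mid_p(data.observed, data.expected0) < alpha1
    dist = region_map.distance_matrix()
    rank = _id_rank(region_map)
    emitted = 0
    seen: set[frozenset[int]] = set()
    for center in range(m):
        if not eligible[center]:
            continue
        d = dist[center].copy()
        d[center] = -1.0
        hood_order = np.lexsort((rank, d))[:neighbor_limit]
        hood = {int(i) for i in hood_order if eligible[int(i)]}
        if center not in hood:
            continue
        for members in _connected_subsets(center, hood, region_map):
            key = frozenset(members)
            if key in seen:
                continue
            seen.add(key)
            yield Window(key)
            emitted += 1
            if emitted >= max_windows:
                logger.warning("flexible window enumeration truncated at %d", max_windows)
                return


def _connected_subsets(root: int, allowed: set[int],
                       region_map: RegionMap) -> Iterator[set[int]]:
    """All connected subsets of ``allowed`` containing ``root``.

    Classic recursive enumeration: each subset is extended by frontier
    vertices, and vertices branched over are forbidden downstream so every
    subset is produced exactly once.
    """
    nbs = region_map.neighbors

    def extend(current: set[int], frontier: list[int],
               forbidden: set[int]) -> Iterator[set[int]]:
        yield set(current)
        local_forbidden = set(forbidden)
        for idx, v in enumerate(frontier):
            if v in local_forbidden:
                continue
            new_frontier = [u for u in frontier[idx + 1:] if u not in local_forbidden]
            for u in sorted(nbs[v]):
                if u in allowed and u not in current and u != v \
                        and u not in local_forbidden and u not in new_frontier \
                        and u not in frontier[: idx + 1]:
                    new_frontier.append(u)
            current.add(v)
            yield from extend(current, new_frontier, local_forbidden)
            current.remove(v)
            local_forbidden.add(v)

    frontier0 = sorted(u for u in nbs[root] if u in allowed)
    yield from extend({root}, frontier0, set())


# ---------------------------------------------------------------------------
# scoring and the SCP


def _score(data: CaseData, members: Iterable[int]) -> tuple[int, float, float]:
    idx = np.fromiter((int(i) for i in members), dtype=np.intp)
    o_w = int(data.observed[idx].sum())
    e_w = float(data.expected0[idx].sum())
    llr = poisson_llr(o_w, e_w, data.total_observed, data.total_expected)
    return o_w, e_w, llr


def most_likely_cluster(data: CaseData,
                        windows: Iterable[Window]) -> ScoredWindow:
    """The window maximizing the scan LLR.

    Ties broken toward the smaller window, then the lexicographically
    smallest sorted member list; deterministic for fixed inputs.
    """
    best: ScoredWindow | None = None
    best_key = None
    n_admissible = 0
    for w in windows:
        try:
            o_w, e_w, llr = _score(data, w.members)
        except ValueError:
            continue  # window covers (or exceeds) the whole study area
        n_admissible += 1
        key = (-llr, w.size, w.sorted_members)
        if best_key is None or key < best_key:
            best_key = key
            best = ScoredWindow(w, o_w, e_w, llr)
    if best is None:
        raise ValueError("no admissible window" if n_admissible == 0 else "unreachable")
    return best


def _materialize_windows(region_map: RegionMap, data: CaseData,
                         config: ScanConfig) -> list[Window]:
    if config.method == "circular":
        return list(circular_windows(region_map, data, config.max_fraction))
    return list(flexible_windows(
        region_map, config.neighbor_limit,
        restricted=(config.method == "restricted"),
        alpha1=config.alpha1, data=data, max_windows=config.max_windows,
    ))


def _null_max_llrs(data: CaseData, region_map: RegionMap, config: ScanConfig,
                   R: int, rng: np.random.Generator) -> np.ndarray:
    """Null distribution of the maximal LLR (multinomial conditional null)."""
    from .inference import simulate_null_counts

    p = data.expected0 / data.total_expected
    total = data.total_observed
    out = np.empty(R, dtype=float)
    if config.method == "circular":
        geom = _get_geometry(region_map, data.expected0, config.max_fraction)
        for r in range(R):
            out[r] = geom.max_llr(simulate_null_counts(data.expected0, total, rng))
        return out
    windows = _materialize_windows(region_map, data, config)
    members = [np.fromiter(w.members, dtype=np.intp) for w in windows]
    e_w = np.array([float(data.expected0[idx].sum()) for idx in members])
    e = data.total_expected
    keep = (e_w > 0) & (e_w < e)
    for r in range(R):
        y = rng.multinomial(total, p)
        o = float(total)
        best = 0.0
        for idx, ew_raw in zip(
            (mi for mi, k in zip(members, keep) if k),
            e_w[keep],
        ):
            o_w = float(y[idx].sum())
            if o_w * (e - ew_raw) <= (o - o_w) * ew_raw:
                continue
            ew = ew_raw * o / e
            val = 0.0
            if o_w > 0:
                val += o_w * math.log(o_w / ew)
            if o - o_w > 0:
                val += (o - o_w) * math.log((o - o_w) / (o - ew))
            if val > best:
                best = val
        out[r] = best
    return out


def window_pvalue(observed_llr: float, data: CaseData, region_map: RegionMap,
                  config: ScanConfig, R: int,
                  rng: np.random.Generator | int | None = None) -> float:
    """Monte Carlo p-value of a window's LLR against the null maximum.

    ``R`` conditional-null datasets are generated (multinomial on the
    baseline expectations); the maximal LLR over the full window set is
    recomputed on each, and ``p_s = (1 + #{max* >= observed}) / (R + 1)``.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(rng)
    nulls = _null_max_llrs(data, region_map, config, R, rng)
    return (1 + int((nulls >= observed_llr).sum())) / (R + 1)


def scp_candidates(data: CaseData, region_map: RegionMap,
                   config: ScanConfig | None = None,
                   rng: np.random.Generator | int | None = None,
                   ) -> CandidateSequence:
    """Sequential secondary-cluster procedure.

    Iteratively finds the most likely cluster among windows avoiding all
    regions already assigned to earlier candidates, attaches its Monte Carlo
    p-value ``p_s`` (if ``config.replications >= 1``), and stops at ``kmax``
    candidates, when ``p_s`` exceeds ``ps_threshold``, or when no admissible
    window remains.  The result is an ordered, pairwise-disjoint list:
    primary cluster first, secondaries in decreasing detection strength.

    Per-candidate p-values all refer to the null distribution of the primary
    (maximal) statistic, computed once per call — the usual secondary-cluster
    convention.
    """
    config = config or ScanConfig()
    if data.m != region_map.m:
        raise ValueError("data and map sizes differ")
    rng = np.random.default_rng(rng)

    nulls: np.ndarray | None = None
    if config.replications >= 1:
        nulls = _null_max_llrs(data, region_map, config, config.replications, rng)

    excluded = np.zeros(region_map.m, dtype=bool)
    out: list[ScoredWindow] = []

    if config.method == "circular":
        geom = _get_geometry(region_map, data.expected0, config.max_fraction)
        id_rank = _id_rank(region_map)
        for _ in range(config.kmax):
            found = geom.best_window(data.observed, excluded, id_rank)
            if found is None:
                break
            members, llr = found
            sw = ScoredWindow(
                Window(frozenset(int(i) for i in members)),
                int(data.observed[members].sum()),
                float(data.expected0[members].sum()),
                llr,
            )
            if nulls is not None:
                sw.p_s = (1 + int((nulls >= sw.llr).sum())) / (config.replications + 1)
                if sw.p_s > config.ps_threshold:
                    break
            out.append(sw)
            excluded[members] = True
    else:
        windows = _materialize_windows(region_map, data, config)
        for _ in range(config.kmax):
            admissible = [w for w in windows
                          if not any(excluded[i] for i in w.members)]
            if not admissible:
                break
            try:
                sw = most_likely_cluster(data, admissible)
            except ValueError:
                break
            if nulls is not None:
                sw.p_s = (1 + int((nulls >= sw.llr).sum())) / (config.replications + 1)
                if sw.p_s > config.ps_threshold:
                    break
            out.append(sw)
            for i in sw.window.members:
                excluded[i] = True

    return CandidateSequence(out, config.kmax, config.ps_threshold)
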