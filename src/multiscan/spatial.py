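"""Study-space data model: regions, adjacency, case counts and baseline expectations.

The study space is a set of ``m`` regions (the smallest spatial units of the
analysis — counties, local authorities, census tracts).  Each region has an
opaque string identifier, a centroid, an observed case count ``y_i`` and a
baseline expected count ``mu0_i`` (the number of cases the region would see
under no spatial clustering, typically from indirect age-sex
standardization).  Adjacency between regions — needed by flexibly shaped
scanning windows and by the synthetic-map generator — is either read from a
file or derived from centroids as a mutualized k-nearest-neighbour graph.

File dialects follow the whitespace/CSV conventions of the common
scan-statistic tools: a coordinates ("geo") file with columns
``id x y``, a case file ``id count``, a population file
``id [stratum] population`` and an adjacency file that is either a square
0/1 matrix with id headers or a two-column edge list.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RegionMap",
    "CaseData",
    "load_regions",
    "load_cases",
    "read_adjacency",
    "derive_adjacency",
    "expected_counts",
    "drop_zero_expected",
    "write_regions",
    "write_cases",
]

_EARTH_RADIUS_KM = 6371.0088


@dataclass
class RegionMap:
    """The study space: region identifiers, centroids and a neighbour relation.

    Parameters
    ----------
    region_ids
        Unique opaque string identifiers, in canonical (file) order.  All
        vectors elsewhere in the package are indexed in this order.
    centroids
        ``(m, 2)`` float array of coordinates.  Planar Cartesian by default;
        ``(latitude, longitude)`` in degrees when ``geographic`` is set.
    neighbors
        Per-region sets of neighbouring region indices.  Symmetric and
        irreflexive.  May be empty (no adjacency attached yet).
    geographic
        Interpret centroids as geographic coordinates and use great-circle
        distances.
    """

    region_ids: list[str]
    centroids: np.ndarray
    neighbors: list[set[int]] = field(default_factory=list)
    geographic: bool = False

    def __post_init__(self) -> None:
        self.region_ids = [str(r) for r in self.region_ids]
        self.centroids = np.asarray(self.centroids, dtype=float)
        if len(set(self.region_ids)) != len(self.region_ids):
            seen: set[str] = set()
            for r in self.region_ids:
                if r in seen:
                    raise ValueError(f"duplicate region id: {r!r}")
                seen.add(r)
        if self.m < 2:
            raise ValueError("a study space needs at least 2 regions")
        if self.centroids.shape != (self.m, 2):
            raise ValueError("centroids must be an (m, 2) array")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("non-finite centroid coordinate")
        if not self.neighbors:
            self.neighbors = [set() for _ in range(self.m)]
        if len(self.neighbors) != self.m:
            raise ValueError("neighbors list length must equal m")
        for i, nb in enumerate(self.neighbors):
            if i in nb:
                raise ValueError("adjacency must be irreflexive")
        self._index = {r: i for i, r in enumerate(self.region_ids)}

    @property
    def m(self) -> int:
        """Number of regions."""
        return len(self.region_ids)

    @property
    def has_adjacency(self) -> bool:
        return any(self.neighbors)

    def index_of(self, region_id: str) -> int:
        try:
            return self._index[region_id]
        except KeyError:
            raise KeyError(f"unknown region: {region_id!r}") from None

    def edges(self) -> set[tuple[int, int]]:
        """Undirected edge set as ``(i, j)`` pairs with ``i < j``."""
        out: set[tuple[int, int]] = set()
        for i, nb in enumerate(self.neighbors):
            for j in nb:
                out.add((min(i, j), max(i, j)))
        return out

    def distance_matrix(self) -> np.ndarray:
        """Pairwise centroid distances (Euclidean, or great-circle in km)."""
        if self.geographic:
            lat = np.radians(self.centroids[:, 0])[:, None]
            lon = np.radians(self.centroids[:, 1])[:, None]
            dlat = lat - lat.T
            dlon = lon - lon.T
            a = np.sin(dlat / 2.0) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2.0) ** 2
            a = np.clip(a, 0.0, 1.0)
            return 2.0 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
        from scipy.spatial.distance import squareform, pdist

        return squareform(pdist(self.centroids))

    def is_connected_subset(self, members: Sequence[int]) -> bool:
        """True iff ``members`` induce a connected subgraph of the adjacency."""
        mem = set(int(i) for i in members)
        if not mem:
            return False
        if len(mem) == 1:
            return True
        start = next(iter(mem))
        seen = {start}
        stack = [start]
        while stack:
            cur = stack.pop()
            for nb in self.neighbors[cur]:
                if nb in mem and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return seen == mem

    def subset(self, keep: Sequence[int]) -> "RegionMap":
        """New map restricted to ``keep`` (canonical order preserved)."""
        keep = sorted(int(i) for i in keep)
        pos = {old: new for new, old in enumerate(keep)}
        nbs = [
            {pos[j] for j in self.neighbors[i] if j in pos} for i in keep
        ]
        return RegionMap(
            [self.region_ids[i] for i in keep],
            self.centroids[keep],
            nbs,
            geographic=self.geographic,
        )


@dataclass
class CaseData:
    """Observed case counts and baseline expectations, aligned to a RegionMap.

    ``observed[i]`` is the case count y_i (non-negative integer) and
    ``expected0[i]`` the baseline expectation mu0_i (positive, in cases).
    """

    observed: np.ndarray
    expected0: np.ndarray

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed)
        if not np.issubdtype(self.observed.dtype, np.integer):
            as_int = np.asarray(np.round(self.observed), dtype=np.int64)
            if not np.allclose(self.observed, as_int):
                raise ValueError("observed counts must be integers")
            self.observed = as_int
        else:
            self.observed = self.observed.astype(np.int64)
        self.expected0 = np.asarray(self.expected0, dtype=float)
        if self.observed.shape != self.expected0.shape or self.observed.ndim != 1:
            raise ValueError("observed and expected0 must be 1-d arrays of equal length")
        if np.any(self.observed < 0):
            raise ValueError("negative case count")
        if np.any(self.expected0 <= 0) or not np.all(np.isfinite(self.expected0)):
            raise ValueError(
                "baseline expectations must be positive and finite; "
                "use drop_zero_expected() to remove zero-expectation regions"
            )

    @property
    def m(self) -> int:
        return self.observed.size

    @property
    def total_observed(self) -> int:
        """O = sum of y_i."""
        return int(self.observed.sum())

    @property
    def total_expected(self) -> float:
        return float(self.expected0.sum())


# ---------------------------------------------------------------------------
# file readers


def _read_table(source, n_min_cols: int) -> pd.DataFrame:
    """Read a whitespace- or comma-separated table with or without a header."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    elif hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
    df = pd.read_csv(io.StringIO(text), sep=None, engine="python", header=None,
                     dtype=str, comment="#", skip_blank_lines=True)
    if df.shape[1] < n_min_cols:
        raise ValueError(
            f"expected at least {n_min_cols} columns, found {df.shape[1]}"
        )
    # Drop a header row if the numeric columns of the first row do not parse.
    first = df.iloc[0, 1:n_min_cols]
    try:
        first.astype(float)
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    return df


def load_regions(coords_source, *, geographic: bool = False) -> RegionMap:
    """Read a coordinates file (``id x y``) into a :class:`RegionMap`.

    Row order becomes the canonical region order.  Adjacency is left empty;
    attach one with :func:`read_adjacency` or :func:`derive_adjacency`.
    """
    df = _read_table(coords_source, 3)
    ids = [str(v).strip() for v in df.iloc[:, 0]]
    seen: set[str] = set()
    for r in ids:
        if r in seen:
            raise ValueError(f"duplicate region id: {r!r}")
        seen.add(r)
    coords = np.empty((len(ids), 2), dtype=float)
    for row in range(len(ids)):
        for col in (1, 2):
            try:
                coords[row, col - 1] = float(df.iloc[row, col])
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric coordinate {df.iloc[row, col]!r} at row {row + 1}"
                ) from None
    return RegionMap(ids, coords, geographic=geographic)


def load_cases(cases_source, region_map: RegionMap,
               expected_source=None) -> CaseData:
    """Read a case file (``id count``) aligned to ``region_map`` order.

    ``expected_source`` optionally supplies user-standardized baseline
    expectations (``id expected``); otherwise compute them with
    :func:`expected_counts` from a population table.
    """
    df = _read_table(cases_source, 2)
    counts = np.zeros(region_map.m, dtype=np.int64)
    seen = np.zeros(region_map.m, dtype=bool)
    for row in range(df.shape[0]):
        i = region_map.index_of(str(df.iloc[row, 0]).strip())
        counts[i] = int(float(df.iloc[row, 1]))
        seen[i] = True
    if not seen.all():
        missing = region_map.region_ids[int(np.flatnonzero(~seen)[0])]
        raise ValueError(f"case file missing region: {missing!r}")
    if expected_source is None:
        raise ValueError("baseline expectations required (expected_source or expected_counts)")
    edf = _read_table(expected_source, 2)
    mu0 = np.zeros(region_map.m, dtype=float)
    for row in range(edf.shape[0]):
        i = region_map.index_of(str(edf.iloc[row, 0]).strip())
        mu0[i] = float(edf.iloc[row, 1])
    return CaseData(counts, mu0)


def read_adjacency(matrix_source, region_map: RegionMap) -> RegionMap:
    """Attach adjacency from a square 0/1 matrix (id headers) or an edge list.

    The relation is symmetrized — an edge present in either direction becomes
    mutual — and the diagonal is ignored.
    """
    if isinstance(matrix_source, (str, Path)):
        text = Path(matrix_source).read_text()
    elif hasattr(matrix_source, "read"):
        text = matrix_source.read()
    else:
        text = str(matrix_source)
    df = pd.read_csv(io.StringIO(text), sep=None, engine="python", header=None,
                     dtype=str, comment="#", skip_blank_lines=True)
    nbs: list[set[int]] = [set() for _ in range(region_map.m)]

    if df.shape[1] == 2:  # edge list
        for row in range(df.shape[0]):
            a = region_map.index_of(str(df.iloc[row, 0]).strip())
            b = region_map.index_of(str(df.iloc[row, 1]).strip())
            if a != b:
                nbs[a].add(b)
                nbs[b].add(a)
    else:  # matrix with id header row and column
        header = [str(v).strip() for v in df.iloc[0, 1:]]
        if df.shape[0] - 1 != len(header):
            raise ValueError("adjacency matrix is not square")
        cols = [region_map.index_of(h) for h in header]
        for row in range(1, df.shape[0]):
            a = region_map.index_of(str(df.iloc[row, 0]).strip())
            for c, b in enumerate(cols):
                if a == b:
                    continue
                val = str(df.iloc[row, c + 1]).strip()
                if float(val) != 0:
                    nbs[a].add(b)
                    nbs[b].add(a)
    return RegionMap(region_map.region_ids, region_map.centroids, nbs,
                     geographic=region_map.geographic)


def derive_adjacency(region_map: RegionMap, k_neighbors: int) -> RegionMap:
    """Mutualized k-nearest-neighbour adjacency from centroids.

    An edge joins i and j iff j is among the k nearest centroids of i or
    vice versa.  Distance ties are broken by lexicographic region id so the
    graph is reproducible across platforms.
    """
    m = region_map.m
    if not 1 <= k_neighbors < m:
        raise ValueError("require 1 <= k_neighbors < m")
    dist = region_map.distance_matrix()
    id_rank = np.argsort(np.argsort(region_map.region_ids))
    nbs: list[set[int]] = [set() for _ in range(m)]
    for i in range(m):
        order = np.lexsort((id_rank, dist[i]))
        order = order[order != i][:k_neighbors]
        for j in order:
            nbs[i].add(int(j))
            nbs[int(j)].add(i)
    return RegionMap(region_map.region_ids, region_map.centroids, nbs,
                     geographic=region_map.geographic)


def write_regions(region_map: RegionMap, path) -> None:
    """Write a coordinates table (``id x y``, whitespace-separated)."""
    lines = [
        f"{rid} {x:.10g} {y:.10g}"
        for rid, (x, y) in zip(region_map.region_ids, region_map.centroids)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_cases(region_map: RegionMap, data: CaseData, path,
                expected_path=None) -> None:
    """Write a case table (``id count``) and optionally the expectations."""
    lines = [f"{rid} {c}" for rid, c in zip(region_map.region_ids, data.observed)]
    Path(path).write_text("\n".join(lines) + "\n")
    if expected_path is not None:
        elines = [f"{rid} {e:.10g}"
                  for rid, e in zip(region_map.region_ids, data.expected0)]
        Path(expected_path).write_text("\n".join(elines) + "\n")


# ---------------------------------------------------------------------------
# baseline expectations


def expected_counts(population, *, total_cases: int | None = None,
                    cases_by_stratum=None) -> np.ndarray:
    """Baseline expected counts by indirect standardization.

    With strata (``population`` of shape ``(m, S)`` and ``cases_by_stratum``
    of length ``S``), ``mu0_i = sum_s pop_is * (C_s / P_s)`` where ``C_s``
    and ``P_s`` are stratum case and population totals.  Without strata,
    ``mu0_i = O * pop_i / P`` (proportional allocation of the total count).
    The returned vector sums to the total case count exactly (up to floating
    tolerance).

    A region with zero population receives ``mu0_i = 0`` with a warning; such
    regions must be removed with :func:`drop_zero_expected` before analysis.
    """
    pop = np.asarray(population, dtype=float)
    if np.any(pop < 0):
        raise ValueError("negative population")
    if cases_by_stratum is not None:
        if pop.ndim != 2:
            raise ValueError("stratified population must be (m, S)")
        cs = np.asarray(cases_by_stratum, dtype=float)
        if cs.shape != (pop.shape[1],):
            raise ValueError("cases_by_stratum must align with population strata")
        ps = pop.sum(axis=0)
        if np.any(ps <= 0):
            raise ValueError("zero total population in a stratum")
        mu0 = pop @ (cs / ps)
    else:
        if pop.ndim != 1:
            raise ValueError("population must be 1-d without strata")
        if total_cases is None:
            raise ValueError("total_cases required without strata")
        p_total = pop.sum()
        if p_total <= 0:
            raise ValueError("zero total population")
        mu0 = float(total_cases) * pop / p_total
    if np.any(mu0 == 0):
        warnings.warn(
            f"{int((mu0 == 0).sum())} region(s) have zero expected count; "
            "remove them with drop_zero_expected() before analysis",
            stacklevel=2,
        )
    return mu0


def drop_zero_expected(region_map: RegionMap, observed, expected0,
                       tol: float = 0.0) -> tuple[RegionMap, CaseData, np.ndarray]:
    """Remove regions with ``mu0 <= tol`` (likelihood undefined there).

    Returns the reduced map, the reduced :class:`CaseData` and the indices
    kept (into the original canonical order).  Logs a warning naming how many
    regions were dropped.
    """
    observed = np.asarray(observed)
    expected0 = np.asarray(expected0, dtype=float)
    keep = np.flatnonzero(expected0 > tol)
    if keep.size < expected0.size:
        logger.warning(
            "dropping %d region(s) with zero baseline expectation",
            expected0.size - keep.size,
        )
    if keep.size == expected0.size:
        return region_map, CaseData(observed, expected0), keep
    return (
        region_map.subset(keep),
        CaseData(observed[keep], expected0[keep]),
        keep,
    )
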