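"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import settings
from scipy.stats import poisson

from multiscan import CaseData, RegionMap, Window

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; never reuse package internals)


def brute_force_connected_subsets(neighbors: list[set[int]], m: int,
                                  max_size: int | None = None):
    """All connected subsets of a graph by powerset + BFS check."""
    out = []
    for size in range(1, (max_size or m) + 1):
        for combo in itertools.combinations(range(m), size):
            mem = set(combo)
            seen = {combo[0]}
            stack = [combo[0]]
            while stack:
                cur = stack.pop()
                for nb in neighbors[cur]:
                    if nb in mem and nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            if seen == mem:
                out.append(frozenset(mem))
    return out


def oracle_llr(o_w, e_w, o, e):
    """Conditional Poisson scan LLR, written independently from scratch."""
    ew = e_w * o / e
    rate_in = o_w / ew if ew else float("inf")
    rate_out = (o - o_w) / (o - ew)
    if rate_in <= rate_out:
        return 0.0
    val = 0.0
    if o_w:
        val += o_w * math.log(o_w / ew)
    if o - o_w:
        val += (o - o_w) * math.log((o - o_w) / (o - ew))
    return val


def oracle_multicluster_loglik(y, mu0, windows, tol=1e-12):
    """Numerically maximize the multiple-cluster Poisson likelihood.

    A general-purpose Newton iteration on (alpha, beta_1..beta_K) with the
    exact gradient and Hessian of the log-link Poisson likelihood — the
    independent oracle for the package's closed-form group MLE.  The
    likelihood is concave, so the iteration converges to the global maximum.
    """
    y = np.asarray(y, dtype=float)
    mu0 = np.asarray(mu0, dtype=float)
    K = len(windows)
    z = np.zeros((K, y.size))
    for k, w in enumerate(windows):
        z[k, sorted(w)] = 1.0
    x = np.zeros(K + 1)
    design = np.vstack([np.ones(y.size), z])  # (K+1, m)
    for _ in range(200):
        mu = np.exp(design.T @ x) * mu0
        grad = design @ (y - mu)
        hess = (design * mu) @ design.T
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        # damped Newton for far-from-optimum starts
        while np.abs(step).max() > 5.0:
            step = step / 2.0
        x = x + step
        if np.abs(grad).max() < tol:
            break
    mu = np.exp(design.T @ x) * mu0
    return float(np.sum(poisson.logpmf(y, mu)))


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def tri_map() -> RegionMap:
    """Three regions: A at origin, B east, C north; A-B and A-C adjacent."""
    return RegionMap(["A", "B", "C"], [[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]],
                     [{1, 2}, {0}, {0}])


@pytest.fixture
def path_map() -> RegionMap:
    """Path graph A - B - C on collinear centroids."""
    return RegionMap(["A", "B", "C"], [[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]],
                     [{1}, {0, 2}, {1}])


@pytest.fixture
def grid4() -> RegionMap:
    """2 x 2 rook lattice."""
    from multiscan import synthetic_map

    return synthetic_map(4)


def random_instance(rng: np.random.Generator, m_max: int = 8):
    """A random small study space with counts, expectations and a window set."""
    m = int(rng.integers(4, m_max + 1))
    mu0 = rng.uniform(0.5, 5.0, size=m)
    y = rng.poisson(mu0 * rng.uniform(0.5, 3.0, size=m)) + (rng.random(m) < 0.2)
    y = np.asarray(y, dtype=np.int64)
    if y.sum() == 0:
        y[int(rng.integers(m))] = 1
    # 1-2 disjoint windows leaving at least one region outside
    perm = rng.permutation(m)
    k = int(rng.integers(1, 3))
    sizes = []
    budget = m - 1
    for _ in range(k):
        if budget <= 0:
            break
        s = int(rng.integers(1, min(3, budget) + 1))
        sizes.append(s)
        budget -= s
    windows = []
    pos = 0
    for s in sizes:
        windows.append(Window(frozenset(int(i) for i in perm[pos:pos + s])))
        pos += s
    # ensure every window holds at least one case (interior MLE), and at
    # least one case falls outside all windows (outside rate well-defined)
    for w in windows:
        idx = sorted(w.members)
        if y[idx].sum() == 0:
            y[idx[0]] = 1
    inside = set().union(*(w.members for w in windows))
    outside = sorted(set(range(m)) - inside)
    if y[outside].sum() == 0:
        y[outside[0]] = 1
    return CaseData(y, mu0), windows
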