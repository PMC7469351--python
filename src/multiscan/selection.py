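"""Information-criterion selection of the number of clusters.

The number of clusters K is chosen by model selection over the nested
sequence of multiple-cluster fits built from the SCP candidate ordering.
The criterion approximates -2 log marginal likelihood of the cluster model,
keeping terms of order O(1) and larger in the number of regions m, with the
window-location probability taken as ``h(z) = (1/m)^K`` (each of K small
windows is one of m placements):

    C(K) = -2 l(psi_hat | z) + (3K + 1) log m,        K >= 1,
    C0   = -2 l(alpha_hat_0) + log m                  (null model, q = 1),

where ``l`` is the full Poisson log-likelihood of the fitted model.  The
relative difference of criterion,

    RDC(K) = (C0 - C(K)) / C0,

is maximized over K to select K_hat (K_hat = 0 when no K improves on the
null); ``max_K RDC(K)`` also serves as the test statistic of the overall
Monte Carlo significance test (module :mod:`multiscan.inference`).

Conventional criteria (-2 log L, AIC, BIC) are emitted alongside for
comparison: with many candidate windows they keep decreasing with K, while
C attains an interior minimum.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .glm import ClusterModelFit, fit_multicluster, fit_null
from .scan import CandidateSequence, Window
from .spatial import CaseData

__all__ = [
    "SelectionResult",
    "criterion",
    "criterion_null",
    "rdc_trace",
    "select",
]


@dataclass
class SelectionResult:
    """C(K)/RDC(K) traces and the selected model.

    ``k_hat = 0`` (no clusters) iff ``max_rdc <= 0``.  ``p_m`` is filled in
    by the overall Monte Carlo test; ``None`` until then.
    """

    c0: float
    c_trace: np.ndarray
    rdc_trace: np.ndarray
    k_hat: int
    selected_windows: list[Window]
    max_rdc: float
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    aic_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    bic_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    p_m: float | None = None

    @property
    def minus2loglik_trace(self) -> np.ndarray:
        return -2.0 * self.loglik_trace


def criterion(fit: ClusterModelFit, m: int) -> float:
    """C(K) = -2 loglik + (3K + 1) log m for a fitted cluster model (K >= 1)."""
    if fit.K < 1:
        raise ValueError("criterion() requires K >= 1; use criterion_null()")
    if m < 2:
        raise ValueError("m must be >= 2")
    return -2.0 * fit.loglik + (3 * fit.K + 1) * math.log(m)


def criterion_null(null_fit: ClusterModelFit, m: int) -> float:
    """C0 = -2 loglik + log m: the criterion under the null model (q = 1,
    no window-location term for an empty selection)."""
    if null_fit.K != 0:
        raise ValueError("criterion_null() requires a K = 0 fit")
    return -2.0 * null_fit.loglik + math.log(m)


def rdc_trace(c0: float, c_values) -> np.ndarray:
    """Elementwise relative difference of criterion (C0 - C(K)) / C0."""
    if c0 == 0:
        raise ValueError("C0 must be nonzero")
    return (c0 - np.asarray(c_values, dtype=float)) / c0


def select(candidates: CandidateSequence | list[Window], data: CaseData,
           m: int | None = None, subset_search: bool = False) -> SelectionResult:
    """Choose the number of clusters by maximizing RDC(K).

    For K = 1..len(candidates) the multiple-cluster model is fitted on the
    first K candidates (prefix nesting in SCP order — candidates arrive in
    decreasing detection strength), C(K) and RDC(K) are computed, and
    K_hat = argmax_K RDC(K) when the maximum is positive, else 0.  Ties
    break toward smaller K.

    With ``subset_search=True`` every non-empty subset of the candidates is
    scored instead (exponential; only sensible for small candidate lists) and
    the reported trace holds, for each K, the best subset of that size.
    """
    windows = candidates.windows if isinstance(candidates, CandidateSequence) \
        else list(candidates)
    if m is None:
        m = data.m
    null_fit = fit_null(data)
    c0 = criterion_null(null_fit, m)
    if c0 <= 0:
        raise ValueError(
            "C0 <= 0: the relative difference statistic is undefined "
            "(degenerate data scale)"
        )
    if not windows:
        empty = np.empty(0)
        return SelectionResult(c0, empty, empty.copy(), 0, [], float("-inf"),
                               empty.copy(), empty.copy(), empty.copy())

    kmax = len(windows)
    c_vals = np.empty(kmax)
    logliks = np.empty(kmax)
    best_subsets: list[list[Window]] = []
    if subset_search:
        for k in range(1, kmax + 1):
            best = None
            for combo in itertools.combinations(windows, k):
                fit = fit_multicluster(data, list(combo))
                if best is None or fit.loglik > best[0]:
                    best = (fit.loglik, list(combo))
            assert best is not None
            logliks[k - 1] = best[0]
            best_subsets.append(best[1])
            c_vals[k - 1] = -2.0 * best[0] + (3 * k + 1) * math.log(m)
    else:
        for k in range(1, kmax + 1):
            fit = fit_multicluster(data, windows[:k])
            logliks[k - 1] = fit.loglik
            c_vals[k - 1] = criterion(fit, m)

    rdc = rdc_trace(c0, c_vals)
    max_rdc = float(rdc.max())
    if max_rdc <= 0:
        k_hat = 0
        selected: list[Window] = []
    else:
        k_hat = int(np.argmax(rdc)) + 1  # argmax returns the first (smallest K)
        selected = best_subsets[k_hat - 1] if subset_search else windows[:k_hat]
    ks = np.arange(1, kmax + 1)
    return SelectionResult(
        c0=c0, c_trace=c_vals, rdc_trace=rdc, k_hat=k_hat,
        selected_windows=selected, max_rdc=max_rdc,
        loglik_trace=logliks,
        aic_trace=-2.0 * logliks + 2.0 * (ks + 1),
        bic_trace=-2.0 * logliks + (ks + 1) * math.log(m),
    )
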