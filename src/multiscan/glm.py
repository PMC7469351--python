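"""Multiple-cluster Poisson generalized linear model.

Given a disjoint set of candidate windows ``w_1..w_K``, region counts are
modelled as independent Poisson with

    log mu_i = alpha + sum_k beta_k z_ki + log mu0_i,

where ``z_ki`` indicates membership of region ``i`` in window ``k`` and
``mu0_i`` is a fixed baseline-expectation offset.  Regions inside window
``k`` share the rate multiplier ``theta_k = exp(alpha + beta_k)``; regions
outside all windows share ``theta_out = exp(alpha)``.  Because the design is
saturated by group, the MLE is closed form: each group's fitted multiplier
is its observed/expected ratio.  The log-likelihood is evaluated with full
Poisson terms (including ``log y_i!``) so that information-criterion values
are comparable across K and against the null model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .spatial import CaseData
from .scan import Window

logger = logging.getLogger(__name__)

__all__ = [
    "IndicatorDesign",
    "ClusterModelFit",
    "indicator_matrix",
    "fit_null",
    "fit_multicluster",
    "loglik_ratio",
]


@dataclass
class IndicatorDesign:
    """Cluster-membership indicators: ``z`` is K x m, ``z0`` its complement."""

    z: np.ndarray
    z0: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.int8)
        self.z0 = np.asarray(self.z0, dtype=np.int8)
        if self.z.size and self.z.sum(axis=0).max() > 1:
            raise ValueError("candidates must be disjoint")
        total = self.z0 + (self.z.sum(axis=0) if self.z.size else 0)
        if not np.all(total == 1):
            raise ValueError("z0 must complement z exactly")


@dataclass
class ClusterModelFit:
    """Maximum-likelihood fit of the multiple-cluster Poisson model.

    Attributes
    ----------
    K
        Number of clusters (0 for the null model).
    alpha
        Log baseline rate multiplier; ``theta_outside = exp(alpha)``.
    betas
        Log relative-rate increments per cluster; ``theta_k =
        exp(alpha + beta_k)``.  A candidate fitted with ``beta_k <= 0`` is a
        cold (misspecified) window — flagged upstream, never an error here.
    loglik
        Maximized log-likelihood (full Poisson terms, base e).
    fitted
        Per-region fitted means ``mu_hat_i``.
    windows
        The windows the fit conditions on (empty for the null model).
    """

    K: int
    alpha: float
    betas: np.ndarray
    loglik: float
    fitted: np.ndarray
    windows: list[Window] = field(default_factory=list)
    group_observed: np.ndarray = field(default_factory=lambda: np.empty(0))
    group_expected: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def q(self) -> int:
        """Parameter count K + 1."""
        return self.K + 1

    @property
    def theta_outside(self) -> float:
        return float(np.exp(self.alpha))

    @property
    def theta_clusters(self) -> np.ndarray:
        return np.exp(self.alpha + np.asarray(self.betas, dtype=float))

    @property
    def relative_risks(self) -> np.ndarray:
        """theta_k / theta_outside = exp(beta_k)."""
        return np.exp(np.asarray(self.betas, dtype=float))


def indicator_matrix(windows: Sequence[Window], m: int) -> IndicatorDesign:
    """Exact 0/1 membership design for ``windows`` over ``m`` regions."""
    K = len(windows)
    z = np.zeros((K, m), dtype=np.int8)
    for k, w in enumerate(windows):
        idx = np.fromiter(w.members, dtype=np.intp)
        if idx.size and idx.max() >= m:
            raise ValueError("window member index out of range")
        z[k, idx] = 1
    if K and z.sum(axis=0).max() > 1:
        raise ValueError("candidates must be disjoint")
    z0 = (1 - (z.sum(axis=0) if K else np.zeros(m, dtype=np.int8))).astype(np.int8)
    return IndicatorDesign(z, z0)


def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    """Full Poisson log-likelihood sum_i [y log mu - mu - log y!].

    ``mu = 0`` with ``y = 0`` contributes 0 (a degenerate group rate at the
    boundary); ``mu = 0`` with ``y > 0`` gives -inf.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = y * np.log(mu)
    t[y == 0] = 0.0
    return float(np.sum(t - mu - gammaln(y + 1.0)))


def fit_null(data: CaseData) -> ClusterModelFit:
    """Null (no-cluster) model ``log mu_i = alpha + log mu0_i``.

    The MLE is ``alpha_hat = log(O / E)`` with O, E the observed and
    baseline totals.
    """
    o = data.total_observed
    e = data.total_expected
    if o == 0:
        raise ValueError("all counts are zero; null rate is degenerate")
    alpha = float(np.log(o / e))
    fitted = np.exp(alpha) * data.expected0
    return ClusterModelFit(
        K=0, alpha=alpha, betas=np.empty(0),
        loglik=_poisson_loglik(data.observed, fitted), fitted=fitted,
    )


def fit_multicluster(data: CaseData, windows: Sequence[Window]) -> ClusterModelFit:
    """Closed-form MLE of the multiple-cluster model for disjoint windows.

    Group rates: ``exp(alpha_hat) = O_out / E_out`` and
    ``exp(alpha_hat + beta_hat_k) = O_k / E_k`` where ``O_k, E_k`` are the
    window totals of counts and baseline expectations.  The score equations
    therefore hold exactly: fitted totals match observed totals within every
    window and outside.
    """
    windows = list(windows)
    if not windows:
        return fit_null(data)
    design = indicator_matrix(windows, data.m)
    inside = design.z.astype(bool)
    outside = design.z0.astype(bool)
    if not outside.any():
        raise ValueError("at least one region must lie outside all windows")
    o_k = np.array([int(data.observed[row].sum()) for row in inside], dtype=float)
    e_k = np.array([float(data.expected0[row].sum()) for row in inside])
    o_out = float(data.observed[outside].sum())
    e_out = float(data.expected0[outside].sum())
    if np.any(e_k <= 0) or e_out <= 0:
        raise ValueError("every group needs positive baseline expectation")
    if o_out == 0:
        raise ValueError("no cases outside the windows; outside rate is degenerate")
    alpha = float(np.log(o_out / e_out))
    with np.errstate(divide="ignore"):
        # O_k = 0 puts theta_k at the boundary: beta_k = -inf, mu_hat = 0
        betas = np.log(o_k / e_k) - alpha
    if np.any(betas <= 0):
        logger.warning(
            "%d candidate window(s) fitted with beta <= 0 (no rate elevation)",
            int((betas <= 0).sum()),
        )
    theta = np.full(data.m, np.exp(alpha))
    for k, row in enumerate(inside):
        theta[row] = o_k[k] / e_k[k]
    fitted = theta * data.expected0
    return ClusterModelFit(
        K=len(windows), alpha=alpha, betas=betas,
        loglik=_poisson_loglik(data.observed, fitted), fitted=fitted,
        windows=windows, group_observed=o_k, group_expected=e_k,
    )


def loglik_ratio(fit: ClusterModelFit, null_fit: ClusterModelFit) -> float:
    """Log-likelihood ratio of a cluster model against the null model.

    For a single window this coincides with the Poisson scan LLR computed
    from the same window totals (the scan statistic conditions on the total
    count but the maximized ratios are identical).
    """
    return float(fit.loglik - null_fit.loglik)
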