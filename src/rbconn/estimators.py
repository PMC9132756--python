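"""Per-voxel connectivity estimators: RBC, GBC and NRC.

RBC (Regularized Brain Connectivity)
------------------------------------
For each gray-matter voxel i, its time series y_i is regressed on the time
series of *all* remaining in-mask voxels.  With p >> N ordinary least squares
is infeasible, so the regression is penalized (ridge): minimize

    sum_t (y_i(t) - b0 - sum_{j != i} b_j y_j(t))^2  +  lam * sum_j b_j^2

with a single penalty lam shared by every voxel and every subject (estimates
are only comparable across voxels/subjects at a fixed lam).  Connectivity of
voxel i is the Pearson correlation Cor(y_hat_i, y_i) between the fitted and
observed series — the multiple correlation coefficient, i.e. sqrt(R^2).

The p >> N regime is handled through the dual (Gram) form: with standardized
columns Y (N x p) and K = Y Y^T (N x N),

    y_hat_i = K_{-i} (K_{-i} + lam I)^{-1} y_i ,   K_{-i} = K - y_i y_i^T ,

so one N x N factorization serves all p voxels via rank-one downdates
(Sherman–Morrison).  The ridge smoother is symmetric PSD, which makes
Cor(y_hat_i, y_i) nonnegative: all raw maps live in [0, 1].

lam here is the raw penalty of the objective above.  Packaged ridge solvers
that normalize the loss by N (e.g. glmnet) use approximately lam/N for the
same shrinkage; see the README.

GBC is the mean absolute bivariate correlation of each voxel with all others;
NRC is a supervised principal-component regression (screen predictors by
marginal correlation, regress the target on the leading PCs of the screened
block).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .volumes import ConnMap, MaskedSeries

__all__ = [
    "LAMBDA_GRID",
    "DEFAULT_LAMBDA",
    "RidgeSolution",
    "NrcConfig",
    "gram_matrix",
    "ridge_fit_loo",
    "rbc_map",
    "gbc_map",
    "nrc_map",
    "fisher",
]

logger = logging.getLogger(__name__)

#: Penalty grid reported in the study; single-lam analyses default to 50,
#: the value that produced the most extensive group differences.
LAMBDA_GRID: tuple[float, ...] = (0.5, 1.0, 5.0, 10.0, 50.0, 100.0, 500.0)
DEFAULT_LAMBDA: float = 50.0

_FISHER_CLIP = 1.0 - 1e-12
_VAR_FLOOR = 1e-14


@dataclass
class RidgeSolution:
    """Dual-form ridge fit for one target voxel.

    ``fitted = K_minus_i @ dual_coef`` and the primal coefficients are
    recoverable as ``beta = X_minus_i.T @ dual_coef``.  The intercept is 0
    because all series are centered before fitting (the intercept sits
    outside the penalty, so centering absorbs it exactly).
    """

    target_index: int
    lam: float
    dual_coef: np.ndarray
    fitted: np.ndarray
    intercept: float = 0.0


@dataclass
class NrcConfig:
    """Supervised PC regression settings.

    Exactly one screening rule is active: ``theta`` keeps predictors with
    |cor| >= theta; ``top_fraction`` keeps the q fraction with largest |cor|.
    ``n_components`` is clipped (with a warning) to the screened-set size.
    """

    n_components: int = 3
    theta: float | None = None
    top_fraction: float | None = 0.05

    def __post_init__(self) -> None:
        if (self.theta is None) == (self.top_fraction is None):
            raise ValueError("exactly one of theta / top_fraction must be set")
        if self.theta is not None and not (0 < self.theta < 1):
            raise ValueError(f"theta must be in (0, 1), got {self.theta}")
        if self.top_fraction is not None and not (0 < self.top_fraction <= 1):
            raise ValueError(f"top_fraction must be in (0, 1], got {self.top_fraction}")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


def _require_standardized(series: MaskedSeries) -> None:
    if not series.standardized:
        raise ValueError("series must be standardized (call standardize first)")


def gram_matrix(series: MaskedSeries) -> np.ndarray:
    """K = Y Y^T over all in-mask voxels (N x N, symmetric PSD)."""
    _require_standardized(series)
    y = series.data
    k = y @ y.T
    return (k + k.T) / 2.0


def ridge_fit_loo(K: np.ndarray, series: MaskedSeries, i: int, lam: float) -> RidgeSolution:
    """Ridge fit of voxel i on all other voxels, via the dual/Gram form.

    The leave-one-voxel-out Gram is the rank-one downdate
    K_{-i} = K - y_i y_i^T; the dual coefficients solve
    (K_{-i} + lam I) a = y_i and the fitted series is K_{-i} a.
    For lam > 0 the system is symmetric positive definite.
    """
    _require_standardized(series)
    if lam <= 0:
        raise ValueError(f"lam must be > 0, got {lam} (the OLS limit is not a ridge fit)")
    y = series.data[:, i]
    k_loo = K - np.outer(y, y)
    n = K.shape[0]
    alpha = np.linalg.solve(k_loo + lam * np.eye(n), y)
    fitted = k_loo @ alpha
    return RidgeSolution(target_index=i, lam=float(lam), dual_coef=alpha, fitted=fitted)


def _safe_corr(fitted: np.ndarray, observed: np.ndarray) -> float:
    """Pearson correlation with the degenerate-fit convention: a fitted
    series of (near-)zero variance gets connectivity 0."""
    f = fitted - fitted.mean()
    o = observed - observed.mean()
    fvar = f @ f
    ovar = o @ o
    if fvar < _VAR_FLOOR or ovar < _VAR_FLOOR:
        return 0.0
    return float((f @ o) / np.sqrt(fvar * ovar))


def rbc_map(series: MaskedSeries, lam: float = DEFAULT_LAMBDA) -> ConnMap:
    """Regularized Brain Connectivity map: Cor(fitted, observed) per voxel.

    All p voxels share one factorization of (K + lam I); each voxel's
    leave-one-out solve is recovered with a Sherman–Morrison downdate, so
    the whole map costs O(N^3 + p N^2) instead of p full solves.  The same
    lam must be used for every voxel and subject of an analysis — values
    computed at different lam are not comparable.
    """
    _require_standardized(series)
    if lam <= 0:
        raise ValueError(f"lam must be > 0, got {lam}")
    y = series.data
    n, p = y.shape
    K = gram_matrix(series)
    a_inv_y = np.linalg.solve(K + lam * np.eye(n), y)  # A^{-1} y_i for all i
    s = np.einsum("ni,ni->i", y, a_inv_y)
    # s_i = y_i^T (K + lam I)^{-1} y_i < 1 strictly since K >= y_i y_i^T
    alpha = a_inv_y / (1.0 - s)
    k_alpha = K @ alpha
    c = np.einsum("ni,ni->i", y, alpha)
    fitted = k_alpha - y * c
    # columns are centered, so Cor reduces to normalized inner products
    num = np.einsum("ni,ni->i", fitted, y)
    fnorm = np.linalg.norm(fitted, axis=0)
    onorm = np.linalg.norm(y, axis=0)
    values = np.zeros(p)
    # correlation is scale invariant (the smoother only attenuates amplitude
    # as lam grows), so "zero variance" must be judged against the floating-
    # point cancellation scale of K@alpha - y (y.alpha), not in absolute terms
    cancel_scale = np.linalg.norm(k_alpha, axis=0) + np.abs(c) * onorm
    ok = fnorm > 1e-8 * cancel_scale
    values[ok] = num[ok] / (fnorm[ok] * onorm[ok])
    n_degenerate = int((~ok).sum())
    if n_degenerate:
        logger.info("rbc_map: %d voxel(s) with degenerate fit set to 0", n_degenerate)
    # the ridge smoother is PSD so true values are >= 0; tiny negatives are
    # roundoff.  Clip below 1 so a later Fisher transform stays finite.
    values = np.clip(values, 0.0, _FISHER_CLIP)
    return ConnMap(values=values, method="RBC", voxel_index=series.voxel_index, lam=float(lam))


def gbc_map(series: MaskedSeries) -> ConnMap:
    """Weighted Global Brain Connectivity: per voxel, the average absolute
    Pearson correlation with every other in-mask voxel."""
    _require_standardized(series)
    y = series.data
    n, p = y.shape
    corr = (y.T @ y) / (n - 1)  # exact correlations for standardized columns
    np.clip(corr, -1.0, 1.0, out=corr)
    abs_sum = np.abs(corr).sum(axis=1) - 1.0  # drop the self-correlation
    values = np.clip(abs_sum / (p - 1), 0.0, 1.0)
    return ConnMap(values=values, method="GBC", voxel_index=series.voxel_index)


def nrc_map(series: MaskedSeries, cfg: NrcConfig | None = None) -> ConnMap:
    """Non-Redundant Connectivity via supervised principal-component regression.

    Per target voxel: (1) screen the remaining voxels by absolute marginal
    correlation with the target, (2) extract the leading principal components
    of the screened block, (3) OLS of the target on those components,
    (4) connectivity = Cor(fitted, observed).  Targets whose screen comes up
    empty get 0 by convention.
    """
    _require_standardized(series)
    cfg = cfg or NrcConfig()
    y = series.data
    n, p = y.shape
    corr = (y.T @ y) / (n - 1)
    values = np.zeros(p)
    clipped_warned = False
    for i in range(p):
        r = np.abs(corr[:, i])
        r[i] = -np.inf  # never screen in the target itself
        if cfg.theta is not None:
            sel = np.flatnonzero(r >= cfg.theta)
        else:
            k = max(int(np.ceil(cfg.top_fraction * (p - 1))), 1)
            sel = np.argpartition(r, -k)[-k:]
        if sel.size == 0:
            logger.info("nrc_map: voxel %d screened out all predictors; value 0", i)
            continue
        block = y[:, sel]
        # principal component scores of the screened block (columns already
        # centered); svd is deterministic up to sign, which cancels in OLS
        u, sv, _ = np.linalg.svd(block, full_matrices=False)
        rank = int((sv > sv[0] * 1e-12).sum()) if sv.size else 0
        m = min(cfg.n_components, rank)
        if m < cfg.n_components and not clipped_warned:
            logger.warning(
                "nrc_map: n_components clipped from %d to %d (screened rank)",
                cfg.n_components, m,
            )
            clipped_warned = True
        if m == 0:
            continue
        um = u[:, :m]
        fitted = um @ (um.T @ y[:, i])  # OLS on orthonormal scores
        values[i] = max(_safe_corr(fitted, y[:, i]), 0.0)
    values = np.clip(values, 0.0, _FISHER_CLIP)
    return ConnMap(values=values, method="NRC", voxel_index=series.voxel_index)


def fisher(conn_map: ConnMap) -> ConnMap:
    """Fisher transform (atanh) of a raw connectivity map.

    Values are clipped to 1 - 1e-12 first so a correlation numerically equal
    to 1 (possible at tiny lam) maps to a large finite value rather than inf.
    """
    if conn_map.fisher:
        raise ValueError("map is already Fisher transformed")
    vals = np.clip(conn_map.values, 0.0, _FISHER_CLIP)
    return ConnMap(
        values=np.arctanh(vals),
        method=conn_map.method,
        voxel_index=conn_map.voxel_index,
        lam=conn_map.lam,
        fisher=True,
    )
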