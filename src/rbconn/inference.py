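"""Group-level inference on connectivity maps.

Voxel-wise general linear model on Fisher-transformed maps, with
family-wise-error control by the permutation distribution of the maximum
TFCE (threshold-free cluster enhancement) score.

The user-facing surface is statsmodels-like: build a
:class:`GroupConnectivityModel` from a stack of per-subject maps and a
:class:`GroupDesign`, call :meth:`~GroupConnectivityModel.fit`, and read the
returned :class:`PermutationResult` (stat map, TFCE map, corrected p-values,
``summary()``).  The underlying steps — :func:`voxel_stat_map`,
:func:`tfce`, :func:`permutation_fwe` — are also exposed as functions.

Nuisance covariates (age, gender, medication type and dose in the intended
application) are handled by the Freedman–Lane scheme: the regressor of
interest and the maps are residualized against the nuisance model, the
permutation shuffles the reduced-model residuals, and the statistic is
recomputed with the nuisance projection applied again.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volumes import ConnMap, VolumeGrid

__all__ = [
    "GroupDesign",
    "TfceParams",
    "PermutationResult",
    "GroupConnectivityModel",
    "voxel_stat_map",
    "t_from_summary",
    "chi2_2x2",
    "tfce",
    "permutation_fwe",
    "stack_maps",
]

logger = logging.getLogger(__name__)

_ALTERNATIVES = ("two-sided", "greater", "less")


# ---------------------------------------------------------------------------
# designs


@dataclass
class GroupDesign:
    """Subject-level design: regressor of interest + nuisance covariates.

    The regressor is either a two-level group indicator or a continuous
    clinical score.  ``contrast`` fixes the tested direction; ``two-sided``
    is realized downstream as two one-sided TFCE runs with a Bonferroni
    factor of 2.
    """

    subjects: list[str]
    regressor: np.ndarray
    nuisance: np.ndarray | None = None
    contrast: str = "two-sided"

    def __post_init__(self) -> None:
        self.regressor = np.asarray(self.regressor, dtype=float)
        n = len(self.subjects)
        if self.regressor.shape != (n,):
            raise ValueError("regressor length must match number of subjects")
        if not np.all(np.isfinite(self.regressor)):
            raise ValueError("regressor contains missing values")
        if np.ptp(self.regressor) == 0:
            raise ValueError("regressor is constant")
        if self.contrast not in _ALTERNATIVES:
            raise ValueError(f"contrast must be one of {_ALTERNATIVES}")
        if self.nuisance is not None:
            self.nuisance = np.atleast_2d(np.asarray(self.nuisance, dtype=float))
            if self.nuisance.shape[0] != n:
                self.nuisance = self.nuisance.T
            if self.nuisance.shape[0] != n:
                raise ValueError("nuisance matrix rows must match subjects")
            if not np.all(np.isfinite(self.nuisance)):
                raise ValueError("nuisance matrix contains missing values")
            if np.linalg.matrix_rank(self.nuisance) < self.nuisance.shape[1]:
                raise ValueError("nuisance matrix is rank deficient")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def is_two_group(self) -> bool:
        return np.unique(self.regressor).size == 2

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        regressor: str,
        nuisance: list[str] | None = None,
        subject_col: str = "subject_id",
        contrast: str = "two-sided",
    ) -> "GroupDesign":
        """Build a design from a subject table.

        A non-numeric regressor column (e.g. group labels) is coded 0/1 by
        sorted label order; non-numeric nuisance columns are dummy-coded
        (dropping the first level).
        """
        subjects = [str(s) for s in table[subject_col]]
        reg = table[regressor]
        if not pd.api.types.is_numeric_dtype(reg):
            levels = sorted(reg.astype(str).unique())
            if len(levels) != 2:
                raise ValueError(
                    f"non-numeric regressor {regressor!r} must have 2 levels, got {levels}"
                )
            reg = reg.astype(str).map({levels[0]: 0.0, levels[1]: 1.0})
        z = None
        if nuisance:
            cols = []
            for name in nuisance:
                col = table[name]
                if pd.api.types.is_numeric_dtype(col):
                    cols.append(col.to_numpy(dtype=float)[:, None])
                else:
                    dummies = pd.get_dummies(col.astype(str), drop_first=True)
                    cols.append(dummies.to_numpy(dtype=float))
            z = np.hstack(cols)
        return cls(subjects=subjects, regressor=reg.to_numpy(dtype=float),
                   nuisance=z, contrast=contrast)


@dataclass
class TfceParams:
    """TFCE parameters: extent exponent E, height exponent H, threshold step.

    Defaults E=0.5, H=2 and 26-connectivity are the published defaults of the
    method.  When ``dh`` is None the step is max(stat)/n_steps, recomputed
    from the observed statistic map and then held fixed across permutations
    so that enhanced scores are comparable.
    """

    E: float = 0.5
    H: float = 2.0
    dh: float | None = None
    connectivity: int = 26
    n_steps: int = 100

    def __post_init__(self) -> None:
        if self.E <= 0 or self.H <= 0:
            raise ValueError("E and H must be > 0")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be > 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    @property
    def structure(self) -> np.ndarray:
        rank = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, rank)


# ---------------------------------------------------------------------------
# scalar statistics (summary-table helpers)


def t_from_summary(mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int):
    """Pooled two-sample t statistic from group summaries.

    The numerator is group2 - group1, so calling with (patients, controls)
    reproduces the control-minus-patient sign convention of a
    patients-first demographics table.  Returns ``(t, p)`` with the
    two-sided p-value at n1 + n2 - 2 degrees of freedom.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (mean2 - mean1) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, p


def chi2_2x2(counts):
    """Pearson chi-square (no continuity correction) on a 2x2 count table.

    Returns ``(statistic, p)``.
    """
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table < 0) or np.any(table != np.round(table)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# voxel-wise GLM


def _nuisance_basis(n: int, nuisance: np.ndarray | None) -> np.ndarray:
    """Orthonormal basis of the reduced model (intercept + nuisance)."""
    cols = [np.ones((n, 1))]
    if nuisance is not None and nuisance.size:
        cols.append(nuisance)
    q, _ = np.linalg.qr(np.hstack(cols))
    return q


def _t_stats(y: np.ndarray, x_res: np.ndarray, q: np.ndarray) -> np.ndarray:
    """t statistics of the slope of each column of y on the residualized
    regressor, after projecting out the reduced-model basis q."""
    n, _ = y.shape
    qty = q.T @ y
    ss_h = np.einsum("ij,ij->j", y, y) - np.einsum("ij,ij->j", qty, qty)
    xtx = float(x_res @ x_res)
    b = (x_res @ y) / xtx
    df = n - q.shape[1] - 1
    rss = np.maximum(ss_h - b**2 * xtx, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b * math.sqrt(xtx) / np.sqrt(rss / df)
    t = np.where(np.isfinite(t), t, 0.0)
    # voxels whose values are numerically constant across subjects carry no
    # signal: both slope and residual collapse to rounding noise, so t := 0
    degenerate = (rss < 1e-20) & (np.abs(b) * math.sqrt(xtx) < 1e-8)
    return np.where(degenerate, 0.0, t)


def stack_maps(maps) -> tuple[np.ndarray, np.ndarray, dict]:
    """Stack per-subject ConnMaps into an (n_subjects x p) matrix.

    All maps must share method, lam and voxel order.  Voxels undefined (NaN)
    in any subject are excluded from inference; the returned metadata carries
    the surviving voxel index and map provenance.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("empty map stack")
    first = maps[0]
    for m in maps[1:]:
        if m.method != first.method or (m.lam or 0) != (first.lam or 0):
            raise ValueError("maps mix methods or lam values")
        if m.fisher != first.fisher:
            raise ValueError("maps mix Fisher and raw values")
        if not np.array_equal(m.voxel_index, first.voxel_index):
            raise ValueError("maps are not on the same voxel set")
    values = np.vstack([m.values for m in maps])
    ok = np.all(np.isfinite(values), axis=0)
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info("stack_maps: excluding %d voxel(s) undefined in some subject", n_drop)
    meta = {"method": first.method, "lam": first.lam, "fisher": first.fisher}
    return values[:, ok], first.voxel_index[ok], meta


def voxel_stat_map(maps, design: GroupDesign) -> np.ndarray:
    """Per-voxel t statistic of the design regressor across subjects.

    Map values and the regressor are residualized against the nuisance
    covariates (plus intercept); the t statistic of the regressor's slope is
    returned per voxel.  With a two-group indicator and no nuisance this is
    exactly the pooled two-sample t (group coded 1 minus group coded 0).
    """
    values, _, _ = stack_maps(maps)
    return _stat_from_values(values, design)


def _stat_from_values(values: np.ndarray, design: GroupDesign) -> np.ndarray:
    n = values.shape[0]
    if n != design.n_subjects:
        raise ValueError("map stack and design disagree on subject count")
    if design.is_two_group:
        _, counts = np.unique(design.regressor, return_counts=True)
        if counts.min() < 3:
            raise ValueError("need at least 3 subjects per group")
    q = _nuisance_basis(n, design.nuisance)
    x_res = design.regressor - q @ (q.T @ design.regressor)
    if float(x_res @ x_res) < 1e-12:
        raise ValueError("regressor is collinear with the nuisance covariates")
    y_res = values - q @ (q.T @ values)
    return _t_stats(y_res, x_res, q)


# ---------------------------------------------------------------------------
# TFCE


def tfce(stat_map: np.ndarray, params: TfceParams, mask: np.ndarray) -> np.ndarray:
    """Threshold-free cluster enhancement of a 3-D statistic map.

    TFCE(v) = sum over thresholds h = dh, 2dh, ... <= stat(v) of
    e(h, v)^E * h^H * dh, where e(h, v) is the voxel count of the connected
    suprathreshold component containing v at height h.  Only positive values
    are enhanced; call with ``-stat_map`` for the negative contrast.
    """
    stat_map = np.asarray(stat_map, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if stat_map.shape != mask.shape:
        raise ValueError("stat map and mask shapes differ")
    if not np.all(np.isfinite(stat_map[mask])):
        raise ValueError("non-finite statistic values inside the mask")
    vol = np.where(mask, stat_map, 0.0)
    vmax = float(vol.max(initial=0.0))
    out = np.zeros_like(vol)
    if vmax <= 0:
        return out
    dh = params.dh if params.dh is not None else vmax / params.n_steps
    return _tfce_accumulate(vol, dh, vmax, params)


def _tfce_accumulate(vol: np.ndarray, dh: float, hmax: float, params: TfceParams) -> np.ndarray:
    out = np.zeros_like(vol)
    structure = params.structure
    eps = dh * 1e-9  # absorb accumulated float error at exact-threshold voxels
    k = 1
    while True:
        h = k * dh
        if h > hmax + eps:
            break
        sup = vol >= h - eps
        if not sup.any():
            break
        labels, _ = ndimage.label(sup, structure=structure)
        sizes = np.bincount(labels.ravel())
        out[sup] += sizes[labels[sup]] ** params.E * h**params.H * dh
        k += 1
    return out


# ---------------------------------------------------------------------------
# permutation engine


@dataclass
class PermutationResult:
    """Results of a permutation-FWE test on a map stack.

    Vectors are aligned with ``voxel_index`` (the voxels that survived
    stacking).  ``fwe_p`` is corrected for the search over all voxels via the
    null distribution of the maximum TFCE score; for a two-sided contrast it
    additionally carries a Bonferroni factor of 2 over the two directions.
    """

    stat_map: np.ndarray
    tfce_map: np.ndarray
    null_max: np.ndarray
    fwe_p: np.ndarray
    n_perm: int
    seed: int | None
    voxel_index: np.ndarray
    grid: VolumeGrid
    alternative: str
    exhaustive: bool = False
    meta: dict = field(default_factory=dict)

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return self.fwe_p < alpha

    def n_significant(self, alpha: float = 0.05) -> int:
        return int(self.significant(alpha).sum())

    def summary(self, alpha: float = 0.05) -> str:
        lines = []
        meta = self.meta
        method = meta.get("method", "?")
        lam = meta.get("lam")
        title = f"Permutation TFCE inference — {method}"
        if lam is not None:
            title += f" (lam={lam:g})"
        lines.append(title)
        lines.append("=" * len(title))
        lines.append(f"voxels tested           : {self.stat_map.size}")
        lines.append(f"permutations            : {self.n_perm}"
                     + (" (exhaustive)" if self.exhaustive else ""))
        lines.append(f"contrast                : {self.alternative}")
        lines.append(f"max |t|                 : {np.abs(self.stat_map).max():.3f}")
        lines.append(f"min FWE-corrected p     : {self.fwe_p.min():.4f}")
        nsig = self.n_significant(alpha)
        lines.append(f"significant voxels (a={alpha:g}): {nsig}")
        if nsig:
            peak = int(np.argmin(self.fwe_p))
            coord = tuple(int(c) for c in self.voxel_index[peak])
            lines.append(f"peak voxel              : {coord} "
                         f"(t={self.stat_map[peak]:.3f}, p={self.fwe_p[peak]:.4f})")
        return "\n".join(lines)

    def to_dict(self, alpha: float = 0.05) -> dict:
        return {
            "method": self.meta.get("method"),
            "lam": self.meta.get("lam"),
            "alternative": self.alternative,
            "n_perm": self.n_perm,
            "exhaustive": self.exhaustive,
            "n_voxels": int(self.stat_map.size),
            "n_significant": self.n_significant(alpha),
            "min_fwe_p": float(self.fwe_p.min()),
            "max_abs_t": float(np.abs(self.stat_map).max()),
        }


def _enumerate_two_group(x: np.ndarray):
    """All distinct two-group assignments, as row-permutation index arrays."""
    n = x.size
    hi = np.flatnonzero(x == x.max())
    base = np.arange(n)
    for subset in itertools.combinations(range(n), hi.size):
        perm = base.copy()
        rest = [i for i in range(n) if i not in subset]
        # rows `subset` land in the high-group positions, the rest fill in
        perm[hi] = subset
        perm[np.setdiff1d(base, hi, assume_unique=True)] = rest
        yield perm


def _n_distinct_perms(design: GroupDesign) -> int:
    n = design.n_subjects
    if design.is_two_group and (design.nuisance is None or design.nuisance.size == 0):
        n1 = int((design.regressor == design.regressor.max()).sum())
        return math.comb(n, n1)
    return math.factorial(n)


def _perm_iterator(design: GroupDesign, n_perm: int, rng: np.random.Generator):
    """Yield permutation index arrays; exhaustively when the number of
    distinct permutations does not exceed n_perm."""
    n = design.n_subjects
    n_distinct = _n_distinct_perms(design)
    if n_distinct < 20:
        warnings.warn(
            f"only {n_distinct} distinct permutations; p-value resolution "
            f"is limited to {1.0 / n_distinct:.3g}",
            stacklevel=3,
        )
    if n_distinct <= n_perm:
        if design.is_two_group and (design.nuisance is None or design.nuisance.size == 0):
            return True, n_distinct, _enumerate_two_group(design.regressor)
        return True, n_distinct, (np.array(p) for p in itertools.permutations(range(n)))
    return False, n_perm, (rng.permutation(n) for _ in range(n_perm))


def permutation_fwe(
    maps,
    design: GroupDesign,
    grid: VolumeGrid,
    params: TfceParams | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> PermutationResult:
    """Permutation test with max-TFCE family-wise error correction.

    The observed voxel-wise t map is TFCE-enhanced and compared against the
    null distribution of the *maximum* TFCE score over voxels under
    permutations.  With nuisance covariates the Freedman–Lane scheme is used:
    residuals from the nuisance-only model are permuted and the full
    statistic recomputed.  fwe_p(v) = (1 + #{perm max >= TFCE(v)}) /
    (n_perm + 1), or the exact count ratio when permutations are fully
    enumerated.  Two-sided contrasts run both directions and apply a
    Bonferroni factor of 2.
    """
    if params is None:
        params = TfceParams()
    if seed is None:
        raise ValueError("a seed is required for permutation inference")
    values, voxel_index, meta = stack_maps(maps)
    return _permutation_fwe_values(values, voxel_index, meta, design, grid,
                                   params, n_perm, seed)


def _embed(vec: np.ndarray, voxel_index: np.ndarray, shape) -> np.ndarray:
    vol = np.zeros(shape)
    vol[voxel_index[:, 0], voxel_index[:, 1], voxel_index[:, 2]] = vec
    return vol


def _permutation_fwe_values(
    values, voxel_index, meta, design, grid, params, n_perm, seed
) -> PermutationResult:
    n, p = values.shape
    shape = grid.shape
    mask = np.zeros(shape, dtype=bool)
    mask[voxel_index[:, 0], voxel_index[:, 1], voxel_index[:, 2]] = True
    in_mask = (voxel_index[:, 0], voxel_index[:, 1], voxel_index[:, 2])

    q = _nuisance_basis(n, design.nuisance)
    x_res = design.regressor - q @ (q.T @ design.regressor)
    if float(x_res @ x_res) < 1e-12:
        raise ValueError("regressor is collinear with the nuisance covariates")
    if design.is_two_group:
        _, counts = np.unique(design.regressor, return_counts=True)
        if counts.min() < 3:
            raise ValueError("need at least 3 subjects per group")
    y_res = values - q @ (q.T @ values)

    stat = _t_stats(y_res, x_res, q)
    alternative = design.contrast
    sides = {"greater": [+1.0], "less": [-1.0], "two-sided": [+1.0, -1.0]}[alternative]

    # step size fixed from the observed map so permuted scores are comparable
    smax = float(np.abs(stat).max())
    eff = TfceParams(E=params.E, H=params.H, connectivity=params.connectivity,
                     n_steps=params.n_steps,
                     dh=params.dh if params.dh is not None else
                     (smax / params.n_steps if smax > 0 else None))

    def enhance(vec: np.ndarray, sign: float) -> np.ndarray:
        vol = _embed(sign * vec, voxel_index, shape)
        if eff.dh is None:
            return np.zeros(p)
        return _tfce_accumulate(np.where(mask, np.maximum(vol, 0.0), 0.0),
                                eff.dh, max(float(vol.max(initial=0.0)), 0.0),
                                eff)[in_mask]

    obs_tfce = {s: enhance(stat, s) for s in sides}

    rng = np.random.default_rng(seed)
    exhaustive, m, perms = _perm_iterator(design, n_perm, rng)
    null_max = np.zeros((len(sides), m))
    for j, perm in enumerate(perms):
        yp = y_res[perm]
        t_perm = _t_stats(yp - q @ (q.T @ yp), x_res, q)
        for si, s in enumerate(sides):
            null_max[si, j] = enhance(t_perm, s).max(initial=0.0)

    fwe = np.ones((len(sides), p))
    for si, s in enumerate(sides):
        exceed = (null_max[si][:, None] >= obs_tfce[s][None, :]).sum(axis=0)
        if exhaustive:
            fwe[si] = exceed / m
        else:
            fwe[si] = (1.0 + exceed) / (m + 1.0)
    if alternative == "two-sided":
        fwe_p = np.minimum(2.0 * fwe.min(axis=0), 1.0)
        tfce_signed = obs_tfce[+1.0] - obs_tfce[-1.0]
    else:
        fwe_p = fwe[0]
        tfce_signed = sides[0] * obs_tfce[sides[0]]

    return PermutationResult(
        stat_map=stat,
        tfce_map=tfce_signed,
        null_max=null_max if len(sides) > 1 else null_max[0],
        fwe_p=fwe_p,
        n_perm=m,
        seed=seed,
        voxel_index=voxel_index,
        grid=grid,
        alternative=alternative,
        exhaustive=exhaustive,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# model front-end


class GroupConnectivityModel:
    """Voxel-wise group GLM on a stack of connectivity maps.

    Parameters
    ----------
    maps : sequence of ConnMap
        One Fisher-transformed map per subject, same method/lam/voxel set,
        ordered as ``design.subjects``.
    design : GroupDesign
    grid : VolumeGrid
        The 3-D grid the maps live on (needed for TFCE neighborhoods).
    tfce_params : TfceParams, optional

    Examples
    --------
    >>> model = GroupConnectivityModel(maps, design, grid)
    >>> res = model.fit(n_perm=1000, seed=7)
    >>> print(res.summary())
    """

    def __init__(self, maps, design: GroupDesign, grid: VolumeGrid,
                 tfce_params: TfceParams | None = None):
        self.maps = list(maps)
        if len(self.maps) != design.n_subjects:
            raise ValueError("one map per design subject is required")
        if not all(m.fisher for m in self.maps):
            warnings.warn("maps are not Fisher transformed; group statistics "
                          "assume approximately normal values", stacklevel=2)
        self.design = design
        self.grid = grid
        self.tfce_params = tfce_params or TfceParams()
        self.values, self.voxel_index, self.meta = stack_maps(self.maps)

    def stat_map(self) -> np.ndarray:
        """Observed voxel-wise t statistics (no correction)."""
        return _stat_from_values(self.values, self.design)

    def fit(self, n_perm: int = 1000, seed: int | None = None) -> PermutationResult:
        """Run the permutation-TFCE inference and return the results object."""
        if seed is None:
            raise ValueError("a seed is required for permutation inference")
        return _permutation_fwe_values(
            self.values, self.voxel_index, self.meta, self.design,
            self.grid, self.tfce_params, n_perm, seed,
        )
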