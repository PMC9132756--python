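"""Volume I/O and time-series preparation.

Reads 4D BOLD NIfTI volumes and a binary gray-matter mask into an
N (time) x p (voxel) matrix, and provides the standard preparation steps
that every connectivity estimator in this package consumes: block-mean
spatial downsampling, hard DFT band-pass filtering, and per-voxel
standardization.

Voxel ordering convention
-------------------------
In-mask voxels are always raveled in raster order with x fastest, then y,
then z (0-based voxel indices).  Every map written by this package uses the
same order, so voxel k of a :class:`ConnMap` always refers to the same grid
location across subjects sharing a mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "MaskedSeries",
    "ConnMap",
    "load_masked_series",
    "resample_block_mean",
    "resample_mask_majority",
    "bandpass",
    "standardize",
    "write_map",
    "load_map",
]

_AFFINE_TOL = 1e-6


@dataclass(frozen=True)
class VolumeGrid:
    """Axis-aligned voxel grid: integer shape, voxel size and origin in mm.

    Only scaling + translation affines are representable; oblique or rotated
    grids are rejected at load time (out of scope for this package).
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (4.0, 4.0, 4.0)
    origin_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "origin_offset", tuple(float(v) for v in self.origin_offset))

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        aff[:3, 3] = self.origin_offset
        return aff

    @classmethod
    def from_affine(cls, shape, affine: np.ndarray) -> "VolumeGrid":
        affine = np.asarray(affine, dtype=float)
        lin = affine[:3, :3]
        off_diag = lin - np.diag(np.diag(lin))
        if np.any(np.abs(off_diag) > _AFFINE_TOL):
            raise ValueError(
                "oblique/rotated affine not supported: only axis-aligned "
                "scaling + translation grids are handled"
            )
        diag = np.diag(lin)
        if np.any(diag <= 0):
            # negative scalings (e.g. radiological x-flip) are folded into a
            # positive voxel size; orientation bookkeeping is out of scope.
            diag = np.abs(diag)
        return cls(tuple(int(s) for s in shape[:3]), tuple(diag), tuple(affine[:3, 3]))


@dataclass
class MaskedSeries:
    """N x p matrix of in-mask voxel time series with grid bookkeeping.

    ``data[t, k]`` is the BOLD value of voxel ``voxel_index[k]`` at time t.
    """

    data: np.ndarray
    voxel_index: np.ndarray  # (p, 3) int voxel coordinates, raster order
    tr: float
    grid: VolumeGrid
    standardized: bool = False
    dropped_voxels: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3), dtype=np.intp)
    )

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.intp)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (time x voxel) matrix")
        n, p = self.data.shape
        if n < 3:
            raise ValueError(f"need at least 3 time points, got {n}")
        if p < 2:
            raise ValueError(f"need at least 2 in-mask voxels, got {p}")
        if self.voxel_index.shape != (p, 3):
            raise ValueError("voxel_index must be (p, 3)")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        shape = np.asarray(self.grid.shape)
        if np.any(self.voxel_index < 0) or np.any(self.voxel_index >= shape):
            raise ValueError("voxel_index entries outside the grid")
        if len(np.unique(self.voxel_index, axis=0)) != p:
            raise ValueError("voxel_index entries must be unique")

    @property
    def n_time(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.tr)


@dataclass
class ConnMap:
    """One connectivity value per in-mask voxel, plus method metadata.

    Raw (non-Fisher) values of all three estimators are correlations or
    means of absolute correlations, hence lie in [0, 1]; after the Fisher
    transform values are finite reals.  Undefined voxels are NaN.
    """

    values: np.ndarray
    method: str  # "RBC" | "GBC" | "NRC"
    voxel_index: np.ndarray
    lam: float | None = None
    fisher: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.intp)
        if self.method not in ("RBC", "GBC", "NRC"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.values.ndim != 1 or self.voxel_index.shape != (self.values.size, 3):
            raise ValueError("values must be 1-D with matching voxel_index")
        defined = self.values[np.isfinite(self.values)]
        if not self.fisher and defined.size and (
            defined.min() < -1e-12 or defined.max() > 1.0 + 1e-12
        ):
            raise ValueError("raw connectivity values must lie in [0, 1]")

    @property
    def n_defined(self) -> int:
        return int(np.isfinite(self.values).sum())


def _raster_order(mask: np.ndarray) -> np.ndarray:
    """(p, 3) coordinates of True voxels, x fastest, then y, then z."""
    xs, ys, zs = np.nonzero(mask)
    order = np.lexsort((xs, ys, zs))
    return np.column_stack([xs, ys, zs])[order]


def load_masked_series(bold_path, mask_path) -> MaskedSeries:
    """Load a 4D BOLD image restricted to a binary 3-D mask.

    The BOLD and mask images must live on the identical grid.  TR is read
    from the 4th pixdim of the BOLD header.
    """
    bold_img = nib.load(str(bold_path))
    mask_img = nib.load(str(mask_path))
    bold = np.asarray(bold_img.dataobj, dtype=float)
    mask_data = np.asarray(mask_img.dataobj, dtype=float)
    if bold.ndim != 4:
        raise ValueError(f"BOLD image must be 4-D, got shape {bold.shape}")
    if mask_data.ndim != 3:
        raise ValueError(f"mask must be 3-D, got shape {mask_data.shape}")
    if bold.shape[:3] != mask_data.shape:
        raise ValueError(
            f"grid mismatch: BOLD {bold.shape[:3]} vs mask {mask_data.shape}"
        )
    if not np.allclose(bold_img.affine, mask_img.affine, atol=_AFFINE_TOL):
        raise ValueError("grid mismatch: BOLD and mask affines differ")
    uniq = np.unique(mask_data)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError(f"mask is not binary: values {uniq[:10]}")
    mask = mask_data > 0.5
    if not mask.any():
        raise ValueError("mask is empty")
    grid = VolumeGrid.from_affine(bold.shape, bold_img.affine)
    coords = _raster_order(mask)
    data = bold[coords[:, 0], coords[:, 1], coords[:, 2], :].T
    zooms = bold_img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return MaskedSeries(data=data, voxel_index=coords, tr=tr, grid=grid)


def _block_reduce_axis(arr: np.ndarray, axis: int, factor: int, reducer) -> np.ndarray:
    """Reduce one axis in blocks of `factor`; trailing partial blocks use
    whatever voxels are available."""
    n = arr.shape[axis]
    starts = np.arange(0, n, factor)
    sums = np.add.reduceat(arr, starts, axis=axis)
    counts = np.minimum(starts + factor, n) - starts
    shape = [1] * arr.ndim
    shape[axis] = counts.size
    return reducer(sums, counts.reshape(shape))


def resample_block_mean(bold: np.ndarray, grid: VolumeGrid, factor: int):
    """Downsample by averaging non-overlapping factor³ blocks per time point.

    Block-mean downsampling preserves spatial means exactly, matching the
    stated purpose of the coarse (4 mm) analysis grid: computational cost
    reduction without distorting the signal level.

    Returns ``(resampled 4-D array, new VolumeGrid)``.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError(f"resampling factor must be >= 1, got {factor}")
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 4:
        raise ValueError("expected a 4-D (x, y, z, t) array")
    out = bold
    if factor > 1:
        for axis in range(3):
            out = _block_reduce_axis(out, axis, factor, lambda s, c: s / c)
    new_grid = VolumeGrid(
        shape=out.shape[:3],
        voxel_size=tuple(v * factor for v in grid.voxel_size),
        # origin moves to the centre of the first source block
        origin_offset=tuple(
            o + (factor - 1) / 2.0 * v
            for o, v in zip(grid.origin_offset, grid.voxel_size)
        ),
    )
    return out, new_grid


def resample_mask_majority(mask: np.ndarray, factor: int) -> np.ndarray:
    """Downsample a binary mask: output voxel kept if > 50% of its source
    block is in the mask."""
    factor = int(factor)
    if factor < 1:
        raise ValueError(f"resampling factor must be >= 1, got {factor}")
    frac = np.asarray(mask, dtype=float)[..., None]  # reuse the 4-D path
    grid = VolumeGrid(mask.shape, (1.0, 1.0, 1.0))
    out, _ = resample_block_mean(frac, grid, factor)
    return out[..., 0] > 0.5


def bandpass(series: MaskedSeries, low_hz: float = 0.02, high_hz: float = 0.1) -> MaskedSeries:
    """Hard DFT band-pass: zero every Fourier component outside [low, high].

    The DC component is always removed.  A hard frequency-domain mask (rather
    than an IIR design) keeps the operation exactly idempotent and testable
    bin by bin.
    """
    nyq = series.nyquist
    if not (0 <= low_hz < high_hz <= nyq + 1e-12):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz invalid for Nyquist {nyq:.4g} Hz"
        )
    n = series.n_time
    freqs = np.fft.rfftfreq(n, d=series.tr)
    keep = (freqs >= low_hz - 1e-12) & (freqs <= high_hz + 1e-12)
    keep[0] = False  # DC always removed
    spec = np.fft.rfft(series.data, axis=0)
    spec[~keep, :] = 0.0
    filtered = np.fft.irfft(spec, n=n, axis=0)
    return replace(series, data=filtered, standardized=False)


def standardize(series: MaskedSeries, var_tol: float = 1e-12) -> MaskedSeries:
    """Center each voxel series and rescale to unit sample variance (N-1).

    Constant (zero-variance) voxels cannot be standardized; they are dropped
    from the matrix and recorded in ``dropped_voxels`` so downstream maps can
    mark them missing, rather than poisoning the predictor set with NaNs.
    Already-standardized input is returned unchanged (idempotent).
    """
    x = series.data
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1)
    good = var > var_tol
    if not good.any() or good.sum() < 2:
        raise ValueError("fewer than 2 non-constant voxels; nothing to analyze")
    out = (x[:, good] - mean[good]) / np.sqrt(var[good])
    dropped = series.voxel_index[~good]
    if series.dropped_voxels.size:
        dropped = np.vstack([series.dropped_voxels, dropped])
    return MaskedSeries(
        data=out,
        voxel_index=series.voxel_index[good],
        tr=series.tr,
        grid=series.grid,
        standardized=True,
        dropped_voxels=dropped,
    )


def write_map(conn_map: ConnMap, grid: VolumeGrid, path) -> None:
    """Write a ConnMap as a 3-D NIfTI: map values at in-mask voxels,
    background 0, undefined voxels NaN."""
    shape = grid.shape
    idx = conn_map.voxel_index
    if np.any(idx < 0) or np.any(idx >= np.asarray(shape)):
        raise ValueError("map voxel_index inconsistent with grid")
    vol = np.zeros(shape, dtype=np.float64)
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = conn_map.values
    img = nib.Nifti1Image(vol, grid.affine)
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))


def load_map(path, mask: np.ndarray, method: str = "RBC", lam: float | None = None,
             fisher: bool = True) -> ConnMap:
    """Read a map written by :func:`write_map` back into a ConnMap using the
    package's raster voxel order."""
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float)
    coords = _raster_order(np.asarray(mask) > 0.5)
    values = vol[coords[:, 0], coords[:, 1], coords[:, 2]]
    return ConnMap(values=values, method=method, voxel_index=coords,
                   lam=lam, fisher=fisher)
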