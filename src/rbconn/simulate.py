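"""Synthetic resting-state fMRI cohorts with known latent-network structure.

Each subject's in-mask voxel series is a weighted sum of band-limited
latent signals shared within voxel communities, plus temporally
autocorrelated AR(1) noise:

    y_v(t) = sum_c  w_v,c * (g_v,c if patient else 1) * L_c(t)  +  e_v(t),
    e_v(t) = rho * e_v(t-1) + innovation,  innovation ~ N(0, sigma^2).

Latents are unit-variance Gaussian processes with spectral support inside
the analysis band (0.02-0.1 Hz by default), drawn fresh per subject; the
AR(1) noise represents the temporal dependence of BOLD series that makes
ordinary cross-validation unsuitable for choosing the ridge penalty.

Closed forms used by the tests: the stationary AR(1) variance is
sigma^2 / (1 - rho^2); the marginal voxel variance is
sum_c w^2 + sigma'^2, and the correlation of two voxels sharing one latent
with weights w_i, w_j is  w_i w_j / sqrt((w_i^2 + s'^2)(w_j^2 + s'^2)).

Group effects multiply a patient voxel's coupling weight to one latent (or
to all its latents) by a factor g; g = 1 everywhere makes the two groups'
generative laws identical, which is the basis of the permutation
calibration tests.  The shipped "multivariate-only" scenario reallocates
patients' coupling between a shared and a voxel-private latent at constant
marginal variance, producing a deficit that a multivariate estimator (RBC)
sees undiluted while a brain-averaged bivariate one (GBC) sees only through
a small fraction of its terms.

Acquisition regime emulated: N = 256 time points at TR = 2 s on a coarse
(4 mm-like) grid; band-limited signal in 0.02-0.1 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import signal as sps

from .volumes import MaskedSeries, VolumeGrid, _raster_order

__all__ = [
    "Community",
    "GroupEffect",
    "CohortSpec",
    "simulate_subject",
    "simulate_subject_series",
    "simulate_cohort",
    "simulate_cohort_series",
    "ellipsoid_mask",
    "null_scenario",
    "multiplicative_effect_scenario",
    "multivariate_effect_scenario",
]

DEFAULT_BAND = (0.02, 0.1)


@dataclass
class Community:
    """A set of voxels sharing one latent signal with per-voxel coupling."""

    voxels: np.ndarray  # (k, 3) int voxel coordinates
    latent: str
    weight: float | np.ndarray = 1.0

    def __post_init__(self) -> None:
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=np.intp))
        w = np.broadcast_to(np.asarray(self.weight, dtype=float), (len(self.voxels),))
        if np.any(w < 0):
            raise ValueError("coupling weights must be >= 0")
        self.weight = w.copy()


@dataclass
class GroupEffect:
    """Multiplicative change g of patients' coupling on a voxel set.

    ``latent=None`` scales the voxels' coupling to every latent; a latent id
    restricts the effect to that one community membership.
    """

    voxels: np.ndarray
    g: float
    latent: str | None = None

    def __post_init__(self) -> None:
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=np.intp))
        if self.g < 0:
            raise ValueError("effect factor g must be >= 0")


@dataclass
class CohortSpec:
    """Generative description of a two-group synthetic cohort."""

    grid: VolumeGrid
    mask: np.ndarray
    communities: list[Community]
    latents: dict[str, tuple[float, float]]  # latent id -> (low, high) Hz
    n_time: int = 256
    tr: float = 2.0
    rho: float = 0.3
    sigma: float = 1.0
    group_effects: list[GroupEffect] = field(default_factory=list)
    n_per_group: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if not (0 <= self.rho < 1):
            raise ValueError(f"AR(1) coefficient must be in [0, 1), got {self.rho}")
        if self.sigma <= 0:
            raise ValueError("innovation sd must be > 0")
        if self.n_time < 8:
            raise ValueError("n_time too small")
        for c in self.communities:
            if c.latent not in self.latents:
                raise ValueError(f"community references unknown latent {c.latent!r}")
            if not self.mask[c.voxels[:, 0], c.voxels[:, 1], c.voxels[:, 2]].all():
                raise ValueError("community voxels must lie inside the mask")
        for e in self.group_effects:
            if not self.mask[e.voxels[:, 0], e.voxels[:, 1], e.voxels[:, 2]].all():
                raise ValueError("effect voxels must lie inside the mask")
            if e.latent is not None and e.latent not in self.latents:
                raise ValueError(f"effect references unknown latent {e.latent!r}")

    @property
    def stationary_noise_var(self) -> float:
        return self.sigma**2 / (1.0 - self.rho**2)

    def subject_seed(self, index: int) -> list[int]:
        """Documented counter scheme: subject `index` (0-based across the
        cohort, controls first) draws from default_rng([seed, index])."""
        return [int(self.seed), int(index)]


def _band_limited_latent(rng: np.random.Generator, n: int, tr: float,
                         band: tuple[float, float]) -> np.ndarray:
    """Unit-variance Gaussian series with spectral support inside `band`."""
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= band[0] - 1e-12) & (freqs <= band[1] + 1e-12) & (freqs > 0)
    if not keep.any():
        raise ValueError(f"band {band} contains no Fourier bin at n={n}, tr={tr}")
    spec = np.zeros(freqs.size, dtype=complex)
    coefs = rng.standard_normal((int(keep.sum()), 2))
    spec[keep] = coefs[:, 0] + 1j * coefs[:, 1]
    x = np.fft.irfft(spec, n=n)
    x -= x.mean()
    return x / x.std(ddof=1)


def _ar1_noise(rng: np.random.Generator, n: int, k: int, rho: float,
               sigma: float) -> np.ndarray:
    """(n, k) stationary AR(1) noise."""
    x0 = rng.standard_normal(k) * sigma / np.sqrt(1.0 - rho**2)
    eps = rng.standard_normal((n, k)) * sigma
    if rho == 0:
        return eps
    out, _ = sps.lfilter([1.0], [1.0, -rho], eps, axis=0, zi=(rho * x0)[None, :])
    return out


def _flat_ids(coords: np.ndarray, shape) -> np.ndarray:
    return np.ravel_multi_index((coords[:, 0], coords[:, 1], coords[:, 2]), shape)


def _effective_weights(spec: CohortSpec, community: Community, group: str) -> np.ndarray:
    w = community.weight.copy()
    if group == "patient":
        ids = _flat_ids(community.voxels, spec.grid.shape)
        for eff in spec.group_effects:
            if eff.latent is not None and eff.latent != community.latent:
                continue
            hit = np.isin(ids, _flat_ids(eff.voxels, spec.grid.shape))
            w[hit] *= eff.g
    return w


def simulate_subject_series(spec: CohortSpec, group: str, subject_seed) -> MaskedSeries:
    """One subject's in-mask series as a MaskedSeries (raster voxel order)."""
    if group not in ("control", "patient"):
        raise ValueError("group must be 'control' or 'patient'")
    rng = np.random.default_rng(subject_seed)
    coords = _raster_order(spec.mask)
    p = len(coords)
    flat = _flat_ids(coords, spec.grid.shape)
    pos = {f: i for i, f in enumerate(flat)}

    data = np.zeros((spec.n_time, p))
    # latents drawn in sorted id order, then noise: deterministic given seeds
    latent_series = {
        name: _band_limited_latent(rng, spec.n_time, spec.tr, spec.latents[name])
        for name in sorted(spec.latents)
    }
    for community in spec.communities:
        w = _effective_weights(spec, community, group)
        cols = np.array([pos[f] for f in _flat_ids(community.voxels, spec.grid.shape)])
        data[:, cols] += np.outer(latent_series[community.latent], w)
    data += _ar1_noise(rng, spec.n_time, p, spec.rho, spec.sigma)
    return MaskedSeries(data=data, voxel_index=coords, tr=spec.tr, grid=spec.grid)


def simulate_subject(spec: CohortSpec, group: str, subject_seed) -> np.ndarray:
    """One subject as a 4-D (x, y, z, t) array; out-of-mask voxels are 0."""
    series = simulate_subject_series(spec, group, subject_seed)
    vol = np.zeros(spec.grid.shape + (spec.n_time,))
    c = series.voxel_index
    vol[c[:, 0], c[:, 1], c[:, 2], :] = series.data.T
    return vol


def _covariate_table(spec: CohortSpec) -> pd.DataFrame:
    """Synthetic demographics: age ~ N(40, 12) clipped to 18-65, gender
    ~ Bernoulli(43/74 male), patients get a clinical severity score
    ~ N(14, 6.6) clipped at 0, a medication type and a chlorpromazine-
    equivalent dose (lognormal, mean 509, sd 518)."""
    rng = np.random.default_rng([int(spec.seed), 999983])
    rows = []
    m = spec.n_per_group
    cpz_mean, cpz_sd = 508.82, 517.55
    s2 = np.log(1.0 + (cpz_sd / cpz_mean) ** 2)
    for idx in range(2 * m):
        group = "control" if idx < m else "patient"
        age = float(np.clip(np.round(rng.normal(40.0, 12.0)), 18, 65))
        gender = "M" if rng.random() < 43 / 74 else "F"
        if group == "patient":
            score = float(max(rng.normal(14.0, 6.6), 0.0))
            med = rng.choice(["atypical", "typical", "both"], p=[109 / 142, 9 / 142, 24 / 142])
            cpz = float(rng.lognormal(np.log(cpz_mean) - s2 / 2.0, np.sqrt(s2)))
        else:
            score, med, cpz = np.nan, "none", 0.0
        rows.append({
            "subject_id": f"sub-{idx:03d}", "group": group, "age": age,
            "gender": gender, "score": score, "med_type": med, "cpz_dose": cpz,
        })
    return pd.DataFrame(rows)


def simulate_cohort_series(spec: CohortSpec):
    """In-memory cohort: (list of MaskedSeries, subject table).

    Subject ``idx`` (controls first, then patients) uses the seed stream
    ``default_rng([spec.seed, idx])``; regenerating with the same spec seed
    reproduces the cohort bit for bit.
    """
    table = _covariate_table(spec)
    series = [
        simulate_subject_series(spec, row.group, spec.subject_seed(idx))
        for idx, row in enumerate(table.itertuples())
    ]
    return series, table


def simulate_cohort(spec: CohortSpec, out_dir) -> pd.DataFrame:
    """Write the cohort to disk: one 4-D NIfTI per subject, the mask, and
    ``participants.csv``.  Returns the subject table with a `bold` column."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = _covariate_table(spec)
    mask_img = nib.Nifti1Image(spec.mask.astype(np.uint8), spec.grid.affine)
    nib.save(mask_img, str(out / "mask.nii"))
    paths = []
    for idx, row in enumerate(table.itertuples()):
        vol = simulate_subject(spec, row.group, spec.subject_seed(idx))
        img = nib.Nifti1Image(vol, spec.grid.affine)
        img.header.set_zooms(spec.grid.voxel_size + (spec.tr,))
        path = out / f"{row.subject_id}_bold.nii"
        nib.save(img, str(path))
        paths.append(path.name)  # relative: the table stays location independent
    table["bold"] = paths
    table.to_csv(out / "participants.csv", index=False)
    return table


# ---------------------------------------------------------------------------
# shipped scenarios


SCENARIOS = {}


def cohort_spec_from_dict(cfg: dict) -> CohortSpec:
    """Build a CohortSpec from a plain dict (the YAML mirror).

    Two forms are accepted.  The scenario form names a shipped scenario and
    passes keyword overrides::

        scenario: multivariate_effect
        grid_shape: [12, 12, 12]
        n_per_group: 20
        seed: 1

    The explicit form mirrors CohortSpec field by field; the mask and voxel
    sets are given either as coordinate lists or as geometric primitives
    ``{type: box}`` / ``{type: ellipsoid, margin: 0.6}``.
    """
    cfg = dict(cfg)
    if "scenario" in cfg:
        name = cfg.pop("scenario")
        if name not in SCENARIOS:
            raise ValueError(f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}")
        return SCENARIOS[name](**cfg)

    grid_cfg = cfg.pop("grid")
    grid = VolumeGrid(
        tuple(grid_cfg["shape"]),
        tuple(grid_cfg.get("voxel_size", (4.0, 4.0, 4.0))),
        tuple(grid_cfg.get("origin_offset", (0.0, 0.0, 0.0))),
    )

    def as_mask(m):
        if isinstance(m, dict):
            if m["type"] == "box":
                return np.ones(grid.shape, dtype=bool)
            if m["type"] == "ellipsoid":
                return ellipsoid_mask(grid.shape, m.get("margin", 0.6))
            raise ValueError(f"unknown mask type {m['type']!r}")
        out = np.zeros(grid.shape, dtype=bool)
        coords = np.asarray(m, dtype=int)
        out[coords[:, 0], coords[:, 1], coords[:, 2]] = True
        return out

    mask = as_mask(cfg.pop("mask"))
    latents = {k: tuple(v) for k, v in cfg.pop("latents").items()}
    communities = [
        Community(voxels=np.asarray(c["voxels"], dtype=int), latent=c["latent"],
                  weight=c.get("weight", 1.0))
        for c in cfg.pop("communities")
    ]
    effects = [
        GroupEffect(voxels=np.asarray(e["voxels"], dtype=int), g=e["g"],
                    latent=e.get("latent"))
        for e in cfg.pop("group_effects", [])
    ]
    return CohortSpec(grid=grid, mask=mask, communities=communities,
                      latents=latents, group_effects=effects, **cfg)


def ellipsoid_mask(shape, margin: float = 0.6) -> np.ndarray:
    """Ellipsoid inscribed in the grid (semi-axes shape/2 - margin)."""
    grids = np.indices(shape).astype(float)
    center = [(s - 1) / 2.0 for s in shape]
    semi = [max(s / 2.0 - margin, 1.0) for s in shape]
    d = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return d <= 1.0


def _make_mask(shape, mask_kind: str) -> np.ndarray:
    if mask_kind == "ellipsoid":
        return ellipsoid_mask(shape)
    if mask_kind == "box":
        return np.ones(shape, dtype=bool)
    raise ValueError(f"unknown mask kind {mask_kind!r}")


def _background_communities(mask: np.ndarray, exclude: np.ndarray | None,
                            n_communities: int, weight: float):
    """Split the (remaining) mask into z-slabs, one latent per slab."""
    coords = _raster_order(mask)
    if exclude is not None and len(exclude):
        flat = _flat_ids(coords, mask.shape)
        coords = coords[~np.isin(flat, _flat_ids(exclude, mask.shape))]
    chunks = np.array_split(coords, n_communities)
    comms, latents = [], {}
    for i, chunk in enumerate(chunks):
        if not len(chunk):
            continue
        name = f"bg{i}"
        comms.append(Community(voxels=chunk, latent=name, weight=weight))
        latents[name] = DEFAULT_BAND
    return comms, latents


def _central_block(mask: np.ndarray, block_shape) -> np.ndarray:
    """A contiguous in-mask box of the requested shape, centred in the grid."""
    shape = mask.shape
    start = [max((s - b) // 2, 0) for s, b in zip(shape, block_shape)]
    sl = tuple(slice(st, st + b) for st, b in zip(start, block_shape))
    block = np.zeros(shape, dtype=bool)
    block[sl] = True
    block &= mask
    if not block.any():
        raise ValueError("block does not intersect the mask")
    return _raster_order(block)


def null_scenario(grid_shape=(12, 12, 12), n_time: int = 256, tr: float = 2.0,
                  n_per_group: int = 20, seed: int = 0, rho: float = 0.3,
                  sigma: float = 1.0, n_communities: int = 3,
                  bg_weight: float = 0.6, mask_kind: str = "ellipsoid") -> CohortSpec:
    """Cohort with identical generative laws in both groups (no effect):
    group labels are exactly exchangeable."""
    grid = VolumeGrid(grid_shape)
    mask = _make_mask(grid_shape, mask_kind)
    comms, latents = _background_communities(mask, None, n_communities, bg_weight)
    return CohortSpec(grid=grid, mask=mask, communities=comms, latents=latents,
                      n_time=n_time, tr=tr, rho=rho, sigma=sigma,
                      n_per_group=n_per_group, seed=seed)


def multiplicative_effect_scenario(grid_shape=(12, 12, 12), n_time: int = 256,
                                   tr: float = 2.0, n_per_group: int = 20,
                                   seed: int = 0, g: float = 0.4,
                                   block_shape=(4, 4, 2), block_weight: float = 1.0,
                                   rho: float = 0.3, sigma: float = 1.0,
                                   n_communities: int = 3, bg_weight: float = 0.6,
                                   mask_kind: str = "ellipsoid") -> CohortSpec:
    """Planted effect: patients' coupling to a block-shared latent is scaled
    by g (< 1 weakens the block's internal connectivity)."""
    base = null_scenario(grid_shape, n_time, tr, n_per_group, seed, rho, sigma,
                         n_communities, bg_weight, mask_kind)
    block = _central_block(base.mask, block_shape)
    comms = list(base.communities)
    latents = dict(base.latents)
    comms.append(Community(voxels=block, latent="block", weight=block_weight))
    latents["block"] = DEFAULT_BAND
    effects = [GroupEffect(voxels=block, g=g, latent="block")]
    return CohortSpec(grid=base.grid, mask=base.mask, communities=comms,
                      latents=latents, n_time=n_time, tr=tr, rho=rho, sigma=sigma,
                      group_effects=effects, n_per_group=n_per_group, seed=seed)


def multivariate_effect_scenario(grid_shape=(12, 12, 12), n_time: int = 256,
                                 tr: float = 2.0, n_per_group: int = 20,
                                 seed: int = 0, shared_var: float = 0.5,
                                 half_var: float = 0.1,
                                 patient_shared_var: float = 0.2,
                                 block_shape=(4, 4, 2),
                                 rho: float = 0.3, sigma: float = 1.0,
                                 n_communities: int = 3, bg_weight: float = 0.6,
                                 mask_kind: str = "ellipsoid") -> CohortSpec:
    """The "multivariate-only" effect: coupling reallocated across latents at
    constant marginal variance and constant mean absolute correlation.

    A block of voxels couples to three kinds of latent: one latent shared by
    the whole block (variance share ``shared_var``), one latent per block
    *half* (share ``half_var``), and one private latent per voxel carrying
    the remaining variance.  In patients the block-wide share drops to
    ``patient_shared_var`` and the freed variance is moved onto the
    half-block and private latents, with the half-latent share solved so
    that every voxel's mean absolute within-block correlation is exactly
    unchanged:

        control pairs:  same half  s + h,          other half  s
        patient pairs:  same half  s' + h',        other half  s'

    with (k/2 - 1)(s + h) + (k/2) s  =  (k/2 - 1)(s' + h') + (k/2) s'.

    Marginal variances are 1 in both groups and correlations to voxels
    outside the block are 0 in both groups, so a bivariate-average measure
    (GBC) sees no systematic change anywhere — while the variance of a block
    voxel that is predictable from the *other* voxels shifts from
    s + h to s' + h', which a multivariate estimator sees at full strength.
    """
    base = null_scenario(grid_shape, n_time, tr, n_per_group, seed, rho, sigma,
                         n_communities, bg_weight, mask_kind)
    block = _central_block(base.mask, block_shape)
    k = len(block)
    if k < 4 or k % 2:
        raise ValueError("block must contain an even number >= 4 of mask voxels")
    s, h, s_pat = shared_var, half_var, patient_shared_var
    half = k // 2
    # mean-|cor| matching: (half-1)(s+h) + half*s = (half-1)(s_pat+h_pat) + half*s_pat
    h_pat = h + (s - s_pat) * (k - 1) / (half - 1)
    priv = 1.0 - s - h
    priv_pat = 1.0 - s_pat - h_pat
    if min(s, h, s_pat, h_pat, priv, priv_pat) < 0 or max(s + h, s_pat + h_pat) > 1:
        raise ValueError(
            f"variance shares infeasible: control (s={s}, h={h}, priv={priv}), "
            f"patient (s={s_pat}, h={h_pat:.3f}, priv={priv_pat:.3f})"
        )
    # background latents do not load on block voxels: the block's correlation
    # structure is entirely governed by the shared/half/private split
    comms, latents = _background_communities(base.mask, block, n_communities, bg_weight)
    comms.append(Community(voxels=block, latent="block_shared", weight=np.sqrt(s)))
    latents["block_shared"] = DEFAULT_BAND
    effects = [GroupEffect(voxels=block, g=np.sqrt(s_pat / s), latent="block_shared")]
    for name, sub in (("half_a", block[:half]), ("half_b", block[half:])):
        comms.append(Community(voxels=sub, latent=name, weight=np.sqrt(h)))
        latents[name] = DEFAULT_BAND
        effects.append(GroupEffect(voxels=sub, g=np.sqrt(h_pat / h), latent=name))
    for j, voxel in enumerate(block):
        name = f"priv{j}"
        comms.append(Community(voxels=voxel[None, :], latent=name, weight=np.sqrt(priv)))
        latents[name] = DEFAULT_BAND
        effects.append(GroupEffect(voxels=voxel[None, :],
                                   g=np.sqrt(priv_pat / priv), latent=name))
    return CohortSpec(grid=base.grid, mask=base.mask, communities=comms,
                      latents=latents, n_time=n_time, tr=tr, rho=rho, sigma=sigma,
                      group_effects=effects, n_per_group=n_per_group, seed=seed)


SCENARIOS.update({
    "null": null_scenario,
    "multiplicative_effect": multiplicative_effect_scenario,
    "multivariate_effect": multivariate_effect_scenario,
})
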