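"""Phantom cohorts with known ground truth.

The canonical phantom is a deterministic, mirror-symmetric "brain" built
from geometric parts — two cerebral ellipsoid hemispheres, two cerebellar
lobes and a midline vermis, each with a white-matter core and grey-matter
shell, wrapped in a CSF layer that defines the endocranial cavity.  A
25-region atlas (12 regions per hemisphere plus the cerebellar vermis,
grouped into 13 lobe groups) and named surface landmarks are carried along.

Every cohort member is the canonical phantom pushed through a known smooth
diffeomorphism: a group-effect velocity (windowed radial contraction of
designated regions, realizing volumetric scale factors, with an optional
extra factor on the right cerebellum) plus an individual Gaussian-smoothed
random velocity.  The two are summed into a single stationary velocity and
exponentiated once, so each specimen stores one invertible ``true_warp``
and remains topologically identical to the canonical phantom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .diffeo_registration import (
    FWHM_TO_SIGMA,
    Deformation,
    VelocityField,
    _identity_lattice,
    exp_velocity,
    transform_points,
    warp,
)
from .imaging_core import (
    LabelVolume,
    LandmarkSet,
    ScalarVolume,
    TissueVolumeSet,
    VoxelGrid,
)

__all__ = [
    "GroupEffect",
    "CohortSpec",
    "PhantomSpecimen",
    "LOBE_GROUPS",
    "make_canonical_phantom",
    "atlas_region_table",
    "sample_cohort",
    "make_damaged_endocast",
    "make_cognition_table",
    "T1_MEANS",
]

# T1-like class intensities (arbitrary but fixed)
T1_MEANS = {"csf": 0.2, "gm": 0.6, "wm": 1.0}

#: the 13 lobe groups used for regional volumetry (frontal superior/middle,
#: frontal inferior, orbitofrontal, sensorimotor, parietal superior/inferior,
#: temporo-parietal junction, temporal superior/middle, temporal inferior,
#: occipital superior/middle, occipital inferior, cerebellar vermis/anterior/
#: posterior)
LOBE_GROUPS = [
    "Fr SM", "Fr I", "Fr O", "Sm", "Pa SI", "Pa TP",
    "Te SM", "Te I", "Oc SM", "Oc I", "Ce V", "Ce A", "Ce P",
]
_CEREBELLAR_GROUPS = {"Ce V", "Ce A", "Ce P"}
_HEMI_GROUPS = [g for g in LOBE_GROUPS if g != "Ce V"]  # 12 per hemisphere


@dataclass
class GroupEffect:
    """Volumetric effect descriptor for one group.

    ``region_scales`` maps a lobe group name (or the shorthand
    ``"cerebellum"`` for all cerebellar groups) to a target *volumetric*
    scale factor; ``right_cerebellum_scale`` multiplies the right-hemisphere
    cerebellar factor on top (lateral asymmetry).
    """

    name: str
    region_scales: dict[str, float] = field(default_factory=dict)
    right_cerebellum_scale: float = 1.0

    def __post_init__(self):
        for k, f in self.region_scales.items():
            if f <= 0:
                raise ValueError(f"scale factor for {k!r} must be > 0")
        if self.right_cerebellum_scale <= 0:
            raise ValueError("asymmetry factor must be > 0")


@dataclass
class CohortSpec:
    n_per_group: int = 4
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    groups: list[GroupEffect] = field(default_factory=lambda: [GroupEffect("MH")])
    variation_sd: float = 0.5   # mm (RMS warp amplitude over the endocast)
    variation_fwhm: float = 8.0  # voxels, smoothing of the random velocity
    noise_sd: float = 0.03      # T1-like intensity noise
    symmetrize: bool = False    # mirror-symmetrize every specimen's warp
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.variation_sd < 0 or self.noise_sd < 0:
            raise ValueError("spread parameters must be >= 0")


@dataclass
class PhantomSpecimen:
    id: str
    group: str
    tissue: TissueVolumeSet
    t1_like: ScalarVolume
    true_warp: VelocityField
    atlas_truth: LabelVolume
    landmarks: LandmarkSet

    @property
    def grid(self) -> VoxelGrid:
        return self.tissue.grid

    def endocast_mask(self) -> ScalarVolume:
        t = self.tissue
        m = (t.gm.values + t.wm.values + t.csf.values) >= 0.5
        return ScalarVolume(t.grid, m.astype(float))

    def brain_mask(self) -> ScalarVolume:
        t = self.tissue
        m = (t.gm.values + t.wm.values) >= 0.5
        return ScalarVolume(t.grid, m.astype(float))

    def true_region_volumes(self, soft: bool = False) -> dict[int, float]:
        """Ground-truth mm^3 per atlas region.

        Default: voxel counts of ``atlas_truth``.  ``soft=True`` instead
        warps each canonical region indicator trilinearly through the true
        deformation and sums it — partial-volume aware, so sub-voxel group
        effects are measured without label-quantization noise.
        """
        vv = self.grid.voxel_volume
        if not soft:
            ids, counts = np.unique(self.atlas_truth.labels, return_counts=True)
            return {int(i): float(c) * vv for i, c in zip(ids, counts) if i > 0}
        canonical_labels = _canonical_labels_for(self.grid.shape)
        phi = exp_velocity(self.true_warp)
        out = {}
        for rid in np.unique(canonical_labels):
            if rid == 0:
                continue
            ind = ScalarVolume(self.grid, (canonical_labels == rid).astype(float))
            out[int(rid)] = float(warp(ind, phi).values.sum()) * vv
        return out


# ---------------------------------------------------------------------------
# canonical phantom geometry

def _normalized_coords(shape):
    idx = _identity_lattice(shape)
    c = (np.array(shape, dtype=float) - 1.0) / 2.0
    half = np.array(shape, dtype=float) / 2.0
    return (idx - c) / half, c


def _ellipsoid(u, center, semi):
    d = (u - np.asarray(center)) / np.asarray(semi)
    return (d * d).sum(-1) <= 1.0


# part geometry in normalized [-1, 1] coordinates; axis 0 = x (left-right),
# axis 1 = y (posterior-anterior), axis 2 = z (inferior-superior)
_CEREBRUM_SEMI = (0.30, 0.60, 0.42)
_CEREBRUM_CENTERS = ((-0.24, 0.05, 0.14), (0.24, 0.05, 0.14))
_CEREBELLUM_SEMI = (0.18, 0.18, 0.16)
_CEREBELLUM_CENTERS = ((-0.20, -0.50, -0.34), (0.20, -0.50, -0.34))
_VERMIS_CENTER = (0.0, -0.52, -0.36)
_VERMIS_SEMI = (0.10, 0.12, 0.11)
_WM_SHRINK = 0.62


def _cerebral_group(uy, uz):
    """Assign a cerebral lobe group from coordinates relative to the
    hemisphere center (normalized units)."""
    if uy > 0.15:
        if uz < -0.12:
            return "Fr O"
        return "Fr I" if uz < 0.12 else "Fr SM"
    if uy > 0.02:
        return "Sm"
    if uy > -0.33:
        if uz >= -0.02:
            return "Pa SI" if uy > -0.16 else "Pa TP"
        return "Te SM" if uy > -0.16 else "Te I"
    return "Oc SM" if uz >= -0.02 else "Oc I"


def atlas_region_table() -> pd.DataFrame:
    """Region table: id, name, hemisphere (L/R/midline), lobe_group,
    cerebellum flag.  Ids 1-12 left, 13-24 right, 25 vermis."""
    rows = []
    rid = 1
    for hemi in ("L", "R"):
        for g in _HEMI_GROUPS:
            rows.append(
                dict(region_id=rid, name=f"{g} {hemi}", hemisphere=hemi,
                     lobe_group=g, cerebellum=g in _CEREBELLAR_GROUPS)
            )
            rid += 1
    rows.append(dict(region_id=25, name="Ce V", hemisphere="midline",
                     lobe_group="Ce V", cerebellum=True))
    return pd.DataFrame(rows)


def make_canonical_phantom(grid_shape=(48, 48, 48)) -> PhantomSpecimen:
    """Deterministic symmetric brain-inside-endocast phantom."""
    shape = tuple(int(s) for s in grid_shape)
    if min(shape) < 32:
        raise ValueError("grid too small to hold all phantom parts (need >= 32)")
    grid = VoxelGrid(shape)
    u, _c = _normalized_coords(shape)

    cer_l = _ellipsoid(u, _CEREBRUM_CENTERS[0], _CEREBRUM_SEMI)
    cer_r = _ellipsoid(u, _CEREBRUM_CENTERS[1], _CEREBRUM_SEMI)
    cb_l = _ellipsoid(u, _CEREBELLUM_CENTERS[0], _CEREBELLUM_SEMI)
    cb_r = _ellipsoid(u, _CEREBELLUM_CENTERS[1], _CEREBELLUM_SEMI)
    vermis = _ellipsoid(u, _VERMIS_CENTER, _VERMIS_SEMI)
    vermis = vermis & ~(cb_l | cb_r)

    parts = [cer_l, cer_r, cb_l, cb_r]
    wm = np.zeros(shape, dtype=bool)
    centers = list(_CEREBRUM_CENTERS) + list(_CEREBELLUM_CENTERS)
    semis = [_CEREBRUM_SEMI, _CEREBRUM_SEMI, _CEREBELLUM_SEMI, _CEREBELLUM_SEMI]
    for center, semi in zip(centers, semis):
        wm |= _ellipsoid(u, center, tuple(s * _WM_SHRINK for s in semi))
    brain = cer_l | cer_r | cb_l | cb_r | vermis
    wm &= brain
    gm = brain & ~wm

    cavity = ndimage.binary_dilation(brain, iterations=2)
    csf = cavity & ~brain

    tissue = TissueVolumeSet(
        ScalarVolume(grid, gm.astype(float)),
        ScalarVolume(grid, wm.astype(float)),
        ScalarVolume(grid, csf.astype(float)),
    )
    t1 = _render_t1(tissue, noise_sd=0.0, rng=None)

    # atlas labels
    table = atlas_region_table()
    key = {(r.hemisphere, r.lobe_group): r.region_id for r in table.itertuples()}
    labels = np.zeros(shape, dtype=np.int32)
    cx = (shape[0] - 1) / 2.0
    idx = _identity_lattice(shape)
    for hemi, cer, cb, cer_c, cb_c in (
        ("L", cer_l, cer_r, _CEREBRUM_CENTERS[0], _CEREBELLUM_CENTERS[0]),
        ("R", cer_r, cer_l, _CEREBRUM_CENTERS[1], _CEREBELLUM_CENTERS[1]),
    ):
        hemi_mask = (u[..., 0] < 0) if hemi == "L" else (u[..., 0] >= 0)
        cer_only = cer & hemi_mask & ~(cb_l | cb_r) & ~vermis
        ii = np.argwhere(cer_only)
        for i, j, k in ii:
            uy = u[i, j, k, 1] - cer_c[1]
            uz = u[i, j, k, 2] - cer_c[2]
            labels[i, j, k] = key[(hemi, _cerebral_group(uy, uz))]
        cb_mask = (cb_l if hemi == "L" else cb_r) & hemi_mask & ~vermis
        ant = u[..., 1] > cb_c[1]
        labels[cb_mask & ant] = key[(hemi, "Ce A")]
        labels[cb_mask & ~ant] = key[(hemi, "Ce P")]
    labels[vermis] = 25
    # any unlabeled brain voxel (hemisphere overlap) -> nearest labeled region
    unl = brain & (labels == 0)
    if unl.any():
        _d, (ci, cj, ck) = ndimage.distance_transform_edt(
            labels == 0, return_indices=True
        )
        labels[unl] = labels[ci[unl], cj[unl], ck[unl]]
    atlas = LabelVolume(grid, labels)

    lmk = _surface_landmarks(ScalarVolume(grid, cavity.astype(float)))
    zero_v = VelocityField(grid, np.zeros(shape + (3,)))
    return PhantomSpecimen("canonical", "canonical", tissue, t1, zero_v, atlas, lmk)


from functools import lru_cache


@lru_cache(maxsize=4)
def _canonical_labels_for(shape: tuple[int, int, int]) -> np.ndarray:
    """Cached canonical atlas labels (needed for soft volume measurement)."""
    return make_canonical_phantom(shape).atlas_truth.labels


_LANDMARK_DIRS = {
    "anterior_pole": (0, 1, 0), "posterior_pole": (0, -1, 0),
    "left_pole": (-1, 0, 0), "right_pole": (1, 0, 0),
    "vertex": (0, 0, 1), "basion_like": (0, 0, -1),
    "left_frontal": (-1, 1, 1), "right_frontal": (1, 1, 1),
    "left_parietal": (-1, -1, 1), "right_parietal": (1, -1, 1),
    "left_temporal": (-1, 1, -1), "right_temporal": (1, 1, -1),
    "left_occipital": (-1, -1, -1), "right_occipital": (1, -1, -1),
}


def _surface_landmarks(mask: ScalarVolume) -> LandmarkSet:
    """Named landmarks where rays from the mask centroid exit the surface."""
    sm = ndimage.gaussian_filter(mask.values.astype(float), 1.0)
    idx = _identity_lattice(mask.grid.shape).reshape(-1, 3)
    w = mask.values.reshape(-1)
    c = (idx * w[:, None]).sum(0) / w.sum()
    names, pts = [], []
    tmax = max(mask.grid.shape)
    ts = np.linspace(0.0, tmax, 4 * tmax)
    for name, d in _LANDMARK_DIRS.items():
        d = np.asarray(d, dtype=float)
        d /= np.linalg.norm(d)
        ray = c[None, :] + ts[:, None] * d[None, :]
        inside = np.all((ray >= 0) & (ray <= np.array(mask.grid.shape) - 1), axis=1)
        ray = ray[inside]
        vals = ndimage.map_coordinates(sm, ray.T, order=1, mode="constant", cval=0.0)
        above = np.nonzero(vals >= 0.5)[0]
        k = above[-1] if len(above) else 0
        names.append(name)
        pts.append(mask.grid.voxel_to_world(ray[k])[0])
    return LandmarkSet(names, np.array(pts))


def _render_t1(tissue: TissueVolumeSet, noise_sd: float, rng) -> ScalarVolume:
    vals = (
        T1_MEANS["gm"] * tissue.gm.values
        + T1_MEANS["wm"] * tissue.wm.values
        + T1_MEANS["csf"] * tissue.csf.values
    )
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
    return ScalarVolume(tissue.grid, vals)


# ---------------------------------------------------------------------------
# cohort sampling

def mirror_velocity(v: np.ndarray) -> np.ndarray:
    """Mirror a velocity lattice about the x (left-right) grid centre plane:
    flip axis 0 and negate the x component."""
    out = v[::-1, :, :, :].copy()
    out[..., 0] = -out[..., 0]
    return out


def _boundary_taper(shape, width: int = 6) -> np.ndarray:
    w = np.ones(shape)
    for ax, s in enumerate(shape):
        ramp = np.clip(np.minimum(np.arange(s), np.arange(s)[::-1]) / width, 0, 1)
        sh = [1, 1, 1]
        sh[ax] = -1
        w = w * ramp.reshape(sh)
    return w


def _group_velocity(canonical: PhantomSpecimen, effect: GroupEffect) -> np.ndarray:
    """Windowed radial contraction realizing volumetric scale factors.

    A region with volumetric factor ``f`` gets the velocity
    ``v(x) = -(ln f / 3) * (x - c) * w(x)`` (pull-back convention: sampling
    upstream of a contraction *enlarges*, so the sign makes exp shrink the
    region for f < 1); ``w`` is 1 inside the region and decays smoothly.
    """
    shape = canonical.grid.shape
    table = atlas_region_table()
    v = np.zeros(shape + (3,))
    idx = _identity_lattice(shape)
    scales: dict[int, float] = {}
    for key, f in effect.region_scales.items():
        if key == "cerebellum":
            rows = table[table.cerebellum]
        else:
            rows = table[table.lobe_group == key]
            if rows.empty:
                raise ValueError(f"unknown region key {key!r}")
        for r in rows.itertuples():
            scales[r.region_id] = scales.get(r.region_id, 1.0) * f
    if effect.right_cerebellum_scale != 1.0:
        rows = table[table.cerebellum & (table.hemisphere == "R")]
        for r in rows.itertuples():
            scales[r.region_id] = scales.get(r.region_id, 1.0) * effect.right_cerebellum_scale
    labels = canonical.atlas_truth.labels
    sigma_win = 2.0  # voxels, window decay outside the region
    # merge regions sharing a factor so adjacent windows do not double-count
    by_factor: dict[float, np.ndarray] = {}
    for rid, f in scales.items():
        if f == 1.0:
            continue
        region = labels == rid
        if region.any():
            by_factor[f] = by_factor.get(f, np.zeros_like(region)) | region
    for f, region in by_factor.items():
        a = -np.log(f) / 3.0
        comp_labels, ncomp = ndimage.label(
            ndimage.binary_dilation(region, iterations=1)
        )
        for comp in range(1, ncomp + 1):
            part = region & (comp_labels == comp)
            if not part.any():
                continue
            c = np.argwhere(part).mean(axis=0)
            dist = ndimage.distance_transform_edt(~part)
            win = np.exp(-0.5 * (dist / sigma_win) ** 2)
            v += a * win[..., None] * (idx - c)
    return v


def _individual_velocity(canonical, variation_sd, fwhm, rng) -> np.ndarray:
    shape = canonical.grid.shape
    v = ndimage.gaussian_filter(
        rng.normal(size=shape + (3,)), (FWHM_TO_SIGMA * fwhm,) * 3 + (0.0,)
    )
    v *= _boundary_taper(shape)[..., None]
    mask = canonical.endocast_mask().values > 0.5
    rms = np.sqrt(np.mean(np.sum(v[mask] ** 2, axis=-1)))
    if rms > 0 and variation_sd > 0:
        # variation_sd is an RMS displacement in mm over the endocast
        v *= variation_sd / (rms * canonical.grid.voxel_volume ** (1.0 / 3.0))
    else:
        v[:] = 0.0
    return v


def _warp_specimen(canonical: PhantomSpecimen, v: np.ndarray, sid: str,
                   group: str, noise_sd: float, rng) -> PhantomSpecimen:
    grid = canonical.grid
    vf = VelocityField(grid, v)
    phi = exp_velocity(vf)
    gm = warp(canonical.tissue.gm, phi)
    wm = warp(canonical.tissue.wm, phi)
    csf = warp(canonical.tissue.csf, phi)
    clip = lambda s: ScalarVolume(grid, np.clip(s.values, 0.0, 1.0))
    gm, wm, csf = clip(gm), clip(wm), clip(csf)
    total = gm.values + wm.values + csf.values
    over = total > 1.0
    if over.any():
        scale = np.where(over, 1.0 / np.maximum(total, 1e-12), 1.0)
        gm = ScalarVolume(grid, gm.values * scale)
        wm = ScalarVolume(grid, wm.values * scale)
        csf = ScalarVolume(grid, csf.values * scale)
    tissue = TissueVolumeSet(gm, wm, csf)
    atlas = warp(canonical.atlas_truth, phi, mode="nearest")
    t1 = _render_t1(tissue, noise_sd, rng)
    # landmarks follow material points: specimen-frame position of canonical
    # landmark p is exp(-v)(p)
    inv = exp_velocity(VelocityField(grid, -v))
    lmk_vox = grid.world_to_voxel(canonical.landmarks.points)
    new_vox = transform_points(inv, lmk_vox)
    lmk = LandmarkSet(list(canonical.landmarks.names), grid.voxel_to_world(new_vox))
    return PhantomSpecimen(sid, group, tissue, t1, vf, atlas, lmk)


def sample_cohort(spec: CohortSpec, canonical: PhantomSpecimen | None = None
                  ) -> list[PhantomSpecimen]:
    """Draw a phantom cohort; bit-reproducible for a fixed spec/seed."""
    canonical = canonical or make_canonical_phantom(spec.grid_shape)
    group_v = {g.name: _group_velocity(canonical, g) for g in spec.groups}
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(len(spec.groups) * spec.n_per_group)
    out = []
    k = 0
    for g in spec.groups:
        for i in range(spec.n_per_group):
            rng = np.random.default_rng(children[k])
            k += 1
            vi = _individual_velocity(
                canonical, spec.variation_sd, spec.variation_fwhm, rng
            )
            v = group_v[g.name] + vi
            if spec.symmetrize:
                v = 0.5 * (v + mirror_velocity(v))
            out.append(
                _warp_specimen(canonical, v, f"{g.name}_{i:03d}", g.name,
                               spec.noise_sd, rng)
            )
    return out


# ---------------------------------------------------------------------------
# damage model

def make_damaged_endocast(endocast: ScalarVolume,
                          holes: list[tuple[tuple[float, float, float], float]]
                          ) -> tuple[ScalarVolume, ScalarVolume]:
    """Punch spherical holes (center voxel coords, radius voxels) into a
    binary endocast mask.  Returns (damaged mask, hole mask).  Holes covering
    more than 30% of the endocast are rejected.
    """
    mask = endocast.values > 0.5
    idx = _identity_lattice(endocast.grid.shape)
    hole = np.zeros(endocast.grid.shape, dtype=bool)
    for center, radius in holes:
        d = np.linalg.norm(idx - np.asarray(center, dtype=float), axis=-1)
        hole |= d <= radius
    hole &= mask
    if mask.sum() and hole.sum() > 0.3 * mask.sum():
        raise ValueError("holes cover more than 30% of the endocast")
    damaged = mask & ~hole
    return (
        ScalarVolume(endocast.grid, damaged.astype(float)),
        ScalarVolume(endocast.grid, hole.astype(float)),
    )


# ---------------------------------------------------------------------------
# cognition tables

_TASKS = [
    "attention_inhibition", "cognitive_flexibility", "speech_comprehension",
    "speech_production", "working_memory", "episodic_memory", "processing_speed",
]


def make_cognition_table(n: int, beta_per_task=None, confound_sds=(0.05, 0.3, 2.0),
                         noise_sd: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """Cognition scores linearly coupled to a size-adjusted regional volume.

    The regional (cerebellar-style) volume is linear in ICV/age/sex plus an
    independent subject effect ``u`` (the size-adjusted component); each of
    the 7 task scores is ``beta * u`` plus its own confound loadings
    (``confound_sds`` = per-unit ICV/age/sex contributions to scores) and
    Gaussian noise.  Columns: subject, 7 task scores, icv_cc, age, sex,
    regional_volume_cc, adjusted_volume_cc (the generative ``u``).
    """
    if n < 20:
        raise ValueError("n must be >= 20")
    betas = np.zeros(len(_TASKS)) if beta_per_task is None else np.asarray(
        beta_per_task, dtype=float
    )
    if betas.shape != (len(_TASKS),):
        raise ValueError(f"beta_per_task must have {len(_TASKS)} entries")
    rng = np.random.default_rng(seed)
    icv = rng.normal(1450.0, 120.0, n)          # cc
    age = rng.uniform(22.0, 36.0, n)
    sex = rng.integers(0, 2, n).astype(float)
    u = rng.normal(0.0, 8.0, n)                 # size-adjusted volume, cc
    volume = 40.0 + 0.05 * icv - 0.3 * (age - 29.0) + 6.0 * sex + u
    c_icv, c_age, c_sex = confound_sds
    data = {"subject": [f"s{i:04d}" for i in range(n)]}
    for t, beta in zip(_TASKS, betas):
        score = (
            beta * u + c_icv * (icv - icv.mean()) + c_age * (age - age.mean())
            + c_sex * sex + rng.normal(0.0, noise_sd, n)
        )
        data[t] = score
    data.update(icv_cc=icv, age=age, sex=sex, regional_volume_cc=volume,
                adjusted_volume_cc=u)
    df = pd.DataFrame(data)
    df.attrs["generative_betas"] = {t: float(b) for t, b in zip(_TASKS, betas)}
    df.attrs["tasks"] = list(_TASKS)
    return df
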