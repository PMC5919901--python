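"""Deform the population-average brain into fossil endocasts and measure
parcel volumes.

The inference runs entirely on endocast shape: the fossil endocast is
affinely pre-aligned to the template frame (moments: centroid, principal
axes, isotropic scale), a stationary velocity is estimated registering the
aligned fossil endocast to the average endocast, and the average brain and
atlas labels are pulled back into the (aligned) fossil frame through the
inverse map ``exp(-v)``.  Volumes measured on the aligned grid are restored
to the fossil's native scale with the affine determinant.

Using the *average* brain rather than any individual brain keeps the
estimate free of subject-specific sulcal/gyral idiosyncrasies; the
individual-brain mode lives in the evaluation module as a control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffeo_registration import (
    Deformation,
    RegistrationConfig,
    VelocityField,
    apply_affine_to_volume,
    compose,
    exp_velocity,
    register,
    affine_prealign,
    smooth_mask,
    warp,
)
from .imaging_core import LabelVolume, ScalarVolume, VoxelGrid

__all__ = [
    "AtlasParcellation",
    "ReconstructedBrain",
    "reconstruct_brain",
    "transfer_atlas",
    "parcel_volumes",
    "expand_fossil_variation",
]

_REQUIRED_COLS = {"region_id", "name", "hemisphere", "lobe_group", "cerebellum"}


@dataclass
class AtlasParcellation:
    """Label volume in template frame plus its region table.

    The table columns are ``region_id, name, hemisphere (L/R/midline),
    lobe_group`` (one of 13 groups partitioning all regions) and a boolean
    ``cerebellum`` flag.
    """

    labels: LabelVolume
    table: pd.DataFrame

    def __post_init__(self):
        missing = _REQUIRED_COLS - set(self.table.columns)
        if missing:
            raise ValueError(f"atlas table missing columns: {sorted(missing)}")
        known = set(self.table.region_id.astype(int))
        present = set(int(i) for i in self.labels.ids())
        orphan = present - known
        if orphan:
            raise ValueError(f"label ids without table rows: {sorted(orphan)}")

    def cerebellar_ids(self) -> list[int]:
        return [int(i) for i in self.table[self.table.cerebellum].region_id]


@dataclass
class ReconstructedBrain:
    specimen_id: str
    group: str
    brain_mask: ScalarVolume              # binary, fossil (aligned) frame
    parcels: LabelVolume | None
    parcel_volumes: dict[int, float] | None   # region id -> mm^3, native scale
    icv: float                            # mm^3, native fossil scale
    deformation_used: Deformation
    velocity: VelocityField | None = None
    prealign: np.ndarray | None = None    # 4x4 fossil->template pull-back
    volume_scale: float = 1.0             # native mm^3 per aligned-frame mm^3


def reconstruct_brain(avg_brain: ScalarVolume, avg_endocast: ScalarVolume,
                      fossil_endocast: ScalarVolume,
                      cfg: RegistrationConfig | None = None,
                      specimen_id: str = "fossil", group: str = "",
                      prealign: bool = True) -> ReconstructedBrain:
    """Estimate the brain enclosed in a fossil endocast.

    ``avg_brain``/``avg_endocast`` are soft (smoothed) template images;
    ``fossil_endocast`` is a binary or soft endocast image on the same grid
    geometry.  Registration failures propagate with the specimen id.
    """
    cfg = cfg or RegistrationConfig()
    grid = avg_endocast.grid
    if prealign:
        M = affine_prealign(avg_endocast, fossil_endocast)
        aligned = apply_affine_to_volume(fossil_endocast, M)
        volume_scale = float(abs(np.linalg.det(M[:3, :3])))
    else:
        M = np.eye(4)
        aligned = fossil_endocast
        volume_scale = 1.0
    # match the template's smoothness: binarize the resampled mask, re-smooth
    aligned_bin = ScalarVolume(grid, (aligned.values >= 0.5).astype(float))
    aligned_sm = smooth_mask(aligned_bin, 2.0)
    try:
        v, _diag = register(avg_endocast, aligned_sm, cfg)
    except Exception as e:
        raise RuntimeError(f"registration failed for specimen {specimen_id!r}: {e}") from e
    # phi = exp(v) maps template voxels -> fossil coords; the inverse map
    # exp(-v) pulls template-frame data into the fossil frame
    inv = exp_velocity(VelocityField(grid, -v.v), cfg.squaring_steps)
    brain = warp(avg_brain, inv)
    brain_bin = ScalarVolume(grid, (brain.values >= 0.5).astype(float))
    ec_bin = aligned_bin.values >= 0.5
    icv = float(ec_bin.sum()) * grid.voxel_volume * volume_scale
    return ReconstructedBrain(
        specimen_id=specimen_id,
        group=group,
        brain_mask=brain_bin,
        parcels=None,
        parcel_volumes=None,
        icv=icv,
        deformation_used=inv,
        velocity=v,
        prealign=M,
        volume_scale=volume_scale,
    )


def transfer_atlas(atlas: AtlasParcellation, deformation: Deformation) -> LabelVolume:
    """Pull atlas labels through a deformation (nearest-label pull-back)."""
    if atlas.labels.grid != deformation.grid:
        raise ValueError("atlas and deformation are in different frames")
    return warp(atlas.labels, deformation, mode="nearest")


def parcel_volumes(parcels: LabelVolume, table: pd.DataFrame,
                   grid: VoxelGrid | None = None, volume_scale: float = 1.0):
    """Aggregate voxel counts into region, 13-group, hemisphere and
    cerebrum/cerebellum volumes (mm^3).

    Returns a dict with keys ``region`` (id -> mm^3), ``lobe_group``,
    ``hemisphere``, ``cerebrum`` and ``cerebellum``.
    """
    grid = grid or parcels.grid
    vv = grid.voxel_volume * volume_scale
    ids, counts = np.unique(parcels.labels, return_counts=True)
    region = {int(i): float(c) * vv for i, c in zip(ids, counts) if i > 0}
    known = set(table.region_id.astype(int))
    orphan = set(region) - known
    if orphan:
        raise ValueError(f"orphan label ids: {sorted(orphan)}")
    info = table.set_index(table.region_id.astype(int))
    lobe: dict[str, float] = {}
    hemi: dict[str, float] = {}
    cerebellum = 0.0
    for rid, vol in region.items():
        row = info.loc[rid]
        lobe[row.lobe_group] = lobe.get(row.lobe_group, 0.0) + vol
        hemi[row.hemisphere] = hemi.get(row.hemisphere, 0.0) + vol
        if bool(row.cerebellum):
            cerebellum += vol
    total = float(sum(region.values()))
    return {
        "region": region,
        "lobe_group": lobe,
        "hemisphere": hemi,
        "cerebrum": total - cerebellum,
        "cerebellum": cerebellum,
    }


def measure_reconstruction(rec: ReconstructedBrain, atlas: AtlasParcellation
                           ) -> ReconstructedBrain:
    """Attach transferred parcels and their volumes to a reconstruction.

    Parcels are masked to the reconstructed brain (dilated by one voxel) so
    labels do not leak far outside the estimated brain.
    """
    from scipy import ndimage

    parcels = transfer_atlas(atlas, rec.deformation_used)
    allowed = ndimage.binary_dilation(rec.brain_mask.values > 0.5)
    labels = np.where(allowed, parcels.labels, 0)
    rec.parcels = LabelVolume(parcels.grid, labels)
    rec.parcel_volumes = parcel_volumes(
        rec.parcels, atlas.table, volume_scale=rec.volume_scale
    )["region"]
    return rec


def expand_fossil_variation(individual_warps: list[VelocityField],
                            fossil_reconstructions: list[ReconstructedBrain],
                            atlas: AtlasParcellation,
                            n_steps: int = 6) -> pd.DataFrame:
    """Pseudo-specimens: every individual's template-space warp composed with
    every fossil deformation; one row of parcel volumes per combination.

    This is how within-fossil-group variation is emulated when only a few
    fossils exist: the modern cohort's shape variation (template-space
    warps) is grafted onto each fossil's deformation.
    """
    rows = []
    for rec in fossil_reconstructions:
        for j, vind in enumerate(individual_warps):
            if vind.grid != rec.deformation_used.grid:
                raise ValueError("frame mismatch between warps and fossils")
            # individual map in template space, then into the fossil frame
            phi_ind = exp_velocity(VelocityField(vind.grid, -vind.v), n_steps)
            phi = compose(phi_ind, rec.deformation_used)
            labels = warp(atlas.labels, phi, mode="nearest")
            vols = parcel_volumes(labels, atlas.table,
                                  volume_scale=rec.volume_scale)
            row = {"specimen": f"{rec.specimen_id}_x_ind{j:04d}",
                   "fossil": rec.specimen_id, "individual": j,
                   "group": rec.group, "cerebrum_mm3": vols["cerebrum"],
                   "cerebellum_mm3": vols["cerebellum"]}
            for rid, vol in vols["region"].items():
                row[f"region_{rid}"] = vol
            rows.append(row)
    return pd.DataFrame(rows)


def make_template_images(cohort, cfg: RegistrationConfig | None = None,
                         n_outer: int = 2, fwhm: float = 2.0):
    """Build average endocast and brain images from a phantom cohort.

    Endocast masks (Gaussian-smoothed, FWHM in voxels) drive the
    registrations; the same deformations average the brain masks, realizing
    the endocast-led template pipeline.  Returns
    ``(avg_endocast, avg_brain, velocities)``.
    """
    from .diffeo_registration import build_template

    cfg = cfg or RegistrationConfig()
    endos = [smooth_mask(s.endocast_mask(), fwhm) for s in cohort]
    brains = [smooth_mask(s.brain_mask(), fwhm) for s in cohort]
    template, velocities, mean_brain, _res = build_template(
        endos, cfg, n_outer=n_outer, paired=brains
    )
    return template, mean_brain, velocities
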