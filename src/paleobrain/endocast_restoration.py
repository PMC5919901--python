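"""Thin-plate-spline landmark warping and endocast gap filling.

The 3-D interpolating TPS uses the biharmonic kernel ``U(r) = r`` (the
mathematically correct choice in three dimensions; the familiar
``r^2 log r`` kernel is the 2-D case).  A fitted warp maps every source
landmark exactly onto its target, reproduces affine maps with zero bending
energy, and extends smoothly everywhere else.

Restoration of a damaged endocast: fit a TPS from landmarks on the damaged
specimen to the corresponding landmarks on an intact reference (pull-back
direction), resample the reference endocast inside the hole mask only, and
close residual cavities of a couple of voxels with morphological closing
(the "gap filler").  An optional second pass adds closest-point
pseudo-landmark pairs on the intact surface near the holes and refits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging_core import LandmarkSet, ScalarVolume, TriangleMesh

__all__ = ["TPSWarp", "fit_tps", "apply_tps", "restore_endocast"]


@dataclass
class TPSWarp:
    source_landmarks: LandmarkSet
    target_landmarks: LandmarkSet
    affine_part: np.ndarray      # 4x3: row 0 constant, rows 1-3 linear
    weights: np.ndarray          # L x 3 kernel coefficients
    bending_energy: float


def _kernel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """U(r) = r between two point sets (3-D biharmonic kernel)."""
    return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)


def fit_tps(source: LandmarkSet, target: LandmarkSet) -> TPSWarp:
    """Fit an interpolating 3-D TPS mapping source landmarks onto targets.

    Landmarks are paired by name; requires >= 4 non-coplanar points.
    """
    if set(source.names) != set(target.names):
        raise ValueError("source/target landmark names do not match")
    target = target.subset(source.names)
    P = source.points
    Q = target.points
    L = len(P)
    if L < 4:
        raise ValueError("need at least 4 landmarks for a 3-D TPS")
    # coplanarity / duplicate check via rank of centered configuration
    centered = P - P.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8 * max(1.0, np.abs(P).max())) < 3:
        raise ValueError("landmarks are coplanar or degenerate; TPS system singular")

    K = _kernel(P, P)
    Pm = np.hstack([np.ones((L, 1)), P])
    A = np.zeros((L + 4, L + 4))
    A[:L, :L] = K
    A[:L, L:] = Pm
    A[L:, :L] = Pm.T
    rhs = np.zeros((L + 4, 3))
    rhs[:L] = Q
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"singular TPS system: {e}") from None
    W = sol[:L]
    affine = sol[L:]
    # bending energy: sum over output dims of w_d^T K w_d
    be = float(np.einsum("ld,lm,md->", W, K, W))
    return TPSWarp(source, target, affine, W, max(be, 0.0))


def apply_tps(warp: TPSWarp, obj):
    """Apply a fitted warp to an N x 3 point array or a TriangleMesh."""
    if isinstance(obj, TriangleMesh):
        return TriangleMesh(apply_tps(warp, obj.vertices), obj.faces.copy())
    pts = np.atleast_2d(np.asarray(obj, dtype=float))
    U = _kernel(pts, warp.source_landmarks.points)
    Pm = np.hstack([np.ones((len(pts), 1)), pts])
    return U @ warp.weights + Pm @ warp.affine_part


def _surface_points(mask: np.ndarray, max_points: int = 200) -> np.ndarray:
    surf = mask & ~ndimage.binary_erosion(mask)
    pts = np.argwhere(surf).astype(float)
    if len(pts) > max_points:
        step = len(pts) // max_points
        pts = pts[::step][:max_points]
    return pts


def restore_endocast(damaged_mask: ScalarVolume, hole_mask: ScalarVolume,
                     reference_endocast: ScalarVolume,
                     landmarks_on_damaged: LandmarkSet,
                     landmarks_on_reference: LandmarkSet,
                     n_iter: int = 2) -> ScalarVolume:
    """Fill holes in a damaged endocast mask from a warped intact reference.

    Only voxels inside ``hole_mask`` are replaced; the damaged mask is
    untouched elsewhere, so the call is idempotent for an empty hole mask.
    Landmark coordinates are world mm on both specimens; at least 4 usable
    pairs are required.
    """
    grid = damaged_mask.grid
    hole = hole_mask.values > 0.5
    damaged = damaged_mask.values > 0.5
    if not hole.any():
        return ScalarVolume(grid, damaged.astype(float))
    common = [n for n in landmarks_on_damaged.names if n in set(landmarks_on_reference.names)]
    if len(common) < 4:
        raise ValueError(f"need >= 4 usable landmark pairs, got {len(common)}")
    base_src = landmarks_on_damaged.subset(common)
    base_tgt = landmarks_on_reference.subset(common)
    src, tgt = base_src, base_tgt

    ref_sm = ndimage.gaussian_filter(reference_endocast.values.astype(float), 0.8)
    filled = damaged.copy()
    for _ in range(max(1, n_iter)):
        tps = fit_tps(src, tgt)  # damaged frame -> reference frame
        hole_pts_world = grid.voxel_to_world(np.argwhere(hole).astype(float))
        mapped = reference_endocast.grid.world_to_voxel(apply_tps(tps, hole_pts_world))
        vals = ndimage.map_coordinates(ref_sm, mapped.T, order=1, mode="nearest",
                                       prefilter=False)
        filled = damaged.copy()
        filled[tuple(np.argwhere(hole).T)] = vals >= 0.5
        # second pass: densify correspondences with closest surface points
        # near the hole, then refit
        if n_iter > 1:
            ref_mask = reference_endocast.values > 0.5
            surf_d = _surface_points(filled)
            hole_centers = np.argwhere(hole).astype(float)
            if len(hole_centers):
                d2 = ((surf_d[:, None, :] - hole_centers[None, :, :]) ** 2).sum(-1).min(1)
                near = surf_d[d2 < 36.0][:60]  # within 6 voxels of a hole
            else:
                near = surf_d[:0]
            if len(near) >= 4:
                near_world = grid.voxel_to_world(near)
                mapped_world = apply_tps(tps, near_world)
                ref_surf = _surface_points(ref_mask, max_points=2000)
                ref_surf_world = reference_endocast.grid.voxel_to_world(ref_surf)
                dd = np.linalg.norm(
                    mapped_world[:, None, :] - ref_surf_world[None, :, :], axis=-1
                )
                closest = ref_surf_world[np.argmin(dd, axis=1)]
                names = list(base_src.names) + [f"_aux{i}" for i in range(len(near))]
                src = LandmarkSet(names, np.vstack([base_src.points, near_world]))
                tgt = LandmarkSet(names, np.vstack([base_tgt.points, closest]))
    # gap filler: close residual cavities of <= 2 voxels, inside holes only
    closed = ndimage.binary_closing(filled, structure=np.ones((3, 3, 3)), iterations=1)
    filled[hole] = closed[hole]
    return ScalarVolume(grid, filled.astype(float))
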