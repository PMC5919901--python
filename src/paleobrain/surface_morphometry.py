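"""Homologous-mesh surface morphometry with vertex-wise Hotelling's T².

All specimen surfaces share one template mesh propagated through each
specimen's inverse deformation, so vertex k corresponds anatomically across
the whole sample.  After generalized Procrustes superimposition (translation,
unit-centroid-size scaling, rotation without reflection), per-vertex 3-D
displacement vectors from the consensus mean are compared between groups
with the two-sample Hotelling T² statistic,

    T² = (n_a n_b / n) d̄ᵀ S⁻¹ d̄,   F = T² (n − p − 1) / (p (n − 2)),

with p = 3 and S the pooled covariance.  Family-wise error over vertices is
controlled by the permutation distribution of the maximum T² (group labels
are exchangeable under the null); random-field-theory inference is a
non-goal here.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

from .diffeo_registration import Deformation, transform_points
from .imaging_core import TriangleMesh

__all__ = [
    "HomologousMeshSet",
    "SurfaceStatMap",
    "propagate_mesh",
    "procrustes_align",
    "displacement_fields",
    "signed_normal_displacement",
    "hotelling_t2_map",
    "pillai_manova_map",
    "fwe_correct",
]


@dataclass
class HomologousMeshSet:
    template_mesh: TriangleMesh
    per_specimen_vertices: np.ndarray    # S x V x 3
    specimen_ids: list[str]
    groups: list[str]

    def __post_init__(self):
        self.per_specimen_vertices = np.asarray(self.per_specimen_vertices, dtype=float)
        S, V, three = self.per_specimen_vertices.shape
        if three != 3 or V != len(self.template_mesh.vertices):
            raise ValueError("vertex array must be S x V x 3 matching the template")
        if len(self.specimen_ids) != S or len(self.groups) != S:
            raise ValueError("ids/groups length mismatch")

    def group_index(self, group: str) -> np.ndarray:
        return np.array([g == group for g in self.groups])


@dataclass
class SurfaceStatMap:
    statistic: np.ndarray        # per-vertex T² (or signed mm)
    p: np.ndarray | None         # parametric per-vertex p
    p_fwe: np.ndarray | None     # corrected p
    mask: np.ndarray | None      # significant at alpha after correction
    kind: str = "t2"

    def __post_init__(self):
        for arr in (self.p, self.p_fwe):
            if arr is not None and ((arr < -1e-12).any() or (arr > 1 + 1e-12).any()):
                raise ValueError("p values outside [0, 1]")


def propagate_mesh(template_mesh: TriangleMesh, deformations: list[Deformation],
                   specimen_ids=None, groups=None) -> HomologousMeshSet:
    """Pull template vertices through each specimen's deformation.

    The deformation is the same pull-back map used to carry the average
    brain into a specimen frame: a template-frame surface point lands at
    the specimen-frame location where the inverse map samples it.  Vertices
    mapped outside the grid are clamped (edge rule) and counted in a
    warning.
    """
    import warnings

    V = len(template_mesh.vertices)
    out = np.empty((len(deformations), V, 3))
    for i, phi in enumerate(deformations):
        vox = phi.grid.world_to_voxel(template_mesh.vertices)
        lo = np.zeros(3)
        hi = np.array(phi.grid.shape, dtype=float) - 1
        clipped = np.clip(vox, lo, hi)
        n_out = int(np.sum(np.any(vox != clipped, axis=1)))
        if n_out:
            warnings.warn(f"specimen {i}: {n_out} vertices clamped to grid edge")
        # note: phi is a pull-back lattice; the *forward* position of a
        # template vertex is where the inverse lattice maps it, which is the
        # deformation supplied by the caller (exp(-v) for specimen v)
        new_vox = transform_points(phi, clipped)
        out[i] = phi.grid.voxel_to_world(new_vox)
    ids = specimen_ids or [f"s{i:03d}" for i in range(len(deformations))]
    grp = groups or [""] * len(deformations)
    return HomologousMeshSet(template_mesh, out, list(ids), list(grp))


def _centroid_size(x: np.ndarray) -> float:
    c = x.mean(axis=0)
    return float(np.sqrt(((x - c) ** 2).sum()))


def _orthogonal_fit(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation (det +1) minimizing ||a R - b||."""
    U, _s, Vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def procrustes_align(meshes: HomologousMeshSet, max_iter: int = 100,
                     tol: float = 1e-10):
    """Generalized Procrustes: center, scale to unit centroid size, rotate to
    the iteratively refined mean.  Returns (aligned set, centroid sizes)."""
    X = meshes.per_specimen_vertices
    S = X.shape[0]
    if S < 2:
        raise ValueError("need at least 2 specimens")
    sizes = np.array([_centroid_size(x) for x in X])
    if np.any(sizes < 1e-12):
        raise ValueError("degenerate specimen (all points coincident)")
    Y = np.stack([(x - x.mean(0)) / s for x, s in zip(X, sizes)])
    mean = Y[0].copy()
    for _ in range(max_iter):
        for i in range(S):
            R = _orthogonal_fit(Y[i], mean)
            Y[i] = Y[i] @ R
        new_mean = Y.mean(axis=0)
        new_mean /= max(_centroid_size(new_mean), 1e-300)
        delta = np.sqrt(((new_mean - mean) ** 2).mean())
        mean = new_mean
        if delta < tol:
            break
    aligned = HomologousMeshSet(
        meshes.template_mesh, Y, list(meshes.specimen_ids), list(meshes.groups)
    )
    return aligned, sizes


def consensus_mesh(aligned: HomologousMeshSet) -> TriangleMesh:
    return TriangleMesh(
        aligned.per_specimen_vertices.mean(axis=0), aligned.template_mesh.faces
    )


def displacement_fields(aligned: HomologousMeshSet) -> np.ndarray:
    """S x V x 3 deviations of each specimen from the consensus mean shape."""
    mean = aligned.per_specimen_vertices.mean(axis=0)
    return aligned.per_specimen_vertices - mean


def signed_normal_displacement(aligned: HomologousMeshSet, group_a: str,
                               group_b: str) -> SurfaceStatMap:
    """Per-vertex (mean_a - mean_b) projected on consensus vertex normals.

    Positive values mean group a lies outward of group b along the surface
    normal; the map is antisymmetric in the group order.
    """
    ia = aligned.group_index(group_a)
    ib = aligned.group_index(group_b)
    mean_a = aligned.per_specimen_vertices[ia].mean(axis=0)
    mean_b = aligned.per_specimen_vertices[ib].mean(axis=0)
    normals = consensus_mesh(aligned).vertex_normals()
    signed = ((mean_a - mean_b) * normals).sum(axis=1)
    return SurfaceStatMap(signed, None, None, None, kind="signed_displacement")


def _t2_stat(disp: np.ndarray, ia: np.ndarray, ib: np.ndarray,
             ridge: float = 1e-8) -> np.ndarray:
    """Vectorized per-vertex two-sample Hotelling T² on V x 3 vectors."""
    a, b = disp[ia], disp[ib]
    na, nb = len(a), len(b)
    da = a - a.mean(axis=0)
    db = b - b.mean(axis=0)
    # pooled covariance per vertex: V x 3 x 3
    Sp = (np.einsum("svi,svj->vij", da, da) + np.einsum("svi,svj->vij", db, db)) / (
        na + nb - 2
    )
    tr = np.trace(Sp, axis1=1, axis2=2)
    Sp = Sp + (ridge * np.maximum(tr, 1e-300))[:, None, None] * np.eye(3)
    dbar = a.mean(axis=0) - b.mean(axis=0)
    sol = np.linalg.solve(Sp, dbar[..., None])[..., 0]
    t2 = (na * nb / (na + nb)) * np.einsum("vi,vi->v", dbar, sol)
    return np.maximum(t2, 0.0)


def hotelling_t2_map(meshes: HomologousMeshSet, group_a: str, group_b: str
                     ) -> SurfaceStatMap:
    """Vertex-wise two-sample T² between groups on displacement vectors,
    with parametric p from the F transform (p = 3 dimensions)."""
    ia = meshes.group_index(group_a)
    ib = meshes.group_index(group_b)
    na, nb = int(ia.sum()), int(ib.sum())
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 specimens")
    n = na + nb
    disp = displacement_fields(meshes)
    t2 = _t2_stat(disp, ia, ib)
    p_dim = 3
    if n - p_dim - 1 > 0:
        f = t2 * (n - p_dim - 1) / (p_dim * (n - 2))
        p = stats.f.sf(f, p_dim, n - p_dim - 1)
    else:
        p = np.full_like(t2, np.nan)
    return SurfaceStatMap(t2, p, None, None, kind="t2")


def pillai_manova_map(meshes: HomologousMeshSet, groups: list[str]) -> SurfaceStatMap:
    """Omnibus k-group one-way MANOVA (Pillai's trace) per vertex."""
    disp = displacement_fields(meshes)
    idx = [meshes.group_index(g) for g in groups]
    ns = np.array([int(i.sum()) for i in idx])
    if (ns < 2).any():
        raise ValueError("each group needs >= 2 specimens")
    sel = np.any(idx, axis=0)
    X = disp[sel]
    n, V, p_dim = X.shape
    k = len(groups)
    grand = X.mean(axis=0)
    H = np.zeros((V, p_dim, p_dim))
    E = np.zeros((V, p_dim, p_dim))
    for gi in idx:
        sub = disp[gi]
        m = sub.mean(axis=0) - grand
        H += len(sub) * np.einsum("vi,vj->vij", m, m)
        d = sub - sub.mean(axis=0)
        E += np.einsum("svi,svj->vij", d, d)
    tr = np.trace(E, axis1=1, axis2=2)
    E = E + (1e-8 * np.maximum(tr, 1e-300))[:, None, None] * np.eye(p_dim)
    M = np.linalg.solve(E + H, H)
    pillai = np.trace(M, axis1=1, axis2=2)
    s = min(p_dim, k - 1)
    m1 = (abs(p_dim - (k - 1)) - 1) / 2.0
    n1 = (n - k - p_dim - 1) / 2.0
    df1 = s * (2 * m1 + s + 1)
    df2 = s * (2 * n1 + s + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (pillai / (s - pillai)) * (df2 / df1)
    p = stats.f.sf(f, df1, df2) if df2 > 0 else np.full(V, np.nan)
    return SurfaceStatMap(np.asarray(pillai), p, None, None, kind="pillai")


def fwe_correct(stat_map: SurfaceStatMap, meshes: HomologousMeshSet,
                group_a: str, group_b: str, n_perm: int = 1000, seed: int = 0,
                alpha: float = 0.05) -> SurfaceStatMap:
    """Max-statistic permutation FWE for a T² map.

    Corrected p(vertex) = fraction of group-label permutations (observed
    labelling included) whose maximum vertex T² is >= the observed T².
    All distinct label assignments are enumerated when there are no more
    than ``n_perm`` of them; otherwise ``n_perm`` random permutations are
    drawn (deterministic given ``seed``).
    """
    import warnings

    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ia = meshes.group_index(group_a)
    ib = meshes.group_index(group_b)
    sel = np.nonzero(ia | ib)[0]
    na = int(ia.sum())
    n = len(sel)
    disp = displacement_fields(meshes)[sel]
    n_distinct = comb(n, na)
    if n_distinct < 20:
        warnings.warn(
            f"only {n_distinct} distinct permutations; exact enumeration used"
        )
    obs = stat_map.statistic
    maxima = []
    if n_distinct <= n_perm:
        for combo in combinations(range(n), na):
            mask_a = np.zeros(n, dtype=bool)
            mask_a[list(combo)] = True
            maxima.append(_t2_stat(disp, mask_a, ~mask_a).max())
        maxima = np.array(maxima)
    else:
        rng = np.random.default_rng(seed)
        maxima = np.empty(n_perm)
        # first entry is the observed labelling
        mask_obs = np.zeros(n, dtype=bool)
        mask_obs[np.isin(sel, np.nonzero(ia)[0])] = True
        maxima[0] = _t2_stat(disp, mask_obs, ~mask_obs).max()
        for i in range(1, n_perm):
            perm = rng.permutation(n)
            mask_a = np.zeros(n, dtype=bool)
            mask_a[perm[:na]] = True
            maxima[i] = _t2_stat(disp, mask_a, ~mask_a).max()
    p_fwe = (maxima[None, :] >= obs[:, None]).mean(axis=1)
    if stat_map.p is not None:
        p_fwe = np.maximum(p_fwe, stat_map.p)
    return SurfaceStatMap(obs, stat_map.p, p_fwe, p_fwe <= alpha, kind=stat_map.kind)
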