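"""Diffeomorphic registration with stationary velocity fields.

Deformations are parameterized by a single time-constant velocity field
``v`` (voxel displacement units per unit flow time) whose group exponential
``exp(v)`` is computed by scaling and squaring: the small-step map
``id + v / 2^N`` self-composed ``N`` times.  Because the flow of ``-v``
inverts the flow of ``v``, inversion is trivial, which is the property the
fossil-reconstruction stage relies on (deform endocasts *into* template
space, pull the average brain *back* with the inverse).

Registration minimizes the sum of squared intensity differences plus a
linear-elastic penalty on the velocity::

    E(v) = sum (M(exp(v)(x)) - F(x))^2
         + lambda * [ mu * sum_ij e_ij(v)^2 + (lam/2) * sum (div v)^2 ]

with ``e_ij = (d_i v_j + d_j v_i)/2`` the strain tensor, discretized by
central differences with replicated (Neumann) boundaries.  The optimizer is
steepest descent with step halving on the exact discrete objective; the
descent direction is the first-order data gradient plus the elastic
gradient, preconditioned by Gaussian smoothing (a positive semi-definite
operator, so descent is preserved).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging_core import LabelVolume, ScalarVolume, VoxelGrid

__all__ = [
    "VelocityField",
    "Deformation",
    "RegistrationConfig",
    "RegistrationError",
    "identity_deformation",
    "exp_velocity",
    "compose",
    "warp",
    "transform_points",
    "register",
    "affine_prealign",
    "build_template",
    "smooth_mask",
    "jacobian_determinant",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class RegistrationError(RuntimeError):
    pass


@dataclass
class VelocityField:
    """Stationary velocity lattice, shape ``grid.shape + (3,)``, voxel units."""

    grid: VoxelGrid
    v: np.ndarray

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        if self.v.shape != self.grid.shape + (3,):
            raise ValueError("velocity lattice shape mismatch")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("non-finite velocity")

    def __neg__(self) -> "VelocityField":
        return VelocityField(self.grid, -self.v)


@dataclass
class Deformation:
    """Pull-back map: ``phi[x]`` is the source voxel coordinate sampled at
    fixed-grid voxel ``x``; ``warp(I, phi)(x) = I(phi(x))``."""

    grid: VoxelGrid
    phi: np.ndarray

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != self.grid.shape + (3,):
            raise ValueError("deformation lattice shape mismatch")

    def displacement(self) -> np.ndarray:
        return self.phi - _identity_lattice(self.grid.shape)


@dataclass
class RegistrationConfig:
    n_levels: int = 3
    iters_per_level: tuple[int, ...] = (40, 30, 20)
    squaring_steps: int = 6
    elastic_mu: float = 1.0
    elastic_lambda: float = 0.5
    step_size: float = 0.4          # max voxel displacement change per trial step
    reg_weight: float = 0.01
    precond_sigma: float = 1.5      # voxels; Gaussian preconditioner
    tol: float = 1e-5               # relative objective decrease to declare converged
    min_step_frac: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.squaring_steps < 1 or self.n_levels < 1:
            raise ValueError("squaring_steps and n_levels must be >= 1")
        if min(self.elastic_mu, self.elastic_lambda, self.reg_weight) < 0:
            raise ValueError("penalty weights must be >= 0")


def _identity_lattice(shape) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    return np.stack(grids, axis=-1)


def identity_deformation(grid: VoxelGrid) -> Deformation:
    return Deformation(grid, _identity_lattice(grid.shape))


def _sample_channels(data: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Trilinearly sample a (..., C) lattice at voxel coords (..., 3)."""
    pts = coords.reshape(-1, 3).T
    out = np.empty((pts.shape[1], data.shape[-1]))
    for c in range(data.shape[-1]):
        out[:, c] = ndimage.map_coordinates(
            data[..., c], pts, order=1, mode="nearest", prefilter=False
        )
    return out.reshape(coords.shape[:-1] + (data.shape[-1],))


def exp_velocity(v: VelocityField, n_steps: int | None = None) -> Deformation:
    """Group exponential of a stationary velocity by scaling and squaring."""
    N = 6 if n_steps is None else int(n_steps)
    if N < 1:
        raise ValueError("n_steps must be >= 1")
    ident = _identity_lattice(v.grid.shape)
    u = v.v / (2.0 ** N)            # small-step displacement
    for _ in range(N):
        # (id+u) o (id+u): u'(x) = u(x) + u(x + u(x))
        u = u + _sample_channels(u, ident + u)
    return Deformation(v.grid, ident + u)


def compose(phi_a: Deformation, phi_b: Deformation) -> Deformation:
    """Deformation with ``warp(I, result) == warp(warp(I, phi_a), phi_b)``,
    i.e. ``result(x) = phi_a(phi_b(x))``."""
    if phi_a.grid != phi_b.grid:
        raise RegistrationError("grid mismatch in compose")
    ua = phi_a.displacement()
    new_phi = phi_b.phi + _sample_channels(ua, phi_b.phi)
    return Deformation(phi_a.grid, new_phi)


def warp(volume, phi: Deformation, mode: str = "trilinear"):
    """Resample a volume through a deformation (pull-back)."""
    if volume.grid != phi.grid:
        raise RegistrationError("grid mismatch in warp")
    pts = phi.phi.reshape(-1, 3).T
    if mode == "trilinear":
        out = ndimage.map_coordinates(
            volume.values, pts, order=1, mode="nearest", prefilter=False
        )
        return ScalarVolume(volume.grid, out.reshape(volume.grid.shape))
    elif mode == "nearest":
        data = volume.labels if isinstance(volume, LabelVolume) else volume.values
        out = ndimage.map_coordinates(
            data, pts, order=0, mode="grid-constant", cval=0, prefilter=False
        )
        out = out.reshape(volume.grid.shape)
        if isinstance(volume, LabelVolume):
            return LabelVolume(volume.grid, out)
        return ScalarVolume(volume.grid, out)
    raise ValueError(f"unknown mode {mode!r}")


def transform_points(phi: Deformation, points: np.ndarray) -> np.ndarray:
    """Evaluate the deformation at arbitrary voxel-coordinate points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return _sample_channels(phi.phi, pts)


def jacobian_determinant(phi: Deformation) -> np.ndarray:
    """Voxelwise Jacobian determinant of a deformation (central differences)."""
    J = np.empty(phi.grid.shape + (3, 3))
    for c in range(3):
        grads = np.gradient(phi.phi[..., c])
        for a in range(3):
            J[..., c, a] = grads[a]
    return np.linalg.det(J)


def smooth_mask(mask: ScalarVolume, fwhm: float = 2.0) -> ScalarVolume:
    """Gaussian-smooth a binary mask (FWHM in voxels) into a soft image."""
    sm = ndimage.gaussian_filter(mask.values.astype(float), FWHM_TO_SIGMA * fwhm)
    return ScalarVolume(mask.grid, sm)


# ---------------------------------------------------------------------------
# objective pieces

def _strain_energy(v: np.ndarray, mu: float, lam: float) -> float:
    grads = [np.gradient(v[..., j]) for j in range(3)]  # grads[j][i] = d_i v_j
    e = 0.0
    div = np.zeros(v.shape[:-1])
    for i in range(3):
        div += grads[i][i]
        for j in range(3):
            eij = 0.5 * (grads[j][i] + grads[i][j])
            e += float(np.sum(eij * eij))
    return mu * e + 0.5 * lam * float(np.sum(div * div))


def _strain_gradient(v: np.ndarray, mu: float, lam: float) -> np.ndarray:
    grads = [np.gradient(v[..., j]) for j in range(3)]
    div = grads[0][0] + grads[1][1] + grads[2][2]
    grad_div = np.gradient(div)
    g = np.empty_like(v)
    for j in range(3):
        lap = sum(np.gradient(grads[j][i], axis=i) for i in range(3))
        g[..., j] = -mu * (lap + grad_div[j]) - lam * grad_div[j]
    return g


def _objective(fixed: np.ndarray, moving: ScalarVolume, v: VelocityField,
               cfg: RegistrationConfig) -> tuple[float, np.ndarray]:
    phi = exp_velocity(v, cfg.squaring_steps)
    warped = warp(moving, phi).values
    res = warped - fixed
    msd = float(np.sum(res * res))
    le = _strain_energy(v.v, cfg.elastic_mu, cfg.elastic_lambda)
    return msd + cfg.reg_weight * le, warped


def _descent_direction(fixed, warped, v, cfg) -> np.ndarray:
    res = warped - fixed
    gw = np.gradient(warped)
    g = np.stack([2.0 * res * gw[a] for a in range(3)], axis=-1)
    g += cfg.reg_weight * _strain_gradient(v, cfg.elastic_mu, cfg.elastic_lambda)
    if cfg.precond_sigma > 0:
        for c in range(3):
            g[..., c] = ndimage.gaussian_filter(g[..., c], cfg.precond_sigma)
    return g


def _downsample(values: np.ndarray, target_shape) -> np.ndarray:
    factors = [t / s for t, s in zip(target_shape, values.shape)]
    return ndimage.zoom(values, factors, order=1, mode="nearest", grid_mode=True)


def _upsample_velocity(v: np.ndarray, target_shape) -> np.ndarray:
    out = np.empty(tuple(target_shape) + (3,))
    for c in range(3):
        out[..., c] = _downsample(v[..., c], target_shape)
        out[..., c] *= target_shape[c] / v.shape[c]  # voxel units rescale
    return out


def register(fixed: ScalarVolume, moving: ScalarVolume,
             cfg: RegistrationConfig | None = None):
    """Estimate a stationary velocity ``v`` such that ``warp(moving, exp(v))``
    matches ``fixed``.  Returns ``(VelocityField, diagnostics dict)``.

    Coarse-to-fine over ``cfg.n_levels`` dyadic levels; the accepted objective
    trace is non-increasing within each level by construction.
    """
    cfg = cfg or RegistrationConfig()
    if fixed.grid != moving.grid:
        raise RegistrationError("fixed and moving must share one grid")
    full_shape = fixed.grid.shape
    iters = list(cfg.iters_per_level)
    while len(iters) < cfg.n_levels:
        iters.append(iters[-1])

    shapes = []
    for lev in range(cfg.n_levels):
        f = 2 ** (cfg.n_levels - 1 - lev)
        shapes.append(tuple(max(8, int(round(s / f))) for s in full_shape))

    v = None
    trace_all = []
    for lev, shape in enumerate(shapes):
        grid = VoxelGrid(shape)
        fx = _downsample(fixed.values, shape)
        mv = ScalarVolume(grid, _downsample(moving.values, shape))
        if v is None:
            v = VelocityField(grid, np.zeros(shape + (3,)))
        else:
            v = VelocityField(grid, _upsample_velocity(v.v, shape))

        energy, warped = _objective(fx, mv, v, cfg)
        trace = [energy]
        for _ in range(iters[lev]):
            g = _descent_direction(fx, warped, v.v, cfg)
            gmax = np.abs(g).max()
            if gmax == 0:
                break
            alpha = cfg.step_size / gmax
            accepted = False
            while alpha > cfg.min_step_frac * cfg.step_size / gmax:
                v_try = VelocityField(grid, v.v - alpha * g)
                e_try, w_try = _objective(fx, mv, v_try, cfg)
                if e_try < energy:
                    v, warped = v_try, w_try
                    rel = (energy - e_try) / max(energy, 1e-30)
                    energy = e_try
                    trace.append(energy)
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:
                break
            if rel < cfg.tol:
                break
        trace_all.append(trace)

    if tuple(v.grid.shape) != full_shape:
        v = VelocityField(fixed.grid, _upsample_velocity(v.v, full_shape))
    else:
        v = VelocityField(fixed.grid, v.v)
    final_energy, _ = _objective(fixed.values, moving, v, cfg)
    diagnostics = {
        "objective_trace": trace_all,
        "final_objective": final_energy,
        "initial_msd": float(np.sum((moving.values - fixed.values) ** 2)),
        "final_msd": float(np.sum((warp(moving, exp_velocity(v, cfg.squaring_steps)).values
                                   - fixed.values) ** 2)),
    }
    return v, diagnostics


def affine_prealign(fixed_mask: ScalarVolume, moving_mask: ScalarVolume) -> np.ndarray:
    """Moment-based affine: centroids + principal axes + isotropic scale.

    Returns a 4x4 matrix ``M`` in the pull-back convention: resampling the
    moving mask at ``M @ (x, 1)`` for fixed-grid voxels ``x`` aligns it with
    the fixed mask.  The linear part has positive determinant (no
    reflection); degenerate inertia tensors fall back to centroid + scale.
    """
    f = np.asarray(fixed_mask.values, dtype=float)
    m = np.asarray(moving_mask.values, dtype=float)
    wf, wm = f.sum(), m.sum()
    if wf <= 0 or wm <= 0:
        raise ValueError("empty mask in affine_prealign")
    idx_f = _identity_lattice(f.shape).reshape(-1, 3)
    idx_m = _identity_lattice(m.shape).reshape(-1, 3)
    cf = (idx_f * f.reshape(-1, 1)).sum(0) / wf
    cm = (idx_m * m.reshape(-1, 1)).sum(0) / wm
    s = (wm * moving_mask.grid.voxel_volume / (wf * fixed_mask.grid.voxel_volume)) ** (1.0 / 3.0)

    def _cov(idx, w, c):
        d = idx - c
        return (d.T * w.reshape(-1)) @ d / w.sum()

    Cf = _cov(idx_f, f, cf)
    Cm = _cov(idx_m, m, cm)
    lin = s * np.eye(3)
    try:
        lf, Uf = np.linalg.eigh(Cf)
        lm, Um = np.linalg.eigh(Cm)
        # reject near-degenerate spectra (axes not identifiable)
        if np.min(np.diff(np.sort(lf))) > 1e-3 * lf.max() and \
           np.min(np.diff(np.sort(lm))) > 1e-3 * lm.max():
            # fix eigenvector signs so rotation is small, and keep det > 0
            for k in range(3):
                if Um[:, k] @ Uf[:, k] < 0:
                    Um[:, k] = -Um[:, k]
            R = Um @ Uf.T
            if np.linalg.det(R) < 0:
                Um[:, 2] = -Um[:, 2]
                R = Um @ Uf.T
            lin = s * R
    except np.linalg.LinAlgError:
        pass
    M = np.eye(4)
    M[:3, :3] = lin
    M[:3, 3] = cm - lin @ cf
    return M


def apply_affine_to_volume(volume, M: np.ndarray, mode: str = "trilinear"):
    """Resample ``volume`` at ``M @ x`` for each voxel ``x`` (pull-back)."""
    ident = _identity_lattice(volume.grid.shape).reshape(-1, 3)
    pts = ident @ M[:3, :3].T + M[:3, 3]
    phi = Deformation(volume.grid, pts.reshape(volume.grid.shape + (3,)))
    return warp(volume, phi, mode=mode)


def build_template(images: list[ScalarVolume], cfg: RegistrationConfig | None = None,
                   n_outer: int = 3, paired: list[ScalarVolume] | None = None):
    """Iterative population template: alternate registration of every image to
    the current template with template refresh as the mean of warped images.

    When ``paired`` volumes are supplied (e.g. brain images paired with the
    endocast images being registered), the same deformations are applied to
    them and their mean is returned as well — this is how the population
    average *brain* is computed from endocast-driven registrations.

    Returns ``(template, velocities, mean_paired_or_None, residual_trace)``.
    """
    cfg = cfg or RegistrationConfig()
    if len(images) < 2:
        raise ValueError("need at least 2 images")
    grid = images[0].grid
    for im in images[1:]:
        if im.grid != grid:
            raise RegistrationError("images must share one grid")
    template = ScalarVolume(grid, np.mean([im.values for im in images], axis=0))
    velocities = [None] * len(images)
    residuals = []
    for _ in range(n_outer):
        warped = []
        for i, im in enumerate(images):
            v, _diag = register(template, im, cfg)
            velocities[i] = v
            warped.append(warp(im, exp_velocity(v, cfg.squaring_steps)).values)
        residuals.append(float(np.sum([(w - template.values) ** 2 for w in warped])))
        template = ScalarVolume(grid, np.mean(warped, axis=0))
    mean_paired = None
    if paired is not None:
        if len(paired) != len(images):
            raise ValueError("paired list length mismatch")
        wp = [warp(p, exp_velocity(v, cfg.squaring_steps)).values
              for p, v in zip(paired, velocities)]
        mean_paired = ScalarVolume(grid, np.mean(wp, axis=0))
    return template, velocities, mean_paired, residuals
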