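"""EM Gaussian-mixture tissue segmentation (GM/WM/CSF) and derived masks.

A three-class 1-D Gaussian mixture is fit to the intensities inside a head
mask by expectation-maximization (k-means++ initialization, deterministic
given a seed).  Classes are reported in CSF < GM < WM mean order regardless
of initialization.  An optional one-parameter Potts/mean-field term couples
neighbouring posteriors (off by default; with it on, the unsmoothed
mixture log-likelihood is no longer guaranteed monotone and is not traced).

Brain and endocast masks use a majority rule on summed posteriors:
brain = (GM+WM >= 0.5), endocast = (GM+WM+CSF >= 0.5).  Intracranial volume
(ICV) is the *soft* sum of the three fractions times the voxel volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.cluster import kmeans_plusplus

from .imaging_core import LabelVolume, ScalarVolume, TissueVolumeSet, VoxelGrid

__all__ = [
    "SegmentationResult",
    "segment_em",
    "brain_mask",
    "endocast_mask",
    "icv",
]


@dataclass
class SegmentationResult:
    tissue: TissueVolumeSet          # posterior fractions (csf/gm/wm maps)
    hard_labels: LabelVolume         # argmax: 1=CSF, 2=GM, 3=WM, 0 outside mask
    class_means: np.ndarray          # ordered CSF < GM < WM
    class_sds: np.ndarray
    mixing: np.ndarray
    n_iter: int
    converged: bool
    log_likelihood_trace: list[float]


def segment_em(t1: ScalarVolume, head_mask: ScalarVolume | np.ndarray,
               k: int = 3, max_iter: int = 100, tol: float = 1e-6,
               seed: int = 0, mrf_beta: float = 0.0) -> SegmentationResult:
    """Segment a T1-like volume into CSF/GM/WM posteriors inside a head mask."""
    mask = head_mask.values if isinstance(head_mask, ScalarVolume) else head_mask
    mask = np.asarray(mask) > 0.5
    if not mask.any():
        raise ValueError("head mask is empty")
    x = t1.values[mask]
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite intensities")
    if len(np.unique(x)) < k:
        raise ValueError(f"fewer than {k} distinct intensities in mask")

    centers, _ = kmeans_plusplus(
        x.reshape(-1, 1), n_clusters=k, random_state=seed
    )
    mu = np.sort(centers.ravel())
    sd = np.full(k, max(x.std() / k, 1e-3))
    pi = np.full(k, 1.0 / k)

    n = x.size
    ll_trace: list[float] = []
    resp = None
    converged = False
    spatial_prior = None
    it = 0
    for it in range(1, max_iter + 1):
        # E step
        logp = (
            -0.5 * ((x[None, :] - mu[:, None]) / sd[:, None]) ** 2
            - np.log(sd[:, None])
            - 0.5 * np.log(2 * np.pi)
            + np.log(pi[:, None])
        )
        if spatial_prior is not None:
            logp = logp + mrf_beta * spatial_prior
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        resp = np.exp(logp - lse)
        ll = float(lse.sum())
        ll_trace.append(ll)
        if len(ll_trace) > 1 and abs(ll_trace[-1] - ll_trace[-2]) < tol * abs(ll_trace[-2]):
            converged = True
            break
        # M step
        nk = resp.sum(axis=1) + 1e-12
        mu = (resp @ x) / nk
        var = np.maximum((resp @ (x * x)) / nk - mu * mu, 1e-8)
        sd = np.maximum(np.sqrt(var), 1e-4)
        pi = nk / n
        if mrf_beta > 0:
            # mean-field Potts: neighbour-averaged posteriors as a prior
            spatial_prior = np.empty_like(resp)
            for c in range(k):
                vol = np.zeros(t1.grid.shape)
                vol[mask] = resp[c]
                sm = ndimage.uniform_filter(vol, size=3)
                spatial_prior[c] = sm[mask]

    order = np.argsort(mu)
    mu, sd, pi = mu[order], sd[order], pi[order]
    resp = resp[order]

    maps = []
    for c in range(k):
        vol = np.zeros(t1.grid.shape)
        vol[mask] = resp[c]
        maps.append(ScalarVolume(t1.grid, vol))
    csf_map, gm_map, wm_map = maps[0], maps[1], maps[2]
    tissue = TissueVolumeSet(gm_map, wm_map, csf_map)

    hard = np.zeros(t1.grid.shape, dtype=np.int32)
    hard[mask] = np.argmax(resp, axis=0) + 1
    return SegmentationResult(
        tissue=tissue,
        hard_labels=LabelVolume(t1.grid, hard),
        class_means=mu,
        class_sds=sd,
        mixing=pi,
        n_iter=it,
        converged=converged,
        log_likelihood_trace=ll_trace,
    )


def brain_mask(tissue: TissueVolumeSet) -> ScalarVolume:
    """GM + WM >= 0.5 (majority rule)."""
    m = (tissue.gm.values + tissue.wm.values) >= 0.5
    return ScalarVolume(tissue.grid, m.astype(float))


def endocast_mask(tissue: TissueVolumeSet) -> ScalarVolume:
    """GM + WM + CSF >= 0.5; always a superset of the brain mask."""
    m = (tissue.gm.values + tissue.wm.values + tissue.csf.values) >= 0.5
    return ScalarVolume(tissue.grid, m.astype(float))


def icv(tissue: TissueVolumeSet, grid: VoxelGrid | None = None) -> float:
    """Intracranial volume in mm^3: soft sum of GM+WM+CSF fractions."""
    grid = grid or tissue.grid
    total = tissue.gm.values + tissue.wm.values + tissue.csf.values
    return float(total.sum() * grid.voxel_volume)
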