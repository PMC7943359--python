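"""Searchlight RSA mapping with sign-flip max-statistic group inference.

A sphere (default radius 3 voxels, 123 voxels) is centered on every
in-mask voxel; the Pearson-distance DM over the sphere's voxels is
regressed on the predictor DM (rank regression, optional covariates) and
the beta is written back to the center.  Subject beta maps are smoothed
with a mask-aware Gaussian kernel and tested at the group level with a
one-sample t statistic whose family-wise error is controlled by the
permutation distribution of the image-wide maximum t under random sign
flips of subject maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from . import rsa


@dataclass(frozen=True)
class SphereSpec:
    radius: float
    offsets: np.ndarray      # (k, 3) integer offsets, includes (0, 0, 0)


@dataclass
class StatMap:
    """Per-voxel statistics defined inside a mask (NaN elsewhere)."""

    data: np.ndarray
    mask: np.ndarray
    fwhm_mm: float = 0.0


def sphere_offsets(radius: float) -> SphereSpec:
    """All integer offsets with Euclidean norm ≤ radius (inclusive;
    radius 3 gives the canonical 123-voxel sphere)."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    r = int(np.floor(radius))
    rng = np.arange(-r, r + 1)
    grid = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1)
    offs = grid.reshape(-1, 3)
    keep = (offs ** 2).sum(axis=1) <= radius ** 2 + 1e-9
    return SphereSpec(radius=radius, offsets=offs[keep])


def run_searchlight(volume: np.ndarray,
                    mask: np.ndarray,
                    predictor_dm,
                    covariate_dms=(),
                    radius: float = 3.0,
                    min_voxels: int = 2) -> StatMap:
    """Regression-RSA beta map for one subject.

    ``volume`` is (4, nx, ny, nz) condition patterns.  Spheres are
    intersected with the mask (shrunk, not skipped, at edges); centers
    whose sphere retains fewer than ``min_voxels`` usable voxels — or
    whose local patterns are degenerate (zero variance) — are marked
    missing (NaN), not zero.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    dims = volume.shape[1:]
    offs = sphere_offsets(radius).offsets
    out = np.full(dims, np.nan)
    pred = rsa._pair_vector(predictor_dm)
    covs = [rsa._pair_vector(c) for c in covariate_dms]
    flat = volume.reshape(4, -1)
    strides = np.array([dims[1] * dims[2], dims[2], 1])
    centers = np.argwhere(mask)
    flat_mask = mask.ravel()
    for center in centers:
        pts = center + offs
        ok = np.all((pts >= 0) & (pts < dims), axis=1)
        idx = pts[ok] @ strides
        idx = idx[flat_mask[idx]]
        if idx.size < min_voxels:
            continue
        pats = flat[:, idx]
        if np.any(pats.std(axis=1) == 0):
            continue
        dm = rsa.neural_dm(pats)
        try:
            beta = rsa.regression_rsa(dm, pred, covs)
        except ValueError:
            continue
        out[tuple(center)] = beta
    return StatMap(data=out, mask=mask)


def smooth_map(stat_map: StatMap, fwhm_mm: float,
               voxel_size_mm: float = 2.0) -> StatMap:
    """Mask-aware Gaussian smoothing.

    sigma = fwhm / (2 sqrt(2 ln 2)) per axis; the smoothed map is
    renormalized by the smoothed mask so constant images stay constant
    at edges.  fwhm 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return StatMap(stat_map.data.copy(), stat_map.mask, fwhm_mm=0.0)
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    valid = stat_map.mask & np.isfinite(stat_map.data)
    filled = np.where(valid, stat_map.data, 0.0)
    num = ndimage.gaussian_filter(filled, sigma_vox)
    den = ndimage.gaussian_filter(valid.astype(float), sigma_vox)
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = num / den
    sm[~valid] = np.nan
    return StatMap(data=sm, mask=stat_map.mask, fwhm_mm=fwhm_mm)


def group_permutation(subject_maps, n_perm: int = 5000, seed: int = 0,
                      alpha: float = 0.05) -> dict:
    """Sign-flip max-statistic permutation test of the voxelwise t map.

    Under exchangeability of map signs (one-sample test against 0), each
    permutation flips the sign of whole subject maps; the corrected
    p-value at a voxel is the rank of its observed t within the null
    distribution of the image-wide maximum t (one-sided, positive
    effects).  Returns the observed t map, corrected p map, the max-t
    null distribution and the alpha-level critical value.
    """
    maps = np.stack([np.asarray(m.data if isinstance(m, StatMap) else m,
                                dtype=float) for m in subject_maps])
    n_sub = maps.shape[0]
    if n_sub < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse permutation null",
                      stacklevel=2)
    flat = maps.reshape(n_sub, -1)
    valid = np.all(np.isfinite(flat), axis=0)
    if not valid.any():
        raise ValueError("no voxel is defined across all subject maps")
    data = flat[:, valid]

    def t_stat(x):
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return mean / (sd / np.sqrt(n_sub))

    t_obs = t_stat(data)
    rng = np.random.default_rng(seed)
    max_null = np.empty(n_perm)
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_sub)
        max_null[i] = np.nanmax(t_stat(data * signs[:, None]))
    # observed statistic counted in its own null (guarantees valid p >= 1/(n+1))
    p_corr = (1.0 + np.sum(max_null[None, :] >= t_obs[:, None], axis=1)) \
        / (n_perm + 1.0)
    t_map = np.full(flat.shape[1], np.nan)
    p_map = np.full(flat.shape[1], np.nan)
    t_map[valid] = t_obs
    p_map[valid] = p_corr
    shape = maps.shape[1:]
    return {
        "t_map": t_map.reshape(shape),
        "p_corrected": p_map.reshape(shape),
        "max_null": max_null,
        "critical_t": float(np.quantile(max_null, 1.0 - alpha)),
        "alpha": alpha,
    }
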