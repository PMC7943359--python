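"""Desk-scale pattern volumes for searchlight analyses.

Generates per-subject 4-D (condition × x × y × z) pattern volumes on a
small grid: voxels inside designated spherical signal regions carry
patterns realizing the subject's planted DM, everything else is pure
noise.  A matching brain mask and signal-region label volume are
returned; NIfTI export lives in :mod:`stereorsa.io`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import DissimilarityMatrix
from .patterns import gen_patterns


@dataclass(frozen=True)
class SignalRegion:
    center: tuple[int, int, int]
    radius: float
    label: int = 1


@dataclass
class VolumeDataset:
    volumes: list[np.ndarray]      # per subject, shape (4, nx, ny, nz)
    mask: np.ndarray               # (nx, ny, nz) bool
    region_labels: np.ndarray      # (nx, ny, nz) int, 0 = no signal


def _region_mask(grid_dims, region: SignalRegion) -> np.ndarray:
    grids = np.indices(grid_dims)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, region.center))
    return d2 <= region.radius ** 2


def gen_volume_dataset(grid_dims: tuple[int, int, int],
                       regions: list[SignalRegion],
                       per_subject_dms: list[DissimilarityMatrix],
                       noise_sd: float = 1.0,
                       signal_noise_sd: float = 0.3,
                       seed: int | np.random.Generator = 0) -> VolumeDataset:
    """Per-subject 4-D condition pattern volumes with planted signal spheres.

    Signal regions must fit inside the grid and must not overlap.  The
    brain mask covers the full grid.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    labels = np.zeros(grid_dims, dtype=int)
    for reg in regions:
        if any(c - reg.radius < 0 or c + reg.radius > d - 1
               for c, d in zip(reg.center, grid_dims)):
            raise ValueError(f"signal region {reg} does not fit inside the grid")
        m = _region_mask(grid_dims, reg)
        if np.any(labels[m] != 0):
            raise ValueError(f"signal region {reg} overlaps another region")
        labels[m] = reg.label

    volumes = []
    for dm in per_subject_dms:
        vol = rng.normal(0.0, noise_sd, (4,) + tuple(grid_dims))
        for reg in regions:
            m = labels == reg.label
            pat = gen_patterns(dm, int(m.sum()), noise_sd=signal_noise_sd,
                               seed=rng)
            vol[:, m] = pat
        volumes.append(vol)
    return VolumeDataset(volumes=volumes,
                         mask=np.ones(grid_dims, dtype=bool),
                         region_labels=labels)
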