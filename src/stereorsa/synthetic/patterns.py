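"""Multi-voxel condition patterns with a planted correlation structure.

Condition patterns are built by mixing four independent unit-variance
voxel component vectors through the matrix square root of the target
correlation matrix C = 1 − DM, then adding independent voxel noise.  The
realized Pearson-distance DM converges to the target as the voxel count
grows and the noise shrinks.
"""

from __future__ import annotations

import numpy as np

from ..core import DissimilarityMatrix


def target_correlation(target_dm: DissimilarityMatrix) -> np.ndarray:
    """C = 1 − DM with unit diagonal; raises if not positive semi-definite
    (i.e. not a realizable correlation structure)."""
    c = target_dm.to_correlation()
    eigvals = np.linalg.eigvalsh(c)
    if eigvals.min() < -1e-8:
        raise ValueError(
            "target DM does not define a valid correlation matrix: "
            f"minimum eigenvalue {eigvals.min():.3g} < 0")
    return c


def gen_patterns(target_dm: DissimilarityMatrix,
                 n_voxels: int,
                 noise_sd: float = 0.0,
                 seed: int | np.random.Generator = 0) -> np.ndarray:
    """Condition × voxel pattern matrix realizing ``target_dm``.

    Deterministic given the seed.  Patterns have (population) unit
    variance per condition before noise; noise is iid N(0, noise_sd²).
    """
    if n_voxels < 2:
        raise ValueError("need at least 2 voxels")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    c = target_correlation(target_dm)
    w, v = np.linalg.eigh(c)
    sqrt_c = (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T
    z = rng.standard_normal((4, n_voxels))
    x = sqrt_c @ z
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(x.shape)
    return x
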