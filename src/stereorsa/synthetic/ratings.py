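"""Descriptor-rating generator with a planted stereotype-strength score.

Each synthetic subject rates 30 descriptors for the categories angry,
happy, male and female on the 1–7 scale.  The generator plants a target
score b ∈ [−2, 2] by construction: with latent unit vectors v ⊥ u,

    angry  = v                      male   = ρ·v + sqrt(1−ρ²)·u
    happy  = −v                     female = −male,         ρ = b / 2

so r(angry, male) = r(happy, female) = ρ and the incongruent pairs equal
−ρ exactly, giving score = 2ρ = b with zero noise.  Element-wise Gaussian
noise attenuates the empirical correlations by amp²/(amp² + σ²); the
latent ρ is pre-inflated by the inverse factor (capped at |ρ| ≤ 1) so the
expected recovered score still tracks the target.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..core import CATEGORIES

SCALE = (1.0, 7.0)
SCALE_MID = 4.0
DEFAULT_AMP = 1.2          # SD of the structured rating component, Likert units


def _unit(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    return x / x.std()


def gen_ratings(n_subjects: int,
                bias_mean: float = 0.49,
                bias_sd: float = 0.62,
                noise_sd: float = 0.3,
                seed: int | np.random.Generator = 0,
                n_descriptors: int = 30,
                amp: float = DEFAULT_AMP) -> tuple[pd.DataFrame, np.ndarray]:
    """Long ratings table plus the per-subject planted scores.

    Per subject the planted score is drawn from N(bias_mean, bias_sd) and
    clipped to [−2, 2].  Ratings are centered at the scale midpoint,
    carry the planted correlation structure at amplitude ``amp``, receive
    element-wise noise, and are clamped to the 1–7 scale (clamping, not
    resampling; negligible for the default amplitudes).

    Returns (DataFrame with columns subject/category/descriptor/rating,
    array of planted scores).
    """
    if not -2.0 <= bias_mean <= 2.0:
        raise ValueError("bias_mean must lie in [-2, 2]")
    if bias_sd < 0 or noise_sd < 0:
        raise ValueError("bias_sd and noise_sd must be non-negative")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    atten = amp ** 2 / (amp ** 2 + noise_sd ** 2)
    frames, planted = [], np.empty(n_subjects)
    for s in range(n_subjects):
        b = float(np.clip(rng.normal(bias_mean, bias_sd) if bias_sd > 0
                          else bias_mean, -2.0, 2.0))
        planted[s] = b
        rho = np.clip((b / 2.0) / atten, -1.0, 1.0)
        v = _unit(rng.standard_normal(n_descriptors))
        u = rng.standard_normal(n_descriptors)
        u = _unit(u - (u @ v) / (v @ v) * v)       # empirically orthogonal
        male = rho * v + np.sqrt(max(0.0, 1.0 - rho ** 2)) * u
        vectors = {"angry": v, "happy": -v, "male": male, "female": -male}
        mat = np.stack([SCALE_MID + amp * vectors[c] for c in CATEGORIES])
        if noise_sd > 0:
            mat = mat + rng.normal(0.0, noise_sd, mat.shape)
        mat = np.clip(mat, *SCALE)
        frames.append(pd.DataFrame({
            "subject": s,
            "category": np.repeat(CATEGORIES, n_descriptors),
            "descriptor": np.tile(np.arange(n_descriptors), 4),
            "rating": mat.ravel(),
        }))
    return pd.concat(frames, ignore_index=True), planted
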