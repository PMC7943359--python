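"""Mouse-trajectory generator with planted congruency and moderation effects.

Each trajectory is a quadratic Bézier curve from the start button (0, 0)
to the chosen response target (±1, 1.5): the control point sits at the
chord midpoint displaced perpendicularly toward the *opposite* response
by amplitude A, which makes the maximum perpendicular deviation exactly
A / 2 (the bulge peaks at the curve midpoint).  Sampling is at ~60 ms
intervals, mimicking a mouse-position logger.

The planted MD for a trial is

    md = baseline + [incongruent]·(congruency_effect
                                   + moderation·(bias_i − bias_mean)) + noise

so stereotype-incongruent faces (angry female, happy male) deviate more,
increasingly so for subjects with stronger stereotypical associations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..core import CONDITIONS, emotion_of, gender_of, is_incongruent
from .design import DesignSpec, GroundTruth

SAMPLE_INTERVAL_MS = 60.0
RT_MEAN_MS = 1200.0
RT_SD_MS = 250.0
RT_MIN_MS = 400.0
DEADLINE_MS = 2000.0


@dataclass
class TrialSet:
    """Batch of trials: metadata table plus NaN-padded path arrays."""

    trials: pd.DataFrame        # subject, block, condition, response,
                                # response_side, rt_ms, correct, timeout
    t_ms: np.ndarray            # (n_trials, max_samples)
    xy: np.ndarray              # (n_trials, max_samples, 2)
    planted_md: np.ndarray      # the noiseless-geometry MD of each trial


def _bezier(end: np.ndarray, amplitude: float, t: np.ndarray) -> np.ndarray:
    """Quadratic Bézier from the origin to ``end`` with the control point
    displaced ``amplitude`` along the unit normal of the chord (toward the
    side opposite the end's x-sign)."""
    normal = np.array([-end[1], end[0]]) / np.hypot(*end)
    if np.sign(normal[0]) == np.sign(end[0]):   # point away from the end side
        normal = -normal
    ctrl = end / 2.0 + amplitude * normal
    t = t[:, None]
    return 2 * t * (1 - t) * ctrl + t ** 2 * end


def gen_trajectories(subject_bias: np.ndarray,
                     truth: GroundTruth,
                     n_faces_per_cell: int = 35,
                     timeout_rate: float = 0.0283,
                     error_rate: float = 0.037,
                     seed: int | np.random.Generator = 0) -> TrialSet:
    """Two-block categorization data for every subject.

    Each subject categorizes every face once per block (gender block and
    emotion block), giving ``2 × 4 × n_faces_per_cell`` trials.  Response
    sides are counterbalanced within subject at random.  Designated
    fractions of trials exceed the 2000 ms deadline or end at the wrong
    response; those trials still carry full paths so the exclusion stage
    has something to drop.
    """
    if not (0 <= timeout_rate < 1 and 0 <= error_rate < 1):
        raise ValueError("timeout_rate and error_rate must lie in [0, 1)")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    subject_bias = np.asarray(subject_bias, dtype=float)
    n_subjects = subject_bias.size
    md_sd = truth.noise_sds.get("md", 0.0)

    records = []
    for s in range(n_subjects):
        centered = subject_bias[s] - truth.stereotype_bias_mean
        for block in ("gender", "emotion"):
            for cond in CONDITIONS:
                for _ in range(n_faces_per_cell):
                    records.append((s, block, cond, centered))
    n = len(records)
    subj = np.array([r[0] for r in records])
    block = np.array([r[1] for r in records])
    cond = np.array([r[2] for r in records])
    centered = np.array([r[3] for r in records])
    incong = np.array([is_incongruent(c) for c in cond], dtype=float)

    # stable per-subject perceptual idiosyncrasies: each subject gets a
    # random baseline shift per block x condition cell, so subjective DMs
    # carry trait-like individual differences beyond the congruency effect
    trait_sd = truth.noise_sds.get("md_subject", 0.0)
    if trait_sd > 0:
        offsets = rng.normal(0.0, trait_sd, (n_subjects, 2, len(CONDITIONS)))
        block_idx = (block == "emotion").astype(int)
        cond_idx = np.array([CONDITIONS.index(c) for c in cond])
        trait = offsets[subj, block_idx, cond_idx]
    else:
        trait = 0.0
    md = (truth.md_baseline + trait
          + incong * (truth.congruency_effect + truth.moderation * centered)
          + (rng.normal(0.0, md_sd, n) if md_sd > 0 else 0.0))

    timeout = rng.random(n) < timeout_rate
    error = rng.random(n) < error_rate
    rt = np.clip(rng.normal(RT_MEAN_MS, RT_SD_MS, n), RT_MIN_MS, DEADLINE_MS)
    rt[timeout] = DEADLINE_MS + rng.exponential(150.0, timeout.sum()) + 1.0

    correct_resp = np.where(block == "gender",
                            [gender_of(c) for c in cond],
                            [emotion_of(c) for c in cond])
    wrong_resp = np.where(block == "gender",
                          np.where(correct_resp == "male", "female", "male"),
                          np.where(correct_resp == "angry", "happy", "angry"))
    response = np.where(error, wrong_resp, correct_resp)
    side = np.where(rng.random(n) < 0.5, "left", "right")

    # vectorized Bézier sampling: parameter proportional to time, NaN-padded
    n_samples = (np.floor(rt / SAMPLE_INTERVAL_MS)).astype(int) + 2
    max_len = int(n_samples.max())
    j = np.arange(max_len)
    valid = j[None, :] < n_samples[:, None]
    u = np.where(valid, j[None, :] / (n_samples[:, None] - 1), np.nan)
    u = np.clip(u, 0.0, 1.0)
    t_arr = u * rt[:, None]
    sx = np.where(side == "right", 1.0, -1.0)
    end = np.stack([sx, np.full(n, 1.5)], axis=1)
    chord = np.hypot(1.0, 1.5)
    normal = np.stack([-sx * 1.5, np.ones(n)], axis=1) / chord  # toward opposite
    ctrl = end / 2.0 + (2.0 * md)[:, None] * normal
    bulge = (2 * u * (1 - u))[:, :, None]
    xy_arr = bulge * ctrl[:, None, :] + (u ** 2)[:, :, None] * end[:, None, :]

    trials = pd.DataFrame({
        "subject": subj, "block": block, "condition": cond,
        "response": response, "response_side": side, "rt_ms": rt,
        "correct": ~error, "timeout": timeout,
    })
    return TrialSet(trials=trials, t_ms=t_arr, xy=xy_arr, planted_md=md)
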