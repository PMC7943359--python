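"""Synthetic BOLD series with planted condition-modulated seed–target coupling.

The seed region's neural activity is the stimulus boxcar; the target
region receives baseline coupling a·seed plus the psychophysiological
interaction c·seed×condition (condition coded masked = −1, unmasked = +1)
and optionally its own evoked component.  Neural series are convolved
with the gamma HRF per run (no bleed across run boundaries) and
measurement noise is added to the convolved signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..glm import HrfParams, build_design, gamma_hrf
from .design import GroundTruth

CONDITION_CODE = {"masked": -1.0, "unmasked": 1.0}


@dataclass
class BoldSession:
    seed_bold: np.ndarray        # (n_vols,)
    target_bold: np.ndarray      # (n_vols,)
    condition: np.ndarray        # (n_vols,) in {-1, +1}
    neural_seed: np.ndarray      # (n_vols,) stimulus boxcar
    run: np.ndarray              # (n_vols,) run index
    tr: float


def _run_layout(schedule: pd.DataFrame, tr: float):
    """Per-run volume counts, boxcars and condition codes from a schedule."""
    runs = sorted(schedule["run"].unique())
    layout = []
    for r in runs:
        ev = schedule[schedule["run"] == r]
        n_vols = int(round((ev["onset"] + ev["duration"]).max() / tr))
        boxcar = np.zeros(n_vols)
        for _, row in ev.iterrows():
            if row["condition"] == "null":
                continue
            a = int(round(row["onset"] / tr))
            b = max(a + 1, int(round((row["onset"] + row["duration"]) / tr)))
            boxcar[a:b] = 1.0
        code = CONDITION_CODE[ev["masking"].iloc[0]]
        layout.append((r, n_vols, boxcar, code))
    return layout


def gen_bold_session(schedule: pd.DataFrame,
                     truth: GroundTruth,
                     hrf: HrfParams = HrfParams(),
                     noise_sd: float | None = None,
                     seed: int | np.random.Generator = 0,
                     a: float = 1.0,
                     target_evoked_amp: float = 0.0,
                     tr: float = 2.0) -> BoldSession:
    """Seed/target ROI time-series pair with interaction coefficient
    c = ``truth.ppi_coupling``.

    Requires the schedule to cover both masking conditions (otherwise the
    interaction is indistinguishable from the baseline coupling).
    """
    maskings = set(schedule["masking"].unique())
    if maskings != {"masked", "unmasked"}:
        raise ValueError("schedule must cover both masked and unmasked runs")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    noise_sd = truth.noise_sds.get("bold", 0.1) if noise_sd is None else noise_sd
    kernel = gamma_hrf(hrf, tr)
    c = truth.ppi_coupling

    seed_parts, target_parts, cond_parts, neural_parts, run_parts = [], [], [], [], []
    for r, n_vols, boxcar, code in _run_layout(schedule, tr):
        cond = np.full(n_vols, code)
        target_neural = (a * boxcar + c * boxcar * cond
                         + target_evoked_amp * boxcar)
        seed_run = np.convolve(boxcar, kernel)[:n_vols]
        target_run = np.convolve(target_neural, kernel)[:n_vols]
        if noise_sd > 0:
            seed_run = seed_run + rng.normal(0.0, noise_sd, n_vols)
            target_run = target_run + rng.normal(0.0, noise_sd, n_vols)
        seed_parts.append(seed_run)
        target_parts.append(target_run)
        cond_parts.append(cond)
        neural_parts.append(boxcar)
        run_parts.append(np.full(n_vols, r))
    return BoldSession(
        seed_bold=np.concatenate(seed_parts),
        target_bold=np.concatenate(target_parts),
        condition=np.concatenate(cond_parts),
        neural_seed=np.concatenate(neural_parts),
        run=np.concatenate(run_parts),
        tr=tr,
    )


def gen_bold_voxels(schedule: pd.DataFrame,
                    patterns: np.ndarray,
                    hrf: HrfParams = HrfParams(),
                    noise_sd: float = 0.5,
                    seed: int | np.random.Generator = 0,
                    tr: float = 2.0,
                    run: int | None = None) -> np.ndarray:
    """Voxelwise BOLD for one run: each voxel responds to each condition
    with amplitude ``patterns[condition, voxel]``, convolved with the HRF.

    Feeding the result through the GLM recovers ``patterns`` (up to a
    common scale) as condition betas.  Returns (n_vols, n_voxels).
    """
    patterns = np.asarray(patterns, dtype=float)
    if run is not None:
        schedule = schedule[schedule["run"] == run]
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_vols = int(round((schedule["onset"] + schedule["duration"]).max() / tr))
    design = build_design(schedule, n_vols, tr=tr, hrf=hrf, scheme="crossed")
    y = design.matrix[:, :4] @ patterns
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, y.shape)
    return y
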