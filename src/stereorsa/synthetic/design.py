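"""Experimental design constants, planted ground truth, and event schedules.

The scanning task presents the four sex × emotion face conditions in four
runs — two backward-masked runs always first, then two unmasked runs.
Each trial repeats a 33 ms face + 167 ms mask + 300 ms fixation sequence
four times, totaling 2000 ms (one TR); fixation-only null events of the
same length are interleaved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..core import CONDITIONS, DissimilarityMatrix

#: Per-trial sub-sequence in ms (face, mask, fixation), repeated 4 times.
SUBSEQUENCE_MS = (33, 167, 300)
TRIAL_MS = 4 * sum(SUBSEQUENCE_MS)  # 2000 ms = 1 TR


@dataclass
class DesignSpec:
    """Study design constants; defaults mirror the reference design."""

    n_subjects: int = 34
    n_faces_per_cell: int = 35        # 35 per sex x emotion cell, 140 faces
    conditions: tuple[str, ...] = CONDITIONS
    trial_duration_ms: int = TRIAL_MS
    n_null_events: int = 77           # per run
    tr: float = 2.0                   # seconds
    n_runs: int = 4                   # two masked then two unmasked
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_faces_per_cell", "n_runs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_null_events < 0:
            raise ValueError("n_null_events must be non-negative")
        if self.trial_duration_ms != 4 * sum(SUBSEQUENCE_MS):
            raise ValueError(
                f"trial_duration_ms must equal 4x{sum(SUBSEQUENCE_MS)} ms")
        if self.n_runs % 2 != 0:
            raise ValueError("n_runs must be even (half masked, half unmasked)")

    @property
    def n_faces(self) -> int:
        return self.n_faces_per_cell * len(self.conditions)

    @property
    def trial_duration_s(self) -> float:
        return self.trial_duration_ms / 1000.0


@dataclass
class GroundTruth:
    """Planted effect sizes the downstream stages must recover.

    Defaults are chosen so the generated data sit in the regime of the
    reference behavioral results: congruent-trial MD around 0.40 standard-
    space units, an incongruent − congruent MD difference of 0.075 (which a
    ±0.5-coded model reads as a gender × emotion coefficient of −0.15), and
    a moderation slope putting the three-way coefficient near −0.057 at the
    observed stereotype-score spread.
    """

    stereotype_bias_mean: float = 0.49   # population mean stereotype score
    stereotype_bias_sd: float = 0.62
    md_baseline: float = 0.40            # congruent-trial MD, standard space
    congruency_effect: float = 0.075     # MD(incongruent) - MD(congruent)
    moderation: float = 0.0285           # d(congruency_effect)/d(stereotype score)
    planted_dm: DissimilarityMatrix | None = None  # per-subject 4x4 target
    ppi_coupling: float = 0.3            # interaction coefficient c
    noise_sds: dict = field(default_factory=lambda: {
        "md": 0.5,        # trial-level MD noise, standard-space units
        "md_subject": 0.08,  # per-subject block x condition trait SD
        "ratings": 0.3,   # element-wise rating noise, Likert units
        "pattern": 0.0,   # voxel pattern noise
        "bold": 0.1,      # BOLD measurement noise
    })

    def __post_init__(self) -> None:
        if self.planted_dm is not None and not isinstance(
                self.planted_dm, DissimilarityMatrix):
            self.planted_dm = DissimilarityMatrix(np.asarray(self.planted_dm))


def make_schedule(spec: DesignSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Randomized event schedule for all runs of one subject.

    Per run, half of the faces are shown twice along with
    ``spec.n_null_events`` null events, every event lasting one trial
    duration and onsets falling on the TR grid.  Masked runs (the first
    half) precede unmasked runs.  Deterministic given ``spec.seed`` or an
    explicit ``rng``.

    Returns columns (onset, duration, condition, run, masking, face_id);
    null events carry condition "null" and face_id −1.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n_cond = len(spec.conditions)
    face_cond = np.repeat(np.arange(n_cond), spec.n_faces_per_cell)
    rows = []
    n_half = spec.n_faces // 2
    base = spec.n_faces_per_cell // 2
    for run in range(1, spec.n_runs + 1):
        masking = "masked" if run <= spec.n_runs // 2 else "unmasked"
        # balanced half-sample: every condition contributes (counterbalanced
        # when the per-cell count is odd)
        extra_cells = rng.permutation(n_cond)[:n_half - n_cond * base]
        faces = []
        for ci in range(n_cond):
            pool = np.flatnonzero(face_cond == ci)
            k = base + (1 if ci in extra_cells else 0)
            faces.append(rng.permutation(pool)[:k])
        faces = np.concatenate(faces)
        events = np.concatenate([np.repeat(faces, 2),
                                 np.full(spec.n_null_events, -1)])
        rng.shuffle(events)
        for i, fid in enumerate(events):
            cond = "null" if fid < 0 else spec.conditions[face_cond[fid]]
            rows.append({
                "onset": i * spec.tr,
                "duration": spec.trial_duration_s,
                "condition": cond,
                "run": run,
                "masking": masking,
                "face_id": int(fid),
            })
    return pd.DataFrame(rows)
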