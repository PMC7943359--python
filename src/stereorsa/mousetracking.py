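"""Mouse-trajectory preprocessing, maximum deviation, and subjective DMs.

In the two-choice categorization task, a face appears at the bottom-center
start button and the subject clicks one of two response options in the top
corners.  The trajectory's maximum perpendicular deviation (MD) toward the
opposite, unchosen option indexes how strongly the alternate category was
co-activated during perception.  Per-condition MD means become similarity
values toward each of the four response categories, and Pearson distances
between those 4-length vectors form the subject's subjective dissimilarity
matrix.

Standard coordinate space: start at (0, 0), response targets at (±1, 1.5)
(the convention of common mouse-tracking software).  After normalization
the chosen response is always mapped to the right target (+1, 1.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (CATEGORIES, CONDITIONS, DissimilarityMatrix, emotion_of,
                   gender_of, pearson_distance_matrix)

START = np.array([0.0, 0.0])
CHOSEN_TARGET = np.array([1.0, 1.5])
OPPOSITE_TARGET = np.array([-1.0, 1.5])

#: Perpendicular distance from the direct start→chosen line to the opposite
#: response location: the farthest meaningful deviation, used as max(MD).
MAX_MD = float(abs(CHOSEN_TARGET[0] * OPPOSITE_TARGET[1]
                   - CHOSEN_TARGET[1] * OPPOSITE_TARGET[0])
               / np.hypot(*CHOSEN_TARGET))

DEADLINE_MS = 2000.0


@dataclass
class TrialTrajectory:
    """One categorization trial with its raw sampled path."""

    subject_id: str
    block: str                 # "gender" or "emotion"
    condition: str             # one of CONDITIONS
    chosen_response: str       # "male"/"female"/"angry"/"happy"
    response_side: str         # "left" or "right"
    rt_ms: float
    t_ms: np.ndarray           # strictly increasing sample times
    xy: np.ndarray             # (n_samples, 2) path, starting at the start button
    correct: bool = True

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.t_ms.size < 3:
            raise ValueError("trajectory needs at least 3 samples")
        if np.any(np.diff(self.t_ms) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.xy.shape != (self.t_ms.size, 2):
            raise ValueError("path shape must be (n_samples, 2)")


@dataclass(frozen=True)
class NormalizedTrajectory:
    """Time-normalized path: origin at start, chosen response on the right."""

    coords: np.ndarray         # (n_bins + 1, 2)
    n_bins: int = 100


@dataclass(frozen=True)
class TrajectoryMetrics:
    md: float                  # signed, positive toward the opposite response
    md_norm: float             # clamp(md / max_md, 0, 1)
    max_md: float


# ---------------------------------------------------------------------------
# Trial exclusion

def exclude_trials(trials: pd.DataFrame,
                   deadline_ms: float = DEADLINE_MS) -> tuple[pd.DataFrame, dict]:
    """Drop timeout (rt > deadline) and incorrect trials.

    A trial at exactly the deadline is retained (the deadline must be
    *exceeded*).  Raises if any subject × condition cell is left empty.
    Returns the retained table plus a report of counts and fractions.
    """
    n = len(trials)
    timeout = trials["rt_ms"].to_numpy(dtype=float) > deadline_ms
    incorrect = ~trials["correct"].to_numpy(dtype=bool)
    keep = ~timeout & ~incorrect
    retained = trials.loc[keep]
    all_cells = set(map(tuple, trials[["subject", "condition"]].itertuples(index=False)))
    kept_cells = set(map(tuple, retained[["subject", "condition"]].itertuples(index=False)))
    empty = sorted(all_cells - kept_cells)
    if empty:
        subj, cond = empty[0]
        raise ValueError(
            f"all trials excluded for subject {subj!r}, condition {cond!r}")
    report = {
        "n_total": int(n),
        "n_timeout": int(timeout.sum()),
        "n_incorrect": int(incorrect.sum()),
        "n_retained": int(keep.sum()),
        "frac_timeout": float(timeout.mean()) if n else 0.0,
        "frac_incorrect": float(incorrect.mean()) if n else 0.0,
        "frac_retained": float(keep.mean()) if n else 0.0,
    }
    return retained.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# Normalization and maximum deviation

def normalize_trajectory(traj: TrialTrajectory, n_bins: int = 100) -> NormalizedTrajectory:
    """Translate start to the origin, mirror left responses to the right,
    and resample to ``n_bins + 1`` equally spaced time points by linear
    interpolation."""
    coords = _normalize_path(traj.t_ms, traj.xy, traj.response_side, n_bins)
    return NormalizedTrajectory(coords=coords, n_bins=n_bins)


def _normalize_path(t_ms: np.ndarray, xy: np.ndarray, side: str,
                    n_bins: int) -> np.ndarray:
    if xy.shape[0] < 2:
        raise ValueError("path needs at least 2 samples to interpolate")
    xy = xy - xy[0]
    grid = np.linspace(t_ms[0], t_ms[-1], n_bins + 1)
    x = np.interp(grid, t_ms, xy[:, 0])
    y = np.interp(grid, t_ms, xy[:, 1])
    if side == "left":
        x = -x
    elif side != "right":
        raise ValueError(f"unknown response side {side!r}")
    return np.column_stack([x, y])


def compute_md(ntraj: NormalizedTrajectory | np.ndarray) -> TrajectoryMetrics:
    """Maximum signed perpendicular deviation from the direct start→response
    line, positive toward the opposite (unchosen) response option.

    ``md_norm`` scales MD by the maximum possible MD (the perpendicular
    distance of the opposite response location from the direct line) and
    clamps to [0, 1] so deviations *away* from the opposite response
    contribute zero bias rather than negative similarity.
    """
    coords = ntraj.coords if isinstance(ntraj, NormalizedTrajectory) else np.asarray(ntraj)
    md = _signed_md(coords[None, :, :])[0]
    return TrajectoryMetrics(md=float(md),
                             md_norm=float(np.clip(md / MAX_MD, 0.0, 1.0)),
                             max_md=MAX_MD)


def _signed_md(coords: np.ndarray) -> np.ndarray:
    """Signed MD for a batch of normalized paths, shape (n_trials, n_pts, 2).

    MD is the signed perpendicular distance of the path point *farthest*
    from the direct line (largest absolute deviation), positive toward
    the opposite response — so a path bulging toward the chosen side has
    a negative MD rather than zero.
    """
    dx, dy = CHOSEN_TARGET
    norm = np.hypot(dx, dy)
    if norm == 0:
        raise ValueError("degenerate zero-length direct line")
    # cross-product sign: positive on the side of the opposite target
    cross = dx * coords[..., 1] - dy * coords[..., 0]
    opp_sign = np.sign(dx * OPPOSITE_TARGET[1] - dy * OPPOSITE_TARGET[0])
    dist = opp_sign * cross / norm
    dist = np.where(np.isnan(dist), 0.0, dist)
    idx = np.argmax(np.abs(dist), axis=-1)
    return np.take_along_axis(dist, idx[..., None], axis=-1)[..., 0]


def metrics_table(t_ms: np.ndarray, xy: np.ndarray, sides,
                  n_bins: int = 100) -> pd.DataFrame:
    """Vectorized MD for many trials at once.

    Parameters
    ----------
    t_ms : (n_trials, max_samples) sample times, NaN-padded on the right.
    xy : (n_trials, max_samples, 2) paths, NaN-padded to match.
    sides : length-n sequence of "left"/"right".

    Returns a DataFrame with columns ``md`` and ``md_norm``.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    xy = np.asarray(xy, dtype=float)
    n = t_ms.shape[0]
    coords = np.empty((n, n_bins + 1, 2))
    for i in range(n):
        m = ~np.isnan(t_ms[i])
        coords[i] = _normalize_path(t_ms[i, m], xy[i, m], sides[i], n_bins)
    md = _signed_md(coords)
    return pd.DataFrame({"md": md, "md_norm": np.clip(md / MAX_MD, 0.0, 1.0)})


# ---------------------------------------------------------------------------
# Bias vectors and dissimilarity matrices

def condition_bias_vector(mean_md_norm_by_block: dict[str, float],
                          condition: str) -> np.ndarray:
    """Similarity of one condition toward each response category.

    Within each block, the mean normalized deviation is the similarity
    toward the *unselected* response and its complement the similarity
    toward the *selected* response.  Assembled over (angry, happy, male,
    female).
    """
    for block in ("emotion", "gender"):
        if block not in mean_md_norm_by_block:
            raise ValueError(f"missing {block!r} block for condition {condition!r}")
    emo, gen = emotion_of(condition), gender_of(condition)
    other_emo = "happy" if emo == "angry" else "angry"
    other_gen = "female" if gen == "male" else "male"
    sim = dict.fromkeys(CATEGORIES, 0.0)
    sim[other_emo] = mean_md_norm_by_block["emotion"]
    sim[emo] = 1.0 - mean_md_norm_by_block["emotion"]
    sim[other_gen] = mean_md_norm_by_block["gender"]
    sim[gen] = 1.0 - mean_md_norm_by_block["gender"]
    return np.array([sim[c] for c in CATEGORIES])


def bias_vector_matrix(trials: pd.DataFrame) -> np.ndarray:
    """Per-condition bias vectors for one subject.

    ``trials`` must carry columns (block, condition, md_norm) for retained
    trials only.  Returns a (4 conditions × 4 categories) matrix in the
    shared orders.
    """
    mat = np.zeros((4, 4))
    for ci, cond in enumerate(CONDITIONS):
        sub = trials[trials["condition"] == cond]
        means = sub.groupby("block")["md_norm"].mean().to_dict()
        mat[ci] = condition_bias_vector(means, cond)
    return mat


def subjective_dm(bias_matrix: np.ndarray) -> DissimilarityMatrix:
    """Pearson distances (1 − r) between the four condition bias vectors."""
    return pearson_distance_matrix(np.asarray(bias_matrix, dtype=float))


def group_average_dm(bias_matrices: list[np.ndarray]) -> DissimilarityMatrix:
    """Mean-then-distance group DM: average subjects' bias vectors
    element-wise first, then compute Pearson distances on the averages."""
    if not bias_matrices:
        raise ValueError("need at least one subject")
    shapes = {np.asarray(m).shape for m in bias_matrices}
    if shapes != {(4, 4)}:
        raise ValueError(f"mismatched bias-vector shapes across subjects: {shapes}")
    mean = np.mean([np.asarray(m, dtype=float) for m in bias_matrices], axis=0)
    return pearson_distance_matrix(mean)


def subject_dms(trials: pd.DataFrame) -> tuple[dict, DissimilarityMatrix]:
    """Subjective DM per subject plus the group-average DM.

    ``trials``: retained trials with (subject, block, condition, md_norm).
    """
    mats, dms = [], {}
    for subj, grp in trials.groupby("subject", sort=True):
        mat = bias_vector_matrix(grp)
        mats.append(mat)
        dms[subj] = subjective_dm(mat)
    return dms, group_average_dm(mats)


# ---------------------------------------------------------------------------
# CSV interchange

def write_trajectories_csv(path, trials: pd.DataFrame, t_ms: np.ndarray,
                           xy: np.ndarray) -> None:
    """Long-format export: one row per path sample, trial metadata repeated."""
    rows = []
    for i, trial in trials.reset_index(drop=True).iterrows():
        m = ~np.isnan(t_ms[i])
        frame = pd.DataFrame({
            "t_ms": t_ms[i, m], "x": xy[i, m, 0], "y": xy[i, m, 1]})
        for col in ("subject", "block", "condition", "response",
                    "response_side", "rt_ms", "correct"):
            frame[col] = trial[col]
        frame["trial"] = i
        rows.append(frame)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_trajectories_csv(path) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Inverse of :func:`write_trajectories_csv`; returns (trials, t_ms, xy)
    with NaN-padded sample arrays."""
    long = pd.read_csv(path)
    meta_cols = ["subject", "block", "condition", "response",
                 "response_side", "rt_ms", "correct"]
    groups = list(long.groupby("trial", sort=True))
    max_len = max(len(g) for _, g in groups)
    t = np.full((len(groups), max_len), np.nan)
    xy = np.full((len(groups), max_len, 2), np.nan)
    meta = []
    for k, (_, g) in enumerate(groups):
        t[k, :len(g)] = g["t_ms"].to_numpy()
        xy[k, :len(g), 0] = g["x"].to_numpy()
        xy[k, :len(g), 1] = g["y"].to_numpy()
        meta.append(g.iloc[0][meta_cols])
    return pd.DataFrame(meta).reset_index(drop=True), t, xy
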