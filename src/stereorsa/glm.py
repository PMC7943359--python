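"""Boxcar × gamma-HRF GLM estimation of condition patterns.

Condition regressors are event boxcars (2000 ms, i.e. one TR) convolved
with a gamma-variate hemodynamic response function; ordinary least
squares per voxel yields betas and t statistics, and per-condition t maps
averaged over runs and z-normalized across in-mask voxels form the
multi-voxel patterns used by the representational analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CONDITIONS


@dataclass(frozen=True)
class HrfParams:
    """Gamma-variate HRF h(t) ∝ (t/(p·q))^p · exp(p − t/q).

    Defaults p = 8.6, q = 0.547 s are the de-facto defaults of this HRF
    family; the kernel peaks at t = p·q ≈ 4.7 s and is peak-normalized.
    """

    shape: float = 8.6        # p
    scale: float = 0.547      # q, seconds
    duration: float = 16.0    # kernel length, seconds

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0 or self.duration <= 0:
            raise ValueError("HRF parameters must be positive")


def gamma_hrf(params: HrfParams = HrfParams(), dt: float = 2.0) -> np.ndarray:
    """Sampled, peak-normalized gamma-variate kernel (h(0) = 0, h ≥ 0)."""
    p, q = params.shape, params.scale
    t = np.arange(0.0, params.duration + dt / 2, dt)
    with np.errstate(divide="ignore"):
        h = np.where(t > 0, np.exp(p * np.log(np.maximum(t, 1e-300) / (p * q))
                                   + p - t / q), 0.0)
    h[0] = 0.0
    peak = h.max()
    if peak <= 0:
        raise ValueError("kernel is identically zero; increase duration or dt")
    return h / peak


@dataclass
class DesignMatrix:
    matrix: np.ndarray          # (n_vols, n_regressors)
    names: list[str]
    tr: float

    @property
    def condition_columns(self) -> list[int]:
        return [i for i, n in enumerate(self.names) if n in CONDITIONS
                or n in ("angry", "happy", "male", "female")]


def build_design(schedule: pd.DataFrame,
                 n_vols: int,
                 tr: float = 2.0,
                 hrf: HrfParams = HrfParams(),
                 nuisance: np.ndarray | None = None,
                 scheme: str = "crossed",
                 oversample: int = 20) -> DesignMatrix:
    """Convolved design matrix for one run.

    ``scheme='crossed'`` gives one regressor per sex × emotion cell;
    ``scheme='categories'`` gives the four non-crossed regressors (angry,
    happy, male, female), each event loading on its emotion and its
    gender regressor.  Events are modeled as boxcars over their duration
    on an oversampled grid, convolved with the gamma HRF and sampled at
    volume acquisition times.  Null events contribute nothing.
    """
    if scheme == "crossed":
        names = list(CONDITIONS)
        loadings = {c: [c] for c in CONDITIONS}
    elif scheme == "categories":
        names = ["angry", "happy", "male", "female"]
        loadings = {c: c.split("_") for c in CONDITIONS}
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    dt = tr / oversample
    n_fine = n_vols * oversample + 1
    fine = np.zeros((n_fine, len(names)))
    duration_limit = n_vols * tr
    for _, ev in schedule.iterrows():
        if ev["condition"] == "null":
            continue
        if ev["onset"] < 0 or ev["onset"] + ev["duration"] > duration_limit + 1e-9:
            raise ValueError(
                f"event at onset {ev['onset']} s falls outside the scan")
        a = int(round(ev["onset"] / dt))
        b = int(round((ev["onset"] + ev["duration"]) / dt))
        for name in loadings[ev["condition"]]:
            fine[a:b, names.index(name)] += 1.0
    kernel = gamma_hrf(hrf, dt)
    conv = np.stack([np.convolve(fine[:, k], kernel)[:n_fine]
                     for k in range(len(names))], axis=1)
    vol_idx = (np.arange(n_vols) * oversample).astype(int)
    cols = [conv[vol_idx]]
    if nuisance is not None:
        nuisance = np.asarray(nuisance, dtype=float)
        if nuisance.shape[0] != n_vols:
            raise ValueError("nuisance rows must match the volume count")
        cols.append(nuisance)
        names = names + [f"nuisance_{i}" for i in range(nuisance.shape[1])]
    return DesignMatrix(matrix=np.hstack(cols), names=names, tr=tr)


def fit_glm(bold: np.ndarray, design: DesignMatrix,
            add_intercept: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel OLS betas and t statistics.

    ``bold`` is (n_vols, n_voxels).  Returns (betas, t) each shaped
    (n_regressors, n_voxels), rows ordered as ``design.names`` (the
    intercept, if added, is excluded from the outputs).
    """
    y = np.asarray(bold, dtype=float)
    x = design.matrix
    if add_intercept:
        x = np.column_stack([x, np.ones(x.shape[0])])
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("design matrix is rank deficient")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    k = len(design.names)
    return beta[:k], t[:k]


@dataclass
class VoxelPatternSet:
    """Condition × voxel matrix of z-normalized statistics within a mask."""

    data: np.ndarray                       # (4, n_voxels)
    labels: tuple[str, ...] = field(default=CONDITIONS)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise ValueError("expected a condition x voxel matrix")


def condition_patterns(run_t_maps: list[np.ndarray],
                       mask: np.ndarray | None = None) -> VoxelPatternSet:
    """Average per-condition t maps over runs, then z-normalize each
    condition across in-mask voxels (population SD, divide by n)."""
    if not run_t_maps:
        raise ValueError("need at least one run")
    shapes = {np.asarray(m).shape for m in run_t_maps}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent map shapes across runs: {shapes}")
    mean = np.mean([np.asarray(m, dtype=float) for m in run_t_maps], axis=0)
    if mask is not None:
        mean = mean[:, np.asarray(mask, dtype=bool)]
    mu = mean.mean(axis=1, keepdims=True)
    sd = mean.std(axis=1, keepdims=True)     # population SD
    if np.any(sd == 0):
        raise ValueError("constant condition map: z-normalization undefined")
    return VoxelPatternSet((mean - mu) / sd)
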