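"""Psychophysiological interaction (PPI) analysis and the link between
connectivity disruption and representational disruption.

The seed region's mean BOLD series is deconvolved against the gamma HRF
(ridge-regularized inversion of the convolution matrix) to estimate the
underlying neural series; the PPI interaction regressor is the neural
series multiplied by the psychological condition (masked = −1,
unmasked = +1, constant within a run) and reconvolved with the HRF.  A
three-predictor GLM — seed time course, condition, interaction (plus
intercept) — is fit to each target; the interaction beta is the
statistic of record.  Across subjects, the interaction beta is
correlated (one-tailed Pearson, positive hypothesis) with the
[unmasked − masked] RSA-beta difference to test whether connectivity
disruption predicts representational disruption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.linalg import solve, toeplitz

from .glm import HrfParams, gamma_hrf
from .rsa import GroupTest, group_test

DEFAULT_RIDGE = 1e-3


@dataclass
class PpiDesign:
    """Predictors of interest: seed BOLD, condition code, interaction."""

    seed: np.ndarray
    condition: np.ndarray
    interaction: np.ndarray

    @property
    def matrix(self) -> np.ndarray:
        return np.column_stack([np.ones(self.seed.size), self.seed,
                                self.condition, self.interaction])


@dataclass
class PpiFit:
    beta_seed: np.ndarray | float
    beta_condition: np.ndarray | float
    beta_interaction: np.ndarray | float   # the statistic of record


@dataclass(frozen=True)
class LinkResult:
    r: float
    p_one_tailed: float
    n: int


def seed_timecourse(bold: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Volume-wise mean BOLD over in-mask voxels.

    ``bold`` may be (n_vols, n_voxels) with a 1-D mask or a 4-D array
    (x, y, z, t) with a 3-D mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty seed mask")
    bold = np.asarray(bold, dtype=float)
    if bold.ndim == 2:
        return bold[:, mask].mean(axis=1)
    if bold.ndim == 4:
        return bold[mask].mean(axis=0)
    raise ValueError("bold must be 2-D (time x voxel) or 4-D (x, y, z, t)")


def _conv_matrix(kernel: np.ndarray, n: int) -> np.ndarray:
    col = np.zeros(n)
    k = min(kernel.size, n)
    col[:k] = kernel[:k]
    return toeplitz(col, np.zeros(n))


def deconvolve(series: np.ndarray, kernel: np.ndarray,
               ridge: float = DEFAULT_RIDGE) -> np.ndarray:
    """Estimate the neural series whose convolution with ``kernel``
    produced ``series``.

    Solves (AᵀA + λ·(tr(AᵀA)/n)·I) x = Aᵀ y, a trace-normalized ridge
    inversion of the convolution matrix A; λ→0 recovers exact
    deconvolution on noiseless input, λ>0 keeps the estimate bounded on
    noisy input.
    """
    y = np.asarray(series, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if not np.any(kernel):
        raise ValueError("all-zero kernel cannot be deconvolved")
    if kernel.size >= y.size:
        raise ValueError("kernel must be shorter than the series")
    a = _conv_matrix(kernel, y.size)
    ata = a.T @ a
    lam = ridge * np.trace(ata) / y.size
    return solve(ata + lam * np.eye(y.size), a.T @ y, assume_a="pos")


def reconvolve(neural: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return np.convolve(neural, kernel)[:neural.size]


def build_ppi_design(seed_bold: np.ndarray,
                     condition: np.ndarray,
                     hrf: HrfParams = HrfParams(),
                     tr: float = 2.0,
                     ridge: float = DEFAULT_RIDGE,
                     run: np.ndarray | None = None,
                     level: str = "neural") -> PpiDesign:
    """Assemble the three PPI predictors.

    ``condition`` is the volume-resolution psychological regressor coded
    masked = −1 / unmasked = +1.  With ``level='neural'`` (default) the
    interaction is formed on the deconvolved seed and reconvolved with
    the HRF; ``level='bold'`` multiplies at the BOLD level directly.
    Deconvolution and reconvolution respect run boundaries when ``run``
    labels are given.
    """
    seed_bold = np.asarray(seed_bold, dtype=float)
    condition = np.asarray(condition, dtype=float)
    levels = set(np.unique(condition))
    if not levels <= {-1.0, 1.0}:
        raise ValueError("condition must be coded -1 (masked) / +1 (unmasked)")
    if len(levels) < 2:
        raise ValueError("condition is constant: interaction would be "
                         "collinear with the seed time course")
    kernel = gamma_hrf(hrf, tr)
    if level == "bold":
        interaction = seed_bold * condition
    elif level == "neural":
        segments = ([np.ones_like(seed_bold)] if run is None
                    else [run == r for r in np.unique(run)])
        interaction = np.empty_like(seed_bold)
        for seg in segments:
            m = np.asarray(seg, dtype=bool)
            neural = deconvolve(seed_bold[m], kernel, ridge)
            interaction[m] = reconvolve(neural * condition[m], kernel)
    else:
        raise ValueError(f"unknown level {level!r}")
    return PpiDesign(seed=seed_bold, condition=condition,
                     interaction=interaction)


def fit_ppi(target, design: PpiDesign) -> PpiFit:
    """Least-squares fit of the PPI model to one target series or to a
    (n_vols, n_voxels) matrix of targets."""
    y = np.asarray(target, dtype=float)
    x = design.matrix
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient PPI design")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    squeeze = y.ndim == 1
    out = [b if not squeeze else float(b) for b in beta[1:4]]
    return PpiFit(beta_seed=out[0], beta_condition=out[1],
                  beta_interaction=out[2])


def group_ppi_test(interaction_betas) -> GroupTest:
    """One-sample t test of per-subject interaction betas against 0."""
    return group_test(interaction_betas, transform="none")


def link_connectivity_representation(ppi_betas, rsa_diffs) -> LinkResult:
    """Pearson correlation of per-subject PPI interaction betas with the
    per-subject [unmasked − masked] RSA-beta difference; one-tailed p for
    the directional hypothesis r > 0."""
    a = np.asarray(ppi_betas, dtype=float)
    b = np.asarray(rsa_diffs, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need >= 3 paired subjects")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(a, b, alternative="greater")
    return LinkResult(r=float(res.statistic), p_one_tailed=float(res.pvalue),
                      n=a.size)


def threshold_clusters(t_map: np.ndarray, t_threshold: float,
                       min_extent: int = 20) -> np.ndarray:
    """Liberal-threshold seed definition: voxels with t above threshold
    belonging to 6-connected clusters of at least ``min_extent`` voxels."""
    above = np.asarray(t_map) > t_threshold
    structure = ndimage.generate_binary_structure(above.ndim, 1)  # faces only
    labels, n = ndimage.label(above, structure=structure)
    keep = np.zeros_like(above, dtype=bool)
    for lab in range(1, n + 1):
        m = labels == lab
        if m.sum() >= min_extent:
            keep |= m
    return keep
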