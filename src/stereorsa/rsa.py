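"""ROI-level representational similarity analysis.

Neural DMs are Pearson distances between condition patterns over the
voxels of a region.  DMs are compared after vectorization (shared
lower-triangle pair order) by Spearman rank correlation — no linearity
assumed — or, when a covariate DM must be adjusted for (the
group-average subjective DM), by multiple-regression RSA on
rank-transformed pair vectors.  Group inference is a one-sample t test
on Fisher-z-transformed rhos or raw betas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import DissimilarityMatrix, pearson_distance_matrix


@dataclass(frozen=True)
class RsaResult:
    rho: float
    fisher_z: float
    n_pairs: int
    beta: float | None = None   # rank-regression coefficient, when computed


@dataclass(frozen=True)
class GroupTest:
    mean: float
    t: float
    df: int
    p: float
    two_sided: bool = True


def neural_dm(patterns: np.ndarray,
              mask: np.ndarray | None = None) -> DissimilarityMatrix:
    """1 − Pearson r between condition patterns over (in-mask) voxels."""
    patterns = np.asarray(patterns, dtype=float)
    if mask is not None:
        patterns = patterns[:, np.asarray(mask, dtype=bool)]
    if patterns.shape[1] < 2:
        raise ValueError("need at least 2 voxels to form a neural DM")
    return pearson_distance_matrix(patterns)


def vectorize_dm(dm: DissimilarityMatrix) -> np.ndarray:
    """Six condition-pair distances in the shared lower-triangle order."""
    return dm.vectorize()


def _pair_vector(dm) -> np.ndarray:
    if isinstance(dm, DissimilarityMatrix):
        return dm.vectorize()
    v = np.asarray(dm, dtype=float)
    if v.shape != (6,):
        raise ValueError("expected a DissimilarityMatrix or 6-length pair vector")
    return v


def spearman_rsa(dm_a, dm_b) -> RsaResult:
    """Spearman rank correlation between two DMs' pair vectors
    (average-rank tie handling)."""
    a, b = _pair_vector(dm_a), _pair_vector(dm_b)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant pair vector: rank correlation undefined")
    rho = float(stats.spearmanr(a, b).statistic)
    z = float(np.arctanh(np.clip(rho, -1 + 1e-12, 1 - 1e-12)))
    return RsaResult(rho=rho, fisher_z=z, n_pairs=a.size)


def regression_rsa(neural, predictor, covariates=()) -> float:
    """Rank-regression coefficient of the predictor DM.

    All pair vectors are rank-transformed (average ranks), then the
    neural vector is regressed on [intercept, predictor, covariates] by
    least squares; the predictor's coefficient is returned.  Raises on
    rank-deficient (collinear) designs.
    """
    y = stats.rankdata(_pair_vector(neural))
    cols = [stats.rankdata(_pair_vector(predictor))]
    cols += [stats.rankdata(_pair_vector(c)) for c in covariates]
    x = np.column_stack([np.ones(y.size)] + cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("collinear predictors after rank transform")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return float(beta[1])


def group_test(values, transform: str = "none") -> GroupTest:
    """One-sample t test of per-subject statistics against 0.

    ``transform='fisher_z'`` applies atanh first (for correlations).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 subjects")
    if transform == "fisher_z":
        values = np.arctanh(np.clip(values, -1 + 1e-12, 1 - 1e-12))
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    if np.all(values == values[0]):
        raise ValueError("zero variance across subjects: t undefined")
    res = stats.ttest_1samp(values, 0.0)
    return GroupTest(mean=float(values.mean()), t=float(res.statistic),
                     df=values.size - 1, p=float(res.pvalue))


def paired_contrast(values_a, values_b) -> GroupTest:
    """Paired t test (a − b) across subjects.

    Identical samples give the degenerate-but-unambiguous t = 0; a
    constant *nonzero* difference has zero variance and raises.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if np.all(a == b):
        return GroupTest(mean=0.0, t=0.0, df=a.size - 1, p=1.0)
    return group_test(a - b)
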