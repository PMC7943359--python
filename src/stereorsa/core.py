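"""Shared condition labels and the dissimilarity-matrix container.

The experimental design crosses face sex and emotion into four stimulus
conditions.  All modules index conditions and response categories in the
fixed orders below, and all dissimilarity matrices (DMs) — subjective,
neural, model, group-average — share one container with one vectorization
convention, so DMs from any stage can be compared pair-for-pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed condition order used by every 4x4 matrix in the package.
CONDITIONS: tuple[str, ...] = (
    "angry_male", "happy_male", "angry_female", "happy_female",
)

#: Fixed response-category order used by bias vectors (similarity axes).
CATEGORIES: tuple[str, ...] = ("angry", "happy", "male", "female")

#: Stereotype-congruent condition pair (male+angry / female+happy).
CONGRUENT = ("angry_male", "happy_female")
#: Stereotype-incongruent condition pair.
INCONGRUENT = ("angry_female", "happy_male")

#: Lower-triangle (row-major) pair order shared by every vectorized DM:
#: (i, j) with i > j, rows scanned top to bottom.
PAIR_INDEX: tuple[tuple[int, int], ...] = (
    (1, 0), (2, 0), (2, 1), (3, 0), (3, 1), (3, 2),
)


def condition_of(emotion: str, gender: str) -> str:
    return f"{emotion}_{gender}"


def emotion_of(condition: str) -> str:
    return condition.split("_")[0]


def gender_of(condition: str) -> str:
    return condition.split("_")[1]


def is_incongruent(condition: str) -> bool:
    """True for the stereotype-incongruent cells (angry female, happy male)."""
    return condition in INCONGRUENT


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric 4x4 Pearson-distance (1 − r) matrix over the conditions.

    Invariants enforced at construction: symmetry, zero diagonal and
    entries in [0, 2] (the range of 1 − r).
    """

    values: np.ndarray
    labels: tuple[str, ...] = field(default=CONDITIONS)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n = len(self.labels)
        if vals.shape != (n, n):
            raise ValueError(f"expected {(n, n)} matrix, got {vals.shape}")
        if not np.allclose(vals, vals.T, atol=1e-10):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(vals), 0.0, atol=1e-10):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if vals.min() < -1e-10 or vals.max() > 2 + 1e-10:
            raise ValueError("Pearson distances must lie in [0, 2]")

    def vectorize(self) -> np.ndarray:
        """Lower-triangle pair vector in the shared ``PAIR_INDEX`` order."""
        return np.array([self.values[i, j] for i, j in PAIR_INDEX])

    @classmethod
    def from_vector(cls, pairs: np.ndarray,
                    labels: tuple[str, ...] = CONDITIONS) -> "DissimilarityMatrix":
        pairs = np.asarray(pairs, dtype=float)
        if pairs.shape != (len(PAIR_INDEX),):
            raise ValueError("expected a 6-length pair vector")
        vals = np.zeros((4, 4))
        for (i, j), v in zip(PAIR_INDEX, pairs):
            vals[i, j] = vals[j, i] = v
        return cls(vals, labels)

    def get(self, cond_a: str, cond_b: str) -> float:
        i, j = self.labels.index(cond_a), self.labels.index(cond_b)
        return float(self.values[i, j])

    def to_correlation(self) -> np.ndarray:
        """Return the implied correlation matrix C = 1 − DM with unit diagonal."""
        c = 1.0 - self.values
        np.fill_diagonal(c, 1.0)
        return c

    def blend(self, other: "DissimilarityMatrix", weight: float) -> "DissimilarityMatrix":
        """Convex mixture ``weight*self + (1-weight)*other`` (stays a valid DM)."""
        if not 0.0 <= weight <= 1.0:
            raise ValueError("blend weight must be in [0, 1]")
        return DissimilarityMatrix(
            weight * self.values + (1.0 - weight) * other.values, self.labels
        )


def pearson_distance_matrix(vectors: np.ndarray,
                            labels: tuple[str, ...] = CONDITIONS) -> DissimilarityMatrix:
    """1 − Pearson r between the rows of ``vectors`` (condition × feature).

    Raises if any row has zero variance (its correlation is undefined).
    """
    vectors = np.asarray(vectors, dtype=float)
    sd = vectors.std(axis=1)
    if np.any(sd == 0):
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance vector(s) for {bad}: correlation undefined")
    r = np.corrcoef(vectors)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return DissimilarityMatrix(d, labels)
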