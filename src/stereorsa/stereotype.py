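"""Stereotype-strength score and the stereotype-congruency model DM.

Subjects rate how well each of 30 descriptors fits the categories angry,
happy, male and female (1–7 Likert).  The stereotype-strength score is
built from the Pearson correlations between the four 30-length rating
vectors: congruent pairings (angry–male, happy–female) minus incongruent
pairings (angry–female, happy–male), normalized so the score spans
[−2, 2] — 2 means a fully stereotypical association (male = angry,
female = happy), 0 no association, −2 fully counterstereotypical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CATEGORIES, CONDITIONS, DissimilarityMatrix

#: Category pairs entering the score, in reporting order.
SCORE_PAIRS = (("angry", "male"), ("happy", "female"),
               ("angry", "female"), ("happy", "male"))


@dataclass(frozen=True)
class StereotypeScore:
    """Score plus the four pairwise correlations it is built from."""

    score: float
    components: dict[str, float]  # keys like "r_angry_male"


def _as_rating_matrix(ratings) -> np.ndarray:
    """Coerce ratings to a 4 × n_descriptors array in CATEGORIES order.

    Accepts a 2-D array (rows already in CATEGORIES order) or a DataFrame
    with columns (category, descriptor, rating).
    """
    if isinstance(ratings, pd.DataFrame):
        wide = ratings.pivot_table(index="category", columns="descriptor",
                                   values="rating", sort=True)
        missing = set(CATEGORIES) - set(wide.index)
        if missing:
            raise ValueError(f"ratings missing categories: {sorted(missing)}")
        return wide.loc[list(CATEGORIES)].to_numpy(dtype=float)
    arr = np.asarray(ratings, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != 4:
        raise ValueError("expected a 4 x n_descriptors rating matrix")
    return arr


def category_correlations(ratings) -> dict[str, float]:
    """Pearson r between every pair of the four category rating vectors."""
    mat = _as_rating_matrix(ratings)
    sd = mat.std(axis=1)
    if np.any(sd == 0):
        bad = [CATEGORIES[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance rating vector for category {bad}")
    r = np.corrcoef(mat)
    out: dict[str, float] = {}
    for i, a in enumerate(CATEGORIES):
        for j in range(i + 1, 4):
            out[f"r_{a}_{CATEGORIES[j]}"] = float(r[i, j])
    return out


def stereotype_score(ratings, halved: bool = True) -> StereotypeScore:
    """Congruent-pair minus incongruent-pair correlation score.

    score = ([r(angry,male) + r(happy,female)]
             − [r(angry,female) + r(happy,male)]) / 2

    The raw difference of correlation sums spans [−4, 4]; the published
    scale spans [−2, 2], so the default divides by 2.  Pass
    ``halved=False`` for the raw sum.
    """
    corr = category_correlations(ratings)
    comp = {f"r_{a}_{b}": corr[f"r_{a}_{b}"] if f"r_{a}_{b}" in corr
            else corr[f"r_{b}_{a}"] for a, b in SCORE_PAIRS}
    raw = (comp["r_angry_male"] + comp["r_happy_female"]
           - comp["r_angry_female"] - comp["r_happy_male"])
    return StereotypeScore(score=raw / 2.0 if halved else raw, components=comp)


def scores_table(ratings_df: pd.DataFrame, halved: bool = True) -> pd.DataFrame:
    """Per-subject scores from a long ratings table.

    Expects columns (subject, category, descriptor, rating); returns one
    row per subject with the score and its four component correlations.
    """
    rows = []
    for subject, grp in ratings_df.groupby("subject", sort=True):
        res = stereotype_score(grp, halved=halved)
        rows.append({"subject": subject, "score": res.score, **res.components})
    return pd.DataFrame(rows)


def congruency_dm() -> DissimilarityMatrix:
    """The two-level stereotype-congruency model DM.

    Hypothesized Pearson distances: 1 between the congruent pair
    (angry male ↔ happy female), 2 between the incongruent pair
    (angry female ↔ happy male).  The four pairs the hypothesis is
    silent about (within-sex and within-emotion) sit at the midpoint 1.5.
    """
    vals = np.full((4, 4), 1.5)
    np.fill_diagonal(vals, 0.0)
    idx = {c: i for i, c in enumerate(CONDITIONS)}
    vals[idx["angry_male"], idx["happy_female"]] = 1.0
    vals[idx["happy_female"], idx["angry_male"]] = 1.0
    vals[idx["angry_female"], idx["happy_male"]] = 2.0
    vals[idx["happy_male"], idx["angry_female"]] = 2.0
    return DissimilarityMatrix(vals)


def congruency_pair_mask() -> np.ndarray:
    """Boolean mask over the shared pair order selecting only the two
    hypothesis-bearing pairs (for analyses excluding the neutral cells)."""
    dm = congruency_dm()
    vec = dm.vectorize()
    return vec != 1.5
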