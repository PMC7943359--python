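"""Masked gender-discrimination responses under a signal-detection model.

After scanning, subjects categorize each masked face's gender once.  The
generator plants a per-subject sensitivity d′ (near chance for effective
masking) with an unbiased criterion: P(respond male | male) = Φ(d′/2),
P(respond male | female) = Φ(−d′/2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from ..core import CONDITIONS, gender_of


def gen_discrimination(n_subjects: int,
                       n_faces_per_cell: int = 35,
                       dprime_mean: float = 0.22,
                       dprime_sd: float = 0.3,
                       seed: int | np.random.Generator = 0
                       ) -> tuple[pd.DataFrame, np.ndarray]:
    """One response per face per subject; returns (long table, planted d′).

    Columns: subject, condition, gender, response ("male"/"female").
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    planted = rng.normal(dprime_mean, dprime_sd, n_subjects)
    rows = []
    for s in range(n_subjects):
        p_male = {"male": norm.cdf(planted[s] / 2.0),
                  "female": norm.cdf(-planted[s] / 2.0)}
        for cond in CONDITIONS:
            g = gender_of(cond)
            resp_male = rng.random(n_faces_per_cell) < p_male[g]
            for rm in resp_male:
                rows.append({"subject": s, "condition": cond, "gender": g,
                             "response": "male" if rm else "female"})
    return pd.DataFrame(rows), planted
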