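"""Multi-level MD regression and signal-detection analysis.

The deviation model regresses trial-level maximum deviation onto face
gender (male = −0.5, female = +0.5), face emotion (angry = −0.5,
happy = +0.5), the subject's mean-centered stereotype score, and all
their interactions, with subjects as clusters: a marginal (GEE) model
with an exchangeable working correlation and robust sandwich standard
errors.  Unstandardized coefficients (B) and Wald Z are reported.

The masked discrimination task is scored with d′ = z(hits) − z(false
alarms), male faces arbitrarily defined as signal, with the log-linear
(add 0.5 / add 1) correction so extreme rates stay finite; subjects
whose |d′| reaches the chance band ±1.74 are flagged for exclusion
(masking failed for them).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
import statsmodels.api as sm

from .core import emotion_of, gender_of

GENDER_CODE = {"male": -0.5, "female": 0.5}
EMOTION_CODE = {"angry": -0.5, "happy": 0.5}
CHANCE_BAND = 1.74

MD_MODEL_TERMS = ["intercept", "gender", "emotion", "stereotype",
                  "gender:emotion", "gender:stereotype",
                  "emotion:stereotype", "gender:emotion:stereotype"]


@dataclass
class GeeFit:
    """Coefficient table plus what simple-slope contrasts need."""

    coefficients: pd.DataFrame    # index: terms; columns B, SE, Z, ci_low, ci_high, p
    cov_params: np.ndarray        # robust covariance of the coefficients
    stereotype_mean: float        # centering constant used in the design
    stereotype_sd: float

    def term(self, name: str) -> pd.Series:
        return self.coefficients.loc[name]


def _md_design(df: pd.DataFrame, center: float) -> np.ndarray:
    g = df["gender_code"].to_numpy()
    e = df["emotion_code"].to_numpy()
    s = df["stereotype"].to_numpy() - center
    return np.column_stack([np.ones(len(df)), g, e, s, g * e, g * s, e * s,
                            g * e * s])


def fit_md_model(trials: pd.DataFrame, value_col: str = "md") -> GeeFit:
    """Fit the deviation model on a trial table.

    ``trials`` needs columns (subject, condition, stereotype) and the
    outcome ``value_col``; gender/emotion codes are derived from the
    condition label.  Requires ≥2 subjects and both levels of each
    factor.
    """
    df = trials.copy()
    df["gender_code"] = [GENDER_CODE[gender_of(c)] for c in df["condition"]]
    df["emotion_code"] = [EMOTION_CODE[emotion_of(c)] for c in df["condition"]]
    if df["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    if df["gender_code"].nunique() < 2 or df["emotion_code"].nunique() < 2:
        raise ValueError("both levels of gender and emotion must be present")
    center = float(df["stereotype"].mean())
    x = _md_design(df, center)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("singular design: a model term is not identified")
    model = sm.GEE(df[value_col].to_numpy(), x, groups=df["subject"].to_numpy(),
                   cov_struct=sm.cov_struct.Exchangeable())
    res = model.fit()            # robust (sandwich) covariance is the default
    b, se = res.params, res.bse
    z = b / se
    table = pd.DataFrame({
        "B": b, "SE": se, "Z": z,
        "ci_low": b - 1.96 * se, "ci_high": b + 1.96 * se,
        "p": 2 * norm.sf(np.abs(z)),
    }, index=MD_MODEL_TERMS)
    per_subject_s = df.groupby("subject")["stereotype"].first()
    return GeeFit(coefficients=table, cov_params=np.asarray(res.cov_params()),
                  stereotype_mean=center,
                  stereotype_sd=float(per_subject_s.std(ddof=1)))


def simple_slopes(fit: GeeFit, sd: float | None = None) -> pd.DataFrame:
    """Gender × emotion interaction at stereotype = ±1 SD.

    Computed as the linear contrast B_ge + B_ges·(±SD) with its sandwich
    variance — algebraically identical to recentring and refitting.
    """
    sd = fit.stereotype_sd if sd is None else sd
    if not sd > 0:
        raise ValueError("stereotype scores have zero variance")
    i_ge = MD_MODEL_TERMS.index("gender:emotion")
    i_ges = MD_MODEL_TERMS.index("gender:emotion:stereotype")
    rows = []
    for label, level in (("+1 SD", sd), ("-1 SD", -sd)):
        contrast = np.zeros(len(MD_MODEL_TERMS))
        contrast[i_ge] = 1.0
        contrast[i_ges] = level
        b = float(contrast @ fit.coefficients["B"].to_numpy())
        se = float(np.sqrt(contrast @ fit.cov_params @ contrast))
        z = b / se
        rows.append({"level": label, "B": b, "SE": se, "Z": z,
                     "ci_low": b - 1.96 * se, "ci_high": b + 1.96 * se,
                     "p": 2 * norm.sf(abs(z))})
    return pd.DataFrame(rows).set_index("level")


@dataclass(frozen=True)
class SignalDetectionResult:
    hits: float            # corrected P(respond male | male face)
    false_alarms: float    # corrected P(respond male | female face)
    d_prime: float
    chance_band: float
    excluded: bool         # |d'| reached the chance band: masking failed


def dprime(responses: pd.DataFrame,
           chance_band: float = CHANCE_BAND) -> SignalDetectionResult:
    """Sensitivity for one subject's discrimination table.

    ``responses`` needs columns (gender, response) with values
    "male"/"female".  Rates use the log-linear correction (0.5 added to
    each count, 1 to each total) before the normal-quantile transform.
    """
    male = responses[responses["gender"] == "male"]
    female = responses[responses["gender"] == "female"]
    if len(male) == 0 or len(female) == 0:
        raise ValueError("need trials of both genders to compute d'")
    hit = (np.sum(male["response"] == "male") + 0.5) / (len(male) + 1)
    fa = (np.sum(female["response"] == "male") + 0.5) / (len(female) + 1)
    d = float(norm.ppf(hit) - norm.ppf(fa))
    return SignalDetectionResult(hits=float(hit), false_alarms=float(fa),
                                 d_prime=d, chance_band=chance_band,
                                 excluded=bool(abs(d) >= chance_band))


def dprime_table(responses: pd.DataFrame,
                 chance_band: float = CHANCE_BAND) -> pd.DataFrame:
    """Per-subject d′ summary with exclusion flags."""
    rows = []
    for subj, grp in responses.groupby("subject", sort=True):
        r = dprime(grp, chance_band)
        rows.append({"subject": subj, "hits": r.hits,
                     "false_alarms": r.false_alarms, "d_prime": r.d_prime,
                     "excluded": r.excluded})
    return pd.DataFrame(rows)
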