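"""Syndromic LRTI case definition and admission clinical scores.

The case definition classifies a patient as a suspected LRTI case from
presenting symptoms alone: cough plus fever, or at least three of nine
listed symptoms (cough, fever, breathlessness, wheeze, pleurisy, abnormal
sputum production, myalgia, headache, general deterioration). Confusion and
falls are recorded as presenting symptoms but never contribute to the
definition.

Clinical scores:

* CRB — pneumonia severity: one point each for acute confusion (AMTS <= 7),
  raised respiratory rate (>= 30/min) and low blood pressure (systolic
  < 90 mmHg or diastolic <= 60 mmHg). No age point: age is the exposure
  under study, so the age-65 point of CRB-65 is deliberately omitted.
* Modified Charlson Comorbidity Index categories 0 / 1-2 / 3-4 / >4,
  computed on a CCI that excludes age and dementia points.
* Frailty flag — Rockwood clinical frailty scale > 4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .base import BaseEstimator
from .errors import ValidationError

#: All eleven presenting-symptom indicators, in canonical column order.
SYMPTOMS = (
    "cough",
    "fever",
    "breathlessness",
    "wheeze",
    "pleurisy",
    "sputum",
    "myalgia",
    "headache",
    "general_deterioration",
    "confusion",
    "falls",
)

#: The nine symptoms that can contribute to the case definition.
DEFINITION_SYMPTOMS = SYMPTOMS[:9]

CCI_CATEGORIES = ("0", "1-2", "3-4", ">4")


@dataclass(frozen=True)
class SymptomVector:
    """Eleven binary presenting-symptom indicators (absence coded 0)."""

    cough: bool = False
    fever: bool = False
    breathlessness: bool = False
    wheeze: bool = False
    pleurisy: bool = False
    sputum: bool = False
    myalgia: bool = False
    headache: bool = False
    general_deterioration: bool = False
    confusion: bool = False
    falls: bool = False

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v not in (0, 1, True, False):
                raise ValidationError(f"symptom {f.name!r} must be binary, got {v!r}")
            object.__setattr__(self, f.name, bool(v))

    @classmethod
    def from_mapping(cls, m: Mapping[str, object]) -> "SymptomVector":
        return cls(**{s: bool(m[s]) for s in SYMPTOMS if s in m})

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SYMPTOMS], dtype=int)


@dataclass(frozen=True)
class CrbInputs:
    """Raw admission observations from which the CRB score is computed."""

    amts: Optional[int] = None
    resp_rate: Optional[float] = None
    sbp: Optional[float] = None
    dbp: Optional[float] = None

    def __post_init__(self):
        if self.amts is not None and not 0 <= self.amts <= 10:
            raise ValidationError(f"AMTS must be in [0, 10], got {self.amts}")


def meets_syndromic_definition(s: SymptomVector) -> bool:
    """True iff (cough and fever) or >=3 of the nine definition symptoms."""
    if s.cough and s.fever:
        return True
    return sum(getattr(s, name) for name in DEFINITION_SYMPTOMS) >= 3


def fever_from_raw(
    reported_fever_chills: bool, temperature_c: Optional[float] = None
) -> bool:
    """Compose the fever indicator: reported fever/chills, or T > 38.0 or < 35.0 C.

    Both temperature bounds follow the definition exactly: 38.0 C itself is
    not fever, 34.9 C is.
    """
    if temperature_c is not None:
        if math.isnan(temperature_c):
            temperature_c = None
        elif not 25.0 <= temperature_c <= 45.0:
            raise ValidationError(
                f"implausible temperature {temperature_c!r} C (expected 25-45)"
            )
    if bool(reported_fever_chills):
        return True
    if temperature_c is None:
        return False
    return temperature_c > 38.0 or temperature_c < 35.0


def general_deterioration_from_raw(
    weakness: bool = False, fatigue: bool = False, anorexia: bool = False
) -> bool:
    """OR-compose the single general-deterioration indicator from raw fields."""
    return bool(weakness) or bool(fatigue) or bool(anorexia)


def crb_score(c: CrbInputs) -> Optional[int]:
    """CRB severity score in {0,1,2,3}; None when any component is missing.

    Complete-case rule: the score is undefined unless AMTS, respiratory rate
    and both blood pressures were recorded.
    """
    parts = (c.amts, c.resp_rate, c.sbp, c.dbp)
    if any(p is None or (isinstance(p, float) and math.isnan(p)) for p in parts):
        return None
    return int(c.amts <= 7) + int(c.resp_rate >= 30) + int(c.sbp < 90 or c.dbp <= 60)


def cci_category(score: Optional[int]) -> Optional[str]:
    """Bin a modified Charlson index (age and dementia points excluded)."""
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return None
    score = int(score)
    if score < 0:
        raise ValidationError(f"CCI score must be >= 0, got {score}")
    if score == 0:
        return "0"
    if score <= 2:
        return "1-2"
    if score <= 4:
        return "3-4"
    return ">4"


def is_frail(rockwood: Optional[int]) -> Optional[bool]:
    """Rockwood clinical frailty scale > 4 indicates frailty; None propagates."""
    if rockwood is None or (isinstance(rockwood, float) and math.isnan(rockwood)):
        return None
    rockwood = int(rockwood)
    if not 1 <= rockwood <= 9:
        raise ValidationError(f"Rockwood score must be in [1, 9], got {rockwood}")
    return rockwood > 4


class SyndromicCaseClassifier(BaseEstimator):
    """Rule-based classifier applying the syndromic LRTI case definition.

    A deterministic rule, not a learned model: ``fit`` only records the
    symptom column order so the estimator composes with sklearn-style
    pipelines and model selection.

    Parameters
    ----------
    compose_fever : bool
        When true and the input frame has a ``temperature_c`` column, the
        fever indicator is recomputed from the stored binary OR the
        temperature rule (reported fever/chills take precedence in the sense
        that either source suffices).
    """

    def __init__(self, compose_fever: bool = False):
        self.compose_fever = compose_fever

    def fit(self, X, y=None):
        self.symptom_names_ = list(SYMPTOMS)
        return self

    def predict(self, X) -> np.ndarray:
        """Vector of 0/1 case-definition outcomes for a symptom frame/array."""
        self._check_fitted("symptom_names_")
        if isinstance(X, pd.DataFrame):
            cols = {}
            for s in SYMPTOMS:
                for cand in (s, f"sym_{s}"):
                    if cand in X.columns:
                        cols[s] = X[cand].to_numpy(dtype=float)
                        break
                else:
                    raise ValidationError(f"missing symptom column {s!r}")
            mat = np.column_stack([cols[s] for s in SYMPTOMS])
            if self.compose_fever and "temperature_c" in X.columns:
                temp = X["temperature_c"].to_numpy(dtype=float)
                hot = ~np.isnan(temp) & ((temp > 38.0) | (temp < 35.0))
                mat[:, SYMPTOMS.index("fever")] = np.maximum(
                    mat[:, SYMPTOMS.index("fever")], hot
                )
        else:
            mat = np.asarray(X, dtype=float)
            if mat.ndim != 2 or mat.shape[1] != len(SYMPTOMS):
                raise ValidationError(
                    f"expected an (n, {len(SYMPTOMS)}) symptom matrix, got {mat.shape}"
                )
        mat = (mat > 0).astype(int)
        cough = mat[:, SYMPTOMS.index("cough")]
        fever = mat[:, SYMPTOMS.index("fever")]
        n_definition = mat[:, : len(DEFINITION_SYMPTOMS)].sum(axis=1)
        return (((cough == 1) & (fever == 1)) | (n_definition >= 3)).astype(int)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict(X)


def classify_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append derived columns to a cohort frame.

    Adds ``meets_definition`` (case definition), ``crb`` (severity score,
    NaN when components missing), ``cci_cat`` (Charlson category) and
    ``frail`` (Rockwood > 4, NaN when missing).
    """
    out = cohort.copy()
    clf = SyndromicCaseClassifier().fit(out)
    out["meets_definition"] = clf.predict(out)

    # vectorised mirror of crb_score / cci_category / is_frail
    amts = out["amts"].to_numpy(dtype=float)
    rr = out["resp_rate"].to_numpy(dtype=float)
    sbp = out["sbp"].to_numpy(dtype=float)
    dbp = out["dbp"].to_numpy(dtype=float)
    crb = (
        (amts <= 7).astype(float) + (rr >= 30) + ((sbp < 90) | (dbp <= 60))
    )
    crb[np.isnan(amts) | np.isnan(rr) | np.isnan(sbp) | np.isnan(dbp)] = np.nan
    out["crb"] = crb

    cci = out["cci_excl_age_dementia"].to_numpy(dtype=float)
    if np.nanmin(cci, initial=0) < 0:
        raise ValidationError("CCI score must be >= 0")
    cat = np.empty(len(cci), dtype=object)
    valid = ~np.isnan(cci)
    cat[~valid] = None
    cat[valid & (cci == 0)] = "0"
    cat[valid & (cci >= 1) & (cci <= 2)] = "1-2"
    cat[valid & (cci >= 3) & (cci <= 4)] = "3-4"
    cat[valid & (cci > 4)] = ">4"
    out["cci_cat"] = cat

    rock = out["rockwood"].to_numpy(dtype=float)
    if np.any((~np.isnan(rock)) & ((rock < 1) | (rock > 9))):
        raise ValidationError("Rockwood score must be in [1, 9]")
    frail = (rock > 4).astype(float)
    frail[np.isnan(rock)] = np.nan
    out["frail"] = frail
    return out
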