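"""Synthetic patient-cohort generator with published-margin calibration.

The confidential microdata behind the analysis cannot be shared, so this
module generates cohorts with the statistical structure the analysis
assumes: admission age drawn from the published eight-band distribution
(uniform within band, the open >=85 band truncated at 100), eleven binary
presenting symptoms drawn Bernoulli with log-odds linear in age
(intercept + slope per decade past 18), and age-dependent clinical
covariates (dementia, care-home residency, frailty, SARS-CoV-2 status and
vaccination, modified Charlson category, CRB component observations).

``default_calibration`` returns a configuration whose *expected* margins
reproduce the published cohort: the age-band totals, the dementia,
care-home, SARS-CoV-2 and CCI>4 prevalences, and the overall fraction of
patients meeting the syndromic case definition (8,487/17,620). Intercepts
are solved deterministically by root-finding against exact expectations
over the age grid — no Monte-Carlo tuning. Symptom slopes are negative
for pleurisy, headache, cough, sputum, fever and myalgia and positive for
confusion, falls and general deterioration, matching the reported
age-symptom gradients.

Symptoms are conditionally independent given age by default; an optional
shared-severity latent factor (``severity_sd``) adds one logistic-scale
Gaussian per patient to every symptom's log-odds for dependence-robustness
checks. Raw vitals (temperature, AMTS, respiratory rate, blood pressure)
are generated consistently with the drawn indicators so the clinical
scores can be recomputed from raw fields downstream.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from . import reference as ref
from .errors import CohortParseError, ConfigurationError, SchemaError, ValidationError
from .scores import DEFINITION_SYMPTOMS, SYMPTOMS, SymptomVector

AGE_MIN, AGE_MAX = 18, 100

#: (low, high) inclusive bounds of the eight admission age bands.
AGE_BAND_BOUNDS = (
    (18, 24),
    (25, 34),
    (35, 44),
    (45, 54),
    (55, 64),
    (65, 74),
    (75, 84),
    (85, 100),
)

#: Default seed: the cohort study's start date, for reproducible docs.
DEFAULT_SEED = 20200801


@dataclass(frozen=True)
class AgeLogisticModel:
    """Bernoulli model with log-odds = intercept + slope * (age - 18)/10."""

    intercept: float
    slope_per_decade: float

    def prob(self, age_years) -> np.ndarray:
        d = (np.asarray(age_years, dtype=float) - AGE_MIN) / 10.0
        return expit(self.intercept + self.slope_per_decade * d)


@dataclass(frozen=True)
class CciModel:
    """Cumulative-logit model over the categories 0, 1-2, 3-4, >4.

    P(category <= k | age) = expit(cutpoint_k - slope * decades); a shared
    slope keeps the three cumulative curves ordered at every age.
    """

    cutpoints: tuple
    slope_per_decade: float

    def cumulative(self, age_years) -> np.ndarray:
        d = (np.asarray(age_years, dtype=float) - AGE_MIN) / 10.0
        return expit(
            np.asarray(self.cutpoints)[:, None] - self.slope_per_decade * d[None, :]
        )


@dataclass(frozen=True)
class CrbComponentModel:
    """Probabilities of the three CRB components given age (and dementia)."""

    confusion: AgeLogisticModel
    tachypnoea: AgeLogisticModel
    hypotension: AgeLogisticModel
    confusion_dementia_log_or: float = 1.5


@dataclass
class CohortConfig:
    """Full data-generating configuration for one synthetic cohort."""

    n_patients: int
    seed: int = DEFAULT_SEED
    age_band_weights: tuple = ()
    symptom_model: dict = field(default_factory=dict)
    covariate_model: dict = field(default_factory=dict)
    cci_model: Optional[CciModel] = None
    crb_model: Optional[CrbComponentModel] = None
    p_male: float = 0.508
    p_symptom_recruited: float = 0.214
    vaccination_unknown_rate: float = 0.0676
    rockwood_missing_rate: float = 0.1972
    score_missing_rate: float = 0.0006
    severity_sd: float = 0.0

    _REQUIRED_COVARIATES = (
        "dementia",
        "care_home",
        "frail",
        "sars_cov2_positive",
        "vaccinated",
        "cap_radiological",
    )

    def validate(self) -> "CohortConfig":
        if int(self.n_patients) != self.n_patients or self.n_patients < 0:
            raise ConfigurationError("n_patients", "must be a non-negative integer")
        w = np.asarray(self.age_band_weights, dtype=float)
        if w.shape != (len(AGE_BAND_BOUNDS),):
            raise ConfigurationError(
                "age_band_weights", f"must have {len(AGE_BAND_BOUNDS)} entries"
            )
        if np.any(w < 0):
            raise ConfigurationError("age_band_weights", "entries must be >= 0")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError("age_band_weights", "must sum to 1 within 1e-9")
        missing = [s for s in SYMPTOMS if s not in self.symptom_model]
        if missing:
            raise ConfigurationError("symptom_model", f"missing symptoms {missing}")
        for name, model in {**self.symptom_model, **self.covariate_model}.items():
            if not (
                math.isfinite(model.intercept) and math.isfinite(model.slope_per_decade)
            ):
                raise ConfigurationError(name, "intercept/slope must be finite")
        missing = [c for c in self._REQUIRED_COVARIATES if c not in self.covariate_model]
        if missing:
            raise ConfigurationError("covariate_model", f"missing covariates {missing}")
        if self.cci_model is None or self.crb_model is None:
            raise ConfigurationError("cci_model", "cci_model and crb_model required")
        for fname in (
            "p_male",
            "p_symptom_recruited",
            "vaccination_unknown_rate",
            "rockwood_missing_rate",
            "score_missing_rate",
        ):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(fname, "must be a probability in [0, 1]")
        if not (math.isfinite(self.severity_sd) and self.severity_sd >= 0):
            raise ConfigurationError("severity_sd", "must be a finite SD >= 0")
        return self


# ---------------------------------------------------------------------------
# Exact expectations over the age grid (used for deterministic calibration)
# ---------------------------------------------------------------------------


def age_grid_weights(band_weights) -> tuple[np.ndarray, np.ndarray]:
    """Per-year ages 18..100 and their probabilities (uniform within band)."""
    ages = np.arange(AGE_MIN, AGE_MAX + 1, dtype=float)
    w = np.zeros_like(ages)
    for (lo, hi), bw in zip(AGE_BAND_BOUNDS, band_weights):
        width = hi - lo + 1
        w[(ages >= lo) & (ages <= hi)] = bw / width
    return ages, w


def _solve_intercept(target, slope, ages, w, dementia_prob=None, dementia_log_or=0.0):
    """Intercept such that the expected prevalence over the age grid = target."""

    def expected(b0):
        d = (ages - AGE_MIN) / 10.0
        p = expit(b0 + slope * d)
        if dementia_prob is not None:
            p = (1 - dementia_prob) * p + dementia_prob * expit(
                b0 + slope * d + dementia_log_or
            )
        return float((w * p).sum()) - target

    return brentq(expected, -30.0, 30.0, xtol=1e-12)


def expected_meeting_fraction(config: CohortConfig) -> float:
    """Exact P(symptoms meet the case definition) under the configuration.

    Enumerates the 2^9 definition-symptom patterns at every age year
    (symptoms conditionally independent given age; ignores severity_sd).
    """
    ages, w = age_grid_weights(config.age_band_weights)
    d = (ages - AGE_MIN) / 10.0
    p = np.array(
        [
            expit(
                config.symptom_model[s].intercept
                + config.symptom_model[s].slope_per_decade * d
            )
            for s in DEFINITION_SYMPTOMS
        ]
    )  # (9, n_ages)
    bits = np.array(
        [[(m >> k) & 1 for k in range(len(DEFINITION_SYMPTOMS))] for m in range(512)],
        dtype=float,
    )  # (512, 9)
    i_cough = DEFINITION_SYMPTOMS.index("cough")
    i_fever = DEFINITION_SYMPTOMS.index("fever")
    meets = ((bits[:, i_cough] * bits[:, i_fever]) > 0) | (bits.sum(axis=1) >= 3)
    with np.errstate(divide="ignore"):
        log_p = np.log(p)
        log_q = np.log1p(-p)
    loglik = bits @ log_p + (1.0 - bits) @ log_q  # (512, n_ages)
    p_meet_age = np.exp(loglik[meets]).sum(axis=0)
    return float((w * p_meet_age).sum())


# ---------------------------------------------------------------------------
# Default calibration against the published margins
# ---------------------------------------------------------------------------

#: Target overall prevalence and per-decade log-odds slope for each symptom.
#: Slope signs follow the reported age gradients; magnitudes are plausible
#: clinical gradients chosen once (see docs/methods.md).
_SYMPTOM_TARGETS = {
    "cough": (0.64, -0.20),
    "fever": (0.28, -0.15),
    "breathlessness": (0.62, 0.02),
    "wheeze": (0.22, -0.05),
    "pleurisy": (0.15, -0.28),
    "sputum": (0.30, -0.12),
    "myalgia": (0.11, -0.25),
    "headache": (0.10, -0.30),
    "general_deterioration": (0.35, 0.22),
    "confusion": (0.14, 0.40),
    "falls": (0.12, 0.35),
}

#: Target overall prevalence and slope for each age-dependent covariate.
_COVARIATE_TARGETS = {
    "dementia": (
        (ref.DEMENTIA[0] + ref.DEMENTIA[1]) / ref.N_TOTAL,
        0.90,
    ),
    "care_home": (
        (ref.CARE_HOME[0] + ref.CARE_HOME[1]) / ref.N_TOTAL,
        0.80,
    ),
    # frailty calibrated among patients with a recorded Rockwood score
    "frail": (
        (ref.FRAIL[0] + ref.FRAIL[1])
        / (ref.N_TOTAL - ref.FRAIL_UNKNOWN[0] - ref.FRAIL_UNKNOWN[1]),
        0.70,
    ),
    "sars_cov2_positive": (ref.N_SARS_POSITIVE_TOTAL / ref.N_TOTAL, -0.05),
    # vaccination calibrated among patients with known status
    "vaccinated": (
        (ref.VACCINATED_YES[0] + ref.VACCINATED_YES[1])
        / (ref.N_TOTAL - ref.VACCINATED_UNKNOWN[0] - ref.VACCINATED_UNKNOWN[1]),
        0.50,
    ),
    # radiologically confirmed pneumonia fraction of the cohort
    "cap_radiological": (
        ref.N_PNEUMONIA * ref.PNEUMONIA_RADIOLOGICAL_FRACTION / ref.N_TOTAL,
        0.05,
    ),
}

#: CRB component targets (overall prevalence, slope per decade).
_CRB_TARGETS = {
    "confusion": (0.12, 0.50),
    "tachypnoea": (0.14, 0.10),
    "hypotension": (0.09, 0.10),
}

_CCI_SLOPE = 0.35

_calibration_cache: dict = {}


def default_calibration(
    n_patients: int = ref.N_TOTAL, seed: int = DEFAULT_SEED
) -> CohortConfig:
    """Configuration whose expected margins reproduce the published cohort."""
    if "models" not in _calibration_cache:
        weights = np.array(
            [t / ref.N_TOTAL for t in ref.band_totals().values()], dtype=float
        )
        weights = weights / weights.sum()
        ages, w = age_grid_weights(weights)

        symptom_model = {}
        for s, (target, slope) in _SYMPTOM_TARGETS.items():
            symptom_model[s] = AgeLogisticModel(
                _solve_intercept(target, slope, ages, w), slope
            )

        covariate_model = {}
        for name, (target, slope) in _COVARIATE_TARGETS.items():
            covariate_model[name] = AgeLogisticModel(
                _solve_intercept(target, slope, ages, w), slope
            )

        # CRB confusion depends on dementia as well as age
        dem_prob = covariate_model["dementia"].prob(ages)
        crb_models = {}
        for name, (target, slope) in _CRB_TARGETS.items():
            if name == "confusion":
                b0 = _solve_intercept(
                    target, slope, ages, w, dementia_prob=dem_prob,
                    dementia_log_or=1.5,
                )
            else:
                b0 = _solve_intercept(target, slope, ages, w)
            crb_models[name] = AgeLogisticModel(b0, slope)

        n_cci_known = ref.N_TOTAL - ref.CCI_UNKNOWN[0] - ref.CCI_UNKNOWN[1]
        cum_targets = np.cumsum(
            [sum(ref.CCI_COUNTS[c]) / n_cci_known for c in ("0", "1-2", "3-4")]
        )
        cutpoints = tuple(
            _solve_intercept(t, -_CCI_SLOPE, ages, w) for t in cum_targets
        )

        base = CohortConfig(
            n_patients=0,
            age_band_weights=tuple(weights),
            symptom_model=symptom_model,
            covariate_model=covariate_model,
            cci_model=CciModel(cutpoints=cutpoints, slope_per_decade=_CCI_SLOPE),
            crb_model=CrbComponentModel(
                confusion=crb_models["confusion"],
                tachypnoea=crb_models["tachypnoea"],
                hypotension=crb_models["hypotension"],
            ),
            vaccination_unknown_rate=(
                (ref.VACCINATED_UNKNOWN[0] + ref.VACCINATED_UNKNOWN[1]) / ref.N_TOTAL
            ),
            rockwood_missing_rate=(
                (ref.FRAIL_UNKNOWN[0] + ref.FRAIL_UNKNOWN[1]) / ref.N_TOTAL
            ),
        )

        # shared offset on the nine definition symptoms so the expected
        # meeting fraction matches the published 8,487/17,620 exactly
        target_meet = ref.N_MEETING / ref.N_TOTAL

        def meet_gap(offset):
            shifted = dict(base.symptom_model)
            for s in DEFINITION_SYMPTOMS:
                m = shifted[s]
                shifted[s] = AgeLogisticModel(m.intercept + offset, m.slope_per_decade)
            probe = CohortConfig(
                n_patients=0,
                age_band_weights=base.age_band_weights,
                symptom_model=shifted,
                covariate_model=base.covariate_model,
                cci_model=base.cci_model,
                crb_model=base.crb_model,
            )
            return expected_meeting_fraction(probe) - target_meet

        offset = brentq(meet_gap, -2.0, 2.0, xtol=1e-12)
        symptom_model = {
            s: (
                AgeLogisticModel(m.intercept + offset, m.slope_per_decade)
                if s in DEFINITION_SYMPTOMS
                else m
            )
            for s, m in base.symptom_model.items()
        }
        base.symptom_model = symptom_model
        _calibration_cache["models"] = base

    base = _calibration_cache["models"]
    cfg = CohortConfig(
        n_patients=n_patients,
        seed=seed,
        age_band_weights=base.age_band_weights,
        symptom_model=dict(base.symptom_model),
        covariate_model=dict(base.covariate_model),
        cci_model=base.cci_model,
        crb_model=base.crb_model,
        p_male=base.p_male,
        p_symptom_recruited=base.p_symptom_recruited,
        vaccination_unknown_rate=base.vaccination_unknown_rate,
        rockwood_missing_rate=base.rockwood_missing_rate,
        score_missing_rate=base.score_missing_rate,
        severity_sd=base.severity_sd,
    )
    return cfg.validate()


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

#: Cohort CSV column order (PatientRecord fields, symptoms flattened).
COHORT_COLUMNS = (
    ("patient_id",)
    + ("age_years", "sex")
    + tuple(f"sym_{s}" for s in SYMPTOMS)
    + (
        "temperature_c",
        "amts",
        "resp_rate",
        "sbp",
        "dbp",
        "dementia",
        "rockwood",
        "cci_excl_age_dementia",
        "care_home",
        "sars_cov2_positive",
        "sars_cov2_vaccinated",
        "cap_radiological",
        "recruited_by_symptom_criteria",
    )
)


def generate_cohort_frame(config: CohortConfig) -> pd.DataFrame:
    """Vectorised cohort generation; identical output for identical seed."""
    config.validate()
    n = int(config.n_patients)
    rng = np.random.default_rng(config.seed)
    cols: dict = {}

    cols["patient_id"] = [f"P{i:06d}" for i in range(1, n + 1)]

    band = rng.choice(len(AGE_BAND_BOUNDS), size=n, p=np.asarray(config.age_band_weights))
    lo = np.array([b[0] for b in AGE_BAND_BOUNDS])[band]
    hi = np.array([b[1] for b in AGE_BAND_BOUNDS])[band]
    age = lo + np.floor(rng.random(n) * (hi - lo + 1)).astype(int)
    age = np.minimum(age, AGE_MAX)
    cols["age_years"] = age
    d = (age - AGE_MIN) / 10.0

    cols["sex"] = np.where(rng.random(n) < config.p_male, "male", "female")

    severity = (
        rng.normal(0.0, config.severity_sd, size=n) if config.severity_sd > 0 else 0.0
    )
    sym: dict[str, np.ndarray] = {}
    for s in SYMPTOMS:
        m = config.symptom_model[s]
        p = expit(m.intercept + m.slope_per_decade * d + severity)
        sym[s] = (rng.random(n) < p).astype(int)
        cols[f"sym_{s}"] = sym[s]

    # temperature consistent with the fever indicator (ranges avoid the
    # 35.0/38.0 boundaries surviving 1-dp rounding)
    u = rng.random(n)
    temp = np.round(rng.uniform(35.1, 37.8, size=n), 1)
    fever = sym["fever"] == 1
    hot = fever & (u < 0.60)
    cold = fever & (u >= 0.60) & (u < 0.65)
    chills = fever & ~hot & ~cold
    temp[hot] = np.round(rng.uniform(38.1, 40.3, size=int(hot.sum())), 1)
    temp[cold] = np.round(rng.uniform(34.0, 34.9, size=int(cold.sum())), 1)
    temp[chills] = np.round(rng.uniform(36.0, 37.9, size=int(chills.sum())), 1)
    cols["temperature_c"] = temp

    dementia = (
        rng.random(n) < config.covariate_model["dementia"].prob(age)
    ).astype(int)
    cols["dementia"] = dementia

    # CRB component indicators, then raw vitals consistent with them
    crb = config.crb_model
    p_conf = expit(
        crb.confusion.intercept
        + crb.confusion.slope_per_decade * d
        + crb.confusion_dementia_log_or * dementia
    )
    conf = rng.random(n) < p_conf
    amts = np.where(conf, rng.integers(0, 8, size=n), rng.integers(8, 11, size=n))
    tachy = rng.random(n) < crb.tachypnoea.prob(age)
    rr = np.where(tachy, rng.integers(30, 45, size=n), rng.integers(12, 30, size=n))
    hypo = rng.random(n) < crb.hypotension.prob(age)
    low_sbp = hypo & (rng.random(n) < 0.5)
    sbp = np.where(low_sbp, rng.integers(70, 90, size=n), rng.integers(95, 165, size=n))
    dbp = np.where(
        hypo & ~low_sbp, rng.integers(40, 61, size=n), rng.integers(61, 96, size=n)
    )
    amts = amts.astype(float)
    rr = rr.astype(float)
    sbp = sbp.astype(float)
    dbp = dbp.astype(float)
    crb_missing = rng.random(n) < config.score_missing_rate
    amts[crb_missing] = np.nan
    rr[crb_missing] = np.nan
    sbp[crb_missing] = np.nan
    dbp[crb_missing] = np.nan
    cols["amts"] = amts
    cols["resp_rate"] = rr
    cols["sbp"] = sbp
    cols["dbp"] = dbp

    rock_missing = rng.random(n) < config.rockwood_missing_rate
    frail = rng.random(n) < config.covariate_model["frail"].prob(age)
    rockwood = np.where(frail, rng.integers(5, 10, size=n), rng.integers(1, 5, size=n))
    rockwood = rockwood.astype(float)
    rockwood[rock_missing] = np.nan
    cols["rockwood"] = rockwood

    cum = config.cci_model.cumulative(age)  # (3, n)
    u_cci = rng.random(n)
    cat = (u_cci[None, :] > cum).sum(axis=0)  # 0..3
    reps = np.select(
        [cat == 0, cat == 1, cat == 2, cat == 3],
        [
            np.zeros(n, dtype=int),
            rng.integers(1, 3, size=n),
            rng.integers(3, 5, size=n),
            rng.integers(5, 9, size=n),
        ],
    ).astype(float)
    cci_missing = rng.random(n) < config.score_missing_rate
    reps[cci_missing] = np.nan
    cols["cci_excl_age_dementia"] = reps

    cols["care_home"] = (
        rng.random(n) < config.covariate_model["care_home"].prob(age)
    ).astype(int)
    cols["sars_cov2_positive"] = (
        rng.random(n) < config.covariate_model["sars_cov2_positive"].prob(age)
    ).astype(int)

    vax_unknown = rng.random(n) < config.vaccination_unknown_rate
    vax_yes = rng.random(n) < config.covariate_model["vaccinated"].prob(age)
    cols["sars_cov2_vaccinated"] = np.where(
        vax_unknown, "unknown", np.where(vax_yes, "yes", "no")
    )

    cols["cap_radiological"] = (
        rng.random(n) < config.covariate_model["cap_radiological"].prob(age)
    ).astype(int)
    cols["recruited_by_symptom_criteria"] = (
        rng.random(n) < config.p_symptom_recruited
    ).astype(int)

    return pd.DataFrame({c: cols[c] for c in COHORT_COLUMNS})


# ---------------------------------------------------------------------------
# Record container and flat-file IO
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientRecord:
    """One admission: demographics, symptoms, covariates, diagnosis flags."""

    patient_id: str
    age_years: int
    sex: str
    symptoms: SymptomVector
    temperature_c: Optional[float] = None
    amts: Optional[int] = None
    resp_rate: Optional[float] = None
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    dementia: int = 0
    rockwood: Optional[int] = None
    cci_excl_age_dementia: Optional[int] = None
    care_home: int = 0
    sars_cov2_positive: int = 0
    sars_cov2_vaccinated: str = "unknown"
    cap_radiological: int = 0
    recruited_by_symptom_criteria: int = 0

    def __post_init__(self):
        if self.age_years < AGE_MIN:
            raise ValidationError(
                f"age_years must be >= {AGE_MIN}, got {self.age_years}"
            )
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be male/female, got {self.sex!r}")
        if self.amts is not None and not 0 <= self.amts <= 10:
            raise ValidationError(f"amts must be in [0, 10], got {self.amts}")
        if self.rockwood is not None and not 1 <= self.rockwood <= 9:
            raise ValidationError(f"rockwood must be in [1, 9], got {self.rockwood}")
        if self.sars_cov2_vaccinated not in ("yes", "no", "unknown"):
            raise ValidationError(
                f"sars_cov2_vaccinated must be yes/no/unknown, "
                f"got {self.sars_cov2_vaccinated!r}"
            )
        if self.temperature_c is not None and (
            self.temperature_c > 38.0 or self.temperature_c < 35.0
        ):
            if not self.symptoms.fever:
                raise ValidationError(
                    f"temperature {self.temperature_c} implies fever but the "
                    "fever indicator is 0"
                )


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    """Convert a cohort frame into validated PatientRecord objects."""
    records = []
    for row in frame.itertuples(index=False):
        row = row._asdict()
        symptoms = SymptomVector(**{s: bool(row[f"sym_{s}"]) for s in SYMPTOMS})

        def opt(name, cast):
            v = row[name]
            return None if pd.isna(v) else cast(v)

        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                age_years=int(row["age_years"]),
                sex=str(row["sex"]),
                symptoms=symptoms,
                temperature_c=opt("temperature_c", float),
                amts=opt("amts", lambda v: int(float(v))),
                resp_rate=opt("resp_rate", float),
                sbp=opt("sbp", float),
                dbp=opt("dbp", float),
                dementia=int(row["dementia"]),
                rockwood=opt("rockwood", lambda v: int(float(v))),
                cci_excl_age_dementia=opt(
                    "cci_excl_age_dementia", lambda v: int(float(v))
                ),
                care_home=int(row["care_home"]),
                sars_cov2_positive=int(row["sars_cov2_positive"]),
                sars_cov2_vaccinated=str(row["sars_cov2_vaccinated"]),
                cap_radiological=int(row["cap_radiological"]),
                recruited_by_symptom_criteria=int(
                    row["recruited_by_symptom_criteria"]
                ),
            )
        )
    return records


def cohort_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "age_years": r.age_years,
            "sex": r.sex,
        }
        for s in SYMPTOMS:
            row[f"sym_{s}"] = int(getattr(r.symptoms, s))
        row.update(
            temperature_c=np.nan if r.temperature_c is None else r.temperature_c,
            amts=np.nan if r.amts is None else r.amts,
            resp_rate=np.nan if r.resp_rate is None else r.resp_rate,
            sbp=np.nan if r.sbp is None else r.sbp,
            dbp=np.nan if r.dbp is None else r.dbp,
            dementia=r.dementia,
            rockwood=np.nan if r.rockwood is None else r.rockwood,
            cci_excl_age_dementia=(
                np.nan if r.cci_excl_age_dementia is None else r.cci_excl_age_dementia
            ),
            care_home=r.care_home,
            sars_cov2_positive=r.sars_cov2_positive,
            sars_cov2_vaccinated=r.sars_cov2_vaccinated,
            cap_radiological=r.cap_radiological,
            recruited_by_symptom_criteria=r.recruited_by_symptom_criteria,
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Generate ``config.n_patients`` validated records (deterministic per seed)."""
    return frame_to_records(generate_cohort_frame(config))


_INT_COLUMNS = {
    "age_years",
    "dementia",
    "care_home",
    "sars_cov2_positive",
    "cap_radiological",
    "recruited_by_symptom_criteria",
} | {f"sym_{s}" for s in SYMPTOMS}
_OPT_INT_COLUMNS = {"amts", "rockwood", "cci_excl_age_dementia"}
_OPT_FLOAT_COLUMNS = {"temperature_c", "resp_rate", "sbp", "dbp"}


def _format_cell(col: str, value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if col == "temperature_c":
        return f"{float(value):.1f}"
    if col in _OPT_FLOAT_COLUMNS or col in _OPT_INT_COLUMNS or col in _INT_COLUMNS:
        return str(int(value)) if float(value) == int(value) else str(float(value))
    return str(value)


def write_cohort(cohort, path) -> None:
    """Write records (or a cohort frame) to the UTF-8 CSV cohort format."""
    frame = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for row in frame.itertuples(index=False):
            row = row._asdict()
            writer.writerow([_format_cell(c, row[c]) for c in COHORT_COLUMNS])


def read_cohort(path) -> list[PatientRecord]:
    """Read and validate a cohort CSV; errors carry the offending line number."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError("empty cohort file") from None
        unknown = set(header) - set(COHORT_COLUMNS)
        missing = set(COHORT_COLUMNS) - set(header)
        if unknown:
            raise SchemaError(f"unknown column(s): {sorted(unknown)}")
        if missing:
            raise SchemaError(f"missing column(s): {sorted(missing)}")
        records = []
        for lineno, rawrow in enumerate(reader, start=2):
            if not rawrow:
                continue
            if len(rawrow) != len(header):
                raise CohortParseError(
                    lineno, f"expected {len(header)} fields, got {len(rawrow)}"
                )
            cell = dict(zip(header, rawrow))
            try:
                symptoms = SymptomVector(
                    **{s: bool(int(cell[f"sym_{s}"])) for s in SYMPTOMS}
                )

                def opt(name, cast):
                    return None if cell[name] == "" else cast(cell[name])

                records.append(
                    PatientRecord(
                        patient_id=cell["patient_id"],
                        age_years=int(cell["age_years"]),
                        sex=cell["sex"],
                        symptoms=symptoms,
                        temperature_c=opt("temperature_c", float),
                        amts=opt("amts", lambda v: int(float(v))),
                        resp_rate=opt("resp_rate", float),
                        sbp=opt("sbp", float),
                        dbp=opt("dbp", float),
                        dementia=int(cell["dementia"]),
                        rockwood=opt("rockwood", lambda v: int(float(v))),
                        cci_excl_age_dementia=opt(
                            "cci_excl_age_dementia", lambda v: int(float(v))
                        ),
                        care_home=int(cell["care_home"]),
                        sars_cov2_positive=int(cell["sars_cov2_positive"]),
                        sars_cov2_vaccinated=cell["sars_cov2_vaccinated"],
                        cap_radiological=int(cell["cap_radiological"]),
                        recruited_by_symptom_criteria=int(
                            cell["recruited_by_symptom_criteria"]
                        ),
                    )
                )
            except ValidationError:
                raise
            except (KeyError, ValueError) as exc:
                raise CohortParseError(lineno, str(exc)) from exc
    return records


# ---------------------------------------------------------------------------
# Config (de)serialisation
# ---------------------------------------------------------------------------


def config_to_dict(config: CohortConfig) -> dict:
    out = asdict(config)
    out["age_band_weights"] = [float(v) for v in config.age_band_weights]
    out["symptom_model"] = {
        s: [float(m.intercept), float(m.slope_per_decade)]
        for s, m in config.symptom_model.items()
    }
    out["covariate_model"] = {
        s: [float(m.intercept), float(m.slope_per_decade)]
        for s, m in config.covariate_model.items()
    }
    out["cci_model"] = {
        "cutpoints": [float(v) for v in config.cci_model.cutpoints],
        "slope_per_decade": config.cci_model.slope_per_decade,
    }
    out["crb_model"] = {
        "confusion": [
            float(config.crb_model.confusion.intercept),
            float(config.crb_model.confusion.slope_per_decade),
        ],
        "tachypnoea": [
            float(config.crb_model.tachypnoea.intercept),
            float(config.crb_model.tachypnoea.slope_per_decade),
        ],
        "hypotension": [
            float(config.crb_model.hypotension.intercept),
            float(config.crb_model.hypotension.slope_per_decade),
        ],
        "confusion_dementia_log_or": config.crb_model.confusion_dementia_log_or,
    }
    return out


def config_from_dict(data: dict) -> CohortConfig:
    def alm(pair):
        return AgeLogisticModel(float(pair[0]), float(pair[1]))

    cfg = CohortConfig(
        n_patients=int(data["n_patients"]),
        seed=int(data.get("seed", DEFAULT_SEED)),
        age_band_weights=tuple(float(v) for v in data["age_band_weights"]),
        symptom_model={s: alm(v) for s, v in data["symptom_model"].items()},
        covariate_model={s: alm(v) for s, v in data["covariate_model"].items()},
        cci_model=CciModel(
            cutpoints=tuple(float(v) for v in data["cci_model"]["cutpoints"]),
            slope_per_decade=float(data["cci_model"]["slope_per_decade"]),
        ),
        crb_model=CrbComponentModel(
            confusion=alm(data["crb_model"]["confusion"]),
            tachypnoea=alm(data["crb_model"]["tachypnoea"]),
            hypotension=alm(data["crb_model"]["hypotension"]),
            confusion_dementia_log_or=float(
                data["crb_model"].get("confusion_dementia_log_or", 1.5)
            ),
        ),
    )
    for fname in (
        "p_male",
        "p_symptom_recruited",
        "vaccination_unknown_rate",
        "rockwood_missing_rate",
        "score_missing_rate",
        "severity_sd",
    ):
        if fname in data:
            setattr(cfg, fname, float(data[fname]))
    return cfg.validate()


def save_config(config: CohortConfig, path) -> None:
    path = Path(path)
    data = config_to_dict(config)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")
    else:
        path.write_text(json.dumps(data, indent=2, sort_keys=True), encoding="utf-8")


def load_config(path) -> CohortConfig:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return config_from_dict(data)
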