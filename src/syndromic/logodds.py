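"""Empirical-Bayes weighted log-odds contrast of symptom expression.

Compares how often each presenting symptom is expressed in two patient
groups (by default adults >= 65y vs < 65y). Rates are shrunk toward the
pooled rate by an informative Dirichlet prior whose pseudo-counts are
proportional to the pooled symptom frequencies, and the posterior log-odds
difference for each symptom is standardised by its approximate posterior
variance, so rare symptoms (noisier estimates) are down-weighted. Results
are reported as z-scores.

For symptom w with counts y_gw in group g (sizes n_g) and prior
pseudo-counts alpha_w summing to alpha_0:

    delta_w = log[(y_iw + a_w) / (n_i + a_0 - y_iw - a_w)]
            - log[(y_jw + a_w) / (n_j + a_0 - y_jw - a_w)]
    var_w   = 1/(y_iw + a_w) + 1/(y_jw + a_w)
    z_w     = delta_w / sqrt(var_w)

Two views of n_g are supported, because a "multinomial model" of symptom
expression can count either patients or symptom occurrences:

* ``multinomial`` (default): n_g = total symptom occurrences in group g,
  so each symptom is contrasted against all other symptom mentions.
* ``bernoulli``: n_g = number of patients in group g, so each symptom is
  contrasted against its own absence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .base import BaseEstimator
from .errors import ValidationError
from .scores import SYMPTOMS

#: Pseudo-count floor applied to symptoms never observed in the pooled data,
#: keeping every Dirichlet weight strictly positive.
ZERO_COUNT_FLOOR = 0.5


@dataclass(frozen=True)
class GroupSymptomCounts:
    """Per-symptom counts and totals for a two-group contrast."""

    symptoms: tuple
    y_i: np.ndarray
    y_j: np.ndarray
    n_i: float
    n_j: float
    label_i: str = "ge_65"
    label_j: str = "lt_65"
    mode: str = "multinomial"

    def __post_init__(self):
        object.__setattr__(self, "symptoms", tuple(self.symptoms))
        for attr in ("y_i", "y_j"):
            arr = np.asarray(getattr(self, attr), dtype=float)
            if arr.shape != (len(self.symptoms),):
                raise ValidationError(f"{attr} must have one count per symptom")
            if np.any(arr < 0):
                raise ValidationError(f"{attr} contains negative counts")
            object.__setattr__(self, attr, arr)
        if self.n_i <= 0 or self.n_j <= 0:
            raise ValidationError("group sizes must be positive")
        if self.mode == "multinomial":
            for tot, y in ((self.n_i, self.y_i), (self.n_j, self.y_j)):
                if not np.isclose(y.sum(), tot):
                    raise ValidationError(
                        "multinomial view requires counts to sum to the group total"
                    )
        elif self.mode == "bernoulli":
            if np.any(self.y_i > self.n_i) or np.any(self.y_j > self.n_j):
                raise ValidationError(
                    "bernoulli view requires each count <= group size"
                )
        else:
            raise ValidationError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class WeightedLogOddsResult:
    """Posterior log-odds contrast, variance and z-score per symptom."""

    symptoms: tuple
    delta: np.ndarray
    variance: np.ndarray
    z_score: np.ndarray
    alpha: np.ndarray
    alpha_0: float
    label_i: str = "ge_65"
    label_j: str = "lt_65"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                symptom=list(self.symptoms),
                alpha=self.alpha,
                delta=self.delta,
                variance=self.variance,
                z=self.z_score,
            )
        )


def group_symptom_counts(
    cohort: pd.DataFrame,
    split: str = "age_ge_65",
    mode: str = "multinomial",
    symptoms: tuple = SYMPTOMS,
) -> GroupSymptomCounts:
    """Aggregate a cohort frame into per-group symptom counts.

    ``split`` may name an existing binary column, or ``"age_ge_65"`` to
    split at the 65th birthday.
    """
    if split == "age_ge_65" and "age_ge_65" not in cohort.columns:
        grouping = (cohort["age_years"] >= 65).to_numpy()
        labels = ("ge_65", "lt_65")
    else:
        grouping = cohort[split].astype(bool).to_numpy()
        labels = (f"{split}=1", f"{split}=0")
    cols = []
    for s in symptoms:
        name = s if s in cohort.columns else f"sym_{s}"
        if name not in cohort.columns:
            raise ValidationError(f"missing symptom column for {s!r}")
        cols.append(cohort[name].to_numpy(dtype=float))
    mat = np.column_stack(cols)
    y_i = mat[grouping].sum(axis=0)
    y_j = mat[~grouping].sum(axis=0)
    if mode == "multinomial":
        n_i, n_j = float(y_i.sum()), float(y_j.sum())
    elif mode == "bernoulli":
        n_i, n_j = float(grouping.sum()), float((~grouping).sum())
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return GroupSymptomCounts(
        symptoms=tuple(symptoms),
        y_i=y_i,
        y_j=y_j,
        n_i=n_i,
        n_j=n_j,
        label_i=labels[0],
        label_j=labels[1],
        mode=mode,
    )


def default_prior_strength(counts: GroupSymptomCounts) -> float:
    """Mean group total divided by the number of symptoms."""
    return 0.5 * (counts.n_i + counts.n_j) / len(counts.symptoms)


def estimate_prior(counts: GroupSymptomCounts, strength: float) -> np.ndarray:
    """Informative Dirichlet weights: pooled symptom frequencies x strength.

    Symptoms with zero pooled count receive a ``ZERO_COUNT_FLOOR``
    pseudo-count before normalisation, so every alpha_w is positive.
    """
    if strength <= 0:
        raise ValidationError("prior strength must be positive")
    pooled = counts.y_i + counts.y_j
    if pooled.sum() <= 0:
        raise ValidationError("pooled symptom counts are all zero")
    pooled = np.where(pooled == 0, ZERO_COUNT_FLOOR, pooled)
    return strength * pooled / pooled.sum()


def weighted_log_odds(
    counts: GroupSymptomCounts, alpha: np.ndarray
) -> WeightedLogOddsResult:
    """Posterior log-odds difference, variance and z-score per symptom."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (len(counts.symptoms),) or np.any(alpha <= 0):
        raise ValidationError("alpha must be positive, one entry per symptom")
    alpha_0 = float(alpha.sum())
    num_i = counts.y_i + alpha
    den_i = counts.n_i + alpha_0 - counts.y_i - alpha
    num_j = counts.y_j + alpha
    den_j = counts.n_j + alpha_0 - counts.y_j - alpha
    if np.any(den_i <= 0) or np.any(den_j <= 0):
        raise ValidationError("implied log-odds denominators are not positive")
    delta = np.log(num_i / den_i) - np.log(num_j / den_j)
    variance = 1.0 / num_i + 1.0 / num_j
    return WeightedLogOddsResult(
        symptoms=counts.symptoms,
        delta=delta,
        variance=variance,
        z_score=delta / np.sqrt(variance),
        alpha=alpha,
        alpha_0=alpha_0,
        label_i=counts.label_i,
        label_j=counts.label_j,
    )


def rank_symptoms(result: WeightedLogOddsResult) -> list:
    """Symptoms sorted by z-score descending; ties broken alphabetically."""
    order = sorted(
        range(len(result.symptoms)),
        key=lambda k: (-result.z_score[k], result.symptoms[k]),
    )
    return [result.symptoms[k] for k in order]


class DirichletLogOddsContrast(BaseEstimator):
    """Estimator wrapper around the weighted log-odds contrast.

    Parameters
    ----------
    split : str
        Grouping column, or ``"age_ge_65"`` for the age dichotomy.
    mode : str
        ``"multinomial"`` or ``"bernoulli"`` group-total convention.
    prior_strength : float or None
        Total Dirichlet mass; None uses mean group total / n symptoms.

    Fitted attributes: ``counts_``, ``alpha_``, ``delta_``, ``variance_``,
    ``z_score_``, ``ranking_``, ``result_``.
    """

    def __init__(
        self,
        split: str = "age_ge_65",
        mode: str = "multinomial",
        prior_strength: float | None = None,
    ):
        self.split = split
        self.mode = mode
        self.prior_strength = prior_strength

    def fit(self, cohort: pd.DataFrame, y=None):
        counts = group_symptom_counts(cohort, split=self.split, mode=self.mode)
        strength = (
            self.prior_strength
            if self.prior_strength is not None
            else default_prior_strength(counts)
        )
        alpha = estimate_prior(counts, strength)
        result = weighted_log_odds(counts, alpha)
        self.counts_ = counts
        self.alpha_ = alpha
        self.delta_ = result.delta
        self.variance_ = result.variance
        self.z_score_ = result.z_score
        self.ranking_ = rank_symptoms(result)
        self.result_ = result
        return self

    def transform(self, cohort: pd.DataFrame = None) -> pd.DataFrame:
        self._check_fitted("result_")
        return self.result_.as_frame()

    def fit_transform(self, cohort: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(cohort).transform()
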