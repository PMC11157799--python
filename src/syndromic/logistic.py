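"""Maximum-likelihood logistic regression via IRLS/Newton, from scratch.

Used to estimate the adjusted odds of presenting symptoms meeting the
syndromic LRTI case definition. The primary exposure is age >= 65y; model
"1a" additionally adjusts for sex, dementia/cognitive impairment and a
modified Charlson comorbidity index > 4, model "1b" adjusts for sex only.

Numerics: Newton steps on the Bernoulli log-likelihood with step-halving
whenever a step would decrease the likelihood; convergence when the
largest absolute score (gradient) component falls below ``tol``. Wald
intervals use the exact normal quantile (1.959964... at alpha=0.05).
Complete-case analysis: rows with any missing model variable are dropped
and the number used is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .base import BaseEstimator
from .errors import SchemaError, SeparationError, ValidationError


@dataclass(frozen=True)
class ModelSpec:
    """Outcome, ordered predictor names, and intercept flag for one model."""

    outcome: str = "meets_definition"
    predictors: tuple = ("age_ge_65",)
    include_intercept: bool = True

    def __post_init__(self):
        preds = tuple(self.predictors)
        if not preds:
            raise ValidationError("predictors must be non-empty")
        if len(set(preds)) != len(preds):
            raise ValidationError("duplicate predictor names")
        object.__setattr__(self, "predictors", preds)


#: Fully adjusted model: age >= 65, sex, dementia, CCI > 4.
MODEL_1A = ModelSpec(predictors=("age_ge_65", "male", "dementia", "cci_gt_4"))
#: Reduced model excluding the dementia and comorbidity covariates.
MODEL_1B = ModelSpec(predictors=("age_ge_65", "male"))


@dataclass
class FitResult:
    """Coefficients, covariance and odds-ratio summaries of one fitted model."""

    terms: list
    coefficients: np.ndarray
    covariance: np.ndarray
    aor: dict = field(default_factory=dict)
    n_used: int = 0
    converged: bool = False
    iterations: int = 0
    log_likelihood: float = np.nan

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.terms:
            entry = self.aor[name]
            rows.append(dict(term=name, **entry))
        return pd.DataFrame(rows)


class IRLSLogisticRegression(BaseEstimator):
    """Binary logistic regression fitted by Newton/IRLS.

    Parameters
    ----------
    tol : float
        Convergence threshold on the max absolute score component.
    max_iter : int
        Maximum Newton iterations before declaring non-convergence.
    alpha : float
        Wald interval level (default 0.05 gives 95% intervals).
    include_intercept : bool
        Prepend a constant column to the design matrix.

    Fitted attributes: ``coef_`` (intercept first when present), ``cov_``,
    ``se_``, ``odds_ratios_``, ``ci_``, ``n_used_``, ``converged_``,
    ``n_iter_``, ``log_likelihood_``.
    """

    def __init__(
        self,
        tol: float = 1e-10,
        max_iter: int = 50,
        alpha: float = 0.05,
        include_intercept: bool = True,
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.alpha = alpha
        self.include_intercept = include_intercept

    @staticmethod
    def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
        # log L = sum y*eta - log(1 + e^eta), computed stably
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValidationError("X must be 2-dimensional")
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValidationError("outcome must be binary 0/1")
        n, p = X.shape
        if self.include_intercept:
            X = np.column_stack([np.ones(n), X])
            p += 1
        if n < p:
            raise ValidationError(f"need at least {p} complete rows, got {n}")

        beta = np.zeros(p)
        eta = X @ beta
        ll = self._log_likelihood(eta, y)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            mu = expit(eta)
            score = X.T @ (y - mu)
            if np.max(np.abs(score)) < self.tol:
                converged = True
                break
            w = mu * (1.0 - mu)
            info = X.T @ (X * w[:, None])
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    "singular information matrix: collinear or degenerate "
                    "predictors"
                ) from exc
            # step-halving safeguard: never accept a likelihood decrease
            scale = 1.0
            for _ in range(50):
                candidate = beta + scale * step
                eta_new = X @ candidate
                ll_new = self._log_likelihood(eta_new, y)
                if ll_new >= ll - 1e-12:
                    break
                scale *= 0.5
            beta, eta, ll = candidate, eta_new, ll_new

        mu = expit(eta)
        diverged = np.max(np.abs(beta)) > 15
        perfectly_predicted = bool(np.all(np.abs(y - mu) < 1e-6))
        if diverged and (not converged or perfectly_predicted):
            raise SeparationError(
                "coefficients diverged "
                f"(max |beta| = {np.max(np.abs(beta)):.1f}); the data are "
                "consistent with perfect or quasi-perfect separation"
            )
        w = mu * (1.0 - mu)
        info = X.T @ (X * w[:, None])
        cov = np.linalg.inv(info)

        z = norm.ppf(1.0 - self.alpha / 2.0)
        se = np.sqrt(np.diag(cov))
        self.coef_ = beta
        self.cov_ = cov
        self.se_ = se
        self.odds_ratios_ = np.exp(beta)
        self.ci_ = np.column_stack([np.exp(beta - z * se), np.exp(beta + z * se)])
        self.n_used_ = n
        self.converged_ = converged
        self.n_iter_ = it
        self.log_likelihood_ = ll
        self._n_features = p - int(self.include_intercept)
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted("coef_")
        X = np.asarray(X, dtype=float)
        if self.include_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        eta = X @ self.coef_
        p1 = expit(eta)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _design_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    """Derive the standard binary covariates used by the published models."""
    out = pd.DataFrame(index=cohort.index)
    if "age_years" in cohort.columns:
        out["age_ge_65"] = (cohort["age_years"] >= 65).astype(float)
    if "sex" in cohort.columns:
        out["male"] = (cohort["sex"] == "male").astype(float)
    if "dementia" in cohort.columns:
        out["dementia"] = cohort["dementia"].astype(float)
    if "cci_cat" in cohort.columns:
        cci = cohort["cci_cat"]
        out["cci_gt_4"] = np.where(cci.isna(), np.nan, (cci == ">4").astype(float))
    elif "cci_excl_age_dementia" in cohort.columns:
        cci = cohort["cci_excl_age_dementia"].astype(float)
        out["cci_gt_4"] = np.where(cci.isna(), np.nan, (cci > 4).astype(float))
    return out


def fit_logistic(
    cohort: pd.DataFrame,
    spec: ModelSpec = MODEL_1A,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> FitResult:
    """Fit a model spec on a classified cohort frame (complete cases only)."""
    derived = _design_columns(cohort)
    frame = pd.DataFrame(index=cohort.index)
    for name in (spec.outcome,) + spec.predictors:
        if name in cohort.columns:
            frame[name] = pd.to_numeric(cohort[name], errors="coerce")
        elif name in derived.columns:
            frame[name] = derived[name]
        else:
            raise SchemaError(f"model variable {name!r} not found in cohort")
    frame = frame.dropna()
    y = frame[spec.outcome].to_numpy(dtype=float)
    X = frame[list(spec.predictors)].to_numpy(dtype=float)

    est = IRLSLogisticRegression(
        tol=tol, max_iter=max_iter, include_intercept=spec.include_intercept
    ).fit(X, y)

    terms = (["intercept"] if spec.include_intercept else []) + list(spec.predictors)
    aor = {
        name: dict(
            coef=float(est.coef_[k]),
            se=float(est.se_[k]),
            odds_ratio=float(est.odds_ratios_[k]),
            ci_low=float(est.ci_[k, 0]),
            ci_high=float(est.ci_[k, 1]),
        )
        for k, name in enumerate(terms)
    }
    return FitResult(
        terms=terms,
        coefficients=est.coef_,
        covariance=est.cov_,
        aor=aor,
        n_used=est.n_used_,
        converged=est.converged_,
        iterations=est.n_iter_,
        log_likelihood=est.log_likelihood_,
    )


def cap_subgroup_filter(cohort: pd.DataFrame) -> pd.DataFrame:
    """Sensitivity-analysis subgroup: radiologically confirmed CAP cases that
    were not recruited on the basis of their symptom profile."""
    for colname in ("cap_radiological", "recruited_by_symptom_criteria"):
        if colname not in cohort.columns:
            raise SchemaError(f"missing column {colname!r}")
    mask = (cohort["cap_radiological"] == 1) & (
        cohort["recruited_by_symptom_criteria"] == 0
    )
    return cohort.loc[mask]
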