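"""Contingency-table and two-sample statistics for cohort comparisons.

Everything here is implemented directly rather than delegated, so the
numerical behaviour (two-sided Fisher convention, tie/continuity handling
in the rank-sum test, asymptotic Kolmogorov distribution) is explicit and
auditable:

* Wald odds ratio and CI on the log scale, with an optional
  Haldane-Anscombe 0.5 correction for zero cells.
* Two-sided Fisher exact test by hypergeometric enumeration in log-gamma
  arithmetic (sum of all tables at most as probable as the observed one).
* Wilcoxon rank-sum test: exact enumeration for small pooled samples,
  otherwise the normal approximation with tie and continuity corrections.
* Two-sample Kolmogorov-Smirnov test with the asymptotic Kolmogorov
  distribution for the p-value.
* ``table1_summary`` — the descriptive comparison of patients meeting vs
  not meeting the case definition, one block per cohort characteristic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, ndtr
from scipy.stats import norm

from .errors import ValidationError
from .scores import CCI_CATEGORIES

#: Relative tolerance when comparing table probabilities in the two-sided
#: Fisher sum; guards against ties lost to floating-point rounding.
_FISHER_RELATIVE_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a,b,c,d = (E+O+, E+O-, E-O+, E-O-) for exposure E, outcome O."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"cell {name} must be a non-negative integer")
            object.__setattr__(self, name, int(v))
        if self.total == 0:
            raise ValidationError("contingency table must have a positive total")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped_rows(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)

    def transposed(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.a, self.c, self.b, self.d)


@dataclass(frozen=True)
class OddsRatioEstimate:
    """Point odds ratio with a Wald CI on the log scale."""

    or_point: float
    ci_low: float
    ci_high: float
    alpha: float
    log_se: float
    corrected: bool = field(default=False)

    def rounded(self, ndigits: int = 2) -> tuple:
        return (
            round(self.or_point, ndigits),
            round(self.ci_low, ndigits),
            round(self.ci_high, ndigits),
        )


def odds_ratio(
    t: ContingencyTable2x2, alpha: float = 0.05, zero_cell_policy: str = "correct"
) -> OddsRatioEstimate:
    """Wald odds ratio (a*d)/(b*c) with exp(log OR +/- z * SE) interval.

    Zero cells: with ``zero_cell_policy='correct'`` (default) the
    Haldane-Anscombe 0.5 is added to every cell and the result is flagged
    ``corrected``; with ``'refuse'`` a :class:`ValidationError` is raised.
    """
    a, b, c, d = (float(x) for x in (t.a, t.b, t.c, t.d))
    corrected = False
    if min(a, b, c, d) == 0:
        if zero_cell_policy == "refuse":
            raise ValidationError("zero cell in 2x2 table; odds ratio undefined")
        if zero_cell_policy != "correct":
            raise ValueError(f"unknown zero_cell_policy {zero_cell_policy!r}")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    z = norm.ppf(1.0 - alpha / 2.0)
    log_or = math.log(a * d) - math.log(b * c)
    log_se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatioEstimate(
        or_point=math.exp(log_or),
        ci_low=math.exp(log_or - z * log_se),
        ci_high=math.exp(log_or + z * log_se),
        alpha=alpha,
        log_se=log_se,
        corrected=corrected,
    )


def _hypergeom_log_pmf_vector(r1: int, c1: int, n: int) -> tuple[np.ndarray, int]:
    """Log-pmf of cell ``a`` over its support for fixed margins (r1, c1, n)."""
    r2 = n - r1
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    a = np.arange(lo, hi + 1)
    logp = (
        gammaln(r1 + 1)
        - gammaln(a + 1)
        - gammaln(r1 - a + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - a + 1)
        - gammaln(r2 - (c1 - a) + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    return logp, lo


def fisher_exact_p(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: sum of table probabilities <= observed.

    Enumerates the hypergeometric support in log-gamma arithmetic, so it is
    stable for cell counts well past 10^4. A degenerate margin yields p = 1.
    """
    n = t.total
    r1, c1 = t.a + t.b, t.a + t.c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    logp, lo = _hypergeom_log_pmf_vector(r1, c1, n)
    pmf = np.exp(logp - logp.max())
    pmf /= pmf.sum()
    p_obs = pmf[t.a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _FISHER_RELATIVE_TOL)].sum())
    return min(1.0, p)


def _midranks(pooled: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their midrank."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled), dtype=float)
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def wilcoxon_rank_sum_p(x, y, exact_threshold: int = 20) -> float:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum p-value.

    Exact enumeration of all rank assignments when the pooled sample size is
    at most ``exact_threshold``; otherwise the normal approximation with tie
    correction and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w_obs = ranks[:nx].sum()
    mean_w = nx * (n + 1) / 2.0

    if np.all(pooled == pooled[0]):
        return 1.0

    if n <= exact_threshold:
        # exact permutation distribution of the rank sum under H0
        count_le = 0
        count_ge = 0
        total = 0
        eps = 1e-9
        for idx in itertools.combinations(range(n), nx):
            w = ranks[list(idx)].sum()
            count_le += w <= w_obs + eps
            count_ge += w >= w_obs - eps
            total += 1
        p = 2.0 * min(count_le, count_ge) / total
        return min(1.0, p)

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3) - counts).sum())
    var_w = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:
        return 1.0
    diff = w_obs - mean_w
    # continuity correction toward the null
    diff = math.copysign(max(abs(diff) - 0.5, 0.0), diff)
    z = diff / math.sqrt(var_w)
    return float(2.0 * ndtr(-abs(z)))


def _kolmogorov_sf(lam: float, terms: int = 100) -> float:
    """Asymptotic Kolmogorov survival function Q(lambda) = 2 sum (-1)^{k-1} e^{-2k^2 lam^2}."""
    if lam <= 0:
        return 1.0
    total = 0.0
    for k in range(1, terms + 1):
        term = 2.0 * (-1.0) ** (k - 1) * math.exp(-2.0 * k * k * lam * lam)
        total += term
        if abs(term) < 1e-16:
            break
    return min(1.0, max(0.0, total))


def ks_two_sample_p(x, y) -> tuple[float, float]:
    """Two-sample KS test: returns (D, p) with p from the asymptotic distribution."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / x.size
    cdf_y = np.searchsorted(y, grid, side="right") / y.size
    d = float(np.abs(cdf_x - cdf_y).max())
    en = math.sqrt(x.size * y.size / (x.size + y.size))
    return d, _kolmogorov_sf(en * d)


# ---------------------------------------------------------------------------
# Descriptive cohort comparison (the Table-1-style summary)
# ---------------------------------------------------------------------------

_AGE_BAND_LABELS = (
    "18-24",
    "25-34",
    "35-44",
    "45-54",
    "55-64",
    "65-74",
    "75-84",
    "85+",
)


def _age_band_label(age: int) -> str:
    if age < 25:
        return "18-24"
    if age >= 85:
        return "85+"
    lo = 25 + 10 * ((age - 25) // 10)
    return f"{lo}-{lo + 9}"


def _fisher_binary(mask_meet: np.ndarray, mask_char: np.ndarray) -> float:
    a = int((mask_char & mask_meet).sum())
    b = int((mask_char & ~mask_meet).sum())
    c = int((~mask_char & mask_meet).sum())
    d = int((~mask_char & ~mask_meet).sum())
    return fisher_exact_p(ContingencyTable2x2(a, b, c, d))


def table1_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Characteristics of cases by whether symptoms meet the case definition.

    Requires a classified cohort (``meets_definition``, ``crb``, ``cci_cat``,
    ``frail`` columns present). Returns one row per characteristic level with
    counts, percentages and the block p-value. Test mapping: continuous /
    ordinal score variables use the Wilcoxon rank-sum test on the underlying
    values, dichotomous characteristics use the Fisher exact test. Unknown
    (missing) levels are reported as their own row with a whole-group
    percentage, but are excluded from the non-missing denominators and from
    every test statistic.
    """
    for col in ("meets_definition", "crb", "cci_cat", "frail"):
        if col not in cohort.columns:
            raise ValidationError(
                f"cohort is not classified: missing column {col!r}; "
                "run classify_cohort first"
            )
    meet = cohort["meets_definition"].to_numpy(dtype=bool)
    n_meet = int(meet.sum())
    n_not = int((~meet).sum())
    rows: list[dict] = []

    def add(characteristic, level, n_not_, pct_not, n_meet_, pct_meet, test, p):
        rows.append(
            dict(
                characteristic=characteristic,
                level=level,
                n_not_meeting=n_not_,
                pct_not_meeting=pct_not,
                n_meeting=n_meet_,
                pct_meeting=pct_meet,
                test=test,
                p_value=p,
            )
        )

    def categorical_block(name, values, p, test, order):
        vals = pd.Series(values, dtype="object")
        known = vals.notna().to_numpy()
        denom_not = int((known & ~meet).sum())
        denom_meet = int((known & meet).sum())
        levels = order if order is not None else sorted(set(vals.dropna()))
        for lev in levels:
            sel = (vals == lev).to_numpy()
            a_not = int((sel & ~meet).sum())
            a_meet = int((sel & meet).sum())
            add(
                name,
                str(lev),
                a_not,
                100.0 * a_not / denom_not if denom_not else np.nan,
                a_meet,
                100.0 * a_meet / denom_meet if denom_meet else np.nan,
                test,
                p,
            )
        n_unk_not = int((~known & ~meet).sum())
        n_unk_meet = int((~known & meet).sum())
        if n_unk_not or n_unk_meet:
            add(
                name,
                "Unknown",
                n_unk_not,
                100.0 * n_unk_not / n_not,
                n_unk_meet,
                100.0 * n_unk_meet / n_meet,
                test,
                np.nan,
            )

    def binary_block(name, values):
        vals = pd.Series(values, dtype="float")
        known = vals.notna().to_numpy()
        pos = (vals == 1).to_numpy()
        p = _fisher_binary(meet[known], pos[known])
        denom_not = int((known & ~meet).sum())
        denom_meet = int((known & meet).sum())
        a_not = int((pos & ~meet).sum())
        a_meet = int((pos & meet).sum())
        add(
            name,
            "yes",
            a_not,
            100.0 * a_not / denom_not if denom_not else np.nan,
            a_meet,
            100.0 * a_meet / denom_meet if denom_meet else np.nan,
            "fisher_exact",
            p,
        )
        n_unk_not = int((~known & ~meet).sum())
        n_unk_meet = int((~known & meet).sum())
        if n_unk_not or n_unk_meet:
            add(name, "Unknown", n_unk_not, 100.0 * n_unk_not / n_not,
                n_unk_meet, 100.0 * n_unk_meet / n_meet, "fisher_exact", np.nan)

    # 1. age in years: median and IQR bounds as separate rows, rank-sum p
    age = cohort["age_years"].to_numpy(dtype=float)
    p_age = wilcoxon_rank_sum_p(age[~meet], age[meet])
    for level, q in (("median", 50), ("iqr_low", 25), ("iqr_high", 75)):
        add(
            "age_years",
            level,
            float(np.percentile(age[~meet], q)) if n_not else np.nan,
            np.nan,
            float(np.percentile(age[meet], q)) if n_meet else np.nan,
            np.nan,
            "wilcoxon_rank_sum",
            p_age,
        )

    # 2. age bands: counts, block p from rank-sum on age (ordinal by construction)
    bands = [_age_band_label(int(a)) for a in cohort["age_years"]]
    categorical_block("age_group", bands, p_age, "wilcoxon_rank_sum", order=_AGE_BAND_LABELS)

    # 3-5. dichotomous characteristics
    binary_block("sars_cov2_positive", cohort["sars_cov2_positive"])
    vax = cohort["sars_cov2_vaccinated"].map({"yes": 1.0, "no": 0.0}).astype(float)
    binary_block("sars_cov2_vaccinated", vax)

    # 6. CRB score: counts per value, rank-sum on the score
    crb = cohort["crb"].to_numpy(dtype=float)
    known = ~np.isnan(crb)
    p_crb = wilcoxon_rank_sum_p(crb[known & ~meet], crb[known & meet])
    categorical_block(
        "crb",
        [None if np.isnan(v) else str(int(v)) for v in crb],
        p_crb,
        "wilcoxon_rank_sum",
        order=["0", "1", "2", "3"],
    )

    # 7-9. sex, care home, dementia
    binary_block("male_sex", (cohort["sex"] == "male").astype(float))
    binary_block("care_home", cohort["care_home"])
    binary_block("dementia", cohort["dementia"])

    # 10a. frailty (binary with unknowns)
    binary_block("frail", cohort["frail"])

    # 10b. comorbidity categories: rank-sum on the underlying score
    cci = cohort["cci_excl_age_dementia"].to_numpy(dtype=float)
    known = ~np.isnan(cci)
    p_cci = wilcoxon_rank_sum_p(cci[known & ~meet], cci[known & meet])
    categorical_block(
        "cci_cat",
        cohort["cci_cat"],
        p_cci,
        "wilcoxon_rank_sum",
        order=list(CCI_CATEGORIES),
    )

    return pd.DataFrame(rows)
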