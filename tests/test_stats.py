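"""Odds ratios, Fisher exact, rank-sum and KS tests against independent oracles."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.special
import scipy.stats as ss
from hypothesis import given
from hypothesis import strategies as st

from syndromic import reference as ref
from syndromic.errors import ValidationError
from syndromic.stats import (
    ContingencyTable2x2,
    fisher_exact_p,
    ks_two_sample_p,
    odds_ratio,
    table1_summary,
    wilcoxon_rank_sum_p,
)


def fisher_bruteforce(a, b, c, d) -> float:
    """Exact two-sided Fisher p with rational arithmetic (independent oracle)."""
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    if r1 == 0 or r2 == 0 or c1 == 0 or n - c1 == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {
        k: Fraction(comb(r1, k) * comb(r2, c1 - k), comb(n, c1))
        for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


cells = st.integers(min_value=0, max_value=60)


class TestOddsRatio:
    def test_published_age_contrast(self):
        meet_old, not_old, meet_young, not_young = ref.age_counts_ge_65()
        est = odds_ratio(
            ContingencyTable2x2(meet_old, not_old, meet_young, not_young)
        )
        assert est.rounded() == (0.62, 0.58, 0.66)

    def test_published_dementia_contrast(self):
        est = odds_ratio(ContingencyTable2x2(668, 1285, 8487 - 668, 9133 - 1285))
        assert round(est.or_point, 2) == 0.52

    def test_symmetric_table_is_exactly_one(self):
        est = odds_ratio(ContingencyTable2x2(10, 10, 10, 10))
        assert est.or_point == 1.0
        assert est.ci_low < 1.0 < est.ci_high

    @given(cells, cells, cells, cells)
    def test_row_swap_inverts_and_transpose_preserves(self, a, b, c, d):
        if min(a, b, c, d) == 0:
            return
        t = ContingencyTable2x2(a, b, c, d)
        assert abs(
            odds_ratio(t).or_point * odds_ratio(t.swapped_rows()).or_point - 1.0
        ) < 1e-12
        assert abs(
            odds_ratio(t).or_point - odds_ratio(t.transposed()).or_point
        ) < 1e-12

    def test_zero_cell_policies(self):
        t = ContingencyTable2x2(0, 10, 10, 10)
        est = odds_ratio(t)
        assert est.corrected and est.or_point > 0
        with pytest.raises(ValidationError):
            odds_ratio(t, zero_cell_policy="refuse")

    def test_wald_ci_coverage_under_the_null(self, rng):
        """95% CI contains OR=1 in 93-97% of 1,000 null tables at n=500."""
        cover = 0
        trials = 1000
        for _ in range(trials):
            x = rng.binomial(500, 0.3)
            y = rng.binomial(500, 0.3)
            if min(x, y) == 0 or max(x, y) == 500:
                trials -= 1
                continue
            est = odds_ratio(ContingencyTable2x2(x, 500 - x, y, 500 - y))
            cover += est.ci_low <= 1.0 <= est.ci_high
        assert 0.93 <= cover / trials <= 0.97


class TestFisherExact:
    def test_tea_tasting_scale_example(self):
        p = fisher_exact_p(ContingencyTable2x2(1, 9, 11, 3))
        assert abs(p - 0.0027594561852200836) < 1e-12

    def test_degenerate_margin_is_one(self):
        assert fisher_exact_p(ContingencyTable2x2(0, 0, 5, 7)) == 1.0
        assert fisher_exact_p(ContingencyTable2x2(3, 0, 4, 0)) == 1.0

    def test_published_male_sex_row_is_nonsignificant(self):
        p = fisher_exact_p(ContingencyTable2x2(4601, 4532, 4353, 4134))
        assert 0.15 < p < 0.30

    @given(cells, cells, cells, cells)
    def test_matches_bruteforce_enumeration(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        ours = fisher_exact_p(ContingencyTable2x2(a, b, c, d))
        assert abs(ours - fisher_bruteforce(a, b, c, d)) < 1e-9

    def test_stable_for_large_counts(self):
        p = fisher_exact_p(ContingencyTable2x2(4765, 6157, 3722, 2976))
        assert 0.0 <= p < 1e-40  # hugely significant age contrast


class TestWilcoxon:
    def test_identical_samples_give_one(self):
        assert wilcoxon_rank_sum_p([1, 2, 3], [1, 2, 3]) == 1.0

    def test_fully_separated_small_samples_exact(self):
        assert abs(wilcoxon_rank_sum_p([1, 2, 3], [4, 5, 6]) - 0.1) < 1e-12

    def test_all_tied_gives_one(self):
        assert wilcoxon_rank_sum_p([5.0] * 30, [5.0] * 40) == 1.0

    def test_exact_matches_scipy_permutation(self, rng):
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(0.5, 1, size=7)
            ours = wilcoxon_rank_sum_p(x, y)
            ref_p = ss.mannwhitneyu(x, y, method="exact").pvalue
            assert abs(ours - ref_p) < 1e-9

    def test_normal_approximation_matches_scipy(self, rng):
        for _ in range(10):
            x = rng.normal(size=120)
            y = np.round(rng.normal(0.2, 1, size=150), 1)  # induce ties
            ours = wilcoxon_rank_sum_p(x, y)
            ref_p = ss.mannwhitneyu(x, y, method="asymptotic").pvalue
            assert abs(ours - ref_p) < 1e-9

    def test_power_against_half_sd_shift(self, rng):
        detected = sum(
            wilcoxon_rank_sum_p(rng.normal(size=500), rng.normal(0.5, 1, size=500))
            < 1e-3
            for _ in range(100)
        )
        assert detected >= 99

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum_p([], [1.0])


class TestKolmogorovSmirnov:
    def test_identical_samples(self):
        d, p = ks_two_sample_p([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == 1.0

    def test_half_shifted_uniforms(self, rng):
        x = rng.uniform(0, 1, 1000)
        y = rng.uniform(0.5, 1.5, 1000)
        d, _ = ks_two_sample_p(x, y)
        assert abs(d - 0.5) < 0.05

    def test_statistic_matches_scipy_and_p_matches_kolmogorov_sf(self, rng):
        x = rng.normal(size=200)
        y = rng.normal(0.3, 1.2, size=240)
        d, p = ks_two_sample_p(x, y)
        assert abs(d - ss.ks_2samp(x, y).statistic) < 1e-12
        en = np.sqrt(200 * 240 / 440)
        assert abs(p - scipy.special.kolmogorov(en * d)) < 1e-9

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=150)
        y = rng.normal(0.4, 1, size=130)
        d1, p1 = ks_two_sample_p(x, y)
        d2, p2 = ks_two_sample_p(np.exp(x), np.exp(y))
        assert d1 == d2 and p1 == p2


def _exact_margin_cohort() -> pd.DataFrame:
    """Cohort whose classified margins equal the published counts exactly
    for status, care home, dementia, sex and age >= 65 (synthetic expansion
    of the published table; other fields filled with neutral values)."""
    meet_old, not_old, meet_young, not_young = ref.age_counts_ge_65()
    rows = {"meets": [], "age": [], "care": [], "dem": [], "male": []}
    for meets, n_group, n_old, n_care, n_dem, n_male in (
        (1, ref.N_MEETING, meet_old, ref.CARE_HOME[1], ref.DEMENTIA[1], ref.MALE_SEX[1]),
        (0, ref.N_NOT_MEETING, not_old, ref.CARE_HOME[0], ref.DEMENTIA[0], ref.MALE_SEX[0]),
    ):
        rows["meets"] += [meets] * n_group
        rows["age"] += [70] * n_old + [50] * (n_group - n_old)
        rows["care"] += [1] * n_care + [0] * (n_group - n_care)
        rows["dem"] += [1] * n_dem + [0] * (n_group - n_dem)
        rows["male"] += [1] * n_male + [0] * (n_group - n_male)
    n = len(rows["meets"])
    frame = pd.DataFrame(
        {
            "meets_definition": rows["meets"],
            "age_years": rows["age"],
            "care_home": rows["care"],
            "dementia": rows["dem"],
            "sex": np.where(np.array(rows["male"]) == 1, "male", "female"),
            "sars_cov2_positive": 0,
            "sars_cov2_vaccinated": "yes",
            "crb": 0.0,
            "frail": 0.0,
            "cci_excl_age_dementia": 0.0,
            "cci_cat": "0",
        }
    )
    return frame


class TestTable1Summary:
    def test_contains_all_characteristic_blocks(self, small_cohort):
        out = table1_summary(small_cohort)
        expected_blocks = {
            "age_years",
            "age_group",
            "sars_cov2_positive",
            "sars_cov2_vaccinated",
            "crb",
            "male_sex",
            "care_home",
            "dementia",
            "frail",
            "cci_cat",
        }
        assert set(out["characteristic"]) == expected_blocks

    def test_group_counts_conserve_patients(self, small_cohort):
        out = table1_summary(small_cohort)
        bands = out[out.characteristic == "age_group"]
        n = bands["n_not_meeting"].sum() + bands["n_meeting"].sum()
        assert n == len(small_cohort)

    def test_exact_margin_cohort_reproduces_printed_care_home_percent(self):
        out = table1_summary(_exact_margin_cohort())
        row = out[(out.characteristic == "care_home") & (out.level == "yes")].iloc[0]
        assert round(row.pct_not_meeting, 1) == 10.0
        assert round(row.pct_meeting, 1) == 5.7
        assert row.p_value < 0.001

    def test_unclassified_cohort_rejected(self):
        with pytest.raises(ValidationError, match="classified"):
            table1_summary(pd.DataFrame({"age_years": [50]}))

    def test_unknowns_reported_but_excluded_from_denominators(self, small_cohort):
        out = table1_summary(small_cohort)
        frail = out[out.characteristic == "frail"]
        assert "Unknown" in set(frail.level)
        known_yes = frail[frail.level == "yes"].iloc[0]
        n_known = small_cohort["frail"].notna()
        n_meet_known = int((n_known & (small_cohort.meets_definition == 1)).sum())
        expected_pct = 100.0 * known_yes.n_meeting / n_meet_known
        assert abs(known_yes.pct_meeting - expected_pct) < 1e-9
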