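"""Woolf 2x2 odds-ratio engine against textbook formulas and printed trials."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from vitd_rct import TwoByTwoTable, ZeroCellError, format_estimate, odds_ratio_ci
from vitd_rct.presets import LAPPE_2017_COUNTS, TABLE4_PRINTED_COUNTS, WHI_COUNTS


def textbook_woolf(a, b, c, d, z=1.959963984540054):
    """Independent direct computation of OR and Woolf CI."""
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return or_, math.exp(math.log(or_) - z * se), math.exp(math.log(or_) + z * se)


class TestPublishedTables:
    @pytest.mark.parametrize(
        "n, treat, control, rendered",
        [
            (1000, 11.7, 22.5, "0.51 (0.25–1.05)"),
            (1500, 17.5, 33.7, "0.51 (0.29–0.92)"),
            (2000, 23.3, 44.9, "0.51 (0.31–0.85)"),
        ],
    )
    def test_lowest_five_decile_sums(self, n, treat, control, rendered):
        est = odds_ratio_ci(
            TwoByTwoTable(
                treatment_cases=treat,
                treatment_person_years=n,
                control_cases=control,
                control_person_years=n,
            )
        )
        assert format_estimate(est) == rendered

    def test_nebraska_2007_three_year_totals(self):
        est = odds_ratio_ci(TABLE4_PRINTED_COUNTS["3 years"])
        assert format_estimate(est, with_p=True) == "0.70 (0.31–1.60, P = 0.40)"

    def test_nebraska_2007_four_year_totals(self):
        est = odds_ratio_ci(TABLE4_PRINTED_COUNTS["4 years"])
        assert round(est.odds_ratio, 2) == 0.71
        assert round(est.ci_lower, 2) == 0.35
        assert round(est.p_value, 2) == 0.34

    def test_whi_unsupplemented_subgroup(self):
        est = odds_ratio_ci(WHI_COUNTS)
        assert round(est.odds_ratio, 2) == 0.86

    def test_nebraska_2017_eight_thousand_person_years(self):
        est = odds_ratio_ci(LAPPE_2017_COUNTS)
        assert round(est.odds_ratio, 2) == 0.70


class TestEngine:
    def test_matches_textbook_on_integer_table(self):
        est = odds_ratio_ci(
            TwoByTwoTable(
                treatment_cases=10,
                treatment_person_years=100,
                control_cases=20,
                control_person_years=100,
            )
        )
        or_, lo, up = textbook_woolf(10, 90, 20, 80)
        assert est.odds_ratio == pytest.approx(or_, abs=1e-12)
        assert est.ci_lower == pytest.approx(lo, abs=1e-12)
        assert est.ci_upper == pytest.approx(up, abs=1e-12)

    def test_identical_arms_are_null(self):
        est = odds_ratio_ci(
            TwoByTwoTable(
                treatment_cases=7,
                treatment_person_years=500,
                control_cases=7,
                control_person_years=500,
            )
        )
        assert est.odds_ratio == 1.0
        assert est.p_value == pytest.approx(1.0, abs=1e-12)

    def test_relative_risk_differs_from_odds_ratio(self):
        est = odds_ratio_ci(
            TwoByTwoTable(
                treatment_cases=93.0,
                treatment_person_years=10_000,
                control_cases=126.5,
                control_person_years=10_000,
            )
        )
        assert est.relative_risk == pytest.approx(93.0 / 126.5, rel=1e-12)
        assert est.odds_ratio < est.relative_risk  # protective effect, OR more extreme

    def test_zero_cell_raises(self):
        with pytest.raises(ZeroCellError):
            odds_ratio_ci(
                TwoByTwoTable(
                    treatment_cases=0,
                    treatment_person_years=100,
                    control_cases=5,
                    control_person_years=100,
                )
            )

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(treatment_cases=-1, treatment_person_years=10, control_cases=1, control_person_years=10),
            dict(treatment_cases=11, treatment_person_years=10, control_cases=1, control_person_years=10),
            dict(treatment_cases=1, treatment_person_years=0, control_cases=1, control_person_years=10),
        ],
    )
    def test_invalid_tables_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TwoByTwoTable(**kwargs)


positive_cases = st.floats(min_value=0.5, max_value=500.0)
person_years = st.floats(min_value=1_000.0, max_value=50_000.0)


class TestProperties:
    @given(a=positive_cases, na=person_years, c=positive_cases, nc=person_years)
    def test_arm_swap_reciprocity(self, a, na, c, nc):
        fwd = odds_ratio_ci(TwoByTwoTable(a, na, c, nc))
        rev = odds_ratio_ci(TwoByTwoTable(c, nc, a, na))
        assert rev.odds_ratio == pytest.approx(1.0 / fwd.odds_ratio, rel=1e-9)
        assert rev.ci_lower == pytest.approx(1.0 / fwd.ci_upper, rel=1e-9)
        assert rev.ci_upper == pytest.approx(1.0 / fwd.ci_lower, rel=1e-9)
        assert rev.p_value == pytest.approx(fwd.p_value, rel=1e-9)

    @given(a=positive_cases, na=person_years, c=positive_cases, nc=person_years,
           k=st.floats(min_value=1.5, max_value=20.0))
    def test_scaling_cells_preserves_or_and_narrows_ci(self, a, na, c, nc, k):
        base = odds_ratio_ci(TwoByTwoTable(a, na, c, nc))
        scaled = odds_ratio_ci(TwoByTwoTable(k * a, k * na, k * c, k * nc))
        assert scaled.odds_ratio == pytest.approx(base.odds_ratio, rel=1e-9)
        assert scaled.ci_upper - scaled.ci_lower < base.ci_upper - base.ci_lower

    @given(a=positive_cases, na=person_years, c=positive_cases, nc=person_years,
           alpha=st.floats(min_value=0.005, max_value=0.5))
    def test_p_value_consistent_with_interval_at_any_alpha(self, a, na, c, nc, alpha):
        est = odds_ratio_ci(TwoByTwoTable(a, na, c, nc), alpha=alpha)
        outside = not (est.ci_lower <= 1.0 <= est.ci_upper)
        assert (est.p_value < alpha) == outside
        assert est.ci_lower <= est.odds_ratio <= est.ci_upper
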