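"""2x2 odds-ratio, relative-risk, Woolf confidence-interval and p-value.

With a = treatment cases, b = treatment non-cases, c = control cases,
d = control non-cases (non-cases = person-years − cases):

    OR  = (a/b) / (c/d)
    SE  = sqrt(1/a + 1/b + 1/c + 1/d)                    (Woolf)
    CI  = exp( ln OR ± z_{1−α/2} · SE )
    p   = two-sided normal tail probability of ln OR / SE
    RR  = (a/N_t) / (c/N_c)

Cell counts may be fractional: the model feeds expected (mean) counts
into the same asymptotic formulas used for observed integer counts.  No
continuity correction and no exact test are applied.  Published trial
reports in this setting usually label the estimate "RR" even when the
printed numbers are odds ratios, so both OR and RR are returned
explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = ["TwoByTwoTable", "EffectEstimate", "ZeroCellError", "odds_ratio_ci", "format_estimate"]


class ZeroCellError(ValueError):
    """Raised when a 2x2 cell is zero.

    The Woolf variance is undefined at zero cells; continuity
    corrections are out of scope for expected-count inputs, which are
    strictly positive whenever the incidence rate is.
    """


@dataclass(frozen=True)
class TwoByTwoTable:
    """Cases and person-years per arm; fractional expected counts allowed."""

    treatment_cases: float
    treatment_person_years: float
    control_cases: float
    control_person_years: float

    def __post_init__(self) -> None:
        if self.treatment_cases < 0 or self.control_cases < 0:
            raise ValueError("case counts must be non-negative")
        if self.treatment_person_years <= 0 or self.control_person_years <= 0:
            raise ValueError("person-years must be positive")
        if (
            self.treatment_cases >= self.treatment_person_years
            or self.control_cases >= self.control_person_years
        ):
            raise ValueError("cases must be fewer than person-years in each arm")

    @property
    def cells(self) -> tuple:
        """(a, b, c, d): treatment cases/non-cases, control cases/non-cases."""
        return (
            self.treatment_cases,
            self.treatment_person_years - self.treatment_cases,
            self.control_cases,
            self.control_person_years - self.control_cases,
        )


@dataclass(frozen=True)
class EffectEstimate:
    """Odds ratio with Woolf confidence interval, p-value and relative risk."""

    odds_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    relative_risk: float
    alpha: float


def odds_ratio_ci(table: TwoByTwoTable, alpha: float = 0.05) -> EffectEstimate:
    """Odds ratio with Woolf (log-normal) confidence interval on a 2x2 table.

    The p-value and the interval use the same normal quantile, so
    ``p < alpha`` exactly when 1.0 lies outside the interval.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha!r}")
    a, b, c, d = table.cells
    if min(a, b, c, d) <= 0:
        raise ZeroCellError(
            "all four 2x2 cells must be positive for the Woolf interval; "
            "continuity corrections are out of scope for expected-count inputs"
        )
    odds_ratio = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    log_or = math.log(odds_ratio)
    p_value = 2.0 * stats.norm.sf(abs(log_or) / se)
    return EffectEstimate(
        odds_ratio=odds_ratio,
        ci_lower=math.exp(log_or - z * se),
        ci_upper=math.exp(log_or + z * se),
        p_value=float(p_value),
        relative_risk=(a / table.treatment_person_years) / (c / table.control_person_years),
        alpha=alpha,
    )


def format_estimate(est: EffectEstimate, with_p: bool = False) -> str:
    """Render an estimate as ``"0.51 (0.25–1.05)"`` (en dash, 2 decimals)."""
    s = f"{est.odds_ratio:.2f} ({est.ci_lower:.2f}–{est.ci_upper:.2f}"
    if with_p:
        s += f", P = {est.p_value:.2f}"
    return s + ")"
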