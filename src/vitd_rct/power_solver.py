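"""Required person-years per arm and OR/CI-versus-N power curves.

The significance criterion is the one used to read sample sizes off
OR/CI plots: a design is significant at level α once the upper
(1−α) Woolf confidence bound on the expected-count odds ratio falls
below 1.0.  Because the expected-count OR does not depend on N while
its log-scale standard error shrinks like 1/sqrt(N), the upper bound is
monotone decreasing in N for a protective effect and the crossing is
unique, so a simple scan over multiples of the step finds it exactly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import pandas as pd

from .expected_cases import expected_cases
from .scenario import TrialScenario
from .trial_stats import EffectEstimate, TwoByTwoTable, odds_ratio_ci

__all__ = [
    "PowerCurve",
    "NoProtectiveEffectError",
    "estimate_at",
    "power_curve",
    "required_n",
]

DEFAULT_N_MAX = 1_000_000.0


class NoProtectiveEffectError(RuntimeError):
    """Raised when the scenario's odds ratio is >= 1.

    The upper confidence bound then never falls below 1.0, so no finite
    person-years requirement exists.
    """


@dataclass(frozen=True)
class PowerCurve:
    """OR and Woolf CI evaluated on a grid of person-years per arm."""

    rows: Tuple[Tuple[float, float, float, float, float], ...]
    """(person_years_per_arm, odds_ratio, ci_lower, ci_upper, p_value) rows."""

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.rows),
            columns=["person_years_per_arm", "odds_ratio", "ci_lower", "ci_upper", "p_value"],
        )

    def to_csv(self, path_or_buf: Union[str, io.TextIOBase]) -> None:
        self.to_dataframe().to_csv(path_or_buf, index=False)


def estimate_at(scenario: TrialScenario, person_years_per_arm: float) -> EffectEstimate:
    """Expected-count effect estimate at the given per-arm person-years."""
    table = expected_cases(scenario.with_person_years(person_years_per_arm))
    two_by_two = TwoByTwoTable(
        treatment_cases=table.treatment_total,
        treatment_person_years=table.treatment_person_years,
        control_cases=table.control_total,
        control_person_years=table.control_person_years,
    )
    return odds_ratio_ci(two_by_two, alpha=scenario.alpha)


def power_curve(scenario: TrialScenario, n_grid: Sequence[float]) -> PowerCurve:
    """Evaluate OR and Woolf CI at each person-years value in ``n_grid``.

    The grid must be positive and strictly increasing.  The odds ratio
    is identical across rows (the expected-count effect size does not
    depend on N); only the interval narrows.
    """
    grid = [float(n) for n in n_grid]
    if len(grid) == 0:
        raise ValueError("n_grid must be non-empty")
    if any(n <= 0 for n in grid):
        raise ValueError("n_grid values must be positive")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("n_grid must be strictly increasing")
    rows = []
    for n in grid:
        est = estimate_at(scenario, n)
        rows.append((n, est.odds_ratio, est.ci_lower, est.ci_upper, est.p_value))
    return PowerCurve(rows=tuple(rows))


def required_n(
    scenario: TrialScenario,
    step: float = 100.0,
    n_max: float = DEFAULT_N_MAX,
) -> Optional[float]:
    """Smallest multiple of ``step`` at which the upper CI bound is < 1.0.

    Returns ``None`` when ``n_max`` person-years per arm are not enough
    to reach significance (the "not reached" sentinel).

    Raises
    ------
    NoProtectiveEffectError
        If the scenario's expected-count odds ratio is >= 1, in which
        case no amount of person-years yields significance.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if n_max < step:
        raise ValueError("n_max must be at least one step")
    if estimate_at(scenario, step).odds_ratio >= 1.0:
        raise NoProtectiveEffectError(
            "expected-count odds ratio is >= 1; the upper confidence bound "
            "cannot fall below 1.0 at any sample size"
        )
    n = step
    while n <= n_max + 1e-9:
        if estimate_at(scenario, n).ci_upper < 1.0:
            return n
        n += step
    return None
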