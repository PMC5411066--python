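"""Expected cancer cases per baseline-25(OH)D decile and trial arm.

For decile i with baseline concentration b_i, achieved concentration a_i
(from the status model at the scenario dose, or an explicit override)
and N_i person-years in the arm, the expected case counts are

    control_i   = r · N_i · OR(b_i) / mean_OR
    treatment_i = r · N_i · OR(a_i) / mean_OR

where r is the assumed population incidence rate and mean_OR is the
arithmetic mean of the baseline odds ratios over the FULL reference
population's deciles, not just the enrolled subset.  The normalization
makes the model reproduce the population incidence exactly when the
whole population is enrolled untreated: summing control_i over all
deciles gives r · N_total by construction.

Counts are expected values and stay fractional; rounding to one decimal
happens only when rendering reports.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import List, Tuple, Union

import pandas as pd

from .dose_response import DoseResponseCurve
from .scenario import PopulationDistribution, TrialScenario

__all__ = ["ExpectedCaseRow", "ExpectedCaseTable", "normalizing_mean_or", "expected_cases"]


def normalizing_mean_or(
    curve: DoseResponseCurve, population: PopulationDistribution
) -> float:
    """Arithmetic mean of baseline odds ratios over all population deciles."""
    baselines = population.decile_baselines
    if len(baselines) == 0:
        raise ValueError("population has no deciles")
    return sum(curve.odds_ratio_at(b) for b in baselines) / len(baselines)


@dataclass(frozen=True)
class ExpectedCaseRow:
    """Per-decile expected cases for both arms."""

    baseline: float
    achieved: float
    control_person_years: float
    treatment_person_years: float
    control_cases: float
    treatment_cases: float


@dataclass(frozen=True)
class ExpectedCaseTable:
    """Per-decile expected cases plus arm totals."""

    rows: Tuple[ExpectedCaseRow, ...]
    control_total: float
    treatment_total: float
    control_person_years: float
    treatment_person_years: float

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                (
                    r.baseline,
                    r.achieved,
                    r.control_person_years,
                    r.treatment_person_years,
                    r.control_cases,
                    r.treatment_cases,
                )
                for r in self.rows
            ],
            columns=[
                "baseline_ng_ml",
                "achieved_ng_ml",
                "control_person_years",
                "treatment_person_years",
                "control_cases",
                "treatment_cases",
            ],
        )
        return df

    def to_csv(self, path_or_buf: Union[str, io.TextIOBase]) -> None:
        self.to_dataframe().to_csv(path_or_buf, index=False)


def expected_cases(scenario: TrialScenario) -> ExpectedCaseTable:
    """Expected cancer cases per selected decile for both trial arms.

    Achieved concentrations come from the scenario's status model at its
    dose unless an ``achieved_override`` is set; a zero dose leaves the
    treatment arm at baseline.
    """
    curve = scenario.curve
    mean_or = normalizing_mean_or(curve, scenario.population)
    r = scenario.incidence_rate
    weights = scenario.allocation_weights()
    n_control = scenario.control_person_years
    n_treatment = scenario.treatment_person_years

    rows: List[ExpectedCaseRow] = []
    for k, (idx, w) in enumerate(zip(scenario.selected_deciles, weights)):
        baseline = scenario.population.decile_baselines[idx]
        if scenario.achieved_override is not None:
            achieved = scenario.achieved_override[k]
        else:
            achieved = scenario.status_model.achieved(baseline, scenario.dose)
        nc_i = n_control * w
        nt_i = n_treatment * w
        rows.append(
            ExpectedCaseRow(
                baseline=baseline,
                achieved=achieved,
                control_person_years=nc_i,
                treatment_person_years=nt_i,
                control_cases=r * nc_i * curve.odds_ratio_at(baseline) / mean_or,
                treatment_cases=r * nt_i * curve.odds_ratio_at(achieved) / mean_or,
            )
        )
    return ExpectedCaseTable(
        rows=tuple(rows),
        control_total=sum(r_.control_cases for r_ in rows),
        treatment_total=sum(r_.treatment_cases for r_ in rows),
        control_person_years=n_control,
        treatment_person_years=n_treatment,
    )
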