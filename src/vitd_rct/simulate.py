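"""Monte Carlo individual-level trial simulator.

The analytic model works with expected case counts; this module draws
the counts instead, to validate the analytic results and to estimate
empirical power.  Person-years are allocated deterministically across
the selected deciles (equal blocks by default); within decile i each
control person-year becomes a case independently with probability
r·OR(b_i)/mean_OR and each treatment person-year with probability
r·OR(a_i)/mean_OR — exactly the per-person-year hazards the analytic
model integrates, so the simulated means converge to the analytic
expected counts.  Only the case events are random.

A replicate is significant when the Woolf upper confidence bound on its
observed 2x2 table falls below 1.0.  Replicates with any zero cell are
counted as non-significant rather than dropped, which matters only at
very small sample sizes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .expected_cases import normalizing_mean_or
from .scenario import TrialScenario

__all__ = ["SimulationResult", "simulate_trial"]


@dataclass(frozen=True)
class SimulationResult:
    """Per-replicate case counts and significance flags."""

    replicates: int
    control_cases: Tuple[int, ...]
    treatment_cases: Tuple[int, ...]
    significant: Tuple[bool, ...]
    empirical_power: float
    mean_control_cases: float
    mean_treatment_cases: float
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "control_cases": self.control_cases,
                "treatment_cases": self.treatment_cases,
                "significant": self.significant,
            }
        )

    def to_csv(self, path_or_buf: Union[str, io.TextIOBase]) -> None:
        self.to_dataframe().to_csv(path_or_buf, index=False)


def simulate_trial(
    scenario: TrialScenario, replicates: int, seed: int
) -> SimulationResult:
    """Simulate the trial ``replicates`` times; reproducible from ``seed``.

    Person-years per decile are rounded to whole years for the binomial
    draws.  Raises a validation error if any per-person-year case
    probability reaches 1.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    curve = scenario.curve
    mean_or = normalizing_mean_or(curve, scenario.population)
    r = scenario.incidence_rate
    weights = scenario.allocation_weights()

    n_control = []
    n_treatment = []
    p_control = []
    p_treatment = []
    for k, (idx, w) in enumerate(zip(scenario.selected_deciles, weights)):
        baseline = scenario.population.decile_baselines[idx]
        if scenario.achieved_override is not None:
            achieved = scenario.achieved_override[k]
        else:
            achieved = scenario.status_model.achieved(baseline, scenario.dose)
        pc = r * curve.odds_ratio_at(baseline) / mean_or
        pt = r * curve.odds_ratio_at(achieved) / mean_or
        if pc >= 1.0 or pt >= 1.0:
            raise ValueError(
                f"per-person-year case probability reaches 1 in the decile "
                f"with baseline {baseline:g} ng/mL (control {pc:.3g}, "
                f"treatment {pt:.3g}); lower the incidence rate or arm size"
            )
        n_control.append(int(round(scenario.control_person_years * w)))
        n_treatment.append(int(round(scenario.treatment_person_years * w)))
        p_control.append(pc)
        p_treatment.append(pt)

    rng = np.random.default_rng(seed)
    # One binomial draw per (decile, replicate); summing deciles gives the
    # per-replicate arm totals.
    control = np.zeros(replicates, dtype=np.int64)
    treatment = np.zeros(replicates, dtype=np.int64)
    for n, p in zip(n_control, p_control):
        control += rng.binomial(n, p, size=replicates)
    for n, p in zip(n_treatment, p_treatment):
        treatment += rng.binomial(n, p, size=replicates)

    nt = float(sum(n_treatment))
    nc = float(sum(n_control))
    a = treatment.astype(float)
    c = control.astype(float)
    b = nt - a
    d = nc - c
    valid = (a > 0) & (b > 0) & (c > 0) & (d > 0)
    z = stats.norm.ppf(1.0 - scenario.alpha / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_or = np.log((a / b) / (c / d))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        upper = np.exp(log_or + z * se)
    significant = valid & (upper < 1.0)

    return SimulationResult(
        replicates=replicates,
        control_cases=tuple(int(x) for x in control),
        treatment_cases=tuple(int(x) for x in treatment),
        significant=tuple(bool(x) for x in significant),
        empirical_power=float(np.mean(significant)),
        mean_control_cases=float(np.mean(control)),
        mean_treatment_cases=float(np.mean(treatment)),
        seed=seed,
    )
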