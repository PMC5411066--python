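"""Trial design scenarios: population, dose, rate and arm-size inputs.

A :class:`TrialScenario` bundles everything needed to evaluate a
two-arm vitamin D supplementation trial design: the reference population
(decile midpoints of baseline 25(OH)D), the subset of deciles enrolled,
the daily dose, the assumed annual cancer incidence rate, person-years
per arm, the dose-response curve and the status-response model.

Person-years, not participant counts, are the primitive unit of
exposure: one participant followed for one year contributes one
person-year, so an N-participant arm followed for Y years can be
expressed either as N·Y person-years directly or via the ``years``
multiplier.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Tuple, Union

import yaml

from .dose_response import DoseResponseCurve
from .status_response import DEFAULT_DECILE_BASELINES, StatusResponseModel

__all__ = [
    "PopulationDistribution",
    "TrialScenario",
    "ScenarioConfigError",
    "CANADIAN_50_79",
    "load_scenario",
    "scenario_from_config",
    "scenario_to_config",
    "save_scenario",
]

logger = logging.getLogger(__name__)


class ScenarioConfigError(ValueError):
    """Raised for missing, ill-typed or inconsistent scenario config keys."""


@dataclass(frozen=True)
class PopulationDistribution:
    """Decile midpoints of baseline 25(OH)D for a reference population.

    ``decile_baselines`` must be non-empty, strictly increasing and all
    at least 1 ng/mL (the dose-response evaluation floor).
    """

    decile_baselines: Tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.decile_baselines)
        object.__setattr__(self, "decile_baselines", vals)
        if len(vals) == 0:
            raise ScenarioConfigError("decile_baselines must be non-empty")
        if any(v < 1.0 for v in vals):
            raise ScenarioConfigError("all decile baselines must be >= 1 ng/mL")
        if any(b >= a for b, a in zip(vals, vals[1:])):
            raise ScenarioConfigError("decile baselines must be strictly increasing")

    def __len__(self) -> int:
        return len(self.decile_baselines)


#: Decile midpoints of baseline 25(OH)D for Canadian adults aged 50-79 y.
CANADIAN_50_79 = PopulationDistribution(
    DEFAULT_DECILE_BASELINES, label="Canadian adults aged 50-79 y"
)


@dataclass(frozen=True)
class TrialScenario:
    """A two-arm supplementation trial design.

    Parameters
    ----------
    population
        Reference population whose full decile set defines the
        normalization of the expected-case model, regardless of which
        deciles are enrolled.
    selected_deciles
        0-based indices into ``population.decile_baselines`` of the
        enrolled deciles (default: all).
    dose
        Daily vitamin D3 dose in the treatment arm, IU/d.
    incidence_rate
        Annual cancer incidence as cases per person-year (default
        0.0176, i.e. 1760 per 100,000 per year, US all-cancer incidence
        at ages 65-69).
    person_years_per_arm
        Person-years of follow-up in the control arm (and in the
        treatment arm unless overridden).
    treatment_person_years_per_arm
        Optional unequal treatment-arm exposure.
    years
        Multiplier applied to both arms' person-years, for the
        "N participants x Y years" style of bookkeeping.
    achieved_override
        Optional achieved 25(OH)D concentrations (ng/mL), one per
        selected decile, used instead of the status model.
    decile_weights
        Optional relative allocation weights over the selected deciles
        (default: equal allocation).
    alpha
        Two-sided significance level for confidence intervals.
    """

    population: PopulationDistribution = CANADIAN_50_79
    selected_deciles: Optional[Tuple[int, ...]] = None
    dose: float = 2000.0
    incidence_rate: float = 0.0176
    person_years_per_arm: float = 4000.0
    treatment_person_years_per_arm: Optional[float] = None
    years: float = 1.0
    curve: DoseResponseCurve = field(default_factory=DoseResponseCurve)
    status_model: StatusResponseModel = field(default_factory=StatusResponseModel)
    alpha: float = 0.05
    achieved_override: Optional[Tuple[float, ...]] = None
    decile_weights: Optional[Tuple[float, ...]] = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.selected_deciles is None:
            object.__setattr__(
                self, "selected_deciles", tuple(range(len(self.population)))
            )
        else:
            object.__setattr__(
                self, "selected_deciles", tuple(int(i) for i in self.selected_deciles)
            )
        sel = self.selected_deciles
        if len(sel) == 0:
            raise ScenarioConfigError("selected_deciles must be a non-empty subset")
        if len(set(sel)) != len(sel):
            raise ScenarioConfigError("selected_deciles contains duplicates")
        if any(i < 0 or i >= len(self.population) for i in sel):
            raise ScenarioConfigError(
                f"selected_deciles out of range for a population of "
                f"{len(self.population)} deciles: {sel}"
            )
        # Zero is tolerated so null-rate simulations can run; analytic
        # 2x2 statistics still require a positive rate.
        if not (0.0 <= self.incidence_rate < 1.0):
            raise ScenarioConfigError(
                f"incidence_rate must be in [0, 1) cases per person-year, "
                f"got {self.incidence_rate!r}"
            )
        if not self.person_years_per_arm > 0:
            raise ScenarioConfigError("person_years_per_arm must be positive")
        if self.treatment_person_years_per_arm is not None:
            if not self.treatment_person_years_per_arm > 0:
                raise ScenarioConfigError("treatment_person_years_per_arm must be positive")
        if not self.years > 0:
            raise ScenarioConfigError("years must be positive")
        if self.dose < 0:
            raise ScenarioConfigError("dose must be non-negative")
        if not (0.0 < self.alpha < 1.0):
            raise ScenarioConfigError("alpha must be in (0, 1)")
        if self.achieved_override is not None:
            ov = tuple(float(v) for v in self.achieved_override)
            if len(ov) != len(sel):
                raise ScenarioConfigError(
                    "achieved_override must give one concentration per selected decile"
                )
            object.__setattr__(self, "achieved_override", ov)
        if self.decile_weights is not None:
            w = tuple(float(v) for v in self.decile_weights)
            if len(w) != len(sel) or any(v <= 0 for v in w):
                raise ScenarioConfigError(
                    "decile_weights must be positive, one per selected decile"
                )
            object.__setattr__(self, "decile_weights", w)

    # ------------------------------------------------------------------
    @property
    def selected_baselines(self) -> Tuple[float, ...]:
        """Baseline 25(OH)D of the enrolled deciles, ng/mL."""
        return tuple(self.population.decile_baselines[i] for i in self.selected_deciles)

    @property
    def control_person_years(self) -> float:
        """Total control-arm person-years after the years multiplier."""
        return self.person_years_per_arm * self.years

    @property
    def treatment_person_years(self) -> float:
        """Total treatment-arm person-years after the years multiplier."""
        base = (
            self.treatment_person_years_per_arm
            if self.treatment_person_years_per_arm is not None
            else self.person_years_per_arm
        )
        return base * self.years

    def allocation_weights(self) -> Tuple[float, ...]:
        """Normalized allocation fractions over the selected deciles."""
        if self.decile_weights is None:
            n = len(self.selected_deciles)
            return tuple(1.0 / n for _ in range(n))
        total = sum(self.decile_weights)
        return tuple(w / total for w in self.decile_weights)

    def with_person_years(self, person_years_per_arm: float) -> "TrialScenario":
        """Copy of this scenario with both arms set to the given person-years."""
        return dataclasses.replace(
            self,
            person_years_per_arm=person_years_per_arm,
            treatment_person_years_per_arm=None,
            years=1.0,
        )


# ----------------------------------------------------------------------
# Config serialization.  Flat keys; deciles are 1-based in configs to
# match the convention of published decile tables.

_CONFIG_KEYS = {
    "label", "population", "population_label", "deciles", "dose",
    "incidence_rate", "person_years_per_arm", "treatment_person_years_per_arm",
    "years", "alpha", "coefficient", "exponent", "min_concentration",
    "backend", "achieved_override", "decile_weights",
}


def scenario_from_config(config: Mapping[str, object]) -> TrialScenario:
    """Build a validated :class:`TrialScenario` from a flat config mapping.

    Every omitted key falls back to a documented default, logged at load
    time so a rendered result is auditable.
    """
    unknown = set(config) - _CONFIG_KEYS
    if unknown:
        raise ScenarioConfigError(f"unknown scenario config keys: {sorted(unknown)}")

    def _get(key: str, default: object) -> object:
        if key in config:
            return config[key]
        logger.info("scenario config: %s defaulted to %r", key, default)
        return default

    try:
        if "population" in config:
            population = PopulationDistribution(
                tuple(config["population"]),  # type: ignore[arg-type]
                label=str(config.get("population_label", "")),
            )
        else:
            population = CANADIAN_50_79
            logger.info("scenario config: population defaulted to %s", population.label)
        deciles_1based = config.get("deciles")
        selected = (
            tuple(int(d) - 1 for d in deciles_1based)  # type: ignore[union-attr]
            if deciles_1based is not None
            else None
        )
        curve = DoseResponseCurve(
            coefficient=float(_get("coefficient", 18.3)),
            exponent=float(_get("exponent", -0.833)),
            min_concentration=float(config.get("min_concentration", 1.0)),
        )
        status_model = StatusResponseModel(
            str(_get("backend", StatusResponseModel.CALIBRATION))
        )
        treatment_py = config.get("treatment_person_years_per_arm")
        achieved = config.get("achieved_override")
        weights = config.get("decile_weights")
        return TrialScenario(
            population=population,
            selected_deciles=selected,
            dose=float(_get("dose", 2000.0)),
            incidence_rate=float(_get("incidence_rate", 0.0176)),
            person_years_per_arm=float(_get("person_years_per_arm", 4000.0)),
            treatment_person_years_per_arm=(
                float(treatment_py) if treatment_py is not None else None  # type: ignore[arg-type]
            ),
            years=float(config.get("years", 1.0)),
            curve=curve,
            status_model=status_model,
            alpha=float(_get("alpha", 0.05)),
            achieved_override=(
                tuple(float(v) for v in achieved) if achieved is not None else None  # type: ignore[union-attr]
            ),
            decile_weights=(
                tuple(float(v) for v in weights) if weights is not None else None  # type: ignore[union-attr]
            ),
            label=str(config.get("label", "")),
        )
    except ScenarioConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ScenarioConfigError(f"ill-typed scenario config value: {exc}") from exc


def scenario_to_config(scenario: TrialScenario) -> dict:
    """Flat config mapping that round-trips through :func:`scenario_from_config`."""
    cfg: dict = {
        "population": list(scenario.population.decile_baselines),
        "population_label": scenario.population.label,
        "deciles": [i + 1 for i in scenario.selected_deciles],
        "dose": scenario.dose,
        "incidence_rate": scenario.incidence_rate,
        "person_years_per_arm": scenario.person_years_per_arm,
        "years": scenario.years,
        "alpha": scenario.alpha,
        "coefficient": scenario.curve.coefficient,
        "exponent": scenario.curve.exponent,
        "min_concentration": scenario.curve.min_concentration,
        "backend": scenario.status_model.backend,
        "label": scenario.label,
    }
    if scenario.treatment_person_years_per_arm is not None:
        cfg["treatment_person_years_per_arm"] = scenario.treatment_person_years_per_arm
    if scenario.achieved_override is not None:
        cfg["achieved_override"] = list(scenario.achieved_override)
    if scenario.decile_weights is not None:
        cfg["decile_weights"] = list(scenario.decile_weights)
    return cfg


def load_scenario(source: Union[str, Path, Mapping[str, object]]) -> TrialScenario:
    """Load a scenario from a YAML file path or an in-memory mapping."""
    if isinstance(source, Mapping):
        return scenario_from_config(source)
    with open(source, "r") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise ScenarioConfigError(f"scenario file {source} does not contain a mapping")
    return scenario_from_config(config)


def save_scenario(scenario: TrialScenario, path: Union[str, Path]) -> None:
    """Write a scenario as a flat-key YAML config."""
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_config(scenario), fh, sort_keys=False)
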