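"""Serum 25(OH)D concentration → disease odds-ratio dose-response curve.

The disease-association model is a power law

    OR(c) = coefficient · c ** exponent

with ``c`` the serum 25-hydroxyvitamin D concentration in ng/mL.  The
default constants (18.3, −0.833) describe the pooled inverse association
between 25(OH)D status and breast-cancer incidence across eleven
case-control studies, used here as a proxy for all-cancer incidence.
With a negative exponent the odds ratio falls monotonically as vitamin D
status improves; OR = 1 is reached near 33 ng/mL.

Concentrations are ng/mL throughout; multiply by 2.5 for nmol/L
(:func:`ng_to_nmol`).  The conversion is never applied implicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np

__all__ = [
    "DoseResponseCurve",
    "ConcentrationBelowFloorError",
    "odds_ratio_at",
    "fit_power_law",
    "ng_to_nmol",
    "nmol_to_ng",
    "NMOL_PER_NG_ML",
]

#: nmol/L per ng/mL of 25(OH)D.
NMOL_PER_NG_ML = 2.5


def ng_to_nmol(concentration_ng_ml: float) -> float:
    """Convert a 25(OH)D concentration from ng/mL to nmol/L."""
    return concentration_ng_ml * NMOL_PER_NG_ML


def nmol_to_ng(concentration_nmol_l: float) -> float:
    """Convert a 25(OH)D concentration from nmol/L to ng/mL."""
    return concentration_nmol_l / NMOL_PER_NG_ML


class ConcentrationBelowFloorError(ValueError):
    """Raised when a curve is evaluated below its concentration floor.

    The power law diverges at zero concentration, so evaluation requests
    below ``min_concentration`` are rejected rather than clamped.
    """


@dataclass(frozen=True)
class DoseResponseCurve:
    """Power-law mapping of serum 25(OH)D (ng/mL) to a disease odds ratio.

    Parameters
    ----------
    coefficient
        Multiplicative constant on the odds-ratio scale; must be positive.
    exponent
        Power-law exponent.  Negative values give a protective
        (decreasing) association with rising concentration.
    min_concentration
        Evaluation floor in ng/mL.  Requests below it raise
        :class:`ConcentrationBelowFloorError`.
    """

    coefficient: float = 18.3
    exponent: float = -0.833
    min_concentration: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.coefficient) and self.coefficient > 0):
            raise ValueError(f"coefficient must be positive, got {self.coefficient!r}")
        if not math.isfinite(self.exponent):
            raise ValueError(f"exponent must be finite, got {self.exponent!r}")
        if not (math.isfinite(self.min_concentration) and self.min_concentration > 0):
            raise ValueError(
                f"min_concentration must be positive, got {self.min_concentration!r}"
            )

    def odds_ratio_at(self, concentration: float) -> float:
        """Evaluate the curve at ``concentration`` ng/mL.

        Raises
        ------
        ConcentrationBelowFloorError
            If ``concentration`` is below ``min_concentration`` (this
            includes zero and negative inputs).
        """
        c = float(concentration)
        if not c >= self.min_concentration:
            raise ConcentrationBelowFloorError(
                f"concentration {c!r} ng/mL is below the evaluation floor "
                f"of {self.min_concentration} ng/mL"
            )
        return self.coefficient * c ** self.exponent


def odds_ratio_at(curve: DoseResponseCurve, concentration: float) -> float:
    """Functional alias for :meth:`DoseResponseCurve.odds_ratio_at`."""
    return curve.odds_ratio_at(concentration)


def fit_power_law(
    points: Iterable[Tuple[float, float]],
    min_concentration: float = 1.0,
) -> DoseResponseCurve:
    """Least-squares power-law fit of odds ratios on concentrations.

    Fits ``log(OR) = log(coefficient) + exponent · log(c)`` by ordinary
    least squares, so points lying exactly on one power law are recovered
    exactly.

    Parameters
    ----------
    points
        Pairs of (concentration ng/mL, odds ratio), all strictly positive;
        at least two distinct concentrations are required.
    min_concentration
        Floor assigned to the returned curve.
    """
    pts: Sequence[Tuple[float, float]] = list(points)
    if len(pts) < 2:
        raise ValueError(f"need at least 2 points to fit a power law, got {len(pts)}")
    conc = np.asarray([p[0] for p in pts], dtype=float)
    odds = np.asarray([p[1] for p in pts], dtype=float)
    if np.any(conc <= 0) or np.any(odds <= 0):
        raise ValueError("all concentrations and odds ratios must be strictly positive")
    if np.unique(conc).size < 2:
        raise ValueError("concentrations must include at least two distinct values")
    exponent, log_coeff = np.polyfit(np.log(conc), np.log(odds), 1)
    return DoseResponseCurve(
        coefficient=float(np.exp(log_coeff)),
        exponent=float(exponent),
        min_concentration=min_concentration,
    )
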