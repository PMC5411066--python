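"""Rendering of preset scenarios as publication-style tables.

Each renderer runs its scenario end-to-end through the expected-case
model and the 2x2 statistics and formats the numbers the way trial
reports print them: case counts to one decimal, odds ratios and
confidence bounds to two, "OR (lo–up)" strings with an en dash.
Rendering is a pure function of the numeric results; a numeric
DataFrame always accompanies the pretty strings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Sequence, Tuple

import pandas as pd

from . import presets
from .expected_cases import expected_cases
from .power_solver import estimate_at, power_curve, required_n
from .trial_stats import format_estimate, odds_ratio_ci

__all__ = ["ReportTable", "render_paper_table", "PRESET_NAMES"]

PRESET_NAMES = ("table2", "table3", "table4_totals", "table5", "fig3", "fig4")


@dataclass(frozen=True)
class ReportTable:
    """A rendered table: title, column labels, string rows, numeric frame."""

    title: str
    columns: Tuple[str, ...]
    rows: Tuple[Tuple[str, ...], ...]
    data: pd.DataFrame

    def __str__(self) -> str:
        widths = [
            max(len(self.columns[j]), *(len(r[j]) for r in self.rows))
            for j in range(len(self.columns))
        ]
        lines = [self.title]
        lines.append("  ".join(c.ljust(w) for c, w in zip(self.columns, widths)))
        for row in self.rows:
            lines.append("  ".join(v.ljust(w) for v, w in zip(row, widths)))
        return "\n".join(lines)


def _render_table2() -> ReportTable:
    base = presets.table2_scenario()
    doses = (0.0, 400.0, 1000.0, 2000.0, 4000.0)
    per_dose = []
    for dose in doses:
        scen = replace(base, dose=dose)
        per_dose.append(expected_cases(scen))
    baselines = [row.baseline for row in per_dose[0].rows]
    records = []
    for i, b in enumerate(baselines):
        rec = {"decile": i + 1, "baseline_ng_ml": b}
        for dose, tab in zip(doses, per_dose):
            rec[f"cases_{int(dose)}_iu_d"] = tab.rows[i].treatment_cases
        records.append(rec)
    df = pd.DataFrame(records)
    rows: List[Tuple[str, ...]] = []
    for rec in records:
        rows.append(
            (str(rec["decile"]), f"{rec['baseline_ng_ml']:g}")
            + tuple(f"{rec[f'cases_{int(d)}_iu_d']:.1f}" for d in doses)
        )
    rows.append(
        ("Sum", "")
        + tuple(f"{tab.treatment_total:.1f}" for tab in per_dose)
    )
    return ReportTable(
        title=(
            "Expected cancer cases per baseline-25(OH)D decile, 400 "
            "person-years per decile per arm, by daily vitamin D3 dose"
        ),
        columns=("Decile", "Baseline (ng/mL)", "Baseline cases", "400 IU/d",
                 "1000 IU/d", "2000 IU/d", "4000 IU/d"),
        rows=tuple(rows),
        data=df,
    )


def _render_sum_table(
    scenario, n_values: Sequence[float], title: str
) -> ReportTable:
    per_decile = expected_cases(scenario.with_person_years(400.0 * len(scenario.selected_deciles)))
    curve = power_curve(scenario, list(n_values))
    records = []
    rows: List[Tuple[str, ...]] = []
    for i, row in enumerate(per_decile.rows):
        rows.append(
            (
                str(scenario.selected_deciles[i] + 1),
                "400",
                f"{row.baseline:g}",
                f"{row.control_cases:.1f}",
                f"{row.treatment_cases:.1f}",
                "",
            )
        )
    for n in n_values:
        table = expected_cases(scenario.with_person_years(n))
        est = estimate_at(scenario, n)
        records.append(
            {
                "person_years_per_arm": n,
                "control_cases": table.control_total,
                "treatment_cases": table.treatment_total,
                "odds_ratio": est.odds_ratio,
                "ci_lower": est.ci_lower,
                "ci_upper": est.ci_upper,
                "p_value": est.p_value,
            }
        )
        rows.append(
            (
                "Sum",
                f"{n:g}",
                "",
                f"{table.control_total:.1f}",
                f"{table.treatment_total:.1f}",
                format_estimate(est),
            )
        )
    return ReportTable(
        title=title,
        columns=("Decile", "N (person-years)", "Baseline (ng/mL)",
                 "Cases, control arm", "Cases, treatment arm", "OR (95% CI)"),
        rows=tuple(rows),
        data=curve.to_dataframe().assign(
            control_cases=[r["control_cases"] for r in records],
            treatment_cases=[r["treatment_cases"] for r in records],
        ),
    )


def _render_table3() -> ReportTable:
    return _render_sum_table(
        presets.table3_scenario(),
        (1000.0, 1500.0, 2000.0),
        "Lowest five deciles of baseline 25(OH)D, 2000 IU/d",
    )


def _render_table5() -> ReportTable:
    return _render_sum_table(
        presets.table5_scenario(),
        (2000.0, 4000.0, 10000.0),
        "Highest five deciles of baseline 25(OH)D, 2000 IU/d",
    )


def _render_table4_totals() -> ReportTable:
    records = []
    rows: List[Tuple[str, ...]] = []
    for period, counts in presets.TABLE4_PRINTED_COUNTS.items():
        est = odds_ratio_ci(counts)
        records.append(
            {
                "period": period,
                "control_person_years": counts.control_person_years,
                "treatment_person_years": counts.treatment_person_years,
                "control_cases": counts.control_cases,
                "treatment_cases": counts.treatment_cases,
                "odds_ratio": est.odds_ratio,
                "ci_lower": est.ci_lower,
                "ci_upper": est.ci_upper,
                "p_value": est.p_value,
            }
        )
        rows.append(
            (
                f"Total, {period}",
                f"{counts.control_person_years:g}",
                f"{counts.treatment_person_years:g}",
                f"{counts.control_cases:.1f}",
                f"{counts.treatment_cases:.1f}",
                format_estimate(est, with_p=True),
            )
        )
    return ReportTable(
        title=(
            "Five deciles centred at 29 ng/mL, 1000 IU/d: 2x2 statistics on "
            "the model-expected totals (placebo 266 and treatment 403 "
            "participants, 3 or 4 years)"
        ),
        columns=("Period", "N placebo (p-y)", "N treatment (p-y)",
                 "Cases, control arm", "Cases, treatment arm", "OR (95% CI)"),
        rows=tuple(rows),
        data=pd.DataFrame(records),
    )


def _render_required_n(scenario, title: str) -> ReportTable:
    n_star = required_n(scenario, step=100.0)
    grid = [n for n in (500.0, 1000.0, 2000.0, 4000.0, 8000.0) if n_star is None or n <= 2 * n_star]
    if n_star is not None and n_star not in grid:
        grid = sorted(set(grid) | {n_star})
    curve = power_curve(scenario, grid)
    rows = tuple(
        (f"{n:g}", f"{or_:.2f}", f"{lo:.2f}", f"{up:.2f}")
        for n, or_, lo, up, _p in curve.rows
    )
    rows += ((f"required N = {n_star:g}" if n_star is not None else "required N not reached", "", "", ""),)
    return ReportTable(
        title=title,
        columns=("N (person-years/arm)", "OR", "95% CI lower", "95% CI upper"),
        rows=rows,
        data=curve.to_dataframe(),
    )


def _render_fig3() -> ReportTable:
    return _render_required_n(
        presets.fig3_scenario(),
        "OR and 95% CI vs person-years per arm: baseline 14 ng/mL, achieved 34 ng/mL (2000 IU/d)",
    )


def _render_fig4() -> ReportTable:
    return _render_required_n(
        presets.fig4_scenario(),
        "OR and 95% CI vs person-years per arm: baseline 26 ng/mL, achieved 42 ng/mL (2000 IU/d)",
    )


_RENDERERS = {
    "table2": _render_table2,
    "table3": _render_table3,
    "table4_totals": _render_table4_totals,
    "table5": _render_table5,
    "fig3": _render_fig3,
    "fig4": _render_fig4,
}


def render_paper_table(name: str) -> ReportTable:
    """Run a named preset end-to-end and render it in the standard layout."""
    try:
        renderer = _RENDERERS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(_RENDERERS)}"
        ) from None
    return renderer()
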