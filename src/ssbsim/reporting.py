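"""Scenario orchestration and presentation tables.

Internal pipelines carry full precision; rounding (event counts to the
nearest 100, percent changes to one decimal) happens only here, at
presentation.  Percent change is always delta / base-case total x 100,
where the base case assumes no change in SSB consumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .costs import per_patient_cost, scenario_cost_savings, total_diabetes_cost
from .engine import calibrate, run_simulation
from .exposure import ScenarioDefinition
from .model import DECILE_LABELS, SEXES, SchemaError, SimulationResult

EVENT_OUTCOMES = (
    "incident_chd",
    "incident_stroke",
    "mi",
    "chd_deaths",
    "stroke_deaths",
    "all_cause_deaths",
)

DEFAULT_GRID: Tuple[Tuple[float, float], ...] = (
    (0.10, 1.00),
    (0.10, 0.39),
    (0.10, 0.00),
    (0.20, 1.00),
    (0.20, 0.39),
    (0.20, 0.00),
)


@dataclass
class ScenarioGrid:
    """The set of (reduction, compensation) scenario pairs to simulate."""

    pairs: Tuple[Tuple[float, float], ...] = DEFAULT_GRID
    horizon_years: int = 10
    start_year: int = 2013

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise SchemaError("scenario grid contains duplicate pairs")

    def scenarios(self) -> List[ScenarioDefinition]:
        return [
            ScenarioDefinition(
                reduction_fraction=r,
                compensation_fraction=c,
                horizon_years=self.horizon_years,
                start_year=self.start_year,
            )
            for r, c in self.pairs
        ]


def percent_change(delta: float, base_total: float) -> float:
    """Percent change from the base case, rounded to one decimal.

    ``delta`` is the number of events prevented (or dollars saved);
    ``base_total`` is the base-case total the presentation tables report
    percentages against.
    """
    if base_total <= 0:
        raise ValueError("base total must be positive")
    return round(100.0 * delta / base_total, 1)


def round_to_hundred(x: float) -> float:
    """Round an event count to the nearest 100 (presentation granularity)."""
    return float(round(x / 100.0) * 100.0)


@dataclass
class GridResults:
    """Everything produced by one scenario-grid run."""

    base: SimulationResult
    scenarios: Dict[Tuple[float, float], SimulationResult]
    cost_table: "pd.Series"
    base_cost_millions: float
    savings_millions: Dict[Tuple[float, float], float]
    risks: object  # calibrated RiskFunctionSet actually used


def run_scenario_grid(
    bundle,
    grid: Optional[ScenarioGrid] = None,
    calibrate_first: bool = True,
) -> GridResults:
    """Calibrate (optionally), run the base case and every grid scenario,
    and compute per-scenario diabetes cost savings."""
    grid = grid or ScenarioGrid()
    risks = bundle.risks
    if calibrate_first:
        risks = calibrate(bundle.baseline, risks, bundle.targets, bundle.demography)
    base = run_simulation(
        bundle.baseline, risks, bundle.demography,
        consumption=bundle.consumption, params=bundle.effect_params,
        horizon_years=grid.horizon_years, start_year=grid.start_year,
    )
    costs = per_patient_cost(bundle.cost_inputs)
    base_cost = total_diabetes_cost(base, costs)
    results: Dict[Tuple[float, float], SimulationResult] = {}
    savings: Dict[Tuple[float, float], float] = {}
    for scen in grid.scenarios():
        key = (scen.reduction_fraction, scen.compensation_fraction)
        res = run_simulation(
            bundle.baseline, risks, bundle.demography, scenario=scen,
            consumption=bundle.consumption, params=bundle.effect_params,
        )
        results[key] = res
        savings[key] = scenario_cost_savings(base, res, costs)["cumulative_millions"]
    return GridResults(
        base=base,
        scenarios=results,
        cost_table=costs.dollars,
        base_cost_millions=base_cost,
        savings_millions=savings,
        risks=risks,
    )


def build_results_tables(
    grid_results: GridResults,
    uis: Optional[Dict[Tuple[float, float], Dict[str, Tuple[float, float]]]] = None,
) -> Dict[str, pd.DataFrame]:
    """Presentation tables for a scenario-grid run.

    Returns a dict with keys:
      ``diabetes``   — per scenario: diabetes cases prevented (rounded to the
                       nearest 100), optional 95% UI, percent change from the
                       base case, cost savings (millions) and percent;
      ``cvd_events`` — per scenario x outcome: events/deaths avoided with
                       percent change;
      ``by_age``     — age-decile-stratified cases/events prevented;
      ``by_sex``     — sex-stratified versions.
    Direction: all tabulated values are reductions relative to the base case.
    """
    gr = grid_results
    base_dm = gr.base.cumulative("incident_diabetes")
    rows = []
    for key, res in gr.scenarios.items():
        prevented = base_dm - res.cumulative("incident_diabetes")
        ui = uis.get(key, {}).get("incident_diabetes") if uis else None
        saving = gr.savings_millions[key]
        cost_ui = uis.get(key, {}).get("cost_savings_millions") if uis else None
        rows.append(
            {
                "reduction": key[0],
                "compensation": key[1],
                "cases_prevented": round_to_hundred(prevented),
                "cases_lower95": round_to_hundred(ui[0]) if ui else np.nan,
                "cases_upper95": round_to_hundred(ui[1]) if ui else np.nan,
                "percent_change": percent_change(prevented, base_dm),
                "cost_savings_millions": round(saving, 0),
                "savings_lower95": round(cost_ui[0], 0) if cost_ui else np.nan,
                "savings_upper95": round(cost_ui[1], 0) if cost_ui else np.nan,
                "cost_percent_change": percent_change(saving, gr.base_cost_millions),
            }
        )
    diabetes = pd.DataFrame(rows)

    rows = []
    for key, res in gr.scenarios.items():
        for outcome in EVENT_OUTCOMES:
            base_total = gr.base.cumulative(outcome)
            avoided = base_total - res.cumulative(outcome)
            ui = uis.get(key, {}).get(outcome) if uis else None
            rows.append(
                {
                    "reduction": key[0],
                    "compensation": key[1],
                    "outcome": outcome,
                    "base_case_total": round_to_hundred(base_total),
                    "events_avoided": round_to_hundred(avoided),
                    "lower95": round_to_hundred(ui[0]) if ui else np.nan,
                    "upper95": round_to_hundred(ui[1]) if ui else np.nan,
                    "percent_change": percent_change(avoided, base_total),
                }
            )
    cvd = pd.DataFrame(rows)

    rows = []
    for key, res in gr.scenarios.items():
        for outcome in ("incident_diabetes",) + EVENT_OUTCOMES:
            base_dec = gr.base.cumulative_by_decile(outcome)
            scen_dec = res.cumulative_by_decile(outcome)
            for d, label in enumerate(DECILE_LABELS):
                rows.append(
                    {
                        "reduction": key[0],
                        "compensation": key[1],
                        "outcome": outcome,
                        "age_group": label,
                        "events_avoided": float(base_dec[d] - scen_dec[d]),
                        "percent_change": percent_change(
                            base_dec[d] - scen_dec[d], base_dec[d]
                        )
                        if base_dec[d] > 0
                        else 0.0,
                    }
                )
    by_age = pd.DataFrame(rows)

    rows = []
    for key, res in gr.scenarios.items():
        for outcome in ("incident_diabetes",) + EVENT_OUTCOMES:
            base_sex = gr.base.cumulative_by_sex(outcome)
            scen_sex = res.cumulative_by_sex(outcome)
            for s, sex in enumerate(SEXES):
                rows.append(
                    {
                        "reduction": key[0],
                        "compensation": key[1],
                        "outcome": outcome,
                        "sex": sex,
                        "events_avoided": float(base_sex[s] - scen_sex[s]),
                    }
                )
    by_sex = pd.DataFrame(rows)
    return {"diabetes": diabetes, "cvd_events": cvd, "by_age": by_age, "by_sex": by_sex}
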