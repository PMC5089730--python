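"""Diabetes healthcare cost accounting.

Per-patient annual direct costs are built bottom-up from institution-level
tables: unit costs are total expenditure divided by service counts; mean
services used per diabetes patient per year (by age decile) are priced at
those unit costs and summed over service types; institution-level costs are
averaged with weights equal to the share of diabetes patients treated at
each institution; and pesos are converted to international dollars at a
purchasing-power-parity rate (7.67 pesos per international dollar) then
inflated to the reporting year (3.57%).

Scenario savings attach those per-patient costs to the reduction in
prevalent-diabetes person-years relative to the base case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .model import DECILE_LABELS, N_DECILES, SchemaError, SimulationResult

SERVICES = ("generalist_visit", "specialist_visit", "hospital_day")
INSTITUTIONS = ("A", "B", "C")


@dataclass
class CurrencyParameters:
    ppp_rate: float = 7.67  # pesos per international dollar
    inflation_rate: float = 0.0357

    def __post_init__(self) -> None:
        if self.ppp_rate <= 0:
            raise SchemaError("ppp_rate must be positive")

    def pesos_to_dollars(self, pesos):
        """PPP-convert and inflate to reporting-year international dollars."""
        return np.asarray(pesos, dtype=float) / self.ppp_rate * (1.0 + self.inflation_rate)

    def dollars_to_pesos(self, dollars):
        return np.asarray(dollars, dtype=float) * self.ppp_rate / (1.0 + self.inflation_rate)


@dataclass
class CostInputs:
    """Institution-level expenditure/utilization tables and weights.

    ``expenditures`` and ``service_counts``: DataFrames indexed by
    institution with one column per service (pesos / counts).
    ``services_per_patient``: mean annual services used per diabetes
    patient, indexed by (institution, age_group), one column per service.
    ``institution_weights``: DataFrame indexed by age_group, one column per
    institution, rows summing to 1.
    """

    expenditures: pd.DataFrame
    service_counts: pd.DataFrame
    services_per_patient: pd.DataFrame
    institution_weights: pd.DataFrame
    currency: CurrencyParameters = field(default_factory=CurrencyParameters)

    def __post_init__(self) -> None:
        for name in ("expenditures", "service_counts"):
            df = getattr(self, name)
            if list(df.columns) != list(SERVICES):
                raise SchemaError(f"{name} must have columns {SERVICES}")
            if (df.to_numpy() < 0).any():
                raise SchemaError(f"{name} must be non-negative")
        w = self.institution_weights
        if (w.to_numpy() < 0).any():
            raise SchemaError("institution weights must be non-negative")
        sums = w.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise SchemaError(
                f"institution weights must sum to 1 per age decile, got {sums.to_dict()}"
            )


@dataclass
class CostPerPatientTable:
    """Mean annual direct cost per diabetes patient, by age decile."""

    dollars: pd.Series  # index: age_group, 2012 international dollars
    pesos: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if (self.dollars < 0).any():
            raise SchemaError("per-patient costs must be non-negative")

    def as_array(self) -> np.ndarray:
        return self.dollars.reindex(list(DECILE_LABELS)).to_numpy()


def unit_costs(inputs: CostInputs) -> pd.DataFrame:
    """Cost per service: expenditure total / service count, per institution."""
    exp = inputs.expenditures
    cnt = inputs.service_counts
    bad = (cnt.to_numpy() == 0) & (exp.to_numpy() > 0)
    if bad.any():
        raise ValueError("service count of zero with positive expenditure")
    with np.errstate(invalid="ignore", divide="ignore"):
        uc = exp.to_numpy() / np.where(cnt.to_numpy() > 0, cnt.to_numpy(), 1.0)
    return pd.DataFrame(uc, index=exp.index, columns=exp.columns)


def per_patient_cost(inputs: CostInputs) -> CostPerPatientTable:
    """Weighted mean annual direct cost per diabetes patient by age decile.

    Per decile: sum over institutions of
    weight x sum over services (mean services x unit cost), in pesos, then
    PPP-converted and inflated to international dollars.
    """
    uc = unit_costs(inputs)
    deciles = inputs.institution_weights.index
    pesos = pd.Series(0.0, index=deciles)
    for inst in inputs.expenditures.index:
        spp = inputs.services_per_patient.xs(inst, level="institution").reindex(deciles)
        inst_cost = (spp * uc.loc[inst]).sum(axis=1)  # pesos per patient-year
        pesos = pesos + inputs.institution_weights[inst] * inst_cost
    dollars = pd.Series(inputs.currency.pesos_to_dollars(pesos), index=deciles)
    return CostPerPatientTable(dollars=dollars, pesos=pesos)


def total_diabetes_cost(
    result: SimulationResult, costs: CostPerPatientTable, discount_rate: float = 0.0
) -> float:
    """Total direct diabetes cost over the horizon, million international dollars."""
    per_cost = costs.as_array()  # (deciles,)
    py = result.tallies["diabetes_person_years"].sum(axis=1)  # (years, deciles)
    yearly = py @ per_cost
    disc = (1.0 + discount_rate) ** -np.arange(len(result.years))
    return float((yearly * disc).sum() / 1e6)


def scenario_cost_savings(
    base: SimulationResult,
    scenario: SimulationResult,
    costs: CostPerPatientTable,
    discount_rate: float = 0.0,
) -> Dict[str, object]:
    """Diabetes cost savings of a scenario relative to the base case.

    Savings = (base prevalent-diabetes person-years - scenario person-years)
    x per-patient cost, summed over years and age deciles.  Returned in
    millions of international dollars with a per-year breakdown.
    """
    if base.years != scenario.years:
        raise SchemaError("base and scenario results must share the same years")
    per_cost = costs.as_array()
    base_py = base.tallies["diabetes_person_years"].sum(axis=1)
    scen_py = scenario.tallies["diabetes_person_years"].sum(axis=1)
    yearly = (base_py - scen_py) @ per_cost
    disc = (1.0 + discount_rate) ** -np.arange(len(base.years))
    yearly = yearly * disc
    return {
        "per_year_millions": pd.Series(yearly / 1e6, index=base.years),
        "cumulative_millions": float(yearly.sum() / 1e6),
    }
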