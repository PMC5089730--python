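"""The SSB exposure chain: consumption units, tax-induced reduction,
calorie compensation, weight/BMI change, SBP change, and the direct
diabetes-incidence multiplier.

A tax-driven reduction in sugar-sweetened beverage (SSB) intake acts on the
model through three pathways: (1) a direct, BMI-independent increase in
diabetes risk per daily serving (relative risk 1.19 per 355-ml serving),
reversed proportionally when consumption falls; (2) a direct SBP effect per
serving (0.78 mm Hg in men, 0.61 in women); and (3) a mediated pathway in
which net calorie change (after partial compensation from other foods)
changes steady-state weight at 3,500 kcal per pound, hence BMI, which in
turn shifts SBP (1.43/1.24 mm Hg per BMI unit in men/women) and flows
through the BMI terms of the risk functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict

import numpy as np
import pandas as pd

from .model import DECILE_LABELS, N_DECILES, N_SEXES, SEXES, SchemaError

DAYS_PER_YEAR = 365.0


@dataclass
class EffectParameters:
    """Effect sizes and unit conversions of the exposure chain.

    ``mean_height_m`` defaults are plausible adult mean heights by sex used to
    convert weight change to BMI change; they are placeholders to be replaced
    with survey-derived values when available.
    """

    rr_diabetes_per_serving: float = 1.19
    rr_diabetes_ci: tuple = (1.09, 1.31)
    sbp_per_serving: Dict[str, float] = field(
        default_factory=lambda: {"men": 0.78, "women": 0.61}
    )
    sbp_per_serving_ci: Dict[str, tuple] = field(
        default_factory=lambda: {"men": (0.09, 1.47), "women": (-0.27, 1.48)}
    )
    sbp_per_bmi_unit: Dict[str, float] = field(
        default_factory=lambda: {"men": 1.43, "women": 1.24}
    )
    kcal_per_serving: float = 150.0
    ml_per_serving: float = 355.0
    kcal_per_pound: float = 3500.0
    kg_per_pound: float = 0.45359237
    mean_height_m: Dict[str, float] = field(
        default_factory=lambda: {"men": 1.64, "women": 1.53}
    )
    beta_multiplier: float = 1.0
    # optional linear phase-in of the steady-state weight change over n years;
    # 1 means the full change applies from year 1 onward
    weight_phase_in_years: int = 1

    def __post_init__(self) -> None:
        if self.rr_diabetes_per_serving <= 0:
            raise SchemaError("rr_diabetes_per_serving must be positive")
        if self.kcal_per_pound <= 0:
            raise SchemaError("kcal_per_pound must be positive")
        for sex, h in self.mean_height_m.items():
            if not 1.0 < h < 2.2:
                raise SchemaError(f"mean height for {sex} must be in (1.0, 2.2) m, got {h}")
        if self.beta_multiplier <= 0:
            raise SchemaError("beta_multiplier must be positive")

    def copy(self) -> "EffectParameters":
        return EffectParameters(
            rr_diabetes_per_serving=self.rr_diabetes_per_serving,
            rr_diabetes_ci=tuple(self.rr_diabetes_ci),
            sbp_per_serving=dict(self.sbp_per_serving),
            sbp_per_serving_ci=dict(self.sbp_per_serving_ci),
            sbp_per_bmi_unit=dict(self.sbp_per_bmi_unit),
            kcal_per_serving=self.kcal_per_serving,
            ml_per_serving=self.ml_per_serving,
            kcal_per_pound=self.kcal_per_pound,
            kg_per_pound=self.kg_per_pound,
            mean_height_m=dict(self.mean_height_m),
            beta_multiplier=self.beta_multiplier,
            weight_phase_in_years=self.weight_phase_in_years,
        )


@dataclass
class ScenarioDefinition:
    """A sustained proportional reduction in SSB consumption.

    ``reduction_fraction`` is the fraction by which mean daily SSB intake
    falls from year 1 onward (0.10 corresponds to the consumption decline
    observed after a 10% excise tax, consistent with soda price elasticities
    of -0.72 to -1.30). ``compensation_fraction`` is the fraction of removed
    SSB calories replaced by calories from other sources.
    """

    reduction_fraction: float = 0.10
    compensation_fraction: float = 0.39
    horizon_years: int = 10
    start_year: int = 2013

    def __post_init__(self) -> None:
        if not 0.0 <= self.reduction_fraction <= 1.0:
            raise SchemaError("reduction_fraction must be in [0, 1]")
        if not 0.0 <= self.compensation_fraction <= 1.0:
            raise SchemaError("compensation_fraction must be in [0, 1]")
        if self.horizon_years < 1:
            raise ValueError("horizon_years must be at least 1")

    def label(self) -> str:
        return (
            f"{self.reduction_fraction:.0%} reduction, "
            f"{self.compensation_fraction:.0%} compensation"
        )


class ConsumptionSummary:
    """Sex x age-decile summary of daily SSB consumption.

    Wraps a DataFrame indexed by (sex, age_group) with columns
    ``volume_ml``, ``volume_se``, ``servings``, ``calories``.
    """

    def __init__(self, table: pd.DataFrame, params: EffectParameters | None = None):
        params = params or EffectParameters()
        required_idx = pd.MultiIndex.from_product(
            [SEXES, DECILE_LABELS], names=["sex", "age_group"]
        )
        missing = required_idx.difference(table.index)
        if len(missing):
            raise SchemaError(f"consumption table missing strata: {list(missing)}")
        table = table.loc[required_idx].copy()
        if "servings" not in table:
            table["servings"] = table["volume_ml"] / params.ml_per_serving
        if "calories" not in table:
            table["calories"] = table["servings"] * params.kcal_per_serving
        if (table[["volume_ml", "servings", "calories"]] < 0).any().any():
            raise SchemaError("consumption values must be non-negative")
        self.table = table
        self.params = params

    @classmethod
    def from_tsv(cls, path, params: EffectParameters | None = None) -> "ConsumptionSummary":
        df = pd.read_csv(path, sep="\t")
        df = df[df["age_group"] != "total"].set_index(["sex", "age_group"])
        return cls(df, params)

    @classmethod
    def mexico_2012(cls, params: EffectParameters | None = None) -> "ConsumptionSummary":
        """The shipped national survey summary of adult SSB intake (2012)."""
        ref = resources.files("ssbsim.data") / "ssb_consumption_2012.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path, params)

    def servings_array(self) -> np.ndarray:
        """Mean daily servings as a (sex, decile) array."""
        return self.table["servings"].to_numpy().reshape(N_SEXES, N_DECILES)


@dataclass
class RiskFactorDelta:
    """Per sex x age-decile reductions implied by a scenario.

    All arrays have shape (N_SEXES, N_DECILES).  Deltas are positive
    magnitudes of *reduction*; ``diabetes_rate_multiplier`` multiplies the
    incident-diabetes hazard (<= 1 for any positive reduction).
    """

    delta_servings: np.ndarray
    net_delta_kcal: np.ndarray
    delta_weight_kg: np.ndarray
    delta_bmi: np.ndarray
    delta_sbp: np.ndarray
    diabetes_rate_multiplier: np.ndarray

    def __post_init__(self) -> None:
        for name in (
            "delta_servings",
            "net_delta_kcal",
            "delta_weight_kg",
            "delta_bmi",
            "delta_sbp",
            "diabetes_rate_multiplier",
        ):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_SEXES, N_DECILES):
                raise SchemaError(f"{name} must have shape ({N_SEXES}, {N_DECILES})")
            setattr(self, name, arr)

    @classmethod
    def identity(cls) -> "RiskFactorDelta":
        z = np.zeros((N_SEXES, N_DECILES))
        return cls(z.copy(), z.copy(), z.copy(), z.copy(), z.copy(), np.ones_like(z))


def volume_to_servings(volume_ml, params: EffectParameters | None = None):
    """Convert a daily SSB volume (ml) to servings/day (355 ml per serving)."""
    params = params or EffectParameters()
    volume_ml = np.asarray(volume_ml, dtype=float)
    if np.any(volume_ml < 0):
        raise ValueError("volume must be non-negative")
    out = volume_ml / params.ml_per_serving
    return float(out) if out.ndim == 0 else out


def servings_to_calories(servings, params: EffectParameters | None = None):
    """Convert servings/day to kcal/day (150 kcal per serving)."""
    params = params or EffectParameters()
    servings = np.asarray(servings, dtype=float)
    if np.any(servings < 0):
        raise ValueError("servings must be non-negative")
    out = servings * params.kcal_per_serving
    return float(out) if out.ndim == 0 else out


def net_calorie_reduction_fraction(compensation_fraction: float) -> float:
    """Fraction of removed SSB calories that actually leave the diet."""
    if not 0.0 <= compensation_fraction <= 1.0:
        raise ValueError("compensation_fraction must be in [0, 1]")
    return 1.0 - compensation_fraction


def compute_risk_factor_deltas(
    baseline: ConsumptionSummary,
    scenario: ScenarioDefinition,
    params: EffectParameters | None = None,
) -> RiskFactorDelta:
    """Translate a consumption scenario into risk-factor reductions per stratum.

    delta_servings  = baseline servings x reduction fraction
    net_delta_kcal  = delta_servings x 150 x (1 - compensation)
    delta_weight_kg = net_delta_kcal x 365 / 3500 x 0.45359237  (steady state)
    delta_bmi       = delta_weight_kg / height^2
    delta_sbp       = delta_servings x sbp_per_serving
                      + delta_bmi x sbp_per_bmi_unit
    multiplier      = RR_per_serving ** (-delta_servings)

    The steady-state weight change is reached in year 1 and maintained for
    the horizon (see the package methods note); the diabetes multiplier is
    the direct, BMI-independent dose-response term and stacks on top of the
    BMI-mediated effect that flows through the risk function via delta_bmi.
    """
    params = params or EffectParameters()
    servings = baseline.servings_array()
    r = scenario.reduction_fraction
    c = scenario.compensation_fraction

    delta_servings = servings * r
    net_delta_kcal = delta_servings * params.kcal_per_serving * (1.0 - c)
    delta_weight_kg = (
        net_delta_kcal * DAYS_PER_YEAR / params.kcal_per_pound * params.kg_per_pound
    )
    heights = np.array([[params.mean_height_m[s]] for s in SEXES])  # (2, 1)
    delta_bmi = delta_weight_kg / heights**2
    sbp_direct = np.array([[params.sbp_per_serving[s]] for s in SEXES])
    sbp_bmi = np.array([[params.sbp_per_bmi_unit[s]] for s in SEXES])
    delta_sbp = delta_servings * sbp_direct + delta_bmi * sbp_bmi
    multiplier = params.rr_diabetes_per_serving ** (-delta_servings)
    return RiskFactorDelta(
        delta_servings=delta_servings,
        net_delta_kcal=net_delta_kcal,
        delta_weight_kg=delta_weight_kg,
        delta_bmi=delta_bmi,
        delta_sbp=delta_sbp,
        diabetes_rate_multiplier=multiplier,
    )
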