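"""Core data structures shared across the simulation pipeline.

The population of adults aged 35-94 is partitioned into cells by sex,
single-year age, diabetes status and cardiovascular-disease state.  Risk
factors (systolic blood pressure, BMI, lipids, smoking) are carried as
age-decile stratum means, the resolution at which survey inputs are
reported; interventions act on those means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np
import pandas as pd

SEXES = ("men", "women")
N_SEXES = 2
AGE_MIN = 35
AGE_MAX = 94
N_AGES = AGE_MAX - AGE_MIN + 1
AGES = np.arange(AGE_MIN, AGE_MAX + 1)

# age deciles used for all stratified inputs/outputs; the last two deciles
# are collapsed (75-94) to match how survey inputs are reported
DECILE_BOUNDS = ((35, 44), (45, 54), (55, 64), (65, 74), (75, 94))
DECILE_LABELS = ("35-44", "45-54", "55-64", "65-74", "75-94")
N_DECILES = len(DECILE_BOUNDS)

#: index of the decile each single-year age belongs to, shape (N_AGES,)
AGE_TO_DECILE = np.empty(N_AGES, dtype=int)
for _d, (_lo, _hi) in enumerate(DECILE_BOUNDS):
    AGE_TO_DECILE[_lo - AGE_MIN : _hi - AGE_MIN + 1] = _d

DIABETES_STATES = ("no", "yes")
CVD_STATES = ("none", "chd", "stroke", "chd_and_stroke")
N_CVD = len(CVD_STATES)
CVD_NONE, CVD_CHD, CVD_STROKE, CVD_BOTH = range(4)

RISK_FACTOR_NAMES = ("sbp", "bmi", "ldl", "hdl", "smoking")

# covariate reference point at which risk-function intercepts are anchored
COVARIATE_REFERENCE = {"age": 60.0, "sbp": 120.0, "bmi": 25.0, "hdl": 50.0, "ldl": 120.0}

OUTCOMES = (
    "incident_diabetes",
    "incident_chd",
    "incident_stroke",
    "mi",
    "chd_deaths",
    "stroke_deaths",
    "non_cvd_deaths",
    "all_cause_deaths",
    "diabetes_person_years",
)


class SchemaError(ValueError):
    """Raised when structured inputs violate the documented schema."""


class CalibrationError(RuntimeError):
    """Raised when hazard calibration fails to converge."""


@dataclass
class RiskFactors:
    """Stratum-mean risk factors, each an array of shape (N_SEXES, N_DECILES)."""

    sbp: np.ndarray
    bmi: np.ndarray
    ldl: np.ndarray
    hdl: np.ndarray
    smoking: np.ndarray

    def __post_init__(self) -> None:
        for name in RISK_FACTOR_NAMES:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_SEXES, N_DECILES):
                raise SchemaError(
                    f"risk factor {name!r} must have shape "
                    f"({N_SEXES}, {N_DECILES}), got {arr.shape}"
                )
            setattr(self, name, arr)
        if np.any((self.smoking < 0) | (self.smoking > 1)):
            raise SchemaError("smoking prevalence must lie in [0, 1]")

    def copy(self) -> "RiskFactors":
        return RiskFactors(**{n: getattr(self, n).copy() for n in RISK_FACTOR_NAMES})

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_product([SEXES, DECILE_LABELS], names=["sex", "age_group"])
        return pd.DataFrame(
            {n: getattr(self, n).ravel() for n in RISK_FACTOR_NAMES}, index=idx
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RiskFactors":
        arrays = {}
        for n in RISK_FACTOR_NAMES:
            arrays[n] = (
                df[n]
                .unstack("age_group")
                .reindex(index=list(SEXES), columns=list(DECILE_LABELS))
                .to_numpy()
            )
        return cls(**arrays)


@dataclass
class PopulationState:
    """Cell-partitioned cohort counts plus stratum-mean risk factors.

    ``counts`` has shape (sex, age, diabetes, cvd_state) =
    (2, 60, 2, 4); counts are expected persons, not integers.
    """

    counts: np.ndarray
    risk_factors: RiskFactors

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_SEXES, N_AGES, 2, N_CVD):
            raise SchemaError(
                f"counts must have shape ({N_SEXES}, {N_AGES}, 2, {N_CVD}), "
                f"got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise SchemaError("population counts must be non-negative")

    def copy(self) -> "PopulationState":
        return PopulationState(self.counts.copy(), self.risk_factors.copy())

    def total(self) -> float:
        return float(self.counts.sum())

    def diabetes_count(self) -> float:
        return float(self.counts[:, :, 1, :].sum())


@dataclass
class RiskFunction:
    """Logistic annual-hazard function of the cell covariates.

    The linear predictor is evaluated at covariates centred on
    :data:`COVARIATE_REFERENCE`; the intercept is therefore the log-odds of
    the annual hazard for a 60-y-old non-smoking, non-diabetic man at
    SBP 120, BMI 25, HDL 50, LDL 120.
    """

    intercept: float
    age: float = 0.0
    female: float = 0.0
    sbp: float = 0.0
    bmi: float = 0.0
    hdl: float = 0.0
    ldl: float = 0.0
    smoking: float = 0.0
    diabetes: float = 0.0

    COEF_NAMES = ("intercept", "age", "female", "sbp", "bmi", "hdl", "ldl", "smoking", "diabetes")

    def hazard(
        self,
        age: np.ndarray,
        female: float,
        sbp: np.ndarray,
        bmi: np.ndarray,
        hdl: np.ndarray,
        ldl: np.ndarray,
        smoking: np.ndarray,
        diabetes: float,
    ) -> np.ndarray:
        ref = COVARIATE_REFERENCE
        lp = (
            self.intercept
            + self.age * (np.asarray(age, dtype=float) - ref["age"])
            + self.female * female
            + self.sbp * (sbp - ref["sbp"])
            + self.bmi * (bmi - ref["bmi"])
            + self.hdl * (hdl - ref["hdl"])
            + self.ldl * (ldl - ref["ldl"])
            + self.smoking * smoking
            + self.diabetes * diabetes
        )
        # numerically stable logistic
        return 1.0 / (1.0 + np.exp(-lp))

    def to_dict(self) -> Dict[str, float]:
        return {n: float(getattr(self, n)) for n in self.COEF_NAMES}

    @classmethod
    def from_dict(cls, d: Dict[str, float]) -> "RiskFunction":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass
class PostCVDParameters:
    """Annual transition parameters for cells already in a CVD state.

    ``case_fatality_*`` are the fractions of incident events that are fatal
    within the cycle; ``*_death_hazard`` apply to prevalent occupants of the
    matching states; ``non_cvd_death_multiplier`` scales the no-CVD
    non-CVD-death hazard; ``recurrent_mi_rate`` is an annual event rate among
    occupants of CHD-containing states (a tally, not a transition).
    """

    case_fatality_chd: float = 0.12
    case_fatality_stroke: float = 0.18
    chd_death_hazard: float = 0.05
    stroke_death_hazard: float = 0.025
    non_cvd_death_multiplier: float = 1.5
    recurrent_mi_rate: float = 0.015

    def __post_init__(self) -> None:
        if not 0.0 <= self.case_fatality_chd <= 1.0:
            raise SchemaError("case_fatality_chd must be in [0, 1]")
        if not 0.0 <= self.case_fatality_stroke <= 1.0:
            raise SchemaError("case_fatality_stroke must be in [0, 1]")
        for name in ("chd_death_hazard", "stroke_death_hazard", "recurrent_mi_rate"):
            if getattr(self, name) < 0:
                raise SchemaError(f"{name} must be non-negative")


@dataclass
class RiskFunctionSet:
    """Cause-specific risk functions plus calibration multipliers.

    The three calibration multipliers scale the incident-CHD hazard, the
    incident-stroke hazard, and all CHD-death parameters (acute case fatality
    and the post-CVD CHD-death hazard) respectively, so that a reference-year
    run reproduces national event/death counts.
    """

    incident_diabetes: RiskFunction
    incident_chd: RiskFunction
    incident_stroke: RiskFunction
    non_cvd_death: RiskFunction
    post_cvd: PostCVDParameters = field(default_factory=PostCVDParameters)
    calibration_multipliers: Dict[str, float] = field(
        default_factory=lambda: {"chd_events": 1.0, "stroke_events": 1.0, "chd_deaths": 1.0}
    )
    mi_share_of_chd: float = 0.30

    def __post_init__(self) -> None:
        for k, v in self.calibration_multipliers.items():
            if v <= 0:
                raise SchemaError(f"calibration multiplier {k!r} must be positive, got {v}")
        if not 0.0 <= self.mi_share_of_chd <= 1.0:
            raise SchemaError("mi_share_of_chd must be in [0, 1]")

    def copy(self) -> "RiskFunctionSet":
        return RiskFunctionSet(
            incident_diabetes=replace(self.incident_diabetes),
            incident_chd=replace(self.incident_chd),
            incident_stroke=replace(self.incident_stroke),
            non_cvd_death=replace(self.non_cvd_death),
            post_cvd=replace(self.post_cvd),
            calibration_multipliers=dict(self.calibration_multipliers),
            mi_share_of_chd=self.mi_share_of_chd,
        )

    def with_diabetes_beta_multiplier(self, m: float) -> "RiskFunctionSet":
        """Scale the diabetes coefficients of the CHD, stroke and non-CVD-death
        risk functions by ``m`` (deterministic sensitivity on the excess risk
        associated with diabetes)."""
        if m <= 0:
            raise ValueError("beta multiplier must be positive")
        out = self.copy()
        out.incident_chd.diabetes *= m
        out.incident_stroke.diabetes *= m
        out.non_cvd_death.diabetes *= m
        return out


@dataclass
class CalibrationTargets:
    """Reference-year national event/death counts the model is tuned to."""

    chd_events: float
    stroke_events: float
    chd_deaths: float
    tolerance: float = 0.01
    reference_year: int = 2010

    def __post_init__(self) -> None:
        for name in ("chd_events", "stroke_events", "chd_deaths"):
            if getattr(self, name) <= 0:
                raise SchemaError(f"calibration target {name} must be positive")
        if self.tolerance <= 0:
            raise SchemaError("calibration tolerance must be positive")


@dataclass
class Demography:
    """Entering 35-year-old cohort sizes per sex per simulated year."""

    entrants_per_year: np.ndarray  # shape (N_SEXES,) — constant across years

    def __post_init__(self) -> None:
        self.entrants_per_year = np.asarray(self.entrants_per_year, dtype=float)
        if self.entrants_per_year.shape != (N_SEXES,):
            raise SchemaError(f"entrants_per_year must have shape ({N_SEXES},)")
        if np.any(self.entrants_per_year < 0):
            raise SchemaError("entrant counts must be non-negative")


class SimulationResult:
    """Per-year, per-sex, per-age-decile outcome tallies.

    ``tallies[outcome]`` has shape (n_years, N_SEXES, N_DECILES).
    ``diabetes_person_years`` counts prevalent diabetes at cycle start.
    """

    def __init__(self, years: list[int], tallies: Dict[str, np.ndarray]):
        self.years = list(years)
        n = len(self.years)
        for k in OUTCOMES:
            if k not in tallies:
                raise SchemaError(f"missing outcome tally {k!r}")
            if tallies[k].shape != (n, N_SEXES, N_DECILES):
                raise SchemaError(f"tally {k!r} has shape {tallies[k].shape}")
        self.tallies = tallies

    def cumulative(self, outcome: str) -> float:
        """10-y (horizon) total of an outcome over all strata."""
        return float(self.tallies[outcome].sum())

    def cumulative_by_decile(self, outcome: str) -> np.ndarray:
        return self.tallies[outcome].sum(axis=(0, 1))

    def cumulative_by_sex(self, outcome: str) -> np.ndarray:
        return self.tallies[outcome].sum(axis=(0, 2))

    def by_year(self, outcome: str) -> np.ndarray:
        return self.tallies[outcome].sum(axis=(1, 2))

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (year, sex, age_group, outcome, value)."""
        rows = []
        for outcome in OUTCOMES:
            arr = self.tallies[outcome]
            for i, year in enumerate(self.years):
                for s, sex in enumerate(SEXES):
                    for d, dec in enumerate(DECILE_LABELS):
                        rows.append((year, sex, dec, outcome, arr[i, s, d]))
        return pd.DataFrame(rows, columns=["year", "sex", "age_group", "outcome", "value"])
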