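"""Synthetic generation of every model input.

The real pipeline would be driven by national survey microdata, vital
statistics and institutional utilization databases.  None of those are
distributable, so this module generates inputs with the same statistical
structure: a zero-inflated, right-skewed daily SSB intake survey whose
age- and sex-stratified weighted means match the published national summary
(consumption declines with age and is higher in men); plausible stratum
risk-factor means; a baseline population with age-increasing diabetes and
CVD prevalence; synthetic Framingham-style logistic risk coefficients with
epidemiologically-signed terms; reference-year calibration targets; and
institution-level cost/utilization tables.

Daily SSB volume is modeled as a two-part (zero-inflated lognormal)
distribution: with probability ``zero_fraction`` a respondent drinks no
SSBs, otherwise volume ~ LogNormal(mu, sigma).  Given a stratum target mean
M, mu = ln(M / (1 - zero_fraction)) - sigma^2 / 2, so the marginal mean is
M and mean > median within every stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .costs import (
    INSTITUTIONS,
    SERVICES,
    CostInputs,
    CurrencyParameters,
)
from .exposure import ConsumptionSummary, EffectParameters
from .model import (
    AGE_TO_DECILE,
    CVD_BOTH,
    CVD_CHD,
    CVD_NONE,
    CVD_STROKE,
    CalibrationTargets,
    DECILE_BOUNDS,
    DECILE_LABELS,
    Demography,
    N_AGES,
    N_DECILES,
    N_SEXES,
    PopulationState,
    PostCVDParameters,
    RiskFactors,
    RiskFunction,
    RiskFunctionSet,
    SEXES,
    SchemaError,
)

# published national survey summary (2012): mean daily SSB volume (ml) and
# survey sample size per sex x age decile — targets the generator reproduces
TARGET_VOLUME_ML = np.array(
    [
        [529.4, 463.2, 418.1, 325.1, 245.7],  # men
        [385.1, 336.2, 203.1, 219.2, 186.0],  # women
    ]
)
SURVEY_N = np.array(
    [
        [248, 237, 184, 214, 137],
        [400, 277, 225, 239, 177],
    ]
)
POPULATION_2012 = np.array(
    [
        [6537458, 6953571, 4053496, 2857241, 1869730],
        [8744682, 6519086, 4593913, 2671939, 2006184],
    ],
    dtype=float,
)


def _default_risk_functions() -> RiskFunctionSet:
    """Synthetic Framingham-style coefficient set.

    Signs follow epidemiologic direction (risk increases with age, SBP, BMI,
    LDL, smoking and diabetes; decreases with HDL); magnitudes are chosen so
    uncalibrated national event counts land within a small factor of the
    reference-year targets, which calibration then absorbs.
    """
    return RiskFunctionSet(
        incident_diabetes=RiskFunction(
            intercept=-4.82, age=0.020, female=-0.10, sbp=0.005, bmi=0.080,
            hdl=-0.010, smoking=0.20,
        ),
        incident_chd=RiskFunction(
            intercept=-5.52, age=0.055, female=-0.40, sbp=0.018, bmi=0.030,
            hdl=-0.025, ldl=0.006, smoking=0.55, diabetes=0.65,
        ),
        incident_stroke=RiskFunction(
            intercept=-6.72, age=0.075, female=-0.15, sbp=0.025, bmi=0.020,
            hdl=-0.010, ldl=0.003, smoking=0.45, diabetes=0.55,
        ),
        non_cvd_death=RiskFunction(
            intercept=-5.11, age=0.085, female=-0.25, sbp=0.004, bmi=0.010,
            smoking=0.45, diabetes=0.50,
        ),
        post_cvd=PostCVDParameters(),
    )


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic-input generator.

    Stratum arrays have shape (sex, age decile) with sexes (men, women) and
    deciles 35-44 ... 75-94.  ``population_scale`` shrinks every population
    quantity (baseline counts, entrants, calibration targets) by a common
    factor, preserving all rates — useful for small test bundles.
    """

    seed: int = 12345
    n_survey: int = int(SURVEY_N.sum())
    zero_fraction: np.ndarray = field(
        default_factory=lambda: np.array([[0.30] * N_DECILES, [0.36] * N_DECILES])
    )
    sigma: np.ndarray = field(default_factory=lambda: np.full((N_SEXES, N_DECILES), 1.0))
    target_volume_ml: np.ndarray = field(default_factory=lambda: TARGET_VOLUME_ML.copy())
    population_by_stratum: np.ndarray = field(default_factory=lambda: POPULATION_2012.copy())
    population_scale: float = 1.0
    # prevalence at baseline by decile
    diabetes_prevalence: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.07, 0.14, 0.22, 0.25, 0.25], [0.08, 0.16, 0.24, 0.26, 0.26]]
        )
    )
    chd_prevalence: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.010, 0.020, 0.040, 0.070, 0.100], [0.007, 0.015, 0.030, 0.055, 0.085]]
        )
    )
    stroke_prevalence: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.003, 0.007, 0.015, 0.030, 0.045], [0.003, 0.006, 0.013, 0.026, 0.040]]
        )
    )
    both_prevalence: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.0005, 0.001, 0.003, 0.006, 0.010], [0.0004, 0.001, 0.002, 0.005, 0.009]]
        )
    )
    # stratum-mean risk factors
    sbp: np.ndarray = field(
        default_factory=lambda: np.array(
            [[122.0, 127.0, 132.0, 138.0, 142.0], [118.0, 124.0, 131.0, 139.0, 144.0]]
        )
    )
    bmi: np.ndarray = field(
        default_factory=lambda: np.array(
            [[27.8, 28.2, 28.0, 27.4, 26.5], [28.9, 29.5, 29.3, 28.6, 27.3]]
        )
    )
    ldl: np.ndarray = field(
        default_factory=lambda: np.array(
            [[118.0, 124.0, 126.0, 124.0, 120.0], [116.0, 123.0, 127.0, 125.0, 121.0]]
        )
    )
    hdl: np.ndarray = field(
        default_factory=lambda: np.array(
            [[42.0, 42.0, 43.0, 43.0, 44.0], [50.0, 50.0, 51.0, 51.0, 52.0]]
        )
    )
    smoking: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.30, 0.27, 0.22, 0.17, 0.12], [0.10, 0.09, 0.08, 0.06, 0.04]]
        )
    )
    entrants_per_year: np.ndarray = field(
        default_factory=lambda: np.array([654000.0, 874000.0])
    )
    calibration_targets: Dict[str, float] = field(
        default_factory=lambda: {
            "chd_events": 310000.0,
            "stroke_events": 95000.0,
            "chd_deaths": 92000.0,
        }
    )
    calibration_tolerance: float = 0.01
    # per-institution unit-cost scales (pesos) and national service counts
    unit_cost_pesos: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            "A": {"generalist_visit": 450.0, "specialist_visit": 850.0, "hospital_day": 5200.0},
            "B": {"generalist_visit": 550.0, "specialist_visit": 950.0, "hospital_day": 5600.0},
            "C": {"generalist_visit": 350.0, "specialist_visit": 700.0, "hospital_day": 4300.0},
        }
    )
    national_service_counts: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            "A": {"generalist_visit": 6.0e7, "specialist_visit": 1.6e7, "hospital_day": 9.0e6},
            "B": {"generalist_visit": 1.4e7, "specialist_visit": 5.0e6, "hospital_day": 2.2e6},
            "C": {"generalist_visit": 5.0e7, "specialist_visit": 9.0e6, "hospital_day": 7.0e6},
        }
    )
    services_per_patient: Dict[str, np.ndarray] = field(
        default_factory=lambda: {
            # rows: services; columns: age deciles
            "generalist_visit": np.array([6.0, 7.0, 8.0, 9.0, 9.0]),
            "specialist_visit": np.array([1.5, 2.0, 2.5, 3.0, 3.0]),
            "hospital_day": np.array([0.4, 0.6, 0.9, 1.4, 1.8]),
        }
    )
    institution_weights: np.ndarray = field(
        default_factory=lambda: np.array([0.42, 0.13, 0.45])  # A, B, C
    )
    effect_params: EffectParameters = field(default_factory=EffectParameters)

    def __post_init__(self) -> None:
        for name in ("zero_fraction", "sigma", "target_volume_ml", "population_by_stratum"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_SEXES, N_DECILES):
                raise SchemaError(f"{name} must have shape ({N_SEXES}, {N_DECILES})")
            setattr(self, name, arr)
        if np.any((self.zero_fraction < 0) | (self.zero_fraction > 1)):
            raise SchemaError("zero fractions must lie in [0, 1]")
        if np.any(self.population_by_stratum < 0):
            raise SchemaError("population counts must be non-negative")
        if self.n_survey <= 0:
            raise ValueError("n_survey must be positive")
        for k, v in self.calibration_targets.items():
            if v <= 0:
                raise SchemaError(f"calibration target {k} must be positive")

    def lognormal_params(self) -> Tuple[np.ndarray, np.ndarray]:
        """(mu, sigma) of the nonzero volume component per stratum, chosen so
        the marginal stratum mean equals ``target_volume_ml``."""
        nonzero_mean = self.target_volume_ml / np.maximum(1e-12, 1.0 - self.zero_fraction)
        mu = np.where(
            self.zero_fraction >= 1.0,
            0.0,
            np.log(np.maximum(nonzero_mean, 1e-12)) - self.sigma**2 / 2.0,
        )
        return mu, self.sigma


@dataclass
class ModelBundle:
    """Everything one simulation run consumes."""

    baseline: PopulationState
    risks: RiskFunctionSet
    demography: Demography
    targets: CalibrationTargets
    cost_inputs: CostInputs
    consumption: ConsumptionSummary
    effect_params: EffectParameters

    def copy(self) -> "ModelBundle":
        return ModelBundle(
            baseline=self.baseline.copy(),
            risks=self.risks.copy(),
            demography=Demography(self.demography.entrants_per_year.copy()),
            targets=self.targets,
            cost_inputs=self.cost_inputs,
            consumption=self.consumption,
            effect_params=self.effect_params.copy(),
        )


def generate_ssb_survey(config: SyntheticConfig) -> pd.DataFrame:
    """Simulate a cross-sectional SSB-consumption survey.

    Respondents are allocated to sex x age-decile strata proportionally to
    the published survey sample sizes; ages are uniform within decile;
    volumes are zero-inflated lognormal; weights are
    population / sampled-count per stratum (self-weighting within stratum).
    """
    if config.n_survey <= 0:
        raise ValueError("n_survey must be positive")
    rng = np.random.default_rng(config.seed)
    alloc = SURVEY_N / SURVEY_N.sum()
    n_strat = np.maximum(1, np.round(alloc * config.n_survey)).astype(int)
    mu, sigma = config.lognormal_params()

    rows = []
    rid = 0
    for s, sex in enumerate(SEXES):
        for d, (lo, hi) in enumerate(DECILE_BOUNDS):
            n = n_strat[s, d]
            ages = rng.integers(lo, hi + 1, size=n)
            zero = rng.random(n) < config.zero_fraction[s, d]
            vol = np.where(
                zero, 0.0, rng.lognormal(mean=mu[s, d], sigma=sigma[s, d], size=n)
            )
            if config.zero_fraction[s, d] >= 1.0:
                vol = np.zeros(n)
            weight = config.population_by_stratum[s, d] / n
            for a, v in zip(ages, vol):
                rows.append((rid, sex, int(a), weight, float(v)))
                rid += 1
    return pd.DataFrame(
        rows, columns=["respondent_id", "sex", "age", "weight", "volume_ml"]
    )


def survey_consumption_summary(
    survey: pd.DataFrame, params: Optional[EffectParameters] = None
) -> ConsumptionSummary:
    """Weighted sex x age-decile consumption summary of a survey table."""
    params = params or EffectParameters()
    df = survey.copy()
    age_idx = df["age"].to_numpy() - 35
    df["age_group"] = [DECILE_LABELS[AGE_TO_DECILE[a]] for a in age_idx]
    rows = []
    for (sex, group), g in df.groupby(["sex", "age_group"], sort=False):
        w = g["weight"].to_numpy()
        v = g["volume_ml"].to_numpy()
        mean = np.average(v, weights=w)
        # self-weighting within stratum: SE of the mean = sd / sqrt(n)
        sd = v.std(ddof=1) if len(v) > 1 else 0.0
        rows.append((sex, group, mean, sd / np.sqrt(len(v))))
    out = pd.DataFrame(rows, columns=["sex", "age_group", "volume_ml", "volume_se"])
    return ConsumptionSummary(out.set_index(["sex", "age_group"]), params)


def _baseline_population(config: SyntheticConfig) -> PopulationState:
    counts = np.zeros((N_SEXES, N_AGES, 2, 4))
    for s in range(N_SEXES):
        for d, (lo, hi) in enumerate(DECILE_BOUNDS):
            width = hi - lo + 1
            per_age = config.population_by_stratum[s, d] * config.population_scale / width
            p_dm = config.diabetes_prevalence[s, d]
            p_chd = config.chd_prevalence[s, d]
            p_str = config.stroke_prevalence[s, d]
            p_both = config.both_prevalence[s, d]
            p_none = 1.0 - p_chd - p_str - p_both
            for a in range(lo - 35, hi - 35 + 1):
                for dm, w_dm in ((0, 1.0 - p_dm), (1, p_dm)):
                    counts[s, a, dm, CVD_NONE] = per_age * w_dm * p_none
                    counts[s, a, dm, CVD_CHD] = per_age * w_dm * p_chd
                    counts[s, a, dm, CVD_STROKE] = per_age * w_dm * p_str
                    counts[s, a, dm, CVD_BOTH] = per_age * w_dm * p_both
    rf = RiskFactors(
        sbp=config.sbp, bmi=config.bmi, ldl=config.ldl, hdl=config.hdl,
        smoking=config.smoking,
    )
    return PopulationState(counts, rf)


def _cost_inputs(config: SyntheticConfig) -> CostInputs:
    exp_rows, cnt_rows = [], []
    for inst in INSTITUTIONS:
        cnts = [config.national_service_counts[inst][svc] for svc in SERVICES]
        exps = [
            config.unit_cost_pesos[inst][svc] * config.national_service_counts[inst][svc]
            for svc in SERVICES
        ]
        cnt_rows.append(cnts)
        exp_rows.append(exps)
    expenditures = pd.DataFrame(exp_rows, index=list(INSTITUTIONS), columns=list(SERVICES))
    counts = pd.DataFrame(cnt_rows, index=list(INSTITUTIONS), columns=list(SERVICES))

    idx = pd.MultiIndex.from_product(
        [list(INSTITUTIONS), list(DECILE_LABELS)], names=["institution", "age_group"]
    )
    spp = pd.DataFrame(
        {
            svc: np.tile(config.services_per_patient[svc], len(INSTITUTIONS))
            for svc in SERVICES
        },
        index=idx,
    )
    weights = pd.DataFrame(
        np.tile(config.institution_weights, (N_DECILES, 1)),
        index=pd.Index(list(DECILE_LABELS), name="age_group"),
        columns=list(INSTITUTIONS),
    )
    return CostInputs(
        expenditures=expenditures,
        service_counts=counts,
        services_per_patient=spp,
        institution_weights=weights,
        currency=CurrencyParameters(),
    )


def generate_model_inputs(config: Optional[SyntheticConfig] = None) -> ModelBundle:
    """Generate the full input bundle for one pipeline run.

    The consumption summary comes from a simulated survey (whose weighted
    stratum means target the published national values); everything else is
    deterministic given the configuration.  Same seed => identical bundle.
    """
    config = config or SyntheticConfig()
    survey = generate_ssb_survey(config)
    consumption = survey_consumption_summary(survey, config.effect_params)
    baseline = _baseline_population(config)
    scale = config.population_scale
    targets = CalibrationTargets(
        chd_events=config.calibration_targets["chd_events"] * scale,
        stroke_events=config.calibration_targets["stroke_events"] * scale,
        chd_deaths=config.calibration_targets["chd_deaths"] * scale,
        tolerance=config.calibration_tolerance,
    )
    demography = Demography(np.asarray(config.entrants_per_year, dtype=float) * scale)
    return ModelBundle(
        baseline=baseline,
        risks=_default_risk_functions(),
        demography=demography,
        targets=targets,
        cost_inputs=_cost_inputs(config),
        consumption=consumption,
        effect_params=config.effect_params,
    )
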