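"""Probabilistic sensitivity analysis.

Every varied parameter gets an independent standard-normal draw per
iteration, scaled to its mean and 95% confidence interval
(SD = CI width / (2 x 1.959964)); ratio parameters are drawn on the log
scale.  Within one iteration the base-case and intervention simulations
share the same drawn parameter set, so outcome differences are paired.
95% uncertainty intervals are the 2.5th/97.5th percentiles of the stored
per-iteration differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .costs import per_patient_cost, scenario_cost_savings
from .engine import run_simulation
from .exposure import ScenarioDefinition
from .model import SchemaError

Z95 = 1.959964
CI_TO_SD = 2.0 * Z95  # divide a 95% CI width by this to get the SD

PSA_OUTCOMES = (
    "incident_diabetes",
    "incident_chd",
    "incident_stroke",
    "mi",
    "chd_deaths",
    "stroke_deaths",
    "all_cause_deaths",
)


@dataclass
class VariedParameter:
    """One parameter varied in the PSA: mean, 95% CI, and draw scale."""

    name: str
    mean: float
    lower95: float
    upper95: float
    scale: str = "natural"  # or "log" for ratio parameters

    def __post_init__(self) -> None:
        if self.upper95 < self.lower95:
            raise ValueError(f"{self.name}: upper95 must be >= lower95")
        if self.scale not in ("natural", "log"):
            raise ValueError(f"{self.name}: scale must be 'natural' or 'log'")
        if self.scale == "log" and (self.lower95 <= 0 or self.mean <= 0):
            raise ValueError(f"{self.name}: log-scale parameters must be positive")

    def sd(self) -> float:
        if self.scale == "log":
            return (np.log(self.upper95) - np.log(self.lower95)) / CI_TO_SD
        return (self.upper95 - self.lower95) / CI_TO_SD

    def value_at(self, z: float) -> float:
        if self.scale == "log":
            return float(np.exp(np.log(self.mean) + z * self.sd()))
        return float(self.mean + z * self.sd())


@dataclass
class UncertaintyConfig:
    n_iterations: int = 1000
    seed: int = 0
    parameters: List[VariedParameter] = field(default_factory=list)
    percentiles: tuple = (2.5, 97.5)

    def __post_init__(self) -> None:
        if self.n_iterations < 2:
            raise ValueError("n_iterations must be at least 2")
        for p in self.parameters:
            if p.upper95 < p.lower95:
                raise ValueError(f"{p.name}: invalid CI")


@dataclass
class UncertaintyResult:
    """Point estimates and percentile uncertainty intervals per outcome."""

    point: Dict[str, float]
    lower95: Dict[str, float]
    upper95: Dict[str, float]
    draws: Optional[Dict[str, np.ndarray]] = None
    n_excluded: int = 0

    def interval(self, outcome: str) -> tuple:
        return (self.lower95[outcome], self.upper95[outcome])


def default_varied_parameters(bundle=None) -> List[VariedParameter]:
    """The default varied-parameter list: published exposure effect sizes
    plus the main synthetic risk-function coefficients (±~30%)."""
    params = [
        VariedParameter("effect.rr_diabetes_per_serving", 1.19, 1.09, 1.31, "log"),
        VariedParameter("effect.sbp_per_serving.men", 0.78, 0.09, 1.47),
        VariedParameter("effect.sbp_per_serving.women", 0.61, -0.27, 1.48),
    ]
    risks = bundle.risks if bundle is not None else None
    if risks is not None:
        for cause, coef in (
            ("incident_diabetes", "bmi"),
            ("incident_chd", "sbp"),
            ("incident_chd", "diabetes"),
            ("incident_stroke", "sbp"),
            ("incident_stroke", "diabetes"),
            ("non_cvd_death", "diabetes"),
        ):
            mean = getattr(getattr(risks, cause), coef)
            half = 0.3 * abs(mean)
            params.append(
                VariedParameter(f"risk.{cause}.{coef}", mean, mean - half, mean + half)
            )
    return params


def draw_parameters(config: UncertaintyConfig, iteration: int) -> Dict[str, float]:
    """Drawn parameter values for one iteration, deterministic in (seed, iteration)."""
    rng = np.random.default_rng([config.seed, iteration])
    z = rng.standard_normal(len(config.parameters))
    return {p.name: p.value_at(z[i]) for i, p in enumerate(config.parameters)}


def apply_parameter(bundle, name: str, value: float) -> None:
    """Apply one drawn parameter to a bundle copy, addressed by dotted path.

    ``effect.<field>[.<sex>]`` targets the effect parameters;
    ``risk.<cause>.<coefficient>`` targets a risk-function coefficient.
    """
    parts = name.split(".")
    if parts[0] == "effect":
        if len(parts) == 2:
            if not hasattr(bundle.effect_params, parts[1]):
                raise SchemaError(f"unknown effect parameter {name!r}")
            setattr(bundle.effect_params, parts[1], value)
        elif len(parts) == 3:
            d = getattr(bundle.effect_params, parts[1], None)
            if not isinstance(d, dict) or parts[2] not in d:
                raise SchemaError(f"unknown effect parameter {name!r}")
            d[parts[2]] = value
        else:
            raise SchemaError(f"cannot parse parameter name {name!r}")
    elif parts[0] == "risk" and len(parts) == 3:
        fn = getattr(bundle.risks, parts[1], None)
        if fn is None or parts[2] not in fn.COEF_NAMES:
            raise SchemaError(f"unknown risk coefficient {name!r}")
        setattr(fn, parts[2], value)
    else:
        raise SchemaError(f"cannot parse parameter name {name!r}")


def _paired_differences(bundle, scenario: ScenarioDefinition) -> Dict[str, float]:
    """Base-minus-scenario cumulative outcomes for one parameter set."""
    base = run_simulation(
        bundle.baseline, bundle.risks, bundle.demography,
        consumption=bundle.consumption, params=bundle.effect_params,
        horizon_years=scenario.horizon_years, start_year=scenario.start_year,
    )
    scen = run_simulation(
        bundle.baseline, bundle.risks, bundle.demography, scenario=scenario,
        consumption=bundle.consumption, params=bundle.effect_params,
    )
    out = {k: base.cumulative(k) - scen.cumulative(k) for k in PSA_OUTCOMES}
    costs = per_patient_cost(bundle.cost_inputs)
    out["cost_savings_millions"] = scenario_cost_savings(base, scen, costs)[
        "cumulative_millions"
    ]
    return out


def run_psa(
    bundle,
    scenario: ScenarioDefinition,
    config: UncertaintyConfig,
    keep_draws: bool = False,
) -> UncertaintyResult:
    """Paired-draw probabilistic sensitivity analysis of one scenario.

    Per iteration a fresh parameter set is drawn, applied to a copy of the
    bundle, and both the base case and the scenario are simulated with it;
    the stored quantity is each outcome's base-minus-scenario difference.
    Iterations where the engine fails are excluded (with a warning if more
    than 1% are).
    """
    point = _paired_differences(bundle.copy(), scenario)
    outcome_names = list(point)
    stored: Dict[str, list] = {k: [] for k in outcome_names}
    n_excluded = 0
    for it in range(config.n_iterations):
        values = draw_parameters(config, it)
        b = bundle.copy()
        try:
            for name, value in values.items():
                apply_parameter(b, name, value)
            diffs = _paired_differences(b, scenario)
        except Exception:  # noqa: BLE001 - any engine failure excludes the draw
            n_excluded += 1
            continue
        for k in outcome_names:
            stored[k].append(diffs[k])
    if n_excluded > 0.01 * config.n_iterations:
        warnings.warn(
            f"{n_excluded} of {config.n_iterations} PSA iterations excluded",
            RuntimeWarning,
        )
    lo_p, hi_p = config.percentiles
    draws = {k: np.asarray(v) for k, v in stored.items()}
    lower = {k: float(np.percentile(v, lo_p)) for k, v in draws.items()}
    upper = {k: float(np.percentile(v, hi_p)) for k, v in draws.items()}
    return UncertaintyResult(
        point=point,
        lower95=lower,
        upper95=upper,
        draws=draws if keep_draws else None,
        n_excluded=n_excluded,
    )
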