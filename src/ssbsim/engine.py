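"""Annual-cycle, cell-partitioned state-transition engine.

Each cycle, cause-specific annual hazards are computed per cell from
logistic risk functions of the stratum-mean covariates, converted to
competing-risk transition probabilities with the hazard-allocation formula

    p_c = (1 - exp(-sum h)) * h_c / sum h,

and applied as deterministic expected flows.  Ages then increment by one
year, cells aging past 94 leave the model, and a new cohort of 35-year-olds
enters.  Baseline cause-specific hazards are calibrated by iterative
proportional adjustment of three multipliers (CHD events, stroke events,
CHD deaths) until a reference-year run matches national targets within a
relative tolerance (default 1%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .exposure import (
    ConsumptionSummary,
    EffectParameters,
    RiskFactorDelta,
    ScenarioDefinition,
    compute_risk_factor_deltas,
)
from .model import (
    AGE_TO_DECILE,
    AGES,
    CVD_BOTH,
    CVD_CHD,
    CVD_NONE,
    CVD_STROKE,
    CalibrationError,
    CalibrationTargets,
    Demography,
    N_AGES,
    N_DECILES,
    N_SEXES,
    OUTCOMES,
    PopulationState,
    RiskFunctionSet,
    SimulationResult,
)

# indicator matrix mapping single-year ages onto age deciles
_DECILE_MATRIX = np.zeros((N_AGES, N_DECILES))
_DECILE_MATRIX[np.arange(N_AGES), AGE_TO_DECILE] = 1.0


def _to_decile(per_age: np.ndarray) -> np.ndarray:
    """Aggregate a (sex, age) or (sex, age, diabetes) array to (sex, decile)."""
    if per_age.ndim == 3:
        per_age = per_age.sum(axis=2)
    return per_age @ _DECILE_MATRIX


@dataclass
class TransitionProbabilities:
    """Per-cell annual transition probabilities, all arrays (sex, age, diabetes).

    ``p_dm`` is zero on the diabetic slice (diabetes is absorbing).
    """

    p_dm: np.ndarray
    p_chd_none: np.ndarray
    p_stroke_none: np.ndarray
    p_ncd_none: np.ndarray
    p_stroke_chd: np.ndarray
    p_chddeath_chd: np.ndarray
    p_ncd_chd: np.ndarray
    p_chd_stroke: np.ndarray
    p_strokedeath_stroke: np.ndarray
    p_ncd_stroke: np.ndarray
    p_chddeath_both: np.ndarray
    p_strokedeath_both: np.ndarray
    p_ncd_both: np.ndarray
    cf_chd: float
    cf_stroke: float
    recurrent_mi_rate: float
    mi_share_of_chd: float


def _competing(hazards: list[np.ndarray]) -> list[np.ndarray]:
    """Hazard-allocation conversion of cause-specific hazards to probabilities."""
    total = np.zeros_like(hazards[0])
    for h in hazards:
        total = total + h
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = np.where(total > 0, -np.expm1(-total) / np.where(total > 0, total, 1.0), 0.0)
    return [h * factor for h in hazards]


def annual_transition_probabilities(
    state: PopulationState,
    risks: RiskFunctionSet,
    deltas: Optional[RiskFactorDelta] = None,
    clamp_covariates: bool = True,
) -> TransitionProbabilities:
    """Compute per-cell cause-specific annual transition probabilities.

    ``deltas`` (if given) shift the stratum-mean SBP and BMI downward and
    scale the incident-diabetes hazard by its direct dose-response
    multiplier before the risk functions are evaluated.
    """
    rf = state.risk_factors
    dec = AGE_TO_DECILE
    # expand stratum means to single-year ages, shape (sex, age)
    sbp = rf.sbp[:, dec].copy()
    bmi = rf.bmi[:, dec].copy()
    hdl = rf.hdl[:, dec]
    ldl = rf.ldl[:, dec]
    smoking = rf.smoking[:, dec]
    dm_mult = np.ones((N_SEXES, N_AGES))
    if deltas is not None:
        sbp -= deltas.delta_sbp[:, dec]
        bmi -= deltas.delta_bmi[:, dec]
        dm_mult = deltas.diabetes_rate_multiplier[:, dec]
    if clamp_covariates:
        low_sbp, low_bmi = 60.0, 12.0
        if np.any(sbp < low_sbp) or np.any(bmi < low_bmi):
            warnings.warn("covariates outside admissible range; clamping", RuntimeWarning)
        sbp = np.maximum(sbp, low_sbp)
        bmi = np.maximum(bmi, low_bmi)

    age = np.broadcast_to(AGES.astype(float), (N_SEXES, N_AGES))
    female = np.array([[0.0], [1.0]])

    def haz(fn, diabetes: float) -> np.ndarray:
        return fn.hazard(age, female, sbp, bmi, hdl, ldl, smoking, diabetes)

    def by_dm(fn) -> np.ndarray:
        return np.stack([haz(fn, 0.0), haz(fn, 1.0)], axis=-1)  # (sex, age, 2)

    m = risks.calibration_multipliers
    m_chd, m_stroke, m_cd = m["chd_events"], m["stroke_events"], m["chd_deaths"]
    pc = risks.post_cvd

    h_dm = np.zeros((N_SEXES, N_AGES, 2))
    h_dm[:, :, 0] = haz(risks.incident_diabetes, 0.0) * dm_mult
    h_chd = by_dm(risks.incident_chd) * m_chd
    h_stroke = by_dm(risks.incident_stroke) * m_stroke
    h_ncd = by_dm(risks.non_cvd_death)
    h_ncd_post = h_ncd * pc.non_cvd_death_multiplier
    h_cd = np.full_like(h_ncd, pc.chd_death_hazard * m_cd)
    h_sd = np.full_like(h_ncd, pc.stroke_death_hazard)

    p_dm, p_chd_none, p_stroke_none, p_ncd_none = _competing(
        [h_dm, h_chd, h_stroke, h_ncd]
    )
    p_stroke_chd, p_chddeath_chd, p_ncd_chd = _competing([h_stroke, h_cd, h_ncd_post])
    p_chd_stroke, p_strokedeath_stroke, p_ncd_stroke = _competing(
        [h_chd, h_sd, h_ncd_post]
    )
    p_chddeath_both, p_strokedeath_both, p_ncd_both = _competing(
        [h_cd, h_sd, h_ncd_post]
    )
    return TransitionProbabilities(
        p_dm=p_dm,
        p_chd_none=p_chd_none,
        p_stroke_none=p_stroke_none,
        p_ncd_none=p_ncd_none,
        p_stroke_chd=p_stroke_chd,
        p_chddeath_chd=p_chddeath_chd,
        p_ncd_chd=p_ncd_chd,
        p_chd_stroke=p_chd_stroke,
        p_strokedeath_stroke=p_strokedeath_stroke,
        p_ncd_stroke=p_ncd_stroke,
        p_chddeath_both=p_chddeath_both,
        p_strokedeath_both=p_strokedeath_both,
        p_ncd_both=p_ncd_both,
        cf_chd=min(1.0, pc.case_fatality_chd * m_cd),
        cf_stroke=min(1.0, pc.case_fatality_stroke),
        recurrent_mi_rate=pc.recurrent_mi_rate,
        mi_share_of_chd=risks.mi_share_of_chd,
    )


def step_year(
    state: PopulationState,
    probs: TransitionProbabilities,
    entrants: np.ndarray,
    entrant_composition: np.ndarray,
) -> Tuple[PopulationState, Dict[str, np.ndarray]]:
    """Advance the population one annual cycle.

    Events and person-years are tallied by age at cycle start.  After
    transitions, ages increment, cells aging past 94 exit, and ``entrants``
    (per-sex counts of new 35-year-olds) enter distributed over
    ``entrant_composition`` (per-sex proportions over diabetes x CVD state).

    Returns the new state and a dict of (sex, age-decile) tallies.  The
    accounting identity  N_next = N_prev - deaths - aged_out + entrants
    holds exactly.
    """
    c = state.counts
    n0 = c[:, :, :, CVD_NONE]
    nc = c[:, :, :, CVD_CHD]
    ns = c[:, :, :, CVD_STROKE]
    nb = c[:, :, :, CVD_BOTH]

    dm_inc = n0 * probs.p_dm  # nonzero only on the non-diabetic slice
    chd_events_none = n0 * probs.p_chd_none
    stroke_events_none = n0 * probs.p_stroke_none
    ncd_deaths_none = n0 * probs.p_ncd_none

    stroke_events_chd = nc * probs.p_stroke_chd
    chd_deaths_chd = nc * probs.p_chddeath_chd
    ncd_deaths_chd = nc * probs.p_ncd_chd

    chd_events_stroke = ns * probs.p_chd_stroke
    stroke_deaths_stroke = ns * probs.p_strokedeath_stroke
    ncd_deaths_stroke = ns * probs.p_ncd_stroke

    chd_deaths_both = nb * probs.p_chddeath_both
    stroke_deaths_both = nb * probs.p_strokedeath_both
    ncd_deaths_both = nb * probs.p_ncd_both

    cf_chd, cf_stroke = probs.cf_chd, probs.cf_stroke
    chd_acute = (chd_events_none + chd_events_stroke) * cf_chd
    stroke_acute = (stroke_events_none + stroke_events_chd) * cf_stroke

    incident_chd = chd_events_none + chd_events_stroke
    incident_stroke = stroke_events_none + stroke_events_chd
    chd_deaths = chd_acute + chd_deaths_chd + chd_deaths_both
    stroke_deaths = stroke_acute + stroke_deaths_stroke + stroke_deaths_both
    ncd_deaths = ncd_deaths_none + ncd_deaths_chd + ncd_deaths_stroke + ncd_deaths_both
    recurrent_mi = (nc + nb) * probs.recurrent_mi_rate
    mi = probs.mi_share_of_chd * incident_chd + recurrent_mi

    new = np.empty_like(c)
    none_out = dm_inc + chd_events_none + stroke_events_none + ncd_deaths_none
    new[:, :, :, CVD_NONE] = n0 - none_out
    new[:, :, 1, CVD_NONE] += dm_inc[:, :, 0]
    new[:, :, :, CVD_CHD] = (
        nc
        - (stroke_events_chd + chd_deaths_chd + ncd_deaths_chd)
        + chd_events_none * (1.0 - cf_chd)
    )
    new[:, :, :, CVD_STROKE] = (
        ns
        - (chd_events_stroke + stroke_deaths_stroke + ncd_deaths_stroke)
        + stroke_events_none * (1.0 - cf_stroke)
    )
    new[:, :, :, CVD_BOTH] = (
        nb
        - (chd_deaths_both + stroke_deaths_both + ncd_deaths_both)
        + stroke_events_chd * (1.0 - cf_stroke)
        + chd_events_stroke * (1.0 - cf_chd)
    )
    if np.any(new < -1e-6):
        raise RuntimeError("internal error: negative cell count after transitions")
    np.clip(new, 0.0, None, out=new)

    # age increment: shift along the age axis; the oldest cells exit
    aged = np.zeros_like(new)
    aged[:, 1:] = new[:, :-1]
    entrants = np.asarray(entrants, dtype=float)
    aged[:, 0] = entrants[:, None, None] * entrant_composition

    tallies = {
        "incident_diabetes": _to_decile(dm_inc),
        "incident_chd": _to_decile(incident_chd),
        "incident_stroke": _to_decile(incident_stroke),
        "mi": _to_decile(mi),
        "chd_deaths": _to_decile(chd_deaths),
        "stroke_deaths": _to_decile(stroke_deaths),
        "non_cvd_deaths": _to_decile(ncd_deaths),
        "all_cause_deaths": _to_decile(chd_deaths + stroke_deaths + ncd_deaths),
        "diabetes_person_years": _to_decile(c[:, :, 1, :].sum(axis=2)),
    }
    return PopulationState(aged, state.risk_factors.copy()), tallies


def _entrant_composition(baseline: PopulationState) -> np.ndarray:
    """Diabetes x CVD-state proportions of the baseline age-35 cells, (sex, 2, 4)."""
    comp = baseline.counts[:, 0].copy()
    totals = comp.sum(axis=(1, 2), keepdims=True)
    default = np.zeros((2, 4))
    default[0, CVD_NONE] = 1.0
    out = np.where(totals > 0, comp / np.where(totals > 0, totals, 1.0), default)
    return out


def run_simulation(
    baseline: PopulationState,
    risks: RiskFunctionSet,
    demography: Demography,
    scenario: Optional[ScenarioDefinition] = None,
    consumption: Optional[ConsumptionSummary] = None,
    params: Optional[EffectParameters] = None,
    horizon_years: Optional[int] = None,
    start_year: Optional[int] = None,
) -> SimulationResult:
    """Run the annual-cycle simulation over the horizon (default 2013-2022).

    ``scenario=None`` (or a zero reduction) is the base case of unchanged
    SSB consumption.  Otherwise the scenario's risk-factor deltas apply from
    year 1 onward (optionally phased in linearly over
    ``params.weight_phase_in_years``).  ``params.beta_multiplier`` scales the
    diabetes coefficients of the CHD/stroke/non-CVD-death risk functions in
    whichever run it is passed to.
    """
    if horizon_years is None:
        horizon_years = scenario.horizon_years if scenario is not None else 10
    if start_year is None:
        start_year = scenario.start_year if scenario is not None else 2013
    horizon, year0 = horizon_years, start_year
    if horizon < 1:
        raise ValueError("horizon must be at least 1 year")

    if params is not None and params.beta_multiplier != 1.0:
        risks = risks.with_diabetes_beta_multiplier(params.beta_multiplier)

    full_deltas = None
    if scenario is not None and scenario.reduction_fraction > 0:
        if consumption is None:
            raise ValueError("a consumption summary is required to run a scenario")
        full_deltas = compute_risk_factor_deltas(consumption, scenario, params)
    phase_in = params.weight_phase_in_years if params is not None else 1

    comp = _entrant_composition(baseline)
    state = baseline.copy()
    years = [year0 + i for i in range(horizon)]
    tallies = {k: np.zeros((horizon, N_SEXES, N_DECILES)) for k in OUTCOMES}

    probs = None
    prev_frac = None
    for i in range(horizon):
        if full_deltas is None:
            frac = 0.0
            deltas = None
        else:
            frac = min(1.0, (i + 1) / max(1, phase_in))
            deltas = _scale_deltas(full_deltas, frac)
        if probs is None or frac != prev_frac:
            probs = annual_transition_probabilities(state, risks, deltas)
            prev_frac = frac
        state, year_tallies = step_year(state, probs, demography.entrants_per_year, comp)
        for k, v in year_tallies.items():
            tallies[k][i] = v
    return SimulationResult(years, tallies)


def _scale_deltas(deltas: RiskFactorDelta, frac: float) -> Optional[RiskFactorDelta]:
    if frac >= 1.0:
        return deltas
    if frac <= 0.0:
        return None
    return RiskFactorDelta(
        delta_servings=deltas.delta_servings * frac,
        net_delta_kcal=deltas.net_delta_kcal * frac,
        delta_weight_kg=deltas.delta_weight_kg * frac,
        delta_bmi=deltas.delta_bmi * frac,
        delta_sbp=deltas.delta_sbp * frac,
        diabetes_rate_multiplier=deltas.diabetes_rate_multiplier**frac,
    )


def reference_year_counts(
    baseline: PopulationState, risks: RiskFunctionSet, demography: Demography
) -> Dict[str, float]:
    """One-cycle event/death counts used as the calibration comparator."""
    probs = annual_transition_probabilities(baseline, risks)
    _, t = step_year(probs=probs, state=baseline, entrants=demography.entrants_per_year,
                     entrant_composition=_entrant_composition(baseline))
    return {
        "chd_events": float(t["incident_chd"].sum()),
        "stroke_events": float(t["incident_stroke"].sum()),
        "chd_deaths": float(t["chd_deaths"].sum()),
    }


def calibrate(
    baseline: PopulationState,
    risks: RiskFunctionSet,
    targets: CalibrationTargets,
    demography: Demography,
    max_iterations: int = 100,
) -> RiskFunctionSet:
    """Fit calibration multipliers so a reference-year run matches targets.

    Iterative proportional fitting: each multiplier is scaled by
    target / simulated until every quantity is within ``targets.tolerance``
    (relative, default 1%) of its target.  Raises :class:`CalibrationError`
    with diagnostics on non-convergence.
    """
    fitted = risks.copy()
    goal = {
        "chd_events": targets.chd_events,
        "stroke_events": targets.stroke_events,
        "chd_deaths": targets.chd_deaths,
    }
    sim: Dict[str, float] = {}
    for _ in range(max_iterations):
        sim = reference_year_counts(baseline, fitted, demography)
        rel = {k: abs(sim[k] / goal[k] - 1.0) for k in goal}
        if all(v <= targets.tolerance for v in rel.values()):
            return fitted
        for k in goal:
            if sim[k] <= 0:
                raise CalibrationError(
                    f"cannot calibrate {k}: simulated count is zero "
                    "(baseline hazards must be positive)"
                )
            fitted.calibration_multipliers[k] *= goal[k] / sim[k]
    raise CalibrationError(
        f"calibration did not converge in {max_iterations} iterations; "
        f"last simulated counts {sim}, targets {goal}, "
        f"multipliers {fitted.calibration_multipliers}"
    )
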