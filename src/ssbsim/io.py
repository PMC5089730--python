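"""Reading and writing input bundles as a directory of delimited text
tables plus one structured YAML config (the documented on-disk interchange
format; see the README for the key schema)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .costs import CostInputs, CurrencyParameters
from .exposure import ConsumptionSummary, EffectParameters
from .model import (
    AGES,
    CVD_STATES,
    CalibrationTargets,
    Demography,
    N_AGES,
    N_CVD,
    N_SEXES,
    PopulationState,
    PostCVDParameters,
    RiskFactors,
    RiskFunction,
    RiskFunctionSet,
    SEXES,
)
from .synthetic import ModelBundle

_CAUSES = ("incident_diabetes", "incident_chd", "incident_stroke", "non_cvd_death")


def save_bundle(bundle: ModelBundle, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    rows = []
    for s, sex in enumerate(SEXES):
        for a in range(N_AGES):
            for dm in (0, 1):
                for cv, cvd in enumerate(CVD_STATES):
                    rows.append((sex, int(AGES[a]), dm, cvd, bundle.baseline.counts[s, a, dm, cv]))
    pd.DataFrame(rows, columns=["sex", "age", "diabetes", "cvd_state", "count"]).to_csv(
        d / "population.tsv", sep="\t", index=False
    )
    bundle.baseline.risk_factors.to_frame().to_csv(d / "risk_factors.tsv", sep="\t")
    bundle.consumption.table.to_csv(d / "consumption.tsv", sep="\t")

    ci = bundle.cost_inputs
    ci.expenditures.to_csv(d / "cost_expenditures.tsv", sep="\t")
    ci.service_counts.to_csv(d / "cost_service_counts.tsv", sep="\t")
    ci.services_per_patient.to_csv(d / "cost_services_per_patient.tsv", sep="\t")
    ci.institution_weights.to_csv(d / "cost_institution_weights.tsv", sep="\t")

    risks = bundle.risks
    ep = bundle.effect_params
    config = {
        "risk_functions": {c: getattr(risks, c).to_dict() for c in _CAUSES},
        "post_cvd": {
            k: float(getattr(risks.post_cvd, k))
            for k in (
                "case_fatality_chd", "case_fatality_stroke", "chd_death_hazard",
                "stroke_death_hazard", "non_cvd_death_multiplier", "recurrent_mi_rate",
            )
        },
        "calibration_multipliers": {k: float(v) for k, v in risks.calibration_multipliers.items()},
        "mi_share_of_chd": float(risks.mi_share_of_chd),
        "calibration_targets": {
            "chd_events": float(bundle.targets.chd_events),
            "stroke_events": float(bundle.targets.stroke_events),
            "chd_deaths": float(bundle.targets.chd_deaths),
            "tolerance": float(bundle.targets.tolerance),
            "reference_year": int(bundle.targets.reference_year),
        },
        "demography": {"entrants_per_year": [float(x) for x in bundle.demography.entrants_per_year]},
        "currency": {
            "ppp_rate": float(ci.currency.ppp_rate),
            "inflation_rate": float(ci.currency.inflation_rate),
        },
        "effect_parameters": {
            "rr_diabetes_per_serving": float(ep.rr_diabetes_per_serving),
            "rr_diabetes_ci": [float(x) for x in ep.rr_diabetes_ci],
            "sbp_per_serving": {k: float(v) for k, v in ep.sbp_per_serving.items()},
            "sbp_per_serving_ci": {k: [float(x) for x in v] for k, v in ep.sbp_per_serving_ci.items()},
            "sbp_per_bmi_unit": {k: float(v) for k, v in ep.sbp_per_bmi_unit.items()},
            "kcal_per_serving": float(ep.kcal_per_serving),
            "ml_per_serving": float(ep.ml_per_serving),
            "kcal_per_pound": float(ep.kcal_per_pound),
            "kg_per_pound": float(ep.kg_per_pound),
            "mean_height_m": {k: float(v) for k, v in ep.mean_height_m.items()},
            "beta_multiplier": float(ep.beta_multiplier),
            "weight_phase_in_years": int(ep.weight_phase_in_years),
        },
    }
    with open(d / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def load_bundle(directory) -> ModelBundle:
    d = Path(directory)
    with open(d / "config.yaml") as fh:
        config = yaml.safe_load(fh)

    pop = pd.read_csv(d / "population.tsv", sep="\t")
    counts = np.zeros((N_SEXES, N_AGES, 2, N_CVD))
    sex_idx = {s: i for i, s in enumerate(SEXES)}
    cvd_idx = {c: i for i, c in enumerate(CVD_STATES)}
    counts[
        pop["sex"].map(sex_idx).to_numpy(),
        pop["age"].to_numpy() - 35,
        pop["diabetes"].to_numpy(),
        pop["cvd_state"].map(cvd_idx).to_numpy(),
    ] = pop["count"].to_numpy()
    rf = RiskFactors.from_frame(
        pd.read_csv(d / "risk_factors.tsv", sep="\t").set_index(["sex", "age_group"])
    )
    baseline = PopulationState(counts, rf)

    ep_cfg = config["effect_parameters"]
    effect_params = EffectParameters(
        rr_diabetes_per_serving=ep_cfg["rr_diabetes_per_serving"],
        rr_diabetes_ci=tuple(ep_cfg["rr_diabetes_ci"]),
        sbp_per_serving=dict(ep_cfg["sbp_per_serving"]),
        sbp_per_serving_ci={k: tuple(v) for k, v in ep_cfg["sbp_per_serving_ci"].items()},
        sbp_per_bmi_unit=dict(ep_cfg["sbp_per_bmi_unit"]),
        kcal_per_serving=ep_cfg["kcal_per_serving"],
        ml_per_serving=ep_cfg["ml_per_serving"],
        kcal_per_pound=ep_cfg["kcal_per_pound"],
        kg_per_pound=ep_cfg["kg_per_pound"],
        mean_height_m=dict(ep_cfg["mean_height_m"]),
        beta_multiplier=ep_cfg["beta_multiplier"],
        weight_phase_in_years=ep_cfg["weight_phase_in_years"],
    )
    consumption = ConsumptionSummary(
        pd.read_csv(d / "consumption.tsv", sep="\t").set_index(["sex", "age_group"]),
        effect_params,
    )
    risks = RiskFunctionSet(
        **{c: RiskFunction.from_dict(config["risk_functions"][c]) for c in _CAUSES},
        post_cvd=PostCVDParameters(**config["post_cvd"]),
        calibration_multipliers=dict(config["calibration_multipliers"]),
        mi_share_of_chd=config["mi_share_of_chd"],
    )
    tcfg = config["calibration_targets"]
    targets = CalibrationTargets(
        chd_events=tcfg["chd_events"], stroke_events=tcfg["stroke_events"],
        chd_deaths=tcfg["chd_deaths"], tolerance=tcfg["tolerance"],
        reference_year=tcfg["reference_year"],
    )
    demography = Demography(np.asarray(config["demography"]["entrants_per_year"]))
    cost_inputs = CostInputs(
        expenditures=pd.read_csv(d / "cost_expenditures.tsv", sep="\t", index_col=0),
        service_counts=pd.read_csv(d / "cost_service_counts.tsv", sep="\t", index_col=0),
        services_per_patient=pd.read_csv(
            d / "cost_services_per_patient.tsv", sep="\t", index_col=[0, 1]
        ),
        institution_weights=pd.read_csv(
            d / "cost_institution_weights.tsv", sep="\t", index_col=0
        ),
        currency=CurrencyParameters(**config["currency"]),
    )
    return ModelBundle(
        baseline=baseline, risks=risks, demography=demography, targets=targets,
        cost_inputs=cost_inputs, consumption=consumption, effect_params=effect_params,
    )
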