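"""Independent brute-force replay oracle for the cohort engine.

Re-implements the annual cycle with plain-Python scalar arithmetic over an
explicit dict of cells, sharing no code with the vectorized engine.  Used
to verify the engine's tallies cell by cell on small instances.
"""

import math

REF = {"age": 60.0, "sbp": 120.0, "bmi": 25.0, "hdl": 50.0, "ldl": 120.0}
DECILES = [(35, 44), (45, 54), (55, 64), (65, 74), (75, 94)]


def _decile(age):
    for i, (lo, hi) in enumerate(DECILES):
        if lo <= age <= hi:
            return i
    raise ValueError(age)


def _logistic_hazard(fn, age, female, sbp, bmi, hdl, ldl, smoking, diabetes):
    lp = (
        fn.intercept
        + fn.age * (age - REF["age"])
        + fn.female * female
        + fn.sbp * (sbp - REF["sbp"])
        + fn.bmi * (bmi - REF["bmi"])
        + fn.hdl * (hdl - REF["hdl"])
        + fn.ldl * (ldl - REF["ldl"])
        + fn.smoking * smoking
        + fn.diabetes * diabetes
    )
    return 1.0 / (1.0 + math.exp(-lp))


def _allocate(hazards):
    total = sum(hazards)
    if total <= 0:
        return [0.0] * len(hazards)
    factor = (1.0 - math.exp(-total)) / total
    return [h * factor for h in hazards]


def oracle_run(baseline, risks, demography, n_years, deltas=None):
    """Replay the simulation cell by cell; returns per-outcome totals."""
    cells = {}
    counts = baseline.counts
    for s in range(2):
        for a in range(60):
            for dm in range(2):
                for cv in range(4):
                    v = float(counts[s, a, dm, cv])
                    if v > 0:
                        cells[(s, 35 + a, dm, cv)] = v

    rf = baseline.risk_factors
    m = risks.calibration_multipliers
    pc = risks.post_cvd
    cf_chd = min(1.0, pc.case_fatality_chd * m["chd_deaths"])
    cf_str = min(1.0, pc.case_fatality_stroke)
    h_cd = pc.chd_death_hazard * m["chd_deaths"]
    h_sd = pc.stroke_death_hazard

    # entrant composition = baseline age-35 proportions (default: no-CVD, no-DM)
    comp = {}
    for s in range(2):
        tot = sum(cells.get((s, 35, dm, cv), 0.0) for dm in range(2) for cv in range(4))
        if tot > 0:
            comp[s] = {
                (dm, cv): cells.get((s, 35, dm, cv), 0.0) / tot
                for dm in range(2)
                for cv in range(4)
            }
        else:
            comp[s] = {(dm, cv): 1.0 if (dm, cv) == (0, 0) else 0.0
                       for dm in range(2) for cv in range(4)}

    totals = {
        k: 0.0
        for k in (
            "incident_diabetes", "incident_chd", "incident_stroke", "mi",
            "chd_deaths", "stroke_deaths", "non_cvd_deaths", "all_cause_deaths",
            "diabetes_person_years",
        )
    }

    def covs(s, age, dm):
        d = _decile(age)
        sbp = rf.sbp[s, d]
        bmi = rf.bmi[s, d]
        dmmult = 1.0
        if deltas is not None:
            sbp -= deltas.delta_sbp[s, d]
            bmi -= deltas.delta_bmi[s, d]
            dmmult = deltas.diabetes_rate_multiplier[s, d]
        return (
            sbp, bmi, rf.hdl[s, d], rf.ldl[s, d], rf.smoking[s, d], float(s), dmmult,
        )

    for _year in range(n_years):
        new = {}

        def add(key, v):
            new[key] = new.get(key, 0.0) + v

        for (s, age, dm, cv), n in cells.items():
            sbp, bmi, hdl, ldl, smoking, female, dmmult = covs(s, age, dm)

            def haz(fn, diabetes=dm):
                return _logistic_hazard(fn, age, female, sbp, bmi, hdl, ldl, smoking, diabetes)

            if dm:
                totals["diabetes_person_years"] += n
            h_chd = haz(risks.incident_chd) * m["chd_events"]
            h_stroke = haz(risks.incident_stroke) * m["stroke_events"]
            h_ncd = haz(risks.non_cvd_death)

            if cv == 0:  # no CVD
                h_dm = 0.0 if dm else haz(risks.incident_diabetes, 0.0) * dmmult
                p_dm, p_chd, p_str, p_ncd = _allocate([h_dm, h_chd, h_stroke, h_ncd])
                dm_inc = n * p_dm
                chd_ev = n * p_chd
                str_ev = n * p_str
                ncd_d = n * p_ncd
                totals["incident_diabetes"] += dm_inc
                totals["incident_chd"] += chd_ev
                totals["incident_stroke"] += str_ev
                totals["non_cvd_deaths"] += ncd_d
                totals["chd_deaths"] += chd_ev * cf_chd
                totals["stroke_deaths"] += str_ev * cf_str
                totals["mi"] += risks.mi_share_of_chd * chd_ev
                add((s, age, dm, 0), n - dm_inc - chd_ev - str_ev - ncd_d)
                add((s, age, 1, 0), dm_inc)
                add((s, age, dm, 1), chd_ev * (1 - cf_chd))
                add((s, age, dm, 2), str_ev * (1 - cf_str))
            elif cv == 1:  # CHD
                p_str, p_cd, p_ncd = _allocate(
                    [h_stroke, h_cd, h_ncd * pc.non_cvd_death_multiplier]
                )
                str_ev = n * p_str
                cd = n * p_cd
                ncd_d = n * p_ncd
                totals["incident_stroke"] += str_ev
                totals["stroke_deaths"] += str_ev * cf_str
                totals["chd_deaths"] += cd
                totals["non_cvd_deaths"] += ncd_d
                totals["mi"] += pc.recurrent_mi_rate * n
                add((s, age, dm, 1), n - str_ev - cd - ncd_d)
                add((s, age, dm, 3), str_ev * (1 - cf_str))
            elif cv == 2:  # stroke
                p_chd, p_sd, p_ncd = _allocate(
                    [h_chd, h_sd, h_ncd * pc.non_cvd_death_multiplier]
                )
                chd_ev = n * p_chd
                sd = n * p_sd
                ncd_d = n * p_ncd
                totals["incident_chd"] += chd_ev
                totals["chd_deaths"] += chd_ev * cf_chd
                totals["stroke_deaths"] += sd
                totals["non_cvd_deaths"] += ncd_d
                totals["mi"] += risks.mi_share_of_chd * chd_ev
                add((s, age, dm, 2), n - chd_ev - sd - ncd_d)
                add((s, age, dm, 3), chd_ev * (1 - cf_chd))
            else:  # CHD and stroke
                p_cd, p_sd, p_ncd = _allocate(
                    [h_cd, h_sd, h_ncd * pc.non_cvd_death_multiplier]
                )
                totals["chd_deaths"] += n * p_cd
                totals["stroke_deaths"] += n * p_sd
                totals["non_cvd_deaths"] += n * p_ncd
                totals["mi"] += pc.recurrent_mi_rate * n
                add((s, age, dm, 3), n * (1 - p_cd - p_sd - p_ncd))

        # age increment, retirement past 94, entrants at 35
        aged = {}
        for (s, age, dm, cv), n in new.items():
            if age + 1 <= 94 and n > 0:
                aged[(s, age + 1, dm, cv)] = aged.get((s, age + 1, dm, cv), 0.0) + n
        for s in range(2):
            e = float(demography.entrants_per_year[s])
            for (dm, cv), frac in comp[s].items():
                if e * frac > 0:
                    aged[(s, 35, dm, cv)] = aged.get((s, 35, dm, cv), 0.0) + e * frac
        cells = aged

    totals["all_cause_deaths"] = (
        totals["chd_deaths"] + totals["stroke_deaths"] + totals["non_cvd_deaths"]
    )
    return totals, cells
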