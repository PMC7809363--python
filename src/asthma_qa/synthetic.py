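"""Synthetic insurance-claims generator.

Produces the four delimited claims tables (patients, visits, prescriptions,
institutions) plus ground-truth frames so that every downstream stage —
cohort selection, severity clustering, quality grading, covariates and the
GEE association models — can be tested without any external data.

Structure emulated:

* July-June claim years; ``n_periods`` assessment periods, each followed by
  a measurement year (so ``n_periods + 1`` years of claims are generated).
* Four severity archetypes with the characteristic trajectory shapes:
  I near-zero year-round, II winter-peaking (January), III moderate and
  flat, IV high with a January peak and a smaller March rebound.  Monthly
  controller prescriptions realize a target mean daily rank with drugs of
  the matching rank; archetype-I monthly targets are capped at 0.42 so the
  realized monthly means stay below 0.5.
* Primary clinics carry a latent quality class (good/poor) that drives
  their quality-indicator propensities (PFT rate, visit intensity, ICS
  preference, steroid habits); the planted grade effect on exacerbation
  uses this latent class (good=Satisfactory-like, poor=Unsatisfactory-like,
  tertiary hospitals the reference).
* Exacerbation outcomes are drawn from a marginal logistic model with the
  planted log-odds; within-patient dependence across periods comes from a
  latent AR(1) standard-normal series thresholded at the marginal
  probability (Gaussian copula), so the planted effects are exactly the
  population-averaged log-odds a GEE estimates.  Outcomes are realized as
  claims: an asthma-coded outpatient visit with a same-day systemic
  corticosteroid burst (>80 mg hydrocortisone-equivalent) or a SABA
  nebulizer treatment; a small fraction of non-cases receive non-qualifying
  decoy events (emergency-only bursts at tertiary hospitals, or exactly
  80 mg dispensings).
"""

from __future__ import annotations

from calendar import isleap
from dataclasses import dataclass
from datetime import date
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from . import covariates as cov
from .catalog import DrugCatalog
from .config import SimulationConfig
from .periods import AssessmentPeriod, make_periods

ARCHETYPES = ("I", "II", "III", "IV")

#: Target mean daily rank-sum per assessment month (Jul..Jun) per archetype.
ARCHETYPE_CURVES = np.array(
    [
        [0.10] * 12,
        [0.45, 0.45, 0.55, 0.80, 1.20, 1.70, 2.10, 1.55, 1.05, 0.80, 0.60, 0.50],
        [2.30, 2.25, 2.30, 2.35, 2.40, 2.45, 2.50, 2.40, 2.40, 2.35, 2.30, 2.25],
        [3.80, 3.70, 3.90, 4.20, 4.60, 5.20, 5.90, 4.90, 5.30, 4.60, 4.20, 3.90],
    ]
)

#: Per-month emission probability (before clinic/patient thinning for I).
EMIT_PROB = np.array([0.30, 0.90, 1.0, 1.0])
NOISE_SD = np.array([0.06, 0.15, 0.20, 0.35])
SABA_MU = np.array([1.3, 1.0, 0.8, 0.8])
AGE_BAND_RANGES = ((15, 34), (35, 44), (45, 54), (55, 64), (65, 90))


def _month_layout(start_year: int):
    """(lengths, start offsets) of the 12 assessment months of one claim year."""
    lengths = [31, 31, 30, 31, 30, 31, 31, 28 + isleap(start_year + 1), 31, 30, 31, 30]
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    return np.array(lengths), starts


@dataclass
class SimulatedClaims:
    patients: pd.DataFrame
    visits: pd.DataFrame
    prescriptions: pd.DataFrame
    institutions: pd.DataFrame
    truth: pd.DataFrame
    institution_truth: pd.DataFrame
    config: SimulationConfig

    def tables(self) -> Dict[str, pd.DataFrame]:
        return {
            "patients": self.patients,
            "visits": self.visits,
            "prescriptions": self.prescriptions,
            "institutions": self.institutions,
        }


def simulate_claims(
    config: SimulationConfig, catalog: Optional[DrugCatalog] = None
) -> SimulatedClaims:
    """Generate a reproducible synthetic claims world (see module docstring)."""
    catalog = catalog or DrugCatalog.default()
    rng = np.random.default_rng(config.seed)
    P = config.n_patients
    n_years = config.n_periods + 1
    periods = make_periods(config.first_year, config.n_periods)

    # -- institutions -----------------------------------------------------
    n_pc, n_th = config.n_primary_clinics, config.n_tertiary_hospitals
    clinic_ids = [f"C{i:04d}" for i in range(n_pc)]
    tert_ids = [f"T{i:03d}" for i in range(n_th)]
    inst_ids = np.array(clinic_ids + tert_ids)
    inst_type = np.array(["primary"] * n_pc + ["tertiary"] * n_th)
    good = rng.random(n_pc) < config.good_clinic_fraction
    # indicator propensities, well separated by latent class
    p_pft = np.where(good, rng.beta(6, 3, n_pc), rng.beta(2, 6, n_pc))
    visit_factor = np.where(good, rng.beta(8, 2, n_pc), rng.beta(2, 5, n_pc))
    p_ics = np.where(good, rng.beta(8, 3, n_pc), rng.beta(3, 5, n_pc))
    p_ocs = np.where(good, rng.beta(2, 30, n_pc), rng.beta(4, 16, n_pc))
    # tertiary hospitals: uniformly high performance
    t_pft = rng.beta(10, 2, n_th)
    t_visit = rng.beta(8, 2, n_th)
    t_ics = rng.beta(10, 2, n_th)
    t_ocs = rng.beta(2, 40, n_th)
    inst_pft = np.concatenate([p_pft, t_pft])
    inst_visit = np.concatenate([visit_factor, t_visit])
    inst_ics = np.concatenate([p_ics, t_ics])
    inst_ocs = np.concatenate([p_ocs, t_ocs])

    # -- patients ---------------------------------------------------------
    arch = rng.choice(4, size=P, p=np.asarray(config.severity_archetype_weights))
    sex = np.where(rng.random(P) < config.male_prob, "M", "F")
    band0 = rng.choice(5, size=P, p=np.asarray(config.age_band_weights))
    lo = np.array([r[0] for r in AGE_BAND_RANGES])[band0]
    hi = np.array([r[1] for r in AGE_BAND_RANGES])[band0]
    age0 = rng.integers(lo, hi + 1)
    birth_year = config.first_year - age0
    engagement = rng.uniform(0.3, 1.0, size=P)
    no_controller = rng.random(P) < 0.03  # level-0 adherence patients

    # institution per patient-year, sticky across years
    inst_idx = np.zeros((P, n_years), dtype=int)
    tert_p = np.asarray(config.tertiary_prob)[arch]

    def draw_inst(mask):
        k = int(mask.sum())
        is_t = rng.random(k) < tert_p[mask]
        idx = np.where(
            is_t,
            n_pc + rng.integers(0, n_th, k),
            rng.integers(0, n_pc, k),
        )
        return idx

    inst_idx[:, 0] = draw_inst(np.ones(P, dtype=bool))
    for yidx in range(1, n_years):
        move = rng.random(P) >= config.stay_prob
        inst_idx[:, yidx] = inst_idx[:, yidx - 1]
        if move.any():
            inst_idx[move, yidx] = draw_inst(move)

    uninsured = rng.random((P, config.n_periods)) < config.uninsured_fraction
    comorbid = rng.random((P, config.n_periods)) < config.comorbidity_prob
    two_clinic = rng.random((P, n_years)) < config.two_clinic_fraction

    # -- prescriptions & visits, year by year, month by month -------------
    rx_parts: List[pd.DataFrame] = []
    visit_parts: List[pd.DataFrame] = []
    code_idx = {c: i for i, c in enumerate(catalog.codes)}
    codes_arr = np.array(catalog.codes)

    def emit_rx(pid, day, inst, code, units, days):
        rx_parts.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "_day": day,
                    "institution_id": inst_ids[inst],
                    "drug_code": codes_arr[code],
                    "daily_units": units,
                    "days_supplied": days,
                }
            )
        )

    def emit_visits(pid, day, inst, setting, icd1, icd2, pft):
        visit_parts.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "_day": day,
                    "institution_id": inst_ids[inst],
                    "setting": setting,
                    "icd10_primary": icd1,
                    "icd10_secondary": icd2,
                    "pft": pft,
                }
            )
        )

    pid_all = np.arange(P)
    year_day0 = np.zeros(n_years, dtype=int)  # day offset of each year start
    off = 0
    for yidx in range(n_years):
        year_day0[yidx] = off
        off += (
            date(config.first_year + yidx + 1, 7, 1)
            - date(config.first_year + yidx, 7, 1)
        ).days

    for yidx in range(n_years):
        ystart = config.first_year + yidx
        mlen, mstart = _month_layout(ystart)
        inst_y = inst_idx[:, yidx]
        clinic_ics_pref = inst_ics[inst_y]
        vfac = inst_visit[inst_y]
        # emission probability per patient this year
        emit_p = EMIT_PROB[arch].copy()
        is_a1 = arch == 0
        emit_p[is_a1] = EMIT_PROB[0] / 0.30 * 0.55 * (
            vfac[is_a1] + 0.25
        ) * engagement[is_a1]
        emit_p = np.clip(emit_p, 0.02, 1.0)
        for m in range(12):
            base = ARCHETYPE_CURVES[arch, m] / EMIT_PROB[arch]
            target = base + rng.normal(0, NOISE_SD[arch], P) * (
                1 + ARCHETYPE_CURVES[arch, m]
            ) * 0.5
            target = np.clip(target, 0.05, np.where(is_a1, 0.42, 8.0))
            emitted = (rng.random(P) < emit_p) & ~no_controller
            if not emitted.any():
                continue
            t = target[emitted]
            pids = pid_all[emitted]
            insts = inst_y[emitted]
            icsp = clinic_ics_pref[emitted]
            # decompose target into at most two same-month scripts
            for part in (0, 1):
                if part == 0:
                    tt = np.minimum(t, 4.0)
                    sel = tt > 0
                else:
                    tt = t - 4.0
                    sel = tt > 0
                if not sel.any():
                    continue
                tsel = tt[sel]
                r = np.minimum(4, np.ceil(tsel)).astype(int)
                frac = np.clip(tsel / r, 0.0, 1.0)
                days = np.clip(np.round(frac * mlen[m]).astype(int), 1, mlen[m])
                start = mstart[m] + rng.integers(0, mlen[m] - days + 1)
                day = year_day0[yidx] + start
                # drug choice by rank and clinic ICS preference
                u1 = rng.random(sel.sum())
                u2 = rng.random(sel.sum())
                code = np.full(sel.sum(), code_idx["ICS_BUD_L"])
                r1 = r == 1
                alt = np.where(
                    u2 < 0.5,
                    code_idx["LTRA_MONT"],
                    np.where(u2 < 0.7, code_idx["XAN_THEO"], code_idx["LABA_SALM"]),
                )
                code = np.where(r1 & (u1 >= icsp[sel]), alt, code)
                code = np.where(
                    r == 2,
                    np.where(u2 < 0.6, code_idx["ICSLABA_L"], code_idx["ICS_BUD_H"]),
                    code,
                )
                code = np.where(r == 3, code_idx["ICSLABA_H"], code)
                pred_ok = (r == 4) & (u1 < 0.15) & (days >= 28)
                code = np.where(r == 4, code_idx["LAMA_TIO"], code)
                code = np.where(pred_ok, code_idx["OCS_PRED5"], code)
                emit_rx(pids[sel], day, insts[sel], code, 1, days)
                icd1 = np.where(u2 < 0.8, "J450", "J069")
                icd2 = np.where(u2 < 0.8, "", "J459")
                pft = rng.random(sel.sum()) < inst_pft[insts[sel]] * 0.4
                emit_visits(pids[sel], day, insts[sel], "outpatient", icd1, icd2, pft)

        # SABA relief scripts (always at least one visit per patient-year)
        n_saba = np.maximum(rng.poisson(SABA_MU[arch]), 1)
        pids = np.repeat(pid_all, n_saba)
        insts = inst_y[pids]
        ylen = (date(ystart + 1, 7, 1) - date(ystart, 7, 1)).days
        day = year_day0[yidx] + rng.integers(0, ylen, len(pids))
        emit_rx(pids, day, insts, np.full(len(pids), code_idx["SABA_SALB"]), 2, 10)
        u = rng.random(len(pids))
        icd1 = np.where(u < 0.8, "J450", "J069")
        icd2 = np.where(u < 0.8, "", "J459")
        pft = rng.random(len(pids)) < inst_pft[insts] * 0.4
        emit_visits(pids, day, insts, "outpatient", icd1, icd2, pft)

        # occasional short oral-steroid habit (drives indicator 7)
        habit = rng.random(P) < inst_ocs[inst_y] * 1.5
        if habit.any():
            pids = pid_all[habit]
            insts = inst_y[habit]
            day = year_day0[yidx] + rng.integers(0, ylen, len(pids))
            emit_rx(pids, day, insts, np.full(len(pids), code_idx["OCS_PRED5"]), 2, 5)
            emit_visits(
                pids, day, insts, "outpatient",
                np.full(len(pids), "J450"), "", False,
            )

        # comorbidity carrier visit (assessment years only)
        if yidx < config.n_periods:
            has = comorbid[:, yidx]
            pids = pid_all[has]
            insts = inst_y[has]
            day = year_day0[yidx] + rng.integers(0, ylen, len(pids))
            codes = rng.choice(
                ["L208", "K219", "J310", "J301", "J320", "F329", "F331",
                 "F400", "F411", "E669"],
                len(pids),
            )
            emit_visits(pids, day, insts, "outpatient", codes, "J459", False)

        # second-clinic contamination (excluded by the one-clinic criterion)
        tc = two_clinic[:, yidx] & (inst_y < n_pc)
        if tc.any():
            pids = pid_all[tc]
            other = (inst_y[tc] + 1 + rng.integers(0, n_pc - 1, len(pids))) % n_pc
            day = year_day0[yidx] + rng.integers(0, ylen, len(pids))
            emit_visits(pids, day, other, "outpatient", "J450", "", False)

    # -- adherence realized per assessment period ------------------------
    origin = pd.Timestamp(date(config.first_year, 7, 1))

    def _materialize(parts: List[pd.DataFrame]) -> pd.DataFrame:
        df = pd.concat(parts, ignore_index=True)
        df["date"] = origin + pd.to_timedelta(df.pop("_day"), unit="D")
        return df

    rx_maintenance = _materialize(rx_parts)
    pid_labels = np.array([f"P{i:06d}" for i in range(P)])
    mpr_level = np.zeros((P, config.n_periods), dtype=int)
    for t, per in enumerate(periods):
        m = cov.compute_mpr(rx_maintenance, catalog, per, patient_ids=pid_all)
        mpr_level[m["patient_id"].to_numpy(), t] = m["mpr_level"].to_numpy()

    # -- planted marginal outcome model ----------------------------------
    grade_eff = config.grade_effects()  # (2, 4)
    cov_eff = config.covariate_effects()
    per_eff = config.period_effects()
    sev_eff = np.asarray(config.severity_log_odds)
    lin = np.full((P, config.n_periods), config.intercept)
    for t in range(config.n_periods):
        iy = inst_idx[:, t]
        is_tert = iy >= n_pc
        latent_sat = np.zeros(P, dtype=bool)
        latent_sat[~is_tert] = good[iy[~is_tert]]
        g = np.zeros(P)
        g[~is_tert & latent_sat] = grade_eff[1, arch[~is_tert & latent_sat]]
        g[~is_tert & ~latent_sat] = grade_eff[0, arch[~is_tert & ~latent_sat]]
        band_t = np.clip(
            np.searchsorted([35, 45, 55, 65], age0 + t, side="right"), 0, 4
        )
        lin[:, t] += (
            g
            + sev_eff[arch]
            + cov_eff["mpr_level"][mpr_level[:, t]]
            + cov_eff["comorbidity"] * comorbid[:, t]
            + cov_eff["sex_male"] * (sex == "M")
            + cov_eff["age_band"][band_t]
            + per_eff[t]
        )
    p = expit(lin)
    z = rng.standard_normal((P, config.n_periods))
    rho = config.ar1_rho
    for t in range(1, config.n_periods):
        z[:, t] = rho * z[:, t - 1] + np.sqrt(1 - rho**2) * z[:, t]
    y = norm.cdf(z) < p

    # -- realize outcomes as measurement-year claims ----------------------
    burst_codes = ["OCS_PRED5", "SYS_MP4", "SYS_DEXA"]
    burst_units = {"OCS_PRED5": 8, "SYS_MP4": 6, "SYS_DEXA": 8}  # all > 80 mg HC-eq
    for t, per in enumerate(periods):
        b_year = t + 1
        ylen = (per.b_end - per.b_start).days
        cases = np.flatnonzero(y[:, t])
        if len(cases):
            insts = inst_idx[cases, b_year]
            day = year_day0[b_year] + rng.integers(0, ylen, len(cases))
            u = rng.random(len(cases))
            is_neb = u < 0.25
            emit_visits(
                cases, day, insts, "outpatient",
                np.full(len(cases), "J450"), "", False,
            )
            neb = is_neb
            if neb.any():
                emit_rx(
                    cases[neb], day[neb], insts[neb],
                    np.full(neb.sum(), code_idx["NEB_SALB"]), 2, 1,
                )
            st = ~is_neb
            if st.any():
                choice = rng.integers(0, len(burst_codes), st.sum())
                code = np.array([code_idx[burst_codes[c]] for c in choice])
                units = np.array([burst_units[burst_codes[c]] for c in choice])
                emit_rx(cases[st], day[st], insts[st], code, units, 5)
        # non-qualifying decoys among non-cases
        non = np.flatnonzero(~y[:, t])
        decoy = non[rng.random(len(non)) < config.decoy_fraction]
        if len(decoy):
            insts = inst_idx[decoy, b_year]
            day = year_day0[b_year] + rng.integers(0, ylen, len(decoy))
            is_tert = insts >= n_pc
            # emergency-only bursts at tertiary hospitals are excluded from
            # the outcome; primary-clinic decoys dispense exactly 80 mg
            if is_tert.any():
                emit_visits(
                    decoy[is_tert], day[is_tert], insts[is_tert], "emergency",
                    np.full(is_tert.sum(), "J460"), "", False,
                )
                emit_rx(
                    decoy[is_tert], day[is_tert], insts[is_tert],
                    np.full(is_tert.sum(), code_idx["SYS_MP4"]), 6, 3,
                )
            pr = ~is_tert
            if pr.any():
                emit_visits(
                    decoy[pr], day[pr], insts[pr], "outpatient",
                    np.full(pr.sum(), "J450"), "", False,
                )
                emit_rx(
                    decoy[pr], day[pr], insts[pr],
                    np.full(pr.sum(), code_idx["OCS_PRED5"]), 4, 3,
                )

    # -- assemble final tables -------------------------------------------
    rx = _materialize(rx_parts)
    visits = _materialize(visit_parts)
    rx["patient_id"] = pid_labels[rx["patient_id"].to_numpy()]
    visits["patient_id"] = pid_labels[visits["patient_id"].to_numpy()]
    rx = rx.sort_values(["patient_id", "date", "drug_code"], kind="stable").reset_index(
        drop=True
    )[
        ["patient_id", "date", "institution_id", "drug_code", "daily_units",
         "days_supplied"]
    ]
    visits = visits.sort_values(
        ["patient_id", "date", "institution_id"], kind="stable"
    ).reset_index(drop=True)[
        ["patient_id", "date", "institution_id", "setting", "icd10_primary",
         "icd10_secondary", "pft"]
    ]

    patients = pd.DataFrame(
        {
            "patient_id": pid_labels,
            "sex": sex,
            "birth_year": birth_year,
            "uninsured_periods": [
                ";".join(str(t + 1) for t in np.flatnonzero(uninsured[i]))
                for i in range(P)
            ],
        }
    )
    institutions = pd.DataFrame({"institution_id": inst_ids, "type": inst_type})
    institution_truth = pd.DataFrame(
        {
            "institution_id": inst_ids,
            "type": inst_type,
            "latent_class": ["good" if g else "poor" for g in good]
            + ["tertiary"] * n_th,
        }
    )
    truth_rows = []
    for t in range(config.n_periods):
        iy = inst_idx[:, t]
        is_tert = iy >= n_pc
        latent = np.where(
            is_tert, "Tertiary", np.where(good[np.minimum(iy, n_pc - 1)],
                                          "Satisfactory", "Unsatisfactory")
        )
        truth_rows.append(
            pd.DataFrame(
                {
                    "patient_id": pid_labels,
                    "period": t + 1,
                    "archetype": np.array(ARCHETYPES)[arch],
                    "institution_id": inst_ids[iy],
                    "latent_grade": latent,
                    "mpr_level": mpr_level[:, t],
                    "comorbidity": comorbid[:, t],
                    "uninsured": uninsured[:, t],
                    "age": age0 + t,
                    "sex": sex,
                    "exacerbated": y[:, t],
                }
            )
        )
    truth = pd.concat(truth_rows, ignore_index=True)

    return SimulatedClaims(
        patients=patients,
        visits=visits,
        prescriptions=rx,
        institutions=institutions,
        truth=truth,
        institution_truth=institution_truth,
        config=config,
    )


def simulate_analysis_rows(
    config: SimulationConfig,
    satisfactory_share: float = 0.35,
    mpr_level_probs=(0.029, 0.245, 0.259, 0.467),
) -> pd.DataFrame:
    """Draw analysis rows directly from the planted marginal outcome model.

    This is the generator's model-level view: instead of realizing claims
    and re-deriving covariates through the pipeline, each patient-period
    draws its grade, severity group, adherence level, comorbidity, sex and
    age band from the configured margins, and the binary outcome from the
    same Gaussian-copula AR(1) logistic model that `simulate_claims` plants.
    Suitable for Monte-Carlo studies of the estimation stage (bias, CI
    coverage) where thousands of replicates are needed.
    """
    rng = np.random.default_rng(config.seed)
    P, T = config.n_patients, config.n_periods
    arch = rng.choice(4, size=P, p=np.asarray(config.severity_archetype_weights))
    sex = np.where(rng.random(P) < config.male_prob, "M", "F")
    band = rng.choice(5, size=P, p=np.asarray(config.age_band_weights))
    comorbid = rng.random((P, T)) < config.comorbidity_prob
    mpr = rng.choice(4, size=(P, T), p=np.asarray(mpr_level_probs))
    tert_p = np.asarray(config.tertiary_prob)[arch]
    is_tert = rng.random((P, T)) < tert_p[:, None]
    is_sat = rng.random((P, T)) < satisfactory_share
    grade_code = np.where(is_tert, 2, np.where(is_sat, 1, 0))
    annual_mean = ARCHETYPE_CURVES.mean(axis=1)[arch]
    total_rank = annual_mean[:, None] * 365.0 * np.exp(
        rng.normal(0, 0.2, (P, T))
    )

    grade_eff = config.grade_effects()
    cov_eff = config.covariate_effects()
    per_eff = config.period_effects()
    sev_eff = np.asarray(config.severity_log_odds)
    lin = np.full((P, T), config.intercept)
    for t in range(T):
        g = np.zeros(P)
        unsat = grade_code[:, t] == 0
        sat = grade_code[:, t] == 1
        g[unsat] = grade_eff[0, arch[unsat]]
        g[sat] = grade_eff[1, arch[sat]]
        lin[:, t] += (
            g
            + sev_eff[arch]
            + cov_eff["mpr_level"][mpr[:, t]]
            + cov_eff["comorbidity"] * comorbid[:, t]
            + cov_eff["sex_male"] * (sex == "M")
            + cov_eff["age_band"][band]
            + per_eff[t]
        )
    p = expit(lin)
    z = rng.standard_normal((P, T))
    rho = config.ar1_rho
    for t in range(1, T):
        z[:, t] = rho * z[:, t - 1] + np.sqrt(1 - rho**2) * z[:, t]
    y = (norm.cdf(z) < p).astype(int)

    grade_names = np.array(["Unsatisfactory", "Satisfactory", "Tertiary"])
    bands = np.array(["15-34", "35-44", "45-54", "55-64", "65+"])
    return pd.DataFrame(
        {
            "patient_id": np.repeat(np.arange(P), T),
            "period": np.tile(np.arange(1, T + 1), P),
            "exacerbated": y.ravel(),
            "grade": grade_names[grade_code.ravel()],
            "severity": np.array(ARCHETYPES)[np.repeat(arch, T)],
            "total_rank": total_rank.ravel(),
            "mpr_level": mpr.ravel().astype(str),
            "comorbidity": np.where(comorbid.ravel(), "yes", "no"),
            "sex": np.repeat(sex, T),
            "age_band": bands[np.repeat(band, T)],
        }
    )
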