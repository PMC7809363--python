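"""Cohort selection from raw claims tables.

One observation per eligible patient per assessment period, split into a
primary-clinic stream and a tertiary-hospital stream.  A patient is
eligible for a period when, during its premeasurement window A, they are at
least 15 years old, carry an asthma diagnosis (ICD-10 J45/J46, primary or
secondary), and satisfy the utilisation criterion: more than two outpatient
visit-days with same-day asthma medication, OR at least one hospitalization
with same-day oral/IV corticosteroids plus at least one medicated
outpatient visit-day.  The primary stream additionally requires an asthma
diagnosis at a primary clinic, continuous insurance eligibility, and visits
to exactly one primary clinic in the window; the tertiary stream requires
diagnosis at exactly one tertiary hospital (and no primary-clinic asthma
diagnosis) plus the utilisation and insurance criteria.  The same patient
may appear in several periods, and in different streams across periods.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Sequence

import pandas as pd

from .catalog import SYSTEMIC_STEROID_CLASSES, DrugCatalog
from .periods import AssessmentPeriod

REQUIRED_COLUMNS: Mapping[str, tuple] = {
    "patients": ("patient_id", "sex", "birth_year"),
    "visits": (
        "patient_id",
        "date",
        "institution_id",
        "setting",
        "icd10_primary",
        "icd10_secondary",
    ),
    "prescriptions": (
        "patient_id",
        "date",
        "institution_id",
        "drug_code",
        "daily_units",
        "days_supplied",
    ),
    "institutions": ("institution_id", "type"),
}


def validate_tables(tables: Mapping[str, pd.DataFrame]) -> None:
    for name, cols in REQUIRED_COLUMNS.items():
        if name not in tables:
            raise ValueError(f"missing claims table {name!r}")
        missing = set(cols) - set(tables[name].columns)
        if missing:
            raise ValueError(f"table {name!r} lacks columns {sorted(missing)}")


def _is_asthma(series: pd.Series) -> pd.Series:
    s = series.fillna("")
    return s.str.startswith("J45") | s.str.startswith("J46")


def select_cohort(
    tables: Mapping[str, pd.DataFrame],
    periods: Sequence[AssessmentPeriod],
    catalog: DrugCatalog,
    min_age: int = 15,
    min_outpatient_visits: int = 3,
) -> pd.DataFrame:
    """Apply inclusion/exclusion rules; one row per patient-period-stream.

    ``min_outpatient_visits=3`` encodes the strict reading of "more than two
    outpatient clinic visits"; visit-days are counted per calendar day per
    institution.  Returns columns (patient_id, period, stream,
    institution_id, age, sex).
    """
    validate_tables(tables)
    patients = tables["patients"]
    visits = tables["visits"].copy()
    rx = tables["prescriptions"].copy()
    institutions = tables["institutions"]

    visits["date"] = pd.to_datetime(visits["date"])
    rx["date"] = pd.to_datetime(rx["date"])
    inst_type = institutions.set_index("institution_id")["type"]
    pat = patients.set_index("patient_id")
    uninsured: Dict = {}
    if "uninsured_periods" in patients.columns:
        for pid, spec in zip(patients["patient_id"], patients["uninsured_periods"]):
            if isinstance(spec, str) and spec:
                uninsured[pid] = {int(x) for x in spec.split(";")}

    steroid_codes = catalog.codes_of(SYSTEMIC_STEROID_CLASSES)
    rows = []
    for per in periods:
        v = visits[(visits["date"] >= pd.Timestamp(per.a_start))
                   & (visits["date"] < pd.Timestamp(per.a_end))]
        r = rx[(rx["date"] >= pd.Timestamp(per.a_start))
               & (rx["date"] < pd.Timestamp(per.a_end))]
        if len(v) == 0:
            continue
        v = v.assign(inst_type=v["institution_id"].map(inst_type))
        med_days = r[["patient_id", "date", "institution_id"]].drop_duplicates()

        # outpatient visit-days with same-day asthma medication
        outp = v[v["setting"] == "outpatient"][
            ["patient_id", "date", "institution_id"]
        ].drop_duplicates()
        outp_med = outp.merge(med_days, on=["patient_id", "date", "institution_id"])
        n_outp_med = outp_med.groupby("patient_id").size()

        # hospitalizations with same-day systemic corticosteroids
        inp = v[v["setting"] == "inpatient"][
            ["patient_id", "date", "institution_id"]
        ].drop_duplicates()
        ster_days = r[r["drug_code"].isin(steroid_codes)][
            ["patient_id", "date", "institution_id"]
        ].drop_duplicates()
        n_hosp_ster = (
            inp.merge(ster_days, on=["patient_id", "date", "institution_id"])
            .groupby("patient_id")
            .size()
        )

        asthma_mask = _is_asthma(v["icd10_primary"]) | _is_asthma(v["icd10_secondary"])
        av = v[asthma_mask]
        asthma_pids = set(av["patient_id"])
        asthma_at_primary = set(av.loc[av["inst_type"] == "primary", "patient_id"])
        asthma_at_tertiary = av.loc[av["inst_type"] == "tertiary"]

        # distinct institutions visited, by type
        per_pid = (
            v[["patient_id", "institution_id", "inst_type"]]
            .drop_duplicates()
            .groupby(["patient_id", "inst_type"])["institution_id"]
        )
        n_inst = per_pid.nunique().unstack(fill_value=0)
        first_inst = per_pid.first().unstack()

        age = (per.a_start.year - pat["birth_year"]).astype(int)

        idx = pd.Index(sorted(asthma_pids), name="patient_id")
        e = pd.DataFrame(index=idx)
        e["age"] = age.reindex(idx)
        e["sex"] = pat["sex"].reindex(idx)
        e["n_outp_med"] = n_outp_med.reindex(idx).fillna(0)
        e["n_hosp_ster"] = n_hosp_ster.reindex(idx).fillna(0)
        for typ in ("primary", "tertiary"):
            col = n_inst[typ] if typ in n_inst.columns else pd.Series(dtype=int)
            e[f"n_{typ}"] = col.reindex(idx).fillna(0)
        e["insured"] = [per.index not in uninsured.get(pid, ()) for pid in idx]
        e["crit1"] = (e["n_outp_med"] >= min_outpatient_visits) | (
            (e["n_hosp_ster"] >= 1) & (e["n_outp_med"] >= 1)
        )
        e["base"] = (e["age"] >= min_age) & e["insured"] & e["crit1"]
        at_primary = idx.isin(asthma_at_primary)

        prim = e[e["base"] & at_primary & (e["n_primary"] == 1)].copy()
        if len(prim):
            prim["institution_id"] = first_inst["primary"].reindex(prim.index)
            prim["stream"] = "primary"
        tert_first = (
            asthma_at_tertiary.sort_values(["patient_id", "date"])
            .groupby("patient_id")["institution_id"]
            .first()
        )
        tert = e[
            e["base"]
            & ~at_primary
            & idx.isin(tert_first.index)
            & (e["n_tertiary"] == 1)
        ].copy()
        if len(tert):
            tert["institution_id"] = tert_first.reindex(tert.index)
            tert["stream"] = "tertiary"
        for sel in (prim, tert):
            if len(sel):
                sel = sel.reset_index()
                sel["period"] = per.index
                rows.append(
                    sel[
                        ["patient_id", "period", "stream", "institution_id",
                         "age", "sex"]
                    ]
                )
    if not rows:
        return pd.DataFrame(
            columns=["patient_id", "period", "stream", "institution_id", "age", "sex"]
        )
    out = pd.concat(rows, ignore_index=True)
    out["age"] = out["age"].astype(int)
    return out.sort_values(["period", "patient_id"]).reset_index(drop=True)
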