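"""Per-observation clinical covariates and the exacerbation outcome.

* Medication possession ratio (MPR): % of follow-up days covered by
  maintenance (non-exacerbation) asthma medication during window A, with
  adherence levels 0 (no maintenance medication), 1 (<20%), 2 (20-80%),
  3 (>80%).
* Comorbidity: any of a fixed ICD-10 category list (atopic dermatitis L20,
  GERD K21, rhinitis J30/J31, sinusitis J32, depression F32/F33, anxiety
  F40/F41, obesity E66) as primary or secondary diagnosis in A; matching is
  on the 3-character category prefix.
* Exacerbation (window B): on a day with a same-day J45/J46 diagnosis,
  either a systemic corticosteroid dispensing totalling more than 80 mg
  hydrocortisone-equivalent, or a SABA-nebulizer treatment.  Diagnosis days
  seen only through emergency or inpatient care outside primary clinics do
  not qualify, because assessment results are disclosed for primary clinics
  only.
"""

from __future__ import annotations

import re
from typing import Optional

import numpy as np
import pandas as pd

from .catalog import SABA_NEB, SYSTEMIC_STEROID_CLASSES, DrugCatalog
from .periods import AssessmentPeriod
from .severity import build_daily_rank_series

DEFAULT_COMORBIDITY_CODES = (
    "L20", "K21", "J31", "J30", "J32", "F32", "F33", "F40", "F41", "E66",
)

_ICD_RE = re.compile(r"^[A-Z]\d{2}")


def _window(df: pd.DataFrame, start, end) -> pd.DataFrame:
    d = pd.to_datetime(df["date"])
    return df[(d >= pd.Timestamp(start)) & (d < pd.Timestamp(end))]


def compute_mpr(
    prescriptions: pd.DataFrame,
    catalog: DrugCatalog,
    period: AssessmentPeriod,
    include_last_supply: bool = True,
    patient_ids=None,
) -> pd.DataFrame:
    """MPR and adherence level per patient over window A.

    The follow-up period runs from the first maintenance prescription to the
    last one plus its supplied days (clipped to A); the numerator is the
    number of distinct days in that span covered by at least one maintenance
    prescription.  ``include_last_supply=False`` ends the denominator at the
    last prescription start date instead.  Patients with no maintenance
    prescriptions (pass `patient_ids` to include them) get level 0 and an
    undefined (NaN) MPR.
    """
    rx = _window(prescriptions, period.a_start, period.a_end)
    # maintenance = carries a positive severity rank (long-term oral
    # prednisolone included, bursts and relievers excluded)
    if len(rx):
        ranked = np.array(
            [
                catalog.rank_for(c, d) > 0
                for c, d in zip(rx["drug_code"], rx["days_supplied"])
            ]
        )
        rx = rx[ranked]
    daily = build_daily_rank_series(rx, catalog, period)
    covered = daily.to_numpy() > 0
    n_days = period.n_days_a

    start_off = (pd.to_datetime(rx["date"]) - pd.Timestamp(period.a_start)).dt.days
    start_off = np.clip(start_off.to_numpy(), 0, n_days)
    g = pd.DataFrame(
        {
            "patient_id": rx["patient_id"].to_numpy(),
            "start": start_off,
            "end": np.clip(start_off + rx["days_supplied"].to_numpy(), 0, n_days),
        }
    ).groupby("patient_id")
    first = g["start"].min().reindex(daily.index).to_numpy(dtype=int)
    last = (
        (g["end"].max() if include_last_supply else g["start"].max())
        .reindex(daily.index)
        .to_numpy(dtype=int)
    )
    cum = np.concatenate(
        [np.zeros((len(daily), 1), dtype=int), covered.cumsum(axis=1)], axis=1
    )
    rows_idx = np.arange(len(daily))
    num = cum[rows_idx, np.maximum(last, first)] - cum[rows_idx, first]
    denom = np.maximum(last - first, 1)
    mpr = np.minimum(100.0, 100.0 * num / denom)
    out = pd.DataFrame(
        {
            "patient_id": daily.index,
            "mpr_percent": mpr,
            "mpr_level": [_mpr_level(m) for m in mpr],
        }
    )
    if patient_ids is not None:
        missing = sorted(set(patient_ids) - set(daily.index))
        if missing:
            out = pd.concat(
                [
                    out,
                    pd.DataFrame(
                        {
                            "patient_id": missing,
                            "mpr_percent": np.nan,
                            "mpr_level": 0,
                        }
                    ),
                ],
                ignore_index=True,
            )
        out = out[out["patient_id"].isin(set(patient_ids))]
    return out.sort_values("patient_id").reset_index(drop=True)


def _mpr_level(mpr: float) -> int:
    if np.isnan(mpr):
        return 0
    if mpr < 20:
        return 1
    if mpr <= 80:
        return 2
    return 3


def mpr_level(mpr: Optional[float]) -> int:
    """Adherence level for an MPR value; NaN/None means level 0."""
    if mpr is None:
        return 0
    return _mpr_level(float(mpr))


def flag_comorbidity(
    visits: pd.DataFrame,
    period: AssessmentPeriod,
    codes=DEFAULT_COMORBIDITY_CODES,
) -> pd.DataFrame:
    """Comorbidity flag per patient from any diagnosis in window A.

    Codes match on their 3-character ICD-10 category (F32.9 matches F32).
    Malformed diagnosis strings raise ``ValueError``.
    """
    v = _window(visits, period.a_start, period.a_end)
    wanted = frozenset(codes)
    found: dict = {}
    for col in ("icd10_primary", "icd10_secondary"):
        if col not in v.columns:
            continue
        vals = v[col].fillna("")
        bad = vals[(vals != "") & ~vals.str.match(_ICD_RE)]
        if len(bad):
            raise ValueError(f"malformed ICD-10 codes: {sorted(bad.unique())[:5]}")
        pref = vals.str[:3]
        hit = pref.isin(wanted)
        for pid, code in zip(v.loc[hit, "patient_id"], pref[hit]):
            found.setdefault(pid, set()).add(code)
    pids = sorted(v["patient_id"].unique())
    return pd.DataFrame(
        {
            "patient_id": pids,
            "comorbidity": [pid in found for pid in pids],
            "codes_found": [",".join(sorted(found.get(pid, ()))) for pid in pids],
        }
    )


def detect_exacerbation(
    visits: pd.DataFrame,
    prescriptions: pd.DataFrame,
    catalog: DrugCatalog,
    period: AssessmentPeriod,
    institutions: Optional[pd.DataFrame] = None,
    threshold_mg: float = 80.0,
    mode: str = "hc_equivalent",
) -> pd.DataFrame:
    """Binary exacerbation outcome per patient over window B.

    A qualifying day has a J45/J46 diagnosis at an outpatient visit or at a
    primary clinic (emergency/inpatient care outside primary clinics is
    excluded).  The trigger is a same-day systemic corticosteroid dispensing
    whose daily dose exceeds ``threshold_mg`` hydrocortisone-equivalent
    (``mode="any_dose"`` accepts any systemic steroid dose instead), or a
    same-day SABA-nebulizer treatment.
    """
    if mode not in ("hc_equivalent", "any_dose"):
        raise ValueError(f"unknown mode {mode!r}")
    v = _window(visits, period.b_start, period.b_end).copy()
    rx = _window(prescriptions, period.b_start, period.b_end).copy()

    asthma = pd.Series(False, index=v.index)
    for col in ("icd10_primary", "icd10_secondary"):
        if col in v.columns:
            vals = v[col].fillna("")
            asthma |= vals.str.startswith("J45") | vals.str.startswith("J46")
    v = v[asthma]
    if institutions is not None:
        typ = institutions.set_index("institution_id")["type"]
        inst_primary = v["institution_id"].map(typ).eq("primary")
    else:
        inst_primary = pd.Series(False, index=v.index)
    v = v[(v["setting"] == "outpatient") | inst_primary]
    qual_days = v[["patient_id", "date"]].drop_duplicates()
    qual_days["date"] = pd.to_datetime(qual_days["date"])

    all_pids = sorted(
        set(_window(visits, period.b_start, period.b_end)["patient_id"])
        | set(rx["patient_id"])
    )
    base = pd.DataFrame(
        {
            "patient_id": all_pids,
            "exacerbated": False,
            "trigger": "none",
            "trigger_date": pd.NaT,
        }
    ).set_index("patient_id")

    if len(rx) and len(qual_days):
        rx["date"] = pd.to_datetime(rx["date"])
        cls = rx["drug_code"].map(catalog.drug_class)
        sys_rx = rx[cls.isin(SYSTEMIC_STEROID_CLASSES)].copy()
        missing = [
            c
            for c in sys_rx["drug_code"].unique()
            if catalog.entry(c).hc_equiv_mg is None
        ]
        if missing:
            raise ValueError(
                f"no hydrocortisone-equivalence factor for: {missing}"
            )
        if len(sys_rx):
            sys_rx["dose"] = sys_rx["daily_units"].to_numpy() * np.array(
                [catalog.hc_equiv_mg(c) for c in sys_rx["drug_code"]]
            )
            day_dose = (
                sys_rx.groupby(["patient_id", "date"])["dose"].sum().reset_index()
            )
            hit = qual_days.merge(day_dose, on=["patient_id", "date"])
            if mode == "hc_equivalent":
                hit = hit[hit["dose"] > threshold_mg]
            for pid, grp in hit.groupby("patient_id"):
                base.loc[pid, ["exacerbated", "trigger", "trigger_date"]] = [
                    True,
                    "steroid_burst",
                    grp["date"].min(),
                ]
        neb = rx[cls == SABA_NEB]
        if len(neb):
            hit = qual_days.merge(
                neb[["patient_id", "date"]].drop_duplicates(),
                on=["patient_id", "date"],
            )
            for pid, grp in hit.groupby("patient_id"):
                d = grp["date"].min()
                cur = base.loc[pid]
                if not cur["exacerbated"] or d < cur["trigger_date"]:
                    # same-day steroid burst takes precedence
                    if cur["exacerbated"] and d == cur["trigger_date"]:
                        continue
                    base.loc[pid, ["exacerbated", "trigger", "trigger_date"]] = [
                        True,
                        "saba_nebulizer",
                        d,
                    ]
    return base.reset_index()
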