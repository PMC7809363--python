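"""Institution quality indicators and assessment grades.

Seven indicators are computed per primary clinic over the premeasurement
window from the clinic's eligible asthma patients:

1. % of patients with at least one pulmonary function test (PFT),
2. % with ongoing visits (at least three visit-days),
3. % prescribed an inhaled corticosteroid (ICS),
4. % prescribed an ICS or a leukotriene receptor antagonist (LTRA),
5. % prescribed a LABA while never prescribed an ICS,
6. % prescribed a SABA while never prescribed an ICS,
7. % prescribed an oral corticosteroid while never prescribed an ICS.

Items 1-4 are mandatory (higher is better): a Satisfactory grade requires a
score strictly above the per-period median on every one of them, and not
falling in the worst decile (the highest 10% of rates) on any of items 5-7.
Tertiary hospitals are always labelled "Tertiary"; their results are not
disclosed.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .catalog import (
    ICS_CLASSES,
    LABA,
    LTRA,
    ORAL_STEROID_CLASSES,
    SABA_CLASSES,
    DrugCatalog,
)
from .periods import AssessmentPeriod

log = logging.getLogger(__name__)

INDICATOR_COLUMNS = ("i1_pft", "i2_ongoing", "i3_ics", "i4_ics_or_ltra",
                     "i5_laba_no_ics", "i6_saba_no_ics", "i7_ocs_no_ics")
MANDATORY = INDICATOR_COLUMNS[:4]
PENALTY = INDICATOR_COLUMNS[4:]


def compute_indicators(
    visits: pd.DataFrame,
    prescriptions: pd.DataFrame,
    catalog: DrugCatalog,
    period: AssessmentPeriod,
    patients: Optional[pd.DataFrame] = None,
    eligible: Optional[pd.DataFrame] = None,
    min_age: int = 15,
) -> pd.DataFrame:
    """Indicator rates per institution over window A of one period.

    The surveyed population of an institution is every patient aged
    ``min_age`` or older with an asthma diagnosis (J45/J46) there during the
    window — the assessment survey is wider than the association cohort.
    Pass ``eligible`` (patient_id, institution_id pairs) to override it.
    Institutions with zero eligible patients are excluded (logged).
    """
    v = visits.copy()
    v["date"] = pd.to_datetime(v["date"])
    v = v[(v["date"] >= pd.Timestamp(period.a_start))
          & (v["date"] < pd.Timestamp(period.a_end))]
    rx = prescriptions.copy()
    rx["date"] = pd.to_datetime(rx["date"])
    rx = rx[(rx["date"] >= pd.Timestamp(period.a_start))
            & (rx["date"] < pd.Timestamp(period.a_end))]

    key = ["patient_id", "institution_id"]
    if eligible is None:
        asthma = pd.Series(False, index=v.index)
        for col in ("icd10_primary", "icd10_secondary"):
            if col in v.columns:
                s = v[col].fillna("")
                asthma |= s.str.startswith("J45") | s.str.startswith("J46")
        eligible = v.loc[asthma, key].drop_duplicates()
        if patients is not None:
            age = period.a_start.year - patients.set_index("patient_id")["birth_year"]
            old_enough = set(age[age >= min_age].index)
            eligible = eligible[eligible["patient_id"].isin(old_enough)]
    pairs = eligible[key].drop_duplicates()
    if not len(pairs):
        return pd.DataFrame(columns=["institution_id", "period", "n_patients",
                                     *INDICATOR_COLUMNS])

    pv = pairs.merge(v, on=key)
    n_days = pv.drop_duplicates(subset=key + ["date"]).groupby(key, sort=True).size()
    has_pft = pv.groupby(key)["pft"].any() if "pft" in pv.columns else n_days * False

    pr = pairs.merge(rx, on=key)
    cls = pr["drug_code"].map(catalog.drug_class)
    by = pr.assign(cls=cls).groupby(key)["cls"]
    has_ics = by.apply(lambda s: bool(set(s) & ICS_CLASSES))
    has_ltra = by.apply(lambda s: LTRA in set(s))
    has_laba = by.apply(lambda s: LABA in set(s))
    has_saba = by.apply(lambda s: bool(set(s) & SABA_CLASSES))
    has_ocs = by.apply(lambda s: bool(set(s) & ORAL_STEROID_CLASSES))

    stats = pd.DataFrame(index=pd.MultiIndex.from_frame(pairs).unique())
    for name, s in (
        ("pft", has_pft),
        ("ongoing", n_days >= 3),
        ("ics", has_ics),
        ("ltra", has_ltra),
        ("laba", has_laba),
        ("saba", has_saba),
        ("ocs", has_ocs),
    ):
        stats[name] = (
            s.reindex(stats.index).astype("boolean").fillna(False).astype(bool)
        )
    stats["ics_or_ltra"] = stats["ics"] | stats["ltra"]
    stats["laba_no_ics"] = stats["laba"] & ~stats["ics"]
    stats["saba_no_ics"] = stats["saba"] & ~stats["ics"]
    stats["ocs_no_ics"] = stats["ocs"] & ~stats["ics"]

    g = stats.groupby(level="institution_id")
    out = pd.DataFrame(
        {
            "n_patients": g.size(),
            "i1_pft": 100 * g["pft"].mean(),
            "i2_ongoing": 100 * g["ongoing"].mean(),
            "i3_ics": 100 * g["ics"].mean(),
            "i4_ics_or_ltra": 100 * g["ics_or_ltra"].mean(),
            "i5_laba_no_ics": 100 * g["laba_no_ics"].mean(),
            "i6_saba_no_ics": 100 * g["saba_no_ics"].mean(),
            "i7_ocs_no_ics": 100 * g["ocs_no_ics"].mean(),
        }
    ).reset_index()
    out.insert(1, "period", period.index)
    empty = out["n_patients"] == 0
    if empty.any():
        log.info("excluding %d institutions with zero eligible patients",
                 int(empty.sum()))
        out = out[~empty]
    return out.reset_index(drop=True)


class InstitutionGrader(TransformerMixin, BaseEstimator):
    """Median / worst-decile grading rule as a fitted transformer.

    ``fit`` learns the per-indicator thresholds from the graded primary
    clinics of one period; ``predict`` labels clinics Satisfactory when they
    exceed every mandatory median strictly and avoid the worst decile
    (rate > the ``1 - worst_decile`` quantile) on all penalty items.
    """

    def __init__(self, worst_decile: float = 0.10):
        self.worst_decile = worst_decile

    def fit(self, X: pd.DataFrame, y=None):
        if len(X) < 2:
            raise ValueError("need at least 2 primary clinics to define medians")
        self.medians_ = {c: float(np.median(X[c])) for c in MANDATORY}
        self.decile_cutoffs_ = {
            c: float(np.quantile(X[c], 1.0 - self.worst_decile)) for c in PENALTY
        }
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "medians_")
        ok = np.ones(len(X), dtype=bool)
        for c, med in self.medians_.items():
            ok &= X[c].to_numpy() > med
        for c, cut in self.decile_cutoffs_.items():
            ok &= X[c].to_numpy() <= cut
        return np.where(ok, "Satisfactory", "Unsatisfactory")

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        out["grade"] = self.predict(X)
        return out


def assign_grades(
    indicators: pd.DataFrame,
    institutions: pd.DataFrame,
    worst_decile: float = 0.10,
) -> pd.DataFrame:
    """Grade every institution for every period present in `indicators`.

    Primary clinics are graded against that period's medians/deciles;
    tertiary hospitals get the fixed label "Tertiary".
    """
    inst_type = institutions.set_index("institution_id")["type"]
    out = []
    for period, ind in indicators.groupby("period"):
        typ = ind["institution_id"].map(inst_type)
        prim = ind[typ == "primary"]
        if len(prim) < 2:
            raise ValueError(f"period {period}: medians undefined "
                             f"({len(prim)} graded primary clinics)")
        grader = InstitutionGrader(worst_decile=worst_decile).fit(prim)
        graded = prim.copy()
        graded["grade"] = grader.predict(prim)
        out.append(graded)
    grades = pd.concat(out, ignore_index=True)
    # tertiary hospitals: fixed label, one row per period seen
    tert_ids = institutions.loc[institutions["type"] == "tertiary", "institution_id"]
    tert = pd.concat(
        [
            pd.DataFrame(
                {"institution_id": tert_ids, "period": p, "grade": "Tertiary"}
            )
            for p in indicators["period"].unique()
        ],
        ignore_index=True,
    )
    grades = pd.concat([grades, tert], ignore_index=True)
    return grades.sort_values(["period", "institution_id"]).reset_index(drop=True)
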