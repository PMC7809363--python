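"""Inclusion/exclusion rules, checked against a hand-built claims fixture
and by brute-force filtering."""

import pandas as pd
import pytest

from asthma_qa.cohort import select_cohort
from asthma_qa.periods import make_periods

PERIODS = make_periods(2013, 1)

INSTITUTIONS = pd.DataFrame(
    {
        "institution_id": ["C1", "C2", "T1"],
        "type": ["primary", "primary", "tertiary"],
    }
)


def world(visits, rx, patients=None):
    if patients is None:
        pids = sorted({v["patient_id"] for v in visits})
        patients = pd.DataFrame(
            {"patient_id": pids, "sex": "F", "birth_year": 1970}
        )
    return {
        "patients": patients,
        "visits": pd.DataFrame(visits),
        "prescriptions": pd.DataFrame(rx),
        "institutions": INSTITUTIONS,
    }


def medicated_visits(pid, dates, inst="C1", code="ICS_BUD_L",
                     visit_factory=None, rx_factory=None):
    v = [visit_factory(pid, d, inst) for d in dates]
    r = [rx_factory(pid, d, inst, code, days=14) for d in dates]
    return v, r


class TestInclusionRules:
    def test_three_medicated_visits_included_in_primary_stream(
        self, catalog, visit_factory, rx_factory
    ):
        v, r = medicated_visits(
            "p1", ["2013-08-01", "2013-10-01", "2014-01-05"],
            visit_factory=visit_factory, rx_factory=rx_factory,
        )
        out = select_cohort(world(v, r), PERIODS, catalog)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["stream"] == "primary"
        assert row["institution_id"] == "C1"

    def test_exactly_two_visits_excluded(self, catalog, visit_factory, rx_factory):
        v, r = medicated_visits(
            "p1", ["2013-08-01", "2013-10-01"],
            visit_factory=visit_factory, rx_factory=rx_factory,
        )
        assert len(select_cohort(world(v, r), PERIODS, catalog)) == 0

    def test_hospitalization_route(self, catalog, visit_factory, rx_factory):
        # 1 hospitalization with systemic steroids + 1 medicated outpatient visit
        v = [
            visit_factory("p1", "2013-08-01", "C1", setting="inpatient"),
            visit_factory("p1", "2013-10-01", "C1"),
        ]
        r = [
            rx_factory("p1", "2013-08-01", "C1", "SYS_MP4", days=3),
            rx_factory("p1", "2013-10-01", "C1", "ICS_BUD_L", days=30),
        ]
        out = select_cohort(world(v, r), PERIODS, catalog)
        assert len(out) == 1

    def test_visits_without_same_day_medication_do_not_count(
        self, catalog, visit_factory, rx_factory
    ):
        v = [
            visit_factory("p1", d, "C1")
            for d in ["2013-08-01", "2013-09-01", "2013-10-01"]
        ]
        r = [rx_factory("p1", "2013-08-15", "C1", "ICS_BUD_L", days=30)]
        assert len(select_cohort(world(v, r), PERIODS, catalog)) == 0

    def test_under_15_excluded(self, catalog, visit_factory, rx_factory):
        v, r = medicated_visits(
            "p1", ["2013-08-01", "2013-10-01", "2014-01-05"],
            visit_factory=visit_factory, rx_factory=rx_factory,
        )
        patients = pd.DataFrame(
            {"patient_id": ["p1"], "sex": "M", "birth_year": [1999]}  # age 14
        )
        assert len(select_cohort(world(v, r, patients), PERIODS, catalog)) == 0

    def test_two_primary_clinics_excluded(self, catalog, visit_factory, rx_factory):
        v, r = medicated_visits(
            "p1", ["2013-08-01", "2013-10-01", "2014-01-05"],
            visit_factory=visit_factory, rx_factory=rx_factory,
        )
        v.append(visit_factory("p1", "2013-12-01", "C2"))
        assert len(select_cohort(world(v, r), PERIODS, catalog)) == 0

    def test_tertiary_stream(self, catalog, visit_factory, rx_factory):
        v, r = medicated_visits(
            "p1", ["2013-08-01", "2013-10-01", "2014-01-05"], inst="T1",
            visit_factory=visit_factory, rx_factory=rx_factory,
        )
        out = select_cohort(world(v, r), PERIODS, catalog)
        assert len(out) == 1
        assert out.iloc[0]["stream"] == "tertiary"

    def test_uninsured_period_excluded(self, catalog, visit_factory, rx_factory):
        v, r = medicated_visits(
            "p1", ["2013-08-01", "2013-10-01", "2014-01-05"],
            visit_factory=visit_factory, rx_factory=rx_factory,
        )
        patients = pd.DataFrame(
            {
                "patient_id": ["p1"],
                "sex": "F",
                "birth_year": [1970],
                "uninsured_periods": ["1"],
            }
        )
        assert len(select_cohort(world(v, r, patients), PERIODS, catalog)) == 0

    def test_empty_tables_give_empty_cohort(self, catalog):
        tables = world([], [])
        tables["visits"] = pd.DataFrame(
            columns=["patient_id", "date", "institution_id", "setting",
                     "icd10_primary", "icd10_secondary"]
        )
        tables["prescriptions"] = pd.DataFrame(
            columns=["patient_id", "date", "institution_id", "drug_code",
                     "daily_units", "days_supplied"]
        )
        tables["patients"] = pd.DataFrame(
            columns=["patient_id", "sex", "birth_year"]
        )
        assert len(select_cohort(tables, PERIODS, catalog)) == 0

    def test_schema_violation_raises(self, catalog, visit_factory, rx_factory):
        v, r = medicated_visits(
            "p1", ["2013-08-01"], visit_factory=visit_factory,
            rx_factory=rx_factory,
        )
        tables = world(v, r)
        tables["visits"] = tables["visits"].drop(columns=["setting"])
        with pytest.raises(ValueError, match="setting"):
            select_cohort(tables, PERIODS, catalog)


def brute_force_select(tables, period, catalog, min_age=15, min_visits=3):
    """Independent per-patient filter looping over raw records."""
    visits = tables["visits"].copy()
    rx = tables["prescriptions"].copy()
    visits["date"] = pd.to_datetime(visits["date"])
    rx["date"] = pd.to_datetime(rx["date"])
    a0, a1 = pd.Timestamp(period.a_start), pd.Timestamp(period.a_end)
    visits = visits[(visits["date"] >= a0) & (visits["date"] < a1)]
    rx = rx[(rx["date"] >= a0) & (rx["date"] < a1)]
    ttypes = tables["institutions"].set_index("institution_id")["type"]
    kept = {}
    for pid, grp in visits.groupby("patient_id"):
        prow = tables["patients"].set_index("patient_id").loc[pid]
        if period.a_start.year - prow["birth_year"] < min_age:
            continue
        spec = prow.get("uninsured_periods", "")
        if isinstance(spec, str) and str(period.index) in spec.split(";"):
            continue
        prx = rx[rx["patient_id"] == pid]
        med_days = {
            (d.date(), i)
            for d, i in zip(prx["date"], prx["institution_id"])
        }
        outp_med = {
            (d.date(), i)
            for d, i, s in zip(grp["date"], grp["institution_id"], grp["setting"])
            if s == "outpatient" and (d.date(), i) in med_days
        }
        ster = set(
            catalog.codes_of(
                {"systemic corticosteroid", "low-dose oral prednisolone"}
            )
        )
        ster_days = {
            (d.date(), i)
            for d, i, c in zip(prx["date"], prx["institution_id"],
                               prx["drug_code"])
            if c in ster
        }
        hosp_ster = {
            (d.date(), i)
            for d, i, s in zip(grp["date"], grp["institution_id"], grp["setting"])
            if s == "inpatient" and (d.date(), i) in ster_days
        }
        if not (len(outp_med) >= min_visits
                or (len(hosp_ster) >= 1 and len(outp_med) >= 1)):
            continue
        asthma = grp[
            grp["icd10_primary"].fillna("").str.startswith(("J45", "J46"))
            | grp["icd10_secondary"].fillna("").str.startswith(("J45", "J46"))
        ]
        if asthma.empty:
            continue
        types = grp["institution_id"].map(ttypes)
        n_prim = grp.loc[types == "primary", "institution_id"].nunique()
        n_tert = grp.loc[types == "tertiary", "institution_id"].nunique()
        asthma_types = asthma["institution_id"].map(ttypes)
        if (asthma_types == "primary").any():
            if n_prim == 1:
                kept[pid] = "primary"
        elif (asthma_types == "tertiary").any() and n_tert == 1:
            kept[pid] = "tertiary"
    return kept


class TestAgainstBruteForce:
    def test_small_world_matches_brute_force(self, small_world, catalog, periods):
        per = periods[0]
        out = select_cohort(small_world.tables(), [per], catalog)
        got = dict(zip(out["patient_id"], out["stream"]))
        sub = {
            k: v
            for k, v in small_world.tables().items()
        }
        # brute force on a 120-patient slice to keep the oracle fast
        pids = set(small_world.patients["patient_id"][:120])
        sub["patients"] = sub["patients"][sub["patients"]["patient_id"].isin(pids)]
        sub["visits"] = sub["visits"][sub["visits"]["patient_id"].isin(pids)]
        sub["prescriptions"] = sub["prescriptions"][
            sub["prescriptions"]["patient_id"].isin(pids)
        ]
        expected = brute_force_select(sub, per, catalog)
        got_sub = {k: v for k, v in got.items() if k in pids}
        assert got_sub == expected


class TestProperties:
    def test_idempotence(self, small_world, catalog, periods):
        tables = small_world.tables()
        first = select_cohort(tables, periods, catalog)
        kept = set(first["patient_id"])
        sub = {
            "patients": tables["patients"][
                tables["patients"]["patient_id"].isin(kept)
            ],
            "visits": tables["visits"][tables["visits"]["patient_id"].isin(kept)],
            "prescriptions": tables["prescriptions"][
                tables["prescriptions"]["patient_id"].isin(kept)
            ],
            "institutions": tables["institutions"],
        }
        second = select_cohort(sub, periods, catalog)
        pd.testing.assert_frame_equal(
            first.reset_index(drop=True), second.reset_index(drop=True)
        )

    def test_lowering_min_age_never_shrinks_cohort(
        self, small_world, catalog, periods
    ):
        tables = small_world.tables()
        sizes = [
            len(select_cohort(tables, periods, catalog, min_age=a))
            for a in (40, 25, 15, 0)
        ]
        assert sizes == sorted(sizes)

    def test_same_patient_may_change_stream_across_periods(
        self, catalog, visit_factory, rx_factory
    ):
        periods2 = make_periods(2013, 2)
        v1, r1 = medicated_visits(
            "p1", ["2013-08-01", "2013-10-01", "2014-01-05"],
            visit_factory=visit_factory, rx_factory=rx_factory,
        )
        v2, r2 = medicated_visits(
            "p1", ["2014-08-01", "2014-10-01", "2015-01-05"], inst="T1",
            visit_factory=visit_factory, rx_factory=rx_factory,
        )
        out = select_cohort(world(v1 + v2, r1 + r2), periods2, catalog)
        assert list(out.sort_values("period")["stream"]) == ["primary", "tertiary"]
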