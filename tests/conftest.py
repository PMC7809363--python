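import pandas as pd
import pytest

from asthma_qa.catalog import DrugCatalog
from asthma_qa.config import SimulationConfig
from asthma_qa.periods import make_periods
from asthma_qa.pipeline import RunConfig, analyze_claims
from asthma_qa.synthetic import simulate_claims


@pytest.fixture(scope="session")
def catalog():
    return DrugCatalog.default()


@pytest.fixture(scope="session")
def periods():
    return make_periods(2013, 3)


@pytest.fixture(scope="session")
def small_world(catalog):
    """A compact simulated claims world shared by read-only tests."""
    cfg = SimulationConfig(
        n_patients=1500, n_primary_clinics=40, n_tertiary_hospitals=8, seed=7
    )
    return simulate_claims(cfg, catalog)


@pytest.fixture(scope="session")
def analyzed(small_world, catalog, periods):
    """All observation-building stages run on the small world."""
    return analyze_claims(
        small_world.tables(), catalog, periods, RunConfig(seed=7)
    )


def make_visit(pid, date, inst, setting="outpatient", icd1="J450", icd2="",
               pft=False):
    return {
        "patient_id": pid,
        "date": date,
        "institution_id": inst,
        "setting": setting,
        "icd10_primary": icd1,
        "icd10_secondary": icd2,
        "pft": pft,
    }


def make_rx(pid, date, inst, code, units=1, days=30):
    return {
        "patient_id": pid,
        "date": date,
        "institution_id": inst,
        "drug_code": code,
        "daily_units": units,
        "days_supplied": days,
    }


@pytest.fixture
def visit_factory():
    return make_visit


@pytest.fixture
def rx_factory():
    return make_rx


def frame(records):
    return pd.DataFrame(records)


@pytest.fixture
def to_frame():
    return frame
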