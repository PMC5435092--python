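"""Shared fixtures: hand-built micro-registries and seeded simulations."""

from __future__ import annotations

import pandas as pd
import pytest

from atopia import EHRDataset, SimulationConfig, generate_population, select_children
from atopia.config import constant_hazard, piecewise_hazard
from atopia.dataset import TABLE_COLUMNS


def make_dataset(
    practices=(),
    patients=(),
    episodes=(),
    care_events=(),
    prescriptions=(),
) -> EHRDataset:
    """Build an EHRDataset from row dicts, with parsed dates."""
    frames = {}
    for name, rows in (
        ("practices", practices),
        ("patients", patients),
        ("episodes", episodes),
        ("care_events", care_events),
        ("prescriptions", prescriptions),
    ):
        cols = TABLE_COLUMNS[name]
        df = pd.DataFrame(list(rows), columns=cols)
        for col in ("reg_start", "reg_end", "start_date", "end_date", "date"):
            if col in cols:
                df[col] = pd.to_datetime(df[col]) if len(df) else df[col]
        frames[name] = df
    return EHRDataset(**frames)


def good_practice_rows(practice_id="pr0", years=range(2002, 2015)):
    return [
        {
            "practice_id": practice_id,
            "year": y,
            "listed_patients": 2350,
            "registration_weeks": 52,
            "coded_fraction": 0.95,
        }
        for y in years
    ]


def patient_row(
    patient_id,
    practice_id="pr0",
    sex="F",
    birth_year=2000,
    birth_quarter=1,
    reg_start="2002-01-01",
    reg_end="2014-12-31",
):
    return {
        "patient_id": patient_id,
        "practice_id": practice_id,
        "sex": sex,
        "birth_year": birth_year,
        "birth_quarter": birth_quarter,
        "reg_start": reg_start,
        "reg_end": reg_end,
    }


@pytest.fixture(scope="session")
def sim_default():
    """Moderate default-parameter simulation with its cohort selection."""
    cfg = SimulationConfig(n_practices=4, patients_per_practice=300, seed=20020101)
    dataset = generate_population(cfg)
    selection = select_children(dataset)
    return cfg, dataset, selection


@pytest.fixture(scope="session")
def sim_closed_cohort():
    """Closed cohort: no turnover, no late entry, no remission.

    Suitable for exact cumulative-incidence properties: every recorded
    disorder stays open, so cumulative case status equals "onset on or
    before the reference date" for every registered child.
    """
    cfg = SimulationConfig(
        n_practices=4,
        patients_per_practice=300,
        seed=77,
        remission_hazards={"eczema": 0.0, "asthma": 0.0, "rhinitis": 0.0},
        turnover=0.0,
        late_entry_fraction=0.0,
        recurrence_probability=0.0,
        annual_contact_probability=0.0,
        irrelevant_prescription_rate=0.0,
        quality_defect_fractions={
            "listed_patients": 0.0,
            "registration_weeks": 0.0,
            "coded_fraction": 0.0,
        },
    )
    dataset = generate_population(cfg)
    selection = select_children(dataset)
    return cfg, dataset, selection


__all__ = [
    "constant_hazard",
    "good_practice_rows",
    "make_dataset",
    "patient_row",
    "piecewise_hazard",
]
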