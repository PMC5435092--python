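"""Age computation, Jan-1 point prevalence, cumulative incidence."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from atopia import (
    age_on,
    cumulative_incidence,
    imputed_birth_date,
    point_prevalence,
    validate_episodes,
)
from atopia.errors import InvalidInputError

from conftest import make_dataset, patient_row


# ------------------------------------------------------------------ ages


@pytest.mark.parametrize(
    "birth_year, quarter, on, expected",
    [
        (2000, 1, date(2005, 1, 1), 4),   # imputed 2000-02-15; birthday not reached
        (2000, 1, date(2000, 2, 15), 0),  # age zero on the imputed birth date
        (2000, 4, date(2019, 1, 1), 18),  # imputed 2000-11-15
        (2000, 2, date(2005, 5, 15), 5),  # birthday exactly reached
        (2000, 3, date(2005, 8, 14), 4),  # day before the imputed birthday
    ],
)
def test_age_on_mid_quarter_imputation(birth_year, quarter, on, expected):
    assert age_on(on, birth_year, quarter) == expected


def test_imputed_birth_dates():
    assert imputed_birth_date(2000, 1) == date(2000, 2, 15)
    assert imputed_birth_date(2000, 4) == date(2000, 11, 15)
    with pytest.raises(InvalidInputError):
        imputed_birth_date(2000, 5)


def test_age_before_birth_raises():
    with pytest.raises(InvalidInputError):
        age_on(date(2000, 1, 1), 2000, 2)


# ------------------------------------------------- forced small examples


def _ten_children(validated_rows):
    patients = pd.DataFrame(
        [
            patient_row(f"p{i}", birth_year=1999, birth_quarter=3,
                        reg_start="2002-01-01", reg_end="2005-12-31")
            for i in range(10)
        ]
    )
    for col in ("reg_start", "reg_end"):
        patients[col] = pd.to_datetime(patients[col])
    validated = pd.DataFrame(
        validated_rows,
        columns=[
            "patient_id", "disorder", "strategy",
            "effective_start", "effective_end", "n_contacts", "n_relevant_rx",
        ],
    )
    for col in ("effective_start", "effective_end"):
        validated[col] = pd.to_datetime(validated[col])
    return patients, validated


def test_point_prevalence_forced_arithmetic():
    """10 age-5 children on 2005-01-01, 2 with open eczema -> 20%."""
    patients, validated = _ten_children(
        [
            ("p0", "eczema", 1, "2004-06-01", "2005-06-01", 3, 2),
            ("p1", "eczema", 1, "2003-01-01", "2006-01-01", 3, 2),
        ]
    )
    table = point_prevalence(
        patients, validated, 1, window=(date(2005, 1, 1), date(2005, 12, 31))
    )
    row = table[(table["disorder"] == "eczema") & (table["age"] == 5)].iloc[0]
    assert (row["numerator"], row["denominator"], row["percent"]) == (2, 10, 20.0)


def test_point_prevalence_no_open_episode_is_zero_percent():
    patients, validated = _ten_children(
        [("p0", "eczema", 1, "2002-02-01", "2002-06-01", 1, 0)]
    )
    table = point_prevalence(
        patients, validated, 1, window=(date(2005, 1, 1), date(2005, 12, 31))
    )
    row = table[(table["disorder"] == "eczema") & (table["age"] == 5)].iloc[0]
    assert row["numerator"] == 0 and row["percent"] == 0.0


def test_zero_denominator_is_undefined_not_zero():
    patients, validated = _ten_children(
        [("p0", "eczema", 1, "2004-06-01", "2005-06-01", 3, 2)]
    )
    table = point_prevalence(
        patients, validated, 1, window=(date(2005, 1, 1), date(2005, 12, 31))
    )
    # nobody is aged 12 on 2005-01-01 in this cohort
    row = table[(table["disorder"] == "eczema") & (table["age"] == 12)].iloc[0]
    assert row["denominator"] == 0
    assert pd.isna(row["percent"])


def test_interval_covering_is_closed_on_both_ends():
    patients, validated = _ten_children(
        [
            ("p0", "eczema", 1, "2005-01-01", "2005-03-01", 1, 0),  # starts on Jan 1
            ("p1", "eczema", 1, "2004-02-01", "2005-01-01", 1, 0),  # ends on Jan 1
            ("p2", "eczema", 1, "2005-01-02", "2005-03-01", 1, 0),  # starts after
        ]
    )
    table = point_prevalence(
        patients, validated, 1, window=(date(2005, 1, 1), date(2005, 12, 31))
    )
    row = table[(table["disorder"] == "eczema") & (table["age"] == 5)].iloc[0]
    assert row["numerator"] == 2


def test_binomial_calibration_six_percent():
    """With cases drawn Bernoulli(0.06), the estimate sits within 3 SE."""
    rng = np.random.default_rng(2002)
    n = 10_000
    p = 0.06
    patients = pd.DataFrame(
        [
            patient_row(f"p{i}", birth_year=1999, birth_quarter=3,
                        reg_start="2002-01-01", reg_end="2005-12-31")
            for i in range(n)
        ]
    )
    for col in ("reg_start", "reg_end"):
        patients[col] = pd.to_datetime(patients[col])
    cases = rng.random(n) < p
    validated = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in np.flatnonzero(cases)],
            "disorder": "eczema",
            "strategy": 1,
            "effective_start": pd.Timestamp("2004-06-01"),
            "effective_end": pd.Timestamp("2005-06-01"),
            "n_contacts": 2,
            "n_relevant_rx": 2,
        }
    )
    table = point_prevalence(
        patients, validated, 1, window=(date(2005, 1, 1), date(2005, 12, 31))
    )
    row = table[(table["disorder"] == "eczema") & (table["age"] == 5)].iloc[0]
    estimate = row["numerator"] / row["denominator"]
    se = np.sqrt(p * (1 - p) / n)
    assert abs(estimate - p) <= 3 * se


# ----------------------------------------------------- pipeline properties


def test_strategy_ordering_per_age(sim_default):
    """s2<=s1 and s4<=s3 and s3>=s1 and s4>=s2 numerators at every age."""
    _, dataset, selection = sim_default
    validated = validate_episodes(dataset, selection.included_ids)
    cohort = dataset.patients[
        dataset.patients["patient_id"].isin(selection.included_ids)
    ]
    tables = {
        s: point_prevalence(cohort, validated, s).set_index(["disorder", "age"])
        for s in (1, 2, 3, 4)
    }
    idx = tables[1].index
    for lo, hi in ((2, 1), (4, 3), (1, 3), (2, 4)):
        a = tables[lo].reindex(idx)["numerator"].fillna(0)
        b = tables[hi].reindex(idx)["numerator"].fillna(0)
        assert (a <= b).all(), f"strategy {lo} exceeds {hi}"


def test_cumulative_monotone_on_single_birth_cohort(sim_closed_cohort):
    """Within one fully observed birth cohort, the curve never decreases."""
    _, dataset, selection = sim_closed_cohort
    cohort = dataset.patients[
        dataset.patients["patient_id"].isin(selection.included_ids)
        & (dataset.patients["birth_year"] == 2002)
    ]
    validated = validate_episodes(dataset, cohort["patient_id"])
    table = cumulative_incidence(cohort, validated, 3)
    for disorder, grp in table.groupby("disorder"):
        grp = grp[grp["denominator"] > 0].sort_values("age")
        pct = (grp["numerator"] / grp["denominator"]).to_numpy()
        assert (np.diff(pct) >= 0).all(), disorder


def test_cumulative_incidence_requires_chronic_strategy(sim_default):
    _, dataset, selection = sim_default
    cohort = dataset.patients[
        dataset.patients["patient_id"].isin(selection.included_ids)
    ]
    with pytest.raises(InvalidInputError):
        cumulative_incidence(cohort, pd.DataFrame(), 2)
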