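"""Per-age point prevalence and cumulative lifetime incidence.

Prevalence is measured on January 1 of every year in the study window:
the denominator for age ``a`` counts children registered on that date
whose completed age is ``a``; the numerator counts those with a
validated episode interval covering the date (closed interval, date
precision).  Numerators and denominators are pooled over calendar years
to give a single per-age curve; per-year output is available.

Birth dates come coarsened to year + quarter, so ages use a mid-quarter
imputed birth date: day 15 of the quarter's middle month (Feb/May/Aug/
Nov).  Applied to the chronically-extended episodes of strategies 3 and
4, the same Jan-1 estimator yields the cumulative incidence, which
approximates the lifetime prevalence when the whole medical history is
observed.
"""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd

from .config import AGES, DEFAULT_WINDOW
from .errors import InvalidInputError

#: Middle month of each birth quarter.
QUARTER_MID_MONTH = {1: 2, 2: 5, 3: 8, 4: 11}

TRIAD = "triad"


def imputed_birth_date(birth_year: int, birth_quarter: int) -> date:
    """Deterministic birth date from year + quarter: day 15, middle month."""
    if birth_quarter not in QUARTER_MID_MONTH:
        raise InvalidInputError(f"birth_quarter must be 1-4, got {birth_quarter}")
    return date(int(birth_year), QUARTER_MID_MONTH[birth_quarter], 15)


def age_on(on_date: date, birth_year: int, birth_quarter: int) -> int:
    """Completed years of age on a date, from the imputed birth date."""
    birth = imputed_birth_date(birth_year, birth_quarter)
    if on_date < birth:
        raise InvalidInputError(
            f"date {on_date} precedes imputed birth date {birth}"
        )
    age = on_date.year - birth.year
    if (on_date.month, on_date.day) < (birth.month, birth.day):
        age -= 1
    return age


def _imputed_births(patients: pd.DataFrame) -> pd.Series:
    months = patients["birth_quarter"].map(QUARTER_MID_MONTH)
    return pd.to_datetime(
        pd.DataFrame(
            {
                "year": patients["birth_year"].astype(int),
                "month": months.astype(int),
                "day": 15,
            }
        )
    )


def _ages_on(patients: pd.DataFrame, on: pd.Timestamp) -> pd.Series:
    births = _imputed_births(patients)
    age = on.year - births.dt.year
    # "birthday not yet reached this year", vectorised
    not_reached = (births.dt.month > on.month) | (
        (births.dt.month == on.month) & (births.dt.day > on.day)
    )
    return age - not_reached.astype(int)


def january_firsts(window: tuple[date, date] = DEFAULT_WINDOW) -> list[pd.Timestamp]:
    """All January 1 reference dates inside the study window."""
    start, end = window
    first = start.year if date(start.year, 1, 1) >= start else start.year + 1
    return [
        pd.Timestamp(year=y, month=1, day=1)
        for y in range(first, end.year + 1)
        if date(y, 1, 1) <= end
    ]


def point_prevalence(
    patients: pd.DataFrame,
    validated: pd.DataFrame,
    strategy: int,
    window: tuple[date, date] = DEFAULT_WINDOW,
    pool_years: bool = True,
) -> pd.DataFrame:
    """Per-age Jan-1 point prevalence for every disorder in ``validated``.

    Parameters
    ----------
    patients
        Cohort patients table (already restricted to the analysis cohort).
    validated
        Output of the episode engine: one row per validated interval with
        columns patient_id, disorder, strategy, effective_start,
        effective_end.
    strategy
        Which strategy's rows of ``validated`` to use (1-4).
    pool_years
        Pool numerators/denominators over calendar years (default); when
        False, rows are emitted per reference year.

    Returns
    -------
    DataFrame with columns disorder, strategy, age, numerator,
    denominator, percent (NaN where the denominator is zero; triad rows
    rounded to 2 decimals, disorders to 1).
    """
    if strategy not in (1, 2, 3, 4):
        raise InvalidInputError(f"strategy must be 1-4, got {strategy}")
    v = validated[validated["strategy"] == strategy]
    disorders = sorted(v["disorder"].unique()) if len(v) else []
    if not disorders:
        disorders = []
    dates = january_firsts(window)

    rows = []
    reg_start = pd.to_datetime(patients["reg_start"])
    reg_end = pd.to_datetime(patients["reg_end"])
    births = _imputed_births(patients) if len(patients) else pd.Series(dtype="datetime64[ns]")

    for ref in dates:
        registered = (reg_start <= ref) & (ref <= reg_end)
        if len(patients):
            ages = _ages_on(patients, ref)
        else:
            ages = pd.Series(dtype=int)
        at_risk = patients.loc[registered & ages.isin(AGES), "patient_id"]
        age_of = dict(zip(at_risk, ages[registered & ages.isin(AGES)]))
        denom = ages[registered & ages.isin(AGES)].value_counts()

        open_now = v[
            (pd.to_datetime(v["effective_start"]) <= ref)
            & (ref <= pd.to_datetime(v["effective_end"]))
        ]
        for disorder in disorders:
            cases = set(open_now.loc[open_now["disorder"] == disorder, "patient_id"])
            case_ages = pd.Series(
                [age_of[p] for p in cases if p in age_of], dtype=int
            ).value_counts()
            for a in AGES:
                rows.append(
                    {
                        "year": ref.year,
                        "disorder": disorder,
                        "strategy": strategy,
                        "age": a,
                        "numerator": int(case_ages.get(a, 0)),
                        "denominator": int(denom.get(a, 0)),
                    }
                )

    out = pd.DataFrame(
        rows,
        columns=["year", "disorder", "strategy", "age", "numerator", "denominator"],
    )
    if pool_years and len(out):
        out = (
            out.groupby(["disorder", "strategy", "age"], as_index=False)[
                ["numerator", "denominator"]
            ].sum()
        )
    elif not len(out):
        out = pd.DataFrame(
            columns=["disorder", "strategy", "age", "numerator", "denominator"]
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * out["numerator"] / out["denominator"].where(out["denominator"] > 0)
    if len(out):
        is_triad = out["disorder"] == TRIAD
        # triad prevalences are an order of magnitude smaller: 2 decimals
        out["percent"] = pct.round(1).where(~is_triad, pct.round(2))
    else:
        out["percent"] = pct
    return out


def cumulative_incidence(
    patients: pd.DataFrame,
    validated: pd.DataFrame,
    strategy: int,
    window: tuple[date, date] = DEFAULT_WINDOW,
    pool_years: bool = True,
) -> pd.DataFrame:
    """Cumulative first-diagnosis incidence by age (strategies 3/4 only).

    Identical to :func:`point_prevalence` applied to chronically extended
    episodes: once diagnosed, a child counts at every later Jan-1 it is
    registered for, so on a closed cohort the curve is non-decreasing in
    age and approximates the lifetime prevalence.
    """
    if strategy not in (3, 4):
        raise InvalidInputError(
            f"cumulative incidence requires a chronic strategy (3 or 4), got {strategy}"
        )
    return point_prevalence(patients, validated, strategy, window, pool_years)
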