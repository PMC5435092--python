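"""Practice-level data-quality gating and cohort selection.

A practice-year passes when it has at least 500 listed patients,
complete morbidity registration (>= 46 weeks of the year) and at least
70% of disease episodes carrying an ICPC label.  Children are then
selected when they are aged 0-18 during the study window, belong to a
practice with acceptable overlapping years, and have at least three
years (1095 days) of observed follow-up.  Exclusions are counted
quality-first, so the attrition categories sum exactly to
eligible - final.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import pandas as pd

from .config import DEFAULT_WINDOW
from .dataset import EHRDataset
from .errors import EmptyCohortError, IntegrityError, InvalidInputError
from .prevalence import _imputed_births

MIN_LISTED_PATIENTS = 500
MIN_REGISTRATION_WEEKS = 46
MIN_CODED_FRACTION = 0.70

#: Three calendar years of follow-up, in days.
MIN_FOLLOWUP_DAYS = 1095


@dataclass(frozen=True)
class PracticeYearAssessment:
    passed: bool
    reasons: tuple[str, ...]


def assess_practice_year(
    listed_patients: int, registration_weeks: float, coded_fraction: float
) -> PracticeYearAssessment:
    """Check one practice-year against the three quality criteria.

    All thresholds are inclusive; a failure lists every violated
    criterion.
    """
    if not 0 <= registration_weeks <= 53:
        raise InvalidInputError(
            f"registration_weeks must be in [0, 53], got {registration_weeks}"
        )
    if not 0 <= coded_fraction <= 1:
        raise InvalidInputError(
            f"coded_fraction must be in [0, 1], got {coded_fraction}"
        )
    reasons = []
    if listed_patients < MIN_LISTED_PATIENTS:
        reasons.append("patient-count")
    if registration_weeks < MIN_REGISTRATION_WEEKS:
        reasons.append("registration-weeks")
    if coded_fraction < MIN_CODED_FRACTION:
        reasons.append("coding-fraction")
    return PracticeYearAssessment(passed=not reasons, reasons=tuple(reasons))


@dataclass(frozen=True)
class CohortSelection:
    """Attrition accounting for one cohort selection run.

    ``final_count`` is derived, never stored: eligible minus the two
    exclusion categories (quality-first, so a child failing both is
    counted once, under quality).  ``included_ids`` carries the selected
    patient ids when the selection ran on data; it may be None for pure
    attrition arithmetic.
    """

    eligible_count: int
    excluded_quality_count: int
    excluded_followup_count: int
    included_ids: tuple[str, ...] | None = None

    @property
    def final_count(self) -> int:
        return (
            self.eligible_count
            - self.excluded_quality_count
            - self.excluded_followup_count
        )

    def __post_init__(self) -> None:
        counts = (
            self.eligible_count,
            self.excluded_quality_count,
            self.excluded_followup_count,
        )
        if any(c < 0 for c in counts) or self.final_count < 0:
            raise InvalidInputError(f"negative attrition counts: {counts}")
        if self.included_ids is not None and len(self.included_ids) != self.final_count:
            raise InvalidInputError(
                f"{len(self.included_ids)} included ids but final count "
                f"{self.final_count}"
            )


def _passing_practice_years(practices: pd.DataFrame) -> set[tuple[str, int]]:
    passing = set()
    for row in practices.itertuples(index=False):
        if assess_practice_year(
            row.listed_patients, row.registration_weeks, row.coded_fraction
        ).passed:
            passing.add((row.practice_id, int(row.year)))
    return passing


def select_children(
    dataset: EHRDataset,
    study_window: tuple[date, date] = DEFAULT_WINDOW,
    min_followup_days: int = MIN_FOLLOWUP_DAYS,
    strict: bool = False,
) -> CohortSelection:
    """Select the analysis cohort and account for every exclusion.

    A child is eligible when it is aged 0-18 for some part of its
    registration inside the study window.  Among eligible children,
    exclusion is quality-first: a child whose overlapping practice-years
    all fail the quality criteria (``strict=True``: any overlapping year
    fails) is excluded under quality even if its follow-up is also too
    short; remaining children need observed follow-up of at least
    ``min_followup_days`` (follow-up = overlap of the registration
    interval with the study window, in days).
    """
    patients = dataset.patients
    if len(patients):
        known = set(dataset.practices["practice_id"])
        bad = patients.loc[~patients["practice_id"].isin(known), "patient_id"]
        if len(bad):
            raise IntegrityError(
                f"patients reference unknown practices: {sorted(bad)[:5]}"
            )
    if not len(patients):
        return CohortSelection(0, 0, 0, ())

    wstart = pd.Timestamp(study_window[0])
    wend = pd.Timestamp(study_window[1])
    reg_start = pd.to_datetime(patients["reg_start"])
    reg_end = pd.to_datetime(patients["reg_end"])
    ov_start = reg_start.clip(lower=wstart)
    ov_end = reg_end.clip(upper=wend)
    has_overlap = ov_start <= ov_end

    births = _imputed_births(patients)
    nineteenth = births + pd.DateOffset(years=19)
    # child is aged 0-18 somewhere in the overlap: born on/before the end
    # of overlap and not yet 19 at its start
    in_age = (births <= ov_end) & (ov_start < nineteenth)
    eligible = has_overlap & in_age

    passing = _passing_practice_years(dataset.practices)
    eligible_vals = eligible.to_numpy()
    quality_ok = []
    for pos, row in enumerate(patients.itertuples(index=False)):
        if not eligible_vals[pos]:
            quality_ok.append(False)  # value unused for ineligible rows
            continue
        y0 = max(pd.Timestamp(row.reg_start).year, wstart.year)
        y1 = min(pd.Timestamp(row.reg_end).year, wend.year)
        years = range(y0, y1 + 1)
        verdicts = [(row.practice_id, y) in passing for y in years]
        if strict:
            quality_ok.append(bool(verdicts) and all(verdicts))
        else:
            quality_ok.append(any(verdicts))
    quality_ok = pd.Series(quality_ok, index=patients.index)

    followup_days = (ov_end - ov_start).dt.days
    followup_ok = followup_days >= min_followup_days

    n_eligible = int(eligible.sum())
    excluded_quality = eligible & ~quality_ok
    excluded_followup = eligible & quality_ok & ~followup_ok
    included = eligible & quality_ok & followup_ok
    return CohortSelection(
        eligible_count=n_eligible,
        excluded_quality_count=int(excluded_quality.sum()),
        excluded_followup_count=int(excluded_followup.sum()),
        included_ids=tuple(patients.loc[included, "patient_id"]),
    )


def attrition_report(selection: CohortSelection) -> pd.DataFrame:
    """Attrition table with exclusion shares as percentages of eligible."""
    if selection.eligible_count == 0:
        raise EmptyCohortError("no eligible children: attrition undefined")
    n = selection.eligible_count

    def pct(k: int) -> float:
        return round(100.0 * k / n, 1)

    rows = [
        ("eligible", n, 100.0),
        ("excluded_quality", selection.excluded_quality_count,
         pct(selection.excluded_quality_count)),
        ("excluded_followup", selection.excluded_followup_count,
         pct(selection.excluded_followup_count)),
        ("final", selection.final_count, pct(selection.final_count)),
    ]
    return pd.DataFrame(rows, columns=["category", "count", "percent"])
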