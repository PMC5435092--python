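"""In-memory container for the five-table primary-care EHR extract.

The tables mirror how Dutch GP registries expose routinely recorded
data: per-practice-year registration quality, listed patients with
coarse (year + quarter) birth dates, ICPC-coded episodes of care with
start/closing dates, episode-related care events, and ATC-coded
prescriptions.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import pandas as pd

from .errors import IntegrityError

PRACTICE_COLUMNS = [
    "practice_id",
    "year",
    "listed_patients",
    "registration_weeks",
    "coded_fraction",
]
PATIENT_COLUMNS = [
    "patient_id",
    "practice_id",
    "sex",
    "birth_year",
    "birth_quarter",
    "reg_start",
    "reg_end",
]
EPISODE_COLUMNS = ["episode_id", "patient_id", "icpc", "start_date", "end_date"]
CARE_EVENT_COLUMNS = ["event_id", "patient_id", "episode_id", "date", "type"]
PRESCRIPTION_COLUMNS = ["rx_id", "patient_id", "atc", "date", "episode_id"]

CARE_EVENT_TYPES = ("consultation", "home visit", "telephone", "prescription")

TABLE_COLUMNS = {
    "practices": PRACTICE_COLUMNS,
    "patients": PATIENT_COLUMNS,
    "episodes": EPISODE_COLUMNS,
    "care_events": CARE_EVENT_COLUMNS,
    "prescriptions": PRESCRIPTION_COLUMNS,
}


def _empty(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


@dataclass
class EHRDataset:
    """The five flat tables of a registry extract."""

    practices: pd.DataFrame
    patients: pd.DataFrame
    episodes: pd.DataFrame
    care_events: pd.DataFrame
    prescriptions: pd.DataFrame

    @classmethod
    def empty(cls) -> "EHRDataset":
        return cls(**{name: _empty(cols) for name, cols in TABLE_COLUMNS.items()})

    def tables(self) -> dict[str, pd.DataFrame]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def validate(self) -> None:
        """Check column layout, foreign keys and date ordering.

        Raises :class:`IntegrityError` on the first violation found.
        """
        for name, cols in TABLE_COLUMNS.items():
            table = getattr(self, name)
            missing = [c for c in cols if c not in table.columns]
            if missing:
                raise IntegrityError(f"{name}: missing columns {missing}")

        practice_ids = set(self.practices["practice_id"])
        patient_ids = set(self.patients["patient_id"])
        episode_ids = set(self.episodes["episode_id"])

        bad = self.patients.loc[
            ~self.patients["practice_id"].isin(practice_ids), "patient_id"
        ]
        if len(bad):
            raise IntegrityError(
                f"patients reference unknown practices: {sorted(bad)[:5]}"
            )
        for name, key in (
            ("episodes", "patient_id"),
            ("care_events", "patient_id"),
            ("prescriptions", "patient_id"),
        ):
            table = getattr(self, name)
            dangling = table.loc[~table[key].isin(patient_ids), key]
            if len(dangling):
                raise IntegrityError(
                    f"{name} reference unknown patients: {sorted(set(dangling))[:5]}"
                )
        for name in ("care_events", "prescriptions"):
            table = getattr(self, name)
            linked = table["episode_id"].dropna()
            linked = linked[linked != ""]
            dangling = linked[~linked.isin(episode_ids)]
            if len(dangling):
                raise IntegrityError(
                    f"{name} reference unknown episodes: {sorted(set(dangling))[:5]}"
                )

        if len(self.episodes):
            closed = self.episodes.dropna(subset=["end_date"])
            reversed_ = closed[closed["end_date"] < closed["start_date"]]
            if len(reversed_):
                raise IntegrityError(
                    "episodes with closing date before start: "
                    f"{sorted(reversed_['episode_id'])[:5]}"
                )
        if len(self.care_events):
            bad_type = self.care_events[
                ~self.care_events["type"].isin(CARE_EVENT_TYPES)
            ]
            if len(bad_type):
                raise IntegrityError(
                    f"care_events with unknown type: {sorted(set(bad_type['type']))}"
                )
        if len(self.patients):
            rev = self.patients[self.patients["reg_end"] < self.patients["reg_start"]]
            if len(rev):
                raise IntegrityError(
                    f"patients with reg_end before reg_start: "
                    f"{sorted(rev['patient_id'])[:5]}"
                )
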