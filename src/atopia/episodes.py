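"""Episode-of-care reconstruction under four strategies.

The four strategies factor into two independent corrections:

* start of the episode — strategy 1 takes the ICPC-coded episodes as
  recorded (accepting the overestimation risk of GP "probability
  diagnoses"); strategy 2 keeps only episodes backed by at least two
  episode-related contacts (consultation, home visit, telephone call or
  prescription) and at least two relevant prescriptions anywhere in the
  child's record, matched by ATC prefix.  A child rejected under
  strategy 2 stays in the population at risk (denominator only).
* closure — strategies 3 and 4 re-use the accepted episodes of 1 and 2
  respectively but treat the disorder as chronic, extending the episode
  to the end of the child's follow-up, which turns the Jan-1 estimator
  into a cumulative (lifetime) incidence.

Episodes without a recorded closing date are treated as open until the
end of follow-up under strategies 1 and 2 as well.

An "atopic triad" episode exists only for children accepted for all
three disorders; it starts at the first diagnosis of any of the three
and closes at the last recorded atopic contact (end of follow-up for the
chronic strategies).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import DEFAULT_WINDOW
from .dataset import EHRDataset
from .definitions import AtopicDefinition, default_definitions
from .errors import DateOrderError, InvalidInputError
from .prevalence import TRIAD

MIN_CONTACTS = 2
MIN_RELEVANT_RX = 2


@dataclass(frozen=True)
class DisorderRecord:
    """Canonical per-child, per-disorder record after episode merging."""

    patient_id: str
    icpc: str
    first_diagnosis: pd.Timestamp
    #: disjoint intervals, sorted; end is None while the episode is open
    intervals: tuple[tuple[pd.Timestamp, pd.Timestamp | None], ...]
    episode_ids: tuple[str, ...]


@dataclass(frozen=True)
class ValidatedEpisode:
    """A per-disorder episode accepted under one strategy."""

    patient_id: str
    disorder: str
    strategy: int
    intervals: tuple[tuple[pd.Timestamp, pd.Timestamp], ...]
    first_diagnosis: pd.Timestamp
    n_contacts: int
    n_relevant_rx: int

    @property
    def effective_start(self) -> pd.Timestamp:
        return self.intervals[0][0]

    @property
    def effective_end(self) -> pd.Timestamp:
        return self.intervals[-1][1]

    def covers(self, when: pd.Timestamp) -> bool:
        return any(s <= when <= e for s, e in self.intervals)


def _union_intervals(
    intervals: Iterable[tuple[pd.Timestamp, pd.Timestamp | None]],
) -> tuple[tuple[pd.Timestamp, pd.Timestamp | None], ...]:
    """Union of closed date intervals; abutting intervals merge."""
    items = sorted(intervals, key=lambda iv: iv[0])
    merged: list[list] = []
    one_day = pd.Timedelta(days=1)
    for start, end in items:
        if merged:
            prev = merged[-1]
            open_prev = prev[1] is None
            if open_prev or start <= prev[1] + one_day:
                if not open_prev and (end is None or end > prev[1]):
                    prev[1] = end
                continue
        merged.append([start, end])
    return tuple((s, e) for s, e in merged)


def merge_disorder_episodes(episodes: pd.DataFrame) -> DisorderRecord | None:
    """Collapse all recorded episodes of one child+ICPC into one record.

    The first-diagnosis date is the minimum start date (a child is
    incident only once); overlapping or abutting intervals are unioned,
    and no linked events are lost because episode ids are retained.
    """
    if not len(episodes):
        return None
    icpcs = set(episodes["icpc"])
    if len(icpcs) > 1:
        raise InvalidInputError(f"mixed ICPC codes in one record: {sorted(icpcs)}")
    patients = set(episodes["patient_id"])
    if len(patients) > 1:
        raise InvalidInputError(f"mixed patients in one record: {sorted(patients)}")
    ivals = []
    for row in episodes.itertuples(index=False):
        start = pd.Timestamp(row.start_date)
        end = None if pd.isna(row.end_date) else pd.Timestamp(row.end_date)
        ivals.append((start, end))
    merged = _union_intervals(ivals)
    return DisorderRecord(
        patient_id=patients.pop(),
        icpc=icpcs.pop(),
        first_diagnosis=merged[0][0],
        intervals=merged,
        episode_ids=tuple(episodes["episode_id"]),
    )


def count_evidence(
    record: DisorderRecord,
    events: pd.DataFrame,
    prescriptions: pd.DataFrame,
    definition: AtopicDefinition,
    *,
    strict_contacts: bool = False,
    rx_window_days: int | None = None,
) -> tuple[int, int]:
    """Count (episode-linked contacts, relevant prescriptions) for a record.

    Contacts are care events linked to any of the record's episodes;
    with ``strict_contacts`` prescription-type events do not count.
    Relevant prescriptions are matched record-wide by ATC prefix (EHRs
    do not reliably link repeat medication to episodes); an optional
    ``rx_window_days`` restricts them to within N days of a recorded
    interval.
    """
    if record.icpc != definition.icpc_code:
        raise InvalidInputError(
            f"record ICPC {record.icpc} does not match definition "
            f"{definition.icpc_code}"
        )
    linked = events[events["episode_id"].isin(record.episode_ids)]
    if strict_contacts:
        linked = linked[linked["type"] != "prescription"]
    n_contacts = int(len(linked))

    if len(prescriptions):
        relevant = prescriptions[
            prescriptions["atc"].str.startswith(definition.relevant_atc_prefixes)
        ]
    else:
        relevant = prescriptions
    if rx_window_days is not None and len(relevant):
        pad = pd.Timedelta(days=rx_window_days)
        dates = pd.to_datetime(relevant["date"])
        keep = pd.Series(False, index=relevant.index)
        for start, end in record.intervals:
            hi = (end + pad) if end is not None else None
            in_win = dates >= start - pad
            if hi is not None:
                in_win &= dates <= hi
            keep |= in_win
        relevant = relevant[keep]
    return n_contacts, int(len(relevant))


def _close_open(
    record: DisorderRecord, followup_end: pd.Timestamp
) -> tuple[tuple[pd.Timestamp, pd.Timestamp], ...]:
    """Missing closing dates mean the episode is open to follow-up end."""
    out = []
    for start, end in record.intervals:
        if start > followup_end:
            continue
        closed_end = followup_end if end is None else min(end, followup_end)
        out.append((start, max(closed_end, start)))
    return tuple(out)


def apply_strategy1(
    record: DisorderRecord,
    disorder: str,
    followup_end: pd.Timestamp,
    n_contacts: int = 0,
    n_relevant_rx: int = 0,
) -> ValidatedEpisode | None:
    """Accept the episodes as recorded (evidence recorded, not enforced)."""
    intervals = _close_open(record, followup_end)
    if not intervals:
        return None
    return ValidatedEpisode(
        patient_id=record.patient_id,
        disorder=disorder,
        strategy=1,
        intervals=intervals,
        first_diagnosis=record.first_diagnosis,
        n_contacts=n_contacts,
        n_relevant_rx=n_relevant_rx,
    )


def apply_strategy2(
    record: DisorderRecord,
    events: pd.DataFrame,
    prescriptions: pd.DataFrame,
    definition: AtopicDefinition,
    followup_end: pd.Timestamp,
    *,
    strict_contacts: bool = False,
    rx_window_days: int | None = None,
) -> ValidatedEpisode | None:
    """Accept only prescription-validated episodes.

    Requires at least :data:`MIN_CONTACTS` episode-related contacts and
    :data:`MIN_RELEVANT_RX` relevant prescriptions; otherwise the child
    drops back into the population at risk (returns None).
    """
    n_contacts, n_rx = count_evidence(
        record,
        events,
        prescriptions,
        definition,
        strict_contacts=strict_contacts,
        rx_window_days=rx_window_days,
    )
    if n_contacts < MIN_CONTACTS or n_rx < MIN_RELEVANT_RX:
        return None
    accepted = apply_strategy1(
        record, definition.disorder, followup_end, n_contacts, n_rx
    )
    if accepted is None:
        return None
    return replace(accepted, strategy=2)


def make_chronic(
    validated: ValidatedEpisode, followup_end: pd.Timestamp
) -> ValidatedEpisode:
    """Extend an accepted episode to the end of follow-up (chronicity).

    Maps strategy 1 -> 3 and 2 -> 4; the effective start (first
    diagnosis) is unchanged and the interval is never shortened.
    """
    if validated.strategy not in (1, 2):
        raise InvalidInputError(
            f"make_chronic expects a strategy-1/2 episode, got {validated.strategy}"
        )
    followup_end = pd.Timestamp(followup_end)
    if followup_end < validated.effective_start:
        raise DateOrderError(
            f"follow-up end {followup_end.date()} precedes episode start "
            f"{validated.effective_start.date()}"
        )
    return replace(
        validated,
        strategy=validated.strategy + 2,
        intervals=((validated.effective_start, followup_end),),
    )


def build_triad(
    validated: Sequence[ValidatedEpisode],
    last_atopic_contact: pd.Timestamp | None = None,
) -> ValidatedEpisode | None:
    """Atopic-triad episode for one child under one strategy.

    Exists only when all three disorders are accepted; starts at the
    earliest first diagnosis of any disorder and closes at the last
    recorded atopic contact (for the chronic strategies the components
    already extend to follow-up end, which then bounds the closure).
    """
    if not validated:
        return None
    strategies = {v.strategy for v in validated}
    if len(strategies) > 1:
        raise InvalidInputError(f"mixed strategies in triad input: {sorted(strategies)}")
    patients = {v.patient_id for v in validated}
    if len(patients) > 1:
        raise InvalidInputError(f"mixed patients in triad input: {sorted(patients)}")
    disorders = {v.disorder for v in validated}
    if len(disorders) < 3:
        return None
    strategy = strategies.pop()
    start = min(v.first_diagnosis for v in validated)
    if strategy in (3, 4):
        end = max(v.effective_end for v in validated)
    else:
        end = last_atopic_contact
        if end is None:
            end = max(v.effective_end for v in validated)
    end = max(pd.Timestamp(end), start)
    return ValidatedEpisode(
        patient_id=patients.pop(),
        disorder=TRIAD,
        strategy=strategy,
        intervals=((start, end),),
        first_diagnosis=start,
        n_contacts=sum(v.n_contacts for v in validated),
        n_relevant_rx=sum(v.n_relevant_rx for v in validated),
    )


def _episodes_to_frame(episodes: Iterable[ValidatedEpisode]) -> pd.DataFrame:
    rows = []
    for v in episodes:
        for start, end in v.intervals:
            rows.append(
                {
                    "patient_id": v.patient_id,
                    "disorder": v.disorder,
                    "strategy": v.strategy,
                    "effective_start": start,
                    "effective_end": end,
                    "n_contacts": v.n_contacts,
                    "n_relevant_rx": v.n_relevant_rx,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "disorder",
            "strategy",
            "effective_start",
            "effective_end",
            "n_contacts",
            "n_relevant_rx",
        ],
    )


def validate_episodes(
    dataset: EHRDataset,
    patient_ids: Iterable[str],
    strategies: Sequence[int] = (1, 2, 3, 4),
    definitions: Mapping[str, AtopicDefinition] | None = None,
    window: tuple[date, date] = DEFAULT_WINDOW,
    *,
    strict_contacts: bool = False,
    rx_window_days: int | None = None,
    include_triad: bool = True,
) -> pd.DataFrame:
    """Run the episode engine for a cohort; one row per validated interval.

    Returns a frame with columns patient_id, disorder, strategy,
    effective_start, effective_end, n_contacts, n_relevant_rx, covering
    the requested strategies and (optionally) the atopic triad.
    """
    bad = [s for s in strategies if s not in (1, 2, 3, 4)]
    if bad:
        raise InvalidInputError(f"unknown strategies {bad}; valid: 1-4")
    definitions = definitions if definitions is not None else default_definitions()
    wend = pd.Timestamp(window[1])
    patient_ids = list(patient_ids)

    patients = dataset.patients.set_index("patient_id")
    icpc_to_disorder = {d.icpc_code: name for name, d in definitions.items()}
    episodes = dataset.episodes[dataset.episodes["icpc"].isin(icpc_to_disorder)]
    eps_by_patient = {pid: grp for pid, grp in episodes.groupby("patient_id")}
    ev_by_patient = {pid: grp for pid, grp in dataset.care_events.groupby("patient_id")}
    rx_by_patient = {pid: grp for pid, grp in dataset.prescriptions.groupby("patient_id")}
    no_events = dataset.care_events.iloc[0:0]
    no_rx = dataset.prescriptions.iloc[0:0]

    out: list[ValidatedEpisode] = []
    for pid in patient_ids:
        p_eps = eps_by_patient.get(pid)
        if p_eps is None:
            continue
        followup_end = min(pd.Timestamp(patients.loc[pid, "reg_end"]), wend)
        events = ev_by_patient.get(pid, no_events)
        rxs = rx_by_patient.get(pid, no_rx)

        per_strategy: dict[int, list[ValidatedEpisode]] = {s: [] for s in (1, 2, 3, 4)}
        atopic_episode_ids: list[str] = []
        for disorder, definition in definitions.items():
            d_eps = p_eps[p_eps["icpc"] == definition.icpc_code]
            d_eps = d_eps[pd.to_datetime(d_eps["start_date"]) <= followup_end]
            record = merge_disorder_episodes(d_eps)
            if record is None:
                continue
            atopic_episode_ids.extend(record.episode_ids)
            n_contacts, n_rx = count_evidence(
                record,
                events,
                rxs,
                definition,
                strict_contacts=strict_contacts,
                rx_window_days=rx_window_days,
            )
            s1 = apply_strategy1(record, disorder, followup_end, n_contacts, n_rx)
            if s1 is None:
                continue
            per_strategy[1].append(s1)
            per_strategy[3].append(make_chronic(s1, followup_end))
            s2 = apply_strategy2(
                record,
                events,
                rxs,
                definition,
                followup_end,
                strict_contacts=strict_contacts,
                rx_window_days=rx_window_days,
            )
            if s2 is not None:
                per_strategy[2].append(s2)
                per_strategy[4].append(make_chronic(s2, followup_end))

        last_contact = None
        if atopic_episode_ids and len(events):
            atopic_events = events[events["episode_id"].isin(atopic_episode_ids)]
            if len(atopic_events):
                last_contact = pd.to_datetime(atopic_events["date"]).max()

        for s in strategies:
            out.extend(per_strategy[s])
            if include_triad:
                triad = build_triad(per_strategy[s], last_contact)
                if triad is not None:
                    out.append(triad)

    return _episodes_to_frame(out)
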