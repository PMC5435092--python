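"""Episode merging, strategy validation, chronic extension, triad."""

from datetime import date, timedelta

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atopia import (
    SimulationConfig,
    apply_strategy1,
    apply_strategy2,
    build_triad,
    default_definitions,
    generate_population,
    make_chronic,
    merge_disorder_episodes,
    select_children,
    validate_episodes,
)
from atopia.episodes import _union_intervals, count_evidence
from atopia.errors import DateOrderError, InvalidInputError

DEFS = default_definitions()
T = pd.Timestamp


def episode_frame(rows):
    df = pd.DataFrame(
        rows, columns=["episode_id", "patient_id", "icpc", "start_date", "end_date"]
    )
    df["start_date"] = pd.to_datetime(df["start_date"])
    df["end_date"] = pd.to_datetime(df["end_date"])
    return df


def ep(eid, start, end, patient="p1", icpc="S87"):
    return {
        "episode_id": eid,
        "patient_id": patient,
        "icpc": icpc,
        "start_date": start,
        "end_date": end,
    }


def ev(eid, episode, day, type_="consultation", patient="p1"):
    return {
        "event_id": eid,
        "patient_id": patient,
        "episode_id": episode,
        "date": pd.Timestamp(day),
        "type": type_,
    }


def rx(rid, atc, day, patient="p1", episode=None):
    return {
        "rx_id": rid,
        "patient_id": patient,
        "atc": atc,
        "date": pd.Timestamp(day),
        "episode_id": episode,
    }


EVENT_COLS = ["event_id", "patient_id", "episode_id", "date", "type"]
RX_COLS = ["rx_id", "patient_id", "atc", "date", "episode_id"]


def frame(rows, cols):
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------- merging


def test_merge_disjoint_keeps_two_intervals():
    record = merge_disorder_episodes(
        episode_frame(
            [ep("e1", "2004-01-10", "2004-06-01"), ep("e2", "2008-02-01", "2008-09-01")]
        )
    )
    assert record.first_diagnosis == T("2004-01-10")
    assert record.intervals == (
        (T("2004-01-10"), T("2004-06-01")),
        (T("2008-02-01"), T("2008-09-01")),
    )


def test_merge_single_episode_identity():
    record = merge_disorder_episodes(episode_frame([ep("e1", "2004-01-10", None)]))
    assert record.intervals == ((T("2004-01-10"), None),)
    assert record.episode_ids == ("e1",)


def test_merge_overlapping_unions():
    record = merge_disorder_episodes(
        episode_frame(
            [ep("e1", "2004-01-10", "2004-06-01"), ep("e2", "2004-05-01", "2004-12-01")]
        )
    )
    assert record.intervals == ((T("2004-01-10"), T("2004-12-01")),)


def test_merge_mixed_icpc_rejected():
    with pytest.raises(InvalidInputError):
        merge_disorder_episodes(
            episode_frame(
                [ep("e1", "2004-01-10", None), ep("e2", "2005-01-01", None, icpc="R96")]
            )
        )


@settings(max_examples=200, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(0, 120), st.integers(0, 60) | st.none()),
        min_size=1,
        max_size=6,
    )
)
def test_interval_union_matches_day_set_oracle(raw):
    """Union of closed day intervals equals a brute-force day-set sweep."""
    base = date(2005, 1, 1)
    intervals = []
    for start_off, length in raw:
        start = T(base + timedelta(days=start_off))
        end = None if length is None else T(base + timedelta(days=start_off + length))
        intervals.append((start, end))
    horizon = T(base + timedelta(days=400))

    merged = _union_intervals(intervals)

    covered = set()
    for start, end in intervals:
        stop = horizon if end is None else end
        covered.update(pd.date_range(start, stop))
    merged_days = set()
    for start, end in merged:
        stop = horizon if end is None else end
        merged_days.update(pd.date_range(start, stop))
    assert merged_days == covered
    # disjoint and non-abutting
    for (s1, e1), (s2, _) in zip(merged, merged[1:]):
        assert e1 is not None and s2 > e1 + pd.Timedelta(days=1)


# ------------------------------------------------------------- strategies


def _asthma_record(end="2005-06-01"):
    return merge_disorder_episodes(
        episode_frame([ep("e1", "2005-01-10", end, icpc="R96")])
    )


def test_strategy1_is_identity_with_recorded_counts():
    record = merge_disorder_episodes(
        episode_frame([ep("e1", "2004-01-10", "2004-06-01")])
    )
    v = apply_strategy1(record, "eczema", T("2014-12-31"), n_contacts=0)
    assert v.strategy == 1
    assert v.intervals == ((T("2004-01-10"), T("2004-06-01")),)
    assert v.n_contacts == 0  # zero contacts still accepted


def test_strategy1_opens_missing_closing_date_to_followup_end():
    record = merge_disorder_episodes(episode_frame([ep("e1", "2004-01-10", None)]))
    v = apply_strategy1(record, "eczema", T("2014-12-31"))
    assert v.intervals == ((T("2004-01-10"), T("2014-12-31")),)


def test_strategy2_rejects_single_contact_no_rx():
    record = _asthma_record()
    events = frame([ev("c1", "e1", "2005-01-10")], EVENT_COLS)
    assert (
        apply_strategy2(record, events, frame([], RX_COLS), DEFS["asthma"], T("2014-12-31"))
        is None
    )


def test_strategy2_accepts_two_contacts_two_matching_rx():
    record = _asthma_record()
    events = frame(
        [ev("c1", "e1", "2005-01-10"), ev("c2", "e1", "2005-03-01")], EVENT_COLS
    )
    rxs = frame(
        [rx("r1", "R03AC02", "2005-02-01"), rx("r2", "R03AC02", "2005-04-01")],
        RX_COLS,
    )
    v = apply_strategy2(record, events, rxs, DEFS["asthma"], T("2014-12-31"))
    assert v is not None and v.strategy == 2
    assert (v.n_contacts, v.n_relevant_rx) == (2, 2)
    # accepted episodes keep their recorded interval
    assert v.intervals == ((T("2005-01-10"), T("2005-06-01")),)


def test_strategy2_wrong_atc_prefix_rejected():
    """R06 antihistamines are rhinitis evidence, not eczema evidence."""
    record = merge_disorder_episodes(
        episode_frame([ep("e1", "2005-01-10", "2005-06-01")])
    )
    events = frame(
        [ev("c1", "e1", "2005-01-10"), ev("c2", "e1", "2005-03-01")], EVENT_COLS
    )
    rxs = frame(
        [rx("r1", "R06AE07", "2005-02-01"), rx("r2", "R06AE07", "2005-04-01")],
        RX_COLS,
    )
    assert apply_strategy2(record, events, rxs, DEFS["eczema"], T("2014-12-31")) is None


def test_strategy2_prescription_events_count_as_contacts():
    record = _asthma_record()
    events = frame(
        [
            ev("c1", "e1", "2005-02-01", type_="prescription"),
            ev("c2", "e1", "2005-04-01", type_="prescription"),
        ],
        EVENT_COLS,
    )
    rxs = frame(
        [rx("r1", "R03BB01", "2005-02-01"), rx("r2", "R03BB01", "2005-04-01")],
        RX_COLS,
    )
    v = apply_strategy2(record, events, rxs, DEFS["asthma"], T("2014-12-31"))
    assert v is not None
    # strict mode requires two non-prescription contacts
    strict = apply_strategy2(
        record, events, rxs, DEFS["asthma"], T("2014-12-31"), strict_contacts=True
    )
    assert strict is None


def test_strategy2_rx_matched_record_wide_not_by_link():
    """Unlinked prescriptions anywhere in the record count as evidence."""
    record = _asthma_record()
    events = frame(
        [ev("c1", "e1", "2005-01-10"), ev("c2", "e1", "2005-03-01")], EVENT_COLS
    )
    rxs = frame(
        [rx("r1", "R03AC02", "2009-02-01"), rx("r2", "R03AC02", "2011-04-01")],
        RX_COLS,
    )
    assert apply_strategy2(record, events, rxs, DEFS["asthma"], T("2014-12-31")) is not None
    # a +/-30-day window excludes those distant prescriptions
    assert (
        apply_strategy2(
            record, events, rxs, DEFS["asthma"], T("2014-12-31"), rx_window_days=30
        )
        is None
    )


def test_count_evidence_mismatched_definition_rejected():
    with pytest.raises(InvalidInputError):
        count_evidence(
            _asthma_record(), frame([], EVENT_COLS), frame([], RX_COLS), DEFS["eczema"]
        )


# ----------------------------------------------------------- chronicity


def test_make_chronic_extends_to_followup_end():
    record = merge_disorder_episodes(
        episode_frame([ep("e1", "2004-01-10", "2004-06-01")])
    )
    v1 = apply_strategy1(record, "eczema", T("2014-12-31"))
    v3 = make_chronic(v1, T("2014-12-31"))
    assert v3.strategy == 3
    assert v3.intervals == ((T("2004-01-10"), T("2014-12-31")),)


def test_make_chronic_idempotent_when_already_open_to_end():
    record = merge_disorder_episodes(episode_frame([ep("e1", "2004-01-10", None)]))
    v1 = apply_strategy1(record, "eczema", T("2014-12-31"))
    v3 = make_chronic(v1, T("2014-12-31"))
    assert v3.intervals == v1.intervals


def test_make_chronic_never_shortens():
    record = merge_disorder_episodes(
        episode_frame(
            [ep("e1", "2004-01-10", "2004-06-01"), ep("e2", "2008-02-01", "2008-09-01")]
        )
    )
    v1 = apply_strategy1(record, "eczema", T("2014-12-31"))
    v3 = make_chronic(v1, T("2014-12-31"))
    for day in ("2004-03-01", "2006-01-01", "2008-05-01", "2012-07-04"):
        if v1.covers(T(day)):
            assert v3.covers(T(day))


def test_make_chronic_date_order_error():
    record = merge_disorder_episodes(episode_frame([ep("e1", "2010-06-01", None)]))
    v1 = apply_strategy1(record, "eczema", T("2014-12-31"))
    with pytest.raises(DateOrderError):
        make_chronic(v1, T("2010-01-01"))


# ----------------------------------------------------------------- triad


def _validated(disorder, icpc, start, strategy=1):
    record = merge_disorder_episodes(
        episode_frame([ep(f"e-{icpc}", start, None, icpc=icpc)])
    )
    v = apply_strategy1(record, disorder, T("2014-12-31"))
    if strategy == 3:
        v = make_chronic(v, T("2014-12-31"))
    return v


def test_triad_start_and_close():
    vs = [
        _validated("eczema", "S87", "2004-03-01"),
        _validated("asthma", "R96", "2006-05-01"),
        _validated("rhinitis", "R97", "2008-09-01"),
    ]
    triad = build_triad(vs, last_atopic_contact=T("2010-01-15"))
    assert triad.intervals == ((T("2004-03-01"), T("2010-01-15")),)


def test_triad_requires_all_three():
    vs = [
        _validated("eczema", "S87", "2004-03-01"),
        _validated("asthma", "R96", "2006-05-01"),
    ]
    assert build_triad(vs, last_atopic_contact=T("2010-01-15")) is None


def test_triad_equal_start_dates():
    vs = [
        _validated("eczema", "S87", "2004-03-01"),
        _validated("asthma", "R96", "2004-03-01"),
        _validated("rhinitis", "R97", "2004-03-01"),
    ]
    triad = build_triad(vs, last_atopic_contact=T("2009-01-01"))
    assert triad.first_diagnosis == T("2004-03-01")


def test_triad_mixed_strategies_rejected():
    vs = [
        _validated("eczema", "S87", "2004-03-01", strategy=3),
        _validated("asthma", "R96", "2006-05-01"),
        _validated("rhinitis", "R97", "2008-09-01"),
    ]
    with pytest.raises(InvalidInputError):
        build_triad(vs)


# ---------------------------------------------- brute-force equivalence


def brute_force_strategy2(dataset, patient_ids, definitions):
    """Independent direct enumeration of the strategy-2 acceptance rule."""
    accepted = set()
    episodes = dataset.episodes
    events = dataset.care_events
    rxs = dataset.prescriptions
    for pid in patient_ids:
        for disorder, d in definitions.items():
            ep_ids = [
                r.episode_id
                for r in episodes.itertuples(index=False)
                if r.patient_id == pid and r.icpc == d.icpc_code
            ]
            if not ep_ids:
                continue
            n_contacts = sum(
                1
                for r in events.itertuples(index=False)
                if r.episode_id in ep_ids
            )
            n_rx = sum(
                1
                for r in rxs.itertuples(index=False)
                if r.patient_id == pid
                and any(r.atc.startswith(p) for p in d.relevant_atc_prefixes)
            )
            if n_contacts >= 2 and n_rx >= 2:
                accepted.add((pid, disorder))
    return accepted


def test_strategy2_matches_brute_force_oracle():
    cfg = SimulationConfig(n_practices=1, patients_per_practice=20, seed=123)
    dataset = generate_population(cfg)
    selection = select_children(dataset)
    validated = validate_episodes(dataset, selection.included_ids, strategies=(2,))
    engine = {
        (r.patient_id, r.disorder)
        for r in validated.itertuples(index=False)
        if r.disorder != "triad"
    }
    oracle = brute_force_strategy2(dataset, selection.included_ids, DEFS)
    assert engine == oracle
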