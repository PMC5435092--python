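"""Seeded synthetic primary-care registry generator.

Emulates the structure of a Dutch GP morbidity registry: practices with
per-year registration-quality metrics (some deliberately defective),
listed children observed 2002-2014, ICPC-coded episodes of care for the
three atopic disorders, episode-related care events, and ATC-coded
prescriptions.

The disease model is a discrete annual-hazard process: each child, for
each disorder, experiences first onset at age ``a`` with probability
``incidence_hazards[disorder][a]``, independently across disorders and
children; an open episode closes (remission) with a constant annual
hazard, and may recur.  The GP records an episode only while the child
is registered: the recorded start is the later of true onset and
registration start, so cumulative first-diagnosis proportions among
children followed from birth converge to ``1 - prod(1 - h(t))``.

Care-seeking is a Poisson process over open episode time; a configurable
share of contacts dispense definition-matching medication, which is
exported twice — as a prescription row and as a prescription-type care
event — because a dispensing is one observation viewed through two
tables.  A fraction of relevant prescriptions is exported without an
episode link, mimicking EHRs that do not link repeat medication to the
originating episode.
"""

from __future__ import annotations

from datetime import date, timedelta
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import ValidationError

from .config import SimulationConfig
from .dataset import EHRDataset, TABLE_COLUMNS
from .definitions import AtopicDefinition, default_definitions
from .errors import ConfigurationError

_IRRELEVANT_ATC = (
    "N02BE01",  # paracetamol
    "J01CA04",  # amoxicillin
    "A01AB09",  # miconazole, oral
    "C09AA05",  # ramipril
    "M01AE01",  # ibuprofen
    "S01AA01",  # chloramphenicol, eye
    "B01AC06",  # acetylsalicylic acid
    "A07DA03",  # loperamide
)

_EVENT_TYPE_POOL = ("consultation", "home visit", "telephone")
_EVENT_TYPE_P = (0.75, 0.05, 0.20)

_YEAR = 365.25


def _coerce_config(config: SimulationConfig | Mapping) -> SimulationConfig:
    if isinstance(config, SimulationConfig):
        return config
    try:
        return SimulationConfig.model_validate(config)
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc


def _uniform_date(rng: np.random.Generator, start: date, end: date) -> date:
    """Uniform date in the closed interval [start, end]."""
    span = (end - start).days
    return start + timedelta(days=int(rng.integers(0, span + 1)))


def _sample_atc(rng: np.random.Generator, prefix: str) -> str:
    """A full 7-character ATC code under the given prefix."""
    code = prefix
    if len(code) == 3:  # e.g. D07 -> D07AA..
        code += "".join(rng.choice(list("ABCX"), size=2))
    elif len(code) == 4:
        code += str(rng.choice(list("ABCX")))
    if len(code) == 5:
        code += f"{int(rng.integers(1, 13)):02d}"
    return code


class _Generator:
    def __init__(self, config: SimulationConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.wstart, self.wend = config.study_window
        self.definitions: dict[str, AtopicDefinition] = default_definitions()
        self.practices: list[dict] = []
        self.patients: list[dict] = []
        self.episodes: list[dict] = []
        self.events: list[dict] = []
        self.rxs: list[dict] = []
        self.truth: list[dict] = []
        self._episode_n = 0
        self._event_n = 0
        self._rx_n = 0

    # ---------------- practices ----------------

    def gen_practices(self) -> None:
        cfg, rng = self.cfg, self.rng
        frac = cfg.quality_defect_fractions
        years = range(self.wstart.year, self.wend.year + 1)
        for p in range(cfg.n_practices):
            pid = f"pr{p:04d}"
            defect_n = rng.random() < frac.listed_patients
            defect_w = rng.random() < frac.registration_weeks
            defect_c = rng.random() < frac.coded_fraction
            for year in years:
                listed = (
                    int(rng.integers(150, 500))
                    if defect_n
                    else int(rng.integers(1800, 3000))
                )
                weeks = (
                    int(rng.integers(30, 46))
                    if defect_w
                    else int(rng.integers(46, 53))
                )
                coded = (
                    round(float(rng.uniform(0.30, 0.69)), 3)
                    if defect_c
                    else round(float(rng.uniform(0.75, 0.99)), 3)
                )
                self.practices.append(
                    {
                        "practice_id": pid,
                        "year": year,
                        "listed_patients": listed,
                        "registration_weeks": weeks,
                        "coded_fraction": coded,
                    }
                )

    # ---------------- patients ----------------

    def _registration(self, birth: date) -> tuple[date, date]:
        cfg, rng = self.cfg, self.rng
        entry = max(birth, self.wstart)
        if rng.random() < cfg.late_entry_fraction:
            max_delay = min(4 * 365, max((self.wend - entry).days - 1, 0))
            entry = entry + timedelta(days=int(rng.integers(0, max_delay + 1)))
        # annual turnover: leave mid-year with the configured hazard
        end = self.wend
        if cfg.turnover > 0:
            t = entry
            while t < self.wend:
                nxt = min(t + timedelta(days=365), self.wend)
                if rng.random() < cfg.turnover:
                    end = _uniform_date(rng, t, nxt)
                    break
                t = nxt
        return entry, max(end, entry)

    def gen_patients(self) -> None:
        cfg, rng = self.cfg, self.rng
        earliest_birth = self.wstart - timedelta(days=round(18 * _YEAR))
        span = (self.wend - earliest_birth).days
        n = 0
        for p in range(cfg.n_practices):
            practice_id = f"pr{p:04d}"
            for _ in range(cfg.patients_per_practice):
                pid = f"pt{n:06d}"
                n += 1
                birth = earliest_birth + timedelta(days=int(rng.integers(0, span + 1)))
                reg_start, reg_end = self._registration(birth)
                self.patients.append(
                    {
                        "patient_id": pid,
                        "practice_id": practice_id,
                        "sex": "M" if rng.random() < 0.511 else "F",
                        "birth_year": birth.year,
                        "birth_quarter": (birth.month - 1) // 3 + 1,
                        "reg_start": reg_start,
                        "reg_end": reg_end,
                    }
                )
                prone = rng.random() < cfg.atopy_prone_fraction
                truth_row = {
                    "patient_id": pid,
                    "birth_date": birth,
                    "reg_start": reg_start,
                    "reg_end": reg_end,
                    "atopy_prone": prone,
                }
                for disorder in self.definitions:
                    onset, remission = self.gen_disease(
                        pid, disorder, birth, reg_start, reg_end, prone
                    )
                    truth_row[f"{disorder}_onset"] = onset
                    truth_row[f"{disorder}_remission"] = remission
                self.gen_background(pid, reg_start, reg_end)
                self.truth.append(truth_row)

    # ---------------- disease process ----------------

    def gen_disease(
        self,
        patient_id: str,
        disorder: str,
        birth: date,
        reg_start: date,
        reg_end: date,
        prone: bool = False,
    ) -> tuple[date | None, date | None]:
        """Simulate one disorder for one child; returns (onset, remission)."""
        cfg, rng = self.cfg, self.rng
        hazards = cfg.incidence_hazards.get(disorder)
        if hazards is None:
            return None, None
        mult = cfg.atopy_hazard_multiplier if prone else 1.0
        onset = None
        for a in range(19):
            if rng.random() < min(hazards[a] * mult, 1.0):
                a_start = birth + timedelta(days=round(a * _YEAR))
                a_end = birth + timedelta(days=round((a + 1) * _YEAR) - 1)
                onset = _uniform_date(rng, a_start, a_end)
                break
        if onset is None or onset > min(reg_end, self.wend):
            return onset, None

        remission = self._draw_remission(disorder, onset)
        self._emit_episode(patient_id, disorder, onset, remission, reg_start, reg_end)

        # recurrence: one possible later episode after observed remission
        obs_end = min(reg_end, self.wend)
        if (
            remission is not None
            and remission < obs_end - timedelta(days=60)
            and rng.random() < cfg.recurrence_probability
        ):
            re_start = _uniform_date(rng, remission + timedelta(days=60), obs_end)
            re_remission = self._draw_remission(disorder, re_start)
            self._emit_episode(
                patient_id, disorder, re_start, re_remission, reg_start, reg_end
            )
        return onset, remission

    def _draw_remission(self, disorder: str, onset: date) -> date | None:
        cfg, rng = self.cfg, self.rng
        h = cfg.remission_hazards.get(disorder, 0.0)
        if h <= 0:
            return None
        for k in range(1, 40):
            if rng.random() < h:
                start = onset + timedelta(days=round((k - 1) * _YEAR) + 1)
                end = onset + timedelta(days=round(k * _YEAR))
                return _uniform_date(rng, start, end)
        return None

    def _emit_episode(
        self,
        patient_id: str,
        disorder: str,
        onset: date,
        remission: date | None,
        reg_start: date,
        reg_end: date,
    ) -> None:
        cfg, rng = self.cfg, self.rng
        definition = self.definitions[disorder]
        recorded_start = max(onset, reg_start)
        obs_end = min(reg_end, self.wend)
        if remission is not None:
            obs_end = min(obs_end, remission)
        if recorded_start > obs_end:
            return
        episode_id = f"ep{self._episode_n:07d}"
        self._episode_n += 1

        # diagnosis consultation plus Poisson follow-up contacts
        contact_dates = [recorded_start]
        dur_years = ((obs_end - recorded_start).days + 1) / _YEAR
        n_extra = int(rng.poisson(cfg.contacts_per_episode_year * dur_years))
        for _ in range(n_extra):
            contact_dates.append(_uniform_date(rng, recorded_start, obs_end))
        contact_dates.sort()

        for i, d in enumerate(contact_dates):
            if i > 0 and rng.random() < cfg.relevant_prescription_probability:
                ev_type = "prescription"
                atc = _sample_atc(rng, str(rng.choice(definition.relevant_atc_prefixes)))
                rx_link = (
                    episode_id
                    if rng.random() >= cfg.unlinked_prescription_fraction
                    else None
                )
                self.rxs.append(
                    {
                        "rx_id": f"rx{self._rx_n:07d}",
                        "patient_id": patient_id,
                        "atc": atc,
                        "date": d,
                        "episode_id": rx_link,
                    }
                )
                self._rx_n += 1
            else:
                ev_type = str(rng.choice(_EVENT_TYPE_POOL, p=_EVENT_TYPE_P))
            self.events.append(
                {
                    "event_id": f"ev{self._event_n:07d}",
                    "patient_id": patient_id,
                    "episode_id": episode_id,
                    "date": d,
                    "type": ev_type,
                }
            )
            self._event_n += 1

        # remission observed within follow-up closes the episode at the
        # last contact date; otherwise the closing date stays empty
        closed = remission is not None and remission <= min(reg_end, self.wend)
        self.episodes.append(
            {
                "episode_id": episode_id,
                "patient_id": patient_id,
                "icpc": definition.icpc_code,
                "start_date": recorded_start,
                "end_date": max(contact_dates) if closed else None,
            }
        )

    # ---------------- background noise ----------------

    def gen_background(self, patient_id: str, reg_start: date, reg_end: date) -> None:
        cfg, rng = self.cfg, self.rng
        obs_start, obs_end = max(reg_start, self.wstart), min(reg_end, self.wend)
        if obs_start > obs_end:
            return
        obs_years = ((obs_end - obs_start).days + 1) / _YEAR
        # unrelated consultations (care-seeking outside atopic episodes)
        if cfg.annual_contact_probability > 0:
            t = obs_start
            while t <= obs_end:
                if rng.random() < cfg.annual_contact_probability:
                    d = _uniform_date(
                        rng, t, min(t + timedelta(days=364), obs_end)
                    )
                    self.events.append(
                        {
                            "event_id": f"ev{self._event_n:07d}",
                            "patient_id": patient_id,
                            "episode_id": None,
                            "date": d,
                            "type": "consultation",
                        }
                    )
                    self._event_n += 1
                t += timedelta(days=365)
        # non-matching prescriptions
        n_irr = int(rng.poisson(cfg.irrelevant_prescription_rate * obs_years))
        for _ in range(n_irr):
            d = _uniform_date(rng, obs_start, obs_end)
            atc = str(rng.choice(_IRRELEVANT_ATC))
            self.rxs.append(
                {
                    "rx_id": f"rx{self._rx_n:07d}",
                    "patient_id": patient_id,
                    "atc": atc,
                    "date": d,
                    "episode_id": None,
                }
            )
            self._rx_n += 1
            self.events.append(
                {
                    "event_id": f"ev{self._event_n:07d}",
                    "patient_id": patient_id,
                    "episode_id": None,
                    "date": d,
                    "type": "prescription",
                }
            )
            self._event_n += 1

    # ---------------- assembly ----------------

    def build(self) -> tuple[EHRDataset, pd.DataFrame]:
        self.gen_practices()
        self.gen_patients()
        tables = {}
        for name, rows in (
            ("practices", self.practices),
            ("patients", self.patients),
            ("episodes", self.episodes),
            ("care_events", self.events),
            ("prescriptions", self.rxs),
        ):
            cols = TABLE_COLUMNS[name]
            df = pd.DataFrame(rows, columns=cols)
            for col in cols:
                if col in ("reg_start", "reg_end", "start_date", "end_date", "date"):
                    df[col] = pd.to_datetime(df[col])
            tables[name] = df
        truth = pd.DataFrame(
            self.truth,
            columns=["patient_id", "birth_date", "reg_start", "reg_end", "atopy_prone"]
            + [f"{d}_{k}" for d in self.definitions for k in ("onset", "remission")],
        )
        for col in truth.columns:
            if col not in ("patient_id", "atopy_prone"):
                truth[col] = pd.to_datetime(truth[col])
        return EHRDataset(**tables), truth


def generate_with_truth(
    config: SimulationConfig | Mapping,
) -> tuple[EHRDataset, pd.DataFrame]:
    """Generate a dataset plus the simulation ground truth.

    The truth table carries the exact birth date and the true per-disorder
    onset/remission dates — information a real registry never has — and is
    meant for calibration checks, never for the analysis pipeline.
    """
    cfg = _coerce_config(config)
    return _Generator(cfg).build()


def generate_population(config: SimulationConfig | Mapping) -> EHRDataset:
    """Generate a synthetic five-table registry extract.

    Deterministic: identical config (including seed) yields identical
    tables, row for row.
    """
    dataset, _ = generate_with_truth(config)
    return dataset
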