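"""Simulation and pipeline configuration models.

Both models are strict (unknown keys rejected) so that a typo in a
configuration file fails loudly instead of silently using a default.
"""

from __future__ import annotations

from datetime import date
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

from .definitions import DISORDERS
from .errors import ConfigurationError

#: Ages (completed years) covered by the analysis.
AGES = tuple(range(19))

DEFAULT_WINDOW = (date(2002, 1, 1), date(2014, 12, 31))


def piecewise_hazard(bands: dict[tuple[int, int], float]) -> dict[int, float]:
    """Expand ``{(lo, hi): h}`` age bands into a full age→hazard map."""
    out: dict[int, float] = {}
    for (lo, hi), h in bands.items():
        for a in range(lo, hi + 1):
            out[a] = h
    return out


def constant_hazard(h: float) -> dict[int, float]:
    return {a: h for a in AGES}


def _default_incidence() -> dict[str, dict[int, float]]:
    # Age profiles shaped after the clinical course of each disorder:
    # eczema front-loaded in infancy, asthma onset mostly pre-school,
    # rhinitis accruing through school age.
    return {
        "eczema": piecewise_hazard({(0, 0): 0.05, (1, 2): 0.04, (3, 6): 0.015,
                                    (7, 12): 0.008, (13, 18): 0.005}),
        "asthma": piecewise_hazard({(0, 4): 0.03, (5, 9): 0.010, (10, 18): 0.004}),
        "rhinitis": piecewise_hazard({(0, 3): 0.002, (4, 10): 0.010, (11, 18): 0.015}),
    }


def _default_remission() -> dict[str, float]:
    # Annual closure hazards; eczema remits most readily, rhinitis least.
    return {"eczema": 0.25, "asthma": 0.15, "rhinitis": 0.08}


class QualityDefectFractions(BaseModel):
    """Fractions of practices violating each registration-quality criterion."""

    model_config = ConfigDict(extra="forbid")

    listed_patients: float = Field(0.0125, ge=0, le=1)
    registration_weeks: float = Field(0.0125, ge=0, le=1)
    coded_fraction: float = Field(0.0125, ge=0, le=1)


class SimulationConfig(BaseModel):
    """Parameters of the synthetic primary-care registry generator.

    Probabilities are per annum unless stated otherwise.  The same
    config plus seed always yields a byte-identical dataset.
    """

    model_config = ConfigDict(extra="forbid")

    n_practices: int = Field(20, ge=0)
    patients_per_practice: int = Field(500, ge=0)
    study_window: tuple[date, date] = DEFAULT_WINDOW
    incidence_hazards: dict[str, dict[int, float]] = Field(
        default_factory=_default_incidence
    )
    remission_hazards: dict[str, float] = Field(default_factory=_default_remission)
    #: Mean number of episode-related contacts per open episode-year.
    contacts_per_episode_year: float = Field(2.5, ge=0)
    #: Probability an episode contact is a dispensing of definition-matching
    #: medication (emitted as a prescription row AND a prescription-type event).
    relevant_prescription_probability: float = Field(0.6, ge=0, le=1)
    #: Poisson rate (per patient-year) of unrelated, non-matching prescriptions.
    irrelevant_prescription_rate: float = Field(0.8, ge=0)
    #: Fraction of relevant prescription rows exported without an episode link.
    unlinked_prescription_fraction: float = Field(0.2, ge=0, le=1)
    #: Probability a child has at least one unrelated GP contact in a year.
    annual_contact_probability: float = Field(0.77, ge=0, le=1)
    quality_defect_fractions: QualityDefectFractions = Field(
        default_factory=QualityDefectFractions
    )
    #: Shared atopic predisposition: a fraction of children carry a latent
    #: frailty that multiplies all three incidence hazards, producing the
    #: excess triple co-occurrence seen in real registries.  Set the
    #: fraction to 0 for fully independent disorders.
    atopy_prone_fraction: float = Field(0.10, ge=0, le=1)
    atopy_hazard_multiplier: float = Field(3.0, ge=0)
    #: Probability a remitted disorder later produces a second recorded episode.
    recurrence_probability: float = Field(0.3, ge=0, le=1)
    #: Fraction of children entering follow-up later than birth/window start.
    late_entry_fraction: float = Field(0.25, ge=0, le=1)
    #: Annual probability a child deregisters (moves to a non-member practice).
    turnover: float = Field(0.03, ge=0, le=1)
    seed: int = 0

    @field_validator("incidence_hazards")
    @classmethod
    def _hazards_cover_all_ages(cls, v):
        for disorder, hazards in v.items():
            missing = [a for a in AGES if a not in hazards]
            if missing:
                raise ValueError(
                    f"incidence_hazards[{disorder!r}] missing ages {missing}"
                )
            bad = {a: h for a, h in hazards.items() if not 0 <= h <= 1}
            if bad:
                raise ValueError(
                    f"incidence_hazards[{disorder!r}] outside [0,1]: {bad}"
                )
        unknown = set(v) - set(DISORDERS)
        if unknown:
            raise ValueError(f"incidence_hazards for unknown disorders {sorted(unknown)}")
        return v

    @field_validator("remission_hazards")
    @classmethod
    def _remission_in_range(cls, v):
        bad = {d: h for d, h in v.items() if not 0 <= h <= 1}
        if bad:
            raise ValueError(f"remission_hazards outside [0,1]: {bad}")
        return v

    @model_validator(mode="after")
    def _window_ordered(self):
        if self.study_window[0] >= self.study_window[1]:
            raise ValueError("study_window start must precede end")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls.model_validate(raw)
        except ValidationError as exc:
            raise ConfigurationError(str(exc)) from exc

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                yaml.safe_load(self.model_dump_json()), fh, sort_keys=False
            )


class PipelineConfig(BaseModel):
    """End-to-end pipeline settings (see the stage modules for semantics)."""

    model_config = ConfigDict(extra="forbid")

    input_dir: Path
    out_dir: Path
    study_window: tuple[date, date] = DEFAULT_WINDOW
    strategies: tuple[int, ...] = (1, 2, 3, 4)
    definitions_path: Optional[Path] = None
    min_followup_days: int = Field(1095, ge=0)
    #: strict: any failing overlapping practice-year excludes the child;
    #: permissive (default): excluded only when every overlapping year fails.
    strict_quality: bool = False
    #: strict: the >=2 episode contacts must be non-prescription events.
    strict_contacts: bool = False
    #: optional +/- day window tying relevant prescriptions to episode dates.
    rx_window_days: Optional[int] = Field(None, ge=0)
    pool_years: bool = True
    remission_ages: tuple[int, ...] = (10, 18)
    seed: Optional[int] = None

    @field_validator("strategies")
    @classmethod
    def _known_strategies(cls, v):
        unknown = [s for s in v if s not in (1, 2, 3, 4)]
        if unknown:
            raise ValueError(f"unknown strategies {unknown}; valid: 1-4")
        return v

    @model_validator(mode="after")
    def _window_ordered(self):
        if self.study_window[0] >= self.study_window[1]:
            raise ValueError("study_window start must precede end")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls.model_validate(raw)
        except ValidationError as exc:
            raise ConfigurationError(str(exc)) from exc
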