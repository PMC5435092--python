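"""Atopic case definitions: ICPC episode codes plus ATC medication proxies.

Each disorder is identified in the EHR by a single ICPC-1 episode code
(S87 atopic eczema, R96 asthma, R97 allergic rhinitis).  Prescription
evidence is matched by ATC prefix, because the accepted proxies mix
3-level (D07, R03, R06) and 5-level (R01AC, R01AD) codes: any dispensed
code whose string starts with a listed prefix counts as relevant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigurationError

#: Lexical shape of an ATC code: anatomical letter, 2-digit therapeutic
#: level, then optional pharmacological letter, chemical letter and
#: 2-digit substance level.
ATC_PATTERN = re.compile(r"^[A-Z]\d{2}([A-Z]([A-Z](\d{2})?)?)?$")

DISORDERS = ("eczema", "asthma", "rhinitis")


@dataclass(frozen=True)
class AtopicDefinition:
    """Case definition for one atopic disorder."""

    disorder: str
    icpc_code: str
    relevant_atc_prefixes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.icpc_code:
            raise ConfigurationError(f"{self.disorder}: empty ICPC code")
        if not self.relevant_atc_prefixes:
            raise ConfigurationError(f"{self.disorder}: no ATC prefixes")
        for prefix in self.relevant_atc_prefixes:
            if not ATC_PATTERN.match(prefix):
                raise ConfigurationError(
                    f"{self.disorder}: ATC prefix {prefix!r} is not a valid "
                    "uppercase ATC string"
                )

    def matches_atc(self, atc: str) -> bool:
        """True if a dispensed ATC code counts as relevant medication."""
        return atc.startswith(self.relevant_atc_prefixes)


def load_definitions(path: str | Path) -> dict[str, AtopicDefinition]:
    """Load a disorder → definition mapping from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping) or not raw:
        raise ConfigurationError(f"{path}: expected a mapping of disorders")
    out: dict[str, AtopicDefinition] = {}
    for disorder, spec in raw.items():
        unknown = set(spec) - {"icpc_code", "relevant_atc_prefixes"}
        if unknown:
            raise ConfigurationError(
                f"{path}: unknown keys {sorted(unknown)} under {disorder!r}"
            )
        out[disorder] = AtopicDefinition(
            disorder=disorder,
            icpc_code=str(spec["icpc_code"]),
            relevant_atc_prefixes=tuple(str(p) for p in spec["relevant_atc_prefixes"]),
        )
    return out


def default_definitions() -> dict[str, AtopicDefinition]:
    """The shipped S87/R96/R97 + D07/R03/R01AC/R01AD/R06 mapping."""
    with resources.as_file(
        resources.files("atopia").joinpath("data/definitions.yaml")
    ) as path:
        return load_definitions(path)


def definition_for(
    disorder: str, definitions: Mapping[str, AtopicDefinition] | None = None
) -> AtopicDefinition:
    definitions = definitions if definitions is not None else default_definitions()
    try:
        return definitions[disorder]
    except KeyError:
        raise ConfigurationError(f"unknown disorder definition: {disorder!r}") from None
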