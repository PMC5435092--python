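"""Period co-occurrence of the atopic disorders and remission contrasts.

Over the whole study period each cohort child either has or does not
have each validated disorder, which partitions the cohort into the
seven non-empty Venn regions over {eczema, asthma, rhinitis} plus the
unaffected remainder.  The triad prevalence expected under independence
is the product of the three marginal period prevalences; the ratio of
observed to expected measures the enrichment of full triple
co-occurrence.

The remission rate at an age contrasts the strategy-4 cumulative
(lifetime) prevalence with the strategy-2 point prevalence: among
children ever validated, the share without a currently open episode,
100 * (cumulative - point) / cumulative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .definitions import DISORDERS
from .errors import InvalidInputError
from .prevalence import TRIAD


def period_case_status(validated: pd.DataFrame, strategy: int) -> dict[str, frozenset]:
    """Per-child disorder sets over the study period for one strategy.

    A disorder belongs to a child's status iff the child has at least
    one validated episode of it; children rejected by the strategy (no
    rows) simply carry an empty set once combined with the cohort.
    """
    v = validated[
        (validated["strategy"] == strategy) & (validated["disorder"] != TRIAD)
    ]
    out: dict[str, set] = {}
    for pid, disorder in zip(v["patient_id"], v["disorder"]):
        out.setdefault(pid, set()).add(disorder)
    return {pid: frozenset(s) for pid, s in out.items()}


_REGIONS = (
    "eczema_only",
    "asthma_only",
    "rhinitis_only",
    "eczema_asthma",
    "eczema_rhinitis",
    "asthma_rhinitis",
    "all_three",
    "none",
)


@dataclass(frozen=True)
class VennCounts:
    """Counts of the 8 regions partitioning the cohort."""

    eczema_only: int
    asthma_only: int
    rhinitis_only: int
    eczema_asthma: int
    eczema_rhinitis: int
    asthma_rhinitis: int
    all_three: int
    none: int

    @property
    def total(self) -> int:
        return sum(getattr(self, r) for r in _REGIONS)

    def marginal(self, disorder: str) -> int:
        """All children with the disorder, regardless of comorbidity."""
        if disorder == "eczema":
            return (
                self.eczema_only
                + self.eczema_asthma
                + self.eczema_rhinitis
                + self.all_three
            )
        if disorder == "asthma":
            return (
                self.asthma_only
                + self.eczema_asthma
                + self.asthma_rhinitis
                + self.all_three
            )
        if disorder == "rhinitis":
            return (
                self.rhinitis_only
                + self.eczema_rhinitis
                + self.asthma_rhinitis
                + self.all_three
            )
        raise InvalidInputError(f"unknown disorder {disorder!r}")

    def as_dict(self) -> dict[str, int]:
        return {r: getattr(self, r) for r in _REGIONS}


def venn_counts(statuses: Iterable[tuple[str, frozenset]] | Mapping[str, frozenset]) -> VennCounts:
    """Tally the Venn regions from per-child disorder sets.

    ``statuses`` maps every cohort child (cases and non-cases alike) to
    its disorder subset; duplicate child ids are rejected.
    """
    items = statuses.items() if isinstance(statuses, Mapping) else list(statuses)
    counts = {r: 0 for r in _REGIONS}
    seen: set[str] = set()
    for pid, status in items:
        if pid in seen:
            raise InvalidInputError(f"duplicate child id {pid!r}")
        seen.add(pid)
        unknown = set(status) - set(DISORDERS)
        if unknown:
            raise InvalidInputError(f"unknown disorders in status: {sorted(unknown)}")
        s = frozenset(status)
        if not s:
            counts["none"] += 1
        elif s == {"eczema"}:
            counts["eczema_only"] += 1
        elif s == {"asthma"}:
            counts["asthma_only"] += 1
        elif s == {"rhinitis"}:
            counts["rhinitis_only"] += 1
        elif s == {"eczema", "asthma"}:
            counts["eczema_asthma"] += 1
        elif s == {"eczema", "rhinitis"}:
            counts["eczema_rhinitis"] += 1
        elif s == {"asthma", "rhinitis"}:
            counts["asthma_rhinitis"] += 1
        else:
            counts["all_three"] += 1
    return VennCounts(**counts)


def expected_by_chance(p_eczema: float, p_asthma: float, p_rhinitis: float) -> float:
    """Triad proportion expected if the three disorders were independent."""
    for name, p in (
        ("p_eczema", p_eczema),
        ("p_asthma", p_asthma),
        ("p_rhinitis", p_rhinitis),
    ):
        if not 0 <= p <= 1:
            raise InvalidInputError(f"{name} must be in [0, 1], got {p}")
    return p_eczema * p_asthma * p_rhinitis


def fold_enrichment(observed: float, expected: float) -> float:
    """Ratio of observed to independence-expected proportion."""
    if expected <= 0:
        raise InvalidInputError("expected proportion must be positive")
    return observed / expected


@dataclass(frozen=True)
class CoOccurrenceStats:
    """Period prevalences and triad enrichment for one cohort."""

    total: int
    prevalence: dict[str, float]  # per-disorder period proportion
    observed_triad: float
    expected_triad: float
    fold: float

    @property
    def fold_rounded(self) -> int:
        return int(math.floor(self.fold + 0.5))


def cooccurrence_stats(venn: VennCounts) -> CoOccurrenceStats:
    """Derive marginals, independence expectation and fold enrichment."""
    total = venn.total
    if total == 0:
        raise InvalidInputError("empty cohort")
    prev = {d: venn.marginal(d) / total for d in DISORDERS}
    observed = venn.all_three / total
    expected = expected_by_chance(prev["eczema"], prev["asthma"], prev["rhinitis"])
    fold = fold_enrichment(observed, expected) if expected > 0 else float("nan")
    return CoOccurrenceStats(
        total=total,
        prevalence=prev,
        observed_triad=observed,
        expected_triad=expected,
        fold=fold,
    )


def remission_rate(point_prevalence: float, cumulative_prevalence: float) -> int:
    """Remission at an age from the strategy-2 vs strategy-4 contrast.

    Both arguments are percentages at the same age: the point prevalence
    of currently open validated episodes and the cumulative prevalence
    of ever-validated children.  Returns the integer percentage of
    ever-diagnosed children with no current disease,
    100 * (cumulative - point) / cumulative.
    """
    if cumulative_prevalence <= 0:
        raise InvalidInputError("cumulative prevalence must be positive")
    if point_prevalence < 0:
        raise InvalidInputError("point prevalence must be non-negative")
    if point_prevalence > cumulative_prevalence:
        raise InvalidInputError(
            "point prevalence exceeds cumulative prevalence "
            "(violates the strategy-ordering invariant)"
        )
    rate = 100.0 * (cumulative_prevalence - point_prevalence) / cumulative_prevalence
    return int(math.floor(rate + 0.5))


def remission_table(
    prevalence_s2: pd.DataFrame,
    prevalence_s4: pd.DataFrame,
    ages: Iterable[int] = (10, 18),
) -> pd.DataFrame:
    """Remission rates per disorder and age from pooled prevalence tables."""
    rows = []
    for age in ages:
        for disorder in DISORDERS:
            s2 = prevalence_s2[
                (prevalence_s2["disorder"] == disorder) & (prevalence_s2["age"] == age)
            ]["percent"]
            s4 = prevalence_s4[
                (prevalence_s4["disorder"] == disorder) & (prevalence_s4["age"] == age)
            ]["percent"]
            if not len(s2) or not len(s4) or pd.isna(s2.iloc[0]) or pd.isna(s4.iloc[0]):
                continue
            point, cumulative = float(s2.iloc[0]), float(s4.iloc[0])
            if cumulative <= 0:
                continue
            rows.append(
                {
                    "disorder": disorder,
                    "age": age,
                    "point_s2": point,
                    "cumulative_s4": cumulative,
                    "remission_percent": remission_rate(point, cumulative),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["disorder", "age", "point_s2", "cumulative_s4", "remission_percent"],
    )
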