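#!/usr/bin/env python
"""Per-age Jan-1 prevalence and cumulative incidence, all four strategies.

Pools numerators and denominators over the thirteen January-1 reference
dates (2002-2014) to one curve per disorder and strategy.  Writes
results/prevalence.csv and one curve figure per disorder under
scratch/figures/.
"""

from pathlib import Path

import pandas as pd

from atopia import point_prevalence, read_dataset, select_children, validate_episodes
from atopia.plots import plot_prevalence_curves

ROOT = Path(__file__).resolve().parents[1]
REGISTRY = ROOT / "scratch" / "registry"
RESULTS = ROOT / "results"
FIGURES = ROOT / "scratch" / "figures"


def main() -> None:
    dataset = read_dataset(REGISTRY)
    selection = select_children(dataset)
    validated = validate_episodes(dataset, selection.included_ids)
    cohort = dataset.patients[
        dataset.patients["patient_id"].isin(selection.included_ids)
    ]
    tables = [point_prevalence(cohort, validated, s) for s in (1, 2, 3, 4)]
    prevalence = pd.concat(tables, ignore_index=True)
    RESULTS.mkdir(exist_ok=True)
    prevalence.to_csv(RESULTS / "prevalence.csv", index=False, float_format="%.2f")

    FIGURES.mkdir(parents=True, exist_ok=True)
    for disorder in sorted(prevalence["disorder"].unique()):
        plot_prevalence_curves(prevalence, disorder, FIGURES / f"{disorder}.png")

    wide = prevalence.pivot_table(
        index=["disorder", "age"], columns="strategy", values="percent"
    )
    for disorder in ("eczema", "asthma", "rhinitis", "triad"):
        sub = wide.loc[disorder]
        print(f"\n{disorder}: prevalence (%) at ages 2 / 7 / 18 by strategy")
        print(sub.loc[[2, 7, 18]].to_string())
    print(f"\nfull table -> {RESULTS / 'prevalence.csv'}; figures -> {FIGURES}")


if __name__ == "__main__":
    main()
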