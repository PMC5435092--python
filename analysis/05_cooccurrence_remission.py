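#!/usr/bin/env python
"""Period co-occurrence of the three disorders and remission contrasts.

Counts the Venn regions of strategy-2 period case status over 2002-2014,
compares the observed triad share with the independence expectation
(product of the marginals), and contrasts strategy-2 point prevalence
with strategy-4 cumulative prevalence at ages 10 and 18 to estimate
remission.  Writes results/comorbidity.csv and results/remission.csv,
and a Venn figure under scratch/figures/.
"""

from pathlib import Path

import pandas as pd

from atopia import (
    period_case_status,
    point_prevalence,
    read_dataset,
    remission_table,
    select_children,
    validate_episodes,
    venn_counts,
)
from atopia.comorbidity import cooccurrence_stats
from atopia.plots import plot_venn

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

    statuses = period_case_status(validated, 2)
    full = {pid: statuses.get(pid, frozenset()) for pid in selection.included_ids}
    venn = venn_counts(full)
    stats = cooccurrence_stats(venn)

    RESULTS.mkdir(exist_ok=True)
    rows = [{"metric": k, "value": v} for k, v in venn.as_dict().items()]
    rows += [
        {"metric": f"marginal_{d}", "value": venn.marginal(d)}
        for d in ("eczema", "asthma", "rhinitis")
    ]
    rows += [
        {"metric": "observed_triad_proportion", "value": round(stats.observed_triad, 6)},
        {"metric": "expected_triad_proportion", "value": round(stats.expected_triad, 6)},
        {"metric": "fold_enrichment", "value": round(stats.fold, 2)},
    ]
    pd.DataFrame(rows).to_csv(RESULTS / "comorbidity.csv", index=False)
    FIGURES.mkdir(parents=True, exist_ok=True)
    plot_venn(venn, FIGURES / "venn.png")

    print(f"cohort of {venn.total} children, strategy-2 period case status:")
    for d in ("eczema", "asthma", "rhinitis"):
        print(f"  {d:9s} {venn.marginal(d):5d} ({100 * stats.prevalence[d]:.1f}%)")
    print(f"  all three {venn.all_three:5d} ({100 * stats.observed_triad:.2f}%)")
    print(f"expected by chance: {100 * stats.expected_triad:.4f}%  "
          f"-> {stats.fold:.1f}-fold enrichment (~{stats.fold_rounded}x)")

    s2 = point_prevalence(cohort, validated, 2)
    s4 = point_prevalence(cohort, validated, 4)
    remission = remission_table(s2, s4, ages=(10, 18))
    remission.to_csv(RESULTS / "remission.csv", index=False, float_format="%.1f")
    print("\nremission (strategy 2 vs 4):")
    print(remission.to_string(index=False))


if __name__ == "__main__":
    main()
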