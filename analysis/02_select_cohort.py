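#!/usr/bin/env python
"""Apply practice-quality criteria and child eligibility; report attrition.

Children must overlap the 2002-2014 window while aged 0-18, sit in a
practice with at least one passing overlapping year (>=500 listed
patients, >=46 registration weeks, >=70% ICPC coding), and have >=1095
days of observed follow-up.  Writes results/attrition.csv.
"""

from pathlib import Path

from atopia import attrition_report, read_dataset, select_children

ROOT = Path(__file__).resolve().parents[1]
REGISTRY = ROOT / "scratch" / "registry"
RESULTS = ROOT / "results"


def main() -> None:
    dataset = read_dataset(REGISTRY)
    selection = select_children(dataset)
    report = attrition_report(selection)
    RESULTS.mkdir(exist_ok=True)
    report.to_csv(RESULTS / "attrition.csv", index=False, float_format="%.1f")
    print(report.to_string(index=False))
    print(f"\ncohort: {selection.final_count} of {selection.eligible_count} "
          f"eligible children -> {RESULTS / 'attrition.csv'}")


if __name__ == "__main__":
    main()
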