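#!/usr/bin/env python
"""Task A: eligibility screening and descriptive cohort tables.

Applies the benchmark exclusion rules (adults, one ICU stay per admission,
length of stay beyond the 48-hour window, at least one observation inside
it) to both simulated cohorts, then writes the demographics/outcome table
and the per-variable missingness profile of each eligible cohort to
results/tables/.

Run analysis/01_simulate_cohorts.py first.
"""

import json
from pathlib import Path

from riskaudit import (
    apply_exclusions,
    demographics_table,
    missingness_profile,
    read_cohort,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    tables = ROOT / "results" / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    for name in ("development", "external"):
        cohort = read_cohort(ROOT / "scratch" / "cohorts" / name, provenance=name)
        eligible, log = apply_exclusions(cohort)
        print(f"{name}: {log.n_input} stays -> {log.n_output} eligible; "
              f"excluded per rule {log.counts}")
        demographics_table(eligible).to_csv(tables / f"demographics_{name}.csv", index=False)
        missingness_profile(eligible).to_csv(tables / f"missingness_{name}.csv", index=False)
        (tables / f"exclusions_{name}.json").write_text(
            json.dumps(log.to_dict(), indent=2) + "\n"
        )
        total = demographics_table(eligible)
        rate = total[total.attribute == "total"].iloc[0].ihm_rate_pct
        print(f"  eligible event rate {rate:.2f}%")


if __name__ == "__main__":
    main()
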