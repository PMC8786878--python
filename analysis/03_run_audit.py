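#!/usr/bin/env python
"""Tasks B-C: the full three-stage audit.

Stage 1 fits the baseline logistic risk model on a split of the
development cohort and audits it internally; stage 2 scores that model on
the external cohort's held-out partition; stage 3 retrains on the external
training partition and audits the same held-out data.  Writes the complete
machine-readable report, a human-readable summary, and a compact
per-stage metric table to results/.

Run analysis/01_simulate_cohorts.py first.
"""

import argparse
from pathlib import Path

import pandas as pd

from riskaudit import (
    BootstrapConfig,
    FrameworkConfig,
    read_cohort,
    render_summary,
    run_framework,
    synthetic_charlson_config,
    write_json,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--bootstrap-k", type=int, default=2_000)
    args = ap.parse_args()

    dev = read_cohort(ROOT / "scratch" / "cohorts" / "development", provenance="development")
    ext = read_cohort(ROOT / "scratch" / "cohorts" / "external", provenance="external")

    cfg = FrameworkConfig(
        bootstrap=BootstrapConfig(n_resamples=args.bootstrap_k, seed=args.seed),
        charlson=synthetic_charlson_config(),
        seed=args.seed,
    )
    report = run_framework(dev, ext, cfg)

    results = ROOT / "results"
    write_json(report, results / "framework_report.json")
    (results / "summary.md").write_text(render_summary(report))

    rows = []
    for stage in report["stages"]:
        for name, est in stage["metric_block"].items():
            rows.append(
                {
                    "stage": stage["stage_id"],
                    "metric": name,
                    "point": est.get("point"),
                    "ci_lo": est.get("ci_lo"),
                    "ci_hi": est.get("ci_hi"),
                    "undefined": bool(est.get("undefined", False)),
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(results / "tables" / "stage_metrics.csv", index=False)
    print(render_summary(report))


if __name__ == "__main__":
    main()
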