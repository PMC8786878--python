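#!/usr/bin/env python
"""Generate the two synthetic study cohorts.

A development-style cohort (large, mostly White, Medicare-heavy, pooled
in-hospital mortality 13.23%) and an external-style cohort (smaller, more
diverse, pooled mortality 10.18%, with pre-admission diagnosis codes).
Cohort CSVs go to scratch/ (they are large); the generator configurations
go to results/ for the record.

Usage: python analysis/01_simulate_cohorts.py [--seed 7]
"""

import argparse
from pathlib import Path

from riskaudit import generate_cohort, mimic_like_config, starr_like_config, write_cohort
from riskaudit._util import stable_seed

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--n-dev", type=int, default=20_000)
    ap.add_argument("--n-ext", type=int, default=6_000)
    args = ap.parse_args()

    out = ROOT / "scratch" / "cohorts"
    cfgdir = ROOT / "results" / "configs"
    cfgdir.mkdir(parents=True, exist_ok=True)

    for name, build, n in (
        ("development", mimic_like_config, args.n_dev),
        ("external", starr_like_config, args.n_ext),
    ):
        cfg = build(n_stays=n, seed=stable_seed(args.seed, name))
        cohort = generate_cohort(cfg)
        write_cohort(cohort, out / name)
        (cfgdir / f"{name}.yaml").write_text(cfg.to_yaml())
        print(
            f"{name}: {len(cohort)} stays, {cohort.n_patients} patients, "
            f"event rate {100 * cohort.event_rate:.2f}%, "
            f"{len(cohort.observations)} observations, "
            f"{len(cohort.diagnoses)} diagnoses -> {out / name}"
        )


if __name__ == "__main__":
    main()
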