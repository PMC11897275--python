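#!/usr/bin/env python
"""End-to-end self-validation on a synthetic victim cohort.

Generates 20 victims with known fm/Fg, runs the coupled DDI engine
against rifampicin (14-day wash-in), recovers each victim's fm by
inverting the analytic clearance-scaling AUCR, and evaluates the
two-fold/Guest pass rates as lognormal observation noise grows.

Writes results/synthetic_recovery.csv and results/noise_pass_rates.csv."""

import argparse
from pathlib import Path

import pandas as pd

from pbpkddi.synthetic_data import SyntheticCohortSpec, generate_victims, recovery_experiment

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--n", type=int, default=20)
    args = parser.parse_args()

    spec = SyntheticCohortSpec(n_victims=args.n, seed=args.seed)
    report = recovery_experiment(spec, noise_gsds=(1.0, 1.5, 2.0, 2.5))
    victims = generate_victims(spec)
    cohort = pd.DataFrame(
        {
            "victim": [v.name for v in victims],
            "fm_true": report.fm_true,
            "fg_true": report.fg_true,
            "aucr_truth": report.aucr_truth,
            "fold_liver_weighted": report.fold_liver,
            "fm_recovered": report.fm_recovered,
        }
    )
    cohort["fm_abs_err"] = (cohort.fm_recovered - cohort.fm_true).abs()
    rates = pd.DataFrame(
        [
            {"noise_gsd": g, **pcts}
            for g, pcts in sorted(report.pass_rates.items())
        ]
    )
    RESULTS.mkdir(exist_ok=True)
    cohort.to_csv(RESULTS / "synthetic_recovery.csv", index=False, float_format="%.5g")
    rates.to_csv(RESULTS / "noise_pass_rates.csv", index=False)
    print(cohort.to_string(index=False))
    print(f"\nmax |fm_recovered - fm_true| = {report.max_fm_error:.4f} "
          f"(n={args.n}, seed={args.seed})")
    print(rates.to_string(index=False))


if __name__ == "__main__":
    main()
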