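#!/usr/bin/env python
"""Epoch-level phenotyping: QC, MVPA detection, timing-group recovery.

Generates full 7-day 5-s traces for a small cohort, runs the complete
phenotyping chain (non-wear detection, same-clock-slot imputation, validity
QC, session/vigorous MVPA, window fractions, nocturnal filter), and reports
how often the planted timing archetype is recovered.
"""

import argparse
from pathlib import Path

from chronoactivity import scenarios
from chronoactivity.pipeline import phenotype_participants
from chronoactivity.simulate import generate_epoch_cohort


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n", type=int, default=200)
    ap.add_argument("--concentration", type=float, default=0.7)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    config = scenarios.epoch_cohort_config(
        n=args.n,
        seed=args.seed,
        concentration=args.concentration,
        nocturnal_outlier_rate=0.05,
    )
    series, truth = generate_epoch_cohort(config, args.n)
    pheno = phenotype_participants(series)
    merged = pheno.merge(truth.table, on="participant_id")
    merged.to_csv(args.out_dir / "epoch_phenotypes.csv", index=False)

    kept = merged["valid_accel"] & merged["nocturnal_keep"].fillna(False)
    recovery = (merged.loc[kept, "timing_group"] == merged.loc[kept, "archetype"]).mean()
    outliers = merged[merged["nocturnal_outlier"]]
    print(f"{args.n} participants; {int(kept.sum())} kept after QC + nocturnal filter")
    print(
        f"archetype recovery at concentration {args.concentration}: {recovery:.1%}"
    )
    print(
        f"nocturnal outliers planted {len(outliers)}, "
        f"filtered {int((~outliers['nocturnal_keep'].astype(bool)).sum())}"
    )
    print(
        "median absolute weekly-MVPA error: "
        f"{(merged['weekly_mvpa_min'] - merged['weekly_mvpa_target']).abs().median():.1f} min/week"
    )


if __name__ == "__main__":
    main()
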