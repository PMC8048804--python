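#!/usr/bin/env python
"""Detect gait events and extract every per-stride parameter from the
simulated trial bundles, mirror right-side inductions to the left-lame
convention, and write the long-format stride table to results/strides.csv.
"""

import argparse
from pathlib import Path

from lamegait.pipeline import extract_cohort
from lamegait.trial_io import read_trial, write_results


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--trials", type=Path, default=Path("scratch/trials"))
    ap.add_argument("--out", type=Path, default=Path("results/strides.csv"))
    args = ap.parse_args()

    bundles = sorted(p for p in args.trials.iterdir() if (p / "metadata.json").exists())
    trials = [read_trial(p) for p in bundles]
    strides = extract_cohort(trials)
    write_results(strides, args.out)
    n = strides.groupby(["gait", "condition"])["stride_index"].count()
    print(f"{len(trials)} trials -> {len(strides)} records ({args.out})")
    print(n.to_string())


if __name__ == "__main__":
    main()
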