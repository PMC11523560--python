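#!/usr/bin/env python
"""Characterize and compare the simulated and synthetic-recorded datasets.

Transfer learning works when source and target datasets are similar, so
this step summarizes both: Tukey boxplot statistics (quartiles, 1.5-IQR
fences, outlier counts) per activation channel and for torque.  The
simulated TRI channel sits at (or near) zero — the minimum-norm solve
recruits no antagonist — while recorded-style TRI carries the co-activation
floor, the one structural difference between the two worlds.

Writes results/distribution_{simulated,recorded}.csv.
"""

import argparse
from pathlib import Path

from fatiguetl.benchmark import (BenchmarkConfig, build_recorded_trials,
                                 build_simulated_trials)
from fatiguetl.evaluation import distribution_summary

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    cfg = BenchmarkConfig()
    sim = build_simulated_trials(cfg, seed=args.seed)
    rec, _ = build_recorded_trials(cfg, seed=args.seed + 1)

    for name, trials in (("simulated", sim), ("recorded", rec)):
        df = distribution_summary(trials)
        df.to_csv(args.out / f"distribution_{name}.csv", index=False)
        torque = df.set_index("channel").loc["torque_Nm"]
        tri = df.set_index("channel").loc["tri"]
        print(f"{name}: torque median {torque['median']:.1f} Nm "
              f"(IQR {torque['q1']:.1f}-{torque['q3']:.1f}), "
              f"TRI median {tri['median']:.3f}, "
              f"TRI outliers {tri['n_outliers']}")


if __name__ == "__main__":
    main()
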