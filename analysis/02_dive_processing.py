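#!/usr/bin/env python
"""Extract dives, trips and time budgets from the simulated TDR records.

Reads results/data/, applies zero-offset correction, the 2 m dive
threshold and wet/dry trip segmentation, and writes dives.csv,
trips.csv and budgets.csv under results/. Prints the stage-level time
budgets the later stages build on.
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

from penguinforage import tdr


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    birds = pd.read_csv(args.data / "birds.csv").set_index("bird_id")
    tdr_df = pd.read_csv(args.data / "tdr.csv")
    all_dives, all_trips, budgets = [], [], []
    for bird_id, g in tdr_df.groupby("bird_id"):
        series = tdr.TDRSeries.from_dataframe(
            g, bird_id=bird_id, stage=birds.loc[bird_id, "stage"]
        )
        corrected = tdr.zero_offset_correct(series)
        dives = tdr.detect_dives(corrected)
        trips = tdr.segment_trips(corrected, dives)
        dives = tdr.assign_dives_to_trips(dives, trips)
        dives["stage"] = series.stage
        all_dives.append(dives)
        all_trips.append(trips)
        budgets.append(dataclasses.asdict(tdr.compute_time_budget(trips, corrected)))

    dives = pd.concat(all_dives, ignore_index=True)
    trips = pd.concat(all_trips, ignore_index=True)
    budgets = pd.DataFrame(budgets)
    args.out.mkdir(parents=True, exist_ok=True)
    dives.to_csv(args.out / "dives.csv", index=False)
    trips.to_csv(args.out / "trips.csv", index=False)
    budgets.to_csv(args.out / "budgets.csv", index=False)

    print(f"{len(dives)} dives on {len(trips)} trips from {len(budgets)} birds")
    for stage, g in budgets.groupby("stage"):
        tr = trips[trips.stage == stage]
        print(
            f"  {stage}: P(at sea) = {g.prop_at_sea.mean():.3f}, "
            f"dive rate = {g.dive_rate_per_h.mean():.2f} h⁻¹, "
            f"trip duration = {tr.duration_min.mean():.0f} min"
        )


if __name__ == "__main__":
    main()
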