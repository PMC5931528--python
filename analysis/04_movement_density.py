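#!/usr/bin/env python
"""Dive locations and foraging-density surfaces.

Fits the CTCRW state-space model to each GPS bird, imputes dive
locations (100 draws per dive), grids them into per-stage dives-per-day
surfaces at 0.005°, maps the chick-rearing minus incubation difference,
and fits the duration→distance regressions. Writes density_*.csv and
distance_regression.csv under results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from penguinforage import movement as mv
from penguinforage.synthetic import COLONY_LONLAT
from penguinforage._rng import child_rng

PAIRS = 390  # breeding pairs at the two focal sub-colonies


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--imputations", type=int, default=100)
    args = ap.parse_args()

    birds = pd.read_csv(args.data / "birds.csv").set_index("bird_id")
    gps = pd.read_csv(args.data / "gps.csv")
    dives = pd.read_csv(args.results / "dives.csv")
    budgets = pd.read_csv(args.results / "budgets.csv")
    x, y = mv.to_planar(gps.lon, gps.lat, COLONY_LONLAT)
    gps["x"], gps["y"] = x, y

    maps = {}
    reg_rows = []
    for stage in sorted(birds.stage.unique()):
        draws_frames = []
        for bird_id, g in gps.groupby("bird_id"):
            if birds.loc[bird_id, "stage"] != stage:
                continue
            usable = g.groupby("trip").filter(lambda t: len(t) >= 4)
            if not len(usable):
                continue
            fit = mv.fit_ctcrw(
                usable, estimate_meas_err=False, meas_err_sd=25.0, origin=COLONY_LONLAT
            )
            bd = dives[(dives.bird_id == bird_id) & (dives.trip_index >= 0)]
            if not len(bd):
                continue
            draws = mv.impute_dive_locations(
                fit, bd.start_s.to_numpy(), n=args.imputations,
                seed=int(child_rng(args.seed, "impute", bird_id).integers(2**31 - 1)),
            )
            draws_frames.append(draws)
            # per-trip distances for the regression
            for trip, t in usable.groupby("trip"):
                dur = (t.time_s.max() - t.time_s.min()) / 60.0
                reg_rows.append(
                    (stage, dur,
                     mv.path_length(t.x, t.y) / 1000.0,
                     mv.max_displacement(t.x, t.y) / 1000.0)
                )
        if draws_frames:
            sb = budgets[budgets.stage == stage]
            dmap = mv.grid_dive_density(
                pd.concat(draws_frames, ignore_index=True),
                prop_at_sea=sb.prop_at_sea.mean(),
                dive_rate_per_h=sb.dive_rate_per_h.mean(),
                pairs=PAIRS, origin=COLONY_LONLAT, stage=stage,
            )
            maps[stage] = dmap
            dmap.to_dataframe().to_csv(args.results / f"density_{stage}.csv", index=False)
            print(
                f"{stage}: {len(dmap.cells)} occupied cells, "
                f"{dmap.total():,.0f} dives/day total, "
                f"max cell {max(dmap.cells.values()):,.0f}"
            )
    if len(maps) == 2:
        diff = mv.density_difference(maps["incubation"], maps["chick-rearing"])
        diff.to_dataframe().to_csv(args.results / "density_difference.csv", index=False)
        pos = sum(v > 0 for v in diff.cells.values())
        print(f"difference map: {pos}/{len(diff.cells)} cells higher in chick-rearing")

    reg = pd.DataFrame(reg_rows, columns=["stage", "duration_min", "total_km", "max_km"])
    out_rows = []
    for response, col in (("total_distance", "total_km"), ("max_distance", "max_km")):
        if len(reg) >= 3 and reg.duration_min.nunique() > 1:
            r = mv.fit_distance_regression(reg.duration_min, reg[col], response=response)
            out_rows.append((response, r.intercept, r.slope, r.fvalue, r.p_value))
            print(f"√{response} = {r.intercept:.2f} + {r.slope:.4f}·t  (F = {r.fvalue:.0f})")
    pd.DataFrame(
        out_rows, columns=["response", "intercept", "slope", "F", "p"]
    ).to_csv(args.results / "distance_regression.csv", index=False)


if __name__ == "__main__":
    main()
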