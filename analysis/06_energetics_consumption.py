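#!/usr/bin/env python
"""Activity-budget energetics and season-scale prey consumption.

Calibrates the affine activity model through the stage (P, DEE) pairs,
evaluates DEE at the estimated time budgets from results/budgets.csv,
and scales adult intake plus chick requirements to the whole-island
season total. Writes energetics.csv under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from penguinforage import energetics as en

CALIBRATION = ((0.162, 405.0), (0.360, 483.0))


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--pairs", type=int, default=1933)
    ap.add_argument("--chicks", type=int, default=1604)
    ap.add_argument("--season-days", type=int, default=137)
    args = ap.parse_args()

    (p1, d1), (p2, d2) = CALIBRATION
    rates = en.derive_activity_rates(p1, d1, p2, d2)
    rows = [("e_land_kJ_kg_day", rates.e_land), ("e_sea_kJ_kg_day", rates.e_sea)]
    print(f"activity rates: ashore {rates.e_land:.1f}, at sea {rates.e_sea:.1f} kJ/kg/day")

    budgets_path = args.results / "budgets.csv"
    if budgets_path.exists():
        budgets = pd.read_csv(budgets_path)
        dees = {}
        for stage, g in budgets.groupby("stage"):
            p = float(g.prop_at_sea.mean())
            dees[stage] = en.dee_from_time_at_sea(p, rates)
            rows.append((f"dee_{stage}", dees[stage]))
            print(f"DEE {stage}: {dees[stage]:.0f} kJ/kg/day (P = {p:.3f})")
        if len(dees) == 2:
            lo, hi = sorted(dees.values())
            print(f"stage increase: {100 * (hi / lo - 1):.0f}%")

    cons = en.colony_consumption(
        en.ColonyParams(pairs=args.pairs, chicks=args.chicks, season_days=args.season_days)
    )
    rows.append(("colony_consumption_t", cons))
    print(f"whole-island consumption over {args.season_days} days: "
          f"{cons:.0f} t (≈{round(cons / 10) * 10:.0f} t)")
    pd.DataFrame(rows, columns=["quantity", "value"]).to_csv(
        args.results / "energetics.csv", index=False
    )


if __name__ == "__main__":
    main()
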