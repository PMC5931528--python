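#!/usr/bin/env python
"""Stage comparisons of behaviour: trip durations, time at sea, dive
depths and dive rates.

Fits the mixed models (with backward selection for the fixed effects),
the stratified-variance dive-depth model with within-trip AR(1)
residuals, and the Poisson dive-rate model with a log-exposure offset.
Writes model_summary.csv and selection_audit.csv under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from penguinforage import models


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    birds = pd.read_csv(args.data / "birds.csv").set_index("bird_id")
    trips = pd.read_csv(args.results / "trips.csv")
    dives = pd.read_csv(args.results / "dives.csv")
    budgets = pd.read_csv(args.results / "budgets.csv")
    rows, audits = [], []

    # trip durations: sqrt transform, individual random intercept,
    # backward selection over stage + mass + gps
    tdata = trips.rename(columns={"duration_min": "duration"}).copy()
    tdata["trip_id"] = tdata.bird_id + "/" + tdata.trip_index.astype(str)
    tdata["mass"] = tdata.bird_id.map(birds.mass_kg)
    tdata["gps"] = tdata.bird_id.map(birds.gps_equipped).astype(str)
    fixed = ["stage", "mass"] + (["gps"] if tdata.gps.nunique() > 1 else [])
    fit, trail = models.backward_select(
        tdata,
        models.ModelSpec(
            response="duration", transform="sqrt", fixed=tuple(fixed), random="individual"
        ),
    )
    trail["model"] = "trip_duration"
    audits.append(trail)
    for stage in sorted(tdata.stage.unique()):
        rows.append(("trip_duration_min", stage, fit.natural_mean(stage=stage)))
    kept = [t for t in fit.params.index if t != "(Intercept)"]
    print(f"trip durations: retained fixed terms {kept or ['(none)']}")

    # proportion of time at sea: arcsine transform, stage-stratified variance
    pfit = models.fit_mixed_model(
        budgets,
        models.ModelSpec(
            response="prop_at_sea", transform="arcsine", fixed=("stage",),
            variance_by_stage=True,
        ),
    )
    p0 = models.fit_mixed_model(
        budgets,
        models.ModelSpec(response="prop_at_sea", transform="arcsine", variance_by_stage=True),
    )
    lr = models.lr_test(pfit, p0)
    for stage in sorted(budgets.stage.unique()):
        rows.append(("prop_at_sea", stage, pfit.natural_mean(stage=stage)))
    print(
        "P(at sea): "
        + ", ".join(
            f"{s} {pfit.natural_mean(stage=s):.3f}" for s in sorted(budgets.stage.unique())
        )
        + f" (stage LR = {lr.statistic:.2f}, p = {lr.p_value:.2g})"
    )

    # dive depths: trip-in-individual random effects, AR(1) within trips,
    # stage-stratified residual variance
    ddata = dives[dives.trip_index >= 0].copy()
    ddata["trip_id"] = ddata.bird_id + "/" + ddata.trip_index.astype(str)
    dfit = models.fit_mixed_model(
        ddata,
        models.ModelSpec(
            response="max_depth_m", fixed=("stage",), random="trip_in_individual",
            ar1_within_trip=True, variance_by_stage=True,
        ),
    )
    for stage in sorted(ddata.stage.unique()):
        rows.append(("mean_dive_depth_m", stage, dfit.natural_mean(stage=stage)))
    rows.append(("dive_depth_ar1_phi", "", dfit.ar1_phi))
    sds = dfit.residual_sd
    if {"incubation", "chick-rearing"} <= set(sds):
        ratio = sds["chick-rearing"] ** 2 / sds["incubation"] ** 2
        rows.append(("dive_depth_variance_ratio", "chick/incubation", ratio))
        print(
            f"dive depths: AR(1) = {dfit.ar1_phi:.2f}, "
            f"chick-rearing variance ratio = {ratio:.2f}"
        )

    # dive rate: Poisson with log trip-hours offset
    pr = models.fit_poisson_rate(trips)
    for stage, rate in pr.rates_per_h.items():
        rows.append(("dive_rate_per_h", stage, rate))
        print(f"dive rate {stage}: {rate:.2f} h⁻¹")

    pd.DataFrame(rows, columns=["quantity", "stage", "value"]).to_csv(
        args.results / "model_summary.csv", index=False
    )
    pd.concat(audits, ignore_index=True).to_csv(
        args.results / "selection_audit.csv", index=False
    )


if __name__ == "__main__":
    main()
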