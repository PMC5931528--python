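"""Config-driven orchestration of the full analysis.

simulate → dive extraction → trips/budgets → stage models → movement &
density → diet models → energetics → report. Each stage writes its
table(s) under the output directory; re-running with the same config and
seed reproduces identical outputs. Stochastic stages draw child streams
from the master seed by stable string keys, so adding a stage never
perturbs earlier streams.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from penguinforage import energetics, isotopes, models, movement, synthetic, tdr
from penguinforage._rng import child_rng, child_seed

__all__ = ["PipelineConfig", "Report", "run_pipeline", "validate_inputs"]

# reported stage calibration pairs for the activity-budget energy model
DEE_CALIBRATION = ((0.162, 405.0), (0.360, 483.0))


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; exactly one of inputs/synthetic."""

    seed: int = 0
    outdir: str = "pipeline_out"
    inputs: dict | None = None  # paths: tdr, gps, isotopes, prey
    synthetic: dict | None = None  # overrides applied onto default_truth
    dive_threshold_m: float = 2.0
    dry_gap_min: float = 10.0
    min_trip_min: float = 30.0
    zoc_window_s: int = 300
    zoc_quantile: float = 0.05
    cell_size_deg: float = 0.005
    n_imputations: int = 100
    tef: float = 2.7
    alpha: float = 0.05
    movement_enabled: bool = True
    mixing_method: str = "grid"
    colony_pairs: int = 390
    consumption: dict = field(
        default_factory=lambda: dict(
            pairs=1933, chicks=1604, adult_intake_kg_day=1.1,
            chick_requirement_kg=60.0, season_days=137,
        )
    )

    def validate(self):
        if (self.inputs is None) == (self.synthetic is None):
            raise ValueError("exactly one of inputs/synthetic must be configured")
        if self.seed is None:
            raise ValueError("seed must be set")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class Report:
    """Pipeline outputs: tidy tables, every number traceable to a stage file."""

    budgets: pd.DataFrame
    trips: pd.DataFrame
    dives: pd.DataFrame
    stage_summary: pd.DataFrame
    model_tests: pd.DataFrame
    mixture_classes: pd.DataFrame
    diet_proportions: pd.DataFrame
    density_summary: pd.DataFrame
    energetics_table: pd.DataFrame


def _build_truth(config: PipelineConfig) -> synthetic.SyntheticTruth:
    truth = synthetic.default_truth(seed=config.seed)
    for key, value in (config.synthetic or {}).items():
        if not hasattr(truth, key):
            raise ValueError(f"unknown synthetic-truth field {key!r}")
        setattr(truth, key, value)
    return truth


def _load_inputs(config: PipelineConfig):
    paths = config.inputs
    birds = pd.read_csv(paths["birds"]) if paths.get("birds") else None
    stage_of = (
        birds.set_index("bird_id")["stage"].to_dict() if birds is not None else {}
    )
    tdr_df = pd.read_csv(paths["tdr"])
    series = {
        bid: tdr.TDRSeries.from_dataframe(g, bird_id=bid, stage=stage_of.get(bid, ""))
        for bid, g in tdr_df.groupby("bird_id")
    }
    gps = {}
    if paths.get("gps"):
        gdf = pd.read_csv(paths["gps"])
        origin = synthetic.COLONY_LONLAT
        x, y = movement.to_planar(gdf["lon"], gdf["lat"], origin)
        gdf["x"], gdf["y"] = x, y
        gps = {bid: g.reset_index(drop=True) for bid, g in gdf.groupby("bird_id")}
    iso = pd.read_csv(paths["isotopes"]) if paths.get("isotopes") else pd.DataFrame()
    prey = pd.read_csv(paths["prey"]) if paths.get("prey") else pd.DataFrame()
    return series, gps, iso, prey, birds


def process_tdr(series_map: dict, config: PipelineConfig):
    """ZOC + dive detection + trip segmentation + budgets for every bird."""
    all_dives, all_trips, budgets = [], [], []
    for bird_id in sorted(series_map):
        series = series_map[bird_id]
        corrected = tdr.zero_offset_correct(
            series, window_s=config.zoc_window_s, quantile=config.zoc_quantile
        )
        dives = tdr.detect_dives(corrected, threshold_m=config.dive_threshold_m)
        trips = tdr.segment_trips(
            corrected, dives, dry_gap_min=config.dry_gap_min, min_trip_min=config.min_trip_min
        )
        dives = tdr.assign_dives_to_trips(dives, trips)
        dives["stage"] = corrected.stage
        budget = tdr.compute_time_budget(trips, corrected)
        budgets.append(dataclasses.asdict(budget))
        all_dives.append(dives)
        all_trips.append(trips)
    return (
        pd.concat(all_dives, ignore_index=True) if all_dives else pd.DataFrame(),
        pd.concat(all_trips, ignore_index=True) if all_trips else pd.DataFrame(),
        pd.DataFrame(budgets),
    )


def run_pipeline(config: PipelineConfig) -> Report:
    """Execute all stages in dependency order and write artifacts."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- data acquisition ---------------------------------------------------
    if config.synthetic is not None:
        truth = _build_truth(config)
        study = synthetic.generate_population(truth)
        series_map, gps_map = study.tdr, study.gps
        iso, prey = study.isotopes, study.prey
        birds = study.birds
    else:
        series_map, gps_map, iso, prey, birds = _load_inputs(config)

    # --- TDR processing -----------------------------------------------------
    dives, trips, budgets = process_tdr(series_map, config)
    stage_of = {bid: s.stage for bid, s in series_map.items()}
    if birds is not None:
        mass = birds.set_index("bird_id")["mass_kg"]
        gps_equipped = birds.set_index("bird_id")["gps_equipped"]
    else:
        mass = gps_equipped = None

    # --- stage-comparison models --------------------------------------------
    tests = []
    stage_rows = []
    if len(trips):
        tdata = trips.rename(columns={"duration_min": "duration"}).copy()
        tdata["trip_id"] = tdata["bird_id"].astype(str) + "/" + tdata["trip_index"].astype(str)
        fixed = ["stage"]
        if mass is not None:
            tdata["mass"] = tdata["bird_id"].map(mass)
            tdata["gps"] = tdata["bird_id"].map(gps_equipped).astype(str)
            fixed.append("mass")
            if tdata["gps"].nunique() > 1:
                fixed.append("gps")
        fixed = tuple(t for t in fixed if tdata[t].nunique() > 1 or t == "mass")
        spec = models.ModelSpec(
            response="duration", transform="sqrt", fixed=fixed, random="individual"
        )
        dur_fit, dur_trail = models.backward_select(tdata, spec, alpha=config.alpha)
        dur_trail["model"] = "trip_duration"
        tests.append(dur_trail)

        rate_fit = models.fit_poisson_rate(trips)
        for stage, r in rate_fit.rates_per_h.items():
            stage_rows.append((stage, "dive_rate_per_h", r))

        ddata = dives[dives["trip_index"] >= 0].copy()
        if len(ddata):
            ddata["trip_id"] = ddata["bird_id"].astype(str) + "/" + ddata["trip_index"].astype(str)
            depth_spec = models.ModelSpec(
                response="max_depth_m",
                fixed=("stage",),
                random="trip_in_individual",
                ar1_within_trip=True,
                variance_by_stage=True,
            )
            depth_fit = models.fit_mixed_model(ddata, depth_spec)
            stage_rows.append(("", "depth_ar1_phi", depth_fit.ar1_phi))
            for stage, sd in depth_fit.residual_sd.items():
                stage_rows.append((stage, "depth_residual_sd_m", sd))
            if {"incubation", "chick-rearing"} <= set(depth_fit.residual_sd):
                ratio = (
                    depth_fit.residual_sd["chick-rearing"] ** 2
                    / depth_fit.residual_sd["incubation"] ** 2
                )
                stage_rows.append(("", "depth_variance_ratio_chick_over_inc", ratio))
            for stage in sorted(ddata["stage"].unique()):
                stage_rows.append(
                    (stage, "mean_dive_depth_m", depth_fit.natural_mean(stage=stage))
                )
        for stage, g in budgets.groupby("stage"):
            stage_rows.append((stage, "prop_at_sea", g["prop_at_sea"].mean()))
            stage_rows.append((stage, "trip_duration_min", trips[trips.stage == stage]["duration_min"].mean()))

    # --- movement & density --------------------------------------------------
    density_rows = []
    if config.movement_enabled and gps_map:
        maps = {}
        for stage in sorted({stage_of[b] for b in gps_map}):
            draws_all = []
            for bird_id in sorted(gps_map):
                if stage_of[bird_id] != stage:
                    continue
                fixes = gps_map[bird_id]
                usable = fixes.groupby("trip").filter(lambda g: len(g) >= 4)
                if not len(usable):
                    continue
                fit = movement.fit_ctcrw(
                    usable, estimate_meas_err=False,
                    meas_err_sd=25.0, origin=synthetic.COLONY_LONLAT,
                )
                bird_dives = dives[(dives.bird_id == bird_id) & (dives.trip_index >= 0)]
                if not len(bird_dives):
                    continue
                draws = movement.impute_dive_locations(
                    fit,
                    bird_dives["start_s"].to_numpy(),
                    n=config.n_imputations,
                    seed=child_seed(config.seed, "impute", bird_id).generate_state(1)[0],
                )
                draws_all.append(draws)
            if draws_all:
                stage_budget = budgets[budgets.stage == stage]
                dmap = movement.grid_dive_density(
                    pd.concat(draws_all, ignore_index=True),
                    prop_at_sea=stage_budget["prop_at_sea"].mean(),
                    dive_rate_per_h=stage_budget["dive_rate_per_h"].mean(),
                    pairs=config.colony_pairs,
                    cell_size=config.cell_size_deg,
                    origin=synthetic.COLONY_LONLAT,
                    stage=stage,
                )
                maps[stage] = dmap
                dmap.to_dataframe().to_csv(outdir / f"density_{stage}.csv", index=False)
                density_rows.append(
                    (stage, len(dmap.cells), dmap.total(), max(dmap.cells.values()))
                )
        if len(maps) == 2:
            a, b = (maps[s] for s in sorted(maps))
            diff = movement.density_difference(a, b)
            diff.to_dataframe().to_csv(outdir / "density_difference.csv", index=False)

    # --- diet ----------------------------------------------------------------
    mixture_df = pd.DataFrame()
    diet_rows = []
    if len(iso):
        gls = models.compare_groups_gls(iso["d15N"], iso["stage"])
        stage_rows.append(("", "d15N_stage_difference", gls.mean_difference))
        stage_rows.append(("", "d15N_variance_ratio", gls.variance_ratio))
        mix = isotopes.fit_mixture_classes(
            iso["d15N"].to_numpy(), seed=child_seed(config.seed, "mixture").generate_state(1)[0]
        )
        mixture_df = pd.DataFrame(
            {
                "bird_id": iso["bird_id"],
                "stage": iso["stage"],
                "d15N": iso["d15N"],
                "mixture_class": mix.assignments,
            }
        )
        if len(prey):
            by_src = prey.groupby("source")["d15N"]
            stats_ = {
                s: isotopes.PreySource(s, g.mean(), g.std(ddof=1), g.size)
                for s, g in by_src
            }
            krill = stats_.get("krill")
            fishes = [v for k, v in stats_.items() if k != "krill"]
            if krill and fishes:
                pooled = fishes[0]
                for other in fishes[1:]:
                    pooled = isotopes.pool_fish_sources(pooled, other)
                groups = {f"stage:{s}": g["d15N"].to_numpy() for s, g in iso.groupby("stage")}
                for k in sorted(mixture_df["mixture_class"].unique()):
                    groups[f"class:{k}"] = mixture_df[mixture_df.mixture_class == k][
                        "d15N"
                    ].to_numpy()
                for name, vals in groups.items():
                    res = isotopes.fit_mixing_model(
                        vals, krill, pooled, tef=config.tef,
                        method=config.mixing_method,
                        seed=int(child_seed(config.seed, "mixing", name).generate_state(1)[0]),
                    )
                    diet_rows.append(
                        (name, len(vals), res.posterior_mean, *res.ci95, res.rhat, res.n_eff)
                    )

    # --- energetics -----------------------------------------------------------
    (p1, d1), (p2, d2) = DEE_CALIBRATION
    rates = energetics.derive_activity_rates(p1, d1, p2, d2)
    energy_rows = [("e_land_kJ_kg_day", rates.e_land), ("e_sea_kJ_kg_day", rates.e_sea)]
    if len(budgets):
        for stage, g in budgets.groupby("stage"):
            p = min(max(g["prop_at_sea"].mean(), 0.0), 1.0)
            energy_rows.append(
                (f"dee_{stage}_kJ_kg_day", energetics.dee_from_time_at_sea(p, rates))
            )
    cons = energetics.colony_consumption(energetics.ColonyParams(**config.consumption))
    energy_rows.append(("colony_consumption_t", cons))

    report = Report(
        budgets=budgets,
        trips=trips,
        dives=dives,
        stage_summary=pd.DataFrame(stage_rows, columns=["stage", "quantity", "value"]),
        model_tests=pd.concat(tests, ignore_index=True) if tests else pd.DataFrame(),
        mixture_classes=mixture_df,
        diet_proportions=pd.DataFrame(
            diet_rows, columns=["group", "n", "p_mean", "ci_low", "ci_high", "rhat", "n_eff"]
        ),
        density_summary=pd.DataFrame(
            density_rows, columns=["stage", "n_cells", "total_dives_per_day", "max_cell"]
        ),
        energetics_table=pd.DataFrame(energy_rows, columns=["quantity", "value"]),
    )
    for name in (
        "budgets", "trips", "dives", "stage_summary", "model_tests",
        "mixture_classes", "diet_proportions", "density_summary", "energetics_table",
    ):
        getattr(report, name).to_csv(outdir / f"{name}.csv", index=False)
    return report


_TDR_COLUMNS = {"bird_id", "timestamp_s", "depth_m"}
_GPS_COLUMNS = {"bird_id", "time_s", "lon", "lat"}


def validate_inputs(paths: dict) -> list:
    """Schema / sanity diagnostics for input CSVs.

    Returns a list of {"level": "error"|"warning", "message": ...}; all
    violations are enumerated, not just the first.
    """
    diags = []
    tdr_birds = set()
    if paths.get("tdr"):
        df = pd.read_csv(paths["tdr"])
        missing = _TDR_COLUMNS - set(df.columns)
        if missing:
            diags.append({"level": "error", "message": f"tdr: missing columns {sorted(missing)}"})
        else:
            tdr_birds = set(df["bird_id"].unique())
            for bid, g in df.groupby("bird_id"):
                ts = g["timestamp_s"].to_numpy()
                bad = np.flatnonzero(np.diff(ts) <= 0)
                if bad.size:
                    diags.append(
                        {
                            "level": "error",
                            "message": f"tdr[{bid}]: non-increasing timestamps at rows {bad[:5].tolist()}",
                        }
                    )
            deep = df[df["depth_m"] > 250]
            if len(deep):
                diags.append(
                    {
                        "level": "warning",
                        "message": f"tdr: {len(deep)} samples deeper than the plausible 250 m range",
                    }
                )
    if paths.get("gps"):
        df = pd.read_csv(paths["gps"])
        missing = _GPS_COLUMNS - set(df.columns)
        if missing:
            diags.append({"level": "error", "message": f"gps: missing columns {sorted(missing)}"})
        else:
            if (df["lat"].abs() > 90).any():
                diags.append({"level": "error", "message": "gps: |lat| > 90"})
            extra = set(df["bird_id"].unique()) - tdr_birds
            if tdr_birds and extra:
                diags.append(
                    {
                        "level": "warning",
                        "message": f"gps: birds without TDR records: {sorted(extra)[:5]}",
                    }
                )
    if paths.get("isotopes"):
        df = pd.read_csv(paths["isotopes"])
        for col in ("bird_id", "stage", "d15N"):
            if col not in df.columns:
                diags.append({"level": "error", "message": f"isotopes: missing column {col}"})
    return diags
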