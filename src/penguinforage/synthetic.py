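"""Seeded synthetic study generator.

Emulates the statistical structure the downstream analyses assume for a
central-place foraging seabird tracked over a breeding season:

* 1 Hz depth/temperature records in which foraging trips (wet, cold)
  alternate with shore bouts (dry, warm); within trips, dives occur at a
  stage-specific hourly rate and successive maximum dive depths follow a
  stationary AR(1) process;
* irregular GPS fixes from a continuous-time correlated random walk
  bridged to start and end at the colony, with Gaussian measurement
  error and optional dropout;
* plasma δ¹⁵N/δ¹³C samples drawn from two latent diet classes (the
  minority, fish-leaning class occurring only during chick-rearing),
  plus morphometrics;
* prey-source isotope samples for krill and two fish species.

Every generator is driven by child streams of a single master seed, so
identical seeds give byte-identical studies. A truth record travels with
each study for parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from penguinforage._rng import child_rng
from penguinforage.movement import simulate_ctcrw_track, to_lonlat
from penguinforage.tdr import TDRSeries

__all__ = [
    "StageParams",
    "DietClassParams",
    "SourceParams",
    "CTCRWConfig",
    "ColonyConfig",
    "SyntheticTruth",
    "SyntheticStudy",
    "default_truth",
    "validate_truth",
    "generate_population",
    "simulate_trip_schedule",
    "simulate_dive_table",
    "simulate_tdr_series",
    "simulate_gps_fixes",
    "simulate_isotopes",
    "simulate_prey_sources",
    "normal_with_exact_moments",
    "write_study",
]

COLONY_LONLAT = (-38.05, -54.01)  # study colony (lon, lat), decimal degrees

STAGES = ("incubation", "chick-rearing")


@dataclass
class StageParams:
    """Breeding-stage behavioural parameters (units in field names)."""

    depth_mean_m: float
    depth_sd_m: float
    ar1_phi: float
    trip_duration_mean_min: float
    trip_duration_sd_min: float
    prop_at_sea: float
    dive_rate_per_h: float
    d13C_mean: float = -20.0
    d13C_sd: float = 0.5


@dataclass
class DietClassParams:
    d15N_mean: float
    d15N_sd: float
    n_birds: int
    depth_shift_m: float = 0.0  # added to dive-depth mean for members


@dataclass
class SourceParams:
    d15N_mean: float
    d15N_sd: float
    n: int
    d13C_mean: float = -20.0
    d13C_sd: float = 0.5


@dataclass
class CTCRWConfig:
    beta_per_s: float = 1.0 / 300.0
    sigma: float = 0.065  # m s⁻¹ · s⁻¹ᐟ²  (stationary speed SD ≈ 0.8 m/s)
    meas_err_sd_m: float = 25.0
    fix_interval_s: float = 180.0
    dropout: float = 0.0


@dataclass
class ColonyConfig:
    pairs: int = 390  # breeding pairs at the two focal sub-colonies (120 + 270)
    chicks: int = 390


@dataclass
class SyntheticTruth:
    """Generating parameters for a synthetic study (the recovery target)."""

    stage_params: dict = field(default_factory=dict)
    class_params: dict = field(default_factory=dict)
    source_params: dict = field(default_factory=dict)
    tef: float = 2.7
    ctcrw: CTCRWConfig = field(default_factory=CTCRWConfig)
    colony: ColonyConfig = field(default_factory=ColonyConfig)
    seed: int = 0
    # cohort sizes / deployment design
    n_birds_per_stage: int = 25
    isotope_n_per_stage: int = 16
    gps_birds: dict = field(default_factory=lambda: {"incubation": 9, "chick-rearing": 12})
    deployment_days: tuple = (4.0, 11.0)
    # dive rendering
    depth_floor_m: float = 2.5
    descent_speed_m_s: float = 1.5
    bottom_time_s: float = 30.0
    # individual/trip heterogeneity in dive depth (metres, SD)
    depth_individual_sd_m: float = 4.0
    depth_trip_sd_m: float = 5.0
    trip_duration_individual_sd_min: float = 15.0
    # sensor artefacts
    surface_offset_max_m: float = 1.5
    surface_offset_change_h: float = 3.0
    depth_noise_sd_m: float = 0.05
    # temperature (wet/dry proxy)
    sea_temp_C: float = 2.0
    land_temp_C: float = 20.0
    temp_noise_sd_C: float = 0.5
    # morphometrics
    mass_mean_kg: float = 6.3
    mass_sd_kg: float = 0.75
    bill_length_mean_mm: float = 53.0
    bill_length_sd_mm: float = 2.5
    bill_depth_mean_mm: float = 16.5
    bill_depth_sd_mm: float = 1.0


def default_truth(seed: int = 0) -> SyntheticTruth:
    """The study-condition defaults (stage, class and source parameters)."""
    return SyntheticTruth(
        stage_params={
            "incubation": StageParams(
                depth_mean_m=36.4,
                depth_sd_m=12.0,
                ar1_phi=0.47,
                trip_duration_mean_min=291.0,
                trip_duration_sd_min=60.0,
                prop_at_sea=0.162,
                dive_rate_per_h=15.39,
                d13C_mean=-20.08,
                d13C_sd=0.44,
            ),
            "chick-rearing": StageParams(
                depth_mean_m=36.4 + 17.7,
                depth_sd_m=12.0 * np.sqrt(1.8),
                ar1_phi=0.47,
                trip_duration_mean_min=291.0 + 25.0,
                trip_duration_sd_min=60.0,
                prop_at_sea=0.360,
                dive_rate_per_h=13.62,
                d13C_mean=-20.24,
                d13C_sd=0.83,
            ),
        },
        class_params={
            "krill": DietClassParams(d15N_mean=9.54, d15N_sd=0.49, n_birds=26),
            "fish": DietClassParams(d15N_mean=11.31, d15N_sd=0.49, n_birds=6, depth_shift_m=10.68),
        },
        source_params={
            "krill": SourceParams(6.55, 0.625, 20, d13C_mean=-20.31, d13C_sd=1.45),
            "icefish": SourceParams(11.03, 1.16, 9, d13C_mean=-20.31, d13C_sd=0.80),
            "notie": SourceParams(11.06, 1.05, 5, d13C_mean=-19.36, d13C_sd=0.38),
        },
        seed=seed,
    )


def validate_truth(truth: SyntheticTruth) -> None:
    """Raise ValueError naming the offending field when invariants fail."""
    for stage, sp in truth.stage_params.items():
        if sp.depth_sd_m <= 0 or sp.trip_duration_sd_min <= 0:
            raise ValueError(f"stage_params[{stage}]: SDs must be > 0")
        if not (0.0 <= sp.prop_at_sea <= 1.0):
            raise ValueError(f"stage_params[{stage}].prop_at_sea must be in [0, 1]")
        if not (0.0 <= sp.ar1_phi < 1.0):
            raise ValueError(f"stage_params[{stage}].ar1_phi must be in [0, 1)")
        if sp.dive_rate_per_h < 0:
            raise ValueError(f"stage_params[{stage}].dive_rate_per_h must be >= 0")
    for name, cp in truth.class_params.items():
        if cp.d15N_sd < 0:
            raise ValueError(f"class_params[{name}].d15N_sd must be >= 0")
        if cp.n_birds < 0:
            raise ValueError(f"class_params[{name}].n_birds must be >= 0")
    for name, srp in truth.source_params.items():
        if srp.d15N_sd <= 0:
            raise ValueError(f"source_params[{name}].d15N_sd must be > 0")
        if srp.n < 0:
            raise ValueError(f"source_params[{name}].n must be >= 0")
    if not np.isfinite(truth.tef):
        raise ValueError("tef must be finite")
    lo, hi = truth.deployment_days
    if not (4.0 <= lo <= hi <= 11.0):
        raise ValueError("deployment_days must lie within [4, 11]")


@dataclass
class SyntheticStudy:
    """A complete generated study plus its truth record."""

    birds: pd.DataFrame
    tdr: dict
    gps: dict
    isotopes: pd.DataFrame
    prey: pd.DataFrame
    truth: SyntheticTruth
    true_trips: pd.DataFrame
    true_dives: pd.DataFrame


# ---------------------------------------------------------------------------
# bout / dive structure
# ---------------------------------------------------------------------------


def simulate_trip_schedule(stage: StageParams, span_s: float, rng) -> list:
    """Alternating shore/at-sea bouts over a deployment.

    Trips are truncated-normal; shore bouts exponential with mean chosen
    so the long-run at-sea fraction equals ``prop_at_sea``. Returns
    (start_s, end_s) pairs, the last possibly clipped at the span.
    """
    p = stage.prop_at_sea
    if p <= 0:
        return []
    trip_mean_s = stage.trip_duration_mean_min * 60.0
    trip_sd_s = stage.trip_duration_sd_min * 60.0
    shore_mean_s = trip_mean_s * (1.0 - p) / p if p < 1 else 0.0
    trips = []
    t = float(rng.exponential(shore_mean_s)) if shore_mean_s > 0 else 0.0
    while t < span_s:
        dur = -1.0
        while dur < 3600.0:  # at least an hour at sea
            dur = float(rng.normal(trip_mean_s, trip_sd_s))
        end = min(t + dur, span_s)
        if end - t >= 1800.0:
            trips.append((t, end))
        t = end + (float(rng.exponential(shore_mean_s)) if shore_mean_s > 0 else 0.0)
    return trips


def _dive_depth_chain(n: int, mean: float, sd: float, phi: float, floor: float, rng):
    """Stationary AR(1) sequence of maximum dive depths, floored."""
    z = rng.standard_normal(n)
    d = np.empty(n)
    if n == 0:
        return d
    d[0] = mean + sd * z[0]
    c = sd * np.sqrt(1.0 - phi * phi)
    for k in range(1, n):
        d[k] = mean + phi * (d[k - 1] - mean) + c * z[k]
    return np.maximum(d, floor)


def simulate_dive_table(
    bird_id: str,
    stage_name: str,
    trips: list,
    truth: SyntheticTruth,
    rng,
    depth_mean_shift: float = 0.0,
) -> pd.DataFrame:
    """Dives for one bird's trips: AR(1) max depths, non-overlapping times.

    Dive count per trip is Poisson at the stage rate; each dive occupies a
    slot so that the trapezoidal profile fits without overlap.
    """
    sp = truth.stage_params[stage_name]
    rows = []
    for trip_index, (t0, t1) in enumerate(trips):
        dur_s = t1 - t0
        n = rng.poisson(sp.dive_rate_per_h * dur_s / 3600.0)
        trip_shift = float(rng.normal(0.0, truth.depth_trip_sd_m))
        if n == 0:
            continue
        depths = _dive_depth_chain(
            n, sp.depth_mean_m + depth_mean_shift + trip_shift, sp.depth_sd_m, sp.ar1_phi,
            truth.depth_floor_m, rng,
        )
        slot = dur_s / n
        for k in range(n):
            d = depths[k]
            dive_dur = 2.0 * d / truth.descent_speed_m_s + truth.bottom_time_s
            dive_dur = min(dive_dur, slot - 4.0)
            if dive_dur < 2.0 * d / truth.descent_speed_m_s:
                # deep dive in a tight slot: keep the depth, drop bottom time
                dive_dur = max(min(slot - 4.0, 2.0 * d / truth.descent_speed_m_s + 2.0), 6.0)
            start = t0 + k * slot + rng.uniform(0.0, max(slot - dive_dur, 1e-6))
            rows.append((bird_id, stage_name, trip_index, start, start + dive_dur, d))
    return pd.DataFrame(
        rows, columns=["bird_id", "stage", "trip_index", "start_s", "end_s", "max_depth_m"]
    )


def _render_depth_trace(n_s: int, dives: pd.DataFrame, truth: SyntheticTruth, rng):
    depth = np.zeros(n_s, dtype=np.float32)
    v = truth.descent_speed_m_s
    for start, end, dmax in dives[["start_s", "end_s", "max_depth_m"]].itertuples(index=False):
        i0, i1 = int(np.ceil(start)), int(np.floor(end))
        if i1 <= i0:
            continue
        tt = np.arange(i0, min(i1 + 1, n_s), dtype=float)
        prof = np.minimum.reduce([v * (tt - start), np.full(tt.size, dmax), v * (end - tt)])
        depth[i0 : i0 + tt.size] = np.maximum(prof, 0.0)
    return depth


def simulate_tdr_series(
    bird_id: str, stage_name: str, truth: SyntheticTruth, rng, span_days: float | None = None,
    depth_mean_shift: float = 0.0,
):
    """One bird's 1 Hz TDR record plus its true trip and dive tables.

    The recorded depth is the true profile plus a piecewise-constant
    surface offset (changing every few hours) and sensor noise; the
    temperature channel is a wet/dry proxy (cold at sea, warm ashore).
    """
    lo, hi = truth.deployment_days
    if span_days is None:
        span_days = float(rng.uniform(lo, hi))
    if not (4.0 <= span_days <= 11.0):
        raise ValueError("deployment span must lie within [4, 11] days")
    sp = truth.stage_params[stage_name]
    span_s = span_days * 86400.0
    n_s = int(span_s)
    # individual-level trip-duration shift; shore-bout mean rescales with it
    # so the expected at-sea fraction stays at the stage value
    if truth.trip_duration_individual_sd_min > 0:
        shift_min = float(rng.normal(0.0, truth.trip_duration_individual_sd_min))
        sp = replace(
            sp, trip_duration_mean_min=max(sp.trip_duration_mean_min + shift_min, 90.0)
        )
    trips = simulate_trip_schedule(sp, span_s, rng)
    dives = simulate_dive_table(bird_id, stage_name, trips, truth, rng, depth_mean_shift)
    depth = _render_depth_trace(n_s, dives, truth, rng)

    # piecewise-constant surface offset + sensor noise
    n_seg = max(int(np.ceil(span_s / (truth.surface_offset_change_h * 3600.0))), 1)
    seg_vals = rng.uniform(-truth.surface_offset_max_m, truth.surface_offset_max_m, n_seg)
    seg_idx = np.minimum(
        (np.arange(n_s) / (truth.surface_offset_change_h * 3600.0)).astype(int), n_seg - 1
    )
    recorded = depth + seg_vals[seg_idx].astype(np.float32)
    recorded += rng.normal(0.0, truth.depth_noise_sd_m, n_s).astype(np.float32)

    at_sea = np.zeros(n_s, dtype=bool)
    for t0, t1 in trips:
        at_sea[int(t0) : int(t1)] = True
    temp = np.where(at_sea, truth.sea_temp_C, truth.land_temp_C).astype(np.float32)
    temp += rng.normal(0.0, truth.temp_noise_sd_C, n_s).astype(np.float32)

    series = TDRSeries(
        bird_id=bird_id,
        timestamps=np.arange(n_s, dtype=np.int64),
        depth=recorded,
        temperature=temp,
        stage=stage_name,
    )
    trips_df = pd.DataFrame(
        [
            (bird_id, stage_name, i, t0, t1, (t1 - t0) / 60.0)
            for i, (t0, t1) in enumerate(trips)
        ],
        columns=["bird_id", "stage", "trip_index", "start_s", "end_s", "duration_min"],
    )
    return series, trips_df, dives


def simulate_gps_fixes(
    trip_start_s: float, trip_end_s: float, truth: SyntheticTruth, rng,
    bird_id: str = "", trip_index: int = 0,
) -> pd.DataFrame:
    """GPS fixes along one trip from the bridged CTCRW, every 180 s.

    Fixes carry Gaussian measurement error; random dropout (never the
    first or last fix) emulates missed surfacing windows.
    """
    dur = trip_end_s - trip_start_s
    if dur <= 0:
        raise ValueError("trip duration must be > 0")
    cw = truth.ctcrw
    times = trip_start_s + np.arange(0.0, dur + 1e-9, cw.fix_interval_s)
    track = simulate_ctcrw_track(
        times, cw.beta_per_s, cw.sigma, cw.meas_err_sd_m, rng, bridge=True
    )
    keep = np.ones(len(track), dtype=bool)
    if cw.dropout > 0:
        keep = rng.random(len(track)) > cw.dropout
        keep[0] = keep[-1] = True
    track = track[keep].reset_index(drop=True)
    lon, lat = to_lonlat(track["x_obs"].to_numpy(), track["y_obs"].to_numpy(), COLONY_LONLAT)
    out = pd.DataFrame(
        {
            "bird_id": bird_id,
            "trip": trip_index,
            "time_s": track["time_s"],
            "x": track["x_obs"],
            "y": track["y_obs"],
            "x_true": track["x"],
            "y_true": track["y"],
            "lon": lon,
            "lat": lat,
        }
    )
    return out


# ---------------------------------------------------------------------------
# isotopes, prey, morphometrics
# ---------------------------------------------------------------------------


def simulate_isotopes(truth: SyntheticTruth, rng=None, n_scale: int = 1) -> pd.DataFrame:
    """Per-class Normal δ¹⁵N draws with stage-specific δ¹³C.

    Class sizes follow the truth (scaled by ``n_scale``); the minority
    class is placed entirely in chick-rearing, the rest fills incubation
    first then chick-rearing.
    """
    if rng is None:
        rng = child_rng(truth.seed, "isotopes")
    rows = []
    classes = dict(truth.class_params)
    n_inc = truth.isotope_n_per_stage * n_scale
    minority = min(classes, key=lambda k: classes[k].n_birds) if len(classes) > 1 else None
    counter = 0
    for name, cp in classes.items():
        n = cp.n_birds * n_scale
        if minority is not None and name == minority:
            stages = ["chick-rearing"] * n
        else:
            stages = ["incubation"] * min(n, n_inc) + ["chick-rearing"] * max(n - n_inc, 0)
        d15 = rng.normal(cp.d15N_mean, cp.d15N_sd, n)
        for k in range(n):
            sp = truth.stage_params.get(stages[k])
            d13 = rng.normal(sp.d13C_mean, sp.d13C_sd) if sp is not None else np.nan
            rows.append((f"iso{counter:03d}", stages[k], name, d15[k], d13, "plasma"))
            counter += 1
    return pd.DataFrame(
        rows, columns=["bird_id", "stage", "diet_class", "d15N", "d13C", "tissue"]
    )


def simulate_prey_sources(truth: SyntheticTruth, rng=None, n_scale: int = 1) -> pd.DataFrame:
    """Normal draws per prey source at the configured sample sizes."""
    if rng is None:
        rng = child_rng(truth.seed, "prey")
    rows = []
    for name, srp in truth.source_params.items():
        n = srp.n * n_scale
        d15 = rng.normal(srp.d15N_mean, srp.d15N_sd, n)
        d13 = rng.normal(srp.d13C_mean, srp.d13C_sd, n)
        rows.extend((name, d15[k], d13[k]) for k in range(n))
    return pd.DataFrame(rows, columns=["source", "d15N", "d13C"])


def normal_with_exact_moments(mean: float, sd: float, n: int, rng) -> np.ndarray:
    """Normal draws affinely standardised to the exact sample mean and SD
    (ddof=1), for reconstructing groups from reported summary statistics."""
    if n < 2:
        raise ValueError("need n >= 2 to fix both moments")
    z = rng.standard_normal(n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------


def generate_population(
    truth: SyntheticTruth,
    include_tdr: bool = True,
    include_gps: bool = True,
    stages=STAGES,
) -> SyntheticStudy:
    """Generate a complete synthetic study from a truth record.

    Per-stage cohorts of ``n_birds_per_stage`` birds with 4–11 day TDR
    deployments; a GPS sub-sample per stage; plasma isotope samples for
    ``isotope_n_per_stage`` birds per stage with the minority diet class
    confined to chick-rearing; prey-source samples; morphometrics.
    """
    validate_truth(truth)
    seed = truth.seed
    classes = dict(truth.class_params)
    minority = min(classes, key=lambda k: classes[k].n_birds) if len(classes) > 1 else None
    majority = max(classes, key=lambda k: classes[k].n_birds) if classes else None

    bird_rows = []
    tdr_map: dict = {}
    gps_map: dict = {}
    all_trips = []
    all_dives = []
    iso_rows = []
    for stage in stages:
        n_birds = truth.n_birds_per_stage
        n_iso = min(truth.isotope_n_per_stage, n_birds)
        n_minority = classes[minority].n_birds if (minority and stage == "chick-rearing") else 0
        n_minority = min(n_minority, n_iso)
        n_gps = min(truth.gps_birds.get(stage, 0), n_birds)
        tag = "inc" if stage == "incubation" else "chk"
        for b in range(n_birds):
            bird_id = f"{tag}{b + 1:02d}"
            rng = child_rng(seed, "bird", stage, b)
            sampled = b < n_iso
            diet_class = minority if (sampled and b < n_minority) else majority
            mass = float(np.clip(rng.normal(truth.mass_mean_kg, truth.mass_sd_kg), 3.5, 9.5))
            bill_l = float(rng.normal(truth.bill_length_mean_mm, truth.bill_length_sd_mm))
            bill_d = float(rng.normal(truth.bill_depth_mean_mm, truth.bill_depth_sd_mm))
            gps_equipped = b < n_gps
            bird_rows.append(
                (bird_id, stage, diet_class, sampled, gps_equipped, mass, bill_l, bill_d)
            )
            shift = classes[diet_class].depth_shift_m if diet_class else 0.0
            shift += float(rng.normal(0.0, truth.depth_individual_sd_m))
            if include_tdr:
                series, trips_df, dives_df = simulate_tdr_series(
                    bird_id, stage, truth, rng, depth_mean_shift=shift
                )
                tdr_map[bird_id] = series
                all_trips.append(trips_df)
                all_dives.append(dives_df)
                if include_gps and gps_equipped:
                    fixes = [
                        simulate_gps_fixes(
                            t0, t1, truth, rng, bird_id=bird_id, trip_index=i
                        )
                        for i, (t0, t1) in enumerate(
                            trips_df[["start_s", "end_s"]].itertuples(index=False)
                        )
                    ]
                    if fixes:
                        gps_map[bird_id] = pd.concat(fixes, ignore_index=True)
            if sampled and diet_class:
                cp = classes[diet_class]
                iso_rng = child_rng(seed, "iso", stage, b)
                sp = truth.stage_params[stage]
                iso_rows.append(
                    (
                        bird_id,
                        stage,
                        diet_class,
                        float(iso_rng.normal(cp.d15N_mean, cp.d15N_sd)),
                        float(iso_rng.normal(sp.d13C_mean, sp.d13C_sd)),
                        "plasma",
                        mass,
                        bill_l,
                        bill_d,
                    )
                )
    birds = pd.DataFrame(
        bird_rows,
        columns=[
            "bird_id", "stage", "diet_class", "isotope_sampled", "gps_equipped",
            "mass_kg", "bill_length_mm", "bill_depth_mm",
        ],
    )
    isotopes = pd.DataFrame(
        iso_rows,
        columns=[
            "bird_id", "stage", "diet_class", "d15N", "d13C", "tissue",
            "mass_kg", "bill_length_mm", "bill_depth_mm",
        ],
    )
    prey = simulate_prey_sources(truth, child_rng(seed, "prey"))
    true_trips = (
        pd.concat(all_trips, ignore_index=True)
        if all_trips
        else pd.DataFrame(columns=["bird_id", "stage", "trip_index", "start_s", "end_s", "duration_min"])
    )
    true_dives = (
        pd.concat(all_dives, ignore_index=True)
        if all_dives
        else pd.DataFrame(columns=["bird_id", "stage", "trip_index", "start_s", "end_s", "max_depth_m"])
    )
    return SyntheticStudy(
        birds=birds,
        tdr=tdr_map,
        gps=gps_map,
        isotopes=isotopes,
        prey=prey,
        truth=truth,
        true_trips=true_trips,
        true_dives=true_dives,
    )


def write_study(study: SyntheticStudy, outdir) -> dict:
    """Write a study to CSV files plus the truth as YAML; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    if study.tdr:
        tdr = pd.concat([s.to_dataframe() for s in study.tdr.values()], ignore_index=True)
        paths["tdr"] = outdir / "tdr.csv"
        tdr.to_csv(paths["tdr"], index=False)
    if study.gps:
        gps = pd.concat(study.gps.values(), ignore_index=True)
        paths["gps"] = outdir / "gps.csv"
        gps[["bird_id", "trip", "time_s", "lon", "lat"]].to_csv(paths["gps"], index=False)
    paths["birds"] = outdir / "birds.csv"
    study.birds.to_csv(paths["birds"], index=False)
    paths["isotopes"] = outdir / "isotopes.csv"
    study.isotopes.to_csv(paths["isotopes"], index=False)
    paths["prey"] = outdir / "prey.csv"
    study.prey.to_csv(paths["prey"], index=False)
    paths["truth"] = outdir / "truth.yaml"

    def _plain(obj):
        if isinstance(obj, dict):
            return {k: _plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_plain(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(_plain(asdict(study.truth)), fh, default_flow_style=False)
    return paths
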