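"""Time-depth-recorder (TDR) processing.

Turns 1 Hz depth records into dives, trips, time budgets and dive rates:

* zero-offset correction — a two-pass running low-quantile filter
  estimates the drifting surface baseline, which is subtracted so 0 m is
  the sea surface;
* dive detection — maximal contiguous runs of samples at or below a
  depth threshold (2 m by default) become dives, each summarised by its
  maximum depth;
* trip segmentation — at-sea bouts identified from the temperature
  (wet/dry proxy) channel, with a dry-gap merge rule replacing the
  manual inspection such records are traditionally segmented by;
* time budgets — proportion of time at sea and dives per at-sea hour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TDRSeries",
    "TimeBudget",
    "zero_offset_correct",
    "detect_dives",
    "segment_trips",
    "assign_dives_to_trips",
    "compute_time_budget",
]


@dataclass
class TDRSeries:
    """One bird's depth record (nominally 1 Hz; positive down, metres)."""

    bird_id: str
    timestamps: np.ndarray  # seconds, strictly increasing
    depth: np.ndarray
    temperature: np.ndarray | None = None
    stage: str = ""
    zoc_applied: bool = field(default=False, repr=False)

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps)
        self.depth = np.asarray(self.depth)  # dtype preserved (float32 storage is fine)
        if self.temperature is not None:
            self.temperature = np.asarray(self.temperature)
        if self.timestamps.size != self.depth.size:
            raise ValueError("timestamps and depth must have equal length")
        if self.timestamps.size < 2:
            raise ValueError("TDR series needs at least 2 samples")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.depth)):
            raise ValueError("depth must be finite")

    @property
    def span_s(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"bird_id": self.bird_id, "timestamp_s": self.timestamps, "depth_m": self.depth}
        )
        if self.temperature is not None:
            out["temp_C"] = self.temperature
        return out

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, bird_id=None, stage="") -> "TDRSeries":
        if bird_id is None:
            bird_id = str(df["bird_id"].iloc[0])
        temp = df["temp_C"].to_numpy() if "temp_C" in df.columns else None
        return cls(
            bird_id=bird_id,
            timestamps=df["timestamp_s"].to_numpy(),
            depth=df["depth_m"].to_numpy(dtype=float),
            temperature=temp,
            stage=stage,
        )


@dataclass
class TimeBudget:
    """Per-bird activity summary: P = proportion of time at sea."""

    bird_id: str
    stage: str
    prop_at_sea: float
    dive_rate_per_h: float
    total_days: float
    n_trips: int = 0
    n_dives: int = 0


def zero_offset_correct(
    series: TDRSeries, window_s: int = 300, quantile: float = 0.05
) -> TDRSeries:
    """Remove the drifting pressure-sensor surface offset.

    Pass 1 takes the ``quantile`` of depth in consecutive ``window_s``
    windows (at the surface most samples sit at the offset, so a low
    quantile tracks it through dive activity); pass 2 smooths the
    window-level baseline with a running median to reject windows that
    fall entirely within dives. The baseline is interpolated back to
    sample resolution and subtracted.
    """
    if window_s < 60:
        raise ValueError("window_s must be >= 60")
    if not (0 < quantile < 0.5):
        raise ValueError("quantile must lie in (0, 0.5)")
    n = series.depth.size
    dt = float(np.median(np.diff(series.timestamps)))
    per_win = max(int(round(window_s / dt)), 2)
    if n < per_win:
        raise ValueError("series shorter than the correction window")
    n_win = n // per_win
    trimmed = series.depth[: n_win * per_win].reshape(n_win, per_win)
    base = np.quantile(trimmed, quantile, axis=1)
    if n_win * per_win < n:  # tail window
        base = np.append(base, np.quantile(series.depth[n_win * per_win :], quantile))
    # pass 2: running median over 5 windows
    k = min(5, base.size if base.size % 2 == 1 else base.size - 1)
    if k >= 3:
        padded = np.pad(base, k // 2, mode="edge")
        base = np.median(np.lib.stride_tricks.sliding_window_view(padded, k), axis=1)
    centers = np.minimum(np.arange(base.size) * per_win + per_win / 2.0, n - 1)
    baseline = np.interp(np.arange(n), centers, base)
    corrected = series.depth - baseline
    return TDRSeries(
        bird_id=series.bird_id,
        timestamps=series.timestamps,
        depth=corrected,
        temperature=series.temperature,
        stage=series.stage,
        zoc_applied=True,
    )


def _runs(mask: np.ndarray):
    """Start/stop index pairs of maximal True runs (stop exclusive)."""
    if mask.size == 0:
        return np.empty((0, 2), dtype=int)
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return np.stack([starts, stops], axis=1)


def detect_dives(series: TDRSeries, threshold_m: float = 2.0) -> pd.DataFrame:
    """Detect dives as maximal runs of samples with depth >= threshold.

    Returns one row per dive: start_s, end_s, duration_s, max_depth_m and
    a boundary flag for dives touching the record edges. Ordered by start
    time.
    """
    mask = series.depth >= threshold_m
    t = series.timestamps
    dt = float(np.median(np.diff(t)))
    rows = []
    for s, e in _runs(mask):
        seg = series.depth[s:e]
        # exclusive end: the dive covers its samples, so a 3-sample dive
        # at 1 Hz lasts 3 s
        end_s = float(t[e]) if e < mask.size else float(t[-1] + dt)
        rows.append(
            (
                series.bird_id,
                float(t[s]),
                end_s,
                end_s - float(t[s]),
                float(seg.max()),
                bool(s == 0 or e == mask.size),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["bird_id", "start_s", "end_s", "duration_s", "max_depth_m", "at_boundary"],
    )


def segment_trips(
    series: TDRSeries,
    dives: pd.DataFrame | None = None,
    dry_gap_min: float = 10.0,
    min_trip_min: float = 30.0,
    wet_temp_C: float = 10.0,
) -> pd.DataFrame:
    """Segment the record into foraging trips (at-sea bouts).

    Wet samples come from the temperature channel (below ``wet_temp_C`` =
    immersed) when present, otherwise from proximity to detected dives.
    Wet runs separated by less than ``dry_gap_min`` are merged; trips
    shorter than ``min_trip_min`` are discarded.
    """
    t = series.timestamps
    if series.temperature is not None:
        wet = series.temperature < wet_temp_C
    elif dives is not None and len(dives) > 0:
        wet = np.zeros(t.size, dtype=bool)
        pad = dry_gap_min * 60.0 / 2.0
        for _, dv in dives.iterrows():
            wet |= (t >= dv.start_s - pad) & (t <= dv.end_s + pad)
    else:
        warnings.warn("no wet/dry information and no dives: returning no trips", stacklevel=2)
        return pd.DataFrame(
            columns=["bird_id", "stage", "trip_index", "start_s", "end_s", "duration_min", "n_dives"]
        )
    runs = _runs(wet)
    # merge runs separated by short dry gaps
    merged = []
    for s, e in runs:
        if merged and (t[s] - t[merged[-1][1] - 1]) < dry_gap_min * 60.0:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    rows = []
    idx = 0
    for s, e in merged:
        dur_min = float(t[e - 1] - t[s]) / 60.0
        if dur_min < min_trip_min:
            continue
        rows.append((series.bird_id, series.stage, idx, float(t[s]), float(t[e - 1]), dur_min, 0))
        idx += 1
    trips = pd.DataFrame(
        rows, columns=["bird_id", "stage", "trip_index", "start_s", "end_s", "duration_min", "n_dives"]
    )
    if dives is not None and len(trips) > 0:
        counts = assign_dives_to_trips(dives, trips)["trip_index"].value_counts()
        trips["n_dives"] = trips["trip_index"].map(counts).fillna(0).astype(int)
    return trips


def assign_dives_to_trips(dives: pd.DataFrame, trips: pd.DataFrame) -> pd.DataFrame:
    """Attach each dive to the trip containing its start (−1 when none)."""
    out = dives.copy()
    trip_idx = np.full(len(dives), -1, dtype=int)
    for _, tr in trips.iterrows():
        inside = (dives["start_s"] >= tr.start_s) & (dives["start_s"] <= tr.end_s)
        trip_idx[inside.to_numpy()] = int(tr.trip_index)
    out["trip_index"] = trip_idx
    return out


def compute_time_budget(trips: pd.DataFrame, series: TDRSeries) -> TimeBudget:
    """P = Σ trip durations / deployment span; rate = Σ dives / Σ trip hours."""
    span = series.span_s
    if span <= 0:
        raise ValueError("zero-length deployment")
    if len(trips) == 0:
        return TimeBudget(series.bird_id, series.stage, 0.0, 0.0, span / 86400.0, 0, 0)
    at_sea_s = float((trips["duration_min"] * 60.0).sum())
    n_dives = int(trips["n_dives"].sum())
    hours = at_sea_s / 3600.0
    return TimeBudget(
        bird_id=series.bird_id,
        stage=series.stage,
        prop_at_sea=at_sea_s / span,
        dive_rate_per_h=n_dives / hours if hours > 0 else 0.0,
        total_days=span / 86400.0,
        n_trips=len(trips),
        n_dives=n_dives,
    )
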