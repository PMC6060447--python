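"""Depth time series: reading, resampling, dive segmentation and summaries.

A dive is a submergence deeper than 1.5 m lasting longer than 10 s; its
start and end are the bracketing 0.1-m depth crossings (found with
sub-sample precision by linear interpolation), and the surface interval is
the time from the current dive back to the previous one. Thresholds are
strict inequalities and configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Dive definition defaults: minimum depth (m), minimum duration (s), and the
#: surface crossing threshold (m) that delimits each submergence.
MIN_DIVE_DEPTH = 1.5
MIN_DIVE_DURATION = 10.0
SURFACE_CROSSING = 0.1


@dataclass(frozen=True)
class DepthSeries:
    """Uniformly sampled depth record (time in s, depth in m >= 0)."""

    time: np.ndarray
    depth: np.ndarray
    sample_rate: float  # Hz

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        d = np.asarray(self.depth, dtype=float)
        if t.ndim != 1 or t.shape != d.shape or t.size < 2:
            raise ValueError("time and depth must be equal-length 1-D arrays (n >= 2)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(d < 0):
            raise ValueError("depth must be non-negative")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "depth", d)

    @property
    def span(self) -> float:
        return float(self.time[-1] - self.time[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "depth_m": self.depth})


@dataclass(frozen=True)
class Dive:
    start_time: float
    end_time: float
    duration_s: float
    max_depth_m: float
    mean_depth_m: float


@dataclass(frozen=True)
class DiveRecord:
    """Segmented dives plus the surface interval preceding each dive."""

    dives: tuple[Dive, ...]
    surface_intervals: tuple[float, ...]  # len = n_dives - 1 (between consecutive dives)
    record_span_s: float

    @property
    def n_dives(self) -> int:
        return len(self.dives)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "start_time_s": d.start_time,
                "end_time_s": d.end_time,
                "duration_s": d.duration_s,
                "max_depth_m": d.max_depth_m,
                "mean_depth_m": d.mean_depth_m,
                "surface_interval_s": (math.nan if i == 0 else self.surface_intervals[i - 1]),
            }
            for i, d in enumerate(self.dives)
        ]
        return pd.DataFrame(rows)


def read_depth_series(
    path,
    time_column: str = "time_s",
    depth_column: str = "depth_m",
    target_hz: float = 1.0,
    negative_tolerance: float = 0.5,
) -> DepthSeries:
    """Read a delimited depth record and return a validated, uniform series.

    Input sampled faster than ``target_hz`` is decimated by block means;
    slower (or irregular) input is linearly interpolated onto the target
    grid. Slightly negative surface readings (>= -``negative_tolerance`` m)
    are clipped to zero with a warning.
    """
    df = pd.read_csv(path)
    for col in (time_column, depth_column):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r} (have {list(df.columns)})")
    t = df[time_column].to_numpy(dtype=float)
    d = df[depth_column].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)) or np.any(~np.isfinite(d)):
        raise ValueError(f"{path}: non-finite values in time/depth")
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    if np.any(d < -negative_tolerance):
        raise ValueError(f"{path}: depths below -{negative_tolerance} m; not a surface artifact")
    if np.any(d < 0):
        log.warning("%s: clipping %d negative depth readings to 0", path, int(np.sum(d < 0)))
        d = np.clip(d, 0.0, None)

    dt_in = np.median(np.diff(t))
    dt_out = 1.0 / target_hz
    if dt_in < dt_out * (1 - 1e-9):
        # decimate by block mean over windows of dt_out
        factor = int(round(dt_out / dt_in))
        n = (len(d) // factor) * factor
        d_out = d[:n].reshape(-1, factor).mean(axis=1)
        t_out = t[:n].reshape(-1, factor)[:, 0]
    elif abs(dt_in - dt_out) <= 1e-9 and np.allclose(np.diff(t), dt_in):
        t_out, d_out = t, d
    else:
        t_out = np.arange(t[0], t[-1] + 1e-9, dt_out)
        d_out = np.interp(t_out, t, d)
    return DepthSeries(time=t_out, depth=np.clip(d_out, 0.0, None), sample_rate=target_hz)


def _crossing_time(t0: float, d0: float, t1: float, d1: float, level: float) -> float:
    """Linear-interpolated time at which depth crosses ``level`` in [t0, t1]."""
    if d1 == d0:
        return t0
    return t0 + (level - d0) * (t1 - t0) / (d1 - d0)


def segment_dives(
    series: DepthSeries,
    min_depth: float = MIN_DIVE_DEPTH,
    min_duration: float = MIN_DIVE_DURATION,
    surface_threshold: float = SURFACE_CROSSING,
) -> DiveRecord:
    """Segment a depth series into dives.

    Each maximal submergence (region with depth > ``surface_threshold``,
    delimited by interpolated crossing times) whose maximum depth exceeds
    ``min_depth`` and whose duration exceeds ``min_duration`` (both strict)
    becomes one dive. Submerged regions separated by a sub-threshold
    excursion shorter than one sample interval are merged (sensor noise).
    """
    t, d = series.time, series.depth
    wet = d > surface_threshold
    if not np.any(wet):
        return DiveRecord(dives=(), surface_intervals=(), record_span_s=series.span)

    # region boundaries in sample indices
    edges = np.flatnonzero(np.diff(wet.astype(np.int8)))
    starts = list(edges[~wet[edges]] + 1) if len(edges) else []
    ends = list(edges[wet[edges]]) if len(edges) else []
    if wet[0]:
        starts.insert(0, 0)
    if wet[-1]:
        ends.append(len(d) - 1)

    # interpolated crossing times per region
    regions: list[tuple[float, float, int, int]] = []  # (t_start, t_end, i_start, i_end)
    for i0, i1 in zip(starts, ends):
        ts = t[i0] if i0 == 0 else _crossing_time(t[i0 - 1], d[i0 - 1], t[i0], d[i0], surface_threshold)
        te = t[i1] if i1 == len(d) - 1 else _crossing_time(t[i1], d[i1], t[i1 + 1], d[i1 + 1], surface_threshold)
        regions.append((ts, te, i0, i1))

    # merge regions split by a sub-threshold blip shorter than one sample
    merged: list[tuple[float, float, int, int]] = []
    min_gap = 1.0 / series.sample_rate
    for reg in regions:
        if merged and reg[0] - merged[-1][1] < min_gap - 1e-12:
            prev = merged[-1]
            merged[-1] = (prev[0], reg[1], prev[2], reg[3])
        else:
            merged.append(reg)

    dives: list[Dive] = []
    for ts, te, i0, i1 in merged:
        seg = d[i0 : i1 + 1]
        duration = te - ts
        if float(seg.max()) > min_depth and duration > min_duration:
            dives.append(
                Dive(
                    start_time=ts,
                    end_time=te,
                    duration_s=duration,
                    max_depth_m=float(seg.max()),
                    mean_depth_m=float(seg.mean()),
                )
            )
    intervals = tuple(
        dives[k].start_time - dives[k - 1].end_time for k in range(1, len(dives))
    )
    return DiveRecord(dives=tuple(dives), surface_intervals=intervals, record_span_s=series.span)


def summarize(record: DiveRecord) -> pd.DataFrame:
    """One-row per-animal summary table (mean +/- sd and min-max semantics).

    Columns follow the conventional dive-record report: counts, dives per
    hour, duration / maximum depth / mean depth / surface interval
    statistics, and counts of dives exceeding 100 m and 200 m. With zero
    dives all statistics are zero and ``empty`` is flagged; with one dive
    the sd is reported as 0 and ``sd_undefined`` flagged.
    """
    n = record.n_dives
    row: dict[str, float | int | bool] = {
        "n_dives": n,
        "empty": n == 0,
        "sd_undefined": n == 1,
        "dives_per_hour": (n / (record.record_span_s / 3600.0)) if record.record_span_s > 0 else 0.0,
    }

    def stats(prefix: str, values: np.ndarray) -> None:
        if values.size == 0:
            row.update({f"{prefix}_{s}": 0.0 for s in ("mean", "sd", "min", "max")})
            return
        row[f"{prefix}_mean"] = float(values.mean())
        row[f"{prefix}_sd"] = float(values.std(ddof=1)) if values.size > 1 else 0.0
        row[f"{prefix}_min"] = float(values.min())
        row[f"{prefix}_max"] = float(values.max())

    durations = np.array([dv.duration_s for dv in record.dives])
    maxdepths = np.array([dv.max_depth_m for dv in record.dives])
    meandepths = np.array([dv.mean_depth_m for dv in record.dives])
    surf = np.array(record.surface_intervals, dtype=float)
    stats("duration_s", durations)
    stats("max_depth_m", maxdepths)
    stats("mean_depth_m", meandepths)
    stats("surface_interval_s", surf)
    row["n_dives_gt_100m"] = int(np.sum(maxdepths > 100.0)) if n else 0
    row["n_dives_gt_200m"] = int(np.sum(maxdepths > 200.0)) if n else 0
    return pd.DataFrame([row])
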