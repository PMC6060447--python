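"""Ecotype-realistic synthetic depth profiles.

The generator emulates the dive statistics of the two study populations so
that every downstream stage is testable without field data:

* coastal (sarasota): short (10-129 s), shallow (<= 10 m) dives;
* offshore (bermuda): a two-mode mixture — a shallow mode (up to ~70 m,
  duration weakly depth-dependent) and a deep mode (>= 100 m, up to 482 m,
  duration increasing steeply with depth, total duration capped at 539 s).

Dives are trapezoids with constant vertical speed (default 2.0 m s^-1,
which makes the deepest printed dive geometrically feasible within the
printed duration cap), interleaved with lognormal surface intervals.
All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import DepthSeries


@dataclass(frozen=True)
class TruncatedLognormal:
    """Lognormal with given (untruncated) mean/sd, resampled into [lo, hi]."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if min(self.mean, self.sd, self.lo) <= 0 or self.hi <= self.lo:
            raise ValueError(f"invalid distribution parameters: {self}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        mu = np.log(self.mean**2 / np.sqrt(self.sd**2 + self.mean**2))
        sigma = np.sqrt(np.log(1.0 + self.sd**2 / self.mean**2))
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.lognormal(mu, sigma, size=max(n - filled, 16))
            ok = draw[(draw > self.lo) & (draw < self.hi)]
            take = min(ok.size, n - filled)
            out[filled : filled + take] = ok[:take]
            filled += take
        return out


@dataclass(frozen=True)
class DiveGeneratorConfig:
    ecotype: str
    duration_dist: TruncatedLognormal          # dive duration, s (shallow mode)
    depth_dist: TruncatedLognormal             # maximum dive depth, m (shallow mode)
    surface_interval_dist: TruncatedLognormal  # s
    deep_mode_weight: float = 0.0              # probability of a deep-mode dive
    deep_depth_dist: TruncatedLognormal | None = None
    deep_bottom_dist: TruncatedLognormal | None = None  # bottom time at depth, s
    max_duration_s: float = 539.0
    vertical_speed: float = 2.0                # m s^-1
    record_span_hours: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.deep_mode_weight <= 1.0):
            raise ValueError("deep_mode_weight must be in [0,1]")
        if self.deep_mode_weight > 0 and (self.deep_depth_dist is None or self.deep_bottom_dist is None):
            raise ValueError("deep mode requires deep_depth_dist and deep_bottom_dist")
        if self.vertical_speed <= 0 or self.record_span_hours <= 0:
            raise ValueError("vertical_speed and record_span_hours must be positive")
        transit = 2.0 * self.depth_dist.hi / self.vertical_speed
        if transit + 2.0 >= self.duration_dist.hi:
            raise ValueError(
                f"infeasible config: deepest shallow-mode dive needs {transit:.0f} s transit "
                f"but the duration cap is {self.duration_dist.hi:.0f} s"
            )


def default_generator_config(ecotype: str, seed: int = 0, record_span_hours: float = 1.0) -> DiveGeneratorConfig:
    """Study-condition defaults per ecotype."""
    if ecotype == "sarasota":
        return DiveGeneratorConfig(
            ecotype="sarasota",
            duration_dist=TruncatedLognormal(mean=35.0, sd=19.0, lo=12.0, hi=129.0),
            depth_dist=TruncatedLognormal(mean=2.5, sd=1.2, lo=1.7, hi=10.0),
            surface_interval_dist=TruncatedLognormal(mean=80.0, sd=100.0, lo=5.0, hi=600.0),
            record_span_hours=record_span_hours,
            seed=seed,
        )
    if ecotype == "bermuda":
        return DiveGeneratorConfig(
            ecotype="bermuda",
            duration_dist=TruncatedLognormal(mean=55.0, sd=35.0, lo=12.0, hi=250.0),
            depth_dist=TruncatedLognormal(mean=8.0, sd=10.0, lo=1.7, hi=70.0),
            surface_interval_dist=TruncatedLognormal(mean=44.0, sd=50.0, lo=5.0, hi=600.0),
            deep_mode_weight=0.15,
            deep_depth_dist=TruncatedLognormal(mean=180.0, sd=80.0, lo=100.0, hi=482.0),
            deep_bottom_dist=TruncatedLognormal(mean=60.0, sd=40.0, lo=10.0, hi=200.0),
            record_span_hours=record_span_hours,
            seed=seed,
        )
    raise ValueError(f"unknown ecotype {ecotype!r}")


def sample_dive(config: DiveGeneratorConfig, rng: np.random.Generator) -> tuple[float, float]:
    """Draw one (max_depth_m, duration_s) pair from the configured mixture."""
    if rng.random() < config.deep_mode_weight:
        depth = float(config.deep_depth_dist.sample(rng, 1)[0])
        transit = 2.0 * depth / config.vertical_speed
        bottom = float(config.deep_bottom_dist.sample(rng, 1)[0])
        duration = min(transit + bottom, config.max_duration_s)
        duration = max(duration, transit + 2.0)  # never thinner than the transit legs
    else:
        depth = float(config.depth_dist.sample(rng, 1)[0])
        transit = 2.0 * depth / config.vertical_speed
        duration = float(config.duration_dist.sample(rng, 1)[0])
        duration = max(duration, transit + 2.0)
    return depth, duration


def generate_dive_plan(config: DiveGeneratorConfig) -> pd.DataFrame:
    """The generator's ground truth: one row per dive with timing and geometry."""
    rng = np.random.default_rng(config.seed)
    span = config.record_span_hours * 3600.0
    rows = []
    t = 10.0  # leading surface padding
    while True:
        depth, duration = sample_dive(config, rng)
        if t + duration + 10.0 > span:
            break
        rows.append({"start_s": t, "duration_s": duration, "max_depth_m": depth})
        t += duration + float(config.surface_interval_dist.sample(rng, 1)[0])
    return pd.DataFrame(rows, columns=["start_s", "duration_s", "max_depth_m"])


def _trapezoid_breakpoints(start: float, depth: float, duration: float, speed: float):
    transit = depth / speed
    bottom = duration - 2.0 * transit
    if bottom < 0:
        raise ValueError(f"infeasible dive geometry: depth {depth} m in {duration} s at {speed} m/s")
    return [(start, 0.0), (start + transit, depth), (start + transit + bottom, depth), (start + duration, 0.0)]


def profile_from_plan(plan: pd.DataFrame, config: DiveGeneratorConfig) -> DepthSeries:
    """Render a dive plan as a 1-Hz trapezoidal depth series."""
    span = config.record_span_hours * 3600.0
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    for row in plan.itertuples():
        points.extend(_trapezoid_breakpoints(row.start_s, row.max_depth_m, row.duration_s, config.vertical_speed))
    points.append((span, 0.0))
    bt = np.array([p[0] for p in points])
    bd = np.array([p[1] for p in points])
    t = np.arange(0.0, span + 1e-9, 1.0)
    return DepthSeries(time=t, depth=np.interp(t, bt, bd), sample_rate=1.0)


def generate_profile(config: DiveGeneratorConfig) -> DepthSeries:
    """Generate a reproducible 1-Hz synthetic depth record."""
    return profile_from_plan(generate_dive_plan(config), config)


def generate_worked_dive(
    shape: str,
    max_depth_m: float,
    duration_s: float,
    vertical_speed: float = 2.0,
    surface_pad_s: float = 60.0,
    sample_rate: float = 1.0,
) -> DepthSeries:
    """Single deterministic dive for worked examples and model experiments.

    ``square`` descends/ascends at the profile's sample resolution (one
    sample ramp); ``trapezoid`` uses constant-speed descent/ascent legs.
    """
    if max_depth_m <= 0 or duration_s <= 0:
        raise ValueError("max_depth_m and duration_s must be positive")
    t0 = surface_pad_s
    if shape == "square":
        points = [(0.0, 0.0), (t0, 0.0), (t0 + 1.0, max_depth_m),
                  (t0 + duration_s - 1.0, max_depth_m), (t0 + duration_s, 0.0)]
    elif shape == "trapezoid":
        points = [(0.0, 0.0)] + _trapezoid_breakpoints(t0, max_depth_m, duration_s, vertical_speed)
    else:
        raise ValueError(f"unknown shape {shape!r}; expected 'square' or 'trapezoid'")
    end = t0 + duration_s + surface_pad_s
    points.append((end, 0.0))
    bt = np.array([p[0] for p in points])
    bd = np.array([p[1] for p in points])
    t = np.arange(0.0, end + 1e-9, 1.0 / sample_rate)
    return DepthSeries(time=t, depth=np.interp(t, bt, bd), sample_rate=sample_rate)
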