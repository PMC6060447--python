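"""End-to-end orchestration: profile -> segmentation -> simulation -> tables.

A run produces a bundle directory with five artifacts plus a metadata
sidecar:

* ``profile.csv``        — the depth series used (written when synthetic)
* ``dives.csv``          — segmented dive table
* ``trajectory.csv``     — simulated tensions/volumes/shunt per output step
* ``end_dive_summary.csv`` — per-dive end-of-dive tensions
* ``o2_stores.csv``      — store breakdown and cADL table
* ``run_metadata.yaml``  — echoed configuration for reproducibility
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import stores
from .kinetics import SolverConfig, end_dive_summary, simulate
from .physio import load_ecotype, validate
from .records import read_depth_series, segment_dives, summarize
from .synthetic import default_generator_config, generate_profile

log = logging.getLogger(__name__)

#: Fixed float format so that identical runs produce byte-identical output.
CSV_FLOAT_FORMAT = "%.6g"

ARTIFACTS = ("dives.csv", "trajectory.csv", "end_dive_summary.csv", "o2_stores.csv", "run_metadata.yaml")


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: exactly one profile source (file or synthetic)."""

    ecotype: str
    output_dir: str | Path
    body_mass: float = 200.0
    profile_path: str | Path | None = None
    synthetic_hours: float | None = None
    seed: int = 0
    solver: SolverConfig = field(default_factory=SolverConfig)
    physiology_overrides: dict | None = None
    compliance_variant: str = "updated_dolphin"

    def __post_init__(self) -> None:
        if (self.profile_path is None) == (self.synthetic_hours is None):
            raise ValueError("exactly one profile source required: profile_path or synthetic_hours")
        if self.profile_path is not None and not Path(self.profile_path).exists():
            raise FileNotFoundError(self.profile_path)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def run_pipeline(config: RunConfig) -> Path:
    """Execute generate/load -> segment -> simulate -> summarize; return bundle dir."""
    t_start = time.perf_counter()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    params = load_ecotype(
        config.ecotype,
        config.body_mass,
        overrides=config.physiology_overrides,
        compliance_variant=config.compliance_variant,
    )
    violations = validate(params)
    if violations:
        raise ValueError(f"[physiology] invalid parameter set: {violations}")

    if config.profile_path is not None:
        log.info("loading profile from %s", config.profile_path)
        profile = read_depth_series(config.profile_path)
    else:
        log.info("generating %.2f h synthetic %s profile (seed %d)", config.synthetic_hours, config.ecotype, config.seed)
        gen = default_generator_config(config.ecotype, seed=config.seed, record_span_hours=config.synthetic_hours)
        profile = generate_profile(gen)
        _write_csv(profile.to_frame(), out / "profile.csv")

    record = segment_dives(profile)
    log.info("segmented %d dives over %.2f h", record.n_dives, record.record_span_s / 3600)
    _write_csv(record.to_frame(), out / "dives.csv")
    _write_csv(summarize(record), out / "dive_summary.csv")

    traj = simulate(profile, params, config.solver)
    _write_csv(traj.to_dataframe(), out / "trajectory.csv")
    _write_csv(end_dive_summary(traj, record), out / "end_dive_summary.csv")

    published = stores.cadl_table(params)
    computed = stores.cadl_table(params, stores.compute_o2_stores(params, config.solver.diving_lung_volume_fraction))
    stores_df = pd.DataFrame([
        {"path": "published", **published},
        {"path": "computed", **computed},
    ])
    _write_csv(stores_df, out / "o2_stores.csv")

    meta = {
        "ecotype": config.ecotype,
        "body_mass_kg": config.body_mass,
        "seed": config.seed,
        "profile_source": str(config.profile_path) if config.profile_path else f"synthetic:{config.synthetic_hours}h",
        "compliance_variant": config.compliance_variant,
        "solver": dataclasses.asdict(config.solver),
        "physiology_overrides": config.physiology_overrides or {},
        "n_dives": record.n_dives,
        "elapsed_s": round(time.perf_counter() - t_start, 3),
    }
    (out / "run_metadata.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    log.info("bundle written to %s", out)
    return out


def compare_ecotypes(bundle_a: str | Path, bundle_b: str | Path) -> pd.DataFrame:
    """Side-by-side store/cADL and end-dive tension comparison of two bundles."""
    frames = []
    for bundle in (bundle_a, bundle_b):
        bundle = Path(bundle)
        for name in ARTIFACTS:
            if not (bundle / name).exists():
                raise ValueError(f"incomplete bundle {bundle}: missing {name}")
        meta = yaml.safe_load((bundle / "run_metadata.yaml").read_text())
        st = pd.read_csv(bundle / "o2_stores.csv")
        published = st[st["path"] == "published"].iloc[0]
        ends = pd.read_csv(bundle / "end_dive_summary.csv")
        row = {
            "ecotype": meta["ecotype"],
            "n_dives": meta["n_dives"],
            "total_o2_store_l": published["total_l"],
            "o2_store_ml_kg": published["mass_specific_ml_kg"],
            "cadl_rest_min": published["cadl_rest_min"],
            "cadl_field_min": published["cadl_field_min"],
            "cadl_field_range_low_min": published["cadl_field_range_low_min"],
            "cadl_field_range_high_min": published["cadl_field_range_high_min"],
        }
        if len(ends):
            row["end_muscle_po2_mean_kpa"] = float(ends["end_muscle_o2_kpa"].mean())
            row["end_venous_pn2_max_kpa"] = float(ends["end_venous_n2_kpa"].max())
            row["n_anaerobic_dives"] = int(ends["anaerobic"].sum())
        frames.append(row)
    return pd.DataFrame(frames)
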