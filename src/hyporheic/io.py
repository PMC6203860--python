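"""Readers and writers for the pipeline's delimited tables.

All formats are plain CSV (comma, UTF-8, ISO-8601 timestamps, "." decimal).
Readers validate hard and report offending line numbers; every table the
pipeline writes can be read back by the functions here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .hydrodynamics import FluxEstimate, SiteClassification, TemperatureSeries

__all__ = [
    "read_sensor_log",
    "write_sensor_log",
    "read_count_table",
    "write_count_table",
    "flux_table",
    "classification_table",
    "PipelineConfig",
    "load_config",
]

KNOWN_GROUPS = ("invertebrate", "ciliate", "flagellate")

FLOAT_FORMAT = "%.10g"


def read_sensor_log(path: str | Path) -> list[TemperatureSeries]:
    """Read a sensor log (site_id, depth_cm, timestamp, temp_c) into series.

    Timestamps must parse as ISO-8601; duplicate (site, depth, timestamp)
    records are a hard error naming the file line.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"site_id", "depth_cm", "timestamp", "temp_c"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    if ts.isna().any():
        line = int(ts.index[ts.isna()][0]) + 2  # header + 1-based
        raise ValueError(f"{path}:{line}: unparseable timestamp "
                         f"{df['timestamp'].iloc[line - 2]!r}")
    df = df.assign(timestamp=ts)
    dup = df.duplicated(subset=["site_id", "depth_cm", "timestamp"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise ValueError(f"{path}:{line}: duplicate (site, depth, timestamp) record")
    out = []
    for (site, depth), grp in df.groupby(["site_id", "depth_cm"], sort=True):
        grp = grp.sort_values("timestamp", kind="mergesort")
        out.append(
            TemperatureSeries(
                site_id=str(site),
                depth_cm=float(depth),
                time=pd.DatetimeIndex(grp["timestamp"]),
                temp_c=grp["temp_c"].to_numpy(dtype=float),
            )
        )
    return out


def write_sensor_log(series: Sequence[TemperatureSeries], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "site_id": s.site_id,
                "depth_cm": s.depth_cm,
                "timestamp": s.time.strftime("%Y-%m-%dT%H:%M:%S"),
                "temp_c": s.temp_c,
            }
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def _parse_layer(value) -> int:
    """Accept a stratum index (0..6) or a depth range like "5-10"."""
    if isinstance(value, str) and "-" in value:
        top, bottom = value.split("-", 1)
        top, bottom = float(top), float(bottom)
        if bottom - top != 5.0 or top % 5.0 != 0.0:
            raise ValueError(f"depth range {value!r} is not a 5-cm stratum")
        return int(top // 5)
    layer = int(value)
    if float(value) != layer:
        raise ValueError(f"layer {value!r} is not an integer stratum index")
    return layer


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read an organism count/measurement table.

    Validates: known group labels, count >= 0, width <= length, positive
    sample volume.  The layer column may hold stratum indices or "top-bottom"
    centimetre ranges.  Unknown taxa are allowed.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {
        "site", "date", "layer", "taxon", "group", "shape_class",
        "length_um", "width_um", "count", "sample_volume_l",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    def fail(mask: pd.Series, message: str) -> None:
        if mask.any():
            line = int(df.index[mask][0]) + 2
            raise ValueError(f"{path}:{line}: {message}")

    fail(~df["group"].isin(KNOWN_GROUPS), "unknown group label")
    fail(df["count"] < 0, "negative count")
    fail(df["width_um"] > df["length_um"], "width exceeds length")
    fail(df["width_um"] <= 0, "non-positive width")
    fail(df["sample_volume_l"] <= 0, "non-positive sample volume")
    df["layer"] = df["layer"].map(_parse_layer)
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    if "condition" not in df.columns:
        df["condition"] = ""
    return df


def write_count_table(measurements: pd.DataFrame, path: str | Path) -> None:
    df = measurements.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def flux_table(estimates: Sequence[FluxEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site": [e.site_id for e in estimates],
            "upper_z_cm": [e.upper_z for e in estimates],
            "lower_z_cm": [e.lower_z for e in estimates],
            "window_start": [e.window_start.strftime("%Y-%m-%d") for e in estimates],
            "amplitude_ratio": [e.amplitude_ratio for e in estimates],
            "velocity_m_day": [e.velocity_v for e in estimates],
            "darcy_flux_m_day": [e.darcy_flux_q for e in estimates],
            "converged": [e.converged for e in estimates],
        }
    )


def classification_table(classifications: Sequence[SiteClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site": [c.site_id for c in classifications],
            "mean_velocity_m_day": [c.mean_velocity for c in classifications],
            "condition": [c.condition for c in classifications],
            "extinction_upper_cm": [
                c.extinction_interval[0] if c.extinction_interval else np.nan
                for c in classifications
            ],
            "extinction_lower_cm": [
                c.extinction_interval[1] if c.extinction_interval else np.nan
                for c in classifications
            ],
            "n_estimates": [c.n_estimates for c in classifications],
        }
    )


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (one YAML file, one seed)."""

    sensor_log: str = ""
    count_table: str = ""
    output_dir: str = "results"
    seed: int = 0
    # hydrodynamics
    kappa_e: float = 0.05
    period_days: float = 1.0
    gamma: float = 1.0
    amplitude_threshold: float = 0.04
    classify_tol: float = 0.01
    # production
    interval_days: float = 7.0
    water_temp_fallback_c: float = 15.0
    # boundary delineation
    alpha: float = 0.05
    n_permutations: int = 1000
    boundary_mode: str = "adjacent"
    # models
    n_draws: int = 5000
    waic_draws: int = 1000
    diversity_family: str = "poisson"
    extra: dict = field(default_factory=dict)


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {k: raw.pop(k) for k in list(raw) if k in PipelineConfig.__dataclass_fields__}
    cfg = PipelineConfig(**known)
    cfg.extra = raw
    return cfg
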