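"""File formats: localization tables, <L> time series, run configs.

All point patterns travel as delimited text with header columns
``x_nm,y_nm[,frame,id]`` — the same dialect across the package — and
time series as ``frame,time_s,mean_L_nm[,sd_L_nm]``.  Run
configurations mirror :class:`~memclust.simulate.SimulationConfig` as
YAML or JSON with explicit validation errors.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .geometry import Box, PointPattern
from .motion import ActinMesh, DisplacementProfile
from .simulate import EnsembleResult, SimulationConfig, TrajectoryRecord

__all__ = [
    "read_localizations",
    "write_localizations",
    "write_labelled_localizations",
    "write_timeseries",
    "read_timeseries",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
    "save_manifest",
]

PathLike = Union[str, Path]


def read_localizations(path: PathLike, box: Optional[Box] = None) -> PointPattern:
    """Read a localization table (columns ``x_nm,y_nm[,frame,id]``).

    When ``box`` is omitted, a box snugly containing the localizations
    (next multiple of 100 nm) is assumed.
    """
    df = pd.read_csv(path)
    for col in ("x_nm", "y_nm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if box is None:
        width = max(100.0, float(np.ceil(df["x_nm"].max() / 100.0) * 100.0))
        height = max(100.0, float(np.ceil(df["y_nm"].max() / 100.0) * 100.0))
        box = Box(width, height)
    return PointPattern.from_xy(df["x_nm"].to_numpy(), df["y_nm"].to_numpy(), box)


def write_localizations(
    path: PathLike, pattern: PointPattern, frame: Optional[int] = None
) -> None:
    """Write a pattern as a localization table (optionally tagging a frame)."""
    df = pd.DataFrame(
        {"x_nm": pattern.positions[:, 0], "y_nm": pattern.positions[:, 1]}
    )
    if frame is not None:
        df["frame"] = frame
    df["id"] = np.arange(pattern.n)
    df.to_csv(path, index=False)


def write_labelled_localizations(
    path: PathLike, pattern: PointPattern, labels: np.ndarray
) -> None:
    """Localization table with a per-molecule ``cluster_id`` column (-1 = noise)."""
    df = pd.DataFrame(
        {
            "x_nm": pattern.positions[:, 0],
            "y_nm": pattern.positions[:, 1],
            "id": np.arange(pattern.n),
            "cluster_id": np.asarray(labels, dtype=int),
        }
    )
    df.to_csv(path, index=False)


def write_timeseries(
    path: PathLike, record_or_ensemble: Union[TrajectoryRecord, EnsembleResult]
) -> None:
    """Write a ``frame,time_s,mean_L_nm[,sd_L_nm]`` series."""
    r = record_or_ensemble
    df = pd.DataFrame(
        {
            "frame": np.arange(r.times.size),
            "time_s": r.times,
            "mean_L_nm": r.l_series if isinstance(r, TrajectoryRecord) else r.mean_l,
        }
    )
    if isinstance(r, EnsembleResult):
        df["sd_L_nm"] = r.sd_l
    df.to_csv(path, index=False)


def read_timeseries(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("time_s", "mean_L_nm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


def config_to_dict(config: SimulationConfig) -> dict:
    d = {
        "box": {"width_nm": config.box.width, "height_nm": config.box.height},
        "n_agents": config.n_agents,
        "dt_ms": config.dt_ms,
        "duration_s": config.duration_s,
        "density_radius_nm": config.density_radius,
        "profile": {
            "family": config.profile.family,
            "d_max_nm_per_ms": config.profile.d_max,
            "d_min_nm_per_ms": config.profile.d_min,
            "l_target_nm": config.profile.l_target,
            "l_anchor_nm": config.profile.l_anchor,
        },
        "step_mode": config.step_mode,
        "seed": config.seed,
        "record_every": config.record_every,
        "update_mode": config.update_mode,
    }
    if config.mesh is not None:
        d["mesh_spacing_nm"] = config.mesh.spacing
    return d


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ValueError(f"config {context}: missing required key {key!r}")
    return mapping[key]


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a validated config from its dict form, with explicit errors."""
    if not isinstance(d, dict):
        raise ValueError(f"config root must be a mapping, got {type(d).__name__}")
    box_d = d.get("box", {})
    box = Box(box_d.get("width_nm", 3000.0), box_d.get("height_nm", 3000.0))
    prof_d = _require(d, "profile", "root")
    profile = DisplacementProfile(
        family=_require(prof_d, "family", "profile"),
        d_max=float(_require(prof_d, "d_max_nm_per_ms", "profile")),
        d_min=float(prof_d.get("d_min_nm_per_ms", 0.0)),
        l_target=float(_require(prof_d, "l_target_nm", "profile")),
        l_anchor=float(prof_d.get("l_anchor_nm", 0.0)),
    )
    mesh = ActinMesh(float(d["mesh_spacing_nm"])) if d.get("mesh_spacing_nm") else None
    return SimulationConfig(
        profile=profile,
        box=box,
        n_agents=int(d.get("n_agents", 2000)),
        dt_ms=float(d.get("dt_ms", 10.0)),
        duration_s=float(d.get("duration_s", 300.0)),
        density_radius=float(d.get("density_radius_nm", 100.0)),
        step_mode=d.get("step_mode", "fixed"),
        mesh=mesh,
        seed=int(d.get("seed", 0)),
        record_every=d.get("record_every", 100),
        update_mode=d.get("update_mode", "synchronous"),
    )


def load_config(path: PathLike) -> SimulationConfig:
    """Load a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return config_from_dict(data)


def save_config(path: PathLike, config: SimulationConfig) -> None:
    path = Path(path)
    d = config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def save_manifest(path: PathLike, config: SimulationConfig, seeds, extra: dict | None = None) -> None:
    """Run manifest: config echo plus the replicate seeds actually used."""
    d = {"config": config_to_dict(config), "seeds": [int(s) for s in seeds]}
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=2))
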