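"""Serialization of sites, plans, toolpaths and measurements.

Formats: meshes as STL (or PLY), point lists and waypoint tables as CSV with
explicit headers (mm, '.' decimal separator), structured metadata as
versioned JSON.  All round trips are lossless to full float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import CompositePath, SurfaceMesh, Trajectory
from .planner import ChannelPlan, PlanParams, PlaneFrame
from .site import ForbiddenStructure, Polyline, Pose, SurgicalSite
from .toolpath import ToolPath, WideningSpec

SCHEMA_VERSION = 1

__all__ = [
    "save_site", "load_site",
    "save_plan", "load_plan",
    "save_toolpath", "load_toolpath",
    "save_measurement",
]


def _require(d: dict, key: str, context: str):
    if key not in d:
        raise ValueError(f"malformed {context}: missing field {key!r}")
    return d[key]


# --- sites -----------------------------------------------------------------


def save_site(site: SurgicalSite, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    site.outer.save(directory / "outer.stl")
    site.inner.save(directory / "inner.stl")
    payload = {
        "schema_version": SCHEMA_VERSION,
        "fiducials": site.fiducials.tolist(),
        "tripod_pose": site.tripod_pose.to_dict(),
        "fantail_pose": site.fantail_pose.to_dict(),
        "fantail_points": site.fantail_points.tolist(),
        "incision": site.incision.to_dict(),
        "trajectory": site.trajectory.to_dict(),
        "forbidden": [f.to_dict() for f in site.forbidden],
        "air_cells": site.air_cells.tolist(),
        "meta": site.meta,
    }
    (directory / "site.json").write_text(json.dumps(payload, indent=1))
    return directory


def load_site(directory) -> SurgicalSite:
    directory = Path(directory)
    d = json.loads((directory / "site.json").read_text())
    return SurgicalSite(
        outer=SurfaceMesh.load(directory / "outer.stl"),
        inner=SurfaceMesh.load(directory / "inner.stl"),
        fiducials=np.asarray(_require(d, "fiducials", "site.json")),
        tripod_pose=Pose.from_dict(_require(d, "tripod_pose", "site.json")),
        fantail_pose=Pose.from_dict(_require(d, "fantail_pose", "site.json")),
        fantail_points=np.asarray(_require(d, "fantail_points", "site.json")),
        incision=Polyline(np.asarray(_require(d, "incision", "site.json")["points"])),
        trajectory=Trajectory.from_dict(_require(d, "trajectory", "site.json")),
        forbidden=[
            ForbiddenStructure(f["name"], np.asarray(f["points"]), f.get("radius", 0.0))
            for f in d.get("forbidden", [])
        ],
        air_cells=np.asarray(d.get("air_cells", [])).reshape(-1, 4),
        meta=d.get("meta", {}),
    )


# --- plans -----------------------------------------------------------------


def save_plan(plan: ChannelPlan, path) -> Path:
    path = Path(path)
    payload = {
        "schema_version": SCHEMA_VERSION,
        "frame": plan.frame.to_dict(),
        "path2d": plan.path2d.to_dict(),
        "s": plan.s.tolist(),
        "surface_points": plan.surface_points.tolist(),
        "bottom_points": plan.bottom_points.tolist(),
        "tool_axes": plan.tool_axes.tolist(),
        "params": plan.params.to_dict(),
        "flags": plan.flags,
        "thin_intervals": plan.thin_intervals,
        "widening": plan.widening.to_dict() if plan.widening is not None else None,
    }
    path.write_text(json.dumps(payload))
    return path


def load_plan(path) -> ChannelPlan:
    d = json.loads(Path(path).read_text())
    plan = ChannelPlan(
        frame=PlaneFrame.from_dict(_require(d, "frame", "plan.json")),
        path2d=CompositePath.from_dict(_require(d, "path2d", "plan.json")),
        s=np.asarray(_require(d, "s", "plan.json")),
        surface_points=np.asarray(_require(d, "surface_points", "plan.json")),
        bottom_points=np.asarray(_require(d, "bottom_points", "plan.json")),
        tool_axes=np.asarray(_require(d, "tool_axes", "plan.json")),
        params=PlanParams.from_dict(_require(d, "params", "plan.json")),
        flags=d.get("flags", {}),
        thin_intervals=[tuple(t) for t in d.get("thin_intervals", [])],
    )
    if d.get("widening") is not None:
        plan.widening = WideningSpec.from_dict(d["widening"])
    return plan


# --- toolpaths -------------------------------------------------------------


def save_toolpath(tp: ToolPath, csv_path, header_path=None) -> Path:
    csv_path = Path(csv_path)
    df = pd.DataFrame(
        {
            "x": tp.positions[:, 0], "y": tp.positions[:, 1], "z": tp.positions[:, 2],
            "ax": tp.axes[:, 0], "ay": tp.axes[:, 1], "az": tp.axes[:, 2],
            "phase": tp.phases, "feed": tp.feeds,
        }
    )
    df.to_csv(csv_path, index=False, float_format="%.17g")
    header_path = Path(header_path) if header_path else csv_path.with_suffix(".json")
    header_path.write_text(
        json.dumps(
            {
                "schema_version": SCHEMA_VERSION,
                "tool_diameter": tp.tool_diameter,
                "spindle_rpm": tp.spindle_rpm,
            }
        )
    )
    return csv_path


def load_toolpath(csv_path, header_path=None) -> ToolPath:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, float_precision="round_trip")
    for col in ("x", "y", "z", "ax", "ay", "az", "phase", "feed"):
        if col not in df.columns:
            raise ValueError(f"malformed toolpath CSV: missing field {col!r}")
    header_path = Path(header_path) if header_path else csv_path.with_suffix(".json")
    hdr = json.loads(header_path.read_text())
    return ToolPath(
        df[["x", "y", "z"]].to_numpy(),
        df[["ax", "ay", "az"]].to_numpy(),
        df["phase"].to_numpy(dtype=str),
        df["feed"].to_numpy(),
        tool_diameter=_require(hdr, "tool_diameter", "toolpath header"),
        spindle_rpm=_require(hdr, "spindle_rpm", "toolpath header"),
    )


# --- measurements ----------------------------------------------------------


def save_measurement(meas, csv_path, summary_path=None) -> Path:
    csv_path = Path(csv_path)
    pd.DataFrame(
        {
            "s": meas.s, "LD": meas.ld, "DD": meas.dd,
            "CW": meas.cw, "CD": meas.cd, "missing": meas.missing.astype(int),
        }
    ).to_csv(csv_path, index=False, float_format="%.17g")
    if summary_path is not None:
        Path(summary_path).write_text(json.dumps(meas.summary, indent=1))
    return csv_path
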