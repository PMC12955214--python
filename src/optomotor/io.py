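"""Delimited-text input/output for marker tables and trajectories.

Marker tables are tab-separated with one row per digitized marker:
``ommatidium_id, marker_role, x, y, z`` (um), where ``marker_role`` is
one of ``outer_tip``, ``inner_tip``, ``base1``..``base6``,
``rhabdomere`` or, for the head-frame rows (``ommatidium_id = head``),
``ocellus1``..``ocellus3``.  Trajectories are tab-separated
``t_s, x_mm, y_mm`` tables; stimulus descriptors and generator ground
truth travel in YAML sidecar files.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .behavior import StimulusCondition, Trajectory
from .eye_geometry import LensMarkerSet

__all__ = [
    "write_marker_table",
    "read_marker_table",
    "write_trajectory",
    "read_trajectory",
    "write_sidecar",
    "read_sidecar",
]

_HEAD_ID = "head"


def write_marker_table(
    path, marker_sets: List[LensMarkerSet], ocelli: Optional[np.ndarray] = None
) -> None:
    """Write marker sets (and optional ocelli rows) as a TSV table."""
    rows = []
    if ocelli is not None:
        for k, p in enumerate(np.asarray(ocelli, dtype=float)):
            rows.append((_HEAD_ID, f"ocellus{k + 1}", *p))
    for m in marker_sets:
        rows.append((m.ommatidium_id, "outer_tip", *m.outer_tip))
        rows.append((m.ommatidium_id, "inner_tip", *m.inner_tip))
        for k, p in enumerate(m.base_points):
            rows.append((m.ommatidium_id, f"base{k + 1}", *p))
        rows.append((m.ommatidium_id, "rhabdomere", *m.rhabdomere_tip))
    table = pd.DataFrame(rows, columns=["ommatidium_id", "marker_role", "x", "y", "z"])
    table.to_csv(path, sep="\t", index=False)


def read_marker_table(path) -> Tuple[Optional[np.ndarray], List[LensMarkerSet]]:
    """Read a marker TSV back into (ocelli or None, marker sets)."""
    table = pd.read_csv(path, sep="\t", dtype={"ommatidium_id": str})
    required = {"ommatidium_id", "marker_role", "x", "y", "z"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"marker table missing columns: {sorted(missing)}")

    ocelli = None
    head = table[table["ommatidium_id"] == _HEAD_ID]
    if not head.empty:
        head = head.set_index("marker_role")
        ocelli = np.array(
            [head.loc[f"ocellus{k + 1}", ["x", "y", "z"]].to_numpy(float) for k in range(3)]
        )

    marker_sets = []
    body = table[table["ommatidium_id"] != _HEAD_ID]
    for omm_id, group in body.groupby("ommatidium_id", sort=True):
        g = group.set_index("marker_role")
        try:
            base = np.array(
                [g.loc[f"base{k + 1}", ["x", "y", "z"]].to_numpy(float) for k in range(6)]
            )
            marker_sets.append(
                LensMarkerSet(
                    ommatidium_id=omm_id,
                    outer_tip=g.loc["outer_tip", ["x", "y", "z"]].to_numpy(float),
                    inner_tip=g.loc["inner_tip", ["x", "y", "z"]].to_numpy(float),
                    base_points=base,
                    rhabdomere_tip=g.loc["rhabdomere", ["x", "y", "z"]].to_numpy(float),
                )
            )
        except KeyError as err:
            raise ValueError(f"ommatidium {omm_id}: missing marker {err}") from err
    return ocelli, marker_sets


def write_trajectory(path, traj: Trajectory, sidecar_path=None) -> None:
    """Write a trajectory TSV; condition and ground truth go to a sidecar."""
    pd.DataFrame({"t_s": traj.t, "x_mm": traj.x, "y_mm": traj.y}).to_csv(
        path, sep="\t", index=False
    )
    if sidecar_path is not None:
        meta: dict = {}
        if traj.animal_id is not None:
            meta["animal_id"] = traj.animal_id
        if traj.condition is not None:
            meta["lambda_deg"] = traj.condition.wavelength
            meta["velocity_deg_s"] = traj.condition.angular_velocity
        if traj.ground_truth:
            meta["ground_truth"] = {
                k: v for k, v in traj.ground_truth.items() if v is not None
            }
        write_sidecar(sidecar_path, meta)


def read_trajectory(path, sidecar_path=None) -> Trajectory:
    """Read a trajectory TSV (plus optional YAML sidecar) back."""
    table = pd.read_csv(path, sep="\t")
    missing = {"t_s", "x_mm", "y_mm"} - set(table.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
    condition = None
    animal_id = None
    ground_truth: dict = {}
    if sidecar_path is not None:
        meta = read_sidecar(sidecar_path)
        animal_id = meta.get("animal_id")
        if "lambda_deg" in meta:
            condition = StimulusCondition(
                wavelength=float(meta["lambda_deg"]),
                angular_velocity=float(meta.get("velocity_deg_s", 0.0)),
            )
        ground_truth = meta.get("ground_truth", {}) or {}
    return Trajectory(
        t=table["t_s"].to_numpy(float),
        x=table["x_mm"].to_numpy(float),
        y=table["y_mm"].to_numpy(float),
        animal_id=animal_id,
        condition=condition,
        ground_truth=ground_truth,
    )


def write_sidecar(path, data: dict) -> None:
    """Write a structured-text (YAML) key/value sidecar."""
    Path(path).write_text(yaml.safe_dump(_plain(data), sort_keys=True))


def read_sidecar(path) -> dict:
    """Read a YAML key/value sidecar."""
    return yaml.safe_load(Path(path).read_text()) or {}


def _plain(value):
    """Recursively convert numpy scalars/arrays for YAML serialization."""
    if isinstance(value, dict):
        return {k: _plain(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_plain(v) for v in value]
    if isinstance(value, np.generic):
        return value.item()
    if isinstance(value, np.ndarray):
        return value.tolist()
    return value
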