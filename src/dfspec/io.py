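"""File formats: force-curve CSV+JSON dialect, event tables, reports.

A dataset directory holds one CSV per curve (columns ``time_s``,
``distance_nm``, ``force_pN``; header mandatory, units fixed in the
column names) plus a ``curves.json`` sidecar mapping curve_id ->
{velocity_nm_s, spring_constant_pN_nm, condition}. Distances are
tip-sample separation: 0 at contact, increasing on retraction.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .events import RuptureEvent
from .exceptions import FormatError, ValidationError
from .simulate import ForceCurve, GroundTruth

__all__ = [
    "CURVE_COLUMNS",
    "SIDECAR_NAME",
    "write_force_curves",
    "read_force_curves",
    "write_ground_truth",
    "read_ground_truth",
    "write_events",
    "read_events",
    "write_json_report",
]

CURVE_COLUMNS = ("time_s", "distance_nm", "force_pN")
SIDECAR_NAME = "curves.json"


def write_force_curves(
    directory, curves: Iterable[ForceCurve], condition: Optional[str] = None
) -> Path:
    """Write one CSV per curve plus the JSON metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {}
    for curve in curves:
        df = pd.DataFrame(
            {
                "time_s": curve.time,
                "distance_nm": curve.tip_sample_distance,
                "force_pN": curve.force,
            }
        )
        df.to_csv(directory / f"{curve.curve_id}.csv", index=False, float_format="%.9g")
        meta[curve.curve_id] = {
            "velocity_nm_s": curve.pulling_velocity,
            "spring_constant_pN_nm": curve.spring_constant,
            "condition": condition,
        }
    with open(directory / SIDECAR_NAME, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return directory


def read_force_curves(directory) -> list[ForceCurve]:
    """Read a dataset directory back into validated ForceCurve objects."""
    directory = Path(directory)
    sidecar = directory / SIDECAR_NAME
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    curves = []
    for curve_id in sorted(meta):
        entry = meta[curve_id]
        for key in ("velocity_nm_s", "spring_constant_pN_nm"):
            if key not in entry:
                raise FormatError(f"curve {curve_id}: sidecar entry lacks {key!r}")
        k_c = float(entry["spring_constant_pN_nm"])
        if k_c <= 0:
            raise ValidationError(f"curve {curve_id}: spring constant must be positive, got {k_c}")
        v = float(entry["velocity_nm_s"])
        if v <= 0:
            raise ValidationError(f"curve {curve_id}: pulling velocity must be positive, got {v}")
        path = directory / f"{curve_id}.csv"
        if not path.exists():
            raise FormatError(f"curve {curve_id}: file {path.name} not found")
        df = pd.read_csv(path)
        for col in CURVE_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"curve {curve_id}: missing required column {col!r}")
        time = df["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(time) <= 0):
            raise ValidationError(f"curve {curve_id}: time_s must be strictly increasing")
        curves.append(
            ForceCurve(
                curve_id=curve_id,
                time=time,
                tip_sample_distance=df["distance_nm"].to_numpy(dtype=float),
                force=df["force_pN"].to_numpy(dtype=float),
                pulling_velocity=v,
                spring_constant=k_c,
            )
        )
    return curves


def write_ground_truth(path, truths: Sequence[GroundTruth]) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "curve_id": [t.curve_id for t in truths],
            "class": [t.true_class for t in truths],
            "rupture_force_pN": [t.true_rupture_force for t in truths],
            "rupture_index": [t.true_rupture_index for t in truths],
            "lc_nm": [t.true_lc for t in truths],
        }
    ).to_csv(path, index=False)
    return path


def read_ground_truth(path) -> list[GroundTruth]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        empty = row._1 == "empty"  # "class" is mangled by itertuples
        out.append(
            GroundTruth(
                curve_id=str(row.curve_id),
                true_class=str(row._1),
                true_rupture_force=None if empty else float(row.rupture_force_pN),
                true_rupture_index=None if empty else int(row.rupture_index),
                true_lc=None if empty else float(row.lc_nm),
            )
        )
    return out


def write_events(path, events: Sequence[RuptureEvent]) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "curve_id": [e.curve_id for e in events],
            "rupture_force_pN": [e.rupture_force for e in events],
            "lc_nm": [e.contour_length for e in events],
            "loading_rate_pN_s": [e.loading_rate for e in events],
            "velocity_nm_s": [e.pulling_velocity for e in events],
            "accepted": [e.accepted for e in events],
        }
    ).to_csv(path, index=False)
    return path


def read_events(path) -> list[RuptureEvent]:
    df = pd.read_csv(path)
    required = {"curve_id", "rupture_force_pN", "lc_nm", "loading_rate_pN_s", "accepted"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"events table missing columns {sorted(missing)}")
    events = []
    for row in df.itertuples(index=False):
        events.append(
            RuptureEvent(
                curve_id=str(row.curve_id),
                rupture_force=float(row.rupture_force_pN),
                rupture_index=-1,
                contour_length=float(row.lc_nm),
                loading_rate=float(row.loading_rate_pN_s),
                pulling_velocity=float(getattr(row, "velocity_nm_s", float("nan"))),
                accepted=bool(row.accepted),
            )
        )
    return events


def write_json_report(path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return path
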