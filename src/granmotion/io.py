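"""Trajectory-table I/O: tab-delimited text with a mandatory header.

Columns: track_id, frame, t_s, x_um, y_um, z_um (blank for 2D), cell_id,
condition, and optionally true_label. One row per point. Units are fixed in
the header names to prevent silent unit mismatches between 100 ms TIRF and
1 s confocal data.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from granmotion.trajsim import Trajectory

REQUIRED_COLUMNS = ("track_id", "frame", "t_s", "x_um", "y_um", "z_um",
                    "cell_id", "condition")


def write_trajectories(
    trajectories: Sequence[Trajectory],
    path,
    labels: Optional[dict[str, str]] = None,
) -> None:
    """Write trajectories to a tab-delimited table (header mandatory).

    ``labels`` optionally maps track_id -> ground-truth label, emitted as a
    ``true_label`` column.
    """
    rows = []
    for traj in trajectories:
        t0 = traj.times[0]
        dt = float(np.min(np.diff(traj.times)))
        for i, (t, p) in enumerate(zip(traj.times, traj.positions)):
            row = {
                "track_id": traj.track_id,
                "frame": int(round((t - t0) / dt)),
                "t_s": float(t),
                "x_um": float(p[0]),
                "y_um": float(p[1]),
                "z_um": float(p[2]) if traj.dim == 3 else "",
                "cell_id": traj.cell_id,
                "condition": traj.condition,
            }
            if labels is not None:
                row["true_label"] = labels.get(traj.track_id, "")
            rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_trajectories(path) -> tuple[list[Trajectory], dict[str, str]]:
    """Read a trajectory table; returns (trajectories, true-label map).

    Rows are sorted by (track_id, frame) so shuffled files round-trip.
    Rejects files missing a required column, tracks mixing 2D (blank z)
    and 3D rows, and tracks with non-monotone times.
    """
    df = pd.read_csv(path, sep="\t", dtype={"track_id": str, "cell_id": str,
                                            "condition": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    df = df.sort_values(["track_id", "frame"], kind="stable")

    trajectories: list[Trajectory] = []
    labels: dict[str, str] = {}
    for tid, grp in df.groupby("track_id", sort=True):
        z = grp["z_um"]
        has_z = z.notna().to_numpy()
        if has_z.any() and not has_z.all():
            raise ValueError(f"track {tid!r} mixes 2D and 3D rows")
        times = grp["t_s"].to_numpy(dtype=float)
        if not np.all(np.diff(times) > 0):
            raise ValueError(f"track {tid!r}: non-monotone times")
        if has_z.all():
            pos = grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        else:
            pos = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        cell = grp["cell_id"].iloc[0]
        cond = grp["condition"].iloc[0]
        trajectories.append(
            Trajectory(
                track_id=str(tid),
                times=times,
                positions=pos,
                cell_id="" if pd.isna(cell) else str(cell),
                condition="" if pd.isna(cond) else str(cond),
            )
        )
        if "true_label" in grp.columns:
            lab = grp["true_label"].iloc[0]
            if not pd.isna(lab) and lab != "":
                labels[str(tid)] = str(lab)
    return trajectories, labels
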