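"""Track-level geometric metrics and pre-analysis filters.

Length is the sum of step displacements, displacement the start-to-end
distance, straightness their ratio (1 for a straight line, 0 for a closed
loop). Metrics can be computed over the full track or over its first
``window_s`` seconds (10 s is the conventional window).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from granmotion.trajsim import Trajectory

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrackMetrics:
    track_id: str
    length: float  # um
    displacement: float  # um
    straightness: float  # in [0, 1]
    mean_speed: float  # um/s
    window_s: float  # seconds covered (full track duration or the window)
    condition: str = ""


def track_metrics(traj: Trajectory, window_s: Optional[float] = None) -> TrackMetrics:
    """Length, displacement, straightness and mean speed of one track.

    With ``window_s`` the track is truncated to its first ``window_s``
    seconds (not a sliding window) before computing the metrics.
    """
    times = traj.times
    pos = traj.positions
    if window_s is not None:
        if window_s <= 0:
            raise ValueError("window_s must be > 0")
        keep = times - times[0] <= window_s + 1e-12
        times, pos = times[keep], pos[keep]
    if len(times) < 2:
        raise ValueError(
            f"track {traj.track_id}: fewer than 2 points in window"
        )
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    length = float(steps.sum())
    displacement = float(np.linalg.norm(pos[-1] - pos[0]))
    straightness = displacement / length if length > 0 else 0.0
    elapsed = float(times[-1] - times[0])
    return TrackMetrics(
        track_id=traj.track_id,
        length=length,
        displacement=displacement,
        straightness=min(straightness, 1.0),
        mean_speed=length / elapsed,
        window_s=window_s if window_s is not None else elapsed,
        condition=traj.condition,
    )


def filter_min_steps(
    trajectories: Sequence[Trajectory], min_steps: int = 6
) -> list[Trajectory]:
    """Keep only tracks with at least ``min_steps`` displacement steps."""
    kept = [t for t in trajectories if t.n_steps >= min_steps]
    dropped = len(trajectories) - len(kept)
    if dropped:
        log.info("filter_min_steps: dropped %d track(s) with < %d steps",
                 dropped, min_steps)
    return kept


@dataclass(frozen=True)
class PlanarMembrane:
    """Axis-aligned planar membrane; inside is the half-space above/below.

    ``signed_distance`` is positive inside the cell, negative outside.
    """

    axis: int = 2  # 0=x, 1=y, 2=z
    offset: float = 0.0  # um, membrane plane position along axis
    inside_positive: bool = True  # cell interior at coordinate > offset

    def signed_distance(self, point: np.ndarray) -> float:
        point = np.asarray(point, dtype=float)
        if self.axis >= point.shape[-1]:
            raise ValueError(
                f"membrane axis {self.axis} undefined for point {point.tolist()}"
            )
        d = float(point[self.axis] - self.offset)
        return d if self.inside_positive else -d


def exclude_membrane_proximal(
    trajectories: Sequence[Trajectory],
    membrane_model: PlanarMembrane | Callable[[np.ndarray], float],
    margin: float = 0.2,
) -> list[Trajectory]:
    """Drop whole tracks that ever come within ``margin`` of the membrane.

    A track is kept only when every point lies at least ``margin`` um inside
    the membrane (signed distance >= margin). Whole-track removal avoids the
    MSD bias that point clipping would introduce.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    sd = (
        membrane_model.signed_distance
        if hasattr(membrane_model, "signed_distance")
        else membrane_model
    )
    kept = []
    for traj in trajectories:
        dists = np.array([sd(p) for p in traj.positions], dtype=float)
        if np.any(~np.isfinite(dists)):
            bad = traj.positions[~np.isfinite(dists)][0]
            raise ValueError(
                f"membrane model undefined at point {bad.tolist()} "
                f"(track {traj.track_id})"
            )
        if np.all(dists >= margin):
            kept.append(traj)
    dropped = len(trajectories) - len(kept)
    if dropped:
        log.info("exclude_membrane_proximal: removed %d track(s) within "
                 "%.3g um of the membrane", dropped, margin)
    return kept
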