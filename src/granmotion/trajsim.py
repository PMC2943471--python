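"""Synthetic trajectory generator for granule-scale motion regimes.

Four kinematic regimes are supported: ``immobile`` (localization noise
only), ``random`` (Brownian), ``directed`` (Brownian plus constant drift)
and ``caged`` (Brownian reflected inside a sphere/disc of radius R).
Reported positions are the true positions plus i.i.d. per-axis Gaussian
localization noise, which is what produces the constant MSD offset the
fitting module estimates as ``k``.

Units: micrometres and seconds throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

MODELS = ("immobile", "random", "directed", "caged")

#: default frame intervals: 1 s/stack for 3D confocal, 100 ms/frame for 2D TIRF
DEFAULT_DT = {3: 1.0, 2: 0.1}


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one simulated track.

    Parameters
    ----------
    model:
        One of ``immobile``, ``random``, ``directed``, ``caged``.
    dim:
        Spatial dimensionality, 2 or 3.
    D:
        Diffusion coefficient, um^2/s.
    v:
        Drift velocity vector, um/s (directed model only).
    R:
        Cage radius, um (caged model only).
    sigma_loc:
        Per-axis localization noise s.d., um.
    n_steps:
        Number of displacement steps (track has ``n_steps + 1`` points).
    dt:
        Frame interval, s.
    seed:
        RNG seed; tracks with equal seeds are bitwise identical.
    """

    model: str
    dim: int = 3
    D: float = 0.0
    v: Sequence[float] = (0.0, 0.0, 0.0)
    R: Optional[float] = None
    sigma_loc: float = 0.0
    n_steps: int = 50
    dt: float = 1.0
    seed: Optional[int] = None
    origin: Sequence[float] = (0.0, 0.0, 0.0)

    def validate(self) -> None:
        if self.model not in MODELS:
            raise ValueError(
                f"unknown model {self.model!r}; expected one of {MODELS}"
            )
        if self.dim not in (2, 3):
            raise ValueError(f"dim must be 2 or 3, got {self.dim}")
        if self.D < 0:
            raise ValueError(f"D must be >= 0, got {self.D}")
        if self.sigma_loc < 0:
            raise ValueError(f"sigma_loc must be >= 0, got {self.sigma_loc}")
        if self.n_steps < 2:
            raise ValueError(f"n_steps must be >= 2, got {self.n_steps}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.model == "caged" and (self.R is None or self.R <= 0):
            raise ValueError("caged model requires cage radius R > 0")
        if self.model == "directed" and len(self.v) < self.dim:
            raise ValueError("drift vector v shorter than dim")


@dataclass(frozen=True, eq=False)
class Trajectory:
    """Ordered positions and timestamps of one tracked object (2D or 3D)."""

    track_id: str
    times: np.ndarray  # seconds, strictly increasing
    positions: np.ndarray  # (n, dim) um
    cell_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)
        if times.ndim != 1 or positions.ndim != 2:
            raise ValueError("times must be 1-D, positions 2-D")
        if len(times) != len(positions):
            raise ValueError(
                f"track {self.track_id}: {len(times)} times "
                f"vs {len(positions)} positions"
            )
        if len(times) < 2:
            raise ValueError(f"track {self.track_id}: needs >= 2 points")
        if positions.shape[1] not in (2, 3):
            raise ValueError(f"track {self.track_id}: dim must be 2 or 3")
        if not np.all(np.diff(times) > 0):
            raise ValueError(f"track {self.track_id}: times not strictly increasing")

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    @property
    def n_points(self) -> int:
        return len(self.times)

    @property
    def n_steps(self) -> int:
        return len(self.times) - 1

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


def _fold_radius(d: float, R: float) -> float:
    """Fold a radial coordinate into [0, R] (specular reflection at r=R)."""
    d = d % (2.0 * R)
    return 2.0 * R - d if d > R else d


def simulate_trajectory(
    params: SimulationParams,
    track_id: str = "sim-0",
    cell_id: str = "",
    condition: str = "",
    rng: Optional[np.random.Generator] = None,
) -> Trajectory:
    """Simulate one trajectory under the given motion regime.

    True positions follow the regime (per-axis Brownian increment variance
    ``2*D*dt``; plus ``v*dt`` drift when directed; reflected at the cage
    boundary when caged; constant when immobile). The reported positions add
    independent per-axis Gaussian noise of s.d. ``sigma_loc``. Identical
    seeds give identical output.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)

    dim = params.dim
    n = params.n_steps
    origin = np.asarray(params.origin, dtype=float)[:dim]
    true = np.empty((n + 1, dim))
    true[0] = origin

    if params.model == "immobile":
        true[1:] = origin
    else:
        step_sd = math.sqrt(2.0 * params.D * params.dt)
        steps = rng.normal(0.0, step_sd, size=(n, dim)) if step_sd > 0 else np.zeros((n, dim))
        if params.model == "directed":
            steps = steps + np.asarray(params.v, dtype=float)[:dim] * params.dt
        if params.model == "caged":
            R = float(params.R)
            # substep so each Brownian increment is small next to the cage;
            # radial folding then approximates specular wall reflection well
            n_sub = max(1, int(math.ceil((5.0 * step_sd / R) ** 2))) if step_sd > 0 else 1
            sub_sd = step_sd / math.sqrt(n_sub)
            sub_steps = rng.normal(0.0, sub_sd, size=(n * n_sub, dim)) if sub_sd > 0 else np.zeros((n * n_sub, dim))
            pos = origin.copy()
            for i in range(n):
                for s in range(n_sub):
                    pos = pos + sub_steps[i * n_sub + s]
                    d = float(np.linalg.norm(pos - origin))
                    if d > R:
                        folded = _fold_radius(d, R)
                        pos = origin + (pos - origin) * (folded / d if d > 0 else 0.0)
                true[i + 1] = pos
        else:
            true[1:] = origin + np.cumsum(steps, axis=0)

    if params.sigma_loc > 0:
        reported = true + rng.normal(0.0, params.sigma_loc, size=true.shape)
    else:
        reported = true

    times = np.arange(n + 1, dtype=float) * params.dt
    return Trajectory(
        track_id=track_id,
        times=times,
        positions=reported,
        cell_id=cell_id,
        condition=condition,
    )


def _child_seed(master: Optional[int], index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(master, spawn_key=(index,))
    return np.random.default_rng(ss)


def simulate_fixed_cell_population(
    sigma_loc: float,
    n_tracks: int,
    n_steps: int = 50,
    dt: float = 1.0,
    seed: Optional[int] = None,
    dim: int = 3,
) -> list[Trajectory]:
    """Immobile tracks with pure localization noise, emulating fixed cells.

    Used to calibrate the immobility threshold as the 95th percentile of
    per-track maximum MSD.
    """
    if sigma_loc < 0:
        raise ValueError("sigma_loc must be >= 0")
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    base = SimulationParams(
        model="immobile", dim=dim, sigma_loc=sigma_loc, n_steps=n_steps, dt=dt
    )
    return [
        simulate_trajectory(
            base,
            track_id=f"fixed-{i}",
            condition="fixed",
            rng=_child_seed(seed, i),
        )
        for i in range(n_tracks)
    ]


@dataclass(frozen=True)
class CohortRow:
    """One row of a cohort specification: ``count`` tracks from ``params``.

    ``seed`` makes the row's tracks independent of row order; when omitted
    a seed is derived from the cohort master seed and the row position.
    """

    params: SimulationParams
    count: int
    seed: Optional[int] = None
    condition: str = "sim"
    cell_id: str = ""


def simulate_cohort(
    spec: Sequence[CohortRow],
    seed: Optional[int] = None,
) -> list[tuple[Trajectory, str]]:
    """Simulate a labelled cohort; returns (trajectory, true_label) pairs.

    The generating regime label travels alongside each trajectory and is
    never attached to the Trajectory object itself, so classifiers cannot
    see it.
    """
    spec = list(spec)
    if not spec:
        raise ValueError("empty cohort spec")
    out: list[tuple[Trajectory, str]] = []
    for row_idx, row in enumerate(spec):
        if row.count < 1:
            raise ValueError(f"row {row_idx}: count must be >= 1")
        row.params.validate()
        row_seed = row.seed
        if row_seed is None:
            row_seed = int(np.random.SeedSequence(seed, spawn_key=(row_idx,)).generate_state(1)[0])
        for i in range(row.count):
            traj = simulate_trajectory(
                row.params,
                track_id=f"{row.condition}-{row.params.model}-s{row_seed}-{i}",
                cell_id=row.cell_id,
                condition=row.condition,
                rng=_child_seed(row_seed, i),
            )
            out.append((traj, row.params.model))
    return out
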