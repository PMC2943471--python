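"""Synthetic movie rendering, spot detection and track linking.

The renderer draws each granule as a Gaussian intensity profile at its true
position (2D frames or 3D stacks), optionally with Poisson noise. Detection
is band-pass smoothing + local maxima + iterative intensity-weighted center
of mass; linking is greedy mutual-nearest-neighbor with gap closing, the
standard open reimplementation of the Crocker–Grier lineage.

Coordinate convention: voxel centers sit at integer indices; positions are
reported in micrometres measured from the center of voxel (0, 0, 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from granmotion.trajsim import Trajectory

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MovieGeometry:
    """Field of view of a synthetic movie."""

    nx: int
    ny: int
    nz: int = 0  # 0 -> 2D movie
    pixel_size_um: float = 0.1
    z_step_um: float = 0.2  # axial step of confocal stacks
    frame_interval_s: float = 1.0

    def validate(self) -> None:
        if self.nx < 1 or self.ny < 1 or self.nz < 0:
            raise ValueError("geometry dims must be >= 1 (nz >= 0)")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel sizes must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")

    @property
    def is_3d(self) -> bool:
        return self.nz > 0


@dataclass(eq=False)
class MovieStack:
    """Pixel data indexed (t, z, y, x) for 3D or (t, y, x) for 2D."""

    data: np.ndarray
    pixel_size_um: float
    z_step_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be (t, y, x) or (t, z, y, x)")
        if min(self.data.shape) < 1:
            raise ValueError("all dims must be >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")

    @property
    def is_3d(self) -> bool:
        return self.data.ndim == 4

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class LinkingConfig:
    """Detection/linking parameters (defaults follow the tracking setup:
    0.3 um estimated diameter, 0.5 um max step, 2-frame gap closing,
    6-step minimum)."""

    estimated_diameter: float = 0.3  # um
    max_distance: float = 0.5  # um per frame interval
    max_gap_frames: int = 2
    min_steps: int = 6

    def validate(self) -> None:
        if self.estimated_diameter <= 0:
            raise ValueError("estimated_diameter must be > 0")
        if self.max_distance <= 0:
            raise ValueError("max_distance must be > 0")
        if self.max_gap_frames < 0:
            raise ValueError("max_gap_frames must be >= 0")
        if self.min_steps < 1:
            raise ValueError("min_steps must be >= 1")


def gaussian_spot_mass(amplitude: float, psf_sigma_um: float,
                       geometry: MovieGeometry) -> float:
    """Analytic integral of one rendered Gaussian spot, in intensity units."""
    sig_px = psf_sigma_um / geometry.pixel_size_um
    mass = amplitude * (2.0 * math.pi * sig_px ** 2)
    if geometry.is_3d:
        sig_z = psf_sigma_um / geometry.z_step_um
        mass *= math.sqrt(2.0 * math.pi) * sig_z
    return mass


def render_movie(
    trajectories: Sequence[Trajectory],
    geometry: MovieGeometry,
    psf_sigma_um: float = 0.15,
    amplitude: float = 1000.0,
    background: float = 10.0,
    noise_model: str = "none",
    seed: Optional[int] = None,
) -> MovieStack:
    """Render trajectories into a synthetic movie.

    Each granule is drawn as a Gaussian of s.d. ``psf_sigma_um`` centred at
    its true position in every frame where the track has a point (frame
    index = round(t / frame_interval)). ``noise_model`` is ``"none"`` or
    ``"poisson"``; output is float64 either way, deterministic under a
    fixed seed.
    """
    geometry.validate()
    if psf_sigma_um <= 0:
        raise ValueError("psf_sigma_um must be > 0")
    if noise_model not in ("none", "poisson"):
        raise ValueError(f"unknown noise model {noise_model!r}")

    n_frames = 0
    for traj in trajectories:
        frames = np.rint(traj.times / geometry.frame_interval_s).astype(int)
        n_frames = max(n_frames, int(frames[-1]) + 1)
    n_frames = max(n_frames, 1)

    if geometry.is_3d:
        shape = (n_frames, geometry.nz, geometry.ny, geometry.nx)
    else:
        shape = (n_frames, geometry.ny, geometry.nx)
    stack = np.full(shape, float(background))

    sig_px = psf_sigma_um / geometry.pixel_size_um
    sig_z = psf_sigma_um / geometry.z_step_um
    half = int(math.ceil(4 * sig_px)) + 1
    half_z = int(math.ceil(4 * sig_z)) + 1

    for traj in trajectories:
        frames = np.rint(traj.times / geometry.frame_interval_s).astype(int)
        for f, p in zip(frames, traj.positions):
            xpx = p[0] / geometry.pixel_size_um
            ypx = p[1] / geometry.pixel_size_um
            if not (0 <= xpx <= geometry.nx - 1 and 0 <= ypx <= geometry.ny - 1):
                raise ValueError(
                    f"track {traj.track_id}: spot at {p.tolist()} um outside field"
                )
            x0, x1 = max(0, int(xpx) - half), min(geometry.nx, int(xpx) + half + 1)
            y0, y1 = max(0, int(ypx) - half), min(geometry.ny, int(ypx) + half + 1)
            xs = np.arange(x0, x1)
            ys = np.arange(y0, y1)
            gx = np.exp(-0.5 * ((xs - xpx) / sig_px) ** 2)
            gy = np.exp(-0.5 * ((ys - ypx) / sig_px) ** 2)
            if geometry.is_3d:
                zpx = (p[2] / geometry.z_step_um) if traj.dim == 3 else 0.0
                if not 0 <= zpx <= geometry.nz - 1:
                    raise ValueError(
                        f"track {traj.track_id}: spot at {p.tolist()} um "
                        "outside axial range"
                    )
                z0, z1 = max(0, int(zpx) - half_z), min(geometry.nz, int(zpx) + half_z + 1)
                zs = np.arange(z0, z1)
                gz = np.exp(-0.5 * ((zs - zpx) / sig_z) ** 2)
                stack[f, z0:z1, y0:y1, x0:x1] += (
                    amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
                )
            else:
                stack[f, y0:y1, x0:x1] += amplitude * gy[:, None] * gx[None, :]

    if noise_model == "poisson":
        rng = np.random.default_rng(seed)
        stack = rng.poisson(np.clip(stack, 0, None)).astype(float)

    return MovieStack(
        data=stack,
        pixel_size_um=geometry.pixel_size_um,
        z_step_um=geometry.z_step_um,
        frame_interval_s=geometry.frame_interval_s,
    )


def _refine_com(frame: np.ndarray, peak: tuple, radius: tuple,
                n_iter: int = 5) -> Optional[np.ndarray]:
    """Iterative background-subtracted center of mass around a peak.

    Returns subpixel coordinates (same axis order as ``frame``) or None if
    the refinement wanders out of the frame.
    """
    center = np.asarray(peak, dtype=float)
    shape = frame.shape
    for _ in range(n_iter):
        sl = []
        for ax, (c, r) in enumerate(zip(center, radius)):
            lo = int(round(c)) - r
            hi = int(round(c)) + r + 1
            if lo < 0 or hi > shape[ax]:
                lo, hi = max(0, lo), min(shape[ax], hi)
            sl.append(slice(lo, hi))
        win = frame[tuple(sl)].astype(float)
        win = win - win.min()
        total = win.sum()
        if total <= 0:
            return None
        grids = np.meshgrid(
            *[np.arange(s.start, s.stop) for s in sl], indexing="ij"
        )
        new = np.array([float((g * win).sum() / total) for g in grids])
        if np.allclose(new, center, atol=1e-4):
            center = new
            break
        center = new
    return center


def detect_spots(
    frame: np.ndarray,
    config: LinkingConfig,
    pixel_size_um: float,
    z_step_um: float = 0.2,
    threshold: Optional[float] = None,
) -> pd.DataFrame:
    """Detect spots in one frame ((y, x) or (z, y, x) array).

    Band-pass smoothing (difference of Gaussians at ~diameter/4 and
    ~diameter), local-maximum candidates above ``threshold`` (default:
    mean + 4 s.d. of the band-passed frame), each refined by iterative
    intensity-weighted center of mass in a window matched to the estimated
    diameter. Returns a table with columns x_um, y_um [, z_um], intensity.

    A constant frame yields an empty table with a logged warning.
    """
    config.validate()
    frame = np.asarray(frame, dtype=float)
    if frame.ndim not in (2, 3):
        raise ValueError("frame must be 2-D or 3-D")
    is_3d = frame.ndim == 3

    diam_px = config.estimated_diameter / pixel_size_um
    if diam_px < 1:
        raise ValueError("estimated diameter below one pixel")
    cols = (["z_um"] if is_3d else []) + ["y_um", "x_um", "intensity"]

    if np.ptp(frame) == 0:
        log.warning("detect_spots: constant frame, no detections")
        return pd.DataFrame(columns=cols)

    sig_small = max(diam_px / 4.0, 0.5)
    sig_large = max(diam_px, 2.0)
    if is_3d:
        scale = pixel_size_um / z_step_um
        small = (sig_small * scale, sig_small, sig_small)
        large = (sig_large * scale, sig_large, sig_large)
    else:
        small, large = sig_small, sig_large
    bp = ndimage.gaussian_filter(frame, small) - ndimage.gaussian_filter(frame, large)

    if threshold is None:
        threshold = float(bp.mean() + 4.0 * bp.std())
    size = max(3, int(round(diam_px)) | 1)
    footprint = (max(3, int(round(diam_px * pixel_size_um / z_step_um)) | 1),
                 size, size) if is_3d else (size, size)
    maxima = (bp == ndimage.maximum_filter(bp, size=footprint)) & (bp > threshold)
    peaks = np.argwhere(maxima)

    r_xy = max(2, int(math.ceil(diam_px)))
    if is_3d:
        r_z = max(2, int(math.ceil(diam_px * pixel_size_um / z_step_um)))
        radius = (r_z, r_xy, r_xy)
    else:
        radius = (r_xy, r_xy)

    rows = []
    for peak in peaks:
        center = _refine_com(bp, tuple(peak), radius)
        if center is None:
            continue
        intensity = float(frame[tuple(peak)])
        if is_3d:
            rows.append(dict(z_um=center[0] * z_step_um,
                             y_um=center[1] * pixel_size_um,
                             x_um=center[2] * pixel_size_um,
                             intensity=intensity))
        else:
            rows.append(dict(y_um=center[0] * pixel_size_um,
                             x_um=center[1] * pixel_size_um,
                             intensity=intensity))
    return pd.DataFrame(rows, columns=cols)


def detect_movie(stack: MovieStack, config: LinkingConfig,
                 threshold: Optional[float] = None) -> list[pd.DataFrame]:
    """Run detect_spots on every frame of a movie."""
    return [
        detect_spots(stack.data[t], config, stack.pixel_size_um,
                     stack.z_step_um, threshold=threshold)
        for t in range(stack.n_frames)
    ]


class _OpenTrack:
    __slots__ = ("frames", "points", "last_frame")

    def __init__(self, frame: int, point: np.ndarray) -> None:
        self.frames = [frame]
        self.points = [point]
        self.last_frame = frame

    def add(self, frame: int, point: np.ndarray) -> None:
        self.frames.append(frame)
        self.points.append(point)
        self.last_frame = frame


def link_detections(
    detections: Sequence[pd.DataFrame],
    config: LinkingConfig,
    frame_interval_s: float = 1.0,
    condition: str = "",
) -> list[Trajectory]:
    """Greedy mutual-nearest-neighbor linking with gap closing.

    Tracks may be bridged across up to ``max_gap_frames`` missing frames
    (bridged positions are omitted, not interpolated) with search radius
    ``max_distance * (gap + 1)``. Ambiguous (non-mutual) assignments link
    nobody — both candidates are terminated, conservatively. Tracks with
    fewer than ``min_steps`` steps are discarded.
    """
    config.validate()
    open_tracks: list[_OpenTrack] = []
    closed: list[_OpenTrack] = []
    ambiguous = 0

    for f, det in enumerate(detections):
        if len(det):
            is_3d = "z_um" in det.columns
            cols = ["x_um", "y_um"] + (["z_um"] if is_3d else [])
            pts = det[cols].to_numpy(dtype=float)
        else:
            pts = np.empty((0, 2))

        # retire tracks whose gap allowance is exhausted
        still_open = []
        for tr in open_tracks:
            if f - tr.last_frame > config.max_gap_frames + 1:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        claimed = np.zeros(len(pts), dtype=bool)
        if open_tracks and len(pts):
            tr_pos = np.array([tr.points[-1] for tr in open_tracks])
            if tr_pos.shape[1] == pts.shape[1]:
                dist = np.linalg.norm(tr_pos[:, None, :] - pts[None, :, :], axis=2)
                radius = np.array([
                    config.max_distance * (f - tr.last_frame)
                    for tr in open_tracks
                ])
                allowed = dist <= radius[:, None]
                dist_masked = np.where(allowed, dist, np.inf)
                nn_det = np.argmin(dist_masked, axis=1)  # per track
                nn_tr = np.argmin(dist_masked, axis=0)  # per detection
                for ti, tr in enumerate(open_tracks):
                    dj = nn_det[ti]
                    if not np.isfinite(dist_masked[ti, dj]):
                        continue
                    if nn_tr[dj] == ti:
                        tr.add(f, pts[dj])
                        claimed[dj] = True
                    else:
                        ambiguous += 1

        for j in range(len(pts)):
            if not claimed[j]:
                open_tracks.append(_OpenTrack(f, pts[j]))

    closed.extend(open_tracks)
    if ambiguous:
        log.info("link_detections: %d ambiguous assignment(s) left unlinked",
                 ambiguous)

    out = []
    for i, tr in enumerate(closed):
        if len(tr.frames) - 1 < config.min_steps:
            continue
        out.append(
            Trajectory(
                track_id=f"linked-{i}",
                times=np.array(tr.frames, dtype=float) * frame_interval_s,
                positions=np.array(tr.points),
                condition=condition,
            )
        )
    dropped = len(closed) - len(out)
    if dropped:
        log.info("link_detections: dropped %d track(s) below %d steps",
                 dropped, config.min_steps)
    return out
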