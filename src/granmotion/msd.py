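"""Time-averaged MSD curves and diffusion-model fits.

Three models are fitted to each curve, all with a constant offset ``k``
absorbing localization error (per-axis noise sigma contributes
``2*dim*sigma^2`` to every lag):

* random:   MSD(t) = 2*dim*D*t + k
* directed: MSD(t) = 2*dim*D*t + (v*t)^2 + k
* caged:    MSD(t) = R^2 * (1 - a1*exp(-2*dim*a2*D*t / R^2)) + k,
            a1 = 0.99, a2 = 0.85

with dim = 3 (6*D*t) for confocal stacks or dim = 2 (4*D*t) for TIRF.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import optimize

from granmotion.trajsim import Trajectory

log = logging.getLogger(__name__)

CAGE_A1 = 0.99
CAGE_A2 = 0.85

#: sentinel goodness-of-fit for a model whose optimizer did not converge
R2_SENTINEL = float("-inf")


class TrackTooShortError(ValueError):
    pass


class NonUniformIntervalError(ValueError):
    pass


@dataclass(frozen=True, eq=False)
class MSDCurve:
    """Time-averaged MSD of one track: MSD(n*dt) over all ordered pairs."""

    track_id: str
    lag_times: np.ndarray  # s, strictly increasing, positive
    msd_values: np.ndarray  # um^2
    n_pairs: np.ndarray  # displacement pairs per lag
    dim: int

    def __post_init__(self) -> None:
        lt = np.asarray(self.lag_times, dtype=float)
        mv = np.asarray(self.msd_values, dtype=float)
        npr = np.asarray(self.n_pairs, dtype=int)
        object.__setattr__(self, "lag_times", lt)
        object.__setattr__(self, "msd_values", mv)
        object.__setattr__(self, "n_pairs", npr)
        if not (len(lt) == len(mv) == len(npr)):
            raise ValueError("lag_times, msd_values, n_pairs length mismatch")
        if len(lt) and (lt[0] <= 0 or np.any(np.diff(lt) <= 0)):
            raise ValueError("lag_times must be positive and strictly increasing")
        if np.any(mv < 0):
            raise ValueError("msd_values must be >= 0")
        if np.any(npr < 1):
            raise ValueError("each retained lag needs >= 1 pair")

    def max_msd(self, within_s: Optional[float] = None) -> float:
        """Maximum MSD over lags, optionally restricted to lags <= within_s."""
        mask = np.ones(len(self.lag_times), dtype=bool)
        if within_s is not None:
            mask = self.lag_times <= within_s
        if not mask.any():
            return 0.0
        return float(self.msd_values[mask].max())


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters and goodness of fit for one diffusion model.

    For the caged model ``D`` is the within-cage diffusion coefficient
    (D_0 in the 2D Kusumi form). ``r_squared`` is the coefficient of
    determination 1 - SS_res/SS_tot; -inf marks a failed fit.
    """

    model: str  # random | directed | caged
    D: float
    k: float
    r_squared: float
    v: Optional[float] = None
    R: Optional[float] = None


def compute_msd(
    traj: Trajectory,
    max_lag_fraction: float = 0.5,
    min_steps: int = 6,
    min_lags: int = 5,
) -> MSDCurve:
    """Time-averaged MSD: MSD(n*dt) = mean_i |r(i+n) - r(i)|^2.

    The base frame interval is the smallest time difference; gaps (missing
    frames) are allowed and handled by pair exclusion, but the observed
    intervals must all sit on that base grid. Lags are retained up to
    ``max_lag_fraction`` of the track duration.

    Raises
    ------
    TrackTooShortError
        Fewer than ``min_steps`` steps, or fewer than ``min_lags`` lags
        retained ("track too short for fitting").
    NonUniformIntervalError
        Timestamps not on a uniform base grid.
    """
    if traj.n_steps < min_steps:
        raise TrackTooShortError(
            f"track {traj.track_id}: {traj.n_steps} steps < required {min_steps}"
        )
    times = traj.times - traj.times[0]
    base = float(np.min(np.diff(traj.times)))
    frames = np.rint(times / base).astype(int)
    if not np.allclose(times, frames * base, rtol=0, atol=1e-6 * base):
        raise NonUniformIntervalError(
            f"track {traj.track_id}: timestamps not on a uniform base interval"
        )
    if len(np.unique(frames)) != len(frames):
        raise NonUniformIntervalError(
            f"track {traj.track_id}: duplicate frames"
        )

    max_lag = int(math.floor(frames[-1] * max_lag_fraction))
    lags, msds, counts = [], [], []
    if len(frames) == frames[-1] + 1:  # contiguous frames: vectorized path
        pos = traj.positions
        for lag in range(1, max_lag + 1):
            d = pos[lag:] - pos[:-lag]
            sq = np.einsum("ij,ij->i", d, d)
            lags.append(lag * base)
            msds.append(float(sq.mean()))
            counts.append(len(sq))
    else:
        frame_to_idx = {int(f): i for i, f in enumerate(frames)}
        for lag in range(1, max_lag + 1):
            sq = []
            for f, i in frame_to_idx.items():
                j = frame_to_idx.get(f + lag)
                if j is not None:
                    d = traj.positions[j] - traj.positions[i]
                    sq.append(float(d @ d))
            if sq:
                lags.append(lag * base)
                msds.append(float(np.mean(sq)))
                counts.append(len(sq))
    if len(lags) < min_lags:
        raise TrackTooShortError(
            f"track {traj.track_id}: track too short for fitting "
            f"({len(lags)} retained lags < {min_lags})"
        )
    return MSDCurve(
        track_id=traj.track_id,
        lag_times=np.array(lags),
        msd_values=np.array(msds),
        n_pairs=np.array(counts),
        dim=traj.dim,
    )


def _weighted_r_squared(y: np.ndarray, yhat: np.ndarray, w: np.ndarray) -> float:
    ybar = float(np.sum(w * y) / np.sum(w))
    ss_res = float(np.sum(w * (y - yhat) ** 2))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    if ss_tot <= 0:
        # flat curve: perfect if residuals vanish, unfit otherwise
        return 1.0 if ss_res <= 1e-24 else R2_SENTINEL
    return 1.0 - ss_res / ss_tot


def _fit_nnls(design: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    coef, _ = optimize.nnls(design * sw[:, None], y * sw)
    return coef


def _fit_random(t, y, w, dim) -> FitResult:
    # linear in (D, k), both bounded below by 0 -> exact via NNLS
    design = np.column_stack([2.0 * dim * t, np.ones_like(t)])
    slope_coef, k = _fit_nnls(design, y, w)
    yhat = design @ np.array([slope_coef, k])
    return FitResult(
        model="random", D=float(slope_coef), k=float(k),
        r_squared=_weighted_r_squared(y, yhat, w),
    )


def _fit_directed(t, y, w, dim) -> FitResult:
    # linear in (D, v^2, k), all >= 0 -> exact via NNLS
    design = np.column_stack([2.0 * dim * t, t ** 2, np.ones_like(t)])
    D, v2, k = _fit_nnls(design, y, w)
    yhat = design @ np.array([D, v2, k])
    return FitResult(
        model="directed", D=float(D), v=float(math.sqrt(v2)), k=float(k),
        r_squared=_weighted_r_squared(y, yhat, w),
    )


def caged_msd(t: np.ndarray, D: float, R: float, k: float, dim: int) -> np.ndarray:
    """Confined-diffusion MSD with offset (Kusumi-form cage)."""
    R2 = R * R
    return R2 * (1.0 - CAGE_A1 * np.exp(-2.0 * dim * CAGE_A2 * D * t / R2)) + k


def _fit_caged(t, y, w, dim) -> FitResult:
    # plateau estimate from the last 3 points seeds R; first lag seeds D
    plateau = max(float(np.mean(y[-3:])), 1e-12)
    R0 = math.sqrt(plateau)
    D0 = max(float(y[0]) / (2.0 * dim * float(t[0])), 1e-9)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                lambda tt, D, R, k: caged_msd(tt, D, R, k, dim),
                t, y,
                p0=[D0, R0, 0.0],
                sigma=1.0 / np.sqrt(w),
                absolute_sigma=False,
                bounds=([0.0, 1e-9, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=20000,
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
    except (RuntimeError, ValueError) as exc:
        log.warning("caged fit failed: %s", exc)
        return FitResult(model="caged", D=float("nan"), R=float("nan"),
                         k=float("nan"), r_squared=R2_SENTINEL)
    D, R, k = (float(p) for p in popt)
    yhat = caged_msd(t, D, R, k, dim)
    return FitResult(model="caged", D=D, R=R, k=k,
                     r_squared=_weighted_r_squared(y, yhat, w))


def fit_msd_models(curve: MSDCurve) -> dict[str, FitResult]:
    """Fit the random, directed and caged models to one MSD curve.

    Weighted least squares with weights ``n_pairs / sqrt(lag index)``: the
    pair count accounts for sample size, the extra 1/sqrt(lag) factor for
    the growing correlation-driven variance of the time-averaged MSD at
    long lags. A failed fit is returned with ``r_squared = -inf`` and never
    aborts the other fits.
    """
    t = curve.lag_times
    y = curve.msd_values
    lag_index = t / t[0]
    w = curve.n_pairs.astype(float) / np.sqrt(lag_index)
    return {
        "random": _fit_random(t, y, w, curve.dim),
        "directed": _fit_directed(t, y, w, curve.dim),
        "caged": _fit_caged(t, y, w, curve.dim),
    }


def average_msd(
    curves: Sequence[MSDCurve],
    class_labels: Optional[Sequence[str]] = None,
    min_presence: float = 0.8,
) -> dict[str, MSDCurve]:
    """Per-class unweighted mean MSD at each lag.

    Lags are kept only when present in at least ``min_presence`` of the
    class's tracks. When ``class_labels`` is None all curves form one class
    labelled ``"all"``. Empty classes are omitted with a warning.
    """
    if class_labels is None:
        class_labels = ["all"] * len(curves)
    if len(class_labels) != len(curves):
        raise ValueError("class_labels length mismatch")

    out: dict[str, MSDCurve] = {}
    for label in dict.fromkeys(class_labels):
        group = [c for c, l in zip(curves, class_labels) if l == label]
        if not group:
            log.warning("average_msd: empty class %r omitted", label)
            continue
        dims = {c.dim for c in group}
        if len(dims) != 1:
            raise ValueError(f"class {label!r} mixes dimensionalities")
        # pool on the union lag grid, then apply the presence cut
        acc: dict[float, list[float]] = {}
        for c in group:
            for lt, mv in zip(c.lag_times, c.msd_values):
                acc.setdefault(round(float(lt), 9), []).append(float(mv))
        need = min_presence * len(group)
        lags = sorted(lt for lt, vals in acc.items() if len(vals) >= need)
        if not lags:
            log.warning("average_msd: class %r has no common lags", label)
            continue
        out[label] = MSDCurve(
            track_id=f"avg:{label}",
            lag_times=np.array(lags),
            msd_values=np.array([np.mean(acc[lt]) for lt in lags]),
            n_pairs=np.array([len(acc[lt]) for lt in lags]),
            dim=dims.pop(),
        )
    return out
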