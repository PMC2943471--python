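"""Five-class motion sorting: immobile, random, directed, caged, complex.

Decision order for one track:

1. immobile  — maximum MSD within the observation window never exceeds the
   immobility bound (default 0.2 um^2, the 95th percentile of fixed-cell
   max MSD);
2. complex   — all three model fits have r^2 below the cutoff (default 0.33);
3. random    — the three r^2 values are nearly identical (population s.d.
   below 0.015), guarding against over-parameterized models winning on
   nearly linear curves;
4. otherwise — the model with the highest r^2 wins; exact ties go to the
   model with fewer parameters (random > caged > directed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from granmotion.msd import (
    FitResult,
    MSDCurve,
    TrackTooShortError,
    compute_msd,
    fit_msd_models,
)
from granmotion.trajsim import Trajectory

log = logging.getLogger(__name__)

LABELS = ("immobile", "random", "directed", "caged", "complex")

#: parsimony order for exact r^2 ties: fewer parameters wins
_TIE_ORDER = {"random": 0, "caged": 1, "directed": 2}


@dataclass(frozen=True)
class ClassificationConfig:
    immobile_msd_max: float = 0.2  # um^2
    observation_window: float = 50.0  # s
    complex_r2_cutoff: float = 0.33
    random_r2_std_cutoff: float = 0.015
    fixed_percentile: float = 95.0

    def validate(self) -> None:
        if self.immobile_msd_max <= 0:
            raise ValueError("immobile_msd_max must be > 0")
        if self.observation_window <= 0:
            raise ValueError("observation_window must be > 0")
        if not 0 < self.complex_r2_cutoff < 1:
            raise ValueError("complex_r2_cutoff must be in (0, 1)")
        if self.random_r2_std_cutoff <= 0:
            raise ValueError("random_r2_std_cutoff must be > 0")
        if not 0 < self.fixed_percentile <= 100:
            raise ValueError("fixed_percentile must be in (0, 100]")


@dataclass(frozen=True)
class MotionClass:
    """Assigned label plus the supporting fit and the rule that fired."""

    label: str
    fit: Optional[FitResult]
    rule_fired: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.label in ("immobile", "complex") and self.fit is not None:
            raise ValueError(f"{self.label} carries no supporting fit")


def calibrate_immobile_threshold(
    fixed_curves: Sequence[MSDCurve],
    config: ClassificationConfig = ClassificationConfig(),
    min_tracks: int = 20,
) -> float:
    """Immobility bound from fixed-cell tracks.

    Returns the ``fixed_percentile``-th percentile of the per-track maximum
    MSD. With no fixed data supplied, keep ``config.immobile_msd_max``.
    """
    config.validate()
    if fixed_curves is None:
        return config.immobile_msd_max
    fixed_curves = list(fixed_curves)
    if not fixed_curves:
        raise ValueError("empty fixed-cell input; pass None to keep the default")
    if len(fixed_curves) < min_tracks:
        raise ValueError(
            f"need >= {min_tracks} fixed-cell tracks, got {len(fixed_curves)}"
        )
    max_msds = [c.max_msd(config.observation_window) for c in fixed_curves]
    return float(np.percentile(max_msds, config.fixed_percentile))


def classify_track(
    curve: MSDCurve,
    fits: Mapping[str, FitResult],
    config: ClassificationConfig = ClassificationConfig(),
    max_msd: Optional[float] = None,
) -> MotionClass:
    """Assign one of the five motion classes to a track (total function).

    ``max_msd`` optionally supplies the track's maximum MSD over *all* lags
    within the observation window when ``curve`` was truncated for fitting;
    by default it is taken from ``curve`` itself.
    """
    config.validate()
    for m in ("random", "directed", "caged"):
        if m not in fits:
            raise ValueError(f"missing fit for model {m!r}")

    if max_msd is None:
        max_msd = curve.max_msd(config.observation_window)
    if max_msd <= config.immobile_msd_max:
        return MotionClass("immobile", None, "max-msd<=immobile_msd_max")

    r2 = {m: fits[m].r_squared for m in ("random", "directed", "caged")}
    finite = {m: r for m, r in r2.items() if math.isfinite(r)}

    if not finite:
        log.warning("track %s: all fits failed; labelled complex", curve.track_id)
        return MotionClass("complex", None, "all-fits-failed")

    if all(r < config.complex_r2_cutoff for r in r2.values()):
        return MotionClass("complex", None, "all-r2<complex_cutoff")

    # population s.d. of the three r^2; only meaningful if all fits converged
    if len(finite) == 3:
        std = float(np.std(list(r2.values())))  # ddof=0
        if std < config.random_r2_std_cutoff:
            return MotionClass("random", fits["random"], "r2-std<random_cutoff")

    best = max(finite, key=lambda m: (finite[m], -_TIE_ORDER[m]))
    return MotionClass(best, fits[best], "best-r2")


def _truncate_curve(curve: MSDCurve, max_lag_fraction: float,
                    min_lags: int) -> MSDCurve:
    """Restrict a full MSD curve to lags <= max_lag_fraction of duration."""
    duration = curve.lag_times[-1]
    keep = curve.lag_times <= max_lag_fraction * duration + 1e-12
    n_keep = max(int(keep.sum()), min(min_lags, len(curve.lag_times)))
    return MSDCurve(
        track_id=curve.track_id,
        lag_times=curve.lag_times[:n_keep],
        msd_values=curve.msd_values[:n_keep],
        n_pairs=curve.n_pairs[:n_keep],
        dim=curve.dim,
    )


def classify_cohort(
    trajectories: Sequence[Trajectory],
    config: ClassificationConfig = ClassificationConfig(),
    max_lag_fraction: float = 0.125,
    min_lags: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every track; returns (labels table, per-condition fractions).

    Tracks are expected to have passed the >= 6-step filter. The immobility
    test uses the maximum MSD over *all* lags inside the observation window;
    the model fits use lags up to ``max_lag_fraction`` of the track duration
    (default 0.125: short-lag MSD estimates carry most of the usable shape
    information, long-lag ones are noise-dominated).
    The labels table has one row per track (track_id, condition, label,
    rule_fired and the winning fit's parameters); the fractions table has
    one row per (condition, label) with fraction and n. ``min_lags`` is
    relaxed to 3 by default so that 6-step tracks (3 usable lags at the
    default lag fraction) remain classifiable.
    """
    rows = []
    for traj in trajectories:
        try:
            full_curve = compute_msd(traj, max_lag_fraction=1.0,
                                     min_lags=min_lags)
            curve = _truncate_curve(full_curve, max_lag_fraction, min_lags)
        except TrackTooShortError as exc:
            log.warning("classify_cohort: %s; labelled complex", exc)
            rows.append(
                dict(track_id=traj.track_id, condition=traj.condition,
                     label="complex", rule_fired="msd-unavailable",
                     best_model="", D=np.nan, v=np.nan, R=np.nan, k=np.nan,
                     r2=np.nan)
            )
            continue
        fits = fit_msd_models(curve)
        mc = classify_track(
            curve, fits, config,
            max_msd=full_curve.max_msd(config.observation_window),
        )
        fit = mc.fit
        rows.append(
            dict(
                track_id=traj.track_id,
                condition=traj.condition,
                label=mc.label,
                rule_fired=mc.rule_fired,
                best_model=fit.model if fit else "",
                D=fit.D if fit else np.nan,
                v=(fit.v if fit and fit.v is not None else np.nan),
                R=(fit.R if fit and fit.R is not None else np.nan),
                k=fit.k if fit else np.nan,
                r2=fit.r_squared if fit else np.nan,
            )
        )
    labels = pd.DataFrame(
        rows,
        columns=["track_id", "condition", "label", "rule_fired", "best_model",
                 "D", "v", "R", "k", "r2"],
    )
    frac_rows = []
    for cond, grp in labels.groupby("condition", sort=True):
        n = len(grp)
        counts = grp["label"].value_counts()
        for label in LABELS:
            frac_rows.append(
                dict(condition=cond, label=label,
                     fraction=counts.get(label, 0) / n, n=n)
            )
    fractions = pd.DataFrame(
        frac_rows, columns=["condition", "label", "fraction", "n"]
    )
    return labels, fractions
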