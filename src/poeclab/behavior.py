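"""Open-field and platter kinematics: distance, turning, and locomotion segmentation.

A freely behaving mouse is tracked as a 2-D point trajectory in a square arena;
a head-fixed mouse walks on a rotating platter whose angular velocity stands in
for body speed.  Both are reduced to the same locomotion/rest segmentation by a
linear-speed threshold (1 cm/s by convention), and open-field sessions are
additionally summarised by total walking distance, total (absolute) turning
angle, and per-frame angular speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "Trajectory",
    "PlatterTrace",
    "KinematicsSummary",
    "LocomotionMask",
    "compute_kinematics",
    "segment_locomotion",
    "platter_locomotion",
    "session_summary_table",
    "percent_change",
    "bonferroni",
    "wrap_angle",
]


@dataclass(frozen=True)
class Trajectory:
    """Timestamped 2-D body positions in arena coordinates (cm)."""

    time_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        x = np.asarray(self.x_cm, dtype=float)
        y = np.asarray(self.y_cm, dtype=float)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise ConfigurationError("time_s, x_cm, y_cm must be 1-D arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ConfigurationError("time_s must be strictly increasing")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(t))):
            raise ConfigurationError("trajectory contains non-finite values")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "x_cm", x)
        object.__setattr__(self, "y_cm", y)

    @property
    def n_frames(self) -> int:
        return self.time_s.size

    @property
    def frame_rate(self) -> float:
        if self.n_frames < 2:
            raise ConfigurationError("frame rate undefined for fewer than 2 samples")
        return 1.0 / float(np.mean(np.diff(self.time_s)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "time_s": self.time_s,
                "x_cm": self.x_cm,
                "y_cm": self.y_cm,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Trajectory":
        return cls(df["time_s"].to_numpy(), df["x_cm"].to_numpy(), df["y_cm"].to_numpy())


@dataclass(frozen=True)
class PlatterTrace:
    """Platter angular velocity (rad/s) over time for head-fixed sessions."""

    time_s: np.ndarray
    omega: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        w = np.asarray(self.omega, dtype=float)
        if t.shape != w.shape or t.ndim != 1:
            raise ConfigurationError("time_s and omega must be 1-D arrays of equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ConfigurationError("time_s must be strictly increasing")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "omega", w)

    @property
    def frame_rate(self) -> float:
        if self.time_s.size < 2:
            raise ConfigurationError("frame rate undefined for fewer than 2 samples")
        return 1.0 / float(np.mean(np.diff(self.time_s)))


@dataclass(frozen=True)
class KinematicsSummary:
    """Per-session movement summary.

    walking_distance is in metres, turning_angle in radians (total absolute
    rotation), and the two series are per-frame (cm/s and rad/s).
    """

    walking_distance: float
    turning_angle: float
    linear_speed_series: np.ndarray
    angular_speed_series: np.ndarray


@dataclass(frozen=True)
class LocomotionMask:
    """Per-frame locomotion/rest segmentation."""

    mask: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.mask.size

    @property
    def bouts(self) -> list[tuple[int, int]]:
        """Locomotion bouts as half-open ``(start_frame, end_frame)`` intervals."""
        return _runs_of(self.mask, True)

    @property
    def locomotion_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "time_s": np.arange(self.n_frames) / self.frame_rate,
                "locomotion": self.mask.astype(int),
            }
        )


def _runs_of(mask: np.ndarray, value: bool) -> list[tuple[int, int]]:
    runs: list[tuple[int, int]] = []
    n = mask.size
    i = 0
    while i < n:
        if bool(mask[i]) == value:
            j = i
            while j < n and bool(mask[j]) == value:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def wrap_angle(theta: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into (-pi, pi]."""
    wrapped = -(np.mod(-np.asarray(theta, dtype=float) + np.pi, 2.0 * np.pi) - np.pi)
    return wrapped


def compute_kinematics(
    traj: Trajectory,
    min_displacement: float = 0.2,
    uniformity_rtol: float = 1e-3,
) -> KinematicsSummary:
    """Walking distance, total turning angle, and speed series for one session.

    Heading is taken from frame-to-frame displacement vectors; displacements
    shorter than ``min_displacement`` (cm) contribute no heading change, which
    suppresses tracking jitter at rest.  Heading increments are wrapped into
    (-pi, pi] before absolute summation, so the turning angle is total absolute
    rotation, not net rotation.  Linear speed uses central differences (one-sided
    at the ends).
    """
    if traj.n_frames < 3:
        raise ConfigurationError("compute_kinematics requires at least 3 samples")
    if min_displacement < 0:
        raise ConfigurationError("min_displacement must be >= 0")
    dt = np.diff(traj.time_s)
    if np.max(np.abs(dt - dt.mean())) > uniformity_rtol * dt.mean():
        raise ConfigurationError("trajectory sampling is not uniform within tolerance")
    frame_rate = 1.0 / float(dt.mean())

    dx = np.diff(traj.x_cm)
    dy = np.diff(traj.y_cm)
    step = np.hypot(dx, dy)
    walking_distance_m = float(step.sum()) / 100.0

    # central differences for speed; np.gradient is central inside, one-sided at ends
    vx = np.gradient(traj.x_cm, traj.time_s)
    vy = np.gradient(traj.y_cm, traj.time_s)
    linear_speed = np.hypot(vx, vy)

    qualifying = np.flatnonzero(step >= min_displacement) if min_displacement > 0 else np.arange(step.size)
    angular_speed = np.zeros(traj.n_frames)
    turning = 0.0
    if qualifying.size >= 2:
        headings = np.arctan2(dy[qualifying], dx[qualifying])
        inc = np.abs(wrap_angle(np.diff(headings)))
        turning = float(inc.sum())
        # attribute each increment to the frame where the later displacement starts
        angular_speed[qualifying[1:]] = inc * frame_rate
    return KinematicsSummary(
        walking_distance=walking_distance_m,
        turning_angle=turning,
        linear_speed_series=linear_speed,
        angular_speed_series=angular_speed,
    )


def segment_locomotion(
    speed: np.ndarray,
    frame_rate: float,
    threshold: float = 1.0,
    min_bout: float = 1.0,
) -> LocomotionMask:
    """Threshold a speed series into locomotion/rest and smooth short runs.

    A frame is locomotion iff ``speed >= threshold`` (cm/s).  Runs of either
    state shorter than ``min_bout`` seconds are absorbed into the neighbouring
    state, shortest run first (ties resolved toward the earlier run), until no
    sub-minimum run remains.
    """
    speed = np.asarray(speed, dtype=float)
    if speed.size == 0:
        raise ConfigurationError("speed series is empty")
    if threshold <= 0:
        raise ConfigurationError("threshold must be positive")
    if frame_rate <= 0:
        raise ConfigurationError("frame_rate must be positive")
    mask = speed >= threshold
    if min_bout > 0:
        mask = _merge_short_runs(mask, min_frames=min_bout * frame_rate)
    return LocomotionMask(mask=mask, frame_rate=frame_rate)


def _merge_short_runs(mask: np.ndarray, min_frames: float) -> np.ndarray:
    """Absorb runs shorter than ``min_frames`` into their neighbours.

    Shortest run first; among equal lengths the earlier run is absorbed first.
    A run is short iff its length (frames) corresponds to a duration strictly
    below the minimum.
    """
    runs: list[list] = [[bool(mask[s]), e - s] for s, e in _all_runs(mask)]
    while len(runs) > 1:
        lengths = [r[1] for r in runs]
        short = [i for i, ln in enumerate(lengths) if ln < min_frames - 1e-9]
        if not short:
            break
        i = min(short, key=lambda k: (runs[k][1], k))
        runs[i][0] = not runs[i][0]
        # coalesce with neighbours of the now-identical state
        merged: list[list] = []
        for state, ln in runs:
            if merged and merged[-1][0] == state:
                merged[-1][1] += ln
            else:
                merged.append([state, ln])
        runs = merged
    out = np.empty(mask.size, dtype=bool)
    pos = 0
    for state, ln in runs:
        out[pos : pos + ln] = state
        pos += ln
    return out


def _all_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    edges = np.flatnonzero(np.diff(mask.astype(int)) != 0) + 1
    bounds = np.concatenate(([0], edges, [mask.size]))
    return list(zip(bounds[:-1], bounds[1:]))


def platter_locomotion(
    platter: PlatterTrace,
    linear_threshold: float = 1.0,
    effective_radius: float = 10.0,
    min_bout: float = 1.0,
) -> LocomotionMask:
    """Segment a head-fixed session from platter angular velocity.

    The linear-speed threshold (cm/s) is converted to an angular threshold
    ``omega_th = linear_threshold / effective_radius`` (rad/s), where
    ``effective_radius`` (cm) is the animal's distance from the rotation axis.
    """
    if effective_radius <= 0:
        raise ConfigurationError("effective_radius must be positive")
    # |omega| >= linear_threshold / effective_radius, expressed as an
    # equivalent linear speed so the same segmentation rule applies
    equivalent_speed = np.abs(platter.omega) * effective_radius
    return segment_locomotion(
        equivalent_speed,
        frame_rate=platter.frame_rate,
        threshold=linear_threshold,
        min_bout=min_bout,
    )


def percent_change(mean_a: float, mean_b: float, rounding: str = "truncate") -> float:
    """Percent change of A relative to B: (A - B) / B * 100.

    ``rounding`` is "truncate" (toward zero, the convention matching integer
    percent reporting of session means), "nearest", or "none".
    """
    if mean_b == 0:
        return math.nan
    pct = (mean_a - mean_b) / mean_b * 100.0
    if rounding == "truncate":
        return float(math.trunc(pct))
    if rounding == "nearest":
        return float(round(pct))
    if rounding == "none":
        return float(pct)
    raise ConfigurationError(f"unknown rounding mode: {rounding!r}")


def session_summary_table(
    sessions: pd.DataFrame,
    metrics: tuple[str, ...] = ("walking_distance", "turning_angle"),
    pairs: tuple[tuple[str, str], ...] = (("on", "off"), ("on", "free"), ("free", "off")),
    rounding: str = "truncate",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Condition means and pairwise percent changes from per-session summaries.

    ``sessions`` is tidy with one row per session and columns ``condition`` plus
    the metric columns.  Returns ``(means, changes)``; a comparison against a
    zero mean is flagged in the ``undefined`` column rather than dropped.
    """
    if "condition" not in sessions.columns:
        raise ConfigurationError("sessions table must have a 'condition' column")
    for m in metrics:
        if m not in sessions.columns:
            raise ConfigurationError(f"sessions table lacks metric column {m!r}")
    means = sessions.groupby("condition", sort=False)[list(metrics)].mean()
    rows = []
    for a, b in pairs:
        if a not in means.index or b not in means.index:
            continue
        for m in metrics:
            ma, mb = float(means.loc[a, m]), float(means.loc[b, m])
            rows.append(
                {
                    "comparison": f"{a}_vs_{b}",
                    "metric": m,
                    "mean_a": ma,
                    "mean_b": mb,
                    "percent_change": percent_change(ma, mb, rounding=rounding),
                    "undefined": mb == 0,
                }
            )
    return means, pd.DataFrame(rows)


def bonferroni(p_values: np.ndarray | float, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p)."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    return np.minimum(1.0, m * p)
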