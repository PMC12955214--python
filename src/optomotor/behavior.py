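"""Scoring of walking optomotor responses from rotating-drum trajectories.

An animal walking freely in a small container at the center of a
rotating striped drum circles in the direction of pattern motion once
the optomotor response engages.  The turning velocity is recovered from
the period of full body rotations: the y-position time trace of a
circling animal is (quasi-)sinusoidal, and the spacing ``dt`` of its
successive positive peaks is the time for one 360-degree rotation, so

    R = 360 deg / mean(dt)        (deg/s)

signed positive when the animal circles with the pattern and negative
against it.  Before scoring, trajectories are discarded when the animal
followed the container wall for more than 3 s (wall-following rather
than a visual response) or walked for less than 10 s in total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "ArenaGeometry",
    "StimulusCondition",
    "Trajectory",
    "RotationSegments",
    "ResponseMeasurement",
    "apply_exclusion_filters",
    "smoothed_speed",
    "detect_rotation_periods",
    "circling_direction",
    "response_from_periods",
    "score_trajectory",
    "normalize_responses",
    "normalize_group",
    "apparent_wavelength",
    "egocentric_correction",
    "pattern_speed_from_marker",
    "onset_latency",
    "assemble_tuning_curve",
]


@dataclass(frozen=True)
class ArenaGeometry:
    """Rotating-drum arena dimensions (mm) and camera frame rate (Hz).

    Defaults describe a 190 mm diameter pattern drum around a stationary
    140 mm translucent cylinder, with the animal walking in a 30 mm
    container at the center; the animal-to-pattern distance therefore
    ranges between 80 and 110 mm.
    """

    drum_radius: float = 95.0
    inner_cylinder_radius: float = 70.0
    container_radius: float = 15.0
    frame_rate: float = 60.0

    def __post_init__(self) -> None:
        if not (self.container_radius < self.inner_cylinder_radius < self.drum_radius):
            raise ValueError(
                "require container < inner cylinder < drum radius, got "
                f"({self.container_radius}, {self.inner_cylinder_radius}, "
                f"{self.drum_radius})"
            )
        if not self.frame_rate > 0:
            raise ValueError(f"frame rate must be > 0, got {self.frame_rate}")

    @property
    def min_animal_pattern_distance(self) -> float:
        return self.drum_radius - self.container_radius

    @property
    def max_animal_pattern_distance(self) -> float:
        return self.drum_radius + self.container_radius

    @property
    def drum_circumference_m(self) -> float:
        """Drum circumference in metres, ``pi * 2 * drum_radius``."""
        return math.pi * 2.0 * self.drum_radius / 1000.0


@dataclass(frozen=True)
class StimulusCondition:
    """Grating stimulus: spatial wavelength (deg) and signed drum velocity (deg/s).

    Positive ``angular_velocity`` denotes counterclockwise pattern motion
    in the camera view (mathematically positive sense).
    """

    wavelength: float
    angular_velocity: float

    def __post_init__(self) -> None:
        if not self.wavelength > 0:
            raise ValueError(f"wavelength must be > 0, got {self.wavelength}")

    @property
    def temporal_frequency(self) -> float:
        """Signed temporal frequency f = v / lambda (Hz)."""
        return self.angular_velocity / self.wavelength

    @property
    def direction(self) -> int:
        return 1 if self.angular_velocity >= 0 else -1


@dataclass
class Trajectory:
    """A tracked walking path: times (s) and x/y positions (mm)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    animal_id: object = None
    condition: Optional[StimulusCondition] = None
    excluded: bool = False
    exclusion_reasons: List[str] = field(default_factory=list)
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape) or self.t.ndim != 1:
            raise ValueError("t, x, y must be 1-D arrays of equal length")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("sample times must be strictly increasing")

    @property
    def frame_rate(self) -> float:
        if self.t.size < 2:
            raise ValueError("need >= 2 samples to infer a frame rate")
        return 1.0 / float(np.median(np.diff(self.t)))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class RotationSegments:
    """Detected full-rotation periods from the y-position trace."""

    peak_times: np.ndarray  # s
    periods: np.ndarray  # s, successive peak-time differences
    no_rotation: bool = False


@dataclass
class ResponseMeasurement:
    """Signed optomotor response of one trajectory."""

    response: float  # R, deg/s, signed
    normalized: Optional[float] = None  # filled by normalize_responses
    mean_distance_from_center: Optional[float] = None  # mm
    onset_latency: Optional[float] = None  # s
    n_rotations: int = 0


def _moving_average(values: np.ndarray, window_frames: int) -> np.ndarray:
    """Centered moving average with edge shrinkage (window forced odd, >= 1)."""
    window_frames = max(1, int(window_frames))
    if window_frames % 2 == 0:
        window_frames += 1
    if window_frames == 1 or values.size < 2:
        return values.astype(float)
    kernel = np.ones(window_frames)
    summed = np.convolve(values, kernel, mode="same")
    counts = np.convolve(np.ones_like(values, dtype=float), kernel, mode="same")
    return summed / counts


def smoothed_speed(traj: Trajectory, window: float = 0.25) -> np.ndarray:
    """Instantaneous walking speed (mm/s) robust to tracking jitter.

    Positions are smoothed by a centered moving average of ``window``
    seconds and the speed taken as the path displacement across that
    window divided by its duration, so uncorrelated per-frame position
    noise is attenuated rather than integrated into spurious speed.
    """
    if traj.t.size < 2:
        return np.zeros_like(traj.t)
    fr = traj.frame_rate
    w = max(1, int(round(window * fr)))
    xs = _moving_average(traj.x, w)
    ys = _moving_average(traj.y, w)
    half = max(1, w // 2)
    idx = np.arange(traj.t.size)
    lo = np.clip(idx - half, 0, traj.t.size - 1)
    hi = np.clip(idx + half, 0, traj.t.size - 1)
    dt = traj.t[hi] - traj.t[lo]
    dt[dt == 0] = np.inf
    return np.hypot(xs[hi] - xs[lo], ys[hi] - ys[lo]) / dt


def apply_exclusion_filters(
    traj: Trajectory,
    arena: ArenaGeometry = ArenaGeometry(),
    walk_speed_threshold: float = 0.5,
    wall_epsilon: float = 0.5,
    max_wall_time: float = 3.0,
    min_walk_time: float = 10.0,
    smoothing_window: float = 0.25,
) -> Trajectory:
    """Flag trajectories that fail either quality rule (flags, no exception).

    Rule "wall_following": the radial distance stays within
    ``wall_epsilon`` (mm) of the container radius for a contiguous span
    longer than ``max_wall_time`` (s).  Rule "short_walk": cumulative
    time at speed above ``walk_speed_threshold`` (mm/s) is less than
    ``min_walk_time`` (s).  Both rules are always evaluated, so the
    flagged set does not depend on rule order.
    """
    if traj.t.size == 0:
        raise ValueError("empty trajectory")
    reasons: List[str] = []

    radial = np.hypot(traj.x, traj.y)
    on_wall = np.abs(radial - arena.container_radius) <= wall_epsilon
    if traj.t.size >= 2 and on_wall.any():
        dt = np.diff(traj.t)
        longest = 0.0
        run = 0.0
        for k in range(dt.size):
            if on_wall[k] and on_wall[k + 1]:
                run += dt[k]
                longest = max(longest, run)
            else:
                run = 0.0
        if longest > max_wall_time:
            reasons.append("wall_following")

    speed = smoothed_speed(traj, smoothing_window)
    if traj.t.size >= 2:
        dt = np.diff(traj.t)
        walking = (speed[:-1] > walk_speed_threshold) & (
            speed[1:] > walk_speed_threshold
        )
        walk_time = float(np.sum(dt[walking]))
    else:
        walk_time = 0.0
    if walk_time < min_walk_time:
        reasons.append("short_walk")

    traj.excluded = bool(reasons)
    traj.exclusion_reasons = reasons
    return traj


def detect_rotation_periods(
    traj: Trajectory,
    smoothing_window: float = 0.25,
    min_prominence: float = 1.0,
) -> RotationSegments:
    """Full-rotation periods from positive peaks of the y-position trace.

    The y trace is smoothed by a centered moving average of
    ``smoothing_window`` seconds; local maxima with prominence of at
    least ``min_prominence`` (mm) mark the top of each walking circle,
    and successive peak spacings are the 360-degree rotation periods.
    Fewer than two peaks yields an empty period list flagged
    ``no_rotation``, not an exception.
    """
    if traj.t.size < 3:
        return RotationSegments(np.array([]), np.array([]), no_rotation=True)
    w = max(1, int(round(smoothing_window * traj.frame_rate)))
    ys = _moving_average(traj.y, w)
    peaks, _ = find_peaks(ys, prominence=min_prominence)
    peak_times = traj.t[peaks]
    if peak_times.size < 2:
        return RotationSegments(peak_times, np.array([]), no_rotation=True)
    return RotationSegments(peak_times, np.diff(peak_times))


def circling_direction(traj: Trajectory) -> int:
    """Sense of circling: +1 counterclockwise, -1 clockwise.

    Taken from the net unwrapped phase progression of
    ``atan2(y - y_c, x - x_c)`` around the path centroid.
    """
    xc, yc = float(np.mean(traj.x)), float(np.mean(traj.y))
    phase = np.unwrap(np.arctan2(traj.y - yc, traj.x - xc))
    net = phase[-1] - phase[0]
    return 1 if net >= 0 else -1


def response_from_periods(
    segments: RotationSegments, direction_sign: int = 1
) -> Optional[ResponseMeasurement]:
    """Optomotor response R = 360 / mean(dt), signed by ``direction_sign``.

    ``direction_sign`` is +1 when the animal circles with the pattern
    (co-directional) and -1 against it.  Returns ``None`` when no
    rotation period was detected.
    """
    if direction_sign not in (1, -1):
        raise ValueError(f"direction_sign must be +1 or -1, got {direction_sign}")
    if segments.periods.size == 0:
        return None
    mean_period = float(np.mean(segments.periods))
    return ResponseMeasurement(
        response=direction_sign * 360.0 / mean_period,
        n_rotations=int(segments.periods.size),
    )


def score_trajectory(
    traj: Trajectory,
    arena: ArenaGeometry = ArenaGeometry(),
    condition: Optional[StimulusCondition] = None,
    smoothing_window: float = 0.25,
    min_prominence: float = 1.0,
    drum_start_time: Optional[float] = None,
    **filter_kwargs,
) -> Optional[ResponseMeasurement]:
    """Filter, detect rotations, and score one trajectory end to end.

    Returns ``None`` for excluded trajectories and for retained ones
    with no detectable rotation.  The sign compares the animal's
    circling sense with the stimulus direction (``condition``, default
    co-directional).
    """
    traj = apply_exclusion_filters(
        traj, arena, smoothing_window=smoothing_window, **filter_kwargs
    )
    if traj.excluded:
        return None
    segments = detect_rotation_periods(traj, smoothing_window, min_prominence)
    pattern_sign = condition.direction if condition is not None else 1
    measurement = response_from_periods(
        segments, circling_direction(traj) * pattern_sign
    )
    if measurement is None:
        return None
    measurement.mean_distance_from_center = float(
        np.mean(np.hypot(traj.x, traj.y))
    )
    if drum_start_time is not None:
        measurement.onset_latency = onset_latency(traj, drum_start_time)
    return measurement


def normalize_group(responses: Sequence[float]) -> np.ndarray:
    """Normalize a group of signed responses by its maximum magnitude.

    The normalization preserves sign and argmax and is idempotent; an
    all-zero group cannot be normalized and raises.
    """
    values = np.asarray(responses, dtype=float)
    peak = float(np.max(np.abs(values))) if values.size else 0.0
    if peak == 0:
        raise ValueError("cannot normalize an all-zero response group")
    return values / peak


def normalize_responses(
    table: pd.DataFrame,
    by: str = "experiment",
    value_col: str = "response",
    out_col: str = "normalized",
) -> pd.DataFrame:
    """Per-experiment normalization of a response table.

    Each response is divided by the maximum response magnitude within
    its ``by`` group (one experiment = one animal's condition series,
    unless a different grouping key is supplied).  Groups whose responses
    are all zero are flagged in a boolean ``<out_col>_undefined`` column
    and left as NaN.
    """
    table = table.copy()
    table[out_col] = np.nan
    table[out_col + "_undefined"] = False
    for _, idx in table.groupby(by).groups.items():
        values = table.loc[idx, value_col].to_numpy(dtype=float)
        peak = float(np.max(np.abs(values))) if values.size else 0.0
        if peak == 0:
            table.loc[idx, out_col + "_undefined"] = True
        else:
            table.loc[idx, out_col] = values / peak
    return table


def apparent_wavelength(
    wavelength: float, distance: float, drum_radius: float = 95.0
) -> float:
    """Apparent grating wavelength (deg) at a given animal-pattern distance.

    A stripe subtending ``wavelength`` degrees from the arena center
    spans an arc of fixed length on the drum; seen from ``distance`` mm
    it subtends approximately ``wavelength * drum_radius / distance``
    degrees — larger when the animal is nearer the pattern, smaller when
    farther, and identical at the center (``distance == drum_radius``).
    """
    if not distance > 0:
        raise ValueError(f"distance must be > 0, got {distance}")
    return wavelength * drum_radius / distance


@dataclass(frozen=True)
class ApparentStimulus:
    """Egocentric stimulus correction for one trajectory."""

    nominal: StimulusCondition
    mean_distance_from_center: float  # mm
    wavelength_near: float  # deg, at drum_radius - mean offset
    wavelength_far: float  # deg, at drum_radius + mean offset


def egocentric_correction(
    traj: Trajectory,
    condition: StimulusCondition,
    arena: ArenaGeometry = ArenaGeometry(),
) -> ApparentStimulus:
    """Apparent-wavelength bounds given the animal's mean offset from center.

    The nominal condition remains the analysis default — within the
    container the apparent-wavelength deviation is small — but the
    near/far apparent wavelengths are reported for any position check.
    """
    offset = float(np.mean(np.hypot(traj.x, traj.y)))
    return ApparentStimulus(
        nominal=condition,
        mean_distance_from_center=offset,
        wavelength_near=apparent_wavelength(
            condition.wavelength, arena.drum_radius - offset, arena.drum_radius
        ),
        wavelength_far=apparent_wavelength(
            condition.wavelength, arena.drum_radius + offset, arena.drum_radius
        ),
    )


def pattern_speed_from_marker(
    marker_angles: np.ndarray,
    n_rotations: int = 10,
    frame_rate: float = 120.0,
) -> float:
    """Drum speed (deg/s) from a tracked marker-angle trace.

    The per-frame marker angles (deg) are unwrapped and the speed is
    ``n_rotations * 360`` divided by the time the marker needed to
    sweep that total rotation.
    """
    angles = np.unwrap(np.deg2rad(np.asarray(marker_angles, dtype=float)))
    total = np.abs(np.degrees(angles - angles[0]))
    target = n_rotations * 360.0
    reached = np.nonzero(total >= target)[0]
    if reached.size == 0:
        achieved = float(total[-1] / 360.0)
        raise ValueError(
            f"marker trace covers only {achieved:.2f} rotations, "
            f"requested {n_rotations}"
        )
    frames = int(reached[0])
    return target / (frames / frame_rate)


def onset_latency(
    traj: Trajectory,
    drum_start_time: float = 0.0,
    min_turn_rate: float = 45.0,
    sustain: float = 0.5,
    smoothing_window: float = 0.25,
    min_speed: float = 0.5,
) -> Optional[float]:
    """Latency (s) from drum start to the onset of sustained circling.

    Circling onset is the first time after ``drum_start_time`` at which
    the smoothed heading turn rate exceeds ``min_turn_rate`` (deg/s)
    continuously for at least ``sustain`` seconds while the animal moves
    faster than ``min_speed`` (mm/s).  ``None`` when the animal never
    circles.
    """
    if traj.t.size < 5:
        return None
    fr = traj.frame_rate
    w = max(1, int(round(smoothing_window * fr)))
    xs = _moving_average(traj.x, w)
    ys = _moving_average(traj.y, w)
    # heading and turn rate from centered differences across the smoothing
    # window: per-frame derivatives would integrate tracking jitter
    half = max(1, w // 2)
    idx = np.arange(traj.t.size)
    lo = np.clip(idx - half, 0, traj.t.size - 1)
    hi = np.clip(idx + half, 0, traj.t.size - 1)
    dt = traj.t[hi] - traj.t[lo]
    dt[dt == 0] = np.inf
    speed = np.hypot(xs[hi] - xs[lo], ys[hi] - ys[lo]) / dt
    heading = np.unwrap(np.arctan2(ys[hi] - ys[lo], xs[hi] - xs[lo]))
    turn_rate = np.abs(np.degrees((heading[hi] - heading[lo]) / dt))
    circling = (turn_rate > min_turn_rate) & (speed > min_speed) & (
        traj.t >= drum_start_time
    )
    need = max(1, int(round(sustain * fr)))
    run = 0
    for k, flag in enumerate(circling):
        run = run + 1 if flag else 0
        if run >= need:
            start_idx = k - need + 1
            # refine: the centered-window turn rate crosses half of the
            # circling plateau exactly when the window center sits on the
            # onset, so that crossing is an unbiased onset estimate
            plateau = float(np.median(turn_rate[start_idx : k + 1]))
            before = turn_rate[
                (traj.t >= drum_start_time) & (traj.t < traj.t[start_idx] - 1.0)
            ]
            pre_level = float(np.median(before)) if before.size else 0.0
            pre_level = min(pre_level, min_turn_rate)
            cross = 0.5 * (pre_level + plateau)
            j = start_idx
            if turn_rate[j] >= cross:
                while (
                    j > 0
                    and turn_rate[j - 1] >= cross
                    and traj.t[j - 1] >= drum_start_time
                ):
                    j -= 1
            else:
                while j < k and turn_rate[j] < cross:
                    j += 1
            return float(max(0.0, traj.t[j] - drum_start_time))
    return None


def assemble_tuning_curve(
    responses: pd.DataFrame,
    wavelength_col: str = "wavelength",
    velocity_col: str = "velocity",
    value_col: str = "normalized",
) -> pd.DataFrame:
    """Condition-wise tuning curve: mean, SD, N per (wavelength, velocity).

    One row per stimulus condition, sorted by wavelength then velocity,
    with the temporal frequency ``f = v / lambda`` as an alternate key.
    """
    if responses.empty:
        raise ValueError("no responses to assemble")
    grouped = (
        responses.groupby([wavelength_col, velocity_col])[value_col]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="size")
        .reset_index()
    )
    grouped = grouped.rename(
        columns={wavelength_col: "wavelength", velocity_col: "velocity"}
    )
    grouped["temporal_frequency"] = grouped["velocity"] / grouped["wavelength"]
    return grouped.sort_values(["wavelength", "velocity"]).reset_index(drop=True)
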