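"""Synthetic marker sets, walking trajectories, and tuning-curve data.

No raw micro-CT marker tables or tracked walking videos accompany the
study conditions this package analyzes, so every downstream stage is
exercised against generated data whose ground truth is known exactly:

* a synthetic compound eye — ommatidial visual axes on a jittered
  spherical-cap lattice calibrated so the mean interommatidial angle of
  the neighbor graph hits a target (default 17.8 deg), each lens with a
  drawn diameter, six base-rim markers, outer/inner tip markers and a
  rhabdomere marker, plus ocelli defining the head frame;
* a synthetic walking bout — a low-curvature random walk before the
  response onset latency, circular walking at a signed ground-truth
  turning velocity after it, optional terminal resting and optional
  wall-following spans;
* synthetic tuning curves — closed-form EMD responses at a known time
  constant with additive noise, renormalized per replicate.

All randomness in a generator flows from the single seed in its spec:
the same seed reproduces every number bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .behavior import Trajectory
from .emd import EMDParams, emd_response
from .eye_geometry import LensMarkerSet, build_neighbor_graph, interommatidial_angles

__all__ = [
    "SyntheticEyeSpec",
    "SyntheticWalkSpec",
    "SyntheticTuningSpec",
    "EyeGroundTruth",
    "SyntheticEye",
    "eye_markers_from_axes",
    "generate_synthetic_eye",
    "generate_walk_trajectory",
    "generate_tuning_dataset",
    "CANONICAL_OCELLI",
]

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))

#: Ocelli triangle in the canonical head pose: centroid at the origin,
#: plane normal along +z, first ocellus on +x.
CANONICAL_OCELLI = np.array(
    [
        [10.0, 0.0, 0.0],
        [-5.0, 8.66025403784438646, 0.0],
        [-5.0, -8.66025403784438646, 0.0],
    ]
)


def _require(condition: bool, fieldname: str, message: str) -> None:
    if not condition:
        raise ValueError(f"invalid {fieldname}: {message}")


# ---------------------------------------------------------------------------
# synthetic compound eye
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticEyeSpec:
    """Parameters of the synthetic compound eye.

    Defaults emulate the miniature-thrips eye: ~60 ommatidia per side,
    mean interommatidial angle 17.8 deg (SD 4.4 deg), mean lens diameter
    8.76 um (SD 0.76 um), outer/inner lens half thickness 1.61/1.28 um,
    rhabdomere tips 15 um beneath the lens base.
    """

    n_ommatidia: int = 60
    target_io_angle: float = 17.8  # deg, mean interommatidial angle
    io_angle_sd: float = 4.4  # deg
    lens_diameter_mean: float = 8.76  # um
    lens_diameter_sd: float = 0.76  # um
    outer_half_thickness: float = 1.61  # um
    inner_half_thickness: float = 1.28  # um
    # depth of the cone/rhabdomere transition below the lens base; at the
    # default eye radius this yields ~5.8 um spacing between neighboring
    # rhabdomere tips, the measured photoreceptor separation
    rhabdomere_depth: float = 9.5  # um
    marker_noise_sd: float = 0.0  # um, isotropic on every marker
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_ommatidia >= 3, "n_ommatidia", "must be >= 3")
        _require(0 < self.target_io_angle < 90, "target_io_angle", "must be in (0, 90) deg")
        _require(self.io_angle_sd >= 0, "io_angle_sd", "must be >= 0")
        for name in (
            "lens_diameter_mean",
            "outer_half_thickness",
            "inner_half_thickness",
            "rhabdomere_depth",
        ):
            _require(getattr(self, name) > 0, name, "must be > 0")
        _require(self.lens_diameter_sd >= 0, "lens_diameter_sd", "must be >= 0")
        _require(self.marker_noise_sd >= 0, "marker_noise_sd", "must be >= 0")


@dataclass
class EyeGroundTruth:
    """Exact per-ommatidium quantities the generator built the eye from."""

    axes: np.ndarray  # (n, 3) unit visual axes (= base normals)
    lens_centers: np.ndarray  # (n, 3) um
    lens_diameters: np.ndarray  # (n,) um
    h_outer: float  # um
    h_inner: float  # um
    eye_radius: float  # um
    edges: set  # neighbor edges on the ground-truth centers
    io_angles: dict  # per-edge interommatidial angle, deg
    io_mean: float  # deg
    io_sd: float  # deg


@dataclass
class SyntheticEye:
    """Generated marker sets plus the ground truth behind them."""

    markers: List[LensMarkerSet]
    ocelli: np.ndarray  # (3, 3)
    truth: EyeGroundTruth
    spec: Optional[SyntheticEyeSpec] = None

    def truth_table(self) -> pd.DataFrame:
        """Ground truth as a per-ommatidium table (axis, center, diameter)."""
        t = self.truth
        return pd.DataFrame(
            {
                "ommatidium_id": [m.ommatidium_id for m in self.markers],
                "axis_x": t.axes[:, 0],
                "axis_y": t.axes[:, 1],
                "axis_z": t.axes[:, 2],
                "center_x_um": t.lens_centers[:, 0],
                "center_y_um": t.lens_centers[:, 1],
                "center_z_um": t.lens_centers[:, 2],
                "lens_diameter_um": t.lens_diameters,
            }
        )


def _tangent_basis(axis: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal pair perpendicular to a unit vector."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis[2]) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(axis, e1)


def eye_markers_from_axes(
    axes: np.ndarray,
    diameters,
    eye_radius: float,
    outer_half_thickness: float,
    inner_half_thickness: float,
    rhabdomere_depth: float,
    marker_noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    side: str = "right",
) -> List[LensMarkerSet]:
    """Exact marker sets for given unit visual axes (noise optional).

    Each lens base is a circle of the given diameter centered at
    ``eye_radius * axis`` in the plane perpendicular to the axis, sampled
    at six equally spaced rim points; tips sit on the axis at the half
    thicknesses and the rhabdomere marker at ``rhabdomere_depth`` inward.
    With ``marker_noise_sd == 0`` the construction is exact, so full
    reconstruction recovers every ground-truth quantity.
    """
    axes = np.atleast_2d(np.asarray(axes, dtype=float))
    diameters = np.broadcast_to(np.asarray(diameters, dtype=float), (axes.shape[0],))
    if marker_noise_sd > 0 and rng is None:
        raise ValueError("marker noise requested but no rng supplied")
    rim_angles = np.deg2rad(np.arange(6) * 60.0)
    markers = []
    for i, axis in enumerate(axes):
        axis = axis / np.linalg.norm(axis)
        center = eye_radius * axis
        e1, e2 = _tangent_basis(axis)
        radius = diameters[i] / 2.0
        base = (
            center
            + radius * np.outer(np.cos(rim_angles), e1)
            + radius * np.outer(np.sin(rim_angles), e2)
        )
        outer = center + outer_half_thickness * axis
        inner = center - inner_half_thickness * axis
        rhabdomere = center - rhabdomere_depth * axis
        if marker_noise_sd > 0:
            base = base + rng.normal(0.0, marker_noise_sd, base.shape)
            outer = outer + rng.normal(0.0, marker_noise_sd, 3)
            inner = inner + rng.normal(0.0, marker_noise_sd, 3)
            rhabdomere = rhabdomere + rng.normal(0.0, marker_noise_sd, 3)
        markers.append(
            LensMarkerSet(
                ommatidium_id=i,
                outer_tip=outer,
                inner_tip=inner,
                base_points=base,
                rhabdomere_tip=rhabdomere,
                side=side,
            )
        )
    return markers


def _cap_axes(
    n: int, scale: float, theta0: np.ndarray, phi0: np.ndarray,
    dtheta: np.ndarray, dphi: np.ndarray,
) -> np.ndarray:
    """Unit axes of the jittered spiral cap lattice at polar scale ``scale``."""
    theta = np.clip(scale * theta0 + dtheta, 1e-4, math.pi - 1e-4)
    sin_base = np.maximum(np.sin(np.clip(scale * theta0, 1e-4, math.pi - 1e-4)), 0.2)
    phi = phi0 + dphi / sin_base
    return np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )


def generate_synthetic_eye(spec: SyntheticEyeSpec) -> SyntheticEye:
    """Generate one synthetic eye with stored ground truth.

    Visual axes are laid out on a spiral (sunflower) lattice over a
    spherical cap.  The cap size is initialized from a hexagonal-packing
    estimate and then calibrated by iterative rescaling of the polar
    angles until the mean neighbor-graph interommatidial angle matches
    ``target_io_angle``; per-axis angular jitter spreads the angles with
    roughly the requested SD.  Only the first two moments of the angle
    distribution are matched — the real eye's layout is not modeled.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_ommatidia

    target_rad = math.radians(spec.target_io_angle)
    # hexagonal-packing estimate of the cap solid angle for the target spacing
    omega = min((math.sqrt(3.0) / 2.0) * n * target_rad**2, 4.0 * math.pi * 0.98)
    cos_cap = 1.0 - omega / (2.0 * math.pi)
    theta_cap = math.acos(max(-1.0, min(1.0, cos_cap)))

    idx = np.arange(n)
    # spiral lattice over the cap, offset so no point sits exactly on the pole
    z = 1.0 - (1.0 - math.cos(theta_cap)) * (idx + 0.5) / n
    theta0 = np.arccos(np.clip(z, -1.0, 1.0))
    phi0 = idx * _GOLDEN_ANGLE

    jitter_sd = math.radians(spec.io_angle_sd) / math.sqrt(2.0)
    dtheta = rng.normal(0.0, jitter_sd, n)
    dphi = rng.normal(0.0, jitter_sd, n)

    scale = 1.0
    axes = _cap_axes(n, scale, theta0, phi0, dtheta, dphi)
    for _ in range(40):
        edges = build_neighbor_graph(axes, method="hull")
        _, summary = interommatidial_angles(axes, edges)
        mean = summary["mean"]
        if abs(mean - spec.target_io_angle) < 1e-4 * spec.target_io_angle:
            break
        scale = min(scale * spec.target_io_angle / mean, math.pi / theta0[-1] * 0.98)
        axes = _cap_axes(n, scale, theta0, phi0, dtheta, dphi)
    edges = build_neighbor_graph(axes, method="hull")
    io_angles, summary = interommatidial_angles(axes, edges)

    diameters = rng.normal(spec.lens_diameter_mean, spec.lens_diameter_sd, n)
    diameters = np.clip(diameters, 0.2 * spec.lens_diameter_mean, None)
    # eye radius such that lenses of the mean diameter roughly tile the cap
    eye_radius = spec.lens_diameter_mean / target_rad

    markers = eye_markers_from_axes(
        axes,
        diameters,
        eye_radius,
        spec.outer_half_thickness,
        spec.inner_half_thickness,
        spec.rhabdomere_depth,
        marker_noise_sd=spec.marker_noise_sd,
        rng=rng,
    )
    truth = EyeGroundTruth(
        axes=axes,
        lens_centers=eye_radius * axes,
        lens_diameters=diameters,
        h_outer=spec.outer_half_thickness,
        h_inner=spec.inner_half_thickness,
        eye_radius=eye_radius,
        edges=edges,
        io_angles=io_angles,
        io_mean=summary["mean"],
        io_sd=summary["sd"],
    )
    return SyntheticEye(
        markers=markers, ocelli=CANONICAL_OCELLI.copy(), truth=truth, spec=spec
    )


# ---------------------------------------------------------------------------
# synthetic walking trajectory
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticWalkSpec:
    """Parameters of one synthetic walking bout.

    Defaults emulate the behavioral assay conditions: 68 s recordings at
    60 frames/s in a 15 mm radius container, circling onset latency
    1.76 s (SD 1.0 s) after drum start.  ``turning_velocity`` is the
    signed ground-truth circling velocity (deg/s, positive =
    counterclockwise); ``rest_fraction`` reserves the end of the
    recording for a resting bout and ``wall_follow_span`` glues the
    first seconds of the path to the container wall.
    """

    turning_velocity: float = 120.0  # deg/s, signed
    path_radius: float = 5.0  # mm
    onset_latency_mean: float = 1.76  # s
    onset_latency_sd: float = 1.0  # s
    duration: float = 68.0  # s
    frame_rate: float = 60.0  # Hz
    position_noise_sd: float = 0.0  # mm
    rest_fraction: float = 0.0  # in [0, 1)
    wall_follow_span: float = 0.0  # s, 0 = none
    container_radius: float = 15.0  # mm
    pre_onset_speed: float = 5.0  # mm/s
    heading_diffusion: float = 10.0  # deg per sqrt(s), pre-onset random walk
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.duration > 0, "duration", "must be > 0")
        _require(self.frame_rate > 0, "frame_rate", "must be > 0")
        _require(self.path_radius > 0, "path_radius", "must be > 0")
        _require(0 <= self.rest_fraction < 1, "rest_fraction", "must be in [0, 1)")
        _require(
            self.wall_follow_span <= self.duration,
            "wall_follow_span",
            "must not exceed duration",
        )
        _require(self.wall_follow_span >= 0, "wall_follow_span", "must be >= 0")
        _require(self.onset_latency_sd >= 0, "onset_latency_sd", "must be >= 0")
        _require(self.position_noise_sd >= 0, "position_noise_sd", "must be >= 0")
        _require(
            self.path_radius + 3.0 * self.position_noise_sd < self.container_radius,
            "path_radius",
            "circling path plus noise must fit inside the container",
        )


def generate_walk_trajectory(spec: SyntheticWalkSpec) -> Trajectory:
    """One synthetic walking bout with stored ground truth.

    Before the (seeded, truncated-normal) onset latency the animal walks
    at constant speed with slowly diffusing heading, reflected off the
    container wall; from onset it circles at the signed ground-truth
    turning velocity on ``path_radius``, position-continuous with the
    preceding walk; an optional terminal fraction rests in place.  The
    true turning velocity and onset time are stored on the trajectory.
    """
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.frame_rate
    n = int(round(spec.duration * spec.frame_rate)) + 1
    t = np.arange(n) * dt

    latency = max(0.0, rng.normal(spec.onset_latency_mean, spec.onset_latency_sd))
    latency = min(latency, spec.duration)
    rest_start = spec.duration * (1.0 - spec.rest_fraction)
    margin = 1.0 + 3.0 * spec.position_noise_sd
    safe_radius = spec.container_radius - margin

    x = np.empty(n)
    y = np.empty(n)

    # wall-following span occupies the start of the recording
    wall_end = spec.wall_follow_span
    wall_omega = spec.pre_onset_speed / spec.container_radius  # rad/s along the wall
    wall_phase0 = rng.uniform(0.0, 2.0 * math.pi)

    heading = rng.uniform(0.0, 2.0 * math.pi)
    sigma_step = math.radians(spec.heading_diffusion) * math.sqrt(dt)
    pos = np.array([rng.uniform(-0.3, 0.3) * safe_radius,
                    rng.uniform(-0.3, 0.3) * safe_radius])

    onset = max(latency, wall_end)
    circle_center = None
    phase0 = 0.0

    for k in range(n):
        tk = t[k]
        if tk < wall_end:
            psi = wall_phase0 + wall_omega * tk
            pos = spec.container_radius * np.array([math.cos(psi), math.sin(psi)])
        elif tk >= rest_start and k > 0:
            pos = np.array([x[k - 1], y[k - 1]])  # resting: speed ~ 0
        elif tk < onset:
            heading += rng.normal(0.0, sigma_step)
            step = spec.pre_onset_speed * dt
            cand = pos + step * np.array([math.cos(heading), math.sin(heading)])
            if np.linalg.norm(cand) > safe_radius:
                # turn back toward the center and retake the step
                heading = math.atan2(-pos[1], -pos[0]) + rng.normal(0.0, 0.3)
                cand = pos + step * np.array([math.cos(heading), math.sin(heading)])
            pos = cand
        else:
            if circle_center is None:
                limit = safe_radius - spec.path_radius
                if limit <= 0:
                    raise ValueError("circling path does not fit inside the container")
                # prefer the circle tangent to the current heading (the
                # animal turns onto it without a heading jump); the center
                # lies on the left of the velocity for counterclockwise
                # circling, on the right for clockwise
                side = 1.0 if spec.turning_velocity >= 0 else -1.0
                normal = np.array([-math.sin(heading), math.cos(heading)])
                center = pos + side * spec.path_radius * normal
                if np.linalg.norm(center) > limit:
                    # tangent circle would leave the container: place the
                    # circle through the current position, center pulled
                    # inward (heading jumps once)
                    d = np.linalg.norm(pos)
                    u = pos / d if d > 1e-9 else np.array([1.0, 0.0])
                    center = pos - spec.path_radius * u
                    cd = np.linalg.norm(center)
                    if cd > limit:
                        center = center / cd * limit
                circle_center = center
                rel = pos - circle_center
                phase0 = math.atan2(rel[1], rel[0])
            phase = phase0 + math.radians(spec.turning_velocity) * (tk - onset)
            pos = circle_center + spec.path_radius * np.array(
                [math.cos(phase), math.sin(phase)]
            )
        x[k], y[k] = pos

    if spec.position_noise_sd > 0:
        wall_mask = t < wall_end
        noise = rng.normal(0.0, spec.position_noise_sd, (n, 2))
        noise[wall_mask] = 0.0  # wall spans stay glued to the circumference
        x = x + noise[:, 0]
        y = y + noise[:, 1]
        radial = np.hypot(x, y)
        over = radial > spec.container_radius
        over &= ~wall_mask
        if over.any():
            shrink = spec.container_radius / radial[over]
            x[over] *= shrink
            y[over] *= shrink

    return Trajectory(
        t=t,
        x=x,
        y=y,
        ground_truth={
            "turning_velocity": spec.turning_velocity,
            "onset_time": onset,
            "latency": latency,
            "rest_start": rest_start if spec.rest_fraction > 0 else None,
        },
    )


# ---------------------------------------------------------------------------
# synthetic tuning curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticTuningSpec:
    """Parameters of a synthetic optomotor tuning-curve dataset.

    Defaults emulate the behavioral protocol at 60 deg wavelength with
    seven drum velocities spanning ~30-700 deg/s, EMD time constant
    41 ms, interommatidial angle 17.8 deg and acceptance angle 17.7 deg.
    ``noise_sd`` is additive on the normalized response; each replicate
    curve is renormalized to its own maximum magnitude.
    """

    tau_true: float = 0.041  # s
    wavelengths: Tuple[float, ...] = (60.0,)  # deg
    velocities: Tuple[float, ...] = (30.0, 60.0, 120.0, 210.0, 300.0, 420.0, 700.0)
    io_angle: float = 17.8  # deg
    acceptance_angle: float = 17.7  # deg
    noise_sd: float = 0.05  # unitless
    n_replicates: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.tau_true > 0, "tau_true", "must be > 0")
        _require(len(self.wavelengths) > 0, "wavelengths", "must be non-empty")
        _require(len(self.velocities) > 0, "velocities", "must be non-empty")
        _require(all(w > 0 for w in self.wavelengths), "wavelengths", "must be > 0")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.n_replicates >= 1, "n_replicates", "must be >= 1")


def generate_tuning_dataset(spec: SyntheticTuningSpec) -> pd.DataFrame:
    """Noisy per-replicate normalized tuning curves from the EMD model.

    Returns one row per (replicate, wavelength, velocity) with columns
    ``replicate, wavelength, velocity, temporal_frequency, response``;
    each replicate curve is the closed-form EMD response at
    ``tau_true`` plus zero-mean Gaussian noise, renormalized to its own
    maximum magnitude.
    """
    rng = np.random.default_rng(spec.seed)
    params = EMDParams(
        tau=spec.tau_true,
        io_angle=spec.io_angle,
        acceptance_angle=spec.acceptance_angle,
    )
    lam, vel = np.meshgrid(spec.wavelengths, spec.velocities, indexing="ij")
    lam, vel = lam.ravel(), vel.ravel()
    clean = emd_response(params, lam, vel)
    rows = []
    for rep in range(spec.n_replicates):
        noisy = clean + rng.normal(0.0, spec.noise_sd, clean.shape)
        peak = np.max(np.abs(noisy))
        if peak > 0:
            noisy = noisy / peak
        rows.append(
            pd.DataFrame(
                {
                    "replicate": rep,
                    "wavelength": lam,
                    "velocity": vel,
                    "temporal_frequency": vel / lam,
                    "response": noisy,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    out.attrs["tau_true"] = spec.tau_true
    return out
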