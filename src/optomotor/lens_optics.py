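"""Geometric optics of single ommatidia: curvature radii, focal length,
acceptance angle, and eye-level summaries.

Each corneal lens is treated as a thin spherical-dome lens.  From the
fitted lens diameter ``D`` and the half thickness ``h`` (distance of a
lens tip from the principal plane), the radius of curvature of the
corresponding surface is that of the sphere through the lens rim:

    r = (D^2 / 4 + h^2) / (2 h)

The focal length follows from the thin-lens lens-maker formula with the
refractive index stepping from air (n_A) into the lens (n_L) at the outer
surface and from the lens into the crystalline cone (n_C) at the inner
surface:

    1 / l = (n_L - n_A) / r_air  -  (n_L - n_C) / r_cone

and the acceptance angle is the small-angle ratio of rhabdomere spacing
to focal length, ``drho = d / l`` (radians, reported in degrees).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "OpticalConstants",
    "OmmatidiumOptics",
    "radius_of_curvature",
    "focal_length",
    "acceptance_angle",
    "ommatidium_optics",
    "summarize_optics",
    "focal_diameter_ratio",
]


@dataclass(frozen=True)
class OpticalConstants:
    """Refractive indices of the media around the corneal lens.

    Defaults follow the honeybee values commonly adopted for compound
    eyes: lens 1.45, air 1.0, crystalline cone 1.35.
    """

    n_lens: float = 1.45
    n_air: float = 1.0
    n_cone: float = 1.35

    def __post_init__(self) -> None:
        if not (self.n_lens > self.n_cone > self.n_air >= 1.0):
            raise ValueError(
                "require n_lens > n_cone > n_air >= 1, got "
                f"({self.n_lens}, {self.n_cone}, {self.n_air})"
            )


@dataclass(frozen=True)
class OmmatidiumOptics:
    """Derived optical quantities for one ommatidium."""

    ommatidium_id: object
    r_outer: float  # um, radius of curvature of the outer (air-facing) surface
    r_inner: float  # um, inner (cone-facing) surface
    focal_length: float  # um
    acceptance_angle: Optional[float]  # deg; None if rhabdomere spacing unknown


def radius_of_curvature(diameter: float, half_thickness: float) -> float:
    """Spherical-dome radius through the lens rim at height ``half_thickness``.

    ``r = (D^2/4 + h^2) / (2h)``.  A flat surface (``h == 0``) is
    signalled by returning ``inf`` rather than raising: the lens-maker
    formula handles a zero-curvature term naturally.
    """
    if diameter <= 0:
        raise ValueError(f"diameter must be > 0, got {diameter}")
    if half_thickness < 0:
        raise ValueError(f"half thickness must be >= 0, got {half_thickness}")
    if half_thickness == 0:
        return math.inf
    return (diameter * diameter / 4.0 + half_thickness * half_thickness) / (
        2.0 * half_thickness
    )


def focal_length(
    r_air_facing: float,
    r_cone_facing: float,
    constants: OpticalConstants = OpticalConstants(),
) -> float:
    """Thin-lens focal length from the two surface radii (um).

    The ``(n_L - n_A)`` term takes the radius of the surface that meets
    air and the ``(n_L - n_C)`` term the surface that meets the
    crystalline cone.  Infinite radii (flat surfaces) contribute zero
    curvature.
    """
    for name, r in (("r_air_facing", r_air_facing), ("r_cone_facing", r_cone_facing)):
        if not r > 0:
            raise ValueError(f"{name} must be > 0, got {r}")
    power = (constants.n_lens - constants.n_air) / r_air_facing - (
        constants.n_lens - constants.n_cone
    ) / r_cone_facing
    if power <= 0:
        raise ValueError(
            "diverging lens: optical power "
            f"{power:.3e} 1/um <= 0 (r_air={r_air_facing}, r_cone={r_cone_facing})"
        )
    return 1.0 / power


def acceptance_angle(rhabdomere_distance: float, focal_len: float) -> float:
    """Acceptance angle in degrees, the small-angle ratio ``d / l``."""
    if not rhabdomere_distance > 0:
        raise ValueError(f"rhabdomere distance must be > 0, got {rhabdomere_distance}")
    if not focal_len > 0:
        raise ValueError(f"focal length must be > 0, got {focal_len}")
    return math.degrees(rhabdomere_distance / focal_len)


def ommatidium_optics(
    ommatidium_id,
    diameter: float,
    h_outer: float,
    h_inner: float,
    rhabdomere_distance: Optional[float] = None,
    constants: OpticalConstants = OpticalConstants(),
    literal_radius_labels: bool = False,
) -> OmmatidiumOptics:
    """Full optical chain for one ommatidium from its dome geometry.

    By default the air-interface term of the lens-maker formula takes
    the outer-surface radius (air physically meets the outer cornea) and
    the cone-interface term the inner radius.  ``literal_radius_labels``
    swaps the assignment.
    """
    r_out = radius_of_curvature(diameter, h_outer)
    r_in = radius_of_curvature(diameter, h_inner)
    if literal_radius_labels:
        l = focal_length(r_in, r_out, constants)
    else:
        l = focal_length(r_out, r_in, constants)
    rho = (
        acceptance_angle(rhabdomere_distance, l)
        if rhabdomere_distance is not None
        else None
    )
    return OmmatidiumOptics(
        ommatidium_id=ommatidium_id,
        r_outer=r_out,
        r_inner=r_in,
        focal_length=l,
        acceptance_angle=rho,
    )


def focal_diameter_ratio(mean_focal_length: float, mean_diameter: float) -> float:
    """Focal-length-to-lens-diameter ratio computed on per-quantity means."""
    if not mean_diameter > 0:
        raise ValueError(f"mean diameter must be > 0, got {mean_diameter}")
    return mean_focal_length / mean_diameter


def summarize_optics(
    optics: Iterable[OmmatidiumOptics],
    diameters: Optional[Iterable[float]] = None,
    io_angles: Optional[Iterable[float]] = None,
) -> dict:
    """Eye-level summary: per-quantity mean, SD, median, N, plus ratios.

    ``diameters`` (um) and ``io_angles`` (deg, per neighbor-graph edge)
    are optional side inputs; when present the summary includes the
    focal-length/diameter and acceptance/interommatidial-angle ratios,
    each computed both on per-quantity means (the conventional way such
    eye statistics are reported) and per ommatidium.
    """
    optics = list(optics)
    if not optics:
        raise ValueError("no ommatidia to summarize")

    def _stats(values: np.ndarray) -> dict:
        values = np.asarray([v for v in values if v is not None and np.isfinite(v)])
        if values.size == 0:
            return {"mean": np.nan, "sd": np.nan, "median": np.nan, "n": 0}
        return {
            "mean": float(np.mean(values)),
            "sd": float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
            "median": float(np.median(values)),
            "n": int(values.size),
        }

    table = pd.DataFrame(
        {
            "r_outer_um": [o.r_outer for o in optics],
            "r_inner_um": [o.r_inner for o in optics],
            "focal_length_um": [o.focal_length for o in optics],
            "acceptance_angle_deg": [o.acceptance_angle for o in optics],
        }
    )
    summary = {col: _stats(table[col].to_numpy()) for col in table.columns}

    if diameters is not None:
        diameters = np.asarray(list(diameters), dtype=float)
        summary["lens_diameter_um"] = _stats(diameters)
        mean_l = summary["focal_length_um"]["mean"]
        summary["focal_diameter_ratio_of_means"] = focal_diameter_ratio(
            mean_l, float(np.mean(diameters))
        )
        if len(diameters) == len(optics):
            per = [o.focal_length / d for o, d in zip(optics, diameters)]
            summary["focal_diameter_ratio_per_ommatidium"] = _stats(np.asarray(per))
    if io_angles is not None:
        io_angles = np.asarray(list(io_angles), dtype=float)
        summary["io_angle_deg"] = _stats(io_angles)
        rho = summary["acceptance_angle_deg"]
        if rho["n"] > 0 and io_angles.size > 0:
            summary["acceptance_io_ratio_of_means"] = rho["mean"] / float(
                np.mean(io_angles)
            )
    return summary
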