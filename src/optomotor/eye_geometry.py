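"""Reconstruction of per-ommatidium geometry from digitized 3-D markers.

The input is a set of manually digitized landmarks per ommatidium (outer
and inner lens tip, six points on the lens base rim, one rhabdomere tip)
plus three ocelli markers that define the head reference frame.  The
reconstruction proceeds in four steps:

1. head orientation is normalized to a canonical pose (ocelli centroid at
   the origin, ocelli-plane normal along +z, first ocellus toward +x);
2. the six base markers of each lens are projected onto their
   least-squares plane, which realizes the maximal-projected-area
   orientation of the lens base;
3. the lens diameter ``D`` is taken from a least-squares circle fitted
   to the projected base markers;
4. the visual axis is the projection line from the fitted circle center
   through the outer lens tip (alternatively the base-plane normal).

Interommatidial angles are then the angles between neighboring visual
axes, with "neighboring" defined by a surface triangulation of the lens
centers (convex hull with long-edge pruning) or by k-nearest centers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, cKDTree
from skimage.measure import CircleModel

__all__ = [
    "LensMarkerSet",
    "HeadFrame",
    "CircleFit",
    "OmmatidiumGeometry",
    "EyeModel",
    "normalize_head",
    "fit_lens_circle",
    "compute_visual_axis",
    "fit_ommatidium",
    "build_neighbor_graph",
    "interommatidial_angles",
    "eye_map_projection",
    "build_eye_model",
    "azimuth_elevation",
]


@dataclass
class LensMarkerSet:
    """Raw digitized 3-D markers (um) for a single ommatidium."""

    ommatidium_id: object
    outer_tip: np.ndarray  # (3,)
    inner_tip: np.ndarray  # (3,)
    base_points: np.ndarray  # (6, 3)
    rhabdomere_tip: np.ndarray  # (3,)
    side: str = "right"

    def __post_init__(self) -> None:
        self.outer_tip = np.asarray(self.outer_tip, dtype=float)
        self.inner_tip = np.asarray(self.inner_tip, dtype=float)
        self.base_points = np.asarray(self.base_points, dtype=float)
        self.rhabdomere_tip = np.asarray(self.rhabdomere_tip, dtype=float)
        if self.base_points.shape != (6, 3):
            raise ValueError(
                f"expected six 3-D base points, got shape {self.base_points.shape}"
            )
        for name in ("outer_tip", "inner_tip", "base_points", "rhabdomere_tip"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite coordinates in {name}")

    def transformed(self, rotation: np.ndarray, origin: np.ndarray) -> "LensMarkerSet":
        """Markers mapped by ``p -> rotation @ (p - origin)``."""

        def t(p):
            return (rotation @ (np.atleast_2d(p) - origin).T).T.squeeze()

        return LensMarkerSet(
            ommatidium_id=self.ommatidium_id,
            outer_tip=t(self.outer_tip),
            inner_tip=t(self.inner_tip),
            base_points=t(self.base_points),
            rhabdomere_tip=t(self.rhabdomere_tip),
            side=self.side,
        )


@dataclass(frozen=True)
class HeadFrame:
    """Rigid transform to the canonical head pose: ``p -> rotation @ (p - origin)``."""

    ocelli: np.ndarray  # (3, 3) original ocelli markers
    rotation: np.ndarray  # (3, 3) orthonormal, det +1
    origin: np.ndarray  # (3,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return (self.rotation @ (np.atleast_2d(points) - self.origin).T).T.squeeze()


def normalize_head(
    ocelli: np.ndarray, markers: Sequence[LensMarkerSet]
) -> Tuple[HeadFrame, List[LensMarkerSet]]:
    """Normalize head orientation to zero angles via the ocelli triangle.

    The rigid transform maps the ocelli centroid to the origin, the
    ocelli-plane normal (right-handed in marker order) to +z, and the
    first ocellus into the +x half of the x-z plane.  No scaling.
    """
    ocelli = np.asarray(ocelli, dtype=float)
    if ocelli.shape != (3, 3):
        raise ValueError(f"expected three 3-D ocelli points, got {ocelli.shape}")
    centroid = ocelli.mean(axis=0)
    a, b = ocelli[1] - ocelli[0], ocelli[2] - ocelli[0]
    normal = np.cross(a, b)
    norm = np.linalg.norm(normal)
    if norm < 1e-12 * max(np.linalg.norm(a), np.linalg.norm(b), 1.0):
        raise ValueError("degenerate head frame: ocelli are collinear")
    z_axis = normal / norm
    x_raw = ocelli[0] - centroid
    x_axis = x_raw - np.dot(x_raw, z_axis) * z_axis
    x_norm = np.linalg.norm(x_axis)
    if x_norm < 1e-12:
        raise ValueError("degenerate head frame: first ocellus at centroid")
    x_axis /= x_norm
    y_axis = np.cross(z_axis, x_axis)
    rotation = np.vstack([x_axis, y_axis, z_axis])  # rows = new basis
    frame = HeadFrame(ocelli=ocelli, rotation=rotation, origin=centroid)
    return frame, [m.transformed(rotation, centroid) for m in markers]


@dataclass(frozen=True)
class CircleFit:
    """Least-squares circle through the lens-base markers."""

    center: np.ndarray  # (3,) lifted back to 3-D
    diameter: float  # um
    normal: np.ndarray  # (3,) unit, oriented outward when a tip is given
    rms_residual: float  # um, in-plane radial residual
    high_residual: bool  # flagged when rms_residual > tolerance


def _plane_basis(points: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares plane of a point cloud: (centroid, in-plane basis (2,3), normal)."""
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    scale = max(s[0], 1e-30)
    if s[1] / scale < 1e-9:
        raise ValueError("degenerate lens base: markers are collinear")
    return centroid, vt[:2], vt[2]


def fit_lens_circle(
    base_points: np.ndarray,
    outer_tip: Optional[np.ndarray] = None,
    residual_tolerance: float = 0.5,
) -> CircleFit:
    """Fit the lens-base circle: plane projection then in-plane circle fit.

    Projecting onto the least-squares plane of the six rim markers is the
    orientation of maximal projected base area; the circle is then fitted
    by least squares in that plane.  The returned normal is oriented
    toward ``outer_tip`` when given.  A fit with in-plane radial RMS
    residual above ``residual_tolerance`` (um) is flagged, not rejected.
    """
    base_points = np.asarray(base_points, dtype=float)
    if base_points.ndim != 2 or base_points.shape[1] != 3 or base_points.shape[0] < 3:
        raise ValueError(f"need >= 3 base points of dim 3, got {base_points.shape}")
    centroid, basis, normal = _plane_basis(base_points)
    xy = (base_points - centroid) @ basis.T  # (n, 2)

    model = CircleModel.from_estimate(xy)
    if not model:
        raise ValueError("circle fit failed on lens base markers")
    xc, yc = model.center
    radius = model.radius
    center3 = centroid + xc * basis[0] + yc * basis[1]
    residual = float(np.sqrt(np.mean(model.residuals(xy) ** 2)))

    if outer_tip is not None:
        outer_tip = np.asarray(outer_tip, dtype=float)
        if np.dot(normal, outer_tip - center3) < 0:
            normal = -normal
    return CircleFit(
        center=center3,
        diameter=2.0 * float(radius),
        normal=normal / np.linalg.norm(normal),
        rms_residual=residual,
        high_residual=residual > residual_tolerance,
    )


def compute_visual_axis(
    markers: LensMarkerSet, circle: CircleFit, method: str = "normal"
) -> np.ndarray:
    """Unit visual axis of one ommatidium, oriented outward.

    ``method="normal"`` (default): the lens-base plane normal.
    ``method="top"``: the projection line from the fitted circle center
    through the outer-tip marker.  The two agree exactly when the outer
    tip sits on the normal through the circle center (a symmetric dome);
    with digitization noise the normal method is far more stable because
    the tip lies only the lens half-thickness above the base plane, a
    very short lever arm.
    """
    if method == "normal":
        return circle.normal.copy()
    if method != "top":
        raise ValueError(f"unknown axis method {method!r}; use 'top' or 'normal'")
    v = markers.outer_tip - circle.center
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError(
            f"ommatidium {markers.ommatidium_id}: outer tip coincides with circle center"
        )
    return v / n


@dataclass
class OmmatidiumGeometry:
    """Derived geometry of one ommatidium (um, unit vectors)."""

    ommatidium_id: object
    lens_center: np.ndarray
    lens_diameter: float
    base_normal: np.ndarray
    visual_axis: np.ndarray
    h_outer: float  # outer tip height above the base plane
    h_inner: float  # inner tip depth below the base plane
    rhabdomere_tip: np.ndarray
    rhabdomere_distance: Optional[float] = None  # to nearest neighbor, set on EyeModel
    fit_residual: float = 0.0
    high_residual: bool = False
    axis_method: str = "normal"


def fit_ommatidium(
    markers: LensMarkerSet,
    axis_method: str = "normal",
    residual_tolerance: float = 0.5,
) -> OmmatidiumGeometry:
    """Steps 2-4 of the reconstruction for a single ommatidium."""
    circle = fit_lens_circle(
        markers.base_points, markers.outer_tip, residual_tolerance
    )
    axis = compute_visual_axis(markers, circle, axis_method)
    h_out = float(np.dot(markers.outer_tip - circle.center, circle.normal))
    h_in = float(-np.dot(markers.inner_tip - circle.center, circle.normal))
    return OmmatidiumGeometry(
        ommatidium_id=markers.ommatidium_id,
        lens_center=circle.center,
        lens_diameter=circle.diameter,
        base_normal=circle.normal,
        visual_axis=axis,
        h_outer=h_out,
        h_inner=h_in,
        rhabdomere_tip=markers.rhabdomere_tip.copy(),
        fit_residual=circle.rms_residual,
        high_residual=circle.high_residual,
        axis_method=axis_method,
    )


def build_neighbor_graph(
    points: np.ndarray,
    method: str = "hull",
    k: int = 6,
    prune_factor: float = 2.5,
) -> Set[Tuple[int, int]]:
    """Neighbor edges between ommatidia from their lens-center positions.

    ``method="hull"`` (default): edges of the convex-hull surface
    triangulation of the 3-D centers, with edges longer than
    ``prune_factor`` times the median edge length removed — on a partial
    eye cap the hull closes across the opening, and those spurious
    closing edges are much longer than lattice edges.  ``method="knn"``:
    symmetrized k-nearest-centers.  Edges are unordered index pairs
    ``(i, j)`` with ``i < j``, no self-edges.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < 2:
        raise ValueError(f"need >= 2 ommatidia, got {n}")
    if n == 2:
        return {(0, 1)}
    edges: Set[Tuple[int, int]] = set()
    if method == "hull":
        if n == 3:
            return {(0, 1), (0, 2), (1, 2)}
        hull = ConvexHull(points)
        for simplex in hull.simplices:
            for a in range(3):
                i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
                edges.add((min(i, j), max(i, j)))
        lengths = {
            e: float(np.linalg.norm(points[e[0]] - points[e[1]])) for e in edges
        }
        median = float(np.median(list(lengths.values())))
        edges = {e for e in edges if lengths[e] <= prune_factor * median}
        # pruning must not isolate a node; reconnect any orphan to its nearest center
        degree = np.zeros(n, dtype=int)
        for i, j in edges:
            degree[i] += 1
            degree[j] += 1
        tree = cKDTree(points)
        for i in np.nonzero(degree == 0)[0]:
            _, idx = tree.query(points[i], k=2)
            j = int(idx[1])
            edges.add((min(i, j), max(i, j)))
    elif method == "knn":
        tree = cKDTree(points)
        kk = min(k + 1, n)
        _, idx = tree.query(points, k=kk)
        for i in range(n):
            for j in idx[i, 1:]:
                edges.add((min(i, int(j)), max(i, int(j))))
    else:
        raise ValueError(f"unknown neighbor method {method!r}; use 'hull' or 'knn'")
    return edges


def interommatidial_angles(
    axes: np.ndarray, edges: Iterable[Tuple[int, int]]
) -> Tuple[Dict[Tuple[int, int], float], dict]:
    """Per-edge interommatidial angle (deg) and its summary statistics.

    The angle between two unit visual axes is computed in the plane the
    two vectors span; the dot product is clamped to [-1, 1] before the
    arccos for floating-point safety.
    """
    axes = np.asarray(axes, dtype=float)
    angles: Dict[Tuple[int, int], float] = {}
    for i, j in edges:
        c = float(np.clip(np.dot(axes[i], axes[j]), -1.0, 1.0))
        angles[(i, j)] = math.degrees(math.acos(c))
    values = np.array(list(angles.values()))
    summary = {
        "mean": float(values.mean()) if values.size else math.nan,
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
        "n": int(values.size),
    }
    return angles, summary


def azimuth_elevation(axis: np.ndarray) -> Tuple[float, float]:
    """(azimuth, elevation) in degrees of a unit vector in the head frame.

    Azimuth is ``atan2(y, x)``; elevation is ``arcsin(z)``; the +x axis
    maps to (0, 0) and +z to elevation 90.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    az = math.degrees(math.atan2(axis[1], axis[0]))
    el = math.degrees(math.asin(np.clip(axis[2], -1.0, 1.0)))
    return az, el


@dataclass
class EyeModel:
    """Assembled eye: per-ommatidium geometry, neighbor graph, IO angles."""

    geometries: List[OmmatidiumGeometry]
    edges: Set[Tuple[int, int]]
    io_angles: Dict[Tuple[int, int], float] = field(default_factory=dict)
    io_summary: dict = field(default_factory=dict)

    @property
    def axes(self) -> np.ndarray:
        return np.array([g.visual_axis for g in self.geometries])

    @property
    def lens_centers(self) -> np.ndarray:
        return np.array([g.lens_center for g in self.geometries])

    def neighbors_of(self, i: int) -> List[int]:
        return sorted(
            {j for a, b in self.edges for j in (a, b) if i in (a, b) and j != i}
        )


def build_eye_model(
    marker_sets: Sequence[LensMarkerSet],
    axis_method: str = "normal",
    neighbor_method: str = "hull",
    k: int = 6,
    residual_tolerance: float = 0.5,
) -> EyeModel:
    """Fit every ommatidium, build the neighbor graph, and score IO angles.

    Also fills each ommatidium's rhabdomere distance with the mean 3-D
    distance to the rhabdomere tips of its graph neighbors (the quantity
    entering the acceptance-angle ratio).
    """
    geometries = [
        fit_ommatidium(m, axis_method, residual_tolerance) for m in marker_sets
    ]
    centers = np.array([g.lens_center for g in geometries])
    edges = build_neighbor_graph(centers, method=neighbor_method, k=k)
    axes = np.array([g.visual_axis for g in geometries])
    io_angles, io_summary = interommatidial_angles(axes, edges)
    eye = EyeModel(
        geometries=geometries, edges=edges, io_angles=io_angles, io_summary=io_summary
    )
    for i, g in enumerate(geometries):
        nbrs = eye.neighbors_of(i)
        if nbrs:
            g.rhabdomere_distance = float(
                np.mean(
                    [
                        np.linalg.norm(g.rhabdomere_tip - geometries[j].rhabdomere_tip)
                        for j in nbrs
                    ]
                )
            )
    return eye


def eye_map_projection(eye: EyeModel) -> pd.DataFrame:
    """Spherical projection map of the eye for plotting.

    One row per ommatidium: azimuth and elevation of its visual axis in
    the normalized head frame (deg), lens diameter (um), and mean IO
    angle over its incident edges (deg).
    """
    rows = []
    for i, g in enumerate(eye.geometries):
        az, el = azimuth_elevation(g.visual_axis)
        incident = [
            angle for (a, b), angle in eye.io_angles.items() if i in (a, b)
        ]
        rows.append(
            {
                "ommatidium_id": g.ommatidium_id,
                "azimuth_deg": az,
                "elevation_deg": el,
                "lens_diameter_um": g.lens_diameter,
                "mean_io_angle_deg": float(np.mean(incident)) if incident else np.nan,
            }
        )
    return pd.DataFrame(rows)
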