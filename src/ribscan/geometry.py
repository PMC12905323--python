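"""Cylindrical probe coordinates, generic-size normalization, and skin projection.

A minimum bounding cylinder is fitted to the rib cage; the probe lives on its
lateral surface at coordinates ``(h, theta)`` (height along the axis, angle
around it) and is mapped to the actual skin by casting an inward radial ray.
Two further rotational degrees of freedom orient the transducer footprint:
``phi`` rotates the probe long axis about the outward skin normal and ``psi``
tilts the probe centerline about the long axis.  Poses whose centerline
deviates more than a configurable limit (20 degrees by default) from the skin
normal are physically infeasible and flagged terminal.

Conventions (fixed, recorded in run manifests):

* the cylinder axis is the longitudinal body axis of the scene frame;
* ``theta = 0`` at the anterior midline, increasing toward the patient's left;
* ``h`` is measured from the caudal end of the fitted extent;
* ``phi`` is a right-handed rotation about the *outward* skin normal, so on a
  cylindrical skin ``phi = +90`` turns the circumferential footprint to point
  along ``+axis``;
* ``psi`` rotates the centerline about the (phi-rotated) long axis, so on a
  cylindrical skin the tilt angle equals ``|psi|``.

All lengths are millimetres, all angles degrees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
import shapely
from scipy.spatial.transform import Rotation

__all__ = [
    "OffSurfaceError",
    "CylindricalFrame",
    "ProbePose",
    "Surface",
    "CylinderSurface",
    "MeshSurface",
    "fit_cylinder",
    "surface_project",
    "build_pose",
]

# Generic cylinder the per-patient frames are affinely resized to.  Radius and
# height approximate an average adult thorax (circumference ~95 cm, rib band
# ~30 cm); every frame carries these so trajectories round-trip exactly.
GENERIC_RADIUS_MM = 150.0
GENERIC_HEIGHT_MM = 300.0


class OffSurfaceError(RuntimeError):
    """The inward radial ray from the cylinder surface misses the skin."""


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return np.asarray(v, dtype=float) / n


class Surface(Protocol):
    """Closed skin surface supporting first-hit ray queries."""

    def ray_intersect(
        self, origin: np.ndarray, direction: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray] | None:
        """First intersection along ``origin + t*direction`` (t > 0).

        Returns ``(point, outward_normal)`` or ``None`` if the ray misses.
        """


@dataclass(frozen=True)
class CylinderSurface:
    """Analytic cylindrical skin, used by the synthetic phantoms."""

    axis_point: np.ndarray  # a point on the axis (caudal end), mm
    axis_dir: np.ndarray  # unit vector
    radius: float  # mm
    h_min: float = -np.inf  # cropped band along the axis, mm
    h_max: float = np.inf

    def ray_intersect(self, origin, direction):
        a = np.asarray(self.axis_dir, float)
        o = np.asarray(origin, float) - np.asarray(self.axis_point, float)
        d = np.asarray(direction, float)
        # components perpendicular to the axis
        o_p = o - np.dot(o, a) * a
        d_p = d - np.dot(d, a) * a
        A = np.dot(d_p, d_p)
        B = 2.0 * np.dot(o_p, d_p)
        C = np.dot(o_p, o_p) - self.radius**2
        if A < 1e-15:
            return None
        disc = B * B - 4 * A * C
        if disc < 0:
            return None
        sq = np.sqrt(disc)
        for t in sorted(((-B - sq) / (2 * A), (-B + sq) / (2 * A))):
            if t <= 1e-9:
                continue
            p = np.asarray(origin, float) + t * d
            h = np.dot(p - self.axis_point, a)
            if self.h_min - 1e-9 <= h <= self.h_max + 1e-9:
                normal = _unit((p - self.axis_point) - h * a)
                return p, normal
        return None


def ray_triangle_hits(
    origin: np.ndarray, direction: np.ndarray, triangles: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Moller-Trumbore over a (F, 3, 3) triangle array.

    Returns (t values, triangle indices) of all forward hits, unsorted.
    """
    o = np.asarray(origin, float)
    d = np.asarray(direction, float)
    v0, v1, v2 = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    pvec = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > 1e-12
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = o - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv
    qvec = np.cross(tvec, e1)
    v = np.einsum("ij,j->i", qvec, d) * inv
    t = np.einsum("ij,ij->i", e2, qvec) * inv
    hit = ok & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1.0 + 1e-12) & (t > 1e-9)
    return t[hit], np.nonzero(hit)[0]


class MeshSurface:
    """Triangulated skin surface with first-hit ray queries."""

    def __init__(self, mesh, name: str = "skin"):
        if not mesh.is_watertight:
            raise ValueError(f"surface mesh '{name}' is not watertight")
        self.mesh = mesh
        self.name = name
        self._triangles = np.asarray(mesh.triangles, float)

    def ray_intersect(self, origin, direction):
        origin = np.asarray(origin, float)
        direction = _unit(direction)
        t, tri = ray_triangle_hits(origin, direction, self._triangles)
        if len(t) == 0:
            return None
        i = int(np.argmin(t))
        point = origin + t[i] * direction
        normal = np.asarray(self.mesh.face_normals[tri[i]], float)
        if np.dot(normal, direction) > 0:  # orient outward (against the ray)
            normal = -normal
        return point, normal


@dataclass(frozen=True)
class CylindricalFrame:
    """Cylinder fitted to the rib cage plus the generic-size affine."""

    axis_point: np.ndarray  # caudal end of the fitted extent, on the axis
    axis_dir: np.ndarray  # unit, cranio-caudal
    e_anterior: np.ndarray  # unit, theta = 0 direction
    radius: float  # R_c, mm
    height: float  # fitted axial extent, mm
    generic_radius: float = GENERIC_RADIUS_MM
    generic_height: float = GENERIC_HEIGHT_MM

    def __post_init__(self):
        object.__setattr__(self, "axis_point", np.asarray(self.axis_point, float))
        object.__setattr__(self, "axis_dir", _unit(self.axis_dir))
        e = np.asarray(self.e_anterior, float)
        e = e - np.dot(e, self.axis_dir) * self.axis_dir
        object.__setattr__(self, "e_anterior", _unit(e))
        if self.radius <= 0:
            raise ValueError("cylinder radius must be positive")

    @property
    def e_left(self) -> np.ndarray:
        return np.cross(self.axis_dir, self.e_anterior)

    @property
    def h_range(self) -> tuple[float, float]:
        return (0.0, self.height)

    def radial_dir(self, theta_deg: float) -> np.ndarray:
        t = np.deg2rad(theta_deg)
        return np.cos(t) * self.e_anterior + np.sin(t) * self.e_left

    def circumferential_dir(self, theta_deg: float) -> np.ndarray:
        t = np.deg2rad(theta_deg)
        return -np.sin(t) * self.e_anterior + np.cos(t) * self.e_left

    def cylinder_point(self, h: float, theta_deg: float) -> np.ndarray:
        return self.axis_point + h * self.axis_dir + self.radius * self.radial_dir(theta_deg)

    # --- generic-size normalization -------------------------------------
    def _basis(self) -> np.ndarray:
        return np.stack([self.e_anterior, self.e_left, self.axis_dir], axis=1)

    def generic_affine(self) -> np.ndarray:
        """4x4 affine mapping patient space to the generic cylinder scale.

        Anisotropic: the transverse plane is scaled by generic_radius/R_c and
        the axial direction by generic_height/height, about axis_point.
        """
        B = self._basis()
        s = np.diag(
            [
                self.generic_radius / self.radius,
                self.generic_radius / self.radius,
                self.generic_height / self.height,
            ]
        )
        M = B @ s @ B.T
        A = np.eye(4)
        A[:3, :3] = M
        A[:3, 3] = self.axis_point - M @ self.axis_point
        return A

    def to_generic(self, points: np.ndarray) -> np.ndarray:
        A = self.generic_affine()
        p = np.atleast_2d(np.asarray(points, float))
        out = p @ A[:3, :3].T + A[:3, 3]
        return out[0] if np.asarray(points).ndim == 1 else out

    def from_generic(self, points: np.ndarray) -> np.ndarray:
        A = np.linalg.inv(self.generic_affine())
        p = np.atleast_2d(np.asarray(points, float))
        out = p @ A[:3, :3].T + A[:3, 3]
        return out[0] if np.asarray(points).ndim == 1 else out


def fit_cylinder(
    bone_points: np.ndarray,
    axis_dir=(0.0, 0.0, 1.0),
    e_anterior=(1.0, 0.0, 0.0),
    generic_radius: float = GENERIC_RADIUS_MM,
    generic_height: float = GENERIC_HEIGHT_MM,
) -> CylindricalFrame:
    """Fit the minimum bounding cylinder (fixed axis direction) to rib points.

    The axis direction is pinned to the longitudinal body axis of the input
    frame; the radius is the minimum enclosing circle of the points projected
    onto the transverse plane, and the height spans the projected axial
    extent.
    """
    pts = np.asarray(bone_points, float)
    if pts.ndim != 2 or pts.shape[0] < 10:
        raise ValueError("need at least 10 bone points")
    a = _unit(np.asarray(axis_dir, float))
    e1 = np.asarray(e_anterior, float)
    e1 = _unit(e1 - np.dot(e1, a) * a)
    e2 = np.cross(a, e1)
    u = pts @ e1
    v = pts @ e2
    xy = np.stack([u, v], axis=1)
    if np.allclose(xy, xy.mean(axis=0), atol=1e-9):
        raise ValueError("degenerate input: all points on the cylinder axis")
    mbc = shapely.minimum_bounding_circle(shapely.MultiPoint(xy))
    radius = float(shapely.minimum_bounding_radius(shapely.MultiPoint(xy)))
    cx, cy = np.asarray(mbc.centroid.coords[0])
    w = pts @ a
    h_min, h_max = float(w.min()), float(w.max())
    height = h_max - h_min
    if height <= 0:
        height = 1.0
    axis_point = cx * e1 + cy * e2 + h_min * a
    return CylindricalFrame(
        axis_point=axis_point,
        axis_dir=a,
        e_anterior=e1,
        radius=radius,
        height=height,
        generic_radius=generic_radius,
        generic_height=generic_height,
    )


def surface_project(
    h: float, theta: float, frame: CylindricalFrame, skin: Surface
) -> tuple[np.ndarray, np.ndarray]:
    """Map cylinder coordinates ``(h, theta)`` to the skin contact point.

    Casts an inward radial ray from well outside the body toward the axis and
    returns the first skin intersection and the outward surface normal there.
    Raises :class:`OffSurfaceError` if the ray misses the (cropped) skin.
    """
    radial = frame.radial_dir(theta)
    start = frame.axis_point + h * frame.axis_dir + (frame.radius + 400.0) * radial
    hit = skin.ray_intersect(start, -radial)
    if hit is None:
        raise OffSurfaceError(f"no skin under (h={h:.1f} mm, theta={theta:.1f} deg)")
    return hit


def _rotate(v: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * _unit(axis)).apply(v)


@dataclass
class ProbePose:
    """Probe configuration on the skin with derived contact frame."""

    h: float
    theta: float
    phi: float
    psi: float
    adj: bool
    contact_point: np.ndarray = field(repr=False, default=None)
    centerline: np.ndarray = field(repr=False, default=None)  # unit, into the body
    long_axis: np.ndarray = field(repr=False, default=None)  # unit, footprint direction
    skin_normal: np.ndarray = field(repr=False, default=None)  # unit, outward
    tilt_deg: float = 0.0

    @property
    def short_axis(self) -> np.ndarray:
        return np.cross(self.centerline, self.long_axis)

    @property
    def transform(self) -> np.ndarray:
        """4x4 world transform: columns long, short, centerline; origin contact."""
        T = np.eye(4)
        T[:3, 0] = self.long_axis
        T[:3, 1] = self.short_axis
        T[:3, 2] = self.centerline
        T[:3, 3] = self.contact_point
        return T

    def to_json(self) -> str:
        return json.dumps(self.to_record())

    def to_record(self) -> dict:
        return {
            "h": self.h,
            "theta": self.theta,
            "phi": self.phi,
            "psi": self.psi,
            "adj": bool(self.adj),
            "transform": self.transform.tolist(),
        }


def build_pose(
    h: float,
    theta: float,
    phi: float,
    psi: float,
    frame: CylindricalFrame,
    skin: Surface,
    adj: bool = False,
) -> ProbePose:
    """Construct the full probe pose for cylinder coordinates and rotations.

    Composition order (fixed convention): the long axis starts tangent to the
    cylinder's circumferential direction, is made orthogonal to the skin
    normal, rotated by ``phi`` about the outward normal; the centerline starts
    at ``-skin_normal`` and is then tilted by ``psi`` about the rotated long
    axis.  The tilt angle stored is the angle between the centerline and
    ``-skin_normal``; the environment terminates above its limit.
    """
    contact, normal = surface_project(h, theta, frame, skin)
    centerline0 = -normal
    long0 = frame.circumferential_dir(theta)
    long0 = long0 - np.dot(long0, centerline0) * centerline0
    long0 = _unit(long0)
    long_axis = _rotate(long0, normal, phi)
    centerline = _rotate(centerline0, long_axis, psi)
    cos_tilt = float(np.clip(np.dot(centerline, -normal), -1.0, 1.0))
    tilt = float(np.degrees(np.arccos(cos_tilt)))
    return ProbePose(
        h=h,
        theta=theta,
        phi=phi,
        psi=psi,
        adj=adj,
        contact_point=np.asarray(contact, float),
        centerline=_unit(centerline),
        long_axis=_unit(long_axis),
        skin_normal=np.asarray(normal, float),
        tilt_deg=tilt,
    )
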