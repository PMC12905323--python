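"""Synthetic thoracic phantoms and readers for segmented anatomy.

The scanning scene needs three things: a closed skin surface the probe slides
on, a rib cage that blocks ultrasound, and one or more target volumes beneath
the ribs.  Real scenes come from segmented CT (STL/PLY meshes or NIfTI label
maps); synthetic phantoms are generated procedurally with exact control over
the intercostal gap width, which is the geometric property that makes the
planning problem hard.

Synthetic model
---------------
Ribs are partial circular arcs of capsules (constant tube radius) wrapped
around a cylindrical torso axis, so the bone-free gap between adjacent ribs is
exactly ``spacing - 2 * rib_radius`` and configurable down to 10 mm.  The skin
is a coaxial cylinder offset outward from the ribs.  Targets are randomly
rotated ellipsoids rejection-sampled to lie beneath the ribs without touching
bone, with volumes drawn from the clinical size classes (small < 4 cm^3,
medium 4-13.5 cm^3, large > 13.5 cm^3).

Units are millimetres everywhere; volumes are reported in cm^3.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import CylinderSurface, MeshSurface, Surface

__all__ = [
    "Ellipsoid",
    "RibCage",
    "AnatomyScene",
    "PhantomConfig",
    "SIZE_CLASS_RANGES",
    "generate_phantom",
    "place_targets",
    "load_scene",
    "write_scene_manifest",
]

# Volume ranges (cm^3) the generator draws from per size class.  The class
# boundaries (4 and 13.5 cm^3) are the reporting thresholds; the sampled
# ranges stay strictly inside them so rounding can never cross a class.
SIZE_CLASS_RANGES: dict[str, tuple[float, float]] = {
    "small": (1.5, 3.9),
    "medium": (4.2, 13.2),
    "large": (14.0, 30.0),
}

_PLACEMENT_ATTEMPTS = 1000  # rejection-sampling budget per target
_CLEARANCE_MM = 1.0  # required margin between a target surface and bone


@dataclass(frozen=True)
class Ellipsoid:
    """Rotated ellipsoid target with closed-form volume and inside test."""

    center: np.ndarray  # (3,) mm
    semi_axes: np.ndarray  # (3,) mm
    rotation: np.ndarray  # (3,3) world <- body

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, float))
        object.__setattr__(self, "semi_axes", np.asarray(self.semi_axes, float))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, float))

    @property
    def volume_cm3(self) -> float:
        return float(4.0 / 3.0 * np.pi * np.prod(self.semi_axes) / 1000.0)

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float)) - self.center
        body = p @ self.rotation  # rotate into body frame
        q = (body / self.semi_axes) ** 2
        inside = q.sum(axis=1) <= 1.0
        return inside if np.asarray(points).ndim > 1 else bool(inside[0])

    def surface_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        return (u * self.semi_axes) @ self.rotation.T + self.center

    @property
    def bounds(self) -> np.ndarray:
        # bounding box of a rotated ellipsoid: half-extent per world axis
        half = np.sqrt(((self.rotation * self.semi_axes) ** 2).sum(axis=1))
        return np.stack([self.center - half, self.center + half])


@dataclass(frozen=True)
class RibCage:
    """Partial-arc capsule ribs around an axial (z) torso axis.

    Each rib i is the set of points within ``rib_radius`` of the arc
    ``{ (ring_radius cos t, ring_radius sin t, z_i) : t in angle_span }``.
    """

    z_centers: np.ndarray  # (n_ribs,) mm
    ring_radius: float  # mm, arc radius about the torso axis
    rib_radius: float  # mm, capsule tube radius
    angle_span: tuple[float, float] = (-110.0, 110.0)  # degrees about anterior

    def __post_init__(self):
        object.__setattr__(self, "z_centers", np.asarray(self.z_centers, float))

    def distance_to_centerlines(self, points: np.ndarray) -> np.ndarray:
        """Exact distance from each point to the nearest rib arc centerline."""
        p = np.atleast_2d(np.asarray(points, float))
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        ang = np.degrees(np.arctan2(y, x))
        r = np.hypot(x, y)
        lo, hi = self.angle_span
        in_span = (ang >= lo) & (ang <= hi)
        d_best = np.full(len(p), np.inf)
        for zc in self.z_centers:
            # within the angular span: distance to the circle of the arc
            d_circ = np.hypot(r - self.ring_radius, z - zc)
            # outside: distance to the nearer arc endpoint
            d_end = np.full(len(p), np.inf)
            for a_deg in (lo, hi):
                a = np.deg2rad(a_deg)
                end = np.array([self.ring_radius * np.cos(a), self.ring_radius * np.sin(a), zc])
                d_end = np.minimum(d_end, np.linalg.norm(p - end, axis=1))
            d = np.where(in_span, d_circ, d_end)
            d_best = np.minimum(d_best, d)
        return d_best

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = self.distance_to_centerlines(points)
        inside = d <= self.rib_radius
        return inside if np.asarray(points).ndim > 1 else bool(inside[0])

    def clearance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance from points to the bone surface (positive outside)."""
        return self.distance_to_centerlines(points) - self.rib_radius

    def sample_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Points on rib tube surfaces, e.g. for cylinder fitting."""
        lo, hi = np.deg2rad(self.angle_span)
        t = rng.uniform(lo, hi, size=n)
        zc = rng.choice(self.z_centers, size=n)
        # random offset on the tube surface
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        cl = np.stack(
            [self.ring_radius * np.cos(t), self.ring_radius * np.sin(t), zc], axis=1
        )
        return cl + self.rib_radius * u

    @property
    def z_band(self) -> tuple[float, float]:
        return (
            float(self.z_centers.min() - self.rib_radius),
            float(self.z_centers.max() + self.rib_radius),
        )


class _MeshOccupancy:
    """Point-in-solid predicate backed by a watertight mesh.

    Inclusion is decided by even-odd ray-crossing counts against all faces
    (suits the small segmentation meshes this reader targets).
    """

    # fixed irrational-ish direction avoids edge/vertex-grazing degeneracies
    _DIR = np.array([0.5773502691896258, 0.5773502691896258, 0.5773502691896258])

    def __init__(self, mesh, name: str):
        if not mesh.is_watertight:
            raise ValueError(f"mesh '{name}' is not watertight")
        self.mesh = mesh
        self.name = name
        self._triangles = np.asarray(mesh.triangles, float)

    def contains(self, points: np.ndarray) -> np.ndarray:
        from .geometry import ray_triangle_hits

        p = np.atleast_2d(np.asarray(points, float))
        lo, hi = self.mesh.bounds
        out = np.zeros(len(p), dtype=bool)
        inside_box = np.all((p >= lo - 1e-9) & (p <= hi + 1e-9), axis=1)
        for i in np.nonzero(inside_box)[0]:
            t, _ = ray_triangle_hits(p[i], self._DIR, self._triangles)
            out[i] = len(t) % 2 == 1
        return out if np.asarray(points).ndim > 1 else bool(out[0])

    def sample_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        from trimesh.sample import sample_surface

        pts, _ = sample_surface(self.mesh, n, seed=int(rng.integers(2**31)))
        return np.asarray(pts, float)


class _MeshTarget(_MeshOccupancy):
    """Watertight target mesh with exact (divergence-theorem) volume."""

    @property
    def volume_cm3(self) -> float:
        return float(abs(self.mesh.volume) / 1000.0)

    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.mesh.center_mass, float)

    @property
    def bounds(self) -> np.ndarray:
        return np.asarray(self.mesh.bounds, float)

    def surface_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.sample_points(n, rng)


class _LabelOccupancy:
    """Occupancy predicate over a NIfTI label map (nearest-voxel lookup)."""

    def __init__(self, data: np.ndarray, affine: np.ndarray, labels: set[int], name: str):
        self.data = np.asarray(data)
        self.inv_affine = np.linalg.inv(affine)
        self.labels = labels
        self.name = name

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float))
        hom = np.c_[p, np.ones(len(p))]
        ijk = np.rint((hom @ self.inv_affine.T)[:, :3]).astype(int)
        ok = np.all((ijk >= 0) & (ijk < self.data.shape), axis=1)
        out = np.zeros(len(p), dtype=bool)
        if ok.any():
            vals = self.data[ijk[ok, 0], ijk[ok, 1], ijk[ok, 2]]
            out[ok] = np.isin(vals, list(self.labels))
        return out if np.asarray(points).ndim > 1 else bool(out[0])


@dataclass
class AnatomyScene:
    """World-space description of skin, bones, and targets (mm)."""

    skin: Surface
    bones: RibCage | _MeshOccupancy
    targets: list
    frame_id: str = "scene"
    provenance: dict = field(default_factory=dict)

    def bone_contains(self, points: np.ndarray) -> np.ndarray:
        return self.bones.contains(points)

    def target_contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float))
        out = np.zeros(len(p), dtype=bool)
        for t in self.targets:
            out |= t.contains(p)
        return out if np.asarray(points).ndim > 1 else bool(out[0])

    @property
    def targets_centroid(self) -> np.ndarray:
        """Volume-weighted centroid of the target union (targets are disjoint)."""
        if not self.targets:
            raise ValueError("scene has no targets")
        w = np.array([t.volume_cm3 for t in self.targets])
        c = np.stack([np.asarray(t.center, float) for t in self.targets])
        return (c * w[:, None]).sum(axis=0) / w.sum()

    @property
    def total_target_volume_cm3(self) -> float:
        return float(sum(t.volume_cm3 for t in self.targets))

    def summary(self) -> dict:
        return {
            "frame_id": self.frame_id,
            "n_targets": len(self.targets),
            "target_volumes_cm3": [round(t.volume_cm3, 6) for t in self.targets],
            "target_centroids_mm": [np.asarray(t.center, float).round(6).tolist() for t in self.targets],
            "provenance": self.provenance,
        }



@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic partial rib cage phantom."""

    n_ribs: int = 4
    rib_radius: float = 6.0  # mm
    intercostal_gap: float = 20.0  # mm, bone-free gap between adjacent ribs
    torso_radius: float = 110.0  # mm, rib arc (ring) radius
    torso_height: float = 240.0  # mm, axial extent of the skin band
    skin_offset: float = 12.0  # mm outward from the outer rib surface
    n_targets: int = 1
    size_class: str = "medium"  # or explicit (lo, hi) via volume_range
    volume_range: tuple[float, float] | None = None
    angle_span: tuple[float, float] = (-110.0, 110.0)
    seed: int = 0

    def __post_init__(self):
        if self.intercostal_gap <= 0:
            raise ValueError("intercostal_gap must be positive")
        if self.n_targets not in (1, 2, 3):
            raise ValueError("n_targets must be 1, 2, or 3")
        if self.volume_range is None and self.size_class not in SIZE_CLASS_RANGES:
            raise ValueError(f"unknown size_class {self.size_class!r}")

    @property
    def skin_radius(self) -> float:
        return self.torso_radius + self.rib_radius + self.skin_offset

    @property
    def target_volume_range(self) -> tuple[float, float]:
        return self.volume_range or SIZE_CLASS_RANGES[self.size_class]


def _sample_ellipsoid(
    cfg: PhantomConfig, cage: RibCage, rng: np.random.Generator, existing: list
) -> Ellipsoid:
    """Rejection-sample one target beneath the ribs, clear of bone and others."""
    vol_lo, vol_hi = cfg.target_volume_range
    z_lo, z_hi = cage.z_band
    for _ in range(_PLACEMENT_ATTEMPTS):
        volume_mm3 = rng.uniform(vol_lo, vol_hi) * 1000.0
        # aspect ratios in [0.6, 1], scaled to the drawn volume
        ratios = rng.uniform(0.6, 1.0, size=3)
        scale = (3.0 * volume_mm3 / (4.0 * np.pi * np.prod(ratios))) ** (1.0 / 3.0)
        semi = ratios * scale
        rot = Rotation.random(rng=rng).as_matrix()
        a_max = semi.max()
        # center beneath the ribs: radially inside the inner rib surface
        r_max = cfg.torso_radius - cfg.rib_radius - a_max - _CLEARANCE_MM
        if r_max <= 5.0:
            continue
        r = rng.uniform(0.3, 1.0) * r_max
        ang = np.deg2rad(rng.uniform(*cfg.angle_span))
        z = rng.uniform(z_lo + a_max, z_hi - a_max)
        ell = Ellipsoid(
            center=np.array([r * np.cos(ang), r * np.sin(ang), z]),
            semi_axes=semi,
            rotation=rot,
        )
        pts = np.vstack([ell.surface_points(600, rng), ell.center[None, :]])
        if cage.clearance(pts).min() < _CLEARANCE_MM:
            continue
        # pairwise disjoint from already placed targets
        if any(other.contains(pts).any() for other in existing):
            continue
        if any(ell.contains(other.surface_points(300, rng)).any() for other in existing):
            continue
        return ell
    raise RuntimeError(
        f"could not place a {cfg.size_class} target after {_PLACEMENT_ATTEMPTS} attempts"
    )


def generate_phantom(config: PhantomConfig) -> AnatomyScene:
    """Generate a synthetic partial-rib-cage scene (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    spacing = config.intercostal_gap + 2 * config.rib_radius
    half = (config.n_ribs - 1) * spacing / 2.0
    z_centers = np.linspace(-half, half, config.n_ribs)
    cage = RibCage(
        z_centers=z_centers,
        ring_radius=config.torso_radius,
        rib_radius=config.rib_radius,
        angle_span=config.angle_span,
    )
    skin = CylinderSurface(
        axis_point=np.array([0.0, 0.0, -config.torso_height / 2.0]),
        axis_dir=np.array([0.0, 0.0, 1.0]),
        radius=config.skin_radius,
        h_min=0.0,
        h_max=config.torso_height,
    )
    targets: list = []
    for _ in range(config.n_targets):
        targets.append(_sample_ellipsoid(config, cage, rng, targets))
    return AnatomyScene(
        skin=skin,
        bones=cage,
        targets=targets,
        frame_id=f"phantom-seed{config.seed}",
        provenance={"kind": "synthetic", "config": _config_record(config)},
    )


def place_targets(scene: AnatomyScene, n: int, size_class: str, seed: int) -> AnatomyScene:
    """Return a copy of the scene with ``n`` freshly sampled ellipsoid targets.

    Used at every training-episode reset to randomize target position,
    orientation and size within the chosen rib cage.
    """
    if n not in (1, 2, 3):
        raise ValueError("n must be 1, 2, or 3")
    if not isinstance(scene.bones, RibCage):
        raise TypeError("place_targets requires a capsule rib cage scene")
    rng = np.random.default_rng(seed)
    cage = scene.bones
    base = scene.provenance.get("config", {})
    cfg = PhantomConfig(
        n_ribs=len(cage.z_centers),
        rib_radius=cage.rib_radius,
        intercostal_gap=float(np.diff(cage.z_centers).min() - 2 * cage.rib_radius)
        if len(cage.z_centers) > 1
        else base.get("intercostal_gap", 20.0),
        torso_radius=cage.ring_radius,
        torso_height=base.get("torso_height", 240.0),
        skin_offset=base.get("skin_offset", 12.0),
        n_targets=n,
        size_class=size_class,
        angle_span=cage.angle_span,
        seed=seed,
    )
    targets: list = []
    for _ in range(n):
        targets.append(_sample_ellipsoid(cfg, cage, rng, targets))
    return AnatomyScene(
        skin=scene.skin,
        bones=scene.bones,
        targets=targets,
        frame_id=scene.frame_id,
        provenance={**scene.provenance, "placement_seed": seed, "size_class": size_class},
    )


def benchmark_scene(target_volume_cm3: float = 3.0, gap_mm: float = 28.0) -> AnatomyScene:
    """Canonical easy benchmark: one wide gap, one spherical target centred in it.

    Two ribs with a wide intercostal gap and a small spherical target placed
    directly beneath the gap's midline at the anterior midline.  The scene is
    fully deterministic; it is the reference task for scaled-down CPU training
    studies and for sanity checks that a policy can beat a random baseline.
    """
    cfg = PhantomConfig(
        n_ribs=2,
        intercostal_gap=gap_mm,
        size_class="small",
        n_targets=1,
        seed=0,
    )
    scene = generate_phantom(cfg)
    radius = (3.0 * target_volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    target = Ellipsoid(
        center=np.array([60.0, 0.0, 0.0]),
        semi_axes=np.full(3, radius),
        rotation=np.eye(3),
    )
    pts = np.vstack(
        [target.surface_points(600, np.random.default_rng(0)), target.center[None, :]]
    )
    assert scene.bones.clearance(pts).min() >= _CLEARANCE_MM
    return AnatomyScene(
        skin=scene.skin,
        bones=scene.bones,
        targets=[target],
        frame_id="benchmark-single-gap",
        provenance={"kind": "benchmark", "target_volume_cm3": target_volume_cm3},
    )


def _config_record(config: PhantomConfig) -> dict:
    rec = {}
    for k, v in config.__dict__.items():
        rec[k] = list(v) if isinstance(v, tuple) else v
    return rec


def _load_mesh(path: str | Path):
    import trimesh

    mesh = trimesh.load(str(path), force="mesh")
    return mesh


def load_scene(
    skin_path: str | Path,
    bone_path: str | Path,
    target_paths: list[str | Path],
    bone_labels: set[int] | None = None,
    target_labels: dict[str, set[int]] | None = None,
) -> AnatomyScene:
    """Build a scene from segmentation files in a common millimetre frame.

    STL/PLY surface meshes must be watertight; a NIfTI label map may serve as
    the bone occupancy (``bone_labels`` selects the label values).  NIfTI
    headers declaring metre units are rejected.
    """
    paths = {"skin": Path(skin_path), "bone": Path(bone_path)}
    skin_mesh = _load_mesh(paths["skin"])
    skin = MeshSurface(skin_mesh, name=paths["skin"].name)

    if paths["bone"].suffix in (".nii", ".gz") or str(bone_path).endswith(".nii.gz"):
        bones = _load_label_occupancy(paths["bone"], bone_labels or {1}, "bone")
    else:
        bones = _MeshOccupancy(_load_mesh(paths["bone"]), name=paths["bone"].name)

    targets = [
        _MeshTarget(_load_mesh(Path(p)), name=Path(p).name) for p in target_paths
    ]
    return AnatomyScene(
        skin=skin,
        bones=bones,
        targets=targets,
        frame_id=paths["skin"].stem,
        provenance={
            "kind": "files",
            "skin": str(skin_path),
            "bone": str(bone_path),
            "targets": [str(p) for p in target_paths],
            "hashes": {
                str(p): _sha256(p)
                for p in [skin_path, bone_path, *target_paths]
                if Path(p).exists()
            },
        },
    )


def _load_label_occupancy(path: Path, labels: set[int], name: str) -> _LabelOccupancy:
    import nibabel as nib

    img = nib.load(str(path))
    units = img.header.get_xyzt_units()[0]
    if units == "meter":
        raise ValueError(f"label map '{path.name}' declares metre units; expected mm")
    return _LabelOccupancy(
        np.asarray(img.dataobj), np.asarray(img.affine, float), labels, name
    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_scene_manifest(scene: AnatomyScene, path: str | Path) -> Path:
    """Write a JSON manifest sufficient to regenerate or re-load the scene."""
    path = Path(path)
    path.write_text(json.dumps(scene.summary(), indent=2))
    return path
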