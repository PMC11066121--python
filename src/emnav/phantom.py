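"""Synthetic parametric phantom: stomach, necrotic cavity, torso shell, markers.

The physical experiment used a patient-derived, 3D-printed stomach and
pancreatic-necrosis model inside a silicone torso, instrumented with
seven target markers (five mural, on the inner stomach wall; two
extramural, on the necrotic cavity) and six registration fiducials
(three on the outer stomach wall, two on the necrosis, one inside the
torso).  No patient geometry is published, so this module generates a
parametric stand-in with the same topology and marker layout:
superellipsoid surfaces for stomach, necrosis and torso, plus seeded
marker placement.  Only the layout matters for the navigation math; the
shapes are representative, not a replica.

Image-space convention: origin at the torso centroid, +x right,
+y anterior, +z superior, millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd
import trimesh
from pydantic import BaseModel, Field

from .errors import InvalidParams, IOFailure, MalformedRow
from .geometry import Point3

__all__ = [
    "MARKER_ROLES",
    "MarkerSpec",
    "PhantomParams",
    "PhantomModel",
    "generate_phantom",
    "export_meshes",
    "export_markers",
    "load_markers",
    "superellipsoid_mesh",
    "superellipsoid_volume",
]

MARKER_ROLES = ("target_mural", "target_extramural", "fiducial")


@dataclass(frozen=True)
class MarkerSpec:
    """One CT marker: identifier, role, image-space position (mm)."""

    id: str
    role: str
    position: Point3

    def __post_init__(self) -> None:
        if self.role not in MARKER_ROLES:
            raise MalformedRow(
                f"unknown marker role {self.role!r}; expected one of {MARKER_ROLES}"
            )


class PhantomParams(BaseModel):
    """Parametric phantom geometry (all lengths in mm).

    Semi-axes and superellipsoid exponents for the three surfaces, organ
    centres in image space, and the icosphere subdivision level that sets
    mesh resolution.  Defaults give an adult-torso-scale layout with the
    necrotic cavity posterior-inferior to the stomach.
    """

    model_config = {"frozen": True}

    stomach_radii: tuple[float, float, float] = (55.0, 40.0, 85.0)
    stomach_exponent: float = Field(2.5, gt=1.0, le=10.0)
    stomach_center: tuple[float, float, float] = (-20.0, 10.0, 30.0)
    necrosis_radii: tuple[float, float, float] = (35.0, 28.0, 45.0)
    necrosis_exponent: float = Field(2.2, gt=1.0, le=10.0)
    necrosis_center: tuple[float, float, float] = (-20.0, -60.0, -45.0)
    torso_radii: tuple[float, float, float] = (150.0, 110.0, 220.0)
    torso_exponent: float = Field(2.0, gt=1.0, le=10.0)
    subdivisions: int = Field(4, ge=2, le=6)
    n_mural_targets: int = Field(5, ge=1, le=12)
    n_extramural_targets: int = Field(2, ge=1, le=12)

    def validate_layout(self) -> None:
        for name in ("stomach_radii", "necrosis_radii", "torso_radii"):
            if any(r <= 0 for r in getattr(self, name)):
                raise InvalidParams(f"{name} must be positive, got {getattr(self, name)}")
        for name, center, radii in (
            ("stomach", self.stomach_center, self.stomach_radii),
            ("necrosis", self.necrosis_center, self.necrosis_radii),
        ):
            reach = np.abs(np.asarray(center)) + np.asarray(radii)
            if np.any(reach >= np.asarray(self.torso_radii)):
                raise InvalidParams(f"{name} does not fit inside the torso shell")


@dataclass
class PhantomModel:
    """Meshes + markers + endoscope entry point, all in image space.

    ``aperture_center`` is the point on the stomach wall facing the
    necrosis through which trajectories to extramural targets are
    routed (the modeled transgastric access).
    """

    stomach_mesh: trimesh.Trimesh
    necrosis_mesh: trimesh.Trimesh
    torso_mesh: trimesh.Trimesh
    markers: List[MarkerSpec]
    esophagus_entry: Point3
    aperture_center: Point3
    params: PhantomParams = field(default_factory=PhantomParams)

    def markers_by_role(self, role: str) -> List[MarkerSpec]:
        return [m for m in self.markers if m.role == role]

    @property
    def targets(self) -> List[MarkerSpec]:
        return [m for m in self.markers if m.role.startswith("target")]

    @property
    def fiducials(self) -> List[MarkerSpec]:
        return self.markers_by_role("fiducial")

    def marker(self, marker_id: str) -> MarkerSpec:
        for m in self.markers:
            if m.id == marker_id:
                return m
        raise KeyError(marker_id)


# ---------------------------------------------------------------------------
# superellipsoid surface


def _surface_scale(dirs: np.ndarray, radii, exponent: float) -> np.ndarray:
    """Scale factor s such that s*d lies on |x/a|^p + |y/b|^p + |z/c|^p = 1."""
    d = np.abs(np.asarray(dirs, dtype=float)) / np.asarray(radii, dtype=float)
    return np.sum(d**exponent, axis=-1) ** (-1.0 / exponent)


def superellipsoid_point(direction, radii, exponent: float) -> np.ndarray:
    """Surface point of the superellipsoid along ``direction`` from its centre."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return d * _surface_scale(d, radii, exponent)


def superellipsoid_mesh(
    radii, exponent: float, subdivisions: int = 4, center=(0.0, 0.0, 0.0)
) -> trimesh.Trimesh:
    """Watertight triangle mesh of a superellipsoid.

    An icosphere of the requested subdivision level provides the (closed,
    manifold) topology; each unit vertex is projected radially onto the
    superellipsoid surface, so the mesh inherits watertightness.
    """
    base = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    dirs = base.vertices / np.linalg.norm(base.vertices, axis=1, keepdims=True)
    verts = dirs * _surface_scale(dirs, radii, exponent)[:, None] + np.asarray(center)
    return trimesh.Trimesh(vertices=verts, faces=base.faces, process=False)


def superellipsoid_volume(radii, exponent: float) -> float:
    """Analytic volume: ``8 a b c Gamma(1 + 1/p)^3 / Gamma(1 + 3/p)``."""
    from scipy.special import gamma

    a, b, c = radii
    p = exponent
    return float(8.0 * a * b * c * gamma(1.0 + 1.0 / p) ** 3 / gamma(1.0 + 3.0 / p))


def point_surface_distance(mesh: trimesh.Trimesh, points) -> np.ndarray:
    """Exact unsigned distance from each point to the mesh surface (mm).

    Brute-force point-to-triangle distance: the closest point on each
    triangle is either the in-plane projection (when it falls inside the
    triangle) or the closest point on one of the three edges.  Intended
    for small point sets against phantom-resolution meshes.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.triangles  # (M, 3, 3)
    A, B, C = tri[:, 0], tri[:, 1], tri[:, 2]
    E0, E1 = B - A, C - A
    n = np.cross(E0, E1)
    nn = np.einsum("ij,ij->i", n, n)
    nn = np.where(nn > 0, nn, 1.0)

    out = np.empty(len(points))
    for k, p in enumerate(points):
        D = p - A
        # in-plane barycentric coordinates of the projection
        dist_plane = np.einsum("ij,ij->i", D, n) / np.sqrt(nn)
        u = np.einsum("ij,ij->i", np.cross(D, E1), n) / nn
        v = np.einsum("ij,ij->i", np.cross(E0, D), n) / nn
        inside = (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0)

        def seg_dist(P0, E):
            ee = np.einsum("ij,ij->i", E, E)
            t = np.clip(np.einsum("ij,ij->i", p - P0, E) / np.where(ee > 0, ee, 1.0), 0.0, 1.0)
            q = P0 + t[:, None] * E
            return np.linalg.norm(p - q, axis=1)

        edge = np.minimum.reduce([seg_dist(A, E0), seg_dist(A, E1), seg_dist(B, C - B)])
        out[k] = np.min(np.where(inside, np.abs(dist_plane), edge))
    return out


# ---------------------------------------------------------------------------
# marker placement


def _sample_directions(
    rng: np.random.Generator,
    n: int,
    min_angle_deg: float = 30.0,
    avoid: Sequence[np.ndarray] = (),
    avoid_angle_deg: float = 25.0,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Seeded unit directions with pairwise angular separation."""
    cos_min = np.cos(np.radians(min_angle_deg))
    cos_avoid = np.cos(np.radians(avoid_angle_deg))
    out: list[np.ndarray] = []
    for _ in range(max_tries):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        if any(np.dot(v, u) > cos_min for u in out):
            continue
        if any(np.dot(v, u) > cos_avoid for u in avoid):
            continue
        out.append(v)
        if len(out) == n:
            return np.array(out)
    raise InvalidParams(
        f"could not place {n} markers with {min_angle_deg} deg separation"
    )


def generate_phantom(params: PhantomParams | None = None, seed: int = 0) -> PhantomModel:
    """Build the default synthetic phantom, deterministic in ``(params, seed)``.

    Marker layout follows the physical model: 5 mural targets on the
    stomach wall, 2 extramural targets on the necrotic cavity, and 6
    registration fiducials (3 stomach wall, 2 necrosis, 1 torso
    interior), ids ``T1..T7`` and ``F1..F6``.
    """
    params = params or PhantomParams()
    params.validate_layout()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9E3779B9]))

    s_c = np.asarray(params.stomach_center)
    n_c = np.asarray(params.necrosis_center)

    stomach = superellipsoid_mesh(
        params.stomach_radii, params.stomach_exponent, params.subdivisions, s_c
    )
    necrosis = superellipsoid_mesh(
        params.necrosis_radii, params.necrosis_exponent, params.subdivisions, n_c
    )
    torso = superellipsoid_mesh(
        params.torso_radii, params.torso_exponent, params.subdivisions
    )

    # anatomy anchors: esophagus entry at the superior stomach pole, access
    # aperture on the stomach wall facing the necrosis
    entry_dir = np.array([0.0, 0.15, 1.0])
    entry = s_c + superellipsoid_point(
        entry_dir, params.stomach_radii, params.stomach_exponent
    )
    ap_dir = n_c - s_c
    aperture = s_c + superellipsoid_point(
        ap_dir, params.stomach_radii, params.stomach_exponent
    )

    avoid = [entry_dir / np.linalg.norm(entry_dir), ap_dir / np.linalg.norm(ap_dir)]
    markers: list[MarkerSpec] = []

    mural_dirs = _sample_directions(rng, params.n_mural_targets, 35.0, avoid)
    for k, d in enumerate(mural_dirs, start=1):
        pos = s_c + superellipsoid_point(d, params.stomach_radii, params.stomach_exponent)
        markers.append(MarkerSpec(f"T{k}", "target_mural", Point3.from_array(pos)))

    extramural_dirs = _sample_directions(rng, params.n_extramural_targets, 45.0)
    for k, d in enumerate(extramural_dirs, start=params.n_mural_targets + 1):
        pos = n_c + superellipsoid_point(
            d, params.necrosis_radii, params.necrosis_exponent
        )
        markers.append(MarkerSpec(f"T{k}", "target_extramural", Point3.from_array(pos)))

    # registration fiducials: 3 outer stomach wall, 2 necrosis, 1 torso interior
    fid_stomach = _sample_directions(rng, 3, 40.0, avoid)
    fid_necrosis = _sample_directions(rng, 2, 60.0)
    fid_positions = [
        s_c + superellipsoid_point(d, params.stomach_radii, params.stomach_exponent)
        for d in fid_stomach
    ] + [
        n_c + superellipsoid_point(d, params.necrosis_radii, params.necrosis_exponent)
        for d in fid_necrosis
    ]
    interior_dir = rng.normal(size=3)
    interior_dir /= np.linalg.norm(interior_dir)
    fid_positions.append(
        0.5 * superellipsoid_point(interior_dir, params.torso_radii, params.torso_exponent)
    )
    for k, pos in enumerate(fid_positions, start=1):
        markers.append(MarkerSpec(f"F{k}", "fiducial", Point3.from_array(pos)))

    return PhantomModel(
        stomach_mesh=stomach,
        necrosis_mesh=necrosis,
        torso_mesh=torso,
        markers=markers,
        esophagus_entry=Point3.from_array(entry),
        aperture_center=Point3.from_array(aperture),
        params=params,
    )


# ---------------------------------------------------------------------------
# IO

_MESH_NAMES = ("stomach", "necrosis", "torso")


def export_meshes(model: PhantomModel, directory) -> dict:
    """Write one binary STL per mesh; returns ``{name: path}``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for name in _MESH_NAMES:
        mesh: trimesh.Trimesh = getattr(model, f"{name}_mesh")
        path = directory / f"{name}.stl"
        try:
            mesh.export(path, file_type="stl")
        except OSError as exc:  # pragma: no cover - disk errors
            raise IOFailure(f"could not write {path}") from exc
        out[name] = path
    return out


def export_markers(model: PhantomModel, path) -> None:
    """Markers to CSV ``id,role,x_mm,y_mm,z_mm`` at 6-decimal precision."""
    rows = [
        {
            "id": m.id,
            "role": m.role,
            "x_mm": m.position.x,
            "y_mm": m.position.y,
            "z_mm": m.position.z,
        }
        for m in model.markers
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def load_markers(path) -> List[MarkerSpec]:
    df = pd.read_csv(path, dtype={"id": str, "role": str})
    required = {"id", "role", "x_mm", "y_mm", "z_mm"}
    if not required.issubset(df.columns):
        raise MalformedRow(f"expected columns {sorted(required)} in {path}")
    markers = []
    for _, row in df.iterrows():
        if row["role"] not in MARKER_ROLES:
            raise MalformedRow(f"unknown role {row['role']!r} for marker {row['id']!r}")
        try:
            pos = Point3(float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"]))
        except (TypeError, ValueError) as exc:
            raise MalformedRow(f"non-numeric coordinate for marker {row['id']!r}") from exc
        markers.append(MarkerSpec(str(row["id"]), str(row["role"]), pos))
    return markers
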