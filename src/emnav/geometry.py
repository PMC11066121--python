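"""Rigid-body geometry: points, unit quaternions, rigid transforms, 6-DoF poses.

All coordinates are millimetres in right-handed frames.  Quaternions are
scalar-first ``(w, x, y, z)`` and stored on the canonical hemisphere
``w >= 0`` so that every rotation has exactly one representation (the
double cover is collapsed at construction time).  The local ``+z`` axis of
a :class:`Pose6DoF` is the instrument axis pointing out of the sensor /
endoscope tip; the fixed tip-offset convention of the navigation module
relies on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Point3",
    "UnitQuaternion",
    "RigidTransform",
    "Pose6DoF",
    "compose",
    "apply",
    "random_rigid_transform",
    "rotation_between",
    "quat_to_matrix",
]


@dataclass(frozen=True)
class Point3:
    """A 3-D point or vector in millimetres."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in (self.x, self.y, self.z)):
            raise ValueError(f"Point3 components must be finite, got {self}")

    @classmethod
    def from_array(cls, a) -> "Point3":
        a = np.asarray(a, dtype=float).reshape(3)
        return cls(float(a[0]), float(a[1]), float(a[2]))

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    def distance_to(self, other: "Point3") -> float:
        return float(np.linalg.norm(self.as_array() - other.as_array()))


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Scalar-first quaternion(s) ``(..., 4)`` to rotation matrix(es) ``(..., 3, 3)``.

    Works on batched input; quaternions must already be unit norm.
    """
    q = np.asarray(q, dtype=float)
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    R = np.empty(q.shape[:-1] + (3, 3), dtype=float)
    R[..., 0, 0] = 1.0 - 2.0 * (y * y + z * z)
    R[..., 0, 1] = 2.0 * (x * y - w * z)
    R[..., 0, 2] = 2.0 * (x * z + w * y)
    R[..., 1, 0] = 2.0 * (x * y + w * z)
    R[..., 1, 1] = 1.0 - 2.0 * (x * x + z * z)
    R[..., 1, 2] = 2.0 * (y * z - w * x)
    R[..., 2, 0] = 2.0 * (x * z - w * y)
    R[..., 2, 1] = 2.0 * (y * z + w * x)
    R[..., 2, 2] = 1.0 - 2.0 * (x * x + y * y)
    return R


@dataclass(frozen=True)
class UnitQuaternion:
    """Unit quaternion, scalar-first, canonical hemisphere ``w >= 0``.

    The constructor normalizes its components (raising if the norm is
    numerically zero) and flips the sign so that ``w >= 0``; when ``w`` is
    exactly zero the first non-zero vector component is made positive.
    """

    w: float
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        v = np.array([self.w, self.x, self.y, self.z], dtype=float)
        n = float(np.linalg.norm(v))
        if not math.isfinite(n) or n < 1e-12:
            raise ValueError(f"quaternion norm ~0 or non-finite: {v}")
        v /= n
        # canonical hemisphere
        if v[0] < 0.0 or (v[0] == 0.0 and _first_nonzero_negative(v[1:])):
            v = -v
        object.__setattr__(self, "w", float(v[0]))
        object.__setattr__(self, "x", float(v[1]))
        object.__setattr__(self, "y", float(v[2]))
        object.__setattr__(self, "z", float(v[3]))

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "UnitQuaternion":
        return cls(1.0, 0.0, 0.0, 0.0)

    @classmethod
    def from_array(cls, a) -> "UnitQuaternion":
        a = np.asarray(a, dtype=float).reshape(4)
        return cls(float(a[0]), float(a[1]), float(a[2]), float(a[3]))

    @classmethod
    def from_axis_angle(cls, axis, angle_rad: float) -> "UnitQuaternion":
        axis = np.asarray(axis, dtype=float).reshape(3)
        n = np.linalg.norm(axis)
        if n < 1e-12:
            raise ValueError("rotation axis has ~zero norm")
        axis = axis / n
        h = 0.5 * angle_rad
        s = math.sin(h)
        return cls(math.cos(h), s * axis[0], s * axis[1], s * axis[2])

    @classmethod
    def from_rotation_matrix(cls, R) -> "UnitQuaternion":
        from scipy.spatial.transform import Rotation

        xyzw = Rotation.from_matrix(np.asarray(R, dtype=float)).as_quat()
        return cls(float(xyzw[3]), float(xyzw[0]), float(xyzw[1]), float(xyzw[2]))

    # -- queries -----------------------------------------------------------
    def as_array(self) -> np.ndarray:
        return np.array([self.w, self.x, self.y, self.z], dtype=float)

    def rotation_matrix(self) -> np.ndarray:
        return quat_to_matrix(self.as_array())

    def rotate(self, v) -> np.ndarray:
        """Rotate vector(s) of shape (3,) or (N, 3)."""
        v = np.asarray(v, dtype=float)
        return v @ self.rotation_matrix().T

    def conjugate(self) -> "UnitQuaternion":
        return UnitQuaternion(self.w, -self.x, -self.y, -self.z)

    inverse = conjugate

    def __mul__(self, other: "UnitQuaternion") -> "UnitQuaternion":
        w1, x1, y1, z1 = self.w, self.x, self.y, self.z
        w2, x2, y2, z2 = other.w, other.x, other.y, other.z
        return UnitQuaternion(
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        )

    def angle_to(self, other: "UnitQuaternion") -> float:
        """Geodesic rotation angle (radians) between the two rotations."""
        d = abs(float(np.dot(self.as_array(), other.as_array())))
        return 2.0 * math.acos(min(1.0, d))


def _first_nonzero_negative(v: np.ndarray) -> bool:
    for c in v:
        if c != 0.0:
            return c < 0.0
    return False


def rotation_between(a, b) -> UnitQuaternion:
    """Minimal rotation carrying direction ``a`` onto direction ``b``.

    Both inputs are 3-vectors (not necessarily normalized).  For
    antiparallel inputs an arbitrary perpendicular axis is chosen.
    """
    a = np.asarray(a, dtype=float).reshape(3)
    b = np.asarray(b, dtype=float).reshape(3)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("cannot rotate between ~zero-length directions")
    a, b = a / na, b / nb
    c = float(np.dot(a, b))
    axis = np.cross(a, b)
    s = float(np.linalg.norm(axis))
    if s < 1e-12:
        if c > 0.0:
            return UnitQuaternion.identity()
        # antiparallel: rotate 180 deg about any axis perpendicular to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return UnitQuaternion.from_axis_angle(perp, math.pi)
    return UnitQuaternion.from_axis_angle(axis, math.atan2(s, c))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> R p + t`` between millimetre frames."""

    rotation: UnitQuaternion
    translation: Point3

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(UnitQuaternion.identity(), Point3(0.0, 0.0, 0.0))

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        return cls(
            UnitQuaternion.from_rotation_matrix(m[:3, :3]),
            Point3.from_array(m[:3, 3]),
        )

    @classmethod
    def from_rotation_translation(cls, R, t) -> "RigidTransform":
        return cls(UnitQuaternion.from_rotation_matrix(R), Point3.from_array(t))

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation.rotation_matrix()
        m[:3, 3] = self.translation.as_array()
        return m

    def apply(self, p: Point3) -> Point3:
        return Point3.from_array(
            self.rotation.rotate(p.as_array()) + self.translation.as_array()
        )

    def transform_points(self, pts) -> np.ndarray:
        """Apply to an (N, 3) array of points."""
        pts = np.asarray(pts, dtype=float)
        return pts @ self.rotation.rotation_matrix().T + self.translation.as_array()

    def rotate_vector(self, v) -> np.ndarray:
        """Rotation part only (for directions)."""
        return self.rotation.rotate(v)

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.conjugate()
        return RigidTransform(
            rinv, Point3.from_array(-rinv.rotate(self.translation.as_array()))
        )


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Transform equal to applying ``b`` first, then ``a``."""
    return RigidTransform(a.rotation * b.rotation, a.apply(b.translation))


def apply(t: RigidTransform, p: Point3) -> Point3:
    """Rotate then translate ``p`` by ``t``."""
    return t.apply(p)


@dataclass(frozen=True)
class Pose6DoF:
    """Position + orientation of a tracked body; local ``+z`` is the tip axis."""

    position: Point3
    orientation: UnitQuaternion

    @property
    def axis(self) -> np.ndarray:
        """Unit instrument axis (local +z expressed in the parent frame)."""
        return self.orientation.rotate(np.array([0.0, 0.0, 1.0]))

    def tip(self, offset_mm: float) -> Point3:
        """Point ``offset_mm`` along the instrument axis from the sensor origin."""
        return Point3.from_array(self.position.as_array() + offset_mm * self.axis)


def random_rigid_transform(seed: int, max_translation_mm: float = 200.0) -> RigidTransform:
    """Uniformly random rotation + uniform translation in a cube, seeded.

    The rotation is drawn uniformly on SO(3) (normalized 4-D Gaussian);
    each translation component is uniform in ``[-max_translation_mm,
    +max_translation_mm]``.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    return RigidTransform(UnitQuaternion.from_array(q), Point3.from_array(t))
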