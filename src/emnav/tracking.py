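"""Simulated electromagnetic tracking chain.

Models the measurement side of the experiment: a ground-truth rigid
relation between tracking space (field-generator frame, +z up, mm) and
image space (phantom CT frame), noisy 6-DoF sensor samples inside a
bounded tracking volume, pointer digitization of registration fiducials,
and smooth endoscope approaches from the esophagus entry to each target.

Noise model: independent per-axis Gaussian positional noise, small
axis-angle orientation perturbations about a uniformly random axis, and
a terminal "operator" touch error describing how precisely a human lands
the tip on a marker.  The field generator's electromagnetic physics
(field distortion, distance-dependent jitter) is not modelled.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field
from scipy.interpolate import CubicSpline

from .errors import InvalidParams, WrongRole
from .geometry import (
    Point3,
    Pose6DoF,
    RigidTransform,
    UnitQuaternion,
    compose,
    rotation_between,
)
from .phantom import MarkerSpec, PhantomModel

__all__ = [
    "NoiseModel",
    "TrackingVolume",
    "TrackingSample",
    "GroundTruth",
    "stage_rng",
    "stage_seed",
    "sample_noisy_pose",
    "simulate_pointer_touch",
    "digitize_fiducials",
    "simulate_target_approach",
    "write_session_log",
    "read_session_log",
]


class NoiseModel(BaseModel):
    """Sensor and operator noise magnitudes.

    ``sigma_pos``: per-axis positional noise (mm); ``sigma_rot_deg``:
    standard deviation of the small-angle orientation perturbation
    (degrees); ``operator_sigma``: per-axis Gaussian error of the final
    tip placement on a marker (mm).  Defaults are stated assumptions
    calibrated so simulated runs land at the scale of a tabletop EM
    tracker plus a careful human operator.
    """

    model_config = {"frozen": True}

    sigma_pos: float = Field(0.2, ge=0.0)
    sigma_rot_deg: float = Field(0.2, ge=0.0)
    operator_sigma: float = Field(1.5, ge=0.0)

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(sigma_pos=0.0, sigma_rot_deg=0.0, operator_sigma=0.0)


class TrackingVolume(BaseModel):
    """Axis-aligned valid box of the field generator, tracking frame (mm).

    ``height_offset`` is the height of the phantom support plane above
    the tabletop field generator (the experiment used 110 mm).
    """

    model_config = {"frozen": True}

    height_offset: float = Field(110.0, ge=0.0)
    min_corner: tuple[float, float, float] = (-275.0, -275.0, 50.0)
    max_corner: tuple[float, float, float] = (275.0, 275.0, 600.0)

    def validate_extents(self) -> None:
        lo, hi = np.asarray(self.min_corner), np.asarray(self.max_corner)
        if np.any(hi - lo <= 0):
            raise InvalidParams("tracking volume extents must be positive")

    def contains(self, position: Point3) -> bool:
        p = position.as_array()
        lo, hi = np.asarray(self.min_corner), np.asarray(self.max_corner)
        return bool(np.all(p >= lo) and np.all(p <= hi))


@dataclass(frozen=True)
class TrackingSample:
    """One time-stamped noisy 6-DoF sensor reading in tracking space."""

    t: float
    pose: Pose6DoF
    valid: bool

    def to_json_dict(self) -> dict:
        return {
            "t": self.t,
            "pos": list(self.pose.position.as_array()),
            "quat": list(self.pose.orientation.as_array()),
            "valid": self.valid,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "TrackingSample":
        return cls(
            t=float(d["t"]),
            pose=Pose6DoF(
                Point3.from_array(d["pos"]),
                UnitQuaternion.from_array(d["quat"]),
            ),
            valid=bool(d["valid"]),
        )


@dataclass(frozen=True)
class GroundTruth:
    """True tracking<->image relation plus the phantom it concerns."""

    tracking_to_image: RigidTransform
    phantom: PhantomModel

    @property
    def image_to_tracking(self) -> RigidTransform:
        return self.tracking_to_image.inverse()

    @classmethod
    def build(
        cls,
        phantom: PhantomModel,
        volume: Optional[TrackingVolume] = None,
        seed: Optional[int] = None,
    ) -> "GroundTruth":
        """Place the supine phantom on the support plane above the generator.

        Image +z (superior) maps to a horizontal tracking axis and image
        +y (anterior) points up; the torso centroid sits centred over the
        generator at plate height plus the anterior half-thickness.  A
        seed adds a random yaw about vertical, a small tilt (<= 3 deg)
        and a tabletop offset (<= 40 mm) so different sessions occupy
        different parts of the tracking volume.
        """
        volume = volume or TrackingVolume()
        # supine base: image x -> track x, image y -> track z, image z -> -track y
        R = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]])
        height = volume.height_offset + float(phantom.params.torso_radii[1])
        base = RigidTransform.from_rotation_translation(R, [0.0, 0.0, height])
        if seed is not None:
            rng = stage_rng(seed, "placement")
            yaw = rng.uniform(-np.pi, np.pi)
            tilt_axis = rng.normal(size=3)
            tilt = UnitQuaternion.from_axis_angle(
                tilt_axis, np.radians(rng.uniform(-3.0, 3.0))
            )
            offset = rng.uniform(-40.0, 40.0, size=2)
            jitter = RigidTransform(
                UnitQuaternion.from_axis_angle([0, 0, 1], yaw) * tilt,
                Point3(offset[0], offset[1], 0.0),
            )
            image_to_tracking = compose(jitter, base)
        else:
            image_to_tracking = base
        return cls(image_to_tracking.inverse(), phantom)


# ---------------------------------------------------------------------------
# seeded sub-streams


def stage_seed(seed: int, stage: str) -> int:
    """Derived integer seed for a named pipeline stage (< 2**31)."""
    return int(
        np.random.SeedSequence(
            [int(seed), zlib.crc32(stage.encode())]
        ).generate_state(1)[0]
        % (2**31)
    )


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator keyed on (master seed, stage name): stages are independent."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    )


# ---------------------------------------------------------------------------
# simulation operations


def sample_noisy_pose(
    true_pose: Pose6DoF,
    noise: NoiseModel,
    rng: np.random.Generator,
    volume: Optional[TrackingVolume] = None,
    t: float = 0.0,
) -> TrackingSample:
    """Perturb a true pose by sensor noise and flag volume validity.

    Position gets independent per-axis Gaussian noise ``sigma_pos``; the
    orientation is rotated about a uniformly random axis by a Gaussian
    angle ``sigma_rot_deg`` (kept a proper rotation rather than noising
    quaternion components).  The rng draw order (3 position normals, 3
    axis normals, 1 angle normal) is fixed so streams stay aligned even
    at zero noise.
    """
    volume = volume or TrackingVolume()
    pos = true_pose.position.as_array() + rng.normal(0.0, 1.0, size=3) * noise.sigma_pos
    axis = rng.normal(size=3)
    angle = rng.normal(0.0, 1.0) * np.radians(noise.sigma_rot_deg)
    if np.linalg.norm(axis) < 1e-12:  # pragma: no cover - measure-zero draw
        axis = np.array([0.0, 0.0, 1.0])
    q = UnitQuaternion.from_axis_angle(axis, angle) * true_pose.orientation
    position = Point3.from_array(pos)
    return TrackingSample(
        t=t, pose=Pose6DoF(position, q), valid=volume.contains(position)
    )


def simulate_pointer_touch(
    fiducial: MarkerSpec,
    truth: GroundTruth,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> Point3:
    """Digitize one registration fiducial with the EM pointer (tracking space)."""
    if fiducial.role != "fiducial":
        raise WrongRole(
            f"marker {fiducial.id!r} has role {fiducial.role!r}; pointer "
            "digitization applies to registration fiducials only"
        )
    p = truth.image_to_tracking.apply(fiducial.position).as_array()
    p = p + rng.normal(0.0, 1.0, size=3) * noise.sigma_pos
    return Point3.from_array(p)


def digitize_fiducials(
    truth: GroundTruth,
    noise: NoiseModel,
    rng: np.random.Generator,
    ids: Optional[Sequence[str]] = None,
):
    """Touch each registration fiducial; returns a FiducialPairSet
    (moving = digitized tracking positions, fixed = image marker centres)."""
    from .registration import FiducialPairSet

    fiducials = truth.phantom.fiducials
    if ids is not None:
        wanted = list(ids)
        fiducials = [truth.phantom.marker(i) for i in wanted]
        for f in fiducials:
            if f.role != "fiducial":
                raise WrongRole(f"marker {f.id!r} is not a registration fiducial")
    moving = [simulate_pointer_touch(f, truth, noise, rng).as_array() for f in fiducials]
    fixed = [f.position.as_array() for f in fiducials]
    return FiducialPairSet(
        tuple(f.id for f in fiducials), np.array(moving), np.array(fixed)
    )


def _approach_waypoints(target: MarkerSpec, phantom: PhantomModel) -> np.ndarray:
    """Image-space waypoints from esophagus entry toward the target.

    Mural targets are approached through the stomach interior; extramural
    targets additionally route through the access aperture in the
    stomach wall before entering the necrotic cavity.
    """
    entry = phantom.esophagus_entry.as_array()
    s_c = np.asarray(phantom.params.stomach_center)
    inside = s_c + 0.35 * (entry - s_c)
    tpos = target.position.as_array()
    if target.role == "target_extramural":
        aperture = phantom.aperture_center.as_array()
        pre_ap = s_c + 0.5 * (aperture - s_c)
        return np.array([entry, inside, pre_ap, aperture, tpos])
    approach = s_c + 0.6 * (tpos - s_c)
    return np.array([entry, inside, approach, tpos])


def simulate_target_approach(
    target: MarkerSpec,
    truth: GroundTruth,
    noise: NoiseModel,
    duration: float,
    rate: float,
    rng: np.random.Generator,
    tip_offset: float = 5.0,
    volume: Optional[TrackingVolume] = None,
) -> List[TrackingSample]:
    """Simulate one endoscope approach terminating on (near) a target.

    A cubic spline through anatomical waypoints models the tip path; the
    final tip lands on the target plus a per-axis Gaussian operator
    error.  The sensor origin trails the tip by ``tip_offset`` mm along
    the local +z axis (the physical sensor protruded 5 mm beyond the
    endoscope tip), and every sample is perturbed by the sensor noise
    model.  Returns ``round(duration * rate)`` samples at uniform
    timestamps, deterministic for a given rng state.
    """
    if duration <= 0 or rate <= 0:
        raise InvalidParams("duration and rate must be positive")
    if target.role not in ("target_mural", "target_extramural"):
        raise WrongRole(f"marker {target.id!r} is not a navigation target")
    n = int(round(duration * rate))
    if n < 2:
        raise InvalidParams("duration * rate must give at least 2 samples")
    volume = volume or TrackingVolume()

    final_tip = target.position.as_array() + rng.normal(0.0, 1.0, size=3) * noise.operator_sigma
    waypoints = _approach_waypoints(target, truth.phantom)
    waypoints[-1] = final_tip
    u = np.linspace(0.0, 1.0, len(waypoints))
    spline = CubicSpline(u, waypoints, axis=0)

    # slow-in easing so the tip decelerates onto the marker
    s = np.sin(0.5 * np.pi * np.linspace(0.0, 1.0, n))
    tips = spline(s)
    tangents = spline(s, 1)

    t_img_to_track = truth.image_to_tracking
    samples: List[TrackingSample] = []
    for i in range(n):
        d = tangents[i]
        nd = np.linalg.norm(d)
        d = d / nd if nd > 1e-9 else np.array([0.0, 0.0, 1.0])
        sensor_pos_img = tips[i] - tip_offset * d
        q_img = rotation_between([0.0, 0.0, 1.0], d)
        pose_track = Pose6DoF(
            t_img_to_track.apply(Point3.from_array(sensor_pos_img)),
            t_img_to_track.rotation * q_img,
        )
        samples.append(
            sample_noisy_pose(pose_track, noise, rng, volume, t=i / rate)
        )
    return samples


# ---------------------------------------------------------------------------
# session-log IO (JSON lines, one sample per line)


def write_session_log(samples: Sequence[TrackingSample], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for s in samples:
            fh.write(json.dumps(s.to_json_dict()) + "\n")


def read_session_log(path) -> List[TrackingSample]:
    out = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(TrackingSample.from_json_dict(json.loads(line)))
    return out
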