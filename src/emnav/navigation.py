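"""Image-space navigation: registered endoscope-tip positions and sensor view.

Turns raw tracking samples into the quantities the assistance system
displays: the effective tip position in image space (sensor position
advanced by a fixed offset along the instrument axis, then mapped
through the registration transform) and the list of targets inside a
conical sensor field of view.  Rendering is out of scope; the computed
quantities are what the accuracy evaluation consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, Field

from .errors import InvalidSample
from .geometry import Point3
from .phantom import MarkerSpec
from .registration import RegistrationResult
from .tracking import TrackingSample

__all__ = [
    "NavigationConfig",
    "NavigationState",
    "tip_position_image_space",
    "distance_to_target",
    "visible_targets",
    "replay_session",
    "write_navigation_trace",
    "read_navigation_trace",
]


class NavigationConfig(BaseModel):
    """Tip offset and sensor-view cone.

    ``tip_offset``: distance (mm) from the sensor origin to the
    effective tip along the local +z axis — 5 mm in the physical setup,
    where the sensor protruded from the working channel beyond the
    endoscope tip.  ``fov_half_angle`` (deg) and ``fov_depth`` (mm)
    bound the simulated camera-view cone.
    """

    model_config = {"frozen": True}

    tip_offset: float = Field(5.0, ge=0.0)
    fov_half_angle: float = Field(70.0, gt=0.0, lt=90.0)
    fov_depth: float = Field(50.0, gt=0.0)


def tip_position_image_space(
    sample: TrackingSample, reg: RegistrationResult, cfg: NavigationConfig
) -> Point3:
    """Registered effective tip position (image space, mm).

    ``reg.transform`` applied to (sensor position + tip_offset * axis).
    Invalid samples (outside the tracking volume) are rejected rather
    than extrapolated.
    """
    if not sample.valid:
        raise InvalidSample(f"sample at t={sample.t} is outside the tracking volume")
    return reg.transform.apply(sample.pose.tip(cfg.tip_offset))


def distance_to_target(tip: Point3, target: MarkerSpec) -> float:
    """Euclidean distance (mm) between tip and marker centre."""
    return tip.distance_to(target.position)


@dataclass(frozen=True)
class NavigationState:
    """Registered view of one tracking sample."""

    registration: RegistrationResult
    sample: TrackingSample
    tip_image: Point3

    @classmethod
    def from_sample(
        cls, sample: TrackingSample, reg: RegistrationResult, cfg: NavigationConfig
    ) -> "NavigationState":
        return cls(reg, sample, tip_position_image_space(sample, reg, cfg))

    @property
    def axis_image(self) -> np.ndarray:
        """Instrument axis expressed in image space."""
        return self.registration.transform.rotate_vector(self.sample.pose.axis)


def visible_targets(
    state: NavigationState,
    markers: Sequence[MarkerSpec],
    cfg: NavigationConfig,
) -> List[Tuple[str, float, float]]:
    """Markers inside the sensor-view cone, sorted by distance.

    Returns ``(id, distance_mm, angle_off_axis_deg)`` for every marker
    within ``fov_depth`` of the tip and within ``fov_half_angle`` of the
    instrument axis.  A marker coincident with the tip is reported at
    angle 0.
    """
    tip = state.tip_image.as_array()
    axis = state.axis_image
    out: List[Tuple[str, float, float]] = []
    for m in markers:
        v = m.position.as_array() - tip
        d = float(np.linalg.norm(v))
        if d > cfg.fov_depth:
            continue
        if d < 1e-12:
            out.append((m.id, 0.0, 0.0))
            continue
        cosang = float(np.clip(np.dot(v, axis) / d, -1.0, 1.0))
        angle = float(np.degrees(np.arccos(cosang)))
        if angle <= cfg.fov_half_angle:
            out.append((m.id, d, angle))
    out.sort(key=lambda item: item[1])
    return out


# ---------------------------------------------------------------------------
# batch replay


def replay_session(
    samples: Iterable[TrackingSample],
    reg: RegistrationResult,
    cfg: NavigationConfig,
) -> List[dict]:
    """Map a session log to image-space tip positions.

    Invalid samples are skipped (not interpolated).  Each entry carries
    the timestamp, tip position and instrument axis in image space.
    """
    trace = []
    for s in samples:
        if not s.valid:
            continue
        state = NavigationState.from_sample(s, reg, cfg)
        trace.append(
            {
                "t": s.t,
                "tip_mm": [state.tip_image.x, state.tip_image.y, state.tip_image.z],
                "axis": list(state.axis_image),
            }
        )
    return trace


def write_navigation_trace(trace: Sequence[dict], path) -> None:
    with Path(path).open("w") as fh:
        for entry in trace:
            fh.write(json.dumps(entry) + "\n")


def read_navigation_trace(path) -> List[dict]:
    out = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(json.loads(line))
    return out
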