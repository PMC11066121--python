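"""Run configuration: one validated JSON manifest for the whole pipeline."""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional

from pydantic import BaseModel, Field, ValidationError

from .errors import InvalidParams
from .navigation import NavigationConfig
from .phantom import PhantomParams
from .tracking import NoiseModel, TrackingVolume

__all__ = ["RunConfig", "load_config"]


class RunConfig(BaseModel):
    """Everything a simulated necrosectomy session needs, range-checked up front.

    ``registration_fiducials`` optionally restricts registration to a
    named subset (e.g. ``["F1", "F2", "F3"]`` to mirror a three-marker
    digitization workflow); ``None`` uses all six.
    """

    model_config = {"frozen": True}

    seed: int = 0
    output_dir: Path = Path("emnav_out")
    phantom: PhantomParams = Field(default_factory=PhantomParams)
    noise: NoiseModel = Field(default_factory=NoiseModel)
    volume: TrackingVolume = Field(default_factory=TrackingVolume)
    navigation: NavigationConfig = Field(default_factory=NavigationConfig)
    registration_fiducials: Optional[List[str]] = None
    approach_duration_s: float = Field(5.0, gt=0.0)
    sample_rate_hz: float = Field(40.0, gt=0.0)

    def validate_ranges(self) -> None:
        self.phantom.validate_layout()
        self.volume.validate_extents()
        if self.registration_fiducials is not None and len(self.registration_fiducials) < 3:
            raise InvalidParams("registration needs at least 3 fiducials")

    def to_json(self, path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional JSON file plus keyword overrides."""
    data = {}
    if path is not None:
        data = json.loads(Path(path).read_text())
    data.update({k: v for k, v in overrides.items() if v is not None})
    try:
        cfg = RunConfig(**data)
    except ValidationError as exc:
        raise InvalidParams(str(exc)) from exc
    cfg.validate_ranges()
    return cfg
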