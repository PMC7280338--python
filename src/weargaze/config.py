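"""Tool configuration: JSON settings file, schema-validated.

The shipped ``defaults.json`` carries the default settings; a user file
passed with ``--config`` fully replaces it.  Unknown keys are rejected with
their location, so typos do not silently fall back to defaults.
"""

from __future__ import annotations

import json
import os
from importlib import resources
from pathlib import Path

import pydantic

from .errors import ConfigError


class _Model(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")


class SgConfig(_Model):
    window_samples: int | None = None  # None: ~100 ms at the recording's rate
    poly_order: int = 2


class QualityConfig(_Model):
    window_ms: float = 300.0


class ClassifierParamConfig(_Model):
    name: str
    value: float
    min: float
    max: float
    user_settable: bool = True


class ClassifierConfig(_Model):
    id: str
    entry_point: str
    parameters: list[ClassifierParamConfig] = []


class ToolConfig(_Model):
    sg: SgConfig = SgConfig()
    quality: QualityConfig = QualityConfig()
    classifiers: list[ClassifierConfig] = []
    export_streams: list[str] = ["gaze", "imu", "quality", "coding"]

    def classifier(self, classifier_id: str) -> ClassifierConfig:
        for c in self.classifiers:
            if c.id == classifier_id:
                return c
        raise ConfigError(
            f"no classifier {classifier_id!r} in config; known: {[c.id for c in self.classifiers]}"
        )


def load_config(path: os.PathLike | str | None = None) -> ToolConfig:
    """Load and validate the JSON settings (the shipped defaults when None)."""
    if path is None:
        text = resources.files("weargaze").joinpath("defaults.json").read_text("utf-8")
        source = "defaults.json"
    else:
        p = Path(path)
        if not p.is_file():
            raise ConfigError(f"config file not found: {p}")
        text = p.read_text("utf-8")
        source = str(p)
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{source}: invalid JSON: {exc}") from exc
    try:
        return ToolConfig.model_validate(obj)
    except pydantic.ValidationError as exc:
        locations = "; ".join(
            f"{'.'.join(str(x) for x in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ConfigError(f"{source}: invalid config: {locations}") from exc
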