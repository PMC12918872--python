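"""Project configuration: JSON settings file and trajectory cataloging."""

from __future__ import annotations

import glob
import json
import re
import warnings
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, field_validator

__all__ = [
    "ProjectSettings",
    "ProjectConfigError",
    "load_project_config",
    "resolve_trajectory_files",
    "natural_sort_key",
]

_KNOWN_KEYS = {
    "structure_path",
    "trajectory_pattern",
    "output_dir",
    "time_step",
    "frame_start",
    "frame_stop",
    "frame_stride",
}


class ProjectConfigError(ValueError):
    pass


class ProjectSettings(BaseModel):
    """Defaults for an analysis project, stored as flat JSON."""

    structure_path: str
    trajectory_pattern: str
    output_dir: str = "."
    time_step: Optional[float] = None  # ps per frame
    frame_start: Optional[int] = None
    frame_stop: Optional[int] = None
    frame_stride: int = 1

    @field_validator("time_step")
    @classmethod
    def _time_step_positive(cls, v):
        if v is not None and v <= 0:
            raise ValueError("time_step must be > 0")
        return v

    @field_validator("frame_stride")
    @classmethod
    def _stride_positive(cls, v):
        if v < 1:
            raise ValueError("frame_stride must be >= 1")
        return v

    def with_overrides(self, **overrides) -> "ProjectSettings":
        """Explicit (non-None) overrides win over file values."""
        data = self.model_dump()
        for key, value in overrides.items():
            if value is not None:
                data[key] = value
        return ProjectSettings(**data)

    def trajectory_files(self) -> list[str]:
        return resolve_trajectory_files(self.trajectory_pattern)


def load_project_config(path) -> ProjectSettings:
    """Load a flat-JSON project file.

    Unknown keys warn rather than fail; missing required keys raise a
    named-key error; syntax errors report the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise ProjectConfigError(f"no project config: {path}")
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ProjectConfigError(
            f"project config syntax error in {path} at line {exc.lineno}: {exc.msg}"
        ) from exc
    if not isinstance(data, dict):
        raise ProjectConfigError(f"project config {path} must be a JSON object")
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        warnings.warn(f"ignoring unknown project config keys: {sorted(unknown)}")
        data = {k: v for k, v in data.items() if k in _KNOWN_KEYS}
    for required in ("structure_path", "trajectory_pattern"):
        if required not in data:
            raise ProjectConfigError(f"project config missing required key: {required!r}")
    return ProjectSettings(**data)


_INT_RE = re.compile(r"(\d+)")


def natural_sort_key(path: str) -> tuple:
    """Sort key putting run2 before run10 (embedded integers compare numerically)."""
    parts = _INT_RE.split(str(path))
    key = []
    for i, part in enumerate(parts):
        if i % 2:  # digit group
            key.append((1, int(part), ""))
        elif part:
            key.append((0, 0, part))
    return tuple(key)


def resolve_trajectory_files(pattern: str) -> list[str]:
    """Expand a glob pattern to a naturally sorted file list."""
    if not pattern:
        raise ProjectConfigError("empty trajectory pattern")
    matches = glob.glob(pattern)
    if not matches:
        raise ProjectConfigError(f"no trajectory files match pattern: {pattern}")
    return sorted(matches, key=lambda p: (natural_sort_key(p), p))
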