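"""Analysis registry, dispatch and reproducibility logging.

Every analysis lives in :mod:`stanalyzer.analysis` and exposes an
``ANALYSIS`` spec: a name, an option schema and a unary ``main(settings)``
entry point.  Invocations are appended to a replayable command log.
"""

from __future__ import annotations

import datetime
import importlib
import pkgutil
import shlex
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Optional

__all__ = [
    "OptionSpec",
    "AnalysisSpec",
    "CommandRecord",
    "discover_analyses",
    "record_invocation",
    "build_argv",
    "run_analysis",
    "RegistryError",
]

COMMAND_LOG = "commands.log"


class RegistryError(RuntimeError):
    pass


@dataclass(frozen=True)
class OptionSpec:
    name: str
    type: str = "str"           # str | int | float | bool
    default: Any = None
    help: str = ""
    required: bool = False

    def convert(self, raw):
        if raw is None:
            return self.default
        if self.type == "int":
            return int(raw)
        if self.type == "float":
            return float(raw)
        if self.type == "bool":
            if isinstance(raw, bool):
                return raw
            return str(raw).lower() in ("1", "true", "yes", "on")
        return str(raw)


@dataclass(frozen=True)
class AnalysisSpec:
    name: str
    category: str
    description: str
    options: tuple[OptionSpec, ...]
    entry_point: Callable[[dict], list[Path]]

    def option(self, name: str) -> OptionSpec:
        for opt in self.options:
            if opt.name == name:
                return opt
        raise KeyError(name)


@dataclass
class CommandRecord:
    analysis: str
    argv: list[str]
    timestamp: str
    outputs: list[Path] = field(default_factory=list)

    @property
    def command_line(self) -> str:
        return shlex.join(self.argv)


_REGISTRY: Optional[dict[str, AnalysisSpec]] = None


def discover_analyses(refresh: bool = False) -> dict[str, AnalysisSpec]:
    """Import every module in the analysis subpackage and collect specs."""
    global _REGISTRY
    if _REGISTRY is not None and not refresh:
        return _REGISTRY
    from . import analysis as analysis_pkg

    registry: dict[str, AnalysisSpec] = {}
    for info in pkgutil.iter_modules(analysis_pkg.__path__):
        if info.name.startswith("_"):
            continue
        module = importlib.import_module(f"{analysis_pkg.__name__}.{info.name}")
        spec = getattr(module, "ANALYSIS", None)
        if spec is None:
            continue
        if spec.name in registry:
            raise RegistryError(f"duplicate analysis name: {spec.name}")
        registry[spec.name] = spec
    _REGISTRY = registry
    return registry


def get_analysis(name: str) -> AnalysisSpec:
    registry = discover_analyses()
    key = name.replace("-", "_")
    if key not in registry:
        raise RegistryError(
            f"unknown analysis {name!r}; valid names: {', '.join(sorted(registry))}"
        )
    return registry[key]


def build_argv(spec: AnalysisSpec, settings: dict) -> list[str]:
    """Canonical replayable command line for a settings mapping."""
    argv = ["stanalyzer", spec.name.replace("_", "-")]
    for key in sorted(settings):
        if key.startswith("_"):
            continue
        value = settings[key]
        if value is None:
            continue
        flag = "--" + key.replace("_", "-")
        if isinstance(value, bool):
            argv += [flag, "true" if value else "false"]
        else:
            argv += [flag, str(value)]
    return argv


def record_invocation(spec: AnalysisSpec, argv: list[str], out_dir) -> CommandRecord:
    """Append the exact replayable command line to the project's log."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = out_dir / COMMAND_LOG
    try:
        with log.open("a") as handle:
            handle.write(shlex.join(argv) + "\n")
    except OSError as exc:
        raise RegistryError(f"cannot write command record in {out_dir}: {exc}") from exc
    return CommandRecord(
        analysis=spec.name,
        argv=list(argv),
        timestamp=datetime.datetime.now().isoformat(timespec="seconds"),
    )


def run_analysis(name: str, settings: dict, record: bool = True) -> list[Path]:
    """Dispatch one analysis: log the invocation, then run its entry point."""
    spec = get_analysis(name)
    merged = dict(settings)
    for opt in spec.options:
        if opt.name not in merged or merged[opt.name] is None:
            if opt.required and opt.default is None:
                raise RegistryError(f"analysis {spec.name}: missing option {opt.name!r}")
            merged[opt.name] = opt.default
        else:
            merged[opt.name] = opt.convert(merged[opt.name])
    if record:
        out_dir = merged.get("output_dir", ".")
        record_invocation(spec, build_argv(spec, merged), out_dir)
    outputs = spec.entry_point(merged)
    return [Path(p) for p in outputs]


def replay_command(line: str) -> list[Path]:
    """Re-execute a recorded command line (deterministic analyses reproduce
    their outputs bit-exactly)."""
    argv = shlex.split(line.strip())
    if len(argv) < 2 or argv[0] != "stanalyzer":
        raise RegistryError(f"not a stanalyzer command: {line!r}")
    name = argv[1]
    settings: dict[str, Any] = {}
    i = 2
    while i < len(argv):
        if not argv[i].startswith("--"):
            raise RegistryError(f"cannot parse recorded argument {argv[i]!r}")
        key = argv[i][2:].replace("-", "_")
        settings[key] = argv[i + 1]
        i += 2
    spec = get_analysis(name)
    for key in list(settings):
        if key in ("frame_start", "frame_stop"):
            settings[key] = int(settings[key])
        elif key == "frame_stride":
            settings[key] = int(settings[key])
        elif key == "time_step":
            settings[key] = float(settings[key])
        else:
            try:
                settings[key] = spec.option(key).convert(settings[key])
            except KeyError:
                pass
    return run_analysis(name, settings, record=False)
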