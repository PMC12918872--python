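"""Shared plumbing for the analysis entry points."""

from __future__ import annotations

from pathlib import Path

from ..project import ProjectSettings
from ..registry import OptionSpec
from ..selection import selection_indices
from ..topology import AtomTable
from ..trajectory import iterate_frames, load_structure

COMMON_OPTIONS = (
    OptionSpec("structure_path", "str", None, "structure file (PDB)", required=True),
    OptionSpec("trajectory_pattern", "str", None, "trajectory file glob", required=True),
    OptionSpec("output_dir", "str", ".", "directory for output files"),
    OptionSpec("time_step", "float", None, "ps per frame"),
    OptionSpec("frame_start", "int", None, "first frame (0-based)"),
    OptionSpec("frame_stop", "int", None, "stop frame (exclusive)"),
    OptionSpec("frame_stride", "int", 1, "frame stride"),
)


def project_from_settings(settings: dict) -> ProjectSettings:
    return ProjectSettings(
        structure_path=settings["structure_path"],
        trajectory_pattern=settings["trajectory_pattern"],
        output_dir=settings.get("output_dir") or ".",
        time_step=settings.get("time_step"),
        frame_start=settings.get("frame_start"),
        frame_stop=settings.get("frame_stop"),
        frame_stride=settings.get("frame_stride") or 1,
    )


def load_context(settings: dict):
    """(project, atoms, frame iterator) from a settings mapping."""
    project = project_from_settings(settings)
    atoms = load_structure(project.structure_path)
    frames = iterate_frames(project, atoms)
    return project, atoms, frames


def out_path(settings: dict, default_name: str) -> Path:
    out_dir = Path(settings.get("output_dir") or ".")
    out_dir.mkdir(parents=True, exist_ok=True)
    return out_dir / (settings.get("out") or default_name)


def parse_groups(spec_text: str, atoms: AtomTable) -> dict[str, str]:
    """Parse 'label=selection;label=selection' group syntax (validated)."""
    groups: dict[str, str] = {}
    for chunk in spec_text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            label, sel = chunk.split("=", 1)
        else:
            label, sel = f"g{len(groups) + 1}", chunk
        selection_indices(sel.strip(), atoms)  # raises on bad grammar
        groups[label.strip()] = sel.strip()
    if not groups:
        raise ValueError(f"no groups in {spec_text!r}")
    return groups


def parse_chain_spec(text: str) -> list[tuple[str, list[str]]]:
    """Parse 'C2:H2A,H2B C3:H3A,H3B' chain specifications."""
    chain = []
    for chunk in text.split():
        if ":" not in chunk:
            raise ValueError(f"bad chain spec element {chunk!r} (want C:H1,H2)")
        carbon, hydrogens = chunk.split(":", 1)
        chain.append((carbon, [h for h in hydrogens.split(",") if h]))
    if not chain:
        raise ValueError("empty chain spec")
    return chain
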