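"""Root mean square deviation (RMSD)."""

from ..protein import rmsd_series
from ..registry import AnalysisSpec, OptionSpec
from ..trajectory import iterate_frames, load_structure
from ._helpers import COMMON_OPTIONS, out_path, project_from_settings


def main(settings: dict):
    project = project_from_settings(settings)
    atoms = load_structure(project.structure_path)
    ref_index = settings["ref_frame"]
    reference = None
    for frame in iterate_frames(project.with_overrides(frame_start=0, frame_stride=1), atoms):
        if frame.index == ref_index:
            reference = frame
            break
    if reference is None:
        raise ValueError(f"reference frame {ref_index} not found")
    frames = iterate_frames(project, atoms)
    table = rmsd_series(frames, settings["sel"], reference, atoms, fit=settings["fit"])
    return [table.write(out_path(settings, "rmsd.tsv"))]


ANALYSIS = AnalysisSpec(
    name="rmsd",
    category="Proteins and Nucleic Acids",
    description="Mass-weighted RMSD to a reference frame (optionally fitted)",
    options=COMMON_OPTIONS
    + (
        OptionSpec("sel", "str", "protein and name CA", "atom selection"),
        OptionSpec("ref_frame", "int", 0, "reference frame index"),
        OptionSpec("fit", "bool", True, "superpose before RMSD"),
        OptionSpec("out", "str", "rmsd.tsv", "output TSV name"),
    ),
    entry_point=main,
)
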