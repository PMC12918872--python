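"""Pore radius histogram."""

from ..protein import pore_radius_profile
from ..registry import AnalysisSpec, OptionSpec
from ._helpers import COMMON_OPTIONS, load_context, out_path


def main(settings: dict):
    _, atoms, frames = load_context(settings)
    table = pore_radius_profile(
        frames, settings["sel"], atoms, bin_width=settings["bin_width"]
    )
    return [table.write(out_path(settings, "pore_radius.tsv"))]


ANALYSIS = AnalysisSpec(
    name="pore_radius",
    category="Proteins and Nucleic Acids",
    description="Mean pore radius per z bin (vdW-corrected min distance to axis)",
    options=COMMON_OPTIONS
    + (
        OptionSpec("sel", "str", "protein", "pore-lining selection"),
        OptionSpec("bin_width", "float", 1.0, "z bin width (Å)"),
        OptionSpec("out", "str", "pore_radius.tsv", "output TSV name"),
    ),
    entry_point=main,
)
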