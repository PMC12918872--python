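"""Membrane thickness D_PP."""

from ..membrane import membrane_thickness
from ..registry import AnalysisSpec, OptionSpec
from ._helpers import COMMON_OPTIONS, load_context, out_path


def main(settings: dict):
    _, atoms, frames = load_context(settings)
    table = membrane_thickness(frames, settings["sel"], atoms)
    return [table.write(out_path(settings, "thickness.tsv"))]


ANALYSIS = AnalysisSpec(
    name="thickness",
    category="Membrane",
    description="Bilayer phosphate-plane distance D_PP per frame",
    options=COMMON_OPTIONS
    + (
        OptionSpec("sel", "str", "name P", "phosphate selection"),
        OptionSpec("out", "str", "thickness.tsv", "output TSV name"),
    ),
    entry_point=main,
)
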