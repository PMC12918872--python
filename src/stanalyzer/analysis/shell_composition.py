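"""Shell composition analysis (Voronoi)."""

from ..membrane import shell_composition
from ..registry import AnalysisSpec, OptionSpec
from ._helpers import COMMON_OPTIONS, load_context, out_path


def main(settings: dict):
    _, atoms, frames = load_context(settings)
    table = shell_composition(
        frames,
        settings["center_type"],
        settings["sel"],
        atoms,
        n_shells=settings["n_shells"],
    )
    return [table.write(out_path(settings, "shell_composition.tsv"))]


ANALYSIS = AnalysisSpec(
    name="shell_composition",
    category="Membrane",
    description="Mean lipid-type counts in Voronoi neighbor shells",
    options=COMMON_OPTIONS
    + (
        OptionSpec("sel", "str", "name P", "one site atom per lipid"),
        OptionSpec("center_type", "str", None, "lipid type at shell center", required=True),
        OptionSpec("n_shells", "int", 3, "number of shells"),
        OptionSpec("out", "str", "shell_composition.tsv", "output TSV name"),
    ),
    entry_point=main,
)
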