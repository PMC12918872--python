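"""Area per lipid (Voronoi)."""

from ..membrane import area_per_lipid
from ..registry import AnalysisSpec, OptionSpec
from ._helpers import COMMON_OPTIONS, load_context, out_path


def main(settings: dict):
    _, atoms, frames = load_context(settings)
    table = area_per_lipid(frames, settings["sel"], atoms)
    return [table.write(out_path(settings, "apl.tsv"))]


ANALYSIS = AnalysisSpec(
    name="apl",
    category="Membrane",
    description="Per-frame, per-lipid-type mean Voronoi area per lipid",
    options=COMMON_OPTIONS
    + (
        OptionSpec("sel", "str", "name P", "one site atom per lipid"),
        OptionSpec("out", "str", "apl.tsv", "output TSV name"),
    ),
    entry_point=main,
)
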