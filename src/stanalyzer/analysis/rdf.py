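"""Radial distribution function."""

from ..contacts import radial_distribution
from ..registry import AnalysisSpec, OptionSpec
from ._helpers import COMMON_OPTIONS, load_context, out_path


def main(settings: dict):
    _, atoms, frames = load_context(settings)
    table = radial_distribution(
        frames,
        settings["sel_a"],
        settings["sel_b"],
        atoms,
        bin_width=settings["bin_width"],
        r_max=settings["r_max"],
    )
    return [table.write(out_path(settings, "rdf.tsv"))]


ANALYSIS = AnalysisSpec(
    name="rdf",
    category="Contacts",
    description="g(r) between two selections (minimum image)",
    options=COMMON_OPTIONS
    + (
        OptionSpec("sel_a", "str", None, "first selection", required=True),
        OptionSpec("sel_b", "str", None, "second selection", required=True),
        OptionSpec("bin_width", "float", 0.1, "bin width (Å)"),
        OptionSpec("r_max", "float", 10.0, "max distance (Å, <= min box/2)"),
        OptionSpec("out", "str", "rdf.tsv", "output TSV name"),
    ),
    entry_point=main,
)
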