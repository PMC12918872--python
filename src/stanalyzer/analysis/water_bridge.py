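"""Water bridge detection."""

from ..nonbonded import records_to_table, water_bridges
from ..registry import AnalysisSpec, OptionSpec
from ._helpers import COMMON_OPTIONS, load_context, out_path


def main(settings: dict):
    _, atoms, frames = load_context(settings)
    records = water_bridges(
        frames,
        settings["sel_a"],
        settings["sel_b"],
        atoms,
        d_cut=settings["d_cut"],
        angle_cut=settings["angle_cut"],
    )
    return [records_to_table(records).write(out_path(settings, "water_bridge.tsv"))]


ANALYSIS = AnalysisSpec(
    name="water_bridge",
    category="Non-bond Interactions",
    description="Single-water bridges between two selections, frame-sorted",
    options=COMMON_OPTIONS
    + (
        OptionSpec("sel_a", "str", None, "first selection", required=True),
        OptionSpec("sel_b", "str", None, "second selection", required=True),
        OptionSpec("d_cut", "float", 3.5, "H-bond distance cutoff (Å)"),
        OptionSpec("angle_cut", "float", 150.0, "H-bond angle cutoff (deg)"),
        OptionSpec("out", "str", "water_bridge.tsv", "output TSV name"),
    ),
    entry_point=main,
)
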