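"""Position with time series."""

from ..membrane import position_timeseries
from ..registry import AnalysisSpec, OptionSpec
from ._helpers import COMMON_OPTIONS, load_context, out_path, parse_groups


def main(settings: dict):
    _, atoms, frames = load_context(settings)
    groups = parse_groups(settings["sel"], atoms)
    table = position_timeseries(frames, groups, atoms)
    return [table.write(out_path(settings, "position.tsv"))]


ANALYSIS = AnalysisSpec(
    name="position",
    category="Membrane",
    description="Group center-of-mass (x, y, z) per frame",
    options=COMMON_OPTIONS
    + (
        OptionSpec("sel", "str", None, "groups: 'label=expr;label=expr'", required=True),
        OptionSpec("out", "str", "position.tsv", "output TSV name"),
    ),
    entry_point=main,
)
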