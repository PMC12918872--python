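"""Salt bridge detection."""

from ..nonbonded import salt_bridges
from ..registry import AnalysisSpec, OptionSpec
from ._helpers import COMMON_OPTIONS, load_context, out_path


def main(settings: dict):
    _, atoms, frames = load_context(settings)
    table = salt_bridges(frames, atoms, d_cut=settings["d_cut"])
    return [table.write(out_path(settings, "salt_bridge.tsv"))]


ANALYSIS = AnalysisSpec(
    name="salt_bridge",
    category="Non-bond Interactions",
    description="Basic-N/acidic-O contacts, frequency-sorted residue pairs",
    options=COMMON_OPTIONS
    + (
        OptionSpec("d_cut", "float", 4.0, "N-O distance cutoff (Å)"),
        OptionSpec("out", "str", "salt_bridge.tsv", "output TSV name"),
    ),
    entry_point=main,
)
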