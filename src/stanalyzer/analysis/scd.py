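"""S_CD deuterium order parameter profile."""

from ..membrane import scd_profile
from ..registry import AnalysisSpec, OptionSpec
from ._helpers import COMMON_OPTIONS, load_context, out_path, parse_chain_spec


def main(settings: dict):
    _, atoms, frames = load_context(settings)
    chain = parse_chain_spec(settings["chain"])
    table = scd_profile(
        frames, chain, settings["sel"], atoms, chain_label=settings["chain_label"]
    )
    return [table.write(out_path(settings, "scd.tsv"))]


ANALYSIS = AnalysisSpec(
    name="scd",
    category="Membrane",
    description="Deuterium order parameter |S_CD| per chain carbon",
    options=COMMON_OPTIONS
    + (
        OptionSpec("sel", "str", None, "lipid selection", required=True),
        OptionSpec(
            "chain", "str", None,
            "chain spec: 'C2:H2A,H2B C3:H3A,H3B ...' in chain order", required=True,
        ),
        OptionSpec("chain_label", "str", "sn-1", "chain label for output"),
        OptionSpec("out", "str", "scd.tsv", "output TSV name"),
    ),
    entry_point=main,
)
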