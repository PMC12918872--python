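"""Root mean square fluctuation (RMSF)."""

from ..protein import rmsf_per_residue
from ..registry import AnalysisSpec, OptionSpec
from ._helpers import COMMON_OPTIONS, load_context, out_path


def main(settings: dict):
    _, atoms, frames = load_context(settings)
    table = rmsf_per_residue(frames, settings["sel"], atoms)
    return [table.write(out_path(settings, "rmsf.tsv"))]


ANALYSIS = AnalysisSpec(
    name="rmsf",
    category="Proteins and Nucleic Acids",
    description="Per-residue fluctuation about the superposed mean structure",
    options=COMMON_OPTIONS
    + (
        OptionSpec("sel", "str", "protein and name CA", "atom selection"),
        OptionSpec("out", "str", "rmsf.tsv", "output TSV name"),
    ),
    entry_point=main,
)
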