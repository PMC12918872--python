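"""Residue contacts."""

from ..contacts import residue_contacts
from ..registry import AnalysisSpec, OptionSpec
from ._helpers import COMMON_OPTIONS, load_context, out_path


def main(settings: dict):
    _, atoms, frames = load_context(settings)
    table, _ = residue_contacts(
        frames, settings["sel_a"], settings["sel_b"], atoms, cutoff=settings["cutoff"]
    )
    return [table.write(out_path(settings, "contacts.tsv"))]


ANALYSIS = AnalysisSpec(
    name="residue_contacts",
    category="Contacts",
    description="Residue-pair contact frequencies (heavy-atom min distance)",
    options=COMMON_OPTIONS
    + (
        OptionSpec("sel_a", "str", None, "first selection", required=True),
        OptionSpec("sel_b", "str", None, "second selection", required=True),
        OptionSpec("cutoff", "float", 4.5, "contact cutoff (Å)"),
        OptionSpec("out", "str", "contacts.tsv", "output TSV name"),
    ),
    entry_point=main,
)
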