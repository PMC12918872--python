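"""Hydrogen bond detection."""

from ..nonbonded import hydrogen_bonds, records_to_table
from ..registry import AnalysisSpec, OptionSpec
from ._helpers import COMMON_OPTIONS, load_context, out_path


def main(settings: dict):
    _, atoms, frames = load_context(settings)
    records = hydrogen_bonds(
        frames,
        settings["donor_sel"],
        settings["acceptor_sel"],
        atoms,
        d_cut=settings["d_cut"],
        angle_cut=settings["angle_cut"],
    )
    return [records_to_table(records).write(out_path(settings, "hbond.tsv"))]


ANALYSIS = AnalysisSpec(
    name="hbond",
    category="Non-bond Interactions",
    description="D-H...A hydrogen bonds (distance + angle gates), frame-sorted",
    options=COMMON_OPTIONS
    + (
        OptionSpec("donor_sel", "str", "protein", "donor selection"),
        OptionSpec("acceptor_sel", "str", "protein", "acceptor selection"),
        OptionSpec("d_cut", "float", 3.5, "donor-acceptor distance cutoff (Å)"),
        OptionSpec("angle_cut", "float", 150.0, "D-H...A angle cutoff (deg)"),
        OptionSpec("out", "str", "hbond.tsv", "output TSV name"),
    ),
    entry_point=main,
)
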