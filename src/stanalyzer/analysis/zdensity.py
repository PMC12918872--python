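"""Z density profile."""

from ..membrane import z_density_profile
from ..registry import AnalysisSpec, OptionSpec
from ._helpers import COMMON_OPTIONS, load_context, out_path, parse_groups


def main(settings: dict):
    _, atoms, frames = load_context(settings)
    groups = parse_groups(settings["sel"], atoms)
    table = z_density_profile(
        frames,
        groups,
        atoms,
        bin_width=settings["bin_width"],
        mode=settings["mode"],
        center_sel=settings.get("center_sel"),
    )
    return [table.write(out_path(settings, "zdensity.tsv"))]


ANALYSIS = AnalysisSpec(
    name="zdensity",
    category="Membrane",
    description="Frame-averaged density profile along z per group",
    options=COMMON_OPTIONS
    + (
        OptionSpec("sel", "str", None, "groups: 'label=expr;label=expr'", required=True),
        OptionSpec("bin_width", "float", 1.0, "bin width (Å)"),
        OptionSpec("mode", "str", "number", "number | mass | electron"),
        OptionSpec("center_sel", "str", None, "midplane selection for re-centering"),
        OptionSpec("out", "str", "zdensity.tsv", "output TSV name"),
    ),
    entry_point=main,
)
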