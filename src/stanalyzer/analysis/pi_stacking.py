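"""Pi stacking detection."""

from ..nonbonded import pi_stacking
from ..registry import AnalysisSpec, OptionSpec
from ._helpers import COMMON_OPTIONS, load_context, out_path


def main(settings: dict):
    _, atoms, frames = load_context(settings)
    table = pi_stacking(frames, atoms, centroid_cut=settings["centroid_cut"])
    return [table.write(out_path(settings, "pi_stacking.tsv"))]


ANALYSIS = AnalysisSpec(
    name="pi_stacking",
    category="Non-bond Interactions",
    description="Aromatic ring stacking classified by interplanar angle",
    options=COMMON_OPTIONS
    + (
        OptionSpec("centroid_cut", "float", 6.0, "ring centroid cutoff (Å)"),
        OptionSpec("out", "str", "pi_stacking.tsv", "output TSV name"),
    ),
    entry_point=main,
)
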