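"""System size: per-frame box dimensions."""

from ..registry import AnalysisSpec, OptionSpec
from ..systemprops import system_size
from ._helpers import COMMON_OPTIONS, load_context, out_path


def main(settings: dict):
    _, _, frames = load_context(settings)
    table = system_size(frames)
    return [table.write(out_path(settings, "system_size.tsv"))]


ANALYSIS = AnalysisSpec(
    name="system_size",
    category="System Dimensions",
    description="Box dimensions and volume in each frame",
    options=COMMON_OPTIONS
    + (OptionSpec("out", "str", "system_size.tsv", "output TSV name"),),
    entry_point=main,
)
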