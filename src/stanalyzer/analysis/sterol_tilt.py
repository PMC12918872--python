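"""Sterol tilt angle Θ."""

from ..membrane import sterol_tilt
from ..registry import AnalysisSpec, OptionSpec
from ._helpers import COMMON_OPTIONS, load_context, out_path


def main(settings: dict):
    _, atoms, frames = load_context(settings)
    series, hist = sterol_tilt(
        frames,
        settings["sel"],
        atoms,
        tail_name=settings["tail"],
        head_name=settings["head"],
    )
    path = out_path(settings, "sterol_tilt.tsv")
    hist_path = path.with_name(path.stem + "_hist.tsv")
    return [series.write(path), hist.write(hist_path)]


ANALYSIS = AnalysisSpec(
    name="sterol_tilt",
    category="Membrane",
    description="Sterol ring-axis tilt angle versus the membrane normal",
    options=COMMON_OPTIONS
    + (
        OptionSpec("sel", "str", "resname STER", "sterol selection"),
        OptionSpec("tail", "str", "C3", "tail atom name"),
        OptionSpec("head", "str", "C17", "head atom name"),
        OptionSpec("out", "str", "sterol_tilt.tsv", "output TSV name"),
    ),
    entry_point=main,
)
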