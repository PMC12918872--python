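"""Area compressibility modulus K_A."""

from ..membrane import area_compressibility_blocks
from ..registry import AnalysisSpec, OptionSpec
from ..tables import TimeSeriesTable
from ._helpers import COMMON_OPTIONS, load_context, out_path


def main(settings: dict):
    _, atoms, frames = load_context(settings)
    areas = [frame.box[0] * frame.box[1] for frame in frames]
    ka, stderr = area_compressibility_blocks(
        areas, settings["temperature"], n_blocks=settings["n_blocks"]
    )
    table = TimeSeriesTable(["ka_mN_per_m", "block_se", "n_frames", "temperature"])
    table.append(float(ka), float(stderr), len(areas), float(settings["temperature"]))
    return [table.write(out_path(settings, "ka.tsv"))]


ANALYSIS = AnalysisSpec(
    name="ka",
    category="Membrane",
    description="Area compressibility modulus from lateral-area fluctuations",
    options=COMMON_OPTIONS
    + (
        OptionSpec("temperature", "float", 303.15, "temperature (K)"),
        OptionSpec("n_blocks", "int", 5, "blocks for the error estimate"),
        OptionSpec("out", "str", "ka.tsv", "output TSV name"),
    ),
    entry_point=main,
)
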