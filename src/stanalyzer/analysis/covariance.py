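"""Covariance analysis."""

from ..protein import covariance_analysis
from ..registry import AnalysisSpec, OptionSpec
from ..tables import TimeSeriesTable
from ._helpers import COMMON_OPTIONS, load_context, out_path


def main(settings: dict):
    _, atoms, frames = load_context(settings)
    result = covariance_analysis(frames, settings["sel"], atoms, fit=settings["fit"])
    table = TimeSeriesTable(["mode", "eigenvalue"])
    for i, value in enumerate(result.eigenvalues):
        table.append(i, float(value))
    path = table.write(out_path(settings, "covariance.tsv"))
    outputs = [path]
    if settings["write_matrix"]:
        matrix_table = TimeSeriesTable(
            [f"c{i}" for i in range(result.matrix.shape[1])]
        )
        for row in result.matrix:
            matrix_table.append(*[float(v) for v in row])
        outputs.append(matrix_table.write(path.with_name(path.stem + "_matrix.tsv")))
    return outputs


ANALYSIS = AnalysisSpec(
    name="covariance",
    category="Others",
    description="3N×3N positional covariance; eigenvalues descending",
    options=COMMON_OPTIONS
    + (
        OptionSpec("sel", "str", "protein and name CA", "atom selection"),
        OptionSpec("fit", "bool", True, "superpose before covariance"),
        OptionSpec("write_matrix", "bool", False, "also write the full matrix"),
        OptionSpec("out", "str", "covariance.tsv", "output TSV name"),
    ),
    entry_point=main,
)
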