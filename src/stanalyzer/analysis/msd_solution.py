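"""Mean square displacement (Solution): 3-D diffusion."""

from ..registry import AnalysisSpec, OptionSpec
from ..systemprops import solution_msd
from ..tables import TimeSeriesTable
from ._helpers import COMMON_OPTIONS, load_context, out_path


def main(settings: dict):
    project, atoms, frames = load_context(settings)
    window = (settings["fit_lo"], settings["fit_hi"])
    table, d_ang, d_cm = solution_msd(
        frames, settings["sel"], atoms, dt=project.time_step or 1.0, fit_window=window
    )
    path = table.write(out_path(settings, "msd_solution.tsv"))
    summary = TimeSeriesTable(["D_A2_per_ps", "D_cm2_per_s"])
    summary.append(float(d_ang), float(d_cm))
    return [path, summary.write(path.with_name(path.stem + "_diffusion.tsv"))]


ANALYSIS = AnalysisSpec(
    name="msd_solution",
    category="Others",
    description="3-D MSD of solute centers of mass and Einstein D",
    options=COMMON_OPTIONS
    + (
        OptionSpec("sel", "str", None, "solute selection", required=True),
        OptionSpec("fit_lo", "float", 0.2, "fit window lower fraction"),
        OptionSpec("fit_hi", "float", 0.8, "fit window upper fraction"),
        OptionSpec("out", "str", "msd_solution.tsv", "output TSV name"),
    ),
    entry_point=main,
)
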