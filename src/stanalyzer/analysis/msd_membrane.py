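"""Mean square displacement (Membrane): lateral lipid diffusion."""

from ..membrane import lateral_msd, msd_diffusion_fit
from ..registry import AnalysisSpec, OptionSpec
from ..tables import TimeSeriesTable
from ._helpers import COMMON_OPTIONS, load_context, out_path


def main(settings: dict):
    project, atoms, frames = load_context(settings)
    table = lateral_msd(frames, settings["sel"], atoms)
    dt = project.time_step or 1.0
    d_coef = msd_diffusion_fit(
        table.column("lag"), table.column("msd"), n_dim=2, dt=dt
    )
    path = table.write(out_path(settings, "msd_membrane.tsv"))
    summary = TimeSeriesTable(["D_A2_per_ps", "D_cm2_per_s", "dt_ps"])
    summary.append(float(d_coef), float(d_coef * 1e-4), float(dt))
    return [path, summary.write(path.with_name(path.stem + "_diffusion.tsv"))]


ANALYSIS = AnalysisSpec(
    name="msd_membrane",
    category="Membrane",
    description="Lateral MSD of lipid centers of mass and fitted D",
    options=COMMON_OPTIONS
    + (
        OptionSpec("sel", "str", None, "lipid selection", required=True),
        OptionSpec("out", "str", "msd_membrane.tsv", "output TSV name"),
    ),
    entry_point=main,
)
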