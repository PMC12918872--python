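"""Distance / angle / dihedral between atom groups."""

from ..contacts import bond_statistics
from ..registry import AnalysisSpec, OptionSpec
from ..tables import TimeSeriesTable
from ._helpers import COMMON_OPTIONS, load_context, out_path, parse_groups


def main(settings: dict):
    _, atoms, frames = load_context(settings)
    groups = parse_groups(settings["sel"], atoms)
    table, mean, sd = bond_statistics(frames, list(groups.values()), atoms)
    path = table.write(out_path(settings, "bond_stats.tsv"))
    summary = TimeSeriesTable(["mean", "sd", "n_frames"])
    summary.append(float(mean), float(sd), len(table.rows))
    return [path, summary.write(path.with_name(path.stem + "_summary.tsv"))]


ANALYSIS = AnalysisSpec(
    name="bond_stats",
    category="Geometry",
    description="COM distance/angle/dihedral between 2-4 groups per frame",
    options=COMMON_OPTIONS
    + (
        OptionSpec("sel", "str", None, "2-4 groups: 'a=expr;b=expr[;c=expr[;d=expr]]'", required=True),
        OptionSpec("out", "str", "bond_stats.tsv", "output TSV name"),
    ),
    entry_point=main,
)
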