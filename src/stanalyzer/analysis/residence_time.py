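"""Contact residence time."""

from ..contacts import contact_residence_time, residue_contacts
from ..registry import AnalysisSpec, OptionSpec
from ..tables import TimeSeriesTable
from ._helpers import COMMON_OPTIONS, load_context, out_path


def main(settings: dict):
    _, atoms, frames = load_context(settings)
    _, series = residue_contacts(
        frames, settings["sel_a"], settings["sel_b"], atoms, cutoff=settings["cutoff"]
    )
    table = TimeSeriesTable(["resA", "resB", "n_events", "mean_frames", "sd_frames"])
    rows = []
    for (res_a, res_b), contact in series.items():
        stats = contact_residence_time(contact, gap_tolerance=settings["gap_tolerance"])
        if stats is None:
            continue
        rows.append(
            (res_a, res_b, stats["n_events"], stats["mean_frames"], stats["sd_frames"])
        )
    rows.sort(key=lambda r: (-r[3] * r[2], r[0], r[1]))
    for row in rows:
        table.append(*row)
    return [table.write(out_path(settings, "residence_time.tsv"))]


ANALYSIS = AnalysisSpec(
    name="residence_time",
    category="Contacts",
    description="Mean/SD of contact run durations (frames) per residue pair",
    options=COMMON_OPTIONS
    + (
        OptionSpec("sel_a", "str", None, "first selection", required=True),
        OptionSpec("sel_b", "str", None, "second selection", required=True),
        OptionSpec("cutoff", "float", 4.5, "contact cutoff (Å)"),
        OptionSpec("gap_tolerance", "int", 0, "merge runs separated by <= k frames"),
        OptionSpec("out", "str", "residence_time.tsv", "output TSV name"),
    ),
    entry_point=main,
)
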