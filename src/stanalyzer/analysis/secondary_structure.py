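"""Secondary structure (DSSP codes)."""

import numpy as np

from ..dssp import dssp_assign
from ..registry import AnalysisSpec, OptionSpec
from ..tables import TimeSeriesTable
from ._helpers import COMMON_OPTIONS, load_context, out_path


def main(settings: dict):
    _, atoms, frames = load_context(settings)
    per_frame = TimeSeriesTable(["frame", "codes"])
    strings = []
    for frame in frames:
        codes = dssp_assign(frame, atoms)
        strings.append(codes)
        per_frame.append(frame.index, codes)
    path = per_frame.write(out_path(settings, "dssp.tsv"))
    # per-residue table: fraction of frames in each code
    protein = np.nonzero(atoms.is_protein())[0]
    groups = atoms.residue_groups(protein)
    residue_table = TimeSeriesTable(
        ["resid", "H", "G", "I", "E", "B", "T", "S", "loop"]
    )
    for i, group in enumerate(groups):
        counts = {c: 0 for c in "HGIEBTS-"}
        for codes in strings:
            counts[codes[i]] += 1
        n = len(strings)
        residue_table.append(
            int(atoms.resids[group[0]]),
            *[counts[c] / n for c in "HGIEBTS-"],
        )
    res_path = residue_table.write(path.with_name(path.stem + "_residues.tsv"))
    return [path, res_path]


ANALYSIS = AnalysisSpec(
    name="secondary_structure",
    category="Proteins and Nucleic Acids",
    description="DSSP-encoded secondary structure per residue per frame",
    options=COMMON_OPTIONS
    + (OptionSpec("out", "str", "dssp.tsv", "output TSV name"),),
    entry_point=main,
)
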