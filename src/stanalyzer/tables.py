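"""Tabular per-frame output written as TSV with a '#'-prefixed header."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["TimeSeriesTable"]


def _fmt(value) -> str:
    if isinstance(value, float):
        if value != value:  # NaN
            return "nan"
        return f"{value:.6f}"
    return str(value)


@dataclass
class TimeSeriesTable:
    """Column-named rows, one per analyzed frame (or per aggregate record)."""

    columns: list[str]
    rows: list[tuple] = field(default_factory=list)

    def append(self, *values) -> None:
        if len(values) != len(self.columns):
            raise ValueError(
                f"row has {len(values)} values, table has {len(self.columns)} columns"
            )
        self.rows.append(tuple(values))

    def column(self, name: str) -> list:
        i = self.columns.index(name)
        return [row[i] for row in self.rows]

    def to_tsv(self) -> str:
        lines = ["#" + "\t".join(self.columns)]
        for row in self.rows:
            lines.append("\t".join(_fmt(v) for v in row))
        return "\n".join(lines) + "\n"

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(self.to_tsv())
        return path

    @classmethod
    def read(cls, path) -> "TimeSeriesTable":
        lines = Path(path).read_text().splitlines()
        if not lines or not lines[0].startswith("#"):
            raise ValueError(f"{path}: missing '#' header line")
        columns = lines[0][1:].split("\t")
        table = cls(columns)
        for line in lines[1:]:
            if not line:
                continue
            values = []
            for tok in line.split("\t"):
                try:
                    values.append(int(tok))
                except ValueError:
                    try:
                        values.append(float(tok))
                    except ValueError:
                        values.append(tok)
            table.append(*values)
        return table
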